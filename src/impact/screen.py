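"""Domain types for phenotype screens and prior gene-relationship data.

A screen is the ``P x N`` matrix ``D`` of phenotypic profiles: each row is
one perturbation experiment (e.g. an siRNA oligo) described by ``N``
quantitative parameters, and a gene may own several rows (``m_i`` profiles,
variable across genes).  Prior information comes in two flavours: gene sets
(GMT format, e.g. protein complexes) and undirected interaction networks
(SIF or two-column edge lists).
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Profile",
    "PhenotypeScreen",
    "GeneSet",
    "GeneSetCollection",
    "InteractionNetwork",
    "read_phenotype_table",
    "write_phenotype_table",
    "znormalize",
    "collapse_profiles",
    "read_gene_sets",
    "write_gene_sets",
    "read_network",
    "write_network",
    "restrict_to_screen",
]


@dataclass(frozen=True)
class Profile:
    """A single perturbation experiment: ``N`` parameter values for one gene."""

    values: np.ndarray
    oligo_id: str
    gene: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


class PhenotypeScreen:
    """The phenotype matrix ``D`` with gene/oligo row labels.

    Rows are stored in a single ``(P, N)`` float array; ``row_genes`` and
    ``row_oligos`` carry the labels.  Gene identifiers are opaque,
    case-sensitive strings.  Missing values may be encoded as NaN; any
    profile containing a NaN is treated as having undefined correlation to
    everything (and therefore never "similar").
    """

    def __init__(
        self,
        values: np.ndarray,
        row_genes: Sequence[str],
        row_oligos: Sequence[str],
        parameter_names: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("screen values must be a 2-D array")
        if values.shape[0] == 0:
            raise ValueError("no profiles")
        if values.shape[0] != len(row_genes) or values.shape[0] != len(row_oligos):
            raise ValueError("row label length does not match value rows")
        if values.shape[1] != len(parameter_names):
            raise ValueError("parameter_names length does not match value columns")
        self.values = values
        self.row_genes = np.asarray(row_genes, dtype=object)
        self.row_oligos = np.asarray(row_oligos, dtype=object)
        self.parameter_names = list(parameter_names)

        seen: dict[str, list[int]] = {}
        for i, g in enumerate(self.row_genes):
            seen.setdefault(g, []).append(i)
        #: genes in first-appearance order
        self.genes: list[str] = list(seen)
        self._gene_rows: dict[str, np.ndarray] = {
            g: np.asarray(rows, dtype=int) for g, rows in seen.items()
        }
        pairs = set(zip(self.row_genes, self.row_oligos))
        if len(pairs) != len(self.row_genes):
            raise ValueError("duplicate (gene, oligo_id) pair in screen")
        self._zrows: np.ndarray | None = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    @property
    def total_profiles(self) -> int:
        """``P``, the total number of profiles over all genes."""
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def profile_count(self, gene: str) -> int:
        return len(self._gene_rows[gene])

    @property
    def profile_counts(self) -> dict[str, int]:
        return {g: len(r) for g, r in self._gene_rows.items()}

    def gene_rows(self, gene: str) -> np.ndarray:
        """Row indices of *gene*'s profiles, in input order."""
        return self._gene_rows[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_rows

    def profiles_of(self, gene: str) -> list[Profile]:
        return [
            Profile(self.values[i], self.row_oligos[i], gene)
            for i in self._gene_rows[gene]
        ]

    def iter_profiles(self) -> Iterator[Profile]:
        for i in range(self.total_profiles):
            yield Profile(self.values[i], self.row_oligos[i], self.row_genes[i])

    # -- correlation support ----------------------------------------------
    def standardized_rows(self) -> np.ndarray:
        """Rows standardised to zero mean / unit population SD.

        With rows standardised this way, the Pearson correlation of rows
        *a* and *b* is ``(z_a @ z_b) / N``.  Rows with zero variance or any
        non-finite entry come back as all-NaN, which propagates to NaN
        ("undefined") correlations.
        """
        if self._zrows is None:
            v = self.values
            mean = v.mean(axis=1, keepdims=True)
            sd = v.std(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (v - mean) / sd
            bad = ~np.isfinite(v).all(axis=1) | (sd[:, 0] == 0)
            z[bad] = np.nan
            self._zrows = z
        return self._zrows

    # -- derivation --------------------------------------------------------
    def subset_rows(self, rows: Sequence[int]) -> "PhenotypeScreen":
        rows = np.asarray(rows, dtype=int)
        return PhenotypeScreen(
            self.values[rows],
            self.row_genes[rows],
            self.row_oligos[rows],
            self.parameter_names,
        )

    def subset_genes(self, genes: Iterable[str]) -> "PhenotypeScreen":
        keep = [g for g in self.genes if g in set(genes)]
        rows = np.concatenate([self._gene_rows[g] for g in keep])
        return self.subset_rows(rows)

    def with_values(self, values: np.ndarray) -> "PhenotypeScreen":
        return PhenotypeScreen(
            values, self.row_genes, self.row_oligos, self.parameter_names
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PhenotypeScreen(P={self.total_profiles}, N={self.n_parameters}, "
            f"genes={self.n_genes})"
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        deduped = tuple(dict.fromkeys(self.members))
        object.__setattr__(self, "members", deduped)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.set_id] = gene_set


class InteractionNetwork:
    """Undirected gene-gene interaction graph (no self-loops, no multi-edges)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_self = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
        if n_self:
            log.info("dropped %d self-loop(s) while building network", n_self)
        self.graph = g
        self.n_self_loops_dropped = n_self

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "InteractionNetwork":
        net = cls()
        net.graph = nx.Graph(graph)
        net.graph.remove_edges_from(nx.selfloop_edges(net.graph))
        return net

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self.graph.neighbors(gene))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionNetwork(nodes={self.n_nodes}, edges={self.n_edges})"


# ---------------------------------------------------------------------------
# readers / writers (all accept plain or gzip-compressed text)
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_phenotype_table(
    path,
    gene_col: str = "gene",
    oligo_col: str | None = "oligo",
) -> PhenotypeScreen:
    """Read a tab-separated phenotype table into a :class:`PhenotypeScreen`.

    The file must carry a header with a *gene* column, an optional *oligo*
    column and the remaining columns numeric parameters.  Rows are grouped
    by gene preserving file order within each gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={gene_col: str})
    if gene_col not in df.columns:
        raise ValueError(f"missing gene column {gene_col!r}")
    if df.shape[0] == 0:
        raise ValueError("no profiles")
    if oligo_col is not None and oligo_col in df.columns:
        oligos = df[oligo_col].astype(str).tolist()
        param_cols = [c for c in df.columns if c not in (gene_col, oligo_col)]
    else:
        counts: dict[str, int] = {}
        oligos = []
        for g in df[gene_col]:
            counts[g] = counts.get(g, 0) + 1
            oligos.append(f"{g}:{counts[g]}")
        param_cols = [c for c in df.columns if c != gene_col]
    if not param_cols:
        raise ValueError("no parameter columns found")
    values = np.empty((df.shape[0], len(param_cols)), dtype=float)
    for j, c in enumerate(param_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c!r}, row {row + 2}"
            )
        values[:, j] = col.to_numpy(dtype=float)
    return PhenotypeScreen(values, df[gene_col].tolist(), oligos, param_cols)


def write_phenotype_table(screen: PhenotypeScreen, path) -> None:
    df = pd.DataFrame(screen.values, columns=screen.parameter_names)
    df.insert(0, "oligo", screen.row_oligos)
    df.insert(0, "gene", screen.row_genes)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def znormalize(screen: PhenotypeScreen) -> PhenotypeScreen:
    """Z-score each parameter across all ``P`` profiles (sample SD, ddof=1).

    Raises if a parameter is constant; the caller may drop such columns.
    """
    v = screen.values
    mean = np.nanmean(v, axis=0)
    sd = np.nanstd(v, axis=0, ddof=1)
    for j, s in enumerate(sd):
        if not np.isfinite(s) or s == 0:
            raise ValueError(
                f"constant parameter {screen.parameter_names[j]!r}: cannot z-normalize"
            )
    return screen.with_values((v - mean) / sd)


def collapse_profiles(screen: PhenotypeScreen, method: str = "average") -> PhenotypeScreen:
    """Collapse each gene's profiles to a single row.

    ``"average"`` takes the per-parameter mean.  ``"mode"`` picks the medoid
    oligo: the profile with maximal summed Pearson correlation to the gene's
    other profiles (a surrogate for a mean-shift mode estimate).
    """
    if method not in ("average", "mode"):
        raise ValueError(f"unknown collapse method {method!r}")
    z = screen.standardized_rows()
    n = screen.n_parameters
    rows_out, genes_out, oligos_out = [], [], []
    for g in screen.genes:
        rows = screen.gene_rows(g)
        if method == "average" or len(rows) == 1:
            rows_out.append(screen.values[rows].mean(axis=0))
        else:
            zr = z[rows]
            with np.errstate(invalid="ignore"):
                r = zr @ zr.T / n
            score = np.where(np.isnan(r), 0.0, r).sum(axis=1)
            rows_out.append(screen.values[rows[int(np.argmax(score))]])
        genes_out.append(g)
        oligos_out.append(f"{g}:{method}")
    return PhenotypeScreen(
        np.asarray(rows_out), genes_out, oligos_out, screen.parameter_names
    )


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (set_id TAB description TAB member...)."""
    coll = GeneSetCollection()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 fields")
            coll.add(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with _open_text(path, "wt") as fh:
        for s in coll:
            fh.write("\t".join([s.set_id, s.name, *s.members]) + "\n")


def read_network(path, format: str | None = None) -> InteractionNetwork:
    """Read a SIF (node TAB relation TAB node) or 2-column edge-list file."""
    if format is None:
        format = "sif" if str(path).replace(".gz", "").endswith(".sif") else "edge-list"
    if format not in ("sif", "edge-list"):
        raise ValueError(f"unknown network format {format!r}")
    edges, nodes = [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if format == "sif":
                if len(fields) == 1:
                    nodes.append(fields[0])
                    continue
                if len(fields) < 3:
                    raise ValueError(f"SIF line {lineno}: expected 1 or >=3 fields")
                for tgt in fields[2:]:
                    edges.append((fields[0], tgt))
            else:
                if len(fields) < 2:
                    raise ValueError(f"edge-list line {lineno}: expected 2 fields")
                edges.append((fields[0], fields[1]))
    return InteractionNetwork(edges, nodes)


def write_network(net: InteractionNetwork, path, format: str = "sif") -> None:
    with _open_text(path, "wt") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            if format == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        if format == "sif":
            for n in sorted(nx.isolates(net.graph)):
                fh.write(f"{n}\n")


def restrict_to_screen(prior, screen: PhenotypeScreen):
    """Drop genes without phenotype data from a gene-set collection or network.

    Sets that lose all members are removed; edges losing an endpoint are
    removed.  Idempotent.  Removal counts are logged.
    """
    if isinstance(prior, GeneSetCollection):
        out = GeneSetCollection()
        dropped_sets = 0
        for s in prior:
            members = tuple(m for m in s.members if m in screen)
            if members:
                out.add(GeneSet(s.set_id, s.name, members))
            else:
                dropped_sets += 1
        log.info(
            "restrict_to_screen: kept %d/%d sets (%d emptied)",
            len(out), len(prior), dropped_sets,
        )
        return out
    if isinstance(prior, InteractionNetwork):
        keep = [n for n in prior.graph.nodes if n in screen]
        sub = prior.graph.subgraph(keep)
        out = InteractionNetwork.from_graph(sub)
        log.info(
            "restrict_to_screen: kept %d/%d nodes, %d/%d edges",
            out.n_nodes, prior.n_nodes, out.n_edges, prior.n_edges,
        )
        return out
    raise TypeError(f"cannot restrict object of type {type(prior).__name__}")
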