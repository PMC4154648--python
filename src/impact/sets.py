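"""IMPACT-sets: enriched-pattern search within gene sets and its
structure-preserving permutation test.

Given a gene set, the search scans every profile of the set as a candidate
*anchor* and selects the anchor whose similar profiles cover the largest
number of distinct genes (``n_T``); ties fall back to the largest sum of
correlation values, then to the lexicographically smallest (gene, oligo)
label.  Counting *genes* rather than profiles avoids biasing the search
towards genes with many oligos.  The per-parameter median of the selected
profiles is the set's reference profile.

Significance comes from randomization: pseudo-sets with the same number of
genes and the same per-gene profile counts are drawn from the screen (whole
per-gene profile bundles travel together, preserving within-gene
correlation), the search is re-run, and the p-value is the fraction of
pseudo-sets selecting at least as many profiles as the real set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .screen import GeneSetCollection, PhenotypeScreen
from .similarity import SimilarityPolicy

log = logging.getLogger(__name__)

__all__ = [
    "SelectedProfile",
    "EnrichedPattern",
    "SetResult",
    "PermutationResult",
    "find_enriched_pattern",
    "reference_profile",
    "permutation_pvalue",
    "run_impact_sets",
    "gene_scores_from_sets",
    "write_set_results",
]

#: profile-count value at and above which genes are pooled into one
#: randomization stratum when exact matching is impossible (few genes have
#: more than 7 oligos, so counts >= 8 share a bin)
DEFAULT_MAX_EXACT_COUNT = 7


@dataclass(frozen=True)
class SelectedProfile:
    gene: str
    oligo_id: str
    row: int          # row index into the screen
    r: float          # correlation to the anchor
    sign: int = 1     # orientation vs the anchor (always +1 in positive mode)


@dataclass
class EnrichedPattern:
    """The winning anchor and the profiles it selects within one gene set."""

    anchor: tuple[str, str]
    selected: list[SelectedProfile]
    n_T: int
    sum_r: float

    @property
    def n_selected_profiles(self) -> int:
        return len(self.selected)

    @property
    def covered_genes(self) -> list[str]:
        return sorted({s.gene for s in self.selected})


@dataclass
class PermutationResult:
    p_value: float
    n_rand: int
    n_greater_equal: int
    statistic: str

    @property
    def resolution(self) -> float:
        """Smallest resolvable non-zero p; a zero count means p < resolution."""
        return 1.0 / self.n_rand

    def adjusted(self) -> float:
        """Optional ``(count + 1) / (n_rand + 1)`` pseudo-count estimator."""
        return (self.n_greater_equal + 1) / (self.n_rand + 1)


@dataclass
class SetResult:
    set_id: str
    n_g: int
    n_p: int
    pattern: EnrichedPattern
    reference: np.ndarray
    p_value: float
    n_rand: int
    permutation: PermutationResult | None = None


# ---------------------------------------------------------------------------
# anchor scan
# ---------------------------------------------------------------------------


def _subset_correlation(screen: PhenotypeScreen, rows: np.ndarray) -> np.ndarray:
    z = screen.standardized_rows()[rows]
    r = z @ z.T / screen.n_parameters
    np.clip(r, -1.0, 1.0, out=r)
    valid = ~np.isnan(z[:, 0])
    idx = np.flatnonzero(valid)
    r[idx, idx] = 1.0
    return r


def _scan_anchors(r: np.ndarray, gene_codes: np.ndarray, n_genes: int, policy: SimilarityPolicy):
    """Vectorised evaluation of every anchor row.

    Returns per-anchor arrays: distinct genes covered ``n_T``, number of
    selected profiles (after per-gene orientation pruning in absolute
    mode), and the tie-break sum of correlation values.
    """
    p = r.shape[0]
    onehot = np.zeros((p, n_genes))
    onehot[np.arange(p), gene_codes] = 1.0
    with np.errstate(invalid="ignore"):
        if policy.mode == "positive":
            passing = r >= policy.T
            passing &= ~np.isnan(r)
            cnt = passing @ onehot                      # (anchors, genes)
            n_t = (cnt > 0).sum(axis=1)
            n_sel = passing.sum(axis=1)
            sum_sel = np.where(passing, r, 0.0).sum(axis=1)
        else:
            a = np.abs(r)
            passing = a >= policy.T
            passing &= ~np.isnan(r)
            pos = passing & (r > 0)
            # r == 0 can pass only when T == 0 (excluded by policy T > 0)
            neg = passing & (r < 0)
            pos_cnt = pos @ onehot
            neg_cnt = neg @ onehot
            pos_sum = np.where(pos, a, 0.0) @ onehot
            neg_sum = np.where(neg, a, 0.0) @ onehot
            keep_pos = pos_sum >= neg_sum               # tie -> positive side
            n_t = ((pos_cnt + neg_cnt) > 0).sum(axis=1)
            n_sel = np.where(keep_pos, pos_cnt, neg_cnt).sum(axis=1).astype(int)
            sum_sel = np.where(keep_pos, pos_sum, neg_sum).sum(axis=1)
    # anchors with undefined self-correlation cannot anchor anything
    invalid = np.isnan(np.diag(r))
    n_t = np.where(invalid, -1, n_t.astype(int))
    return n_t, np.asarray(n_sel, dtype=int), sum_sel


def _best_anchor(n_t, n_sel, sum_sel, lex_rank) -> int:
    """Deterministic argmax by (n_T, sum of correlations, label order)."""
    sums = np.round(sum_sel, 9)  # guard float-order noise in tie detection
    best = -1
    for i in range(len(n_t)):
        if n_t[i] < 0:
            continue
        if best < 0:
            best = i
            continue
        key_i = (n_t[i], sums[i], -lex_rank[i])
        key_b = (n_t[best], sums[best], -lex_rank[best])
        if key_i > key_b:
            best = i
    return best


def _pattern_statistics(screen, rows, gene_codes, n_genes, policy):
    """Fast path: (n_T, n_selected_profiles) of the best anchor only."""
    r = _subset_correlation(screen, rows)
    n_t, n_sel, sum_sel = _scan_anchors(r, gene_codes, n_genes, policy)
    labels = list(zip(screen.row_genes[rows], screen.row_oligos[rows]))
    lex_rank = np.empty(len(rows), dtype=int)
    for rank, i in enumerate(sorted(range(len(rows)), key=lambda i: labels[i])):
        lex_rank[i] = rank
    best = _best_anchor(n_t, n_sel, sum_sel, lex_rank)
    if best < 0:
        return 0, 0
    return int(n_t[best]), int(n_sel[best])


def _rows_and_codes(screen: PhenotypeScreen, genes: Sequence[str]):
    rows_list, codes = [], []
    present = []
    for g in genes:
        if g in screen:
            present.append(g)
    for c, g in enumerate(present):
        rr = screen.gene_rows(g)
        rows_list.append(rr)
        codes.append(np.full(len(rr), c, dtype=int))
    if not rows_list:
        raise ValueError("empty set after restriction: no set gene has profiles")
    return np.concatenate(rows_list), np.concatenate(codes), present


def find_enriched_pattern(
    set_genes: Sequence[str],
    screen: PhenotypeScreen,
    policy: SimilarityPolicy,
) -> EnrichedPattern:
    """Find the anchor profile covering the most genes of the set."""
    rows, codes, present = _rows_and_codes(screen, set_genes)
    r = _subset_correlation(screen, rows)
    n_t, n_sel, sum_sel = _scan_anchors(r, codes, len(present), policy)
    labels = [
        (screen.row_genes[i], screen.row_oligos[i]) for i in rows
    ]
    lex_rank = np.empty(len(rows), dtype=int)
    for rank, i in enumerate(sorted(range(len(rows)), key=lambda i: labels[i])):
        lex_rank[i] = rank
    best = _best_anchor(n_t, n_sel, sum_sel, lex_rank)
    if best < 0:
        raise ValueError("no profile with defined correlations in set")
    rb = r[best]
    selected: list[SelectedProfile] = []
    with np.errstate(invalid="ignore"):
        if policy.mode == "positive":
            passing = np.flatnonzero(~np.isnan(rb) & (rb >= policy.T))
            for i in passing:
                selected.append(
                    SelectedProfile(labels[i][0], labels[i][1], int(rows[i]), float(rb[i]), 1)
                )
        else:
            passing = ~np.isnan(rb) & (np.abs(rb) >= policy.T)
            for c in np.unique(codes[passing]):
                idx = np.flatnonzero(passing & (codes == c))
                pos_sum = float(np.abs(rb[idx][rb[idx] > 0]).sum())
                neg_sum = float(np.abs(rb[idx][rb[idx] < 0]).sum())
                sign = 1 if pos_sum >= neg_sum else -1
                for i in idx:
                    if (rb[i] > 0 and sign == 1) or (rb[i] < 0 and sign == -1):
                        selected.append(
                            SelectedProfile(
                                labels[i][0], labels[i][1], int(rows[i]), float(rb[i]), sign
                            )
                        )
    selected.sort(key=lambda s: (s.gene, s.oligo_id))
    return EnrichedPattern(
        anchor=(str(labels[best][0]), str(labels[best][1])),
        selected=selected,
        n_T=int(n_t[best]),
        sum_r=float(sum_sel[best]),
    )


def reference_profile(profiles, signs=None) -> np.ndarray:
    """Per-parameter median of (sign-adjusted) profiles."""
    x = np.asarray(
        [p.values if hasattr(p, "values") else np.asarray(p, float) for p in profiles]
    )
    if x.shape[0] == 0:
        raise ValueError("need at least one profile")
    if signs is not None:
        x = x * np.asarray(signs, dtype=float)[:, None]
    return np.median(x, axis=0)


# ---------------------------------------------------------------------------
# structure-preserving permutation test
# ---------------------------------------------------------------------------


def _structure_strata(
    structure: Sequence[int],
    screen: PhenotypeScreen,
    max_exact: int = DEFAULT_MAX_EXACT_COUNT,
):
    """Map required per-gene profile counts to sampling pools.

    Exact-count pools are used whenever the screen has enough genes with
    exactly that many profiles; otherwise counts fall back to a binned
    stratum (one bin per count up to ``max_exact``, a pooled bin above).
    Returns ``{stratum_key: (needed, pool_of_genes)}``.
    """
    counts = screen.profile_counts
    by_count: dict[int, list[str]] = {}
    for g, m in counts.items():
        by_count.setdefault(m, []).append(g)
    need_exact: dict[int, int] = {}
    for m in structure:
        need_exact[m] = need_exact.get(m, 0) + 1
    strata: dict[object, tuple[int, list[str]]] = {}
    binned_need: dict[int, int] = {}
    for m, need in sorted(need_exact.items()):
        pool = by_count.get(m, [])
        if len(pool) >= need:
            strata[("exact", m)] = (need, sorted(pool))
        else:
            b = min(m, max_exact + 1)
            binned_need[b] = binned_need.get(b, 0) + need
    for b, need in sorted(binned_need.items()):
        if b <= max_exact:
            pool = sorted(by_count.get(b, []))
        else:
            pool = sorted(g for g, m in counts.items() if m > max_exact)
        if len(pool) < need:
            raise ValueError(
                f"randomization pool too small for profile-count stratum {b}: "
                f"need {need} genes, have {len(pool)}"
            )
        strata[("bin", b)] = (need, pool)
    return strata


def permutation_pvalue(
    observed: EnrichedPattern,
    set_structure: Sequence[int],
    screen: PhenotypeScreen,
    policy: SimilarityPolicy,
    n_rand: int,
    rng_seed,
    statistic: str = "profiles",
) -> PermutationResult:
    """Empirical p-value from structure-matched pseudo-sets.

    ``set_structure`` is the list of per-gene profile counts of the real
    set.  The comparison statistic is the number of selected profiles
    (``statistic="profiles"``, the default) or the number of covered genes
    (``statistic="genes"``).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if statistic not in ("profiles", "genes"):
        raise ValueError(f"unknown permutation statistic {statistic!r}")
    obs = observed.n_selected_profiles if statistic == "profiles" else observed.n_T
    strata = _structure_strata(set_structure, screen)
    rng = np.random.default_rng(rng_seed)
    pools = {key: np.asarray(pool, dtype=object) for key, (_, pool) in strata.items()}
    n_ge = 0
    for _ in range(n_rand):
        genes: list[str] = []
        for key, (need, _) in strata.items():
            pool = pools[key]
            pick = rng.choice(len(pool), size=need, replace=False)
            genes.extend(pool[pick])
        rows, codes, present = _rows_and_codes(screen, genes)
        n_t, n_sel = _pattern_statistics(screen, rows, codes, len(present), policy)
        stat = n_sel if statistic == "profiles" else n_t
        if stat >= obs:
            n_ge += 1
    return PermutationResult(n_ge / n_rand, n_rand, n_ge, statistic)


def run_impact_sets(
    sets: GeneSetCollection,
    screen: PhenotypeScreen,
    policy: SimilarityPolicy | None = None,
    n_rand: int = 5000,
    rng_seed=0,
    statistic: str = "profiles",
) -> list[SetResult]:
    """Run the set-based search over a whole collection.

    Each set gets its own structure-matched background ("specific
    background distribution for each tested complex").  Results are sorted
    by ascending p-value.
    """
    from .screen import restrict_to_screen

    policy = policy or SimilarityPolicy(T=0.7, mode="positive")
    sets = restrict_to_screen(sets, screen)
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    results: list[SetResult] = []
    set_ids = sorted(sets.sets)
    children = ss.spawn(len(set_ids))
    for child, set_id in zip(children, set_ids):
        s = sets[set_id]
        pattern = find_enriched_pattern(s.members, screen, policy)
        structure = [screen.profile_count(g) for g in s.members if g in screen]
        perm = permutation_pvalue(
            pattern, structure, screen, policy, n_rand, child, statistic
        )
        values = [screen.values[p.row] for p in pattern.selected]
        signs = [p.sign for p in pattern.selected]
        results.append(
            SetResult(
                set_id=set_id,
                n_g=len(structure),
                n_p=int(sum(structure)),
                pattern=pattern,
                reference=reference_profile(values, signs),
                p_value=perm.p_value,
                n_rand=n_rand,
                permutation=perm,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def gene_scores_from_sets(results: Sequence[SetResult], sets: GeneSetCollection) -> dict[str, float]:
    """Score each gene by the smallest p-value of the sets containing it."""
    scores: dict[str, float] = {}
    for res in results:
        members = sets[res.set_id].members if res.set_id in sets.sets else res.pattern.covered_genes
        for g in members:
            scores[g] = min(scores.get(g, 1.0), res.p_value)
    return scores


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (optional; raw p thresholds are the default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def write_set_results(
    results: Sequence[SetResult], path, parameter_names=None, fdr: bool = False
) -> None:
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "set_id": r.set_id,
            "n_g": r.n_g,
            "n_p": r.n_p,
            "n_selected_genes": r.pattern.n_T,
            "n_selected_profiles": r.pattern.n_selected_profiles,
            "p_value": r.p_value,
        }
        names = parameter_names or [f"param_{j}" for j in range(len(r.reference))]
        row.update({f"ref_{c}": v for c, v in zip(names, r.reference)})
        rows.append(row)
    frame = pd.DataFrame(rows)
    if fdr and len(frame):
        q = bh_qvalues(frame["p_value"].to_numpy())
        frame.insert(int(frame.columns.get_loc("p_value")) + 1, "q_value", q)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
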