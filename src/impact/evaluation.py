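"""Classification-performance machinery, randomization controls, and
profile-agreement statistics.

Gene rankings (smaller score = more significant) are evaluated against
positive/negative label sets with ROC, precision-recall and balanced-
accuracy curves; the area under the ROC curve is integrated with the
trapezoidal rule (equal to the tie-corrected Mann-Whitney statistic), its
standard error follows Hanley & McNeil, and AUC-vs-0.5 significance uses a
one-sided z-test.  Two rankings are compared by stratified bootstrap.

Randomization controls shuffle network edges (degree-preserving), gene
labels, or per-gene profile bundles, and Gaussian noise can be injected
into the screen, mirroring the degradation experiments used to validate
the module search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .screen import InteractionNetwork, PhenotypeScreen, collapse_profiles
from .similarity import pearson

log = logging.getLogger(__name__)

__all__ = [
    "GeneRanking",
    "EvalCurves",
    "roc_pr_bacc",
    "auc_trapezoid",
    "hanley_sem",
    "auc_ztest",
    "bootstrap_auc_compare",
    "shuffle_network",
    "add_noise",
    "profile_agreement",
    "compare_correlations",
    "phenotype_map_coords",
    "chi_square_baseline",
]


@dataclass
class GeneRanking:
    """Gene scores (ascending = better, e.g. p-values) plus binary labels."""

    scores: dict[str, float]
    labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in self.labels if g not in self.scores]
        if missing:
            raise ValueError(f"labeled genes without scores: {missing[:5]} ...")

    def labeled_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        genes = sorted(self.labels)
        s = np.asarray([self.scores[g] for g in genes], dtype=float)
        y = np.asarray([self.labels[g] for g in genes], dtype=bool)
        return s, y


@dataclass
class EvalCurves:
    roc: list[tuple[float, float]]
    pr: list[tuple[float, float]]
    bacc: list[tuple[float, float]]
    auc: float
    sem: float
    p_vs_random: float
    n_pos: int
    n_neg: int


def _curve_points(scores: np.ndarray, y: np.ndarray):
    """Threshold sweep over distinct scores (ascending; score <= t = positive call)."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    yy = y[order]
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])  # last index per tie group
    tp = np.cumsum(yy)[distinct]
    fp = np.cumsum(~yy)[distinct]
    thresholds = s[distinct]
    return thresholds, tp.astype(float), fp.astype(float)


def roc_pr_bacc(ranking: GeneRanking) -> EvalCurves:
    scores, y = ranking.labeled_arrays()
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    thr, tp, fp = _curve_points(scores, y)
    tpr = tp / n_pos
    fpr = fp / n_neg
    roc = [(0.0, 0.0)] + list(zip(fpr, tpr))
    precision = tp / (tp + fp)
    pr = list(zip(tpr, precision))
    bacc = [(float(t), float((tp_i / n_pos + (n_neg - fp_i) / n_neg) / 2))
            for t, tp_i, fp_i in zip(thr, tp, fp)]
    auc = auc_trapezoid(roc)
    sem = hanley_sem(auc, n_pos, n_neg)
    return EvalCurves(roc, pr, bacc, auc, sem, auc_ztest(auc, sem), n_pos, n_neg)


def auc_trapezoid(roc: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal integral of a ROC curve given as (FPR, TPR) points."""
    x = np.asarray([p[0] for p in roc], dtype=float)
    y = np.asarray([p[1] for p in roc], dtype=float)
    return float(np.trapezoid(y, x))


def hanley_sem(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need n_pos, n_neg >= 1")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(math.sqrt(max(var, 0.0)))


def auc_ztest(auc: float, sem: float) -> float:
    """One-sided p for AUC > 0.5."""
    if sem == 0:
        return 0.0 if auc > 0.5 else (0.5 if auc == 0.5 else 1.0)
    z = (auc - 0.5) / sem
    return float(sps.norm.sf(z))


def _auc_from_labeled(scores: np.ndarray, y: np.ndarray) -> float:
    thr, tp, fp = _curve_points(scores, y)
    n_pos = y.sum()
    n_neg = (~y).sum()
    roc = [(0.0, 0.0)] + list(zip(fp / n_neg, tp / n_pos))
    return auc_trapezoid(roc)


def bootstrap_auc_compare(
    rank1: GeneRanking,
    rank2: GeneRanking,
    n_boot: int = 1000,
    rng_seed=0,
) -> float:
    """Two-sided p for a difference between two AUCs on shared labels.

    Stratified bootstrap: positives and negatives are resampled separately,
    both AUCs are recomputed on each replicate, and the statistic is
    ``D = (A1 - A2) / sd(A1_r - A2_r)``.  Identical rankings give p = 1
    (0/0 guarded by convention).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if set(rank1.labels) != set(rank2.labels) or any(
        rank1.labels[g] != rank2.labels[g] for g in rank1.labels
    ):
        raise ValueError("rankings must share an identical label set")
    genes = sorted(rank1.labels)
    y = np.asarray([rank1.labels[g] for g in genes], dtype=bool)
    s1 = np.asarray([rank1.scores[g] for g in genes], dtype=float)
    s2 = np.asarray([rank2.scores[g] for g in genes], dtype=float)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    a1 = _auc_from_labeled(s1, y)
    a2 = _auc_from_labeled(s2, y)
    rng = np.random.default_rng(rng_seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        yb = y[idx]
        diffs[b] = _auc_from_labeled(s1[idx], yb) - _auc_from_labeled(s2[idx], yb)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0
    d = (a1 - a2) / sd
    return float(2 * sps.norm.sf(abs(d)))


# ---------------------------------------------------------------------------
# randomization controls
# ---------------------------------------------------------------------------


def shuffle_network(
    network: InteractionNetwork,
    mode: str,
    screen: PhenotypeScreen,
    rng_seed=0,
) -> tuple[InteractionNetwork, PhenotypeScreen]:
    """Randomization controls for the network-based search.

    ``"edges"``: degree-preserving double-edge swaps (>= 10x|E| swaps).
    ``"genes"``: permute gene labels over the nodes; each gene keeps its
    profiles.  ``"profiles"``: permute whole per-gene profile bundles
    between genes with identical profile counts.  ``"edges+profiles"``
    composes the first and third.
    """
    if mode not in ("edges", "genes", "profiles", "edges+profiles"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    net_out, screen_out = network, screen
    if mode in ("edges", "edges+profiles"):
        g = network.graph.copy()
        n_edges = g.number_of_edges()
        if n_edges > 1 and g.number_of_nodes() > 3:
            import networkx as nx

            nx.double_edge_swap(
                g,
                nswap=10 * n_edges,
                max_tries=200 * n_edges + 100,
                seed=int(rng.integers(2**31 - 1)),
            )
        net_out = InteractionNetwork.from_graph(g)
    if mode == "genes":
        nodes = network.nodes
        perm = list(np.asarray(nodes, dtype=object)[rng.permutation(len(nodes))])
        import networkx as nx

        mapping = dict(zip(nodes, perm))
        net_out = InteractionNetwork.from_graph(nx.relabel_nodes(network.graph, mapping))
    if mode in ("profiles", "edges+profiles"):
        by_count: dict[int, list[str]] = {}
        for g_ in screen.genes:
            by_count.setdefault(screen.profile_count(g_), []).append(g_)
        source_of: dict[str, str] = {}
        for genes in by_count.values():
            perm = list(np.asarray(genes, dtype=object)[rng.permutation(len(genes))])
            source_of.update(zip(genes, perm))
        values, row_genes, row_oligos = [], [], []
        for g_ in screen.genes:
            src = source_of[g_]
            for i in screen.gene_rows(src):
                values.append(screen.values[i])
                row_genes.append(g_)
                row_oligos.append(screen.row_oligos[i])
        screen_out = PhenotypeScreen(
            np.asarray(values), row_genes, row_oligos, screen.parameter_names
        )
    return net_out, screen_out


def add_noise(screen: PhenotypeScreen, sigma: float, rng_seed=0) -> PhenotypeScreen:
    """Add independent N(0, sigma) noise to every parameter of every profile."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return screen.with_values(screen.values.copy())
    rng = np.random.default_rng(rng_seed)
    return screen.with_values(screen.values + rng.normal(0.0, sigma, screen.values.shape))


# ---------------------------------------------------------------------------
# profile agreement (rescreen-style comparison)
# ---------------------------------------------------------------------------


def profile_agreement(group_a, group_b) -> np.ndarray:
    """All pairwise Pearson correlations between two groups of profiles."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    out = []
    for a in group_a:
        for b in group_b:
            r = pearson(a, b)
            if not np.isnan(r):
                out.append(r)
    return np.asarray(out, dtype=float)


def compare_correlations(corr1, corr2) -> tuple[float, float]:
    """Two-sample KS and Mann-Whitney p-values for two correlation
    distributions (e.g. selected-vs-rescreen against rejected-vs-rescreen)."""
    ks = sps.ks_2samp(corr1, corr2)
    mw = sps.mannwhitneyu(corr1, corr2, alternative="two-sided")
    return float(ks.pvalue), float(mw.pvalue)


def phenotype_map_coords(
    reference: np.ndarray,
    channel1: Sequence[int],
    channel2: Sequence[int],
) -> tuple[float, float]:
    """Phenotype-map coordinates from a reference profile.

    x is the difference of the channel L2 norms (channel 2 minus channel
    1), y is their sum (overall phenotype strength).  Which parameters
    form which channel is up to the caller (e.g. transferrin vs EGF
    readouts).
    """
    c1 = set(channel1)
    c2 = set(channel2)
    if c1 & c2:
        raise ValueError("channel index sets must be disjoint")
    ref = np.asarray(reference, dtype=float)
    n1 = float(np.linalg.norm(ref[sorted(c1)])) if c1 else 0.0
    n2 = float(np.linalg.norm(ref[sorted(c2)])) if c2 else 0.0
    return n2 - n1, n2 + n1


def chi_square_baseline(screen: PhenotypeScreen, collapse: str = "mode") -> GeneRanking:
    """Phenotypic-strength baseline: chi-square of a collapsed profile.

    Each gene's profiles are collapsed to one (average, or the medoid
    "mode" profile); the score is the upper-tail probability of the sum of
    squared z-values on ``N`` degrees of freedom.  Assumes a z-normalized
    screen.
    """
    collapsed = collapse_profiles(screen, collapse)
    n = collapsed.n_parameters
    scores: dict[str, float] = {}
    for g in collapsed.genes:
        v = collapsed.values[collapsed.gene_rows(g)[0]]
        stat = float((v * v).sum())
        scores[g] = float(sps.chi2.sf(stat, df=n))
    return GeneRanking(scores)


def write_curves(curves: EvalCurves, path_prefix: str) -> None:
    """Export ROC/PR/BACC points as TSV plus a summary JSON."""
    import json

    import pandas as pd

    pd.DataFrame(curves.roc, columns=["fpr", "tpr"]).to_csv(
        f"{path_prefix}_roc.tsv", sep="\t", index=False
    )
    pd.DataFrame(curves.pr, columns=["recall", "precision"]).to_csv(
        f"{path_prefix}_pr.tsv", sep="\t", index=False
    )
    pd.DataFrame(curves.bacc, columns=["p_threshold", "balanced_accuracy"]).to_csv(
        f"{path_prefix}_bacc.tsv", sep="\t", index=False
    )
    with open(f"{path_prefix}_summary.json", "w") as fh:
        json.dump(
            {
                "auc": curves.auc,
                "sem": curves.sem,
                "p_vs_random": curves.p_vs_random,
                "n_pos": curves.n_pos,
                "n_neg": curves.n_neg,
            },
            fh,
            indent=2,
        )
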