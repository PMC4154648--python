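"""IMPACT-modules: greedy network-module search with semi-analytical
significance.

The search has three stages:

1. **Seed selection** — every node with at least ``k_s`` profiles is tested
   by running the enriched-pattern search (absolute-correlation policy at
   threshold ``T_s``) over the node plus its direct neighbours.  If the
   node participates in the winning pattern (at least one of its own and
   one neighbour profile selected), it becomes a seed; its seed profile is
   the sign-adjusted median of the selected profiles.

2. **Module expansion** — starting from the seed gene, all non-member
   neighbours whose profiles match the *fixed* seed profile (at least ``k``
   profiles with ``|r| >= T``, mutually positively correlated after
   orientation resolution) join simultaneously; this repeats until no
   neighbour qualifies or 50 steps have been taken.

3. **Module assessment** — each expansion state treats the current
   neighbours as independent Bernoulli trials whose success probabilities
   come from profile-specific empirical backgrounds, stratified by bins of
   per-gene profile counts.  The state probability is the Poisson-binomial
   mass at the observed number of successes (which reduces to the binomial
   mass when all probabilities are equal); the module p-value is the
   product of state probabilities, evaluated in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .screen import InteractionNetwork, PhenotypeScreen, restrict_to_screen
from .sets import SelectedProfile, find_enriched_pattern, reference_profile
from .similarity import SimilarityPolicy

log = logging.getLogger(__name__)

__all__ = [
    "ModuleParams",
    "Seed",
    "BackgroundTable",
    "ExpansionState",
    "ModuleResult",
    "select_seeds",
    "estimate_background",
    "expand_module",
    "binomial_pmf",
    "binomial_cdf",
    "poisson_binomial_pmf",
    "state_probability",
    "module_pvalue",
    "run_impact_modules",
    "gene_scores_from_modules",
    "write_module_results",
]


@dataclass(frozen=True)
class ModuleParams:
    """Tunable parameters of the module search.

    ``T``/``k`` govern expansion (k is a minimal count by default, or a
    minimal fraction of a gene's profiles when ``k_is_fraction``),
    ``T_s``/``k_s`` govern seed selection, ``max_steps`` caps expansion.
    Backgrounds use one bin per exact profile count up to
    ``max_exact_count`` plus one pooled bin above, with ``n_rand_bg``
    draws per bin (or exhaustive enumeration when ``exact_background``).
    """

    T: float = 0.7
    k: float = 3
    k_is_fraction: bool = False
    T_s: float = 0.8
    k_s: int = 2
    max_steps: int = 50
    max_exact_count: int = 7
    n_bins: int | None = None
    n_rand_bg: int = 1000
    exact_background: bool = False
    state_variant: str = "pmf"  # "pmf" | "config" | "tail"
    mode: str = "absolute"      # expansion similarity: "absolute" | "positive"

    def __post_init__(self) -> None:
        if not (0 < self.T <= 1 and 0 < self.T_s <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.k_is_fraction:
            if not 0 < self.k <= 1:
                raise ValueError("fractional k must lie in (0, 1]")
        elif self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_s < 1 or self.max_steps < 1:
            raise ValueError("k_s and max_steps must be >= 1")
        if self.state_variant not in ("pmf", "config", "tail"):
            raise ValueError(f"unknown state variant {self.state_variant!r}")
        if self.mode not in ("absolute", "positive"):
            raise ValueError(f"unknown expansion mode {self.mode!r}")

    def required_k(self, m: int) -> int:
        """Minimal number of similar profiles for a gene with m profiles."""
        if self.k_is_fraction:
            return max(1, math.ceil(self.k * m))
        return int(self.k)


@dataclass
class Seed:
    gene: str
    seed_profile: np.ndarray
    selected_neighborhood: list[SelectedProfile]


@dataclass
class ExpansionState:
    """One step of greedy growth viewed as a set of Bernoulli trials."""

    step: int
    neighbors: list[tuple[str, int, bool]]  # (gene, profile-count bin, similar?)
    state_probability: float | None = None

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def k_obs(self) -> int:
        return sum(1 for _, _, sim in self.neighbors if sim)


@dataclass
class MemberSelection:
    gene: str
    rows: tuple[int, ...]
    oligo_ids: tuple[str, ...]
    sign: int
    joined_at_step: int


@dataclass
class ModuleResult:
    seed: Seed
    members: dict[str, MemberSelection]
    states: list[ExpansionState]
    p_value: float
    reference: np.ndarray

    @property
    def member_genes(self) -> list[str]:
        return sorted(self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def seed_only(self) -> bool:
        return len(self.members) == 1


# ---------------------------------------------------------------------------
# profile-count bins
# ---------------------------------------------------------------------------


class ProfileCountBins:
    """Strata of genes with similar numbers of profiles.

    Default: one bin per exact count ``1 .. max_exact_count`` and one
    pooled bin for larger counts.  ``n_bins`` switches to quantile bins
    over the screen's profile-count distribution.
    """

    def __init__(self, screen: PhenotypeScreen, params: ModuleParams):
        counts = screen.profile_counts
        if params.n_bins is None:
            self._edges = None
            self._max_exact = params.max_exact_count
        else:
            qs = np.quantile(
                sorted(counts.values()), np.linspace(0, 1, params.n_bins + 1)
            )
            self._edges = np.unique(qs)[:-1]
            self._max_exact = None
        self.members: dict[int, list[str]] = {}
        for g in sorted(counts):
            self.members.setdefault(self.bin_of(counts[g]), []).append(g)

    def bin_of(self, m: int) -> int:
        if self._edges is None:
            return min(m, self._max_exact + 1)
        return int(np.searchsorted(self._edges, m, side="right") - 1)

    @property
    def bin_ids(self) -> list[int]:
        return sorted(self.members)


@dataclass
class BackgroundTable:
    """Seed-profile-specific inclusion probabilities per profile-count bin."""

    seed_gene: str
    probs: dict[int, float | None]
    n_draws: int
    method: str
    bins: ProfileCountBins

    def prob_for_bin(self, b: int) -> float:
        p = self.probs.get(b)
        if p is None:
            defined = [bb for bb, pp in self.probs.items() if pp is not None]
            if not defined:
                raise ValueError("background table has no defined bins")
            nearest = min(defined, key=lambda bb: (abs(bb - b), bb))
            log.debug("bin %d empty: using nearest non-empty bin %d", b, nearest)
            p = self.probs[nearest]
        return p

    def prob_for_count(self, m: int) -> float:
        return self.prob_for_bin(self.bins.bin_of(m))


# ---------------------------------------------------------------------------
# qualification of a gene against a fixed seed profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneQualification:
    qualifies: bool
    sign: int
    rows: tuple[int, ...]  # kept (passing, orientation-consistent) rows


def _seed_correlations(seed_profile: np.ndarray, screen: PhenotypeScreen) -> np.ndarray:
    """Correlation of every screen profile with the seed profile (NaN = undefined)."""
    z = screen.standardized_rows()
    s = np.asarray(seed_profile, dtype=float)
    sd = s.std()
    if not np.isfinite(s).all() or sd == 0:
        return np.full(screen.total_profiles, np.nan)
    zs = (s - s.mean()) / sd
    r = z @ zs / screen.n_parameters
    return np.clip(r, -1.0, 1.0)


def _qualify_gene(
    gene: str,
    r_seed: np.ndarray,
    screen: PhenotypeScreen,
    params: ModuleParams,
) -> GeneQualification:
    """Apply the k/T inclusion rule for one gene vs a fixed seed profile.

    Profiles pass at ``|r| >= T`` (or ``r >= T`` in positive mode); genes
    with passing profiles on both sides keep the orientation with the
    larger summed |r| (tie -> positive); the kept profiles must number at
    least ``k`` and be mutually positively correlated.
    """
    rows = screen.gene_rows(gene)
    r = r_seed[rows]
    with np.errstate(invalid="ignore"):
        if params.mode == "positive":
            passing = ~np.isnan(r) & (r >= params.T)
            sign = 1
            kept = rows[passing]
        else:
            passing = ~np.isnan(r) & (np.abs(r) >= params.T)
            pos = passing & (r > 0)
            neg = passing & (r < 0)
            sign = 1 if np.abs(r[pos]).sum() >= np.abs(r[neg]).sum() else -1
            kept = rows[pos] if sign == 1 else rows[neg]
    kreq = params.required_k(len(rows))
    if len(kept) < kreq:
        return GeneQualification(False, sign, tuple(int(i) for i in kept))
    if len(kept) > 1:
        z = screen.standardized_rows()[kept]
        rr = z @ z.T / screen.n_parameters
        off = rr[np.triu_indices(len(kept), k=1)]
        if np.isnan(off).any() or (off <= 0).any():
            return GeneQualification(False, sign, tuple(int(i) for i in kept))
    return GeneQualification(True, sign, tuple(int(i) for i in kept))


class _SeedContext:
    """Per-seed cache: seed correlations and per-gene qualification."""

    def __init__(self, seed_profile: np.ndarray, screen: PhenotypeScreen, params: ModuleParams):
        self.screen = screen
        self.params = params
        self.r_seed = _seed_correlations(seed_profile, screen)
        self._qual: dict[str, GeneQualification] = {}

    def qualification(self, gene: str) -> GeneQualification:
        q = self._qual.get(gene)
        if q is None:
            q = _qualify_gene(gene, self.r_seed, self.screen, self.params)
            self._qual[gene] = q
        return q


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------


def select_seeds(
    network: InteractionNetwork,
    screen: PhenotypeScreen,
    params: ModuleParams | None = None,
) -> list[Seed]:
    """Scan every sufficiently measured node as a potential seed.

    Nodes are enumerated in ascending identifier order so the output does
    not depend on file input order.
    """
    params = params or ModuleParams()
    policy = SimilarityPolicy(T=params.T_s, mode="absolute")
    seeds: list[Seed] = []
    n_skipped = 0
    for node in network.nodes:
        if node not in screen or screen.profile_count(node) < params.k_s:
            n_skipped += 1
            continue
        genes = [node] + [g for g in network.neighbors(node) if g in screen]
        if len(genes) == 1:
            n_skipped += 1
            continue
        pattern = find_enriched_pattern(genes, screen, policy)
        # the centre must participate in the enriched pattern (its profiles
        # are similar to the neighbours') and at least one neighbour profile
        # must be selected; the anchor row itself may belong to a neighbour
        if not any(s.gene == node for s in pattern.selected):
            n_skipped += 1
            continue
        if not any(s.gene != node for s in pattern.selected):
            n_skipped += 1
            continue
        values = [screen.values[s.row] for s in pattern.selected]
        signs = [s.sign for s in pattern.selected]
        seeds.append(
            Seed(node, reference_profile(values, signs), pattern.selected)
        )
    log.info("select_seeds: %d seeds, %d nodes skipped", len(seeds), n_skipped)
    return seeds


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def estimate_background(
    seed_profile: np.ndarray,
    screen: PhenotypeScreen,
    params: ModuleParams | None = None,
    rng_seed=0,
    context: _SeedContext | None = None,
    seed_gene: str = "",
) -> BackgroundTable:
    """Estimate the per-bin probability that a random gene matches the seed.

    Per bin, genes are drawn uniformly with replacement and the fraction
    satisfying the k/T inclusion rule against the seed profile is the
    bin's probability.  With ``exact_background`` the fraction is computed
    over all bin members instead (the sampling limit).  Monte-Carlo
    estimates of exactly 0 or 1 are pulled ``1/(2 n_rand_bg)`` inside the
    open interval so that downstream state probabilities stay positive.
    """
    params = params or ModuleParams()
    bins = ProfileCountBins(screen, params)
    ctx = context or _SeedContext(seed_profile, screen, params)
    rng = np.random.default_rng(rng_seed)
    probs: dict[int, float | None] = {}
    for b in bins.bin_ids:
        pool = bins.members[b]
        if not pool:
            probs[b] = None
            continue
        flags = np.asarray([ctx.qualification(g).qualifies for g in pool], dtype=float)
        if params.exact_background:
            probs[b] = float(flags.mean())
        else:
            draws = rng.integers(0, len(pool), size=params.n_rand_bg)
            p = float(flags[draws].mean())
            eps = 1.0 / (2 * params.n_rand_bg)
            probs[b] = min(max(p, eps), 1.0 - eps)
    method = "exact" if params.exact_background else "monte-carlo"
    return BackgroundTable(seed_gene, probs, params.n_rand_bg, method, bins)


# ---------------------------------------------------------------------------
# probability engine
# ---------------------------------------------------------------------------


def binomial_pmf(kk: int, n: int, p: float) -> float:
    """``C(n, kk) p^kk (1-p)^(n-kk)`` with explicit domain checks."""
    if not (0 <= kk <= n):
        raise ValueError("require 0 <= kk <= n")
    if not (0 <= p <= 1):
        raise ValueError("require 0 <= p <= 1")
    return float(sps.binom.pmf(kk, n, p))


def binomial_cdf(kk: int, n: int, p: float) -> float:
    if not (0 <= kk <= n):
        raise ValueError("require 0 <= kk <= n")
    if not (0 <= p <= 1):
        raise ValueError("require 0 <= p <= 1")
    return float(sps.binom.cdf(kk, n, p))


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Full pmf of the number of successes among independent, heterogeneous
    Bernoulli trials, via the dynamic-programming convolution.

    Returns an array of length ``n + 1``; entry ``k`` is ``P(X = k)``.
    """
    p = np.asarray(probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("Bernoulli probabilities must lie in [0, 1]")
    dp = np.zeros(len(p) + 1)
    dp[0] = 1.0
    for i, pi in enumerate(p):
        dp[1 : i + 2] = dp[1 : i + 2] * (1 - pi) + dp[: i + 1] * pi
        dp[0] *= 1 - pi
    return dp


def state_probability(
    state: ExpansionState,
    background: BackgroundTable,
    variant: str = "pmf",
) -> float:
    """Probability of one expansion state under the random-placement null.

    ``"pmf"`` (default): Poisson-binomial ``P(X = k_obs)`` over the
    neighbours' bin probabilities — reduces to the plain binomial mass
    when all probabilities are equal.  ``"config"``: the literal product
    over the observed success/failure assignment.  ``"tail"``:
    ``P(X >= k_obs)``.  An empty neighbour set has probability 1.
    """
    if variant not in ("pmf", "config", "tail"):
        raise ValueError(f"unknown state variant {variant!r}")
    if state.n == 0:
        return 1.0
    p = np.asarray([background.prob_for_bin(b) for _, b, _ in state.neighbors])
    sim = np.asarray([s for _, _, s in state.neighbors], dtype=bool)
    if variant == "config":
        return float(np.prod(np.where(sim, p, 1 - p)))
    pmf = poisson_binomial_pmf(p)
    k = int(sim.sum())
    if variant == "pmf":
        return float(pmf[k])
    return float(pmf[k:].sum())


def module_pvalue(states: Sequence[ExpansionState]) -> float:
    """Product of the state probabilities, accumulated in log space."""
    if len(states) == 0:
        raise ValueError("module has no recorded states")
    logs = 0.0
    for s in states:
        if s.state_probability is None:
            raise ValueError("state probability not computed")
        if not 0 < s.state_probability <= 1:
            raise ValueError("state probabilities must lie in (0, 1]")
        logs += math.log(s.state_probability)
    return math.exp(logs)


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def expand_module(
    seed: Seed,
    network: InteractionNetwork,
    screen: PhenotypeScreen,
    params: ModuleParams | None = None,
    background: BackgroundTable | None = None,
    context: _SeedContext | None = None,
    rng_seed=0,
) -> ModuleResult:
    """Grow a module around a seed against the fixed seed profile."""
    params = params or ModuleParams()
    ctx = context or _SeedContext(seed.seed_profile, screen, params)
    if background is None:
        background = estimate_background(
            seed.seed_profile, screen, params, rng_seed, context=ctx, seed_gene=seed.gene
        )
    bins = background.bins

    own = [s for s in seed.selected_neighborhood if s.gene == seed.gene]
    members: dict[str, MemberSelection] = {
        seed.gene: MemberSelection(
            seed.gene,
            tuple(s.row for s in own),
            tuple(s.oligo_id for s in own),
            1,
            joined_at_step=0,
        )
    }
    states: list[ExpansionState] = []
    graph = network.graph
    while len(states) < params.max_steps:
        frontier = sorted(
            {
                nbr
                for m in members
                if m in graph
                for nbr in graph.neighbors(m)
            }
            - set(members)
        )
        entries: list[tuple[str, int, bool]] = []
        joiners: list[str] = []
        for g in frontier:
            if g not in screen:
                continue
            q = ctx.qualification(g)
            entries.append((g, bins.bin_of(screen.profile_count(g)), q.qualifies))
            if q.qualifies:
                joiners.append(g)
        state = ExpansionState(step=len(states), neighbors=entries)
        states.append(state)
        if not joiners:
            break
        for g in joiners:
            q = ctx.qualification(g)
            members[g] = MemberSelection(
                g,
                q.rows,
                tuple(screen.row_oligos[i] for i in q.rows),
                q.sign,
                joined_at_step=len(states),
            )
    for s in states:
        s.state_probability = state_probability(s, background, params.state_variant)
    p_value = module_pvalue(states)

    # sign-aware reference: align every selected profile to the seed
    # orientation, then flip the result if the majority was anti-correlated
    values, signs = [], []
    for m in members.values():
        for i in m.rows:
            values.append(screen.values[i])
            signs.append(m.sign)
    if values:
        aligned = reference_profile(values, signs)
        majority = 1 if sum(1 for s in signs if s > 0) >= sum(1 for s in signs if s < 0) else -1
        reference = majority * aligned
    else:  # pragma: no cover - seed always contributes profiles
        reference = np.array(seed.seed_profile, dtype=float)
    return ModuleResult(seed, members, states, p_value, reference)


def run_impact_modules(
    network: InteractionNetwork,
    screen: PhenotypeScreen,
    params: ModuleParams | None = None,
    rng_seed=0,
) -> list[ModuleResult]:
    """Full pipeline: seeds, backgrounds, expansion, assessment.

    Modules with identical member sets are deduplicated, keeping the
    smallest p-value.  Deterministic for a fixed ``rng_seed``.
    """
    params = params or ModuleParams()
    network = restrict_to_screen(network, screen)
    seeds = select_seeds(network, screen, params)
    if not seeds:
        log.info("run_impact_modules: no node passed seed selection")
        return []
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = ss.spawn(len(seeds))
    results: list[ModuleResult] = []
    for child, seed in zip(children, seeds):
        ctx = _SeedContext(seed.seed_profile, screen, params)
        bg = estimate_background(
            seed.seed_profile, screen, params, child, context=ctx, seed_gene=seed.gene
        )
        results.append(
            expand_module(seed, network, screen, params, background=bg, context=ctx)
        )
    best: dict[frozenset, ModuleResult] = {}
    for res in results:
        key = frozenset(res.members)
        cur = best.get(key)
        if cur is None or res.p_value < cur.p_value:
            best[key] = res
    out = sorted(best.values(), key=lambda r: (r.p_value, r.seed.gene))
    log.info(
        "run_impact_modules: %d seeds -> %d unique modules covering %d genes",
        len(seeds), len(out), len({g for r in out for g in r.members}),
    )
    return out


def gene_scores_from_modules(
    results: Sequence[ModuleResult],
    universe: Sequence[str] | None = None,
) -> dict[str, float]:
    """Score genes by the smallest p-value over the modules containing them.

    Genes from ``universe`` (e.g. all network nodes with phenotype data)
    that belong to no module receive the uninformative score 1.0; genes
    outside the universe are absent from the ranking.
    """
    scores: dict[str, float] = {g: 1.0 for g in (universe or [])}
    for res in results:
        for g in res.members:
            scores[g] = min(scores.get(g, 1.0), res.p_value)
    return scores


def write_module_results(results: Sequence[ModuleResult], path, parameter_names=None) -> None:
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        row = {
            "module_id": f"M{i:04d}",
            "seed_gene": r.seed.gene,
            "n_members": r.n_members,
            "n_states": len(r.states),
            "p_value": r.p_value,
            "members": ";".join(
                f"{g}:{'+' if r.members[g].sign > 0 else '-'}" for g in r.member_genes
            ),
        }
        names = parameter_names or [f"param_{j}" for j in range(len(r.reference))]
        row.update({f"ref_{c}": v for c, v in zip(names, r.reference)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_module_sif(results: Sequence[ModuleResult], network: InteractionNetwork, path) -> None:
    """Export the union of module sub-networks for viewer tools."""
    with open(path, "w") as fh:
        for r in results:
            genes = set(r.members)
            for a, b in network.graph.subgraph(genes).edges:
                a, b = sorted((a, b))
                fh.write(f"{a}\tpp\t{b}\n")
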