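# Methods

This package integrates multi-parametric, multi-replicate loss-of-function
phenotype profiles with two kinds of prior gene-relationship information:
gene sets (e.g. protein complexes) and undirected interaction networks.
Its purpose is to separate a gene's *true* phenotype from reagent-specific
off-target effects (OTEs): different silencing reagents against the same
gene often produce discordant profiles, and the consistent subset can only
be recognised by asking which profiles agree *across related genes*.

## Input model

A screen is a `P x N` matrix `D`: one row per perturbation experiment
(oligo), `N` quantitative parameters per row, and `m_i >= 1` rows per gene
(counts may differ between genes, `P = sum m_i`).  Parameters must be on
comparable scales; `znormalize` z-scores each column over all `P` rows
(sample SD, denominator `P-1` — the common screen-analysis convention; for
realistic `P` the difference from the population SD is immaterial).
Profile similarity is the Pearson correlation `r` between rows, with a
closed threshold (`>= T`), one-sided (`r >= T`) for the set search and
two-sided (`|r| >= T`) for seed selection and module expansion.  A profile
with missing values or zero variance has undefined correlations and is
never similar to anything; it is retained in the data but cannot
contribute to any selection (no imputation).

## Gene-set search

For a gene set, every profile of the set is scanned as a candidate
*anchor*.  An anchor covers a gene if at least one of the gene's profiles
is similar to it; the anchor covering the most genes (`n_T`) wins.
Counting genes rather than profiles prevents genes with many oligos from
dominating.  Ties fall back to the largest sum of correlation values of
the selected profiles, then to the lexicographically smallest
(gene, oligo) anchor label, making the result independent of input order
(sums are compared after rounding at 1e-9 to keep float summation order
from breaking ties).  All of a covered gene's passing profiles are
selected, and the per-parameter median of the selected profiles is the
set's *reference profile*.  In the optional absolute-similarity mode a
gene whose passing profiles disagree in sign keeps the orientation with
the larger summed |r| (ties resolve to positive) and drops the rest.

Significance is assessed against the set's own structure: `n_rand`
pseudo-sets (default 5000) with the same number of genes and the same
per-gene profile counts are drawn from the screen, whole per-gene bundles
travelling together so within-gene correlation survives.  Genes are
matched on exact profile count when the screen has enough such genes, else
on a binned count (one bin per count 1..7, counts above pooled, matching
the module-search binning).  The p-value is the fraction of pseudo-sets
selecting at least as many profiles as the real set.  The comparison
statistic is the number of selected profiles by default ("the same or more
profiles are selected"); comparing covered genes (`n_T`) is available via
`statistic="genes"`.  A zero count is reported as `p = 0` with resolution
`1/n_rand` ("< 1/5000"), keeping the estimator an honest fraction; a
`(count+1)/(n_rand+1)` variant is available as
`PermutationResult.adjusted()`.

## Network-module search

**Seed selection.**  Every node with at least `k_s` profiles (default 2)
is tested: the enriched-pattern search runs over the node plus its direct
neighbours with the absolute policy at `T_s` (default 0.8).  The node
becomes a seed when it *participates* in the winning pattern — at least
one of its own profiles and one neighbour profile are selected.  (The
anchor row itself may belong to a neighbour: inside a tight module the
best anchor is usually someone else's profile, and demanding anchor
ownership would make the members of exactly the strongest modules reject
each other.)  The *seed profile* is the per-parameter median of the
selected profiles after sign alignment.

**Expansion.**  Starting from the seed gene, every non-member neighbour of
the current module is tested against the *fixed* seed profile: at least
`k` of its profiles (default 3; `k` may also be a fraction of `m_i`,
applied as `ceil(k * m_i)`, minimum 1) must have `|r| >= T` (default 0.7),
and after orientation resolution the kept profiles must be mutually
positively correlated (pairwise `r > 0`).  All qualifying neighbours join
simultaneously; expansion stops when none qualifies or after `max_steps`
(default 50) states.  The state in which no neighbour qualifies is
recorded too, and a seed-only module (one state, zero successes) is
reported rather than suppressed.  The module's reference profile is the
sign-aware median of all members' selected profiles, oriented to the
majority sign (ties resolve to the seed orientation).

**Assessment.**  Each expansion state is a set of Bernoulli trials — the
current neighbours either qualify or not.  The success probability of a
neighbour with `m` profiles against seed `s` is estimated empirically:
genes are grouped into profile-count bins (one bin per exact count up to
7, one pooled bin above; quantile binning available via `n_bins`), and per
bin the fraction of `n_rand_bg` draws (default 1000, with replacement)
satisfying the same qualification rule is recorded.  The same rule is used
deliberately for backgrounds and for expansion, so the estimated
probability describes exactly the event whose surprise is being measured.
When a bin has no genes the nearest non-empty bin substitutes.  A
Monte-Carlo estimate of exactly 0 or 1 is pulled `1/(2 n_rand_bg)` inside
the open interval so downstream products stay positive; with
`exact_background=True` the bin fraction is enumerated exactly (the
sampling limit — preferable whenever the bin is smaller than the draw
budget) and needs no clamping.

The state probability is the Poisson-binomial mass `P(X = k_obs)` over the
neighbours' heterogeneous success probabilities, computed by the `O(n k)`
dynamic-programming convolution; with equal probabilities it reduces
exactly to the binomial mass.  Two alternative readings are exposed:
`"config"` (the literal product over the observed success/failure
assignment, which lacks the combinatorial factor) and `"tail"`
(`P(X >= k_obs)`).  The module p-value multiplies the state probabilities
in log space.  Rejected neighbours stay in later states' Bernoulli sets as
failures while still adjacent; the states are therefore statistically
dependent, and the product rests on an explicit independence assumption —
see *Calibration*, below.

Genes are ranked by the smallest p-value over the modules (or sets)
containing them; network genes in no module receive the uninformative
score 1.0, genes outside the network are absent from the ranking.  Seeds
are enumerated in ascending gene order and per-seed random streams are
spawned from one root seed, so runs are bit-reproducible.

## Synthetic screens

The generator emulates an image-based RNAi screen: `N = 40` parameters,
~7 oligos per gene (1 + Poisson(6)), z-normalized output.  True
phenotypes come from a pool of `n_archetypes = 12` random unit-norm,
mean-centred shapes kept mutually dissimilar (pairwise |r| < 0.3 by
rejection sampling) — multiparametric screens cluster into tens of
recurring phenotype patterns.  Planted-module genes share an archetype (up
to a per-member sign); null genes have a zero true profile.  Each oligo
emits its gene's true profile plus N(0, sigma_w) noise (sigma_w = 0.1), or
— with probability `ote_rate = 0.3` — an *off-target* profile drawn from a
random archetype of the same pool.  Drawing OTEs from the shared pool
makes some profile shapes systematically frequent, which is exactly the
bias the profile-specific backgrounds must correct.

The amplitude default (`signal_norm = 1.5`) puts two on-target oligos of
the same gene at `r ~ 0.85`: on-target replicates agree comfortably above
the method's operating thresholds, and visible replicate *dis*agreement
comes from the off-target mechanism — screens attribute replicate
inconsistency chiefly to reagent-specific OTEs, not to measurement noise.

What the generator does not emulate: correlated parameters within a
channel, plate/batch effects, dose-dependent silencing, partially
penetrant phenotypes, or OTE profiles outside the archetype pool.  Passing
tests on these screens therefore demonstrate the algorithms' correctness
and their qualitative behaviour (recovery, degradation under
randomization, multi-profile advantage), not quantitative performance on
any real screen.

## Evaluation machinery

ROC, precision-recall and balanced-accuracy curves sweep the distinct
score values (ascending p; `score <= t` predicts positive), grouping ties
into single steps, so the trapezoidal AUC equals the tie-corrected
Mann-Whitney statistic.  The AUC standard error follows Hanley-McNeil
(`Q1 = A/(2-A)`, `Q2 = 2A^2/(1+A)`), with a one-sided z-test against
AUC = 0.5.  Two rankings on the same labels are compared by stratified
bootstrap (positives and negatives resampled separately, default 1000
replicates) on `D = (A1 - A2)/sd(A1* - A2*)`, two-sided normal p;
identical rankings return p = 1 by convention (0/0 guard).

Randomization controls: `"edges"` performs degree-preserving double-edge
swaps (10x the edge count); `"genes"` permutes gene labels over nodes
(profiles travel with their gene); `"profiles"` permutes whole per-gene
profile bundles between genes with identical profile counts, so every
`m_i`-dependent parameter stays valid; `"edges+profiles"` composes the
two.  Gaussian noise injection adds independent N(0, sigma) to every
matrix cell.  The chi-square baseline collapses each gene to its average
or "mode" profile — implemented as the medoid (maximal summed correlation
to the gene's other profiles), a deterministic surrogate for a mean-shift
mode estimate — and scores the upper tail of `sum_j z_j^2` on `N` degrees
of freedom.  Phenotype-map coordinates reduce a reference profile to the
difference and the sum of the L2 norms of two disjoint parameter channels
(e.g. two cargo readouts).

## Calibration and known limitations

The set-level permutation p-value is a genuine exchangeability p-value,
but its statistic (selected-profile count) is discrete; with ties counted
as "at least as extreme" it is conservative by about half the typical
atom mass of the null statistic.  Null calibration is therefore checked
where the statistic has rich support — thresholds inside the null
correlation bulk (|r| ~ N^-1/2, i.e. T ~ 0.1 at N = 40) and large,
heterogeneous sets.  At stringent thresholds (T = 0.7) the null statistic
degenerates to a few atoms and the p-values, while valid, are visibly
conservative.

The module p-value is a *score*, not a calibrated tail probability: it
multiplies point masses `P(X = k_obs)` across dependent states, so even
under a perfect null it is not uniformly distributed (a product of
independent uniform tail p-values would itself already be sub-uniform).
It orders modules by surprise and supports thresholding, and the
randomization controls show it collapses to uninformative under shuffled
inputs, but its absolute scale should not be read as a frequentist error
rate.  Larger modules also accrue more (small) factors, so among modules
capturing the same signal the variant with more members tends to rank
first.

Numerical choices: correlations are computed from population-standardised
rows (`r = z_a . z_b / N`) and clipped to [-1, 1]; products of state
probabilities are accumulated in log space; tie-breaks are deterministic
(positive orientation, seed orientation, lexicographic labels); modules
with identical member sets are deduplicated keeping the smallest p-value.

Problem sizes used in the test suite and the acceptance script — e.g. a
500-gene screen with three planted 8-gene modules for recovery studies,
300-gene null screens with 200 random sets for calibration, 1e5-draw
Monte-Carlo oracles per expansion state — were chosen so the full
validation runs comfortably on a single CPU while keeping binomial /
Monte-Carlo standard errors well below the effect sizes being asserted.
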