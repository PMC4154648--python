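import itertools
import math

import numpy as np
import pytest

from impact.modules import (
    ExpansionState,
    ModuleParams,
    binomial_cdf,
    binomial_pmf,
    estimate_background,
    expand_module,
    gene_scores_from_modules,
    module_pvalue,
    poisson_binomial_pmf,
    run_impact_modules,
    select_seeds,
    state_probability,
)
from impact.screen import InteractionNetwork
from impact.similarity import pearson

from conftest import build_screen, noisy_copies


# ---------------------------------------------------------------------------
# probability engine
# ---------------------------------------------------------------------------


def test_binomial_pmf_cdf_reference_values():
    assert binomial_pmf(2, 3, 0.5) == pytest.approx(0.375, abs=1e-12)
    assert binomial_pmf(0, 5, 0.0) == 1.0
    assert binomial_cdf(7, 7, 0.3) == pytest.approx(1.0, abs=1e-12)
    assert sum(binomial_pmf(k, 7, 0.3) for k in range(8)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        binomial_pmf(4, 3, 0.5)
    with pytest.raises(ValueError):
        binomial_pmf(1, 3, 1.5)


def brute_force_pmf(probs):
    """Oracle: enumerate all 2^n Bernoulli outcomes."""
    n = len(probs)
    out = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        p = 1.0
        for b, q in zip(bits, probs):
            p *= q if b else (1 - q)
        out[sum(bits)] += p
    return out


def test_poisson_binomial_matches_enumeration(rng):
    for n in (1, 2, 5, 8):
        probs = rng.uniform(0, 1, size=n)
        np.testing.assert_allclose(
            poisson_binomial_pmf(probs), brute_force_pmf(probs), atol=1e-13
        )


def test_poisson_binomial_reduces_to_binomial():
    probs = [0.3] * 9
    pmf = poisson_binomial_pmf(probs)
    for k in range(10):
        assert pmf[k] == pytest.approx(binomial_pmf(k, 9, 0.3), abs=1e-12)


class FakeBackground:
    """Background stub mapping bin id -> fixed probability."""

    def __init__(self, probs):
        self._p = probs

    def prob_for_bin(self, b):
        return self._p[b]


def make_state(probs, successes):
    neighbors = [
        (f"g{i}", i, i in successes) for i in range(len(probs))
    ]
    return ExpansionState(0, neighbors), FakeBackground(dict(enumerate(probs)))


def test_state_probability_variants():
    state, bg = make_state([0.5, 0.5, 0.5], {0, 1})
    assert state_probability(state, bg, "pmf") == pytest.approx(0.375)
    state, bg = make_state([0.5, 0.1], {0})
    assert state_probability(state, bg, "pmf") == pytest.approx(0.5 * 0.9 + 0.5 * 0.1)
    assert state_probability(state, bg, "config") == pytest.approx(0.5 * 0.9)
    assert state_probability(state, bg, "tail") == pytest.approx(1 - 0.5 * 0.9)
    state, bg = make_state([1.0, 1.0], {0, 1})
    for v in ("pmf", "config", "tail"):
        assert state_probability(state, bg, v) == pytest.approx(1.0)


def test_module_pvalue_log_space():
    def states(probs):
        out = []
        for p in probs:
            s = ExpansionState(0, [("g", 1, True)])
            s.state_probability = p
            out.append(s)
        return out

    assert module_pvalue(states([0.375, 0.2])) == pytest.approx(0.075)
    assert module_pvalue(states([1.0])) == 1.0
    assert module_pvalue(states([0.9] * 50)) == pytest.approx(
        math.exp(50 * math.log(0.9)), rel=1e-12
    )
    with pytest.raises(ValueError):
        module_pvalue([])


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------


def star_fixture(rng):
    shape = rng.normal(size=30)
    screen = build_screen({
        "hub": noisy_copies(shape, 2, 0.05, rng),
        "l1": noisy_copies(shape, 2, 0.05, rng),
        "l2": noisy_copies(shape, 2, 0.05, rng),
    })
    net = InteractionNetwork([("hub", "l1"), ("hub", "l2")])
    return screen, net, shape


def test_select_seeds_star(rng):
    screen, net, shape = star_fixture(rng)
    seeds = select_seeds(net, screen, ModuleParams())
    assert {s.gene for s in seeds} == {"hub", "l1", "l2"}
    hub = next(s for s in seeds if s.gene == "hub")
    assert pearson(hub.seed_profile, shape) > 0.95
    assert any(s.gene != "hub" for s in hub.selected_neighborhood)


def test_seed_requires_min_profiles(rng):
    screen, net, _ = star_fixture(rng)
    seeds = select_seeds(net, screen, ModuleParams(k_s=3))
    assert seeds == []  # every node has only 2 profiles


def test_no_seed_when_neighbors_uncorrelated(rng):
    screen = build_screen({
        "hub": [rng.normal(size=30) for _ in range(2)],
        "l1": [rng.normal(size=30) for _ in range(2)],
    })
    net = InteractionNetwork([("hub", "l1")])
    assert select_seeds(net, screen, ModuleParams()) == []


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def test_background_saturation_and_zero(rng):
    # single-profile genes: at T -> 0 every draw matches, so p-hat saturates
    screen = build_screen({g: [rng.normal(size=20)] for g in "ABCDEF"})
    seed_profile = rng.normal(size=20)
    low_t = ModuleParams(T=1e-9, k=1)
    bg = estimate_background(seed_profile, screen, low_t, rng_seed=0)
    assert all(p > 0.99 for p in bg.probs.values() if p is not None)
    screen = build_screen(
        {g: [rng.normal(size=20) for _ in range(2)] for g in "ABCDEF"}
    )
    # a seed orthogonal to everything never matches at a high threshold
    high_t = ModuleParams(T=0.99, k=1, exact_background=True)
    bg = estimate_background(seed_profile, screen, high_t, rng_seed=0)
    assert all(p == 0.0 for p in bg.probs.values() if p is not None)


def test_background_fraction_matches_bin_composition(rng):
    """A bin where exactly 30% of genes match gives p-hat near 0.3."""
    shape = rng.normal(size=30)
    data = {}
    for i in range(30):
        if i < 9:
            data[f"g{i}"] = noisy_copies(shape, 2, 0.05, rng)
        else:
            data[f"g{i}"] = [rng.normal(size=30) for _ in range(2)]
    screen = build_screen(data)
    params = ModuleParams(T=0.7, k=2, n_rand_bg=1000)
    bg = estimate_background(shape, screen, params, rng_seed=3)
    p_hat = bg.prob_for_count(2)
    se = math.sqrt(0.3 * 0.7 / 1000)
    assert abs(p_hat - 0.3) <= 3 * se
    exact = estimate_background(
        shape, screen, ModuleParams(T=0.7, k=2, exact_background=True), rng_seed=0
    )
    assert exact.prob_for_count(2) == pytest.approx(9 / 30)


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def clique_fixture(rng, n_clique=5, n_null=8):
    shape = rng.normal(size=40)
    data = {}
    clique = [f"c{i}" for i in range(n_clique)]
    for g in clique:
        data[g] = noisy_copies(shape, 3, 0.05, rng)
    nulls = [f"x{i}" for i in range(n_null)]
    for g in nulls:
        data[g] = [rng.normal(size=40) for _ in range(3)]
    edges = [(a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]]
    edges += [(clique[0], nulls[0])] + list(zip(nulls, nulls[1:]))
    return build_screen(data), InteractionNetwork(edges), clique, shape


def test_planted_clique_recovered(rng):
    screen, net, clique, _ = clique_fixture(rng)
    params = ModuleParams(k=2)
    seeds = select_seeds(net, screen, params)
    seed = next(s for s in seeds if s.gene == clique[0])
    res = expand_module(seed, net, screen, params)
    assert set(res.member_genes) == set(clique)
    assert len(res.states) <= 3
    assert 0 < res.p_value <= 1
    # oracle: every member individually passes the per-neighbour check
    for g in res.member_genes:
        rs = [pearson(seed.seed_profile, v) for v in screen.values[screen.gene_rows(g)]]
        assert sum(abs(r) >= params.T for r in rs) >= 2


def test_seed_only_module_records_one_state(rng):
    screen = build_screen({
        "a": noisy_copies(rng.normal(size=30), 2, 0.01, rng),
        "b": [rng.normal(size=30) for _ in range(2)],
    })
    # a's two profiles correlate with each other; b does not -> a seeds via b? no:
    # use a self-consistent seed with an uncorrelated neighbour
    net = InteractionNetwork([("a", "b")])
    params = ModuleParams(k=2)
    from impact.modules import Seed
    seed = Seed("a", screen.values[screen.gene_rows("a")[0]].copy(), [])
    res = expand_module(seed, net, screen, params)
    assert res.member_genes == ["a"]
    assert len(res.states) == 1
    assert res.states[0].k_obs == 0
    assert res.states[0].n == 1


def test_mixed_sign_orientation_resolution(rng):
    shape = rng.normal(size=40)
    data = {
        "s": noisy_copies(shape, 2, 0.01, rng),
        # 2 profiles correlated, 2 anti-correlated, positive side stronger
        "m": noisy_copies(shape, 2, 0.005, rng) + noisy_copies(-shape, 2, 0.05, rng),
    }
    screen = build_screen(data)
    net = InteractionNetwork([("s", "m")])
    params = ModuleParams(k=2)
    from impact.modules import _SeedContext
    ctx = _SeedContext(shape, screen, params)
    q = ctx.qualification("m")
    assert q.qualifies
    assert q.sign == 1
    assert len(q.rows) == 2  # only the same-sign profiles are selected
    rows = screen.gene_rows("m")
    assert set(q.rows) == {rows[0], rows[1]}


def test_sign_flip_invariance(rng):
    """Flipping all profiles of one gene leaves membership and p unchanged."""
    screen, net, clique, _ = clique_fixture(rng)
    params = ModuleParams(k=2, exact_background=True)
    res1 = run_impact_modules(net, screen, params, rng_seed=0)
    flipped = screen.values.copy()
    flipped[screen.gene_rows(clique[2])] *= -1
    screen2 = screen.with_values(flipped)
    res2 = run_impact_modules(net, screen2, params, rng_seed=0)
    sets1 = sorted(frozenset(r.members) for r in res1)
    sets2 = sorted(frozenset(r.members) for r in res2)
    assert sets1 == sets2
    p1 = {frozenset(r.members): r.p_value for r in res1}
    p2 = {frozenset(r.members): r.p_value for r in res2}
    for key in p1:
        assert p1[key] == pytest.approx(p2[key], rel=1e-9)
    # the flipped gene joins with the opposite orientation
    m1 = next(r for r in res1 if clique[2] in r.members)
    m2 = next(r for r in res2 if clique[2] in r.members)
    assert m1.members[clique[2]].sign == -m2.members[clique[2]].sign


def test_lowering_k_keeps_qualified_members(rng):
    screen, net, clique, _ = clique_fixture(rng)
    seeds3 = select_seeds(net, screen, ModuleParams(k=3))
    seed = next(s for s in seeds3 if s.gene == clique[0])
    res_k3 = expand_module(seed, net, screen, ModuleParams(k=3, exact_background=True))
    res_k2 = expand_module(seed, net, screen, ModuleParams(k=2, exact_background=True))
    assert set(res_k3.member_genes) <= set(res_k2.member_genes)


def test_fractional_k(rng):
    params = ModuleParams(k=0.5, k_is_fraction=True)
    assert params.required_k(7) == 4
    assert params.required_k(1) == 1
    assert ModuleParams(k=0.1, k_is_fraction=True).required_k(3) == 1


def test_run_impact_modules_determinism_and_dedup(rng):
    screen, net, clique, _ = clique_fixture(rng)
    params = ModuleParams(k=2)
    res1 = run_impact_modules(net, screen, params, rng_seed=11)
    res2 = run_impact_modules(net, screen, params, rng_seed=11)
    assert [r.p_value for r in res1] == [r.p_value for r in res2]
    assert [r.seed.gene for r in res1] == [r.seed.gene for r in res2]
    keys = [frozenset(r.members) for r in res1]
    assert len(keys) == len(set(keys))  # exact-duplicate modules removed
    scores = gene_scores_from_modules(res1, universe=net.nodes)
    assert scores[clique[0]] == min(r.p_value for r in res1 if clique[0] in r.members)
    assert all(0 <= v <= 1 for v in scores.values())


def test_empty_seed_list_yields_no_modules(rng):
    screen = build_screen({g: [rng.normal(size=30)] for g in "abcd"})
    net = InteractionNetwork([("a", "b"), ("c", "d")])
    assert run_impact_modules(net, screen, ModuleParams(), rng_seed=0) == []
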