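import itertools

import numpy as np
import pytest

from impact.screen import GeneSet, GeneSetCollection
from impact.sets import (
    find_enriched_pattern,
    gene_scores_from_sets,
    permutation_pvalue,
    reference_profile,
    run_impact_sets,
)
from impact.similarity import SimilarityPolicy

from conftest import build_screen, noisy_copies

POS = SimilarityPolicy(0.7, "positive")


def test_singleton_set(rng):
    screen = build_screen({"A": [rng.normal(size=10)]})
    pat = find_enriched_pattern(["A"], screen, POS)
    assert pat.n_T == 1
    assert [s.oligo_id for s in pat.selected] == ["A:0"]


def test_shared_shape_covers_all_genes(small_screen):
    """A,B,C share one profile shape; the winning anchor covers all three."""
    pat = find_enriched_pattern(list("ABCDEF"), small_screen, POS)
    assert pat.n_T == 3
    assert set(s.gene for s in pat.selected) == {"A", "B", "C"}
    assert pat.anchor[0] in "ABC"


def test_no_enrichment_floor(rng):
    screen = build_screen({g: [rng.normal(size=30)] for g in "ABC"})
    pat = find_enriched_pattern(["A", "B", "C"], screen, POS)
    assert pat.n_T == 1
    assert len(pat.selected) == 1


def test_empty_set_after_restriction(small_screen):
    with pytest.raises(ValueError, match="empty set"):
        find_enriched_pattern(["nope"], small_screen, POS)


def test_gene_count_beats_profile_count(rng):
    """An anchor covering 3 genes wins over one covering 4 profiles of 2 genes."""
    u = rng.normal(size=30)
    v = rng.normal(size=30)
    screen = build_screen({
        "A": noisy_copies(u, 1, 0.01, rng),
        "B": noisy_copies(u, 1, 0.01, rng),
        "C": noisy_copies(u, 1, 0.01, rng),
        "D": noisy_copies(v, 3, 0.01, rng),
        "E": noisy_copies(v, 3, 0.01, rng),
    })
    pat = find_enriched_pattern(list("ABCDE"), screen, POS)
    assert pat.n_T == 3
    assert {s.gene for s in pat.selected} == {"A", "B", "C"}


def test_input_order_invariance(small_screen, rng):
    genes = list("ABCDEF")
    base = find_enriched_pattern(genes, small_screen, POS)
    for _ in range(3):
        rng.shuffle(genes)
        again = find_enriched_pattern(genes, small_screen, POS)
        assert again.anchor == base.anchor
        assert [(s.gene, s.oligo_id) for s in again.selected] == [
            (s.gene, s.oligo_id) for s in base.selected
        ]


def test_raising_threshold_never_increases_coverage(small_screen):
    n_prev = None
    for t in (0.3, 0.5, 0.7, 0.9):
        pat = find_enriched_pattern(list("ABCDEF"), small_screen, SimilarityPolicy(t))
        if n_prev is not None:
            assert pat.n_T <= n_prev
        n_prev = pat.n_T


def test_absolute_mode_keeps_one_orientation_per_gene(rng):
    u = rng.normal(size=30)
    screen = build_screen({
        "A": [u + rng.normal(0, 0.01, 30)],
        "B": [-u + rng.normal(0, 0.01, 30), -u + rng.normal(0, 0.01, 30)],
    })
    pat = find_enriched_pattern(["A", "B"], screen, SimilarityPolicy(0.8, "absolute"))
    assert pat.n_T == 2
    signs = {s.gene: s.sign for s in pat.selected}
    assert signs["A"] != signs["B"]


def test_reference_profile_medians():
    np.testing.assert_allclose(
        reference_profile([[1.0, 2.0], [1.0, 2.0]]), [1, 2]
    )
    np.testing.assert_allclose(
        reference_profile([[0.0, 2.0], [2.0, 0.0]]), [1, 1]
    )
    x = np.random.default_rng(7).normal(size=(5, 6))
    np.testing.assert_allclose(
        reference_profile(list(x)), np.sort(x, axis=0)[2], atol=1e-12
    )
    np.testing.assert_allclose(
        reference_profile([[1.0, -1.0]], signs=[-1]), [-1, 1]
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _enumerate_exact_p(observed, structure, screen, policy, statistic="profiles"):
    """Oracle: exhaustive enumeration over structure-matching pseudo-sets."""
    from impact.sets import _pattern_statistics, _rows_and_codes, _structure_strata

    strata = _structure_strata(structure, screen)
    pools = [(need, pool) for need, pool in strata.values()]
    choices_per_stratum = [
        list(itertools.combinations(pool, need)) for need, pool in pools
    ]
    total, ge = 0, 0
    for combo in itertools.product(*choices_per_stratum):
        genes = [g for part in combo for g in part]
        rows, codes, present = _rows_and_codes(screen, genes)
        n_t, n_sel = _pattern_statistics(screen, rows, codes, len(present), policy)
        stat = n_sel if statistic == "profiles" else n_t
        total += 1
        if stat >= observed:
            ge += 1
    return ge / total


def test_permutation_matches_exhaustive_enumeration(rng):
    """Pools of 6 genes, sets of <= 3: sampled p within 3 binomial SE of exact."""
    shape = rng.normal(size=20)
    screen = build_screen({
        "A": noisy_copies(shape, 2, 0.05, rng),
        "B": noisy_copies(shape, 2, 0.05, rng),
        "C": [rng.normal(size=20) for _ in range(2)],
        "D": [rng.normal(size=20) for _ in range(2)],
        "E": noisy_copies(shape, 3, 0.05, rng),
        "F": [rng.normal(size=20) for _ in range(3)],
    })
    for genes in (["A", "B", "E"], ["C", "D"], ["A", "C", "F"]):
        pat = find_enriched_pattern(genes, screen, POS)
        structure = [screen.profile_count(g) for g in genes]
        perm = permutation_pvalue(pat, structure, screen, POS, 3000, rng_seed=9)
        exact = _enumerate_exact_p(
            pat.n_selected_profiles, structure, screen, POS
        )
        se = np.sqrt(max(exact * (1 - exact), 1e-9) / 3000)
        assert abs(perm.p_value - exact) <= 3 * se + 1e-12


def test_permutation_trivial_cases(small_screen):
    pat = find_enriched_pattern(["A", "B", "C"], small_screen, POS)
    perm = permutation_pvalue(pat, [3, 3, 3], small_screen, POS, 1, rng_seed=0)
    assert perm.p_value in (0.0, 1.0)
    full = permutation_pvalue(pat, [3, 3, 3], small_screen, POS, 200, rng_seed=1)
    again = permutation_pvalue(pat, [3, 3, 3], small_screen, POS, 200, rng_seed=1)
    assert full.p_value == again.p_value  # bitwise reproducible
    assert 0 <= full.p_value <= 1
    assert full.resolution == 1 / 200
    assert full.adjusted() == (full.n_greater_equal + 1) / 201


def test_permutation_insufficient_pool(small_screen):
    pat = find_enriched_pattern(["A"], small_screen, POS)
    with pytest.raises(ValueError, match="stratum"):
        permutation_pvalue(pat, [3] * 10, small_screen, POS, 10, rng_seed=0)


def test_run_impact_sets_planted_complex_ranks_first(rng):
    shape = rng.normal(size=40)
    data = {f"n{i}": [rng.normal(size=40) for _ in range(3)] for i in range(30)}
    for g in ("P1", "P2", "P3", "P4"):
        data[g] = noisy_copies(shape, 3, 0.1, rng)
    screen = build_screen(data)
    coll = GeneSetCollection()
    coll.add(GeneSet("planted", "", ("P1", "P2", "P3", "P4")))
    nulls = [f"n{i}" for i in range(30)]
    for j in range(10):
        members = tuple(rng.choice(nulls, size=4, replace=False))
        coll.add(GeneSet(f"rand{j}", "", members))
    results = run_impact_sets(coll, screen, POS, n_rand=300, rng_seed=5)
    assert results[0].set_id == "planted"
    assert results[0].p_value == min(r.p_value for r in results)
    rerun = run_impact_sets(coll, screen, POS, n_rand=300, rng_seed=5)
    assert [r.p_value for r in rerun] == [r.p_value for r in results]
    scores = gene_scores_from_sets(results, coll)
    assert scores["P1"] == results[0].p_value


def test_bh_qvalues_match_stepup_oracle():
    from impact.sets import bh_qvalues

    p = np.array([0.01, 0.04, 0.03, 0.5, 1.0])
    q = bh_qvalues(p)
    # step-up oracle computed by hand: sorted p * n / rank with running min
    expected = {0.01: 0.05, 0.03: 0.0666666667, 0.04: 0.0666666667, 0.5: 0.625, 1.0: 1.0}
    for pi, qi in zip(p, q):
        assert qi == pytest.approx(expected[pi], rel=1e-8)
    assert np.all(q >= p - 1e-15)
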