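"""NBS core: thresholding, components, permutation null, FWE p-values, sweep."""

import itertools

import numpy as np
import pytest

import nbsfc
from nbsfc import (
    ContrastSpec,
    InvalidArgumentError,
    NBSResult,
    NullDistribution,
    connected_components,
    fwe_pvalue,
    null_distribution,
    permute_within_subject,
    run_nbs,
    threshold_edges,
    threshold_sweep,
)
from nbsfc.glm import edge_tstats
from nbsfc.nbs import default_p_grid

RNG = np.random.default_rng(515)


def _statmap_from_t(t_by_pair: dict, n_nodes: int):
    """Build an EdgeStatMap whose t equals the given per-pair values.

    Subject diffs are constructed so that edge_tstats reproduces the
    requested t exactly (two subjects, mean m, sd s -> t = m/(s/sqrt(2))).
    """
    iu, ju = np.triu_indices(n_nodes, k=1)
    t = np.zeros(len(iu))
    for (i, j), val in t_by_pair.items():
        k = np.flatnonzero((iu == min(i, j)) & (ju == max(i, j)))[0]
        t[k] = val
    # two-subject construction: diffs (m - d, m + d) give sd = d*sqrt(2)
    d = 1.0
    m = t * d  # t = m / (d*sqrt(2)/sqrt(2)) = m/d
    D = np.vstack([m - d, m + d])
    stats = edge_tstats(D)
    assert np.allclose(stats.t, t, atol=1e-10)
    return stats


class TestThresholdEdges:
    def test_retains_exactly_qualifying(self):
        stats = _statmap_from_t({(0, 1): 4.0, (1, 2): 2.0}, 4)
        g = threshold_edges(stats, 3.0, "two")
        assert g.pairs.tolist() == [[0, 1]]
        assert g.t.tolist() == [4.0]

    def test_negative_edge_kept_two_sided_with_sign(self):
        stats = _statmap_from_t({(2, 3): -4.0}, 5)
        g = threshold_edges(stats, 3.0, "two")
        assert g.pairs.tolist() == [[2, 3]]
        assert g.t[0] == -4.0
        comp = connected_components(g)[0]
        assert comp.sign_profile.tolist() == [-1]

    def test_one_sided_drops_negative(self):
        stats = _statmap_from_t({(2, 3): -4.0, (0, 1): 3.5}, 5)
        g = threshold_edges(stats, 3.0, "one")
        assert g.pairs.tolist() == [[0, 1]]

    def test_empty_graph_valid(self):
        stats = _statmap_from_t({(0, 1): 2.0}, 4)
        g = threshold_edges(stats, 5.0, "two")
        assert g.edge_indices.size == 0
        assert connected_components(g) == []


from conftest import brute_force_components


class TestConnectedComponents:
    def test_two_components_example(self):
        stats = _statmap_from_t(
            {(1, 2): 4.0, (2, 3): 4.5, (4, 5): 5.0}, 6
        )
        comps = connected_components(threshold_edges(stats, 3.0, "two"))
        sizes = sorted(c.size for c in comps)
        assert sizes == [1, 2]

    def test_component_statistics_arithmetic(self):
        stats = _statmap_from_t(
            {(0, 1): 3.0, (1, 2): 3.0, (2, 3): 3.0, (3, 4): 3.0}, 5
        )
        (comp,) = connected_components(threshold_edges(stats, 2.9, "two"))
        assert comp.size == 4
        assert comp.mass_t2 == pytest.approx(36.0)
        assert comp.intensity_abs == pytest.approx(12.0)

    def test_matches_brute_force_on_random_graphs(self):
        """Random graphs on <= 8 nodes against the transitive-closure oracle."""
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(2, 9))
            pairs = list(itertools.combinations(range(n), 2))
            chosen = [p for p in pairs if rng.random() < 0.3]
            if not chosen:
                continue
            t_by_pair = {p: float(rng.uniform(3.1, 8.0)) for p in chosen}
            stats = _statmap_from_t(t_by_pair, n)
            comps = connected_components(threshold_edges(stats, 3.0, "two"))
            got = sorted(
                (sorted(map(tuple, c.pairs.tolist())) for c in comps),
                key=lambda g: g[0],
            )
            assert got == brute_force_components(chosen)

    def test_node_relabelling_invariance(self):
        rng = np.random.default_rng(21)
        pairs = [(0, 1), (1, 2), (3, 4), (5, 6), (2, 6)]
        t_by_pair = {p: float(rng.uniform(3.5, 6.0)) for p in pairs}
        stats = _statmap_from_t(t_by_pair, 7)
        comps = connected_components(threshold_edges(stats, 3.0, "two"))
        perm = rng.permutation(7)
        relabeled = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])): v
            for (i, j), v in t_by_pair.items()
        }
        stats2 = _statmap_from_t(relabeled, 7)
        comps2 = connected_components(threshold_edges(stats2, 3.0, "two"))
        masses1 = sorted(round(c.mass_t2, 9) for c in comps)
        masses2 = sorted(round(c.mass_t2, 9) for c in comps2)
        assert masses1 == masses2


class TestPermutation:
    def test_sign_semantics(self):
        D = RNG.normal(size=(6, 10))
        perm = permute_within_subject(D, seed=3)
        signs = perm[:, 0] / D[:, 0]
        assert np.allclose(np.abs(signs), 1.0)
        # the same sign applies to the subject's entire edge vector
        assert np.allclose(perm, D * signs[:, None], atol=1e-12)

    def test_identity_and_full_negation(self):
        D = RNG.normal(size=(5, 8))
        assert np.allclose(D * 1.0, D)
        t_neg = edge_tstats(-D).t
        assert np.allclose(t_neg, -edge_tstats(D).t, atol=1e-12)

    def test_reproducible_given_seed(self):
        D = RNG.normal(size=(7, 4))
        assert np.allclose(
            permute_within_subject(D, seed=11), permute_within_subject(D, seed=11)
        )


class TestNullDistribution:
    def test_all_zero_data_gives_zero_null(self):
        D = np.zeros((6, 10))
        nd = null_distribution(D, n_perms=20, seed=0)
        assert np.all(nd.max_stat == 0.0)

    def test_identity_signs_reproduce_observed(self):
        """With explicit all-+1 signs, the single permutation records the
        observed maximal component statistic."""
        D = RNG.normal(size=(10, 45)) + 0.0
        D[:, 0] += 4.0  # strong edge (0,1) of a 10-node graph
        nd = null_distribution(
            D, height_p=0.001, n_perms=1, seed=0,
            signs=np.ones((1, 10)), statistic_kind="intensity_abs",
        )
        stats = edge_tstats(D)
        crit = nbsfc.height_threshold(stats.df, 0.001, "two")
        g = threshold_edges(stats, crit, "two")
        comps = connected_components(g)
        observed = max((c.intensity_abs for c in comps), default=0.0)
        assert nd.max_stat[0] == pytest.approx(observed, abs=1e-10)

    def test_full_negation_preserves_max_stats(self):
        D = RNG.normal(size=(8, 28))
        a = null_distribution(D, n_perms=5, signs=np.ones((5, 8)), seed=0)
        b = null_distribution(D, n_perms=5, signs=-np.ones((5, 8)), seed=0)
        assert np.allclose(a.max_stat, b.max_stat)


class TestFwePvalue:
    def test_hand_counted_proportion(self):
        nd = NullDistribution(np.array([10.0, 20, 30, 40]), "size", 0)
        assert fwe_pvalue(25.0, nd, "proportion") == pytest.approx(0.5)

    def test_tie_counts_as_greater_equal(self):
        nd = NullDistribution(np.array([1.0, 4.0, 2.0, 3.0]), "size", 0)
        assert fwe_pvalue(4.0, nd, "proportion") == pytest.approx(0.25)

    def test_extremes_and_plus_one_floor(self):
        nd = NullDistribution(np.array([1.0, 2.0, 3.0, 4.0]), "size", 0)
        assert fwe_pvalue(99.0, nd, "proportion") == 0.0
        assert fwe_pvalue(99.0, nd, "plus_one") == pytest.approx(1 / 5)
        assert fwe_pvalue(0.0, nd, "plus_one") == pytest.approx(1.0)

    def test_empty_null_rejected(self):
        nd = NullDistribution(np.array([1.0]), "size", 0)
        nd.max_stat = np.array([])
        with pytest.raises(InvalidArgumentError):
            fwe_pvalue(1.0, nd)


class TestRunNBS:
    def test_recovers_planted_component(self, small_cohort_z, star_effect):
        spec = ContrastSpec("self_gt_stranger", {"self": 1, "stranger": -1})
        res = run_nbs(small_cohort_z, spec, n_perms=200, seed=9)
        assert res.components, "planted star not detected"
        top = res.largest
        truth = {tuple(e) for e in star_effect.edge_set}
        got = {tuple(p) for p in top.pairs.tolist()}
        assert len(truth & got) >= 3
        assert top.p_fwe["intensity_abs"] <= 0.05

    def test_deterministic_given_seed(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        r1 = run_nbs(small_cohort_z, spec, n_perms=50, seed=4)
        r2 = run_nbs(small_cohort_z, spec, n_perms=50, seed=4)
        assert r1.to_json() == r2.to_json()

    def test_serialization_round_trip(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        res = run_nbs(small_cohort_z, spec, n_perms=30, seed=2)
        back = NBSResult.from_json(res.to_json())
        assert back.to_json() == res.to_json()

    def test_label_permute_scheme_runs(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 0.5, "stranger": -0.5})
        res = run_nbs(
            small_cohort_z, spec, n_perms=30, seed=2,
            perm_scheme="label_permute",
        )
        assert res.n_perms == 30
        for comp in res.components:
            assert 0.0 <= comp.p_fwe["intensity_abs"] <= 1.0


class TestThresholdSweep:
    def test_grid_of_one_reduces_to_run_nbs(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        tab, results = threshold_sweep(
            small_cohort_z, spec, p_grid=[0.001], n_perms=40, seed=3
        )
        single = run_nbs(small_cohort_z, spec, height_p=0.001, n_perms=40, seed=3)
        assert len(tab) == 1
        assert results[0].to_json() == single.to_json()

    def test_nesting_of_suprathreshold_sets(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        tab, results = threshold_sweep(
            small_cohort_z, spec, p_grid=default_p_grid(0.05, 0.001),
            n_perms=5, seed=1,
        )
        prev_edges = None
        for res in results:  # grid is descending: later = stricter
            edges = {
                tuple(p)
                for c in res.components
                for p in c.pairs.tolist()
            }
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_strict_component_maps_into_one_loose_component(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        _, results = threshold_sweep(
            small_cohort_z, spec, p_grid=[0.01, 0.001], n_perms=5, seed=1
        )
        loose, strict = results
        loose_sets = [
            {tuple(p) for p in c.pairs.tolist()} for c in loose.components
        ]
        for comp in strict.components:
            edges = {tuple(p) for p in comp.pairs.tolist()}
            containers = [s for s in loose_sets if edges <= s]
            assert len(containers) == 1

    def test_empty_grid_rejected(self, small_cohort_z):
        spec = ContrastSpec("c", {"self": 1, "stranger": -1})
        with pytest.raises(InvalidArgumentError):
            threshold_sweep(small_cohort_z, spec, p_grid=[])


def test_default_p_grid_ten_percent_steps():
    g = default_p_grid(0.05, 0.0001)
    assert g[0] == pytest.approx(0.05)
    assert np.allclose(g[1:] / g[:-1], 0.9)
    assert g[-1] >= 0.0001 > g[-1] * 0.9
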