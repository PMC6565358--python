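"""Cluster-mass permutation test: t-maps, clustering, exchangeability."""
import itertools

import numpy as np
import pytest
from scipy import stats

from seqerp.cluster import (
    TestSpec,
    build_comparison_grid,
    cluster_mass_test,
    form_clusters,
    paired_t_map,
)


def _chain(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


# --- comparison grids -------------------------------------------------------


def test_whole_brain_grid_counts():
    _, _, n = build_comparison_grid([f"ch{i}" for i in range(62)],
                                    (0.0, 600.0), 500.0)
    assert n == 18600


def test_roi_grid_counts():
    _, _, n = build_comparison_grid(list("abcdefghi"), (300.0, 600.0), 500.0)
    assert n == 1350


def test_inclusive_endpoint_convention():
    _, _, n = build_comparison_grid([f"ch{i}" for i in range(62)],
                                    (300.0, 500.0), 500.0, inclusive=True)
    assert n == 6262  # 62 x 101 samples with a closed upper endpoint


def test_single_point_grid():
    chs, times, n = build_comparison_grid(["Cz"], (100.0, 102.0), 500.0)
    assert n == 1 and len(times) == 1


def test_empty_selection_rejected():
    with pytest.raises(ValueError):
        build_comparison_grid([], (0.0, 600.0), 500.0)


# --- t-maps -----------------------------------------------------------------


def test_t_map_zero_for_identical_conditions():
    diffs = np.zeros((5, 3, 10))
    t, df = paired_t_map(diffs)
    assert df == 4
    assert np.allclose(t, 0.0)


def test_t_map_infinite_for_constant_nonzero_difference():
    diffs = np.full((4, 2, 5), 1.5)
    with pytest.warns(UserWarning, match="zero-variance"):
        t, _ = paired_t_map(diffs)
    assert np.all(np.isposinf(t))


def test_t_map_matches_closed_form(rng):
    diffs = rng.normal(0.3, 1.0, size=(4, 1, 3))
    t, df = paired_t_map(diffs)
    for c in range(1):
        for ti in range(3):
            x = diffs[:, c, ti]
            expected = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
            assert t[c, ti] == pytest.approx(expected)
    assert df == 3


# --- cluster formation ------------------------------------------------------


def test_no_suprathreshold_points_no_clusters():
    t = np.zeros((3, 10))
    assert form_clusters(t, 9, 0.05, "two", _chain(3)) == []


def test_temporal_contiguity_on_one_channel():
    t = np.zeros((1, 15))
    t[0, [4, 5, 6]] = 10.0
    t[0, 10] = 10.0
    clusters = form_clusters(t, 9, 0.05, "two", _chain(1))
    sizes = sorted(len(c.members) for c in clusters)
    assert sizes == [1, 3]
    assert {c.mass for c in clusters} == {10.0, 30.0}


def test_adjacent_channels_merge_simultaneous_points():
    t = np.zeros((3, 5))
    t[0, 2] = t[1, 2] = 8.0  # channels 0-1 adjacent on the chain
    clusters = form_clusters(t, 9, 0.05, "two", _chain(3))
    assert len(clusters) == 1
    assert len(clusters[0].members) == 2


def test_non_adjacent_channels_stay_separate():
    t = np.zeros((3, 5))
    t[0, 2] = t[2, 2] = 8.0  # channels 0 and 2 are not neighbours
    clusters = form_clusters(t, 9, 0.05, "two", _chain(3))
    assert len(clusters) == 2


def test_opposite_signs_never_join():
    t = np.zeros((1, 6))
    t[0, 2], t[0, 3] = 9.0, -9.0
    clusters = form_clusters(t, 9, 0.05, "two", _chain(1))
    assert len(clusters) == 2
    assert sorted(c.sign for c in clusters) == [-1, 1]


# --- permutation test vs brute-force oracle ---------------------------------


def _oracle_cluster_p(diffs, cluster_alpha=0.05):
    """Independent brute force: enumerate all 2^n sign assignments, compute
    max |cluster mass| by direct scanning of 1-channel runs."""
    n, _, T = diffs.shape
    thr = stats.t.ppf(1 - cluster_alpha / 2, n - 1)

    def max_mass(x):  # x: (n, T) signed data, single channel
        with np.errstate(divide="ignore", invalid="ignore"):
            t = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(n))
        finite = np.isfinite(t)
        cap = np.abs(t[finite]).max() if finite.any() else 1.0
        t = np.clip(np.nan_to_num(t, posinf=cap, neginf=-cap), -cap, cap)
        best = 0.0
        for sign in (1, -1):
            mass = 0.0
            for v in list(sign * t) + [0.0]:
                if v >= thr:
                    mass += v
                else:
                    best = max(best, mass)
                    mass = 0.0
        return best

    x = diffs[:, 0, :]
    masses = [max_mass(np.array(s)[:, None] * x)
              for s in itertools.product([1, -1], repeat=n)]
    masses = np.array(masses)
    obs = masses[0]
    return obs, float((masses >= obs - 1e-12).sum()) / len(masses)


def test_enumeration_agrees_with_brute_force_oracle():
    diffs = np.array(
        [[[1.0, 2, 3, 0, 0]], [[2, 1, 2, 0, 0]], [[1, 3, 1, 0, 0]],
         [[2, 2, 2, 0, 0]]])
    obs_mass, p_oracle = _oracle_cluster_p(diffs)
    res = cluster_mass_test(diffs, _chain(1),
                            TestSpec(n_permutations=5000, seed=0))
    assert res.mode == "enumerated"
    assert len(res.null_max_masses) == 16
    assert res.clusters[0].mass == pytest.approx(obs_mass)
    assert res.clusters[0].p == pytest.approx(p_oracle)


def test_oracle_agreement_on_random_instances(rng):
    for _ in range(5):
        diffs = rng.normal(0.5, 1.0, size=(5, 1, 8))
        obs_mass, p_oracle = _oracle_cluster_p(diffs)
        res = cluster_mass_test(diffs, _chain(1),
                                TestSpec(n_permutations=5000, seed=0))
        assert res.mode == "enumerated"
        if res.clusters:
            assert res.clusters[0].p == pytest.approx(p_oracle)
        else:
            assert obs_mass == 0.0


def test_sampled_p_converges_to_enumerated(rng):
    diffs = rng.normal(0.8, 1.0, size=(8, 2, 10))
    exact = cluster_mass_test(diffs, _chain(2),
                              TestSpec(n_permutations=2**8, seed=0))
    sampled = cluster_mass_test(diffs, _chain(2),
                                TestSpec(n_permutations=200, seed=3))
    assert exact.mode == "enumerated" and sampled.mode == "sampled"
    p_exact = exact.clusters[0].p
    p_sampled = sampled.clusters[0].p
    mc_sd = np.sqrt(p_exact * (1 - p_exact) / 200)
    assert abs(p_sampled - p_exact) <= 3 * mc_sd + 1 / 200


def test_all_zero_differences_give_no_clusters():
    res = cluster_mass_test(np.zeros((6, 2, 10)), _chain(2), TestSpec())
    assert res.clusters == []
    assert res.significant == []


def test_p_values_never_zero(rng):
    diffs = rng.normal(0, 1, size=(6, 2, 10)) + 5.0  # strong effect
    res = cluster_mass_test(diffs, _chain(2),
                            TestSpec(n_permutations=100, seed=0))
    assert res.clusters
    assert all(c.p >= 1 / len(res.null_max_masses) for c in res.clusters)
    assert all(c.p > 0 for c in res.clusters)


def test_scaling_up_never_raises_p(rng):
    diffs = rng.normal(0.4, 1.0, size=(7, 2, 12))
    spec = TestSpec(n_permutations=2**7, seed=0)
    p1 = cluster_mass_test(diffs, _chain(2), spec).clusters[0].p
    p2 = cluster_mass_test(3.0 * diffs, _chain(2), spec).clusters[0].p
    assert p2 <= p1 + 1e-12


def test_one_sided_thresholds_only_hypothesised_sign(rng):
    diffs = np.zeros((5, 1, 10))
    diffs[:, 0, 2:5] = -3.0
    diffs += rng.normal(0, 0.3, diffs.shape)
    res_pos = cluster_mass_test(diffs, _chain(1),
                                TestSpec(sidedness="one", tail=1,
                                         n_permutations=64, seed=0))
    res_neg = cluster_mass_test(diffs, _chain(1),
                                TestSpec(sidedness="one", tail=-1,
                                         n_permutations=64, seed=0))
    assert all(c.sign == 1 for c in res_pos.clusters)
    assert any(c.sign == -1 for c in res_neg.clusters)
    assert res_neg.clusters and res_neg.clusters[0].p < 0.2


def test_null_p_distribution_is_calibrated(rng):
    """Under exchangeable null data, corrected p-values are not anti-
    conservative: P(p <= .05) stays near or below .05."""
    hits = 0
    n_rep = 120
    for i in range(n_rep):
        diffs = rng.standard_normal((8, 3, 30))
        res = cluster_mass_test(diffs, _chain(3),
                                TestSpec(n_permutations=120, seed=i))
        if res.significant:
            hits += 1
    rate = hits / n_rep
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)
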