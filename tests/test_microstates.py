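"""Microstate segmentation: GFP, AAHC, map-count selection, back-fitting."""
import itertools

import numpy as np
import pandas as pd
import pytest

from seqerp.microstates import (
    aahc,
    aahc_concatenated,
    aahc_per_condition,
    backfit,
    compare_conditions,
    gfp,
    segment_stats,
    select_n_maps,
)
from seqerp.synthetic import simulate_microstate_erps


def _two_map_data(n=40, n_ch=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = np.zeros(n_ch)
    a[: n_ch // 2] = 1.0
    a -= a.mean()
    a /= np.linalg.norm(a)
    b = np.zeros(n_ch)
    b[:: 2] = 1.0
    b -= b.mean()
    b /= np.linalg.norm(b)
    b -= (b @ a) * a  # orthogonalise
    b /= np.linalg.norm(b)
    amps = rng.uniform(1.0, 3.0, n)
    which = np.arange(n) % 2
    X = np.where(which[:, None] == 0, amps[:, None] * a, amps[:, None] * b)
    X = X + rng.normal(0, noise, X.shape)
    return X, np.stack([a, b]), which


# --- GFP --------------------------------------------------------------------


def test_gfp_uniform_map_is_zero():
    assert gfp(np.full(10, 3.3)) == 0.0


def test_gfp_two_channel_example():
    assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)


def test_gfp_homogeneous_in_scale(rng):
    u = rng.normal(size=16)
    assert gfp(-2.5 * u) == pytest.approx(2.5 * gfp(u))


# --- AAHC -------------------------------------------------------------------


def test_aahc_recovers_two_orthogonal_generators():
    X, truth, which = _two_map_data()
    res = aahc(X, [2])
    assert res.explained_variance[2] == pytest.approx(1.0)
    # centroids match the generators up to sign and order
    match = np.abs(res.templates[2] @ truth.T)
    assert np.allclose(np.sort(match.max(axis=1)), 1.0)
    lab = res.labels[2]
    assert (np.all(lab == which) or np.all(lab == 1 - which))


def test_aahc_full_k_explains_everything(rng):
    X = rng.normal(size=(12, 6))
    res = aahc(X, [12])
    assert res.explained_variance[12] == pytest.approx(1.0)


def test_aahc_rejects_k_above_sample_count(rng):
    with pytest.raises(ValueError):
        aahc(rng.normal(size=(5, 4)), [6])


def test_aahc_explained_variance_monotone_in_k(rng):
    X = rng.normal(size=(60, 10))
    res = aahc(X, range(2, 20))
    evs = [res.explained_variance[k] for k in sorted(res.explained_variance)]
    assert all(b >= a - 1e-12 for a, b in zip(evs, evs[1:]))


def test_aahc_beats_exhaustive_random_bipartitions():
    """On a small instance the greedy AAHC solution explains at least as
    much variance as the best of all 2-partitions found by brute force."""
    X, _, _ = _two_map_data(n=8, n_ch=4, noise=0.4, seed=5)
    Xc = X - X.mean(axis=1, keepdims=True)
    total = (Xc**2).sum()

    def partition_ev(groups):
        expl = 0.0
        for g in groups:
            sub = Xc[list(g)]
            ref = sub[0]
            signs = np.sign(sub @ ref)
            signs[signs == 0] = 1
            c = (sub * signs[:, None]).mean(axis=0)
            nc = np.linalg.norm(c)
            if nc == 0:
                continue
            expl += ((sub @ (c / nc)) ** 2).sum()
        return expl / total

    best = 0.0
    idx = range(8)
    for r in range(1, 4 + 1):
        for combo in itertools.combinations(idx, r):
            rest = tuple(i for i in idx if i not in combo)
            best = max(best, partition_ev((combo, rest)))
    res = aahc(X, [2])
    assert res.explained_variance[2] >= best - 1e-9


def test_aahc_invariant_to_channel_permutation(rng):
    X = rng.normal(size=(30, 8))
    perm = rng.permutation(8)
    res_a = aahc(X, [3])
    res_b = aahc(X[:, perm], [3])
    assert np.array_equal(res_a.labels[3], res_b.labels[3])
    assert res_a.explained_variance[3] == pytest.approx(
        res_b.explained_variance[3])


# --- map-count selection ----------------------------------------------------


def test_select_recovers_twelve_generating_maps():
    erps, _ = simulate_microstate_erps(n_maps=12, noise_sd=0.15, seed=3)
    res = aahc_concatenated(erps, range(2, 21))
    assert select_n_maps(res, "cv") == 12
    assert select_n_maps(res, "kl") == 12
    assert select_n_maps(res, "meta") == 12


def test_select_single_generating_map():
    erps, _ = simulate_microstate_erps(n_maps=1, noise_sd=0.0, seed=0,
                                       n_conditions=1, n_times=60,
                                       segments_per_condition=1)
    res = aahc(np.asarray(erps["cond0"]).T, range(1, 6))
    assert select_n_maps(res, "cv") == 1


def test_selection_invariant_to_global_rescaling():
    erps, _ = simulate_microstate_erps(n_maps=5, noise_sd=0.1, seed=4,
                                       n_conditions=2, n_times=100)
    res_a = aahc_concatenated(erps, range(2, 10))
    scaled = {c: 7.5 * e for c, e in erps.items()}
    res_b = aahc_concatenated(scaled, range(2, 10))
    assert select_n_maps(res_a, "cv") == select_n_maps(res_b, "cv")


def test_per_condition_mode_returns_one_result_each():
    erps, _ = simulate_microstate_erps(n_maps=4, noise_sd=0.1, seed=1,
                                       n_conditions=3, n_times=60,
                                       segments_per_condition=3)
    per = aahc_per_condition(erps, [2, 3])
    assert set(per) == set(erps)
    for res in per.values():
        assert set(res.templates) == {2, 3}


# --- back-fitting and segment statistics ------------------------------------


def test_backfit_reproduces_generating_segmentation():
    erps, truth = simulate_microstate_erps(n_maps=6, noise_sd=0.0, seed=2,
                                           n_conditions=2, n_times=120)
    res = aahc_concatenated(erps, [6])
    seg = backfit(res.templates[6], erps["cond0"], polarity="ignore")
    assert seg.explained_variance == pytest.approx(1.0)
    # label identity up to template permutation: boundaries must agree
    truth_changes = np.flatnonzero(np.diff(truth["labels"]["cond0"]))
    seg_changes = np.flatnonzero(np.diff(seg.labels))
    assert np.array_equal(truth_changes, seg_changes)


def test_backfit_polarity_ignore_is_sign_invariant():
    erps, _ = simulate_microstate_erps(n_maps=4, noise_sd=0.05, seed=6,
                                       n_conditions=1, n_times=80,
                                       segments_per_condition=4)
    res = aahc(np.asarray(erps["cond0"]).T, [4])
    a = backfit(res.templates[4], erps["cond0"], polarity="ignore")
    b = backfit(res.templates[4], -erps["cond0"], polarity="ignore")
    assert np.array_equal(a.labels, b.labels)


def test_backfit_respect_leaves_anticorrelated_samples_unassigned():
    tm = np.array([[1.0, -1.0, 0.0, 0.0]])
    tm /= np.linalg.norm(tm)
    erp = np.array([[-1.0], [1.0], [0.0], [0.0]])  # exactly -template
    seg = backfit(tm, erp, polarity="respect")
    assert seg.labels[0] == -1


def test_segment_stats_onsets_and_durations():
    labels = np.array([0] * 25 + [1] * 25 + [0] * 10)
    times = np.arange(60) * 2.0 + 100.0
    from seqerp.microstates import Segmentation

    seg = Segmentation(labels, np.ones(60), 1.0, times)
    st = segment_stats(seg)
    runs0 = st[st["template"] == 0]
    assert list(runs0["onset"]) == [100.0, 200.0]  # split visits, in order
    assert list(runs0["duration"]) == [50.0, 20.0]
    run1 = st[st["template"] == 1].iloc[0]
    assert run1["onset"] == 150.0 and run1["duration"] == 50.0


def test_compare_conditions_welch():
    rows = []
    rng = np.random.default_rng(0)
    for pid in range(10):
        rows.append(dict(participant=pid, condition="STD", template=2,
                         onset=236.0, mean_gfp=rng.normal(3.0, 0.2)))
        rows.append(dict(participant=pid, condition="PE", template=2,
                         onset=284.0, mean_gfp=rng.normal(2.6, 0.6)))
    df = pd.DataFrame(rows)
    out = compare_conditions(df, 2, "STD", "PE", metric="gfp")
    assert out["t"] > 0 and 9 <= out["df"] <= 18
    equal = df.copy()
    equal["mean_gfp"] = 1.0
    out = compare_conditions(equal, 2, "STD", "PE", metric="gfp")
    assert out["t"] == 0.0
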