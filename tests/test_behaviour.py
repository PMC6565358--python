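"""Behavioural scoring: latencies, PR, ANOVA, subgroup statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seqerp.behaviour import (
    ResponseRecord,
    build_latency_table,
    classify_responses,
    compare_correlations,
    correlate_surprise_latency,
    fdr_bh,
    median_split_gain,
    offset_latency,
    onset_latency,
    rm_anova_2x3,
    window_release_counts,
)
from seqerp.task import TaskConfig, build_session


@pytest.fixture(scope="module")
def toy_session():
    cfg = TaskConfig(n_blocks_low=1, n_blocks_high=1, sequences_per_block=5,
                     composition_low=(0.2, 0.6, 0.2),
                     composition_high=(0.2, 0.6, 0.2))
    return build_session(cfg, seed=2)


def _press_for(session, seq, onset_lat=800.0, offset_lat=500.0, pid=0):
    dur = session.config.trial_duration
    press = (seq.start_index + 1) * dur + onset_lat
    release = (seq.start_index + seq.realized_length) * dur + offset_lat
    return ResponseRecord(pid, press, release)


def test_all_hits_perfect_pr(toy_session):
    resp = [_press_for(toy_session, s) for s in toy_session.sequences]
    out = classify_responses(toy_session, resp)
    row = out.iloc[0]
    assert row.hits == len(toy_session.sequences)
    assert row.misses == 0 and row.false_alarms == 0
    assert row.pr == pytest.approx(1.0)


def test_partial_hits_and_strays_counted(toy_session):
    seqs = toy_session.sequences
    resp = [_press_for(toy_session, s) for s in seqs[:-2]]
    # two stray presses far outside any attribution span (before first cue)
    first_cue = seqs[0].start_index * toy_session.config.trial_duration
    resp = ([ResponseRecord(0, first_cue - 900.0, first_cue - 800.0),
             ResponseRecord(0, first_cue - 700.0, first_cue - 600.0)]
            + resp)
    out = classify_responses(toy_session, resp).iloc[0]
    n = len(seqs)
    assert out.hits == n - 2
    assert out.misses == 2
    assert out.false_alarms == 2
    assert out.pr == pytest.approx((n - 2) / n - 2 / n)


def test_no_presses_all_missed(toy_session):
    out = classify_responses(toy_session, []).iloc[0]
    assert out.hits == 0
    assert out.misses == len(toy_session.sequences)
    assert out.pr == pytest.approx(0.0)


def test_overlapping_presses_rejected(toy_session):
    resp = [ResponseRecord(0, 1000.0, 2000.0), ResponseRecord(0, 1500.0, 2500.0)]
    with pytest.raises(ValueError, match="overlapping"):
        classify_responses(toy_session, resp)


def test_onset_latency_relative_to_second_trial(toy_session):
    seq = toy_session.sequences[0]
    dur = toy_session.config.trial_duration
    second = (seq.start_index + 1) * dur
    r = ResponseRecord(0, second, second + 3000.0)
    assert onset_latency(seq, r, toy_session) == 0.0
    r = ResponseRecord(0, second + 788.0, second + 3000.0)
    assert onset_latency(seq, r, toy_session) == pytest.approx(788.0)
    # press during the cue trial: negative onset latency, retained
    r = ResponseRecord(0, second - 200.0, second + 3000.0)
    assert onset_latency(seq, r, toy_session) == pytest.approx(-200.0)


@pytest.mark.parametrize(
    "offset,excluded",
    [(0.0, False), (2100.0, True), (-300.0, False), (-600.0, True),
     (2000.0, False)],
)
def test_offset_latency_and_exclusion_rule(toy_session, offset, excluded):
    seq = toy_session.sequences[0]
    dur = toy_session.config.trial_duration
    ref = (seq.start_index + seq.realized_length) * dur
    r = ResponseRecord(0, seq.start_index * dur + 100.0, ref + offset)
    lat, excl = offset_latency(seq, r, toy_session)
    assert lat == pytest.approx(offset)
    assert excl == excluded


def test_latency_table_counts_and_nan_for_misses(toy_session):
    seqs = toy_session.sequences
    resp = [_press_for(toy_session, s) for s in seqs[:-1]]
    table = build_latency_table(toy_session, resp)
    assert len(table) == len(seqs)
    assert table["onset_latency"].isna().sum() == 1
    hit = table.dropna(subset=["offset_latency"])
    assert np.allclose(hit["offset_latency"], 500.0)
    assert np.allclose(hit["onset_latency"], 800.0)


# --- repeated-measures ANOVA ------------------------------------------------


def _anova_table(n=5, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        base = rng.normal(500, 50)
        for unc in ("low", "high"):
            for i, comp in enumerate(("terminated", "regular", "extended")):
                val = base + effect * i + rng.normal(0, 30)
                rows.append(dict(participant=pid, uncertainty=unc,
                                 compliance=comp, offset_latency=val,
                                 excluded=False))
    return pd.DataFrame(rows)


def test_rm_anova_identical_cells_give_zero_f():
    df = _anova_table(effect=0.0, seed=1)
    df["offset_latency"] = 100.0
    out = rm_anova_2x3(df)
    assert np.allclose(out["F"], 0.0)
    assert np.all(out["p"] == 1.0)


def test_rm_anova_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    df = _anova_table(n=5, seed=3, effect=40.0)
    ours = rm_anova_2x3(df).set_index("effect")
    theirs = pingouin.rm_anova(
        data=df, dv="offset_latency", within=["uncertainty", "compliance"],
        subject="participant", detailed=True)
    mapping = {"uncertainty": "uncertainty", "compliance": "compliance",
               "uncertainty * compliance": "uncertainty x compliance"}
    for pg_name, our_name in mapping.items():
        row = theirs[theirs["Source"] == pg_name].iloc[0]
        assert ours.loc[our_name, "F"] == pytest.approx(row["F"], rel=1e-6)
        assert ours.loc[our_name, "p"] == pytest.approx(row["p_unc"], rel=1e-6)


def test_rm_anova_dfs_for_thirty_participants():
    df = _anova_table(n=30, seed=4, effect=20.0)
    out = rm_anova_2x3(df).set_index("effect")
    assert (out.loc["compliance", "df1"], out.loc["compliance", "df2"]) == (2, 58)
    assert (out.loc["uncertainty", "df1"], out.loc["uncertainty", "df2"]) == (1, 29)


def test_rm_anova_null_pvalues_roughly_uniform():
    """Calibration: with no true effects, p-values are uniform on [0, 1]."""
    from scipy import stats

    ps = [rm_anova_2x3(_anova_table(n=8, seed=s)).set_index("effect")
          .loc["compliance", "p"] for s in range(120)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_rm_anova_requires_two_participants():
    df = _anova_table(n=1)
    with pytest.raises(ValueError):
        rm_anova_2x3(df)


# --- FDR --------------------------------------------------------------------


def test_fdr_bh_hand_example():
    out = fdr_bh([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_fdr_bh_edge_cases():
    assert fdr_bh([0.37]) == pytest.approx([0.37])
    assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
@settings(max_examples=60, deadline=None)
def test_fdr_bh_monotone_bounded_and_conservative(ps):
    adj = fdr_bh(ps)
    assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(ps) - 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order
    # reapplication can only be more conservative, and tied inputs (hence
    # any fully adjusted flat vector) are fixed points
    again = fdr_bh(adj)
    assert np.all(again >= adj - 1e-12)
    if np.ptp(adj) == 0:
        assert np.allclose(again, adj)


# --- subgroup pipeline ------------------------------------------------------


def _post_table(scores):
    rows = []
    for pid, score in enumerate(scores):
        rows.append(dict(participant=pid, cued_colour="learned",
                         onset_latency=800.0, excluded=False))
        rows.append(dict(participant=pid, cued_colour="new",
                         onset_latency=800.0 + score, excluded=False))
    return pd.DataFrame(rows)


def test_median_split_equal_groups_of_fifteen():
    rng = np.random.default_rng(0)
    groups = median_split_gain(_post_table(rng.normal(50, 100, 30)))
    assert (groups["group"] == "gain").sum() == 15
    assert (groups["group"] == "no_gain").sum() == 15


def test_median_split_hand_example():
    groups = median_split_gain(_post_table([-50.0, 0.0, 100.0, 200.0]))
    got = dict(zip(groups["participant"], groups["group"]))
    assert got == {0: "no_gain", 1: "no_gain", 2: "gain", 3: "gain"}
    assert groups.attrs["median"] == pytest.approx(50.0)


def test_median_split_all_tied_is_deterministic():
    a = median_split_gain(_post_table([10.0] * 6))
    b = median_split_gain(_post_table([10.0] * 6))
    assert a.equals(b)
    sizes = a["group"].value_counts()
    assert abs(sizes.get("gain", 0) - sizes.get("no_gain", 0)) <= 1


def test_perfect_linear_relation_gives_r_minus_one():
    rows = []
    for i in range(10):
        rows.append(dict(participant=0, compliance="extended", excluded=False,
                         I=float(i), offset_latency=1000.0 - 50.0 * i))
    r, df = correlate_surprise_latency(pd.DataFrame(rows), [0])
    assert r == pytest.approx(-1.0)
    assert df == 8


def test_zero_variance_correlation_rejected():
    rows = [dict(participant=0, compliance="extended", excluded=False,
                 I=1.0, offset_latency=float(i)) for i in range(6)]
    with pytest.raises(ValueError, match="variance"):
        correlate_surprise_latency(pd.DataFrame(rows), [0])


def test_fisher_z_group_comparison():
    z, p = compare_correlations(-0.29, 74, 0.06, 74)
    assert abs(z) == pytest.approx(2.14, abs=0.05)
    assert p == pytest.approx(0.016, abs=0.005)
    z0, p0 = compare_correlations(0.4, 30, 0.4, 30)
    assert z0 == 0.0 and p0 == pytest.approx(0.5)


def test_window_release_counts_binning():
    rows = [dict(participant=0, offset_latency=v, excluded=False)
            for v in (-950.0, -50.0, 499.0)]
    out = window_release_counts(pd.DataFrame(rows), (-1000.0, 500.0), 100.0)
    total = out[out.get("total", False)]
    assert total["count"].iloc[0] == 3
    bins = out[~out.get("total", False)]
    hot = bins[bins["count"] > 0]
    assert set(hot["bin_lo"]) == {-1000.0, -100.0, 400.0}
    assert (hot["count"] == 1).all()


def test_window_release_counts_empty_window():
    rows = [dict(participant=0, offset_latency=900.0, excluded=False)]
    out = window_release_counts(pd.DataFrame(rows), (-500.0, 500.0), 100.0)
    assert (out["count"] == 0).all()


def test_window_endpoints_must_align_with_bins():
    with pytest.raises(ValueError):
        window_release_counts(pd.DataFrame(
            [dict(participant=0, offset_latency=0.0, excluded=False)]),
            (-450.0, 500.0), 100.0)
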