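"""Behavioural scoring and statistics.

Participants hold a button for the duration of each detected ordered
sequence.  This module scores press/release streams against the generated
stream (hits, misses, false alarms, the two-high-threshold discrimination
index PR = hit rate - false-alarm rate), derives per-sequence latencies,

- *onset latency*: press time relative to the onset of the second trial of
  the sequence (the earliest point at which a pattern is detectable),
- *offset latency*: release time relative to the onset of the first random
  trial after the sequence (releases before -500 ms or after +2000 ms are
  flagged excluded),

and runs the study-level statistics: a 2 (uncertainty) x 3 (expectation
compliance) within-subject ANOVA on offset latency, Benjamini-Hochberg FDR
correction, the post-session median split into cue-learning *gain* /
*no gain* subgroups, pooled surprise-latency correlations with a Fisher-z
group comparison, and windowed release counts around sequence ends.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .observer import score_session
from .task import Session, SequenceInstance

__all__ = [
    "ResponseRecord",
    "classify_responses",
    "onset_latency",
    "offset_latency",
    "build_latency_table",
    "rm_anova_2x3",
    "fdr_bh",
    "median_split_gain",
    "correlate_surprise_latency",
    "compare_correlations",
    "window_release_counts",
]

OFFSET_EXCLUDE_LO = -500.0  # ms, releases earlier than this are excluded
OFFSET_EXCLUDE_HI = 2000.0  # ms, releases later than this are excluded
GRACE_MS = 2000.0  # attribution window after the sequence end


@dataclass(frozen=True)
class ResponseRecord:
    participant: int
    press_time: float  # ms
    release_time: float  # ms

    def __post_init__(self):
        if not self.release_time > self.press_time:
            raise ValueError("release_time must be later than press_time")


def _sequence_span(seq: SequenceInstance, session: Session) -> tuple[float, float]:
    """Half-open attribution span [cue onset, offset reference + grace)."""
    dur = session.config.trial_duration
    cue_onset = seq.start_index * dur
    offset_ref = (seq.start_index + seq.realized_length) * dur
    return cue_onset, offset_ref + GRACE_MS


def _offset_reference(seq: SequenceInstance, session: Session) -> float:
    """Onset (ms) of the first random trial after the sequence."""
    return (seq.start_index + seq.realized_length) * session.config.trial_duration


def _check_sorted(responses: list[ResponseRecord]) -> None:
    by_pp: dict[int, float] = {}
    for r in responses:
        last = by_pp.get(r.participant)
        if last is not None and r.press_time < last:
            raise ValueError(
                f"overlapping presses for participant {r.participant}"
            )
        by_pp[r.participant] = r.release_time


def attribute_presses(session: Session, responses: list[ResponseRecord]
                      ) -> tuple[dict[int, list[ResponseRecord]], list[ResponseRecord]]:
    """Map sequence index -> attributed presses; second element = false alarms."""
    _check_sorted(responses)
    spans = [_sequence_span(s, session) for s in session.sequences]
    hits: dict[int, list[ResponseRecord]] = {i: [] for i in range(len(spans))}
    strays: list[ResponseRecord] = []
    for r in responses:
        for i, (lo, hi) in enumerate(spans):
            if lo <= r.press_time < hi:
                hits[i].append(r)
                break
        else:
            strays.append(r)
    return hits, strays


def classify_responses(session: Session, responses: list[ResponseRecord],
                       by_uncertainty: bool = False) -> pd.DataFrame:
    """Hits / misses / false alarms and PR per participant.

    A sequence with at least one press inside its span (cue onset to end
    plus a 2000 ms grace window) counts as a hit; presses attributable to no
    sequence are false alarms.  The false-alarm rate denominator is the
    number of inter-sequence random gaps (one opportunity per sequence), the
    natural unit in which a spurious press could occur.
    """
    pids = sorted({r.participant for r in responses}) or [0]
    rows = []
    for pid in pids:
        resp = [r for r in responses if r.participant == pid]
        hit_map, strays = attribute_presses(session, resp)
        groups: dict[str, list[int]]
        if by_uncertainty:
            unc = dict(session.blocks)
            groups = {u: [] for u in ("low", "high")}
            for i, s in enumerate(session.sequences):
                groups[unc[s.block]].append(i)
        else:
            groups = {"all": list(range(len(session.sequences)))}
        for gname, idx in groups.items():
            n_seq = len(idx)
            hits = sum(1 for i in idx if hit_map[i])
            misses = n_seq - hits
            # false alarms cannot be split by uncertainty-specific sequences;
            # attribute them to the block they occur in
            if by_uncertainty:
                unc_map = dict(session.blocks)
                fa = sum(
                    1 for r in strays
                    if unc_map[_block_at(session, r.press_time)] == gname
                )
            else:
                fa = len(strays)
            n_fa_opp = n_seq if n_seq else 1
            pr = (hits / n_seq if n_seq else 0.0) - fa / n_fa_opp
            rows.append(
                dict(participant=pid, scope=gname, n_sequences=n_seq, hits=hits,
                     misses=misses, false_alarms=fa, pr=pr)
            )
    return pd.DataFrame(rows)


def _block_at(session: Session, t_ms: float) -> int:
    idx = min(int(t_ms // session.config.trial_duration), session.n_trials - 1)
    return session.trials[max(idx, 0)].block


def onset_latency(seq: SequenceInstance, response: ResponseRecord,
                  session: Session) -> float:
    """Press time minus the onset of the sequence's second trial (ms)."""
    dur = session.config.trial_duration
    return response.press_time - (seq.start_index + 1) * dur


def offset_latency(seq: SequenceInstance, response: ResponseRecord,
                   session: Session) -> tuple[float, bool]:
    """(offset latency ms, excluded flag) for a hit sequence's release."""
    lat = response.release_time - _offset_reference(seq, session)
    excluded = lat < OFFSET_EXCLUDE_LO or lat > OFFSET_EXCLUDE_HI
    return lat, excluded


def build_latency_table(session: Session, responses: list[ResponseRecord],
                        surprise_scope: str = "block") -> pd.DataFrame:
    """Per-sequence latency table across all participants in ``responses``.

    Columns: participant, sequence, block, uncertainty, compliance,
    cue_type, cued_colour, onset_latency, offset_latency, I (surprise in
    nats under ``surprise_scope``), excluded.  Missed sequences appear with
    NaN latencies.
    """
    recs = score_session(session, scope=surprise_scope)
    I = {r.sequence: r.I for r in recs}
    unc = dict(session.blocks)
    pids = sorted({r.participant for r in responses}) or [0]
    rows = []
    for pid in pids:
        resp = [r for r in responses if r.participant == pid]
        hit_map, _ = attribute_presses(session, resp)
        for si, seq in enumerate(session.sequences):
            presses = hit_map[si]
            if presses:
                first = presses[0]
                on = onset_latency(seq, first, session)
                off, excl = offset_latency(seq, presses[-1], session)
            else:
                on = off = math.nan
                excl = True
            rows.append(
                dict(participant=pid, sequence=si, block=seq.block,
                     uncertainty=unc[seq.block], compliance=seq.compliance,
                     cue_type=seq.cue_type, cued_colour=seq.cued_colour,
                     onset_latency=on, offset_latency=off, I=I[si],
                     excluded=excl)
            )
    return pd.DataFrame(rows)


def rm_anova_2x3(table: pd.DataFrame, dv: str = "offset_latency",
                 within=("uncertainty", "compliance"),
                 subject: str = "participant") -> pd.DataFrame:
    """Two-way fully within-subject ANOVA from the classical SS decomposition.

    Cell means are formed per participant; participants with any empty cell
    are dropped.  Each effect is tested against its own participant-by-effect
    interaction (F(a-1, (a-1)(n-1)) etc.).  Returns a tidy frame with one
    row per effect: effect, F, df1, df2, p.
    """
    fa, fb = within
    cells = (
        table.dropna(subset=[dv])
        .groupby([subject, fa, fb], observed=True)[dv]
        .mean()
        .reset_index()
    )
    a_levels = sorted(cells[fa].unique())
    b_levels = sorted(cells[fb].unique())
    a, b = len(a_levels), len(b_levels)
    wide = cells.pivot_table(index=subject, columns=[fa, fb], values=dv)
    wide = wide.dropna()
    n = len(wide)
    if n < 2:
        raise ValueError("need at least 2 participants with complete cells")
    Y = wide.to_numpy().reshape(n, a, b)  # pivot columns sort lexicographically

    gm = Y.mean()
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_s = Y.mean(axis=(1, 2))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_s = a * b * np.sum((m_s - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    ss_tot = np.sum((Y - gm) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_s - ss_ab - ss_as - ss_bs

    def effect(name, ss, df1, ss_err, df2):
        ms, ms_err = ss / df1, ss_err / df2
        f = 0.0 if ms_err == 0 and ms == 0 else ms / ms_err
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return dict(effect=name, F=float(f), df1=df1, df2=df2, p=p)

    rows = [
        effect(fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        effect(fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        effect(f"{fa} x {fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
               (a - 1) * (b - 1) * (n - 1)),
    ]
    return pd.DataFrame(rows)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_split_gain(post_table: pd.DataFrame) -> pd.DataFrame:
    """Median-split participants by post-session cue-learning gain.

    The gain score is mean onset latency to *new* cues minus mean onset
    latency to *learned* cues (positive = faster to learned cues).  Scores
    strictly above the median form the *gain* group; scores below form
    *no gain*; participants tied exactly at the median are assigned to
    no-gain first and promoted in stable participant-id order only as far
    as needed to keep group sizes within one of each other.
    """
    means = (
        post_table.dropna(subset=["onset_latency"])
        .groupby(["participant", "cued_colour"], observed=True)["onset_latency"]
        .mean()
        .unstack("cued_colour")
    )
    missing = means.index[means.isna().any(axis=1)]
    if len(missing):
        import warnings

        warnings.warn(
            f"dropping participants without both cue conditions: {list(missing)}"
        )
        means = means.dropna()
    gain = (means["new"] - means["learned"]).rename("gain_score")
    med = float(gain.median())
    group = pd.Series("no_gain", index=gain.index, name="group")
    group[gain > med] = "gain"
    tied = sorted(gain.index[gain == med])
    target_gain = len(gain) // 2
    for pid in tied:
        if (group == "gain").sum() >= target_gain:
            break
        group[pid] = "gain"
    out = pd.DataFrame({"gain_score": gain, "group": group})
    out.attrs["median"] = med
    return out.reset_index()


def correlate_surprise_latency(latency_table: pd.DataFrame,
                               group_pids,
                               compliance: str = "extended") -> tuple[float, int]:
    """Pooled Pearson r between surprise I and offset latency for one group.

    Trials (default: extended sequences) of all participants in the group
    are pooled into one set of (I, offset latency) pairs; returns (r, df)
    with df = n_pairs - 2.
    """
    sub = latency_table[
        latency_table["participant"].isin(list(group_pids))
        & (latency_table["compliance"] == compliance)
        & (~latency_table["excluded"])
    ].dropna(subset=["offset_latency"])
    if len(sub) < 4:
        raise ValueError("need at least 4 (I, latency) pairs")
    x = sub["I"].to_numpy()
    y = sub["offset_latency"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(sub) - 2


def compare_correlations(r1: float, n1: int, r2: float, n2: int
                         ) -> tuple[float, float]:
    """Fisher-z comparison of two independent correlations.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the returned p is
    one-tailed (normal upper tail of |Z|).
    """
    if min(n1, n2) < 4:
        raise ValueError("need n > 3 in both groups")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(stats.norm.sf(abs(z)))
    return z, p


def window_release_counts(latency_table: pd.DataFrame,
                          window: tuple[float, float] = (-1000.0, 500.0),
                          bin_ms: float = 100.0,
                          by: str = "participant") -> pd.DataFrame:
    """Counts of releases whose offset latency falls in [lo, hi), binned.

    Returns one row per (``by`` value, bin) with columns bin_lo, bin_hi,
    count, plus the window total per group under bin label ``total``.
    Window endpoints must be multiples of ``bin_ms``.
    """
    lo, hi = window
    if (lo % bin_ms) or (hi % bin_ms):
        raise ValueError("window endpoints must be multiples of bin_ms")
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    sub = latency_table.dropna(subset=["offset_latency"])
    rows = []
    for key, grp in sub.groupby(by, observed=True):
        lat = grp["offset_latency"].to_numpy()
        in_win = (lat >= lo) & (lat < hi)
        counts, _ = np.histogram(lat[in_win], bins=edges)
        for blo, c in zip(edges[:-1], counts):
            rows.append({by: key, "bin_lo": blo, "bin_hi": blo + bin_ms,
                         "count": int(c)})
        rows.append({by: key, "bin_lo": lo, "bin_hi": hi,
                     "count": int(in_win.sum()), "total": True})
    out = pd.DataFrame(rows)
    if "total" in out.columns:
        out["total"] = out["total"].astype("boolean").fillna(False).astype(bool)
    return out
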