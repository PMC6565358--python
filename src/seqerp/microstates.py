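"""Topographic microstate segmentation of group ERPs.

ERP scalp maps are clustered into a small set of template topographies with
the AAHC (atomize-and-agglomerate hierarchical clustering) algorithm: every
time sample starts as its own cluster, and the cluster contributing least
globally explained variance is repeatedly dissolved, its members reassigned
to the remaining cluster with the highest squared spatial correlation,
until the requested number of templates remains.  The number of maps is
chosen by a cross-validation criterion

    CV(K) = sigma2_K * ((C - 1) / (C - 1 - K))**2,

with sigma2_K the residual variance and C the channel count; a
Krzanowski-Lai criterion and a median "meta" vote over both are available.
Selected templates are fitted back to each condition's ERP sample by
sample, yielding segment onsets/durations and per-template mean global
field power (GFP, the spatial standard deviation of an average-referenced
map), compared across conditions with Welch t-tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gfp",
    "AAHCResult",
    "aahc",
    "select_n_maps",
    "backfit",
    "Segmentation",
    "segment_stats",
    "compare_conditions",
]


def gfp(maps: np.ndarray) -> np.ndarray:
    """Global field power: spatial (population) SD over channels.

    ``maps`` is (..., channels); returns the GFP of each map.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[-1] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return maps.std(axis=-1)


def _avg_ref(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v if n == 0 else v / n


def _centroid(members: np.ndarray, X: np.ndarray, polarity: str) -> np.ndarray:
    """Normalised mean of member maps (sign-aligned to the first member)."""
    sub = X[members]
    if polarity == "ignore" and len(members) > 1:
        ref = sub[0]
        signs = np.sign(sub @ ref)
        signs[signs == 0] = 1.0
        sub = sub * signs[:, None]
    return _normalize(sub.mean(axis=0))


@dataclass
class AAHCResult:
    templates: dict  # K -> (K, C) unit-norm centroids
    labels: dict  # K -> (T,) template index per sample
    explained_variance: dict  # K -> fraction in [0, 1]
    residual_variance: dict  # K -> sigma2_K
    n_channels: int


def aahc(X: np.ndarray, k_range, polarity: str = "ignore") -> AAHCResult:
    """AAHC descent over time x channel maps, snapshotting each K in range.

    ``X`` is (samples, channels), average-referenced; samples may be the
    concatenation of several conditions.  ``polarity='ignore'`` (the
    topographic-clustering convention) assigns by squared spatial
    correlation and sign-aligns members before averaging;
    ``polarity='respect'`` uses signed correlation.
    """
    X = _avg_ref(np.asarray(X, dtype=float))
    n, n_ch = X.shape
    ks = sorted(set(int(k) for k in np.atleast_1d(k_range)))
    if ks[0] < 1:
        raise ValueError("K must be >= 1")
    if ks[-1] > n:
        raise ValueError("K cannot exceed the number of samples")
    total_ss = float((X**2).sum())

    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    centroids = [_normalize(X[i]) for i in range(n)]
    # per-cluster contribution to globally explained SS: sum_t (x_t . c)^2
    contrib = [float((X[i] @ centroids[i]) ** 2) for i in range(n)]

    result = AAHCResult({}, {}, {}, {}, n_ch)

    def snapshot(k: int) -> None:
        labels = np.empty(n, dtype=int)
        for ci, m in enumerate(members):
            labels[m] = ci
        cent = np.stack(centroids)
        expl = sum(contrib) / total_ss if total_ss else 1.0
        result.templates[k] = cent
        result.labels[k] = labels
        result.explained_variance[k] = float(expl)
        result.residual_variance[k] = max(0.0, float(
            (total_ss - sum(contrib)) / (n * (n_ch - 1))))

    if n in ks:
        snapshot(n)
    while len(members) > ks[0]:
        worst = int(np.argmin(contrib))
        freed = members.pop(worst)
        centroids.pop(worst)
        contrib.pop(worst)
        cent = np.stack(centroids)
        corr = X[freed] @ cent.T  # cosine similarity (all unit-norm, 0-mean)
        score = corr**2 if polarity == "ignore" else corr
        target = np.argmax(score, axis=1)
        touched = set()
        for s, tgt in zip(freed, target):
            members[tgt] = np.append(members[tgt], s)
            touched.add(int(tgt))
        for ci in touched:
            centroids[ci] = _centroid(members[ci], X, polarity)
            contrib[ci] = float(((X[members[ci]] @ centroids[ci]) ** 2).sum())
        if len(members) in ks:
            snapshot(len(members))
    return result


def aahc_concatenated(erps: dict, k_range, polarity: str = "ignore"
                      ) -> AAHCResult:
    """AAHC over the concatenated (time x condition) maps of several ERPs.

    This is the default segmentation mode: one shared template pool
    describing all conditions, selected on the pooled description.
    """
    conds = sorted(erps)
    X = np.concatenate([np.asarray(erps[c]).T for c in conds], axis=0)
    return aahc(X, k_range, polarity)


def aahc_per_condition(erps: dict, k_range, polarity: str = "ignore"
                       ) -> dict:
    """Alternative mode: an independent AAHC descent per condition.

    Returns condition -> AAHCResult; template pools can afterwards be
    merged and back-fitted condition by condition.
    """
    return {c: aahc(np.asarray(e).T, k_range, polarity)
            for c, e in erps.items()}


def select_n_maps(result: AAHCResult, method: str = "cv") -> int:
    """Optimal template count from an evaluated K range.

    ``cv`` minimises the cross-validation criterion, ``kl`` maximises the
    Krzanowski-Lai curvature index, ``meta`` takes the median of the
    criteria's choices.  Ks at or above C - 1 are excluded (the CV penalty
    degenerates there).
    """
    C = result.n_channels
    ks = sorted(k for k in result.residual_variance if k < C - 1)
    if not ks:
        raise ValueError("no admissible K below n_channels - 1")
    if method == "cv":
        cv = {
            k: result.residual_variance[k] * ((C - 1) / (C - 1 - k)) ** 2
            for k in ks
        }
        return min(ks, key=lambda k: (cv[k], k))
    if method == "kl":
        return _krzanowski_lai(result, ks)
    if method == "meta":
        votes = sorted([select_n_maps(result, "cv"),
                        select_n_maps(result, "kl")])
        return int(np.floor(np.median(votes)))
    raise ValueError(f"unknown method {method!r}")


def _krzanowski_lai(result: AAHCResult, ks) -> int:
    C = result.n_channels
    w = {k: result.residual_variance[k] for k in ks}
    diff = {}
    for k in ks:
        if (k - 1) in w:
            diff[k] = (k - 1) ** (2 / C) * w[k - 1] - k ** (2 / C) * w[k]
    kl = {}
    for k in ks:
        if k in diff and (k + 1) in diff and diff[k + 1] != 0:
            kl[k] = abs(diff[k] / diff[k + 1])
    if not kl:
        return min(ks)
    return max(kl, key=lambda k: (kl[k], -k))


@dataclass
class Segmentation:
    labels: np.ndarray  # template id per sample (-1 = unassigned)
    gfp: np.ndarray
    explained_variance: float
    times: np.ndarray


def backfit(templates: np.ndarray, erp: np.ndarray,
            times: np.ndarray | None = None,
            polarity: str = "respect",
            min_duration: int = 1) -> Segmentation:
    """Label each time sample with its best-matching template.

    ``templates`` is (K, channels) unit-norm; ``erp`` is (channels, times).
    ``polarity='respect'`` (the ERP convention) assigns by signed spatial
    correlation and leaves samples unassigned when no template correlates
    positively; ``'ignore'`` uses squared correlation, making labels
    invariant to flipping the ERP's sign.  Runs shorter than
    ``min_duration`` samples are merged into the neighbouring run with the
    higher correlation (off by default).
    """
    erp = np.asarray(erp, dtype=float)
    T = erp.shape[1]
    if times is None:
        times = np.arange(T, dtype=float)
    templates = np.asarray(templates, dtype=float)
    norm_maps = _avg_ref(erp.T)  # average reference across channels
    norms = np.linalg.norm(norm_maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = (norm_maps / norms) @ templates.T  # (T, K)
    if polarity == "ignore":
        labels = np.argmax(corr**2, axis=1)
        fit = corr[np.arange(T), labels] ** 2
    else:
        labels = np.argmax(corr, axis=1)
        fit = corr[np.arange(T), labels]
        labels = np.where(fit > 0, labels, -1)
        fit = np.clip(fit, 0, None) ** 2
    if min_duration > 1:
        labels = _enforce_min_duration(labels, corr, min_duration, polarity)
        fit = np.where(labels >= 0,
                       corr[np.arange(T), np.clip(labels, 0, None)] ** 2, 0.0)
    ss = (np.linalg.norm(norm_maps, axis=1) ** 2)
    ev = float((fit * ss).sum() / ss.sum()) if ss.sum() else 1.0
    return Segmentation(labels, gfp(norm_maps), ev, np.asarray(times))


def _enforce_min_duration(labels, corr, min_duration, polarity):
    labels = labels.copy()
    score = corr**2 if polarity == "ignore" else corr
    changed = True
    while changed:
        changed = False
        for start, end, lab in _runs(labels):
            if lab < 0 or end - start >= min_duration:
                continue
            left = labels[start - 1] if start > 0 else None
            right = labels[end] if end < len(labels) else None
            cands = [c for c in (left, right) if c is not None and c >= 0]
            if not cands:
                continue
            seg_scores = {c: score[start:end, c].sum() for c in set(cands)}
            labels[start:end] = max(seg_scores, key=seg_scores.get)
            changed = True
    return labels


def _runs(labels: np.ndarray):
    """Yield (start, end, label) maximal runs (end exclusive)."""
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield start, i, int(labels[start])
            start = i


def segment_stats(seg: Segmentation) -> pd.DataFrame:
    """Onset, duration and mean GFP of every template visit.

    Templates can appear in several separate runs; each run yields a row,
    in temporal order (matching split notations like "236 | 368").
    """
    if len(seg.times) > 1:
        step = float(seg.times[1] - seg.times[0])
    else:
        step = 1.0
    rows = []
    for start, end, lab in _runs(seg.labels):
        if lab < 0:
            continue
        rows.append(
            dict(template=lab, onset=float(seg.times[start]),
                 duration=(end - start) * step,
                 mean_gfp=float(seg.gfp[start:end].mean()))
        )
    return pd.DataFrame(rows, columns=["template", "onset", "duration",
                                       "mean_gfp"])


def compare_conditions(per_participant: pd.DataFrame, template: int,
                       cond_a: str, cond_b: str, metric: str = "gfp",
                       one_sided: bool = True) -> dict:
    """Welch t-test comparing a template's metric between two conditions.

    ``per_participant`` needs columns participant, condition, template, and
    the metric columns ``onset`` / ``mean_gfp``.  Participants in whom the
    template never appears for a condition are excluded for that condition
    (first visit is used when a template appears repeatedly).  Returns a
    dict with t, df (Satterthwaite), p, and the per-group n.
    """
    col = {"gfp": "mean_gfp", "onset": "onset"}[metric]
    sub = per_participant[per_participant["template"] == template]
    first = (sub.sort_values("onset")
             .groupby(["participant", "condition"], observed=True)
             .first().reset_index())
    a = first.loc[first["condition"] == cond_a, col].to_numpy(float)
    b = first.loc[first["condition"] == cond_b, col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 participants per condition")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        # degenerate equal groups: no evidence either way
        return dict(t=0.0, df=float(len(a) + len(b) - 2), p=0.5, n_a=len(a),
                    n_b=len(b), template=template, metric=metric)
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if one_sided:
        p = p / 2 if t >= 0 else 1 - p / 2
    return dict(t=t, df=float(res.df), p=p, n_a=len(a), n_b=len(b),
                template=template, metric=metric)
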