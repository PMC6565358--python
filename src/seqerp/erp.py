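"""Epoching, artifact handling, referencing, and averaging.

The preprocessing chain mirrors a conventional ERP pipeline: zero-phase
0.1-30 Hz band-pass, epoching into [-100, 600) ms windows with [-100, 0) ms
baseline subtraction, epoch rejection on absolute amplitude (+-200 uV) and
sample-to-sample steps (50 uV), kurtosis-based channel interpolation
(z > 6 across channels, replaced by the unweighted neighbour mean), common
average reference, then per-participant and grand averaging.  Every stage
is pure: inputs are never modified in place.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "EpochSet",
    "ERPSet",
    "bandpass_filter",
    "epoch_data",
    "reject_artifacts",
    "interpolate_channels",
    "rereference_average",
    "average_erp",
    "grand_average",
]

DEFAULT_WINDOW = (-100.0, 600.0)  # ms, half-open
DEFAULT_BASELINE = (-100.0, 0.0)


@dataclass
class EpochSet:
    """Epochs x channels x time (uV) with labels and channel geometry."""

    data: np.ndarray  # (n_epochs, n_channels, n_times)
    times: np.ndarray  # ms, uniform grid
    channels: list[str]
    coords: np.ndarray  # (n_channels, 2)
    labels: list[str]  # condition per epoch
    participant: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, times)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must equal epoch count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time-point count mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / float(self.times[1] - self.times[0])

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(),
                        list(self.channels), self.coords.copy(),
                        list(self.labels), self.participant)


@dataclass
class ERPSet:
    """Condition -> channels x time average, with epoch counts."""

    erps: dict[str, np.ndarray]
    n_epochs: dict[str, int]
    times: np.ndarray
    channels: list[str]
    coords: np.ndarray
    level: str = "participant"  # {"participant", "grand"}
    participant: int | None = None


def bandpass_filter(data: np.ndarray, sfreq: float,
                    low: float = 0.1, high: float = 30.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis (removes DC).

    High-pass and low-pass stages are designed separately and cascaded;
    with cut-offs three decades apart (0.1 / 30 Hz) a single band-pass
    design is numerically ill-conditioned.
    """
    nyq = sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("need 0 < low < high < Nyquist")
    hp = signal.butter(order, low, btype="highpass", fs=sfreq, output="sos")
    lp = signal.butter(order, high, btype="lowpass", fs=sfreq, output="sos")
    sos = np.vstack([hp, lp])
    data = np.asarray(data, dtype=float)
    # the 0.1 Hz stage rings for seconds: pad generously to keep edge
    # transients out of the record
    padlen = int(min(data.shape[-1] - 1, 3 * sfreq / low))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def epoch_data(continuous: np.ndarray, sfreq: float, event_samples,
               labels, channels, coords,
               window: tuple[float, float] = DEFAULT_WINDOW,
               baseline: tuple[float, float] | None = DEFAULT_BASELINE,
               participant: int = 0) -> EpochSet:
    """Cut a (channels x samples) record into event-locked epochs.

    The window is half-open [lo, hi) on the sampling grid; with the default
    [-100, 600) ms at 500 Hz each epoch has 350 samples.  The per-channel
    mean over the baseline interval is subtracted.  Events whose window
    would cross the recording edge are dropped with a warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    step = 1000.0 / sfreq
    lo_s = int(round(window[0] / step))
    hi_s = int(round(window[1] / step))
    n_times = hi_s - lo_s
    times = (np.arange(lo_s, hi_s)) * step
    kept, kept_labels = [], []
    dropped = 0
    for ev, lab in zip(event_samples, labels):
        a, b = ev + lo_s, ev + hi_s
        if a < 0 or b > continuous.shape[1]:
            dropped += 1
            continue
        kept.append(continuous[:, a:b])
        kept_labels.append(lab)
    if dropped:
        import warnings

        warnings.warn(f"dropped {dropped} events too close to recording edge")
    data = (np.stack(kept) if kept
            else np.empty((0, continuous.shape[0], n_times)))
    if baseline is not None and len(kept):
        mask = (times >= baseline[0]) & (times < baseline[1])
        if mask.any():
            data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data, times, list(channels), np.asarray(coords),
                    kept_labels, participant)


def reject_artifacts(epochs: EpochSet, max_abs: float = 200.0,
                     max_step: float = 50.0
                     ) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs exceeding amplitude or sample-to-sample step limits.

    An epoch is rejected if any channel sample exceeds ``max_abs`` uV in
    magnitude or any consecutive-sample difference exceeds ``max_step`` uV.
    Returns the cleaned set and a log with one row per input epoch.
    """
    if max_abs <= 0 or max_step <= 0:
        raise ValueError("thresholds must be positive")
    amp_bad = np.abs(epochs.data).max(axis=(1, 2)) > max_abs
    steps = np.abs(np.diff(epochs.data, axis=2))
    step_bad = (steps.max(axis=(1, 2)) > max_step
                if steps.size else np.zeros(len(amp_bad), bool))
    bad = amp_bad | step_bad
    log = pd.DataFrame(
        dict(epoch=np.arange(len(bad)), label=epochs.labels,
             amplitude_reject=amp_bad, step_reject=step_bad, rejected=bad)
    )
    keep = ~bad
    cleaned = EpochSet(epochs.data[keep], epochs.times.copy(),
                       list(epochs.channels), epochs.coords.copy(),
                       [l for l, k in zip(epochs.labels, keep) if k],
                       epochs.participant)
    return cleaned, log


def interpolate_channels(epochs: EpochSet, adjacency: np.ndarray,
                         kurtosis_z: float = 6.0
                         ) -> tuple[EpochSet, pd.DataFrame]:
    """Replace heavy-tailed channels by their unweighted neighbour mean.

    Excess kurtosis is computed per channel over all epochs and samples and
    z-scored across channels (population SD); channels with z above the
    threshold are replaced by the mean of their adjacent channels (using the
    original, pre-replacement data).
    """
    n_ch = len(epochs.channels)
    flat = epochs.data.transpose(1, 0, 2).reshape(n_ch, -1)
    kurt = stats.kurtosis(flat, axis=1, fisher=True, bias=True)
    sd = kurt.std()
    z = np.zeros_like(kurt) if sd == 0 else (kurt - kurt.mean()) / sd
    offenders = np.flatnonzero(z > kurtosis_z)
    data = epochs.data.copy()
    for ch in offenders:
        nbrs = np.flatnonzero(adjacency[ch])
        nbrs = nbrs[~np.isin(nbrs, offenders)]
        if len(nbrs) == 0:
            raise ValueError(
                f"channel {epochs.channels[ch]} has no clean neighbours"
            )
        data[:, ch, :] = epochs.data[:, nbrs, :].mean(axis=1)
    log = pd.DataFrame(
        dict(channel=list(epochs.channels), kurtosis=kurt, z=z,
             interpolated=np.isin(np.arange(n_ch), offenders))
    )
    out = EpochSet(data, epochs.times.copy(), list(epochs.channels),
                   epochs.coords.copy(), list(epochs.labels),
                   epochs.participant)
    return out, log


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Common average reference: per-sample channel mean subtracted."""
    if len(epochs.channels) < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(data, epochs.times.copy(), list(epochs.channels),
                    epochs.coords.copy(), list(epochs.labels),
                    epochs.participant)


def average_erp(epochs: EpochSet, conditions=None) -> ERPSet:
    """Arithmetic mean per condition; empty conditions omitted with warning."""
    labels = np.asarray(epochs.labels)
    wanted = conditions if conditions is not None else sorted(set(epochs.labels))
    erps: dict[str, np.ndarray] = {}
    n: dict[str, int] = {}
    for cond in wanted:
        mask = labels == cond
        if not mask.any():
            import warnings

            warnings.warn(f"no epochs for condition {cond!r}; omitted")
            continue
        erps[cond] = epochs.data[mask].mean(axis=0)
        n[cond] = int(mask.sum())
    return ERPSet(erps, n, epochs.times.copy(), list(epochs.channels),
                  epochs.coords.copy(), "participant", epochs.participant)


def grand_average(erp_sets: list[ERPSet]) -> ERPSet:
    """Unweighted mean over participants, per condition present in all."""
    if not erp_sets:
        raise ValueError("no ERP sets to average")
    common = set(erp_sets[0].erps)
    for es in erp_sets[1:]:
        common &= set(es.erps)
    erps = {
        c: np.mean([es.erps[c] for es in erp_sets], axis=0)
        for c in sorted(common)
    }
    n = {c: len(erp_sets) for c in common}
    first = erp_sets[0]
    return ERPSet(erps, n, first.times.copy(), list(first.channels),
                  first.coords.copy(), "grand", None)
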