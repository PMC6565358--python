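"""Synthetic participants: response streams and multichannel ERP epochs.

The generator produces data with the statistical structure the downstream
analyses assume, so the whole pipeline can be exercised end to end without
recorded data.

Behaviour.  Button presses follow the onset of the second sequence trial by
a Gaussian latency; releases follow the sequence-end reference by a
Gaussian latency whose mean/SD depend on expectation compliance
(terminated 619.48/96.55 ms, regular 532.81/99.74 ms, extended
346.68/219.35 ms -- the shipped calibration of the group statistics the
analyses are meant to recover).  A negative surprise slope couples more
surprising extensions to earlier releases (applied to surprise centred
within compliance class, so configured condition means are preserved); a
premature-release probability places some extended-sequence releases near
the cued "would-be" end; misses and false alarms are injected at configured
rates.  Cue learning is modelled as a two-population gain score (new-cue
minus learned-cue onset latency): gain 178.54 +- 106.62 ms versus no-gain
-45.40 +- 82.24 ms.

EEG.  Epochs are a linear forward model: each component contributes
(condition weight x amplitude x unit-norm scalp topography x Gaussian
temporal kernel); spatially smoothed Gaussian sensor noise is added.  The
default component set places a parieto-central P3b (peak 388 ms for PE,
420 ms for CP, absent for STD), a centro-parietal N400 (PE only, 418 ms), a
right-parietal P600 (500-554 ms), and an early frontal map (~300 ms,
strongest for STD).  Relative amplitudes are a calibration choice, not an
inference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from . import layout
from .behaviour import ResponseRecord
from .erp import EpochSet
from .observer import score_session
from .task import Session, TaskConfig, build_session, event_condition

__all__ = [
    "BehaviourModel",
    "Component",
    "ERPModel",
    "SyntheticCohort",
    "simulate_responses",
    "simulate_cohort",
    "simulate_epochs",
    "simulate_microstate_erps",
]


def generator_defaults() -> dict:
    """The versioned generator defaults shipped with the package."""
    text = resources.files(__package__).joinpath(
        "generator_defaults.yaml").read_text()
    return yaml.safe_load(text)


_BEH = generator_defaults()["behaviour"]


@dataclass(frozen=True)
class BehaviourModel:
    """Generative response model; times in ms, rates as probabilities.

    Defaults come from :data:`generator_defaults.yaml`.
    """

    offset_mean: dict = field(default_factory=lambda: dict(_BEH["offset_mean"]))
    offset_between_sd: dict = field(
        default_factory=lambda: dict(_BEH["offset_between_sd"]))
    offset_within_sd: float = _BEH["offset_within_sd"]
    onset_mean_learned: float = _BEH["onset_mean_learned"]
    onset_between_sd: float = _BEH["onset_between_sd"]
    onset_within_sd: float = _BEH["onset_within_sd"]
    gain_mean: dict = field(default_factory=lambda: dict(_BEH["gain_mean"]))
    gain_sd: dict = field(default_factory=lambda: dict(_BEH["gain_sd"]))
    surprise_slope: float = _BEH["surprise_slope"]  # centred within compliance
    premature_release_rate: dict = field(
        default_factory=lambda: dict(_BEH["premature_release_rate"]))
    miss_rate: float = _BEH["miss_rate"]
    fa_rate: float = _BEH["fa_rate"]  # per inter-sequence gap

    def validate(self) -> None:
        for sd in (*self.offset_between_sd.values(), self.offset_within_sd,
                   self.onset_between_sd, self.onset_within_sd,
                   *self.gain_sd.values()):
            if sd < 0:
                raise ValueError("SDs must be non-negative")
        for r in (self.miss_rate, self.fa_rate,
                  *self.premature_release_rate.values()):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground-truth per-participant parameters drawn by the generator."""

    participant: int
    group: str  # {"gain", "no_gain"}
    gain_score: float  # ms, new minus learned onset latency
    onset_shift: float  # ms, participant offset around onset_mean_learned
    offset_shift: dict  # compliance -> ms


def _draw_participant(pid: int, model: BehaviourModel,
                      rng: np.random.Generator,
                      group: str) -> ParticipantTruth:
    gain = float(rng.normal(model.gain_mean[group], model.gain_sd[group]))
    onset_shift = float(rng.normal(0.0, model.onset_between_sd))
    offset_shift = {
        c: float(rng.normal(0.0, sd))
        for c, sd in model.offset_between_sd.items()
    }
    return ParticipantTruth(pid, group, gain, onset_shift, offset_shift)


def simulate_responses(session: Session, model: BehaviourModel,
                       seed: int | np.random.Generator = 0,
                       truth: ParticipantTruth | None = None,
                       participant: int = 0) -> list[ResponseRecord]:
    """Simulate one participant's press/release stream for a session.

    With all SDs, the surprise slope, and the rates at zero, recovered
    condition means equal the configured means exactly.
    """
    model.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if truth is None:
        truth = ParticipantTruth(participant, "no_gain", 0.0, 0.0,
                                 {c: 0.0 for c in model.offset_mean})
    dur = session.config.trial_duration
    recs = score_session(session, scope="block")
    I = np.array([r.I for r in recs])
    compliance = np.array([session.sequences[r.sequence].compliance
                           for r in recs])
    order = [r.sequence for r in recs]
    # centre surprise within compliance class so the slope shifts trial
    # latencies without moving configured condition means
    I_centred = I.copy()
    for c in set(compliance):
        m = compliance == c
        I_centred[m] -= I[m].mean()
    I_by_seq = {si: Ic for si, Ic in zip(order, I_centred)}

    events: list[tuple[float, float]] = []
    for si, seq in enumerate(session.sequences):
        if rng.random() < model.miss_rate:
            continue
        cue_onset = seq.start_index * dur
        second_onset = cue_onset + dur
        offset_ref = (seq.start_index + seq.realized_length) * dur
        onset_mu = model.onset_mean_learned + truth.onset_shift
        if seq.cued_colour == "new":
            onset_mu += truth.gain_score
        press = second_onset + rng.normal(onset_mu, model.onset_within_sd)
        press = max(press, cue_onset)  # presses precede the cue only as FAs
        prem = model.premature_release_rate.get(truth.group, 0.0)
        if seq.compliance == "extended" and rng.random() < prem:
            # release near the cued "would-be" end, i.e. delta_items trials
            # (= 1000 ms at default timing) before the actual end
            release = offset_ref + rng.uniform(-2 * dur, -dur)
        else:
            mu = (model.offset_mean[seq.compliance]
                  + truth.offset_shift[seq.compliance]
                  + model.surprise_slope * I_by_seq[si]
                  * (seq.compliance == "extended"))
            release = offset_ref + rng.normal(mu, model.offset_within_sd)
        release = max(release, press + 1.0)
        events.append((press, release))

    # false alarms: brief presses inside inter-sequence gaps, placed after
    # the preceding sequence's attribution window and before the next cue
    for si, seq in enumerate(session.sequences):
        if rng.random() >= model.fa_rate:
            continue
        free_lo = (seq.start_index + seq.realized_length) * dur + 2000.0
        nxt = (session.sequences[si + 1].start_index * dur
               if si + 1 < len(session.sequences)
               else session.n_trials * dur)
        if nxt - free_lo < 300.0:  # gap too short to host a spurious press
            continue
        press = rng.uniform(free_lo, nxt - 200.0)
        events.append((press, press + rng.uniform(100.0, min(500.0, nxt - press))))

    events.sort()
    out: list[ResponseRecord] = []
    last_release = -math.inf
    for press, release in events:
        press = max(press, last_release + 1.0)  # button cannot overlap itself
        if release <= press:
            release = press + 1.0
        out.append(ResponseRecord(participant, press, release))
        last_release = release
    return out


@dataclass
class SyntheticCohort:
    """Sessions, responses, and ground truth for a simulated sample."""

    sessions: dict[int, Session]  # per participant (main session)
    post_sessions: dict[int, Session]
    responses: dict[int, list[ResponseRecord]]
    post_responses: dict[int, list[ResponseRecord]]
    truth: dict[int, ParticipantTruth]
    master_seed: int


def simulate_cohort(n_participants: int = 30,
                    task_config: TaskConfig | None = None,
                    model: BehaviourModel | None = None,
                    seed: int = 0,
                    gain_fraction: float = 0.5,
                    with_post: bool = True) -> SyntheticCohort:
    """Simulate a cohort; bit-reproducible from (configs, seed).

    Each participant receives an individually randomised session with the
    same configuration (as in the experiment) plus, optionally, a post
    session in which half the sequences carry new cue colours.  Group
    membership (gain / no-gain cue learners) is assigned to the first
    ``gain_fraction`` of participants after a seeded shuffle.
    """
    task_config = task_config or TaskConfig()
    model = model or BehaviourModel()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_participants + 1)
    rng = np.random.default_rng(child[-1])
    n_gain = int(round(gain_fraction * n_participants))
    groups = np.array(["gain"] * n_gain
                      + ["no_gain"] * (n_participants - n_gain))
    rng.shuffle(groups)

    sessions, post_sessions, responses, post_responses, truth = {}, {}, {}, {}, {}
    post_cfg = replace(task_config, session_kind="post")
    for pid in range(n_participants):
        prng = np.random.default_rng(child[pid])
        truth[pid] = _draw_participant(pid, model, prng, str(groups[pid]))
        sess_seed = int(prng.integers(2**31))
        sessions[pid] = build_session(task_config, seed=sess_seed)
        responses[pid] = simulate_responses(sessions[pid], model, prng,
                                            truth[pid], pid)
        if with_post:
            post_seed = int(prng.integers(2**31))
            post_sessions[pid] = build_session(post_cfg, seed=post_seed)
            post_responses[pid] = simulate_responses(post_sessions[pid], model,
                                                     prng, truth[pid], pid)
    return SyntheticCohort(sessions, post_sessions, responses, post_responses,
                           truth, seed)


# --------------------------------------------------------------------------
# EEG forward model


@dataclass(frozen=True)
class Component:
    """One ERP component: scalp topography x temporal kernel x weights."""

    name: str
    center: str  # channel name at the topography peak
    spatial_scale: float  # Gaussian falloff in layout units
    peak_ms: dict  # condition -> peak latency (missing -> default key "*")
    width_ms: float
    amplitude: float  # uV at the peak channel-time before weighting
    weights: dict  # condition -> multiplicative weight (missing -> 0)

    def peak_for(self, condition: str) -> float:
        if condition in self.peak_ms:
            return self.peak_ms[condition]
        return self.peak_ms.get("*", 400.0)


def default_components() -> list[Component]:
    return [
        Component("P3b", "Pz", 0.45, {"PE": 388.0, "CP": 420.0, "*": 400.0},
                  90.0, 5.0, {"PE": 1.0, "CP": 0.9}),
        Component("N400", "CPz", 0.45, {"*": 418.0}, 60.0, -2.5, {"PE": 1.0}),
        Component("P600", "P6", 0.40, {"PE": 500.0, "CP": 554.0, "*": 520.0},
                  80.0, 2.0, {"PE": 1.0, "CP": 1.0, "STD": -0.3}),
        Component("early_frontal", "Fz", 0.45, {"*": 300.0}, 50.0, 2.5,
                  {"STD": 1.0, "PE": 0.5, "CP": 0.5}),
    ]


@dataclass(frozen=True)
class ERPModel:
    """Forward model: channel layout, components, noise, sampling."""

    components: tuple = tuple(default_components())
    noise_sd: float = 3.0  # uV per sensor sample
    spatial_smoothing: float = 0.35  # Gaussian kernel scale over coords
    participant_amp_sd: float = 0.15  # multiplicative between-subject scatter
    sampling_rate: float = 500.0  # Hz
    window: tuple[float, float] = (-100.0, 600.0)

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        lo = int(round(self.window[0] / step))
        hi = int(round(self.window[1] / step))
        return np.arange(lo, hi) * step


def _unit_topography(center: str, scale: float, names: list[str],
                     coords: np.ndarray) -> np.ndarray:
    ci = layout.channel_index(names, [center])[0]
    d2 = np.sum((coords - coords[ci]) ** 2, axis=1)
    topo = np.exp(-d2 / (2 * scale**2))
    topo -= topo.mean()  # average-referenced
    return topo / np.linalg.norm(topo)


def _noise_chol(coords: np.ndarray, scale: float) -> np.ndarray:
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    cov = np.exp(-d2 / (2 * scale**2))
    cov += 1e-6 * np.eye(len(coords))
    return np.linalg.cholesky(cov)


def condition_signal(model: ERPModel, condition: str, names: list[str],
                     coords: np.ndarray,
                     comp_gains: np.ndarray | None = None) -> np.ndarray:
    """Noise-free channels x time signal for one condition."""
    t = model.times()
    sig = np.zeros((len(names), len(t)))
    gains = (np.ones(len(model.components)) if comp_gains is None
             else comp_gains)
    for comp, g in zip(model.components, gains):
        w = comp.weights.get(condition, 0.0)
        if w == 0.0:
            continue
        topo = _unit_topography(comp.center, comp.spatial_scale, names, coords)
        # normalise so the configured amplitude is the actual peak-channel uV
        kern = np.exp(-0.5 * ((t - comp.peak_for(condition)) / comp.width_ms) ** 2)
        sig += (w * g * comp.amplitude / topo.max()) * topo[:, None] * kern[None, :]
    return sig


def simulate_epochs(session: Session, model: ERPModel | None = None,
                    n_participants: int = 1, seed: int = 0,
                    conditions: tuple = ("PE", "CP", "STD")
                    ) -> list[EpochSet]:
    """Forward-model epochs for every labelled event, per participant.

    Each event of the session contributes one epoch of its collapsed
    condition (PE / CP / STD); per-participant multiplicative component
    gains (1 +- participant_amp_sd) add between-subject variance, and
    spatially smoothed Gaussian sensor noise is added per epoch.
    """
    model = model or ERPModel()
    names, coords = layout.standard_62()
    ss = np.random.SeedSequence(seed)
    chol = _noise_chol(coords, model.spatial_smoothing)
    t = model.times()
    out = []
    ev_conditions = [event_condition(e.klass) for e in session.events]
    unknown = set(ev_conditions) - {"PE", "CP", "STD"}
    if unknown:
        raise ValueError(f"unknown condition labels {unknown}")
    for pid, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        gains = np.clip(
            rng.normal(1.0, model.participant_amp_sd, len(model.components)),
            0.0, None)
        base = {c: condition_signal(model, c, names, coords, gains)
                for c in conditions}
        epochs, labels = [], []
        for cond in ev_conditions:
            if cond not in base:
                continue
            noise = chol @ rng.standard_normal((len(names), len(t)))
            epochs.append(base[cond] + model.noise_sd * noise)
            labels.append(cond)
        data = (np.stack(epochs) if epochs
                else np.empty((0, len(names), len(t))))
        out.append(EpochSet(data, t.astype(float), names, coords, labels, pid))
    return out


# --------------------------------------------------------------------------
# Microstate-style group ERPs


def _orthonormal_zero_mean_maps(n_maps: int, n_channels: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Well-separated unit-norm, average-referenced topographies (K x C)."""
    if n_maps > n_channels - 1:
        raise ValueError("cannot fit that many orthogonal zero-mean maps")
    raw = rng.standard_normal((n_channels, n_maps))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    maps = q.T[:n_maps]
    maps -= maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def default_gfp_profile(n_times: int) -> np.ndarray:
    """Smooth positive GFP time course (uV), mean around 3."""
    x = np.linspace(0.0, 1.0, n_times)
    return 2.0 + 2.0 * np.sin(np.pi * x) ** 2


def simulate_microstate_erps(n_maps: int = 12,
                             durations: dict | None = None,
                             gfp_profile: np.ndarray | None = None,
                             noise_sd: float = 0.15,
                             seed: int = 0,
                             n_channels: int = 62,
                             n_conditions: int = 4,
                             n_times: int = 350,
                             segments_per_condition: int = 6):
    """Group-level ERPs pieced together from a shared pool of template maps.

    Each condition's channels x time ERP is a piecewise-constant sequence of
    topographies from a pool of ``n_maps`` orthonormal, average-referenced
    maps, scaled so the noise-free GFP follows ``gfp_profile``, plus white
    sensor noise of SD ``noise_sd`` (uV).  Conditions share and omit maps
    (condition c starts its rotation at map 3c), so the pool is identifiable
    only across conditions.  Returns (erps: condition -> (C, T), truth dict
    with maps, labels per condition, and the profile).
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    maps = _orthonormal_zero_mean_maps(n_maps, n_channels, rng)
    if gfp_profile is None:
        gfp_profile = default_gfp_profile(n_times)
    gfp_profile = np.asarray(gfp_profile, dtype=float)
    if len(gfp_profile) != n_times:
        raise ValueError("gfp_profile length must equal n_times")

    erps: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for c in range(n_conditions):
        cond = f"cond{c}"
        if durations is not None:
            segs = durations[cond]
            if sum(d for _, d in segs) != n_times:
                raise ValueError("durations must tile the epoch")
        else:
            n_seg = min(segments_per_condition, n_maps)
            ids = [(3 * c + i) % n_maps for i in range(n_seg)]
            bounds = np.linspace(0, n_times, n_seg + 1).astype(int)
            segs = [(mid, int(b - a))
                    for mid, a, b in zip(ids, bounds[:-1], bounds[1:])]
        lab = np.concatenate([np.full(d, mid, dtype=int) for mid, d in segs])
        # unit-norm map scaled so that gfp(signal) == gfp_profile
        sig = maps[lab].T * gfp_profile[None, :] * np.sqrt(n_channels)
        noise = rng.standard_normal(sig.shape) * noise_sd
        erps[cond] = sig + noise
        labels[cond] = lab
    truth = dict(maps=maps, labels=labels, gfp_profile=gfp_profile)
    return erps, truth
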