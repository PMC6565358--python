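"""Cued serial-pattern task generation.

Participants watch a stream of coloured single digits (500 ms each).  Hidden
in the pseudorandom stream are *ordered sequences* in which each digit
increases its predecessor by one, wrapping circularly after 9.  Two colours
act as cues: one marks the first digit of a *short* sequence (regular length
5), the other a *long* sequence (regular length 7).  Cues are valid with
p = .80 overall; invalid sequences are either *terminated* (two items
shorter than cued) or *extended* (two items longer).  The mix of
terminated/regular/extended sequences is manipulated blockwise to create
*low* and *high* irreducible-uncertainty contexts.

Three event classes are labelled on the stream:

- ``PE_termination`` / ``PE_extension`` -- prediction errors: the first digit
  violating the cue-based length expectation (a random digit appearing too
  early, or a sequential digit appearing past the regular end).
- ``CP_term_check`` / ``CP_ext_check`` -- checkpoints: the same sequential
  positions when the *expected* stimulus appears instead.
- ``STD`` -- deterministic standards: the fourth digit of every long
  extended sequence, which carries no outcome information.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as _Seq

import numpy as np

__all__ = [
    "OUTCOMES",
    "TaskConfig",
    "Trial",
    "SequenceInstance",
    "EventLabel",
    "Session",
    "make_sequence",
    "realized_length",
    "build_session",
    "label_events",
]

#: Expectation-compliance outcomes of a cued sequence, in canonical order.
OUTCOMES = ("terminated", "regular", "extended")

EVENT_CLASSES = (
    "CP_term_check",
    "CP_ext_check",
    "PE_termination",
    "PE_extension",
    "STD",
)

# Colour ids: 0 = learned short cue, 1 = learned long cue, 2/3 = the fixed
# "new" cue colours used only in the post session, remaining ids = fillers.
CUE_SHORT, CUE_LONG = 0, 1
NEW_CUE_SHORT, NEW_CUE_LONG = 2, 3


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one experimental session.

    ``composition_low``/``composition_high`` are the per-block proportions of
    (terminated, regular, extended) sequences; multiplied by
    ``sequences_per_block`` they must give whole counts -- composition is
    realized by exact counts, not sampling, so the regular fraction is
    deterministic (0.80 across the default 4 low + 4 high blocks).
    """

    n_blocks_low: int = 4
    n_blocks_high: int = 4
    sequences_per_block: int = 20
    composition_low: tuple[float, float, float] = (0.05, 0.90, 0.05)
    composition_high: tuple[float, float, float] = (0.15, 0.70, 0.15)
    regular_length_short: int = 5
    regular_length_long: int = 7
    delta_items: int = 2
    n_filler_colours: int = 6
    trial_duration: float = 500.0  # ms
    random_gap_range: tuple[int, int] = (4, 9)
    session_kind: str = "main"  # {"training", "main", "post"}
    post_new_cue_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.session_kind not in ("training", "main", "post"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.delta_items < 1:
            raise ValueError("delta_items must be >= 1")
        if not (0 < self.regular_length_short < self.regular_length_long):
            raise ValueError("need 0 < regular_length_short < regular_length_long")
        if self.regular_length_short - self.delta_items < 1:
            raise ValueError("terminated short sequences would be empty")
        if self.n_filler_colours < 3:
            raise ValueError("need at least 3 filler colours")
        lo, hi = self.random_gap_range
        if not (1 <= lo <= hi):
            raise ValueError("random_gap_range must satisfy 1 <= lo <= hi")
        for name, comp in (
            ("composition_low", self.composition_low),
            ("composition_high", self.composition_high),
        ):
            if len(comp) != 3 or any(c < 0 for c in comp):
                raise ValueError(f"{name} must be 3 non-negative proportions")
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            for c in comp:
                n = c * self.sequences_per_block
                if abs(n - round(n)) > 1e-9:
                    raise ValueError(
                        f"{name} x sequences_per_block must be integral, got {n}"
                    )
        if not (0.0 <= self.post_new_cue_fraction <= 1.0):
            raise ValueError("post_new_cue_fraction must be in [0, 1]")
        n_new = self.post_new_cue_fraction * self.sequences_per_block
        if self.session_kind == "post" and abs(n_new - round(n_new)) > 1e-9:
            raise ValueError("post_new_cue_fraction x sequences_per_block not integral")

    def block_plan(self) -> list[tuple[int, str]]:
        """(block id, uncertainty) list for this session kind."""
        if self.session_kind == "training":
            pairs = ["low", "high"]
        elif self.session_kind == "post":
            pairs = ["low"]
        else:
            pairs = []
            lo, hi = self.n_blocks_low, self.n_blocks_high
            while lo or hi:  # alternate, starting with low
                if lo:
                    pairs.append("low")
                    lo -= 1
                if hi:
                    pairs.append("high")
                    hi -= 1
        return list(enumerate(pairs))

    def composition_counts(self, uncertainty: str) -> dict[str, int]:
        comp = self.composition_low if uncertainty == "low" else self.composition_high
        return {
            o: int(round(p * self.sequences_per_block)) for o, p in zip(OUTCOMES, comp)
        }

    def regular_length(self, cue_type: str) -> int:
        return (
            self.regular_length_short
            if cue_type == "short"
            else self.regular_length_long
        )

    @property
    def colour_ids(self) -> tuple[int, ...]:
        return tuple(range(4 + self.n_filler_colours))

    @property
    def filler_colour_ids(self) -> tuple[int, ...]:
        return tuple(range(4, 4 + self.n_filler_colours))


@dataclass(frozen=True)
class Trial:
    index: int
    digit: int
    colour: int
    role: str  # {"random", "cue", "sequential"}
    block: int
    onset: float  # ms from stream start


@dataclass(frozen=True)
class SequenceInstance:
    cue_type: str  # {"short", "long"}
    compliance: str  # {"terminated", "regular", "extended"}
    start_index: int  # trial index of the cue
    realized_length: int  # number of sequential digits, cue included
    block: int
    cued_colour: str = "learned"  # {"learned", "new"} (post sessions)


@dataclass(frozen=True)
class EventLabel:
    trial_index: int
    klass: str
    sequence: int  # index into Session.sequences
    uncertainty: str


@dataclass
class Session:
    trials: list[Trial]
    sequences: list[SequenceInstance]
    events: list[EventLabel]
    blocks: list[tuple[int, str]]
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block_uncertainty(self, block: int) -> str:
        return dict(self.blocks)[block]

    def digits(self) -> np.ndarray:
        return np.array([t.digit for t in self.trials], dtype=int)


def make_sequence(start_digit: int, length: int) -> list[int]:
    """Ascending digit run starting at ``start_digit``, wrapping mod 10.

    >>> make_sequence(8, 5)
    [8, 9, 0, 1, 2]
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= start_digit <= 9:
        raise ValueError("start_digit must be a digit 0-9")
    return [(start_digit + i) % 10 for i in range(length)]


def realized_length(cue_type: str, compliance: str, config: TaskConfig) -> int:
    """Actual number of sequential digits (cue included) for a sequence."""
    if cue_type not in ("short", "long"):
        raise ValueError(f"unknown cue_type {cue_type!r}")
    if compliance not in OUTCOMES:
        raise ValueError(f"unknown compliance {compliance!r}")
    base = config.regular_length(cue_type)
    if compliance == "terminated":
        return base - config.delta_items
    if compliance == "extended":
        return base + config.delta_items
    return base


def _balanced_cue_types(n: int, rng: np.random.Generator) -> list[str]:
    types = ["short", "long"] * (n // 2)
    if n % 2:
        types.append(rng.choice(["short", "long"]))
    rng.shuffle(types)
    return types


class _RoundRobin:
    """Reshuffled round-robin pool: successive draws stay balanced (+-1)."""

    def __init__(self, items: _Seq, rng: np.random.Generator):
        self._items = list(items)
        self._rng = rng
        self._queue: list = []

    def draw(self, exclude=()) -> object:
        if not self._queue:
            self._queue = list(self._items)
            self._rng.shuffle(self._queue)
        for i, item in enumerate(self._queue):
            if item not in exclude:
                return self._queue.pop(i)
        # everything excluded in this cycle: refill and accept the constraint
        self._queue = list(self._items)
        self._rng.shuffle(self._queue)
        for i, item in enumerate(self._queue):
            if item not in exclude:
                return self._queue.pop(i)
        raise ValueError("round-robin pool exhausted by exclusions")


def build_session(config: TaskConfig, seed: int | None = None) -> Session:
    """Generate a full session stream (deterministic given the seed).

    Per-block sequence composition matches the configured proportions
    exactly; sequences are separated by 4-9 random trials (uniform).  Random
    digits never continue the previous digit by +1, so the sequence rule
    only ever holds inside ordered sequences.  In post sessions a configured
    fraction of sequences is cued by the fixed non-learned colours.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    trials: list[Trial] = []
    sequences: list[SequenceInstance] = []
    blocks = config.block_plan()

    gap_lo, gap_hi = config.random_gap_range
    start_digit_pool = _RoundRobin(range(10), rng)

    def append_random(n: int, block: int, colour_pool: _RoundRobin,
                      forbidden_colours: tuple[int, ...]) -> None:
        for _ in range(n):
            prev = trials[-1].digit if trials else None
            choices = [d for d in range(10) if prev is None or d != (prev + 1) % 10]
            digit = int(rng.choice(choices))
            colour = colour_pool.draw(exclude=forbidden_colours)
            trials.append(
                Trial(len(trials), digit, int(colour), "random", block,
                      len(trials) * config.trial_duration)
            )

    for block, uncertainty in blocks:
        counts = config.composition_counts(uncertainty)
        spec: list[str] = []
        for outcome, n in counts.items():
            spec.extend([outcome] * n)
        rng.shuffle(spec)
        cue_types = _balanced_cue_types(len(spec), rng)

        cued_colours = ["learned"] * len(spec)
        if config.session_kind == "post":
            n_new = int(round(config.post_new_cue_fraction * len(spec)))
            idx = rng.permutation(len(spec))[:n_new]
            for i in idx:
                cued_colours[i] = "new"

        # outside post sessions the later "new cue" colours are ordinary
        # fillers, so they have a presentation history without cue meaning
        pool_ids = config.filler_colour_ids
        if config.session_kind != "post":
            pool_ids = (NEW_CUE_SHORT, NEW_CUE_LONG) + pool_ids
        colour_pool = _RoundRobin(pool_ids, rng)
        # learned cue colours (and, in post blocks, the new-cue colours)
        # never occur on non-cue trials, so cue onsets are unambiguous
        forbidden = (CUE_SHORT, CUE_LONG)
        if config.session_kind == "post":
            forbidden = forbidden + (NEW_CUE_SHORT, NEW_CUE_LONG)

        for compliance, cue_type, cued_colour in zip(spec, cue_types, cued_colours):
            append_random(int(rng.integers(gap_lo, gap_hi + 1)), block,
                          colour_pool, forbidden)
            length = realized_length(cue_type, compliance, config)
            start_digit = int(start_digit_pool.draw())
            digits = make_sequence(start_digit, length)
            if cued_colour == "new":
                cue_colour = NEW_CUE_SHORT if cue_type == "short" else NEW_CUE_LONG
            else:
                cue_colour = CUE_SHORT if cue_type == "short" else CUE_LONG
            start_index = len(trials)
            for j, digit in enumerate(digits):
                role = "cue" if j == 0 else "sequential"
                colour = cue_colour if j == 0 else int(
                    colour_pool.draw(exclude=forbidden))
                trials.append(
                    Trial(len(trials), digit, colour, role, block,
                          len(trials) * config.trial_duration)
                )
            sequences.append(
                SequenceInstance(cue_type, compliance, start_index, length,
                                 block, cued_colour)
            )
        # trailing gap closes the block so every sequence has random
        # successors (needed for offset references and extension checks)
        append_random(int(rng.integers(gap_lo, gap_hi + 1)), block,
                      colour_pool, forbidden)

    session = Session(trials, sequences, [], blocks, config)
    session.events = label_events(session)
    return session


def label_events(session: Session) -> list[EventLabel]:
    """Label checkpoints, prediction errors, and standards on a session.

    Positions are 1-based from the cue trial.  For a sequence with cued
    regular length L and shortening/prolongation delta: position L-delta+1
    carries the termination check (PE if terminated, CP otherwise); position
    L+1 carries the extension check (PE if extended, CP if the sequence
    ended regularly); position 4 of long extended sequences is the STD.
    """
    config = session.config
    events: list[EventLabel] = []
    unc = dict(session.blocks)
    for si, seq in enumerate(session.sequences):
        L = config.regular_length(seq.cue_type)
        d = config.delta_items
        u = unc[seq.block]
        term_pos = L - d + 1
        term_idx = seq.start_index + term_pos - 1
        if seq.compliance == "terminated":
            events.append(EventLabel(term_idx, "PE_termination", si, u))
        else:
            events.append(EventLabel(term_idx, "CP_term_check", si, u))
        ext_idx = seq.start_index + L
        if seq.compliance == "extended":
            events.append(EventLabel(ext_idx, "PE_extension", si, u))
        elif seq.compliance == "regular":
            events.append(EventLabel(ext_idx, "CP_ext_check", si, u))
        if seq.cue_type == "long" and seq.compliance == "extended":
            events.append(EventLabel(seq.start_index + 3, "STD", si, u))
    events.sort(key=lambda e: e.trial_index)
    return events


def event_condition(klass: str) -> str:
    """Collapse event classes to the three ERP conditions PE / CP / STD."""
    if klass.startswith("PE"):
        return "PE"
    if klass.startswith("CP"):
        return "CP"
    return "STD"
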