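"""Ideal-observer surprise over sequence outcomes.

An ideal Bayesian observer tracks how often each expectation-compliance
outcome (terminated / regular / extended) has occurred and quantifies the
surprise of each new outcome as Shannon information,

    I(x) = -ln p(x),      p(x) = (n_j + 1) / (sum_k n_k + 1),

where ``n_j`` counts past occurrences of outcome ``j`` and the sum runs over
all outcomes observed so far.  Note that this weight is deliberately *not* a
normalised distribution over the three outcomes (with an empty history every
outcome gets p = 1, I = 0); it is implemented exactly in this add-one form.
A normalised variant with denominator ``sum_k n_k + K`` is available for
sensitivity analyses but is never the default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .task import OUTCOMES, Session

__all__ = [
    "ObserverState",
    "SurpriseRecord",
    "surprise",
    "update",
    "score_session",
]

SCOPES = ("session", "block", "block_x_cue")


@dataclass(frozen=True)
class ObserverState:
    """Running outcome counts under one context key."""

    counts: tuple[int, int, int] = (0, 0, 0)  # terminated, regular, extended
    scope_key: tuple = ()

    def __post_init__(self):
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be non-negative integers")

    def count(self, outcome: str) -> int:
        return self.counts[OUTCOMES.index(outcome)]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SurpriseRecord:
    sequence: int
    outcome: str
    p: float  # probability-like weight in (0, 1]
    I: float  # surprise, nats
    scope: str = "block"


def surprise(state: ObserverState, outcome: str,
             normalized: bool = False) -> SurpriseRecord:
    """Surprise of observing ``outcome`` given the counts accumulated so far.

    The state is left unchanged; counts are those *before* the current
    observation.  ``normalized=True`` switches the denominator to
    ``total + K`` (a proper Laplace-smoothed distribution).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    denom = state.total + (len(OUTCOMES) if normalized else 1)
    p = (state.count(outcome) + 1) / denom
    return SurpriseRecord(-1, outcome, p, -math.log(p))


def update(state: ObserverState, outcome: str) -> ObserverState:
    """Return a new state with the outcome's count incremented."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    counts = list(state.counts)
    counts[OUTCOMES.index(outcome)] += 1
    return ObserverState(tuple(counts), state.scope_key)


def score_session(session: Session, scope: str = "block",
                  normalized: bool = False) -> list[SurpriseRecord]:
    """Surprise of every sequence outcome, visited in stream order.

    ``scope`` controls when counts reset: ``"session"`` accumulates over the
    whole stream, ``"block"`` (default) restarts the observer at each block
    boundary, ``"block_x_cue"`` additionally keeps separate counts per cue
    type.  Within a scope, surprise is computed *before* the counts are
    updated with the current outcome.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    states: dict[tuple, ObserverState] = {}
    records: list[SurpriseRecord] = []
    order = sorted(range(len(session.sequences)),
                   key=lambda i: session.sequences[i].start_index)
    for si in order:
        seq = session.sequences[si]
        if scope == "session":
            key = ()
        elif scope == "block":
            key = (seq.block,)
        else:
            key = (seq.block, seq.cue_type)
        state = states.get(key, ObserverState(scope_key=key))
        rec = surprise(state, seq.compliance, normalized=normalized)
        records.append(SurpriseRecord(si, seq.compliance, rec.p, rec.I, scope))
        states[key] = update(state, seq.compliance)
    return records


def surprise_table(records: list[SurpriseRecord]) -> pd.DataFrame:
    """Tidy frame (sequence, outcome, p, I_nats, scope) for TSV export."""
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "outcome": [r.outcome for r in records],
            "p": [r.p for r in records],
            "I_nats": [r.I for r in records],
            "scope": [r.scope for r in records],
        }
    )
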