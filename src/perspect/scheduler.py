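"""Daily message selection for both trial arms.

The recommender policy filters the library to the participant's readiness
stage, ranks the unsent candidates by predicted rating under the current
per-user factor posterior, sends the best one, and re-infers the user's
factors after every rating.  The rule-based comparator emulates a standard
tailored-messaging system: it applies the same stage filter but picks a
seeded-uniform unsent candidate and ignores the ratings entirely.

"Day" is the message ordinal (1st, 2nd, ... message), not calendar time;
a session ends when the participant has rated ``n`` messages (30 in the
trial).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import recommender_core as rc
from .message_store import MessageLibrary, ReadinessStage
from .synthetic_data import Participant

__all__ = [
    "PolicyKind",
    "Policy",
    "SessionState",
    "SessionComplete",
    "select_next",
    "record_rating",
    "run_session",
    "session_log",
]


class SessionComplete(Exception):
    """Raised when no unsent message remains."""


class PolicyKind(enum.Enum):
    PERSPECT = "PERSPECT"
    RULE_BASED = "RULE_BASED"


@dataclass
class Policy:
    kind: PolicyKind
    model: rc.PosteriorSamples | None = None
    seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind is PolicyKind.PERSPECT and self.model is None:
            raise ValueError("the recommender policy requires a fitted model")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng


@dataclass
class SessionState:
    """One participant's delivery history."""

    user: str
    stage: ReadinessStage
    sent: list[str] = field(default_factory=list)
    received_ratings: list[tuple[str, int, int]] = field(default_factory=list)  # (msg, rating, day)
    user_params: np.ndarray | None = None  # (S, D) per-sample factors
    predicted: dict[str, float] = field(default_factory=dict)

    @property
    def day(self) -> int:
        return len(self.sent)

    @property
    def rated_messages(self) -> dict[str, int]:
        return {m: r for m, r, _ in self.received_ratings}


def _candidates(state: SessionState, lib: MessageLibrary) -> list:
    """Stage-matched unsent messages, relaxing outward when exhausted.

    Relaxation order: exact stage match, then messages whose nearest coded
    stage is 1 ladder level away, then 2, ..., then all unsent.
    """
    sent = set(state.sent)
    unsent = [m for m in lib if m.id not in sent]
    if not unsent:
        raise SessionComplete(f"library exhausted for user {state.user}")
    for dist in range(len(ReadinessStage)):
        pool = [
            m for m in unsent if min(abs(int(s) - int(state.stage)) for s in m.stages) == dist
        ]
        if pool:
            return pool
    return unsent


def _predicted_scores(state: SessionState, policy: Policy, message_ids: list[str]) -> np.ndarray:
    model = policy.model
    assert model is not None
    known = [m for m in message_ids if m in model.message_index]
    if state.user_params is None:
        u = np.zeros((model.sample_count, model.latent_dim))
    else:
        u = state.user_params
    scores = dict(zip(known, rc.predict_new_user(model, u, known)))
    # messages absent from the training corpus score at the offset
    return np.asarray([scores.get(m, model.global_offset) for m in message_ids])


def select_next(state: SessionState, policy: Policy, lib: MessageLibrary) -> str:
    """Pick the next message id to send (does not mutate the state)."""
    pool = _candidates(state, lib)
    ids = [m.id for m in pool]
    if policy.kind is PolicyKind.RULE_BASED:
        return ids[int(policy.rng.integers(len(ids)))]
    scores = _predicted_scores(state, policy, ids)
    # highest predicted rating; ties resolve to the lowest message id
    best = min(zip(-scores, ids))
    state.predicted[best[1]] = float(-best[0])
    return best[1]


def record_rating(state: SessionState, policy: Policy, message_id: str, rating: int) -> SessionState:
    """Record a rating and (recommender arm only) update the user factors."""
    if message_id not in state.sent:
        raise ValueError(f"message {message_id!r} was never sent to {state.user}")
    if message_id in {m for m, _, _ in state.received_ratings}:
        raise ValueError(f"message {message_id!r} already rated")
    if not 1 <= rating <= 5:
        raise ValueError("rating must lie in 1..5")
    day = state.sent.index(message_id) + 1
    state.received_ratings.append((message_id, int(rating), day))
    if policy.kind is PolicyKind.PERSPECT:
        model = policy.model
        assert model is not None
        known = {m: r for m, r in state.rated_messages.items() if m in model.message_index}
        state.user_params = rc.infer_new_user(model, known)
    return state


def run_session(
    profile: Participant | SessionState,
    policy: Policy,
    lib: MessageLibrary,
    rating_oracle: Callable[[Participant, str], int],
    n: int = 30,
) -> SessionState:
    """Alternate select / rate / record until ``n`` messages are rated."""
    if len(lib) < n:
        raise ValueError(f"library has {len(lib)} messages; session needs {n}")
    if isinstance(profile, SessionState):
        state, participant = profile, None
    else:
        state = SessionState(user=profile.id, stage=profile.baseline_stage)
        participant = profile
    for _ in range(n):
        mid = select_next(state, policy, lib)
        state.sent.append(mid)
        rating = int(rating_oracle(participant, mid))
        record_rating(state, policy, mid, rating)
    return state


def session_log(state: SessionState) -> pd.DataFrame:
    """Tidy per-day log: (day, message id, predicted rating, rating)."""
    ratings = {m: r for m, r, _ in state.received_ratings}
    return pd.DataFrame(
        {
            "day": range(1, len(state.sent) + 1),
            "message": state.sent,
            "predicted": [state.predicted.get(m, np.nan) for m in state.sent],
            "rating": [ratings.get(m, np.nan) for m in state.sent],
        }
    )
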