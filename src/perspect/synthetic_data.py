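"""Synthetic message libraries, sparse ordinal ratings, and trial cohorts.

Every downstream component — the factor models, the strong-generalization
bake-off, the two-arm message-delivery simulator and the trial analysis —
is exercised on data from this module, so the generators encode the study
conditions explicitly:

* a pilot rating corpus shaped like 846 raters × 20 ratings each over a
  261-message library on a 1–5 Likert scale (16,920 ratings);
* a 120-smoker cohort block-randomized 2:1 (blocks of 10, default
  composition 7 intervention : 3 comparison) rated over 30 message days.

Ratings are generated from a Gaussian latent-factor model: a continuous
score ``offset + u·v + bias + N(0, noise_sd)`` is rounded and clipped to
{1..5}.  True factors are returned next to each dataset so that recovery
tests never have to re-simulate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .message_store import (
    LIST_SEP,
    Message,
    MessageLibrary,
    MessageSource,
    ReadinessStage,
)

__all__ = [
    "RatingDataset",
    "TrueFactors",
    "GeneratorConfig",
    "LibraryGenConfig",
    "CohortConfig",
    "FollowupEffects",
    "Arm",
    "Participant",
    "generate_library",
    "generate_ratings",
    "generate_cohort",
    "simulate_followup",
    "make_rating_oracle",
    "cohort_to_frame",
]

RATING_MIN, RATING_MAX = 1, 5


def ordinal_rating(score: np.ndarray | float) -> np.ndarray:
    """Round-and-clip a continuous score to the 1–5 ordinal scale."""
    return np.clip(np.round(score), RATING_MIN, RATING_MAX)


# --------------------------------------------------------------------------
# Rating dataset container


class RatingDataset:
    """Sparse explicit ratings: (user, message, rating in {1..5}[, day]).

    Wraps a tidy :class:`pandas.DataFrame` plus dense user/message index
    maps.  Duplicate (user, message) pairs are rejected.
    """

    COLUMNS = ("user", "message", "rating", "day")

    def __init__(self, triplets: pd.DataFrame, *, validate: bool = True):
        cols = ["user", "message", "rating"] + (["day"] if "day" in triplets.columns else [])
        self.triplets = triplets[cols].reset_index(drop=True)
        if validate:
            r = self.triplets["rating"].to_numpy()
            if len(r) == 0:
                raise ValueError("rating dataset is empty")
            if (r < RATING_MIN).any() or (r > RATING_MAX).any():
                raise ValueError("ratings must lie in {1..5}")
            if self.triplets.duplicated(["user", "message"]).any():
                dup = self.triplets[self.triplets.duplicated(["user", "message"])].iloc[0]
                raise ValueError(f"duplicate rating for ({dup['user']}, {dup['message']})")
        users = pd.unique(self.triplets["user"])
        messages = pd.unique(self.triplets["message"])
        self.user_index: dict = {u: i for i, u in enumerate(users)}
        self.message_index: dict = {m: j for j, m in enumerate(messages)}
        self._u = self.triplets["user"].map(self.user_index).to_numpy(dtype=np.int64)
        self._m = self.triplets["message"].map(self.message_index).to_numpy(dtype=np.int64)
        self._r = self.triplets["rating"].to_numpy(dtype=np.float64)

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def n_users(self) -> int:
        return len(self.user_index)

    @property
    def n_messages(self) -> int:
        return len(self.message_index)

    @property
    def users(self) -> list:
        return list(self.user_index)

    @property
    def messages(self) -> list:
        return list(self.message_index)

    @property
    def global_mean(self) -> float:
        return float(self._r.mean())

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(user row index, message column index, rating) aligned arrays."""
        return self._u, self._m, self._r

    def matrix(self) -> np.ndarray:
        """Dense (n_users, n_messages) matrix with NaN for missing cells."""
        mat = np.full((self.n_users, self.n_messages), np.nan)
        mat[self._u, self._m] = self._r
        return mat

    def user_ratings(self, user) -> pd.DataFrame:
        return self.triplets[self.triplets["user"] == user]

    def subset_users(self, users: Sequence) -> "RatingDataset":
        keep = self.triplets["user"].isin(set(users))
        return RatingDataset(self.triplets[keep], validate=False)

    # -- I/O --------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.triplets.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "RatingDataset":
        return cls(pd.read_csv(path))


@dataclass
class TrueFactors:
    """Ground-truth latent structure behind a generated dataset."""

    user_factors: np.ndarray  # (n_users, D)
    item_factors: np.ndarray  # (n_messages, D)
    offset: float
    user_ids: list
    message_ids: list

    def score(self, user_pos: int, message_pos: int) -> float:
        """Noise-free continuous score for a (user, message) position."""
        return float(self.offset + self.user_factors[user_pos] @ self.item_factors[message_pos])


# --------------------------------------------------------------------------
# Configs


@dataclass
class GeneratorConfig:
    """Pilot rating-corpus generator settings.

    Defaults emulate the bootstrap corpus: 846 raters, 261 messages,
    20 ratings per rater.  ``factor_scale`` sets the SD of each latent
    coordinate; with D=2 and scale 0.8 the generated ratings have SD ≈ 1,
    a realistic Likert spread.
    """

    n_users: int = 846
    n_messages: int = 261
    ratings_per_user: int = 20
    latent_dim: int = 2
    factor_scale: float = 0.8
    noise_sd: float = 0.5
    offset: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_users", "n_messages", "ratings_per_user", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ratings_per_user > self.n_messages:
            raise ValueError("ratings_per_user cannot exceed n_messages")
        if self.factor_scale < 0 or self.noise_sd < 0:
            raise ValueError("scales must be nonnegative")


@dataclass
class LibraryGenConfig:
    """Synthetic message-library settings.

    Tag proportions default to the canonical library composition:
    102/261 messages with motivational content and 139/261 with
    behavioral-treatment content.
    """

    n_messages: int = 261
    tag_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "MOTIVATIONAL_CONTENT": 102 / 261,
            "BEHAVIORAL_TREATMENT": 139 / 261,
        }
    )
    expert_fraction: float = 0.5
    extra_stage_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_messages <= 0:
            raise ValueError("n_messages must be positive")
        for tag, p in self.tag_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"tag proportion for {tag!r} outside [0,1]")
        if not 0.0 <= self.expert_fraction <= 1.0:
            raise ValueError("expert_fraction outside [0,1]")


class Arm(enum.Enum):
    INTERVENTION = "INTERVENTION"
    COMPARISON = "COMPARISON"


@dataclass
class CohortConfig:
    """Two-arm trial cohort settings.

    ``allocation_block`` is the per-block arm composition applied in
    registration order (default (7, 3): 7 intervention + 3 comparison per
    block of 10, the 2:1 target).  ``arm_effect`` is an additive shift on
    the intervention arm's latent rating propensity (the scalar bias
    component of each participant's preference record); follow-up outcome
    probabilities are logistic in the same quantity.  ``arm_effect`` is the
    simulator's controlled effect size: with it at zero the two arms'
    rating distributions are exchangeable, so participant preference
    heterogeneity (``pref_scale``) defaults to a modest value — enough for
    a recommender to rank a user's messages, small enough that selection
    alone does not move daily means across the agree threshold.
    """

    n_participants: int = 120
    allocation_block: tuple[int, int] = (7, 3)
    n_messages_per_user: int = 30
    followup_rate: float = 0.79
    arm_effect: float = 1.0
    latent_dim: int = 2
    pref_scale: float = 0.3
    bias_sd: float = 0.2
    stage_distribution: tuple[float, ...] = (0.15, 0.55, 0.15, 0.05, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if len(self.allocation_block) != 2 or min(self.allocation_block) < 0:
            raise ValueError("allocation_block must be (intervention, comparison) counts")
        if sum(self.allocation_block) <= 0:
            raise ValueError("allocation_block must be nonempty")
        if not 0.0 <= self.followup_rate <= 1.0:
            raise ValueError("followup_rate outside [0,1]")
        if len(self.stage_distribution) != len(ReadinessStage):
            raise ValueError("stage_distribution needs one weight per ladder level")
        if abs(sum(self.stage_distribution) - 1.0) > 1e-9:
            raise ValueError("stage_distribution must sum to 1")


@dataclass
class Participant:
    id: str
    arm: Arm
    baseline_stage: ReadinessStage
    female: bool
    age_45_plus: bool
    college_graduate: bool
    latent_preference: np.ndarray  # (D,)
    rating_bias: float


@dataclass
class FollowupEffects:
    """Base (comparison-arm) outcome probabilities and arm log-odds slopes.

    Base probabilities follow the comparison arm of the motivating trial:
    ~32% one-day quit, ~30% moved up the ladder, and per-question influence
    agreement between 38% and 81%.  The intervention arm's probabilities are
    shifted on the log-odds scale by ``slope × arm_effect``.
    """

    quit_base_prob: float = 0.32
    quit_slope: float = 0.2
    stage_up_base_prob: float = 0.30
    stage_up_slope: float = 0.2
    influence_base_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "nicotine_replacement": 0.46,
            "talk_to_doctor": 0.57,
            "quit_smoking": 0.62,
            "list_reasons": 0.73,
            "behavioral_strategies": 0.81,
            "get_support": 0.76,
            "set_quit_date": 0.38,
        }
    )
    influence_slope: float = 0.5

    def __post_init__(self) -> None:
        probs = [self.quit_base_prob, self.stage_up_base_prob, *self.influence_base_probs.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("base probabilities must lie in [0,1]")


# --------------------------------------------------------------------------
# Generators


def _exact_count(p: float, n: int) -> int:
    # round half away from zero, matching display-style rounding
    return int(np.floor(p * n + 0.5))


def generate_library(config: LibraryGenConfig | None = None, seed: int | None = None) -> MessageLibrary:
    """Generate a synthetic message library.

    Realized tag counts are exact: ``round(proportion × n)`` messages carry
    each tag (drawn without replacement, independently per tag).  Every
    message gets one uniformly drawn primary stage plus each further stage
    independently with probability ``extra_stage_prob``.  Deterministic for
    a fixed seed.
    """
    config = config or LibraryGenConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n = config.n_messages
    width = max(4, len(str(n)))
    stages_all = list(ReadinessStage)

    tagged: dict[str, set[int]] = {}
    for tag, p in config.tag_proportions.items():
        k = _exact_count(p, n)
        tagged[tag] = set(rng.choice(n, size=k, replace=False).tolist())

    n_expert = _exact_count(config.expert_fraction, n)
    expert_idx = set(rng.choice(n, size=n_expert, replace=False).tolist())

    messages = []
    for i in range(n):
        primary = stages_all[rng.integers(len(stages_all))]
        stages = {primary}
        for s in stages_all:
            if s is not primary and rng.random() < config.extra_stage_prob:
                stages.add(s)
        source = MessageSource.EXPERT if i in expert_idx else MessageSource.PEER
        tags = frozenset(tag for tag, members in tagged.items() if i in members)
        messages.append(
            Message(
                id=f"m{i:0{width}d}",
                text=f"synthetic motivational message {i}",
                source=source,
                stages=frozenset(stages),
                tags=tags,
            )
        )
    return MessageLibrary(messages)


def generate_ratings(
    gc: GeneratorConfig, lib: MessageLibrary | None = None
) -> tuple[RatingDataset, TrueFactors]:
    """Generate a sparse ordinal rating dataset plus its true factors.

    Latent user and item vectors are i.i.d. N(0, factor_scale²) per
    coordinate; the continuous score is ``offset + u·v + N(0, noise_sd)``;
    the ordinal rating is the score rounded and clipped to {1..5}.  Each
    user rates exactly ``ratings_per_user`` distinct messages sampled
    uniformly without replacement; the ``day`` column is the rating ordinal
    (0-based) within the user.
    """
    rng = np.random.default_rng(gc.seed)
    if lib is not None and len(lib) != gc.n_messages:
        raise ValueError(f"library size {len(lib)} != configured n_messages {gc.n_messages}")
    message_ids = lib.ids if lib is not None else [f"m{j:04d}" for j in range(gc.n_messages)]
    user_ids = [f"u{i:04d}" for i in range(gc.n_users)]

    U = rng.normal(0.0, gc.factor_scale, size=(gc.n_users, gc.latent_dim))
    V = rng.normal(0.0, gc.factor_scale, size=(gc.n_messages, gc.latent_dim))

    rows_u = np.empty(gc.n_users * gc.ratings_per_user, dtype=np.int64)
    rows_m = np.empty_like(rows_u)
    for i in range(gc.n_users):
        sl = slice(i * gc.ratings_per_user, (i + 1) * gc.ratings_per_user)
        rows_u[sl] = i
        rows_m[sl] = rng.choice(gc.n_messages, size=gc.ratings_per_user, replace=False)
    scores = gc.offset + np.einsum("nd,nd->n", U[rows_u], V[rows_m])
    scores = scores + rng.normal(0.0, gc.noise_sd, size=scores.shape)
    ratings = ordinal_rating(scores).astype(np.int64)

    frame = pd.DataFrame(
        {
            "user": [user_ids[i] for i in rows_u],
            "message": [message_ids[j] for j in rows_m],
            "rating": ratings,
            "day": np.tile(np.arange(gc.ratings_per_user), gc.n_users),
        }
    )
    data = RatingDataset(frame)
    truth = TrueFactors(
        user_factors=U, item_factors=V, offset=gc.offset, user_ids=user_ids, message_ids=message_ids
    )
    return data, truth


def generate_cohort(cc: CohortConfig) -> list[Participant]:
    """Generate a block-randomized two-arm cohort in registration order.

    Each block holds ``allocation_block`` = (intervention, comparison)
    slots in a seeded random order; blocks are concatenated until
    ``n_participants`` records exist.  Baseline readiness stages follow
    ``stage_distribution``; demographics follow the trial's marginal rates
    (64% female, 38% aged ≥45, 59% college graduates).  The intervention
    arm's scalar rating bias is shifted by ``arm_effect``.
    """
    rng = np.random.default_rng(cc.seed)
    n_int, n_cmp = cc.allocation_block
    block = [Arm.INTERVENTION] * n_int + [Arm.COMPARISON] * n_cmp
    arms: list[Arm] = []
    while len(arms) < cc.n_participants:
        perm = rng.permutation(len(block))
        arms.extend(block[k] for k in perm)
    arms = arms[: cc.n_participants]

    stages = rng.choice(
        len(ReadinessStage), size=cc.n_participants, p=np.asarray(cc.stage_distribution)
    )
    participants = []
    for i, arm in enumerate(arms):
        bias = rng.normal(0.0, cc.bias_sd)
        if arm is Arm.INTERVENTION:
            bias += cc.arm_effect
        participants.append(
            Participant(
                id=f"p{i:04d}",
                arm=arm,
                baseline_stage=ReadinessStage(int(stages[i]) + 1),
                female=bool(rng.random() < 0.64),
                age_45_plus=bool(rng.random() < 0.38),
                college_graduate=bool(rng.random() < 0.59),
                latent_preference=rng.normal(0.0, cc.pref_scale, size=cc.latent_dim),
                rating_bias=float(bias),
            )
        )
    return participants


def cohort_to_frame(cohort: Sequence[Participant]) -> pd.DataFrame:
    """Tidy one-row-per-participant view (latent vector ';'-joined)."""
    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "arm": [p.arm.value for p in cohort],
            "baseline_stage": [p.baseline_stage.name for p in cohort],
            "female": [p.female for p in cohort],
            "age_45_plus": [p.age_45_plus for p in cohort],
            "college_graduate": [p.college_graduate for p in cohort],
            "latent_preference": [
                LIST_SEP.join(f"{x:.6g}" for x in p.latent_preference) for p in cohort
            ],
            "rating_bias": [p.rating_bias for p in cohort],
        }
    )


def _shifted_prob(base: float, slope: float, arm_effect: float, is_intervention: bool) -> float:
    if base <= 0.0:
        return 0.0
    if base >= 1.0:
        return 1.0
    if not is_intervention:
        return base
    return float(expit(logit(base) + slope * arm_effect))


def simulate_followup(
    cohort: Sequence[Participant],
    followup_rate: float,
    effects: FollowupEffects | None = None,
    seed: int = 0,
    arm_effect: float | None = None,
) -> pd.DataFrame:
    """Simulate 30-day follow-up outcomes for a cohort.

    Each participant independently completes follow-up with probability
    ``followup_rate``.  Completers get a one-day-quit indicator, a final
    ladder stage (one rung up with the stage-movement probability, capped
    at the top), and 5-level Likert responses to the seven influence
    questions.  Intervention-arm probabilities are shifted on the log-odds
    scale by the per-outcome slope times ``arm_effect``.

    Returns a tidy frame with one row per participant; outcome columns are
    NA for non-completers.
    """
    if not 0.0 <= followup_rate <= 1.0:
        raise ValueError("followup_rate outside [0,1]")
    effects = effects or FollowupEffects()
    if arm_effect is None:
        arm_effect = 0.0
    rng = np.random.default_rng(seed)
    rows = []
    for p in cohort:
        isi = p.arm is Arm.INTERVENTION
        completed = bool(rng.random() < followup_rate)
        row: dict = {
            "id": p.id,
            "arm": p.arm.value,
            "baseline_stage": p.baseline_stage.name,
            "completed": completed,
        }
        p_quit = _shifted_prob(effects.quit_base_prob, effects.quit_slope, arm_effect, isi)
        p_up = _shifted_prob(effects.stage_up_base_prob, effects.stage_up_slope, arm_effect, isi)
        quit_one_day = bool(rng.random() < p_quit)
        moved = bool(rng.random() < p_up) and p.baseline_stage is not ReadinessStage.ALREADY_QUIT
        final_stage = (
            ReadinessStage(p.baseline_stage + 1) if moved else p.baseline_stage
        )
        influence: dict[str, int] = {}
        for q, base in effects.influence_base_probs.items():
            p_agree = _shifted_prob(base, effects.influence_slope, arm_effect, isi)
            if rng.random() < p_agree:
                influence[q] = int(4 + rng.integers(2))  # agree / strongly agree
            else:
                influence[q] = int(1 + rng.integers(3))  # disagree .. neutral
        if completed:
            row["quit_one_day"] = quit_one_day
            row["final_stage"] = final_stage.name
            for q, v in influence.items():
                row[f"influence_{q}"] = v
        else:
            row["quit_one_day"] = pd.NA
            row["final_stage"] = pd.NA
            for q in influence:
                row[f"influence_{q}"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def make_rating_oracle(
    truth: TrueFactors,
    noise_sd: float = 0.5,
    seed: int = 0,
    bias_lookup: Callable[[Participant], float] | None = None,
) -> Callable[[Participant, str], int]:
    """Build a seeded oracle that rates a message for a trial participant.

    The continuous score is ``offset + u_p·v_m + bias_p + noise``, with the
    message factors ``v_m`` taken from *truth* (the same latent space the
    pilot corpus was generated from) and ``u_p`` the participant's latent
    preference vector; the returned rating is round-and-clipped to 1..5.
    """
    rng = np.random.default_rng(seed)
    vindex = {m: j for j, m in enumerate(truth.message_ids)}

    def oracle(participant: Participant, message_id: str) -> int:
        v = truth.item_factors[vindex[message_id]]
        bias = (
            bias_lookup(participant) if bias_lookup is not None else participant.rating_bias
        )
        score = truth.offset + float(participant.latent_preference @ v) + bias
        score += rng.normal(0.0, noise_sd)
        return int(ordinal_rating(score))

    return oracle


def true_score(truth: TrueFactors, participant: Participant, message_id: str) -> float:
    """Noise-free preference score of a participant for a message."""
    j = truth.message_ids.index(message_id)
    return float(
        truth.offset + participant.latent_preference @ truth.item_factors[j] + participant.rating_bias
    )
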