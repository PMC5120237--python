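"""Strong-generalization algorithm bake-off.

Test users are held out of training entirely; a fitted model sees only a
small budget of each test user's own ratings (5, 10, or 16 of 20) when
inferring user-specific parameters, and is scored on a constant set of 4
held-out ratings per rating fold.  The design is fully crossed:

    algorithm x user fold (5) x train/validation repeat (3)
              x observed-rating budget {5, 10, 16}

with users randomly split into five folds and each test user's ratings
further split into five folds of four test ratings.  Metrics: RMSE,
Kendall tau-b, and NDCG (exponential gain, log2 discount, pessimistic
tie-breaking).  Algorithms are compared to a reference by paired t tests
with Bonferroni correction over matched cells.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import Algorithm
from .synthetic_data import RatingDataset

__all__ = [
    "ProtocolConfig",
    "EvalReport",
    "UserRatingSplit",
    "split_users",
    "split_user_ratings",
    "rmse",
    "kendall_tau_b",
    "ndcg",
    "grid_search",
    "GridSearchResult",
    "run_protocol",
    "paired_bonferroni",
]


# --------------------------------------------------------------------------
# Configuration


@dataclass
class ProtocolConfig:
    n_user_folds: int = 5
    n_train_val_repeats: int = 3
    ratings_folds_per_user: int = 5
    observed_sizes: tuple[int, ...] = (5, 10, 16)
    test_ratings_per_fold: int = 4
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_user_folds, self.n_train_val_repeats, self.ratings_folds_per_user) < 1:
            raise ValueError("fold/repeat counts must be positive")
        if self.test_ratings_per_fold < 1:
            raise ValueError("test_ratings_per_fold must be positive")
        if any(s < 1 for s in self.observed_sizes):
            raise ValueError("observed sizes must be positive")

    def required_ratings_per_user(self) -> int:
        return max(
            self.ratings_folds_per_user * self.test_ratings_per_fold,
            max(self.observed_sizes) + self.test_ratings_per_fold,
        )


# --------------------------------------------------------------------------
# Metrics


def rmse(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Root mean squared error."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predicted and actual must be equal-length nonempty vectors")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b rank correlation with tie correction.

    tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2)), with n0 the number of
    pairs, n1/n2 the tied pairs within x and within y.  Returns NaN when
    either vector is entirely tied (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0.0:
        return float("nan")
    return (conc - disc) / denom


def _dcg(relevances: np.ndarray) -> float:
    ranks = np.arange(1, len(relevances) + 1)
    return float(np.sum((2.0 ** relevances - 1.0) / np.log2(ranks + 1)))


def ndcg(
    predicted_scores: Sequence[float], true_relevances: Sequence[float], depth: int | None = None
) -> float:
    """Normalized discounted cumulative gain of the predicted ordering.

    Gain is exponential, ``(2^rel - 1) / log2(rank + 1)``.  Ties in the
    predicted scores are broken pessimistically (lowest true relevance
    first), so reported NDCG never benefits from ties.  Returns NaN when
    every relevance is zero (the ideal DCG is then zero).
    """
    p = np.asarray(predicted_scores, dtype=float)
    r = np.asarray(true_relevances, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("inputs must be equal-length nonempty vectors")
    if depth is None:
        depth = len(p)
    if depth < 1:
        raise ValueError("depth must be positive")
    # sort by predicted desc; within ties, ascending relevance (worst case)
    order = sorted(range(len(p)), key=lambda i: (-p[i], r[i]))
    ideal = np.sort(r)[::-1]
    idcg = _dcg(ideal[:depth])
    if idcg == 0.0:
        return float("nan")
    return _dcg(r[order][:depth]) / idcg


# --------------------------------------------------------------------------
# Splits


def split_users(
    users: Sequence, n_folds: int, seed: int | np.random.Generator = 0
) -> list[list]:
    """Random partition of users into folds with sizes differing by <= 1."""
    users = list(users)
    if len(users) < n_folds:
        raise ValueError(f"need at least {n_folds} users, got {len(users)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(users))
    base, extra = divmod(len(users), n_folds)
    folds, start = [], 0
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        folds.append([users[i] for i in perm[start : start + size]])
        start += size
    return folds


@dataclass
class UserRatingSplit:
    """Per-user rating folds: test indices plus per-size observed indices."""

    user: object
    folds: list[dict]  # each: {"test": [idx...], "observed": {size: [idx...]}}


def split_user_ratings(
    user_ratings: pd.DataFrame | Sequence,
    cfg: ProtocolConfig,
    seed: int | np.random.Generator = 0,
    user=None,
) -> UserRatingSplit:
    """Split one user's ratings into test folds and observed subsets.

    Each of the ``ratings_folds_per_user`` test folds holds exactly
    ``test_ratings_per_fold`` ratings; for every observed budget, a subset
    of that size is drawn from the remaining ratings, so observed and test
    sets are disjoint by construction.
    """
    n = len(user_ratings)
    need = cfg.required_ratings_per_user()
    if n < need:
        raise ValueError(f"user {user!r} has {n} ratings; protocol requires >= {need}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = []
    k = cfg.test_ratings_per_fold
    for f in range(cfg.ratings_folds_per_user):
        test = perm[f * k : (f + 1) * k].tolist()
        pool = np.asarray([i for i in range(n) if i not in set(test)])
        observed = {}
        for size in sorted(cfg.observed_sizes):
            if size > len(pool):
                raise ValueError(
                    f"observed size {size} exceeds the {len(pool)} non-test ratings"
                )
            observed[size] = rng.choice(pool, size=size, replace=False).tolist()
        folds.append({"test": test, "observed": observed})
    return UserRatingSplit(user=user, folds=folds)


# --------------------------------------------------------------------------
# Grid search with boundary extension


@dataclass
class GridSearchResult:
    params: dict
    validation_rmse: float
    n_evaluations: int
    extensions: dict[str, int]
    boundary_warning: bool
    trace: pd.DataFrame


def _extend(values: list, direction: int) -> list:
    """Extend a numeric grid by one step at the given end."""
    if len(values) < 2:
        return values
    if direction < 0:
        step = values[1] - values[0]
        new = values[0] - step
    else:
        step = values[-1] - values[-2]
        new = values[-1] + step
    if isinstance(values[0], int) and isinstance(step, int):
        new = int(new)
    if direction < 0 and new <= 0 and all(v > 0 for v in values):
        return values  # keep positive-only grids positive
    return ([new] + values) if direction < 0 else (values + [new])


def grid_search(
    make_algorithm: Callable[..., Algorithm],
    grid: Mapping[str, Sequence],
    train: RatingDataset,
    validation: Sequence[tuple[Mapping, Mapping]],
    seed: int = 0,
    max_extensions: int = 5,
) -> GridSearchResult:
    """Exhaustive grid search on validation RMSE with boundary extension.

    ``validation`` is a list of (observed, test) pairs, each a mapping
    message -> rating for one held-out user.  If the selected value of any
    hyperparameter sits at an endpoint of its range, the range is extended
    one step in that direction and the search repeats, up to
    ``max_extensions`` rounds; a persisting boundary selection is flagged.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("every hyperparameter needs a nonempty value list")
    grid = {k: list(v) for k, v in grid.items()}
    extensions = {k: 0 for k in grid}
    evaluated: dict[tuple, float] = {}
    rows = []

    def evaluate(params: dict) -> float:
        key = tuple(sorted(params.items()))
        if key not in evaluated:
            alg = make_algorithm(**params)
            alg.fit(train, seed=seed)
            errs: list[float] = []
            for observed, test in validation:
                targets = list(test)
                preds = alg.predict_for_user(observed, targets)
                errs.extend((preds - np.asarray([test[t] for t in targets])) ** 2)
            evaluated[key] = float(np.sqrt(np.mean(errs)))
            rows.append({**params, "validation_rmse": evaluated[key]})
        return evaluated[key]

    boundary_warning = False
    for round_idx in range(max_extensions + 1):
        names = list(grid)
        best_params, best_err = None, np.inf
        for combo in itertools.product(*(grid[k] for k in names)):
            params = dict(zip(names, combo))
            err = evaluate(params)
            if err < best_err:
                best_params, best_err = params, err
        assert best_params is not None
        to_extend = []
        for k, values in grid.items():
            if len(values) < 2:
                continue
            if best_params[k] == values[0]:
                to_extend.append((k, -1))
            elif best_params[k] == values[-1]:
                to_extend.append((k, +1))
        if not to_extend:
            break
        if round_idx == max_extensions:
            # cap reached with a boundary value still selected
            boundary_warning = True
            break
        grew = False
        for k, direction in to_extend:
            new_values = _extend(grid[k], direction)
            if new_values != grid[k]:
                grid[k] = new_values
                extensions[k] += 1
                grew = True
        if not grew:
            boundary_warning = True
            break

    return GridSearchResult(
        params=best_params,
        validation_rmse=best_err,
        n_evaluations=len(evaluated),
        extensions=extensions,
        boundary_warning=boundary_warning,
        trace=pd.DataFrame(rows),
    )


# --------------------------------------------------------------------------
# Protocol driver


@dataclass
class EvalReport:
    """Tidy per-cell metric table plus bookkeeping from a protocol run."""

    cells: pd.DataFrame
    config: ProtocolConfig
    user_folds: list[list]
    hyperparameters: dict[str, dict]
    splits: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def cell_table(self, metric: str) -> pd.DataFrame:
        return self.cells.pivot_table(
            index=["user_fold", "repeat", "observed_size"], columns="algorithm", values=metric
        )

    def summary(self) -> pd.DataFrame:
        return (
            self.cells.groupby(["algorithm", "observed_size"])[["rmse", "kendall_tau_b", "ndcg"]]
            .mean()
            .reset_index()
        )

    def save(self, path) -> None:
        self.cells.to_csv(path, index=False)


def run_protocol(
    algorithms: Mapping[str, Algorithm],
    dataset: RatingDataset,
    cfg: ProtocolConfig | None = None,
    record_splits: bool = False,
) -> EvalReport:
    """Run the full strong-generalization bake-off.

    For each user fold, every algorithm is fitted on all other users'
    ratings (refitted per repeat with a distinct derived seed); each test
    user's ratings are split into test folds and observed subsets; metrics
    are aggregated per (algorithm, user fold, repeat, observed size) cell.
    RMSE pools all of a cell's prediction errors; tau-b and NDCG are
    averaged over the per-(user, rating-fold) lists, skipping lists where
    the statistic is undefined.
    """
    cfg = cfg or ProtocolConfig()
    counts = dataset.triplets.groupby("user").size()
    need = cfg.required_ratings_per_user()
    too_few = counts[counts < need]
    if len(too_few):
        raise ValueError(
            f"users with fewer than {need} ratings: {list(too_few.index[:5])}"
        )

    rng = np.random.default_rng(cfg.seed)
    user_folds = split_users(dataset.users, cfg.n_user_folds, rng)
    by_user = {u: g.reset_index(drop=True) for u, g in dataset.triplets.groupby("user")}

    rows = []
    split_log: dict = {}
    for fold_idx, test_users in enumerate(user_folds):
        test_set = set(test_users)
        train_users = [u for u in dataset.users if u not in test_set]
        train = dataset.subset_users(train_users)
        for repeat in range(cfg.n_train_val_repeats):
            fit_seed = int((cfg.seed * 1009 + fold_idx * 101 + repeat * 7 + 1) % (2**31))
            # per-(algorithm, cell) accumulators
            acc: dict[tuple, dict] = {
                (name, size): {"sq": [], "tau": [], "ndcg": []}
                for name in algorithms
                for size in cfg.observed_sizes
            }
            fitted = {}
            for name, alg in algorithms.items():
                alg.fit(train, seed=fit_seed)
                fitted[name] = alg
            for user in test_users:
                ur = by_user[user]
                split_seed = zlib.crc32(f"{user}|{repeat}|{cfg.seed}".encode()) % (2**31)
                split = split_user_ratings(
                    ur, cfg, np.random.default_rng(split_seed), user=user
                )
                if record_splits:
                    split_log[(fold_idx, repeat, str(user))] = split
                for fold in split.folds:
                    test_idx = fold["test"]
                    test_msgs = ur["message"].iloc[test_idx].tolist()
                    test_vals = ur["rating"].iloc[test_idx].to_numpy(dtype=float)
                    for size in cfg.observed_sizes:
                        obs_idx = fold["observed"][size]
                        observed = dict(
                            zip(
                                ur["message"].iloc[obs_idx],
                                ur["rating"].iloc[obs_idx].astype(float),
                            )
                        )
                        for name, alg in fitted.items():
                            if hasattr(alg, "current_user"):
                                alg.current_user = user
                            preds = np.asarray(alg.predict_for_user(observed, test_msgs))
                            cell = acc[(name, size)]
                            cell["sq"].extend((preds - test_vals) ** 2)
                            t = kendall_tau_b(preds, test_vals)
                            if not math.isnan(t):
                                cell["tau"].append(t)
                            g = ndcg(preds, test_vals)
                            if not math.isnan(g):
                                cell["ndcg"].append(g)
            for (name, size), cell in acc.items():
                rows.append(
                    {
                        "algorithm": name,
                        "user_fold": fold_idx,
                        "repeat": repeat,
                        "observed_size": size,
                        "rmse": float(np.sqrt(np.mean(cell["sq"]))),
                        "kendall_tau_b": float(np.mean(cell["tau"])) if cell["tau"] else np.nan,
                        "ndcg": float(np.mean(cell["ndcg"])) if cell["ndcg"] else np.nan,
                        "n_predictions": len(cell["sq"]),
                    }
                )
    cells = pd.DataFrame(rows)
    return EvalReport(
        cells=cells,
        config=cfg,
        user_folds=user_folds,
        hyperparameters={name: alg.hyperparameters for name, alg in algorithms.items()},
        splits=split_log,
    )


# --------------------------------------------------------------------------
# Paired comparisons


def paired_bonferroni(
    report: EvalReport | pd.DataFrame, metric: str = "rmse", reference: str = "bpmf"
) -> pd.DataFrame:
    """Paired t tests of the reference against every competitor.

    Cells are matched on (user fold, repeat, observed size); the adjusted
    p-value is ``min(1, raw_p x n_competitors)``.  A zero-variance,
    nonzero-mean difference vector makes t undefined and is flagged in the
    ``degenerate`` column (identical vectors give t=0, p=1).
    """
    cells = report.cells if isinstance(report, EvalReport) else report
    wide = cells.pivot_table(
        index=["user_fold", "repeat", "observed_size"], columns="algorithm", values=metric
    )
    if reference not in wide.columns:
        raise ValueError(f"reference algorithm {reference!r} not in report")
    competitors = [c for c in wide.columns if c != reference]
    if len(wide) < 2:
        raise ValueError("need at least two paired cells")
    out = []
    for comp in competitors:
        pair = wide[[reference, comp]].dropna()
        d = (pair[reference] - pair[comp]).to_numpy()
        n = len(d)
        sd = d.std(ddof=1) if n > 1 else 0.0
        if sd <= 1e-12 * max(1.0, float(abs(d).max(initial=0.0))):
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
                degenerate = False
            else:
                t, p = np.nan, np.nan
                degenerate = True
        else:
            t = d.mean() / (sd / math.sqrt(n))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
            degenerate = False
        out.append(
            {
                "competitor": comp,
                "n_cells": n,
                "mean_difference": float(d.mean()),
                "t": t,
                "p_raw": p,
                "p_adjusted": min(1.0, p * len(competitors)) if not math.isnan(p) else np.nan,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(out)
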