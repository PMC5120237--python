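"""Uniform cold-start interface over the rating-prediction methods.

The strong-generalization bake-off treats every method the same way:
``fit`` on the training users' ratings, then ``predict_for_user`` for a
test user described only by a handful of observed (message -> rating)
pairs.  These adapters wrap the estimators in :mod:`.recommender_core`
behind that interface.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import recommender_core as rc
from .synthetic_data import RatingDataset

__all__ = [
    "Algorithm",
    "BPMFAlgorithm",
    "PMFAlgorithm",
    "KNNAlgorithm",
    "BaselineAlgorithm",
    "OracleAlgorithm",
    "default_algorithms",
]


class Algorithm:
    """Fit-once, cold-start-predict interface used by the protocol."""

    name: str = "algorithm"

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        raise NotImplementedError

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        raise NotImplementedError

    @property
    def hyperparameters(self) -> dict:
        return {}


class BPMFAlgorithm(Algorithm):
    name = "bpmf"

    def __init__(self, config: rc.FactorModelConfig | None = None, **overrides):
        base = config or rc.FactorModelConfig()
        if overrides:
            from dataclasses import replace

            base = replace(base, **overrides)
        self.config = base
        self.model: rc.PosteriorSamples | None = None

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        from dataclasses import replace

        self.model = rc.fit_bpmf(train, replace(self.config, seed=seed))

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        assert self.model is not None, "fit before predicting"
        known = {m: r for m, r in observed.items() if m in self.model.message_index}
        u = rc.infer_new_user(self.model, known)
        known_targets = [t for t in targets if t in self.model.message_index]
        preds = dict(zip(known_targets, rc.predict_new_user(self.model, u, known_targets)))
        return np.asarray([preds.get(t, self.model.global_offset) for t in targets])

    @property
    def hyperparameters(self) -> dict:
        return {
            "latent_dim": self.config.latent_dim,
            "noise_precision": self.config.noise_precision,
            "n_samples": self.config.n_samples,
            "burn_in": self.config.burn_in,
        }


class PMFAlgorithm(Algorithm):
    name = "pmf"

    def __init__(self, config: rc.PmfConfig | None = None, **overrides):
        base = config or rc.PmfConfig()
        if overrides:
            from dataclasses import replace

            base = replace(base, **overrides)
        self.config = base
        self.model: rc.FactorModel | None = None

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        from dataclasses import replace

        self.model = rc.fit_pmf(train, replace(self.config, seed=seed))

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        assert self.model is not None
        known = {m: r for m, r in observed.items() if m in self.model.message_index}
        u = self.model.infer_new_user(known)
        known_targets = [t for t in targets if t in self.model.message_index]
        preds = dict(zip(known_targets, self.model.predict_new_user(u, known_targets)))
        return np.asarray([preds.get(t, self.model.global_offset) for t in targets])

    @property
    def hyperparameters(self) -> dict:
        return {"latent_dim": self.config.latent_dim, "regularization": self.config.regularization}


class KNNAlgorithm(Algorithm):
    name = "knn"

    def __init__(self, config: rc.KnnConfig | None = None, **overrides):
        from dataclasses import replace

        base = config or rc.KnnConfig()
        if overrides:
            base = replace(base, **overrides)
        self.config = base
        self.train: RatingDataset | None = None

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        self.train = train

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        assert self.train is not None
        return np.asarray(
            [
                rc.knn_predict(self.train, self.config, None, t, profile=observed)
                for t in targets
            ]
        )

    @property
    def hyperparameters(self) -> dict:
        return {"k": self.config.k, "min_overlap": self.config.min_overlap}


class BaselineAlgorithm(Algorithm):
    def __init__(self, mode: str = "GLOBAL_MEAN"):
        if mode not in rc.BASELINE_MODES:
            raise ValueError(f"mode must be one of {rc.BASELINE_MODES}")
        self.mode = mode
        self.name = mode.lower()
        self.train: RatingDataset | None = None

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        self.train = train

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        assert self.train is not None
        if self.mode == "USER_MEAN":
            # cold-start user mean comes from the observed ratings
            val = float(np.mean(list(observed.values()))) if observed else self.train.global_mean
            return np.full(len(targets), val)
        return np.asarray(
            [rc.baseline_predict(self.train, self.mode, None, t) for t in targets]
        )

    @property
    def hyperparameters(self) -> dict:
        return {"mode": self.mode}


class OracleAlgorithm(Algorithm):
    """Returns the true held-out rating; a structural test plug-in."""

    name = "oracle"

    def __init__(self, lookup: Mapping):
        self.lookup = dict(lookup)  # (user, message) -> rating
        self.current_user = None

    def fit(self, train: RatingDataset, seed: int = 0) -> None:
        pass

    def predict_for_user(self, observed: Mapping, targets: Sequence) -> np.ndarray:
        return np.asarray([self.lookup[(self.current_user, t)] for t in targets], dtype=float)


def default_algorithms() -> dict[str, Algorithm]:
    return {
        "bpmf": BPMFAlgorithm(),
        "pmf": PMFAlgorithm(),
        "knn": KNNAlgorithm(),
        "global_mean": BaselineAlgorithm("GLOBAL_MEAN"),
        "message_mean": BaselineAlgorithm("MESSAGE_MEAN"),
        "user_mean": BaselineAlgorithm("USER_MEAN"),
    }
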