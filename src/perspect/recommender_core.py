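"""Rating-prediction models: BPMF, MAP PMF, user K-NN, and mean baselines.

The deployed model is Bayesian probabilistic matrix factorization (BPMF):
a hierarchical Gaussian factor model of the centred ratings matrix,

    r_ij - mu  ~  N(u_i · v_j, 1/alpha),
    u_i ~ N(mu_U, Lambda_U^-1),   v_j ~ N(mu_V, Lambda_V^-1),
    (mu_U, Lambda_U), (mu_V, Lambda_V) ~ Normal-Wishart(mu0, beta0, W0, nu0),

inferred by Gibbs sampling.  A prediction is the posterior expectation of
``mu + u_i·v_j`` over the retained samples, clipped to the 1–5 rating scale.

Cold-start ("strong generalization") prediction for a user absent from
training keeps every non-user-specific parameter frozen: for each retained
posterior sample, the new user's factor is the conditional Gaussian
posterior mean given that sample's item factors and hyperparameters and the
user's few observed ratings — a ridge regression with prior precision
Lambda_U and design rows v_j.

PMF is the MAP point-estimate counterpart, fitted by alternating ridge
least squares.  K-NN is classical user-based collaborative filtering with
Pearson similarity.  The mean baselines are the reference floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import wishart

from .synthetic_data import RATING_MAX, RATING_MIN, RatingDataset

__all__ = [
    "NormalWishartPrior",
    "FactorModelConfig",
    "PosteriorSamples",
    "PmfConfig",
    "FactorModel",
    "KnnConfig",
    "fit_bpmf",
    "predict",
    "infer_new_user",
    "predict_new_user",
    "fit_pmf",
    "knn_predict",
    "baseline_predict",
]


def clip_rating(x):
    return np.clip(x, RATING_MIN, RATING_MAX)


# --------------------------------------------------------------------------
# Configuration


@dataclass
class NormalWishartPrior:
    """Conjugate Normal-Wishart hyperprior for a factor population."""

    mu0: np.ndarray  # (D,)
    beta0: float = 2.0
    W0: np.ndarray | None = None  # (D, D); identity when None
    nu0: float | None = None  # defaults to D

    @classmethod
    def default(cls, latent_dim: int) -> "NormalWishartPrior":
        return cls(
            mu0=np.zeros(latent_dim),
            beta0=2.0,
            W0=np.eye(latent_dim),
            nu0=float(latent_dim),
        )

    def resolved(self, latent_dim: int) -> "NormalWishartPrior":
        mu0 = np.asarray(self.mu0, dtype=float)
        if mu0.shape != (latent_dim,):
            raise ValueError(f"mu0 must have shape ({latent_dim},)")
        W0 = np.eye(latent_dim) if self.W0 is None else np.asarray(self.W0, dtype=float)
        nu0 = float(latent_dim) if self.nu0 is None else float(self.nu0)
        if nu0 < latent_dim:
            raise ValueError("nu0 must be >= latent_dim")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if W0.shape != (latent_dim, latent_dim) or not np.allclose(W0, W0.T):
            raise ValueError("W0 must be symmetric (D, D)")
        np.linalg.cholesky(W0)  # raises if not positive definite
        return NormalWishartPrior(mu0=mu0, beta0=self.beta0, W0=W0, nu0=nu0)


@dataclass
class FactorModelConfig:
    """BPMF sampler settings.

    ``noise_precision`` (alpha) is the fixed observation precision of the
    centred ratings; 2.0 is the conventional default for 1–5 scales.
    """

    latent_dim: int = 10
    noise_precision: float = 2.0
    prior: NormalWishartPrior | None = None
    n_samples: int = 200
    burn_in: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.noise_precision <= 0:
            raise ValueError("noise_precision must be positive")


@dataclass
class PosteriorSamples:
    """Retained Gibbs samples of a fitted BPMF model."""

    user_factors: np.ndarray  # (S, N, D)
    item_factors: np.ndarray  # (S, M, D)
    user_hyper_mean: np.ndarray  # (S, D)
    user_hyper_precision: np.ndarray  # (S, D, D)
    global_offset: float
    user_index: dict
    message_index: dict
    config: FactorModelConfig

    @property
    def sample_count(self) -> int:
        return self.user_factors.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.user_factors.shape[2]

    def item_vectors(self, message_ids: Sequence) -> np.ndarray:
        """(S, len(ids), D) item factors for the given message ids."""
        idx = [self.message_index[m] for m in message_ids]
        return self.item_factors[:, idx, :]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        cfg = self.config
        prior = cfg.prior.resolved(cfg.latent_dim) if cfg.prior else NormalWishartPrior.default(cfg.latent_dim)
        meta = {
            "global_offset": self.global_offset,
            "users": list(self.user_index),
            "messages": list(self.message_index),
            "config": {
                "latent_dim": cfg.latent_dim,
                "noise_precision": cfg.noise_precision,
                "n_samples": cfg.n_samples,
                "burn_in": cfg.burn_in,
                "seed": cfg.seed,
                "prior": {
                    "mu0": prior.mu0.tolist(),
                    "beta0": prior.beta0,
                    "W0": prior.W0.tolist(),
                    "nu0": prior.nu0,
                },
            },
        }
        np.savez_compressed(
            path,
            user_factors=self.user_factors,
            item_factors=self.item_factors,
            user_hyper_mean=self.user_hyper_mean,
            user_hyper_precision=self.user_hyper_precision,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            prior_doc = meta["config"].pop("prior")
            prior = NormalWishartPrior(
                mu0=np.asarray(prior_doc["mu0"]),
                beta0=prior_doc["beta0"],
                W0=np.asarray(prior_doc["W0"]),
                nu0=prior_doc["nu0"],
            )
            cfg = FactorModelConfig(prior=prior, **meta["config"])
            return cls(
                user_factors=z["user_factors"],
                item_factors=z["item_factors"],
                user_hyper_mean=z["user_hyper_mean"],
                user_hyper_precision=z["user_hyper_precision"],
                global_offset=meta["global_offset"],
                user_index={u: i for i, u in enumerate(meta["users"])},
                message_index={m: j for j, m in enumerate(meta["messages"])},
                config=cfg,
            )


# --------------------------------------------------------------------------
# BPMF Gibbs sampler


def _group_structure(idx: np.ndarray, n_groups: int):
    """Sort order plus reduceat boundaries for grouped accumulation.

    Returns (order, starts, counts) such that ``order`` sorts rows by
    group, ``starts[g]`` is the first sorted position of group g, and
    groups with zero rows are flagged by counts == 0.
    """
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    counts = np.bincount(idx, minlength=n_groups)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return order, sorted_idx, starts, counts


def _sample_hyper(
    factors: np.ndarray, prior: NormalWishartPrior, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu, Lambda) from the Normal-Wishart conditional posterior."""
    n, d = factors.shape
    xbar = factors.mean(axis=0)
    S = (factors - xbar).T @ (factors - xbar)
    beta_n = prior.beta0 + n
    mu_n = (prior.beta0 * prior.mu0 + n * xbar) / beta_n
    dev = (xbar - prior.mu0)[:, None]
    W_inv = np.linalg.inv(prior.W0) + S + (prior.beta0 * n / beta_n) * (dev @ dev.T)
    W_n = np.linalg.inv(W_inv)
    W_n = (W_n + W_n.T) / 2.0
    nu_n = prior.nu0 + n
    Lam = wishart.rvs(df=nu_n, scale=W_n, random_state=rng)
    Lam = np.atleast_2d(Lam)
    cov = np.linalg.inv(beta_n * Lam)
    mu = rng.multivariate_normal(mu_n, (cov + cov.T) / 2.0)
    return mu, Lam


def _sample_factors(
    other: np.ndarray,  # (M, D) conditioning factors
    row_of: np.ndarray,  # sorted row indices aligned with cols/vals
    cols_sorted: np.ndarray,
    vals_sorted: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    mu: np.ndarray,
    Lam: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Batched conditional Gaussian draw of all row factors."""
    n = len(counts)
    d = other.shape[1]
    G = other[cols_sorted]  # (R, D)
    outer = np.einsum("rd,re->rde", G, G)
    prec = alpha * np.add.reduceat(outer, starts, axis=0)
    rhs = alpha * np.add.reduceat(G * vals_sorted[:, None], starts, axis=0)
    # reduceat misbehaves for empty groups; every row is required to have
    # at least one rating (checked by the caller)
    prec += Lam[None, :, :]
    rhs = rhs + (Lam @ mu)[None, :]
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    cov = np.linalg.inv(prec)
    L = np.linalg.cholesky((cov + cov.transpose(0, 2, 1)) / 2.0)
    z = rng.standard_normal((n, d))
    return mean + np.einsum("nde,ne->nd", L, z)


def fit_bpmf(data: RatingDataset, cfg: FactorModelConfig | None = None) -> PosteriorSamples:
    """Fit BPMF by Gibbs sampling.

    Ratings are centred by the training mean (the global offset) before
    factorization.  Each sweep draws (i) Normal-Wishart hyperparameters for
    the user and item populations, (ii) every user factor from its
    conditional Gaussian given the item factors and that user's ratings,
    (iii) item factors symmetrically.  The first ``burn_in`` sweeps are
    discarded; the remaining ``n_samples`` sweeps are retained.
    Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        if the dataset is empty, or a user or message has no ratings
        (cold-start entities must go through :func:`infer_new_user`).
    """
    cfg = cfg or FactorModelConfig()
    if len(data) == 0:
        raise ValueError("cannot fit on an empty dataset")
    u_idx, m_idx, r = data.arrays()
    n, m = data.n_users, data.n_messages
    if np.bincount(u_idx, minlength=n).min() == 0 or np.bincount(m_idx, minlength=m).min() == 0:
        raise ValueError(
            "every user and message must have at least one rating; "
            "use infer_new_user for cold-start entities"
        )
    d = cfg.latent_dim
    prior = (cfg.prior or NormalWishartPrior.default(d)).resolved(d)
    alpha = cfg.noise_precision
    rng = np.random.default_rng(cfg.seed)

    offset = data.global_mean
    rc = r - offset

    uo, u_sorted, u_starts, u_counts = _group_structure(u_idx, n)
    mo, m_sorted, m_starts, m_counts = _group_structure(m_idx, m)
    u_cols, u_vals = m_idx[uo], rc[uo]
    m_cols, m_vals = u_idx[mo], rc[mo]

    U = rng.normal(0.0, 0.1, size=(n, d))
    V = rng.normal(0.0, 0.1, size=(m, d))

    S = cfg.n_samples
    Us = np.empty((S, n, d))
    Vs = np.empty((S, m, d))
    mus = np.empty((S, d))
    lams = np.empty((S, d, d))

    for sweep in range(cfg.burn_in + S):
        mu_u, lam_u = _sample_hyper(U, prior, rng)
        mu_v, lam_v = _sample_hyper(V, prior, rng)
        U = _sample_factors(V, u_sorted, u_cols, u_vals, u_starts, u_counts, mu_u, lam_u, alpha, rng)
        V = _sample_factors(U, m_sorted, m_cols, m_vals, m_starts, m_counts, mu_v, lam_v, alpha, rng)
        k = sweep - cfg.burn_in
        if k >= 0:
            Us[k], Vs[k], mus[k], lams[k] = U, V, mu_u, lam_u

    return PosteriorSamples(
        user_factors=Us,
        item_factors=Vs,
        user_hyper_mean=mus,
        user_hyper_precision=lams,
        global_offset=offset,
        user_index=dict(data.user_index),
        message_index=dict(data.message_index),
        config=cfg,
    )


def predict(model: PosteriorSamples, user, message) -> float:
    """Posterior-mean rating prediction, clipped to [1, 5]."""
    try:
        i = model.user_index[user]
    except KeyError:
        raise KeyError(f"unknown user {user!r}") from None
    try:
        j = model.message_index[message]
    except KeyError:
        raise KeyError(f"unknown message {message!r}") from None
    raw = np.einsum("sd,sd->s", model.user_factors[:, i, :], model.item_factors[:, j, :])
    return float(clip_rating(raw.mean() + model.global_offset))


def infer_new_user(
    model: PosteriorSamples, observed: Mapping, *, noise_precision: float | None = None
) -> np.ndarray:
    """Per-sample cold-start user factors from a few observed ratings.

    For each retained sample s, the returned factor is the conditional
    Gaussian posterior mean given that sample's item factors, that sample's
    user-population hyperparameters, and the observed ratings (centred by
    the global offset): a ridge solve with prior precision Lambda_U^(s).

    With no observed ratings the prior mean factor (zero vector) is
    returned for every sample, so predictions fall back to the offset.
    """
    S, d = model.sample_count, model.latent_dim
    if len(observed) == 0:
        return np.zeros((S, d))
    unknown = [mid for mid in observed if mid not in model.message_index]
    if unknown:
        raise KeyError(f"messages not known to the model: {unknown}")
    alpha = noise_precision if noise_precision is not None else model.config.noise_precision
    mids = list(observed)
    rc = np.asarray([observed[mid] for mid in mids], dtype=float) - model.global_offset
    Vo = model.item_vectors(mids)  # (S, k, D)
    prec = model.user_hyper_precision + alpha * np.einsum("skd,ske->sde", Vo, Vo)
    rhs = (
        np.einsum("sde,se->sd", model.user_hyper_precision, model.user_hyper_mean)
        + alpha * np.einsum("skd,k->sd", Vo, rc)
    )
    return np.linalg.solve(prec, rhs[..., None])[..., 0]


def predict_new_user(
    model: PosteriorSamples, user_factors: np.ndarray, messages: Sequence
) -> np.ndarray:
    """Predictions for a cold-start user given per-sample factors (S, D)."""
    Vm = model.item_vectors(messages)  # (S, k, D)
    raw = np.einsum("sd,skd->k", user_factors, Vm) / model.sample_count
    return clip_rating(raw + model.global_offset)


# --------------------------------------------------------------------------
# MAP probabilistic matrix factorization (alternating ridge least squares)


@dataclass
class PmfConfig:
    latent_dim: int = 10
    regularization: float = 0.5
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.regularization < 0 or self.max_iter < 1:
            raise ValueError("invalid PMF configuration")


@dataclass
class FactorModel:
    """Point-estimate factor model (MAP PMF)."""

    user_factors: np.ndarray  # (N, D)
    item_factors: np.ndarray  # (M, D)
    global_offset: float
    user_index: dict
    message_index: dict
    config: PmfConfig
    objective_history: list[float] = field(default_factory=list)

    def predict(self, user, message) -> float:
        i = self.user_index[user]
        j = self.message_index[message]
        return float(clip_rating(self.user_factors[i] @ self.item_factors[j] + self.global_offset))

    def infer_new_user(self, observed: Mapping) -> np.ndarray:
        """Ridge-regression user factor from observed ratings (cold start)."""
        if len(observed) == 0:
            return np.zeros(self.item_factors.shape[1])
        mids = list(observed)
        Vo = self.item_factors[[self.message_index[m] for m in mids]]
        rc = np.asarray([observed[m] for m in mids], dtype=float) - self.global_offset
        lam = self.config.regularization
        return np.linalg.solve(Vo.T @ Vo + lam * np.eye(Vo.shape[1]), Vo.T @ rc)

    def predict_new_user(self, user_factor: np.ndarray, messages: Sequence) -> np.ndarray:
        Vm = self.item_factors[[self.message_index[m] for m in messages]]
        return clip_rating(Vm @ user_factor + self.global_offset)


def _ridge_update(
    other: np.ndarray,
    cols_sorted: np.ndarray,
    vals_sorted: np.ndarray,
    starts: np.ndarray,
    lam: float,
) -> np.ndarray:
    d = other.shape[1]
    G = other[cols_sorted]
    outer = np.einsum("rd,re->rde", G, G)
    A = np.add.reduceat(outer, starts, axis=0) + lam * np.eye(d)[None]
    b = np.add.reduceat(G * vals_sorted[:, None], starts, axis=0)
    return np.linalg.solve(A, b[..., None])[..., 0]


def fit_pmf(data: RatingDataset, cfg: PmfConfig | None = None) -> FactorModel:
    """MAP PMF by alternating ridge least squares on centred ratings.

    Each alternation exactly minimises the penalised squared error in one
    factor block, so the objective is monotone non-increasing; iteration
    stops when the relative objective change drops below ``tol``.
    """
    cfg = cfg or PmfConfig()
    if len(data) == 0:
        raise ValueError("cannot fit on an empty dataset")
    u_idx, m_idx, r = data.arrays()
    n, m, d = data.n_users, data.n_messages, cfg.latent_dim
    offset = data.global_mean
    rc = r - offset
    rng = np.random.default_rng(cfg.seed)

    uo, _, u_starts, _ = _group_structure(u_idx, n)
    mo, _, m_starts, _ = _group_structure(m_idx, m)
    u_cols, u_vals = m_idx[uo], rc[uo]
    m_cols, m_vals = u_idx[mo], rc[mo]

    U = rng.normal(0.0, 0.1, size=(n, d))
    V = rng.normal(0.0, 0.1, size=(m, d))
    lam = cfg.regularization

    def objective() -> float:
        resid = rc - np.einsum("rd,rd->r", U[u_idx], V[m_idx])
        return float(resid @ resid + lam * ((U * U).sum() + (V * V).sum()))

    history = [objective()]
    for _ in range(cfg.max_iter):
        U = _ridge_update(V, u_cols, u_vals, u_starts, lam)
        V = _ridge_update(U, m_cols, m_vals, m_starts, lam)
        history.append(objective())
        prev, cur = history[-2], history[-1]
        if prev - cur <= cfg.tol * max(abs(prev), 1.0):
            break

    return FactorModel(
        user_factors=U,
        item_factors=V,
        global_offset=offset,
        user_index=dict(data.user_index),
        message_index=dict(data.message_index),
        config=cfg,
        objective_history=history,
    )


# --------------------------------------------------------------------------
# User-based K-NN with Pearson similarity


@dataclass
class KnnConfig:
    k: int = 20
    similarity: str = "PEARSON"
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.similarity != "PEARSON":
            raise ValueError("only PEARSON similarity is supported")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _pearson(a: np.ndarray, b: np.ndarray, min_overlap: int) -> float | None:
    """Pearson correlation over co-rated items; None when undefined."""
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < min_overlap:
        return None
    x, y = a[mask], b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def knn_predict(
    data: RatingDataset,
    cfg: KnnConfig,
    user,
    message,
    *,
    profile: Mapping | None = None,
) -> float:
    """User-based K-NN prediction.

    Neighbours are the K users most Pearson-similar to the target (overlap
    of co-rated items at least ``min_overlap``) who rated the target
    message; the prediction is the target's mean plus the
    similarity-weighted average of neighbours' mean-centred ratings.  Ties
    in similarity break toward the lower user row index.  Fallback chain:
    message mean, then global mean.

    A cold-start user can be supplied as ``profile`` (message -> rating)
    instead of a trained ``user`` id.
    """
    mat = data.matrix()
    if profile is not None:
        target = np.full(data.n_messages, np.nan)
        for mid, val in profile.items():
            if mid in data.message_index:
                target[data.message_index[mid]] = float(val)
    else:
        if user not in data.user_index:
            raise KeyError(f"unknown user {user!r}")
        target = mat[data.user_index[user]]
    if message not in data.message_index:
        return float(clip_rating(data.global_mean))
    j = data.message_index[message]

    target_seen = ~np.isnan(target)
    target_mean = float(np.nanmean(target)) if target_seen.any() else data.global_mean

    candidates: list[tuple[float, int]] = []
    for i in range(data.n_users):
        if profile is None and i == data.user_index[user]:
            continue
        if np.isnan(mat[i, j]):
            continue
        sim = _pearson(target, mat[i], cfg.min_overlap)
        if sim is None:
            continue
        candidates.append((sim, i))
    # K most similar; equal similarity resolved toward the lower row index
    candidates.sort(key=lambda t: (-t[0], t[1]))
    top = candidates[: cfg.k]

    if top:
        wsum = sum(abs(s) for s, _ in top)
        if wsum > 0:
            num = sum(s * (mat[i, j] - np.nanmean(mat[i])) for s, i in top)
            return float(clip_rating(target_mean + num / wsum))
    col = mat[:, j]
    if np.isfinite(col).any():
        return float(clip_rating(np.nanmean(col)))
    return float(clip_rating(data.global_mean))


# --------------------------------------------------------------------------
# Mean baselines

BASELINE_MODES = ("GLOBAL_MEAN", "MESSAGE_MEAN", "USER_MEAN")


def baseline_predict(data: RatingDataset, mode: str, user=None, message=None) -> float:
    """The named mean, with global-mean fallback for empty groups."""
    if mode not in BASELINE_MODES:
        raise ValueError(f"mode must be one of {BASELINE_MODES}")
    if len(data) == 0:
        raise ValueError("empty dataset")
    g = data.global_mean
    if mode == "GLOBAL_MEAN":
        return float(g)
    if mode == "MESSAGE_MEAN":
        sel = data.triplets["rating"][data.triplets["message"] == message]
        return float(sel.mean()) if len(sel) else float(g)
    sel = data.triplets["rating"][data.triplets["user"] == user]
    return float(sel.mean()) if len(sel) else float(g)
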