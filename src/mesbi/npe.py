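"""Amortized neural posterior estimation for the middle-ear model.

The workflow mirrors standard simulation-based inference: draw parameter
sets from a box prior, run the deterministic simulator, flatten to
observation vectors, inject measurement noise, z-score both sides, and
train a conditional density estimator q(theta | x) by maximum likelihood.
Once trained, the estimator answers any number of observations without
further simulation (amortization): posterior samples, log-densities, and
MAP estimates all come from the learned conditional density.

The public surface is the sklearn-style :class:`NeuralPosterior`
estimator; the module-level functions (:func:`sample_prior`,
:func:`build_training_set`, :func:`train_npe`, :func:`sample_posterior`,
:func:`map_estimate`) are thin wrappers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .features import FeatureScaler, FeatureVector, NoiseModel, assemble_batch
from .mdn import MDN
from .simulator import (
    PARAM_NAMES,
    FixedConstants,
    FrequencyGrid,
    MiddleEarParams,
    simulate_batch,
)

__all__ = [
    "PriorBox",
    "ArchConfig",
    "TrainingSet",
    "NeuralPosterior",
    "PosteriorModel",
    "sample_prior",
    "build_training_set",
    "train_npe",
    "sample_posterior",
    "map_estimate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorBox:
    """Independent box prior over the seven parameters.

    Each parameter is uniform between its bounds, on a linear or log
    scale.  Setting ``low == high`` clamps a parameter (useful for slice
    studies); clamped parameters are excluded from the learned density
    and reinserted as constants in samples.
    """

    low: tuple = (1.0, 0.005, 1.0, 1.0, 1.0, 0.05, 3.0)
    high: tuple = (20.0, 1.0, 10.0, 10.0, 10.0, 0.2, 30.0)
    scale: tuple = ("linear",) * 7
    names: tuple = PARAM_NAMES

    def __post_init__(self) -> None:
        lo, hi = self.low_arr, self.high_arr
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValueError("low/high must match the parameter names")
        if np.any(lo > hi) or np.any(lo <= 0):
            raise ValueError("need 0 < low <= high for every parameter")
        for s in self.scale:
            if s not in ("linear", "log"):
                raise ValueError(f"unknown sampling scale {s!r}")

    @property
    def low_arr(self) -> np.ndarray:
        return np.asarray(self.low, dtype=float)

    @property
    def high_arr(self) -> np.ndarray:
        return np.asarray(self.high, dtype=float)

    @property
    def free_mask(self) -> np.ndarray:
        return self.low_arr < self.high_arr

    def sample(self, n: int, seed=0) -> np.ndarray:
        """n iid draws, uniform per parameter on its stated scale."""
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo, hi = self.low_arr, self.high_arr
        u = rng.uniform(size=(n, lo.shape[0]))
        out = np.empty_like(u)
        for j, s in enumerate(self.scale):
            if s == "log":
                out[:, j] = np.exp(np.log(lo[j]) + u[:, j] * (np.log(hi[j]) - np.log(lo[j])))
            else:
                out[:, j] = lo[j] + u[:, j] * (hi[j] - lo[j])
        return out

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta >= self.low_arr) & (theta <= self.high_arr), axis=1)

    def clamp(self, **fixed: float) -> "PriorBox":
        """Return a prior with the named parameters fixed at given values."""
        lo, hi = list(self.low), list(self.high)
        for name, value in fixed.items():
            j = self.names.index(name)
            lo[j] = hi[j] = float(value)
        return PriorBox(low=tuple(lo), high=tuple(hi), scale=self.scale, names=self.names)


@dataclass(frozen=True)
class ArchConfig:
    """Density-estimator architecture and optimization settings.

    Defaults: a 3x50 tanh embedding network feeding a Gaussian-mixture
    head with 8 components; Adam at 5e-4, batch 200, 10% validation
    split, early-stop patience 20, at most 500 epochs.
    """

    embedding_layers: int = 3
    embedding_units: int = 50
    n_components: int = 8
    mean_skip: bool = False
    lr: float = 5e-4
    batch_size: int = 200
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embedding_layers, self.embedding_units, self.n_components,
               self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("architecture counts must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainingSet:
    """Paired prior draws and noise-injected observation vectors."""

    thetas: np.ndarray  # (N, 7)
    features: np.ndarray  # (N, d) after masking
    noise: NoiseModel
    prior: PriorBox
    grid: FrequencyGrid
    feature_mask: np.ndarray | None = None  # bool over the full 5F vector
    seed: int = 0
    n_resampled: int = 0

    def __post_init__(self) -> None:
        if self.thetas.shape[0] != self.features.shape[0]:
            raise ValueError("thetas and features must have matching rows")


def sample_prior(prior: PriorBox, n: int, seed=0) -> np.ndarray:
    """Draw n parameter sets from the prior (thin wrapper)."""
    return prior.sample(n, seed)


def build_training_set(
    prior: PriorBox,
    n: int,
    noise: NoiseModel,
    seed: int = 0,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
    feature_mask: np.ndarray | None = None,
) -> TrainingSet:
    """Simulate n prior draws and build the noise-injected training pairs.

    Any draw whose simulation fails its validity checks is resampled (the
    count is logged); with the shipped surrogate this does not occur for
    in-prior draws.
    """
    if n < 2:
        raise ValueError("need n >= 2 training pairs")
    grid = grid or FrequencyGrid()
    rng = np.random.default_rng(seed)
    thetas = prior.sample(n, rng)
    n_resampled = 0
    for _ in range(100):
        try:
            vst, zec, ab = simulate_batch(thetas, grid, constants)
            break
        except (ValueError, FloatingPointError):
            # locate failing rows one by one and redraw them
            bad = []
            for i in range(n):
                try:
                    simulate_batch(thetas[i : i + 1], grid, constants)
                except (ValueError, FloatingPointError):
                    bad.append(i)
            if not bad:
                raise
            n_resampled += len(bad)
            thetas[bad] = prior.sample(len(bad), rng)
    else:
        raise RuntimeError("simulator kept failing after repeated resampling")
    if n_resampled:
        logger.info("resampled %d failing prior draws", n_resampled)
    clean = assemble_batch(vst, zec, ab)
    noisy = clean + noise.scale * noise.sigma * rng.standard_normal(clean.shape)
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        noisy = noisy[:, feature_mask]
    return TrainingSet(
        thetas=thetas,
        features=noisy,
        noise=noise,
        prior=prior,
        grid=grid,
        feature_mask=feature_mask,
        seed=seed,
        n_resampled=n_resampled,
    )


class NeuralPosterior(BaseEstimator):
    """Amortized conditional posterior estimator q(theta | x).

    sklearn-style estimator: ``fit(X, y)`` takes observation vectors X
    (N, d) and parameter rows y (N, 7); afterwards :meth:`sample`,
    :meth:`log_prob`, :meth:`map_estimate` and :meth:`predict` answer
    arbitrarily many observations without further simulation.

    Parameters clamped in the prior (``low == high``) are excluded from
    the learned density and reinserted as constants.

    Attributes (fitted)
    -------------------
    mdn_ : the trained mixture density network (standardized space)
    theta_scaler_, feature_scaler_ : the z-scoring transforms
    history_ : training history (per-epoch train loss / validation
        log-density, plus the untrained initialization's score)
    free_idx_ : indices of the non-clamped parameters
    last_rejection_fraction_ : out-of-prior rejection rate of the most
        recent :meth:`sample` call
    """

    def __init__(
        self,
        prior: PriorBox | None = None,
        arch: ArchConfig | None = None,
        sigma_floor: float = 1e-12,
    ):
        self.prior = prior
        self.arch = arch
        self.sigma_floor = sigma_floor

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, metadata: dict | None = None):
        prior = self.prior if self.prior is not None else PriorBox()
        arch = self.arch if self.arch is not None else ArchConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be 2-D with matching rows")
        if X.shape[0] < 50:
            logger.warning("training on only %d pairs; posteriors will be crude", X.shape[0])
        if not np.all(prior.contains(y)):
            raise ValueError("all training thetas must lie inside the prior box")

        self.prior_ = prior
        self.arch_ = arch
        self.free_idx_ = np.flatnonzero(prior.free_mask)
        if self.free_idx_.size == 0:
            raise ValueError("prior clamps every parameter; nothing to infer")
        y_free = y[:, self.free_idx_]

        self.feature_scaler_ = FeatureScaler(eps=self.sigma_floor).fit(X)
        self.theta_scaler_ = FeatureScaler(eps=self.sigma_floor).fit(y_free)
        Xs = self.feature_scaler_.transform(X)
        ys = self.theta_scaler_.transform(y_free)

        self.mdn_ = MDN(
            x_dim=X.shape[1],
            theta_dim=self.free_idx_.size,
            n_components=arch.n_components,
            hidden_units=arch.embedding_units,
            n_hidden_layers=arch.embedding_layers,
            mean_skip=arch.mean_skip,
            seed=arch.seed,
        )
        self.history_ = self.mdn_.fit(
            Xs,
            ys,
            lr=arch.lr,
            batch_size=arch.batch_size,
            max_epochs=arch.max_epochs,
            patience=arch.patience,
            val_fraction=arch.val_fraction,
            seed=arch.seed,
        )
        self.val_logprob_ = max(self.history_.val_logprob)
        self.metadata_ = dict(metadata or {})
        self.metadata_.setdefault("n_train", int(X.shape[0]))
        self.metadata_["final_val_logprob"] = self.val_logprob_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "mdn_"):
            raise RuntimeError("NeuralPosterior is not fitted")

    def _obs(self, x_obs) -> np.ndarray:
        x = x_obs.values if isinstance(x_obs, FeatureVector) else np.asarray(x_obs, float)
        if x.shape != (self.n_features_in_,):
            raise ValueError(
                f"observation must have dimension {self.n_features_in_}, got {x.shape}"
            )
        return self.feature_scaler_.transform(x[None, :])[0]

    # -- posterior queries -------------------------------------------------

    def sample(self, x_obs, n: int, seed=0, max_rounds: int = 200) -> np.ndarray:
        """n posterior draws (n, 7), rejection-sampled into the prior box.

        Clamped parameters are filled in at their fixed values.  Raises if
        more than 99% of proposals fall outside the prior.
        """
        self._check_fitted()
        xs = self._obs(x_obs)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo = self.prior_.low_arr[self.free_idx_]
        hi = self.prior_.high_arr[self.free_idx_]
        accepted: list[np.ndarray] = []
        n_proposed = n_accepted = 0
        for _ in range(max_rounds):
            m = max(n - n_accepted, 1000)
            zs = self.mdn_.sample(xs, m, rng)
            draws = self.theta_scaler_.inverse_transform(zs)
            ok = np.all((draws >= lo) & (draws <= hi), axis=1)
            n_proposed += m
            n_accepted += int(ok.sum())
            accepted.append(draws[ok])
            if n_accepted >= n:
                break
            if n_proposed >= 100 * max(n, 1000) and n_accepted / n_proposed < 0.01:
                raise RuntimeError(
                    "posterior mass leaks outside the prior box "
                    f"(acceptance {n_accepted / n_proposed:.2%})"
                )
        free = np.concatenate(accepted, axis=0)[:n]
        if free.shape[0] < n:
            raise RuntimeError("could not draw enough in-prior posterior samples")
        self.last_rejection_fraction_ = 1.0 - n_accepted / n_proposed
        out = np.tile(self.prior_.low_arr, (n, 1))
        out[:, self.free_idx_] = free
        return out

    def log_prob(self, thetas, x_obs) -> np.ndarray:
        """log q(theta | x) in raw parameter units (Jacobian included)."""
        self._check_fitted()
        xs = self._obs(x_obs)
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        zs = self.theta_scaler_.transform(thetas[:, self.free_idx_])
        jac = -np.sum(np.log(self.theta_scaler_.spread_))
        return self.mdn_.log_prob_single(zs, xs) + jac

    def map_estimate(self, x_obs, n_seed_samples: int = 10_000, seed: int = 0) -> np.ndarray:
        """MAP parameter vector: best of n posterior samples, then local ascent.

        The ascent (L-BFGS-B with the analytic mixture gradient) runs in
        standardized space with the prior box as bounds, so the estimate
        cannot leave the prior.  Deterministic for a fixed seed.
        """
        self._check_fitted()
        xs = self._obs(x_obs)
        samples = self.sample(x_obs, n_seed_samples, seed=seed)
        zs = self.theta_scaler_.transform(samples[:, self.free_idx_])
        lp = self.mdn_.log_prob_single(zs, xs)
        z0 = zs[int(np.argmax(lp))]
        lo = self.theta_scaler_.transform(self.prior_.low_arr[None, self.free_idx_])[0]
        hi = self.theta_scaler_.transform(self.prior_.high_arr[None, self.free_idx_])[0]
        bounds = list(zip(np.minimum(lo, hi), np.maximum(lo, hi)))
        res = minimize(
            lambda z: -self.mdn_.log_prob_single(z[None, :], xs)[0],
            z0,
            jac=lambda z: -self.mdn_.grad_log_prob_single(z, xs),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        z_best = res.x if -res.fun >= lp.max() else z0
        theta = np.array(self.prior_.low_arr)
        theta[self.free_idx_] = self.theta_scaler_.inverse_transform(z_best[None, :])[0]
        theta[self.free_idx_] = np.clip(
            theta[self.free_idx_],
            self.prior_.low_arr[self.free_idx_],
            self.prior_.high_arr[self.free_idx_],
        )
        return theta

    def predict(self, X, seed: int = 0) -> np.ndarray:
        """MAP estimates for each observation row (sklearn-style predict)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([self.map_estimate(x, seed=seed) for x in X])


#: A fitted NeuralPosterior is the posterior-model artifact.
PosteriorModel = NeuralPosterior


def train_npe(training: TrainingSet, arch: ArchConfig | None = None) -> NeuralPosterior:
    """Train a NeuralPosterior on a TrainingSet (thin wrapper)."""
    model = NeuralPosterior(prior=training.prior, arch=arch)
    meta = {
        "noise_scale": training.noise.scale,
        "training_seed": training.seed,
        "feature_mask": None
        if training.feature_mask is None
        else training.feature_mask.tolist(),
        "grid": {
            "n_freq": training.grid.n_freq,
            "f_lo": training.grid.f_lo,
            "f_hi": training.grid.f_hi,
        },
    }
    return model.fit(training.features, training.thetas, metadata=meta)


def sample_posterior(model: NeuralPosterior, x_obs, n: int, seed=0) -> np.ndarray:
    return model.sample(x_obs, n, seed=seed)


def map_estimate(model: NeuralPosterior, x_obs, seed: int = 0) -> MiddleEarParams:
    return MiddleEarParams.from_array(model.map_estimate(x_obs, seed=seed))
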