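"""Observation vectors, measurement-noise model, and synthetic test-retest data.

The three simulated spectra are flattened into one real observation vector
of ``5 * n_freq`` elements (250 on the default grid), in the fixed block
order ``[|Vst| dB, angle(Vst) cycles, |Zec| dB, angle(Zec) cycles, Abs]``.
Magnitudes are 20*log10 of the linear values; phases are unwrapped along
frequency and expressed in cycles, with the first point in (-0.5, 0.5].

Measurement noise is modelled as additive, element-wise independent
Gaussian noise in this feature space, with per-element standard deviations
estimated from replicate (test-retest) measurements and an overall scale
multiplier.  The synthetic test-retest generator emulates a wideband
acoustic immittance + stapes-velocity session repeated K times on a single
specimen: K noisy copies of the same underlying clean response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulator import (
    FixedConstants,
    FrequencyGrid,
    MiddleEarParams,
    SpectrumSet,
    simulate_batch,
    simulate_spectra,
)

__all__ = [
    "BLOCK_NAMES",
    "FeatureVector",
    "NoiseModel",
    "TestRetestDataset",
    "FeatureScaler",
    "assemble_features",
    "assemble_batch",
    "decode_features",
    "block_slices",
    "feature_mask",
    "default_base_sigma",
    "inject_noise",
    "generate_test_retest",
    "estimate_noise_std",
    "fit_scaler",
]

#: Fixed ordering of the five 50-point feature blocks.
BLOCK_NAMES = ("vst_mag_db", "vst_phase_cycles", "zec_mag_db", "zec_phase_cycles", "abs")

# default per-block replicate variability used by the synthetic generator
# (feature units: dB for magnitudes, cycles for phases, absorbance unitless)
DEFAULT_SIGMA_MAG_DB = 0.5
DEFAULT_SIGMA_PHASE_CYCLES = 0.02
DEFAULT_SIGMA_ABS = 0.02


def block_slices(n_freq: int = 50) -> dict[str, slice]:
    """Slice into the flat feature vector for each named block."""
    return {name: slice(i * n_freq, (i + 1) * n_freq) for i, name in enumerate(BLOCK_NAMES)}


def feature_mask(blocks, n_freq: int = 50) -> np.ndarray:
    """Boolean mask over the flat feature vector selecting whole blocks.

    ``blocks`` is an iterable of BLOCK_NAMES entries, or the shorthands
    ``"vst"`` (both stapes-velocity blocks), ``"zec"`` (both impedance
    blocks), ``"abs"``, ``"all"``.
    """
    expand = {
        "vst": ("vst_mag_db", "vst_phase_cycles"),
        "zec": ("zec_mag_db", "zec_phase_cycles"),
        "abs": ("abs",),
        "all": BLOCK_NAMES,
    }
    if isinstance(blocks, str):
        blocks = [blocks]
    names: list[str] = []
    for b in blocks:
        if b in expand:
            names.extend(expand[b])
        elif b in BLOCK_NAMES:
            names.append(b)
        else:
            raise ValueError(f"unknown feature block {b!r}")
    mask = np.zeros(5 * n_freq, dtype=bool)
    sl = block_slices(n_freq)
    for name in names:
        mask[sl[name]] = True
    return mask


@dataclass
class FeatureVector:
    """Flat real observation vector with its grid (length 5 * n_freq)."""

    values: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (5 * self.grid.n_freq,):
            raise ValueError(
                f"feature vector must have length {5 * self.grid.n_freq}, "
                f"got {self.values.shape}"
            )

    def block(self, name: str) -> np.ndarray:
        return self.values[block_slices(self.grid.n_freq)[name]]


def _phase_cycles(z: np.ndarray) -> np.ndarray:
    """Unwrapped phase in cycles along the last (frequency) axis."""
    return np.unwrap(np.angle(z), axis=-1) / (2.0 * np.pi)


def assemble_batch(vst: np.ndarray, z_ec: np.ndarray, abs_ec: np.ndarray) -> np.ndarray:
    """Assemble (N, 5*F) feature matrix from batched spectra arrays."""
    if np.any(np.abs(vst) == 0) or np.any(np.abs(z_ec) == 0):
        raise ValueError("zero magnitude: dB feature undefined")
    return np.concatenate(
        [
            20.0 * np.log10(np.abs(vst)),
            _phase_cycles(vst),
            20.0 * np.log10(np.abs(z_ec)),
            _phase_cycles(z_ec),
            np.asarray(abs_ec, dtype=float),
        ],
        axis=-1,
    )


def assemble_features(spectra: SpectrumSet) -> FeatureVector:
    """Flatten a SpectrumSet into the canonical observation vector."""
    vals = assemble_batch(
        spectra.vst_over_pec[None, :], spectra.z_ec[None, :], spectra.abs_ec[None, :]
    )[0]
    return FeatureVector(values=vals, grid=spectra.grid)


def decode_features(fv: FeatureVector):
    """Inverse of assemble_features: recover (vst, z_ec, abs_ec) arrays."""
    mag_v = 10.0 ** (fv.block("vst_mag_db") / 20.0)
    ph_v = fv.block("vst_phase_cycles") * 2.0 * np.pi
    mag_z = 10.0 ** (fv.block("zec_mag_db") / 20.0)
    ph_z = fv.block("zec_phase_cycles") * 2.0 * np.pi
    return (
        mag_v * np.exp(1j * ph_v),
        mag_z * np.exp(1j * ph_z),
        fv.block("abs").copy(),
    )


# ---------------------------------------------------------------------------
# z-scoring


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Per-element z-scoring with a floored spread (sklearn transformer).

    Uses the sample standard deviation (divisor n-1).  Elements that are
    constant across the fitting set get their spread floored at ``eps`` so
    the transform stays finite; their transformed values are 0.
    """

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("scaler needs a 2-D array with at least 2 rows")
        self.center_ = X.mean(axis=0)
        self.spread_ = np.maximum(X.std(axis=0, ddof=1), self.eps)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.center_) / self.spread_

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        return X * self.spread_ + self.center_

    def to_dict(self) -> dict:
        return {
            "eps": self.eps,
            "center": self.center_.tolist(),
            "spread": self.spread_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        sc = cls(eps=d["eps"])
        sc.center_ = np.asarray(d["center"], dtype=float)
        sc.spread_ = np.asarray(d["spread"], dtype=float)
        sc.n_features_in_ = sc.center_.shape[0]
        return sc


def fit_scaler(vectors, eps: float = 1e-12) -> FeatureScaler:
    """Fit a FeatureScaler on a stack of vectors (rows)."""
    return FeatureScaler(eps=eps).fit(np.asarray(vectors, dtype=float))


# ---------------------------------------------------------------------------
# noise model and synthetic test-retest data


@dataclass
class NoiseModel:
    """Additive Gaussian noise: x' = x + scale * sigma * eps, eps ~ N(0, 1)."""

    sigma: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative elementwise")
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")

    def with_scale(self, scale: float) -> "NoiseModel":
        return NoiseModel(sigma=self.sigma.copy(), scale=scale)


def default_base_sigma(
    grid: FrequencyGrid | None = None,
    mag_db: float = DEFAULT_SIGMA_MAG_DB,
    phase_cycles: float = DEFAULT_SIGMA_PHASE_CYCLES,
    absorbance: float = DEFAULT_SIGMA_ABS,
) -> np.ndarray:
    """Default per-element replicate STD for the synthetic generator.

    Per-block constants in feature units; the shape of real test-retest
    variability across frequency is specimen-specific and not modelled.
    """
    grid = grid or FrequencyGrid()
    n = grid.n_freq
    return np.concatenate(
        [
            np.full(n, mag_db),
            np.full(n, phase_cycles),
            np.full(n, mag_db),
            np.full(n, phase_cycles),
            np.full(n, absorbance),
        ]
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def inject_noise(x, noise: NoiseModel, seed) -> np.ndarray:
    """Add seeded Gaussian noise to a feature vector or matrix of rows."""
    arr = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if arr.shape[-1] != noise.sigma.shape[0]:
        raise ValueError("sigma length does not match feature dimension")
    eps = _rng(seed).standard_normal(arr.shape)
    out = arr + noise.scale * noise.sigma * eps
    if isinstance(x, FeatureVector):
        return FeatureVector(values=out, grid=x.grid)
    return out


@dataclass
class TestRetestDataset:
    """K replicate observation vectors of one specimen, with summary stats.

    ``mean`` and ``std`` are the elementwise sample mean/STD (ddof=1) of
    the replicates; ``theta_true`` is recorded for synthetic data and
    ``None`` for imported real measurements.
    """

    replicates: np.ndarray  # (K, 5F)
    grid: FrequencyGrid
    theta_true: np.ndarray | None = None
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.ndim != 2 or self.replicates.shape[0] < 2:
            raise ValueError("need at least K=2 replicates")
        if self.replicates.shape[1] != 5 * self.grid.n_freq:
            raise ValueError("replicate length does not match grid")
        if self.mean is None:
            self.mean = self.replicates.mean(axis=0)
        if self.std is None:
            self.std = self.replicates.std(axis=0, ddof=1)
        if self.theta_true is not None:
            self.theta_true = np.asarray(self.theta_true, dtype=float)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


def estimate_noise_std(dataset: TestRetestDataset) -> np.ndarray:
    """Per-element sample STD (ddof=1) across replicates."""
    if dataset.n_replicates < 2:
        raise ValueError("need at least 2 replicates to estimate noise")
    return dataset.replicates.std(axis=0, ddof=1)


def generate_test_retest(
    theta_true: MiddleEarParams | np.ndarray,
    n_replicates: int = 17,
    base_sigma: np.ndarray | None = None,
    seed=0,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
) -> TestRetestDataset:
    """Synthesize a K-replicate test-retest session for one specimen.

    Simulates the clean response at ``theta_true`` and draws K independent
    Gaussian perturbations of it with per-element STD ``base_sigma``
    (defaults to :func:`default_base_sigma`).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    grid = grid or FrequencyGrid()
    if isinstance(theta_true, MiddleEarParams):
        theta_true = theta_true.to_array()
    theta_true = np.asarray(theta_true, dtype=float)
    spectra = simulate_spectra(MiddleEarParams.from_array(theta_true), grid, constants)
    clean = assemble_features(spectra).values
    sigma = default_base_sigma(grid) if base_sigma is None else np.asarray(base_sigma, float)
    noise = NoiseModel(sigma=sigma, scale=1.0)
    rng = _rng(seed)
    reps = inject_noise(np.tile(clean, (n_replicates, 1)), noise, rng)
    return TestRetestDataset(replicates=reps, grid=grid, theta_true=theta_true)
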