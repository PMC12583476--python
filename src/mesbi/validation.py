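"""Evaluation program: spectral agreement, posterior width, exact oracle, sweeps.

Diagnostics follow the standard recipe for validating amortized posterior
estimators against a known simulator:

* **MAP re-simulation** — infer the MAP for an observation, push it back
  through the simulator, and score monotonic agreement per feature block
  with Spearman's rank correlation over the frequency grid.
* **Coefficient of variation** — posterior STD / posterior mean per
  parameter, a relative width of the inferred distribution.
* **Grid oracle** — because the simulator is deterministic and the noise
  model Gaussian, the exact posterior on a 2-parameter slice (others
  clamped) is computable by brute-force grid evaluation of
  log N(x_obs; f(theta), (s*sigma)^2) + log prior; this is an
  NPE-independent reference.
* **Experiment suites** — held-out validation, noise-scale sweep
  (0.1/1/10x), training-size sweep (100/1000/10000), and single-feature
  versus multi-feature training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .features import (
    BLOCK_NAMES,
    FeatureVector,
    NoiseModel,
    TestRetestDataset,
    assemble_batch,
    assemble_features,
    block_slices,
    default_base_sigma,
    estimate_noise_std,
    feature_mask,
    generate_test_retest,
)
from .npe import ArchConfig, NeuralPosterior, PriorBox, TrainingSet, build_training_set, train_npe
from .simulator import (
    PARAM_NAMES,
    FixedConstants,
    FrequencyGrid,
    MiddleEarParams,
    SpectrumSet,
    simulate_batch,
    simulate_spectra,
)

__all__ = [
    "ValidationReport",
    "MarginalHistograms",
    "GridPosterior",
    "spearman_spectra",
    "coefficient_of_variation",
    "marginal_histograms",
    "grid_oracle_posterior",
    "run_experiment_suite",
]


@dataclass
class ValidationReport:
    """Per-feature Spearman agreement and per-parameter posterior width."""

    rho: dict  # block name -> rho (may be NaN for constant blocks)
    mean_rho: float
    mean_abs_rho: float
    cv: np.ndarray | None = None  # (7,) posterior CV per parameter
    coverage95: np.ndarray | None = None  # bool (7,), theta_true in central 95%
    theta_map: np.ndarray | None = None
    theta_true: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "rho": {k: None if np.isnan(v) else float(v) for k, v in self.rho.items()},
            "mean_rho": float(self.mean_rho),
            "mean_abs_rho": float(self.mean_abs_rho),
        }
        for name in ("cv", "coverage95", "theta_map", "theta_true"):
            v = getattr(self, name)
            out[name] = None if v is None else np.asarray(v).tolist()
        return out


def _as_feature_values(obj) -> np.ndarray:
    if isinstance(obj, SpectrumSet):
        return assemble_features(obj).values
    if isinstance(obj, FeatureVector):
        return obj.values
    return np.asarray(obj, dtype=float)


def spearman_spectra(a, b, n_freq: int = 50):
    """Per-block Spearman rho between two spectra/feature vectors.

    Accepts SpectrumSet, FeatureVector or raw 5*n_freq arrays.  Ties get
    average ranks (scipy convention); a constant block has undefined rank
    correlation and is reported as NaN and excluded from the means.
    Returns (rho_dict, mean_rho, mean_abs_rho).
    """
    va, vb = _as_feature_values(a), _as_feature_values(b)
    if va.shape != vb.shape:
        raise ValueError("inputs must share the same feature layout")
    sl = block_slices(n_freq)
    rho = {}
    for name in BLOCK_NAMES:
        xa, xb = va[sl[name]], vb[sl[name]]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rho[name] = float("nan")
        else:
            rho[name] = float(spearmanr(xa, xb).statistic)
    vals = np.array([v for v in rho.values() if not np.isnan(v)])
    if vals.size == 0:
        raise ValueError("all feature blocks constant; Spearman undefined")
    return rho, float(vals.mean()), float(np.abs(vals).mean())


def coefficient_of_variation(samples: np.ndarray) -> np.ndarray:
    """Per-column CV = sample STD (ddof=1) / sample mean."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    mean = samples.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("CV undefined for non-positive means")
    return samples.std(axis=0, ddof=1) / mean


# ---------------------------------------------------------------------------
# histograms


@dataclass
class MarginalHistograms:
    """1D and pairwise 2D posterior histograms over the prior box."""

    edges_1d: list  # per parameter, bin edges
    counts_1d: np.ndarray  # (7, bins_1d)
    pairs: list  # list of (i, j) index pairs
    counts_2d: np.ndarray  # (n_pairs, bins_2d, bins_2d)
    n_samples: int


def marginal_histograms(
    samples: np.ndarray,
    prior: PriorBox,
    bins_1d: int = 50,
    bins_2d: int = 30,
) -> MarginalHistograms:
    """Histogram posterior samples over the full prior ranges."""
    samples = np.asarray(samples, dtype=float)
    n, d = samples.shape
    lo, hi = prior.low_arr, prior.high_arr
    edges_1d, counts_1d = [], []
    for j in range(d):
        e = np.linspace(lo[j], hi[j], bins_1d + 1) if lo[j] < hi[j] else np.array([lo[j] - 0.5, hi[j] + 0.5])
        c, e = np.histogram(samples[:, j], bins=e)
        edges_1d.append(e)
        counts_1d.append(c)
    pad = max(len(c) for c in counts_1d)
    counts_arr = np.zeros((d, pad), dtype=int)
    for j, c in enumerate(counts_1d):
        counts_arr[j, : len(c)] = c
    pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
    counts_2d = np.zeros((len(pairs), bins_2d, bins_2d), dtype=int)
    for p, (i, j) in enumerate(pairs):
        ei = np.linspace(lo[i], hi[i], bins_2d + 1) if lo[i] < hi[i] else np.array([lo[i] - 0.5, hi[i] + 0.5])
        ej = np.linspace(lo[j], hi[j], bins_2d + 1) if lo[j] < hi[j] else np.array([lo[j] - 0.5, hi[j] + 0.5])
        h, _, _ = np.histogram2d(samples[:, i], samples[:, j], bins=[ei, ej])
        counts_2d[p, : h.shape[0], : h.shape[1]] = h.astype(int)
    return MarginalHistograms(
        edges_1d=edges_1d,
        counts_1d=counts_arr,
        pairs=pairs,
        counts_2d=counts_2d,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# exact grid oracle


@dataclass
class GridPosterior:
    """Exact posterior on a 2-parameter slice, on a regular grid."""

    pair: tuple  # (i, j) parameter indices
    axes: tuple  # (values_i, values_j) cell-center coordinates
    log_post: np.ndarray  # (R, R) unnormalized
    prob: np.ndarray  # (R, R), sums to 1
    argmax_cell: tuple


def grid_oracle_posterior(
    pair: tuple,
    clamped: np.ndarray | MiddleEarParams,
    x_obs: np.ndarray,
    noise: NoiseModel,
    prior: PriorBox,
    resolution: int = 50,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
    mask: np.ndarray | None = None,
) -> GridPosterior:
    """Brute-force exact posterior over two parameters, others clamped.

    Evaluates the Gaussian log-likelihood
    ``sum_e log N(x_obs[e]; f(theta)[e], (scale * sigma[e])^2)`` on a
    ``resolution x resolution`` grid of cell centers spanning the two
    parameters' prior ranges, adds the (flat) log prior, and normalizes
    in log space.  Entirely independent of the neural estimator.
    """
    grid = grid or FrequencyGrid()
    i, j = pair
    if isinstance(clamped, MiddleEarParams):
        clamped = clamped.to_array()
    clamped = np.asarray(clamped, dtype=float)
    sig = noise.scale * noise.sigma
    if mask is not None:
        sig = sig[mask]
    if np.any(sig <= 0):
        raise ValueError("oracle needs strictly positive noise STD on used elements")
    lo, hi = prior.low_arr, prior.high_arr
    # cell centers of a regular partition of the prior rectangle
    ci = lo[i] + (np.arange(resolution) + 0.5) * (hi[i] - lo[i]) / resolution
    cj = lo[j] + (np.arange(resolution) + 0.5) * (hi[j] - lo[j]) / resolution
    II, JJ = np.meshgrid(ci, cj, indexing="ij")
    thetas = np.tile(clamped, (resolution * resolution, 1))
    thetas[:, i] = II.ravel()
    thetas[:, j] = JJ.ravel()
    vst, zec, ab = simulate_batch(thetas, grid, constants)
    f = assemble_batch(vst, zec, ab)
    if mask is not None:
        f = f[:, mask]
    x = np.asarray(x_obs, dtype=float)
    loglik = -0.5 * np.sum(((x - f) / sig) ** 2, axis=1) - np.sum(np.log(sig))
    log_post = loglik.reshape(resolution, resolution)  # + flat log prior (const)
    prob = np.exp(log_post - logsumexp(log_post))
    prob /= prob.sum()
    amax = np.unravel_index(int(np.argmax(prob)), prob.shape)
    return GridPosterior(pair=pair, axes=(ci, cj), log_post=log_post, prob=prob, argmax_cell=amax)


# ---------------------------------------------------------------------------
# experiment suites


def _map_report(model, x_obs_values, reference_values, theta_true=None,
                n_posterior=4000, seed=0, grid=None, constants=None,
                n_freq=50) -> ValidationReport:
    """Common path: MAP -> re-simulate -> Spearman (+ CV/coverage)."""
    theta_map = model.map_estimate(x_obs_values, seed=seed)
    spectra = simulate_spectra(MiddleEarParams.from_array(theta_map), grid, constants)
    x_map = assemble_features(spectra).values
    rho, mean_rho, mean_abs = spearman_spectra(reference_values, x_map, n_freq=n_freq)
    samples = model.sample(x_obs_values, n_posterior, seed=seed + 1)
    cv = coefficient_of_variation(samples)
    coverage = None
    if theta_true is not None:
        qlo = np.quantile(samples, 0.025, axis=0)
        qhi = np.quantile(samples, 0.975, axis=0)
        coverage = (theta_true >= qlo) & (theta_true <= qhi)
    return ValidationReport(
        rho=rho,
        mean_rho=mean_rho,
        mean_abs_rho=mean_abs,
        cv=cv,
        coverage95=coverage,
        theta_map=theta_map,
        theta_true=None if theta_true is None else np.asarray(theta_true, float),
    )


def run_experiment_suite(
    kind: str,
    seed: int = 0,
    prior: PriorBox | None = None,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
    base_sigma: np.ndarray | None = None,
    n_train: int = 2000,
    n_heldout: int = 5,
    n_replicates: int = 17,
    arch: ArchConfig | None = None,
    noise_scales: tuple = (0.1, 1.0, 10.0),
    train_sizes: tuple = (100, 1000, 10000),
) -> dict:
    """Run one of the standard evaluation experiments.

    ``kind`` is one of:

    * ``"validation"`` — train once, then for ``n_heldout`` unseen prior
      draws run the MAP-re-simulation loop and report per-feature rho,
      posterior CV and 95% coverage of the truth.
    * ``"noise_sweep"`` — train one estimator per noise scale
      (default 0.1/1/10x the replicate STD) and fit a synthetic
      test-retest reference; reports CV and rho per scale.
    * ``"size_sweep"`` — same reference, one estimator per training-set
      size (default 100/1000/10000).
    * ``"feature_subsets"`` — estimators trained on stapes velocity only,
      impedance only, absorbance only, and all blocks; each MAP fit is
      scored on every block of the full reference.

    Returns a JSON-serializable report dict.
    """
    prior = prior or PriorBox()
    grid = grid or FrequencyGrid()
    arch = arch or ArchConfig()
    if base_sigma is None:
        base_sigma = default_base_sigma(grid)
    rng = np.random.default_rng(seed)

    report: dict = {"kind": kind, "seed": seed, "n_train": n_train}

    if kind == "validation":
        noise = NoiseModel(sigma=base_sigma, scale=1.0)
        ts = build_training_set(prior, n_train, noise, seed=seed, grid=grid, constants=constants)
        model = train_npe(ts, arch)
        reports = []
        stars = prior.sample(n_heldout, rng)
        for k in range(n_heldout):
            sp = simulate_spectra(MiddleEarParams.from_array(stars[k]), grid, constants)
            x = assemble_features(sp).values
            rep = _map_report(model, x, x, theta_true=stars[k], seed=seed + 10 + k,
                              grid=grid, constants=constants, n_freq=grid.n_freq)
            reports.append(rep.to_dict())
        report["heldout"] = reports
        report["mean_rho"] = float(np.mean([r["mean_rho"] for r in reports]))
        return report

    # remaining kinds share a synthetic test-retest reference
    theta_ref = prior.sample(1, rng)[0]
    ds = generate_test_retest(theta_ref, n_replicates=n_replicates, base_sigma=base_sigma,
                              seed=int(rng.integers(2**31)), grid=grid, constants=constants)
    sigma_hat = estimate_noise_std(ds)
    report["theta_ref"] = theta_ref.tolist()

    if kind == "noise_sweep":
        out = []
        for s in noise_scales:
            noise = NoiseModel(sigma=sigma_hat, scale=float(s))
            ts = build_training_set(prior, n_train, noise, seed=seed + 1, grid=grid,
                                    constants=constants)
            model = train_npe(ts, arch)
            rep = _map_report(model, ds.mean, ds.mean, theta_true=theta_ref,
                              seed=seed + 2, grid=grid, constants=constants,
                              n_freq=grid.n_freq)
            out.append({"scale": float(s), **rep.to_dict(),
                        "mean_cv": float(np.mean(rep.cv))})
        report["scales"] = out
        return report

    if kind == "size_sweep":
        noise = NoiseModel(sigma=sigma_hat, scale=1.0)
        out = []
        for n in train_sizes:
            ts = build_training_set(prior, int(n), noise, seed=seed + 1, grid=grid,
                                    constants=constants)
            model = train_npe(ts, arch)
            rep = _map_report(model, ds.mean, ds.mean, theta_true=theta_ref,
                              seed=seed + 2, grid=grid, constants=constants,
                              n_freq=grid.n_freq)
            out.append({"n_train": int(n), **rep.to_dict(),
                        "mean_cv": float(np.mean(rep.cv))})
        report["sizes"] = out
        return report

    if kind == "feature_subsets":
        noise = NoiseModel(sigma=sigma_hat, scale=1.0)
        out = []
        for label in ("vst", "zec", "abs", "all"):
            mask = feature_mask(label, grid.n_freq)
            ts = build_training_set(prior, n_train, noise, seed=seed + 1, grid=grid,
                                    constants=constants, feature_mask=mask)
            model = train_npe(ts, arch)
            theta_map = model.map_estimate(ds.mean[mask], seed=seed + 2)
            sp = simulate_spectra(MiddleEarParams.from_array(theta_map), grid, constants)
            x_map = assemble_features(sp).values
            rho, mean_rho, mean_abs = spearman_spectra(ds.mean, x_map, n_freq=grid.n_freq)
            out.append({
                "subset": label,
                "rho": {k: None if np.isnan(v) else float(v) for k, v in rho.items()},
                "mean_rho": mean_rho,
                "mean_abs_rho": mean_abs,
                "theta_map": theta_map.tolist(),
            })
        report["subsets"] = out
        return report

    raise ValueError(f"unknown experiment kind {kind!r}")
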