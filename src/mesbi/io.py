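"""File formats, run manifests, and seed management.

All numeric text output uses ``%.17g`` so that every float round-trips
exactly; the documented contract is losslessness to 12 significant
digits.  Artifacts:

* spectra CSV — one row per frequency with columns ``freq_hz,
  vst_mag_db, vst_phase_cycles, zec_mag_db, zec_phase_cycles, abs``
  (dB re 1 m/s/Pa and dB re 1 Pa*s*m^-3; phases unwrapped, in cycles);
* test-retest bundle — a directory with ``replicates.csv`` (K rows of
  feature elements), ``mean.csv``, ``std.csv`` and ``meta.json``;
* model bundle — a directory with the network weights (``weights.npz``),
  scalers/prior/architecture (``model.json``) and a ``manifest.json``
  carrying SHA-256 checksums of every file; loading verifies the
  checksums and refuses tampered bundles.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BLOCK_NAMES, FeatureScaler, TestRetestDataset, assemble_features
from .mdn import MDN
from .npe import ArchConfig, NeuralPosterior, PriorBox
from .simulator import FrequencyGrid, SpectrumSet

__all__ = [
    "FORMAT_VERSION",
    "IntegrityError",
    "stage_seed",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_testretest",
    "read_testretest",
    "testretest_from_spectra_csvs",
    "save_model",
    "load_model",
    "write_report",
    "write_manifest",
    "sha256_file",
]

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"

SPECTRA_COLUMNS = ["freq_hz", "vst_mag_db", "vst_phase_cycles", "zec_mag_db",
                   "zec_phase_cycles", "abs"]


class IntegrityError(RuntimeError):
    """A bundle's content does not match its manifest checksums."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one master seed.

    The mapping is ``SeedSequence([master_seed, crc32(stage)])``; the
    result is a non-negative int below 2**31.  Changing either the master
    seed or the stage name changes the derived seed.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# spectra CSV


def write_spectra_csv(path, spectra: SpectrumSet) -> None:
    fv = assemble_features(spectra)
    n = spectra.grid.n_freq
    df = pd.DataFrame({
        "freq_hz": spectra.grid.values,
        "vst_mag_db": fv.block("vst_mag_db"),
        "vst_phase_cycles": fv.block("vst_phase_cycles"),
        "zec_mag_db": fv.block("zec_mag_db"),
        "zec_phase_cycles": fv.block("zec_phase_cycles"),
        "abs": fv.block("abs"),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra_csv(path) -> SpectrumSet:
    """Read a spectra CSV back into a SpectrumSet.

    The grid is reconstructed from the ``freq_hz`` column (assumed
    logarithmically spaced, endpoints inclusive).
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    f = df["freq_hz"].to_numpy(dtype=float)
    grid = FrequencyGrid(n_freq=len(f), f_lo=float(f[0]), f_hi=float(f[-1]))
    vst = 10.0 ** (df["vst_mag_db"].to_numpy() / 20.0) * np.exp(
        2j * np.pi * df["vst_phase_cycles"].to_numpy()
    )
    zec = 10.0 ** (df["zec_mag_db"].to_numpy() / 20.0) * np.exp(
        2j * np.pi * df["zec_phase_cycles"].to_numpy()
    )
    return SpectrumSet(grid=grid, vst_over_pec=vst, z_ec=zec,
                       abs_ec=df["abs"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# test-retest bundle


def _feature_columns(n_freq: int) -> list[str]:
    return [f"{b}_{i}" for b in BLOCK_NAMES for i in range(n_freq)]


def write_testretest(path, ds: TestRetestDataset) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = _feature_columns(ds.grid.n_freq)
    pd.DataFrame(ds.replicates, columns=cols).to_csv(
        path / "replicates.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame([ds.mean], columns=cols).to_csv(
        path / "mean.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame([ds.std], columns=cols).to_csv(
        path / "std.csv", index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "format_version": FORMAT_VERSION,
        "grid": {"n_freq": ds.grid.n_freq, "f_lo": ds.grid.f_lo, "f_hi": ds.grid.f_hi},
        "n_replicates": ds.n_replicates,
        "theta_true": None if ds.theta_true is None else ds.theta_true.tolist(),
        "units": {
            "vst_mag_db": "dB re 1 m s^-1 Pa^-1",
            "vst_phase_cycles": "cycles",
            "zec_mag_db": "dB re 1 Pa s m^-3",
            "zec_phase_cycles": "cycles",
            "abs": "dimensionless in [0, 1]",
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_testretest(path) -> TestRetestDataset:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    grid = FrequencyGrid(**meta["grid"])
    reps = pd.read_csv(path / "replicates.csv").to_numpy(dtype=float)
    theta_true = meta.get("theta_true")
    ds = TestRetestDataset(
        replicates=reps,
        grid=grid,
        theta_true=None if theta_true is None else np.asarray(theta_true, float),
    )
    # cross-check stored summaries against recomputed ones
    mean = pd.read_csv(path / "mean.csv").to_numpy(dtype=float)[0]
    std = pd.read_csv(path / "std.csv").to_numpy(dtype=float)[0]
    if not (np.allclose(mean, ds.mean, rtol=1e-12, atol=0)
            and np.allclose(std, ds.std, rtol=1e-12, atol=1e-300)):
        raise IntegrityError(f"{path}: stored mean/std disagree with replicates")
    return ds


def testretest_from_spectra_csvs(paths) -> TestRetestDataset:
    """Build a replicate dataset from per-replicate spectra CSV files.

    This is the import path for real measurement sessions exported in the
    package's spectra CSV format (one file per test-retest run).
    """
    sets = [read_spectra_csv(p) for p in paths]
    grid = sets[0].grid
    reps = np.stack([assemble_features(s).values for s in sets])
    return TestRetestDataset(replicates=reps, grid=grid, theta_true=None)


# ---------------------------------------------------------------------------
# model bundle


def save_model(path, model: NeuralPosterior) -> None:
    """Serialize a fitted NeuralPosterior to a checksummed directory bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.mdn_.get_weights())
    doc = {
        "format_version": FORMAT_VERSION,
        "prior": {
            "low": list(model.prior_.low),
            "high": list(model.prior_.high),
            "scale": list(model.prior_.scale),
            "names": list(model.prior_.names),
        },
        "arch": asdict(model.arch_),
        "theta_scaler": model.theta_scaler_.to_dict(),
        "feature_scaler": model.feature_scaler_.to_dict(),
        "metadata": model.metadata_,
        "val_logprob": model.val_logprob_,
        "init_val_logprob": model.history_.init_val_logprob,
    }
    (path / "model.json").write_text(json.dumps(doc, indent=2))
    manifest = {
        "format_version": FORMAT_VERSION,
        "files": {name: sha256_file(path / name) for name in ("weights.npz", "model.json")},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> NeuralPosterior:
    """Load a model bundle, verifying the manifest checksums first."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        actual = sha256_file(path / name)
        if actual != digest:
            raise IntegrityError(f"{path / name}: checksum mismatch; refusing to load")
    doc = json.loads((path / "model.json").read_text())
    prior = PriorBox(
        low=tuple(doc["prior"]["low"]),
        high=tuple(doc["prior"]["high"]),
        scale=tuple(doc["prior"]["scale"]),
        names=tuple(doc["prior"]["names"]),
    )
    arch = ArchConfig(**doc["arch"])
    model = NeuralPosterior(prior=prior, arch=arch)
    model.prior_ = prior
    model.arch_ = arch
    model.free_idx_ = np.flatnonzero(prior.free_mask)
    model.theta_scaler_ = FeatureScaler.from_dict(doc["theta_scaler"])
    model.feature_scaler_ = FeatureScaler.from_dict(doc["feature_scaler"])
    with np.load(path / "weights.npz") as z:
        model.mdn_ = MDN.from_weights({k: z[k] for k in z.files})
    model.metadata_ = doc["metadata"]
    model.val_logprob_ = doc["val_logprob"]
    from .mdn import TrainingHistory

    model.history_ = TrainingHistory(init_val_logprob=doc["init_val_logprob"])
    model.n_features_in_ = model.mdn_.x_dim
    return model


# ---------------------------------------------------------------------------
# reports and manifests


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def write_manifest(path, config_hash: str, seeds: dict, files: dict) -> None:
    """Write a run manifest recording config hash, seeds and artifact checksums."""
    from . import __version__

    manifest = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "config_hash": config_hash,
        "seeds": seeds,
        "files": {str(k): v for k, v in files.items()},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
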