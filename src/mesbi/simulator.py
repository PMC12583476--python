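"""Lumped-element surrogate simulator of middle-ear acoustics.

The middle ear is modelled as an acoustic ladder network seen from the
eardrum: a tympanic-membrane branch in series with the parallel combination
of the mallear-ligament branch and the ossicular path, which itself splits
between the soft-tissue (suspensory ligaments/tendons) shunt and the
stapes branch (annular ligament in series with a resistive cochlear load
referred through the ossicular-lever/area transformer).  The ear canal
between the tympanometer probe and the drum is a lossless cylindrical
transmission line; measurement quantities are evaluated on a plane a few
millimetres from the probe, as wideband-tympanometry probes do.

The network maps seven tissue/load parameters -- five Young's moduli, a
structural loss factor, and a cochlear acoustic resistance -- to the three
measured spectra: normalized stapes velocity V_st/P_ec, ear-canal input
impedance Z_ec, and absorbance Abs_ec, on a logarithmic frequency grid.
Each Young's modulus E enters through a geometry-to-stiffness gain g so
that the branch acoustic stiffness is K = g * E (E in MPa); structural
damping makes every stiffness complex, K(1 + j*eta).

Conventions
-----------
* Time dependence ``e^{+j omega t}``: positive reactance is mass-like.
* Impedances are acoustic (Pa*s*m^-3); volume velocities in m^3/s.
* The model is deterministic: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "MiddleEarParams",
    "FixedConstants",
    "FrequencyGrid",
    "SpectrumSet",
    "branch_impedance",
    "middle_ear_input_impedance",
    "tube_transform",
    "characteristic_impedance",
    "compute_absorbance",
    "simulate_spectra",
    "simulate_batch",
]

#: Canonical ordering of the seven inferred parameters.
PARAM_NAMES = (
    "e_drum",
    "e_sal",
    "e_mallear",
    "e_soft",
    "e_joint",
    "damping",
    "cochlear_load",
)

_MPA = 1.0e6  # Young's moduli are carried in MPa
_GOHM = 1.0e9  # cochlear load carried in GΩ acoustic (1e9 Pa*s*m^-3)


@dataclass(frozen=True)
class MiddleEarParams:
    """The seven tuned middle-ear parameters.

    Young's moduli are in MPa, ``damping`` is the dimensionless structural
    loss factor eta, and ``cochlear_load`` is the resistive cochlear
    acoustic impedance in GΩ acoustic (10^9 Pa*s*m^-3).
    """

    e_drum: float
    e_sal: float
    e_mallear: float
    e_soft: float
    e_joint: float
    damping: float
    cochlear_load: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "MiddleEarParams":
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))


@dataclass(frozen=True)
class FixedConstants:
    """Fixed physical constants and surrogate calibration gains.

    ``canal_radius`` and ``plane_distance_from_probe`` mirror the
    wideband-tympanometry measurement convention (pressure and volume
    velocity averaged on a 3 mm radius plane, 3 mm from the probe).  The
    acoustic masses ``m_td``/``m_os`` and the geometry-to-stiffness gains
    ``g_*`` (acoustic stiffness Pa*m^-3 per MPa of modulus) are surrogate
    calibration constants chosen so the network's resonance, absorbance
    peak and low-frequency impedance land in physiologically plausible
    ranges; ``transformer`` is the combined ossicular-lever/area factor
    referring the cochlear load to the drum side.
    """

    rho_air: float = 1.205  # kg/m^3
    c_air: float = 343.0  # m/s
    canal_radius: float = 3.0e-3  # m
    canal_length_probe_to_drum: float = 10.0e-3  # m
    plane_distance_from_probe: float = 3.0e-3  # m
    footplate_area: float = 3.2e-6  # m^2
    m_td: float = 4.5e3  # kg/m^4, tympanic branch acoustic mass
    m_os: float = 2.0e3  # kg/m^4, ossicular branch acoustic mass
    g_td: float = 1.8e4  # (Pa/m^3)/MPa gains, see class docstring
    g_ml: float = 5.0e3
    g_j: float = 2.0e4
    g_s: float = 5.0e3
    g_sal: float = 4.0e5
    transformer: float = 675.0  # dimensionless

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.plane_distance_from_probe < self.canal_length_probe_to_drum:
            raise ValueError("measurement plane must lie between probe and drum")

    @property
    def canal_area(self) -> float:
        """Canal cross-sectional area a = pi r^2 (m^2)."""
        return float(np.pi * self.canal_radius**2)


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmically spaced frequency grid, endpoints inclusive."""

    n_freq: int = 50
    f_lo: float = 250.0
    f_hi: float = 8000.0

    def __post_init__(self) -> None:
        if self.n_freq < 2:
            raise ValueError("n_freq must be >= 2")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")

    @property
    def values(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_freq)

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.values


@dataclass
class SpectrumSet:
    """The three simulated/measured spectra on a common grid.

    ``vst_over_pec`` is complex normalized stapes velocity (m/s/Pa),
    ``z_ec`` the complex ear-canal input impedance (Pa*s*m^-3) at the
    measurement plane, ``abs_ec`` the real absorbance in [0, 1].
    """

    grid: FrequencyGrid
    vst_over_pec: np.ndarray
    z_ec: np.ndarray
    abs_ec: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_freq
        self.vst_over_pec = np.asarray(self.vst_over_pec, dtype=complex)
        self.z_ec = np.asarray(self.z_ec, dtype=complex)
        self.abs_ec = np.asarray(self.abs_ec, dtype=float)
        for name in ("vst_over_pec", "z_ec", "abs_ec"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if not np.all(self.z_ec.real > 0):
            raise ValueError("passivity violated: Re(z_ec) must be > 0 everywhere")
        if np.any(self.abs_ec < -1e-12) or np.any(self.abs_ec > 1 + 1e-12):
            raise ValueError("absorbance must lie in [0, 1]")


# ---------------------------------------------------------------------------
# network elements


def branch_impedance(omega, M, K, eta):
    """Acoustic impedance of a mass--stiffness branch with structural damping.

    Z(omega) = j*omega*M + K*(1 + j*eta)/(j*omega).  The loss factor eta
    multiplies the stiffness imaginary part, giving the frequency law
    Re(Z) = K*eta/omega >= 0 characteristic of structural (hysteretic)
    tissue damping.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be strictly positive")
    if np.any(np.asarray(M) < 0) or np.any(np.asarray(K) < 0) or np.any(np.asarray(eta) < 0):
        raise ValueError("M, K and eta must be non-negative")
    jw = 1j * omega
    return jw * M + K * (1.0 + 1j * np.asarray(eta)) / jw


def _ladder(theta_cols, constants: FixedConstants, omega):
    """Core ladder evaluation, broadcastable over parameter batches.

    ``theta_cols`` is a sequence of the seven parameter arrays in
    PARAM_NAMES order, each broadcastable against ``omega``.
    Returns (z_drum, u_st_fraction).
    """
    e_drum, e_sal, e_ml, e_soft, e_joint, eta, q_c = theta_cols
    c = constants
    z_td = branch_impedance(omega, c.m_td, c.g_td * e_drum * _MPA, eta)
    z_ml = branch_impedance(omega, 0.0, c.g_ml * e_ml * _MPA, eta)
    z_j = branch_impedance(omega, c.m_os, c.g_j * e_joint * _MPA, eta)
    z_s = branch_impedance(omega, 0.0, c.g_s * e_soft * _MPA, eta)
    z_sal = branch_impedance(omega, 0.0, c.g_sal * e_sal * _MPA, eta)
    z_coch = q_c * _GOHM / c.transformer  # pure resistance referred to drum side

    b2 = z_sal + z_coch  # stapes branch
    b1 = z_j + z_s * b2 / (z_s + b2)  # ossicular path with soft-tissue shunt
    z_drum = z_td + z_ml * b1 / (z_ml + b1)
    # volume-velocity dividers: drum flow -> ossicular path -> stapes branch
    u_frac = (z_ml / (z_ml + b1)) * (z_s / (z_s + b2))
    return z_drum, u_frac


def middle_ear_input_impedance(params: MiddleEarParams, constants: FixedConstants, omega):
    """Drum-side input impedance and stapes volume-velocity fraction.

    Evaluates the fixed ladder topology
    ``Z_drum = Z_td + Z_ml || (Z_j + Z_s || (Z_sal + Z_c/T))`` and the
    product of the two current dividers giving the fraction of drum
    volume velocity that reaches the stapes branch.
    """
    theta = params.to_array()
    cols = [theta[i] for i in range(len(PARAM_NAMES))]
    return _ladder(cols, constants, np.asarray(omega, dtype=float))


def characteristic_impedance(constants: FixedConstants) -> float:
    """Characteristic acoustic impedance Z0 = rho*c/a of the canal."""
    return constants.rho_air * constants.c_air / constants.canal_area


def tube_transform(z_load, length: float, constants: FixedConstants, omega):
    """Input impedance of a lossless tube of given length closed by ``z_load``.

    Uses the cos/sin form
    ``Z = Z0t (z_L cos(kl) + j Z0t sin(kl)) / (Z0t cos(kl) + j z_L sin(kl))``
    which is analytic through the tan(kl) poles (at kl = pi/2 it reduces
    exactly to the quarter-wave inversion Z0t^2 / z_L).
    """
    if length < 0:
        raise ValueError("tube length must be non-negative")
    omega = np.asarray(omega, dtype=float)
    z0t = characteristic_impedance(constants)
    kl = omega / constants.c_air * length
    cos, sin = np.cos(kl), np.sin(kl)
    return z0t * (z_load * cos + 1j * z0t * sin) / (z0t * cos + 1j * z_load * sin)


def compute_absorbance(z_ec, z0: float):
    """Absorbance 1 - |Gamma|^2 with Gamma = (Z_ec/Z0 - 1)/(Z_ec/Z0 + 1).

    The fraction of incident acoustic energy absorbed by the middle ear,
    computed from the ear-canal impedance and the tube characteristic
    impedance.  Valid (in [0, 1]) for passive loads Re(Z_ec) >= 0.
    """
    if z0 <= 0:
        raise ValueError("z0 must be positive")
    z_ec = np.asarray(z_ec, dtype=complex)
    if np.any(z_ec.real < 0):
        raise ValueError("active load: Re(z_ec) < 0 is an invalid simulator state")
    zn = z_ec / z0
    gamma = (zn - 1.0) / (zn + 1.0)
    return 1.0 - np.abs(gamma) ** 2


# ---------------------------------------------------------------------------
# full forward model


def _forward(theta_cols, grid: FrequencyGrid, constants: FixedConstants):
    """Vectorized forward model; theta columns broadcast against omega."""
    omega = grid.omega
    z_drum, u_frac = _ladder(theta_cols, constants, omega)
    l2 = constants.canal_length_probe_to_drum - constants.plane_distance_from_probe
    z_ec = tube_transform(z_drum, l2, constants, omega)
    z0 = characteristic_impedance(constants)
    abs_ec = compute_absorbance(z_ec, z0)
    # propagate plane pressure/velocity (P_plane = 1) down the line to the drum
    kl = omega / constants.c_air * l2
    u_plane = 1.0 / z_ec
    u_drum = u_plane * np.cos(kl) - 1j * np.sin(kl) / z0
    vst_over_pec = u_frac * u_drum / constants.footplate_area
    return vst_over_pec, z_ec, abs_ec


def simulate_spectra(
    params: MiddleEarParams,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
) -> SpectrumSet:
    """Simulate the three measurement spectra for one parameter set.

    Deterministic: two calls with identical inputs are bit-identical.
    """
    grid = grid or FrequencyGrid()
    constants = constants or FixedConstants()
    cols = list(params.to_array())
    vst, z_ec, abs_ec = _forward(cols, grid, constants)
    return SpectrumSet(grid=grid, vst_over_pec=vst, z_ec=z_ec, abs_ec=abs_ec)


def simulate_batch(
    thetas: np.ndarray,
    grid: FrequencyGrid | None = None,
    constants: FixedConstants | None = None,
):
    """Simulate a batch of parameter sets at once.

    Parameters
    ----------
    thetas : (N, 7) array in PARAM_NAMES order, all entries positive.

    Returns
    -------
    vst, z_ec : complex (N, n_freq) arrays; abs_ec : real (N, n_freq).
    """
    grid = grid or FrequencyGrid()
    constants = constants or FixedConstants()
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"thetas must be (N, {len(PARAM_NAMES)})")
    if np.any(thetas <= 0):
        raise ValueError("all parameters must be strictly positive")
    cols = [thetas[:, i : i + 1] for i in range(len(PARAM_NAMES))]
    return _forward(cols, grid, constants)
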