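"""Closed-form models of intra-methyl 1H-1H triple-quantum (3Q) relaxation.

In the forbidden/allowed 3Q experiment, transverse single-quantum (SQ)
methyl-proton coherence partially evolves into triple-quantum coherence
during a relaxation delay ``T``, driven by intra-methyl 1H-1H dipolar
cross-correlated relaxation at rate ``eta``.  The "forbidden" spectrum
reports the converted fraction, the "allowed" spectrum the unconverted
one, and their intensity ratio follows

    I_forb / I_all = (3 N_all / 4 N_forb) *
        eta * tanh(sqrt(eta^2 + delta^2) T)
        / (sqrt(eta^2 + delta^2) - delta * tanh(sqrt(eta^2 + delta^2) T))

with ``delta`` (< 0) a coupling between the rapidly and slowly decaying SQ
coherences and ``N`` the number of scans per experiment.  The allowed
intensity itself decays biexponentially,

    I_all(T) = (A / 2) * (3 exp(-R_slow T) + exp(-R_fast T)),

and eta is half the spread of the two SQ rates,

    eta = (R_fast - R_slow) / 2  ∝  S2_axis * tau_c,

so eta is a direct, per-methyl reporter of the methyl-axis order parameter
S2_axis for a particle of known rotational correlation time tau_c.

All functions use SI units internally: seconds and s^-1.  I/O layers
convert from the millisecond delays customary in pulse programs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "GAMMA_H",
    "HBAR",
    "MU0_OVER_4PI",
    "DEFAULT_R_HH",
    "DEFAULT_THETA_AXIS_HH",
    "ScanCounts",
    "MethylGeometry",
    "RelaxationParams",
    "forbidden_allowed_ratio",
    "allowed_intensity",
    "eta_from_rates",
    "rates_from_eta",
    "eta_to_s2axis",
    "s2axis_to_eta",
]

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: reduced Planck constant, J s
HBAR = 1.054571817e-34
#: mu_0 / 4 pi, T m A^-1
MU0_OVER_4PI = 1e-7
#: intra-methyl H-H distance, m (1.813 Angstrom)
DEFAULT_R_HH = 1.813e-10
#: angle between the methyl symmetry axis and the H-H vector, rad
DEFAULT_THETA_AXIS_HH = math.pi / 2.0


@dataclass(frozen=True)
class ScanCounts:
    """Scans per allowed / forbidden experiment (the Eq.-1 prefactor)."""

    n_allowed: int = 1
    n_forbidden: int = 1

    def __post_init__(self) -> None:
        if self.n_allowed < 1 or self.n_forbidden < 1:
            raise DomainError("scan counts must be >= 1")

    @property
    def prefactor(self) -> float:
        """3 N_all / (4 N_forb)."""
        return 0.75 * self.n_allowed / self.n_forbidden


@dataclass(frozen=True)
class MethylGeometry:
    """Geometry and tumbling inputs for the eta <-> S2_axis conversion.

    Parameters
    ----------
    tau_c : float
        Overall rotational correlation time of the particle, seconds.
    r_hh : float
        Intra-methyl H-H distance, metres.
    theta_axis_hh : float
        Angle between the methyl three-fold axis and the H-H vector, rad.
    """

    tau_c: float
    r_hh: float = DEFAULT_R_HH
    theta_axis_hh: float = DEFAULT_THETA_AXIS_HH

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise DomainError("tau_c must be positive")
        if self.r_hh <= 0:
            raise DomainError("r_hh must be positive")
        if not 0 < self.theta_axis_hh < math.pi:
            raise DomainError("theta_axis_hh must lie in (0, pi)")

    @property
    def dipolar_constant(self) -> float:
        """Proportionality constant C in eta = C * tau_c * S2_axis, s^-2.

        C = (9/10) * P2(cos theta)^2 * gamma_H^4 * hbar^2 * (mu0/4pi)^2 / r_HH^6
        """
        p2 = 0.5 * (3.0 * math.cos(self.theta_axis_hh) ** 2 - 1.0)
        return (
            0.9
            * p2**2
            * GAMMA_H**4
            * HBAR**2
            * MU0_OVER_4PI**2
            / self.r_hh**6
        )


@dataclass
class RelaxationParams:
    """Parameters of the 3Q relaxation observables for one methyl.

    ``eta`` and ``delta`` always exist; the single-quantum rates and the
    amplitude are populated only by fits that constrain them (the reduced
    scheme, which fits the allowed decay jointly with the ratio).
    """

    eta: float
    delta: float
    r_slow: float | None = None
    r_fast: float | None = None
    amplitude: float | None = None

    def validate(self, allow_zero_delta: bool = False) -> None:
        if self.eta <= 0:
            raise DomainError(f"eta must be > 0, got {self.eta}")
        if self.delta > 0 or (self.delta == 0 and not allow_zero_delta):
            raise DomainError(f"delta must be < 0, got {self.delta}")
        if (self.r_slow is None) != (self.r_fast is None):
            raise DomainError("r_slow and r_fast must be populated together")
        if self.r_slow is not None and self.r_fast is not None:
            if self.r_slow <= 0 or self.r_fast < self.r_slow:
                raise DomainError("require r_fast >= r_slow > 0")
            implied = eta_from_rates(self.r_fast, self.r_slow)
            if not math.isclose(implied, self.eta, rel_tol=1e-9, abs_tol=1e-12):
                raise DomainError(
                    "eta inconsistent with (r_fast - r_slow)/2: "
                    f"{self.eta} vs {implied}"
                )
        if self.amplitude is not None and self.amplitude <= 0:
            raise DomainError("amplitude must be > 0")


def forbidden_allowed_ratio(delay, params: RelaxationParams, scans: ScanCounts | None = None):
    """Forbidden/allowed intensity ratio at relaxation delay(s) ``delay``.

    ``delay`` may be a scalar or array of delays in seconds.  ``delta = 0``
    is accepted (the expression collapses to the pure-tanh limit); fitting
    layers impose the strict ``delta < 0`` constraint themselves.
    """
    if scans is None:
        scans = ScanCounts()
    t = np.asarray(delay, dtype=float)
    if np.any(t < 0):
        raise DomainError("relaxation delay must be non-negative")
    if params.eta <= 0:
        raise DomainError("eta must be > 0")
    if params.delta > 0:
        raise DomainError("delta must be <= 0")
    out = _ratio_kernel(t, params.eta, params.delta, scans.prefactor)
    return float(out) if np.isscalar(delay) else out


def _ratio_kernel(t, eta, delta, prefactor):
    """Vectorized Eq.-1 kernel; no domain checks (hot path for fitting)."""
    lam = np.sqrt(eta * eta + delta * delta)
    th = np.tanh(lam * t)
    return prefactor * eta * th / (lam - delta * th)


def allowed_intensity(delay, params: RelaxationParams):
    """Allowed-experiment peak intensity at delay(s) ``delay`` (seconds)."""
    t = np.asarray(delay, dtype=float)
    if np.any(t < 0):
        raise DomainError("relaxation delay must be non-negative")
    if params.r_slow is None or params.r_fast is None or params.amplitude is None:
        raise DomainError("allowed_intensity requires r_slow, r_fast and amplitude")
    if params.r_slow <= 0 or params.r_fast <= 0:
        raise DomainError("relaxation rates must be > 0")
    if params.amplitude <= 0:
        raise DomainError("amplitude must be > 0")
    out = _allowed_kernel(t, params.amplitude, params.r_slow, params.r_fast)
    return float(out) if np.isscalar(delay) else out


def _allowed_kernel(t, amplitude, r_slow, r_fast):
    """Vectorized Eq.-3 kernel; no domain checks."""
    return 0.5 * amplitude * (3.0 * np.exp(-r_slow * t) + np.exp(-r_fast * t))


def eta_from_rates(r_fast: float, r_slow: float) -> float:
    """eta = (R_fast - R_slow) / 2."""
    if r_fast < r_slow:
        raise DomainError(f"r_fast ({r_fast}) < r_slow ({r_slow})")
    return 0.5 * (r_fast - r_slow)


def rates_from_eta(eta: float, r_slow: float) -> tuple[float, float]:
    """Inverse decomposition: (r_slow, r_fast = r_slow + 2 eta)."""
    if eta < 0:
        raise DomainError("eta must be >= 0")
    if r_slow <= 0:
        raise DomainError("r_slow must be > 0")
    return r_slow, r_slow + 2.0 * eta


def eta_to_s2axis(eta: float, geometry: MethylGeometry) -> float:
    """Convert a cross-correlation rate to the methyl-axis order parameter.

    S2_axis = eta / (C * tau_c).  A value outside [0, 1] is physically
    suspect (wrong tau_c or geometry) and triggers a warning, but is
    returned unclamped so the caller can inspect it.
    """
    if eta < 0:
        raise DomainError("eta must be >= 0")
    s2 = eta / (geometry.dipolar_constant * geometry.tau_c)
    if not 0.0 <= s2 <= 1.0:
        warnings.warn(
            f"S2_axis = {s2:.4g} outside [0, 1]; check tau_c and geometry",
            RuntimeWarning,
            stacklevel=2,
        )
    return s2


def s2axis_to_eta(s2_axis: float, geometry: MethylGeometry) -> float:
    """Exact algebraic inverse of :func:`eta_to_s2axis`."""
    if s2_axis < 0:
        raise DomainError("S2_axis must be >= 0")
    return s2_axis * geometry.dipolar_constant * geometry.tau_c
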