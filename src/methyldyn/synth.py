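"""Synthetic datasets with known ground truth for every pipeline input.

Three generators, all pure functions of their spec (seed included):

* noisy forbidden/allowed intensity series from the 3Q relaxation model,
  with per-peak (eta, delta, R_slow) drawn uniformly from realistic ranges
  and homoscedastic Gaussian spectral noise;
* paired paramagnetic/diamagnetic intensity tables with prescribed true
  attenuation ratios;
* bond-vector trajectories diffusing inside a cone of known half-angle,
  whose analytic S2 = [cos(theta0)(1+cos(theta0))/2]^2 serves as an
  order-parameter oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError
from .fitting import MethylPeak, RelaxationSeries
from .mdorder import BondVectorTrajectory
from .model import ScanCounts, _allowed_kernel, _ratio_kernel

__all__ = [
    "SyntheticRelaxationSpec",
    "ConeTrajectorySpec",
    "simulate_relaxation_dataset",
    "simulate_cone_trajectory",
    "simulate_pre_dataset",
    "sample_cone_vectors",
    "MBP_DELAYS_S",
    "REDUCED_ALLOWED_DELAYS_S",
    "REDUCED_FORBIDDEN_DELAYS_S",
]

#: full-scheme delays (s): forbidden and allowed both at 0.8, 2, 4, 8, 16 ms
MBP_DELAYS_S = (0.0008, 0.002, 0.004, 0.008, 0.016)
#: reduced-scheme allowed delays (s): 0.8, 2, 4, 8, 14 ms
REDUCED_ALLOWED_DELAYS_S = (0.0008, 0.002, 0.004, 0.008, 0.014)
#: reduced-scheme forbidden delays (s): the single 8 ms point
REDUCED_FORBIDDEN_DELAYS_S = (0.008,)

# noise floor (fraction of I(0)) recorded when noise_fraction == 0, so the
# sigma > 0 series invariant holds without perturbing noiseless data
_SIGMA_FLOOR = 1e-9


@dataclass(frozen=True)
class SyntheticRelaxationSpec:
    """Conditions for a simulated forbidden/allowed relaxation dataset."""

    n_peaks: int = 25
    eta_range: tuple[float, float] = (10.0, 100.0)
    delta_range: tuple[float, float] = (-10.0, -0.5)
    r_slow_range: tuple[float, float] = (20.0, 60.0)
    amplitude: float = 1000.0
    allowed_delays: tuple[float, ...] = MBP_DELAYS_S
    forbidden_delays: tuple[float, ...] = MBP_DELAYS_S
    noise_fraction: float = 0.02
    scans: ScanCounts = field(default_factory=ScanCounts)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise DomainError("n_peaks must be >= 1")
        for name, rng_ in (("eta_range", self.eta_range),
                           ("delta_range", self.delta_range),
                           ("r_slow_range", self.r_slow_range)):
            if rng_[0] > rng_[1]:
                raise DomainError(f"{name} must be ordered (lo, hi)")
        if self.eta_range[0] <= 0:
            raise DomainError("eta must be positive")
        if self.delta_range[1] >= 0:
            raise DomainError("delta must be negative")
        if any(d <= 0 for d in self.allowed_delays + self.forbidden_delays):
            raise DomainError("delays must be positive")
        if self.noise_fraction < 0:
            raise DomainError("noise_fraction must be >= 0")
        if self.amplitude <= 0:
            raise DomainError("amplitude must be > 0")


@dataclass(frozen=True)
class ConeTrajectorySpec:
    """Reflective diffusion of a unit vector inside a cone (oracle input)."""

    theta0: float
    correlation_time: float = 1.0  # ns
    dt: float = 0.01  # ns
    duration: float = 100.0  # ns
    seed: int = 0
    methyl_id: str = "cone"

    def __post_init__(self) -> None:
        if not 0 < self.theta0 <= np.pi:
            raise DomainError("theta0 must be in (0, pi]")
        if self.dt >= self.correlation_time:
            raise DomainError("dt must be smaller than the correlation time")
        if self.duration <= self.dt:
            raise DomainError("duration must exceed dt")


def simulate_relaxation_dataset(
    spec: SyntheticRelaxationSpec,
) -> tuple[list[RelaxationSeries], dict[str, dict[str, float]]]:
    """Simulate noisy intensity series plus the generating truth table.

    Per peak, (eta, delta, R_slow) are uniform draws from the spec ranges
    and R_fast = R_slow + 2 eta.  Allowed intensities follow the
    biexponential decay; forbidden intensities are the allowed model value
    times the forbidden/allowed ratio at the same delay.  One Gaussian
    noise sigma per experiment type, sigma = noise_fraction * I_all(0).
    """
    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_fraction * 2.0 * spec.amplitude
    sigma_rec = max(sigma, _SIGMA_FLOOR * 2.0 * spec.amplitude)
    pref = spec.scans.prefactor

    dataset: list[RelaxationSeries] = []
    truths: dict[str, dict[str, float]] = {}
    for i in range(spec.n_peaks):
        eta = rng.uniform(*spec.eta_range)
        delta = rng.uniform(*spec.delta_range)
        r_slow = rng.uniform(*spec.r_slow_range)
        r_fast = r_slow + 2.0 * eta
        pid = f"syn{i:03d}"

        ad = np.asarray(spec.allowed_delays)
        fd = np.asarray(spec.forbidden_delays)
        i_all = _allowed_kernel(ad, spec.amplitude, r_slow, r_fast)
        i_forb = _allowed_kernel(fd, spec.amplitude, r_slow, r_fast) * _ratio_kernel(
            fd, eta, delta, pref
        )
        if sigma > 0:
            i_all = i_all + rng.normal(0.0, sigma, i_all.shape)
            i_forb = i_forb + rng.normal(0.0, sigma, i_forb.shape)

        dataset.append(
            RelaxationSeries(
                peak=MethylPeak(peak_id=pid),
                allowed=[(float(d), float(v), sigma_rec) for d, v in zip(ad, i_all)],
                forbidden=[(float(d), float(v), sigma_rec) for d, v in zip(fd, i_forb)],
                scans=spec.scans,
            )
        )
        truths[pid] = {
            "eta": float(eta),
            "delta": float(delta),
            "r_slow": float(r_slow),
            "r_fast": float(r_fast),
            "amplitude": float(spec.amplitude),
        }
    return dataset, truths


def sample_cone_vectors(
    theta0: float, n: int, rng: np.random.Generator, axis: np.ndarray | None = None
) -> np.ndarray:
    """n i.i.d. unit vectors uniform (in solid angle) within a cone.

    theta0 = pi gives the full sphere (isotropic sampling).
    """
    if not 0 < theta0 <= np.pi:
        raise DomainError("theta0 must be in (0, pi]")
    cos_t = rng.uniform(np.cos(theta0), 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    v = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    if axis is not None:
        v = v @ _rotation_to(axis).T
    return v


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(vcross) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    k = vcross / np.linalg.norm(vcross)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    s = np.linalg.norm(vcross)
    return np.eye(3) + s * kx + (1 - c) * kx @ kx


def simulate_cone_trajectory(spec: ConeTrajectorySpec) -> BondVectorTrajectory:
    """Reflective random-walk diffusion of a unit vector within a cone.

    Each step rotates the vector by a Gaussian tangent-plane kick of
    angular scale sqrt(2 dt / tau); excursions past the cone boundary are
    reflected in the polar angle (theta -> 2 theta0 - theta).  The
    long-run orientation distribution is uniform within the cone, which is
    all the S2 estimator depends on.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.dt)) + 1
    step = np.sqrt(2.0 * spec.dt / spec.correlation_time)

    half = spec.theta0 / 2.0
    v = np.array([np.sin(half), 0.0, np.cos(half)])
    out = np.empty((n, 3))
    kicks = rng.normal(0.0, step, (n, 3))
    for i in range(n):
        out[i] = v
        # isotropic tangent-plane kick: uniform stationary law on the sphere
        k = kicks[i]
        k -= (k @ v) * v
        v = v + k
        v /= np.linalg.norm(v)
        theta = np.arccos(np.clip(v[2], -1.0, 1.0))
        if theta > spec.theta0:
            # reflect the polar angle at the cone edge, keeping the azimuth
            theta_new = max(2.0 * spec.theta0 - theta, 1e-9)
            s_old = np.hypot(v[0], v[1])
            st = np.sin(theta_new)
            if s_old < 1e-12:
                v = np.array([st, 0.0, np.cos(theta_new)])
            else:
                v = np.array(
                    [st * v[0] / s_old, st * v[1] / s_old, np.cos(theta_new)]
                )
    times = np.arange(n) * spec.dt
    return BondVectorTrajectory(methyl_id=spec.methyl_id, times=times, vectors=out)


def simulate_pre_dataset(
    true_ratios: dict[str, float],
    noise: float = 0.0,
    seed: int = 0,
    dia_scale: float = 100.0,
) -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
    """Paired paramagnetic/diamagnetic intensity tables from true ratios.

    Diamagnetic intensities are drawn around ``dia_scale``; paramagnetic
    intensities are ratio * diamagnetic; Gaussian noise of absolute scale
    ``noise`` is added to both.  Returns (para, dia) tables in the
    ``peak_id -> (intensity, sigma)`` form :func:`methyldyn.pre.pre_ratios`
    consumes.
    """
    if any(r < 0 or r > 1.5 for r in true_ratios.values()):
        raise InputError("true ratios must lie in [0, 1.5]")
    if noise < 0:
        raise InputError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_rec = max(noise, 1e-9 * dia_scale)
    para: dict[str, tuple[float, float]] = {}
    dia: dict[str, tuple[float, float]] = {}
    for pid in sorted(true_ratios):
        i_dia = dia_scale * rng.uniform(0.8, 1.2)
        i_para = true_ratios[pid] * i_dia
        if noise > 0:
            i_dia += rng.normal(0.0, noise)
            i_para += rng.normal(0.0, noise)
        dia[pid] = (float(i_dia), sigma_rec)
        para[pid] = (float(i_para), sigma_rec)
    return para, dia
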