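"""Methyl-axis order parameters from MD bond-vector time series.

S2_axis for an Ile delta-1 methyl is estimated from the Cgamma1-Cdelta1
unit bond vector e(t) in a molecule-fixed frame (overall tumbling already
removed — frame alignment of raw trajectories is a preprocessing contract,
not done here) via the Lipari-Szabo plateau of the second-rank tensor
average:

    S2 = (3/2) * sum_ab <e_a e_b>^2 - 1/2,   a, b in {x, y, z}.

The estimate is exactly 1 for a rigid vector and tends to 0 for isotropic
disorder; for uniform diffusion inside a cone of half-angle theta0 it has
the closed form [cos(theta0) (1 + cos(theta0)) / 2]^2, used as the test
oracle throughout.

To expose slower-than-window motions, the trajectory is split into
overlapping windows (default 32 ns long, 28 ns overlap, after discarding a
25 ns equilibration) and S2 is reported per window with the across-window
mean and standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "BondVectorTrajectory",
    "WindowScheme",
    "OrderParameterResult",
    "ConditionDifference",
    "window_trajectory",
    "s2axis_from_vectors",
    "windowed_s2",
    "condition_difference",
    "cone_s2",
]

_UNIT_TOL = 1e-6


@dataclass
class BondVectorTrajectory:
    """Uniformly sampled unit bond vectors for one methyl, times in ns."""

    methyl_id: str
    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise InputError("vectors must be an (n, 3) array")
        if self.times.shape[0] != self.vectors.shape[0]:
            raise InputError("times and vectors length mismatch")
        if self.times.size < 2:
            raise InputError("need >= 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise InputError("times must be strictly increasing with uniform step")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise InputError("bond vectors must have unit norm")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class WindowScheme:
    """Equilibration discard, window length and overlap, all in ns."""

    discard: float = 25.0
    window_length: float = 32.0
    overlap: float = 28.0

    def __post_init__(self) -> None:
        if self.discard < 0:
            raise DomainError("discard must be >= 0")
        if not 0 <= self.overlap < self.window_length:
            raise DomainError("require 0 <= overlap < window_length")

    @property
    def stride(self) -> float:
        return self.window_length - self.overlap


@dataclass
class OrderParameterResult:
    methyl_id: str
    per_window_s2: list[float]
    mean_s2: float
    sd_s2: float | None
    window_starts: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConditionDifference:
    """Per-peak difference between two ligand conditions (a - b)."""

    delta: float
    err: float

    @property
    def increased_motion(self) -> bool:
        """Negative differences mean faster ps-ns motions in condition a."""
        return self.delta < 0


def window_trajectory(
    traj: BondVectorTrajectory, scheme: WindowScheme | None = None
) -> list[BondVectorTrajectory]:
    """Split a trajectory into overlapping windows after the discard.

    Windows start at ``discard``, ``discard + stride``, ... and each spans
    ``window_length``; the count is floor((usable - window) / stride) + 1.
    """
    if scheme is None:
        scheme = WindowScheme()
    t0 = traj.times[0] + scheme.discard
    usable = traj.times[-1] - t0
    if usable < scheme.window_length - 1e-9:
        raise InputError(
            f"{traj.methyl_id}: usable duration {usable:.3g} ns shorter than "
            f"window length {scheme.window_length:.3g} ns"
        )
    n_windows = int(math.floor((usable - scheme.window_length) / scheme.stride + 1e-9)) + 1
    windows: list[BondVectorTrajectory] = []
    for k in range(n_windows):
        start = t0 + k * scheme.stride
        stop = start + scheme.window_length
        sel = (traj.times >= start - 1e-9) & (traj.times <= stop + 1e-9)
        windows.append(
            BondVectorTrajectory(
                methyl_id=traj.methyl_id,
                times=traj.times[sel],
                vectors=traj.vectors[sel],
            )
        )
    return windows


def s2axis_from_vectors(vectors: np.ndarray) -> float:
    """Tensor-average order parameter of a unit-vector series.

    S2 = (3/2) sum_ab <e_a e_b>^2 - 1/2.  Values outside [0, 1] by more
    than 1e-3 (possible from finite sampling) are still returned; callers
    that need a hard range should clamp.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise InputError("need an (n>=2, 3) array of vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise InputError("vectors must have unit norm")
    m = v.T @ v / v.shape[0]
    return float(1.5 * np.sum(m * m) - 0.5)


def windowed_s2(
    traj: BondVectorTrajectory,
    scheme: WindowScheme | None = None,
    window_subset: list[int] | None = None,
) -> OrderParameterResult:
    """Per-window S2 with across-window mean and sample SD.

    ``window_subset`` selects windows by index (default: all), mirroring
    protocols that report statistics over a subset of the windows.
    """
    windows = window_trajectory(traj, scheme)
    if window_subset is not None:
        windows = [windows[i] for i in window_subset]
    s2 = [s2axis_from_vectors(w.vectors) for w in windows]
    mean = float(np.mean(s2))
    sd = float(np.std(s2, ddof=1)) if len(s2) > 1 else None
    return OrderParameterResult(
        methyl_id=traj.methyl_id,
        per_window_s2=s2,
        mean_s2=mean,
        sd_s2=sd,
        window_starts=[float(w.times[0]) for w in windows],
    )


def condition_difference(
    a: dict[str, tuple[float, float]],
    b: dict[str, tuple[float, float]],
) -> dict[str, ConditionDifference]:
    """Per-peak difference a - b with errors added in quadrature.

    Applies equally to eta (NMR) and S2_axis (MD); only peaks present in
    both conditions are compared.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise InputError("no shared peak IDs between conditions")
    return {
        pid: ConditionDifference(
            delta=a[pid][0] - b[pid][0],
            err=math.hypot(a[pid][1], b[pid][1]),
        )
        for pid in shared
    }


def cone_s2(theta0: float) -> float:
    """Closed-form S2 for uniform diffusion in a cone of half-angle theta0."""
    c = math.cos(theta0)
    return (c * (1.0 + c) / 2.0) ** 2
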