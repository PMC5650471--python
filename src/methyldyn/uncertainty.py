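"""Monte-Carlo bootstrap uncertainties for fitted relaxation parameters.

Each replicate redraws every measured intensity from a Gaussian centred on
the measurement with its spectral noise sigma, refits with the chosen
scheme, and the reported parameters are the mean over converged replicates
with the standard deviation as the error (mean +/- SD).  The direct point
fit is kept alongside for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .fitting import (
    EtaFitResult,
    RelaxationSeries,
    fit_full_scheme,
    fit_reduced_scheme,
)
from .model import RelaxationParams

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_fit", "child_seed"]

_FITTERS = {"full": fit_full_scheme, "reduced": fit_reduced_scheme}


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise InputError("n_replicates must be >= 2")
        if self.noise_model != "gaussian":
            raise InputError(f"unknown noise model {self.noise_model!r}")


@dataclass
class BootstrapResult:
    """Bootstrap summary plus the direct point fit for one peak."""

    fit: EtaFitResult
    point_fit: EtaFitResult
    n_converged: int
    n_replicates: int

    @property
    def nonconverged_fraction(self) -> float:
        return 1.0 - self.n_converged / self.n_replicates


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-peak seed derived from one master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _resample(
    series: RelaxationSeries, rng: np.random.Generator
) -> RelaxationSeries:
    allowed = [(d, rng.normal(i, s), s) for d, i, s in series.allowed]
    forbidden = [(d, rng.normal(i, s), s) for d, i, s in series.forbidden]
    return RelaxationSeries(
        peak=series.peak, allowed=allowed, forbidden=forbidden, scans=series.scans
    )


def bootstrap_fit(
    series: RelaxationSeries,
    scheme: str = "reduced",
    config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Bootstrap a relaxation fit; see the module docstring for the model.

    Negative resampled intensities are passed to the fit unchanged — the
    parameter constraints protect the result.  If more than half of the
    replicates fail to converge the result is flagged ``unreliable``.
    """
    if scheme not in _FITTERS:
        raise InputError(f"unknown scheme {scheme!r}")
    if config is None:
        config = BootstrapConfig()
    fitter = _FITTERS[scheme]
    point = fitter(series)

    rng = np.random.default_rng(config.seed)
    rows: list[tuple[float, ...]] = []
    for _ in range(config.n_replicates):
        rep = fitter(_resample(series, rng))
        if rep.converged:
            p = rep.params
            rows.append(
                (
                    p.eta,
                    p.delta,
                    p.r_slow if p.r_slow is not None else np.nan,
                    p.r_fast if p.r_fast is not None else np.nan,
                    p.amplitude if p.amplitude is not None else np.nan,
                )
            )
    n_conv = len(rows)
    if n_conv == 0:
        raise InputError(f"{series.peak.peak_id}: no bootstrap replicate converged")
    arr = np.asarray(rows)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if n_conv > 1 else np.zeros(arr.shape[1])

    has_rates = not np.isnan(mean[2])
    params = RelaxationParams(
        eta=float(mean[0]),
        delta=float(mean[1]),
        r_slow=float(mean[2]) if has_rates else None,
        r_fast=float(mean[2] + 2.0 * mean[0]) if has_rates else None,
        amplitude=float(mean[4]) if has_rates else None,
    )
    fit = EtaFitResult(
        peak_id=series.peak.peak_id,
        params=params,
        scheme=scheme,
        residual_sse=point.residual_sse,
        converged=point.converged,
        eta_err=float(sd[0]),
        delta_err=float(sd[1]),
        n_ratio_points=point.n_ratio_points,
        unreliable=(n_conv < 0.5 * config.n_replicates),
    )
    return BootstrapResult(
        fit=fit,
        point_fit=point,
        n_converged=n_conv,
        n_replicates=config.n_replicates,
    )
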