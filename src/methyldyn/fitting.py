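"""Per-methyl eta estimation from forbidden/allowed intensity series.

Two acquisition schemes are supported:

* **full** — forbidden and allowed spectra at every relaxation delay; the
  forbidden/allowed ratios alone are fit to the ratio model for (eta,
  delta).
* **reduced** — five allowed spectra but only one or two forbidden
  spectra, for samples too short-lived for the full series.  Allowed
  intensities are fit to the biexponential decay jointly with the
  available ratio point(s), with eta tied to the rate spread
  (R_fast - R_slow)/2, so the allowed decay supplies the information the
  missing forbidden delays would have carried.

Also here: the ratio/noise propagation used by both schemes, the
low-intensity peak filter, and the forbidden-delay subset selection used
to decide which single delay the reduced scheme should keep.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InputError
from .model import (
    RelaxationParams,
    ScanCounts,
    _allowed_kernel,
    _ratio_kernel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MethylPeak",
    "RelaxationSeries",
    "EtaFitResult",
    "DelaySelectionReport",
    "compute_ratios",
    "filter_low_intensity_peaks",
    "fit_full_scheme",
    "fit_reduced_scheme",
    "mask_forbidden",
    "select_forbidden_delays",
]

# delays coming through ms->s conversion match to well under 0.1 us
_DELAY_ATOL = 1e-7
# bound offsets keeping the optimizer strictly inside the sign constraints
_EPS_RATE = 1e-8
_EPS_DELTA = 1e-12


@dataclass(frozen=True)
class MethylPeak:
    """One labeled Ile delta-1 probe."""

    peak_id: str
    assignment: str | None = None
    shift_h: float | None = None
    shift_c: float | None = None


@dataclass
class RelaxationSeries:
    """Allowed and forbidden intensities vs. delay for one peak.

    ``allowed`` and ``forbidden`` are lists of ``(delay_s, intensity,
    noise_sigma)`` tuples; delays are seconds.
    """

    peak: MethylPeak
    allowed: list[tuple[float, float, float]]
    forbidden: list[tuple[float, float, float]]
    scans: ScanCounts = field(default_factory=ScanCounts)

    def __post_init__(self) -> None:
        if len(self.allowed) < 2:
            raise InputError(f"{self.peak.peak_id}: need >= 2 allowed points")
        if len(self.forbidden) < 1:
            raise InputError(f"{self.peak.peak_id}: need >= 1 forbidden point")
        for name, rows in (("allowed", self.allowed), ("forbidden", self.forbidden)):
            delays = [r[0] for r in rows]
            if any(d <= 0 for d in delays):
                raise InputError(f"{self.peak.peak_id}: {name} delays must be > 0")
            if len(set(delays)) != len(delays):
                raise InputError(f"{self.peak.peak_id}: duplicate {name} delays")
            if any(r[2] <= 0 for r in rows):
                raise InputError(f"{self.peak.peak_id}: {name} noise_sigma must be > 0")

    def allowed_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.asarray(sorted(self.allowed), dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]

    def forbidden_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = np.asarray(sorted(self.forbidden), dtype=float)
        return f[:, 0], f[:, 1], f[:, 2]


@dataclass
class EtaFitResult:
    """Fit outcome for one peak, with optional bootstrap uncertainties."""

    peak_id: str
    params: RelaxationParams
    scheme: str
    residual_sse: float
    converged: bool
    eta_err: float | None = None
    delta_err: float | None = None
    n_ratio_points: int = 0
    unreliable: bool = False


@dataclass
class DelaySelectionReport:
    """Comparison of forbidden-delay subsets against the full scheme."""

    candidate_subsets: list[tuple[float, ...]]
    per_peak_eta_differences: dict[tuple[float, ...], dict[str, float]]
    ssd: dict[tuple[float, ...], float]
    selected: tuple[float, ...]


def compute_ratios(
    series: RelaxationSeries,
) -> list[tuple[float, float, float]]:
    """Pair forbidden with allowed intensities at matching delays.

    Returns ``(delay, ratio, ratio_sigma)`` per matched delay, with the
    standard first-order error propagation
    ``sigma = ratio * sqrt((s_f/I_f)^2 + (s_a/I_a)^2)`` (evaluated in a
    form that stays finite at I_f = 0).  Delays without a partner, or with
    non-positive allowed intensity, are skipped with a log record.
    """
    ad, ai, asig = series.allowed_arrays()
    out: list[tuple[float, float, float]] = []
    for fd, fi, fsig in sorted(series.forbidden):
        match = np.flatnonzero(np.isclose(ad, fd, rtol=0.0, atol=_DELAY_ATOL))
        if match.size == 0:
            logger.warning(
                "%s: forbidden delay %.4g s has no allowed partner; skipped",
                series.peak.peak_id,
                fd,
            )
            continue
        j = int(match[0])
        if ai[j] <= 0:
            logger.warning(
                "%s: allowed intensity <= 0 at %.4g s; delay excluded",
                series.peak.peak_id,
                fd,
            )
            continue
        ratio = fi / ai[j]
        sigma = np.hypot(fsig / ai[j], fi * asig[j] / ai[j] ** 2)
        out.append((fd, float(ratio), float(sigma)))
    if not out:
        logger.warning("%s: no matched forbidden/allowed delays", series.peak.peak_id)
    return out


def filter_low_intensity_peaks(
    dataset: list[RelaxationSeries],
    fold_threshold: float = 10.0,
    reference_delay: float | None = None,
) -> tuple[list[RelaxationSeries], list[tuple[RelaxationSeries, str]]]:
    """Exclude peaks too weak at the reference forbidden delay.

    A series is excluded iff its forbidden intensity at the reference delay
    (default: the longest forbidden delay in the dataset) is less than
    ``fold_threshold`` times that measurement's noise sigma.  Returns
    ``(kept, excluded)`` where excluded entries carry a reason code.
    """
    if not dataset:
        return [], []
    if reference_delay is None:
        reference_delay = max(d for s in dataset for d, _, _ in s.forbidden)
    kept: list[RelaxationSeries] = []
    excluded: list[tuple[RelaxationSeries, str]] = []
    for series in dataset:
        fd, fi, fsig = series.forbidden_arrays()
        match = np.flatnonzero(
            np.isclose(fd, reference_delay, rtol=0.0, atol=_DELAY_ATOL)
        )
        if match.size == 0:
            excluded.append((series, "missing_reference_delay"))
            continue
        j = int(match[0])
        if fi[j] < fold_threshold * fsig[j]:
            excluded.append((series, "below_noise_threshold"))
        else:
            kept.append(series)
    return kept, excluded


def _eta_initial(ratios: list[tuple[float, float, float]], scans: ScanCounts) -> float:
    """Data-driven start: invert the small-T linear regime of the ratio."""
    t_min, r_min, _ = min(ratios)
    eta0 = r_min / (scans.prefactor * t_min)
    return float(np.clip(eta0, 0.5, 500.0))


def fit_full_scheme(series: RelaxationSeries) -> EtaFitResult:
    """Fit (eta, delta) to the forbidden/allowed ratios at all delays.

    Noise-weighted least squares of the ratio model, with box constraints
    eta > 0, delta < 0.  Requires at least two matched ratio points.
    """
    ratios = compute_ratios(series)
    if len(ratios) < 2:
        raise InputError(
            f"{series.peak.peak_id}: full-scheme fit needs >= 2 ratio points"
        )
    t = np.array([r[0] for r in ratios])
    y = np.array([r[1] for r in ratios])
    w = 1.0 / np.array([r[2] for r in ratios])
    pref = series.scans.prefactor

    def resid(x):
        eta, delta = x
        return (_ratio_kernel(t, eta, delta, pref) - y) * w

    x0 = np.array([_eta_initial(ratios, series.scans), -1.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([_EPS_RATE, -np.inf], [np.inf, -_EPS_DELTA]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=10_000,
    )
    eta, delta = sol.x
    return EtaFitResult(
        peak_id=series.peak.peak_id,
        params=RelaxationParams(eta=float(eta), delta=float(delta)),
        scheme="full",
        residual_sse=float(2.0 * sol.cost),
        converged=bool(sol.status > 0),
        n_ratio_points=len(ratios),
    )


def fit_reduced_scheme(series: RelaxationSeries) -> EtaFitResult:
    """Joint fit of allowed decay and available ratio point(s).

    Free parameters are (A, R_slow, eta, delta) with R_fast = R_slow +
    2 eta enforced by construction, so the rate ordering can never be
    violated.  Allowed and ratio residuals enter one objective, each in
    its own noise units.
    """
    if len(series.allowed) < 3:
        raise InputError(
            f"{series.peak.peak_id}: reduced-scheme fit needs >= 3 allowed points"
        )
    ratios = compute_ratios(series)
    if not ratios:
        raise InputError(
            f"{series.peak.peak_id}: reduced-scheme fit needs >= 1 ratio point"
        )
    ad, ai, asig = series.allowed_arrays()
    rt = np.array([r[0] for r in ratios])
    ry = np.array([r[1] for r in ratios])
    rw = 1.0 / np.array([r[2] for r in ratios])
    aw = 1.0 / asig
    pref = series.scans.prefactor

    def resid(x):
        amp, r_slow, eta, delta = x
        res_a = (_allowed_kernel(ad, amp, r_slow, r_slow + 2.0 * eta) - ai) * aw
        res_r = (_ratio_kernel(rt, eta, delta, pref) - ry) * rw
        return np.concatenate([res_a, res_r])

    # log-linear allowed decay -> effective rate and extrapolated I(0)
    coeff = np.polyfit(ad, np.log(np.clip(ai, 1e-12, None)), 1)
    r_eff = float(np.clip(-coeff[0], 1.0, 1000.0))
    amp0 = float(np.clip(np.exp(coeff[1]) / 2.0, 1e-6, None))
    eta0 = _eta_initial(ratios, series.scans)
    x0 = np.array([amp0, r_eff, eta0, -1.0])
    sol = least_squares(
        resid,
        x0,
        bounds=(
            [1e-12, _EPS_RATE, _EPS_RATE, -np.inf],
            [np.inf, np.inf, np.inf, -_EPS_DELTA],
        ),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=10_000,
        x_scale="jac",
    )
    amp, r_slow, eta, delta = (float(v) for v in sol.x)
    params = RelaxationParams(
        eta=eta,
        delta=delta,
        r_slow=r_slow,
        r_fast=r_slow + 2.0 * eta,
        amplitude=amp,
    )
    return EtaFitResult(
        peak_id=series.peak.peak_id,
        params=params,
        scheme="reduced",
        residual_sse=float(2.0 * sol.cost),
        converged=bool(sol.status > 0),
        n_ratio_points=len(ratios),
    )


def mask_forbidden(
    series: RelaxationSeries, keep_delays: tuple[float, ...] | list[float]
) -> RelaxationSeries:
    """Copy of ``series`` keeping only the named forbidden delays."""
    keep = [
        row
        for row in series.forbidden
        if any(abs(row[0] - d) <= _DELAY_ATOL for d in keep_delays)
    ]
    if not keep:
        raise InputError(
            f"{series.peak.peak_id}: no forbidden points at delays {keep_delays}"
        )
    return RelaxationSeries(
        peak=series.peak,
        allowed=list(series.allowed),
        forbidden=keep,
        scans=series.scans,
    )


def pick_best_subset(
    candidates: list[tuple[float, ...]], ssd: dict[tuple[float, ...], float]
) -> tuple[float, ...]:
    """Argmin-SSD subset; ties break to fewer delays, then shorter max delay."""
    return min(candidates, key=lambda c: (ssd[c], len(c), max(c)))


def select_forbidden_delays(
    dataset: list[RelaxationSeries],
    subset_sizes: tuple[int, ...] = (1, 2),
) -> DelaySelectionReport:
    """Find the forbidden-delay subset whose reduced fits best match full fits.

    Every peak is refit with :func:`fit_reduced_scheme` on each candidate
    subset of forbidden delays; per-peak |delta eta| against the
    full-scheme fit and the across-peak sum of squared differences (SSD)
    are reported.  The subset minimising SSD is selected; ties break to
    fewer delays, then to the shorter maximum delay.
    """
    if not dataset:
        raise InputError("empty dataset")
    delay_sets = [tuple(sorted(d for d, _, _ in s.forbidden)) for s in dataset]
    all_delays = delay_sets[0]
    if any(ds != all_delays for ds in delay_sets):
        raise InputError("dataset lacks full forbidden-delay coverage")

    full_eta = {s.peak.peak_id: fit_full_scheme(s).params.eta for s in dataset}

    candidates: list[tuple[float, ...]] = []
    for k in sorted(subset_sizes):
        candidates.extend(itertools.combinations(all_delays, k))

    per_peak: dict[tuple[float, ...], dict[str, float]] = {}
    ssd: dict[tuple[float, ...], float] = {}
    for subset in candidates:
        diffs: dict[str, float] = {}
        for s in dataset:
            res = fit_reduced_scheme(mask_forbidden(s, subset))
            diffs[s.peak.peak_id] = abs(res.params.eta - full_eta[s.peak.peak_id])
        per_peak[subset] = diffs
        ssd[subset] = float(sum(d * d for d in diffs.values()))

    selected = pick_best_subset(candidates, ssd)
    return DelaySelectionReport(
        candidate_subsets=candidates,
        per_peak_eta_differences=per_peak,
        ssd=ssd,
        selected=selected,
    )
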