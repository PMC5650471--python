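"""Solvent paramagnetic relaxation enhancement (PRE) accessibility analysis.

A soluble paramagnetic agent (e.g. Gd3+-DTPA) attenuates peaks of
solvent-exposed methyls.  The effect is quantified per peak as the ratio
of paramagnetic to diamagnetic peak intensity; strongly attenuated peaks
(ratio below the across-peak mean minus k standard deviations, default
k = 1) are flagged as solvent-exposed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import InputError
from .fitting import MethylPeak

logger = logging.getLogger(__name__)

__all__ = ["PREMeasurement", "PRESummary", "pre_ratios", "flag_exposed"]


@dataclass
class PREMeasurement:
    """Paired paramagnetic/diamagnetic intensities and their ratio."""

    peak: MethylPeak
    i_para: float
    sigma_para: float
    i_dia: float
    sigma_dia: float
    ratio: float
    ratio_err: float
    exposed_flag: bool = False


@dataclass(frozen=True)
class PRESummary:
    mean: float
    sd: float
    threshold: float
    k: float
    n: int


def pre_ratios(
    para: dict[str, tuple[float, float]],
    dia: dict[str, tuple[float, float]],
    peaks: dict[str, MethylPeak] | None = None,
) -> tuple[list[PREMeasurement], list[str]]:
    """Per-peak paramagnetic/diamagnetic intensity ratios.

    ``para`` and ``dia`` map peak_id -> (intensity, noise_sigma).  Returns
    the measurements plus the IDs present in only one table (reported, not
    fitted).  Peaks with non-positive diamagnetic intensity are skipped
    with a log record.
    """
    shared = sorted(set(para) & set(dia))
    unmatched = sorted(set(para) ^ set(dia))
    for pid in unmatched:
        logger.warning("PRE: peak %s present in only one table; skipped", pid)
    out: list[PREMeasurement] = []
    for pid in shared:
        ip, sp = para[pid]
        idia, sd = dia[pid]
        if idia <= 0:
            logger.warning("PRE: peak %s has diamagnetic intensity <= 0; skipped", pid)
            unmatched.append(pid)
            continue
        ratio = ip / idia
        err = abs(ratio) * math.hypot(
            sp / ip if ip != 0 else 0.0, sd / idia
        ) if ip != 0 else sp / idia
        peak = (peaks or {}).get(pid, MethylPeak(peak_id=pid))
        out.append(
            PREMeasurement(
                peak=peak,
                i_para=ip,
                sigma_para=sp,
                i_dia=idia,
                sigma_dia=sd,
                ratio=ratio,
                ratio_err=err,
            )
        )
    return out, unmatched


def flag_exposed(
    results: list[PREMeasurement], k: float = 1.0
) -> tuple[list[PREMeasurement], PRESummary]:
    """Flag peaks with ratio below mean - k * SD as solvent-exposed.

    Uses the sample (n-1) standard deviation across peaks.  Flags are set
    in place on the measurements, which are also returned for chaining.
    """
    n = len(results)
    if n < 3:
        raise InputError("flag_exposed needs >= 3 measurements")
    ratios = [m.ratio for m in results]
    mean = sum(ratios) / n
    sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1))
    threshold = mean - k * sd
    for m in results:
        m.exposed_flag = m.ratio < threshold
    return results, PRESummary(mean=mean, sd=sd, threshold=threshold, k=k, n=n)
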