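import numpy as np
import pytest

from methyldyn import (
    MethylPeak,
    RelaxationParams,
    RelaxationSeries,
    ScanCounts,
    allowed_intensity,
    forbidden_allowed_ratio,
)


def make_series(
    eta: float,
    delta: float,
    r_slow: float = 40.0,
    amplitude: float = 1000.0,
    allowed_delays=(0.0008, 0.002, 0.004, 0.008, 0.016),
    forbidden_delays=(0.0008, 0.002, 0.004, 0.008, 0.016),
    sigma: float = 1e-6,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    peak_id: str = "p1",
    scans: ScanCounts | None = None,
) -> RelaxationSeries:
    """Series generated from the closed-form model, optionally noisy."""
    scans = scans or ScanCounts()
    params = RelaxationParams(
        eta=eta, delta=delta, r_slow=r_slow, r_fast=r_slow + 2 * eta, amplitude=amplitude
    )
    allowed = []
    for d in allowed_delays:
        v = allowed_intensity(d, params)
        if noise:
            v += rng.normal(0.0, noise)
        allowed.append((d, float(v), sigma if not noise else noise))
    forbidden = []
    for d in forbidden_delays:
        v = allowed_intensity(d, params) * forbidden_allowed_ratio(d, params, scans)
        if noise:
            v += rng.normal(0.0, noise)
        forbidden.append((d, float(v), sigma if not noise else noise))
    return RelaxationSeries(
        peak=MethylPeak(peak_id=peak_id), allowed=allowed, forbidden=forbidden, scans=scans
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
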