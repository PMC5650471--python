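"""Eta estimation: ratio computation, filtering, both schemes, delay selection."""

import numpy as np
import pytest

from methyldyn import (
    InputError,
    MethylPeak,
    RelaxationSeries,
    ScanCounts,
    compute_ratios,
    filter_low_intensity_peaks,
    fit_full_scheme,
    fit_reduced_scheme,
    mask_forbidden,
    select_forbidden_delays,
    simulate_relaxation_dataset,
)
from methyldyn.model import _ratio_kernel
from methyldyn.synth import SyntheticRelaxationSpec

from conftest import make_series

# 0.3 * sqrt((1/30)^2 + (1/100)^2), 30-digit arithmetic, frozen
RATIO_SIGMA_30_100 = 0.010440306508910550


class TestComputeRatios:
    def test_propagated_error(self):
        s = RelaxationSeries(
            peak=MethylPeak("p"),
            allowed=[(0.008, 100.0, 1.0), (0.016, 50.0, 1.0)],
            forbidden=[(0.008, 30.0, 1.0)],
        )
        [(d, r, sig)] = compute_ratios(s)
        assert d == 0.008
        assert r == pytest.approx(0.300, abs=1e-12)
        assert sig == pytest.approx(RATIO_SIGMA_30_100, rel=1e-12)

    def test_zero_forbidden_intensity_limit(self):
        s = RelaxationSeries(
            peak=MethylPeak("p"),
            allowed=[(0.008, 100.0, 2.0), (0.016, 50.0, 2.0)],
            forbidden=[(0.008, 0.0, 1.5)],
        )
        [(_, r, sig)] = compute_ratios(s)
        assert r == 0.0
        assert sig == pytest.approx(1.5 / 100.0, rel=1e-12)

    def test_no_common_delays_gives_empty(self, caplog):
        s = RelaxationSeries(
            peak=MethylPeak("p"),
            allowed=[(0.002, 100.0, 1.0), (0.004, 80.0, 1.0)],
            forbidden=[(0.008, 30.0, 1.0)],
        )
        assert compute_ratios(s) == []

    def test_nonpositive_allowed_excluded(self):
        s = RelaxationSeries(
            peak=MethylPeak("p"),
            allowed=[(0.008, -5.0, 1.0), (0.016, 50.0, 1.0)],
            forbidden=[(0.008, 30.0, 1.0), (0.016, 20.0, 1.0)],
        )
        out = compute_ratios(s)
        assert [d for d, _, _ in out] == [0.016]


class TestLowIntensityFilter:
    def _series_with_reference(self, fold: float, sigma: float = 10.0):
        return RelaxationSeries(
            peak=MethylPeak(f"f{fold}"),
            allowed=[(0.008, 500.0, sigma), (0.016, 400.0, sigma)],
            forbidden=[(0.008, 300.0, sigma), (0.016, fold * sigma, sigma)],
        )

    def test_threshold_boundary(self):
        kept, excluded = filter_low_intensity_peaks(
            [self._series_with_reference(10.1), self._series_with_reference(9.9)]
        )
        assert [s.peak.peak_id for s in kept] == ["f10.1"]
        assert [s.peak.peak_id for s, _ in excluded] == ["f9.9"]
        assert excluded[0][1] == "below_noise_threshold"

    def test_partition_is_exhaustive(self, rng):
        folds = rng.uniform(5.0, 20.0, 25)
        dataset = [self._series_with_reference(round(f, 3)) for f in folds]
        kept, excluded = filter_low_intensity_peaks(dataset)
        assert len(kept) + len(excluded) == len(dataset)
        assert len(excluded) == int(np.sum(folds < 10.0))

    def test_missing_reference_delay_excluded_with_reason(self):
        s = RelaxationSeries(
            peak=MethylPeak("nomax"),
            allowed=[(0.008, 500.0, 1.0), (0.016, 400.0, 1.0)],
            forbidden=[(0.008, 300.0, 1.0)],
        )
        kept, excluded = filter_low_intensity_peaks([s], reference_delay=0.016)
        assert not kept
        assert excluded[0][1] == "missing_reference_delay"


class TestFullScheme:
    def test_noiseless_round_trip(self):
        s = make_series(eta=30.0, delta=-5.0)
        res = fit_full_scheme(s)
        assert res.converged
        assert res.params.eta == pytest.approx(30.0, rel=1e-6)
        assert res.params.delta == pytest.approx(-5.0, rel=1e-6)

    def test_mean_recovery_under_noise(self, rng):
        etas = []
        for _ in range(100):
            s = make_series(eta=40.0, delta=-4.0, noise=20.0, rng=rng)
            etas.append(fit_full_scheme(s).params.eta)
        assert np.mean(etas) == pytest.approx(40.0, rel=0.02)

    def test_sign_constraints_always_hold(self, rng):
        for _ in range(20):
            s = make_series(eta=15.0, delta=-1.0, noise=50.0, rng=rng)
            res = fit_full_scheme(s)
            assert res.params.eta > 0
            assert res.params.delta < 0

    def test_too_few_ratio_points_rejected(self):
        s = make_series(eta=30.0, delta=-5.0, forbidden_delays=(0.008,))
        with pytest.raises(InputError):
            fit_full_scheme(s)


class TestReducedScheme:
    def test_noiseless_round_trip_single_forbidden(self):
        s = make_series(
            eta=55.0,
            delta=-3.0,
            allowed_delays=(0.0008, 0.002, 0.004, 0.008, 0.014),
            forbidden_delays=(0.008,),
        )
        res = fit_reduced_scheme(s)
        assert res.converged
        assert res.params.eta == pytest.approx(55.0, rel=1e-6)
        assert res.params.delta == pytest.approx(-3.0, rel=1e-6)
        assert res.params.r_fast == pytest.approx(res.params.r_slow + 2 * 55.0, rel=1e-9)
        res.params.validate()

    def test_agrees_with_full_when_allowed_noiseless(self, rng):
        # noise on the forbidden intensities only: the extra allowed-decay
        # information cannot pull the joint fit away from the ratio fit
        for eta in (20.0, 50.0, 80.0):
            s = make_series(eta=eta, delta=-4.0, sigma=1.0)
            forb = [(d, v + rng.normal(0, 2.0), 2.0) for d, v, _ in s.forbidden]
            s_noisy = RelaxationSeries(peak=s.peak, allowed=s.allowed, forbidden=forb)
            eta_full = fit_full_scheme(s_noisy).params.eta
            eta_red = fit_reduced_scheme(s_noisy).params.eta
            assert eta_red == pytest.approx(eta_full, rel=0.01)

    def test_forbidden_point_required(self):
        s = make_series(eta=30.0, delta=-5.0, forbidden_delays=(0.012,))
        with pytest.raises(InputError):
            fit_reduced_scheme(s)  # 12 ms has no allowed partner -> no ratio

    def test_optimizer_beats_parameter_grid(self):
        """SSE from the optimizer is at most the best exhaustive-grid SSE."""
        spec = SyntheticRelaxationSpec(n_peaks=3, noise_fraction=0.02, seed=7)
        dataset, _ = simulate_relaxation_dataset(spec)
        etas = np.arange(0.1, 150.0, 0.1)
        deltas = np.arange(-15.0, -0.05, 0.1)
        for s in dataset:
            ratios = compute_ratios(s)
            t = np.array([r[0] for r in ratios])
            y = np.array([r[1] for r in ratios])
            w = 1.0 / np.array([r[2] for r in ratios])
            model = _ratio_kernel(
                t[None, None, :], etas[:, None, None], deltas[None, :, None],
                s.scans.prefactor,
            )
            grid_sse = np.min(np.sum(((model - y) * w) ** 2, axis=2))
            fit_sse = fit_full_scheme(s).residual_sse
            assert fit_sse <= grid_sse + 1e-9


class TestDelaySelection:
    def test_selected_minimizes_ssd(self):
        spec = SyntheticRelaxationSpec(n_peaks=6, noise_fraction=0.01, seed=11)
        dataset, _ = simulate_relaxation_dataset(spec)
        report = select_forbidden_delays(dataset, subset_sizes=(1,))
        assert len(report.candidate_subsets) == 5
        best = min(report.candidate_subsets, key=lambda c: report.ssd[c])
        assert report.ssd[report.selected] == report.ssd[best]
        for subset in report.candidate_subsets:
            assert len(report.per_peak_eta_differences[subset]) == 6

    def test_single_peak_ssd_is_squared_difference(self):
        spec = SyntheticRelaxationSpec(n_peaks=1, noise_fraction=0.01, seed=3)
        dataset, _ = simulate_relaxation_dataset(spec)
        report = select_forbidden_delays(dataset, subset_sizes=(1,))
        pid = dataset[0].peak.peak_id
        for subset in report.candidate_subsets:
            d = report.per_peak_eta_differences[subset][pid]
            assert report.ssd[subset] == pytest.approx(d * d, rel=1e-12)

    def test_incomplete_coverage_rejected(self):
        full = make_series(eta=30, delta=-3, peak_id="a")
        partial = make_series(eta=40, delta=-3, forbidden_delays=(0.008,), peak_id="b")
        with pytest.raises(InputError):
            select_forbidden_delays([full, partial])

    def test_tie_break_prefers_fewer_then_shorter_delays(self):
        from methyldyn.fitting import pick_best_subset

        candidates = [(0.016,), (0.008,), (0.002, 0.008), (0.002, 0.004)]
        ssd = {c: 1.0 for c in candidates}
        assert pick_best_subset(candidates, ssd) == (0.008,)
        ssd[(0.002, 0.004)] = 0.5
        assert pick_best_subset(candidates, ssd) == (0.002, 0.004)

    def test_mask_forbidden_keeps_named_delays(self):
        s = make_series(eta=30.0, delta=-5.0)
        masked = mask_forbidden(s, (0.008,))
        assert [d for d, _, _ in masked.forbidden] == [0.008]
        assert masked.allowed == s.allowed


def test_scan_count_prefactor_passes_through_fit():
    sc = ScanCounts(n_allowed=8, n_forbidden=2)
    s = make_series(eta=45.0, delta=-2.0, scans=sc)
    res = fit_full_scheme(s)
    assert res.params.eta == pytest.approx(45.0, rel=1e-6)
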