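"""Calibration, binning, and hydrolysis-rate computation."""

import numpy as np
import pytest

from flapskit import chrom, synth
from flapskit.chrom import (MWBinning, MWDistribution, fit_calibration,
                            mw_of_dp)


def wide_grid(calib, n=2000, pad=0.8):
    """Elution grid extending past the calibrated range so edge peaks are
    captured whole."""
    lo, hi = calib.elution_range
    return np.linspace(lo - pad, hi + pad, n)


def gaussian_profile(grid, centers, masses, sigma=0.15):
    y = np.zeros_like(grid)
    for c, m in zip(centers, masses):
        y += m * np.exp(-0.5 * ((grid - c) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi))
    return y


class TestCalibration:
    def test_exact_log_linear_standards_interpolate_exactly(self):
        mw = np.array([180.0, 1.8e3, 1.8e4, 1.8e5])
        elu = 12.0 - 2.0 * np.log10(mw)
        cal = fit_calibration(np.column_stack([mw, elu]))
        assert cal.residual_rms < 1e-10
        assert cal.elution_of_mw(5e3) == pytest.approx(12.0 - 2.0 * np.log10(5e3))
        assert cal.mw_of_elution(cal.elution_of_mw(777.0)) == pytest.approx(777.0)

    def test_two_standards_rejected(self):
        with pytest.raises(ValueError, match="3 calibration standards"):
            fit_calibration([(100.0, 10.0), (1000.0, 8.0)])

    def test_non_monotone_standards_rejected(self):
        bad = [(100.0, 10.0), (1000.0, 8.0), (10000.0, 9.0)]
        with pytest.raises(ValueError, match="monotone"):
            fit_calibration(bad)

    def test_generator_calibration_round_trips(self, calib):
        """Refitting on emitted standards reproduces the map within 1% in MW."""
        standards = synth.calibration_standards(calib, n=8)
        refit = fit_calibration(standards)
        mw = np.geomspace(calib.mw_min, calib.mw_max, 25)
        back = refit.mw_of_elution(calib.elution_of_mw(mw))
        assert np.all(np.abs(back / mw - 1.0) < 0.01)


class TestBinning:
    def test_default_binning_contains_parent_and_monomer(self):
        b = MWBinning.default(100)
        assert b.edges[0] > 100 and b.edges[-1] <= 1.0
        assert b.reps[0] == pytest.approx(100.0)
        assert b.reps[-1] == pytest.approx(1.0)
        assert b.bin_of_dp(100.0) == 0
        assert b.bin_of_dp(1.0) == b.n_bins - 1

    def test_log_spaced_reps_are_geometric(self):
        b = MWBinning.log_spaced(100, 11)
        ratios = np.asarray(b.reps[:-1]) / np.asarray(b.reps[1:])
        assert np.allclose(ratios, ratios[0])

    def test_geometric_mean_fallback_and_validation(self):
        b = MWBinning(edges=(100.0, 10.0, 0.9))
        assert b.reps == pytest.approx((np.sqrt(1000.0), 3.0))
        with pytest.raises(ValueError):
            MWBinning(edges=(10.0, 100.0, 0.5))  # not decreasing
        with pytest.raises(ValueError):
            MWBinning(edges=(100.0, 10.0, 2.0))  # excludes monomer


class TestBinDistribution:
    def test_single_parent_peak(self, laminarin, calib, fine_bins):
        grid = wide_grid(calib, 1200)
        pos = calib.elution_of_mw(mw_of_dp(laminarin.parent_dp))
        y = gaussian_profile(grid, [pos], [1.0], sigma=0.08)
        d = chrom.bin_distribution(grid, y, calib, fine_bins)
        assert d.fractions[0] >= 0.99

    def test_equal_area_peaks_split_evenly(self, calib):
        bins = MWBinning.log_spaced(100, 6)
        grid = wide_grid(calib)
        pos = calib.elution_of_mw(mw_of_dp(np.array([100.0, 1.0])))
        y = gaussian_profile(grid, pos, [1.0, 1.0], sigma=0.1)
        d = chrom.bin_distribution(grid, y, calib, bins)
        assert d.fractions[0] == pytest.approx(0.5, abs=0.01)
        assert d.fractions[-1] == pytest.approx(0.5, abs=0.01)

    def test_known_per_bin_mass_recovered(self, calib):
        """Constructed mass split 0.5/0.3/0.2 recovered within 2% absolute."""
        # 5 log-spaced classes put representatives exactly at DP 100, 10, 1
        bins = MWBinning.log_spaced(100, 5)
        grid = wide_grid(calib)
        dps = np.array([100.0, 10.0, 1.0])
        masses = np.array([0.5, 0.3, 0.2])
        y = gaussian_profile(grid, calib.elution_of_mw(mw_of_dp(dps)), masses,
                             sigma=0.12)
        d = chrom.bin_distribution(grid, y, calib, bins)
        for dp, m in zip(dps, masses):
            assert d.fractions[bins.bin_of_dp(dp)] == pytest.approx(m, abs=0.02)

    def test_blank_subtraction_and_rejection(self, calib, fine_bins):
        grid = wide_grid(calib, 800)
        blank = np.full_like(grid, 0.2)
        with pytest.raises(ValueError, match="total signal"):
            chrom.bin_distribution(grid, blank, calib, fine_bins, blank=blank)


def make_dist(bins, frac_map, timepoint_h):
    f = np.zeros(bins.n_bins)
    for dp, v in frac_map.items():
        f[bins.bin_of_dp(dp)] += v
    return MWDistribution(timepoint_h=timepoint_h, fractions=tuple(f),
                          total_signal=1.0)


class TestComputeRate:
    def test_no_change_means_zero_rate(self, laminarin, fine_bins):
        d0 = make_dist(fine_bins, {100.0: 1.0}, 0.0)
        dt = make_dist(fine_bins, {100.0: 1.0}, 24.0)
        est = chrom.compute_rate(d0, dt, laminarin, fine_bins)
        assert est.rate == 0.0

    def test_complete_depolymerization_hand_value(self, laminarin, fine_bins):
        """3500 nmol/L over 144 h, P=100: 3500 * (1 - 1/100) / 144 = 24.06."""
        d0 = make_dist(fine_bins, {100.0: 1.0}, 0.0)
        dt = make_dist(fine_bins, {1.0: 1.0}, 144.0)
        est = chrom.compute_rate(d0, dt, laminarin, fine_bins)
        assert est.rate == pytest.approx(3500.0 * (1 - 1 / 100) / 144.0)
        assert est.rate == pytest.approx(24.0625)

    def test_rate_halves_at_doubled_elapsed_time(self, laminarin, fine_bins):
        d0 = make_dist(fine_bins, {100.0: 1.0}, 0.0)
        frac = {100.0: 0.4, 10.0: 0.4, 1.0: 0.2}
        r1 = chrom.compute_rate(d0, make_dist(fine_bins, frac, 144.0),
                                laminarin, fine_bins).rate
        r2 = chrom.compute_rate(d0, make_dist(fine_bins, frac, 288.0),
                                laminarin, fine_bins).rate
        assert r2 == r1 / 2.0

    def test_zero_elapsed_rejected(self, laminarin, fine_bins):
        d0 = make_dist(fine_bins, {100.0: 1.0}, 5.0)
        with pytest.raises(ValueError, match="elapsed"):
            chrom.compute_rate(d0, d0, laminarin, fine_bins)

    def test_rate_bounded_by_complete_depolymerization(self, laminarin,
                                                       fine_bins):
        d0 = make_dist(fine_bins, {100.0: 1.0}, 0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.dirichlet(np.ones(fine_bins.n_bins))
            dt = MWDistribution(24.0, tuple(f), 1.0)
            est = chrom.compute_rate(d0, dt, laminarin, fine_bins)
            bound = laminarin.monomer_conc * (1 - 1 / laminarin.parent_dp) / 24.0
            assert 0.0 <= est.rate <= bound + 1e-9

    def test_rate_invariant_to_signal_rescaling(self, laminarin, calib,
                                                fine_bins):
        kin = synth.KineticsSpec("endo_random", cleavage_rate=0.002)
        series, _ = synth.generate_chromatogram_series(
            laminarin, kin, [0.0, 72.0], calib=calib, seed=3)
        rates = []
        for scale in (1.0, 37.5):
            d0 = chrom.bin_distribution(series.elution,
                                        scale * series.signals[0], calib,
                                        fine_bins, timepoint_h=0.0)
            dt = chrom.bin_distribution(series.elution,
                                        scale * series.signals[1], calib,
                                        fine_bins, timepoint_h=72.0)
            rates.append(chrom.compute_rate(d0, dt, laminarin, fine_bins).rate)
        assert rates[0] == pytest.approx(rates[1], rel=1e-12)


class TestKilledCorrection:
    def test_subtraction_floor_and_passthrough(self):
        def est(rate, sub="laminarin", t=144.0):
            return chrom.HydrolysisRateEstimate(rate=rate, substrate=sub,
                                                elapsed_h=t)

        assert chrom.correct_with_killed(est(4.0), est(0.5)).rate == pytest.approx(3.5)
        assert chrom.correct_with_killed(est(4.0), est(0.0)).rate == 4.0
        assert chrom.correct_with_killed(est(1.0), est(2.0)).rate == 0.0
        assert chrom.correct_with_killed(est(4.0), est(0.5)).killed_corrected
        with pytest.raises(ValueError, match="substrate"):
            chrom.correct_with_killed(est(4.0), est(0.5, sub="xylan"))
        with pytest.raises(ValueError, match="elapsed"):
            chrom.correct_with_killed(est(4.0), est(0.5, t=72.0))


class TestRateTimecourse:
    def test_identical_replicates_have_zero_sd(self, laminarin, calib,
                                               fine_bins):
        kin = synth.KineticsSpec("endo_random", cleavage_rate=0.002)
        series, _ = synth.generate_chromatogram_series(
            laminarin, kin, [0.0, 72.0, 144.0], calib=calib, seed=11)
        df = chrom.rate_timecourse([series, series, series], laminarin, calib,
                                   fine_bins)
        summary = chrom.summarize_replicates(df)
        assert (summary["rate_sd"].abs() < 1e-12).all()
        assert len(summary) == 2

    def test_recovers_true_rate_before_saturation(self, laminarin, calib,
                                                  fine_bins):
        """Dense timepoints on a constant-rate simulation: within 20% of truth."""
        kin = synth.KineticsSpec("endo_random", cleavage_rate=0.0005)
        series, truth = synth.generate_chromatogram_series(
            laminarin, kin, [0.0, 12.0, 24.0, 48.0], calib=calib, seed=12,
            n_chains=3000)
        df = chrom.rate_timecourse([series], laminarin, calib, fine_bins)
        true_rates = truth.true_rate(laminarin.monomer_conc)
        est = df["rate_nmol_monomer_L_h"].to_numpy()
        assert np.all(np.abs(est - true_rates) / true_rates < 0.20)

    def test_sparse_late_sampling_underestimates(self, laminarin, calib,
                                                 fine_bins):
        """Only {0, 18 d} sampled on a fast hydrolysis: estimate falls below
        the dense-timepoint estimate (the late-timepoint caveat)."""
        kin = synth.KineticsSpec("endo_random", cleavage_rate=0.01)
        dense_t = [0.0, 12.0, 24.0, 72.0, 144.0, 288.0, 432.0]
        series, _ = synth.generate_chromatogram_series(
            laminarin, kin, dense_t, calib=calib, seed=13)
        df = chrom.rate_timecourse([series], laminarin, calib, fine_bins)
        dense_early = df.loc[df["timepoint_h"] == 12.0,
                             "rate_nmol_monomer_L_h"].iloc[0]
        sparse = df.loc[df["timepoint_h"] == 432.0,
                        "rate_nmol_monomer_L_h"].iloc[0]
        assert sparse < dense_early

    def test_missing_t0_rejected(self, laminarin, calib, fine_bins):
        kin = synth.KineticsSpec("endo_random", cleavage_rate=0.002)
        series, _ = synth.generate_chromatogram_series(
            laminarin, kin, [0.0, 72.0], calib=calib, seed=14)
        no_t0 = synth.ChromatogramSeries(
            sample_id=series.sample_id, substrate=series.substrate,
            elution=series.elution, timepoints_h=(24.0, 72.0),
            signals=series.signals)
        with pytest.raises(ValueError, match="t0"):
            chrom.rate_timecourse([no_t0], laminarin, calib, fine_bins)


def test_series_tsv_round_trip(tmp_path, laminarin, calib):
    kin = synth.KineticsSpec("endo_random", cleavage_rate=0.002)
    series, _ = synth.generate_chromatogram_series(
        laminarin, kin, [0.0, 72.0], calib=calib, noise_sd=0.01, seed=15)
    path = tmp_path / "chrom.tsv"
    series.to_tsv(path)
    back = synth.ChromatogramSeries.from_tsv(path)
    assert len(back) == 1
    assert back[0].timepoints_h == series.timepoints_h
    assert np.allclose(back[0].signals, series.signals)
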