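"""Feature extraction: time-domain arithmetic, Welch calibration, band indices."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hrvbalance import features as ft
from hrvbalance import simulate as sim
from hrvbalance.errors import TooShortError, UndefinedIndexError
from hrvbalance.series import RRSeries, Tachogram


class TestTimeDomain:
    def test_reference_arithmetic(self):
        rr = RRSeries(intervals=np.array([800.0, 810.0, 790.0, 805.0] * 3)[:10])
        # exact oracle values computed by direct arithmetic on the 4-cycle
        rr4 = np.array([800.0, 810.0, 790.0, 805.0])
        series = RRSeries(intervals=np.tile(rr4, 3)[:12])
        mean_rr, mean_hr, hr_range, sdnn = ft.time_domain_features(series)
        assert mean_rr == pytest.approx(801.25)
        hr = 60000.0 / np.tile(rr4, 3)
        assert mean_hr == pytest.approx(hr.mean())
        assert hr_range == pytest.approx(hr.max() - hr.min())
        assert sdnn == pytest.approx(np.std(np.tile(rr4, 3), ddof=1))

    def test_four_beat_example_values(self):
        # the canonical 4-interval example, padded by repetition to meet n>=10
        rr4 = [800.0, 810.0, 790.0, 805.0]
        mean_rr = np.mean(rr4)
        sdnn = np.std(rr4, ddof=1)
        hr = 60000.0 / np.asarray(rr4)
        assert mean_rr == pytest.approx(801.25)
        assert sdnn == pytest.approx(8.539, abs=1e-3)
        assert hr.mean() == pytest.approx(74.89, abs=0.01)
        assert hr.max() - hr.min() == pytest.approx(1.88, abs=0.01)

    def test_constant_series(self):
        mean_rr, mean_hr, hr_range, sdnn = ft.time_domain_features(
            RRSeries(intervals=np.full(50, 1000.0))
        )
        assert mean_hr == 60.0 and sdnn == 0.0 and hr_range == 0.0

    def test_calibrated_pre_phase_heart_rate(self, default_recording):
        from hrvbalance import preprocess as pp

        seg, _, _ = pp.extract_phase_segment(default_recording, "pre")
        corrected, _ = pp.detect_and_correct_artifacts(seg)
        _, mean_hr, _, _ = ft.time_domain_features(corrected)
        assert 85.0 <= mean_hr <= 92.0  # ~60000/680

    def test_too_short(self):
        with pytest.raises(TooShortError):
            ft.time_domain_features(RRSeries(intervals=np.full(5, 800.0)))


class TestWelch:
    def test_zero_input_zero_density(self):
        spec = ft.welch_psd(Tachogram(values=np.zeros(1200)))
        assert np.max(spec.density) < 1e-20

    def test_parseval_on_white_noise(self):
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(2400)
            spec = ft.welch_psd(Tachogram(values=x))
            ratios.append(np.trapezoid(spec.density, spec.freqs) / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.10

    def test_sinusoid_band_power_closed_form(self):
        t = np.arange(2400) / 4.0
        x = 50.0 * np.sin(2 * np.pi * 0.10 * t)
        bp = ft.band_powers(ft.welch_psd(Tachogram(values=x)))
        assert abs(bp.lf - 1250.0) / 1250.0 < 0.10

    def test_short_segment_single_window_flag(self):
        x = np.random.default_rng(0).standard_normal(720)  # 180 s at 4 Hz
        spec = ft.welch_psd(Tachogram(values=x), window_s=300.0)
        assert spec.single_window and spec.window_s == pytest.approx(180.0)

    def test_below_minimum_rejected(self):
        with pytest.raises(TooShortError):
            ft.welch_psd(Tachogram(values=np.zeros(200)))


class TestBandPowers:
    def test_printed_lhfp_arithmetic(self):
        bp = ft.BandPowers(vlf=47.0, lf=643.0, hf=295.0)
        assert bp.lhfp == 938.0
        assert bp.total == pytest.approx(47.0 + 938.0)

    def test_boundary_and_symmetry(self):
        eq = ft.BandPowers(vlf=0.0, lf=200.0, hf=200.0)
        assert eq.lhfnd == 0.0
        pure_lf = ft.BandPowers(vlf=0.0, lf=100.0, hf=0.0)
        assert pure_lf.lhfnd == 1.0

    def test_derived_indices(self):
        bp = ft.BandPowers(vlf=10.0, lf=300.0, hf=100.0)
        assert bp.lf_nu == 75.0 and bp.hf_nu == 25.0
        assert bp.lf_hf_ratio == 3.0 and bp.lhfnd == 0.5
        assert bp.lf_nu + bp.hf_nu == 100.0
        assert bp.lhfnd == (bp.lf_nu - bp.hf_nu) / 100.0

    def test_zero_power_flagged_not_silent(self):
        bp = ft.BandPowers(vlf=5.0, lf=0.0, hf=0.0)
        with pytest.raises(UndefinedIndexError):
            bp.lhfnd

    @given(
        lf=hst.floats(min_value=1e-3, max_value=1e5),
        hf=hst.floats(min_value=1e-3, max_value=1e5),
    )
    @settings(max_examples=100, deadline=None)
    def test_lhfnd_antisymmetry(self, lf, hf):
        a = ft.BandPowers(vlf=0.0, lf=lf, hf=hf)
        b = ft.BandPowers(vlf=0.0, lf=hf, hf=lf)
        assert a.lhfnd == pytest.approx(-b.lhfnd, rel=1e-12, abs=1e-12)

    def test_scale_equivariance(self):
        t = np.arange(1200) / 4.0
        x = 30 * np.sin(2 * np.pi * 0.1 * t) + 15 * np.sin(2 * np.pi * 0.25 * t)
        b1 = ft.band_powers(ft.welch_psd(Tachogram(values=x)))
        b2 = ft.band_powers(ft.welch_psd(Tachogram(values=3.0 * x)))
        assert b2.lf == pytest.approx(9.0 * b1.lf, rel=1e-9)
        assert b2.hf == pytest.approx(9.0 * b1.hf, rel=1e-9)
        assert b2.lhfnd == pytest.approx(b1.lhfnd, rel=1e-9)
        assert b2.lf_nu == pytest.approx(b1.lf_nu, rel=1e-9)

    def test_total_at_least_lhfp(self, ipfm_series):
        from hrvbalance import preprocess as pp

        tach = pp.resample_tachogram(ipfm_series)
        _, resid = pp.detrend_smoothness_priors(tach)
        bp = ft.band_powers(ft.welch_psd(resid))
        assert bp.total >= bp.lhfp


class TestBandRecovery:
    def test_band_powers_recover_modulator_targets(self):
        """IPFM with known amplitudes: LF/HF land within 15 % of a^2/2."""
        lf_err, hf_err = [], []
        for seed in range(10):
            spec = sim.ModulatorSpec(
                mean_rr=680.0, lf_amp=35.9, hf_amp=24.3, noise_sd=5.0
            )
            beats = sim.ipfm_beat_times(spec, 320.0, seed=seed)
            series = RRSeries(
                intervals=np.diff(np.concatenate([[0.0], beats])) * 1000.0
            )
            from hrvbalance import preprocess as pp

            tach = pp.resample_tachogram(series)
            _, resid = pp.detrend_smoothness_priors(tach)
            bp = ft.band_powers(ft.welch_psd(resid))
            lf_err.append(abs(bp.lf - 643.0) / 643.0)
            hf_err.append(abs(bp.hf - 295.0) / 295.0)
        assert np.mean(lf_err) < 0.15 and np.mean(hf_err) < 0.15


class TestFeatureTable:
    def test_rows_and_pattern(self):
        recs, cohort = sim.simulate_cohort(sim.CohortConfig(n_subjects=8), seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feat = ft.compute_feature_table(recs)
        assert len(feat) == 24  # 8 subjects x 3 phases
        ok = feat[~feat["flags"].str.contains("error|excluded", na=False)]
        means = ok.groupby("phase")["lhfp"].mean()
        assert means["post"] > means["interview"]

    def test_quality_gate_flags_not_drops(self):
        recs, _ = sim.simulate_cohort(
            sim.CohortConfig(n_subjects=6, artifact_spec=sim.ArtifactSpec()), seed=3
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feat = ft.compute_feature_table(recs)
        assert len(feat) == 18  # every subject x phase row present
        assert feat["flags"].notna().all()
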