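"""Validation schemes V1-V5, ranking, benchmark sweeps and calibration."""

import numpy as np
import pytest

import cdvalid as cv
from cdvalid.errors import CalibrationError, ConfigurationError
from cdvalid.validation import PRESETS, SensitivityParameter

OPTS = {"n_starts": 40, "seed": 0}


class TestErrorFromRmsd:
    @pytest.mark.parametrize("rmsd,mf,expected", [
        (0.0, 15.6, 0.0),
        (3.07, 30.7, 0.10),
        (15.6, 15.6, 1.0),
    ])
    def test_quotient(self, rmsd, mf, expected):
        assert cv.error_from_rmsd(rmsd, SensitivityParameter(mf)) == \
            pytest.approx(expected)

    def test_presets_carry_documented_slopes(self):
        assert PRESETS["V4"].m_f == 15.6
        assert PRESETS["V5"].m_f == 30.7


class TestEstimateModelError:
    def test_correct_spectrum_correct_model_v2(self, benchmark):
        models, spectra, basis, *_ = benchmark
        est = cv.estimate_model_error("V2", spectra[0].spectrum,
                                      models[0].composition, basis,
                                      deconv_options=OPTS)
        assert est.estimated_error < 0.01

    @pytest.mark.parametrize("method", ["V4", "V5"])
    def test_correct_pair_prediction_methods_zero(self, benchmark, method):
        models, spectra, basis, *_ = benchmark
        est = cv.estimate_model_error(method, spectra[0].spectrum,
                                      models[0].composition, basis)
        assert est.estimated_error == pytest.approx(0.0, abs=1e-9)
        assert est.fit_rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["V2", "V4", "V5"])
    def test_scaled_spectrum_rescaling_methods_unaffected(self, benchmark,
                                                          method):
        models, _, basis, _, correct = benchmark
        scaled = correct.scaled(1.3)
        est = cv.estimate_model_error(method, scaled, models[0].composition,
                                      basis, deconv_options=OPTS)
        assert est.estimated_error < 0.01

    def test_scaled_spectrum_breaks_v1(self, benchmark):
        models, _, basis, _, correct = benchmark
        est = cv.estimate_model_error("V1", correct.scaled(1.3),
                                      models[0].composition, basis,
                                      deconv_options=OPTS)
        assert est.estimated_error > 0.01

    def test_v4_v5_estimate_is_rmsd_over_mf(self, benchmark):
        models, spectra, basis, *_ = benchmark
        for method in ("V4", "V5"):
            est = cv.estimate_model_error(method, spectra[17].spectrum,
                                          models[5].composition, basis)
            assert est.estimated_error * PRESETS[method].m_f == \
                pytest.approx(est.fit_rmsd, abs=1e-9)

    def test_v3_applies_model_based_scale(self, benchmark):
        models, _, basis, _, correct = benchmark
        est = cv.estimate_model_error("V3", correct.scaled(1.3),
                                      models[0].composition, basis,
                                      deconv_options=OPTS)
        # correct model: rescaling inverts the injected 1.3 factor
        assert est.applied_scale == pytest.approx(1 / 1.3, rel=1e-6)
        assert est.estimated_error < 0.01


class TestRankScore:
    def test_strictly_smallest_correct_scores_zero(self):
        assert cv.rank_score([0.01, 0.2, 0.3, 0.4], 0) == 0

    def test_exact_ties_count(self):
        assert cv.rank_score([0.1, 0.1, 0.1, 0.1, 0.5], 0) == 3

    def test_matches_brute_force_loop(self, rng):
        for _ in range(50):
            errors = rng.uniform(0, 1, size=21)
            idx = int(rng.integers(0, 21))
            expected = sum(1 for j, e in enumerate(errors)
                           if j != idx and e <= errors[idx])
            assert cv.rank_score(errors, idx) == expected


class TestEvaluateBenchmark:
    def test_perfect_estimator_scores_zero(self, benchmark):
        models, spectra, basis, *_ = benchmark
        report = cv.evaluate_benchmark(
            models, spectra, "V5", basis,
            estimator=lambda m, s: m.true_ss_deviation)
        np.testing.assert_allclose(report.per_spectrum_error, 0.0, atol=1e-12)
        np.testing.assert_array_equal(report.per_spectrum_rank, 0)
        assert report.n_models == 20

    def test_additive_bias_shifts_error_not_rank(self, benchmark):
        models, spectra, basis, *_ = benchmark
        report = cv.evaluate_benchmark(
            models, spectra, "V5", basis,
            estimator=lambda m, s: m.true_ss_deviation + 0.05)
        np.testing.assert_allclose(report.per_spectrum_error, 0.05, atol=1e-12)
        np.testing.assert_array_equal(report.per_spectrum_rank, 0)

    @pytest.mark.parametrize("method", ["V2", "V4", "V5"])
    def test_correct_spectrum_identifies_correct_model(self, benchmark,
                                                       method):
        models, spectra, basis, *_ = benchmark
        report = cv.evaluate_benchmark(models, spectra[:1], method, basis,
                                       deconv_options=OPTS)
        assert report.per_spectrum_rank[0] == 0

    def test_report_summaries_recompute(self, benchmark):
        models, spectra, basis, *_ = benchmark
        report = cv.evaluate_benchmark(
            models, spectra, "V5", basis,
            estimator=lambda m, s: m.true_ss_deviation + s.true_cd_deviation)
        assert report.mean_error == pytest.approx(
            float(np.mean(report.per_spectrum_error)))
        round_trip = cv.BenchmarkReport.from_dict(report.to_dict())
        np.testing.assert_allclose(round_trip.per_spectrum_error,
                                   report.per_spectrum_error)

    def test_missing_correct_model_rejected(self, benchmark):
        models, spectra, basis, *_ = benchmark
        with pytest.raises(ConfigurationError):
            cv.evaluate_benchmark(models[1:], spectra, "V5", basis)


class TestCalibration:
    def test_exact_linear_pairs_recover_slope(self):
        dss = np.linspace(0.05, 0.6, 12)
        pairs = list(zip(20.0 * dss, dss))
        param = cv.calibrate_sensitivity(pairs)
        assert param.m_f == pytest.approx(20.0)
        assert param.fit_r == pytest.approx(1.0)

    def test_all_zero_rmsd_rejected(self):
        pairs = [(0.0, 0.1), (0.0, 0.2), (0.0, 0.3)]
        with pytest.raises(CalibrationError):
            cv.calibrate_sensitivity(pairs)

    def test_zero_spread_rejected(self):
        with pytest.raises(CalibrationError):
            cv.calibrate_sensitivity([(1.0, 0.2)] * 5)

    def test_slope_matches_grid_minimization(self, rng):
        dss = rng.uniform(0.05, 0.6, size=40)
        rmsd = 17.0 * dss + rng.normal(0, 0.8, size=40)
        param = cv.calibrate_sensitivity(list(zip(rmsd, dss)))
        grid = np.arange(5.0, 40.0, 1e-3)
        losses = [np.sum((rmsd - m * dss) ** 2) for m in grid]
        assert param.m_f == pytest.approx(grid[int(np.argmin(losses))],
                                          abs=1e-3)

    def test_population_calibration_recovers_generating_slope(self):
        rng = np.random.default_rng(11)
        m_true = 25.0
        dss = rng.uniform(0.02, 0.7, size=500)
        rmsd = np.abs(m_true * dss + rng.normal(0, 1.0, size=500))
        param = cv.calibrate_sensitivity(list(zip(rmsd, dss)))
        assert param.m_f == pytest.approx(m_true, rel=0.02)


class TestReferencePopulation:
    def test_compositions_normalized_and_truths_recompute(self, basis):
        population = cv.sample_reference_population(20, seed=3, basis=basis)
        assert len(population) == 20
        for protein in population:
            assert protein.composition.fractions.sum() == pytest.approx(1.0)
            assert protein.alpha > 0.2
            ss_signal = cv.predict_spectrum(protein.composition, basis)
            assert protein.cd_deviation == pytest.approx(
                cv.spectrum_error(protein.spectrum, ss_signal), abs=1e-9)

    def test_alpha_distribution_matches_target(self, basis):
        population = cv.sample_reference_population(2000, seed=5, basis=basis)
        alphas = np.array([p.alpha for p in population])
        se_mean = 0.25 / np.sqrt(2000)
        assert abs(alphas.mean() - 0.87) < 3 * se_mean + 0.003
        # truncation at 0.2 shrinks the SD by < 2%
        assert abs(alphas.std(ddof=1) - 0.25) < 0.02

    def test_invalid_parameters_rejected(self, basis):
        with pytest.raises(ConfigurationError):
            cv.sample_reference_population(0, seed=1, basis=basis)
        with pytest.raises(ConfigurationError):
            cv.sample_reference_population(5, seed=1, basis=basis,
                                           scale_sd=-1.0)

    def test_model_grid_rmsd_tracks_ss_deviation(self, benchmark):
        # against the ideal spectrum, rescaled prediction RMSD grows with
        # the true SS deviation of the model (positive correlation; larger
        # deviations cost measurably more RMSD than small ones)
        models, spectra, basis, *_ = benchmark
        pairs = []
        for m in models[1:]:
            pred = cv.predict_spectrum(m.composition, basis)
            scale = cv.optimal_scale(spectra[0].spectrum, pred)
            pairs.append((cv.rmsd(pred, spectra[0].spectrum.scaled(scale)),
                          m.true_ss_deviation))
        param = cv.calibrate_sensitivity(pairs)
        assert param.m_f > 0
        assert param.fit_r > 0
        arr = np.asarray(pairs)
        small = arr[arr[:, 1] <= 0.10, 0].mean()
        large = arr[arr[:, 1] >= 0.20, 0].mean()
        assert large > small

    def test_calibration_pairs_from_population_usable(self, basis):
        population = cv.sample_reference_population(
            100, seed=7, basis=basis, contamination_median=0.1)
        pairs = cv.calibration_pairs_from_population(population, basis, seed=7)
        # anti-correlated model draws are dropped, the rest kept
        assert len(pairs) > 50
        param = cv.calibrate_sensitivity(pairs)
        assert param.m_f > 0
        assert 0 < param.fit_r <= 1.0
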