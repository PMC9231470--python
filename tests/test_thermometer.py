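"""Thermometer training/prediction contracts and validation statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from pyrotrace import synth, thermometer
from pyrotrace.exceptions import InputError, TrainingError, UndefinedStatisticError
from pyrotrace.spectra import PreprocessRecipe, Spectrum, make_grid
from pyrotrace.thermometer import (
    EvalReport,
    ThermometerModel,
    _log10_p_two_sided,
    estimate_artifact,
    evaluate,
    pearson_ci,
    predict_batch,
    predict_spectrum,
    train_thermometer,
)


class TestPearsonCI:
    def test_printed_intervals_recovered(self):
        """The Fisher-z interval reproduces both published validation CIs
        from (r, n) alone at 2-decimal rounding."""
        lo, hi = pearson_ci(0.78, 1569)
        assert (round(lo, 2), round(hi, 2)) == (0.76, 0.80)
        lo, hi = pearson_ci(0.72, 1569)
        assert (round(lo, 2), round(hi, 2)) == (0.70, 0.74)

    def test_symmetric_about_zero(self):
        lo, hi = pearson_ci(0.0, 50)
        assert lo == pytest.approx(-hi)

    def test_brackets_r(self):
        for r in (-0.9, -0.3, 0.2, 0.95):
            lo, hi = pearson_ci(r, 40)
            assert lo < r < hi

    def test_degenerate_and_small_n_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_ci(1.0, 100)
        with pytest.raises(InputError):
            pearson_ci(0.5, 3)

    def test_coverage_at_nominal_level(self):
        """95% Fisher-z CI covers the true correlation 95% ± 1.5% of the
        time over 2,000 bivariate-normal datasets (ρ=0.5, n=100)."""
        rho, n = 0.5, 100
        rng = np.random.default_rng(2024)
        cov = [[1.0, rho], [rho, 1.0]]
        hits = 0
        for _ in range(2000):
            xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
            r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            lo, hi = pearson_ci(r, n)
            hits += lo <= rho <= hi
        assert hits / 2000 == pytest.approx(0.95, abs=0.015)


class TestPearsonCIProperties:
    from hypothesis import given, settings, strategies as st

    @given(r=st.floats(-0.99, 0.99), n=st.integers(4, 5000))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_interval_brackets_r_and_tightens_with_n(self, r, n):
        lo, hi = pearson_ci(r, n)
        assert -1.0 < lo < r < hi < 1.0
        if n >= 8:
            lo2, hi2 = pearson_ci(r, 2 * n)
            assert (hi2 - lo2) < (hi - lo)


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep.mae_per_spectrum == 0.0
        assert rep.pearson_r == 1.0
        assert rep.df == 2

    def test_perfect_anticorrelation(self):
        truth = [1.0, 2.0, 3.0, 4.0]
        rep = evaluate([-t for t in truth], truth)
        assert rep.pearson_r == -1.0

    def test_matches_brute_force_formulas(self):
        """r, t and MAE agree with independent from-scratch computation."""
        rng = np.random.default_rng(50)
        truth = rng.uniform(0, 900, size=50)
        pred = truth + rng.normal(0, 80, size=50)
        rep = evaluate(pred, truth)
        # brute-force product-moment formula
        mp, mt = pred.mean(), truth.mean()
        cov = float(np.sum((pred - mp) * (truth - mt)))
        r_oracle = cov / math.sqrt(
            float(np.sum((pred - mp) ** 2)) * float(np.sum((truth - mt) ** 2))
        )
        assert rep.pearson_r == pytest.approx(r_oracle, abs=1e-12)
        assert rep.mae_per_spectrum == pytest.approx(
            float(np.mean(np.abs(pred - truth))), abs=1e-12
        )
        t_oracle = r_oracle * math.sqrt((50 - 2) / (1 - r_oracle**2))
        assert rep.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert rep.p_two_sided == pytest.approx(
            2 * stats.t.sf(abs(t_oracle), 48), rel=1e-10
        )

    def test_zero_variance_raises_with_mae(self):
        with pytest.raises(UndefinedStatisticError) as err:
            evaluate([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert err.value.mae == pytest.approx(3.0)  # mean of |4|, |3|, |2|

    def test_report_invariants(self):
        rng = np.random.default_rng(9)
        truth = rng.uniform(0, 900, 30)
        rep = evaluate(truth + rng.normal(0, 50, 30), truth)
        assert -1.0 <= rep.pearson_r <= 1.0
        assert rep.ci95[0] <= rep.pearson_r <= rep.ci95[1]
        assert rep.df == rep.n_spectra - 2


class TestLogP:
    def test_matches_scipy_where_finite(self):
        for t_abs, df in ((2.0, 10), (5.0, 100), (20.0, 500)):
            expected = math.log10(2 * stats.t.sf(t_abs, df))
            assert _log10_p_two_sided(t_abs, df) == pytest.approx(expected, rel=1e-6)

    def test_monotone_past_underflow(self):
        vals = [_log10_p_two_sided(t, 700) for t in (30, 36, 38, 60, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(math.isfinite(v) for v in vals)


def _linear_spectra(temps, grid):
    """Spectra whose single band height is an exact linear map of temp."""
    out = []
    for temp in temps:
        y = 1e-3 * temp * np.exp(-0.5 * ((grid - 800.0) / 60.0) ** 2)
        out.append(Spectrum(grid, y))
    return out


class TestTraining:
    RECIPE = PreprocessRecipe(target_grid=(200.0, 1800.0, 16.0),
                              baseline="none", normalization="none")

    def test_linear_target_learned_below_10C(self):
        """Intensity exactly linear in temperature: held-out MAE < 10 °C."""
        grid = make_grid(200.0, 1800.0, 16.0)
        train_temps = [t for t in range(100, 1000, 100) for _ in range(3)]
        model = train_thermometer(
            _linear_spectra(train_temps, grid), train_temps,
            arch="fcann",
            hyperparams={"epochs": 400, "hidden": (16,), "lr": 5e-3, "batch_size": 16},
            seed=2, recipe=self.RECIPE,
        )
        held_temps = [150.0, 450.0, 750.0]
        preds = predict_batch(model, _linear_spectra(held_temps, grid))
        assert float(np.mean(np.abs(preds - held_temps))) < 10.0

    def test_sklearn_oracle_agrees_linear_target_is_learnable(self):
        """Independent learner cross-check: sklearn's MLP also drives the
        held-out error low on the same design matrix, so the task truly
        is linearly learnable and low error is not an artifact of our
        training loop."""
        sklearn = pytest.importorskip("sklearn.neural_network")
        grid = make_grid(200.0, 1800.0, 16.0)
        train_temps = [t for t in range(100, 1000, 100) for _ in range(3)]
        x = np.stack([sp.intensities for sp in _linear_spectra(train_temps, grid)])
        t = np.asarray(train_temps, dtype=float)
        reg = sklearn.MLPRegressor(hidden_layer_sizes=(16,), max_iter=5000,
                                   random_state=0, tol=1e-9)
        reg.fit(x, (t - t.mean()) / t.std())  # standardized target, as ours
        held = np.array([150.0, 450.0, 750.0])
        xh = np.stack([sp.intensities for sp in _linear_spectra(held, grid)])
        preds = reg.predict(xh) * t.std() + t.mean()
        assert float(np.mean(np.abs(preds - held))) < 10.0

    def test_single_temperature_rejected(self):
        grid = make_grid(200.0, 1800.0, 16.0)
        with pytest.raises(TrainingError, match="degenerate"):
            train_thermometer(_linear_spectra([300.0] * 4, grid), [300.0] * 4,
                              recipe=self.RECIPE)

    def test_loss_decreases(self, small_model):
        model, _, _ = small_model
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_same_seed_identical_weights(self):
        grid = make_grid(200.0, 1800.0, 16.0)
        temps = [t for t in range(100, 1000, 200) for _ in range(2)]
        kwargs = dict(
            arch="fcann", hyperparams={"epochs": 5, "hidden": (8,)},
            seed=4, recipe=self.RECIPE,
        )
        m1 = train_thermometer(_linear_spectra(temps, grid), temps, **kwargs)
        m2 = train_thermometer(_linear_spectra(temps, grid), temps, **kwargs)
        for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
            assert np.array_equal(w1, w2)


class TestPrediction:
    def test_training_example_memorized_within_mae(self, small_model):
        model, spectra, temps = small_model
        preds = predict_batch(model, spectra)
        train_mae = float(np.mean(np.abs(preds - temps)))
        assert abs(predict_spectrum(model, spectra[0]) - temps[0]) <= max(train_mae, 50.0)

    def test_all_zero_spectrum_clipped_to_range(self, small_model):
        model, _, _ = small_model
        grid = make_grid(150.0, 1900.0, 2.0)
        pred = predict_spectrum(model, Spectrum(grid, np.zeros(grid.size)))
        assert model.tmin <= pred <= model.tmax

    def test_noise_free_600C_recovered(self, small_model):
        model, _, _ = small_model
        rng = np.random.default_rng(123)
        src = synth.random_source("probe", rng)
        sp = synth.simulate_flint_raman(600.0, src, snr=None)
        assert abs(predict_spectrum(model, sp) - 600.0) <= 160.0  # held-out source

    def test_estimate_artifact_aggregation(self, small_model):
        model, spectra, _ = small_model
        sp = spectra[0]
        mean1, sd1, per1 = estimate_artifact(model, [sp, sp, sp])
        assert sd1 == pytest.approx(0.0, abs=1e-9)
        assert mean1 == pytest.approx(per1[0])
        other = spectra[-1]
        p1, p2 = predict_spectrum(model, sp), predict_spectrum(model, other)
        mean2, sd2, _ = estimate_artifact(model, [sp, other])
        assert mean2 == pytest.approx((p1 + p2) / 2.0)
        assert sd2 == pytest.approx(abs(p1 - p2) / math.sqrt(2.0))

    def test_empty_replicates_rejected(self, small_model):
        model, _, _ = small_model
        with pytest.raises(InputError):
            estimate_artifact(model, [])

    def test_save_load_identical_predictions(self, small_model, tmp_path):
        model, spectra, _ = small_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = ThermometerModel.load(path)
        np.testing.assert_array_equal(
            predict_batch(back, spectra[:6]), predict_batch(model, spectra[:6])
        )
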