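import numpy as np
import pytest
from scipy.special import psi
from scipy.stats import spearmanr

from dfctest import (
    BinSpec,
    ExpressionDataset,
    FlatProfile,
    Mas5Profile,
    NullModel,
    SimulationConfig,
    classify_null_features,
    estimate_null_model,
    evaluate_null_model,
    generate_dataset,
    summarize_features,
)
from dfctest.exceptions import EstimationError, ParameterError
from dfctest.null_model import null_model_table


def lv_truth(v: float, n: int) -> float:
    """E[log2 v_total | d = 0] for i.i.d. normals with variance v.

    Conditional on zero logFC the between-class term vanishes and
    (n-1) * v_total / v ~ chi2(n-2), giving the Jensen-bias-adjusted mean.
    """
    return np.log2(v) + (np.log(2.0) + psi((n - 2) / 2.0) - np.log(n - 1)) / np.log(2.0)


class TestBinSpec:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ParameterError):
            BinSpec(n_bins=2)
        with pytest.raises(ParameterError):
            BinSpec(min_per_bin=5)
        with pytest.raises(ParameterError):
            BinSpec(strategy="quantile-ish")

    def test_auto_bin_count_clamped(self):
        spec = BinSpec()
        assert spec.resolve_n_bins(1000) == 10
        assert spec.resolve_n_bins(5000) == 25
        assert spec.resolve_n_bins(100_000) == 50


class TestEstimation:
    def test_flat_profile_recovery(self, null_summaries, null_config):
        model = estimate_null_model(null_summaries)
        v = null_config.profile.v
        n = null_config.n1 + null_config.n2
        expected_lv = lv_truth(v, n)
        # recovered variance level within 10% of the adjusted truth, all bins
        rel = np.abs(2.0 ** (model.lv_th - expected_lv) - 1.0)
        assert np.all(rel < 0.10)
        sigma0_true = np.sqrt(v / null_config.n1 + v / null_config.n2)
        sigma0_err = np.abs(model.sigma0 / sigma0_true - 1.0)
        assert np.median(sigma0_err[1:-1]) < 0.10  # interior bins
        assert np.all(sigma0_err < 0.15)

    def test_decreasing_variance_trend_recovered(self):
        rng = np.random.default_rng(5)
        n_features, n1, n2 = 6000, 10, 10
        mu = rng.uniform(2, 14, n_features)
        v = 2.0 * 2.0 ** (-mu / 2.0)
        x = rng.normal(mu[:, None], np.sqrt(v)[:, None], (n_features, n1 + n2))
        ds = ExpressionDataset(
            values=x,
            feature_ids=np.array([f"g{i}" for i in range(n_features)], dtype=object),
            class_labels=np.array([1] * n1 + [2] * n2),
        )
        model = estimate_null_model(summarize_features(ds))
        assert model.lv_th[0] > model.lv_th[-1]
        true_curve = np.log2(2.0) - model.bin_centers / 2.0
        rho = spearmanr(model.lv_th, true_curve).statistic
        assert rho > 0.9

    def test_equal_width_strategy_works(self, null_summaries):
        model = estimate_null_model(null_summaries, bins=BinSpec(strategy="equal-width"))
        assert model.n_bins >= 3

    def test_too_few_features_error(self):
        cfg = SimulationConfig(n_features=200, pi=0.0, seed=0)
        ds, _ = generate_dataset(cfg)
        with pytest.raises(EstimationError, match="at least"):
            estimate_null_model(summarize_features(ds))

    def test_degenerate_bins_error(self):
        # every feature has an identical noise pattern: constant LV and d
        # within each bin, so the strict null-set inequality selects nothing
        rng = np.random.default_rng(1)
        pattern = rng.normal(0, 0.5, 8)
        mu = np.linspace(2, 12, 300)
        values = mu[:, None] + pattern[None, :]
        ds = ExpressionDataset(
            values=values,
            feature_ids=np.array([f"g{i}" for i in range(300)], dtype=object),
            class_labels=np.array([1] * 4 + [2] * 4),
        )
        with pytest.raises(EstimationError, match="bin"):
            estimate_null_model(summarize_features(ds), bins=BinSpec(min_per_bin=20))

    def test_shift_offset_moves_centers_only(self, null_dataset):
        dataset, _ = null_dataset
        model = estimate_null_model(summarize_features(dataset))
        shifted = ExpressionDataset(
            values=dataset.values + 3.0,
            feature_ids=dataset.feature_ids,
            class_labels=dataset.class_labels,
        )
        model_s = estimate_null_model(summarize_features(shifted))
        np.testing.assert_allclose(model_s.bin_centers, model.bin_centers + 3.0, atol=1e-9)
        np.testing.assert_allclose(model_s.lv_th, model.lv_th, atol=1e-9)
        np.testing.assert_allclose(model_s.sigma0, model.sigma0, atol=1e-9)

    def test_center_d0_tracks_normalization_drift(self, null_dataset):
        dataset, _ = null_dataset
        # push class 1 up by a constant: d-bar becomes 0.3 everywhere
        drifted = ExpressionDataset(
            values=dataset.values + 0.3 * (dataset.class_labels == 1),
            feature_ids=dataset.feature_ids,
            class_labels=dataset.class_labels,
        )
        model = estimate_null_model(summarize_features(drifted), center_d0=True)
        assert np.all(np.abs(model.d0_center - 0.3) < 0.1)

    def test_sigma0_recovery_over_seeds(self):
        errors = []
        for seed in range(3):
            cfg = SimulationConfig(n_features=5000, pi=0.0, profile=FlatProfile(0.25), seed=seed)
            ds, _ = generate_dataset(cfg)
            model = estimate_null_model(summarize_features(ds))
            sigma0_true = np.sqrt(0.25 / 10 + 0.25 / 10)
            interior = slice(1, -1)
            errors.append(
                np.median(np.abs(model.sigma0[interior] / sigma0_true - 1.0))
            )
        assert np.median(errors) < 0.10


class TestEvaluate:
    @pytest.fixture
    def toy_model(self):
        return NullModel(
            bin_centers=np.array([1.0, 2.0, 3.0]),
            lv_th=np.array([3.0, 5.0, 4.0]),
            sigma0=np.array([0.5, 0.4, 0.3]),
            d0_center=np.zeros(3),
            bin_counts=np.array([100.0, 100.0, 100.0]),
        )

    def test_exact_at_knots(self, toy_model):
        curves = evaluate_null_model(toy_model, 2.0)
        assert curves.lv_th == 5.0
        assert curves.sigma0 == 0.4
        assert curves.v_bar_ee == 2.0**5.0

    def test_clamped_outside_grid(self, toy_model):
        low = evaluate_null_model(toy_model, -10.0)
        high = evaluate_null_model(toy_model, 99.0)
        assert low.lv_th == 3.0 and low.sigma0 == 0.5
        assert high.lv_th == 4.0 and high.sigma0 == 0.3

    def test_linear_midpoint(self, toy_model):
        curves = evaluate_null_model(toy_model, 1.5)
        assert curves.lv_th == pytest.approx(4.0)

    def test_rejects_nonpositive_sigma0(self):
        with pytest.raises(EstimationError, match="sigma0"):
            NullModel(
                bin_centers=np.array([1.0, 2.0, 3.0]),
                lv_th=np.zeros(3),
                sigma0=np.array([0.5, 0.0, 0.3]),
                d0_center=np.zeros(3),
                bin_counts=np.full(3, 50.0),
            )


class TestClassify:
    def test_boundary_is_non_null(self):
        model = NullModel(
            bin_centers=np.array([0.0, 5.0, 10.0]),
            lv_th=np.full(3, 2.0),
            sigma0=np.full(3, 0.3),
            d0_center=np.zeros(3),
            bin_counts=np.full(3, 50.0),
        )
        x = np.array([[1.0, 3.0, 1.0, 3.0]])  # v_total = 4/3 ... build explicit
        ds = ExpressionDataset(
            values=x, feature_ids=np.array(["f"], dtype=object),
            class_labels=np.array([1, 1, 2, 2]),
        )
        summ = summarize_features(ds)
        summ.lv[0] = 2.0  # exactly on the threshold
        assert not classify_null_features(summ, model)[0]
        summ.lv[0] = 2.0 - 1e-9
        assert classify_null_features(summ, model)[0]

    def test_zero_variance_feature_is_null(self, null_model_fitted):
        ds = ExpressionDataset(
            values=np.vstack([np.full(20, 8.0), np.random.default_rng(0).normal(8, 1, 20)]),
            feature_ids=np.array(["flat", "noisy"], dtype=object),
            class_labels=np.array([1] * 10 + [2] * 10),
        )
        summ = summarize_features(ds)
        mask = classify_null_features(summ, null_model_fitted)
        assert mask[0]

    def test_planted_high_variance_feature_is_non_null(self, null_dataset):
        dataset, _ = null_dataset
        values = dataset.values.copy()
        center = values[0].mean()
        values[0] = center + (values[0] - center) * 4.0  # 16x total variance
        ds = ExpressionDataset(values, dataset.feature_ids, dataset.class_labels)
        summ = summarize_features(ds)
        model = estimate_null_model(summ)
        assert not classify_null_features(summ, model)[0]

    def test_null_fraction_reasonable_on_pure_null(self, null_summaries, null_model_fitted):
        frac_non_null = 1.0 - classify_null_features(null_summaries, null_model_fitted).mean()
        assert 0.2 < frac_non_null < 0.8


def test_diagnostic_table_columns(null_summaries, null_model_fitted):
    table = null_model_table(null_summaries, null_model_fitted)
    assert {"feature_id", "mu", "d", "lv", "lv_th", "sigma0", "is_null"} <= set(table.columns)
    assert len(table) == len(null_summaries)
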