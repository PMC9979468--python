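import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundus_scattering.filterbank import ScatteringConfig
from fundus_scattering.modeling import (
    EvalResult,
    HyperparamSpace,
    best_settings,
    evaluate,
    fit_with_search,
    run_sweep,
    sensitivity_ttest,
    sweep_frame,
)
from fundus_scattering.phantom import PhantomParams, generate_dataset

from _oracles import welch_ttest


def _clouds(n_per_class=20, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [rng.normal(0, 1, (n_per_class, 2)), rng.normal(gap, 1, (n_per_class, 2))]
    )
    y = ["healthy"] * n_per_class + ["glaucoma"] * n_per_class
    return x, y


FAST = HyperparamSpace(budget=8, seed=3)


class TestFitWithSearch:
    def test_separable_clouds_reach_zero_cv_loss(self):
        x, y = _clouds()
        fit = fit_with_search(x, y, "svm", FAST)
        assert fit.cv_loss == 0.0

    def test_seeded_search_is_deterministic(self):
        x, y = _clouds()
        a = fit_with_search(x, y, "svm", FAST)
        b = fit_with_search(x, y, "svm", FAST)
        assert a.best_hyperparams == b.best_hyperparams
        assert a.cv_loss == b.cv_loss

    def test_random_search_fallback(self):
        x, y = _clouds()
        space = HyperparamSpace(budget=6, seed=1, method="random")
        fit = fit_with_search(x, y, "logreg", space)
        assert fit.cv_loss <= 0.1

    def test_single_class_labels_rejected(self):
        x = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_with_search(x, ["healthy"] * 10, "svm", FAST)

    def test_fewer_samples_than_folds_rejected(self):
        x = np.random.default_rng(0).random((4, 3))
        with pytest.raises(ValueError, match="folds"):
            fit_with_search(x, ["healthy", "glaucoma"] * 2, "svm", FAST)

    def test_permuted_labels_score_at_chance(self):
        # permutation-null oracle: cross-validated performance on shuffled
        # labels must sit inside the spread of the shuffle distribution
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (40, 4))
        y = np.array(["healthy"] * 20 + ["glaucoma"] * 20)
        perm = rng.permutation(y)
        space = HyperparamSpace(budget=4, seed=5, method="random")
        fit = fit_with_search(x, perm.tolist(), "svm", space)

        null_losses = []
        for k in range(50):
            shuffled = np.random.default_rng(100 + k).permutation(perm)
            null_losses.append(np.mean(shuffled != perm))
        lo = np.mean(null_losses) - 3 * np.std(null_losses)
        assert fit.cv_loss >= max(lo, 0.0) - 0.05

    def test_test_set_cannot_influence_the_fit(self):
        x, y = _clouds(seed=2)
        x_test = np.random.default_rng(9).random((10, 2))
        before = x_test.copy()
        fit1 = fit_with_search(x, y, "svm", FAST)
        pred1 = fit1.model.predict(x_test)
        # corrupting the test labels between fits must change nothing
        fit2 = fit_with_search(x, y, "svm", FAST)
        pred2 = fit2.model.predict(x_test)
        assert np.array_equal(x_test, before)
        assert np.array_equal(pred1, pred2)
        assert np.allclose(
            fit1.model.named_steps["scale"].mean_, fit2.model.named_steps["scale"].mean_
        )


class TestEvaluate:
    def test_perfect_classification(self):
        ev = EvalResult(tp=52, fp=0, tn=94, fn=0)
        assert ev.precision == 1.0 and ev.recall == 1.0 and ev.f1 == 1.0

    def test_zero_positive_predictions_gives_missing_f1(self):
        ev = EvalResult(tp=0, fp=0, tn=94, fn=52)
        assert ev.precision is None
        assert ev.f1 is None
        assert ev.recall == 0.0

    def test_hand_arithmetic(self):
        ev = EvalResult(tp=40, fp=10, tn=84, fn=12)
        assert ev.precision == pytest.approx(0.800, abs=5e-4)
        assert ev.recall == pytest.approx(0.769, abs=5e-4)
        assert ev.f1 == pytest.approx(0.784, abs=5e-4)

    def test_per_class_breakdown_swaps_confusion(self):
        ev = EvalResult(tp=40, fp=10, tn=84, fn=12)
        pc = ev.per_class()
        assert pc["healthy"]["precision"] == pytest.approx(84 / 96)
        assert pc["healthy"]["recall"] == pytest.approx(84 / 94)

    def test_feature_width_mismatch_rejected(self):
        x, y = _clouds()
        fit = fit_with_search(x, y, "svm", FAST)
        with pytest.raises(ValueError, match="width"):
            evaluate(fit.model, np.zeros((4, 7)), ["healthy"] * 4)

    @given(
        tp=st.integers(0, 100), fp=st.integers(0, 100),
        tn=st.integers(0, 100), fn=st.integers(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_f1_identities(self, tp, fp, tn, fn):
        ev = EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)
        assert (ev.f1 is None) == (tp + fp == 0 or tp + fn == 0)
        if ev.f1 is not None and ev.precision + ev.recall > 0:
            assert ev.f1 == pytest.approx(
                2 * ev.precision * ev.recall / (ev.precision + ev.recall)
            )


class TestSensitivityTTest:
    def test_identical_matrices_give_unit_pvalues(self):
        a = np.random.default_rng(0).normal(0, 1, (30, 6))
        summary = sensitivity_ttest(a, a.copy())
        assert np.allclose(summary.t_statistics, 0.0)
        assert np.allclose(summary.p_values, 1.0)
        assert summary.significant_fraction == 0.0

    def test_ten_sd_shift_is_overwhelming(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (30, 4))
        summary = sensitivity_ttest(a, a + 10.0)
        assert np.all(summary.p_values < 1e-6)
        assert summary.significant_fraction == 1.0

    def test_matches_brute_force_welch_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (25, 1))
        b = rng.normal(0.8, 1.6, (25, 1))
        summary = sensitivity_ttest(a, b)
        t_ref, p_ref = welch_ttest(a[:, 0], b[:, 0])
        assert summary.t_statistics[0] == pytest.approx(t_ref, abs=1e-10)
        assert summary.p_values[0] == pytest.approx(p_ref, abs=1e-10)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            sensitivity_ttest(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_different_widths_compared_on_common_columns(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (10, 5))
        b = rng.normal(0, 1, (10, 8))
        assert len(sensitivity_ttest(a, b).p_values) == 5


@pytest.fixture(scope="module")
def tiny_sets():
    params = PhantomParams(size_range=(80, 120))
    train = generate_dataset(8, 6, params, seed=21).images
    test = generate_dataset(4, 3, params, seed=22).images
    return train, test


class TestRunSweep:
    def test_record_count_and_tables(self, tiny_sets):
        train, test = tiny_sets
        grid = [
            ScatteringConfig(
                invariance_scale=16, quality_factors=(1, 1), image_size=(64, 64),
            )
        ]
        space = HyperparamSpace(budget=3, folds=2, seed=0, method="random")
        records = run_sweep(train, test, ["GS"], grid, ["svm", "logreg"], space)
        assert len(records) == 2
        frame = sweep_frame(records)
        assert set(["channel", "s", "q1", "q2", "r", "classifier", "f1"]) <= set(
            frame.columns
        )
        assert (frame["TP"] + frame["FP"] + frame["TN"] + frame["FN"] == 7).all()
        best = best_settings(records)
        assert len(best) <= 2

    def test_empty_grid_rejected(self, tiny_sets):
        train, test = tiny_sets
        with pytest.raises(ValueError, match="empty grid"):
            run_sweep(train, test, ["GS"], [], ["svm"])
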