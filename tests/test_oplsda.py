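import numpy as np
import pytest

from duonorm import oplsda
from duonorm.oplsda import CvSpec, fit_oplsda, jackknife_vip_ci, pareto_scale, pcorr, vip


def _two_class_data(n=12, p=80, n_signal=8, shift=2.0, seed=0, orth_sd=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    x[: n // 2, :n_signal] += shift
    if orth_sd > 0:
        # structured noise along a direction orthogonal to the class split
        direction = rng.normal(size=p)
        factor = rng.normal(size=n)
        factor -= factor.mean()
        x += orth_sd * np.outer(factor, direction)
    return x, y


class TestParetoScale:
    def test_divisor_is_sqrt_sd(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=200)
        col = (col - col.mean()) / col.std(ddof=1) * 4.0  # sd exactly 4
        x = np.column_stack([col, rng.normal(size=200)])
        scaled = pareto_scale(x)
        np.testing.assert_allclose(scaled.X[:, 0], col / 2.0, atol=1e-10)

    def test_unit_sd_column_unchanged(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=300)
        col = (col - col.mean()) / col.std(ddof=1)
        scaled = pareto_scale(np.column_stack([col, rng.normal(size=300)]))
        np.testing.assert_allclose(scaled.X[:, 0], col, atol=1e-10)

    def test_columns_centered(self):
        x = np.random.default_rng(3).lognormal(size=(20, 10))
        scaled = pareto_scale(x)
        np.testing.assert_allclose(scaled.X.mean(axis=0), 0, atol=1e-10)

    def test_preserves_sd_ordering(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 6)) * np.array([0.1, 0.5, 1, 2, 5, 10])
        scaled = pareto_scale(x)
        sds = scaled.X.std(axis=0, ddof=1)
        assert np.all(np.diff(sds) > 0)  # pareto keeps magnitude ordering

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError):
            pareto_scale(np.ones((5, 3)))

    def test_zero_variance_column_dropped(self):
        x = np.random.default_rng(5).normal(size=(10, 3))
        x[:, 1] = 7.0
        scaled = pareto_scale(x)
        assert scaled.dropped == [1]
        assert scaled.X.shape == (10, 2)


class TestFitOplsda:
    def test_n_orth_zero_is_pls1(self):
        x, y = _two_class_data(seed=10)
        scaled = pareto_scale(x)
        model = fit_oplsda(scaled, y, n_orth=0, positive_level="A")
        # single-component PLS1: w ∝ X'y, t = Xw
        yc = np.where(y == "A", 1.0, -1.0)
        yc -= yc.mean()
        w = scaled.X.T @ yc
        w /= np.linalg.norm(w)
        t = scaled.X @ w
        if t[: len(t) // 2].mean() < 0:
            w, t = -w, -t
        np.testing.assert_allclose(model.t_p, t, atol=1e-10)
        np.testing.assert_allclose(model.w, w, atol=1e-10)

    def test_separation(self):
        x, y = _two_class_data(shift=3.0, seed=11)
        model = fit_oplsda(pareto_scale(x), y, n_orth=1, positive_level="A")
        assert model.t_p[y == "A"].min() > model.t_p[y == "B"].max()

    def test_orthogonal_scores_uncorrelated_with_y(self):
        x, y = _two_class_data(seed=12, orth_sd=2.0)
        model = fit_oplsda(pareto_scale(x), y, n_orth=2, positive_level="A")
        for a in range(2):
            r = np.corrcoef(model.t_o[a], model.y)[0, 1]
            assert abs(r) <= 1e-8

    def test_deflation_conserves_ssq(self):
        x, y = _two_class_data(seed=13, orth_sd=1.5)
        scaled = pareto_scale(x)
        model = fit_oplsda(scaled, y, n_orth=1, positive_level="A")
        deflated = scaled.X - np.outer(model.t_o[0], model.p_o[0])
        ss_removed = np.sum(np.outer(model.t_o[0], model.p_o[0]) ** 2)
        assert np.sum(scaled.X**2) == pytest.approx(np.sum(deflated**2) + ss_removed, rel=1e-8)

    def test_label_swap_flips_signs(self):
        x, y = _two_class_data(seed=14)
        a = fit_oplsda(pareto_scale(x), y, n_orth=1, positive_level="A")
        b = fit_oplsda(pareto_scale(x), y, n_orth=1, positive_level="B")
        np.testing.assert_allclose(a.t_p, -b.t_p, atol=1e-10)
        np.testing.assert_allclose(a.w, -b.w, atol=1e-10)
        np.testing.assert_allclose(a.pcorr, -b.pcorr, atol=1e-10)
        np.testing.assert_allclose(a.vip, b.vip, atol=1e-12)

    def test_orth_recovers_discriminant_better_than_pls1(self):
        # strong structured orthogonal noise: OPLS predictive weights should
        # align with the planted discriminant better than plain PLS1
        rng = np.random.default_rng(15)
        n, p, n_signal = 12, 60, 6
        planted = np.zeros(p)
        planted[:n_signal] = 1.0
        planted /= np.linalg.norm(planted)
        x = rng.normal(size=(n, p)) * 0.3
        y = np.array(["A"] * 6 + ["B"] * 6)
        x[:6] += 1.0 * planted
        direction = rng.normal(size=p)
        direction -= (direction @ planted) * planted
        direction /= np.linalg.norm(direction)
        factor = rng.normal(size=n) * 3.0
        factor -= factor.mean()
        x += np.outer(factor, direction)
        scaled = pareto_scale(x)
        pls1 = fit_oplsda(scaled, y, n_orth=0, positive_level="A")
        opls = fit_oplsda(scaled, y, n_orth=1, positive_level="A")
        planted_w = np.abs(planted)

        def cosine(w):
            return abs(w @ planted_w) / np.linalg.norm(w)

        assert cosine(opls.w) > cosine(pls1.w)

    def test_rank_exhaustion_raises(self):
        x, y = _two_class_data(n=6, p=4, n_signal=2, seed=16)
        with pytest.raises(ValueError):
            fit_oplsda(pareto_scale(x), y, n_orth=5, positive_level="A")


class TestPcorrVip:
    def test_pcorr_of_tp_copy_is_one(self):
        x, y = _two_class_data(seed=20)
        scaled = pareto_scale(x)
        model = fit_oplsda(scaled, y, n_orth=0, positive_level="A")
        scaled.X[:, 0] = model.t_p
        assert pcorr(model, scaled)[0] == pytest.approx(1.0, abs=1e-12)
        scaled.X[:, 1] = -model.t_p
        assert pcorr(model, scaled)[1] == pytest.approx(-1.0, abs=1e-12)

    def test_pcorr_bounded(self):
        x, y = _two_class_data(seed=21)
        model = fit_oplsda(pareto_scale(x), y, n_orth=1, positive_level="A")
        assert np.all(model.pcorr >= -1) and np.all(model.pcorr <= 1)

    def test_null_pcorr_below_point_nine(self):
        # random independent variables at n=12 essentially never reach |r|=0.9
        x, y = _two_class_data(n=12, p=200, n_signal=0, shift=0.0, seed=22)
        model = fit_oplsda(pareto_scale(x), y, n_orth=0, positive_level="A")
        assert np.quantile(np.abs(model.pcorr), 0.99) < 0.9

    def test_vip_mean_square_one(self):
        x, y = _two_class_data(seed=23)
        model = fit_oplsda(pareto_scale(x), y, n_orth=1, positive_level="A")
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_vip_equal_weights(self):
        model = fit_oplsda(
            pareto_scale(np.array([[3.0, 3.0], [4.0, 4.0], [0.0, 0.0], [1.0, 1.0]])),
            ["A", "A", "B", "B"],
            n_orth=0,
            positive_level="A",
        )
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-9)

    def test_vip_concentrated_weight(self):
        m = oplsda.OplsModel(
            w=np.r_[1.0, np.zeros(99)], t_p=np.zeros(4), p_p=np.zeros(100),
            w_o=np.empty((0, 100)), t_o=np.empty((0, 4)), p_o=np.empty((0, 100)),
            pcorr=np.empty(0), vip=np.empty(0), y=np.zeros(4), n_orth=0,
        )
        v = vip(m)
        assert v[0] == pytest.approx(10.0)
        assert np.all(v[1:] == 0)


class TestJackknife:
    def test_ci_brackets_vip(self):
        x, y = _two_class_data(seed=30)
        lower, upper, model = jackknife_vip_ci(x, y, CvSpec(6, seed=1), n_orth=1,
                                               positive_level="A")
        assert np.all(lower <= model.vip + 1e-12)
        assert np.all(upper >= model.vip - 1e-12)

    def test_strong_variable_positive_lower_ci(self):
        x, y = _two_class_data(n=12, p=50, n_signal=4, shift=3.0, seed=31)
        lower, _, model = jackknife_vip_ci(x, y, CvSpec(6, seed=2), n_orth=1,
                                           positive_level="A")
        assert np.all(lower[:4] > 0)

    def test_null_variables_mostly_nonpositive_lower_ci(self):
        x, y = _two_class_data(n=12, p=200, n_signal=0, shift=0.0, seed=32)
        lower, _, _ = jackknife_vip_ci(x, y, CvSpec(6, seed=3), n_orth=0,
                                       positive_level="A")
        assert np.mean(lower <= 0) >= 0.9

    def test_fold_count_clamped_to_minority_class(self):
        x, y = _two_class_data(n=12, seed=33)
        # requesting 7 folds with 6 per class must still work (clamped to 6)
        lower, upper, _ = jackknife_vip_ci(x, y, CvSpec(7, seed=4), n_orth=1,
                                           positive_level="A")
        assert lower.shape == upper.shape

    def test_deterministic(self):
        x, y = _two_class_data(seed=34)
        a = jackknife_vip_ci(x, y, CvSpec(6, seed=5), n_orth=1, positive_level="A")
        b = jackknife_vip_ci(x, y, CvSpec(6, seed=5), n_orth=1, positive_level="A")
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
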