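"""NIPALS PLSR: exact-mixture recovery, least-squares equivalence, LOO metrics."""

import numpy as np
import pytest

from oleochem import (BlendDesign, GeneratorConfig, PreprocessConfig,
                      blend_spectrum, build_endmember_library,
                      endmember_template, figures_of_merit, generate_design,
                      loo_cv, plsr_fit, plsr_predict, run_calibration_suite)
from oleochem.spectra import SpectrumSet


def mixture_data(levels, grid_pts=120, noise=0.0, seed=0):
    """Noise-free (or noisy) two-endmember linear mixtures."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, grid_pts)
    a = np.exp(-((x - 0.3) / 0.1) ** 2)
    b = np.exp(-((x - 0.7) / 0.15) ** 2)
    y = np.asarray(levels, dtype=float)
    X = np.outer(1 - y / 100, a) + np.outer(y / 100, b)
    if noise:
        X = X + rng.normal(0, noise, X.shape)
    return X, y


class TestFit:
    def test_one_factor_recovers_noise_free_mixtures(self):
        X, y = mixture_data([0, 5, 10, 20, 35, 50])
        model = plsr_fit(X, y, 1)
        assert np.max(np.abs(plsr_predict(model, X) - y)) < 1e-6

    def test_full_rank_equals_min_norm_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        beta = rng.normal(size=6)
        y = X @ beta + 0.1 * rng.normal(size=10)
        a = np.linalg.matrix_rank(X - X.mean(axis=0))
        model = plsr_fit(X, y, a)
        Xc = X - X.mean(axis=0)
        b_ls = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.allclose(model.regression_vector, b_ls, atol=1e-6)

    def test_constant_y_rejected(self):
        X, _ = mixture_data([0, 10, 20])
        with pytest.raises(ValueError, match="constant"):
            plsr_fit(X, np.full(3, 7.0), 1)

    def test_factor_bounds(self):
        X, y = mixture_data([0, 10, 20])
        with pytest.raises(ValueError, match="factors"):
            plsr_fit(X, y, 3)  # n-1 = 2

    def test_score_orthogonality_and_dual_prediction_paths(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 20))
        y = rng.normal(size=15)
        a = 4
        # recompute scores by sequential deflation and check mutual orthogonality
        model = plsr_fit(X, y, a)
        E = X - model.x_mean
        T = np.zeros((15, a))
        for j in range(a):
            T[:, j] = E @ model.weights[:, j]
            E = E - np.outer(T[:, j], model.x_loadings[:, j])
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))
        seq = T @ model.y_loadings + model.y_mean
        assert np.allclose(seq, plsr_predict(model, X), atol=1e-8)

    def test_agrees_with_sklearn_pls(self):
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        model = plsr_fit(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(plsr_predict(model, X), ref.predict(X).ravel(), atol=1e-8)

    def test_rmsec_non_increasing_in_factor_count(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 25))
        y = rng.normal(size=18)
        rmsecs = []
        for a in range(1, 8):
            model = plsr_fit(X, y, a)
            rmsecs.append(np.sqrt(np.mean((plsr_predict(model, X) - y) ** 2)))
        assert all(r1 >= r2 - 1e-10 for r1, r2 in zip(rmsecs, rmsecs[1:]))


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self):
        X, y = mixture_data([0, 10, 25, 40], noise=1e-3, seed=1)
        model = plsr_fit(X, y, 2)
        assert plsr_predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_held_out_level_interpolated(self):
        levels = [0, 1, 3, 5, 10, 15, 20, 30, 35, 40, 45, 50]
        X, y = mixture_data(levels + [25])
        model = plsr_fit(X[:-1], y[:-1], 1)
        assert plsr_predict(model, X[-1])[0] == pytest.approx(25.0, abs=0.01)

    def test_empty_and_mismatched_inputs_error(self):
        X, y = mixture_data([0, 10, 20])
        model = plsr_fit(X, y, 1)
        with pytest.raises(ValueError, match="empty"):
            plsr_predict(model, np.empty((0, X.shape[1])))
        with pytest.raises(ValueError, match="dimension"):
            plsr_predict(model, np.zeros((2, 5)))


class TestLooCv:
    def test_collinear_noise_free_exact(self):
        X, y = mixture_data([0, 25, 50])
        preds = loo_cv(X, y, 1)
        assert np.max(np.abs(preds - y)) < 1e-6

    def test_residual_multiset_invariant_under_shuffling(self):
        X, y = mixture_data([0, 5, 10, 20, 35, 50], noise=1e-3, seed=2)
        res = np.sort(loo_cv(X, y, 2) - y)
        perm = np.random.default_rng(0).permutation(len(y))
        res_p = np.sort(loo_cv(X[perm], y[perm], 2) - y[perm])
        assert np.allclose(res, res_p, atol=1e-10)

    def test_rmsecv_exceeds_rmsec_on_pure_noise(self):
        """Out-of-fold error dominates in-sample error when y is noise."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 15))
            y = rng.normal(size=12)
            model = plsr_fit(X, y, 3)
            rmsec = np.sqrt(np.mean((plsr_predict(model, X) - y) ** 2))
            rmsecv = np.sqrt(np.mean((loo_cv(X, y, 3) - y) ** 2))
            wins += rmsecv >= rmsec
        assert wins == 20

    def test_too_few_samples(self):
        X, y = mixture_data([0, 10])
        with pytest.raises(ValueError, match="at least 3"):
            loo_cv(X, y, 1)


class TestFiguresOfMerit:
    def test_perfect_predictions(self):
        y = np.array([0.0, 10, 20, 30, 40])
        m = figures_of_merit(y, y, y)
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.offset == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.rmsec == 0.0 and m.rmsecv == 0.0

    def test_constant_bias(self):
        y = np.array([0.0, 10, 20, 30, 40])
        m = figures_of_merit(y, y + 2.0, y + 2.0)
        assert m.slope == pytest.approx(1.0)
        assert m.offset == pytest.approx(2.0)
        assert m.rmsec == pytest.approx(2.0)

    def test_five_point_arithmetic_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        m = figures_of_merit(y, yhat, yhat)
        slope, offset = np.polyfit(y, yhat, 1)
        r = np.corrcoef(y, yhat)[0, 1]
        assert m.slope == pytest.approx(slope, abs=1e-12)
        assert m.offset == pytest.approx(offset, abs=1e-12)
        assert m.r2 == pytest.approx(r * r, abs=1e-12)
        assert m.rmsec == pytest.approx(np.sqrt(np.mean((yhat - y) ** 2)), abs=1e-12)

    def test_degenerate_y_rejected(self):
        y = np.full(4, 3.0)
        with pytest.raises(ValueError, match="variance"):
            figures_of_merit(y, y, y)
        with pytest.raises(ValueError, match="length"):
            figures_of_merit(np.arange(3.0), np.arange(4.0), np.arange(3.0))


class TestCalibrationSuite:
    def test_15_models_meet_published_bounds(self, gen_cfg):
        design = BlendDesign.table5()
        sset = generate_design(design, gen_cfg)
        metrics = run_calibration_suite(sset, design, a=4)
        assert len(metrics) == 15
        assert (metrics.r2 >= 0.9836).all()
        assert (metrics.slope >= 0.9703).all()
        assert (metrics.rmsecv <= 3.8136).all()

    def test_noise_free_ladders_near_exact(self, library, grid):
        cao = endmember_template(library["CAO"], grid)
        rso = endmember_template(library["RSO"], grid)
        levels = (1, 3, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
        from oleochem.spectra import SampleMeta, Spectrum
        spectra = []
        for v in (0,) + levels:
            s = blend_spectrum(cao, rso, float(v))
            if v == 0:
                meta = SampleMeta(sample_id="pure", oil_type="CAO", base_brand="CAO-t")
            else:
                meta = SampleMeta(sample_id=f"b{v}", oil_type="BLEND",
                                  blend_fraction_v=float(v), base_brand="CAO-t",
                                  adulterant_brand="RSO-t")
            spectra.append(Spectrum(s.wavenumbers, s.absorbance, meta))
        design = BlendDesign(cao_brands=("CAO-t",), rso_brands=("RSO-t",), levels=levels)
        metrics = run_calibration_suite(SpectrumSet(spectra), design, a=1)
        assert (metrics.rmsec < 0.1).all()

    def test_missing_ladder_names_pair(self, gen_cfg):
        design = BlendDesign.table5()
        sset = generate_design(design, gen_cfg)
        trimmed = sset.subset(lambda m: not (m.oil_type == "BLEND"
                                             and m.base_brand == "CAO-3"
                                             and m.adulterant_brand == "RSO-2"
                                             and m.blend_fraction_v == 25.0))
        with pytest.raises(ValueError, match=r"RSO-2.*CAO-3"):
            run_calibration_suite(trimmed, design, a=4)
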