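"""Calibration algebra: PLS1/NIPALS against independent oracles, the
OPLS/PLS1 predictive equivalence, orthogonality invariants and component
selection."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from ramcal.chemometrics import fit_opls, fit_pls1, select_components
from ramcal.validation import make_cv_groups


def _random_problem(rng, n=40, k=120, rank=5, noise=0.0):
    T = rng.normal(size=(n, rank))
    P = rng.normal(size=(rank, k))
    X = T @ P + noise * rng.normal(size=(n, k))
    beta = rng.normal(size=rank)
    y = T @ beta + noise * rng.normal(size=n)
    return X, y


def _reference_pls1(X, y, n_components):
    """Textbook NIPALS PLS1, written independently of the implementation:
    returns predictions on the training X."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    y_mean, y_sd = y.mean(), y.std(ddof=1)
    E = X - x_mean
    f = (y - y_mean) / y_sd
    E0 = E.copy()
    Ws, Ps, Qs = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q = f @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - q * t
        Ws.append(w); Ps.append(p); Qs.append(q)
    # prediction by sequential deflation
    E = E0.copy()
    yhat = np.zeros(X.shape[0])
    for w, p, q in zip(Ws, Ps, Qs):
        t = E @ w
        yhat += q * t
        E = E - np.outer(t, p)
    return yhat * y_sd + y_mean


class TestPls1:
    def test_exact_rank_case_interpolates(self):
        rng = np.random.default_rng(0)
        X, y = _random_problem(rng, rank=2)
        model = fit_pls1(X, y, 2)
        assert np.abs(model.predict(X) - y).max() < 1e-8

    def test_zero_components_predict_mean(self):
        rng = np.random.default_rng(1)
        X, y = _random_problem(rng, rank=3)
        model = fit_pls1(X, y, 0)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_against_independent_nipals(self):
        rng = np.random.default_rng(2)
        X, y = _random_problem(rng, n=30, k=80, rank=6, noise=0.3)
        model = fit_pls1(X, y, 3)
        np.testing.assert_allclose(model.predict(X), _reference_pls1(X, y, 3),
                                   atol=1e-8)

    def test_against_sklearn(self):
        rng = np.random.default_rng(3)
        X, y = _random_problem(rng, n=35, k=60, rank=5, noise=0.2)
        model = fit_pls1(X, y, 4)
        sk = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(model.predict(X),
                                   sk.predict(X).ravel(), atol=1e-8)

    def test_constant_y_rejected(self):
        rng = np.random.default_rng(4)
        X, _ = _random_problem(rng)
        with pytest.raises(ValueError):
            fit_pls1(X, np.ones(X.shape[0]), 1)


class TestOpls:
    def test_zero_ortho_equals_one_component_pls(self):
        rng = np.random.default_rng(5)
        X, y = _random_problem(rng, noise=0.2)
        opls = fit_opls(X, y, 0)
        pls = fit_pls1(X, y, 1)
        np.testing.assert_allclose(opls.predict(X), pls.predict(X), atol=1e-10)

    def test_predictive_equivalence_with_pls1(self):
        """OPLS with n_o orthogonal components predicts identically to PLS1
        with 1+n_o components, on held-out data, across 25 random problems."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            n_o = int(rng.integers(0, 4))
            X, y = _random_problem(rng, n=40, k=int(rng.integers(30, 120)),
                                   rank=n_o + 3, noise=0.2)
            X_new = rng.normal(size=(15, X.shape[1])) @ np.linalg.qr(
                rng.normal(size=(X.shape[1], X.shape[1])))[0]
            opls = fit_opls(X, y, n_o)
            pls = fit_pls1(X, y, 1 + n_o)
            np.testing.assert_allclose(opls.predict(X_new),
                                       pls.predict(X_new), atol=1e-8)

    def test_orthogonal_scores_carry_no_y_information(self):
        rng = np.random.default_rng(7)
        X, y = _random_problem(rng, noise=0.3)
        model = fit_opls(X, y, 3)
        yc = (y - y.mean()) / y.std(ddof=1)
        Xc = X - model.x_center
        for w_o, p_o in zip(model.w_ortho, model.p_ortho):
            t_o = Xc @ w_o
            corr = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert corr < 1e-8
            Xc = Xc - np.outer(t_o, p_o)

    def test_modeled_orthogonal_interference_does_not_shift_predictions(self):
        """Two-factor textbook case: one y-predictive and one interfering
        direction. With the interferent modeled (n_ortho=1), predictions are
        exactly invariant to shifts along the interfering direction, and the
        training fit becomes exact."""
        rng = np.random.default_rng(8)
        n, k = 50, 40
        v_pred, v_int = rng.normal(size=k), rng.normal(size=k)
        t, s = rng.normal(size=n), rng.normal(size=n)
        X = np.outer(t, v_pred) + np.outer(s, v_int)
        model = fit_opls(X, t, n_ortho=1)
        x = X[:5]
        np.testing.assert_allclose(model.predict(x + 2.5 * v_int),
                                   model.predict(x), atol=1e-10)
        assert np.abs(model.predict(X) - t).max() < 1e-10
        # without the orthogonal component the interferent leaks through
        plain = fit_opls(X, t, n_ortho=0)
        assert np.abs(plain.predict(X) - t).max() > 1e-3

    def test_training_reproduction_and_center_prediction(self):
        rng = np.random.default_rng(9)
        X, y = _random_problem(rng, noise=0.2)
        model = fit_opls(X, y, 2)
        np.testing.assert_allclose(model.predict(X), model.predict(X.copy()))
        assert model.predict(model.x_center[None, :])[0] == \
            pytest.approx(y.mean(), abs=1e-10)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        X, y = _random_problem(rng)
        model = fit_opls(X, y, 1)
        with pytest.raises(ValueError):
            model.predict(np.ones((3, X.shape[1] + 1)))

    def test_noise_free_linear_dataset_recovered(self, noiseless_records):
        """Spectra built as an exact linear mixture of component profiles:
        the calibration recovers the generating concentrations to 1e-6."""
        from ramcal.synthetic_data import DEFAULT_AXIS, PureComponentLibrary
        from ramcal.experiment_design import ANALYTES
        lib = PureComponentLibrary()
        rng = np.random.default_rng(15)
        C = rng.uniform(0.5, 8.0, size=(40, len(ANALYTES)))
        S = np.vstack([lib.profile(a, DEFAULT_AXIS) for a in ANALYTES])
        X = C @ S
        y = C[:, 0]  # glucose
        model = fit_opls(X, y, n_ortho=4)
        assert np.abs(model.predict(X) - y).max() < 1e-6

    def test_json_round_trip(self):
        from ramcal.chemometrics import OPLSModel
        rng = np.random.default_rng(11)
        X, y = _random_problem(rng)
        model = fit_opls(X, y, 2, analyte="glucose")
        clone = OPLSModel.from_json(model.to_json())
        np.testing.assert_allclose(clone.predict(X), model.predict(X),
                                   atol=1e-12)


class TestSelectComponents:
    def test_pure_single_factor_needs_no_orthogonal_components(self):
        rng = np.random.default_rng(12)
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=50))
        y = 2.0 * t + 1.0
        vessels = np.repeat(np.arange(6), 5)
        plan = make_cv_groups(vessels, k=3)
        n_o, info = select_components(X, y, plan.splits(vessels), max_ortho=4)
        assert n_o == 0 and not info["overfit_flagged"]

    def test_strong_interferent_selects_orthogonal_component(self):
        rng = np.random.default_rng(13)
        n = 60
        t = rng.normal(size=n)
        v_pred, v_int = np.zeros(50), np.zeros(50)
        v_pred[:10] = 1.0
        v_int[20:40] = 1.0
        interferent = 5.0 * rng.normal(size=n)
        X = np.outer(t, v_pred) + np.outer(interferent, v_int) \
            + 0.01 * rng.normal(size=(n, 50))
        y = t + 0.05 * rng.normal(size=n)
        vessels = np.repeat(np.arange(6), 10)
        plan = make_cv_groups(vessels, k=3)
        splits = list(plan.splits(vessels))
        n_o, info = select_components(X, y, splits, max_ortho=3)
        by_n = {m["n_ortho"]: m["q2"] for m in info["candidates"]}
        assert n_o >= 1
        assert by_n[n_o] >= by_n[0]

    def test_unlearnable_target_is_flagged(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        vessels = np.repeat(np.arange(8), 5)
        plan = make_cv_groups(vessels, k=4)
        n_o, info = select_components(X, y, list(plan.splits(vessels)),
                                      max_ortho=2)
        gaps = [m["r2"] - m["q2"] for m in info["candidates"]]
        if all(g > 0.3 for g in gaps):
            assert info["overfit_flagged"]
            assert gaps[n_o] == min(gaps)
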