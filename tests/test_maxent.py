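"""The maximum-entropy engine: features, solver, predictions, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

import streamsdm as sdm
from streamsdm import maxent
from streamsdm.maxent import (AUTOFEATURE_MIN_N, Feature, FeatureSet,
                              build_features, class_regularization)
from streamsdm.synthetic import RiverscapeParams, generate_riverscape

from conftest import make_segments


# ---------------------------------------------------------------------------
# independent oracles

def _setup_problem(model, segments, presence_ids):
    X = model.featureset.design_matrix(segments.data)
    pos = {s: i for i, s in enumerate(segments.data["segment_id"])}
    pres_idx = np.unique([pos[s] for s in presence_ids])
    return X, pres_idx


def penalized_gain(lam, X, pres_idx, penalties):
    eta = X @ lam
    return eta[pres_idx].mean() - logsumexp(eta) - penalties @ np.abs(lam)


def grid_refine_oracle(X, pres_idx, penalties, lo=-20.0, hi=20.0,
                       n_grid=13, n_rounds=14):
    """Brute-force maximizer: dense grid over lambda, iteratively refined."""
    J = X.shape[1]
    lo_v = np.full(J, lo)
    hi_v = np.full(J, hi)
    best = None
    for _ in range(n_rounds):
        axes = [np.linspace(lo_v[j], hi_v[j], n_grid) for j in range(J)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([penalized_gain(p, X, pres_idx, penalties) for p in pts])
        best = pts[int(np.argmax(vals))]
        width = (hi_v - lo_v) / (n_grid - 1)
        lo_v = best - width
        hi_v = best + width
    return best


def iwlr_oracle(model, segments, presence_ids, W=1e7):
    """Infinitely weighted logistic regression on the same features:
    all segments as weighted non-events plus the presences as events."""
    X, pres_idx = _setup_problem(model, segments, presence_ids)
    J = X.shape[1]
    n_p = len(pres_idx)
    bj = model.penalties
    Xa = np.vstack([X, X[pres_idx]])
    ya = np.concatenate([np.zeros(len(X)), np.ones(n_p)])
    wa = np.where(ya == 1, 1.0, W)

    def fg(z):
        alpha, a, b = z[0], z[1:1 + J], z[1 + J:]
        eta = alpha + Xa @ (a - b)
        ll = wa * (ya * log_expit(eta) + (1 - ya) * log_expit(-eta))
        f = (-ll.sum() + n_p * (bj @ (a + b))) / n_p
        r = wa * (expit(eta) - ya)
        g = Xa.T @ r
        return f, np.concatenate([[r.sum()], g + n_p * bj, -g + n_p * bj]) / n_p

    z0 = np.zeros(1 + 2 * J)
    z0[0] = np.log(n_p / (W * len(X)))
    res = minimize(fg, z0, jac=True, method="L-BFGS-B",
                   bounds=[(None, None)] + [(0, None)] * (2 * J),
                   options=dict(maxiter=100000, maxfun=300000,
                                ftol=1e-17, gtol=1e-12))
    lam = res.x[1:1 + J] - res.x[1 + J:]
    eta = X @ lam
    return np.exp(eta - logsumexp(eta))


def _tiny_instance(n_covs=1, classes=("linear",), n_bg=6, n_pres=2, seed=0):
    rng = np.random.default_rng(seed)
    covs = {f"c{i}": rng.uniform(0, 10, n_bg) for i in range(n_covs)}
    seg = make_segments(n_bg, covs=covs)
    pres_ids = seg.data["segment_id"].iloc[:n_pres]
    fs = build_features(seg, pres_ids, classes=classes)
    return seg, pres_ids, fs


# ---------------------------------------------------------------------------
# autofeature and penalties

class TestAutofeature:
    @pytest.mark.parametrize("n,expected", [
        (5, {"linear"}),
        (12, {"linear", "quadratic"}),
        (29, {"linear", "quadratic", "hinge"}),
        (100, {"linear", "quadratic", "hinge", "product"}),
    ])
    def test_classes_by_presence_count(self, riverscape, n, expected):
        _, seg, _, _ = riverscape
        ids = seg.data["segment_id"].iloc[:n]
        fs = build_features(seg, ids, classes="auto", n_knots=5)
        assert set(fs.classes) == expected

    def test_too_few_presences_errors(self, riverscape):
        _, seg, _, _ = riverscape
        with pytest.raises(ValueError):
            build_features(seg, seg.data["segment_id"].iloc[:1])

    def test_unknown_class_errors(self, riverscape):
        _, seg, _, _ = riverscape
        with pytest.raises(ValueError, match="threshold"):
            build_features(seg, seg.data["segment_id"].iloc[:20],
                           classes=("linear", "threshold"))

    def test_hinge_knots_inside_background_range(self, riverscape):
        _, seg, _, _ = riverscape
        fs = build_features(seg, seg.data["segment_id"].iloc[:20], n_knots=10)
        for f in fs.features:
            if f.cls == "hinge":
                assert 0.0 <= f.knot <= 1.0
                # a forward hinge needs room above the knot, a reverse below
                assert f.knot < 1.0 if f.direction == 1 else f.knot > 0.0

    def test_features_scaled_to_unit_interval(self, riverscape):
        _, seg, _, _ = riverscape
        fs = build_features(seg, seg.data["segment_id"].iloc[:20], n_knots=10)
        X = fs.design_matrix(seg.data)
        assert X.min() >= 0.0 and X.max() <= 1.0 + 1e-12

    def test_class_regularization_interpolates(self):
        assert class_regularization("linear", 5) == 1.0
        assert class_regularization("linear", 30) == pytest.approx(0.2)
        assert class_regularization("linear", 200) == 0.05
        assert class_regularization("hinge", 30) == 0.5


# ---------------------------------------------------------------------------
# solver correctness

class TestFit:
    def test_raw_sums_to_one(self, small_fit):
        seg, _, model = small_fit
        pred = sdm.predict(model, seg)
        assert pred.raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_entropy_matches_definition(self, small_fit):
        seg, _, model = small_fit
        raw = sdm.predict(model, seg).raw
        assert model.entropy == pytest.approx(-(raw * np.log(raw)).sum(), abs=1e-8)

    def test_full_shrinkage_limit_is_uniform(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=10)
        m = sdm.fit(fs, pres.segment_ids, seg, beta=1e6)
        assert sdm.count_nonzero(m) == 0
        pred = sdm.predict(m, seg)
        np.testing.assert_allclose(pred.raw, 1.0 / len(seg), atol=1e-12)
        np.testing.assert_allclose(pred.cloglog, 1.0 - np.exp(-1.0), atol=1e-9)
        assert m.entropy == pytest.approx(np.log(len(seg)))

    def test_single_linear_feature_matches_dense_grid(self):
        seg, pres_ids, fs = _tiny_instance(n_covs=1, n_bg=6, n_pres=2, seed=1)
        m = sdm.fit(fs, pres_ids, seg, beta=1.0, tol=1e-10)
        X, pres_idx = _setup_problem(m, seg, pres_ids)
        lam_star = grid_refine_oracle(X, pres_idx, m.penalties, n_grid=101, n_rounds=10)
        assert np.abs(m.lambdas - lam_star).max() < 1e-4

    @pytest.mark.parametrize("seed", [2, 3])
    def test_three_feature_instance_matches_refined_grid(self, seed):
        seg, pres_ids, fs = _tiny_instance(
            n_covs=3, classes=("linear",), n_bg=12, n_pres=4, seed=seed)
        m = sdm.fit(fs, pres_ids, seg, beta=1.0, tol=1e-10)
        X, pres_idx = _setup_problem(m, seg, pres_ids)
        lam_star = grid_refine_oracle(X, pres_idx, m.penalties)
        assert np.abs(m.lambdas - lam_star).max() < 1e-4

    def test_objective_monotone_across_cycles(self, small_fit):
        _, _, model = small_fit
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) >= -1e-12).all()

    def test_gain_and_penalty_monotone_in_beta(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=8)
        gains, l1s = [], []
        for b in np.arange(1.0, 5.5, 0.5):
            m = sdm.fit(fs, pres.segment_ids, seg, beta=float(b))
            pred = sdm.predict(m, seg)
            pos = {s: i for i, s in enumerate(pred.segment_ids)}
            idx = [pos[s] for s in pres.segment_ids]
            gains.append(np.log(pred.raw[idx] * len(seg)).mean())
            l1s.append(np.abs(m.lambdas).sum())
        assert (np.diff(gains) <= 1e-6).all()
        assert (np.diff(l1s) <= 1e-6).all()

    def test_iwlr_equivalence(self):
        """The fitted raw density agrees with an infinitely weighted
        logistic regression fit of the same penalized problem."""
        params = RiverscapeParams(n_segments=200, n_presences=15, seed=5)
        seg, pres, _ = generate_riverscape(params)
        pres = sdm.dedupe_presences(pres, seg)
        fs = build_features(seg, pres.segment_ids, classes=("linear", "quadratic"),
                            covariates=["Q", "ELEV", "SLOPE"])
        m = sdm.fit(fs, pres.segment_ids, seg, beta=1.0, tol=1e-10)
        raw_iwlr = iwlr_oracle(m, seg, pres.segment_ids)
        raw = sdm.predict(m, seg).raw
        assert np.abs(raw - raw_iwlr).max() < 1e-4

    def test_invalid_beta_errors(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=5)
        with pytest.raises(ValueError):
            sdm.fit(fs, pres.segment_ids, seg, beta=0.0)

    def test_presence_outside_background_errors(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=5)
        with pytest.raises(ValueError, match="GHOST"):
            sdm.fit(fs, ["GHOST"], seg)


# ---------------------------------------------------------------------------
# diagnostics

class TestDiagnostics:
    def test_count_nonzero_on_hand_built_model(self, small_fit):
        seg, _, model = small_fit
        import copy
        m = copy.copy(model)
        m.lambdas = np.zeros(len(model.lambdas))
        m.lambdas[:3] = [0.5, 0.0, -1.0]
        assert sdm.count_nonzero(m) == 2

    def test_default_fit_more_parameters_than_aicc_fit(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=20)
        k_default = sdm.count_nonzero(sdm.fit(fs, pres.segment_ids, seg, beta=1.0))
        k_heavy = sdm.count_nonzero(sdm.fit(fs, pres.segment_ids, seg, beta=4.5))
        assert k_default > k_heavy

    def test_percent_contribution_sums_to_100(self, small_fit):
        _, _, model = small_fit
        pc = sdm.percent_contribution(model)
        assert pc.sum() == pytest.approx(100.0, abs=1e-6)
        assert (pc >= 0).all()

    def test_single_covariate_model_gets_full_contribution(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, covariates=["Q"], n_knots=10)
        m = sdm.fit(fs, pres.segment_ids, seg, beta=1.0)
        pc = sdm.percent_contribution(m)
        assert pc["Q"] == pytest.approx(100.0)

    def test_permutation_importance_sums_to_100(self, small_fit):
        seg, pres, model = small_fit
        pi = sdm.permutation_importance(model, pres.segment_ids, seg, seed=1)
        assert pi.sum() == pytest.approx(100.0, abs=1e-6)

    def test_absent_covariate_zero_importance(self, small_fit):
        seg, pres, model = small_fit
        import copy
        m = copy.copy(model)
        m.lambdas = model.lambdas.copy()
        drop = [j for j, f in enumerate(m.featureset.features) if "ELEV" in f.covs]
        m.lambdas[drop] = 0.0
        pi = sdm.permutation_importance(m, pres.segment_ids, seg, seed=1)
        assert pi["ELEV"] == 0.0


class TestResponseCurve:
    def test_constant_model_flat_curve(self, riverscape):
        _, seg, pres, _ = riverscape
        fs = build_features(seg, pres.segment_ids, n_knots=10)
        m = sdm.fit(fs, pres.segment_ids, seg, beta=1e6)  # fully shrunk
        rc = sdm.response_curve(m, "Q", 50)
        assert rc["cloglog"].std() == pytest.approx(0.0, abs=1e-12)

    def test_curve_in_unit_interval(self, small_fit):
        _, _, model = small_fit
        rc = sdm.response_curve(model, "Q", 80)
        assert rc["cloglog"].between(0, 1).all()

    def test_unknown_covariate_errors(self, small_fit):
        _, _, model = small_fit
        with pytest.raises(ValueError):
            sdm.response_curve(model, "NOPE")


class TestSerialization:
    def test_round_trip_predictions_identical(self, small_fit, tmp_path):
        seg, _, model = small_fit
        p = tmp_path / "model.json"
        maxent.save_model(model, p)
        back = maxent.load_model(p)
        a = sdm.predict(model, seg)
        b = sdm.predict(back, seg)
        np.testing.assert_array_equal(a.raw, b.raw)
        np.testing.assert_array_equal(a.cloglog, b.cloglog)
        assert sdm.count_nonzero(back) == sdm.count_nonzero(model)


def test_missing_covariates_imputed_with_background_mean(riverscape):
    _, seg, pres, _ = riverscape
    df = seg.data.copy()
    df.loc[df.index[:20], "SAND"] = np.nan
    seg2 = sdm.SegmentTable(df, covariates=seg.covariates)
    fs = build_features(seg2, pres.segment_ids, n_knots=5)
    m = sdm.fit(fs, pres.segment_ids, seg2, beta=1.0)
    pred = sdm.predict(m, seg2)
    assert np.isfinite(pred.raw).all()
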