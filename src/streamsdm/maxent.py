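"""Presence-background maximum-entropy modeling on samples-with-data input.

The model fits a Gibbs density over the background segments,
raw_i = exp(sum_j lambda_j f_j(x_i)) / Z, by maximizing the L1-penalized
presence log-likelihood

    mean_presence(eta) - ln Z(lambda) - sum_j beta_j |lambda_j|,

where eta = sum_j lambda_j f_j(x) and Z sums exp(eta) over the full
background.  Minimizing the relative entropy between presence and
background covariate distributions subject to moment constraints is the
dual of exactly this problem.  Features are built from the covariates by
the usual expansion (linear, quadratic, product, and forward/reverse
hinge pieces with knots at background quantiles), all min-max scaled to
[0, 1] over the background; an "autofeature" rule enables classes by
presence sample size.  The per-feature penalty is
beta_j = beta_multiplier * r_class(n) * sd_j / sqrt(n), with sd_j the
feature's sample deviation over the presences and r_class the published
class default interpolated by presence count.

The solver is cyclic coordinate descent with proximal-Newton updates and
soft-thresholding, with a backtracking safeguard so the penalized
objective never decreases; exact zeros fall out of the soft-threshold,
giving the nonzero-parameter counts used later for AICc.  The cloglog
transform 1 - exp(-e^H * raw), with H the entropy of the fitted
background density, maps raw densities to a 0-1 suitability index.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._util import rank_auc
from .swd_io import SegmentTable

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentModel",
    "PredictionVector",
    "build_features",
    "fit",
    "predict",
    "count_nonzero",
    "percent_contribution",
    "permutation_importance",
    "response_curve",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# autofeature activation thresholds by presence count
AUTOFEATURE_MIN_N = {"linear": 2, "quadratic": 10, "hinge": 15, "product": 80}

# piecewise-linear class default regularization vs presence count
_R_BREAKS = np.array([10.0, 30.0, 100.0])
_R_VALUES = np.array([1.0, 0.2, 0.05])
_SD_FLOOR = 1e-3


def class_regularization(cls: str, n: int) -> float:
    """Default per-class regularization constant, interpolated by n."""
    if cls == "hinge":
        return 0.5
    return float(np.interp(n, _R_BREAKS, _R_VALUES))


@dataclass(frozen=True)
class Feature:
    """One basis function of the expansion.

    ``covs`` names the source covariate(s); hinges carry a knot on the
    [0,1]-scaled covariate and a direction (+1 forward, -1 reverse).
    """

    name: str
    cls: str
    covs: tuple[str, ...]
    knot: float | None = None
    direction: int | None = None


@dataclass
class FeatureSet:
    """Feature definitions plus the background scaling that anchors them."""

    features: list[Feature]
    cov_min: dict[str, float]
    cov_max: dict[str, float]
    classes: tuple[str, ...]
    n_presences: int

    def __len__(self) -> int:
        return len(self.features)

    def scaled_covariates(self, df: pd.DataFrame) -> dict[str, np.ndarray]:
        out = {}
        for c in self.cov_min:
            lo, hi = self.cov_min[c], self.cov_max[c]
            u = (df[c].to_numpy(float) - lo) / (hi - lo)
            out[c] = np.clip(u, 0.0, 1.0)
        return out

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Evaluate every feature on rows of ``df`` (raw covariate columns)."""
        u = self.scaled_covariates(df)
        cols = np.empty((len(df), len(self.features)))
        for j, f in enumerate(self.features):
            if f.cls == "linear":
                cols[:, j] = u[f.covs[0]]
            elif f.cls == "quadratic":
                cols[:, j] = u[f.covs[0]] ** 2
            elif f.cls == "product":
                cols[:, j] = u[f.covs[0]] * u[f.covs[1]]
            else:  # hinge
                v = u[f.covs[0]]
                t = f.knot
                if f.direction == 1:
                    cols[:, j] = np.maximum(0.0, (v - t) / (1.0 - t))
                else:
                    cols[:, j] = np.maximum(0.0, (t - v) / t)
        return cols


@dataclass
class MaxentModel:
    """A fitted candidate: coefficients, normalizers, entropy, gain trace."""

    featureset: FeatureSet
    lambdas: np.ndarray
    beta_multiplier: float
    penalties: np.ndarray
    log_z: float                    # density normalizer over training background
    entropy: float                  # H of the fitted background distribution
    n_presences: int
    presence_cov_means: dict[str, float]
    gain_by_covariate: dict[str, float]
    objective_trace: list = field(default_factory=list, repr=False)
    converged: bool = True
    n_iter: int = 0


@dataclass
class PredictionVector:
    """Per-segment raw density and cloglog suitability for one model."""

    segment_ids: np.ndarray
    raw: np.ndarray
    cloglog: np.ndarray
    model: MaxentModel | None = None


# ---------------------------------------------------------------------------
# feature construction


def build_features(segments: SegmentTable, presence_ids, classes="auto",
                   covariates: list[str] | None = None,
                   n_knots: int = 50) -> FeatureSet:
    """Expand covariates into a scaled feature basis.

    With ``classes='auto'`` the allowed classes follow the presence count
    n: linear always, quadratic at n >= 10, hinge at n >= 15, product at
    n >= 80.  Hinge knots sit at background quantiles (``n_knots`` per
    covariate and direction); all features are [0,1]-scaled over the
    background.
    """
    covs = covariates if covariates is not None else list(segments.covariates)
    n = len(pd.unique(pd.Series(list(presence_ids))))
    if n < 2:
        raise ValueError("need at least 2 presence segments to build features")
    if classes == "auto":
        use = tuple(c for c in FEATURE_CLASSES if n >= AUTOFEATURE_MIN_N[c])
    else:
        use = tuple(classes)
        bad = [c for c in use if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature class {bad[0]!r}; "
                             f"allowed: {FEATURE_CLASSES}")
    df = segments.data
    cov_min, cov_max, kept = {}, {}, []
    for c in covs:
        v = df[c].to_numpy(float)
        v = v[~np.isnan(v)]
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-12:
            logger.info("dropping zero-range covariate %r from feature basis", c)
            continue
        cov_min[c], cov_max[c] = lo, hi
        kept.append(c)

    feats: list[Feature] = []
    for c in kept:
        if "linear" in use:
            feats.append(Feature(f"L({c})", "linear", (c,)))
        if "quadratic" in use:
            feats.append(Feature(f"Q({c})", "quadratic", (c,)))
    if "product" in use:
        for a, b in itertools.combinations(kept, 2):
            feats.append(Feature(f"P({a}*{b})", "product", (a, b)))
    if "hinge" in use:
        for c in kept:
            u = (df[c].to_numpy(float) - cov_min[c]) / (cov_max[c] - cov_min[c])
            u = np.clip(u[~np.isnan(u)], 0, 1)
            qs = np.arange(n_knots) / n_knots
            fwd = np.unique(np.quantile(u, qs))
            fwd = fwd[fwd < 1.0]
            rev = np.unique(np.quantile(u, 1.0 - qs))
            rev = rev[rev > 0.0]
            for t in fwd:
                feats.append(Feature(f"HF({c}@{t:.6g})", "hinge", (c,), float(t), 1))
            for t in rev:
                feats.append(Feature(f"HR({c}@{t:.6g})", "hinge", (c,), float(t), -1))
    return FeatureSet(feats, cov_min, cov_max, use, n)


def _impute(df: pd.DataFrame, covs: list[str]) -> pd.DataFrame:
    """Fill missing covariate cells with the background mean (warn via log)."""
    out = df.copy()
    for c in covs:
        if out[c].isna().any():
            m = float(out[c].mean())
            logger.warning("imputing %d missing value(s) of %r with background mean %.4g",
                           int(out[c].isna().sum()), c, m)
            out[c] = out[c].fillna(m)
    return out


# ---------------------------------------------------------------------------
# fitting


def _objective(eta: np.ndarray, pres_idx: np.ndarray, lambdas: np.ndarray,
               penalties: np.ndarray) -> float:
    return float(eta[pres_idx].mean() - logsumexp(eta) - penalties @ np.abs(lambdas))


def fit(featureset: FeatureSet, presence_ids, background: SegmentTable,
        beta: float = 1.0, tol: float = 1e-5, max_iter: int = 10000) -> MaxentModel:
    """L1-penalized maximum-entropy fit by cyclic coordinate descent.

    The objective is concave, so the fitted density is unique; the
    per-update objective deltas are recorded and credited to each
    feature's source covariate(s) for the path-dependent percent
    contribution.  Raises if the iteration cap is hit before the
    per-cycle gain change drops below ``tol``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    covs = list(featureset.cov_min)
    df = _impute(background.data, covs)
    X = featureset.design_matrix(df)
    ids = background.data["segment_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    try:
        pres_idx = np.array([pos[s] for s in presence_ids])
    except KeyError as e:
        raise ValueError(f"presence segment {e.args[0]!r} not in background") from e
    pres_idx = np.unique(pres_idx)
    n = len(pres_idx)

    # drop features constant over the background
    keep = np.ptp(X, axis=0) > 1e-12
    dropped = [featureset.features[j].name for j in np.flatnonzero(~keep)]
    for name in dropped:
        logger.info("dropping degenerate (constant) feature %r", name)
    fs = FeatureSet([f for f, k in zip(featureset.features, keep) if k],
                    featureset.cov_min, featureset.cov_max,
                    featureset.classes, featureset.n_presences)
    X = X[:, keep]
    J = X.shape[1]

    sd = X[pres_idx].std(axis=0, ddof=1) if n > 1 else np.zeros(J)
    # hinge features that barely vary over the presences would otherwise
    # carry a vanishing penalty; the canonical default floors their sample
    # deviation at 1/sqrt(n)
    is_hinge = np.array([f.cls == "hinge" for f in fs.features])
    sd = np.where(is_hinge, np.maximum(sd, 1.0 / np.sqrt(n)), sd)
    sd = np.maximum(sd, _SD_FLOOR)
    r = np.array([class_regularization(f.cls, n) for f in fs.features])
    penalties = beta * r * sd / np.sqrt(n)

    p_mean = X[pres_idx].mean(axis=0)
    lam = np.zeros(J)
    eta = np.zeros(len(ids))
    obj = _objective(eta, pres_idx, lam, penalties)
    trace: list[tuple[int, float]] = []
    obj_trace: list[float] = [obj]
    n_cycles = 0
    active: np.ndarray | None = None
    full_pass = True
    while True:
        n_cycles += 1
        if n_cycles > max_iter:
            raise RuntimeError(
                f"maxent solver did not converge in {max_iter} cycles "
                f"(last regularized gain {obj:.6f})")
        order = np.arange(J) if full_pass else active
        cycle_gain = 0.0
        log_z = logsumexp(eta)
        w = np.exp(eta - log_z)
        base_penalty = float(penalties @ np.abs(lam))
        for j in order:
            xj = X[:, j]
            m = float(w @ xj)
            v = float(w @ (xj * xj)) - m * m
            if v < 1e-10:
                continue
            g = p_mean[j] - m
            z = lam[j] + g / v
            t = penalties[j] / v
            d = np.sign(z) * max(abs(z) - t, 0.0) - lam[j]
            if d == 0.0:
                continue
            # backtracking safeguard: the proximal-Newton step must never
            # decrease the penalized objective (keeps the ascent monotone)
            accepted = False
            for _ in range(25):
                lam_j_new = lam[j] + d
                eta_new = eta + d * xj
                pen_new = base_penalty - penalties[j] * abs(lam[j]) \
                    + penalties[j] * abs(lam_j_new)
                obj_new = float(eta_new[pres_idx].mean() - logsumexp(eta_new) - pen_new)
                if obj_new >= obj - 1e-12:
                    accepted = True
                    break
                d *= 0.5
            if not accepted:
                continue
            lam[j] = lam_j_new
            eta = eta_new
            delta = obj_new - obj
            obj = obj_new
            base_penalty = pen_new
            if delta > 0:
                trace.append((j, delta))
            cycle_gain += max(delta, 0.0)
            log_z = logsumexp(eta)
            w = np.exp(eta - log_z)
        obj_trace.append(obj)
        if full_pass:
            active = np.flatnonzero(lam != 0.0)
        if cycle_gain < tol:
            if full_pass:
                break
            full_pass = True
        else:
            full_pass = len(active) == 0

    log_z = float(logsumexp(eta))
    raw = np.exp(eta - log_z)
    nz = raw > 0
    entropy = float(-(raw[nz] * np.log(raw[nz])).sum())

    gain_by_cov: dict[str, float] = {c: 0.0 for c in covs}
    for j, delta in trace:
        fcovs = fs.features[j].covs
        for c in fcovs:
            gain_by_cov[c] += delta / len(fcovs)

    pres_means = {c: float(df[c].to_numpy(float)[pres_idx].mean()) for c in covs}
    return MaxentModel(
        featureset=fs, lambdas=lam, beta_multiplier=beta, penalties=penalties,
        log_z=log_z, entropy=entropy, n_presences=n,
        presence_cov_means=pres_means, gain_by_covariate=gain_by_cov,
        objective_trace=obj_trace, converged=True, n_iter=n_cycles)


# ---------------------------------------------------------------------------
# prediction and diagnostics


def _predict_frame(model: MaxentModel, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = _impute(df, list(model.featureset.cov_min))
    X = model.featureset.design_matrix(df)
    eta = X @ model.lambdas
    raw = np.exp(eta - model.log_z)
    cloglog = 1.0 - np.exp(-np.exp(model.entropy) * raw)
    return raw, cloglog


def predict(model: MaxentModel, segments: SegmentTable) -> PredictionVector:
    """Raw density (normalized over the training background) and cloglog."""
    missing = [c for c in model.featureset.cov_min if c not in segments.data.columns]
    if missing:
        raise ValueError(f"segment table lacks model covariate {missing[0]!r}")
    raw, cloglog = _predict_frame(model, segments.data)
    return PredictionVector(segments.data["segment_id"].to_numpy(), raw, cloglog, model)


def count_nonzero(model: MaxentModel) -> int:
    """Number of features with nonzero coefficients (the AICc parameter count)."""
    return int(np.count_nonzero(model.lambdas))


def percent_contribution(model: MaxentModel) -> pd.Series:
    """Path-dependent covariate contributions: per-update gain increases
    credited to the updated feature's covariate(s), normalized to 100."""
    s = pd.Series(model.gain_by_covariate, dtype=float).clip(lower=0.0)
    total = s.sum()
    if total == 0:
        return s  # all-zero model: nothing contributed
    return s / total * 100.0


def permutation_importance(model: MaxentModel, presence_ids,
                           background: SegmentTable, seed: int = 0) -> pd.Series:
    """Drop in training AUC when each covariate is permuted, normalized to 100.

    The covariate's values are shuffled jointly across the presence +
    background rows (presences are background rows here), the model is
    re-evaluated, and the AUC decrease is the raw importance.
    """
    ids = background.data["segment_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    pres_idx = np.unique([pos[s] for s in presence_ids])
    raw, _ = _predict_frame(model, background.data)
    base = rank_auc(raw[pres_idx], raw)
    rng = np.random.default_rng(seed)
    drops = {}
    for c in model.featureset.cov_min:
        df = background.data.copy()
        df[c] = rng.permutation(df[c].to_numpy())
        raw_p, _ = _predict_frame(model, df)
        drops[c] = max(0.0, base - rank_auc(raw_p[pres_idx], raw_p))
    s = pd.Series(drops, dtype=float)
    total = s.sum()
    return s if total == 0 else s / total * 100.0


def response_curve(model: MaxentModel, covariate: str, n_points: int = 100) -> pd.DataFrame:
    """Marginal single-variable response: sweep one covariate across its
    background range with the others held at their presence-sample means."""
    if covariate not in model.featureset.cov_min:
        raise ValueError(f"unknown covariate {covariate!r}")
    lo = model.featureset.cov_min[covariate]
    hi = model.featureset.cov_max[covariate]
    sweep = np.linspace(lo, hi, n_points)
    df = pd.DataFrame({c: np.full(n_points, model.presence_cov_means[c])
                       for c in model.featureset.cov_min})
    df[covariate] = sweep
    _, cloglog = _predict_frame(model, df)
    return pd.DataFrame({covariate: sweep, "cloglog": cloglog})


# ---------------------------------------------------------------------------
# serialization (plain-text ".lambdas" analogue)


def save_model(model: MaxentModel, path) -> None:
    """Write a plain-text coefficient file: features, lambdas, scaling,
    normalizers and entropy; round-trip safe via :func:`load_model`."""
    payload = {
        "beta_multiplier": model.beta_multiplier,
        "log_z": model.log_z,
        "entropy": model.entropy,
        "n_presences": model.n_presences,
        "classes": list(model.featureset.classes),
        "cov_min": model.featureset.cov_min,
        "cov_max": model.featureset.cov_max,
        "presence_cov_means": model.presence_cov_means,
        "gain_by_covariate": model.gain_by_covariate,
        "features": [
            {"name": f.name, "cls": f.cls, "covs": list(f.covs),
             "knot": f.knot, "direction": f.direction,
             "lambda": float(l), "penalty": float(b)}
            for f, l, b in zip(model.featureset.features, model.lambdas, model.penalties)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> MaxentModel:
    with open(path) as fh:
        d = json.load(fh)
    feats = [Feature(f["name"], f["cls"], tuple(f["covs"]), f["knot"], f["direction"])
             for f in d["features"]]
    fs = FeatureSet(feats, d["cov_min"], d["cov_max"], tuple(d["classes"]),
                    d["n_presences"])
    return MaxentModel(
        featureset=fs,
        lambdas=np.array([f["lambda"] for f in d["features"]]),
        beta_multiplier=d["beta_multiplier"],
        penalties=np.array([f["penalty"] for f in d["features"]]),
        log_z=d["log_z"], entropy=d["entropy"], n_presences=d["n_presences"],
        presence_cov_means=d["presence_cov_means"],
        gain_by_covariate=d["gain_by_covariate"])
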