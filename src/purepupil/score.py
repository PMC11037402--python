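"""The Pupil Reactivity (PuRe) score.

The published score is a linear combination of the raw baseline diameter
INIT and five lighting-corrected parameters::

    PuRe = 0.007*INIT - 2.438*END_c + 2.773*FIN_c + 0.838*MCV_c
           + 1.239*PDV_c + 2.604*CAMP_c

(no intercept; MCV enters signed). The raw score is mapped onto a clinical
0-5 scale by a piecewise-linear function calibrated on the distributions of
raw scores from reactive ("pre", before a mydriatic) and unreactive
("post") recordings: the anchors send

    median(post) - 3*sd(post) -> -0.5      median(post) - sd(post) -> 0.2
    median(post)              ->  0.8      median(post) + sd(post) -> 1.0
    0                         ->  3.0      median(pre) - 3*sd(pre) -> 4.0
    median(pre)               ->  4.5

with linear interpolation between anchors, extrapolation with the end
segments' slopes beyond them, and clamping to [0, 5]. On the resulting
scale 0 means a non-reactive pupil, 0-3 an abnormal/"sluggish" response and
3-5 a normal/brisk response.

A training pipeline (:func:`train_pure_model`) re-derives a score of the
same family on new cohorts: L1-regularised logistic regression separating
reactive from unreactive recordings, with an optional differentiable
penalty on the variance of per-illumination-level mean scores to keep the
score light-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "PURE_COEFFICIENTS",
    "PURE_FEATURES",
    "PuReModel",
    "PiecewiseScaler",
    "ScoreTrainingConfig",
    "CalibrationError",
    "ScoreError",
    "pure_linear_score",
    "fit_piecewise_scaler",
    "apply_scaler",
    "train_pure_model",
    "expanded_feature_value",
    "score_expanded",
    "evaluate_discrimination",
    "classify",
]

#: published coefficients (three decimals); INIT enters uncorrected
PURE_COEFFICIENTS = {
    "init": 0.007,
    "end_c": -2.438,
    "fin_c": 2.773,
    "mcv_c": 0.838,
    "pdv_c": 1.239,
    "camp_c": 2.604,
}
PURE_FEATURES = tuple(PURE_COEFFICIENTS)

#: fixed scaled ordinates of the seven calibration anchors
_SCALED_ANCHORS = (-0.5, 0.2, 0.8, 1.0, 3.0, 4.0, 4.5)

SCALE_MIN, SCALE_MAX = 0.0, 5.0
NORMAL_BOUNDARY = 3.0


class ScoreError(ValueError):
    pass


class CalibrationError(ValueError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PiecewiseScaler:
    """Monotone piecewise-linear map from raw score to the 0-5 scale."""

    raw_anchors: tuple
    scaled_anchors: tuple = _SCALED_ANCHORS
    calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        raw = np.asarray(self.raw_anchors, dtype=float)
        scaled = np.asarray(self.scaled_anchors, dtype=float)
        if raw.shape != scaled.shape or raw.ndim != 1 or len(raw) < 2:
            raise CalibrationError("anchor lists must be 1-D and of equal length >= 2")
        if not np.all(np.diff(raw) > 0):
            raise CalibrationError(
                "raw anchors not strictly increasing (calibration "
                "distributions overlap zero badly)",
                diagnostics={"raw_anchors": raw.tolist()},
            )
        if not np.all(np.diff(scaled) > 0):
            raise CalibrationError("scaled anchors not strictly increasing")
        object.__setattr__(self, "raw_anchors", tuple(raw.tolist()))
        object.__setattr__(self, "scaled_anchors", tuple(scaled.tolist()))

    def to_dict(self) -> dict:
        return {
            "anchors": [list(p) for p in zip(self.raw_anchors, self.scaled_anchors)],
            "calibration": self.calibration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseScaler":
        anchors = d["anchors"]
        return cls(
            raw_anchors=tuple(a[0] for a in anchors),
            scaled_anchors=tuple(a[1] for a in anchors),
            calibration=dict(d.get("calibration", {})),
        )


def fit_piecewise_scaler(pre_scores, post_scores) -> PiecewiseScaler:
    """Calibrate the 0-5 scaler from raw scores of reactive (pre) and
    unreactive (post) recordings.

    Medians and sample standard deviations (n-1 denominator) of the two
    samples place the seven anchors; a :class:`CalibrationError` is raised
    if they fail to be strictly increasing in raw score (e.g. the post
    median is not negative).
    """
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if len(pre) < 3 or len(post) < 3:
        raise CalibrationError("need >= 3 scores in each calibration sample")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise CalibrationError("calibration scores must be finite")
    m_pre, s_pre = float(np.median(pre)), float(np.std(pre, ddof=1))
    m_post, s_post = float(np.median(post)), float(np.std(post, ddof=1))
    if s_pre == 0 or s_post == 0:
        raise CalibrationError("calibration samples must have positive spread")
    raw = (
        m_post - 3 * s_post,
        m_post - s_post,
        m_post,
        m_post + s_post,
        0.0,
        m_pre - 3 * s_pre,
        m_pre,
    )
    return PiecewiseScaler(
        raw_anchors=raw,
        calibration={
            "median_pre": m_pre, "stdev_pre": s_pre,
            "median_post": m_post, "stdev_post": s_post,
            "n_pre": int(len(pre)), "n_post": int(len(post)),
        },
    )


def apply_scaler(scaler: PiecewiseScaler, raw) -> np.ndarray | float:
    """Map raw score(s) to the 0-5 scale.

    Linear interpolation between anchors; beyond the end anchors the
    adjacent segment's slope is extrapolated; the result is clamped to
    [0, 5] (so the map is monotone and surjective onto [0, 5]).
    """
    x = np.asarray(scaler.raw_anchors)
    y = np.asarray(scaler.scaled_anchors)
    r = np.asarray(raw, dtype=float)
    out = np.interp(r, x, y)
    lo_slope = (y[1] - y[0]) / (x[1] - x[0])
    hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    out = np.where(r < x[0], y[0] + (r - x[0]) * lo_slope, out)
    out = np.where(r > x[-1], y[-1] + (r - x[-1]) * hi_slope, out)
    out = np.clip(out, SCALE_MIN, SCALE_MAX)
    return float(out) if out.ndim == 0 else out


def classify(scaled) -> np.ndarray:
    """Clinical class from the scaled score: ``non-reactive`` (0),
    ``abnormal`` (0-3, "sluggish"), ``normal`` (3-5, brisk)."""
    s = np.atleast_1d(np.asarray(scaled, dtype=float))
    out = np.where(s <= SCALE_MIN, "non-reactive",
                   np.where(s < NORMAL_BOUNDARY, "abnormal", "normal"))
    return out


@dataclass
class PuReModel:
    """Linear score model: ``coefficients`` over the six published inputs
    (or any trained feature set), an intercept, and an optional calibrated
    scaler."""

    coefficients: dict = field(default_factory=lambda: dict(PURE_COEFFICIENTS))
    intercept: float = 0.0
    scaler: PiecewiseScaler | None = None

    def raw_score(self, features: dict) -> float:
        total = self.intercept
        for name, w in self.coefficients.items():
            if name not in features:
                raise ScoreError(f"missing input '{name}' for the PuRe score")
            v = float(features[name])
            if not math.isfinite(v):
                raise ScoreError(f"non-finite input '{name}'")
            total += w * v
        return float(total)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "scaler": self.scaler.to_dict() if self.scaler else None,
        }

    @classmethod
    def from_dict(cls, d: dict, strict: bool = True) -> "PuReModel":
        known = {"coefficients", "intercept", "scaler", "provenance"}
        extra = set(d) - known
        if strict and extra:
            raise ScoreError(f"unknown fields in PuRe model: {sorted(extra)}")
        if "coefficients" not in d:
            raise ScoreError("missing 'coefficients'")
        return cls(
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d.get("intercept", 0.0)),
            scaler=PiecewiseScaler.from_dict(d["scaler"]) if d.get("scaler") else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def pure_linear_score(model: PuReModel, init: float, corrected: dict) -> float:
    """Raw PuRe score: intercept + coefficients . (INIT, corrected params).

    ``corrected`` maps corrected-parameter names (``end_c`` ... ``camp_c``)
    to values; LAT_c and T75_c are not used by the published model.
    """
    features = {"init": init, **corrected}
    return model.raw_score(features)


# ---------------------------------------------------------------------------
# training


@dataclass
class ScoreTrainingConfig:
    """Recipe for re-deriving a PuRe-style score on a new cohort.

    ``alpha`` weights the L1 penalty; ``invariance_penalty_weight`` (gamma)
    weights the variance of per-illumination-level mean scores on the
    reactive class. Feature expansion follows the published recipe (powers
    2 and -1 and first-order products of the base parameters), each
    switchable.
    """

    alpha: float = 0.006
    invariance_penalty_weight: float = 0.0
    powers: bool = True
    inverses: bool = True
    products: bool = True
    parameters: tuple = PURE_FEATURES
    reactive_label: int = 1

    def __post_init__(self):
        if self.alpha < 0 or self.invariance_penalty_weight < 0:
            raise ScoreError("penalty weights must be >= 0")


def expand_features(base: np.ndarray, names, config: ScoreTrainingConfig):
    """Published feature expansion: base columns, optional squares,
    inverses and pairwise products. Returns (matrix, names)."""
    cols = [base[:, i] for i in range(base.shape[1])]
    out_names = list(names)
    if config.powers:
        for i, nm in enumerate(names):
            cols.append(base[:, i] ** 2)
            out_names.append(f"{nm}^2")
    if config.inverses:
        for i, nm in enumerate(names):
            cols.append(1.0 / base[:, i])
            out_names.append(f"{nm}^-1")
    if config.products:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                cols.append(base[:, i] * base[:, j])
                out_names.append(f"{names[i]}*{names[j]}")
    return np.column_stack(cols), out_names


def expanded_feature_value(name: str, base: dict) -> float:
    """Value of an expanded-feature name (``x^2``, ``x^-1``, ``a*b``) from
    the base feature mapping; inverse of the :func:`expand_features`
    naming convention."""
    if "*" in name:
        a, b = name.split("*", 1)
        return expanded_feature_value(a, base) * expanded_feature_value(b, base)
    if name.endswith("^2"):
        return float(base[name[:-2]]) ** 2
    if name.endswith("^-1"):
        return 1.0 / float(base[name[:-3]])
    return float(base[name])


def score_expanded(model: PuReModel, base: dict) -> float:
    """Raw score of a trained model whose coefficients may refer to
    expanded features, given only the base features."""
    return model.intercept + sum(
        w * expanded_feature_value(name, base)
        for name, w in model.coefficients.items()
    )


def train_pure_model(
    features: np.ndarray | "pd.DataFrame",
    labels,
    illumination=None,
    config: ScoreTrainingConfig | None = None,
    feature_names=None,
) -> PuReModel:
    """Fit a PuRe-style score by penalised logistic regression.

    Minimises ``mean log-loss + alpha*||w||_1 + gamma*V`` where ``V`` is the
    variance of per-illumination-level mean raw scores over the reactive
    class (zero when ``illumination`` is None or gamma is 0). Features are
    standardised internally; returned coefficients are on the original
    scale, restricted to nonzero weights. The fitted model has no scaler
    (calibrate one with :func:`fit_piecewise_scaler`).
    """
    config = config or ScoreTrainingConfig()
    if hasattr(features, "columns"):  # DataFrame
        feature_names = list(features.columns)
        features = features.to_numpy(dtype=float)
    base = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(base.shape[1])]
    y = (np.asarray(labels) == config.reactive_label).astype(float)
    if y.min() == y.max():
        raise ScoreError("training data must contain both classes")
    X, names = expand_features(base, feature_names, config)
    if not np.all(np.isfinite(X)):
        raise ScoreError("non-finite features after expansion")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n, p = Z.shape

    gamma = config.invariance_penalty_weight
    G = None
    if gamma > 0 and illumination is not None:
        illum = np.asarray(illumination)
        react = y == 1
        levels = np.unique(illum[react])
        G = np.zeros((len(levels), n))
        for li, lv in enumerate(levels):
            m = react & (illum == lv)
            G[li, m] = 1.0 / m.sum()

    # w = p - q with p, q >= 0 makes the L1 term smooth under L-BFGS-B
    def objective(theta):
        wp, wq = theta[:p], theta[p : 2 * p]
        b = theta[-1]
        w = wp - wq
        z = Z @ w + b
        # stable log(1+exp(-yz)) with y in {-1, +1}
        ysgn = 2 * y - 1
        loss = np.mean(np.logaddexp(0.0, -ysgn * z))
        grad_z = -ysgn * expit(-ysgn * z) / n
        gw = Z.T @ grad_z
        gb = grad_z.sum()
        pen = config.alpha * np.sum(wp + wq)
        g_pen = config.alpha
        if G is not None:
            m = G @ z
            mbar = m.mean()
            V = np.mean((m - mbar) ** 2)
            loss += gamma * V
            dV_dm = 2 * (m - mbar) / len(m)
            dV_dz = G.T @ dV_dm
            gw += gamma * (Z.T @ dV_dz)
            gb += gamma * dV_dz.sum()
        grad = np.concatenate([gw + g_pen, -gw + g_pen, [gb]])
        return loss + pen, grad

    theta0 = np.zeros(2 * p + 1)
    bounds = [(0, None)] * (2 * p) + [(None, None)]
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10})
    w_std = res.x[:p] - res.x[p : 2 * p]
    w = w_std / sd
    intercept = float(res.x[-1] - w_std @ (mu / sd))
    tol = 1e-8 * max(1.0, np.abs(w_std).max())
    coeffs = {nm: float(c) for nm, c, cs in zip(names, w, w_std) if abs(cs) > tol}
    return PuReModel(coefficients=coeffs, intercept=intercept, scaler=None)


# ---------------------------------------------------------------------------
# discrimination


def evaluate_discrimination(scores_reactive, scores_unreactive, threshold_raw=0.0):
    """Accuracy at a threshold plus rank-based AUC and ROC points.

    Reactive recordings are predicted when score >= threshold. AUC is the
    Mann-Whitney statistic P(reactive > unreactive) with ties counted 0.5.
    """
    a = np.asarray(scores_reactive, dtype=float)
    b = np.asarray(scores_unreactive, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ScoreError("both samples must be non-empty")
    correct = np.sum(a >= threshold_raw) + np.sum(b < threshold_raw)
    accuracy = float(correct) / (len(a) + len(b))
    ranks = rankdata(np.concatenate([a, b]))
    auc = (ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2) / (len(a) * len(b))
    labels = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    fpr, tpr, thr = roc_curve(labels, np.concatenate([a, b]))
    return {
        "accuracy": accuracy,
        "auc": float(auc),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                "thresholds": thr.tolist()},
    }
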