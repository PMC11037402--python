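"""Ambient-light correction of PLR parameters.

Each PLR parameter (except INIT, which serves as a predictor) is corrected
for ambient lighting in two steps. First a regression model predicts the
parameter from the baseline pupil diameter B (the INIT measurement, which in
healthy eyes tracks ambient light) and the camera exposure E (a firmware
value that decreases monotonically with illuminance). The candidate feature
pool contains linear and nonlinear terms of both predictors plus two
interactions; model structure is chosen by BIC over subsets of the pool and
the leading candidates are fine-tuned with LASSO (alpha = 0.006 on
standardised features), the winner being picked by leave-one-subject-out
cross-validated MSE. Second, the correction::

    corrected = average + measured - predicted

replaces the lighting-explained part of the measurement by the training
grand mean, leaving a lighting-invariant quantity that still carries each
subject's deviation from the norm.

How well the correction works is quantified by the F statistic for a
categorical illumination factor in a linear model with per-subject
intercepts: the corrected parameter should show a much smaller F than the
raw one.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.linear_model import Lasso

__all__ = [
    "FeatureTerm",
    "FULL_TERM_POOL",
    "CorrectionInput",
    "CorrectionModel",
    "CorrectionError",
    "CORRECTABLE_PARAMETERS",
    "build_feature_matrix",
    "stepwise_bic_select",
    "lasso_finetune",
    "predict_parameter",
    "apply_correction",
    "fit_correction_models",
    "apply_correction_models",
    "correct_dataset_loso",
    "illumination_f_statistic",
]

#: parameters that receive a lighting correction (INIT is a predictor)
CORRECTABLE_PARAMETERS = ("end", "fin", "camp", "mcv", "pdv", "lat", "t75")

DEFAULT_ALPHA = 0.006


class CorrectionError(ValueError):
    pass


class FeatureTerm(enum.Enum):
    """Candidate regression terms in Baseline (B) and Exposure (E)."""

    B = "B"
    E = "E"
    B2 = "B^2"
    E2 = "E^2"
    B_INV = "B^-1"
    E_INV = "E^-1"
    LOG_B = "log(B)"
    LOG_E = "log(E)"
    LOG_B2 = "log(B)^2"
    LOG_E2 = "log(E)^2"
    BxE = "B*E"
    LOGBxLOGE = "log(B)*log(E)"

    def __call__(self, baseline, exposure):
        b = np.asarray(baseline, dtype=float)
        e = np.asarray(exposure, dtype=float)
        return _TERM_FUNCS[self](b, e)


_TERM_FUNCS = {
    FeatureTerm.B: lambda b, e: b,
    FeatureTerm.E: lambda b, e: e,
    FeatureTerm.B2: lambda b, e: b**2,
    FeatureTerm.E2: lambda b, e: e**2,
    FeatureTerm.B_INV: lambda b, e: 1.0 / b,
    FeatureTerm.E_INV: lambda b, e: 1.0 / e,
    FeatureTerm.LOG_B: lambda b, e: np.log(b),
    FeatureTerm.LOG_E: lambda b, e: np.log(e),
    FeatureTerm.LOG_B2: lambda b, e: np.log(b) ** 2,
    FeatureTerm.LOG_E2: lambda b, e: np.log(e) ** 2,
    FeatureTerm.BxE: lambda b, e: b * e,
    FeatureTerm.LOGBxLOGE: lambda b, e: np.log(b) * np.log(e),
}

FULL_TERM_POOL = tuple(FeatureTerm)


@dataclass(frozen=True)
class CorrectionInput:
    """Predictors of a lighting correction: baseline diameter (mm) and
    camera exposure (opaque positive firmware units)."""

    baseline: float
    exposure: float

    def __post_init__(self):
        if not (self.baseline > 0 and self.exposure > 0):
            raise CorrectionError("baseline and exposure must be positive")


def build_feature_matrix(inputs, terms=FULL_TERM_POOL) -> np.ndarray:
    """Design matrix with one column per term, in the given term order.

    ``inputs`` is a sequence of :class:`CorrectionInput` (or an (n, 2) array
    of baseline, exposure pairs). Values are on the original scale;
    standardisation for penalised fitting happens inside the fitters.
    """
    arr = np.asarray(
        [(i.baseline, i.exposure) if isinstance(i, CorrectionInput) else tuple(i)
         for i in inputs],
        dtype=float,
    )
    if arr.size == 0:
        return np.empty((0, len(terms)))
    b, e = arr[:, 0], arr[:, 1]
    if np.any(b <= 0) or np.any(e <= 0):
        raise CorrectionError("baseline and exposure must be positive")
    return np.column_stack([term(b, e) for term in terms])


# ---------------------------------------------------------------------------
# model-structure search


def _bic_from_rss(rss: float, n: int, n_terms: int) -> float:
    # Gaussian BIC up to an additive constant: n ln(RSS/n) + k ln(n),
    # k counting the intercept
    rss = max(rss, 1e-12)
    return n * math.log(rss / n) + (n_terms + 1) * math.log(n)


_SUBSET_CACHE: dict[int, list] = {}


class _SubsetOLS:
    """Cheap RSS for many column subsets of one design matrix via the Gram
    matrix of centred, unit-scaled columns (equivalent to OLS with an
    intercept on the raw columns)."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.n = len(y)
        yc = y - y.mean()
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        self.G = Z.T @ Z
        self.c = Z.T @ yc
        self.tss = float(yc @ yc)

    def rss(self, subset: tuple[int, ...]) -> float:
        if not subset:
            return self.tss
        idx = list(subset)
        G = self.G[np.ix_(idx, idx)]
        c = self.c[idx]
        try:
            beta = np.linalg.solve(G, c)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(G) @ c
        return max(self.tss - float(c @ beta), 0.0)


def stepwise_bic_select(
    y,
    inputs,
    terms=FULL_TERM_POOL,
    top: int = 250,
    exhaustive_limit: int = 4096,
):
    """Rank term subsets by BIC of their OLS fit.

    Returns a list of ``(subset, bic)`` pairs, best first, at most ``top``
    long; each subset is a tuple of :class:`FeatureTerm`. Pools with at most
    ``exhaustive_limit`` subsets are enumerated exhaustively (the default
    covers the full 12-term pool); larger pools fall back to
    forward-backward stepwise search, ranking every model visited.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise CorrectionError(f"need >= 10 observations, got {n}")
    terms = tuple(terms)
    if np.std(y) < 1e-12:
        warnings.warn("constant response: returning intercept-only model")
        return [((), _bic_from_rss(0.0, n, 0))]

    X = build_feature_matrix(inputs, terms)
    ols = _SubsetOLS(X, y)
    p = len(terms)

    def bic_of(subset):
        return _bic_from_rss(ols.rss(subset), n, len(subset))

    scored: dict[tuple[int, ...], float] = {}
    if 2**p <= exhaustive_limit:
        if p not in _SUBSET_CACHE:
            _SUBSET_CACHE[p] = [
                tuple(j for j in range(p) if mask >> j & 1) for mask in range(2**p)
            ]
        for subset in _SUBSET_CACHE[p]:
            scored[subset] = bic_of(subset)
    else:
        current: tuple[int, ...] = ()
        scored[current] = bic_of(current)
        improved = True
        while improved:
            improved = False
            moves = [current + (j,) for j in range(p) if j not in current]
            moves += [tuple(k for k in current if k != j) for j in current]
            for cand in moves:
                cand = tuple(sorted(cand))
                if cand not in scored:
                    scored[cand] = bic_of(cand)
            best_move = min(moves, key=lambda s: scored[tuple(sorted(s))])
            best_move = tuple(sorted(best_move))
            if scored[best_move] < scored[current] - 1e-12:
                current = best_move
                improved = True

    ranked = sorted(scored.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    return [
        (tuple(terms[j] for j in subset), bic) for subset, bic in ranked[:top]
    ]


# ---------------------------------------------------------------------------
# LASSO fine-tuning


@dataclass
class CorrectionModel:
    """Winning per-parameter lighting model plus everything needed to apply
    the correction formula."""

    parameter_name: str
    terms: list[FeatureTerm]
    coefficients: dict[FeatureTerm, float]
    intercept: float
    average: float
    alpha: float = DEFAULT_ALPHA
    diagnostics: dict = field(default_factory=dict)

    def predict(self, inputs) -> np.ndarray:
        if not self.terms:
            n = len(inputs) if hasattr(inputs, "__len__") else 1
            return np.full(n, self.intercept)
        X = build_feature_matrix(inputs, self.terms)
        w = np.array([self.coefficients[t] for t in self.terms])
        return self.intercept + X @ w

    # --- serialization (lossless round trip) ---

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "terms": [t.name for t in self.terms],
            "coefficients": {t.name: self.coefficients[t] for t in self.terms},
            "intercept": self.intercept,
            "average": self.average,
            "alpha": self.alpha,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict, strict: bool = True) -> "CorrectionModel":
        known = {"parameter", "terms", "coefficients", "intercept", "average",
                 "alpha", "diagnostics"}
        extra = set(d) - known
        if strict and extra:
            raise CorrectionError(f"unknown fields in correction model: {sorted(extra)}")
        missing = {"parameter", "terms", "coefficients", "intercept", "average"} - set(d)
        if missing:
            raise CorrectionError(f"missing fields in correction model: {sorted(missing)}")
        terms = [FeatureTerm[name] for name in d["terms"]]
        coeffs = {FeatureTerm[k]: float(v) for k, v in d["coefficients"].items()}
        if set(coeffs) != set(terms):
            raise CorrectionError("coefficients do not match terms")
        avg = float(d["average"])
        if not math.isfinite(avg):
            raise CorrectionError("average must be finite")
        return cls(
            parameter_name=d["parameter"], terms=terms, coefficients=coeffs,
            intercept=float(d["intercept"]), average=avg,
            alpha=float(d.get("alpha", DEFAULT_ALPHA)),
            diagnostics=dict(d.get("diagnostics", {})),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _lasso_std(Z, yc, alpha, gram=None, tol=1e-5, max_iter=20000):
    """L1 coefficients for standardised columns Z and centred response yc
    (no intercept). A precomputed Gram matrix makes repeated small fits
    cheap; alpha = 0 falls back to OLS."""
    if Z.shape[1] == 0:
        return np.empty(0)
    if alpha == 0:
        return np.linalg.lstsq(Z, yc, rcond=None)[0]
    reg = Lasso(alpha=alpha, fit_intercept=False, tol=tol, max_iter=max_iter,
                precompute=gram if gram is not None else False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg.fit(Z, yc)
    return np.asarray(reg.coef_)


def _lasso_fit(X, y, alpha):
    """L1 fit on standardised columns; coefficients on the original scale."""
    Z, mu, sd = _standardize(X)
    ybar = float(np.mean(y))
    coef_std = _lasso_std(Z, y - ybar, alpha, gram=Z.T @ Z)
    coef = coef_std / sd
    intercept = ybar - float(coef @ mu)
    return coef, intercept


def lasso_finetune(
    candidates,
    y,
    inputs,
    subjects,
    alpha: float = DEFAULT_ALPHA,
    parameter_name: str = "",
) -> CorrectionModel:
    """Refit each candidate subset with an L1 penalty and pick the winner.

    Every candidate (from :func:`stepwise_bic_select`) is refit with LASSO
    (features standardised internally, ``alpha`` on the standardised scale);
    zeroed terms are dropped. The winner minimises leave-one-subject-out
    cross-validated MSE, ties broken toward fewer terms then earlier BIC
    rank. The training grand mean of ``y`` is stored as ``average``.
    """
    if not candidates:
        raise CorrectionError("no candidate models")
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    pairs = np.asarray(
        [(i.baseline, i.exposure) if isinstance(i, CorrectionInput) else tuple(i)
         for i in inputs],
        dtype=float,
    )
    uniq = np.unique(subjects)

    subsets = []
    for cand in candidates:
        terms = tuple(cand[0] if isinstance(cand, tuple) and len(cand) == 2
                      and not isinstance(cand[0], FeatureTerm) else cand)
        # duplicated columns make the L1 problem degenerate; keep one copy
        subsets.append(tuple(dict.fromkeys(terms)))
    union = tuple(dict.fromkeys(t for s in subsets for t in s))
    col_of = {t: j for j, t in enumerate(union)}
    X_u = build_feature_matrix(pairs, union) if union else np.empty((len(y), 0))

    # per-fold standardisation and Gram of the union pool, computed once
    folds = []
    for s in uniq:
        hold = subjects == s
        if hold.all() or not hold.any():
            continue
        Z_tr, mu, sd = _standardize(X_u[~hold])
        ybar = float(np.mean(y[~hold]))
        folds.append({
            "Z": Z_tr, "yc": y[~hold] - ybar, "ybar": ybar,
            "Zh": (X_u[hold] - mu) / sd, "yh": y[hold],
            "G": Z_tr.T @ Z_tr,
        })

    best = None
    for rank, terms in enumerate(subsets):
        idx = [col_of[t] for t in terms]
        sse = 0.0
        for f in folds:
            if idx:
                coef = _lasso_std(
                    f["Z"][:, idx], f["yc"], alpha,
                    gram=f["G"][np.ix_(idx, idx)], tol=1e-4, max_iter=5000,
                )
                pred = f["ybar"] + f["Zh"][:, idx] @ coef
            else:
                pred = f["ybar"]
            sse += float(np.sum((f["yh"] - pred) ** 2))
        mse = sse / len(y)
        key = (mse, len(terms), rank)
        if best is None or key < best[0]:
            best = (key, terms)

    terms = best[1]
    if terms:
        X = build_feature_matrix(pairs, terms)
        coef, intercept = _lasso_fit(X, y, alpha)
        keep = [i for i, c in enumerate(coef) if c != 0.0]
        terms = tuple(terms[i] for i in keep)
        coef = coef[keep]
    else:
        coef, intercept = np.empty(0), float(np.mean(y))
    if not len(terms):
        warnings.warn(
            f"all coefficients zeroed for {parameter_name or 'parameter'}; "
            "falling back to intercept-only model"
        )
        terms, coef, intercept = (), np.empty(0), float(np.mean(y))

    model = CorrectionModel(
        parameter_name=parameter_name,
        terms=list(terms),
        coefficients={t: float(c) for t, c in zip(terms, coef)},
        intercept=float(intercept),
        average=float(np.mean(y)),
        alpha=alpha,
    )
    resid = y - model.predict(pairs)
    tss = float(np.sum((y - y.mean()) ** 2))
    model.diagnostics["r2"] = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    model.diagnostics["cv_mse"] = best[0][0]
    return model


def predict_parameter(model: CorrectionModel, input: CorrectionInput) -> float:
    """Model prediction for one recording's (baseline, exposure)."""
    return float(model.predict([input])[0])


def apply_correction(measured, predicted, average):
    """corrected = average + measured - predicted (shift-equivariant).

    Grouped as ``average + (measured - predicted)`` so a measurement that
    equals its prediction returns the grand mean exactly.
    """
    out = np.asarray(average, dtype=float) + (
        np.asarray(measured, dtype=float) - np.asarray(predicted, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dataset-level pipelines

_REQUIRED_COLS = ("subject_id", "baseline", "exposure")


def _check_dataset(df: pd.DataFrame, parameters):
    missing = [c for c in (*_REQUIRED_COLS, *parameters) if c not in df.columns]
    if missing:
        raise CorrectionError(f"dataset missing columns: {missing}")


def fit_correction_models(
    df: pd.DataFrame,
    parameters=CORRECTABLE_PARAMETERS,
    alpha: float = DEFAULT_ALPHA,
    top: int = 250,
    terms=FULL_TERM_POOL,
) -> dict[str, CorrectionModel]:
    """Train one winning CorrectionModel per parameter on a full study table.

    ``df`` needs columns ``subject_id``, ``baseline``, ``exposure`` and one
    column per parameter; rows whose parameter value is NaN are dropped for
    that parameter only.
    """
    _check_dataset(df, parameters)
    models = {}
    for p in parameters:
        ok = np.isfinite(df[p].to_numpy(dtype=float))
        sub = df.loc[ok]
        inputs = sub[["baseline", "exposure"]].to_numpy(dtype=float)
        y = sub[p].to_numpy(dtype=float)
        cands = stepwise_bic_select(y, inputs, terms=terms, top=top)
        models[p] = lasso_finetune(
            [c for c, _ in cands], y, inputs, sub["subject_id"].to_numpy(),
            alpha=alpha, parameter_name=p,
        )
    return models


def apply_correction_models(
    models: dict[str, CorrectionModel], df: pd.DataFrame
) -> pd.DataFrame:
    """Append ``<param>_c`` columns: corrected = average + measured - predicted."""
    out = df.copy()
    inputs = df[["baseline", "exposure"]].to_numpy(dtype=float)
    for p, model in models.items():
        pred = model.predict(inputs)
        out[p + "_c"] = apply_correction(df[p].to_numpy(dtype=float), pred, model.average)
    return out


def correct_dataset_loso(
    df: pd.DataFrame,
    parameters=CORRECTABLE_PARAMETERS,
    alpha: float = DEFAULT_ALPHA,
    top: int = 250,
    terms=FULL_TERM_POOL,
) -> pd.DataFrame:
    """Leave-one-subject-out corrected table.

    For each subject, correction models (including their grand-mean
    ``average``) are trained on all other subjects only, so no recording is
    corrected by a model that saw its own subject.
    """
    _check_dataset(df, parameters)
    subjects = df["subject_id"].unique()
    if len(subjects) < 3:
        raise CorrectionError("LOSO correction needs >= 3 subjects")
    out = df.copy()
    for p in parameters:
        out[p + "_c"] = np.nan
    for s in sorted(subjects, key=str):
        hold = df["subject_id"] == s
        if not hold.any():
            continue
        train = df.loc[~hold]
        models = fit_correction_models(
            train, parameters=parameters, alpha=alpha, top=top, terms=terms
        )
        corrected = apply_correction_models(models, df.loc[hold])
        for p in parameters:
            out.loc[hold, p + "_c"] = corrected[p + "_c"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# light-dependence test


def illumination_f_statistic(values, illumination, subject):
    """F test for a categorical illumination factor, with fixed per-subject
    intercepts approximating the random-intercept model (exact for balanced
    designs). Returns ``(F, df_num, df_den)``. NaN values are dropped."""
    data = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "illum": np.asarray(illumination).astype(str),
        "subj": np.asarray(subject).astype(str),
    }).dropna()
    if data["illum"].nunique() < 2 or data["subj"].nunique() < 2:
        raise CorrectionError("need >= 2 illumination levels and >= 2 subjects")
    if (data.groupby("illum").size() < 1).any():
        raise CorrectionError("empty illumination level")
    model = smf.ols("y ~ C(illum) + C(subj)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f = float(table.loc["C(illum)", "F"])
    df_num = float(table.loc["C(illum)", "df"])
    df_den = float(table.loc["Residual", "df"])
    # a factor whose sum of squares is numerically zero explains nothing,
    # even when the residual is also zero (perfect subject fit)
    total_ss = float(table["sum_sq"].sum())
    if float(table.loc["C(illum)", "sum_sq"]) <= 1e-12 * max(total_ss, 1e-12):
        f = 0.0
    if not math.isfinite(f):
        f = 0.0
    return f, df_num, df_den
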