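"""The adjusted-GMI regression and its evaluation.

The core estimator predicts the current laboratory HbA1c from three
predictors taken at a follow-up pair:

    aGMI(%) = b0 + b1 * GMI + b2 * prior discordance + b3 * last HbA1c

where "prior" quantities come from the subject's immediately preceding
pair. :class:`GmiAdjuster` fits the coefficients by ordinary least squares
through an explicit pivoted-QR solve; :class:`GamLite` is a penalized
natural-cubic-spline variant used to probe for nonlinearity. Both follow
the scikit-learn estimator contract (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.

A versioned default coefficient set (the published values) ships in
``agmi/data/default_model.json`` and loads via :func:`load_default_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .discordance import DISCORDANCE_THRESHOLD
from .stats import MengTestResult, meng_test  # noqa: F401  (re-export)

CORE_PREDICTORS = ("gmi", "prior_discordance", "last_hba1c")
COVARIATE_COLUMNS = ("age", "sex")


@dataclass(frozen=True)
class EvaluationResult:
    """Agreement between predicted and observed HbA1c."""

    r: float
    p: float
    r2: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "r2": self.r2, "mae": self.mae, "n": self.n}


class RankDeficiencyError(np.linalg.LinAlgError):
    """The design matrix is rank deficient; names the collinear columns."""


class GmiAdjuster(RegressorMixin, BaseEstimator):
    """Ordinary least-squares adjusted-GMI model.

    Parameters
    ----------
    include_covariates : bool, default False
        Whether rows are expected to carry the optional demographic
        covariate columns (age, sex) in addition to the three core
        predictors. Only meaningful when fitting from a DataFrame via
        :func:`fit_ols`; with plain arrays every column of X is used.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    se_ : ndarray of shape (n_features + 1,)
        Standard errors for (intercept, *coef) from the unbiased residual
        variance.
    n_fit_ : int
        Rows used in the fit.
    feature_names_in_ : ndarray of str, when fitted from a DataFrame.
    """

    def __init__(self, include_covariates: bool = False):
        self.include_covariates = include_covariates

    def fit(self, X, y):
        feature_names = None
        if isinstance(X, pd.DataFrame):
            feature_names = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if n < p + 2:
            raise ValueError(f"need at least {p + 2} rows to fit {p + 1} coefficients")
        design = np.column_stack([np.ones(n), X])
        q, r, piv = sla.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag[0] * max(design.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < p + 1:
            cols = ["intercept"] + (
                list(feature_names) if feature_names is not None
                else [f"x{i}" for i in range(p)]
            )
            bad = [cols[j] for j in piv[rank:]]
            raise RankDeficiencyError(f"design matrix is rank deficient; "
                                      f"collinear column(s): {bad}")
        beta_piv = sla.solve_triangular(r, q.T @ y)
        beta = np.empty_like(beta_piv)
        beta[piv] = beta_piv
        resid = y - design @ beta
        sigma2 = float(resid @ resid) / (n - p - 1)
        rinv = sla.solve_triangular(r, np.eye(p + 1))
        cov_piv = sigma2 * (rinv @ rinv.T)
        se = np.empty(p + 1)
        se[piv] = np.sqrt(np.diag(cov_piv))
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.se_ = se
        self.n_fit_ = n
        self.sigma2_ = sigma2
        if feature_names is not None:
            self.feature_names_in_ = feature_names
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    def coefficients(self) -> dict:
        """Named coefficient/SE mapping (JSON-serializable)."""
        check_is_fitted(self, "coef_")
        names = list(getattr(self, "feature_names_in_",
                             [f"x{i}" for i in range(len(self.coef_))]))
        return {
            "intercept": self.intercept_,
            "coef": dict(zip(names, map(float, self.coef_))),
            "se": dict(zip(["intercept"] + names, map(float, self.se_))),
            "n_fit": int(self.n_fit_),
        }


def make_model_rows(pairs: pd.DataFrame) -> pd.DataFrame:
    """Build the regression table from a discordance-annotated pair table.

    One row per follow-up pair (``pair_index >= 1``): the response is the
    current HbA1c; predictors are the current GMI plus the previous pair's
    discordance and HbA1c. Baseline pairs contribute predictors only.
    """
    srt = pairs.sort_values(["subject_id", "pair_index"], kind="stable").copy()
    grp = srt.groupby("subject_id")
    srt["prior_discordance"] = grp["discordance"].shift(1)
    srt["last_hba1c"] = grp["hba1c"].shift(1)
    srt["prior_group"] = grp["group"].shift(1)
    rows = srt.loc[srt["pair_index"] >= 1].copy()
    cols = ["subject_id", "pair_index", "gmi", "prior_discordance", "last_hba1c",
            "prior_group", "hba1c", "days_since_baseline"]
    extra = [c for c in COVARIATE_COLUMNS if c in rows.columns]
    return rows[cols + extra].reset_index(drop=True)


def fit_ols(rows: pd.DataFrame, include_covariates: bool = False) -> GmiAdjuster:
    """Fit :class:`GmiAdjuster` on a model-row table from :func:`make_model_rows`."""
    predictors = list(CORE_PREDICTORS)
    if include_covariates:
        predictors += [c for c in COVARIATE_COLUMNS if c in rows.columns]
    est = GmiAdjuster(include_covariates=include_covariates)
    return est.fit(rows[predictors], rows["hba1c"].to_numpy())


def apply_agmi(gmi, prior_discordance, last_hba1c, model) -> np.ndarray | float:
    """Adjusted GMI for given inputs under a fitted or default model.

    ``model`` may be a fitted :class:`GmiAdjuster` or a mapping with keys
    ``beta0..beta3`` (the serialized default-model format).
    """
    g = np.asarray(gmi, dtype=float)
    d = np.asarray(prior_discordance, dtype=float)
    a = np.asarray(last_hba1c, dtype=float)
    if isinstance(model, GmiAdjuster):
        check_is_fitted(model, "coef_")
        b0 = model.intercept_
        b1, b2, b3 = model.coef_[:3]
    else:
        b0, b1, b2, b3 = (model["beta0"], model["beta1"], model["beta2"], model["beta3"])
    out = b0 + b1 * g + b2 * d + b3 * a
    return out.item() if np.isscalar(gmi) else out


def load_default_model() -> dict:
    """Published adjusted-GMI coefficients (versioned package data)."""
    text = resources.files("agmi").joinpath("data/default_model.json").read_text()
    return json.loads(text)


def evaluate(predicted, observed) -> EvaluationResult:
    """Pearson r (with two-sided p), squared-correlation R^2 and MAE.

    R^2 is the squared Pearson correlation between prediction and
    observation (so a constant offset hurts MAE but not r/R^2).
    """
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("predicted and observed must have equal length")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(yhat) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    res = sps.pearsonr(yhat, y)
    mae = float(np.mean(np.abs(yhat - y)))
    return EvaluationResult(float(res.statistic), float(res.pvalue),
                            float(res.statistic) ** 2, mae, n)


def subgroup_evaluate(rows: pd.DataFrame, model,
                      threshold: float = DISCORDANCE_THRESHOLD) -> dict:
    """Unadjusted vs adjusted agreement within prior-discordance subgroups.

    Subgroups hold the rows whose prior discordance was clinically positive
    (>= threshold) or negative (<= -threshold). Empty subgroups are reported
    with a notice instead of metrics.
    """
    out = {}
    masks = {
        "positive": rows["prior_discordance"] >= threshold,
        "negative": rows["prior_discordance"] <= -threshold,
    }
    for name, mask in masks.items():
        sub = rows.loc[mask]
        if len(sub) < 3:
            out[name] = {"notice": f"subgroup {name!r} has {len(sub)} rows; skipped"}
            continue
        y = sub["hba1c"].to_numpy()
        unadj = evaluate(sub["gmi"].to_numpy(), y)
        adj = evaluate(apply_agmi(sub["gmi"].to_numpy(),
                                  sub["prior_discordance"].to_numpy(),
                                  sub["last_hba1c"].to_numpy(), model), y)
        out[name] = {"unadjusted": unadj.as_dict(), "adjusted": adj.as_dict(),
                     "n": int(len(sub))}
    return out


# ---------------------------------------------------------------------------
# GAM-lite: natural cubic splines + ridge
# ---------------------------------------------------------------------------

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    With K knots the basis has K - 1 columns: x itself plus K - 2
    truncated-cubic contrasts.
    """
    k = len(knots)
    last, penult = knots[-1], knots[-2]

    def d(j):
        num = (np.clip(x - knots[j], 0, None) ** 3
               - np.clip(x - last, 0, None) ** 3)
        return num / (last - knots[j])

    dk1 = d(k - 2)
    cols = [x]
    for j in range(k - 2):
        cols.append(d(j) - dk1)
    return np.column_stack(cols)


class GamLite(RegressorMixin, BaseEstimator):
    """Additive spline model: each predictor in a natural-cubic basis, ridge fit.

    Parameters
    ----------
    n_interior_knots : int, default 5
        Interior knots per predictor, placed at quantiles; two boundary
        knots sit at the 1st and 99th percentiles.
    alpha : float, default 1.0
        Ridge penalty on the (standardized) basis coefficients.
    """

    def __init__(self, n_interior_knots: int = 5, alpha: float = 1.0):
        self.n_interior_knots = n_interior_knots
        self.alpha = alpha

    def _basis(self, X: np.ndarray) -> np.ndarray:
        blocks = [_natural_spline_basis(X[:, j], self.knots_[j])
                  for j in range(X.shape[1])]
        return np.column_stack(blocks)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        qs = np.linspace(0.01, 0.99, self.n_interior_knots + 2)
        self.knots_ = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
        for j, kn in enumerate(self.knots_):
            if len(kn) < 3:
                raise ValueError(f"predictor {j} has too few distinct values "
                                 "for a spline basis")
        basis = self._basis(X)
        if len(y) <= basis.shape[1]:
            raise ValueError("fewer rows than basis dimension")
        self.center_ = basis.mean(axis=0)
        scale = basis.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        z = (basis - self.center_) / self.scale_
        self.ridge_ = Ridge(alpha=self.alpha).fit(z, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "ridge_")
        X = check_array(X)
        z = (self._basis(X) - self.center_) / self.scale_
        return self.ridge_.predict(z)


def _subject_folds(subjects: np.ndarray, k: int, rng: np.random.Generator):
    """Deterministic subject-level fold assignment: subject -> fold id."""
    uniq = np.unique(subjects)
    perm = rng.permutation(len(uniq))
    fold_of = {s: perm[i] % k for i, s in enumerate(uniq)}
    return np.asarray([fold_of[s] for s in subjects])


def cross_validate_estimator(rows: pd.DataFrame, estimator, k_folds: int = 5,
                             seed: int = 0, predictors=CORE_PREDICTORS
                             ) -> EvaluationResult:
    """Subject-level k-fold CV; pooled out-of-fold agreement metrics.

    Folds are assigned per subject (never splitting a subject's repeated
    pairs across folds) from a seeded permutation, so the same seed yields
    the same assignment and metrics.
    """
    rng = np.random.default_rng(seed)
    folds = _subject_folds(rows["subject_id"].to_numpy(), k_folds, rng)
    X = rows[list(predictors)].to_numpy(dtype=float)
    y = rows["hba1c"].to_numpy(dtype=float)
    pred = np.full(len(y), np.nan)
    for f in range(k_folds):
        test = folds == f
        if not test.any() or test.all():
            continue
        est = estimator.__class__(**estimator.get_params())
        est.fit(X[~test], y[~test])
        pred[test] = est.predict(X[test])
    ok = ~np.isnan(pred)
    return evaluate(pred[ok], y[ok])


def fit_gam_lite(rows: pd.DataFrame, k_folds: int = 5, seed: int = 0,
                 alphas=(0.01, 0.1, 1.0, 10.0, 100.0),
                 predictors=CORE_PREDICTORS) -> EvaluationResult:
    """Cross-validated GAM-lite agreement with observed HbA1c.

    The ridge penalty is chosen per outer fold by an inner 3-fold
    subject-level CV over ``alphas`` (lowest mean squared error); the
    returned metrics pool the outer out-of-fold predictions. Deterministic
    given the seed.
    """
    if len(rows) < 50:
        raise ValueError("fit_gam_lite requires at least 50 rows")
    rng = np.random.default_rng(seed)
    folds = _subject_folds(rows["subject_id"].to_numpy(), k_folds, rng)
    X = rows[list(predictors)].to_numpy(dtype=float)
    y = rows["hba1c"].to_numpy(dtype=float)
    subjects = rows["subject_id"].to_numpy()
    pred = np.full(len(y), np.nan)
    for f in range(k_folds):
        test = folds == f
        if not test.any() or test.all():
            continue
        x_tr, y_tr, s_tr = X[~test], y[~test], subjects[~test]
        inner = _subject_folds(s_tr, 3, np.random.default_rng(seed + 1000 + f))
        best_alpha, best_mse = alphas[0], np.inf
        for a in alphas:
            errs = []
            for g in range(3):
                itest = inner == g
                if not itest.any() or itest.all():
                    continue
                gam = GamLite(alpha=a).fit(x_tr[~itest], y_tr[~itest])
                errs.append(np.mean((gam.predict(x_tr[itest]) - y_tr[itest]) ** 2))
            mse = float(np.mean(errs)) if errs else np.inf
            if mse < best_mse:
                best_alpha, best_mse = a, mse
        gam = GamLite(alpha=best_alpha).fit(x_tr, y_tr)
        pred[test] = gam.predict(X[test])
    ok = ~np.isnan(pred)
    return evaluate(pred[ok], y[ok])
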