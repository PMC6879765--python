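"""Propensity-score matching weights for sex-comparison analyses.

Observed covariates (age, race, smoking, tumour stage) are not identically
distributed between male and female patients, so raw sex comparisons are
confounded. A logistic model of sex on the covariates yields each patient's
propensity e = P(male | covariates); the *matching weight*

    w = min(e, 1 - e) / e          for males,
    w = min(e, 1 - e) / (1 - e)    for females

emulates 1:1 propensity matching while keeping every subject: w <= 1 always,
with equality exactly at e = 0.5.

Balance is checked with the standardized mean difference (SMD) of each design
column between sexes after weighting, against the conventional |SMD| < 0.1.
If any covariate remains unbalanced, the model is enriched (squared terms and
pairwise interactions involving the offending covariates) and refit, up to
``max_iter`` rounds; failure to balance is flagged, never silent.

Models are fit within each cancer type separately by default, since covariate
mixes differ radically across cancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PropensityWeighter",
    "SeparationError",
    "fit_propensity",
    "matching_weights",
    "smd",
    "balance_loop",
]

DEFAULT_COVARIATES = ("age", "race", "smoking", "stage")
BALANCE_THRESHOLD = 0.1


class SeparationError(RuntimeError):
    """The logistic model separates the sexes perfectly."""


def matching_weights(e: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Matching weight per patient from propensity e = P(male)."""
    e = np.asarray(e, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    sex = np.asarray(sex)
    num = np.minimum(e, 1 - e)
    return np.where(sex == "male", num / e, num / (1 - e))


def smd(x: np.ndarray, male_mask: np.ndarray, weights=None) -> float:
    """Standardized mean difference (male − female) of one design column.

    Means are weighted; the pooling SD is always the unweighted one, so the
    before/after comparison shares a denominator. Zero pooled SD (constant
    column) is defined as SMD 0.
    """
    x = np.asarray(x, dtype=float)
    male_mask = np.asarray(male_mask, dtype=bool)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    xm, wm = x[male_mask], w[male_mask]
    xf, wf = x[~male_mask], w[~male_mask]
    if len(xm) == 0 or len(xf) == 0:
        raise ValueError("both sexes must be present")
    var_m = xm.var(ddof=1) if len(xm) > 1 else 0.0
    var_f = xf.var(ddof=1) if len(xf) > 1 else 0.0
    pooled = np.sqrt((var_m + var_f) / 2)
    if pooled == 0:
        return 0.0
    return (np.average(xm, weights=wm) - np.average(xf, weights=wf)) / pooled


def _design_matrix(
    clinical: pd.DataFrame, covariates
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix: age median-imputed, categoricals one-hot with an
    explicit 'missing' level. Returns (X, {covariate: [its columns]})."""
    cols: dict[str, list[str]] = {}
    pieces = []
    for cov in covariates:
        s = clinical[cov]
        if pd.api.types.is_numeric_dtype(s):
            filled = s.fillna(s.median())
            if filled.isna().all():
                continue  # covariate entirely absent
            pieces.append(filled.rename(cov).astype(float).to_frame())
            cols[cov] = [cov]
        else:
            cat = s.astype("string").fillna("missing")
            dummies = pd.get_dummies(cat, prefix=cov, drop_first=True).astype(float)
            if dummies.shape[1] == 0:
                continue
            pieces.append(dummies)
            cols[cov] = list(dummies.columns)
    if not pieces:
        raise ValueError("no usable covariates")
    X = pd.concat(pieces, axis=1)
    return X, cols


def _enrich(X: pd.DataFrame, cols: dict[str, list[str]], unbalanced: set[str]) -> pd.DataFrame:
    """Add squares of unbalanced numeric columns and pairwise interactions
    involving the unbalanced covariates."""
    X = X.copy()
    bad_cols = [c for cov in unbalanced for c in cols[cov]]
    for c in bad_cols:
        if X[c].nunique() > 2:  # squaring a 0/1 dummy adds nothing
            name = f"{c}^2"
            if name not in X:
                X[name] = X[c] ** 2
    base = [c for cs in cols.values() for c in cs]
    for c in bad_cols:
        for other in base:
            if other == c:
                continue
            name = f"{min(c, other)}*{max(c, other)}"
            if name not in X:
                X[name] = X[c] * X[other]
    return X


class PropensityWeighter(BaseEstimator):
    """Estimator computing sex-propensity matching weights with a balance loop.

    Parameters
    ----------
    covariates : tuple of str
        Clinical columns to balance.
    balance_threshold : float
        |SMD| below which a design column counts as balanced.
    max_iter : int
        Maximum model-enrichment rounds.
    per_cancer : bool
        Fit a separate model within each cancer type.

    Attributes (after ``fit``)
    --------------------------
    propensity_ : pd.Series        e = P(male) per patient_id
    weights_ : pd.Series           matching weight per patient_id
    iteration_ : int               rounds used (max over cancers)
    balance_report_ : pd.DataFrame covariate-level SMD before/after + flag
    converged_ : bool              all covariates balanced everywhere
    """

    def __init__(
        self,
        covariates=DEFAULT_COVARIATES,
        balance_threshold: float = BALANCE_THRESHOLD,
        max_iter: int = 5,
        per_cancer: bool = True,
    ):
        self.covariates = covariates
        self.balance_threshold = balance_threshold
        self.max_iter = max_iter
        self.per_cancer = per_cancer

    def fit(self, clinical: pd.DataFrame, y=None):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        groups = (
            clinical.groupby("cancer_type")
            if self.per_cancer
            else [("all", clinical)]
        )
        prop, wts, reports = [], [], []
        self.iteration_ = 0
        self.converged_ = True
        for cancer, sub in groups:
            e, w, report, n_iter, ok = self._fit_one(sub.reset_index(drop=True))
            report.insert(0, "cancer_type", cancer)
            prop.append(e)
            wts.append(w)
            reports.append(report)
            self.iteration_ = max(self.iteration_, n_iter)
            self.converged_ &= ok
        self.propensity_ = pd.concat(prop)
        self.weights_ = pd.concat(wts)
        self.balance_report_ = pd.concat(reports, ignore_index=True)
        return self

    def transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        """Return the fitted per-patient weights aligned to ``clinical``."""
        out = clinical[["patient_id", "sex", "cancer_type"]].copy()
        out["e"] = self.propensity_.reindex(out["patient_id"]).to_numpy()
        out["w"] = self.weights_.reindex(out["patient_id"]).to_numpy()
        out["iteration"] = self.iteration_
        return out

    fit_transform = None  # weights are only defined for the fitted cohort

    def _fit_one(self, clinical: pd.DataFrame):
        sexes = set(clinical["sex"])
        if not {"female", "male"} <= sexes:
            raise ValueError("both sexes required to fit a propensity model")
        if clinical["sex"].value_counts().min() < 2:
            raise ValueError("need at least two patients per sex")
        male = (clinical["sex"] == "male").to_numpy()
        X0, cols = _design_matrix(clinical, self.covariates)
        X = X0

        before = {
            cov: max(
                abs(smd(X0[c].to_numpy(), male)) for c in cs
            )
            for cov, cs in cols.items()
        }

        e = w = None
        after = dict(before)
        for n_iter in range(1, self.max_iter + 1):
            e = _fit_logistic(X.to_numpy(), male)
            w = matching_weights(e, clinical["sex"].to_numpy())
            after = {
                cov: max(abs(smd(X0[c].to_numpy(), male, w)) for c in cs)
                for cov, cs in cols.items()
            }
            unbalanced = {
                cov for cov, v in after.items() if v >= self.balance_threshold
            }
            if not unbalanced:
                break
            if n_iter < self.max_iter:
                X = _enrich(X, cols, unbalanced)
        ok = all(v < self.balance_threshold for v in after.values())

        ids = clinical["patient_id"]
        report = pd.DataFrame(
            {
                "covariate": list(cols),
                "smd_before": [before[c] for c in cols],
                "smd_after": [after[c] for c in cols],
                "balanced": [after[c] < self.balance_threshold for c in cols],
            }
        )
        return (
            pd.Series(e, index=ids, name="e"),
            pd.Series(w, index=ids, name="w"),
            report,
            n_iter,
            ok,
        )


def _fit_logistic(X: np.ndarray, male: np.ndarray) -> np.ndarray:
    # standardize for conditioning; C large enough that the ridge is inert
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    model.fit((X - mu) / sd, male.astype(int))
    e = model.predict_proba((X - mu) / sd)[:, 1]
    extreme = (e < 5e-3) | (e > 1 - 5e-3)
    if extreme.all():
        raise SeparationError(
            "complete separation: the covariates perfectly predict sex; "
            "remove the offending covariate from the model"
        )
    return np.clip(e, 1e-8, 1 - 1e-8)


def fit_propensity(clinical: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.Series:
    """One-round propensity fit (no balance loop): e = P(male) per patient."""
    pw = PropensityWeighter(covariates=covariates, max_iter=1).fit(clinical)
    return pw.propensity_


def balance_loop(
    clinical: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    max_iter: int = 5,
    per_cancer: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full weighting-and-balance-checking loop.

    Returns ``(weights, balance_report)``: weights has columns patient_id, sex,
    cancer_type, e, w, iteration.
    """
    pw = PropensityWeighter(
        covariates=covariates, max_iter=max_iter, per_cancer=per_cancer
    ).fit(clinical)
    return pw.transform(clinical), pw.balance_report_
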