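"""Phenotype/FACS dimension reduction and covariate-adjusted aging models.

All regressions are ordinary least squares with classical standard errors
(statsmodels under the hood); phenotype and cell-composition feature tables
are reduced to principal components fitted on the training sample and
applied, frozen, to everyone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "FeaturePCA",
    "pca_reduce",
    "RegressionFit",
    "ols",
    "attenuation",
    "cr_effect",
    "cr_interaction",
    "cr_duration_residual",
    "kruskal_wallis",
]


class FeaturePCA(TransformerMixin, BaseEstimator):
    """PCA of a feature table fitted on training samples only.

    Features are z-scored with training means/sds (zero-sd features dropped
    with a warning); PC1 is oriented toward positive correlation with a
    training reference vector (chronological age) when one is supplied; the
    transform standardises each returned score to unit variance in the
    transformed sample, matching the reporting convention of coefficients
    "per 1 s.d.".
    """

    def __init__(self, n_components: int = 3, standardize_scores: bool = True):
        self.n_components = n_components
        self.standardize_scores = standardize_scores

    def fit(self, X: pd.DataFrame, y=None) -> "FeaturePCA":
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance features", int((~keep).sum()))
        self.feature_names_ = list(X.columns[keep])
        self.mean_ = mean[keep].to_numpy()
        self.sd_ = sd[keep].to_numpy()
        Z = (X.loc[:, self.feature_names_].to_numpy() - self.mean_) / self.sd_
        k = min(self.n_components, Z.shape[0] - 1, Z.shape[1])
        _, _, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        self.loadings_ = Vt[:k].T
        self.orientation_ = np.ones(k)
        if y is not None:
            y = np.asarray(y, dtype=float)
            scores = Z @ self.loadings_
            for j in range(k):
                if np.corrcoef(scores[:, j], y)[0, 1] < 0:
                    self.orientation_[j] = -1.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        Z = (X.loc[:, self.feature_names_].to_numpy() - self.mean_) / self.sd_
        S = (Z @ self.loadings_) * self.orientation_
        if self.standardize_scores:
            sd = S.std(axis=0, ddof=0)
            S = S / np.where(sd > 0, sd, 1.0)
        cols = [f"PC{j + 1}" for j in range(S.shape[1])]
        return pd.DataFrame(S, index=X.index, columns=cols)


def pca_reduce(features: pd.DataFrame, train_ids, n_pcs: int = 3,
               train_ages=None) -> pd.DataFrame:
    """Training-sample PCA of a feature table applied to all samples."""
    est = FeaturePCA(n_components=n_pcs)
    est.fit(features.loc[list(train_ids)], y=train_ages)
    return est.transform(features)


class RegressionFit:
    """OLS output: coefficients, classical SEs, t statistics, p-values."""

    def __init__(self, result, terms):
        self._result = result
        self.terms = pd.Series(result.params.to_numpy(), index=terms)
        self.se = pd.Series(result.bse.to_numpy(), index=terms)
        self.t = pd.Series(result.tvalues.to_numpy(), index=terms)
        self.p = pd.Series(result.pvalues.to_numpy(), index=terms)
        self.n = int(result.nobs)
        self.residuals = np.asarray(result.resid)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.terms, "se": self.se,
                             "t": self.t, "p": self.p})

    def __repr__(self) -> str:
        return f"RegressionFit(n={self.n})\n{self.summary_frame()}"


def ols(y, design: pd.DataFrame, add_intercept: bool = True) -> RegressionFit:
    """Closed-form least squares with classical standard errors.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    design = pd.DataFrame(design).astype(float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(design, has_constant="add") if add_intercept else design
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        dep = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"design is rank deficient; collinear terms: {dep}")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than terms")
    result = sm.OLS(y, X).fit()
    return RegressionFit(result, list(X.columns))


def attenuation(b_before: float, b_after: float) -> float:
    """Percent attenuation of a coefficient after adding covariates:
    ``100 * (b_before - b_after) / b_before``."""
    if b_before == 0:
        raise ZeroDivisionError("b_before must be nonzero")
    return 100.0 * (b_before - b_after) / b_before


def _check_diet(diet) -> np.ndarray:
    diet = np.asarray(diet)
    cr = (diet == "CR").astype(float) if diet.dtype.kind in "OU" else diet.astype(float)
    if len(np.unique(cr)) < 2:
        raise ValueError("both diet groups (AL and CR) must be present")
    return cr


def cr_effect(dnam_age, age, diet) -> RegressionFit:
    """Age-adjusted effect of caloric restriction on DNAmAge (months)."""
    cr = _check_diet(diet)
    design = pd.DataFrame({"age": np.asarray(age, float), "CR": cr})
    return ols(dnam_age, design)


def cr_interaction(dnam_age, age, diet) -> RegressionFit:
    """Adds an age x CR product term to the CR model."""
    cr = _check_diet(diet)
    age = np.asarray(age, float)
    design = pd.DataFrame({"age": age, "CR": cr, "age_x_CR": age * cr})
    return ols(dnam_age, design)


def cr_duration_residual(dnam_age, age, diet, duration):
    """Correlation of CR animals' age residuals with time on diet.

    The age model is fitted on control (AL) animals only, applied to CR
    animals; residual = observed - predicted DNAmAge.  Returns (Pearson r,
    two-sided p).
    """
    dnam_age = np.asarray(dnam_age, float)
    age = np.asarray(age, float)
    duration = np.asarray(duration, float)
    is_cr = np.asarray(diet) == "CR" if np.asarray(diet).dtype.kind in "OU" \
        else np.asarray(diet).astype(bool)
    if (~is_cr).sum() < 3 or is_cr.sum() < 3:
        raise ValueError("need at least 3 control and 3 CR animals")
    fit = ols(dnam_age[~is_cr], pd.DataFrame({"age": age[~is_cr]}))
    predicted = fit.terms["const"] + fit.terms["age"] * age[is_cr]
    resid = dnam_age[is_cr] - predicted
    dur = duration[is_cr]
    if np.ptp(dur) == 0:
        raise ValueError("CR durations are all equal: correlation undefined")
    r, p = scipy.stats.pearsonr(resid, dur)
    return float(r), float(p)


def kruskal_wallis(values, groups):
    """Rank-based H test across groups (tie-corrected, chi-square p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)
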