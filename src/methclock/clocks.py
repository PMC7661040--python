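"""DNA-methylation age clocks.

Two estimators are provided, both in months:

* :class:`PCClock` — the unsupervised clock: principal component analysis of
  the training beta matrix (centred, unscaled), followed by an ordinary
  least-squares rescaling of the selected component scores onto chronological
  age.  With a single component the prediction is an affine function of the
  PC1 score, ``age_hat = intercept + slope * score``; applied to new samples
  the training means and loadings are frozen (never re-centred).

* :class:`ElasticNetClock` — the supervised clock: elastic-net penalised
  regression of age on CpG beta values, with the penalty chosen by K-fold
  cross-validation on a logarithmic grid; the fitted weights are sparse.

Model evaluation uses the biweight midcorrelation (:func:`bicor`), a robust
correlation built from Tukey biweights around the medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .matrix import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "split_by_age",
    "bicor",
    "PCAModel",
    "fit_pca",
    "PCClock",
    "fit_pc_clock",
    "select_components_cv",
    "ElasticNetClock",
    "fit_enet_clock",
    "predict_age",
]

DEFAULT_TEST_AGES = frozenset({2, 6, 10, 14, 18, 22, 26})


# --------------------------------------------------------------------- split
@dataclass(frozen=True)
class SplitPlan:
    test_ages: frozenset
    train_ids: tuple
    test_ids: tuple


def split_by_age(samples: pd.DataFrame, test_ages=DEFAULT_TEST_AGES) -> SplitPlan:
    """Deterministic age-stratified split: a sample is in test iff its age is
    one of ``test_ages`` (default 2, 6, 10, 14, 18, 22, 26 months)."""
    test_ages = frozenset(test_ages)
    if samples["age_months"].isna().any():
        raise ValueError("all samples need an age")
    ids = samples["sample_id"] if "sample_id" in samples.columns \
        else samples.index.to_series()
    in_test = samples["age_months"].isin(test_ages)
    test_ids = tuple(ids[in_test.to_numpy()])
    train_ids = tuple(ids[~in_test.to_numpy()])
    if not train_ids or not test_ids:
        raise ValueError(
            f"degenerate split: {len(train_ids)} train / {len(test_ids)} test samples"
        )
    logger.info("age split: %d train, %d test", len(train_ids), len(test_ids))
    return SplitPlan(test_ages=test_ages, train_ids=train_ids, test_ids=test_ids)


# --------------------------------------------------------------------- bicor
def bicor(x, y) -> float:
    """Biweight midcorrelation.

    Weights are Tukey biweights ``w_i = (1 - u_i^2)^2`` for ``|u_i| < 1`` (else
    0) with ``u_i = (x_i - median(x)) / (9 * MAD(x))``.  If either vector has
    zero MAD the function falls back to the Pearson correlation (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")

    def _weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    xt, yt = _weighted(x), _weighted(y)
    if xt is None or yt is None:
        logger.info("bicor: zero MAD, falling back to Pearson")
        return float(np.corrcoef(x, y)[0, 1])
    return float(np.sum(xt * yt) / np.sqrt(np.sum(xt**2) * np.sum(yt**2)))


# ----------------------------------------------------------------------- PCA
@dataclass
class PCAModel:
    """Centred, unscaled PCA of a training beta matrix (n_train << n_sites)."""

    sites: pd.Index
    means: np.ndarray          # (p,)
    loadings: np.ndarray       # (p, k), orthonormal columns
    var_fraction: np.ndarray   # (k,)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Project samples x sites data using the frozen training means."""
        X = np.asarray(X, dtype=float)
        return (X - self.means) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int | None = None, sites=None) -> PCAModel:
    """PCA by economy SVD of the centred samples x sites matrix.

    Centres by training means only — beta values share a common [0, 1] scale,
    so no per-site variance scaling is applied.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    means = X.mean(axis=0)
    Xc = X - means
    total_var = float((Xc**2).sum())
    if total_var == 0:
        raise ValueError("constant matrix: PCA undefined")
    max_k = min(n - 1, p)
    k = max_k if n_components is None else min(n_components, max_k)
    # economy SVD: loadings are right singular vectors (p x k)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:k].T
    var_fraction = (s[:k] ** 2) / total_var
    if sites is None:
        sites = pd.RangeIndex(p)
    return PCAModel(sites=pd.Index(sites), means=means, loadings=loadings, var_fraction=var_fraction)


# ------------------------------------------------------------------- PCClock
class PCClock(RegressorMixin, BaseEstimator):
    """PCA-based DNAmAge: affine rescaling of selected PC scores onto months.

    Parameters
    ----------
    components : tuple of 1-based component indices to regress age on
        (default ``(1,)`` — PC1 alone).
    n_components : components to retain in the PCA (default: all available).

    Attributes (fitted)
    -------------------
    pca_ : the underlying :class:`PCAModel`.
    orientation_ : per-component sign chosen so each training score correlates
        non-negatively with age.
    slope_, intercept_ : months per oriented score unit and months.  With
        centred scores the intercept equals the mean training age.
    """

    def __init__(self, components: tuple = (1,), n_components: int | None = None):
        self.components = components
        self.n_components = n_components

    # X: samples x sites (ndarray or BetaMatrix)
    def fit(self, X, y, sites=None) -> "PCClock":
        if isinstance(X, BetaMatrix):
            sites = X.site_ids
            X = X.X
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("clock training requires a complete (imputed) matrix")
        comp = tuple(self.components)
        if min(comp) < 1:
            raise ValueError("components are 1-based")
        self.pca_ = fit_pca(X, n_components=max(max(comp), self.n_components or 0), sites=sites)
        scores = self.pca_.scores(X)[:, [c - 1 for c in comp]]
        if np.any(scores.std(axis=0) == 0):
            raise ValueError("zero-variance component score")
        # orient each included component toward positive age correlation
        corr = np.array([np.corrcoef(scores[:, i], y)[0, 1] for i in range(scores.shape[1])])
        self.orientation_ = np.where(corr < 0, -1.0, 1.0)
        S = scores * self.orientation_
        design = np.column_stack([np.ones(len(y)), S])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.slope_ = coef[1:]
        self.components_ = comp
        self.sites_ = self.pca_.sites
        self.n_features_in_ = X.shape[1]
        return self

    def transform_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        if isinstance(X, BetaMatrix):
            X = _align(X, self.sites_)
        S = self.pca_.scores(np.asarray(X, dtype=float))
        return S[:, [c - 1 for c in self.components_]] * self.orientation_

    def predict(self, X) -> np.ndarray:
        S = self.transform_scores(X)
        return self.intercept_ + S @ self.slope_


def fit_pc_clock(X, ages, components=(1,), sites=None) -> PCClock:
    """Functional wrapper: fit a :class:`PCClock` on training data."""
    return PCClock(components=components).fit(X, ages, sites=sites)


def select_components_cv(X, ages, folds: int = 10, max_k: int = 10, random_state: int = 0) -> int:
    """Choose how many leading PCs to include by K-fold cross-validation.

    Evaluates cumulative sets {1}, {1,2}, ..., {1..max_k} by CV mean squared
    error of the OLS rescaling and returns the smallest k whose CV MSE is
    within one standard error of the minimum (parsimony rule).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if isinstance(X, BetaMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    max_k = min(max_k, min(X.shape[0] - 2, X.shape[1]))
    kf = KFold(n_splits=folds, shuffle=True, random_state=random_state)
    mse = np.zeros((max_k, folds))
    for f, (tr, te) in enumerate(kf.split(X)):
        pca = fit_pca(X[tr], n_components=max_k)
        s_tr, s_te = pca.scores(X[tr]), pca.scores(X[te])
        for k in range(1, max_k + 1):
            d_tr = np.column_stack([np.ones(len(tr)), s_tr[:, :k]])
            coef, *_ = np.linalg.lstsq(d_tr, ages[tr], rcond=None)
            pred = np.column_stack([np.ones(len(te)), s_te[:, :k]]) @ coef
            mse[k - 1, f] = float(np.mean((pred - ages[te]) ** 2))
    mean_mse = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se[best]
    return int(np.flatnonzero(mean_mse <= threshold)[0]) + 1


# ------------------------------------------------------------ elastic net
class ElasticNetClock(RegressorMixin, BaseEstimator):
    """Sparse CpG clock: elastic-net regression of age on beta values.

    Predictors are standardised internally; the penalty is chosen by K-fold
    CV (minimum-MSE rule) over ``n_alphas`` log-spaced values; returned
    weights are on the original beta scale.
    """

    def __init__(self, alpha_mix: float = 0.5, folds: int = 10, n_alphas: int = 100,
                 alphas=None, random_state: int = 0):
        self.alpha_mix = alpha_mix
        self.folds = folds
        self.n_alphas = n_alphas
        self.alphas = alphas  # explicit penalty grid (overrides n_alphas)
        self.random_state = random_state

    def _alpha_grid(self, Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Logarithmic penalty grid from the largest useful penalty down."""
        n = len(y)
        alpha_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * max(self.alpha_mix, 1e-3))
        return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3),
                           self.n_alphas)

    def fit(self, X, y, sites=None) -> "ElasticNetClock":
        if isinstance(X, BetaMatrix):
            sites = X.site_ids
            X = X.X
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("clock training requires a complete (imputed) matrix")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - mean) / sd_safe
        cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.random_state)
        grid = self.alphas if self.alphas is not None \
            else self._alpha_grid(Xs, y)
        model = ElasticNetCV(
            l1_ratio=self.alpha_mix, alphas=grid, cv=cv, max_iter=50_000,
        )
        model.fit(Xs, y)
        w_std = model.coef_
        self.coef_ = np.where(sd > 0, w_std / sd_safe, 0.0)
        self.intercept_ = float(model.intercept_ - np.sum(w_std * mean / sd_safe))
        self.lambda_ = float(model.alpha_)
        self.support_ = np.flatnonzero(self.coef_)
        self.sites_ = pd.Index(sites) if sites is not None else pd.RangeIndex(X.shape[1])
        self.n_features_in_ = X.shape[1]
        logger.info("elastic net clock: %d of %d sites selected", len(self.support_), X.shape[1])
        return self

    @property
    def weights_(self) -> pd.Series:
        """Sparse CpG -> coefficient map (selected sites only)."""
        check_is_fitted(self, "coef_")
        return pd.Series(self.coef_[self.support_], index=self.sites_[self.support_])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, BetaMatrix):
            X = _align(X, self.sites_)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def fit_enet_clock(X, ages, alpha_mix: float = 0.5, folds: int = 10, sites=None) -> ElasticNetClock:
    return ElasticNetClock(alpha_mix=alpha_mix, folds=folds).fit(X, ages, sites=sites)


# ------------------------------------------------------------------- predict
def _align(matrix: BetaMatrix, sites: pd.Index) -> np.ndarray:
    idx = matrix.site_ids.get_indexer(sites)
    if (idx < 0).any():
        missing = list(sites[idx < 0][:10])
        raise KeyError(f"matrix lacks {int((idx < 0).sum())} clock sites, e.g. {missing}")
    return matrix.values[idx].T


def predict_age(clock, matrix: BetaMatrix) -> pd.Series:
    """Apply a fitted clock to a beta matrix, aligning sites by id."""
    pred = clock.predict(matrix)
    return pd.Series(pred, index=matrix.samples, name="dnam_age_months")
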