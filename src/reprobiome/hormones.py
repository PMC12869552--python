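"""Fecal steroid hormone processing.

Fecal estrogen (fE), progesterone (fP), and glucocorticoid (fGC)
metabolite concentrations (ng/g dry feces) degrade with time in storage.
Each hormone is natural-log transformed and regressed on the two storage
covariates (days from collection to extraction, days from extraction to
assay); the mean-centered residuals are the storage-corrected hormone
values used downstream.  The module also provides global z-scoring, a
Brown-Forsythe test of variance heterogeneity across reproductive
states, and variance inflation factors for design-matrix diagnostics.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["HormoneResidualizer", "residualize", "standardize",
           "state_variance_test", "vif", "HORMONES"]

HORMONES = ("fE", "fP", "fGC")
STORAGE_COVARIATES = ("days_to_extraction", "days_to_assay")


class HormoneResidualizer(BaseEstimator, TransformerMixin):
    """Storage-time correction for one fecal hormone.

    ``fit`` runs OLS of log concentration on days-to-extraction and
    days-to-assay; ``transform`` returns mean-centered residuals.  The
    model is fitted once on the full analysis set (before any
    subsetting) so residuals are comparable across states.

    Attributes
    ----------
    params_ : Series of fitted coefficients (const + storage slopes).
    dropped_covariate_ : name of a storage covariate removed because it
        was collinear/constant, else None.
    """

    def __init__(self, hormone: str = "fE"):
        self.hormone = hormone

    def _design(self, X: pd.DataFrame, covs) -> pd.DataFrame:
        return sm.add_constant(X[list(covs)].astype(float), has_constant="add")

    def fit(self, X: pd.DataFrame, y=None):
        conc = X[self.hormone].astype(float)
        if len(conc) < 3:
            raise ValueError("need at least 3 records to residualize")
        bad = conc <= 0
        if bad.any():
            ids = list(X.index[bad])[:10]
            raise ValueError(
                f"non-positive {self.hormone} concentrations for samples "
                f"{ids}; log transform requires > 0")
        covs = list(STORAGE_COVARIATES)
        self.dropped_covariate_ = None
        exog = self._design(X, covs)
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            # collinear or constant storage covariates: drop the one with
            # the lesser spread and fall back to a single-covariate fit
            spread = X[covs].std()
            drop = spread.idxmin()
            covs.remove(drop)
            self.dropped_covariate_ = drop
            warnings.warn(f"storage covariates collinear; dropped {drop}")
            exog = self._design(X, covs)
        self.covariates_ = covs
        self.model_ = sm.OLS(np.log(conc), exog).fit()
        self.params_ = self.model_.params
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "model_")
        conc = X[self.hormone].astype(float)
        pred = self.model_.predict(self._design(X, self.covariates_))
        resid = np.log(conc) - pred
        resid = resid - resid.mean()   # explicit global mean-centering
        return resid.rename(f"{self.hormone}_resid")


def residualize(records: pd.DataFrame, hormone: str) -> pd.Series:
    """Storage-corrected, mean-centered log hormone values (full-set fit)."""
    est = HormoneResidualizer(hormone).fit(records)
    return est.fit_transform(records)


def standardize(values) -> pd.Series | np.ndarray:
    """Z-score over the full analysis set, sample SD (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or undefined variance; cannot standardize")
    z = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index, name=values.name)
    return z


def state_variance_test(residuals: pd.Series, states: pd.Series,
                        min_n: int = 2) -> pd.DataFrame:
    """Pairwise Brown-Forsythe (median-centered Levene) variance tests.

    One row per state pair with each state's variance, the F statistic,
    p, and a Bonferroni-corrected q across the pairwise contrasts.
    States with fewer than ``min_n`` samples are skipped with a warning.
    """
    groups = {}
    for s, vals in residuals.groupby(states):
        if len(vals) < min_n:
            warnings.warn(f"state {s!r} has {len(vals)} < {min_n} samples; "
                          "skipped")
            continue
        groups[s] = vals.to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least two states with enough samples")
    rows = []
    pairs = list(combinations(sorted(groups), 2))
    for a, b in pairs:
        F, p = stats.levene(groups[a], groups[b], center="median")
        rows.append({"state_a": a, "state_b": b,
                     "var_a": groups[a].var(ddof=1),
                     "var_b": groups[b].var(ddof=1),
                     "F": F, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_k).

    Rank-deficient designs yield ``inf`` for the involved columns.
    An intercept is added internally so centering does not distort R^2.
    """
    X = design.astype(float)
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
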