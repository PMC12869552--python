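"""Non-reproductive covariates: group-level diet and rainfall.

Diet is estimated at the social-group level from 10-minute focal feeding
observations grouped into 14 food categories.  Feeding records within a
focal sample are autocorrelated, so the proportion estimate repeatedly
subsamples one feeding record per focal and averages the resulting
category proportions.  Rainfall is summed over the 30 days before each
sample.  Windows are half-open ``(date - window, date]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["DietProfile", "diet_proportions", "diet_shannon",
           "DietPCA", "diet_pca", "rainfall_window", "FOOD_CATEGORIES"]

FOOD_CATEGORIES = (
    "grass_blades", "grass_seed_heads", "grass_corms", "tree_leaves",
    "tree_seeds", "tree_pods", "fruit", "blossoms", "roots_tubers",
    "shrub_leaves", "shrub_berries", "invertebrates", "vertebrates",
    "other",
)


@dataclass
class DietProfile:
    """Group-level diet in the 30 days before one fecal sample."""

    sample_id: str
    proportions: pd.Series      # over food categories, sums to 1
    n_focals: int
    missing: bool = False


def diet_proportions(focals: pd.DataFrame, group, date,
                     categories=FOOD_CATEGORIES, window: int = 30,
                     min_focals: int = 15, n_subsets: int = 1000,
                     rng=None, sample_id: str = "") -> DietProfile:
    """Estimate diet proportions for one (group, date) pair.

    ``focals`` needs columns focal_id, group, date, food_category; dates
    are integer study days.  For each of ``n_subsets`` draws, one feeding
    record is sampled per focal in the group's prior 30-day window and
    category proportions are averaged across draws.  Profiles built from
    fewer than ``min_focals`` focals are marked missing.
    """
    rng = np.random.default_rng(rng)
    cats = list(categories)
    unknown = set(focals["food_category"]) - set(cats)
    if unknown:
        raise ValueError(f"unknown food categories: {sorted(unknown)}")
    date = int(date)
    win = focals[(focals["group"] == group)
                 & (focals["date"] > date - window)
                 & (focals["date"] <= date)]
    n_focals = win["focal_id"].nunique()
    if n_focals < min_focals:
        return DietProfile(sample_id, pd.Series(np.nan, index=cats),
                           n_focals, missing=True)
    cat_codes = pd.Categorical(win["food_category"], categories=cats).codes
    by_focal = [grp.to_numpy() for _, grp in
                pd.Series(cat_codes).groupby(win["focal_id"].to_numpy())]
    counts = np.zeros(len(cats))
    for codes in by_focal:
        if len(codes) == 1:
            counts[codes[0]] += n_subsets
        else:
            # one uniform feeding record per focal per subset; the subset
            # draws are iid, so their category tally is one multinomial
            probs = np.bincount(codes, minlength=len(cats)) / len(codes)
            counts += rng.multinomial(n_subsets, probs)
    props = counts / counts.sum()
    return DietProfile(sample_id, pd.Series(props, index=cats), n_focals)


def diet_shannon(profile: DietProfile | pd.Series) -> float:
    """Shannon diversity H = -sum p ln p over nonzero categories."""
    p = profile.proportions if isinstance(profile, DietProfile) else profile
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


class DietPCA(BaseEstimator):
    """PCA on the 14-category diet matrix (centered, unscaled).

    ``n_selected_`` is the smallest number of leading components whose
    cumulative explained variance exceeds ``target_variance``.
    """

    def __init__(self, target_variance: float = 0.5):
        self.target_variance = target_variance

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 diet profiles for PCA")
        self.pca_ = PCA()
        self.scores_ = self.pca_.fit_transform(X.to_numpy(dtype=float))
        self.components_ = self.pca_.components_
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        cum = np.cumsum(self.explained_variance_ratio_)
        self.n_selected_ = int(np.searchsorted(cum, self.target_variance,
                                               side="left") + 1)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, dtype=float))


def diet_pca(profiles: pd.DataFrame, target_variance: float = 0.5) -> DietPCA:
    return DietPCA(target_variance).fit(profiles)


def rainfall_window(rain: pd.DataFrame, date, window: int = 30) -> float:
    """Total rainfall (mm) over the half-open window (date-30, date].

    ``rain`` needs columns date (integer study day) and mm; missing days
    count as 0 and gaps are reported with a warning.
    """
    date = int(date)
    win = rain[(rain["date"] > date - window) & (rain["date"] <= date)]
    gaps = window - win["date"].nunique()
    if gaps > 0:
        warnings.warn(f"{gaps} day(s) missing from the rainfall window "
                      f"ending day {date}; treated as 0 mm")
    return float(win["mm"].sum())
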