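"""Mixed-model associations between the microbiota, reproductive state,
hormones, and covariates.

ASV richness and per-taxon CLR abundances are modelled with linear mixed
models: fixed effects of reproductive state (or phase), storage-corrected
hormone residuals, host age, rainfall, sequencing depth, collection-date
index and diet; random intercepts for host identity, social group and
extraction plate.  Continuous fixed effects are z-scored over the full
analysis set so effect sizes are comparable.  Per-taxon p-values are
pooled per term and Benjamini-Hochberg corrected across taxa of one
rank; taxa are flagged when q < 0.05 and |effect| > 0.4 on the CLR scale
(a ~1.5-fold change).

Model fitting delegates to statsmodels MixedLM; the three random
intercepts are expressed as host-identity groups plus variance
components for social group and plate, and p-values use the normal
approximation to the Wald statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .hormones import standardize

__all__ = ["DesignMatrix", "build_design", "RichnessMixedModel",
           "TaxonMixedModels", "fit_richness", "fit_taxa",
           "bh_adjust", "report_fraction"]

CONTINUOUS_COVARIATES = ("age", "rainfall", "depth", "collection_index",
                         "diet_shannon")
HORMONE_COLS = ("fE_resid", "fP_resid", "fGC_resid")


@dataclass
class DesignMatrix:
    """Fixed effects plus random-effect groupings, complete cases only."""

    X: pd.DataFrame                  # fixed effects (no intercept column)
    groups: pd.DataFrame             # female_id, social_group, plate
    sample_ids: pd.Series
    reference_state: str
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def frame(self) -> pd.DataFrame:
        """Single DataFrame for formula-based fitting."""
        return pd.concat([self.X, self.groups], axis=1)


def build_design(samples: pd.DataFrame,
                 state_col: str = "state",
                 reference_state: str = "CYCLING",
                 hormones: bool = True,
                 interactions: bool = False,
                 diet_pcs: int = 5) -> DesignMatrix:
    """Assemble the standardized fixed-effect design.

    ``samples`` carries one row per retained sample with the state (or
    phase) column, hormone residuals, continuous covariates, diet PC
    scores (``diet_pc1..``), and the grouping columns female_id,
    social_group, plate.  Continuous columns are z-scored over the full
    set; state indicators use reference coding; interaction columns are
    hormone z-score x state indicator.  Rows with missing values are
    dropped with a logged reason.
    """
    pc_cols = [f"diet_pc{i}" for i in range(1, diet_pcs + 1)
               if f"diet_pc{i}" in samples.columns]
    cont = [c for c in CONTINUOUS_COVARIATES if c in samples.columns] + pc_cols
    horm = [h for h in HORMONE_COLS if hormones and h in samples.columns]
    needed = [state_col, "female_id", "social_group", "plate"] + cont + horm
    missing_mask = samples[needed].isna().any(axis=1)
    if missing_mask.any():
        warnings.warn(f"dropped {int(missing_mask.sum())} sample(s) with "
                      "missing covariates")
    df = samples.loc[~missing_mask].reset_index(drop=True)

    X = pd.DataFrame(index=df.index)
    levels = [s for s in pd.unique(df[state_col]) if s != reference_state]
    for s in sorted(map(str, levels)):
        X[f"{state_col}_{s}"] = (df[state_col] == s).astype(float)
    for c in cont + horm:
        X[c] = standardize(df[c].astype(float))
    if interactions:
        for h in horm:
            for s in sorted(map(str, levels)):
                X[f"{h}:{state_col}_{s}"] = X[h] * X[f"{state_col}_{s}"]
    groups = df[["female_id", "social_group", "plate"]].astype(str)
    return DesignMatrix(X=X, groups=groups,
                        sample_ids=df["sample_id"],
                        reference_state=reference_state,
                        dropped=samples.loc[missing_mask])


_VC_FULL = {"social_group": "0 + C(social_group)", "plate": "0 + C(plate)"}


def _fit_mixedlm(y: pd.Series, design: DesignMatrix):
    """MixedLM with host random intercept + group/plate variance
    components; on failure, drop the weakest variance component and
    refit."""
    data = design.frame().copy()
    data["_y"] = np.asarray(y, dtype=float)
    data.columns = [c.replace(":", "_x_") for c in data.columns]
    fixed = [c for c in data.columns
             if c not in ("_y", "female_id", "social_group", "plate")]
    formula = "_y ~ " + " + ".join(f"Q('{c}')" for c in fixed)
    vc = dict(_VC_FULL)
    last_err = None
    while True:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                md = sm.MixedLM.from_formula(
                    formula, data, groups=data["female_id"],
                    re_formula="1", vc_formula=vc or None)
                res = md.fit(reml=True, method="lbfgs", maxiter=200)
            if np.isfinite(res.params).all():
                return res, fixed
            raise np.linalg.LinAlgError("non-finite estimates")
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            if not vc:
                raise RuntimeError(
                    f"mixed model failed even without variance components: "
                    f"{last_err}") from err
            dropped = sorted(vc)[-1]
            vc.pop(dropped)
            warnings.warn(f"singular fit; refitting without random term "
                          f"{dropped!r}")


def _tidy(res, fixed, response: str) -> pd.DataFrame:
    rows = []
    for name in ["Intercept"] + [f"Q('{c}')" for c in fixed]:
        if name not in res.params.index:
            continue
        term = (name[3:-2] if name.startswith("Q('") else name)
        term = term.replace("_x_", ":")
        rows.append({"response": response, "term": term,
                     "beta": float(res.params[name]),
                     "se": float(res.bse[name]),
                     "p": float(res.pvalues[name])})
    return pd.DataFrame(rows)


class RichnessMixedModel(BaseEstimator):
    """Linear mixed model for ASV richness.

    ``fit(design, y)`` fits richness on the fixed effects with random
    intercepts for host, social group and plate.  ``results_`` is a tidy
    frame (term, beta, se, p).
    """

    def fit(self, design: DesignMatrix, y):
        for col in design.groups.columns:
            if design.groups[col].nunique() < 2:
                warnings.warn(f"random grouping {col!r} has a single level")
        res, fixed = _fit_mixedlm(pd.Series(np.asarray(y, float)), design)
        self.model_result_ = res
        self.results_ = _tidy(res, fixed, "richness")
        self.df_method_ = "normal-approximation"
        return self

    def coef(self, term: str) -> float:
        check_is_fitted(self, "results_")
        row = self.results_.set_index("term")
        return float(row.loc[term, "beta"])


class TaxonMixedModels(BaseEstimator):
    """Per-taxon linear mixed models on CLR abundances.

    One model per taxon with the shared design; p-values are pooled per
    fixed-effect term and BH-corrected across taxa.  ``results_`` adds
    q and a significance flag (q < q_threshold and |beta| >
    effect_threshold); non-convergent taxa are recorded in ``failed_``
    and excluded from the BH family.
    """

    def __init__(self, effect_threshold: float = 0.4,
                 q_threshold: float = 0.05):
        self.effect_threshold = effect_threshold
        self.q_threshold = q_threshold

    def fit(self, design: DesignMatrix, clr: pd.DataFrame):
        tidy, failed = [], []
        for taxon in clr.columns:
            try:
                res, fixed = _fit_mixedlm(clr[taxon], design)
            except RuntimeError as err:
                failed.append({"response": taxon, "error": str(err)})
                continue
            tidy.append(_tidy(res, fixed, str(taxon)))
        if not tidy:
            raise RuntimeError("no taxon model converged")
        out = pd.concat(tidy, ignore_index=True)
        out["q"] = np.nan
        for term, idx in out.groupby("term").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
        out["significant"] = ((out["q"] < self.q_threshold)
                              & (out["beta"].abs() > self.effect_threshold)
                              & (out["term"] != "Intercept"))
        self.results_ = out
        self.failed_ = pd.DataFrame(failed)
        self.n_tested_ = clr.shape[1] - len(failed)
        return self

    def flagged(self, term: str) -> list[str]:
        check_is_fitted(self, "results_")
        r = self.results_
        return list(r.loc[(r["term"] == term) & r["significant"], "response"])


def fit_richness(design: DesignMatrix, richness) -> pd.DataFrame:
    return RichnessMixedModel().fit(design, richness).results_


def fit_taxa(clr: pd.DataFrame, design: DesignMatrix,
             effect_threshold: float = 0.4,
             q_threshold: float = 0.05) -> pd.DataFrame:
    return TaxonMixedModels(effect_threshold, q_threshold).fit(
        design, clr).results_


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def report_fraction(k: int, n: int) -> float:
    """Percent k/n rounded half-up to one decimal (e.g. 92 of 401 -> 22.9)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
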