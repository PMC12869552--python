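"""End-to-end pipeline glue: label a cohort, build the per-sample
analysis table, and run the standard analyses in one call each.

These helpers wire the module layers together in the order a full
analysis runs: state labeling and exclusions, compositional metrics,
hormone residualization, covariate attachment, then the mixed-model and
autocorrelation analyses.  They operate on the synthetic-cohort bundle
but only through its plain tabular members, so a real data set loaded
into the same frames works identically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import DesignMatrix, RichnessMixedModel, build_design
from .compositional import (aitchison_distance, asv_richness, clr_transform,
                            filter_prevalence, to_similarity)
from .config import LifeHistoryConfig
from .covariates import diet_pca, diet_proportions, diet_shannon, \
    rainfall_window
from .hormones import HORMONES, residualize
from .life_history import FilterReport, apply_exclusions, assign_labels
from .personalization import (compare_curves, enumerate_pairs,
                              similarity_curves, subset_for_personalization)

__all__ = ["label_cohort", "analysis_table", "attach_environment",
           "richness_analysis", "personalization_analysis"]


def label_cohort(cohort, config: LifeHistoryConfig | None = None
                 ) -> tuple[pd.DataFrame, FilterReport]:
    """Assign and filter state labels; social group attached for pairing."""
    labels = assign_labels(cohort.samples, cohort.timelines, config)
    labels, report = apply_exclusions(labels, config)
    labels = labels.merge(cohort.samples[["sample_id", "social_group"]],
                          on="sample_id")
    return labels, report


def analysis_table(cohort, labels: pd.DataFrame,
                   hormones: bool = True) -> pd.DataFrame:
    """Per-sample analysis frame: metadata, labels, richness, depth,
    and storage-corrected hormone residuals (fitted on the full set)."""
    df = cohort.samples.merge(
        labels[["sample_id", "state", "phase", "event_id", "day_in_state",
                "excluded", "exclusion_reason"]],
        on="sample_id")
    counts = cohort.counts.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["richness"] = asv_richness(counts).loc[df["sample_id"]].values
    df["depth"] = counts.sum(axis=1).loc[df["sample_id"]].values
    if hormones:
        keyed = df.set_index("sample_id")
        for h in HORMONES:
            df[f"{h}_resid"] = residualize(keyed, h).values
    return df


def attach_environment(df: pd.DataFrame, rainfall: pd.DataFrame,
                       focals: pd.DataFrame, n_subsets: int = 1000,
                       diet_pcs: int = 5, rng=None) -> pd.DataFrame:
    """Add 30-day rainfall, diet Shannon diversity, and diet PC scores."""
    rng = np.random.default_rng(rng)
    out = df.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["rainfall"] = [rainfall_window(rainfall, d)
                           for d in out["date"]]
        profiles = {}
        for key in zip(out["social_group"], out["date"]):
            if key not in profiles:
                profiles[key] = diet_proportions(
                    focals, key[0], key[1], n_subsets=n_subsets, rng=rng)
        profs = [profiles[k] for k in zip(out["social_group"], out["date"])]
    out["diet_shannon"] = [np.nan if p.missing else diet_shannon(p)
                           for p in profs]
    complete = [p.proportions for p in profs if not p.missing]
    if len(complete) >= 2:
        mat = pd.DataFrame(complete).reset_index(drop=True)
        est = diet_pca(mat)
        scores = np.full((len(out), diet_pcs), np.nan)
        scores[[not p.missing for p in profs], :] = est.transform(mat)[
            :, :diet_pcs]
        for i in range(diet_pcs):
            out[f"diet_pc{i + 1}"] = scores[:, i]
    return out


def richness_analysis(df: pd.DataFrame, hormones: bool = True,
                      interactions: bool = False,
                      reference_state: str = "CYCLING"
                      ) -> tuple[RichnessMixedModel, DesignMatrix]:
    """Mixed model of ASV richness on the retained samples."""
    kept = df[~df["excluded"]].reset_index(drop=True)
    design = build_design(kept, hormones=hormones,
                          interactions=interactions,
                          reference_state=reference_state)
    y = kept.set_index("sample_id").loc[design.sample_ids, "richness"]
    model = RichnessMixedModel().fit(design, y)
    return model, design


def personalization_analysis(cohort, labels: pd.DataFrame
                             ) -> dict:
    """Similarity curves and category contrasts for one cohort."""
    sub, report = subset_for_personalization(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clr = clr_transform(cohort.counts.counts)
        sim = to_similarity(aitchison_distance(clr))
        pairs = enumerate_pairs(sub, sim)
        curves = similarity_curves(pairs)
        tests = compare_curves(pairs)
    return {"subset": report, "pairs": pairs, "curves": curves,
            "tests": tests}
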