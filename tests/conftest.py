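"""Shared fixtures: one small seeded synthetic cohort, labeled and with
its compositional products, reused by the read-only tests."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from reprobiome.compositional import (aitchison_distance, asv_richness,
                                      clr_transform, to_similarity)
from reprobiome.life_history import apply_exclusions, assign_labels
from reprobiome.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(CohortParams(n_females=20, seed=11))


@pytest.fixture(scope="session")
def labeled(cohort):
    """Cohort labels (with social group attached) and filter report."""
    labels = assign_labels(cohort.samples, cohort.timelines)
    labels, report = apply_exclusions(labels)
    labels = labels.merge(cohort.samples[["sample_id", "social_group"]],
                          on="sample_id")
    return {"labels": labels, "report": report}


@pytest.fixture(scope="session")
def composition(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clr = clr_transform(cohort.counts.counts)
        dist = aitchison_distance(clr)
        sim = to_similarity(dist)
        rich = asv_richness(cohort.counts.counts)
    return {"clr": clr, "dist": dist, "sim": sim, "richness": rich}


@pytest.fixture()
def analysis_frame(cohort, labeled, composition):
    """Per-sample analysis table: labels + metadata + richness."""
    df = cohort.samples.merge(
        labeled["labels"][["sample_id", "state", "phase", "event_id",
                           "day_in_state", "excluded"]],
        on="sample_id")
    df["richness"] = composition["richness"].loc[df["sample_id"]].values
    df["depth"] = cohort.counts.counts.sum(axis=1).loc[df["sample_id"]].values
    return df
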