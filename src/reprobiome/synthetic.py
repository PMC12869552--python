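"""Seeded synthetic cohort generator.

Produces a cohort of female life histories, fecal samples, hormone
measurements, environmental covariates, and Dirichlet-multinomial
microbiome counts with the statistical structure the analysis pipeline
assumes: state durations drawn from truncated normals matching the
study population (gestation 178 +/- 6 d, cycling-to-conception
138 +/- 82 d, postpartum amenorrhea 322 +/- 87 d), state-dependent
hormone means and variances on the log scale, small linear storage-time
artifacts on raw concentrations, host-personalized taxon intensities
with Ornstein-Uhlenbeck (continuous-time AR(1)) within-host temporal
decay, a set of pregnancy-recruited taxa that raises expected richness
by a known amount, and a set of taxa with a known additive log-scale
pregnancy effect for differential-abundance recovery tests.

All randomness flows from one seed fanned out to named substreams, so
modules can be regenerated independently and runs are byte-identical
under a fixed seed.  Ground truth sufficient for every recovery metric
is exported alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import CountTable
from .life_history import FemaleTimeline, Milestone, State

__all__ = ["CohortParams", "GroundTruth", "SyntheticCohort",
           "generate_timelines", "generate_samples", "generate_counts",
           "generate_cohort"]

# fixed substream tags so one seed fans out reproducibly
_STREAMS = {"timelines": 101, "samples": 202, "hormones": 303,
            "covariates": 404, "counts": 505}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), _STREAMS[stream]])


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draw = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)
    return np.round(draw).astype(int)


@dataclass
class CohortParams:
    """Generator settings; defaults mirror the study conditions.

    Durations are (mean, SD, low, high) in days.  Hormone state means
    are log ng/g; state variances are log-scale variances.
    """

    n_females: int = 169
    events_per_female: int = 3
    sampling_rate_per_month: float = 0.45
    n_groups: int = 10
    samples_per_plate: int = 27

    gestation: tuple = (178, 6, 157, 194)
    cycling: tuple = (138, 82, 18, 590)
    ppa: tuple = (322, 87, 71, 635)
    swelling: tuple = (20, 4, 12, 30)
    luteal_days: int = 14
    menses_to_swelling: tuple = (4, 8)    # uniform range
    miscarriage_rate: float = 0.06
    infant_death_rate: float = 0.05
    aberrant_cycle_rate: float = 0.04
    weaning_day: int = 490                # ~70 weeks

    hormone_means: dict = field(default_factory=lambda: {
        "fE": {"CYCLING": 4.0, "PREGNANT": 5.2, "PPA": 3.6},
        "fP": {"CYCLING": 4.5, "PREGNANT": 5.5, "PPA": 4.0},
        "fGC": {"CYCLING": 4.6, "PREGNANT": 4.7, "PPA": 4.6},
    })
    hormone_vars: dict = field(default_factory=lambda: {
        "fE": {"CYCLING": 0.205, "PREGNANT": 0.838, "PPA": 0.182},
        "fP": {"CYCLING": 0.442, "PREGNANT": 0.502, "PPA": 0.232},
        "fGC": {"CYCLING": 0.20, "PREGNANT": 0.20, "PPA": 0.20},
    })
    storage_slope_extraction: float = -8e-4   # per day, log scale
    storage_slope_assay: float = -5e-4
    days_to_extraction_range: tuple = (30, 400)
    days_to_assay_range: tuple = (30, 300)

    n_taxa: int = 898
    n_families: int = 50
    n_phyla: int = 14
    sigma_base: float = 2.5               # spread of baseline log-abundances
    sigma_host: float = 0.8               # host-identity offset SD
    sigma_time: float = 1.0               # within-host temporal noise SD
    decay_per_day: float = 0.008          # OU decay of temporal noise
    dm_concentration: float = 1000.0      # Dirichlet-multinomial precision
    depth_log_mean: float = np.log(25000.0)
    depth_log_sd: float = 0.9
    depth_range: tuple = (1028, 477241)
    n_recruited_taxa: int = 13            # pregnancy-recruited (richness +13)
    recruited_rel_abundance: float = 2e-3
    n_effect_taxa: int = 40               # log-scale pregnancy effect set
    effect_size: float = 0.6

    seed: int = 0


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulation."""

    labels: pd.DataFrame                  # sample_id, state, event_no, day
    recruited_taxa: list = field(default_factory=list)
    effect_taxa: list = field(default_factory=list)
    effect_size: float = 0.0
    richness_effect: float = 0.0          # expected pregnancy richness boost
    sigma_host: float = 0.0
    decay_per_day: float = 0.0
    storage_slopes: tuple = (0.0, 0.0)
    hormone_means: dict = field(default_factory=dict)
    hormone_vars: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------

def _build_cycling_milestones(rng, params, start, duration):
    """Milestones of one cycling interval; returns (milestones, conception).

    Cycles run menses -> swelling onset -> deturgescence -> luteal ->
    next menses.  Conception coincides with the final deturgescence (the
    egg is fertilized at the close of the ovulation window), placed so
    the interval length matches the drawn duration; the conception cycle
    always has a normal swelling length.
    """
    ms = []
    t_menses = start
    end = start + duration
    while True:
        gap = int(rng.integers(*params.menses_to_swelling))
        if rng.random() < params.aberrant_cycle_rate:
            swell = int(rng.choice([8, 9, 41, 45]))
        else:
            swell = int(_truncnorm(rng, *params.swelling))
        onset = t_menses + gap
        deturg = onset + swell
        next_menses = deturg + params.luteal_days
        if next_menses >= end - 31:
            break
        ms += [(onset, Milestone.SWELLING_ONSET),
               (deturg, Milestone.DETURGESCENCE),
               (next_menses, Milestone.CYCLE_ONSET)]
        t_menses = next_menses
    swell = int(_truncnorm(rng, *params.swelling))
    onset = max(t_menses + 2, end - swell)
    ms += [(onset, Milestone.SWELLING_ONSET),
           (end, Milestone.DETURGESCENCE)]
    return ms, end


def generate_timelines(params: CohortParams, seed: int | None = None
                       ) -> list[FemaleTimeline]:
    """Simulate milestone calendars (with attached ``true_intervals``).

    Each female alternates cycling -> pregnancy -> PPA events with
    durations from the configured truncated normals; miscarriages and
    infant deaths occur at the configured rates to exercise the
    exclusion rules.  The generator records its own state intervals on
    each timeline (``true_intervals``) as an assignment oracle.
    """
    rng = _rng(params.seed if seed is None else seed, "timelines")
    timelines = []
    for f in range(params.n_females):
        fid = f"F{f:03d}"
        birth = -int(rng.integers(int(4.5 * 365), int(18 * 365)))
        t = int(rng.integers(0, 200))
        ms: list[tuple[int, Milestone]] = []
        truth: list[dict] = []
        event_no = 0
        for _ in range(params.events_per_female):
            event_no += 1
            ms.append((t, Milestone.RESUMPTION))
            cyc_len = int(_truncnorm(rng, *params.cycling))
            cyc_ms, conception = _build_cycling_milestones(
                rng, params, t, cyc_len)
            ms += cyc_ms
            truth.append({"state": State.CYCLING.value, "start": t,
                          "end": conception, "event_no": event_no})
            ms.append((conception, Milestone.CONCEPTION))
            gest = int(_truncnorm(rng, *params.gestation))
            miscarried = rng.random() < params.miscarriage_rate
            if miscarried:
                loss = conception + int(rng.integers(30, 110))
                ms.append((loss, Milestone.MISCARRIAGE))
                truth.append({"state": State.PREGNANT.value,
                              "start": conception, "end": loss,
                              "event_no": event_no, "miscarriage": True})
                ppa_end = loss + int(rng.integers(20, 60))
                truth.append({"state": State.PPA.value, "start": loss,
                              "end": ppa_end, "event_no": event_no,
                              "after_miscarriage": True})
                t = ppa_end
                continue
            birth_day = conception + gest
            ms.append((birth_day, Milestone.LIVE_BIRTH))
            truth.append({"state": State.PREGNANT.value, "start": conception,
                          "end": birth_day, "event_no": event_no})
            ppa_len = int(_truncnorm(rng, *params.ppa))
            resumption = birth_day + ppa_len
            death = None
            if rng.random() < params.infant_death_rate and ppa_len > 80:
                death = birth_day + int(rng.integers(30, ppa_len - 40))
                ms.append((death, Milestone.INFANT_DEATH))
            if death is None and ppa_len > params.weaning_day:
                ms.append((birth_day + params.weaning_day, Milestone.WEANING))
            truth.append({"state": State.PPA.value, "start": birth_day,
                          "end": resumption, "event_no": event_no,
                          "infant_death": death})
            t = resumption
        ms.append((t, Milestone.RESUMPTION))  # closes the last PPA
        ms.sort(key=lambda m: m[0])
        tl = FemaleTimeline(fid, ms, birth_date=birth)
        tl.true_intervals = truth
        timelines.append(tl)
    return timelines


# ---------------------------------------------------------------------------
# samples, hormones, covariates
# ---------------------------------------------------------------------------

def _true_label(truth, day):
    for iv in truth:
        if iv["start"] <= day < iv["end"]:
            return iv
    return None


def generate_samples(timelines, params: CohortParams,
                     seed: int | None = None):
    """Simulate fecal samples with hormones plus rainfall/diet inputs.

    Returns ``(samples, rainfall, focals, label_truth)``.  Sample dates
    follow a per-female Poisson process; log hormones are drawn with
    state-dependent mean/variance and perturbed by linear storage
    effects; rainfall and group diets carry seasonal structure.
    """
    seed = params.seed if seed is None else seed
    rng = _rng(seed, "samples")
    hrng = _rng(seed, "hormones")
    crng = _rng(seed, "covariates")

    rows, truth_rows = [], []
    k = 0
    for tl in timelines:
        lo, hi = tl.span
        n = rng.poisson(params.sampling_rate_per_month * (hi - lo) / 30.0)
        if n == 0:
            continue
        days = np.unique(rng.integers(lo, hi, size=n))
        group = f"G{rng.integers(params.n_groups):02d}"
        for d in days:
            iv = _true_label(tl.true_intervals, int(d))
            if iv is None:
                continue
            sid = f"S{k:05d}"
            k += 1
            rows.append({
                "sample_id": sid, "female_id": tl.female_id, "date": int(d),
                "social_group": group,
                "age": (int(d) - tl.birth_date) / 365.25,
            })
            truth_rows.append({
                "sample_id": sid, "female_id": tl.female_id,
                "state": iv["state"], "event_no": iv["event_no"],
                "day_in_state": int(d) - iv["start"],
                "miscarriage": bool(iv.get("miscarriage")
                                    or iv.get("after_miscarriage")),
                "infant_death": iv.get("infant_death"),
            })
    samples = pd.DataFrame(rows)
    label_truth = pd.DataFrame(truth_rows)
    if samples.empty:
        raise ValueError("no samples generated; raise the sampling rate")

    samples = samples.sort_values("date", kind="stable").reset_index(drop=True)
    label_truth = (label_truth.set_index("sample_id")
                   .loc[samples["sample_id"]].reset_index())
    samples["collection_index"] = samples["date"] - samples["date"].min()
    samples["plate"] = [f"P{i // params.samples_per_plate:03d}"
                        for i in range(len(samples))]
    samples["days_to_extraction"] = rng.integers(
        *params.days_to_extraction_range, size=len(samples))
    samples["days_to_assay"] = rng.integers(
        *params.days_to_assay_range, size=len(samples))

    # hormones: state-dependent log-normal + storage decay on raw values
    states = label_truth["state"].to_numpy()
    for h in ("fE", "fP", "fGC"):
        mu = np.array([params.hormone_means[h][s] for s in states])
        sd = np.sqrt([params.hormone_vars[h][s] for s in states])
        log_true = hrng.normal(mu, sd)
        log_obs = (log_true
                   + params.storage_slope_extraction
                   * samples["days_to_extraction"].to_numpy()
                   + params.storage_slope_assay
                   * samples["days_to_assay"].to_numpy())
        samples[h] = np.exp(log_obs)

    # rainfall: seasonal gamma process, daily
    d0, d1 = samples["date"].min() - 60, samples["date"].max() + 1
    days = np.arange(d0, d1)
    wet = 0.5 * (1 + np.sin(2 * np.pi * days / 365.25))
    rain_mm = np.where(crng.random(len(days)) < 0.15 + 0.5 * wet,
                       crng.gamma(2.0, 4.0, len(days)), 0.0)
    rainfall = pd.DataFrame({"date": days, "mm": np.round(rain_mm, 1)})

    # focal feeding observations: per group per day, seasonal diet drift
    from .covariates import FOOD_CATEGORIES
    n_cat = len(FOOD_CATEGORIES)
    groups = sorted(samples["social_group"].unique())
    base = crng.dirichlet(np.full(n_cat, 2.0), size=len(groups))
    seasonal = crng.dirichlet(np.full(n_cat, 2.0))
    focal_rows = []
    fk = 0
    for gi, g in enumerate(groups):
        n_focal = crng.poisson(1.0, size=len(days))
        for d, nf in zip(days, n_focal):
            if nf == 0:
                continue
            w = 0.5 * (1 + np.sin(2 * np.pi * d / 365.25))
            p = (1 - 0.3 * w) * base[gi] + 0.3 * w * seasonal
            p = p / p.sum()
            for _ in range(nf):
                nrec = int(crng.integers(1, 6))
                cats = crng.choice(n_cat, size=nrec, p=p)
                fid = f"FOC{fk:06d}"
                fk += 1
                focal_rows += [{"focal_id": fid, "group": g, "date": int(d),
                                "food_category": FOOD_CATEGORIES[c]}
                               for c in cats]
    focals = pd.DataFrame(focal_rows)
    return samples, rainfall, focals, label_truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(samples: pd.DataFrame, label_truth: pd.DataFrame,
                    params: CohortParams, seed: int | None = None
                    ) -> tuple[CountTable, GroundTruth]:
    """Dirichlet-multinomial counts with host, state and temporal structure.

    Per-sample log-intensities are baseline + host offset (SD
    ``sigma_host``) + an OU temporal process (SD ``sigma_time``,
    correlation ``exp(-decay_per_day * dt)`` within host).  During
    pregnancy the effect-taxon set gains a relative-abundance factor
    ``exp(effect_size)`` and ``n_recruited_taxa`` extra taxa enter at a
    relative abundance high enough to be detected essentially always,
    so the expected richness contrast between pregnancy and the other
    states is the recruited count itself; the displaced probability
    mass is drawn from abundant taxa only, leaving detection of
    marginal taxa unchanged.
    """
    rng = _rng(params.seed if seed is None else seed, "counts")
    n_s, n_t = len(samples), params.n_taxa
    taxa = [f"ASV{j:04d}" for j in range(n_t)]

    # taxonomy: families within phyla; a slice left unidentified
    phyla = [f"Phylum{p:02d}" for p in range(params.n_phyla)]
    fam_phylum = rng.integers(params.n_phyla, size=params.n_families)
    fam_of_taxon = rng.integers(params.n_families, size=n_t)
    family = np.array([f"Family{f:02d}" for f in fam_of_taxon], dtype=object)
    family[rng.random(n_t) < 0.08] = "unidentified"
    taxonomy = pd.DataFrame({
        "family": family,
        "phylum": [phyla[fam_phylum[f]] for f in fam_of_taxon],
    }, index=pd.Index(taxa, name="taxon"))

    ordinary = np.arange(n_t - params.n_recruited_taxa)
    recruited = np.arange(n_t - params.n_recruited_taxa, n_t)

    # baseline log-abundances on a stratified lognormal quantile grid
    # (shuffled): the abundance spectrum is the same for every cohort, so
    # expected richness does not wobble with the luck of the tail draws
    n_ord = len(ordinary)
    base = params.sigma_base * stats.norm.ppf((np.arange(n_ord) + 0.5) / n_ord)
    rng.shuffle(base)
    # differential-abundance effect taxa come from a high-abundance band:
    # detection there is already saturated (so boosting them cannot leak
    # into the richness contrast) and expected counts sit far above the
    # CLR pseudocount, yet shares stay small enough that closure barely
    # attenuates the injected log-fold change
    lo_q, hi_q = np.quantile(base, [0.92, 0.98])
    band = ordinary[(base >= lo_q) & (base <= hi_q)]
    effect_taxa = rng.choice(band, size=params.n_effect_taxa, replace=False)
    females = samples["female_id"].to_numpy()
    uniq_f = pd.unique(females)
    host = {f: rng.normal(0.0, params.sigma_host, size=len(ordinary))
            for f in uniq_f}

    pregnant = (label_truth["state"] == State.PREGNANT.value).to_numpy()
    dates = samples["date"].to_numpy()
    order = np.lexsort((dates, females))

    log_lam = np.empty((n_s, len(ordinary)))
    prev_idx: dict[str, int] = {}
    eps = {f: None for f in uniq_f}
    for i in order:
        f = females[i]
        if eps[f] is None:
            e = rng.normal(0.0, params.sigma_time, size=len(ordinary))
        else:
            dt = dates[i] - dates[prev_idx[f]]
            rho = np.exp(-params.decay_per_day * dt)
            e = (rho * eps[f]
                 + np.sqrt(1 - rho ** 2)
                 * rng.normal(0.0, params.sigma_time, size=len(ordinary)))
        eps[f], prev_idx[f] = e, i
        log_lam[i] = base + host[f] + e

    lam = np.exp(log_lam - log_lam.max(axis=1, keepdims=True))
    probs = np.zeros((n_s, n_t))
    probs[:, ordinary] = lam / lam.sum(axis=1, keepdims=True)
    # pregnancy composition shifts are applied in probability space: the
    # effect taxa gain a factor exp(effect_size), the recruited taxa enter
    # at a fixed relative abundance, and all displaced mass is taken from
    # abundant, always-detected taxa so that marginal taxa — and with them
    # the expected ordinary richness — are untouched by renormalization
    rec_total = params.n_recruited_taxa * params.recruited_rel_abundance
    boost = np.exp(params.effect_size)
    for i in pregnant.nonzero()[0]:
        row = probs[i]
        extra = row[effect_taxa].sum() * (boost - 1.0)
        row[effect_taxa] *= boost
        heavy = row > 0.005
        heavy[effect_taxa] = False
        row[heavy] *= 1.0 - (extra + rec_total) / row[heavy].sum()
        row[recruited] = params.recruited_rel_abundance

    depth = np.exp(rng.normal(params.depth_log_mean, params.depth_log_sd,
                              size=n_s))
    depth = np.clip(depth, *params.depth_range).astype(int)

    counts = np.zeros((n_s, n_t), dtype=np.int64)
    c = params.dm_concentration
    for i in range(n_s):
        pos = probs[i] > 0
        alpha = c * probs[i, pos]
        q = rng.dirichlet(alpha)
        counts[i, pos] = rng.multinomial(depth[i], q)

    table = CountTable(
        pd.DataFrame(counts, index=pd.Index(samples["sample_id"],
                                            name="sample_id"),
                     columns=taxa),
        taxonomy)
    # detection probability of a recruited taxon (beta-binomial zero mass)
    a = c * params.recruited_rel_abundance
    b = c - a
    mean_depth = float(np.mean(depth))
    p_detect = 1.0 - (b / (b + mean_depth)) ** a
    truth = GroundTruth(
        labels=label_truth.copy(),
        recruited_taxa=[taxa[j] for j in recruited],
        effect_taxa=[taxa[j] for j in sorted(effect_taxa)],
        effect_size=params.effect_size,
        richness_effect=params.n_recruited_taxa * p_detect,
        sigma_host=params.sigma_host,
        decay_per_day=params.decay_per_day,
        storage_slopes=(params.storage_slope_extraction,
                        params.storage_slope_assay),
        hormone_means=params.hormone_means,
        hormone_vars=params.hormone_vars,
    )
    return table, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    params: CohortParams
    timelines: list
    samples: pd.DataFrame
    rainfall: pd.DataFrame
    focals: pd.DataFrame
    counts: CountTable
    truth: GroundTruth

    def milestones_frame(self) -> pd.DataFrame:
        rows = [{"female_id": tl.female_id, "date": d, "kind": kind.value}
                for tl in self.timelines for d, kind in tl.milestones]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Write the full input bundle as plain-text files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.milestones_frame().to_csv(out / "milestones.csv", index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.rainfall.to_csv(out / "rainfall.csv", index=False)
        self.focals.to_csv(out / "focals.csv", index=False)
        self.counts.counts.to_csv(out / "counts.tsv", sep="\t")
        self.counts.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
        self.truth.labels.to_csv(out / "truth_labels.csv", index=False)


def generate_cohort(params: CohortParams | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Run the full generator under one seed."""
    params = params or CohortParams()
    seed = params.seed if seed is None else seed
    timelines = generate_timelines(params, seed)
    samples, rainfall, focals, label_truth = generate_samples(
        timelines, params, seed)
    table, truth = generate_counts(samples, label_truth, params, seed)
    return SyntheticCohort(params, timelines, samples, rainfall, focals,
                           table, truth)
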