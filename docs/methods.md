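# Methods

This note records the models, rules, and design choices behind the
package, and what the synthetic-data experiments do and do not
demonstrate.

## Reproductive-state model

A female's history is a calendar of milestones. A *reproductive event*
is one cycling → pregnancy → PPA sequence running from a cycling
resumption to the next one. Segmentation produces half-open intervals
`[start, end)`; the trailing interval is censored (`end = None`). Dates
are integer study days; calendar dates are converted to ordinals on
ingestion. A "month" is 30 days everywhere — the same convention the
reproductive-month lag bins use — so phase boundaries and lag bins
cannot drift apart.

Phase rules, with the conventions chosen where a boundary was genuinely
open:

- **Ovarian cycle.** Follicular runs from swelling onset; the
  periovulatory window is the five days ending the day *before*
  deturgescence; the day of deturgescence itself opens the luteal
  phase (deturgescence marks the end of the ovulation window, so the
  flat-skin day is assigned to the phase it begins); anestrus runs from
  the next menses to the next swelling onset. Samples before the first
  recorded swelling onset of a cycling interval are treated as anestrus
  of an unobserved leading cycle.
- **Pregnancy.** Trimesters are half-open 60-day bins [0,60), [60,120),
  [120, term]. Conception coincides with the final deturgescence when
  no explicit conception milestone exists; gestation defaults to 178
  days when back-dating from a birth.
- **PPA.** Five periods in 30-day months: 0–3, 3–6, 6–9 months,
  9 months to weaning (~70 weeks), and the 30 days before cycling
  resumption, which overrides the others. Samples between weaning and
  the pre-resumption window stay in period 4 (the gap is otherwise
  unclassifiable). The first seven postpartum days are excluded, as are
  samples after an infant death unless they fall inside the
  pre-resumption window.

Exclusion filters: swelling lengths outside [10, 39] days (aberrant
cycles), PPA intervals over 496 days, miscarriage pregnancies and their
PPAs. Every removal carries an enumerated reason, and the filter report
enforces `retained + excluded = input` and that per-state retained
counts sum to the retained total.

## Compositional layer

CLR uses a pseudocount of 1 added to counts before closure — the
standard choice for sparse count tables; it is exposed in the config
for sensitivity runs. Aitchison distance is the Euclidean distance on
CLR rows. Similarity is `1 − d/d_max` with `d_max` fitted once on the
full analysis set and reused for subsets, so similarities remain
comparable across states. Prevalence thresholds follow their stated
wording: inclusive (≥) at 20% for the "common taxa" set, strict (>) at
5% for the analysis-set floor. Family aggregation keeps unidentified
taxa as separate `unidentified:<phylum>` bins rather than pooling them.

## Hormones

Each hormone (fE, fP, fGC; ng/g dry feces) is natural-log transformed
and regressed once, on the full data set, on days-to-extraction and
days-to-assay; residuals are mean-centered globally (not per female).
Variance heterogeneity between states uses the Brown–Forsythe variant
of Levene's test (deviations from group medians — the robust default)
with Bonferroni correction across the three pairwise state contrasts
per hormone. Standardization is `(x − mean)/sd` with the sample SD
(n−1) over the full set, never per subset.

## Personalization analysis

Within each state, all unordered sample pairs are classified: same
female and event (1), same female across events (2), different females
sharing a social group at both collection dates (3); cross-group pairs
between different females are uninformative for shared exposure and are
dropped. The lag is the within-state day difference in half-open 30-day
bins, 1–6; larger lags are dropped. Category-2 lags use within-state
day alignment only (day 40 of one pregnancy vs day 60 of another is a
one-month lag regardless of calendar separation). Confidence intervals
are Student-t on pair-level similarities; pairs sharing a sample are
not independent, so the CIs are descriptive rather than exact — the
hypothesis tests are Welch t-tests between categories within each
(state, lag), BH-corrected within state across all lags (≤18 tests per
state).

## Association models

Richness and per-taxon CLR abundances are fitted with linear mixed
models: fixed effects (state or phase indicators with a configurable
reference, hormone residuals, age, 30-day rainfall, sequencing depth,
collection-date index, diet Shannon, diet PCs, optional hormone×state
interactions; continuous columns z-scored over the full set) and random
intercepts for host, social group, and extraction plate. Fitting
delegates to statsmodels MixedLM with host as the grouping factor and
variance components for group and plate; p-values use the normal
approximation to the Wald statistic (recorded in the fitted object as
`df_method_`). A singular fit is retried with the weakest variance
component removed. Per-taxon p-values are pooled per term and
BH-adjusted across the taxa of one rank; a taxon is flagged at q < 0.05
and |β| > 0.4 (e^0.4 ≈ 1.49, a ~1.5-fold change). Non-convergent taxa
are recorded and excluded from the BH family.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume:

- **Durations** from truncated normals: gestation 178 ± 6 d clipped to
  [157, 194]; cycling-to-conception 138 ± 82 d clipped to [18, 590];
  PPA 322 ± 87 d clipped to [71, 635] (so ~2.5% of PPAs naturally
  exceed the 496-day filter). Full events average ~640 days.
  Miscarriages (6%), infant deaths (5%), and aberrant swelling lengths
  (4%) occur at rates chosen to exercise every exclusion rule.
- **Hormones** log-normal per state with the variance structure the
  analyses test (fE variance 0.838 pregnancy / 0.205 cycling / 0.182
  PPA; fP 0.502 / 0.442 / 0.232); state log-means follow the
  qualitative profile of pregnancy-elevated fE and fP. Raw
  concentrations decay log-linearly with storage (−8×10⁻⁴/day to
  extraction, −5×10⁻⁴/day to assay), giving residualization a known
  signal.
- **Counts**: 898 taxa; baseline log-abundances on a fixed lognormal
  quantile spectrum (σ = 2.5, shuffled per cohort) so expected richness
  does not wobble with tail draws; host offsets (σ = 0.8) per
  female×taxon; an Ornstein–Uhlenbeck within-host process (σ = 1.0,
  decay 0.008/day, i.e. correlation e^(−0.008·Δt)) drives the
  similarity decay over reproductive-month lags; counts are
  Dirichlet-multinomial (precision 1000) at log-normal depths (median
  25,000, log-SD 0.9, clipped to [1,028, 477,241]). σ and depth
  parameters were calibrated once so that default mean per-sample
  richness sits near 240 of the 898 taxa, and frozen.
- **Pregnancy signals.** Two independent injections, applied in
  probability space so compositional renormalization cannot leak into
  unintended taxa: (i) 13 *recruited* taxa enter at relative abundance
  2×10⁻³ during pregnancy (detection ≈ 0.999), raising expected
  richness by ≈13; (ii) an *effect set* (default 40 taxa from a
  high-abundance band where detection is saturated) gains a
  relative-abundance factor e^0.6. In both cases the displaced mass is
  taken exclusively from abundant, always-detected taxa, leaving
  marginal-taxon detection — and with it ordinary richness — unchanged.
- **Determinism.** One seed fans out to named substreams (timelines,
  samples, hormones, covariates, counts), so any stage can be
  regenerated independently and runs are byte-identical.

What the generator does *not* emulate: seasonal diet–microbiome
coupling, genuine phylogenetic structure among taxa, depth-dependent
taxon biases, within-state phase effects on composition, or hormone
effects on the microbiota (hormone–state associations arise only
through their shared dependence on state). Passing recovery tests
therefore demonstrate that the pipeline's rules and estimators are
correct and calibrated under the assumed structure — not that the
biological effects would be estimable in any particular real data set.

## Recovery experiments and problem sizes

Each recovery experiment isolates the signal it scores, with the other
injection switched off, so ground truth is exact:

- *State assignment*: 200 simulated timelines (~5,500 samples);
  assignment must match generator truth for every sample, and each
  constructed edge case must trigger its exclusion.
- *Richness model*: 50 cohorts of 60 females (~1,600 samples each) with
  only the +13 recruitment active; the replicate-mean pregnancy
  coefficient must sit within 2 ASVs of truth. Measured bias is about
  −1 ASV, a finite-sample attenuation of the mixed model under
  within-host autocorrelated residuals. Type-I error is checked on 100
  null cohorts (25 females) and must fall in [2%, 10%] at nominal 5%.
- *Taxon models*: 20 cohorts of 50 females with a 3-taxon effect set at
  e^0.6; sensitivity ≥ 0.9 at q < 0.05 and |β| > 0.4 with unaffected
  taxa staying unflagged.
- *Personalization*: 20 cohorts of 30 females; the category ordering
  1 > 2 > 3 at lag 1 must be significant (q < 0.05) in ≥18 replicates,
  and the replicate-averaged within-event curve must be non-increasing
  within sampling error (each adjacent-lag increase ≤ 2 replicate SEMs
  — the sparse six-month pregnancy bin, near the length of gestation
  itself, wobbles by construction).
- *Hormones*: slope recovery is scored on replicate-averaged estimates
  (20 cohorts of 60 females) against model-based standard errors;
  variance tests are checked both for power at the generator's variance
  contrast and for calibration under the null.

These sizes keep the full test suite within a few minutes on one CPU
while leaving each experiment's Monte-Carlo error well below its
acceptance margin.

## Known limitations

- The three random intercepts are expressed as host groups plus
  variance components inside statsmodels MixedLM — the standard
  approximation for crossed factors there; p-values use the normal
  approximation rather than Satterthwaite degrees of freedom.
- The similarity rescaling constant `d_max` is taken from the analysis
  set at hand; comparisons across separately processed data sets
  require refitting it jointly.
- Diet subsampling draws each focal's contribution as a single
  multinomial over its feeding records — distributionally identical to
  drawing one record per subset, and much faster — so per-subset
  downstream propagation is not available (profiles are averaged over
  subsets).
- CLR effects under closure are interdependent: injecting abundance
  changes into some taxa necessarily shifts the CLR of all others
  slightly; the generator's mass-displacement rule confines this to
  abundant taxa, but real data offer no such guarantee.
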