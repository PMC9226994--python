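# Methods

This note records the statistical model behind `immunosig`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not establish about real data.

## The signature model

The pipeline treats each immune subset independently. Healthy-control
(HC) values define a reference; patients are scored by how far they sit
from it.

**Reference (per subset).** Q1 and Q3 are linear-interpolation quantiles
(the order statistic k placed at probability (k−1)/(n−1)); the convention
is recorded in every serialized model because other conventions move the
fences. Outliers are values *strictly* beyond the Tukey fences
Q1 − 1.5·IQR / Q3 + 1.5·IQR; boundary values are retained. Removal is a
single pass — fences are computed once from the full HC sample and applied
once; iterated refencing is a different (and more aggressive) estimator
and is deliberately not used. AVG and SD are the mean and sample SD
(denominator n−1) of the retained values. A subset needs at least four
non-missing HC values; with fewer, or with SD = 0 after cleaning, it is
excluded from scoring and listed in the model's skip table (a zero SD
would make the SD/10 step undefined, and silently scoring it as 0 would
bias signatures toward typicality).

**Zero zone.** Candidate ranges AVG ± n·SD/10 for n = 0…n_max (default
50, which saturates both groups long before the limit in every simulated
regime) are scored by the cover-ratio difference
C_HC(n) − C_SLE(n), with inclusive bounds. The smallest maximizing n is
chosen: among equally separating ranges, the tightest zone is the most
conservative definition of "normal". The cover ratios use the *raw* HC
values, not the outlier-cleaned ones — cleaning exists to stabilize AVG
and SD, and the zone search should see the data as observed; the choice is
stored in the model (`cover_on_cleaned`, default false). Note the zone
search uses both groups: the zones are supervised, which makes in-sample
ROC figures optimistic (see the leave-one-out audit below).

**Ranking.** A value inside the zone (inclusive) ranks 0. Outside, the
distance to the nearest boundary is converted to k = ceil(d/(SD/10))
deviation steps and banded: ten steps (one SD) per rank, i.e. k ∈ [1,10]
→ −1, [11,20] → −2, k ≥ 21 → −3. This banding is a reconstruction — it
extends the SD/10 "decile" granularity of the zone search to the rank
bands and caps at −3 beyond two SD — and is configurable (`band_steps`,
`rank_floor`) rather than asserted as the only reading. Band and zone
boundaries resolve toward the less negative rank, so a value exactly one
SD outside the zone ranks −1, not −2; a small relative epsilon (1e−9)
protects these boundaries from float round-off. All modelled subsets
contribute to the score by default; restricting to a shortlist (e.g. the
significant subsets) is available via `subset_filter` but is not the
default.

**Evaluation.** The signature is a sum of nonpositive integer ranks, so
lower means more SLE-like; the classifier calls a subject positive when
the score falls below a threshold. The AUC is computed as the
Mann–Whitney ordered-pair probability (ties count half), the curve is
enumerated at every distinct cutpoint (midpoints between adjacent
distinct scores plus sentinels beyond the extremes), and the operating
threshold maximizes Youden's J with ties broken toward the more negative
threshold. The 95% CI is a stratified percentile bootstrap (default 2000
resamples, seeded); the bootstrap scheme is a package choice, as is the
decision not to attach a p-value to the AUC (no specific test is
canonical here). `loocv_evaluate` refits the entire model — reference and
zones — without each subject and scores them held out, exposing the
optimism of the supervised zone fit.

## Differential and longitudinal statistics

The subset screen is the classical pooled-variance (Student's) unpaired
two-sided t-test per subset; Welch's variant is available by flag.
Holm–Bonferroni adjustment is offered for simulation work where the
family-wise error matters, but it is never applied silently — an
uncorrected p < 0.05 screen over 93 subsets expects ~3 false positives
among true nulls, which is why the package's own recovery checks use
Holm. The sex table uses the two-sided Fisher exact test under the
probability-mass rule (sum of all tables with the observed margins no
more probable than the observed one). Age comparisons are exposed as a
summary-statistics t-test in both variants because published tables often
cannot be traced to one: from the rounded summaries 45.9 ± 10.7 (n=13)
vs 38.3 ± 14.5 (n=9), the pooled variant gives p ≈ 0.17 and Welch ≈ 0.20,
and neither should be forced onto a differently printed value.

Monitored treatment courses have only three timepoints (weeks 0, 4, 12),
so trajectory association is a per-patient Spearman rank correlation
(midrank ties) between a subset's percentage and the SLEDAI-2K score —
the weakest assumption consistent with a qualitative "trend". |rho| ≥ 0.5
labels a direction (the threshold keeps a 3-point monotone series with
one tie, rho ≈ 0.87, in the labelled class); undefined rho (a constant
series) labels "none". Per-patient correlations are tallied across
patients, never pooled: a 3-point rho is a direction indicator, not an
estimate worth averaging. The bundled
`data/monitored_patients.csv` carries an example four-patient course
(SLEDAI-2K and leucocyte counts only) used in tests and documentation.

## The synthetic cohort generator

The generator's defaults are the study conditions the rest of the package
is validated against: 13 SLE and 9 HC subjects; 93 subsets of which 29
carry a group effect of |δ| = 3.5 HC standard deviations, signed to match
the reported biology (dendritic cells, NK cells, PD-L1⁺ subsets and
MHC II⁺ dendritic cells down in SLE; CD8 T, PD-1⁺ and the remaining
MHC II⁺ subsets up); female probabilities 12/13 and 8/9; ages
Normal(45.9, 10.7) and Normal(38.3, 14.5) truncated to the eligibility
window [20, 65]; master seed 42. The 3.5 SD effect size gives essentially
unit per-test power at Holm-corrected thresholds for these group sizes.
The 93 subset names are programmatic reconstructions of plausible PBMC
populations — the original gate list was never published — and must not be
read as the published definitions. HC means are field-plausible
percentages (lineages tens of percent, checkpoint-positive overlays a few
percent) with SD set to 20% of the mean (floored at 0.3 points), a
mid-range coefficient of variation for between-donor subset variability.

Subset values are *independent* truncated normals,
Normal(μ + δ·σ·[SLE], σ) resampled into [0, 100] (up to 100 draws, then
clipped): the subsets are overlapping gates, so no compositional
sum-to-100 constraint applies, but independence is still a
simplification — real panels are strongly correlated through shared
parent populations. Parent/child consistency holds automatically only in
cell-level mode. Every value has its own RNG substream keyed by (seed,
subject index, CRC32 of the subset name), so runs are byte-reproducible
and panel edits do not reshuffle unrelated values.

Far-tail contamination is available but off by default
(`outlier_rate = 0`, replacement value μ + 6σ, HC arm only). The baseline
conditions are the clean group-shift model: with only 9 controls, even a
3% per-value contamination rate places a 6σ value inside an affected
subset's HC sample in roughly a quarter of cohorts, and a single such
value inflates the pooled SD enough to mask a genuine 3.5 SD shift about
half the time — turning a generator meant to reproduce the 29-subset
structure into one that randomly hides parts of it. Contamination is
therefore a robustness dial, exercised explicitly in tests of the fence
path, not part of the default study conditions.

Cell-level mode draws each subject's cells × markers intensity matrix
from a mixture of phenotyped populations (expressed markers ~3× the
positivity threshold, unexpressed ~⅓ of it, Gaussian with fixed CVs,
clipped at zero), over a default 15-marker panel (CD3, CD4, CD8, CD14,
CD19, CD56, CD11c, HLA-DR, TCRαβ, TCRγδ, CD25, CD69, FoxP3, PD-1,
PD-L1). Gating is boolean conjunctions of per-marker signs with strict
">" positivity (ties negative) and percent-of-parent denominators
(percent-of-all-cells for root gates); an empty parent yields a missing
value, never zero. No spillover, compensation, doublets or acquisition
artifacts are modelled, and no 2-D geometric gating is provided.

Longitudinal mode gives each monitored patient a SLEDAI-2K course
starting uniformly in 6–30 with a stochastic ~35% per-interval decline
under treatment, and generates monitored subsets as
μ + σ·(c·z + √(1−c²)·ε) where z is the standardized SLEDAI course —
so the coupling c (default +0.9 for PD-1⁺ CD4/CD8 T cells, −0.9 for
PD-L1⁺ monocytes) is the model-scale correlation.

## What passing tests do and do not show

Passing the simulation suite shows the algorithm recovers structure it
was told to plant under clean, independent, near-normal noise at a large
(3.5 SD) effect size. It does not show the signature separates real SLE
cohorts: real subset percentages are correlated, non-normal, measured
with gating error, and real effects are heterogeneous and smaller. The
perfect AUC on the default cohort mirrors a strong-signal regime, and is
additionally in-sample-optimistic because the zero zones are fitted with
the patient group in view; the leave-one-out audit is the honest check.
On null cohorts at the study's group sizes the held-out AUC centres on
0.5, but at very small cohorts (≤ ~6 per group) it sits visibly below
0.5 — a held-out control is scored against a reference refit from one
fewer control, whose noisier zones make its score more negative, while a
held-out patient keeps every control. That asymmetry is a property of
leave-one-out with a control-anchored score at tiny n, worth remembering
when reading published LOOCV figures on small cohorts.

## Numerical and degenerate-input choices

- Quantiles: numpy's linear interpolation; recorded in the model file.
- Inclusive cover-ratio and zone bounds; rank bands resolve toward the
  less negative rank with a 1e−9 relative guard.
- Zero-zone argmax ties: smallest n.
- Youden ties: most negative threshold; reported thresholds are midpoints
  between adjacent distinct scores.
- Missing values: excluded pairwise everywhere; a missing subset is
  skipped (and counted) in scoring, never imputed or zeroed.
- Degenerate SD, short HC samples, empty gate parents: excluded with an
  explicit skip reason that propagates to warnings and the run manifest.
- Problem sizes used by the test and acceptance runs: default cohorts of
  22 subjects × 93 subsets; property suites use 200–250 random instances
  per oracle comparison; recovery and calibration checks use 20 seeds;
  bootstrap CIs use 2000 resamples.

## Known limitations

- Independence across subsets in the percentage-level generator (see
  above); cell-level mode restores parent/child coherence but covers a
  reduced panel.
- The rank-band reconstruction (ten SD/10 steps per rank, floor −3) is
  one defensible reading of a decile-based ranking; alternatives are
  configurable but untested against any published per-subject scores,
  since none exist.
- The ROC threshold on a discrete integer score is coarse: with 22
  subjects, sensitivity/specificity move in steps of 1/13 and 1/9.
- No nonparametric subset screen, no effect-size CIs beyond the mean
  difference, no mixed-effects modelling of the longitudinal courses.
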