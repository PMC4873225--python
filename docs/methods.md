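# Methods

`markerval` implements a multi-stage tissue-biomarker workflow for
prostate cancer: candidate prioritization from a grouped expression
matrix, spike-in standardized qRT-PCR validation statistics, siRNA
functional-assay quantification, and organoid morphometry. Every stage
can be exercised on synthetic cohorts with known ground truth; this
note records the models, the defaults and why, and what the synthetic
data does and does not establish.

## Prioritization cascade

The cascade operates on a genes × samples log2 expression matrix with
sample groups N (normal prostate), T (primary tumor) and M (metastasis).

1. **Differential expression.** For each contrast (T-vs-N, M-vs-T,
   oriented so positive fold change means overexpression in the later
   stage) we compute the log2 ratio of linear-scale group means, a
   Welch t test, a z statistic, a Mann-Whitney U test and the SAM
   relative difference d = (x̄_A − x̄_B)/(s + s₀), where s is the pooled
   standard error. The z statistic — mean difference divided by the
   standard deviation of the reference (normal) group — is one
   admissible reading of an underspecified convention; it is reported,
   not used for gating. s₀ defaults to the median of the per-gene
   pooled standard errors; a permutation-based FDR for d is not
   implemented — Benjamini-Hochberg q-values on the t p-values play
   that role, since in practice the two selections produce closely
   overlapping gene sets.
2. **Significance gate and truncation.** Genes with Bonferroni-adjusted
   p < α (default 0.05; BH optional) are ranked by |log2 FC|, ties
   broken lexicographically by gene id, and truncated to the top K =
   300 per contrast. The gate is applied before truncation.
3. **Combined ranking.** The T-vs-N order is the base; a gene also in
   the M-vs-T top list has its 1-based rank score reduced by a bonus
   (default 5) and the list is stably re-sorted — agreement between the
   two contrasts promotes a gene without discarding the base order.
4. **Tissue filter.** Keep a gene iff its prostate specificity score
   divided by the median score over the other tissues is ≥ 2
   (inclusive). A missing table row fails that gene only.
5. **Survival filter.** Patients are split on the gene's expression:
   round(n·0.15) highest-expressing patients form the high-risk
   stratum (half-up rounding; ties resolved by stable input order).
   The gene passes iff the two-group log-rank p is below α *and* the
   high stratum has the smaller restricted-mean survival — high
   expression must associate with worse outcome, the direction relevant
   for an overexpressed marker.
6. **Literature filter.** Genes mentioned more than 5 times in indexed
   publications are excluded as already described; a count of exactly 5
   is retained. Missing counts are treated as zero with a warning.

Every gene entering the cascade leaves with a per-filter verdict and a
single first-failing-filter attribution (`CandidateTrace`).

Mann-Whitney U uses the exact null distribution when n_A·n_B ≤ 400 and
there are no ties, otherwise the tie-corrected normal approximation;
a perfectly balanced U = n_A·n_B/2 reports p = 1 exactly. Kaplan-Meier
curves and the log-rank statistic are delegated to `lifelines`;
multiple-testing adjustment to `statsmodels`.

## qPCR validation

Copy numbers are made absolute against a known quantity of artificial
spike-in RNA added before extraction: recovery = measured/added spiked
copies, and copies/µg = raw/(recovery · RNA mass). Recovery above 1 is
computed normally but logged. A sample is *positive* for a gene iff all
three replicates strictly exceed the lowest detection limit (LDL);
detection percentages are rounded to the nearest integer, half away
from zero. The published contingency table this rule mirrors mixes two
rounding conventions in a few cells; nearest-integer is used throughout
and the tests assert only cells where it matches the printed value.

The contrast battery compares normalized copy numbers (replicate mean
by default, median optional) across the four tissue groups — CP-B
(true normal from cystoprostatectomy), CP-IPCa (benign tissue from
glands with incidental cancer), RP-B (histologically benign tissue from
cancer-bearing glands) and RP-PCa (cancerous tissue) — with the
Mann-Whitney U test: pooled CP vs pooled RP, CP vs each RP arm, the
field-effect comparisons, and RP-PCa vs RP-B. Clinical dichotomies
(Gleason ≥ 7, pT3/pT4 vs pT2, PSA relapse, tumor content > 33%) are
tested on one value per patient, taken consistently from the right
lobe when a patient has two samples (smaller sample id on a tie);
group contrasts use all samples, matching the narrower footnote scope
of the per-patient rule.

ROC analysis uses the rank-sum identity AUC = U/(n₁·n₂) with midrank
half-credit for ties; curve points come from a full threshold sweep.
The identity against the U statistic is asserted exactly in tests and
cross-checked against scikit-learn.

## Assays

Knockdown efficiency is 100·(1 − treated/control) on normalized
expression; negative values (upregulation) are reported and flagged,
never clamped. Viability and apoptosis tables are percent of the
control-condition mean. Wound kinetics on binary confluence masks:
wound width is the mean per-row open extent inside the fixed wound
region; wound confluence the percent of that region occupied; relative
wound density RWD(t) = 100·(w(t) − w(0))/(c(t) − w(0)) with w the
density inside and c outside the wound, clamped to [0, 100].

## Morphometry

Analysis is 2-D on maximum-intensity projections (live/dead channels).
Segmentation is a global threshold (Otsu by default) with 8-connected
labeling, components below `min_area` dropped and labels ordered by
first raster-scan pixel for determinism. Descriptors per organoid:

* **Area** — pixel count; **perimeter** — weighted boundary-step
  estimator (diagonal weight √2; a filled s×s square measures 4(s−1)).
* **Roundness** — 4π·area/perimeter², clamped to ≤ 1. The estimator
  overestimates circle perimeter by ≈5%, so rasterized disks plateau
  near 0.90–0.95 rather than 1; comparisons between conditions are
  unaffected because the bias is shared.
* **Roughness** — mean absolute radial deviation of the boundary from
  the boundary of a morphologically opened (smoothed) copy, normalized
  by the equivalent radius. Smoothing radius: ¼ of equivalent radius.
* **Protrusions** — the body is the morphological opening with a disk
  of `opening_radius` (default: ¼ of the median equivalent organoid
  radius, overridable); protrusions are 8-connected components of
  mask∖body with ≥ `min_spike_area` pixels. The count and the
  protrusion-area fraction are this package's documented reading of
  the protrusion descriptors; they are validated against synthetic
  ground truth, not against any external implementation.
* **Density / dead signal** — mean live intensity over the mask; mean
  and total dead-channel signal; **cell number** — nuclei-blob count
  when a nuclei image is given, else area/typical cell area.

Condition summaries express apoptosis mean/total, dead-stain
mean/total and summed area as percent of the untreated control.

## Synthetic cohorts

The generators draw from named child streams of one master seed
(`numpy` SeedSequence spawn keys), so outputs are bit-reproducible and
adding a generator never perturbs an existing one.

**Expression cohort.** Defaults: 2,000 genes, N/T/M = 10/60/12 — a
one-third-scale rendering of a 29/181/37 discovery cohort — baseline
log2 expression uniform on [4, 12], additive Gaussian noise with SD 0.5
log2 units. Eight planted marker genes carry a +2 log2 shift in T (and
+1 further in M for the three that separate metastases), prostate
specificity ratio 5, and 2 literature citations; background genes have
Poisson(20) citations, making them "well described". Prognostic planted
genes co-express with a per-patient latent aggressiveness factor
(correlation 0.9 of their within-group noise), and survival for the
primary-tumor patients is exponential with log hazard = 2 × the factor,
baseline median 60 months, administratively censored at 120 months.
The latent-factor construction is what makes each planted gene
*individually* prognostic — summing independent per-gene hazards would
bury each gene's signal in the frailty contributed by the others.

**qPCR cohort.** Groups CP-B/CP-IPCa/RP-B/RP-PCa of 7/12/20/20 samples
(the two CP arms at their small published sizes, the RP arms reduced).
True copy numbers are lognormal (σ = 0.6) around 5,000 copies/µg times
a group multiplier: 1 for CP-B, √3 for CP-IPCa, 3 for RP-B (the field
effect: benign tissue from cancer-bearing glands is already elevated)
and 10 for RP-PCa, preserving the ordering CP-B < RP-B < RP-PCa. Raw
replicate counts fold in a per-sample spike recovery drawn uniformly
from [0.3, 0.9], an RNA mass from [0.05, 0.2] µg, and 15% lognormal
replicate noise — so spike-in normalization is genuinely required to
recover the truth. LDL defaults to 100 copies and the spike to 10⁶
copies; neither is published, both are free parameters. Paired RP
samples share a patient id with left/right lobes; clinical annotations
are drawn independently of expression, so clinical dichotomies are
null and their p-values calibrated.

**Images and wounds.** Organoids are non-overlapping disks (radius
25–40 px on a 512² canvas) with evenly spaced rectangular or triangular
protrusions and a dead-cell speckle channel at a configured fraction of
body pixels; the truth table lists centers, radii, protrusion counts
and dead fractions. Wound series are binary masks of a centered strip
(60 px) closing symmetrically at a fixed rate per frame.

What the synthetic data does *not* emulate: probe-level noise and
amplification chemistry (copies are drawn directly), batch and section
effects, correlated background genes, histology mixtures within a
sample, image blur/background gradients, and biological heterogeneity
of organoid shape beyond disks-with-protrusions. Passing tests
therefore demonstrate that the implemented rules are correct and
recover planted structure under the stated statistical model — not
that the workflow would reach the same conclusions on raw clinical
material.

## Numerical choices and degenerate inputs

* Ties are broken lexicographically by gene id (ranking), by stable
  input order (risk stratification), and by smaller sample id
  (per-patient reduction) — all deterministic.
* Zero variance in both groups of a t test returns p = 1 with a
  degeneracy flag rather than NaN; an all-background image segments to
  zero labels without error; an opening that erases a mask yields
  protrusion count 0 with a degeneracy flag.
* Strict inequalities: detection requires replicates strictly above
  the LDL; literature exclusion is strictly more than the cap; tumor
  content must strictly exceed 33%.
* Percentages are rounded half away from zero.

## Problem sizes

Default test and demonstration runs use 2,000-gene cohorts (5,000 for
the truncation checks), 20 seeds for recovery rates and 200 seeds for
null calibration — sizes at which every rate or recovery statement in
the test suite is reproduced in well under the stated wall-clock of a
desktop run, while preserving the cohort structure of the study design.
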