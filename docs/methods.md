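# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Behavioral measures and day-adjusted scores

Each subject contributes four measurements per symptom measure: m11/m12
(Day 1 baseline / post-vection) and m21/m22 (Day 2).  The day-adjusted score
DAS = (m22 − m21) − (m12 − m11) is the Day-2 stimulus-induced change
corrected for the Day-1 change; for nausea and motion sickness a negative
DAS means relief on the treatment day, for the log NTT a positive DAS means
an attenuated gastric disturbance.  DAS values enter two-way fixed-effects
ANOVAs (group × sex, Type II sums of squares; with a balanced design the SS
types coincide, and Type II remains well behaved after outlier removal).
Outliers are flagged by Tukey fences at 1.5×IQR computed per arm — the
standard boxplot convention — and the ANOVA is re-fit without them; both
tables are reported.

A placebo responder shows at least a 50% reduction of the within-day
vection-induced rise from Day 1 to Day 2: responder iff
(m22 − m21) ≤ 0.5·(m12 − m11), boundary inclusive.  The criterion is defined
on the rises, not on the DAS itself, because the DAS can be negative and a
"percent reduction" of it is not well defined.  Subjects with a non-positive
Day-1 rise have no defined reduction and are excluded from the counts (the
exclusion count is reported).  Responder proportions are compared by Pearson
χ² with one degree of freedom and **no** continuity correction; the
uncorrected statistic reproduces the published values for both responder
tables (≈18.70 and 14.06) while the Yates-corrected one does not.

## Electrogastrogram NTT

The gastric slow wave cycles near 3 cpm; nausea shifts power toward
tachygastria.  The analysis takes the last 300 s of a period, splits it into
three 3-min epochs advanced by 1 min (minutes 1–3, 2–4, 3–5), detrends each
epoch linearly, tapers with a Hamming window, and sums periodogram power
over bins whose center frequency lies in the closed normogastric
(2.5–3 cpm) or tachygastric (3.75–9.75 cpm) band.  NTT is the arithmetic
mean of the three per-epoch normo/tachy ratios; its natural log is used in
statistics.  Two wording ambiguities were resolved as: epochs are 3-min
windows (matching the listed minute ranges, not the "1-min" shorthand), and
the ratio is formed per epoch and then averaged ("mean ratio").  Degenerate
inputs fail loudly: traces shorter than 300 s, bands containing no FFT bin
at the given resolution, and epochs with zero tachygastric power (no
infinities are returned).  One spectral subtlety matters for testing: with a
Hamming taper the mainlobe spans ±1 bin, so a pure tone concentrates ~95% of
its power inside a band only when the tone is near a bin center *and* the
adjacent bins lie inside the band; the spectral tests are constructed
accordingly.

## Intensity matrices

Two extraction variants of the same DIA experiment are consumed: "qvalue"
(strict per-observation confidence, more missing cells) and "qvalue sparse"
(any analyte passing confidence at least once, few missing cells).  The
peptide dataset keeps sparse-variant peptides with ≤10% missing values
(boundary kept, strict > removed).  The protein dataset sums proteotypic
peptides per protein (cell missing only when all constituent peptides are
missing), fills missing qvalue cells from the sparse variant, and deletes
proteins with >5% missing after the fill.  Every sample is scaled to median
1 over its non-missing cells (missing cells carry no intensity, so they do
not enter the median); intensities are then natural-log transformed, while
fold changes are computed on the un-logged normalized scale as
log2(measurement 2 / measurement 1) per subject and day — the two log bases
coexist deliberately, matching the construction of the two datasets.
Haemolytic or otherwise excluded samples are dropped by an explicit
config-level list before any filtering; matrix operations never drop
columns silently.

## Peptide-level ANCOVA

For each protein, all Day-2 peptide log2 fold changes are stacked as
observations and modeled as fc2 ~ grp + sex + fc1 with centered ±0.5 factor
codes and the same peptide's Day-1 fold change as covariate; the Type II
group main-effect p decides significance (α = 0.05, uncorrected — an FDR
column is reported for transparency but selection follows the uncorrected
rule), and the sign of the adjusted group contrast gives the direction.
Stacking peptides multiplies the effective sample size and is the method's
deliberate power device, but it treats within-subject peptides as
independent replicates; a per-subject-averaged sensitivity mode (one
observation per subject) is provided, off by default.  A group×sex
interaction mode exists but the default model is main-effects (the
interaction is not part of the stated model).  Proteins represented in only
one arm, or with fewer observations than parameters, are skipped with an
explicit reason.

One consequence of the stacked design is visible in null simulations at
small proteome size: the per-sample median used for normalization is itself
an estimate, and its error is shared by all peptides of a sample.  At 50
proteins (~225 peptides) this inflates the empirical type-I rate of the
group test to roughly 6–7% at nominal 5%; the inflation shrinks as the
number of peptides grows (at 200 proteins it is ~5.5%) and is negligible at
real-data scale (thousands of peptides).

## Variance dissection

Per protein, the Day-2 fold change across subjects is modeled with seven
non-intercept terms: DAS, grp, sex, DAS·grp, DAS·sex, grp·sex, DAS·grp·sex,
with grp/sex as centered two-level factors.  Missing cells (≤5% per row by
construction) are completed by predictive mean matching: observed cells of
the row are regressed on (DAS, grp, sex), and each missing cell is filled
with the observed value of a donor drawn uniformly from the k = 5 donors
with the nearest predicted mean; m = 5 independent completions are
generated from a seeded stream, with a single-nearest-donor fallback (and a
warning) when fewer than k donors exist.  Each completion is fit after a
robust pre-pass: bisquare (Tukey biweight) IRLS with tuning constant 4.685
(95% Gaussian efficiency) and MAD scale; observations whose converged
weight falls below 0.01 are removed — the weight function is specified by
the method, the cutoff is this package's choice — and at least 12 subjects
must remain.  The final fit is plain OLS.  Model R² is SS_regression/SS_total;
per-term shares are Type II partial SS rescaled so the seven terms sum to
the model R² (only the total R² is defined by the method; the rescaled
Type II attribution is a documented choice, exact under orthogonal
predictors).  Per-imputation results are pooled by element-wise medians
(fractions, R², and p-values alike; Rubin's rules were considered but the
median matches the stated summarization and is what significance screening
uses).  Proteins with at least one term p ≤ 0.05 feed the per-factor GO
enrichment.

## GO enrichment and GO-signature regressions

Enrichment of a study set (e.g. the ANCOVA-significant proteins) is tested
per term with the hypergeometric upper tail P(X ≥ k) under
Hypergeometric(N, K, n), where the background N is the detected proteome —
for synthetic runs, all proteins surviving the 5% filter — not the whole
annotation universe.  Benjamini–Hochberg FDR is applied across the tested
terms within one analysis.  Terms annotating identical protein sets after
restriction to the background are fully redundant and collapse to the
lexicographically first term id.  Significant terms are clustered by
Jaccard similarity: edge iff J > 0.4 (strict), clusters are connected
components, invariant to input order.  Annotation input is a GAF-style
3-column TSV filtered to the biological-process namespace; GO-graph
ancestor propagation is not performed (flat annotation files are assumed;
propagation would be a pre-processing step).

For each enriched term, the day-adjusted score is regressed on the Day-2
fold changes of the term's proteins *restricted to the significantly
regulated set*, separately per arm, with the same bisquare outlier removal;
the model F-test p is FDR-corrected across terms within each arm.
Restricting predictors to the significant set is part of the method and
also what keeps the models small relative to the arm sizes; fitting whole
terms as predictors (up to 25 proteins on a 30-subject arm) makes the
robust F-test strongly anti-conservative and is refused when predictors
outnumber arm subjects.

## Responder prediction

Features are Day-2 baseline (measurement 1) protein log-intensities of
placebo-arm subjects with complete protein data; labels follow the
behavioral responder rule.  Selection is two-stage: one-way ANOVA F ranks
proteins and keeps the top 5 (ties broken by protein id), then greedy
sequential forward selection over the complement adds a candidate only when
it lowers the cross-validated misclassification of a linear SVM by more
than 0.02 (5 inner folds, at most 5 additions); the tolerance is roughly
one misclassified subject at n≈50 and keeps pure-noise additions rare while
retaining sensitivity to genuinely informative proteins.  For tractability
the forward search considers the 30 best remaining proteins by F (the full
complement is available via a parameter).  The SVM is linear with C = 1 and
features z-scored by training-fold statistics; no hyperparameters are
tuned.

Evaluation runs stratified k-fold CV (k = 10, reduced automatically when a
class has fewer members) over 10 independent fold permutations; held-out
decision values are pooled into one ROC per permutation; the median ROC is
the vertical (per-FPR) median on a 101-point grid; mean ± SD AUC is
reported, plus a pooled confusion matrix at decision threshold 0.  The
RANDOM null repeats the evaluation with uniformly drawn protein sets of the
selected size.  Whether feature selection belongs inside the CV folds is
ambiguous in the described sequence; both modes are implemented.  The
default is the honest mode (preselection and forward selection re-run
inside every training split), whose AUC is unbiased; `full_data_selection=True`
selects once on the full data and is optimistic by construction.  Chance-
level behavior under permuted labels holds in expectation over
permutations: a single permutation retains chance correlation with strong
planted cluster structure, so permutation checks average several
independent permutations.

## Synthetic study generator

The generator emulates the trial: 60 placebo / 30 control subjects, both
arms half female; per measure, a latent baseline and vection-induced rise
per day with additive Gaussian day-to-day noise, clipped and rounded to the
instrument scales (NRS 0–10, SSMS 0–18; log-NTT stays continuous).  The
Day-1 nausea rise is drawn ≥5, emulating the inclusion screen.  Placebo
effects attenuate the Day-2 rise by a configured multiple of the day-noise
SD: 1.3 for nausea, 0.85 for motion sickness, 0.65 (females only) for the
NTT drop.  These defaults were calibrated once so the emulated behavioral
analyses land in the regime of the trial this design mirrors — group F
near 40 for DAS-nausea with roughly 65% vs 15% responders, F near 15 for
DAS-MS, and a female-only NTT effect with F near 4 — and are not adjusted
thereafter.  With the simple shared-noise model the MS responder fraction
(~35%) is lower than its real-trial counterpart; matching both the F
statistic and the responder fraction simultaneously would need a
heavier-tailed noise model and is a documented infidelity.

Peptide intensities are log-normal: protein mean ~N(14, 1.5) (ln scale),
peptide offset ~N(0, 1), subject effect ~N(0, 0.3), cell noise ~N(0, 0.25).
30% of proteins carry a ±1.0 ln-unit sex effect; 5% carry a group×day
effect (±1 log2 on placebo Day-2 post-vection samples); 5% carry a ±1.0
ln-unit baseline shift on Day-2 measurement 1 for placebo-arm subjects who
qualify as *nausea* responders (responder signal is tied to the nausea
labels; MS-responder prediction on synthetic data therefore performs at
chance, which the analysis scripts report as the built-in negative
control).  Missingness is Bernoulli with logistic probability decreasing in
log-intensity (steepness 1.5), with the logistic midpoint calibrated by
bisection to a 4% marginal rate — the MNAR pattern typical of DIA — and the
sparse variant un-masks a random 80% of masked cells.  Annotation terms are
random protein sets of size 5–25; three "enriched" terms draw 60% of their
members from the regulated set.  All draws come from one seeded generator;
identical seeds give byte-identical studies.

What the generator does **not** emulate: correlated protein modules,
batch/run-order drift, peptide-level interference or shared peptides,
heavy-tailed behavioral noise, and annotation hierarchy.  Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated generative model, not robustness to every
real-data pathology.

## Problem sizes and seeds

Default analysis runs use 200 proteins (~900 peptides, 360 samples); null
calibrations use 500 replicates at 50 proteins; planted variance recovery
uses 100 replicates at n = 90.  The detected proteome of the motivating
experiment is larger (hundreds of proteins, thousands of peptides); matrix
dimensions here are a configurable choice that keeps full-pipeline runs in
the minutes range, and no analysis asserts fidelity to detected-proteome
size.  Every stochastic component (generator, imputation donors, fold
assignment, random feature sets) derives from explicit integer seeds.
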