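# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Discovery stage: spectral-count statistics

**Pooling.** Counts are summed across all samples within a group (PT or
LT) before any ratio or test; a per-case mode (mean of within-case Rsc
values over the paired cases) is available via `mode="per_case"` but is
not the default, because a pooled comparison yields the single Rsc/p pair
per protein that the selection rule needs. The G-test always uses pooled
margins.

**Rsc.** The log2 spectral-count ratio with pseudo-count *f*:

    Rsc = log2((n_LT + f)/(n_PT + f)) + log2((t_PT − n_PT + f)/(t_LT − n_LT + f))

The second term corrects for unequal group depth; the pseudo-count keeps
the ratio finite for proteins identified in only one group. Default
f = 0.5, the common convention for this statistic; it is exposed as a flag.
Sign convention: **positive Rsc (and SpI) = LT-enriched**. Reported fold
change is `2^|Rsc|` (always ≥ 1, direction carried separately).

**NSAF.** `NSAF_i = (n_i/L_i) / Σ_j (n_j/L_j)` within each group, with
L the protein length in amino acids. Proteins with zero pooled count get
NSAF 0; the remainder sum to 1 per group (checked to 1e−12). A detected
protein without a length is an error, never silently dropped.

**SpI.** With c the pooled group counts, d the number of the group's
samples with a positive count and m the group size:

    SpI = (c_LT/(c_PT+c_LT))·(d_LT/m_LT) − (c_PT/(c_PT+c_LT))·(d_PT/m_PT)

SpI is ±1 exactly when a protein is detected in every sample of one group
and none of the other; a protein with no counts at all has *undefined*
SpI, returned as NaN — never 0, since 0 means "balanced".

**G-test.** Likelihood-ratio test on the 2×2 table
[(n_PT, n_LT), (t_PT−n_PT, t_LT−n_LT)] with expected counts from the
margins, `G = 2·Σ O·ln(O/E)` with the convention `0·ln(0/E) = 0`, referred
to χ²(1). No Williams or continuity correction by default (a
`williams=True` flag exists): the plain G-test is the cited form, and at
pooled depths of hundreds of counts per group the corrections are
negligible. With ~10,000 proteins at such depths the empirical null
rejection rate at α = 0.05 is within two binomial standard errors of 0.05
(verified in the test suite and the acceptance script).

**Selection.** `selected ⇔ |Rsc| > 1 AND p < 0.05`, both inequalities
strict; the two gates commute (the selected set is the intersection of the
gates computed independently). BH q-values are always reported but play no
role in selection — the rule reproduces the original single-test
procedure, and the q column lets users apply modern FDR control if they
prefer. Optional secondary filters `--spi-min` (|SpI| with sign agreeing
with Rsc) and `--nsaf-ratio-min` (NSAF ratio in the direction of change)
are off by default because no numeric cutoff is part of the published
rule. Output is sorted by |Rsc| descending, ties by ascending p then
accession.

**Venn summaries.** A protein is "identified" in a group iff its pooled
group count is positive. `VennSummary.from_set_sizes` reconstructs the
partition from printed set sizes (|PT|, |LT|, |shared|) so published
Venn figures can be checked without count-level data. Note that
1,893/3,722 = 50.86%, which prints as 50.9 under round-half rules; the
conventional printed value 50.8 reflects truncation, so comparisons
against printed percentages should allow ±0.1.

## Validation stage: survival statistics

**Exclusions.** Patients with synchronous liver metastasis have no liver
recurrence-free survival time and are removed before any RFS computation;
the count removed is reported.

**Kaplan–Meier.** Standard right-continuous product-limit estimator
(delegated to lifelines), with Greenwood standard errors. Subjects
censored at an event time remain at risk at that time. Landmark survival
(default 120 months = "10-year liver RFS") is read from the step function
with events at t included — the universal KM convention, consistent with
the closed-form checks in the test suite.

**Log-rank.** The O−E/V chi-square across strata (df = groups−1), equal to
the Cox partial-likelihood score test at β = 0 for a binary covariate with
untied event times (verified to 1e−6 in tests). A cohort with no events
returns statistic 0, p = 1 rather than NaN.

**Cox proportional hazards.** Partial-likelihood maximization through
statsmodels' implementation, chosen because it supports both Efron
(default — better under the heavy ties of month-resolution follow-up) and
Breslow tie handling. Wald CIs and p-values. Degeneracies are surfaced,
not smoothed over: zero events raise an explicit error; constant
covariates are flagged non-identifiable with NaN HR while the rest of the
model is fit; |coef| > 15 or non-finite standard errors flag suspected
monotone likelihood (separation) and mark the fit non-converged. The
small-sample correctness is checked against a brute-force grid search of
the explicit partial likelihood, and whole fits against an independent
Cox implementation.

**ROC cutoffs.** AUC by the Mann–Whitney construction (ties count 1/2),
p-value from the two-sided Mann–Whitney test of AUC = 0.5. The cutoff
maximizes Youden's J = sensitivity + specificity − 1 over midpoints of
adjacent distinct observed values plus both boundaries, classifying
`value ≥ cutoff` as positive; ties in J break toward the lower cutoff
(the conservative choice for a "size ≥ cutoff" rule). Continuous
covariates (Ki-67, tumor size) are dichotomized at their ROC cutoffs
before entering the Cox screen, mirroring clinical practice.

**Univariate → multivariate gate.** Every covariate (function type, grade
contrasts, dichotomized Ki-67 and size, nodal/vascular/lymphatic invasion,
stage III/IV, each marker) is screened with a single-covariate Cox model;
those with univariate p < 0.05 enter the multivariate model. A
`force_covariates` argument can override the gate.

**Categorical tests.** Fisher's exact test for 2×2, Pearson χ² without
Yates correction by default, and for r×c tables with small expected cells
a Monte-Carlo exact test: tables are sampled with the observed margins
fixed and the p-value is the null probability of a table no more probable
than the observed one (the Fisher-exact generalization; 20,000 draws by
default, with the +1 correction keeping the estimate a valid p-value).
The `auto` method applies χ² and falls back to an exact test when any
expected cell is below 5. Three-group comparisons test all three
metastasis groups jointly.

## Synthetic data

**Counts.** Per protein, a latent expected count λ is drawn log-normal
(default median 2.0 counts/sample, σ = 1.2 on the log scale — a heavy
tail matching spectral-count data); per sample the count is
Poisson(λ·depth), thinned by Bernoulli dropout with probability
`p0·exp(−λ/τ)`, which mechanically produces the one-group-only
identifications seen in Venn figures. Differential proteins (a configured
fraction, direction split at random) have one group's λ multiplied by the
fold. Lengths are log-normal (median 400 aa, σ = 0.45, floor 50) and
independent of abundance by default; a length-proportional option
exercises NSAF's length correction the other way. Per-sample depth
variability (`sample_depth_sigma`) is off by default — the pooled
comparison assumes stable depth, and the knob exists precisely to stress
that assumption. An LT depth factor > 1 emulates the deeper
identification usually seen in one tissue; it cancels from Rsc's
depth-corrected ratio and the G-test margins, but interacts with dropout,
so under the calibrated configuration the pooled G-test also responds to
detection asymmetry — as real presence/absence patterns do.

**Calibration fixture.** `fixtures/venn_calibration.json` freezes
(median 0.3, σ 1.4, p0 0.8, τ 9.0, LT depth 1.4), chosen by scanning the
generator until the PT-only/LT-only/shared fractions of the simulated
union matched the ~19.6/29.6/50.8 overlap structure of a deep paired FFPE
discovery set; at 6,000 simulated proteins this yields ≈2,500/2,900
identifications per group. Across seeds the fractions vary by ~±3
percentage points.

**Cohorts.** Each patient is synchronous with probability 8/70 (no RFS
time, covariates shifted upward ×1.8 to reflect more advanced disease);
for the rest, time to liver recurrence follows h(t) = h₀·exp(β_m·marker +
β_s·1[size ≥ 42 mm]) with exponential baseline h₀ = 0.0005/month by
default (Weibull available) and administrative censoring uniform on 6–240
months. Metastasis group is outcome-derived: metachronous if the
recurrence is observed, none otherwise — so marker-positivity rates are
configured for the synchronous and at-risk strata
(defaults 0.875 / 0.45), and the enrichment of positivity among
metachronous patients *emerges* from the planted hazard rather than being
imposed. Defaults plant HR 6.19 for marker positivity and 4.63 for
size ≥ 42 mm and give mean group sizes ≈ 8/13/49 at n = 70. Ki-67 and
tumor size are log-normal (medians 3% and 22 mm); grade and stage are
deterministic functions of Ki-67 and size plus the synchronous flag.
Follow-up is recorded at month resolution (rounded to 0.1, floored at 0.1
so times stay positive); tumor size in whole millimetres, with the hazard
computed from the recorded (rounded) value so analysis covariates match
the generative ones.

**What the generator does not emulate.** No peptide- or spectrum-level
structure, shared peptides, or search-engine scores; no correlation
between protein abundance and length by default; no informative censoring,
competing risks (death before recurrence is treated as censoring), or
covariate missingness; invasion flags are independent of the hazard, so
their univariate HRs are null. Passing recovery tests therefore shows the
statistics are implemented and calibrated correctly, not that the pipeline
is robust to batch effects, shared-peptide inference or informative
dropout in real data.

## Problem sizes used in tests and the acceptance script

Null calibration uses 10,000 proteins at high depth (median 20
counts/sample, no dropout) so the χ² approximation is in its valid range;
selection recovery uses 4,000 proteins with 5% planted at 4-fold and is
evaluated among planted proteins with pooled count ≥ 10 (below that, no
count-based statistic can reliably call a 4-fold change); hazard-ratio
recovery uses cohorts of 2,000 with censoring set for ≈40% events and 200
replicate fits for CI coverage. These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping a full run in the order of a
minute.

## Known limitations

* The pooled G-test treats pooled counts as one multinomial draw; real
  between-case overdispersion (off by default in the generator) inflates
  its type-I error, which is why the per-case mode and the
  `sample_depth_sigma` knob exist.
* The Monte-Carlo exact test's resolution is limited by the number of
  draws (default 20,000 → p-values below ~5e−5 are reported at the
  resolution floor).
* Separation detection in the Cox fit is heuristic (coefficient/SE
  thresholds), not a formal monotone-likelihood test.
* The ROC cutoff is chosen on the same cohort it is then tested on, as in
  the original two-stage design; the resulting multivariate p-values are
  optimistic in the usual way and no internal validation (bootstrap,
  cross-validation) is attempted.
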