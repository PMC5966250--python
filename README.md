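# specount

Label-free spectral-counting differential proteomics with a
clinicopathological survival-validation stage.

## The problem

Paired tumor proteomics by shotgun LC-MS/MS often starts from spectral
counts: the number of MS/MS spectra assigned to each protein is a
semi-quantitative proxy for its abundance. A typical study design — here
modeled on the comparison of primary pancreatic neuroendocrine tumors (PT)
with paired liver metastases (LT) — has two stages:

1. **Discovery.** Pool spectral counts across paired cases per group and,
   per protein, compute

   * the spectral-count log-ratio with pseudo-count *f*
     (positive = LT-enriched):

     `Rsc = log2((n_LT + f)/(n_PT + f)) + log2((t_PT − n_PT + f)/(t_LT − n_LT + f))`

     with `n` the protein's pooled counts and `t` the group totals; the
     reported fold change is `2^|Rsc|`;
   * the normalized spectral abundance factor
     `NSAF_i = (n_i/L_i) / Σ_j (n_j/L_j)` (length-corrected relative
     abundance, summing to 1 per group);
   * the spectral index `SpI ∈ [−1, +1]`, weighting each group's share of
     the counts by its detection frequency across replicates;
   * a G-test (likelihood-ratio χ², df = 1) of the protein's count split
     against the group margins.

   Candidates satisfy the strict rule **|Rsc| > 1 and p < 0.05**;
   Benjamini–Hochberg q-values are reported alongside. Identification-set
   (Venn) summaries count a protein as identified in a group when its
   pooled count is positive.

2. **Validation.** On a surgical cohort scored by immunohistochemistry
   (positive = ≥ 10% of tumor cells stained), compare clinicopathological
   factors across metastasis groups (χ²/Fisher/exact, Mann–Whitney,
   Kruskal–Wallis), discover ROC/Youden cutoffs for continuous markers
   (Ki-67 index, tumor size), estimate liver recurrence-free survival
   (RFS) by Kaplan–Meier with the log-rank test — excluding synchronous-
   metastasis patients, who have no RFS time — and screen covariates with
   univariate Cox proportional-hazards models, passing those with p < 0.05
   into a multivariate model (Efron ties by default).

Because raw MS and patient-level data of such studies are rarely public, a
seeded synthetic-data module generates count matrices (log-normal expected
counts, Poisson sampling, abundance-dependent detection dropout, planted
fold changes) and cohorts (proportional-hazards event times with planted
hazard ratios, administrative censoring) with ground truth, so every stage
can be tested for recovery and calibration.

## Worked example

Simulate a paired 7-case count matrix with the packaged
identification-overlap calibration, run the discovery stage, then simulate
a 70-patient cohort and run the validation stage:

```bash
specount simulate --kind counts --calibrated --seed 7 --out-dir sim
specount differential --counts sim/counts.tsv --sample-map sim/sample_map.tsv \
    --lengths sim/annotations.tsv --out-dir diff
specount simulate --kind cohort --seed 7 --out-dir simc
specount survival --cohort simc/cohort.csv --marker CNPY2 --out-dir surv
```

prints

```
identified: 3638 (PT-only 698, LT-only 1162, shared 1778); selected: 406
log-rank chi2=15.445 p=0.0001; landmark S(120m) 0: 0.922, 1: 0.555
```

The first line is the discovery funnel: 3,638 proteins identified in at
least one group, partitioned into PT-only / LT-only / shared (19.2% /
31.9% / 48.9% here — the calibrated generator reproduces the ~20/30/50
overlap structure of deep paired FFPE experiments), of which 406 pass the
|Rsc| > 1 and p < 0.05 gate. The second line is the validation stage for
the marker `CNPY2`: marker-positive patients have markedly worse liver RFS
(10-year RFS 55.5% vs 92.2%, log-rank p = 1e-4). The multivariate report
(`surv/validation_multivariate.tsv`) carries the Cox hazard ratios with
Wald 95% CIs, e.g. here `marker_CNPY2  HR 9.40 (2.03–43.51)  p = 0.0042`
against a planted hazard ratio of 6.19.

`diff/discovery_differential.tsv` holds the full per-protein table with
columns `accession, symbol, n_PT, n_LT, Rsc, fold_change, direction, G, p,
q, NSAF_PT, NSAF_LT, SpI, selected`; all JSON summaries echo the config
and seed and carry a content hash, so identical runs are verifiably
identical.

The same analyses are available as library functions
(`specount.differential_table`, `specount.liver_rfs_analysis`, …); see
`docs/methods.md` for the statistical details and design choices.

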