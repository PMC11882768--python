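# Methods

## Screen scoring

The pipeline starts from a per-guide integer count table with control and
treated samples. Each sample is scaled to reads per million by its own
column total, then replicate samples of the same condition (arm × drug ×
concentration × timepoint) are averaged — normalisation before averaging,
so unequal replicate depths do not bias the condition mean. The CRISPR
Score of a gene is the mean over its guides of
`log2((treated + c) / (control + c))` with a pseudocount `c` of 1 RPM.
The pseudocount guards guides that drop to zero under selection; it only
matters for abundances near or below 1 RPM, and the value used is
recorded in the run configuration alongside every score.

Significance uses the two-sample Kolmogorov–Smirnov test comparing the
gene's guide abundance vector between treated and control conditions
(SciPy's implementation; exact p-values at the small per-gene sample
sizes, asymptotic otherwise). An alternative reading — the gene's guide
log-ratios against the all-guide background ratio distribution — is
available behind `RunConfig.ks_mode = "gene_vs_background"`; the
treated-vs-control form is the default because it is the direct
two-sample statement of the comparison. Genes with fewer than two guides
get no p-value and can never be candidates.

Benjamini–Hochberg FDR is computed across the genes that pass the
guide-count inclusion rules (the analysis set); it is reported but does
not gate candidate selection, which uses the raw p-value as the published
cut-off does. The inclusion rules themselves are: exclude any gene with
fewer than 4 non-zero control guides, then include genes with more than 3
non-zero treated guides, or exactly 3 with 4–7 non-zero control guides,
or exactly 2 with 4–5 non-zero control guides. Candidates satisfy
CS > 0.5 and p < 0.05, both strict. Ranked output orders by CS
descending, then p ascending, then gene id, so ties are deterministic.

When a screen has several treated conditions each is scored separately
against the pooled control; no pooling across concentrations or
timepoints is performed, matching per-screen candidate lists.

## Panels and Max_CS groups

Panel genes carry a CS group: group 1 (moderate) for 0.5 < CS < 5, group
2 (high) for CS ≥ 5. The boundary is inclusive on the high side; with
the reported candidate score range (1.4–7.15 and a clear break below the
top three genes) the inclusivity choice does not move any gene between
groups. Panels are per drug; a combined panel takes the union with each
gene's maximum CS.

## Cohort filtering

Patient inclusion (in order, each step logged): fewer than 1000 raw
mutations (strict); treated with the drug under study; genetic
information present (the patient appears in the mutation table) and a
known response label. Response dichotomisation maps complete and partial
response to sensitive, stable and clinical progressive disease to
resistant; any other label is an error, never a silent drop.

Mutation inclusion, applied in order to eligible patients' rows:

1. variant class in {Frame_Shift_Del, Nonsense_Mutation, Frame_Shift_Ins,
   Splice_Region, In_Frame_Ins, Splice_Site, In_Frame_Del,
   Translation_Start_Site, Missense_Mutation};
2. read depth > 20 (strict);
3. variant allele fraction t_alt_count / t_depth > 10% (strict);
4. in highly mutated genes — genes mutated in more than 3.5% of eligible
   patients, with prevalence computed after steps 1–3 within the same
   drug cohort the rule de-noises — only loss-of-function classes
   (Frame_Shift_Del, Nonsense_Mutation, Frame_Shift_Ins) with percent
   alteration > 80% are kept;
5. nuclear chromosomes only (drop MT/chrM/M).

"Percent alteration" is interpreted as the variant allele fraction × 100
throughout (including the cell-line classification): it is the only
per-variant percentage the MAF fields support. Filtering is conservative
in bookkeeping: every stage's removed-plus-retained equals its input, the
chain is idempotent, and the per-rule counts are emitted as the audit
log. Multiple retained mutations in one gene count once for panel
membership.

## Prediction and statistics

A patient's Max_CS is the maximum CS over panel genes carrying retained
mutations; group 0 (label "none") with no panel hit, otherwise the CS
group of the best-scoring hit (1 = "moderate", 2 = "high"). The cohort
statistics are:

* Pearson chi-square on the 2×2 flagged (group ≥ 1) × response table,
  1 df, no continuity correction (Yates available behind a flag);
* odds ratio (a·d)/(b·c) with the Woolf log-scale CI, z = 1.96; the
  Haldane–Anscombe +0.5 applied to all cells only when some cell is zero,
  and a degenerate margin reported as undefined;
* a binomial GLM (statsmodels) of resistance on the group code entered
  *numerically* (0/1/2). The numeric coding is deliberate: the fitted
  probabilities are a two-parameter logistic smooth of the three raw
  group proportions, which is what reproduces the published fitted values
  (e.g. raw paclitaxel proportions 0.213/0.455/0.667 smooth to
  0.21/0.44/0.69). Both the likelihood-ratio test against the
  intercept-only model and the Wald p-value on the slope are reported —
  the published significance level matches the Wald form. Perfect
  separation is flagged explicitly. The score equation
  Σ n_g·p̂(g) = Σ resistant_g holds at any ML solution and is asserted in
  the tests;
* objective response rate = fraction with complete/partial response,
  for the whole cohort and the flagged subset.

## Validation analyses

Expression: per panel gene, log2 fold change of mean TPM (resistant vs
sensitive, pseudocount ε = 1 TPM), Welch t-test on log2(TPM + 1), BH FDR
across the tested panel genes; summaries report the fraction
downregulated and the fractions at FDR < 0.05 and < 0.1. Welch's test is
used wherever a t-test is otherwise unspecified. Survival: Kaplan–Meier
product-limit curves via lifelines and the Mantel–Cox log-rank test with
the standard hypergeometric tie variance. Cell lines: TP53-LoF requires a
frame-shift/nonsense mutation, percent alteration > 80 and Nutlin IC50
> 50 (Nutlin kills only p53-proficient cells, so insensitivity
corroborates functional loss); WT requires no TP53 mutation and Nutlin
IC50 < 10; everything else is unclassified. Sensitive lines have
Z < −1.5 strictly; classes are compared by Welch t on Z-scores and a
two-proportion z-test on sensitive fractions.

## Synthetic data

The generators produce every input the pipeline reads, with truth labels
sufficient for exact confusion matrices, and are pure functions of
(spec, seed).

*Screen*: per-guide abundances are Gamma-distributed (shape 4) to mimic
library composition skew, scaled to a mean depth of 500 reads per guide;
counts are negative binomial with dispersion α = 0.15 (overdispersion is
the norm in screen count data). Treated means are multiplied by the
enrichment factor (default 8) for planted resistant genes — survival of
knockout cells under selection — and an independent 5% dropout zeroes
treated guide counts regardless of class, emulating guide loss. Nine
guides per gene match the screens' reported average guide representation.
The published study gives no screen noise parameters, so depth and
dispersion were chosen once for realistic test power rather than fidelity
to any particular deposited dataset.

*Cohort*: patients draw a Max_CS group from the published paclitaxel
group sizes (160/44/18 of 222) and a Bernoulli response with the
published group resistance probabilities (0.21/0.44/0.69 paclitaxel,
0.33/0.43/0.55 carboplatin available as a preset). Panel mutations are
injected as high-VAF (≥ 85%) loss-of-function calls so they pass every
mutation filter including the highly-mutated-gene rule, making the
generated group exactly recoverable; background mutations (Poisson, mean
25 per patient, at least one so every patient has genetic information on
file) land only on non-panel genes and mix passing and failing rows to
exercise each filter. Survival is exponential with baseline hazard 1/12
per month (median ≈ 8.3 months) multiplied by the hazard ratio (default
2) for carriers, with independent exponential censoring tuned to the
censor rate — the simplest model consistent with a log-rank comparison.

*Expression*: log-normal TPM (log2 means N(5, 2), unit within-gene SD)
with panel genes shifted by the downregulation effect (default −1 log2)
in resistant patients. *Cell lines*: LoF and WT lines constructed to
satisfy their classification criteria exactly, Z-scores normal with unit
SD and a mean shift (default 1) making LoF lines less sensitive.

What the generators do **not** emulate: clonal heterogeneity and
copy-number structure of real tumours, guide-efficiency variation,
correlated mutational signatures, non-proportional hazards, and
expression covariance between genes. Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration under its own
assumptions, not clinical performance on real cohorts.

## Problem sizes and numerical choices

Recovery and calibration experiments run at reduced scale chosen to keep
the whole suite fast while retaining power: screens of 1000 genes × 9
guides (20 planted, enrichment 8, depth 500), cohorts of 2000 patients
over 100 seeds for predictor calibration, and 200 replicates per arm for
log-rank type-I error (n = 200/arm) and power (hazard ratio 2,
n = 300/arm). Desk-scale statistics (odds ratio, CI, logistic fits, ORR)
are exact recomputations from the published cohort tables and run in
milliseconds. Thresholds are strict as printed; ties in ranked outputs
break deterministically; and all randomness flows from a single integer
seed per spec.

## Known limitations

The KS test at 9 guides per arm has a coarse discrete null, so per-gene
p-values are super-uniform and candidate selection leans on the CS
threshold for specificity. The highly-mutated-gene denominator is the
eligible cohort, which makes filter 4 cohort-dependent by design. The
synthetic cell-line table contains only clearly classifiable lines; real
sensitivity data include lines failing both criterion sets.
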