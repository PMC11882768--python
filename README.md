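# crispredict

Predicting tumour resistance to paclitaxel and carboplatin from genome-wide
CRISPR loss-of-function screen results and patient mutation profiles.

Many tumours have innate resistance to first-line chemotherapies. A
genome-wide knockout screen in haploid cells identifies the genes whose loss
lets cells survive drug exposure; a tumour that already carries inactivating
mutations in those genes is a candidate for innate resistance. `crispredict`
implements the full computational chain from raw guide-count tables to a
clinically interpretable resistance prediction, together with the synthetic
data needed to exercise and calibrate every stage. It is aimed at
computational biologists working with pooled CRISPR screens and retrospective
clinical cohorts.

## The model

**CRISPR Score.** Guide counts are normalised to reads per million within
each sample and replicates averaged per condition. For guide *g* of a gene,

    ratio_g = log2((trt_g + c) / (ctrl_g + c)),      c = 1 RPM pseudocount

and the gene's CRISPR Score is CS = mean(ratio_g) over its guides. CS > 0
means knockouts of that gene were enriched under drug selection. Significance
is a two-sample Kolmogorov–Smirnov test of the gene's guide abundances
(treated vs control) with Benjamini–Hochberg FDR across genes. Genes pass
guide-count inclusion rules (at least four non-zero control guides, and
enough non-zero treated guides relative to control), and candidates satisfy
CS > 0.5 and p < 0.05 (strict).

**Max_CS grouping.** Candidate genes form a drug panel split at CS = 5 into
moderate (group 1, 0.5 < CS < 5) and high (group 2, CS ≥ 5) scorers. After
MAF-style mutation filtering (whitelisted variant classes, depth > 20,
VAF > 10%, the highly-mutated-gene rule, nuclear genes only), each patient is
assigned Max_CS = max CS over mutated panel genes, giving groups 0/1/2.

**Cohort statistics.** Flagged (group ≥ 1) vs unflagged patients are compared
against observed response (CR/PR = sensitive, SD/PD = resistant) with a
Pearson chi-square, the odds ratio with Woolf CI
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), and a grouped logistic regression

    P(resistant | group) = expit(β0 + β1 · group),   group ∈ {0, 1, 2},

whose fitted probabilities are the headline prediction. Kaplan–Meier /
log-rank survival, panel-gene expression fold changes, and a TP53-LoF vs WT
cell-line comparison provide orthogonal validation.

## Worked example

`examples/02_cohort_prediction.py` generates a 2000-patient cohort whose
resistance probability by Max_CS group is 0.21/0.44/0.69, filters it, and
refits:

```
cohort: 2000 patients, 50996 raw mutation calls
eligible patients: 2000; retained mutations: 34853
  removed by variant_class_whitelist: 10165
  removed by read_depth: 4005
  removed by vaf: 1248
  removed by highly_mutated_gene_lof_only: 0
  removed by nuclear_genes_only: 725

flagged among resistant patients: 48%
flagged among sensitive patients: 19%
odds ratio: 3.81 (95% CI 3.09-4.69), chi-square p = 1.5e-38
fitted P(resistant) by Max_CS group: {0: 0.22, 1: 0.44, 2: 0.7}
ORR (all patients): 0.70
```

The refitted probabilities recover the generating 0.21/0.44/0.69 up to
binomial noise: patients with a mutation in a high-CS panel gene are about
three times as likely to resist treatment, and the filter log accounts for
every removed mutation row. The other examples cover screen scoring and
panel recovery (`01`), survival and expression validation (`03`), and the
cell-line comparison (`04`).

The same chain is available as a CLI:

```bash
crispredict simulate --out run/
crispredict score-screen --counts run/counts.tsv --samples run/samples.tsv --out run/
crispredict build-panel --scores run/gene_scores.tsv --drug paclitaxel --out run/screen_panel
crispredict filter-cohort --maf run/maf.tsv --clinical run/clinical.tsv --drug paclitaxel --out run/
crispredict predict --profiles run/profiles.tsv --panel run/panel.tsv --out run/
crispredict validate --profiles run/profiles.tsv --panel run/panel.tsv \
    --tpm run/expression.tsv --ccl run/ccl.tsv --out run/
crispredict report --dir run/
```

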