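"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the pipeline's inputs end to end:

* ``gen_screen_counts`` — negative-binomial guide counts with a planted
  set of resistance genes whose treated-arm means are multiplied by an
  enrichment factor (knockout cells surviving selection), plus an
  independent per-guide dropout.
* ``gen_cohort`` — a patient cohort whose resistance probability depends
  on the Max_CS group; panel mutations are injected as high-VAF
  loss-of-function calls so they survive every mutation filter, and
  background mutations never touch panel genes, keeping the truth labels
  unambiguous. Survival is exponential with a proportional carrier
  hazard and independent exponential censoring.
* ``gen_expression`` — log-normal TPM with panel genes shifted down in
  resistant patients.
* ``gen_ccl_table`` — cell lines satisfying the TP53-LoF / WT
  classification criteria with a normal Z-score shift between classes.

Every generator is a pure function of (spec, seed): the same spec gives
byte-identical tables. Default cohort parameters are the published group
resistance probabilities (0.21/0.44/0.69 for paclitaxel) and group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GuideCountTable, SampleDescriptor
from .panel import PANEL_COLUMNS, GenePanel

PACLITAXEL_GROUP_PROBS = {0: 0.21, 1: 0.44, 2: 0.69}
CARBOPLATIN_GROUP_PROBS = {0: 0.33, 1: 0.43, 2: 0.55}
# published paclitaxel cohort: 160 / 44 / 18 of 222 patients per group
PACLITAXEL_GROUP_PREVALENCE = {0: 160 / 222, 1: 44 / 222, 2: 18 / 222}

_WHITELIST_BG = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Splice_Site",
    "Frame_Shift_Del",
    "In_Frame_Del",
)
_FAIL_CLASSES = ("Silent", "3'UTR", "Intron", "5'Flank")
_LOF_INJECT = ("Frame_Shift_Del", "Nonsense_Mutation", "Frame_Shift_Ins")
_NUCLEAR_CHROMS = [str(i) for i in range(1, 23)] + ["X"]


@dataclass
class ScreenSimSpec:
    """Parameters of a synthetic loss-of-function screen.

    ``mean_depth`` is the expected reads per guide; ``nb_dispersion`` the
    negative-binomial dispersion alpha (variance = mu + alpha * mu^2);
    ``enrichment_factor`` multiplies the treated-arm mean of every guide
    of a planted resistant gene; ``dropout_prob`` zeroes a treated count
    regardless of gene class (guide loss under selection).
    """

    n_genes: int = 1000
    guides_per_gene: int = 9
    n_resistant: int = 20
    enrichment_factor: float = 8.0
    nb_dispersion: float = 0.15
    mean_depth: int = 500
    n_control_reps: int = 2
    n_treated_samples: int = 2
    dropout_prob: float = 0.05
    drug: str = "paclitaxel"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_resistant <= self.n_genes:
            raise ValueError("need 0 <= n_resistant <= n_genes")
        if self.enrichment_factor <= 0 or self.nb_dispersion <= 0 or self.mean_depth <= 0:
            raise ValueError("enrichment_factor, nb_dispersion, mean_depth must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")


@dataclass
class CohortSimSpec:
    """Parameters of a synthetic retrospective patient cohort."""

    n_patients: int = 2000
    panel: GenePanel | None = None
    group_probs: dict[int, float] = field(default_factory=lambda: dict(PACLITAXEL_GROUP_PROBS))
    group_prevalence: dict[int, float] = field(
        default_factory=lambda: dict(PACLITAXEL_GROUP_PREVALENCE)
    )
    background_mutation_rate: float = 25.0
    n_background_genes: int = 2000
    survival_hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 12.0
    censor_rate: float = 0.3
    expression_downreg_log2fc: float = -1.0
    drug: str = "paclitaxel"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_probs) != set(self.group_prevalence):
            raise ValueError("group_probs and group_prevalence must share keys")
        if abs(sum(self.group_prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("group prevalences must sum to 1")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def gen_screen_counts(spec: ScreenSimSpec) -> tuple[GuideCountTable, pd.Series]:
    """Simulate a guide count table plus the planted-gene truth.

    Control counts are negative binomial around a depth-scaled per-guide
    abundance; treated counts share the abundance except for the planted
    resistant genes, whose means are multiplied by the enrichment factor.
    Returns (table, truth) where truth maps gene_id -> is_resistant.
    """
    rng = np.random.default_rng(spec.seed)
    n_guides = spec.n_genes * spec.guides_per_gene
    width = len(str(spec.n_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(spec.n_genes)])
    gene_per_guide = np.repeat(genes, spec.guides_per_gene)
    guide_ids = np.array(
        [f"{g}_sg{j}" for g in genes for j in range(spec.guides_per_gene)]
    )

    resistant = rng.choice(spec.n_genes, size=spec.n_resistant, replace=False)
    is_resistant = np.zeros(spec.n_genes, dtype=bool)
    is_resistant[resistant] = True
    truth = pd.Series(is_resistant, index=pd.Index(genes, name="gene_id"), name="is_resistant")

    # per-guide relative abundance (library composition skew)
    w = rng.gamma(shape=4.0, scale=1.0, size=n_guides)
    mu_ctrl = spec.mean_depth * w / w.mean()
    enrich = np.where(np.repeat(is_resistant, spec.guides_per_gene), spec.enrichment_factor, 1.0)
    mu_trt = mu_ctrl * enrich

    samples = []
    cols = {}
    for r in range(spec.n_control_reps):
        sid = f"ctrl_r{r + 1}"
        samples.append(SampleDescriptor(sample_id=sid, arm="control", replicate=r + 1))
        cols[sid] = _nb_counts(rng, mu_ctrl, spec.nb_dispersion)
    for r in range(spec.n_treated_samples):
        sid = f"trt_r{r + 1}"
        samples.append(
            SampleDescriptor(
                sample_id=sid,
                arm="treated",
                drug=spec.drug,
                concentration=1.0,
                concentration_unit="x",
                replicate=r + 1,
            )
        )
        counts = _nb_counts(rng, mu_trt, spec.nb_dispersion)
        if spec.dropout_prob > 0:
            counts = np.where(rng.random(n_guides) < spec.dropout_prob, 0, counts)
        cols[sid] = counts

    counts_df = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id")).astype(np.int64)
    gene_series = pd.Series(gene_per_guide, index=counts_df.index, name="gene_id")
    return GuideCountTable(counts_df, gene_series, samples), truth


def synthetic_panel(
    n_group1: int = 47, n_group2: int = 3, drug: str = "paclitaxel", seed: int = 0
) -> GenePanel:
    """A stand-alone synthetic resistance panel (synthetic stand-in for a
    screen-derived gene list): moderate genes drawn with CS in (0.6, 4.9),
    high genes with CS in (5, 8)."""
    rng = np.random.default_rng(seed)
    genes, cs, group = [], [], []
    for i in range(n_group2):
        genes.append(f"HI{i:02d}")
        cs.append(float(rng.uniform(5.0, 8.0)))
        group.append(2)
    for i in range(n_group1):
        genes.append(f"MOD{i:02d}")
        cs.append(float(rng.uniform(0.6, 4.9)))
        group.append(1)
    entries = pd.DataFrame(
        {
            "gene_id": genes,
            "cs": cs,
            "p_value": np.full(len(genes), 1e-4),
            "fdr": np.full(len(genes), 1e-3),
            "cs_group": group,
        },
        columns=list(PANEL_COLUMNS),
    )
    entries = entries.sort_values(
        ["cs", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return GenePanel(drug=drug, entries=entries)


def gen_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (MAF, clinical table, truth) for one drug cohort.

    Each patient draws a Max_CS group from ``group_prevalence``, panel
    mutations consistent with that group (high-VAF LoF calls that pass
    every mutation filter), a Bernoulli response with the group's
    resistance probability, background mutations on non-panel genes, and
    an exponential survival time whose hazard is multiplied by
    ``survival_hazard_ratio`` for panel-mutation carriers. The truth table
    carries patient_id, group, response and carrier status.
    """
    if spec.panel is None:
        raise ValueError("CohortSimSpec.panel is required")
    panel = spec.panel
    rng = np.random.default_rng(spec.seed)
    groups_avail = sorted(spec.group_prevalence)
    for g in (1, 2):
        if g in groups_avail and spec.group_prevalence[g] > 0 and not panel.genes_in_group(g):
            raise ValueError(f"panel has no group-{g} gene but group_prevalence[{g}] > 0")

    n = spec.n_patients
    patient_ids = np.array([f"P{i:05d}" for i in range(n)])
    prev = np.array([spec.group_prevalence[g] for g in groups_avail])
    group = rng.choice(groups_avail, size=n, p=prev / prev.sum())
    p_resist = np.array([spec.group_probs[g] for g in group])
    resistant = rng.random(n) < p_resist

    maf_rows: list[dict] = []
    g1_genes = panel.genes_in_group(1)
    g2_genes = panel.genes_in_group(2)

    def inject(pid: str, gene: str) -> None:
        depth = int(rng.integers(40, 120))
        alt = int(np.ceil(depth * rng.uniform(0.85, 1.0)))
        maf_rows.append(
            {
                "Hugo_Symbol": gene,
                "Tumor_Sample_Barcode": pid,
                "Variant_Classification": str(rng.choice(_LOF_INJECT)),
                "t_depth": depth,
                "t_alt_count": min(alt, depth),
                "Chromosome": str(rng.choice(_NUCLEAR_CHROMS)),
            }
        )

    for pid, g in zip(patient_ids, group):
        if g >= 2:
            inject(pid, str(rng.choice(g2_genes)))
            if g1_genes and rng.random() < 0.3:  # high patients may also carry moderate hits
                inject(pid, str(rng.choice(g1_genes)))
        elif g == 1:
            inject(pid, str(rng.choice(g1_genes)))

    # background mutations: never on panel genes; a mix of rows that pass
    # and fail the filters, at least one row per patient so everyone has
    # genetic information on file
    bg_genes = np.array([f"BG{i:04d}" for i in range(spec.n_background_genes)])
    n_bg = np.maximum(rng.poisson(spec.background_mutation_rate, size=n), 1)
    total_bg = int(n_bg.sum())
    bg_patient = np.repeat(patient_ids, n_bg)
    bg_gene = rng.choice(bg_genes, size=total_bg)
    pass_class = rng.random(total_bg) < 0.8
    bg_class = np.where(
        pass_class,
        rng.choice(_WHITELIST_BG, size=total_bg, p=[0.7, 0.1, 0.05, 0.1, 0.05]),
        rng.choice(_FAIL_CLASSES, size=total_bg),
    )
    bg_depth = rng.poisson(60, size=total_bg) + 1
    shallow = rng.random(total_bg) < 0.1
    bg_depth = np.where(shallow, rng.integers(5, 21, size=total_bg), bg_depth)
    bg_vaf = rng.beta(4, 8, size=total_bg)  # mostly > 10%, some below
    bg_alt = rng.binomial(bg_depth, bg_vaf)
    bg_chrom = rng.choice(_NUCLEAR_CHROMS, size=total_bg).astype(object)
    mito = rng.random(total_bg) < 0.02
    bg_chrom[mito] = "MT"

    maf = pd.concat(
        [
            pd.DataFrame(maf_rows),
            pd.DataFrame(
                {
                    "Hugo_Symbol": bg_gene,
                    "Tumor_Sample_Barcode": bg_patient,
                    "Variant_Classification": bg_class,
                    "t_depth": bg_depth.astype(np.int64),
                    "t_alt_count": bg_alt.astype(np.int64),
                    "Chromosome": bg_chrom,
                }
            ),
        ],
        ignore_index=True,
    )
    maf = maf.sort_values(
        ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"], kind="mergesort"
    ).reset_index(drop=True)

    carrier = group >= 1
    hazard = spec.baseline_hazard * np.where(carrier, spec.survival_hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        c_rate = spec.baseline_hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    sens_labels = np.array(["Complete Response", "Partial Response"])
    res_labels = np.array(["Stable Disease", "Clinical Progressive Disease"])
    response_label = np.where(
        resistant,
        rng.choice(res_labels, size=n),
        rng.choice(sens_labels, size=n),
    )
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "drug": spec.drug,
            "response": response_label,
            "time": np.round(time, 6),
            "event": event.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "group": group,
            "response": np.where(resistant, "resistant", "sensitive"),
            "carrier": carrier,
        }
    )
    return maf, clinical, truth


def gen_expression(
    truth: pd.DataFrame,
    panel_genes: list[str],
    downreg_log2fc: float = -1.0,
    n_background_genes: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal TPM matrix with panel genes shifted in resistant patients.

    ``truth`` needs patient_id and response columns. Panel genes receive
    ``downreg_log2fc`` (<= 0) on the log2 scale in resistant patients;
    background genes are exchangeable between groups.
    """
    if downreg_log2fc > 0:
        raise ValueError("downreg_log2fc must be <= 0")
    rng = np.random.default_rng(seed)
    patients = truth["patient_id"].to_numpy()
    resistant = (truth["response"].to_numpy() == "resistant")
    genes = list(panel_genes) + [f"EXBG{i:04d}" for i in range(n_background_genes)]
    base = rng.normal(5.0, 2.0, size=len(genes))
    log2tpm = rng.normal(0.0, 1.0, size=(len(genes), len(patients))) + base[:, None]
    n_panel = len(panel_genes)
    log2tpm[:n_panel, resistant] += downreg_log2fc
    tpm = np.power(2.0, log2tpm)
    return pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=patients)


def gen_ccl_table(
    n_lof: int = 55,
    n_wt: int = 47,
    effect: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-line sensitivity table with a planted Z-score shift.

    LoF lines satisfy all three TP53-LoF criteria (LoF mutation class,
    percent alteration > 80, Nutlin IC50 > 50); WT lines satisfy both WT
    criteria (no mutation, Nutlin IC50 < 10). LoF Z-scores are normal with
    mean ``effect`` (less sensitive), WT with mean 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lof):
        rows.append(
            {
                "line_id": f"LOF{i:03d}",
                "tp53_mutation_class": str(rng.choice(_LOF_INJECT)),
                "alteration_pct": float(np.round(rng.uniform(81.0, 100.0), 3)),
                "nutlin_ic50": float(np.round(rng.uniform(55.0, 150.0), 3)),
                "z_score": float(np.round(rng.normal(effect, 1.0), 6)),
            }
        )
    for i in range(n_wt):
        rows.append(
            {
                "line_id": f"WT{i:03d}",
                "tp53_mutation_class": "",
                "alteration_pct": np.nan,
                "nutlin_ic50": float(np.round(rng.uniform(1.0, 9.5), 3)),
                "z_score": float(np.round(rng.normal(0.0, 1.0), 6)),
            }
        )
    return pd.DataFrame(rows)
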