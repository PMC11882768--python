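"""Patient- and mutation-level inclusion criteria for retrospective cohorts.

Patients enter the analysis if they carry fewer than 1000 raw mutations,
were treated with the drug under study, and have both genetic data and a
known response label. Their mutations are then filtered in a fixed order:
whitelisted variant classes, read depth > 20, variant allele fraction
> 10%, the highly-mutated-gene rule (genes mutated in more than 3.5% of
eligible patients keep only loss-of-function mutations with percent
alteration > 80), and finally nuclear chromosomes only. Every stage logs
how many rows each rule removed; removed + retained always equals input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .io import log_stage, logger

WHITELIST_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Splice_Region",
        "In_Frame_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "Translation_Start_Site",
        "Missense_Mutation",
    }
)

LOF_CLASSES = frozenset({"Frame_Shift_Del", "Nonsense_Mutation", "Frame_Shift_Ins"})

MITO_CHROMOSOMES = frozenset({"MT", "CHRM", "M", "CHRMT"})

_SENSITIVE = {"complete response", "partial response"}
_RESISTANT = {"stable disease", "clinical progressive disease"}


@dataclass
class FilterLog:
    """Audit trail of one filtering stage: rows removed per rule, in order."""

    stage: str
    n_input: int
    removed: list[tuple[str, int]] = field(default_factory=list)

    def record(self, rule: str, n: int) -> None:
        self.removed.append((rule, int(n)))

    @property
    def n_output(self) -> int:
        return self.n_input - sum(n for _, n in self.removed)

    def emit(self) -> None:
        log_stage(self.stage, self.n_input, self.removed, self.n_output)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": self.stage, "rule": "input", "rows": self.n_input}]
        rows += [{"stage": self.stage, "rule": r, "rows": -n} for r, n in self.removed]
        rows.append({"stage": self.stage, "rule": "output", "rows": self.n_output})
        return pd.DataFrame(rows)


@dataclass
class PatientProfile:
    """One analysis-ready patient: response class, survival, filtered genes."""

    patient_id: str
    drug: str
    response: str  # "sensitive" | "resistant"
    mutated_genes: tuple[str, ...]
    survival_time: float
    event: bool


def classify_response(label: str) -> str:
    """Dichotomise a clinical response label.

    Complete/partial response -> sensitive; stable disease / clinical
    progressive disease -> resistant. Anything else is rejected, never
    silently dropped.
    """
    key = str(label).strip().lower()
    if key in _SENSITIVE:
        return "sensitive"
    if key in _RESISTANT:
        return "resistant"
    raise ValueError(f"unrecognised response label {label!r}")


def _has_known_response(label: object) -> bool:
    return str(label).strip().lower() in (_SENSITIVE | _RESISTANT)


def filter_patients(
    clinical: pd.DataFrame,
    maf: pd.DataFrame,
    drug: str,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the three patient inclusion criteria for one drug.

    (1) fewer than ``max_mutations_per_patient`` raw mutations;
    (2) treated with ``drug``; (3) genetic information present (the patient
    appears in the mutation table) and a known response label. Returns the
    eligible rows of ``clinical`` and the per-criterion removal log.
    """
    config = config or RunConfig()
    log = FilterLog("filter_patients", len(clinical))
    df = clinical

    counts = maf["Tumor_Sample_Barcode"].value_counts()
    n_mut = df["patient_id"].map(counts).fillna(0).astype(int)
    keep = n_mut < config.max_mutations_per_patient
    log.record("mutation_count_lt_max", (~keep).sum())
    df = df[keep]

    keep = df["drug"].str.strip().str.lower() == drug.strip().lower()
    log.record("treated_with_drug", (~keep).sum())
    df = df[keep]

    keep = df["patient_id"].isin(set(maf["Tumor_Sample_Barcode"])) & df["response"].map(
        _has_known_response
    )
    log.record("genetic_info_and_known_response", (~keep).sum())
    df = df[keep]

    log.emit()
    return df.reset_index(drop=True), log


def filter_mutations(
    maf: pd.DataFrame,
    eligible_patients: set[str],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the five mutation inclusion criteria, in order.

    The highly-mutated-gene prevalence (criterion 4) is computed within the
    eligible cohort after criteria 1-3, as distinct mutated patients per
    gene over the number of eligible patients. Percent alteration is the
    variant allele fraction times 100. Rows are dropped and logged, never
    erred.
    """
    config = config or RunConfig()
    df = maf[maf["Tumor_Sample_Barcode"].isin(eligible_patients)]
    log = FilterLog("filter_mutations", len(df))

    keep = df["Variant_Classification"].isin(WHITELIST_CLASSES)
    log.record("variant_class_whitelist", (~keep).sum())
    df = df[keep]

    keep = df["t_depth"] > config.depth_threshold
    log.record("read_depth", (~keep).sum())
    df = df[keep]

    vaf = df["t_alt_count"] / df["t_depth"]
    keep = vaf > config.vaf_threshold
    log.record("vaf", (~keep).sum())
    df = df[keep]

    n_eligible = len(eligible_patients)
    prevalence = (
        df.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique() / max(n_eligible, 1)
    )
    highly_mutated = set(prevalence.index[prevalence > config.highly_mutated_fraction])
    in_hot = df["Hugo_Symbol"].isin(highly_mutated)
    vaf_pct = df["t_alt_count"] / df["t_depth"] * 100
    keep = ~in_hot | (
        df["Variant_Classification"].isin(LOF_CLASSES)
        & (vaf_pct > config.alteration_pct_threshold)
    )
    log.record("highly_mutated_gene_lof_only", (~keep).sum())
    df = df[keep]

    chrom = df["Chromosome"].astype(str).str.strip().str.upper()
    keep = ~chrom.isin(MITO_CHROMOSOMES)
    log.record("nuclear_genes_only", (~keep).sum())
    df = df[keep]

    log.emit()
    if highly_mutated:
        logger.info(
            "filter_mutations: %d highly mutated genes (> %.1f%% of %d patients)",
            len(highly_mutated),
            config.highly_mutated_fraction * 100,
            n_eligible,
        )
    return df.reset_index(drop=True), log


def build_profiles(
    eligible: pd.DataFrame,
    retained: pd.DataFrame,
    drug: str,
) -> list[PatientProfile]:
    """One profile per eligible patient; a patient may have no mutations.

    Multiple retained mutations in one gene collapse to a single gene
    membership (panel lookups are per-gene, not per-variant).
    """
    by_patient = retained.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"].agg(
        lambda g: tuple(sorted(set(g)))
    )
    profiles = []
    for row in eligible.itertuples(index=False):
        profiles.append(
            PatientProfile(
                patient_id=row.patient_id,
                drug=drug,
                response=classify_response(row.response),
                mutated_genes=by_patient.get(row.patient_id, ()),
                survival_time=float(row.time),
                event=bool(row.event),
            )
        )
    logger.info("build_profiles: %d profiles for %s", len(profiles), drug)
    return profiles


def profiles_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Serialise profiles to a flat table (genes joined by ';')."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "drug": [p.drug for p in profiles],
            "response": [p.response for p in profiles],
            "mutated_genes": [";".join(p.mutated_genes) for p in profiles],
            "time": [p.survival_time for p in profiles],
            "event": [int(p.event) for p in profiles],
        }
    )


def frame_to_profiles(df: pd.DataFrame) -> list[PatientProfile]:
    return [
        PatientProfile(
            patient_id=row.patient_id,
            drug=row.drug,
            response=row.response,
            mutated_genes=tuple(g for g in str(row.mutated_genes).split(";") if g)
            if not pd.isna(row.mutated_genes)
            else (),
            survival_time=float(row.time),
            event=bool(row.event),
        )
        for row in df.itertuples(index=False)
    ]
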