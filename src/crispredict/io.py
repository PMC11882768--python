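"""Readers and writers for every table the pipeline touches.

All on-disk formats are tab-separated text with mandatory headers. Mutation
tables use the standard MAF column names (Hugo_Symbol, Tumor_Sample_Barcode,
Variant_Classification, t_depth, t_alt_count, Chromosome) so real MAF files
drop in unchanged; MAF coordinates are 1-based and are carried through
untouched — the gene symbol is the only join key the pipeline uses.

Every reader validates its input and raises :class:`TableFormatError` naming
the offending column, row or cell; every reader/writer pair is a lossless
round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crispredict")

RESPONSE_LABELS = (
    "Complete Response",
    "Partial Response",
    "Stable Disease",
    "Clinical Progressive Disease",
)

MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "t_depth",
    "t_alt_count",
    "Chromosome",
)

CLINICAL_COLUMNS = ("patient_id", "drug", "response", "time", "event")

CCL_COLUMNS = ("line_id", "tp53_mutation_class", "alteration_pct", "nutlin_ic50", "z_score")


class TableFormatError(ValueError):
    """A table violates its format contract (missing column, bad cell...)."""


@dataclass(frozen=True)
class SampleDescriptor:
    """Condition labels for one sequencing sample of the screen.

    ``arm`` is ``"control"`` or ``"treated"``; treated samples must name the
    drug and concentration they were exposed to. ``condition`` groups
    replicates: all samples sharing a condition are averaged after
    normalisation.
    """

    sample_id: str
    arm: str
    drug: str = ""
    concentration: float = 0.0
    concentration_unit: str = ""
    timepoint: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.arm not in ("control", "treated"):
            raise ValueError(f"arm must be control/treated, got {self.arm!r}")
        if self.arm == "treated" and not self.drug:
            raise ValueError(f"treated sample {self.sample_id!r} must name a drug")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def condition(self) -> str:
        if self.arm == "control":
            return "control"
        parts = [self.drug, f"{self.concentration:g}{self.concentration_unit}"]
        if self.timepoint:
            parts.append(self.timepoint)
        return "_".join(parts)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call from a MAF row."""

    patient_id: str
    gene_id: str
    variant_classification: str
    t_depth: int
    t_alt_count: int
    chromosome: str

    def __post_init__(self) -> None:
        if not 0 <= self.t_alt_count <= self.t_depth:
            raise ValueError(
                f"t_alt_count {self.t_alt_count} outside [0, t_depth={self.t_depth}] "
                f"for {self.patient_id}/{self.gene_id}"
            )


class GuideCountTable:
    """Per-guide integer counts across control and treated samples.

    ``counts`` is a guides x samples DataFrame indexed by guide_id;
    ``gene_ids`` maps each guide to exactly one gene; ``samples`` carries
    the condition labels, in the same order as the count columns.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        gene_ids: pd.Series,
        samples: Sequence[SampleDescriptor],
    ) -> None:
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise TableFormatError("duplicate sample_id in sample descriptors")
        if list(counts.columns) != sample_ids:
            missing = set(sample_ids) - set(counts.columns)
            if missing:
                raise TableFormatError(f"count table missing sample columns: {sorted(missing)}")
            counts = counts[sample_ids]
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate guide_id {dup!r}")
        if not counts.index.equals(gene_ids.index):
            raise TableFormatError("gene_ids index does not match guide index")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count {arr[g, s]} at guide {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        self.counts = counts
        self.gene_ids = gene_ids
        self.samples = list(samples)

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_guides(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GuideCountTable)
            and self.counts.equals(other.counts)
            and self.gene_ids.equals(other.gene_ids)
            and self.samples == other.samples
        )


def read_guide_counts(path: str | Path, samples: Sequence[SampleDescriptor]) -> GuideCountTable:
    """Read a guide count TSV (guide_id, gene_id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("guide_id", "gene_id"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    sample_ids = [s.sample_id for s in samples]
    missing = set(sample_ids) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing sample columns {sorted(missing)}")
    counts = {}
    for sid in sample_ids:
        try:
            col = pd.to_numeric(df[sid], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: non-numeric count in column {sid!r}: {exc}") from exc
        if (col != col.astype(np.int64, errors="ignore")).any() or not np.issubdtype(
            col.dtype, np.number
        ):
            raise TableFormatError(f"{path}: non-integer count in column {sid!r}")
        frac = col % 1
        if (frac != 0).any():
            row = int(np.argmax(frac.to_numpy() != 0))
            raise TableFormatError(
                f"{path}: non-integer count {col.iloc[row]!r} in column {sid!r}, "
                f"guide {df['guide_id'].iloc[row]!r}"
            )
        if (col < 0).any():
            row = int(np.argmax(col.to_numpy() < 0))
            raise TableFormatError(
                f"{path}: negative count {int(col.iloc[row])} in column {sid!r}, "
                f"guide {df['guide_id'].iloc[row]!r}"
            )
        counts[sid] = col.astype(np.int64)
    if df["guide_id"].duplicated().any():
        dup = df["guide_id"][df["guide_id"].duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate guide_id {dup!r}")
    count_df = pd.DataFrame(counts)
    count_df.index = pd.Index(df["guide_id"], name="guide_id")
    gene_ids = pd.Series(df["gene_id"].to_numpy(), index=count_df.index, name="gene_id")
    table = GuideCountTable(count_df, gene_ids, samples)
    logger.info("read_guide_counts: %d guides x %d samples from %s", table.n_guides, len(samples), path)
    return table


def write_guide_counts(table: GuideCountTable, path: str | Path) -> None:
    out = table.counts.reset_index()
    out.insert(1, "gene_id", table.gene_ids.to_numpy())
    out.to_csv(path, sep="\t", index=False)


SAMPLE_COLUMNS = (
    "sample_id",
    "arm",
    "drug",
    "concentration",
    "concentration_unit",
    "timepoint",
    "replicate",
)


def write_samples(samples: Sequence[SampleDescriptor], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples], columns=SAMPLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_samples(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing sample columns {sorted(missing)}")
    return [
        SampleDescriptor(
            sample_id=row.sample_id,
            arm=row.arm,
            drug=row.drug,
            concentration=float(row.concentration or 0.0),
            concentration_unit=row.concentration_unit,
            timepoint=row.timepoint,
            replicate=int(float(row.replicate or 1)),
        )
        for row in df.itertuples(index=False)
    ]


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-style TSV into a validated DataFrame.

    Requires the standard MAF columns; extra columns are carried through
    untouched (coordinates included — never recomputed). Raises
    :class:`TableFormatError` on a missing column, an unparseable depth
    field (with its row number) or t_alt_count > t_depth.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    missing = set(MAF_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing MAF columns {sorted(missing)}")
    for col in ("t_depth", "t_alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise TableFormatError(
                f"{path}: unparseable {col} {df[col].iloc[row]!r} at row {row + 2}"
            )
        df[col] = vals.astype(np.int64)
    bad = (df["t_alt_count"] > df["t_depth"]) | (df["t_alt_count"] < 0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise TableFormatError(
            f"{path}: t_alt_count {df['t_alt_count'].iloc[row]} outside "
            f"[0, t_depth={df['t_depth'].iloc[row]}] at row {row + 2}"
        )
    logger.info("read_maf: %d mutation rows from %s", len(df), path)
    return df


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def maf_records(df: pd.DataFrame) -> list[MutationRecord]:
    """View MAF rows as validated :class:`MutationRecord` objects."""
    return [
        MutationRecord(
            patient_id=row.Tumor_Sample_Barcode,
            gene_id=row.Hugo_Symbol,
            variant_classification=row.Variant_Classification,
            t_depth=int(row.t_depth),
            t_alt_count=int(row.t_alt_count),
            chromosome=str(row.Chromosome),
        )
        for row in df.itertuples(index=False)
    ]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical response table (patient_id, drug, response, time, event)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "drug": str, "response": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing clinical columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate patient_id {dup!r}")
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    df["event"] = df["event"].astype(int)
    if not df["event"].isin((0, 1)).all():
        raise TableFormatError(f"{path}: event must be 0/1")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x patients TPM matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    if not np.isfinite(mat).all() or (mat < 0).any():
        raise TableFormatError(f"{path}: TPM values must be finite and non-negative")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_ccl(path: str | Path) -> pd.DataFrame:
    """Read a cell-line sensitivity table.

    Columns: line_id, tp53_mutation_class (empty = no TP53 mutation),
    alteration_pct, nutlin_ic50 (either may be empty), z_score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "tp53_mutation_class": str})
    missing = set(CCL_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing cell-line columns {sorted(missing)}")
    for col in ("alteration_pct", "nutlin_ic50", "z_score"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["z_score"].isna().any():
        raise TableFormatError(f"{path}: z_score missing for a tested line")
    return df


def write_ccl(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def log_stage(stage: str, n_in: int, removed: Iterable[tuple[str, int]], n_out: int) -> None:
    """Emit the audit trail for one filtering stage: in, removed per rule, out."""
    logger.info("%s: input rows = %d", stage, n_in)
    for rule, n in removed:
        logger.info("%s: removed by %s = %d", stage, rule, n)
    logger.info("%s: output rows = %d", stage, n_out)
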