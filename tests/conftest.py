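import numpy as np
import pandas as pd
import pytest

from crispredict import (
    GuideCountTable,
    RunConfig,
    SampleDescriptor,
    synthetic_panel,
)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def two_arm_samples():
    return [
        SampleDescriptor("ctrl_r1", "control", replicate=1),
        SampleDescriptor("ctrl_r2", "control", replicate=2),
        SampleDescriptor("trt_r1", "treated", drug="paclitaxel", concentration=1.0, replicate=1),
        SampleDescriptor("trt_r2", "treated", drug="paclitaxel", concentration=1.0, replicate=2),
    ]


def make_table(counts: dict, gene_of: dict, samples) -> GuideCountTable:
    """Build a GuideCountTable from {sample_id: [counts...]} and
    {guide_id: gene_id} preserving insertion order."""
    guides = list(gene_of)
    df = pd.DataFrame(counts, index=pd.Index(guides, name="guide_id")).astype(np.int64)
    genes = pd.Series([gene_of[g] for g in guides], index=df.index, name="gene_id")
    return GuideCountTable(df, genes, samples)


@pytest.fixture
def small_table(two_arm_samples):
    # two genes x 3 guides, gene B enriched in treatment
    gene_of = {f"{g}_sg{i}": g for g in ("A", "B") for i in range(3)}
    counts = {
        "ctrl_r1": [100, 110, 90, 100, 100, 100],
        "ctrl_r2": [105, 95, 100, 95, 105, 100],
        "trt_r1": [100, 100, 100, 420, 380, 400],
        "trt_r2": [95, 108, 97, 400, 410, 390],
    }
    return make_table(counts, gene_of, two_arm_samples)


@pytest.fixture
def panel():
    return synthetic_panel(n_group1=10, n_group2=3, seed=0)


def make_maf(rows) -> pd.DataFrame:
    """rows: tuples (patient, gene, classification, depth, alt, chrom)."""
    return pd.DataFrame(
        rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Variant_Classification",
            "t_depth",
            "t_alt_count",
            "Chromosome",
        ],
    )[
        [
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "t_depth",
            "t_alt_count",
            "Chromosome",
        ]
    ]


def make_clinical(rows) -> pd.DataFrame:
    """rows: tuples (patient_id, drug, response, time, event)."""
    return pd.DataFrame(rows, columns=["patient_id", "drug", "response", "time", "event"])
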