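"""Run configuration shared by every pipeline stage.

All thresholds default to the published cut-offs of the analysis they
parameterise: candidate genes need CRISPR Score > 0.5 at p < 0.05, the
moderate/high CS-group boundary sits at 5, mutations must have read depth
> 20 and variant allele fraction > 10%, genes mutated in more than 3.5% of
the cohort are treated as highly mutated, and patients with 1000 or more
mutations are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Thresholds and switches for a full pipeline run.

    Parameters
    ----------
    pseudocount
        Reads-per-million pseudocount added inside the log2 ratio when
        computing per-guide fold changes; guards zero counts.
    cs_threshold, p_threshold
        Candidate-gene selection cut-offs (strict inequalities).
    cs_group_boundary
        CRISPR Score separating moderate (group 1) from high (group 2)
        panel genes; CS at or above the boundary is group 2.
    highly_mutated_fraction
        A gene mutated in more than this fraction of eligible patients is
        "highly mutated": only loss-of-function mutations with variant
        allele fraction above ``alteration_pct_threshold`` are kept in it.
    vaf_threshold
        Minimum variant allele fraction (t_alt_count / t_depth), strict.
    depth_threshold
        Minimum read depth, strict.
    max_mutations_per_patient
        Patients with this many raw mutations or more are excluded.
    alteration_pct_threshold
        Percent-alteration floor (strict) for LoF mutations kept in highly
        mutated genes, and for calling a cell line TP53-LoF.
    ks_mode
        ``"treated_vs_control"`` compares a gene's guide abundances between
        arms; ``"gene_vs_background"`` compares the gene's guide log-ratios
        against all guides' log-ratios.
    yates
        Apply the Yates continuity correction in the chi-square test.
    seed
        Seed for every stochastic stage.
    """

    pseudocount: float = 1.0
    cs_threshold: float = 0.5
    p_threshold: float = 0.05
    cs_group_boundary: float = 5.0
    highly_mutated_fraction: float = 0.035
    vaf_threshold: float = 0.10
    depth_threshold: int = 20
    max_mutations_per_patient: int = 1000
    alteration_pct_threshold: float = 80.0
    ks_mode: str = "treated_vs_control"
    yates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pseudocount",
            "cs_threshold",
            "p_threshold",
            "cs_group_boundary",
            "highly_mutated_fraction",
            "vaf_threshold",
            "depth_threshold",
            "max_mutations_per_patient",
            "alteration_pct_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.ks_mode not in ("treated_vs_control", "gene_vs_background"):
            raise ValueError(f"unknown ks_mode {self.ks_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
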