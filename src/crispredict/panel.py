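"""Drug-specific resistance gene panels with CS groups.

A panel is the candidate list of one screen, each gene labelled by its
CRISPR Score group: group 1 (moderate) for 0.5 < CS < boundary, group 2
(high) for CS >= boundary. The default boundary of 5 reflects the clear
break observed between the top-scoring genes (TP53-tier, CS up to ~7)
and the rest of the candidate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .io import TableFormatError, logger

PANEL_COLUMNS = ("gene_id", "cs", "p_value", "fdr", "cs_group")


def assign_cs_group(cs: float, boundary: float = 5.0) -> int:
    """Map a panel gene's CRISPR Score to group 1 (moderate) or 2 (high).

    CS at or above the boundary is group 2; scores must exceed the 0.5
    candidate threshold to belong to a panel at all.
    """
    if cs <= 0.5:
        raise ValueError(f"CS {cs} <= 0.5 is not a panel gene")
    return 2 if cs >= boundary else 1


@dataclass
class GenePanel:
    """A drug's resistance panel: genes with CS, significance and group."""

    drug: str
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PANEL_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(PANEL_COLUMNS) - set(self.entries.columns)
        if missing:
            raise TableFormatError(f"panel missing columns {sorted(missing)}")
        if self.entries["gene_id"].duplicated().any():
            dup = self.entries["gene_id"][self.entries["gene_id"].duplicated()].iloc[0]
            raise TableFormatError(f"duplicate panel gene {dup!r}")
        if len(self.entries) and (self.entries["cs"] <= 0.5).any():
            raise TableFormatError("panel genes must have CS > 0.5")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene_id"])

    def cs_of(self) -> dict[str, float]:
        return dict(zip(self.entries["gene_id"], self.entries["cs"]))

    def group_of(self) -> dict[str, int]:
        return dict(zip(self.entries["gene_id"], self.entries["cs_group"]))

    def genes_in_group(self, group: int) -> list[str]:
        return list(self.entries.loc[self.entries["cs_group"] == group, "gene_id"])


def build_panel(scores: pd.DataFrame, drug: str, config: RunConfig | None = None) -> GenePanel:
    """Build a panel from candidate-flagged gene scores.

    Keeps exactly the candidates, ordered CS descending / p ascending /
    gene_id, each assigned its CS group. An empty candidate list yields a
    valid empty panel (with a warning).
    """
    config = config or RunConfig()
    cand = scores[scores["candidate"]].reset_index()
    if cand.empty:
        logger.warning("build_panel[%s]: no candidate genes, emitting empty panel", drug)
        return GenePanel(drug=drug)
    cand = cand.sort_values(
        ["cs", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    entries = pd.DataFrame(
        {
            "gene_id": cand["gene_id"].to_numpy(),
            "cs": cand["cs"].to_numpy(),
            "p_value": cand["p_value"].to_numpy(),
            "fdr": cand["fdr"].to_numpy(),
            "cs_group": [
                assign_cs_group(c, config.cs_group_boundary) for c in cand["cs"]
            ],
        }
    )
    logger.info(
        "build_panel[%s]: %d genes (%d moderate, %d high)",
        drug,
        len(entries),
        int((entries["cs_group"] == 1).sum()),
        int((entries["cs_group"] == 2).sum()),
    )
    return GenePanel(drug=drug, entries=entries)


def combine_panels(a: GenePanel, b: GenePanel) -> GenePanel:
    """Union of two panels keeping each gene's maximum CS (and its row)."""
    merged = pd.concat([a.entries, b.entries], ignore_index=True)
    merged = merged.sort_values(["gene_id", "cs"], ascending=[True, False], kind="mergesort")
    merged = merged.drop_duplicates("gene_id", keep="first")
    merged = merged.sort_values(
        ["cs", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return GenePanel(drug=f"{a.drug}+{b.drug}", entries=merged)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    out = panel.entries.copy()
    out.insert(0, "drug", panel.drug)
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> GenePanel:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "drug": str})
    missing = ({"drug"} | set(PANEL_COLUMNS)) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing panel columns {sorted(missing)}")
    if df.empty:
        return GenePanel(drug="")
    drugs = df["drug"].unique()
    if len(drugs) > 1:
        raise TableFormatError(f"{path}: panel mixes drugs {list(drugs)}")
    return GenePanel(drug=drugs[0], entries=df.drop(columns="drug").reset_index(drop=True))
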