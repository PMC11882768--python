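"""Per-gene CRISPR Score computation from guide count tables.

The scoring chain is: (1) normalise each sample to reads per million and
average replicate samples of the same condition; (2) for each guide form the
log2 ratio of treated to control abundance (with a pseudocount); (3) average
ratios over a gene's guides to get its CRISPR Score (CS); (4) attach a
two-sample Kolmogorov-Smirnov p-value and a Benjamini-Hochberg FDR;
(5) apply the guide-count inclusion rules; (6) select candidates with
CS > cs_threshold and p < p_threshold (strict).

A positive CS means the gene's knockouts were enriched under drug
selection, i.e. loss of the gene confers resistance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import GuideCountTable, logger


def normalize_counts(table: GuideCountTable) -> pd.DataFrame:
    """Normalise to reads per million and average replicates per condition.

    Returns a guides x conditions DataFrame whose first column is
    ``"control"`` followed by one column per treated condition. Each sample
    is scaled to RPM by its own total first; replicate columns of the same
    condition are averaged after normalisation.
    """
    conditions: dict[str, list[str]] = {}
    for s in table.samples:
        conditions.setdefault(s.condition, []).append(s.sample_id)
    if "control" not in conditions:
        raise ValueError("no control samples in table")
    if len(conditions) < 2:
        raise ValueError("need at least one treated condition")

    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    rpm = table.counts / totals * 1e6

    cols = {}
    order = ["control"] + [c for c in conditions if c != "control"]
    for cond in order:
        cols[cond] = rpm[conditions[cond]].mean(axis=1)
    return pd.DataFrame(cols)


def compute_cs(
    norm_ctrl: pd.Series,
    norm_trt: pd.Series,
    gene_ids: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-guide log2 ratios and per-gene CRISPR Scores.

    ratio_g = log2((trt_g + pseudocount) / (ctrl_g + pseudocount));
    CS(gene) = mean of ratio_g over the gene's guides.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not norm_ctrl.index.equals(norm_trt.index):
        raise ValueError("control and treated vectors not aligned on guide_id")
    ratios = np.log2((norm_trt + pseudocount) / (norm_ctrl + pseudocount))
    ratios.name = "log2_ratio"
    cs = ratios.groupby(gene_ids).mean()
    cs.name = "cs"
    return ratios, cs


def ks_gene_test(gene_trt: np.ndarray, gene_ctrl: np.ndarray) -> float:
    """Two-sided two-sample KS p-value for one gene's guide abundances."""
    gene_trt = np.asarray(gene_trt, dtype=float)
    gene_ctrl = np.asarray(gene_ctrl, dtype=float)
    if len(gene_trt) < 2 or len(gene_ctrl) < 2:
        raise ValueError("KS test needs at least 2 guides per arm")
    return float(stats.ks_2samp(gene_trt, gene_ctrl, alternative="two-sided").pvalue)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_guide_filters(nonzero_ctrl: int, nonzero_trt: int) -> bool:
    """Gene inclusion by non-zero guide counts in control and treatment.

    A gene with fewer than four non-zero control guides is excluded
    outright. Otherwise it is included if it (1) has more than 3 non-zero
    guides in the treatment, (2) has exactly 3 with 4-7 non-zero control
    guides, or (3) has exactly 2 with 4-5 non-zero control guides.
    """
    if nonzero_ctrl < 0 or nonzero_trt < 0:
        raise ValueError("guide counts must be non-negative")
    if nonzero_ctrl < 4:
        return False
    if nonzero_trt > 3:
        return True
    if nonzero_trt == 3 and 4 <= nonzero_ctrl <= 7:
        return True
    if nonzero_trt == 2 and 4 <= nonzero_ctrl <= 5:
        return True
    return False


def score_screen(
    table: GuideCountTable,
    config: RunConfig | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Score every gene of a screen against one treated condition.

    Returns a DataFrame indexed by gene_id with columns cs, p_value, fdr,
    n_guides, nonzero_ctrl, nonzero_trt, included, candidate. ``condition``
    defaults to the table's single treated condition and must be given when
    there are several (each concentration/timepoint is scored separately).

    Genes with fewer than 2 guides carry no p-value and are never
    candidates. The FDR is computed across the genes that pass the
    guide-count inclusion rules (the analysis set) and reported alongside;
    candidate selection gates on the raw p-value.
    """
    config = config or RunConfig()
    norm = normalize_counts(table)
    treated_conditions = [c for c in norm.columns if c != "control"]
    if condition is None:
        if len(treated_conditions) > 1:
            raise ValueError(
                f"several treated conditions {treated_conditions}; pass condition="
            )
        condition = treated_conditions[0]
    elif condition not in treated_conditions:
        raise ValueError(f"unknown condition {condition!r}; have {treated_conditions}")

    ctrl = norm["control"]
    trt = norm[condition]
    ratios, cs = compute_cs(ctrl, trt, table.gene_ids, config.pseudocount)

    rows = []
    for gene, idx in table.gene_ids.groupby(table.gene_ids).groups.items():
        g_ctrl = ctrl.loc[idx].to_numpy()
        g_trt = trt.loc[idx].to_numpy()
        n = len(idx)
        if n >= 2:
            if config.ks_mode == "treated_vs_control":
                p = ks_gene_test(g_trt, g_ctrl)
            else:
                p = float(
                    stats.ks_2samp(
                        ratios.loc[idx].to_numpy(), ratios.to_numpy()
                    ).pvalue
                )
        else:
            p = np.nan
        rows.append(
            {
                "gene_id": gene,
                "cs": cs.loc[gene],
                "p_value": p,
                "n_guides": n,
                "nonzero_ctrl": int((g_ctrl > 0).sum()),
                "nonzero_trt": int((g_trt > 0).sum()),
            }
        )
    scores = pd.DataFrame(rows).set_index("gene_id").sort_index()
    scores["included"] = [
        apply_guide_filters(c, t)
        for c, t in zip(scores["nonzero_ctrl"], scores["nonzero_trt"])
    ]
    scores["fdr"] = np.nan
    mask = scores["included"] & scores["p_value"].notna()
    if mask.any():
        scores.loc[mask, "fdr"] = bh_fdr(scores.loc[mask, "p_value"].to_numpy())
    scores["candidate"] = (
        scores["included"]
        & (scores["cs"] > config.cs_threshold)
        & (scores["p_value"] < config.p_threshold)
    )
    logger.info(
        "score_screen[%s]: %d genes, %d included, %d candidates",
        condition,
        len(scores),
        int(scores["included"].sum()),
        int(scores["candidate"].sum()),
    )
    return scores


def select_candidates(scores: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Candidate genes (included, CS > threshold, p < threshold, strict).

    Ordered by CS descending, then p ascending, then gene_id.
    """
    config = config or RunConfig()
    ok = (
        scores["included"]
        & (scores["cs"] > config.cs_threshold)
        & (scores["p_value"] < config.p_threshold)
    )
    out = scores[ok].reset_index()
    out = out.sort_values(
        ["cs", "p_value", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    return out.set_index("gene_id")
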