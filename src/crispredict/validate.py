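"""Orthogonal validations of a resistance panel.

Three analyses: (1) expression — are panel genes expressed lower in
resistant than sensitive tumours (log2 fold change of mean TPM, Welch t on
log2(TPM+1), BH FDR)? (2) survival — do panel-mutation carriers die
earlier (Kaplan-Meier curves, Mantel-Cox log-rank)? (3) cell lines —
TP53-LoF vs wild-type classification of cancer cell lines and the
difference in their drug-sensitivity Z-scores (Welch t) and in the
fraction of sensitive lines, Z < -1.5 strictly (two-proportion z-test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .cohort import LOF_CLASSES
from .io import logger
from .screen import bh_fdr

SENSITIVITY_Z_CUTOFF = -1.5

# CTD2-style tables may spell mutation classes in lower case
_CCL_LOF_CLASSES = LOF_CLASSES | {"frame_shift_del", "frame_shift_ins", "nonsense_mutation"}


def expression_fold_change(
    tpm: pd.DataFrame,
    panel_genes: list[str],
    resistant_patients: list[str],
    sensitive_patients: list[str],
    epsilon: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-panel-gene expression comparison between response groups.

    log2fc = log2((mean TPM resistant + eps) / (mean TPM sensitive + eps));
    p from a two-sided Welch t-test on log2(TPM + 1); BH FDR across the
    panel genes present in the matrix. A panel gene absent from the matrix
    is reported missing, not erred.

    Returns the per-gene table and a summary dict with the fraction of
    genes downregulated (log2fc < 0) and the fractions downregulated at
    FDR < 0.05 and FDR < 0.1.
    """
    if not resistant_patients or not sensitive_patients:
        raise ValueError("both response groups must be non-empty")
    res = [p for p in resistant_patients if p in tpm.columns]
    sens = [p for p in sensitive_patients if p in tpm.columns]
    present = [g for g in panel_genes if g in tpm.index]
    missing = [g for g in panel_genes if g not in tpm.index]

    rows = []
    for gene in present:
        x_res = tpm.loc[gene, res].to_numpy(dtype=float)
        x_sens = tpm.loc[gene, sens].to_numpy(dtype=float)
        log2fc = float(np.log2((x_res.mean() + epsilon) / (x_sens.mean() + epsilon)))
        t, p = stats.ttest_ind(
            np.log2(x_res + 1.0), np.log2(x_sens + 1.0), equal_var=False
        )
        rows.append({"gene_id": gene, "log2fc": log2fc, "p_value": float(p)})
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    table["direction"] = np.where(table["log2fc"] < 0, "down", "up_or_flat")

    down = table["log2fc"] < 0
    n = len(table)
    summary = {
        "n_panel_genes": len(panel_genes),
        "n_tested": n,
        "missing_genes": missing,
        "frac_down": float(down.mean()) if n else float("nan"),
        "n_down": int(down.sum()),
        "frac_down_fdr_05": float((down & (table["fdr"] < 0.05)).mean()) if n else float("nan"),
        "frac_down_fdr_10": float((down & (table["fdr"] < 0.1)).mean()) if n else float("nan"),
    }
    logger.info(
        "expression_fold_change: %d/%d genes down, %d at FDR<0.1",
        summary["n_down"],
        n,
        int((down & (table["fdr"] < 0.1)).sum()),
    )
    return table, summary


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a DataFrame with columns ``time`` and ``survival`` — the step
    function evaluated at every observed time, honouring right-censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def log_rank(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two survival samples (1 df,
    hypergeometric variance for ties)."""
    r = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(r.test_statistic), float(r.p_value)


def ccl_classify(
    tp53_mutation_class: str | None,
    alteration_pct: float | None,
    nutlin_ic50: float | None,
    lof_pct_threshold: float = 80.0,
) -> str:
    """Classify a cancer cell line as TP53_LoF, WT or unclassified.

    TP53_LoF needs all three: a loss-of-function TP53 mutation
    (frame-shift del/ins or nonsense), percent alteration above the
    threshold, and a Nutlin IC50 above 50 (Nutlin toxicity requires
    functional p53, so insensitivity corroborates the LoF call). WT needs
    both: no TP53 mutation at all and Nutlin IC50 below 10.
    """
    has_mutation = tp53_mutation_class is not None and str(tp53_mutation_class).strip() != ""
    is_lof = has_mutation and str(tp53_mutation_class).strip() in _CCL_LOF_CLASSES
    if (
        is_lof
        and alteration_pct is not None
        and alteration_pct > lof_pct_threshold
        and nutlin_ic50 is not None
        and nutlin_ic50 > 50
    ):
        return "TP53_LoF"
    if not has_mutation and nutlin_ic50 is not None and nutlin_ic50 < 10:
        return "WT"
    return "unclassified"


def classify_ccl_table(ccl: pd.DataFrame, lof_pct_threshold: float = 80.0) -> pd.Series:
    """Vectorised :func:`ccl_classify` over a cell-line table."""
    return pd.Series(
        [
            ccl_classify(
                row.tp53_mutation_class if not pd.isna(row.tp53_mutation_class) else None,
                row.alteration_pct if not pd.isna(row.alteration_pct) else None,
                row.nutlin_ic50 if not pd.isna(row.nutlin_ic50) else None,
                lof_pct_threshold,
            )
            for row in ccl.itertuples(index=False)
        ],
        index=ccl.index,
        name="tp53_class",
    )


def ccl_sensitivity_tests(lof_z: np.ndarray, wt_z: np.ndarray) -> dict:
    """Compare drug sensitivity between TP53-LoF and WT cell lines.

    Two-sided Welch t-test on the Z-scores, plus a two-proportion z-test
    on the fraction of sensitive lines (Z < -1.5, strict).
    """
    lof_z = np.asarray(lof_z, dtype=float)
    wt_z = np.asarray(wt_z, dtype=float)
    if len(lof_z) < 2 or len(wt_z) < 2:
        raise ValueError("need at least 2 lines per class")
    t, t_p = stats.ttest_ind(lof_z, wt_z, equal_var=False)
    n_sens_lof = int((lof_z < SENSITIVITY_Z_CUTOFF).sum())
    n_sens_wt = int((wt_z < SENSITIVITY_Z_CUTOFF).sum())
    if n_sens_lof + n_sens_wt in (0, len(lof_z) + len(wt_z)):
        prop_p = 1.0  # identical proportions in both arms, no evidence either way
        prop_z = 0.0
    else:
        prop_z, prop_p = proportions_ztest(
            [n_sens_lof, n_sens_wt], [len(lof_z), len(wt_z)]
        )
    return {
        "t_stat": float(t),
        "t_p": float(t_p),
        "n_lof": len(lof_z),
        "n_wt": len(wt_z),
        "n_sensitive_lof": n_sens_lof,
        "n_sensitive_wt": n_sens_wt,
        "prop_z": float(prop_z),
        "prop_z_p": float(prop_p),
    }
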