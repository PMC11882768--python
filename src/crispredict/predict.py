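"""Max_CS-group resistance prediction and its cohort statistics.

Each patient is mapped to the maximum CRISPR Score among panel genes in
which they carry a retained mutation (Max_CS), which places them in group
0 (no panel mutation, label "none"), group 1 (moderate, 0.5 < CS <
boundary) or group 2 (high, CS >= boundary). Cohort-level inference then
compares flagged (group >= 1) against unflagged patients: Pearson
chi-square on the 2x2 contingency table, the odds ratio with a Woolf
(log-scale) 95% CI, a logistic regression of response on the numeric group
code, and the objective response rate.

The group code enters the logistic model numerically (0/1/2), so the
fitted probabilities are a two-parameter smooth of the three raw group
proportions rather than the proportions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PatientProfile
from .io import logger
from .panel import GenePanel

GROUP_LABELS = {0: "none", 1: "moderate", 2: "high"}


@dataclass(frozen=True)
class PredictionOutcome:
    """One patient's Max_CS classification."""

    patient_id: str
    max_cs: float | None
    group: int
    label: str


@dataclass
class LogisticFit:
    """Grouped logistic fit of resistance on the numeric group code."""

    intercept: float
    slope: float
    fitted_probs: dict[int, float]
    lrt_p: float
    wald_p: float
    separation: bool

    def predict(self, group: float) -> float:
        eta = self.intercept + self.slope * group
        return float(1.0 / (1.0 + np.exp(-eta)))


def predict_patient(profile: PatientProfile, panel: GenePanel) -> PredictionOutcome:
    """Assign a patient's Max_CS group from their retained mutations.

    Group 0 if no retained mutation hits a panel gene; otherwise the CS
    group of the highest-scoring mutated panel gene. Deterministic and
    independent of mutation order.
    """
    cs_map = panel.cs_of()
    group_map = panel.group_of()
    hits = [g for g in profile.mutated_genes if g in cs_map]
    if not hits:
        return PredictionOutcome(profile.patient_id, None, 0, GROUP_LABELS[0])
    best = max(hits, key=lambda g: (cs_map[g], g))
    group = int(group_map[best])
    return PredictionOutcome(profile.patient_id, float(cs_map[best]), group, GROUP_LABELS[group])


def predict_cohort(
    profiles: list[PatientProfile], panel: GenePanel
) -> list[PredictionOutcome]:
    return [predict_patient(p, panel) for p in profiles]


def contingency_2x2(
    outcomes: list[PredictionOutcome], responses: dict[str, str]
) -> np.ndarray:
    """2x2 table [[flagged&resistant, unflagged&resistant],
    [flagged&sensitive, unflagged&sensitive]].

    Flagged means group >= 1 (any panel mutation). ``responses`` maps
    patient_id to "resistant"/"sensitive".
    """
    a = b = c = d = 0
    for o in outcomes:
        resp = responses[o.patient_id]
        if resp not in ("resistant", "sensitive"):
            raise ValueError(f"bad response {resp!r} for {o.patient_id}")
        flagged = o.group >= 1
        if resp == "resistant":
            a, b = a + flagged, b + (not flagged)
        else:
            c, d = c + flagged, d + (not flagged)
    return np.array([[a, b], [c, d]], dtype=np.int64)


def group_counts(
    outcomes: list[PredictionOutcome], responses: dict[str, str]
) -> dict[int, tuple[int, int]]:
    """Per group: (number resistant, number total)."""
    out: dict[int, tuple[int, int]] = {}
    for o in outcomes:
        r, n = out.get(o.group, (0, 0))
        out[o.group] = (r + (responses[o.patient_id] == "resistant"), n + 1)
    return dict(sorted(out.items()))


def chi_square(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction
    by default."""
    table = np.asarray(table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def odds_ratio_ci(table: np.ndarray, z: float = 1.959963984540054) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with the Woolf log-scale 95% CI.

    The Haldane-Anscombe 0.5 correction is applied to every cell only when
    some cell is zero. A table with two zero cells in one row or column has
    an undefined odds ratio and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: a row or column is all zero")
    if (t == 0).any():
        t = t + 0.5
    (a, b), (c, d) = t
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), float(lo), float(hi)


def fit_group_logistic(counts: dict[int, tuple[int, int]]) -> LogisticFit:
    """Maximum-likelihood logistic regression of resistance on group code.

    ``counts`` maps the numeric group code to (n_resistant, n_total).
    Fits P(resistant) = expit(intercept + slope * code) on the grouped
    binomial data, evaluates the fitted probability at each observed code,
    and reports both a likelihood-ratio test (vs intercept-only, 1 df) and
    the Wald p-value on the slope. Perfect separation is flagged rather
    than allowed to diverge silently.
    """
    groups = sorted(counts)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with observations")
    codes = np.array(groups, dtype=float)
    res = np.array([counts[g][0] for g in groups], dtype=float)
    tot = np.array([counts[g][1] for g in groups], dtype=float)
    if (tot <= 0).any():
        raise ValueError("every group needs n_total > 0")
    if (res < 0).any() or (res > tot).any():
        raise ValueError("n_resistant must lie in [0, n_total]")

    endog = np.column_stack([res, tot - res])
    exog = sm.add_constant(codes)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    fit = model.fit()
    null_fit = sm.GLM(endog, np.ones((len(groups), 1)), family=sm.families.Binomial()).fit()
    lrt = max(2.0 * (fit.llf - null_fit.llf), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, df=1))

    # separation: a fitted probability saturating at 0/1, or an exploding slope
    probs = fit.predict(exog)
    separation = bool(np.any((probs < 1e-8) | (probs > 1 - 1e-8)) or abs(fit.params[1]) > 30)

    fitted = {g: float(p) for g, p in zip(groups, probs)}
    return LogisticFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        fitted_probs=fitted,
        lrt_p=lrt_p,
        wald_p=float(fit.pvalues[1]),
        separation=separation,
    )


def orr(responses: dict[str, str], subset: set[str] | None = None) -> float:
    """Objective response rate: fraction of the subset that is sensitive
    (complete or partial response). ``subset=None`` means all patients."""
    ids = set(responses) if subset is None else set(subset)
    if not ids:
        raise ValueError("ORR undefined for an empty subset")
    n_sens = sum(responses[i] == "sensitive" for i in ids)
    return n_sens / len(ids)


def cohort_statistics(
    profiles: list[PatientProfile],
    panel: GenePanel,
    yates: bool = False,
) -> dict:
    """Run the full prediction and return every cohort-level statistic.

    Returns a plain dict (JSON-serialisable) with the contingency table,
    per-group counts and proportions, chi-square, odds ratio + CI,
    logistic fit, and objective response rates for all patients and for
    the algorithm-flagged subset.
    """
    outcomes = predict_cohort(profiles, panel)
    responses = {p.patient_id: p.response for p in profiles}
    table = contingency_2x2(outcomes, responses)
    counts = group_counts(outcomes, responses)
    chi2, chi2_p = chi_square(table, yates=yates)
    or_, lo, hi = odds_ratio_ci(table)
    logistic = fit_group_logistic(counts)
    flagged = {o.patient_id for o in outcomes if o.group >= 1}
    stats_out = {
        "n_patients": len(profiles),
        "n_resistant": int(table[0].sum()),
        "n_sensitive": int(table[1].sum()),
        "table": table.tolist(),
        "group_counts": {g: list(c) for g, c in counts.items()},
        "prop_flagged_resistant": float(table[0, 0] / table[0].sum()),
        "prop_flagged_sensitive": float(table[1, 0] / table[1].sum()),
        "chi2": chi2,
        "chi2_p": chi2_p,
        "odds_ratio": or_,
        "ci95": [lo, hi],
        "logit_intercept": logistic.intercept,
        "logit_slope": logistic.slope,
        "fitted_probs": {g: p for g, p in logistic.fitted_probs.items()},
        "lrt_p": logistic.lrt_p,
        "wald_p": logistic.wald_p,
        "separation": logistic.separation,
        "orr_all": orr(responses),
        "orr_flagged": orr(responses, flagged) if flagged else None,
    }
    logger.info(
        "cohort_statistics: OR=%.3f (%.3f, %.3f), chi2 p=%.3g, fitted probs %s",
        or_,
        lo,
        hi,
        chi2_p,
        {g: round(p, 3) for g, p in logistic.fitted_probs.items()},
    )
    return stats_out
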