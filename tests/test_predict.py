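"""Max_CS grouping and the cohort contingency / odds-ratio / logistic
statistics, anchored on the published paclitaxel and carboplatin tables."""

import numpy as np
import pandas as pd
import pytest

from crispredict import (
    GenePanel,
    PatientProfile,
    chi_square,
    contingency_2x2,
    fit_group_logistic,
    group_counts,
    odds_ratio_ci,
    orr,
    predict_patient,
)

# published grouped counts: group -> (n_resistant, n_total)
PACLITAXEL_COUNTS = {0: (34, 160), 1: (20, 44), 2: (12, 18)}
CARBOPLATIN_COUNTS = {0: (68, 209), 1: (8, 17), 2: (9, 17)}
# published 2x2: [[flagged&resistant, unflagged&resistant],
#                 [flagged&sensitive, unflagged&sensitive]]
PACLITAXEL_TABLE = np.array([[32, 34], [30, 126]])
CARBOPLATIN_TABLE = np.array([[17, 68], [17, 141]])


def make_panel(cs_by_gene):
    entries = pd.DataFrame(
        {
            "gene_id": list(cs_by_gene),
            "cs": list(cs_by_gene.values()),
            "p_value": 0.01,
            "fdr": 0.02,
            "cs_group": [1 if c < 5 else 2 for c in cs_by_gene.values()],
        }
    )
    return GenePanel(drug="paclitaxel", entries=entries)


def profile(genes, response="resistant", pid="P1"):
    return PatientProfile(pid, "paclitaxel", response, tuple(genes), 1.0, True)


class TestPredictPatient:
    PANEL = make_panel({"A": 1.4, "B": 5.2, "C": 7.15})

    def test_max_cs_picks_highest_scoring_gene(self):
        out = predict_patient(profile(["A", "B"]), self.PANEL)
        assert (out.max_cs, out.group, out.label) == (5.2, 2, "high")

    def test_no_panel_mutation_is_group_zero(self):
        out = predict_patient(profile(["NOT_IN_PANEL"]), self.PANEL)
        assert (out.max_cs, out.group, out.label) == (None, 0, "none")

    def test_single_high_gene(self):
        out = predict_patient(profile(["C"]), self.PANEL)
        assert (out.max_cs, out.group) == (7.15, 2)

    def test_moderate_gene(self):
        out = predict_patient(profile(["A"]), self.PANEL)
        assert (out.group, out.label) == (1, "moderate")

    def test_independent_of_mutation_order(self):
        a = predict_patient(profile(["A", "B", "C"]), self.PANEL)
        b = predict_patient(profile(["C", "B", "A"]), self.PANEL)
        assert a == b


def synthetic_outcomes(table):
    """Reconstruct per-patient outcomes/responses realising a 2x2 table."""
    outcomes, responses = [], {}
    k = 0
    for (flagged, resp), n in [
        ((True, "resistant"), table[0][0]),
        ((False, "resistant"), table[0][1]),
        ((True, "sensitive"), table[1][0]),
        ((False, "sensitive"), table[1][1]),
    ]:
        for _ in range(n):
            pid = f"P{k}"
            k += 1
            outcomes.append(
                predict_patient(
                    profile(["A"] if flagged else [], resp, pid), TestPredictPatient.PANEL
                )
            )
            responses[pid] = resp
    return outcomes, responses


class TestContingency:
    def test_published_paclitaxel_table(self):
        outcomes, responses = synthetic_outcomes(PACLITAXEL_TABLE)
        table = contingency_2x2(outcomes, responses)
        assert (table == PACLITAXEL_TABLE).all()
        assert table[0].sum() == 66 and table[1].sum() == 156  # margins

    def test_all_unflagged(self):
        outcomes, responses = synthetic_outcomes(np.array([[0, 5], [0, 7]]))
        table = contingency_2x2(outcomes, responses)
        assert (table == [[0, 5], [0, 7]]).all()

    def test_published_proportions(self):
        # 48% of resistant and 19% of sensitive patients flagged
        # (paclitaxel); 20% and 11% (carboplatin)
        assert round(100 * 32 / 66) == 48 and round(100 * 30 / 156) == 19
        t = CARBOPLATIN_TABLE
        assert round(100 * t[0, 0] / t[0].sum()) == 20
        assert round(100 * t[1, 0] / t[1].sum()) == 11


class TestChiSquare:
    def test_independent_table(self):
        chi2, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_published_table_significant(self):
        _, p = chi_square(PACLITAXEL_TABLE)
        assert p < 0.0001

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2)).astype(float)
            chi2, _ = chi_square(t)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(row, col) / n
            assert chi2 == pytest.approx(((t - expected) ** 2 / expected).sum())


class TestOddsRatio:
    def test_published_paclitaxel_or_and_ci(self):
        or_, lo, hi = odds_ratio_ci(PACLITAXEL_TABLE)
        assert or_ == pytest.approx(3.95, abs=0.005)
        assert lo == pytest.approx(2.11, abs=0.005)
        assert hi == pytest.approx(7.39, abs=0.005)

    def test_carboplatin_or(self):
        or_, _, _ = odds_ratio_ci(CARBOPLATIN_TABLE)
        assert or_ == pytest.approx(141 / 68, rel=1e-12)

    def test_unit_table(self):
        assert odds_ratio_ci([[1, 1], [1, 1]])[0] == pytest.approx(1.0)

    def test_invariances(self):
        t = np.array([[7, 3], [2, 11]])
        or0 = odds_ratio_ci(t)[0]
        assert odds_ratio_ci(t[::-1, ::-1])[0] == pytest.approx(or0)  # swap both
        assert odds_ratio_ci(t[::-1, :])[0] == pytest.approx(1 / or0)  # swap one

    def test_zero_cell_haldane(self):
        or_, lo, hi = odds_ratio_ci([[5, 0], [3, 9]])
        assert np.isfinite([or_, lo, hi]).all() and lo <= or_ <= hi

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_ci([[0, 0], [3, 9]])


class TestGroupLogistic:
    def test_published_paclitaxel_probs(self):
        fit = fit_group_logistic(PACLITAXEL_COUNTS)
        assert [round(fit.fitted_probs[g], 2) for g in (0, 1, 2)] == [0.21, 0.44, 0.69]

    def test_published_carboplatin_probs(self):
        fit = fit_group_logistic(CARBOPLATIN_COUNTS)
        assert [round(fit.fitted_probs[g], 2) for g in (0, 1, 2)] == [0.33, 0.43, 0.55]

    def test_published_wald_significance(self):
        # the published paclitaxel "significance level" of 9.50e-06 is the
        # Wald p-value on the slope
        fit = fit_group_logistic(PACLITAXEL_COUNTS)
        assert fit.wald_p == pytest.approx(9.50e-06, rel=0.01)
        assert fit.lrt_p < 1e-4

    @pytest.mark.parametrize("counts", [PACLITAXEL_COUNTS, CARBOPLATIN_COUNTS])
    def test_score_equation_identity(self, counts):
        # sum over groups of n_g * fitted_prob equals the resistant total
        fit = fit_group_logistic(counts)
        expected = sum(r for r, _ in counts.values())
        got = sum(n * fit.fitted_probs[g] for g, (_, n) in counts.items())
        assert got == pytest.approx(expected, abs=1e-6)

    def test_two_group_fit_is_saturated(self):
        # with 2 groups and 2 parameters the ML fit must reproduce the raw
        # proportions exactly (closed-form oracle for the ML machinery)
        counts = {0: (12, 50), 1: (30, 40)}
        fit = fit_group_logistic(counts)
        assert fit.fitted_probs[0] == pytest.approx(12 / 50, abs=1e-9)
        assert fit.fitted_probs[1] == pytest.approx(30 / 40, abs=1e-9)

    def test_equal_proportions_flat_fit(self):
        fit = fit_group_logistic({0: (10, 40), 1: (10, 40), 2: (10, 40)})
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert all(p == pytest.approx(0.25, abs=1e-8) for p in fit.fitted_probs.values())

    def test_perfect_separation_flagged(self):
        fit = fit_group_logistic({0: (0, 50), 1: (50, 50)})
        assert fit.separation

    def test_predict_interpolates(self):
        fit = fit_group_logistic(PACLITAXEL_COUNTS)
        assert fit.predict(0) == pytest.approx(fit.fitted_probs[0], abs=1e-9)


class TestOrr:
    def test_published_paclitaxel_orr(self):
        responses = {f"P{i}": "sensitive" for i in range(156)}
        responses.update({f"R{i}": "resistant" for i in range(66)})
        assert orr(responses) == pytest.approx(156 / 222)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            orr({"P1": "sensitive"}, set())

    def test_all_sensitive_subset(self):
        responses = {"P1": "sensitive", "P2": "resistant"}
        assert orr(responses, {"P1"}) == 1.0


class TestGroupCounts:
    def test_counts_per_group(self):
        outcomes, responses = synthetic_outcomes(np.array([[3, 2], [1, 4]]))
        counts = group_counts(outcomes, responses)
        # flagged patients all hit gene A (group 1)
        assert counts[1] == (3, 4) and counts[0] == (2, 6)
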