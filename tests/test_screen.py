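"""CRISPR Score computation, KS significance, FDR and guide filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crispredict import (
    RunConfig,
    SampleDescriptor,
    apply_guide_filters,
    bh_fdr,
    compute_cs,
    ks_gene_test,
    normalize_counts,
    score_screen,
    select_candidates,
)
from crispredict.io import GuideCountTable

from conftest import make_table


class TestNormalize:
    def test_rpm_arithmetic(self):
        samples = [SampleDescriptor("c", "control"), SampleDescriptor("t", "treated", drug="d")]
        table = make_table({"c": [10, 30, 60], "t": [1, 1, 98]}, {"g1": "A", "g2": "A", "g3": "B"}, samples)
        norm = normalize_counts(table)
        assert np.allclose(norm["control"], [100000, 300000, 600000])

    def test_identical_replicates_average_to_either(self, two_arm_samples):
        gene_of = {"g1": "A", "g2": "A"}
        table = make_table(
            {"ctrl_r1": [10, 90], "ctrl_r2": [10, 90], "trt_r1": [50, 50], "trt_r2": [50, 50]},
            gene_of,
            two_arm_samples,
        )
        norm = normalize_counts(table)
        assert np.allclose(norm["control"], [1e5, 9e5])

    def test_replicate_mean(self):
        # one guide at RPM 100 in rep1 and 300 in rep2 -> averaged 200
        samples = [
            SampleDescriptor("c1", "control", replicate=1),
            SampleDescriptor("c2", "control", replicate=2),
            SampleDescriptor("t", "treated", drug="d"),
        ]
        table = make_table(
            {"c1": [1, 9999], "c2": [3, 9997], "t": [1, 9999]}, {"g1": "A", "g2": "B"}, samples
        )
        norm = normalize_counts(table)
        assert norm["control"].iloc[0] == pytest.approx(200.0)

    def test_zero_total_sample_rejected(self):
        samples = [SampleDescriptor("c", "control"), SampleDescriptor("t", "treated", drug="d")]
        table = make_table({"c": [0, 0], "t": [1, 1]}, {"g1": "A", "g2": "A"}, samples)
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(table)

    def test_control_required(self):
        samples = [
            SampleDescriptor("t1", "treated", drug="d"),
            SampleDescriptor("t2", "treated", drug="d", concentration=2.0),
        ]
        table = make_table({"t1": [1], "t2": [2]}, {"g1": "A"}, samples)
        with pytest.raises(ValueError, match="control"):
            normalize_counts(table)


class TestComputeCs:
    def _genes(self, n, per):
        idx = pd.Index([f"g{i}" for i in range(n * per)], name="guide_id")
        return idx, pd.Series(np.repeat([f"G{i}" for i in range(n)], per), index=idx)

    def test_identity_gives_zero(self):
        idx, genes = self._genes(3, 4)
        v = pd.Series(np.linspace(10, 200, 12), index=idx)
        _, cs = compute_cs(v, v.copy(), genes, pseudocount=1.0)
        assert np.allclose(cs, 0.0)

    def test_four_guide_example(self):
        # ctrl (10,10,10,10), trt (40,20,10,10), pseudocount -> 0:
        # CS = (2 + 1 + 0 + 0)/4 = 0.75
        idx, genes = self._genes(1, 4)
        ctrl = pd.Series([10.0, 10, 10, 10], index=idx)
        trt = pd.Series([40.0, 20, 10, 10], index=idx)
        _, cs = compute_cs(ctrl, trt, genes, pseudocount=1e-9)
        assert cs.iloc[0] == pytest.approx(0.75, abs=1e-6)

    def test_doubling_treated_adds_one(self):
        idx, genes = self._genes(4, 3)
        rng = np.random.default_rng(0)
        ctrl = pd.Series(rng.uniform(5, 500, 12), index=idx)
        trt = pd.Series(rng.uniform(5, 500, 12), index=idx)
        _, cs1 = compute_cs(ctrl, trt, genes, pseudocount=1e-12)
        _, cs2 = compute_cs(ctrl, 2 * trt, genes, pseudocount=1e-12)
        assert np.allclose(cs2 - cs1, 1.0)

    def test_antisymmetric_in_arms(self):
        idx, genes = self._genes(4, 3)
        rng = np.random.default_rng(1)
        a = pd.Series(rng.uniform(5, 500, 12), index=idx)
        b = pd.Series(rng.uniform(5, 500, 12), index=idx)
        _, cs_ab = compute_cs(a, b, genes)
        _, cs_ba = compute_cs(b, a, genes)
        assert np.allclose(cs_ab, -cs_ba)


class TestKs:
    def test_identical_vectors(self):
        assert ks_gene_test([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated(self):
        # {1,2,3} vs {4,5,6}: D = 1, exact two-sided p = 2/C(6,3) = 0.1
        from scipy import stats

        r = stats.ks_2samp([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(1.0)
        assert ks_gene_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_null_super_uniform(self):
        # p-values under the null are uniform or super-uniform (discrete
        # small-sample correction only inflates them)
        rng = np.random.default_rng(7)
        ps = np.array(
            [ks_gene_test(rng.normal(size=9), rng.normal(size=9)) for _ in range(2000)]
        )
        frac = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert frac <= 0.05 + 3 * se

    def test_too_few_guides_rejected(self):
        with pytest.raises(ValueError):
            ks_gene_test([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        # p*m/i = (.04, .04, .04, .04) after monotone step-up
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def brute_force_guide_rule(ctrl: int, trt: int) -> bool:
    """Literal transcription of the published inclusion rules."""
    if ctrl < 4:
        return False
    rule1 = trt > 3
    rule2 = trt == 3 and ctrl in (4, 5, 6, 7)
    rule3 = trt == 2 and ctrl in (4, 5)
    return rule1 or rule2 or rule3


class TestGuideFilters:
    @pytest.mark.parametrize(
        "ctrl,trt,expected",
        [
            (3, 9, False),  # too few non-zero control guides
            (9, 4, True),  # rule 1
            (6, 3, True),  # rule 2
            (5, 2, True),  # rule 3
            (8, 3, False),
            (6, 2, False),
        ],
    )
    def test_published_examples(self, ctrl, trt, expected):
        assert apply_guide_filters(ctrl, trt) is expected

    def test_exhaustive_against_brute_force(self):
        for ctrl in range(11):
            for trt in range(11):
                assert apply_guide_filters(ctrl, trt) == brute_force_guide_rule(ctrl, trt), (
                    ctrl,
                    trt,
                )


@pytest.fixture(scope="module")
def scored():
    from crispredict import ScreenSimSpec, gen_screen_counts

    table, truth = gen_screen_counts(ScreenSimSpec(n_genes=120, n_resistant=6, seed=3))
    return score_screen(table), truth


class TestScoreScreenSelection:
    def test_threshold_is_strict(self):
        scores = pd.DataFrame(
            {
                "cs": [0.5, 0.6],
                "p_value": [0.01, 0.2],
                "fdr": [0.02, 0.3],
                "n_guides": [9, 9],
                "nonzero_ctrl": [9, 9],
                "nonzero_trt": [9, 9],
                "included": [True, True],
                "candidate": [False, False],
            },
            index=pd.Index(["A", "B"], name="gene_id"),
        )
        out = select_candidates(scores)
        assert "A" not in out.index  # cs == 0.5 exactly
        assert "B" not in out.index  # p >= 0.05

    def test_monotone_in_thresholds(self, scored):
        scores, _ = scored
        base = set(select_candidates(scores, RunConfig(cs_threshold=0.5)).index)
        tighter = set(select_candidates(scores, RunConfig(cs_threshold=1.5)).index)
        assert tighter <= base
        tighter_p = set(select_candidates(scores, RunConfig(p_threshold=0.01)).index)
        assert tighter_p <= base

    def test_recovers_planted_genes(self, scored):
        scores, truth = scored
        cand = set(select_candidates(scores).index)
        planted = set(truth[truth].index)
        assert len(planted & cand) >= 5  # 6 planted at enrichment 8

    def test_ordering(self, scored):
        scores, _ = scored
        out = select_candidates(scores)
        cs = out["cs"].to_numpy()
        assert np.all(np.diff(cs) <= 1e-12)

    def test_cs_invariant_under_depth_rescale(self, small_table):
        scores1 = score_screen(small_table)
        scaled = GuideCountTable(
            small_table.counts * 3, small_table.gene_ids, small_table.samples
        )
        scores2 = score_screen(scaled)
        assert np.allclose(scores1["cs"], scores2["cs"])

    def test_single_guide_gene_has_no_p(self, two_arm_samples):
        gene_of = {"g1": "A", "g2": "B", "g3": "B"}
        table = make_table(
            {s.sample_id: [10, 20, 30] for s in two_arm_samples}, gene_of, two_arm_samples
        )
        scores = score_screen(table)
        assert np.isnan(scores.loc["A", "p_value"])
        assert not scores.loc["A", "candidate"]
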