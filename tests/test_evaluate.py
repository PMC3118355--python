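import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import mann_whitney_auc

from kdnorm import (
    LOG2,
    ExpressionMatrix,
    compression_slope,
    gene_scores,
    make_truth,
    null_bias,
    roc_curve,
    roc_from_scores,
)


def _matrix(rows, array_ids):
    rows = np.asarray(rows, dtype=float)
    return ExpressionMatrix(
        values=rows,
        probe_ids=[f"g{i}" for i in range(rows.shape[0])],
        array_ids=array_ids,
        scale=LOG2,
    )


class TestGeneScores:
    def test_fold_change_is_mean_difference(self):
        m = _matrix([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], list("abcdef"))
        s = gene_scores(m, ["a", "b", "c"], ["d", "e", "f"])
        assert s["log2_fc"].iloc[0] == pytest.approx(-2.0)

    def test_pooled_t_against_closed_form(self):
        m = _matrix([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], list("abcdef"))
        s = gene_scores(m, ["a", "b", "c"], ["d", "e", "f"])
        # pooled sd = 1, se = sqrt(2/3), |t| = 2 / sqrt(2/3) = sqrt(6)
        t_expected = -np.sqrt(6.0)
        p_expected = 2 * stats.t.sf(np.sqrt(6.0), df=4)
        assert s["t_stat"].iloc[0] == pytest.approx(t_expected, abs=1e-6)
        assert s["p_value"].iloc[0] == pytest.approx(p_expected, abs=1e-6)
        assert p_expected == pytest.approx(0.0705, abs=2e-3)

    def test_constant_gene_gets_p_one(self):
        m = _matrix([[2.0] * 6, [1, 2, 3, 3, 4, 5]], list("abcdef"))
        s = gene_scores(m, ["a", "b", "c"], ["d", "e", "f"])
        assert s["p_value"].iloc[0] == 1.0
        assert np.isnan(s["t_stat"].iloc[0])

    def test_zero_pooled_variance_with_distinct_means_gets_p_one(self):
        # constant within each group: no within-group information
        m = _matrix([[1.0, 1.0, 1.0, 4.0, 4.0, 4.0]], list("abcdef"))
        s = gene_scores(m, ["a", "b", "c"], ["d", "e", "f"])
        assert s["p_value"].iloc[0] == 1.0

    def test_small_group_needs_fold_change_only_mode(self):
        m = _matrix([[1.0, 2.0, 3.0]], list("abc"))
        with pytest.raises(ValueError, match="with_t=False"):
            gene_scores(m, ["a"], ["b", "c"])
        s = gene_scores(m, ["a"], ["b", "c"], with_t=False)
        assert s["log2_fc"].iloc[0] == pytest.approx(-1.5)


class TestRoc:
    def test_perfect_separation(self):
        auc = roc_from_scores([5, 6, 7, 1, 2, 3], [True] * 3 + [False] * 3).auc
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc = roc_from_scores([1.0] * 6, [True] * 3 + [False] * 3).auc
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        score = rng.normal(size=10)
        score[3] = score[7]  # inject a tie across classes
        is_de = np.array([True] * 4 + [False] * 6)
        auc = roc_from_scores(score, is_de).auc
        assert auc == pytest.approx(mann_whitney_auc(score, is_de), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        score = np.abs(rng.normal(size=30)) + 0.1
        is_de = rng.random(30) < 0.4
        if not is_de.any() or is_de.all():
            is_de[:3] = [True, False, True]
        a = roc_from_scores(score, is_de).auc
        b = roc_from_scores(np.log(score), is_de).auc
        c = roc_from_scores(score**3, is_de).auc
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one DE and one non-DE"):
            roc_from_scores([1.0, 2.0], [True, True])

    def test_empty_genes_excluded_by_default(self, rng):
        truth = make_truth(
            gene_ids=["g0", "g1", "g2", "g3"],
            designed_log2_fc=[1.0, 0.0, 0.0, 0.0],
            is_de=[True, False, False, False],
            is_empty=[False, False, True, True],
        )
        # empty genes carry huge spurious scores; excluding them restores AUC 1
        scores = pd.DataFrame({"gene_id": truth.gene_id, "log2_fc": [2.0, 0.1, 9.0, 9.0]})
        assert roc_curve(scores, truth, criterion="fc").auc == 1.0
        assert roc_curve(scores, truth, criterion="fc", include_empty=True).auc < 1.0


class TestCompressionSlope:
    def _truth(self, designed):
        designed = np.asarray(designed, dtype=float)
        return make_truth(
            gene_ids=[f"g{i}" for i in range(len(designed))],
            designed_log2_fc=designed,
            is_de=designed != 0,
            is_empty=[False] * len(designed),
        )

    def test_identity_slope_one(self):
        designed = np.array([0.5, 1.0, 1.5, 2.0, 0.0])
        truth = self._truth(designed)
        scores = pd.DataFrame({"gene_id": truth.gene_id, "log2_fc": designed})
        slope, intercept = compression_slope(scores, truth)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_half_compression(self):
        designed = np.array([0.5, 1.0, 1.5, 2.0])
        truth = self._truth(designed)
        scores = pd.DataFrame({"gene_id": truth.gene_id, "log2_fc": 0.5 * designed})
        assert compression_slope(scores, truth)[0] == pytest.approx(0.5, abs=1e-12)

    def test_noisy_case_matches_closed_form(self, rng):
        designed = rng.uniform(0.3, 2.0, 40)
        observed = 0.8 * designed + rng.normal(0, 0.1, 40)
        truth = self._truth(designed)
        scores = pd.DataFrame({"gene_id": truth.gene_id, "log2_fc": observed})
        slope, _ = compression_slope(scores, truth)
        xc = designed - designed.mean()
        yc = observed - observed.mean()
        assert slope == pytest.approx(np.dot(xc, yc) / np.dot(xc, xc), abs=1e-10)

    def test_degenerate_design_rejected(self):
        truth = self._truth([1.0, 1.0, 1.0])
        scores = pd.DataFrame({"gene_id": truth.gene_id, "log2_fc": [1.0, 1.1, 0.9]})
        with pytest.raises(ValueError, match="degenerate"):
            compression_slope(scores, truth)


class TestNullBias:
    def test_reports_median_of_null_genes(self):
        truth = make_truth(
            gene_ids=["g0", "g1", "g2", "g3"],
            designed_log2_fc=[2.0, 0.0, 0.0, 0.0],
            is_de=[True, False, False, False],
            is_empty=[False, False, False, False],
        )
        scores = pd.DataFrame(
            {"gene_id": truth.gene_id, "log2_fc": [5.0, 0.1, 0.2, 0.3]}
        )
        assert null_bias(scores, truth) == pytest.approx(0.2)
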