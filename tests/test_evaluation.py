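"""Masking plans, the three metrics, and summary arithmetic."""

import math
from fractions import Fraction

import numpy as np
import pytest

from imputeval.core_io import MISSING
from imputeval.evaluation import (
    ContingencyTable3x3,
    MaskPlan,
    SnpMetrics,
    build_mask_plans,
    concordance,
    contingency,
    estimated_rsq,
    iqs,
    is_defined,
    maf_bin_index,
    most_likely_genotype,
    summarize,
    true_rsq,
)

from conftest import hwe_genotypes


def kappa_oracle(table: np.ndarray) -> float:
    """Independently coded Cohen's kappa in exact rational arithmetic."""
    table = np.asarray(table, dtype=object)
    n = int(table.sum())
    po = Fraction(int(np.trace(table)), n)
    pe = sum(
        Fraction(int(table[g, :].sum()), n) * Fraction(int(table[:, g].sum()), n)
        for g in range(3)
    )
    if pe == 1:
        return float("nan")
    return float((po - pe) / (1 - pe))


class TestMaskPlans:
    def test_two_percent_of_chr22_snp_count(self):
        vids = [f"rs{i}" for i in range(8101)]
        plans = build_mask_plans(vids, fraction=0.02, reps=10, base_seed=7)
        assert len(plans) == 10
        assert all(len(p.masked_vids) == 162 for p in plans)
        assert all(p.masked_vids <= set(vids) for p in plans)

    def test_single_snp_boundary(self):
        vids = [f"rs{i}" for i in range(100)]
        plans = build_mask_plans(vids, fraction=1 / 100, reps=2, base_seed=0)
        assert all(len(p.masked_vids) == 1 for p in plans)

    def test_deterministic_and_seed_offsets(self):
        vids = [f"rs{i}" for i in range(500)]
        a = build_mask_plans(vids, 0.02, reps=5, base_seed=42)
        b = build_mask_plans(vids, 0.02, reps=5, base_seed=42)
        assert [p.masked_vids for p in a] == [p.masked_vids for p in b]
        assert [p.seed for p in a] == [43, 44, 45, 46, 47]
        assert len({p.masked_vids for p in a}) > 1  # reps differ

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_mask_plans(["a", "b", "c"], fraction=0.01, reps=1, base_seed=0)


class TestMostLikelyGenotype:
    @pytest.mark.parametrize(
        "triplet,expected",
        [((0.1, 0.2, 0.7), 2), ((0.5, 0.5, 0.0), 0), ((1 / 3, 1 / 3, 1 / 3), 0)],
    )
    def test_argmax_with_low_tie_break(self, triplet, expected):
        assert most_likely_genotype(np.array(triplet)) == expected


class TestContingency:
    def test_diagonal(self):
        t = contingency([0, 1, 2], [0, 1, 2])
        assert np.trace(t.array) == 3 and t.n == 3

    def test_missing_truth_excluded(self):
        t = contingency([0, MISSING], [0, 0])
        assert t.n == 1

    def test_hand_tally(self):
        truth = [0, 0, 1, 2, 1, MISSING]
        imp = [0, 1, 1, 2, 0, 2]
        t = contingency(truth, imp).array
        expected = np.zeros((3, 3), dtype=int)
        for a, b in zip(truth, imp):
            if a != MISSING:
                expected[a, b] += 1
        np.testing.assert_array_equal(t, expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            contingency([MISSING, MISSING], [0, 0])


class TestConcordanceIqs:
    def test_concordance_examples(self):
        diag = ContingencyTable3x3(((5, 0, 0), (0, 3, 0), (0, 0, 2)))
        assert concordance(diag) == 1.0
        anti = ContingencyTable3x3(((0, 0, 5), (0, 0, 0), (5, 0, 0)))
        assert concordance(anti) == 0.0
        t = ContingencyTable3x3(((50, 5, 0), (4, 30, 6), (0, 2, 3)))
        assert concordance(t) == pytest.approx(83 / 100)

    def test_outer_product_table_gives_zero(self):
        # margins (20, 5, 0) x (20, 5, 0) / 25: P0 == Pc by construction
        t = ContingencyTable3x3(((16, 4, 0), (4, 1, 0), (0, 0, 0)))
        assert iqs(t) == 0.0

    def test_diagonal_table_gives_one(self):
        t = ContingencyTable3x3(((5, 0, 0), (0, 7, 0), (0, 0, 0)))
        assert iqs(t) == 1.0

    def test_single_cell_undefined(self):
        t = ContingencyTable3x3(((9, 0, 0), (0, 0, 0), (0, 0, 0)))
        assert math.isnan(iqs(t))

    def test_matches_kappa_oracle_on_random_tables(self, rng):
        for _ in range(300):
            table = rng.integers(0, 51, size=(3, 3))
            if table.sum() == 0:
                continue
            t = ContingencyTable3x3(tuple(tuple(int(x) for x in r) for r in table))
            expected = kappa_oracle(table)
            got = iqs(t)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_iqs_one_iff_perfect_concordance(self, rng):
        for _ in range(100):
            table = rng.integers(0, 20, size=(3, 3))
            if table.sum() == 0:
                continue
            t = ContingencyTable3x3(tuple(tuple(int(x) for x in r) for r in table))
            v = iqs(t)
            if is_defined(v):
                assert (v == 1.0) == (concordance(t) == 1.0)


class TestRsq:
    def test_hwe_dosages_give_one_in_expectation(self, rng):
        g = hwe_genotypes(rng, 0.3, 10_000).astype(float)
        assert estimated_rsq(g) == pytest.approx(1.0, abs=0.02)

    def test_constant_dosage_zero(self):
        assert estimated_rsq(np.full(100, 0.6)) == 0.0
        assert estimated_rsq(np.zeros(10)) == 0.0

    def test_mixture_recovers_q_squared(self, rng):
        p, q = 0.2, 0.7
        g = hwe_genotypes(rng, p, 10_000).astype(float)
        d = q * g + (1 - q) * 2 * p
        # replicate-based 3 SE for the variance-ratio estimator
        reps = [
            estimated_rsq(q * hwe_genotypes(rng, p, 10_000) + (1 - q) * 2 * p)
            for _ in range(20)
        ]
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - q**2) < 3 * max(se, 1e-4)
        assert estimated_rsq(d) == pytest.approx(q**2, abs=0.05)

    def test_true_rsq_identities(self):
        g = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        assert true_rsq(g.astype(float), g) == pytest.approx(1.0)
        assert true_rsq(2.0 - g, g) == pytest.approx(1.0)  # anti-correlated
        assert math.isnan(true_rsq(np.full(5, 0.5), g))

    def test_true_rsq_excludes_missing(self):
        g = np.array([0, 1, 2, MISSING], dtype=np.int8)
        d = np.array([0.0, 1.0, 2.0, 0.77])
        assert true_rsq(d, g) == pytest.approx(1.0)


class TestSummarize:
    def _plan(self, rep, vids):
        return MaskPlan(rep=rep, seed=rep, fraction=0.02,
                        masked_vids=frozenset(vids))

    def test_rep_mean(self):
        plans = [self._plan(1, {"a", "b"})]
        per_snp = [
            SnpMetrics(vid="a", rep=1, concordance=0.9, iqs=0.8, maf=0.1),
            SnpMetrics(vid="b", rep=1, concordance=1.0, iqs=1.0, maf=0.2),
        ]
        s = summarize(per_snp, plans)
        assert s.per_rep.loc[0, "concordance"] == pytest.approx(0.95)
        assert s.pooled_concordance == pytest.approx(0.95)

    def test_pooled_is_mean_of_rep_means(self):
        plans = [self._plan(1, {"a"}), self._plan(2, {"b", "c"})]
        per_snp = [
            SnpMetrics(vid="a", rep=1, concordance=1.0, iqs=1.0, maf=0.1),
            SnpMetrics(vid="b", rep=2, concordance=0.5, iqs=0.4, maf=0.1),
            SnpMetrics(vid="c", rep=2, concordance=0.7, iqs=0.6, maf=0.1),
        ]
        s = summarize(per_snp, plans)
        assert s.pooled_concordance == pytest.approx((1.0 + 0.6) / 2)
        assert s.pooled_iqs == pytest.approx((1.0 + 0.5) / 2)

    def test_maf_bin_boundaries(self):
        assert maf_bin_index(0.02) == 2    # (0.01, 0.02] - the MAF<=2% stratum edge
        assert maf_bin_index(0.0201) == 3
        assert maf_bin_index(0.01) == 1
        assert maf_bin_index(0.5) == 50
        assert maf_bin_index(0.0) == 0     # monomorphic: below every bin
        assert maf_bin_index(float("nan")) == 0

    def test_binned_recombination_equals_rsq_mean(self, rng):
        per_snp = [
            SnpMetrics(vid=f"v{i}", rsq_est=float(rng.uniform(0, 1)),
                       maf=float(rng.uniform(0.001, 0.5)))
            for i in range(200)
        ]
        s = summarize(per_snp)
        recombined = (s.binned["rsq_mean"] * s.binned["n_snps"]).sum() / s.binned[
            "n_snps"
        ].sum()
        assert s.rsq_mean == pytest.approx(recombined, abs=1e-12)
        assert s.n_rsq_snps == 200

    def test_monomorphic_dosage_excluded_and_counted(self):
        per_snp = [
            SnpMetrics(vid="a", rsq_est=0.8, maf=0.1),
            SnpMetrics(vid="b", rsq_est=0.0, maf=0.0),  # monomorphic dosage
        ]
        s = summarize(per_snp)
        assert s.rsq_mean == pytest.approx(0.8)
        assert s.counts["n_monomorphic_dosage_excluded"] == 1

    def test_undefined_metrics_excluded_not_zeroed(self):
        plans = [self._plan(1, {"a", "b"})]
        per_snp = [
            SnpMetrics(vid="a", rep=1, concordance=1.0, iqs=float("nan"), maf=0.01),
            SnpMetrics(vid="b", rep=1, concordance=0.8, iqs=0.5, maf=0.2),
        ]
        s = summarize(per_snp, plans)
        assert s.per_rep.loc[0, "iqs"] == pytest.approx(0.5)
        assert s.counts["n_undefined_iqs"] == 1

    def test_pooled_concordance_invariant_to_snp_order(self, rng):
        vids = [f"v{i}" for i in range(30)]
        plans = [self._plan(1, set(vids))]
        per_snp = [
            SnpMetrics(vid=v, rep=1, concordance=float(rng.uniform(0.5, 1)),
                       iqs=float(rng.uniform(0, 1)), maf=0.2)
            for v in vids
        ]
        s1 = summarize(per_snp, plans)
        perm = [per_snp[i] for i in rng.permutation(len(per_snp))]
        s2 = summarize(perm, plans)
        assert s1.pooled_concordance == pytest.approx(s2.pooled_concordance, abs=1e-12)
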