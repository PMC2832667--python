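"""Deflated chi-square, GC correction, LD categorization, pruning, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolancestry.aims import (
    VarianceComponents,
    categorize,
    corrected_af_difference,
    corrected_chi2,
    gc_correct,
    ld_neighbors,
    pooled_error_variance,
    prune_by_distance,
    sampling_variance,
    select_candidates,
    weighted_pool_af,
)
from poolancestry.simulate import simulate_ld_blocks


class TestSamplingVariance:
    def test_arithmetic(self):
        assert sampling_variance(0.5, 250, 0.5, 250) == pytest.approx(0.001)

    def test_fixed_allele_term_vanishes(self):
        v = sampling_variance(0.0, 100, 0.5, 100)
        assert v == pytest.approx(0.25 / 200)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sampling_variance(0.5, 0, 0.5, 100)

    def test_components_validated(self):
        with pytest.raises(ValueError):
            VarianceComponents(v=-1e-3, var_e_case=0, var_e_control=0,
                               n_case=10, n_control=10)


class TestPooledErrorVariance:
    def test_single_pool(self):
        assert pooled_error_variance([0.01], [250]) == pytest.approx(1e-4)

    def test_two_equal_pools(self):
        assert pooled_error_variance([0.01, 0.01], [250, 250]) == pytest.approx(5e-5)

    def test_weighted_total_af(self):
        assert weighted_pool_af([0.2, 0.6], [300, 100])[0] == pytest.approx(0.3)

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError):
            pooled_error_variance([np.nan, 0.01], [250, 250])


class TestCorrectedChi2:
    def test_no_pooling_error_equals_naive(self):
        naive, corrected, _ = corrected_chi2(0.6, 0.4, 100, 100)
        assert corrected == pytest.approx(naive)

    def test_equal_frequencies_zero(self):
        naive, corrected, _ = corrected_chi2(0.35, 0.35, 100, 150, 1e-4, 0.0)
        assert naive == 0.0 and corrected == 0.0

    def test_naive_matches_contingency_oracle(self):
        """Pearson chi2 of the implied 2x2 allele-count table, to 1e-9."""
        p_case, p_control, n = 0.6, 0.4, 100
        naive, _, _ = corrected_chi2(p_case, p_control, n, n)
        table = np.array(
            [
                [2 * n * p_case, 2 * n * (1 - p_case)],
                [2 * n * p_control, 2 * n * (1 - p_control)],
            ]
        )
        oracle = stats.chi2_contingency(table, correction=False).statistic
        assert naive == pytest.approx(oracle, abs=1e-9)

    def test_negative_maf_excluded(self):
        naive, corrected, excluded = corrected_chi2(
            np.array([-0.02, 0.3]), np.array([0.3, 0.3]), 100, 100
        )
        assert excluded[0] and not excluded[1]
        assert np.isnan(naive[0]) and np.isnan(corrected[0])

    @given(
        st.floats(0.05, 0.95),
        st.floats(0.05, 0.95),
        st.floats(0.0, 1e-2),
        st.floats(0.0, 1e-2),
    )
    def test_deflation_inequality(self, pc, pt, ve1, ve2):
        """corrected <= naive for every input; equality iff no pooling error."""
        naive, corrected, _ = corrected_chi2(pc, pt, 200, 120, ve1, ve2)
        assert corrected <= naive + 1e-12
        if ve1 == ve2 == 0:
            assert corrected == pytest.approx(naive)

    def test_deflation_equals_variance_ratio_form(self):
        """corrected ~ dp^2 / (V + var_e) when naive ~ dp^2 / V (equal n)."""
        pc, pt, n, ve = 0.55, 0.45, 250, 2e-4
        naive, corrected, _ = corrected_chi2(pc, pt, n, n, ve, 0.0)
        v = sampling_variance(pc, n, pt, n)
        assert corrected == pytest.approx(naive * v / (v + ve))


class TestGcCorrect:
    def test_chi2_quantile(self):
        p, lam = gc_correct(np.array([3.841]), lam=1.0)
        assert p[0] == pytest.approx(0.05, abs=1e-3)

    def test_lambda_scaling(self):
        p1, _ = gc_correct(np.array([7.682]), lam=2.0)
        p2, _ = gc_correct(np.array([3.841]), lam=1.0)
        assert p1[0] == pytest.approx(p2[0])

    def test_lambda_floored_at_one(self):
        _, lam = gc_correct(np.full(101, 0.1))
        assert lam == 1.0

    def test_null_p_values_uniform(self, rng):
        x = rng.chisquare(1, 50_000)
        p, _ = gc_correct(x)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCorrectedAfDifference:
    def test_zero_statistic_zero_difference(self):
        assert corrected_af_difference(0.0, 1e-3, 0.2) == 0.0

    def test_no_pooling_error_recovers_raw(self):
        """With var_e = 0 the implied dAF equals the raw dAF up to the
        naive-chi2/V linearization (exact as the difference shrinks)."""
        pc, pt, n = 0.501, 0.499, 500
        naive, corrected, _ = corrected_chi2(pc, pt, n, n)
        v = sampling_variance(pc, n, pt, n)
        d = corrected_af_difference(corrected, v, pc - pt)
        assert d == pytest.approx(pc - pt, abs=1e-6)

    def test_shrinks_monotonically_in_pooling_error(self):
        pc, pt, n = 0.6, 0.4, 250
        v = sampling_variance(pc, n, pt, n)
        diffs = []
        for ve in (0.0, 1e-4, 1e-3, 1e-2):
            _, corrected, _ = corrected_chi2(pc, pt, n, n, ve, 0.0)
            diffs.append(abs(corrected_af_difference(corrected, v, pc - pt)))
        assert np.all(np.diff(diffs) < 0)

    def test_never_exceeds_raw(self, rng):
        pc = rng.uniform(0.1, 0.9, 200)
        pt = rng.uniform(0.1, 0.9, 200)
        n1, n2 = 500, 120
        _, corrected, _ = corrected_chi2(pc, pt, n1, n2)
        v = sampling_variance(pc, n1, pt, n2)
        d = corrected_af_difference(corrected, v, pc - pt)
        assert np.all(np.abs(d) <= np.abs(pc - pt) + 1e-12)
        assert np.array_equal(np.sign(d), np.sign(pc - pt))


class TestLdNeighbors:
    def test_no_snps_in_window(self, rng):
        g = rng.integers(0, 3, size=(50, 2))
        out = ld_neighbors(g, ["a", "b"], [1, 2], [100, 200])
        assert out == {"a": [], "b": []}

    def test_perfect_duplicate_included(self, rng):
        col = rng.integers(0, 3, size=50)
        g = np.stack([col, col], axis=1)
        out = ld_neighbors(g, ["a", "b"], [1, 1], [100, 1_000_100])
        assert out["a"] == ["b"] and out["b"] == ["a"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(12)
        afs = rng.uniform(0.2, 0.8, 30)
        g, _ = simulate_ld_blocks(afs, 200, block_size=5, rho=0.9, rng=rng)
        pos = np.arange(30) * 1_000_000 + 1
        chrom = np.ones(30, int)
        ids = [f"s{i}" for i in range(30)]
        out = ld_neighbors(g, ids, chrom, pos, window=20_000_000, r2_min=0.5)
        corr = np.corrcoef(g.T) ** 2
        for i in range(30):
            oracle = {
                ids[j]
                for j in range(30)
                if j != i and abs(pos[j] - pos[i]) <= 20_000_000 and corr[i, j] > 0.5
            }
            assert set(out[ids[i]]) == oracle


class TestCategorize:
    def test_no_neighbors_inconclusive(self):
        assert categorize([]) == "inconclusive"

    def test_encouraging_rule(self):
        assert categorize([0.01, 0.04, 0.2, 0.05]) == "encouraging"

    def test_discouraging_rule(self):
        assert categorize([0.5, 0.9]) == "discouraging"

    def test_mixed_inconclusive(self):
        # one neighbor < 0.1 but none < 0.05 -> neither rule fires
        assert categorize([0.07, 0.5, 0.9]) == "inconclusive"


def _records(pos_mb, pvals, chrom=None, category="inconclusive"):
    n = len(pos_mb)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom if chrom is not None else np.ones(n, int),
            "pos": (np.asarray(pos_mb) * 1_000_000).astype(int),
            "gc_p": pvals,
            "category": category,
        }
    )


class TestPrune:
    def test_close_pair_keeps_best(self):
        rec = prune_by_distance(_records([10, 13], [1e-6, 1e-5]))
        assert rec["kept"].tolist() == [True, False]

    def test_distant_pair_keeps_both(self):
        rec = prune_by_distance(_records([10, 15], [1e-6, 1e-5]))
        assert rec["kept"].tolist() == [True, True]

    def test_discouraging_never_kept(self):
        rec = _records([10, 20], [1e-6, 1e-5], category="discouraging")
        assert not prune_by_distance(rec)["kept"].any()

    def test_chain_matches_greedy_oracle(self, rng):
        n = 40
        pos = np.cumsum(rng.uniform(1, 5, n))  # Mb, chained spacing
        p = rng.uniform(0, 1, n)
        rec = prune_by_distance(_records(pos, p))
        # independent greedy re-implementation on the same integer positions
        pos_int = (pos * 1_000_000).astype(int)
        kept, removed = [], set()
        for i in np.argsort(p, kind="stable"):
            if i in removed:
                continue
            kept.append(i)
            for j in range(n):
                if j != i and abs(pos_int[j] - pos_int[i]) < 4_000_000:
                    removed.add(j)
        expected = np.zeros(n, bool)
        expected[kept] = True
        np.testing.assert_array_equal(rec["kept"].to_numpy(), expected)


class TestSelectCandidates:
    def test_top_list_excludes_discouraging(self):
        rec = _records(np.arange(30) * 10, np.linspace(1e-8, 1e-4, 30))
        ld_f = {f"s{i}": [0.5, 0.9] for i in range(5)}  # first five discouraging
        l1, _ = select_candidates(rec, ld_f, {}, list_size=25)
        assert len(l1) == 25
        assert not set(l1["snp_id"]) & {f"s{i}" for i in range(5)}

    def test_single_neighbor_ineligible_for_list2(self):
        rec = _records([10], [1e-5])
        _, l2 = select_candidates(rec, {"s0": [0.01]}, {"s0": [0.01]})
        assert len(l2) == 0

    def test_list2_ranked_by_significant_neighbors_then_p(self):
        rec = _records([10, 100, 200], [5e-4, 4e-4, 1e-4])
        ld = {
            "s0": [0.01, 0.02, 0.03],  # 3 significant neighbors
            "s1": [0.01, 0.02, 0.5],  # 2 significant
            "s2": [0.01, 0.02, 0.5],  # 2 significant, smaller P
        }
        _, l2 = select_candidates(rec, ld, ld)
        assert l2["snp_id"].tolist() == ["s0", "s2", "s1"]
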