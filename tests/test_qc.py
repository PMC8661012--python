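"""QC cascade: exact HWE test, threshold semantics, LD pruning audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidirmr.errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from bidirmr.qc import (
    filter_hwe,
    filter_individual_missingness,
    filter_snp_call_rate,
    hwe_chi2_test,
    hwe_exact_test,
    ld_audit,
    ld_prune,
    pairwise_r2,
    run_qc,
)
from bidirmr.simulate import GenotypeMatrix, simulate_genotypes

from oracles import hwe_exact_bruteforce


def make_matrix(calls, chrom=None, pos=None):
    calls = np.asarray(calls, dtype=float)
    m = calls.shape[1]
    meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else [(j + 1) * 100 for j in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        }
    )
    ids = np.array([f"i{k}" for k in range(calls.shape[0])])
    return GenotypeMatrix(calls, meta, ids)


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 25) == 1.0
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_two_configuration_case_full_enumeration(self):
        # 2 ref + 2 alt alleles: het count is 0 or 2 with P = 1/3, 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "counts", [(57, 78, 13), (10, 1, 10), (100, 50, 5), (3, 4, 3), (0, 1, 40)]
    )
    def test_matches_bruteforce_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_bruteforce(*counts), abs=1e-12
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(1.5, 2, 3)

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=200, deadline=None)
    def test_p_value_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0.0 < p <= 1.0

    def test_chi2_option_agrees_at_large_counts(self):
        # equilibrium-ish large table: asymptotics hold
        p_exact = hwe_exact_test(4900, 4200, 900)
        p_chi2 = hwe_chi2_test(4900, 4200, 900)
        assert abs(p_exact - p_chi2) < 0.02

    def test_midp_smaller_than_standard(self):
        assert hwe_exact_test(57, 78, 13, midp=True) < hwe_exact_test(57, 78, 13)


class TestMissingnessFilters:
    def test_individual_strict_boundary(self):
        # 100 SNPs: 5% missing retained (strict >), 6% removed
        calls = np.ones((3, 100))
        calls[1, :5] = np.nan   # exactly 5%
        calls[2, :6] = np.nan   # 6%
        G = make_matrix(calls)
        out, stage = filter_individual_missingness(G, 0.05)
        assert list(out.individual_ids) == ["i0", "i1"]
        assert stage.removed_ids == ("i2",)

    def test_engineered_individual_count(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(100, 50)).astype(float)
        bad = rng.choice(100, 7, replace=False)
        for i in bad:
            calls[i, :10] = np.nan  # 20% missing
        G = make_matrix(calls)
        out, stage = filter_individual_missingness(G, 0.05)
        assert len(stage.removed_ids) == 7
        assert out.n_individuals == 93

    def test_snp_call_rate_strict_boundary(self):
        calls = np.ones((100, 3))
        calls[:3, 1] = np.nan  # call rate 0.97 exactly -> retained
        calls[:5, 2] = np.nan  # 0.95 -> removed
        G = make_matrix(calls)
        out, stage = filter_snp_call_rate(G, 0.97)
        assert list(out.snp_ids) == ["snp0", "snp1"]
        assert stage.removed_ids == ("snp2",)

    def test_engineered_snp_count(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(200, 50)).astype(float)
        for j in (4, 17, 33):
            calls[:20, j] = np.nan  # call rate 0.9
        G = make_matrix(calls)
        out, stage = filter_snp_call_rate(G, 0.97)
        assert set(stage.removed_ids) == {"snp4", "snp17", "snp33"}

    def test_empty_matrix_rejected(self):
        G = make_matrix(np.ones((2, 1)))
        empty = G.take_snps(np.zeros(1, dtype=bool))
        with pytest.raises(InvalidInputError):
            filter_snp_call_rate(empty, 0.97)


class TestFilterHWE:
    def test_gross_heterozygote_excess_removed(self):
        calls = np.column_stack([
            np.ones(1000),                       # all-het: p << 1e-6
            np.repeat([0, 1, 2], [490, 420, 90]),  # near equilibrium
        ])
        G = make_matrix(calls)
        out, stage = filter_hwe(G, alpha=1e-6)
        assert stage.removed_ids == ("snp0",)
        assert hwe_exact_bruteforce(0, 1000, 0) < 1e-6

    def test_null_removal_fraction_bounded(self):
        G = simulate_genotypes(10_000, np.full(1000, 0.3), seed=3)
        out, stage = filter_hwe(G, alpha=1e-3)
        # under the null the exact test is conservative: removals <= 10 * alpha
        assert len(stage.removed_ids) <= 1000 * 1e-3 * 10

    def test_alpha_domain(self):
        G = make_matrix(np.ones((10, 1)))
        with pytest.raises(InvalidParameterError):
            filter_hwe(G, alpha=1.0)
        with pytest.raises(InvalidParameterError):
            filter_hwe(G, alpha=0.0)


class TestPairwiseR2:
    def test_identity_and_allele_flip(self, rng):
        g = rng.integers(0, 3, 500).astype(float)
        assert pairwise_r2(g, g) == pytest.approx(1.0, abs=1e-12)
        assert pairwise_r2(g, 2 - g) == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_pearson(self, rng):
        g1 = rng.integers(0, 3, 300).astype(float)
        g2 = rng.integers(0, 3, 300).astype(float)
        expected = np.corrcoef(g1, g2)[0, 1] ** 2
        assert pairwise_r2(g1, g2) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_handling(self, rng):
        g1 = rng.integers(0, 3, 300).astype(float)
        g2 = g1.copy()
        g1[:50] = np.nan
        g2[250:] = np.nan
        assert pairwise_r2(g1, g2) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pairwise_r2(np.ones(10), np.arange(10) % 3)


class TestLDPrune:
    def test_duplicate_pair_keeps_earlier(self, rng):
        g = rng.integers(0, 3, 400).astype(float)
        other = rng.integers(0, 3, 400).astype(float)
        G = make_matrix(np.column_stack([g, other, g]))
        out, stage = ld_prune(G, r2_threshold=0.8)
        assert list(out.snp_ids) == ["snp0", "snp1"]
        assert stage.removed_ids == ("snp2",)

    def test_no_high_ld_identity(self, rng):
        calls = rng.integers(0, 3, size=(500, 10)).astype(float)
        G = make_matrix(calls)
        out, stage = ld_prune(G, r2_threshold=0.8)
        assert out.n_snps == 10
        assert stage.removed_ids == ()

    def test_planted_block_one_survivor_and_audit_clean(self, rng):
        cols = [rng.integers(0, 3, 600).astype(float) for _ in range(16)]
        block = rng.integers(0, 3, 600).astype(float)
        calls = np.column_stack(cols[:8] + [block, block, 2 - block, block] + cols[8:])
        G = make_matrix(calls)
        out, stage = ld_prune(G, r2_threshold=0.8, window_snps=50)
        assert out.n_snps == 17
        assert len(stage.removed_ids) == 3
        assert "snp8" in out.snp_ids  # earliest block member survives
        assert ld_audit(out, r2_threshold=0.8, window_snps=50) == []

    def test_unsorted_positions_rejected(self, rng):
        calls = rng.integers(0, 3, size=(50, 3)).astype(float)
        G = make_matrix(calls, pos=[300, 100, 200])
        with pytest.raises(InvalidInputError):
            ld_prune(G)

    def test_windowing_spans_step_boundaries(self, rng):
        # duplicates placed farther apart than the step but inside a window
        base = rng.integers(0, 3, size=(500, 12)).astype(float)
        base[:, 9] = base[:, 2]
        G = make_matrix(base)
        out, _ = ld_prune(G, r2_threshold=0.8, window_snps=10, step_snps=5)
        assert "snp9" not in out.snp_ids


class TestRunQC:
    def test_cascade_order_conservation_single_reason(self, rng):
        n = 300
        # 30 SNPs so one missing call (1/30 = 3.3%) keeps an individual
        # under the 5% threshold: stages stay independent
        good = [rng.binomial(2, 0.3, n).astype(float) for _ in range(27)]
        low_call = rng.binomial(2, 0.3, n).astype(float)
        low_call[10:70] = np.nan  # 20% missing
        all_het = np.ones(n)
        dup = good[0].copy()
        calls = np.column_stack(good[:13] + [low_call, all_het] + good[13:] + [dup])
        calls[0, :] = np.nan  # individual 0: fully missing
        G = make_matrix(calls)
        out, report = run_qc(G, hwe_alpha=1e-6)
        report.validate_conservation()
        assert report.stage_order == ["missingness", "call_rate", "hwe", "ld_pruned"]
        removed = report.removed_snps
        assert removed.set_index("id")["reason"].to_dict() == {
            "snp13": "call_rate",
            "snp14": "hwe",
            "snp29": "ld_pruned",
        }
        assert list(report.removed_individuals["id"]) == ["i0"]
        assert report.n_snps_out == 27
        # every removed item carries exactly one reason
        assert removed["id"].is_unique

    def test_report_round_trip_fields(self, rng):
        G = make_matrix(rng.integers(0, 3, size=(80, 5)).astype(float))
        _, report = run_qc(G)
        d = report.to_dict()
        assert d["n_snps_in"] == 5
        assert set(d["thresholds_used"]) >= {
            "max_individual_missing",
            "min_call_rate",
            "hwe_alpha",
            "r2_threshold",
        }
        assert "retained" in report.summary()
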