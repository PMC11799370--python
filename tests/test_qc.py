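from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import cohortpgs as cp
from cohortpgs import (
    CohortConfig,
    PipelineError,
    hwe_exact_test,
    intersect_snps,
    king_kinship,
    kinship_filter,
    sample_qc,
    simulate_genotypes,
    snp_qc,
)
from cohortpgs.qc import SnpQCReport

from conftest import make_geno, make_pheno


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional HWE test.

    P(het = h | allele counts) is proportional to the number of genotype
    configurations: n! / (homr! h! homc!) * 2^h.  Sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        homr = (rare - h) // 2
        homc = n - h - homr
        weights[h] = Fraction(
            comb(n, homr) * comb(n - homr, h) * 2**h, 1
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExactTest:
    def test_monomorphic_single_table(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_matches_enumeration_oracle_small_table(self):
        assert hwe_exact_test(3, 5, 2) == pytest.approx(hwe_oracle(3, 5, 2),
                                                        rel=1e-12)

    @pytest.mark.parametrize("table", [(1, 0, 9), (0, 10, 0), (5, 1, 5),
                                       (12, 2, 11), (2, 17, 6)])
    def test_matches_enumeration_oracle_assorted(self, table):
        assert hwe_exact_test(*table) == pytest.approx(hwe_oracle(*table),
                                                       rel=1e-12)

    def test_exhaustive_small_totals(self):
        # all genotype tables with at most 25 observations
        for n in range(1, 26):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-9), (n_AA, n_Aa, n_aa)
                    assert 0 < got <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSampleQC:
    def test_miss_rate_above_threshold_excluded(self):
        dos = np.ones((3, 100))
        dos[0, :11] = np.nan  # miss rate 0.11 > 0.1
        dos[1, :10] = np.nan  # miss rate 0.10 exactly -> retained
        geno = make_geno(dos)
        pheno = make_pheno(geno, heights=170.0)
        rep = sample_qc(geno, pheno)
        t = rep.table.set_index("sample_id")
        assert t.loc["S000", "reasons"] == "MISS_RATE"
        assert t.loc["S001", "pass"] and t.loc["S002", "pass"]

    def test_birth_window_is_closed(self):
        geno = make_geno(np.ones((4, 10)))
        pheno = make_pheno(geno, heights=170.0,
                           birth_year=[1945, 1946, 1986, 1987])
        rep = sample_qc(geno, pheno)
        assert rep.excluded_ids == ["S000", "S003"]
        assert set(rep.table.loc[~rep.table["pass"], "reasons"]) == {"BIRTHYEAR"}

    def test_clean_cohort_no_exclusions(self):
        geno = make_geno(np.ones((5, 10)))
        pheno = make_pheno(geno, heights=170.0)
        assert sample_qc(geno, pheno).excluded_ids == []

    def test_idempotent_on_passing_subset(self):
        dos = np.ones((6, 50))
        dos[2, :30] = np.nan
        geno = make_geno(dos)
        pheno = make_pheno(geno, heights=170.0,
                           birth_year=[1966, 1940, 1966, 1966, 1990, 1966])
        first = sample_qc(geno, pheno)
        sub = geno.subset(sample_ids=first.passing_ids)
        sub_p = pheno[pheno["sample_id"].isin(first.passing_ids)]
        second = sample_qc(sub, sub_p)
        assert second.excluded_ids == []

    def test_sex_error_stub_honored(self):
        geno = make_geno(np.ones((2, 10)))
        pheno = make_pheno(geno, heights=170.0)
        pheno["sex_error"] = [True, False]
        rep = sample_qc(geno, pheno)
        assert rep.table.set_index("sample_id").loc["S000", "reasons"] == "SEX_STUB"


class TestSnpQC:
    def test_call_rate_boundary(self):
        dos = np.tile([0.0, 1, 2, 1, 0, 1, 2, 1, 0, 1], (100, 1)).T.reshape(10, 100).T
        dos = np.asarray(dos, dtype=float)
        dos[:11, 0] = np.nan  # call rate 0.89 -> fail
        dos[:10, 1] = np.nan  # call rate 0.90 exactly -> pass
        geno = make_geno(dos)
        rep = snp_qc(geno)
        t = rep.table.set_index("snp_id")
        assert "CALL_RATE" in t.loc["snp000", "reasons"]
        assert "CALL_RATE" not in t.loc["snp001", "reasons"]

    def test_maf_boundary_exactly_min_retained(self):
        # 100 samples, two heterozygotes -> MAF exactly 0.01, HWE p = 1
        col_boundary = np.zeros(100)
        col_boundary[:2] = 1.0
        col_fail = np.zeros(100)
        col_fail[0] = 1.0  # MAF 0.005 < 0.01
        col_ok = np.tile([0.0, 1, 2, 1], 25)
        geno = make_geno(np.column_stack([col_boundary, col_fail, col_ok]))
        rep = snp_qc(geno)
        t = rep.table.set_index("snp_id")
        assert t.loc["snp000", "pass"]
        assert t.loc["snp001", "reasons"] == "MAF"
        assert t.loc["snp002", "pass"]

    def test_generator_hwe_violators_all_flagged(self):
        cfg = CohortConfig(n_samples=800, n_snps=60, n_causal=5,
                           n_hwe_violators=4, missing_rate=0.0, seed=31)
        geno = simulate_genotypes(cfg)
        rep = snp_qc(geno)
        flagged = set(rep.table.loc[rep.table["reasons"].str.contains("HWE"),
                                    "snp_id"])
        violators = set(geno.snps.loc[geno.snps["hwe_violator"], "snp_id"])
        assert violators <= flagged

    def test_zero_call_snp_flagged_without_hwe(self):
        dos = np.tile([0.0, 1, 2, 1], 5).reshape(-1, 1) @ np.ones((1, 2))
        dos[:, 1] = np.nan
        geno = make_geno(dos)
        rep = snp_qc(geno)
        t = rep.table.set_index("snp_id")
        assert t.loc["snp001", "reasons"] == "CALL_RATE"
        assert np.isnan(t.loc["snp001", "hwe_p"])

    def test_verdicts_order_independent(self):
        cfg = CohortConfig(n_samples=150, n_snps=40, n_causal=5,
                           n_hwe_violators=2, seed=32)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(geno.n_samples)
        perm_j = rng.permutation(geno.n_snps)
        shuffled = make_geno(
            geno.dosages[np.ix_(perm_s, perm_j)],
            sample_ids=[geno.sample_ids[i] for i in perm_s],
            snp_ids=[geno.snps["snp_id"].iat[j] for j in perm_j],
        )
        base = snp_qc(geno).table.set_index("snp_id")["pass"]
        shuf = snp_qc(shuffled).table.set_index("snp_id")["pass"]
        assert base.sort_index().equals(shuf.sort_index())


class TestKinship:
    def test_duplicate_sample_flagged_lexicographic_tiebreak(self):
        cfg = CohortConfig(n_samples=40, n_snps=500, n_causal=5, seed=33,
                           missing_rate=0.0, n_related_pairs=0,
                           n_hwe_violators=0)
        geno = simulate_genotypes(cfg)
        dos = geno.dosages.copy()
        dos[1] = dos[0]  # S000001 duplicates S000000
        dup = make_geno(dos, sample_ids=geno.sample_ids)
        phi = king_kinship(dup)
        assert phi[0, 1] == pytest.approx(0.5, abs=1e-6)
        rep = kinship_filter(dup)
        pair = rep.kinship_pairs.set_index("sample_a").loc["S000000"]
        # equal missing rates: the lexicographically larger id is dropped
        assert pair["excluded"] == "S000001"
        assert "S000001" in rep.excluded_ids

    def test_unrelated_cohort_untouched(self):
        cfg = CohortConfig(n_samples=60, n_snps=5000, n_causal=5, seed=34,
                           missing_rate=0.0, n_related_pairs=0,
                           n_hwe_violators=0)
        geno = simulate_genotypes(cfg)
        phi = king_kinship(geno)
        off = phi[np.triu_indices(60, 1)]
        # upper tail only: the estimator has a small negative bias, so the
        # relevant bound is that no pair crosses the relatedness cutoff
        assert off.max() < cp.KINSHIP_3RD_DEGREE
        assert kinship_filter(geno).excluded_ids == []

    def test_parent_offspring_detected(self):
        cfg = CohortConfig(n_samples=100, n_snps=5000, n_causal=5, seed=35,
                           missing_rate=0.01, n_related_pairs=3,
                           n_hwe_violators=0)
        geno = simulate_genotypes(cfg)
        phi = king_kinship(geno)
        for parent, child in cp.related_pairs(cfg):
            i, j = geno.sample_index([parent, child])
            assert 0.177 <= phi[i, j] <= 0.354
        excluded = set(kinship_filter(geno).excluded_ids)
        assert len(excluded) == 3
        for parent, child in cp.related_pairs(cfg):
            assert parent in excluded or child in excluded


class TestIntersectSnps:
    @staticmethod
    def report(passing, failing=()):
        ids = list(passing) + list(failing)
        return SnpQCReport(
            table=pd.DataFrame(
                {
                    "snp_id": ids,
                    "reasons": [""] * len(passing) + ["MAF"] * len(failing),
                    "pass": [True] * len(passing) + [False] * len(failing),
                }
            )
        )

    def test_identity(self):
        r = self.report(["a", "b", "c"], ["d"])
        assert intersect_snps(r, r) == ["a", "b", "c"]

    def test_disjoint_raises(self):
        with pytest.raises(PipelineError):
            intersect_snps(self.report(["a", "b"]), self.report(["c", "d"]))

    def test_partial_overlap_counts(self):
        shared = [f"s{i}" for i in range(500)]
        a = self.report(shared + [f"a{i}" for i in range(100)])
        b = self.report(shared + [f"b{i}" for i in range(50)])
        out = intersect_snps(a, b)
        assert len(out) == 500 and out == sorted(shared)
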