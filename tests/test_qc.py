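"""QC filters, HWE exact test, trend test, association table."""

import math

import numpy as np
import pytest
from scipy.special import comb
from scipy import stats

from snpcombo._util import MISSING
from snpcombo.qc import (AssociationError, QCError, QCThresholds, apply_qc,
                         catt_trend_test, hwe_exact_test, run_association)
from tests.conftest import make_genotypes


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Independent enumeration oracle using binomial coefficients."""
    n = n_hom1 + n_het + n_hom2
    na = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)  # minor alleles
    if na == 0:
        return 1.0
    probs = {}
    for h in range(na % 2, na + 1, 2):
        hom_minor = (na - h) // 2
        hom_major = n - h - hom_minor
        # multinomial count of genotype arrangements over permutations
        # of the 2n alleles, conditional on the allele counts
        num = (
            math.factorial(n)
            / (math.factorial(hom_minor) * math.factorial(h)
               * math.factorial(hom_major))
            * 2**h
        )
        den = comb(2 * n, na, exact=True)
        probs[h] = num / den
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestHweExact:
    def test_degenerate_support_gives_p_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        assert hwe_exact_test(5, 10, 5) == pytest.approx(
            hwe_oracle(5, 10, 5), rel=1e-9
        )
        for table in [(10, 2, 8), (0, 10, 0), (7, 1, 1), (3, 3, 3)]:
            assert hwe_exact_test(*table) == pytest.approx(
                hwe_oracle(*table), rel=1e-9
            )

    def test_exhaustive_sweep_small_n(self):
        for n in range(1, 26):
            for n2 in range(0, n + 1):
                for h in range(0, n - n2 + 1):
                    n0 = n - n2 - h
                    assert hwe_exact_test(n0, h, n2) == pytest.approx(
                        hwe_oracle(n0, h, n2), rel=1e-9
                    ), (n0, h, n2)

    def test_monotone_in_distance_from_expectation(self):
        # for fixed allele counts, tables farther from the HWE-expected
        # heterozygosity never have larger p
        n, na = 30, 20
        support = list(range(na % 2, na + 1, 2))
        probs = {h: hwe_oracle((na - h) // 2 + 0, h, 0) for h in support}
        pvals = [hwe_exact_test((na - h) // 2, h, n - h - (na - h) // 2)
                 for h in support]
        peak = int(np.argmax([hwe_oracle_prob(n, na, h) for h in support]))
        left = pvals[: peak + 1]
        right = pvals[peak:]
        assert all(a <= b + 1e-12 for a, b in zip(left, left[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(right, right[1:]))

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def hwe_oracle_prob(n, na, h):
    hom_minor = (na - h) // 2
    hom_major = n - h - hom_minor
    num = (
        math.factorial(n)
        / (math.factorial(hom_minor) * math.factorial(h)
           * math.factorial(hom_major))
        * 2**h
    )
    return num / comb(2 * n, na, exact=True)


def catt_oracle(case_counts, control_counts):
    """Independent oracle: the trend chi-square equals N * corr(g, y)^2."""
    g = np.concatenate(
        [np.repeat([0, 1, 2], case_counts), np.repeat([0, 1, 2],
                                                      control_counts)]
    )
    y = np.concatenate(
        [np.ones(sum(case_counts)), np.zeros(sum(control_counts))]
    )
    rho = np.corrcoef(g, y)[0, 1]
    stat = len(g) * rho**2
    return stat, float(stats.chi2.sf(stat, 1))


class TestTrendTest:
    def test_identical_distributions_give_zero(self):
        assert catt_trend_test((10, 10, 10), (10, 10, 10)) == (0.0, 1.0)

    def test_matches_textbook_oracle(self):
        stat, p = catt_trend_test((10, 20, 30), (30, 20, 10))
        ostat, op = catt_oracle((10, 20, 30), (30, 20, 10))
        assert stat == pytest.approx(ostat, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_thousand_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            r = tuple(int(v) for v in rng.integers(0, 60, 3))
            s = tuple(int(v) for v in rng.integers(0, 60, 3))
            if sum(r) == 0 or sum(s) == 0:
                continue
            stat, p = catt_trend_test(r, s)
            g = np.repeat([0, 1, 2], np.add(r, s))
            if np.ptp(g) == 0:  # monomorphic: degenerate by convention
                assert (stat, p) == (0.0, 1.0)
                continue
            ostat, op = catt_oracle(r, s)
            assert stat == pytest.approx(ostat, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    def test_invariant_to_reversing_genotype_order(self):
        s1 = catt_trend_test((5, 15, 30), (25, 15, 5))
        s2 = catt_trend_test((30, 15, 5), (5, 15, 25))
        assert s1 == pytest.approx(s2)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            catt_trend_test((-1, 0, 1), (1, 1, 1))

    def test_null_calibration(self):
        """Type-I error at alpha=0.05 within [0.04, 0.06], n=500+500."""
        rng = np.random.default_rng(12345)
        n_sim = 10_000
        maf = 0.3
        g = rng.binomial(2, maf, size=(n_sim, 1000))
        cases, controls = g[:, :500], g[:, 500:]
        r = np.stack([(cases == k).sum(axis=1) for k in (0, 1, 2)], axis=1)
        s = np.stack([(controls == k).sum(axis=1) for k in (0, 1, 2)],
                     axis=1)
        from snpcombo.qc import _catt_stat_vec

        stat = _catt_stat_vec(r.astype(float), s.astype(float))
        p = np.where(stat > 0, stats.chi2.sf(stat, 1), 1.0)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestApplyQC:
    def test_clean_matrix_removes_nothing(self):
        rng = np.random.default_rng(0)
        # MAF 0.5, HWE-exact counts per SNP
        block = np.array([[0] * 5 + [1] * 10 + [2] * 5]).T
        d = np.tile(block, (1, 4))
        g = make_genotypes(d)
        res = apply_qc(g)
        assert len(res.removals) == 0
        assert res.genotypes.dosages.shape == d.shape

    def test_bad_sample_and_bad_snp_removed_with_reasons(self):
        d = np.ones((10, 5), dtype=np.int8)
        d[:, :] = np.tile(np.array([0, 1, 2, 1, 0, 1, 2, 1, 0, 1],
                                   dtype=np.int8)[:, None], (1, 5))
        d[0, :2] = MISSING          # sample 0: 40% missing
        d[1:3, 2] = MISSING         # SNP 2: 22% missing among the rest
        g = make_genotypes(d)
        # at 5 SNPs one missing cell is already 20% per sample, so the
        # sample filter is set above that to isolate the two target hits
        res = apply_qc(g, QCThresholds(sample_missing_max=0.25))
        rem = dict(zip(res.removals["id"], res.removals["reason"]))
        assert rem == {"S0": "sample_missing", "rs2": "snp_missing"}

    def test_hwe_outlier_removed(self):
        # 50/0/50 in controls: heterozygote deficit, exact p ~ 1e-30
        col = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        ok = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        d = np.stack([col, ok], axis=1)
        g = make_genotypes(d, phenotype=[1] * 100)  # all controls
        res = apply_qc(g)
        rem = dict(zip(res.removals["id"], res.removals["reason"]))
        assert rem == {"rs0": "hwe"}

    def test_qc_is_idempotent(self, small_panel):
        cfg, g, _, _ = small_panel
        from snpcombo.simulate import inject_missingness
        import dataclasses
        cfg2 = dataclasses.replace(cfg, missing_rate=0.002,
                                   bad_sample_fraction=0.01,
                                   bad_snp_fraction=0.01)
        g2 = inject_missingness(g, cfg2)
        first = apply_qc(g2)
        second = apply_qc(first.genotypes)
        assert len(second.removals) == 0

    def test_all_removed_raises(self):
        d = np.full((4, 3), MISSING, dtype=np.int8)
        with pytest.raises(QCError):
            apply_qc(make_genotypes(d))


class TestRunAssociation:
    def test_single_class_phenotype_raises(self):
        d = np.array([[0, 1], [1, 2]], dtype=np.int8)
        g = make_genotypes(d, phenotype=[1, 1])
        with pytest.raises(AssociationError):
            run_association(g)

    def test_row_count_and_rank_permutation(self, small_panel):
        _, g, y, _ = small_panel
        tab = run_association(g, y)
        assert len(tab) == g.n_snps
        assert sorted(tab["rank"]) == list(range(1, g.n_snps + 1))

    def test_permuted_phenotype_p_values_near_uniform(self, small_panel):
        _, g, y, _ = small_panel
        rng = np.random.default_rng(1)
        tab = run_association(g, rng.permutation(y))
        poly = tab.loc[tab["stat"] > 0, "p"]
        ks = stats.kstest(poly, "uniform")
        assert ks.pvalue > 1e-4

    def test_planted_main_effect_ranks_highly(self):
        """A strong main-effect SNP lands near the top of the ranking."""
        from snpcombo.simulate import SimConfig, simulate_panel
        ranks = []
        for seed in range(10):
            cfg = SimConfig(
                n_cases=500, n_controls=500, n_chromosomes=1,
                snps_per_chrom=200, block_size_snps=1,
                n_founder_haplotypes=64, n_main_causal=1,
                main_effect_or=2.0, n_epistatic_pairs=0,
                prevalence_intercept=-0.5, missing_rate=0.0,
                bad_sample_fraction=0.0, bad_snp_fraction=0.0, seed=seed,
            )
            g, y, truth = simulate_panel(cfg)
            tab = run_association(g, y).set_index("snp")
            ranks.append(tab.loc[truth.causal_snp_ids[0], "rank"])
        assert np.median(ranks) <= 10
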