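"""SNP-gene mapping, Fisher over-representation, BH FDR, genome-wide GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from snpcombo.enrichment import (EnrichmentError, bh_fdr, fisher_enrichment,
                                 genomewide_gsea, map_snps_to_genes)
from snpcombo.io import GeneAnnotation, GeneSetCollection
from snpcombo.qc import run_association
from snpcombo.simulate import generate_annotation


def annotation(records):
    return GeneAnnotation(
        pd.DataFrame(records, columns=["chrom", "start", "end", "gene"])
    )


def snps(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


class TestSnpGeneMapping:
    def test_snp_inside_gene_maps_with_distance_zero(self):
        ann = annotation([("1", 100, 200, "G1")])
        m = map_snps_to_genes(snps([("rs1", "1", 150)]), ann, flank_bp=0)
        assert list(m.itertuples(index=False))[0] == ("rs1", "G1",
                                                      "overlap", 0)

    def test_equidistant_snp_maps_to_both_genes(self):
        ann = annotation([("1", 0, 100, "G1"), ("1", 301, 400, "G2")])
        # p0 = 200: distance 101 bp to either gene interval
        m = map_snps_to_genes(snps([("rs1", "1", 201)]), ann, flank_bp=0)
        assert set(m["gene"]) == {"G1", "G2"}
        assert (m["relation"] == "nearest").all()

    def test_far_snp_is_unmapped(self):
        ann = annotation([("1", 0, 100, "G1")])
        m = map_snps_to_genes(snps([("rs1", "1", 900_000)]), ann,
                              flank_bp=0, max_nearest_bp=500_000)
        assert len(m) == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        genes = []
        cursor = 0
        for i in range(30):
            cursor += int(rng.integers(1, 5000))
            end = cursor + int(rng.integers(100, 4000))
            genes.append(("1", cursor, end, f"G{i}"))
            cursor = end
        ann = annotation(genes)
        snp_rows = [("rs%d" % i, "1", int(rng.integers(1, cursor + 10_000)))
                    for i in range(200)]
        flank, max_near = 500, 20_000
        got = map_snps_to_genes(snps(snp_rows), ann, flank_bp=flank,
                                max_nearest_bp=max_near)
        got_pairs = set(zip(got["snp"], got["gene"]))
        expected = set()
        for sid, _c, pos in snp_rows:
            p0 = pos - 1
            overlaps = [g for (_, s, e, g) in genes
                        if s - flank <= p0 < e + flank]
            if overlaps:
                expected.update((sid, g) for g in overlaps)
                continue
            dists = {g: (s - p0 if p0 < s else p0 - e + 1)
                     for (_, s, e, g) in genes}
            dmin = min(dists.values())
            if dmin <= max_near:
                expected.update(
                    (sid, g) for g, d in dists.items() if d == dmin
                )
        assert got_pairs == expected


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = len(p)
        sp = np.sort(p)
        expected = []
        for pi in p:
            # brute force: min over tail ranks of m*p_j/rank_j
            cand = [m * sp[j] / (j + 1) for j in range(m) if sp[j] >= pi]
            expected.append(min(min(cand), 1.0))
        assert np.allclose(bh_fdr(p), expected)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_stable_under_input_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


def hypergeom_tail_oracle(a, N, K, n):
    """Independent sum of hypergeometric terms P(X >= a)."""
    total = comb(N, n, exact=True)
    s = 0
    for x in range(a, min(K, n) + 1):
        s += comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
    return s / total


class TestFisherEnrichment:
    def collection(self, d):
        coll = GeneSetCollection()
        for name, members in d.items():
            coll.add(name, "pathway", members)
        return coll

    def test_disjoint_set_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        coll = self.collection({"S": universe[10:]})
        tab = fisher_enrichment(universe[:5], universe, coll)
        assert tab["a"].iloc[0] == 0
        assert tab["p"].iloc[0] == 1.0

    def test_matches_hypergeometric_oracle(self):
        universe = [f"G{i}" for i in range(100)]
        coll = self.collection({"S": universe[:10]})
        selected = universe[5:25]  # overlap a = 5
        tab = fisher_enrichment(selected, universe, coll)
        assert tab["p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(5, 100, 10, 20), abs=1e-12
        )

    def test_exhaustive_small_universe_sweep(self):
        for N in (5, 12, 25, 40):
            universe = [f"G{i}" for i in range(N)]
            for K in (1, N // 3, N // 2):
                if K == 0:
                    continue
                coll = self.collection({"S": universe[:K]})
                for n in (1, N // 4, N // 2, N):
                    if n == 0:
                        continue
                    selected = universe[N - n:]
                    a = len(set(universe[:K]) & set(selected))
                    tab = fisher_enrichment(selected, universe, coll)
                    assert tab["p"].iloc[0] == pytest.approx(
                        hypergeom_tail_oracle(a, N, K, n), abs=1e-12
                    ), (N, K, n)

    def test_selected_outside_universe_raises(self):
        coll = self.collection({"S": ["G1"]})
        with pytest.raises(EnrichmentError):
            fisher_enrichment(["X"], ["G1", "G2"], coll)

    def test_fdr_within_category_and_invariants(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(50)]
        coll = GeneSetCollection()
        for i in range(20):
            cat = ["pathway", "GO"][i % 2]
            coll.add(f"S{i}", cat,
                     rng.choice(universe, size=8, replace=False))
        tab = fisher_enrichment(universe[:12], universe, coll)
        assert (tab["fdr"] >= tab["p"] - 1e-15).all()
        for _, grp in tab.groupby("category"):
            assert (grp["fdr"].diff().dropna() >= -1e-12).all()
            assert np.allclose(grp["fdr"], bh_fdr(grp["p"].to_numpy()))

    def test_planted_module_ranks_first(self, small_panel):
        cfg, g, y, truth = small_panel
        ann, sets = generate_annotation(g.snp_map, cfg, truth)
        m = map_snps_to_genes(g.snp_map, ann, flank_bp=0)
        universe = sorted(set(m["gene"]))
        causal_genes = sorted(
            set(m.loc[m["snp"].isin(truth.causal_snp_ids), "gene"])
        )
        tab = fisher_enrichment(causal_genes, universe, sets)
        best = tab.sort_values("p", kind="mergesort").iloc[0]
        assert best["set"] in truth.enriched_module_ids


class TestGenomewideGsea:
    def test_cutoff_one_makes_enrichment_impossible(self, small_panel):
        cfg, g, y, truth = small_panel
        ann, sets = generate_annotation(g.snp_map, cfg, truth)
        m = map_snps_to_genes(g.snp_map, ann, flank_bp=0)
        assoc = run_association(g, y)
        tab = genomewide_gsea(assoc, m, sets, gene_p_cutoff=1.1)
        assert (tab["p"] == 1.0).all()

    def test_planted_module_near_top(self):
        """With adequately powered main effects the planted module leads
        the genome-wide enrichment ranking in most simulations."""
        from snpcombo.simulate import SimConfig, simulate_panel

        top = 0
        for seed in range(5):
            cfg = SimConfig(
                n_cases=300, n_controls=300, n_chromosomes=2,
                snps_per_chrom=200, block_size_snps=1,
                n_founder_haplotypes=64, n_main_causal=6,
                main_effect_or=1.8, n_epistatic_pairs=0,
                prevalence_intercept=-1.0, missing_rate=0.0,
                bad_sample_fraction=0.0, bad_snp_fraction=0.0,
                snps_per_gene=3, n_gene_sets=80, n_enriched_sets=1,
                set_size_range=(6, 20), planted_fillers=5, seed=700 + seed,
            )
            g, y, truth = simulate_panel(cfg)
            ann, sets = generate_annotation(g.snp_map, cfg, truth)
            m = map_snps_to_genes(g.snp_map, ann, flank_bp=0)
            assoc = run_association(g, y)
            tab = genomewide_gsea(assoc, m, sets, gene_p_cutoff=0.05)
            ranked = tab.sort_values("p", kind="mergesort")["set"].tolist()
            top += min(ranked.index(x)
                       for x in truth.enriched_module_ids) < 5
        assert top >= 4
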