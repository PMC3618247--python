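"""Synthetic case-control GWAS panels with LD, epistasis and annotations.

The generator emulates the statistical structure of a genotyping-array
case-control panel: biallelic SNPs with a configurable MAF spectrum,
haplotype-block LD from a small founder pool, a binary phenotype drawn from
a logistic penetrance model with weak main effects plus centered-product
epistatic pairs, missing genotypes with designated bad samples/SNPs, and a
matching gene annotation plus gene-set collection in which the causal genes
are concentrated in a few planted modules.

LD arises because each individual draws, per block, two founder haplotypes
from a pool of ``n_founder_haplotypes``; alleles on the same founder
haplotype co-occur, so within-block r-squared is high while blocks are
independent. Genotypes at a SNP are two iid draws from the founder-pool
allele frequency, so the null panel is Hardy-Weinberg consistent by
construction. Case-control ascertainment uses rejection sampling: cohorts
are simulated from the population model until exactly ``n_cases`` cases and
``n_controls`` controls have accumulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import MISSING
from .io import GenotypeMatrix, GeneAnnotation, GeneSetCollection

__all__ = ["SimConfig", "TruthRecord", "AscertainmentError",
           "simulate_panel", "inject_missingness", "generate_annotation"]

#: categories cycled over non-planted gene sets, mirroring the five kinds of
#: functional module the enrichment layer distinguishes
CATEGORIES = ("pathway", "TF-target", "miRNA-target", "GO", "complex")


class AscertainmentError(RuntimeError):
    """Rejection sampling failed to reach the requested case count."""


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults describe a desk-scale panel with the 2:3 case-control
    imbalance of a typical consortium panel, array-like MAF spectrum
    (5-50%), haplotype blocks of 5 SNPs drawn from 8 founders, a handful
    of weak main effects plus epistatic pairs, and light missingness with
    a few designated bad samples/SNPs that the QC stage should catch.
    """

    n_cases: int = 400
    n_controls: int = 600
    n_chromosomes: int = 4
    snps_per_chrom: int = 250
    block_size_snps: int = 5
    n_founder_haplotypes: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: founder MAF range for causal SNPs; the default keeps causal
    #: variants common, matching the premise that weak-effect causal SNPs
    #: are common variants rather than rare ones
    causal_maf_range: tuple[float, float] = (0.2, 0.4)
    spacing_bp: int = 20_000
    n_main_causal: int = 4
    main_effect_or: float = 1.8
    #: optional per-SNP odds ratios for the main-effect SNPs; overrides
    #: main_effect_or when set (length must equal n_main_causal)
    main_effect_ors: tuple[float, ...] | None = None
    n_epistatic_pairs: int = 1
    epistasis_or: float = 2.5
    prevalence_intercept: float = -1.0
    missing_rate: float = 0.002
    bad_sample_fraction: float = 0.005
    bad_snp_fraction: float = 0.005
    bad_sample_missing_rate: float = 0.10
    bad_snp_missing_rate: float = 0.05
    max_attempt_factor: int = 200
    # annotation / gene-set layer
    snps_per_gene: int = 4
    gene_gap_bp: int = 0
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (5, 30)
    n_enriched_sets: int = 2
    #: random filler genes added to each planted module on top of the
    #: causal genes; kept small so causal genes dominate the module
    planted_fillers: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases, self.n_controls, self.n_chromosomes,
            self.snps_per_chrom, self.block_size_snps,
            self.n_founder_haplotypes, self.spacing_bp,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_main_causal + 2 * self.n_epistatic_pairs > self.n_snps:
            raise ValueError("more causal SNPs than SNPs in the panel")
        if (self.main_effect_ors is not None
                and len(self.main_effect_ors) != self.n_main_causal):
            raise ValueError("main_effect_ors length must be n_main_causal")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chrom


@dataclass
class TruthRecord:
    """Ground truth emitted by the simulator.

    ``main_effects`` maps SNP id to its per-allele log-odds beta;
    ``epistatic_pairs`` holds (snp_i, snp_j, gamma) for the centered
    dosage-product interaction terms; ``enriched_module_ids`` names the
    gene sets built to contain all causal genes. ``founder_freq`` records
    the realized founder-pool allele frequency per SNP (the frequency the
    sample MAF estimates).
    """

    causal_snp_ids: list[str] = field(default_factory=list)
    main_effects: dict[str, float] = field(default_factory=dict)
    epistatic_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    enriched_module_ids: list[str] = field(default_factory=list)
    founder_freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.causal_snp_ids)
        for s in self.main_effects:
            if s not in ids:
                raise ValueError(f"main effect on non-causal SNP {s}")
        for a, b, _ in self.epistatic_pairs:
            if a not in ids or b not in ids:
                raise ValueError(f"epistatic pair ({a},{b}) not in causal ids")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["epistatic_pairs"] = [list(t) for t in d["epistatic_pairs"]]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["epistatic_pairs"] = [tuple(t) for t in d["epistatic_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------


def _build_founders(config: SimConfig, rng: np.random.Generator,
                    causal_cols: np.ndarray | None = None):
    """Founder haplotype pool per block and the pool allele frequencies."""
    m = config.n_snps
    k = config.n_founder_haplotypes
    lo, hi = config.maf_range
    target = rng.uniform(lo, hi, size=m)
    if causal_cols is not None and len(causal_cols):
        clo, chi = config.causal_maf_range
        target[causal_cols] = rng.uniform(clo, chi, size=len(causal_cols))
    founders = (rng.random((k, m)) < target).astype(np.int8)
    pool_freq = founders.mean(axis=0)
    return founders, pool_freq


def _draw_genotypes(config, founders, rng, n):
    """Dosages for n individuals: two founder draws per block each."""
    m = config.n_snps
    k = founders.shape[0]
    block_id = _block_ids(config)
    n_blocks = block_id[-1] + 1
    h1 = rng.integers(0, k, size=(n, n_blocks))
    h2 = rng.integers(0, k, size=(n, n_blocks))
    # expand block-level founder choice to SNP level
    g = founders[h1[:, block_id], np.arange(m)] + founders[
        h2[:, block_id], np.arange(m)
    ]
    return g.astype(np.int8)


def _block_ids(config: SimConfig) -> np.ndarray:
    """Block index per SNP; blocks never span a chromosome boundary."""
    per_chrom = np.arange(config.snps_per_chrom) // config.block_size_snps
    blocks_per_chrom = per_chrom[-1] + 1
    return np.concatenate(
        [per_chrom + c * blocks_per_chrom for c in range(config.n_chromosomes)]
    )


def _choose_causal(config: SimConfig, rng: np.random.Generator):
    """Causal SNP column indices, spread over distinct LD blocks.

    Keeping causal SNPs in distinct blocks ensures LD pruning cannot
    collapse two planted signals into one marker.
    """
    block_id = _block_ids(config)
    n_needed = config.n_main_causal + 2 * config.n_epistatic_pairs
    blocks = np.unique(block_id)
    if n_needed > len(blocks):
        raise ValueError("not enough LD blocks to host all causal SNPs")
    chosen_blocks = rng.choice(blocks, size=n_needed, replace=False)
    cols = []
    for b in chosen_blocks:
        members = np.flatnonzero(block_id == b)
        cols.append(int(rng.choice(members)))
    return np.array(sorted(cols))


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, np.ndarray, TruthRecord]:
    """Simulate a case-control panel under the logistic penetrance model.

    Returns the genotype matrix (cases first, then controls; phenotype
    coded 2 = case, 1 = control), the 0/1 phenotype vector, and the
    :class:`TruthRecord`. Identical configs (including seed) give
    bit-identical output.

    Raises
    ------
    AscertainmentError
        If ``max_attempt_factor * (n_cases + n_controls)`` simulated
        individuals do not yield the requested case and control counts.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    causal_cols = _choose_causal(config, rng)
    founders, pool_freq = _build_founders(config, rng, causal_cols)
    main_cols = causal_cols[: config.n_main_causal]
    epi_cols = causal_cols[config.n_main_causal:]
    if config.main_effect_ors is not None:
        betas = np.log(np.asarray(config.main_effect_ors, dtype=float))
    else:
        betas = np.full(config.n_main_causal, np.log(config.main_effect_or))
    gamma = float(np.log(config.epistasis_or))

    n_target = config.n_cases + config.n_controls
    budget = config.max_attempt_factor * n_target
    batch = max(1024, n_target)

    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    n_case_kept = n_control_kept = 0
    attempts = 0
    while n_case_kept < config.n_cases or n_control_kept < config.n_controls:
        if attempts >= budget:
            raise AscertainmentError(
                f"drew {attempts} individuals (budget "
                f"{config.max_attempt_factor} x cohort size) without "
                f"reaching {config.n_cases} cases / {config.n_controls} "
                "controls; adjust prevalence_intercept or the budget"
            )
        g = _draw_genotypes(config, founders, rng, batch)
        attempts += batch
        logit = np.full(batch, config.prevalence_intercept)
        if len(main_cols):
            logit += g[:, main_cols].astype(float) @ betas
        for k in range(config.n_epistatic_pairs):
            i, j = epi_cols[2 * k], epi_cols[2 * k + 1]
            ci = g[:, i] - 2 * pool_freq[i]
            cj = g[:, j] - 2 * pool_freq[j]
            logit += gamma * ci * cj
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        need_cases = config.n_cases - n_case_kept
        if need_cases > 0:
            take = g[is_case][:need_cases]
            case_rows.append(take)
            n_case_kept += len(take)
        need_controls = config.n_controls - n_control_kept
        if need_controls > 0:
            take = g[~is_case][:need_controls]
            control_rows.append(take)
            n_control_kept += len(take)

    dosages = np.vstack(case_rows + control_rows)
    phenotype01 = np.r_[
        np.ones(config.n_cases, dtype=np.int8),
        np.zeros(config.n_controls, dtype=np.int8),
    ]

    # Recode each SNP to its sample minor allele so the PED round trip
    # (which determines the counted allele from the data) is the identity.
    # Counted allele is written as 'A', the other as 'G'; an exact 50/50
    # tie keeps 'A' as counted, matching the reader's lexicographic rule.
    flip = dosages.mean(axis=0) > 1.0
    dosages[:, flip] = 2 - dosages[:, flip]
    pool_freq = np.where(flip, 1.0 - pool_freq, pool_freq)

    chrom = np.repeat(
        [f"{c + 1}" for c in range(config.n_chromosomes)],
        config.snps_per_chrom,
    )
    pos = np.tile(
        (np.arange(config.snps_per_chrom) + 1) * config.spacing_bp,
        config.n_chromosomes,
    )
    width = len(str(m))
    snp_ids = np.array([f"rs{i + 1:0{width}d}" for i in range(m)])
    snp_map = pd.DataFrame(
        {"snp": snp_ids, "chrom": chrom, "pos": pos, "a1": "G", "a2": "A"}
    )
    samples = pd.DataFrame(
        {
            "sample": [f"S{i + 1:05d}" for i in range(n_target)],
            "phenotype": np.where(phenotype01 == 1, 2, 1),
        }
    )
    gmat = GenotypeMatrix(dosages, snp_map, samples)

    truth = TruthRecord(
        causal_snp_ids=[str(snp_ids[c]) for c in causal_cols],
        main_effects={
            str(snp_ids[c]): float(b) for c, b in zip(main_cols, betas)
        },
        epistatic_pairs=[
            (str(snp_ids[epi_cols[2 * k]]), str(snp_ids[epi_cols[2 * k + 1]]), gamma)
            for k in range(config.n_epistatic_pairs)
        ],
        founder_freq={str(snp_ids[i]): float(pool_freq[i])
                      for i in range(m)},
    )
    return gmat, phenotype01, truth


def inject_missingness(
    genotypes: GenotypeMatrix, config: SimConfig
) -> GenotypeMatrix:
    """Set entries to the missing sentinel.

    Background entries go missing at ``missing_rate``; a designated
    ``bad_sample_fraction`` of samples and ``bad_snp_fraction`` of SNPs
    receive elevated rates (defaults 10% and 5%) chosen to exceed the QC
    thresholds of 3% and 1%. Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed + 1_000_000_007)
    n, m = genotypes.dosages.shape
    rate = np.full((n, m), config.missing_rate)
    n_bad_samples = int(round(config.bad_sample_fraction * n))
    n_bad_snps = int(round(config.bad_snp_fraction * m))
    bad_samples = rng.choice(n, size=n_bad_samples, replace=False)
    bad_snps = rng.choice(m, size=n_bad_snps, replace=False)
    rate[bad_samples, :] = config.bad_sample_missing_rate
    rate[:, bad_snps] = np.maximum(rate[:, bad_snps],
                                   config.bad_snp_missing_rate)
    mask = rng.random((n, m)) < rate
    dosages = genotypes.dosages.copy()
    dosages[mask] = MISSING
    return GenotypeMatrix(
        dosages, genotypes.snp_map.copy(), genotypes.samples.copy()
    )


def generate_annotation(
    snp_map: pd.DataFrame, config: SimConfig, truth: TruthRecord
) -> tuple[GeneAnnotation, GeneSetCollection]:
    """Build a gene annotation tiling the panel plus gene-set collections.

    Genes are non-overlapping intervals of ``snps_per_gene`` consecutive
    SNPs per chromosome (separated by ``gene_gap_bp``), so with zero gap
    every SNP falls inside exactly one gene. ``n_enriched_sets`` planted
    modules contain every causal gene plus ``planted_fillers`` random
    fillers, so causal genes are concentrated in them; the remaining sets
    are uniform random gene draws. Categories cycle through the five
    functional-module kinds.
    """
    rng = np.random.default_rng(config.seed + 2_000_000_011)
    records = []
    snp_gene: dict[str, str] = {}
    gi = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        snps = grp["snp"].to_numpy()
        pos = grp["pos"].to_numpy()
        half_gap = config.gene_gap_bp // 2
        for start_idx in range(0, len(snps), config.snps_per_gene):
            last_idx = min(start_idx + config.snps_per_gene, len(snps)) - 1
            gi += 1
            gene = f"GENE{gi:04d}"
            # gene boundaries sit midway between adjacent SNP chunks
            if start_idx == 0:
                left0 = max(0, int(pos[0]) - 1 - config.spacing_bp // 2)
            else:
                left0 = (int(pos[start_idx - 1]) + int(pos[start_idx])) // 2
            if last_idx + 1 < len(snps):
                right0 = (int(pos[last_idx]) + int(pos[last_idx + 1])) // 2
            else:
                right0 = int(pos[last_idx]) - 1 + config.spacing_bp // 2 + 1
            records.append((chrom, left0 + half_gap, right0 - half_gap, gene))
            for s in snps[start_idx:last_idx + 1]:
                snp_gene[s] = gene
    annotation = GeneAnnotation(
        pd.DataFrame(records, columns=["chrom", "start", "end", "gene"])
    )

    causal_genes = sorted({snp_gene[s] for s in truth.causal_snp_ids})
    all_genes = annotation.records["gene"].to_numpy()
    if len(all_genes) < len(causal_genes):
        raise ValueError("fewer genes than causal SNPs")

    coll = GeneSetCollection()
    lo, hi = config.set_size_range
    lo = min(lo, len(all_genes))
    hi = min(hi, len(all_genes))
    non_causal = np.setdiff1d(all_genes, causal_genes)
    enriched_ids = []
    for k in range(config.n_enriched_sets):
        n_fill = min(config.planted_fillers, len(non_causal))
        fillers = rng.choice(non_causal, size=n_fill, replace=False)
        name = f"PLANTED_MODULE_{k + 1}"
        coll.add(name, CATEGORIES[k % len(CATEGORIES)],
                 list(causal_genes) + list(fillers))
        enriched_ids.append(name)
    for k in range(config.n_gene_sets - config.n_enriched_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(all_genes, size=size, replace=False)
        coll.add(
            f"RANDOM_SET_{k + 1:04d}",
            CATEGORIES[(k + config.n_enriched_sets) % len(CATEGORIES)],
            list(members),
        )
    truth.enriched_module_ids = enriched_ids
    return annotation, coll
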