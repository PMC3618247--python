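# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the known limitations of `snpcombo`.

## Statistical tests

**Cochran-Armitage trend test.** For a SNP with case genotype counts
(r₀, r₁, r₂) and control counts (s₀, s₁, s₂), additive weights w = (0, 1, 2),
r = Σrᵢ, s = Σsᵢ, n = r + s:

    T = Σᵢ wᵢ (s·rᵢ − r·sᵢ)
    Var(T) = (r·s/n) · [ n·Σᵢ wᵢ² nᵢ − (Σᵢ wᵢ nᵢ)² ]
    χ² = T² / Var(T),  1 df

p-values are asymptotic (upper chi-square tail), no continuity correction —
the behavior of PLINK's trend test. Degenerate tables (monomorphic SNP,
zero variance) return (0, 1). The statistic is algebraically N·ρ², with ρ
the Pearson correlation between dosage and case status; the test suite
uses that identity as an independent oracle. Missing genotypes are
excluded per SNP; ranks break p ties by genomic position so downstream
subsets are deterministic.

**Hardy-Weinberg exact test.** The exact conditional test: given n
individuals and the minor-allele count nₐ, the heterozygote count h has

    P(h) ∝ n! / (n_AA! n_Aa! n_aa!) · 2^h

normalized over the support {nₐ mod 2, …, nₐ}; the p-value sums P(h) over
all tables no more probable than the observed one. Computed in log-space
(gammaln), so it is exact at any n. By default HWE is evaluated in
controls only (case enrichment can distort HWE at true loci); a flag
switches to all samples. A table at exactly the observed probability is
included with a 1e-12 relative tolerance so float noise cannot drop it.

**QC order.** Samples with missingness > 3% are removed first; on the
remaining samples, markers are filtered by missingness > 1%, then MAF < 1%
(recomputed after sample removal), then HWE p ≤ 10⁻⁴. Each removed marker
records the first filter it failed. QC is idempotent in practice; the
only way a second pass can remove anything is a sample sitting exactly at
the missingness boundary whose fraction shifts when high-missingness
markers leave the denominator.

**Fisher enrichment and FDR.** Over-representation p = P(X ≥ a) for a
hypergeometric draw (universe N, module K∩universe, selected n). The gene
universe is every gene reachable from the analyzed panel by the mapping
rule — numerator and denominator condition on the same measurable space.
FDR is Benjamini-Hochberg within each module category, mirroring
per-category reporting. For the genome-wide analysis each gene is scored
by the minimum SNP p over its mapped SNPs and "selected" means score
below 0.05. The min-p score is not size-adjusted: genes with more SNPs
are more likely selected under the null. This construction is a
documented stand-in — threshold GSEA is under-specified in general — and
both the cutoff and the score are configurable.

## LD pruning

Pruning is greedy in ascending-p order: retain the best remaining SNP,
prune every still-unpruned SNP on the same chromosome within 1 Mb
(inclusive, 1-based positions) whose dosage r² with it exceeds 0.8. r² is
the squared Pearson correlation of dosage vectors over pairwise-complete
samples (composite LD; no phasing). A monomorphic vector over the shared
support defines r² = 0. The contract is enforced by a brute-force
checker (`snpcombo.ld.check_pruning`): no retained pair in range exceeds
the threshold, and every pruned SNP is no more significant than its
keeper. Pruning is idempotent and invariant to input order because the
association ranks impose a strict total order.

## Random forests and backward elimination

Trees are scikit-learn `DecisionTreeClassifier`s (Gini splitting, grown to
purity, `mtry = round(mtry_factor·√p)` candidate features per split,
floor 1). Everything OOB is computed by this package from explicit
per-tree bootstrap bags:

- *OOB error* — majority vote over the trees for which a sample was
  out-of-bag, among samples with ≥ 1 OOB vote; its standard error is the
  binomial √(e(1−e)/n).
- *Permutation importance* — per tree, the decrease in OOB accuracy when
  a variable's OOB values are permuted, averaged over all trees
  (unscaled). Only variables actually used in a tree's splits are
  permuted — unused variables cannot change predictions, so their
  contribution is exactly 0.
- Gini importance is available as a configured alternative.

Backward elimination ranks variables once on the initial forest (`ntree`
trees), then repeatedly keeps `floor(current·(1−vars_drop_frac))` of the
top-ranked variables (dropping at least one) and refits with
`ntree_iterat` trees, down to 2 variables. Importances are not recomputed
during elimination by default (limits selection bias; a flag recomputes).
The selected set is the smallest one whose OOB error is within
`se_rule_c` standard errors of the history minimum; `se_rule_c = 1` is
the package default, while subset comparison (`evaluate_subsets`,
`optimal_subset`) ranks datasets by the recorded error itself. Missing
dosages are mode-imputed per SNP before any forest. Defaults follow the
conventional backward-elimination parameterization: mtry_factor 1,
ntree 5,000, ntree_iterat 2,000, vars_drop_frac 0.2. Tests and the
acceptance script scale tree counts down (typically 200–1,000) to keep
desk runtimes in minutes; the elimination behavior is unchanged, only
the Monte-Carlo noise of error and importance estimates grows.

Per-subset and per-random-set seeds are derived from the master seed by
CRC-32 hashing of the label, so grids are reproducible and independent of
evaluation order.

## The synthetic panel

The generator produces what the pipeline needs and nothing more:

- **LD**: per block of `block_size_snps` consecutive SNPs, each
  individual draws two founder haplotypes uniformly from a pool of
  `n_founder_haplotypes` (default 8) whose alleles are Bernoulli draws at
  per-SNP frequencies from `maf_range`. Within-block r² is high (alleles
  co-occur on founders), between-block r² ≈ 0, and null genotypes are
  Hardy-Weinberg by construction (two iid allele draws). Blocks are
  recombination-free; there is no population structure, no imputation
  uncertainty, no recombination map — passing tests say nothing about
  those features of real data.
- **Phenotype**: logit P(case) = intercept + Σβ·g + Σγ·(gᵢ−2pᵢ)(gⱼ−2pⱼ),
  i.e. weak additive main effects plus centered-product epistasis — the
  simplest interaction invisible to single-SNP trend tests. Case-control
  ascertainment is exact rejection sampling with a configurable attempt
  budget (default 200× the cohort size) whose exhaustion raises a named
  error rather than looping forever.
- **Causal MAFs** are drawn from `causal_maf_range` (default 0.2–0.4):
  the scientific premise being emulated is *common* variants with weak
  effects, and a weak odds ratio at a rare frequency carries no signal at
  desk-scale n.
- **Missingness** is background Bernoulli (default 0.2%) plus designated
  bad samples (10%) and bad SNPs (5%), placed to exceed the QC
  thresholds.
- **Annotation**: genes tile each chromosome with boundaries midway
  between SNP chunks (`snps_per_gene` each, optional gap), so every SNP
  has exactly one host gene at zero gap. Planted modules contain every
  causal gene plus `planted_fillers` (default 5) random genes — causal
  genes are concentrated, as the detectability experiments require; all
  other sets are uniform random draws, with category labels cycling over
  pathway / TF-target / miRNA-target / GO / complex.
- After simulation each SNP is recoded to its sample minor allele
  (counted allele written as `A`, the other as `G`), which makes the
  PED/MAP round trip an identity under the reader's
  minor-allele-from-data rule.

Effect sizes are configuration, not constants: the underlying joint
effect-size distribution of weak causal variants is unknown, so β and γ
are exposed per SNP (`main_effect_ors`, `epistasis_or`).

## Problem sizes used by tests and the acceptance script

Test panels range from 10×5 toy matrices to 1,000 samples × 200–1,000
SNPs. The acceptance script runs the full pipeline at 1,000 samples ×
1,000 SNPs with ntree 400/200, five p-range cutoffs, four rank cutoffs
and five random control sets — the package's chosen desk-scale study
conditions. Statistical acceptance checks use 10 seeds (20 for null
calibrations).

## Known limitations

- Pure centered-product epistasis is close to invisible to forest
  permutation importance at desk scale: with no marginal effect, trees
  rarely split on either member of a pair, so their importance sits at
  noise level. This is a known weakness of importance-ranked backward
  elimination, shared by the reference R implementation (`randomForest`)
  against which the forest layer was cross-checked: both rank strong
  mains 1–3 and epistatic-pair members in the noise. Consequently,
  recovery experiments that count an epistatic pair among their planted
  SNPs recover the mains and the pair only occasionally.
- OOB error has binomial noise (SE ≈ 0.015 at n = 1,000). Differences
  between candidate sets smaller than that are not resolvable at desk
  scale, so the minimum-error entry of a flat elimination history is
  effectively a random draw among near-optimal sizes; selected-set sizes
  vary accordingly between seeds.
- The exact enrichment test is conservative on discrete counts: under a
  null panel the fraction of sets at p < 0.05 sits at or somewhat below
  0.05, and the calibration test asserts exactly that behavior.
- The trend test is unadjusted (no covariates, no genomic control); the
  LD r² is composite (dosage) LD, not haplotype EM r².
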