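"""SNP-to-gene mapping and gene-set over-representation analysis.

SNPs are assigned to every gene whose interval, expanded by a flank,
contains their position; SNPs hitting no gene fall back to the single
nearest gene within a maximum distance (ties keep both). Enrichment is
the threshold form of GSEA: a one-sided Fisher exact test (hypergeometric
upper tail) of the selected genes against each functional module,
followed by Benjamini-Hochberg FDR within each module category (pathway,
TF-target, miRNA-target, GO, complex). The gene universe is everything
reachable from the analyzed panel by the mapping rule, so numerator and
denominator condition on the same measurable gene space.

For the genome-wide analysis each gene is scored by the minimum
association p over its mapped SNPs and "selected" means score below a
cutoff; this min-p construction is a documented operationalization, not
a claim about how any particular study computed its gene scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, GeneSetCollection

__all__ = [
    "map_snps_to_genes",
    "fisher_enrichment",
    "bh_fdr",
    "genomewide_gsea",
    "EnrichmentError",
]


class EnrichmentError(ValueError):
    """Invalid enrichment input (e.g. selected genes outside the universe)."""


def map_snps_to_genes(
    snps: pd.DataFrame,
    annotation: GeneAnnotation,
    flank_bp: int = 20_000,
    max_nearest_bp: int = 500_000,
) -> pd.DataFrame:
    """Map SNPs to nearby genes.

    Parameters
    ----------
    snps
        DataFrame with columns ``snp``, ``chrom``, ``pos`` (1-based).
    annotation
        Gene intervals (0-based, half-open).
    flank_bp
        Genes are expanded by this many bp on both sides for the overlap
        test: a SNP overlaps iff ``start - flank <= pos - 1 < end + flank``.
    max_nearest_bp
        A SNP overlapping nothing maps to the nearest gene within this
        distance (equidistant genes are both kept); farther SNPs stay
        unmapped.

    Returns
    -------
    DataFrame with columns ``snp, gene, relation, distance`` where
    ``relation`` is ``overlap`` (distance 0) or ``nearest`` (distance in
    bp to the unexpanded gene interval).
    """
    if len(annotation) == 0:
        raise EnrichmentError("empty gene annotation")
    rows: list[tuple[str, str, str, int]] = []
    ann_by_chrom = {
        str(c): grp.reset_index(drop=True)
        for c, grp in annotation.records.groupby("chrom", sort=False)
    }
    for rec in snps.itertuples(index=False):
        genes = ann_by_chrom.get(str(rec.chrom))
        if genes is None:
            continue
        p0 = int(rec.pos) - 1
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        hit = (start - flank_bp <= p0) & (p0 < end + flank_bp)
        if hit.any():
            for gname in genes["gene"].to_numpy()[hit]:
                rows.append((rec.snp, gname, "overlap", 0))
            continue
        # distance to the unexpanded interval
        dist = np.where(p0 < start, start - p0, np.where(p0 >= end,
                                                         p0 - end + 1, 0))
        dmin = int(dist.min())
        if dmin <= max_nearest_bp:
            for gname in genes["gene"].to_numpy()[dist == dmin]:
                rows.append((rec.snp, gname, "nearest", dmin))
    return pd.DataFrame(rows, columns=["snp", "gene", "relation", "distance"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_i = min over j with p_j >= p_i of m * p_j / rank_j``, capped at
    1; stable under input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enrichment(
    selected_genes,
    universe,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided Fisher over-representation test per gene set.

    ``p = P(X >= a)`` for a hypergeometric draw of ``|selected|`` genes
    from a universe containing ``|set ∩ universe|`` successes. FDR is
    Benjamini-Hochberg within each category. Gene sets are intersected
    with the universe first; an empty intersection reports p = 1.

    Returns a DataFrame sorted by (category, p) with columns
    ``set, category, a, set_size, selected_size, universe_size, p, fdr``.
    """
    universe = frozenset(universe)
    selected = frozenset(selected_genes)
    if not selected <= universe:
        raise EnrichmentError("selected genes must be a subset of the universe")
    N = len(universe)
    n_sel = len(selected)
    rows = []
    for name, (category, members) in sets:
        in_universe = members & universe
        K = len(in_universe)
        a = len(in_universe & selected)
        if K == 0 or n_sel == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(a - 1, N, K, n_sel))
            p = min(1.0, max(p, np.nextafter(0, 1)))
        rows.append((name, category, a, K, n_sel, N, p))
    tab = pd.DataFrame(
        rows,
        columns=["set", "category", "a", "set_size", "selected_size",
                 "universe_size", "p"],
    )
    tab["fdr"] = np.nan
    for cat, grp in tab.groupby("category", sort=False):
        tab.loc[grp.index, "fdr"] = bh_fdr(grp["p"].to_numpy())
    return tab.sort_values(["category", "p", "set"],
                           kind="mergesort").reset_index(drop=True)


def gene_scores(assoc: pd.DataFrame, snp_gene_map: pd.DataFrame) -> pd.Series:
    """Per-gene score: minimum SNP p over the gene's mapped SNPs."""
    merged = snp_gene_map.merge(assoc[["snp", "p"]], on="snp", how="inner")
    return merged.groupby("gene")["p"].min()


def genomewide_gsea(
    assoc: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    sets: GeneSetCollection,
    gene_p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Threshold GSEA over the whole (pruned) panel.

    Genes are scored by min SNP p; genes with score below
    ``gene_p_cutoff`` form the selected list, tested against every set
    with :func:`fisher_enrichment` over the universe of all mapped genes.
    """
    scores = gene_scores(assoc, snp_gene_map)
    universe = set(scores.index)
    selected = set(scores.index[scores < gene_p_cutoff])
    return fisher_enrichment(selected, universe, sets)
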