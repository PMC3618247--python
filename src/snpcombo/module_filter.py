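"""Functional-module-based filtration and its random-set control.

Each functional module surviving an FDR cutoff in the genome-wide
enrichment defines a SNP set: every panel SNP mapping to any of the
module's genes. These sets are scored by random-forest OOB error with
and without backward-elimination selection and compared against
size-matched random SNP sets drawn from the same panel, against unions
of the top-k modules, and against p-value-based reference sets (top-1,
top-10, the Bonferroni set, the full panel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import derive_seed
from .enrichment import EnrichmentError
from .forest import RFParams, backward_elimination, fit_forest, impute_mode
from .io import GenotypeMatrix
from .subsets import SNPSubset

__all__ = [
    "module_snp_sets",
    "compare_module_vs_random",
    "combine_top_modules",
    "reference_sets",
]


def module_snp_sets(
    enrich: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    fdr_max: float = 0.05,
) -> list[SNPSubset]:
    """SNP sets of the modules with FDR below the cutoff.

    The SNP set of a module is every panel SNP mapping to any module
    gene (deduplicated); modules whose genes host no panel SNP are
    dropped. Sets may overlap when modules share genes.
    """
    gene_snps = snp_gene_map.groupby("gene")["snp"].agg(set)
    out: list[SNPSubset] = []
    hits = enrich.loc[enrich["fdr"] < fdr_max].sort_values(
        ["fdr", "p", "set"], kind="mergesort"
    )
    for row in hits.itertuples(index=False):
        members = _module_snps(row.set, enrich, gene_snps, snp_gene_map)
        if not members:
            continue
        out.append(
            SNPSubset(
                label=f"module_{row.set}",
                criterion="module",
                parameter=float(row.fdr),
                snps=sorted(members),
            )
        )
    return out


def _module_snps(set_name, enrich, gene_snps, snp_gene_map) -> set[str]:
    # module membership is recovered through the SNP->gene map: the genes
    # that both belong to the module and host panel SNPs
    genes = enrich.attrs.get("collections", {}).get(set_name)
    if genes is None:
        raise KeyError(
            "enrichment table lacks set memberships; build it with "
            "genomewide_gsea and attach the collection (see attach_sets)"
        )
    members: set[str] = set()
    for gname in genes:
        if gname in gene_snps.index:
            members |= gene_snps.loc[gname]
    return members


def attach_sets(enrich: pd.DataFrame, sets) -> pd.DataFrame:
    """Attach set memberships to an enrichment table so module SNP sets
    can be reconstructed without re-reading the GMT file."""
    enrich.attrs["collections"] = {
        name: set(members) for name, (_c, members) in sets
    }
    return enrich


def combine_top_modules(
    enrich: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    k: int,
) -> SNPSubset:
    """Union of the SNP sets of the k smallest-FDR modules.

    Ties are broken by p then set name; k larger than the number of
    modules with mapped SNPs is capped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gene_snps = snp_gene_map.groupby("gene")["snp"].agg(set)
    ranked = enrich.sort_values(["fdr", "p", "set"], kind="mergesort")
    union: set[str] = set()
    taken = 0
    for row in ranked.itertuples(index=False):
        members = _module_snps(row.set, enrich, gene_snps, snp_gene_map)
        if not members:
            continue
        union |= members
        taken += 1
        if taken >= k:
            break
    return SNPSubset(
        label=f"top_{k}_modules",
        criterion="combination",
        parameter=float(k),
        snps=sorted(union),
        capped=taken < k,
    )


def reference_sets(assoc: pd.DataFrame, alpha: float = 0.05
                   ) -> list[SNPSubset]:
    """p-value-based reference sets: top-1, top-10, the Bonferroni set,
    and the full panel."""
    order = assoc.sort_values("rank")
    ids = order["snp"].to_numpy()
    p = order["p"].to_numpy()
    r = int((p < alpha / len(ids)).sum())
    refs = [
        SNPSubset("ref_top1", "pvalue_reference", 1.0, list(ids[:1])),
        SNPSubset("ref_top10", "pvalue_reference", 10.0,
                  list(ids[: min(10, len(ids))])),
        SNPSubset("ref_bonferroni", "pvalue_reference", float(r),
                  list(ids[:r])),
        SNPSubset("ref_all", "pvalue_reference", float(len(ids)), list(ids)),
    ]
    return [s for s in refs if not s.empty]


def _score_set(sub: SNPSubset, g: GenotypeMatrix, y, params: RFParams,
               seed: int) -> tuple[float, int, float]:
    X = impute_mode(g.subset_snps(sub.snps).dosages)
    full = fit_forest(X, y, params, seed=seed, compute_importance=False)
    sel = backward_elimination(X, y, params, var_names=sub.snps,
                               seed=seed + 1)
    return full.oob_error, sel.n_selected, sel.selected_error


def compare_module_vs_random(
    sets: list[SNPSubset],
    g: GenotypeMatrix,
    y: np.ndarray,
    params: RFParams | None = None,
    n_random: int = 0,
    seed: int = 0,
    references: list[SNPSubset] | None = None,
) -> pd.DataFrame:
    """Score module SNP sets against size-matched random sets.

    Random sets are drawn without replacement from the panel with size
    equal to the rounded mean module-set size, each with a seed derived
    from ``(seed, index)``; reference sets (when given) are scored with
    the same RF parameters. Average rows over modules and over random
    sets are appended. Returns a comparison frame with columns
    ``label, kind, n_snps, error_full, n_selected, error_selected``.
    """
    if not sets:
        raise ValueError("no module SNP sets to compare")
    params = params or RFParams()
    panel_ids = np.asarray(g.snp_map["snp"])
    rows = []

    for sub in sets:
        if sub.size > len(panel_ids):
            raise EnrichmentError(f"module set {sub.label} larger than panel")
        e_full, n_sel, e_sel = _score_set(
            sub, g, y, params, derive_seed(seed, "module", sub.label)
        )
        rows.append((sub.label, "module", sub.size, e_full, n_sel, e_sel))

    mean_size = int(round(float(np.mean([s.size for s in sets]))))
    mean_size = max(1, min(mean_size, len(panel_ids)))
    for k in range(n_random):
        rng = np.random.default_rng(derive_seed(seed, "random", k))
        snps = list(rng.choice(panel_ids, size=mean_size, replace=False))
        sub = SNPSubset(f"random_{k + 1}", "random", float(mean_size), snps)
        e_full, n_sel, e_sel = _score_set(
            sub, g, y, params, derive_seed(seed, "random_score", k)
        )
        rows.append((sub.label, "random", sub.size, e_full, n_sel, e_sel))

    for sub in references or []:
        e_full, n_sel, e_sel = _score_set(
            sub, g, y, params, derive_seed(seed, "reference", sub.label)
        )
        rows.append((sub.label, sub.criterion, sub.size, e_full, n_sel,
                     e_sel))

    tab = pd.DataFrame(
        rows,
        columns=["label", "kind", "n_snps", "error_full", "n_selected",
                 "error_selected"],
    )
    summaries = []
    for kind in ("module", "random"):
        grp = tab.loc[tab["kind"] == kind]
        if len(grp):
            summaries.append(
                (f"average_{kind}", f"{kind}_average",
                 float(grp["n_snps"].mean()), grp["error_full"].mean(),
                 float(grp["n_selected"].mean()),
                 grp["error_selected"].mean())
            )
    if summaries:
        tab = pd.concat(
            [tab, pd.DataFrame(summaries, columns=tab.columns)],
            ignore_index=True,
        )
    return tab
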