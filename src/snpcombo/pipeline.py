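"""End-to-end pipeline: simulate/load -> QC -> association -> LD pruning ->
threshold subsets -> RF selection -> enrichment -> module filtration.

Every stage writes its artifact as a TSV (floats at 6 decimals) into the
output directory, and a JSON manifest records parameters, derived seeds
and per-stage row counts. Re-running the same config reproduces every
output byte-for-byte; a stage failure leaves a ``FAILED`` marker naming
the stage and the underlying error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import derive_seed
from . import __version__
from .enrichment import fisher_enrichment, genomewide_gsea, map_snps_to_genes
from .forest import RFParams, evaluate_subsets, optimal_subset
from .io import (GenotypeMatrix, read_gene_bed, read_gmt, read_ped_map,
                 write_gene_bed, write_gmt, write_ped_map)
from .ld import PruneParams, ld_prune
from .module_filter import (attach_sets, combine_top_modules,
                            compare_module_vs_random, module_snp_sets,
                            reference_sets)
from .qc import QCThresholds, apply_qc, run_association
from .simulate import SimConfig, generate_annotation, inject_missingness, \
    simulate_panel
from .subsets import bonferroni_sets, range_sets, rank_sets

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "qc", "assoc", "prune", "subsets", "select",
          "gsea", "modulefilter")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One document driving the whole run.

    Exactly one genotype source: either ``sim`` (synthetic panel) or the
    ``ped/map/bed/gmt`` file paths. Per-stage seeds are derived from
    ``seed`` by stable hashing of the stage name.
    """

    sim: SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    bed_path: str | None = None
    gmt_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    prune: PruneParams = field(default_factory=PruneParams)
    rf: RFParams = field(default_factory=RFParams)
    bonferroni_multipliers: tuple[int, ...] = (1, 2, 5, 10)
    rank_k_values: tuple[int, ...] = (1, 5, 10, 25)
    range_cutoffs: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                                        0.6, 0.7, 0.8, 0.9, 1.0)
    flank_bp: int = 0
    max_nearest_bp: int = 500_000
    gene_p_cutoff: float = 0.05
    module_fdr_max: float = 0.05
    n_random_sets: int = 10
    top_module_ks: tuple[int, ...] = (5,)
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.ped_path is not None
        if from_files == (self.sim is not None):
            raise ValueError(
                "exactly one genotype source: sim config xor PED/MAP paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = dict(doc)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim = dict(kwargs["sim"])
            for key in ("maf_range", "set_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        for key, typ in (("qc", QCThresholds), ("prune", PruneParams),
                         ("rf", RFParams)):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = typ(**kwargs[key])
        for key in ("bonferroni_multipliers", "rank_k_values",
                    "range_cutoffs", "top_module_ks"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "parameters": _jsonable(config),
    }
    stage = "simulate"
    try:
        truth = None
        if config.sim is not None:
            sim = dataclasses.replace(
                config.sim, seed=derive_seed(config.seed, "simulate")
            )
            g, _pheno, truth = simulate_panel(sim)
            g = inject_missingness(g, sim)
            annotation, gene_sets = generate_annotation(g.snp_map, sim, truth)
            write_ped_map(g, outdir / "panel.ped", outdir / "panel.map")
            write_gene_bed(annotation, outdir / "genes.bed")
            write_gmt(gene_sets, outdir / "gene_sets.gmt")
            truth.to_json(outdir / "truth.json")
        else:
            g = read_ped_map(config.ped_path, config.map_path)
            annotation = read_gene_bed(config.bed_path)
            gene_sets = read_gmt(config.gmt_path)
        manifest["stages"]["simulate"] = {
            "n_samples": g.n_samples, "n_snps": g.n_snps,
            "source": "simulation" if config.sim is not None else "files",
        }

        stage = "qc"
        qc_res = apply_qc(g, config.qc)
        _write(qc_res.report(), outdir / "qc_report.tsv")
        g2 = qc_res.genotypes
        manifest["stages"]["qc"] = {
            "n_samples": g2.n_samples, "n_snps": g2.n_snps,
            "n_removed": int(len(qc_res.removals)),
        }

        stage = "assoc"
        assoc = run_association(g2)
        _write(assoc, outdir / "association.tsv")
        manifest["stages"]["assoc"] = {"n_snps": int(len(assoc))}

        stage = "prune"
        pruned = ld_prune(assoc, g2, config.prune)
        g3 = g2.subset_snps(pruned.retained)
        assoc_p = assoc.loc[
            assoc["snp"].isin(set(pruned.retained))
        ].reset_index(drop=True)
        order = assoc_p.sort_values(["p", "chrom", "pos"],
                                    kind="mergesort").index.to_numpy()
        rank = np.empty(len(assoc_p), dtype=int)
        rank[order] = np.arange(1, len(assoc_p) + 1)
        assoc_p["rank"] = rank
        _write(assoc_p, outdir / "association_pruned.tsv")
        _write(pruned.cluster_table(), outdir / "prune_clusters.tsv")
        manifest["stages"]["prune"] = {
            "n_retained": pruned.n_retained,
            "n_pruned": int(len(pruned.pruned_ids())),
        }

        stage = "subsets"
        subs = (
            bonferroni_sets(assoc_p, multipliers=config.bonferroni_multipliers)
            + rank_sets(assoc_p, k_values=list(config.rank_k_values))
            + range_sets(assoc_p, cutoffs=config.range_cutoffs)
        )
        sub_manifest = pd.DataFrame(
            [(s.label, s.criterion, s.parameter, s.size, s.empty)
             for s in subs],
            columns=["label", "criterion", "parameter", "size", "empty"],
        )
        _write(sub_manifest, outdir / "subsets.tsv")
        manifest["stages"]["subsets"] = {"n_subsets": len(subs)}

        stage = "select"
        rf = dataclasses.replace(config.rf,
                                 seed=derive_seed(config.seed, "select"))
        y = g3.phenotype01()
        grid = evaluate_subsets(subs, g3, y, rf)
        _write(grid, outdir / "subset_grid.tsv")
        best = optimal_subset(grid)
        best_sub = next(s for s in subs if s.label == best["label"])
        from .forest import backward_elimination, impute_mode
        X = impute_mode(g3.subset_snps(best_sub.snps).dosages)
        sel = backward_elimination(
            X, y, rf, var_names=best_sub.snps,
            seed=derive_seed(rf.seed, best_sub.label) + 1,
        )
        combo = pd.DataFrame({"snp": sel.selected})
        _write(combo, outdir / "combination.tsv")
        _write(sel.history, outdir / "selection_history.tsv")
        manifest["stages"]["select"] = {
            "optimal_subset": str(best["label"]),
            "subset_size": int(best["n_snps"]),
            "n_selected": int(best["n_selected"]),
            "error_full": float(best["error_full"]),
            "error_selected": float(best["error_selected"]),
        }

        stage = "gsea"
        snp_gene = map_snps_to_genes(
            g3.snp_map, annotation, flank_bp=config.flank_bp,
            max_nearest_bp=config.max_nearest_bp,
        )
        universe = sorted(set(snp_gene["gene"]))
        combo_genes = sorted(
            set(snp_gene.loc[snp_gene["snp"].isin(set(sel.selected)),
                             "gene"])
        )
        combo_enrich = fisher_enrichment(combo_genes, universe, gene_sets)
        _write(combo_enrich, outdir / "enrichment_combination.tsv")
        gw_enrich = genomewide_gsea(
            assoc_p, snp_gene, gene_sets, gene_p_cutoff=config.gene_p_cutoff
        )
        attach_sets(gw_enrich, gene_sets)
        _write(gw_enrich, outdir / "enrichment_genomewide.tsv")
        manifest["stages"]["gsea"] = {
            "n_mapped_genes": len(universe),
            "n_combination_genes": len(combo_genes),
            "n_sets_fdr_lt_cutoff": int(
                (gw_enrich["fdr"] < config.module_fdr_max).sum()
            ),
        }

        stage = "modulefilter"
        mod_sets = module_snp_sets(gw_enrich, snp_gene,
                                   fdr_max=config.module_fdr_max)
        if mod_sets:
            combos = [
                combine_top_modules(gw_enrich, snp_gene, k)
                for k in config.top_module_ks
            ]
            refs = reference_sets(assoc_p) + [
                c for c in combos if not c.empty
            ]
            mf_rf = dataclasses.replace(
                config.rf, seed=derive_seed(config.seed, "modulefilter")
            )
            module_table = compare_module_vs_random(
                mod_sets, g3, y, mf_rf, n_random=config.n_random_sets,
                seed=mf_rf.seed, references=refs,
            )
            _write(module_table, outdir / "module_filter.tsv")
            manifest["stages"]["modulefilter"] = {
                "n_modules": len(mod_sets),
                "n_random": config.n_random_sets,
            }
        else:
            manifest["stages"]["modulefilter"] = {
                "n_modules": 0, "n_random": 0,
            }
        if truth is not None:
            recovered = set(sel.selected) & set(truth.causal_snp_ids)
            manifest["truth"] = {
                "n_causal": len(truth.causal_snp_ids),
                "n_recovered": len(recovered),
                "enriched_modules": truth.enriched_module_ids,
            }
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
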