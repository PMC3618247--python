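"""Significance-ordered LD pruning.

Among SNPs in linkage disequilibrium (dosage r-squared above a threshold
within a base-pair window) only the most significant is kept. The
algorithm is greedy in ascending-p order: a still-unpruned SNP is
retained and every still-unpruned SNP on the same chromosome within the
window whose r-squared with it exceeds the threshold is pruned. Because
the association ranks impose a strict total order, the result does not
depend on the input SNP ordering.

r-squared is the squared Pearson correlation of dosage vectors over the
samples non-missing in both (composite LD); phase is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import MISSING
from .io import GenotypeMatrix

__all__ = ["PruneParams", "PrunedPanel", "LDError", "genotype_r2", "ld_prune"]


class LDError(ValueError):
    """Invalid LD computation input (e.g. <2 shared non-missing samples)."""


@dataclass
class PruneParams:
    r2_threshold: float = 0.8
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class PrunedPanel:
    """Retained SNP ids plus, per keeper, the SNPs it pruned with their r²."""

    retained: list[str]
    clusters: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def pruned_ids(self) -> list[str]:
        return [s for members in self.clusters.values() for s, _ in members]

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            (keeper, snp, r2)
            for keeper, members in self.clusters.items()
            for snp, r2 in members
        ]
        return pd.DataFrame(rows, columns=["keeper", "pruned", "r2"])


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both vectors. A vector that is
    monomorphic over the shared support gives r² = 0 (the undefined-
    correlation convention used throughout the pruning stage).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LDError("dosage vectors differ in length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise LDError("fewer than 2 shared non-missing samples")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))


def _r2_one_vs_many(d: np.ndarray, j: int, cols: np.ndarray) -> np.ndarray:
    """r² of column j against each column in cols, pairwise-masked."""
    x = d[:, j].astype(float)
    out = np.empty(len(cols))
    Y = d[:, cols].astype(float)
    x_missing = x == MISSING
    y_missing = Y == MISSING
    any_missing = x_missing.any() or y_missing.any()
    if not any_missing:
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        vx = (xc**2).mean()
        vy = (Yc**2).mean(axis=0)
        cov = (xc[:, None] * Yc).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), 0.0)
        return r2
    for k in range(len(cols)):
        out[k] = genotype_r2(x, Y[:, k])
    return out


def ld_prune(
    assoc: pd.DataFrame, g: GenotypeMatrix, params: PruneParams | None = None
) -> PrunedPanel:
    """Greedy best-p-first LD pruning.

    ``assoc`` must be an association table covering exactly the SNPs of
    ``g`` (columns ``snp``, ``chrom``, ``pos``, ``p``, ``rank``).
    """
    params = params or PruneParams()
    if set(assoc["snp"]) != set(g.snp_map["snp"]):
        raise LDError("association table and genotypes cover different SNPs")

    snp_to_col = {s: i for i, s in enumerate(g.snp_map["snp"])}
    order = assoc.sort_values("rank")
    ids = order["snp"].to_numpy()
    chroms = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy().astype(np.int64)
    pvals = order["p"].to_numpy()
    m = len(ids)

    alive = np.ones(m, dtype=bool)
    retained: list[str] = []
    clusters: dict[str, list[tuple[str, float]]] = {}
    d = g.dosages

    for i in range(m):
        if not alive[i]:
            continue
        keeper = ids[i]
        retained.append(keeper)
        alive[i] = False
        cand = np.flatnonzero(
            alive
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= params.window_bp)
        )
        if len(cand) == 0:
            continue
        cols = np.array([snp_to_col[s] for s in ids[cand]])
        r2 = _r2_one_vs_many(d, snp_to_col[keeper], cols)
        hit = r2 > params.r2_threshold
        if hit.any():
            clusters[keeper] = [
                (ids[c], float(v)) for c, v in zip(cand[hit], r2[hit])
            ]
            alive[cand[hit]] = False
    _ = pvals  # ranks already encode ascending p; kept for readability
    return PrunedPanel(retained=retained, clusters=clusters)


def check_pruning(
    panel: PrunedPanel,
    assoc: pd.DataFrame,
    g: GenotypeMatrix,
    params: PruneParams | None = None,
) -> None:
    """Brute-force post-condition checker (the pruning contract).

    Verifies that (1) retained and pruned SNPs partition the input, (2) no
    retained pair on the same chromosome within the window has r² above
    the threshold, and (3) every pruned SNP's p-value is >= its keeper's.
    Raises AssertionError on violation.
    """
    params = params or PruneParams()
    pruned = panel.pruned_ids()
    assert set(panel.retained) | set(pruned) == set(assoc["snp"])
    assert not set(panel.retained) & set(pruned)

    info = assoc.set_index("snp")
    snp_to_col = {s: i for i, s in enumerate(g.snp_map["snp"])}
    kept = panel.retained
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            sa, sb = kept[a], kept[b]
            if info.at[sa, "chrom"] != info.at[sb, "chrom"]:
                continue
            if abs(int(info.at[sa, "pos"]) - int(info.at[sb, "pos"])) > params.window_bp:
                continue
            r2 = genotype_r2(
                g.dosages[:, snp_to_col[sa]], g.dosages[:, snp_to_col[sb]]
            )
            assert r2 <= params.r2_threshold, (sa, sb, r2)
    for keeper, members in panel.clusters.items():
        for snp, r2 in members:
            assert r2 > params.r2_threshold
            assert info.at[snp, "p"] >= info.at[keeper, "p"] or (
                info.at[snp, "rank"] > info.at[keeper, "rank"]
            )
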