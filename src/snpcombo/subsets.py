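"""Candidate SNP datasets from the pruned association table.

Three families of threshold criteria are built from the post-pruning
association ranks: Bonferroni multiples (r, 2r, 5r, 10r SNPs where r is
the count below alpha / M), cumulative p-value-rank sets (top-1 through
top-k), and cumulative p-value-range sets (all SNPs with p below each
cutoff; cutoff 1.0 is the whole panel). All membership is strict
(p < threshold) with ties resolved by the association rank order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SNPSubset", "bonferroni_sets", "rank_sets", "range_sets",
           "DEFAULT_RANGE_CUTOFFS"]

DEFAULT_RANGE_CUTOFFS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                         0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class SNPSubset:
    """A labelled candidate SNP set in ascending-p order."""

    label: str
    criterion: str  # bonferroni | rank | range | module | random | combination
    parameter: float
    snps: list[str] = field(default_factory=list)
    capped: bool = False

    @property
    def size(self) -> int:
        return len(self.snps)

    @property
    def empty(self) -> bool:
        return not self.snps


def _ordered_ids(assoc: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    order = assoc.sort_values("rank")
    return order["snp"].to_numpy(), order["p"].to_numpy()


def bonferroni_sets(
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    multipliers: tuple[int, ...] = (1, 2, 5, 10),
) -> list[SNPSubset]:
    """Top r*m SNPs for each multiplier m, where r counts SNPs with
    p below the Bonferroni threshold alpha / M (M = panel size).

    When r = 0 the subsets are flagged empty; when r*m exceeds M the
    subset is capped at the whole panel and flagged.
    """
    if len(assoc) == 0:
        raise ValueError("empty association table")
    ids, p = _ordered_ids(assoc)
    M = len(ids)
    threshold = alpha / M
    r = int((p < threshold).sum())
    out = []
    for m in multipliers:
        size = min(r * m, M)
        out.append(
            SNPSubset(
                label=f"bonferroni_{m}r",
                criterion="bonferroni",
                parameter=float(m),
                snps=list(ids[:size]),
                capped=r * m > M,
            )
        )
    return out


def bonferroni_r(assoc: pd.DataFrame, alpha: float = 0.05) -> int:
    """The count r of SNPs below the Bonferroni threshold alpha / M."""
    _, p = _ordered_ids(assoc)
    return int((p < alpha / len(p)).sum())


def rank_sets(
    assoc: pd.DataFrame,
    k_max: int = 500,
    k_values: list[int] | None = None,
) -> list[SNPSubset]:
    """Cumulative top-k sets for k = 1..min(k_max, M) (nested by
    construction). ``k_values`` restricts to an explicit list of ranks,
    for desk-scale grids."""
    ids, _ = _ordered_ids(assoc)
    M = len(ids)
    ks = k_values if k_values is not None else range(1, min(k_max, M) + 1)
    out = []
    for k in ks:
        if k < 1:
            raise ValueError("rank k must be >= 1")
        k_eff = min(k, M)
        out.append(
            SNPSubset(
                label=f"rank_{k}",
                criterion="rank",
                parameter=float(k),
                snps=list(ids[:k_eff]),
                capped=k > M,
            )
        )
    return out


def range_sets(
    assoc: pd.DataFrame,
    cutoffs: tuple[float, ...] = DEFAULT_RANGE_CUTOFFS,
) -> list[SNPSubset]:
    """Cumulative p-value-range sets: all SNPs with p < cutoff.

    A cutoff of 1.0 includes every SNP (p = 1 SNPs as well), so the last
    set is the whole pruned panel.
    """
    if list(cutoffs) != sorted(cutoffs) or not all(0 < c <= 1 for c in cutoffs):
        raise ValueError("cutoffs must be ascending and in (0, 1]")
    ids, p = _ordered_ids(assoc)
    out = []
    for c in cutoffs:
        if c == 1.0:
            size = len(ids)
        else:
            size = int((p < c).sum())
        out.append(
            SNPSubset(
                label=f"range_p{c:g}",
                criterion="range",
                parameter=float(c),
                snps=list(ids[:size]),
            )
        )
    return out
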