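"""Quality control and single-SNP trend-test association.

QC follows standard case-control GWAS practice: samples with too much
missingness are dropped first, then markers failing missingness, MAF or
Hardy-Weinberg filters (in that fixed order; each removed marker is
labelled with the first filter it fails). The association statistic is the
Cochran-Armitage trend test with additive weights (0, 1, 2), the score
statistic PLINK reports for ``--model trend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._util import MISSING
from .io import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCResult",
    "QCError",
    "AssociationError",
    "apply_qc",
    "hwe_exact_test",
    "catt_trend_test",
    "run_association",
    "genotype_counts",
]


class QCError(ValueError):
    """QC removed every sample or every SNP."""


class AssociationError(ValueError):
    """Invalid association input (e.g. single-class phenotype)."""


@dataclass
class QCThresholds:
    """Filter thresholds: sample missingness > 3%, SNP missingness > 1%,
    MAF < 1%, HWE exact p <= 1e-4 (computed in controls by default)."""

    sample_missing_max: float = 0.03
    snp_missing_max: float = 0.01
    maf_min: float = 0.01
    hwe_p_max: float = 1e-4
    hwe_controls_only: bool = True

    def __post_init__(self) -> None:
        for v in (self.sample_missing_max, self.snp_missing_max,
                  self.maf_min, self.hwe_p_max):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class QCResult:
    kept_samples: list[str]
    kept_snps: list[str]
    removals: pd.DataFrame  # columns: id, kind, reason
    genotypes: GenotypeMatrix

    def report(self) -> pd.DataFrame:
        return self.removals


def apply_qc(g: GenotypeMatrix, thresholds: QCThresholds | None = None
             ) -> QCResult:
    """Apply per-individual then per-marker QC in the fixed order
    sample missingness -> SNP missingness -> MAF -> HWE.

    MAF and HWE are computed on the samples that survive step one; HWE
    uses control samples only unless ``hwe_controls_only`` is False.
    """
    t = thresholds or QCThresholds()
    if g.n_samples == 0 or g.n_snps == 0:
        raise QCError("empty genotype matrix")
    d = g.dosages
    removals: list[tuple[str, str, str]] = []

    sample_missing = (d == MISSING).mean(axis=1)
    keep_samples = sample_missing <= t.sample_missing_max
    for sid in g.samples["sample"].to_numpy()[~keep_samples]:
        removals.append((sid, "sample", "sample_missing"))
    if not keep_samples.any():
        raise QCError("all samples removed by missingness filter")

    d = d[keep_samples]
    phenotype = g.samples["phenotype"].to_numpy()[keep_samples]

    obs = d != MISSING
    snp_missing = 1.0 - obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(d == MISSING, 0, d).sum(axis=0) / (2 * np.maximum(obs.sum(axis=0), 1)),
            0.0,
        )
    maf = np.minimum(freq, 1.0 - freq)

    if t.hwe_controls_only:
        hwe_rows = phenotype == 1
        if not hwe_rows.any():  # no controls: fall back to all samples
            hwe_rows = np.ones(len(phenotype), dtype=bool)
    else:
        hwe_rows = np.ones(len(phenotype), dtype=bool)
    dh = d[hwe_rows]

    snp_ids = g.snp_map["snp"].to_numpy()
    keep_snps = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        if snp_missing[j] > t.snp_missing_max:
            removals.append((snp_ids[j], "snp", "snp_missing"))
            keep_snps[j] = False
        elif maf[j] < t.maf_min:
            removals.append((snp_ids[j], "snp", "maf"))
            keep_snps[j] = False
        else:
            col = dh[:, j]
            col = col[col != MISSING]
            n0 = int((col == 0).sum())
            n1 = int((col == 1).sum())
            n2 = int((col == 2).sum())
            if n0 + n1 + n2 == 0:
                removals.append((snp_ids[j], "snp", "snp_missing"))
                keep_snps[j] = False
            elif hwe_exact_test(n0, n1, n2) <= t.hwe_p_max:
                removals.append((snp_ids[j], "snp", "hwe"))
                keep_snps[j] = False
    if not keep_snps.any():
        raise QCError("all SNPs removed by marker QC")

    out = GenotypeMatrix(
        d[:, keep_snps],
        g.snp_map.loc[keep_snps].reset_index(drop=True),
        g.samples.loc[keep_samples].reset_index(drop=True),
    )
    return QCResult(
        kept_samples=list(out.samples["sample"]),
        kept_snps=list(out.snp_map["snp"]),
        removals=pd.DataFrame(removals, columns=["id", "kind", "reason"]),
        genotypes=out,
    )


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the genotype counts, conditions on the total sample size and
    minor-allele count and sums, over all heterozygote counts of the same
    parity, the probabilities of tables no more probable than the one
    observed. Probabilities are computed in log space from factorials, so
    the test is exact for any sample size.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_minor == 0:
        return 1.0

    # conditional distribution of the heterozygote count given allele counts,
    # over all counts of the same parity as the minor-allele total
    support = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - support) // 2
    hom_major = n - support - hom_minor
    logs = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(support + 1)
        - gammaln(hom_major + 1)
        + support * np.log(2)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = np.flatnonzero(support == n_het)[0]
    # include all tables at most as probable as the observed one, with a
    # small relative tolerance so float noise cannot drop the observed table
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(1.0, p)


def catt_trend_test(
    case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]
) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive weights (0, 1, 2).

    Returns the 1-df chi-square statistic and its asymptotic upper-tail
    p-value. A degenerate table (monomorphic, or zero null variance)
    returns (0, 1).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if (r < 0).any() or (s < 0).any():
        raise ValueError("negative genotype count")
    if r.sum() <= 0 or s.sum() <= 0:
        raise ValueError("empty case or control group")
    stat = _catt_stat_vec(r[None, :], s[None, :])[0]
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return float(stat), p


def _catt_stat_vec(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized trend statistic for stacked (k, 3) count tables.

    T = sum_i w_i (s R_i - r S_i) with weights w = (0, 1, 2), variance
    (r s / n)(n sum w^2 n_i - (sum w n_i)^2) / n; the statistic is
    T^2 / Var(T).
    """
    w = np.array([0.0, 1.0, 2.0])
    n_i = r + s
    rr = r.sum(axis=1)
    ss = s.sum(axis=1)
    n = rr + ss
    T = (w * (ss[:, None] * r - rr[:, None] * s)).sum(axis=1)
    var = (rr * ss / n) * (
        n * (w**2 * n_i).sum(axis=1) - ((w * n_i).sum(axis=1)) ** 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, T**2 / var, 0.0)
    return stat


def genotype_counts(
    g: GenotypeMatrix, phenotype01: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype counts: (cases (m,3), controls (m,3))."""
    d = g.dosages
    case = phenotype01.astype(bool)
    counts = []
    for rows in (case, ~case):
        sub = d[rows]
        counts.append(
            np.stack([(sub == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
        )
    return counts[0].astype(float), counts[1].astype(float)


def run_association(
    g: GenotypeMatrix, phenotype01: np.ndarray | None = None
) -> pd.DataFrame:
    """Trend-test every SNP and rank by ascending p.

    Missing genotypes are excluded per SNP. Ties in p are broken by
    (chromosome, position) so every downstream threshold set is
    deterministic; ``rank`` is 1-based and a permutation of the SNPs.

    Returns a DataFrame with columns ``snp, chrom, pos, r0, r1, r2,
    s0, s1, s2, stat, p, rank``.
    """
    if phenotype01 is None:
        phenotype01 = g.phenotype01()
    phenotype01 = np.asarray(phenotype01)
    if len(np.unique(phenotype01)) < 2:
        raise AssociationError("phenotype has a single class")
    r, s = genotype_counts(g, phenotype01)
    stat = _catt_stat_vec(r, s)
    p = np.where(stat > 0, stats.chi2.sf(stat, df=1), 1.0)
    tab = pd.DataFrame(
        {
            "snp": g.snp_map["snp"].to_numpy(),
            "chrom": g.snp_map["chrom"].to_numpy(),
            "pos": g.snp_map["pos"].to_numpy(),
            "r0": r[:, 0].astype(int), "r1": r[:, 1].astype(int),
            "r2": r[:, 2].astype(int),
            "s0": s[:, 0].astype(int), "s1": s[:, 1].astype(int),
            "s2": s[:, 2].astype(int),
            "stat": stat,
            "p": p,
        }
    )
    order = tab.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).index.to_numpy()
    rank = np.empty(len(tab), dtype=int)
    rank[order] = np.arange(1, len(tab) + 1)
    tab["rank"] = rank
    return tab
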