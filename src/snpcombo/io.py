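"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as PLINK 1.x text PED/MAP (two allele columns per SNP,
``0 0`` meaning missing), gene sets as MSigDB-dialect GMT, and gene
annotations as 4-column BED. Dosages are coded against the dataset minor
allele, matching PLINK's default allele counting; binary PLINK and VCF are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import MISSING

__all__ = [
    "GenotypeMatrix",
    "GeneAnnotation",
    "GeneSetCollection",
    "PedMapError",
    "GmtParseError",
    "BedParseError",
    "read_ped_map",
    "write_ped_map",
    "read_gmt",
    "write_gmt",
    "read_gene_bed",
    "write_gene_bed",
]


class PedMapError(ValueError):
    """Malformed PED/MAP input (column mismatch, >2 alleles, bad position)."""


class GmtParseError(ValueError):
    """Malformed GMT line (fewer than three tab-separated fields)."""


class BedParseError(ValueError):
    """Malformed BED record (start >= end, wrong column count)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with its marker map.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array with values in {0, 1, 2} and
        ``-1`` for missing.
    snp_map
        One row per SNP with columns ``snp``, ``chrom``, ``pos`` (1-based
        bp), ``a1`` (major / other allele) and ``a2`` (minor / counted
        allele). Positions are strictly increasing within a chromosome.
    samples
        One row per sample with columns ``sample`` and ``phenotype``
        (PLINK coding: 1 = control, 2 = case, 0 or -9 = missing).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.snp_map) != m:
            raise ValueError("dosage shape does not match sample/SNP tables")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")
        if self.snp_map["snp"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(np.sort(pos)) <= 0):
                raise ValueError("positions must be unique within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp"].to_numpy()

    def phenotype01(self) -> np.ndarray:
        """Phenotype as 0 = control, 1 = case (raises on missing codes)."""
        ph = self.samples["phenotype"].to_numpy()
        if not np.isin(ph, (1, 2)).all():
            raise ValueError("phenotype contains missing codes")
        return (ph == 2).astype(np.int8)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Column subset in the given SNP order."""
        idx = self.snp_map.reset_index(drop=True).set_index("snp")
        cols = idx.index.get_indexer(list(snp_ids))
        if (cols < 0).any():
            missing = [s for s, c in zip(snp_ids, cols) if c < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.snp_map.iloc[cols].reset_index(drop=True),
            self.samples.reset_index(drop=True),
        )

    def subset_samples(self, row_mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[row_mask],
            self.snp_map.reset_index(drop=True),
            self.samples.loc[row_mask].reset_index(drop=True),
        )


@dataclass
class GeneAnnotation:
    """Gene intervals in BED convention: 0-based, half-open.

    A SNP at 1-based position ``p`` overlaps a gene iff
    ``start <= p - 1 < end``.
    """

    records: pd.DataFrame  # columns: chrom, start, end, gene

    def __post_init__(self) -> None:
        r = self.records
        if (r["start"] >= r["end"]).any():
            raise BedParseError("gene interval with start >= end")
        if r["gene"].duplicated().any():
            raise ValueError("gene symbols must be unique")
        self.records = (
            r.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a category label and member symbols."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, category: str, members) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate set name: {name}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"empty gene set: {name}")
        self.sets[name] = (category, members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def category(self, name: str) -> str:
        return self.sets[name][0]

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


# ---------------------------------------------------------------------------
# PED/MAP


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a minor-allele dosage matrix.

    The minor (counted) allele at each SNP is determined from the data;
    a 50/50 tie is broken toward the lexicographically smaller allele.
    ``0 0`` genotypes become the missing sentinel.
    """
    snp_map = _read_map(map_path)
    m = len(snp_map)

    sample_rows: list[tuple[str, int]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PedMapError(
                    f"PED line {ln}: expected {6 + 2 * m} fields for {m} "
                    f"SNPs, got {len(fields)}"
                )
            sample_rows.append((fields[1], int(float(fields[5]))))
            allele_rows.append(np.array(fields[6:], dtype=object))
    if not sample_rows:
        alleles = np.empty((0, 2 * m), dtype=object)
    else:
        alleles = np.vstack(allele_rows)

    n = len(sample_rows)
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    a1_list: list[str] = []
    a2_list: list[str] = []
    for j in range(m):
        x = alleles[:, 2 * j]
        y = alleles[:, 2 * j + 1]
        called = (x != "0") & (y != "0")
        if ((x == "0") ^ (y == "0")).any():
            raise PedMapError(
                f"half-missing genotype at SNP {snp_map['snp'].iloc[j]}"
            )
        observed = sorted(set(x[called]) | set(y[called]))
        if len(observed) > 2:
            raise PedMapError(
                f"more than 2 alleles at SNP {snp_map['snp'].iloc[j]}: "
                f"{observed}"
            )
        if not observed:  # all missing
            a1_list.append("0")
            a2_list.append("0")
            continue
        if len(observed) == 1:
            major = minor = observed[0]
        else:
            counts = {
                a: int((x[called] == a).sum() + (y[called] == a).sum())
                for a in observed
            }
            # minor = rarer allele; tie -> lexicographically smaller
            minor = min(observed, key=lambda a: (counts[a], a))
            major = observed[0] if observed[1] == minor else observed[1]
        a1_list.append(major)
        a2_list.append(minor)
        d = (x[called] == minor).astype(np.int8) + (y[called] == minor).astype(
            np.int8
        )
        if major == minor:  # monomorphic: count the single allele as 0 copies
            d[:] = 0
        dosages[called, j] = d

    snp_map = snp_map.assign(a1=a1_list, a2=a2_list)
    samples = pd.DataFrame(sample_rows, columns=["sample", "phenotype"])
    return GenotypeMatrix(dosages, snp_map, samples)


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedMapError(f"MAP line {ln}: expected 4 columns")
            chrom, snp, _cm, bp = fields
            try:
                pos = int(bp)
            except ValueError as exc:
                raise PedMapError(
                    f"MAP line {ln}: non-numeric position {bp!r}"
                ) from exc
            rows.append((snp, chrom, pos))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def write_ped_map(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP (genetic distance column written as 0)."""
    with open(map_path, "w") as fh:
        for row in g.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")

    a1 = g.snp_map["a1"].to_numpy()
    a2 = g.snp_map["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(g.samples.itertuples(index=False)):
            d = g.dosages[i]
            pairs = np.where(
                d[:, None] == MISSING,
                np.array(["0", "0"], dtype=object),
                np.where(
                    d[:, None] == 0,
                    np.stack([a1, a1], axis=1),
                    np.where(
                        d[:, None] == 1,
                        np.stack([a1, a2], axis=1),
                        np.stack([a2, a2], axis=1),
                    ),
                ),
            )
            geno = " ".join(" ".join(p) for p in pairs)
            fh.write(
                f"F{srow.sample} {srow.sample} 0 0 0 "
                f"{int(srow.phenotype)} {geno}\n".rstrip()
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> category <TAB> gene...`` per line."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"GMT line {ln}: expected at least 3 tab-separated fields"
                )
            name, category = fields[0], fields[1]
            genes = [f for f in fields[2:] if f]
            coll.add(name, category, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (category, members) in coll:
            genes = "\t".join(sorted(members))
            fh.write(f"{name}\t{category}\t{genes}\n")


# ---------------------------------------------------------------------------
# BED


def read_gene_bed(path) -> GeneAnnotation:
    """Read a 4-column BED gene annotation (0-based, half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise BedParseError(f"BED line {ln}: expected >= 4 columns")
            chrom, start, end, gene = fields[:4]
            start, end = int(start), int(end)
            if start >= end:
                raise BedParseError(
                    f"BED line {ln}: start {start} >= end {end}"
                )
            rows.append((chrom, start, end, gene))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    )


def write_gene_bed(ann: GeneAnnotation, path) -> None:
    ann.records.to_csv(path, sep="\t", header=False, index=False)
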