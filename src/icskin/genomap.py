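"""Genetic maps and diploid genotype containers.

Conventions shared by every other module:

* Loci are ordered by the genetic map, chromosome by chromosome; genotype
  containers never reorder loci independently of their map.
* All lengths are genetic distances in centi-Morgans (cM).  Physical (bp)
  positions are carried through for export but never enter a computation.
* Genotypes are biallelic and unordered, stored as the dosage of the "1"
  allele: 0 (hom ref), 1 (het), 2 (hom alt), or :data:`MISSING` (-1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1

#: Text spellings of the diploid genotype calls used by the TSV dialect.
_GT_TO_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class MapFormatError(ValueError):
    """A genetic-map file could not be parsed."""


class MapValidationError(ValueError):
    """A genetic map violates an ordering or uniqueness invariant."""


class GenotypeFormatError(ValueError):
    """A genotype file could not be parsed or aligned to the map."""


@dataclass(frozen=True)
class GeneticMap:
    """An ordered set of SNP loci with chromosome and cM coordinates.

    Parameters
    ----------
    chromosomes : array of str, one label per locus, grouped and ordered.
    snp_ids : array of str, unique across the map.
    cm : array of float, genetic positions; non-decreasing within each
        chromosome.
    bp : array of int, physical positions (-1 when unknown).
    """

    chromosomes: np.ndarray
    snp_ids: np.ndarray
    cm: np.ndarray
    bp: np.ndarray

    def __post_init__(self) -> None:
        chroms = np.asarray(self.chromosomes, dtype=object)
        snps = np.asarray(self.snp_ids, dtype=object)
        cm = np.asarray(self.cm, dtype=float)
        bp = np.asarray(self.bp, dtype=np.int64)
        if not (len(chroms) == len(snps) == len(cm) == len(bp)):
            raise MapValidationError("map columns have unequal lengths")
        if len(cm) == 0:
            raise MapValidationError("a genetic map needs at least one locus")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "snp_ids", snps)
        object.__setattr__(self, "cm", cm)
        object.__setattr__(self, "bp", bp)
        if np.any(cm < 0):
            raise MapValidationError("genetic positions must be >= 0")
        if len(set(snps)) != len(snps):
            raise MapValidationError("duplicate snp_id in map")
        seen: set[str] = set()
        prev = None
        for label in chroms:
            if label != prev:
                if label in seen:
                    raise MapValidationError(
                        f"chromosome {label!r} appears in two separate blocks"
                    )
                seen.add(label)
                prev = label
        for label, (lo, hi) in self.chromosome_slices.items():
            seg = cm[lo:hi]
            if np.any(np.diff(seg) < 0):
                raise MapValidationError(
                    f"cM positions decrease within chromosome {label!r}"
                )

    @cached_property
    def chromosome_slices(self) -> dict[str, tuple[int, int]]:
        """Half-open locus index range of each chromosome, in map order."""
        slices: dict[str, tuple[int, int]] = {}
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                slices[str(self.chromosomes[start])] = (start, i)
                start = i
        return slices

    @cached_property
    def chromosome_order(self) -> tuple[str, ...]:
        return tuple(self.chromosome_slices)

    @cached_property
    def snp_index(self) -> dict[str, int]:
        return {str(s): i for i, s in enumerate(self.snp_ids)}

    @property
    def n_loci(self) -> int:
        return len(self.cm)

    def chromosome_of(self) -> np.ndarray:
        """Integer chromosome code per locus (index into chromosome_order)."""
        codes = np.empty(self.n_loci, dtype=np.int32)
        for code, (label, (lo, hi)) in enumerate(self.chromosome_slices.items()):
            codes[lo:hi] = code
        return codes

    def total_length(self) -> float:
        """Sum over chromosomes of (last cM - first cM)."""
        return float(
            sum(self.cm[hi - 1] - self.cm[lo] for lo, hi in self.chromosome_slices.values())
        )

    def write(self, path: str | Path) -> None:
        """Write in PLINK .map layout: chrom, snp_id, cM, bp (no header)."""
        with open(path, "w", encoding="utf-8") as fh:
            for c, s, g, b in zip(self.chromosomes, self.snp_ids, self.cm, self.bp):
                fh.write(f"{c}\t{s}\t{g:.6f}\t{b}\n")


def total_map_length(gmap: GeneticMap) -> float:
    """Genome length in cM; equals the maximum attainable ICS value."""
    return gmap.total_length()


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a PLINK-style .map file (chrom, snp_id, cM, bp; whitespace-split)."""
    chroms: list[str] = []
    snps: list[str] = []
    cm: list[float] = []
    bp: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MapFormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                chroms.append(parts[0])
                snps.append(parts[1])
                cm.append(float(parts[2]))
                bp.append(int(parts[3]))
            except ValueError as exc:
                raise MapFormatError(f"{path}: line {lineno}: {exc}") from exc
    if not chroms:
        raise MapFormatError(f"{path}: no data rows")
    return GeneticMap(
        np.array(chroms, dtype=object),
        np.array(snps, dtype=object),
        np.array(cm, dtype=float),
        np.array(bp, dtype=np.int64),
    )


@dataclass
class DiploidGenotypes:
    """Unphased diploid genotypes for a set of samples, aligned to a map.

    ``dosages`` is an int8 matrix of shape (n_samples, n_loci) holding the
    count of the "1" allele, or :data:`MISSING`.
    """

    gmap: GeneticMap
    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), self.gmap.n_loci):
            raise ValueError(
                "dosage matrix shape does not match (n_samples, n_loci) = "
                f"({len(self.sample_ids)}, {self.gmap.n_loci})"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages contain values outside {0, 1, 2, MISSING}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample id")

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sample_dosages(self, sample: str) -> np.ndarray:
        return self.dosages[self.sample_index(sample)]


def call_rate(genotypes: DiploidGenotypes, sample: str) -> float:
    """Fraction of map loci with a called (non-missing) genotype."""
    row = genotypes.sample_dosages(sample)
    return float(np.mean(row != MISSING))


def check_call_rates(
    genotypes: DiploidGenotypes, threshold: float = 0.99
) -> dict[str, float]:
    """Per-sample call rates; raises if any falls below ``threshold``.

    The 0.99 default mirrors the array-QC convention that only samples
    with genotyping success above 99% are analysed.
    """
    rates = {s: call_rate(genotypes, s) for s in genotypes.sample_ids}
    failing = {s: r for s, r in rates.items() if r < threshold}
    if failing:
        raise ValueError(
            "samples below call-rate threshold "
            f"{threshold}: " + ", ".join(f"{s} ({r:.4f})" for s, r in failing.items())
        )
    return rates


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path, gmap: GeneticMap, format: str = "tsv"
) -> DiploidGenotypes:
    """Read genotypes and align them to ``gmap`` order by snp_id.

    Loci present in the map but absent from the file become MISSING; loci in
    the file but not in the map are dropped (count logged).  ``format`` is
    ``"tsv"`` (the dialect written by :func:`write_genotypes_tsv`) or
    ``"vcf"`` (biallelic sites with GT).
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, gmap)
    if format == "vcf":
        return _read_genotypes_vcf(path, gmap)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str | Path, gmap: GeneticMap) -> DiploidGenotypes:
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    file_snps = list(table.columns)
    known = gmap.snp_index
    dropped = sum(1 for s in file_snps if s not in known)
    if dropped:
        logger.info("dropping %d genotype columns absent from the map", dropped)
    overlap = [s for s in file_snps if s in known]
    if not overlap:
        raise GenotypeFormatError(f"{path}: no snp_ids overlap the map")
    samples = [str(s) for s in table.index]
    dosages = np.full((len(samples), gmap.n_loci), MISSING, dtype=np.int8)
    for snp in overlap:
        col = table[snp]
        j = known[snp]
        for i, cell in enumerate(col):
            try:
                dosages[i, j] = _GT_TO_DOSAGE[cell]
            except KeyError:
                raise GenotypeFormatError(
                    f"{path}: sample {samples[i]!r}, SNP {snp!r}: "
                    f"bad genotype cell {cell!r}"
                ) from None
    return DiploidGenotypes(gmap, samples, dosages)


def _read_genotypes_vcf(path: str | Path, gmap: GeneticMap) -> DiploidGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    known = gmap.snp_index
    dosages = np.full((len(samples), gmap.n_loci), MISSING, dtype=np.int8)
    dropped = 0
    seen_any = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic site %s", variant.ID)
            continue
        j = known.get(variant.ID)
        if j is None:
            dropped += 1
            continue
        seen_any = True
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dosages[i, j] = MISSING
            else:
                dosages[i, j] = a + b
    vcf.close()
    if dropped:
        logger.info("dropped %d VCF sites absent from the map", dropped)
    if not seen_any:
        raise GenotypeFormatError(f"{path}: no snp_ids overlap the map")
    return DiploidGenotypes(gmap, samples, dosages)


def write_genotypes_tsv(genotypes: DiploidGenotypes, path: str | Path) -> None:
    """Write the TSV dialect: header of snp_ids, one row per sample."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, genotypes.gmap.snp_ids)) + "\n")
        for sid, row in zip(genotypes.sample_ids, genotypes.dosages):
            cells = "\t".join(_DOSAGE_TO_GT[int(d)] for d in row)
            fh.write(f"{sid}\t{cells}\n")


def write_vcf(
    gmap: GeneticMap,
    sample_ids: Sequence[str],
    genotype_strings: Iterable[Sequence[str]],
    path: str | Path,
) -> None:
    """Write a minimal VCF 4.2 with GT-only records over the map loci.

    ``genotype_strings`` yields, per locus, one GT string per sample
    (e.g. ``"0/1"`` or ``"0|1"``).  Used by both the unphased cohort
    exporter and the phased panel exporter.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for label, (lo, hi) in gmap.chromosome_slices.items():
            fh.write(f"##contig=<ID={label}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, row in enumerate(genotype_strings):
            pos = int(gmap.bp[j]) if gmap.bp[j] > 0 else j + 1
            fh.write(
                f"{gmap.chromosomes[j]}\t{pos}\t{gmap.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(row)
                + "\n"
            )


def write_genotypes_vcf(genotypes: DiploidGenotypes, path: str | Path) -> None:
    """Write unphased genotypes as a GT-only VCF."""
    rows = (
        [_DOSAGE_TO_GT[int(d)] for d in genotypes.dosages[:, j]]
        for j in range(genotypes.gmap.n_loci)
    )
    write_vcf(genotypes.gmap, genotypes.sample_ids, rows, path)
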