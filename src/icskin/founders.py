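"""Synthetic genetic maps and LD-structured phased founder panels.

The real calibration input for ICS — a phased haplotype panel from ~1500
cohort individuals on a ~174k-SNP array — is emulated here by a standard
haplotype-copying (Li–Stephens-style) mosaic: every panel haplotype copies,
locus by locus, from one of K latent ancestral haplotypes, switching
ancestors between adjacent loci with probability ``1 - exp(-d / ld_scale)``
for a cM gap ``d``.  This produces linkage disequilibrium that decays with
genetic distance, the property that makes IBS-segment statistics behave
realistically (unrelated pairs share short chance segments, not none).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomap import GeneticMap, write_vcf

#: Default autosome genetic lengths (cM), chr1..chr22.  They total exactly
#: 3662.5 cM — matching the conventional sex-averaged autosomal map total
#: used as the maximum ICS — with chromosome 21 fixed at 63.0 cM, the
#: shortest autosome.
DEFAULT_CHROMOSOME_LENGTHS: tuple[float, ...] = (
    295.9, 277.9, 230.9, 221.8, 211.0, 198.5, 193.5, 173.7, 172.0, 187.2,
    163.5, 180.6, 129.9, 124.3, 146.2, 138.5, 132.8, 121.2, 111.5, 112.0,
    63.0, 76.6,
)

#: 2000 SNPs per autosome (44,000 genome-wide, ~12 per cM) is the default
#: density: a scaled-down stand-in for a ~174k genotyping array that keeps
#: unrelated pairs' chance segments short relative to true IBD segments.
DEFAULT_SNPS_PER_CHROMOSOME = 2000

#: Default LD decay scale in cM.  Human r^2 decays over roughly 50-100 kb
#: (~0.05-0.1 cM), so 0.1 cM gives realistic short-range LD without
#: correlating loci across segment-length scales.
DEFAULT_LD_SCALE = 0.1


@dataclass(frozen=True)
class HaplotypePanel:
    """A phased, gap-free haplotype panel over a genetic map.

    ``haplotypes`` is a uint8 matrix (n_haplotypes, n_loci); haplotypes
    2i and 2i+1 belong to donor ``donor_ids[i]``.
    """

    gmap: GeneticMap
    haplotypes: np.ndarray
    donor_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        haps = np.asarray(self.haplotypes, dtype=np.uint8)
        object.__setattr__(self, "haplotypes", haps)
        if haps.ndim != 2 or haps.shape[1] != self.gmap.n_loci:
            raise ValueError("haplotype matrix must be (n_hap, n_loci)")
        if haps.shape[0] % 2:
            raise ValueError("haplotype count must be even (2 per donor)")
        if haps.shape[0] != 2 * len(self.donor_ids):
            raise ValueError("donor_ids must pair haplotypes 2i, 2i+1")
        if not np.isin(haps, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    def donor_haplotypes(self, donor: int | str) -> np.ndarray:
        """The (2, n_loci) haplotype pair of one donor."""
        i = donor if isinstance(donor, int) else self.donor_ids.index(donor)
        return self.haplotypes[2 * i : 2 * i + 2]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


def make_synthetic_map(
    n_chromosomes: int = 22,
    snps_per_chromosome: int = DEFAULT_SNPS_PER_CHROMOSOME,
    chromosome_lengths: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> GeneticMap:
    """Generate a synthetic multi-chromosome genetic map.

    Per chromosome, locus cM positions are sorted uniform draws spanning
    [0, length], with the first locus pinned at 0 and the last at the
    chromosome length, so the total map length equals the configured sum
    exactly.  The default preset is 22 autosomes totalling 3662.5 cM with
    the shortest chromosome at 63 cM.
    """
    if chromosome_lengths is None:
        if n_chromosomes == 22:
            chromosome_lengths = DEFAULT_CHROMOSOME_LENGTHS
        else:
            raise ValueError("chromosome_lengths required when n_chromosomes != 22")
    if len(chromosome_lengths) != n_chromosomes:
        raise ValueError("need one length per chromosome")
    if snps_per_chromosome < 2:
        raise ValueError("snps_per_chromosome must be >= 2")
    if any(l <= 0 for l in chromosome_lengths):
        raise ValueError("chromosome lengths must be > 0")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    snps: list[str] = []
    cm: list[np.ndarray] = []
    bp: list[np.ndarray] = []
    for c, length in enumerate(chromosome_lengths, start=1):
        pos = np.sort(rng.uniform(0.0, length, size=snps_per_chromosome - 2))
        pos = np.concatenate(([0.0], pos, [float(length)]))
        chroms.extend([str(c)] * snps_per_chromosome)
        snps.extend(f"c{c}s{i}" for i in range(snps_per_chromosome))
        cm.append(pos)
        # bp is for export only; strictly increasing within the chromosome
        bp.append(np.round(pos * 1e6).astype(np.int64) + np.arange(snps_per_chromosome) + 1)
    return GeneticMap(
        np.array(chroms, dtype=object),
        np.array(snps, dtype=object),
        np.concatenate(cm),
        np.concatenate(bp),
    )


def make_haplotype_panel(
    gmap: GeneticMap,
    n_individuals: int,
    ld_scale: float = DEFAULT_LD_SCALE,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator | None = None,
    n_ancestors: int = 50,
    max_resample: int = 50,
) -> HaplotypePanel:
    """Simulate a phased founder panel with distance-decaying LD.

    Parameters
    ----------
    ld_scale : cM scale of LD decay; the ancestor-switch probability over a
        gap ``d`` is ``1 - exp(-d / ld_scale)``.
    maf_range : ancestral allele frequencies are drawn uniformly in this
        minor-allele-frequency range and folded to either allele; the lower
        bound also acts as the panel MAF floor, enforced by resampling
        offending loci.
    n_ancestors : number K of latent ancestral haplotypes per chromosome.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if ld_scale <= 0:
        raise ValueError("ld_scale must be > 0")
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    haps = np.empty((n_hap, gmap.n_loci), dtype=np.uint8)
    for label, (a, b) in gmap.chromosome_slices.items():
        _simulate_chromosome(
            haps[:, a:b], gmap.cm[a:b], ld_scale, (lo, hi), n_ancestors, rng,
            max_resample,
        )
    donors = tuple(f"donor{i:04d}" for i in range(n_individuals))
    return HaplotypePanel(gmap, haps, donors)


def _simulate_chromosome(
    out: np.ndarray,
    cm: np.ndarray,
    ld_scale: float,
    maf_range: tuple[float, float],
    n_ancestors: int,
    rng: np.random.Generator,
    max_resample: int,
) -> None:
    n_hap, n_loci = out.shape
    lo, hi = maf_range
    maf = rng.uniform(lo, hi, size=n_loci)
    fold = rng.random(n_loci) < 0.5
    p = np.where(fold, maf, 1.0 - maf)
    ancestors = (rng.random((n_ancestors, n_loci)) < p).astype(np.uint8)
    switch = 1.0 - np.exp(-np.diff(cm) / ld_scale)
    source = np.empty((n_hap, n_loci), dtype=np.int32)
    source[:, 0] = rng.integers(0, n_ancestors, size=n_hap)
    for j in range(1, n_loci):
        jump = rng.random(n_hap) < switch[j - 1]
        source[:, j] = np.where(
            jump, rng.integers(0, n_ancestors, size=n_hap), source[:, j - 1]
        )
    out[:] = ancestors[source, np.arange(n_loci)]
    # enforce the MAF floor: redraw ancestral alleles at offending loci with
    # a safely interior frequency, keeping the copying mosaic intact
    for _ in range(max_resample):
        freq = out.mean(axis=0)
        bad = np.flatnonzero(np.minimum(freq, 1 - freq) <= lo)
        if bad.size == 0:
            return
        p_new = rng.uniform(max(lo * 2, 0.1), hi, size=bad.size)
        ancestors[:, bad] = (rng.random((n_ancestors, bad.size)) < p_new).astype(
            np.uint8
        )
        out[:, bad] = ancestors[source[:, bad], bad]
    raise RuntimeError(
        "could not satisfy the MAF floor after bounded resampling; "
        "increase n_individuals or maf_range"
    )


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Export the panel as a phased (GT with ``|``) VCF."""
    haps = panel.haplotypes
    rows = (
        [
            f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}"
            for i in range(panel.n_donors)
        ]
        for j in range(panel.gmap.n_loci)
    )
    write_vcf(panel.gmap, list(panel.donor_ids), rows, path)


def load_panel_vcf(path: str | Path, gmap: GeneticMap) -> HaplotypePanel:
    """Load a phased VCF (all sites biallelic, fully called) as a panel."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = tuple(vcf.samples)
    haps = np.full((2 * len(donors), gmap.n_loci), 255, dtype=np.uint8)
    known = gmap.snp_index
    for variant in vcf:
        j = known.get(variant.ID)
        if j is None:
            continue
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"panel VCF has a missing call at {variant.ID}, donor "
                    f"{donors[i]}; panels must be gap-free"
                )
            haps[2 * i, j] = a
            haps[2 * i + 1, j] = b
    vcf.close()
    if (haps == 255).any():
        raise ValueError("panel VCF does not cover every map locus")
    return HaplotypePanel(gmap, haps, donors)


def expected_mean_ibs(allele_freq: np.ndarray) -> float:
    """Closed-form mean IBS per locus between two unrelated HWE individuals.

    With allele frequency p and q = 1 - p, the genotype dosages of two
    independent individuals are Binomial(2, p); the mean IBS state is
    ``2 - E|g1 - g2|`` where ``E|g1 - g2| = 4pq(p^2 + q^2) + 2 * 2 p^2 q^2``.
    Used as an independent sanity oracle for the panel generator.
    """
    p = np.asarray(allele_freq, dtype=float)
    q = 1.0 - p
    e_absdiff = 4 * p * q * (p * p + q * q) + 4 * p * p * q * q
    return float(np.mean(2.0 - e_absdiff))
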