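"""Per-locus IBS states, shared-segment detection and the ICS statistic.

The index of chromosome sharing (ICS) between two individuals is the sum of
the genetic lengths (cM) of their IBS shared segments that exceed a length
threshold Th.  A shared segment is a maximal run of consecutive called loci
with IBS state >= 1 on a single chromosome; runs of a single locus
("isolated sharing") are not segments.  Loci where either individual is
uncalled are removed before run detection, so a segment may bridge a
missing locus but its endpoints are always called loci.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomap import MISSING, DiploidGenotypes, GeneticMap


@dataclass(frozen=True)
class IbsTrack:
    """IBS states at the called loci of one sample pair, in map order."""

    gmap: GeneticMap
    locus_indices: np.ndarray  # int64, indices into the map
    states: np.ndarray         # int8 in {0, 1, 2}

    def __post_init__(self) -> None:
        if len(self.locus_indices) != len(self.states):
            raise ValueError("locus_indices and states differ in length")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SharedSegment:
    """A maximal multi-SNP run of IBS >= 1 within one chromosome."""

    chromosome: str
    first_snp: str
    last_snp: str
    first_index: int
    last_index: int
    n_snps: int
    length_cm: float


@dataclass(frozen=True)
class IcsValue:
    """An ICS value together with the threshold and group that defined it."""

    value: float
    threshold: float
    group: str  # "C" or "L"


def ibs_states_from_dosages(
    a: np.ndarray, b: np.ndarray, gmap: GeneticMap
) -> IbsTrack:
    """IBS state per called locus for two dosage vectors on the same map.

    For unordered biallelic genotype pairs the maximum allele matching is
    ``2 - |dosage_a - dosage_b|`` (het vs het shares both alleles; opposite
    homozygotes share none).  Loci missing in either vector are dropped.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != (gmap.n_loci,) or b.shape != (gmap.n_loci,):
        raise ValueError("dosage vectors must have one entry per map locus")
    called = (a != MISSING) & (b != MISSING)
    idx = np.flatnonzero(called)
    states = (2 - np.abs(a[idx].astype(np.int16) - b[idx].astype(np.int16))).astype(
        np.int8
    )
    return IbsTrack(gmap, idx.astype(np.int64), states)


def ibs_states(
    genotypes: DiploidGenotypes,
    sample_a: str,
    sample_b: str,
    other: DiploidGenotypes | None = None,
) -> IbsTrack:
    """IBS track between two samples (optionally from two containers)."""
    gb = other if other is not None else genotypes
    if gb.gmap is not genotypes.gmap and not (
        np.array_equal(gb.gmap.snp_ids, genotypes.gmap.snp_ids)
        and np.array_equal(gb.gmap.cm, genotypes.gmap.cm)
    ):
        raise ValueError("samples are aligned to different maps")
    return ibs_states_from_dosages(
        genotypes.sample_dosages(sample_a), gb.sample_dosages(sample_b), genotypes.gmap
    )


def detect_shared_segments(track: IbsTrack) -> list[SharedSegment]:
    """Maximal runs of IBS >= 1 over the called loci, per chromosome.

    Runs of exactly one locus are discarded; chromosome boundaries always
    break runs.  Segments are returned in map order.
    """
    if len(track) == 0:
        return []
    gmap = track.gmap
    chrom_codes = gmap.chromosome_of()[track.locus_indices]
    shared = track.states >= 1
    # run starts: shared here, and either first entry, not shared before,
    # or a chromosome change
    prev_shared = np.concatenate(([False], shared[:-1]))
    chrom_change = np.concatenate(([True], chrom_codes[1:] != chrom_codes[:-1]))
    starts = np.flatnonzero(shared & (~prev_shared | chrom_change))
    next_shared = np.concatenate((shared[1:], [False]))
    chrom_change_next = np.concatenate((chrom_codes[1:] != chrom_codes[:-1], [True]))
    ends = np.flatnonzero(shared & (~next_shared | chrom_change_next))
    order = tuple(gmap.chromosome_order)
    segments: list[SharedSegment] = []
    for s, e in zip(starts, ends):
        if e == s:  # isolated sharing
            continue
        i0 = int(track.locus_indices[s])
        i1 = int(track.locus_indices[e])
        segments.append(
            SharedSegment(
                chromosome=order[int(chrom_codes[s])],
                first_snp=str(gmap.snp_ids[i0]),
                last_snp=str(gmap.snp_ids[i1]),
                first_index=i0,
                last_index=i1,
                n_snps=int(e - s + 1),
                length_cm=float(gmap.cm[i1] - gmap.cm[i0]),
            )
        )
    return segments


def segment_lengths(track: IbsTrack) -> np.ndarray:
    """cM lengths of all shared segments of a track (fast path for sweeps)."""
    return np.array([seg.length_cm for seg in detect_shared_segments(track)])


def ics(segments: Sequence[SharedSegment] | np.ndarray, th: float) -> float:
    """Sum of segment lengths strictly greater than ``th`` (cM)."""
    if th < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(segments, np.ndarray):
        lengths = segments
    else:
        lengths = np.array([seg.length_cm for seg in segments])
    if len(lengths) == 0:
        return 0.0
    return float(lengths[lengths > th].sum())


def ics_pair(
    genotypes: DiploidGenotypes,
    sample_a: str,
    sample_b: str,
    th: float,
    group: str = "C",
    other: DiploidGenotypes | None = None,
) -> IcsValue:
    """ICS between two samples: IBS states -> segments -> thresholded sum."""
    track = ibs_states(genotypes, sample_a, sample_b, other)
    value = ics(detect_shared_segments(track), th)
    return IcsValue(value=value, threshold=float(th), group=group)


def ics_from_dosages(
    a: np.ndarray, b: np.ndarray, gmap: GeneticMap, th: float
) -> float:
    """ICS between two dosage vectors (simulation fast path)."""
    return ics(detect_shared_segments(ibs_states_from_dosages(a, b, gmap)), th)


def segments_to_tsv(segments: Sequence[SharedSegment], path: str | Path) -> None:
    """Export segments as BED-like TSV: chrom, first/last SNP, count, cM."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chromosome\tfirst_snp\tlast_snp\tn_snps\tlength_cm\n")
        for seg in segments:
            fh.write(
                f"{seg.chromosome}\t{seg.first_snp}\t{seg.last_snp}\t"
                f"{seg.n_snps}\t{seg.length_cm:.6f}\n"
            )
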