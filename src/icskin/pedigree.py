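"""Gene-dropping simulation through the 12-member calibration pedigree.

The calibration pedigree couples six founders (A, B, C, F, G, J) so that a
single family realisation contains one pair of every target relationship:

* collateral: sibling C-1 = (D, E), uncle–nephew C-2 = (D, I), first cousin
  C-3 = (H, I), first cousin once removed C-4 = (H, L), second cousin
  C-5 = (K, L);
* lineal: parent–child L-1 = (A, E), grandparent–grandchild L-2 = (A, I),
  great-grandparent–great-grandchild L-3 = (A, L).

Unrelated (UN) pairs are founders taken from two different families.

Meiosis uses an interference-free crossover model: between adjacent loci a
crossover occurs independently with probability cM-distance / 100, capped
at 0.5 (free recombination); the starting parental haplotype of each
chromosome is chosen uniformly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .founders import HaplotypePanel
from .genomap import MISSING, DiploidGenotypes, GeneticMap

#: Fixed pedigree structure: child -> (parent, parent).
_DEFAULT_PARENTS: dict[str, tuple[str, str]] = {
    "D": ("A", "B"),
    "E": ("A", "B"),
    "H": ("C", "D"),
    "I": ("E", "F"),
    "K": ("G", "H"),
    "L": ("I", "J"),
}

#: Relationship label -> member pair within one family.
RELATIONSHIP_PAIRS: dict[str, tuple[str, str]] = {
    "C-1": ("D", "E"),
    "C-2": ("D", "I"),
    "C-3": ("H", "I"),
    "C-4": ("H", "L"),
    "C-5": ("K", "L"),
    "L-1": ("A", "E"),
    "L-2": ("A", "I"),
    "L-3": ("A", "L"),
}

C_RELATIONSHIPS: tuple[str, ...] = ("C-1", "C-2", "C-3", "C-4", "C-5")
L_RELATIONSHIPS: tuple[str, ...] = ("L-1", "L-2", "L-3")

FOUNDERS_PER_FAMILY = 6


class PedigreeError(ValueError):
    """The pedigree structure is invalid (cycle, missing parent, ...)."""


@dataclass(frozen=True)
class Pedigree:
    """A pedigree given as child -> (parent, parent); founders implied."""

    parents: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        members = self.members
        for child, (pa, ma) in self.parents.items():
            if pa not in members or ma not in members:
                raise PedigreeError(f"parent of {child!r} not among members")
        self.topological_order()  # raises on cycles

    @property
    def members(self) -> tuple[str, ...]:
        names = set(self.parents)
        for pa, ma in self.parents.values():
            names.update((pa, ma))
        return tuple(sorted(names))

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m not in self.parents)

    def topological_order(self) -> tuple[str, ...]:
        """Members ordered founders-first; raises PedigreeError on a cycle."""
        order: list[str] = list(self.founders)
        placed = set(order)
        remaining = dict(self.parents)
        while remaining:
            ready = [
                c for c, (pa, ma) in remaining.items() if pa in placed and ma in placed
            ]
            if not ready:
                raise PedigreeError("pedigree contains a cycle")
            for c in sorted(ready):
                order.append(c)
                placed.add(c)
                del remaining[c]
        return tuple(order)


def default_pedigree() -> Pedigree:
    """The 12-member calibration pedigree described in the module docstring."""
    return Pedigree(dict(_DEFAULT_PARENTS))


@dataclass(frozen=True)
class MeiosisModel:
    """Interference-free crossover model; rate per interval = cM/100, <= cap."""

    max_rate: float = 0.5

    def interval_rates(self, gmap: GeneticMap) -> dict[str, np.ndarray]:
        """Per-chromosome crossover probabilities between adjacent loci."""
        rates: dict[str, np.ndarray] = {}
        for label, (a, b) in gmap.chromosome_slices.items():
            rates[label] = np.minimum(np.diff(gmap.cm[a:b]) / 100.0, self.max_rate)
        return rates


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    model: MeiosisModel,
    rng: np.random.Generator,
    return_sources: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """One gamete from a (2, n_loci) parental haplotype pair.

    Per chromosome the source haplotype starts at 0 or 1 with equal
    probability and flips independently per interval with the model's
    crossover probability.  With ``return_sources`` the per-locus source
    indicator is also returned (transmission bookkeeping for tests).
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, gmap.n_loci):
        raise ValueError("parent haplotypes must have shape (2, n_loci)")
    sources = np.empty(gmap.n_loci, dtype=np.int8)
    for label, (a, b) in gmap.chromosome_slices.items():
        n = b - a
        rates = np.minimum(np.diff(gmap.cm[a:b]) / 100.0, model.max_rate)
        flips = rng.random(n - 1) < rates
        start = rng.integers(0, 2)
        sources[a:b] = (start + np.concatenate(([0], np.cumsum(flips)))) % 2
    gamete = parent_haplotypes[sources, np.arange(gmap.n_loci)]
    if return_sources:
        return gamete, sources
    return gamete


@dataclass
class FamilyRealization:
    """Haplotypes of the 12 pedigree members for one simulated family.

    ``origins`` (optional) maps each member to an int array of the same
    shape giving, per allele, the index of the founder panel haplotype it
    descends from.
    """

    family_index: int
    gmap: GeneticMap
    haplotypes: dict[str, np.ndarray]
    founder_donors: dict[str, str]
    origins: dict[str, np.ndarray] | None = None

    def dosages(self, member: str) -> np.ndarray:
        h = self.haplotypes[member]
        return (h[0].astype(np.int8) + h[1].astype(np.int8))


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: Mapping[str, np.ndarray],
    gmap: GeneticMap,
    model: MeiosisModel,
    rng: np.random.Generator,
    track_origins: bool = False,
    family_index: int = 0,
    founder_donors: Mapping[str, str] | None = None,
) -> FamilyRealization:
    """Drop founder haplotypes through the pedigree with recombination."""
    haps: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] | None = {} if track_origins else None
    n = gmap.n_loci
    for k, f in enumerate(pedigree.founders):
        fh = np.asarray(founder_haplotypes[f])
        if fh.shape != (2, n):
            raise ValueError(f"founder {f!r} haplotypes must be (2, n_loci)")
        haps[f] = fh
        if origins is not None:
            origins[f] = np.tile(
                np.array([[2 * k], [2 * k + 1]], dtype=np.int32), (1, n)
            )
    for child in pedigree.topological_order():
        if child in haps:
            continue
        pa, ma = pedigree.parents[child]
        gametes = []
        child_orig = []
        for parent in (pa, ma):
            gamete, src = meiosis(haps[parent], gmap, model, rng, return_sources=True)
            gametes.append(gamete)
            if origins is not None:
                child_orig.append(origins[parent][src, np.arange(n)])
        haps[child] = np.stack(gametes)
        if origins is not None:
            origins[child] = np.stack(child_orig)
    return FamilyRealization(
        family_index=family_index,
        gmap=gmap,
        haplotypes=haps,
        founder_donors=dict(founder_donors or {}),
        origins=origins,
    )


@dataclass
class Cohort:
    """A batch of simulated families sharing one map and founder panel."""

    gmap: GeneticMap
    families: list[FamilyRealization]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.families)


def max_families(n_donors: int) -> int:
    """Largest family count supported by a donor pool (6 founders each)."""
    return n_donors // FOUNDERS_PER_FAMILY


def simulate_cohort(
    panel: HaplotypePanel,
    n_families: int,
    model: MeiosisModel | None = None,
    seed: int | None = None,
    pedigree: Pedigree | None = None,
    track_origins: bool = False,
) -> Cohort:
    """Simulate families with disjoint founder sextets from the panel.

    Donors are assigned to families without replacement after a seeded
    permutation; each family descends from its own independent random
    substream so cohorts are reproducible family-by-family.
    """
    pedigree = pedigree or default_pedigree()
    model = model or MeiosisModel()
    feasible = max_families(panel.n_donors)
    if n_families > feasible:
        raise ValueError(
            f"panel of {panel.n_donors} donors supports at most "
            f"{feasible} families of {FOUNDERS_PER_FAMILY} founders"
        )
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    donor_order = perm_rng.permutation(panel.n_donors)
    child_seeds = ss.spawn(n_families)
    families: list[FamilyRealization] = []
    founder_names = pedigree.founders
    for fam in range(n_families):
        rng = np.random.default_rng(child_seeds[fam])
        donors = donor_order[
            fam * FOUNDERS_PER_FAMILY : (fam + 1) * FOUNDERS_PER_FAMILY
        ]
        founder_haps = {
            name: panel.donor_haplotypes(int(d))
            for name, d in zip(founder_names, donors)
        }
        donor_map = {
            name: panel.donor_ids[int(d)] for name, d in zip(founder_names, donors)
        }
        families.append(
            gene_drop(
                pedigree,
                founder_haps,
                panel.gmap,
                model,
                rng,
                track_origins=track_origins,
                family_index=fam,
                founder_donors=donor_map,
            )
        )
    return Cohort(gmap=panel.gmap, families=families, seed=seed)


def relationship_pairs(
    cohort: Cohort,
    relationships: Sequence[str] | None = None,
    n_unrelated: int | None = None,
    seed: int | None = None,
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Dosage-vector pairs per relationship label, plus UN pairs.

    Within-family pairs follow :data:`RELATIONSHIP_PAIRS`.  UN pairs are
    founders of two different families (panel members, never pedigree
    descendants), sampled with a seeded generator.
    """
    if not cohort.families:
        raise ValueError("cohort is empty")
    labels = list(relationships or RELATIONSHIP_PAIRS)
    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for label in labels:
        if label == "UN":
            continue
        a, b = RELATIONSHIP_PAIRS[label]
        out[label] = [
            (fam.dosages(a), fam.dosages(b)) for fam in cohort.families
        ]
    n_un = len(cohort.families) if n_unrelated is None else n_unrelated
    if n_un:
        if len(cohort.families) < 2:
            raise ValueError("UN pairs need at least 2 families")
        rng = np.random.default_rng(seed)
        founders = default_pedigree().founders
        pairs = []
        for _ in range(n_un):
            i, j = rng.choice(len(cohort.families), size=2, replace=False)
            fa = str(rng.choice(founders))
            fb = str(rng.choice(founders))
            pairs.append(
                (cohort.families[i].dosages(fa), cohort.families[j].dosages(fb))
            )
        out["UN"] = pairs
    return out


def apply_genotype_errors(
    dosages: np.ndarray,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inject i.i.d. uniform miscalls and missingness into dosage vectors.

    Both rates default to 0: calibration simulations are error-free, and the
    error model exists to study how array typing errors depress ICS values
    for parent–child pairs.
    """
    rng = rng or np.random.default_rng()
    out = np.array(dosages, dtype=np.int8, copy=True)
    flat = out.reshape(-1)
    if miscall_rate:
        hit = np.flatnonzero(
            (flat != MISSING) & (rng.random(flat.size) < miscall_rate)
        )
        # uniform miscall: replace with one of the two other genotypes
        shift = rng.integers(1, 3, size=hit.size)
        flat[hit] = (flat[hit] + shift) % 3
    if missing_rate:
        hit = rng.random(flat.size) < missing_rate
        flat[hit] = MISSING
    return out


def cohort_to_genotypes(
    cohort: Cohort, members: Sequence[str] | None = None
) -> DiploidGenotypes:
    """Flatten a cohort into one genotype container (samples fam{i}_{M})."""
    members = list(members or default_pedigree().members)
    sample_ids = [
        f"fam{fam.family_index}_{m}" for fam in cohort.families for m in members
    ]
    dosages = np.stack(
        [fam.dosages(m) for fam in cohort.families for m in members]
    )
    return DiploidGenotypes(cohort.gmap, sample_ids, dosages)


def truth_pairs_table(cohort: Cohort) -> list[tuple[str, str, str]]:
    """(relationship, sample_a, sample_b) rows for the cohort's labelled pairs."""
    rows = []
    for fam in cohort.families:
        for label, (a, b) in RELATIONSHIP_PAIRS.items():
            rows.append(
                (label, f"fam{fam.family_index}_{a}", f"fam{fam.family_index}_{b}")
            )
    return rows
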