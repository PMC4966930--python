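"""Shared fixtures: small handmade maps plus one session-scoped calibration.

The expensive objects (genome-scale map, founder panel, 250-family cohort,
threshold sweep and fitted models) are built once per session and shared by
the simulation-physics and end-to-end tests.
"""
from __future__ import annotations

import numpy as np
import pytest

import icskin as ik
from icskin.genomap import GeneticMap
from icskin.pedigree import Cohort
from icskin.thresholds import select_threshold, sweep

SEED_MAP = 101
SEED_PANEL = 102
SEED_COHORT = 103
SEED_PAIRS = 104

N_CALIBRATION_FAMILIES = 200
N_FRESH_FAMILIES = 50


def make_map(chrom_cm: dict[str, list[float]]) -> GeneticMap:
    """Handmade map from {chrom: [cM positions]}."""
    chroms, snps, cm = [], [], []
    for label, positions in chrom_cm.items():
        for k, pos in enumerate(positions):
            chroms.append(label)
            snps.append(f"{label}_{k}")
            cm.append(pos)
    bp = (np.array(cm) * 1e4).astype(np.int64) + np.arange(len(cm)) + 1
    return GeneticMap(
        np.array(chroms, dtype=object), np.array(snps, dtype=object),
        np.array(cm, dtype=float), bp,
    )


@pytest.fixture()
def ten_snp_map() -> GeneticMap:
    """One chromosome, ten equally spaced SNPs at 0..9 cM."""
    return make_map({"1": list(map(float, range(10)))})


@pytest.fixture(scope="session")
def mini_map() -> GeneticMap:
    """Four chromosomes, 300 SNPs each — cheap but multi-chromosome."""
    return ik.make_synthetic_map(
        n_chromosomes=4, snps_per_chromosome=300,
        chromosome_lengths=(100.0, 80.0, 70.0, 63.0), seed=11,
    )


@pytest.fixture(scope="session")
def mini_panel(mini_map) -> ik.HaplotypePanel:
    return ik.make_haplotype_panel(mini_map, 80, seed=12)


@pytest.fixture(scope="session")
def mini_cohort(mini_panel) -> Cohort:
    return ik.simulate_cohort(mini_panel, 12, seed=13, track_origins=True)


# ---------------------------------------------------------------------------
# session-scoped genome-scale calibration (simulation physics + end-to-end)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def genome_map() -> GeneticMap:
    return ik.make_synthetic_map(seed=SEED_MAP)


@pytest.fixture(scope="session")
def founder_panel(genome_map) -> ik.HaplotypePanel:
    n_donors = 6 * (N_CALIBRATION_FAMILIES + N_FRESH_FAMILIES)
    return ik.make_haplotype_panel(genome_map, n_donors, seed=SEED_PANEL)


@pytest.fixture(scope="session")
def full_cohort(founder_panel) -> Cohort:
    return ik.simulate_cohort(
        founder_panel, N_CALIBRATION_FAMILIES + N_FRESH_FAMILIES, seed=SEED_COHORT
    )


@pytest.fixture(scope="session")
def calibration(full_cohort, genome_map):
    """Thresholds, fitted models and fresh-pair sweeps, computed once.

    Families 0..199 calibrate; families 200..249 supply the held-out pairs.
    Returns a dict with the sweep objects, the selected thresholds and the
    fitted KinshipResults for both groups.
    """
    calib = Cohort(genome_map, full_cohort.families[:N_CALIBRATION_FAMILIES])
    fresh = Cohort(genome_map, full_cohort.families[N_CALIBRATION_FAMILIES:])
    calib_pairs = ik.relationship_pairs(calib, seed=SEED_PAIRS)
    fresh_pairs = ik.relationship_pairs(fresh, seed=SEED_PAIRS + 1)
    calib_sweep = sweep(calib_pairs, genome_map)
    fresh_sweep = sweep(fresh_pairs, genome_map)
    th_c = select_threshold(calib_sweep, "C")
    th_l = select_threshold(calib_sweep, "L")

    def ics_at(sweep_obj, th):
        idx = int(np.flatnonzero(sweep_obj.th_grid == th)[0])
        return {lbl: m[:, idx] for lbl, m in sweep_obj.values.items()}

    results = {}
    for group, th in (("C", th_c.selected_th), ("L", th_l.selected_th)):
        values = ics_at(calib_sweep, th)
        model = ik.KinshipModel(
            values, group, max_ics=genome_map.total_length(), threshold=th
        )
        results[group] = model.fit()
    return {
        "map": genome_map,
        "calib_cohort": calib,
        "fresh_cohort": fresh,
        "calib_sweep": calib_sweep,
        "fresh_sweep": fresh_sweep,
        "threshold_C": th_c,
        "threshold_L": th_l,
        "results_C": results["C"],
        "results_L": results["L"],
        "ics_at": ics_at,
    }
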