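"""Threshold (Th) calibration for ICS by ROC AUC over simulated pairs.

``ics(Th)`` — the sum of shared-segment lengths strictly greater than Th —
is swept over a cM grid for every simulated pair.  For each Th the AUC of
each adjacent-relationship comparison (C-1 vs C-2, ..., C-5 vs UN for the
collateral chain; L-1 vs L-2, L-2 vs L-3, L-3 vs UN for the lineal chain)
is computed with the Mann–Whitney estimator, and the Th maximising the mean
AUC of the chain is adopted (C-Th or L-Th; ties go to the smallest Th).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .genomap import GeneticMap
from .ibs import detect_shared_segments, ibs_states_from_dosages

#: Adjacent comparisons whose AUCs are averaged, per group.
GROUP_COMPARISONS: dict[str, tuple[tuple[str, str], ...]] = {
    "C": (("C-1", "C-2"), ("C-2", "C-3"), ("C-3", "C-4"), ("C-4", "C-5"),
          ("C-5", "UN")),
    "L": (("L-1", "L-2"), ("L-2", "L-3"), ("L-3", "UN")),
}


def auc(closer_scores: Sequence[float], farther_scores: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(closer > farther) + 1/2 P(equal), midrank ties.

    Higher ICS is treated as evidence of a closer relationship.
    """
    x = np.asarray(closer_scores, dtype=float)
    y = np.asarray(farther_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("AUC needs nonempty score lists")
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


@dataclass(frozen=True)
class IcsSweep:
    """ics(Th) matrices (pairs x thresholds) per relationship label."""

    th_grid: np.ndarray
    values: dict[str, np.ndarray]

    def relationship_labels(self) -> tuple[str, ...]:
        return tuple(self.values)


@dataclass(frozen=True)
class ThresholdResult:
    """Mean-AUC curve and the adopted threshold for one group (C or L)."""

    group: str
    th_grid: np.ndarray
    mean_auc: np.ndarray
    component_auc: dict[tuple[str, str], np.ndarray]
    selected_th: float

    @property
    def selected_index(self) -> int:
        return int(np.flatnonzero(self.th_grid == self.selected_th)[0])


def _ics_curve(lengths: np.ndarray, th_grid: np.ndarray) -> np.ndarray:
    """ics(Th) for every Th at once via a sorted suffix-sum."""
    if lengths.size == 0:
        return np.zeros(th_grid.size)
    s = np.sort(lengths)
    suffix = np.concatenate([np.cumsum(s[::-1])[::-1], [0.0]])
    idx = np.searchsorted(s, th_grid, side="right")
    return suffix[idx]


def sweep(
    pairs_by_relationship: Mapping[str, Sequence[tuple[np.ndarray, np.ndarray]]],
    gmap: GeneticMap,
    th_grid: Sequence[float] | None = None,
) -> IcsSweep:
    """Compute ics(Th) for every pair over the grid (default 0..63 cM by 1).

    Segments are detected once per pair and re-thresholded across the grid.
    A grid extending beyond the shortest chromosome is allowed but warned
    about: no single segment can exceed that length.
    """
    shortest = min(
        gmap.cm[hi - 1] - gmap.cm[lo] for lo, hi in gmap.chromosome_slices.values()
    )
    if th_grid is None:
        th_grid = np.arange(0.0, min(63.0, shortest) + 0.5, 1.0)
    grid = np.asarray(th_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("thresholds must be >= 0")
    if grid.max() > shortest:
        warnings.warn(
            f"threshold grid exceeds the shortest chromosome ({shortest:.1f} cM)",
            stacklevel=2,
        )
    values: dict[str, np.ndarray] = {}
    for label, pairs in pairs_by_relationship.items():
        rows = np.empty((len(pairs), grid.size))
        for i, (a, b) in enumerate(pairs):
            segs = detect_shared_segments(ibs_states_from_dosages(a, b, gmap))
            rows[i] = _ics_curve(np.array([s.length_cm for s in segs]), grid)
        values[label] = rows
    return IcsSweep(th_grid=grid, values=values)


def select_threshold(ics_sweep: IcsSweep, group: str) -> ThresholdResult:
    """Adopt the Th with maximal mean adjacent-comparison AUC (C-Th / L-Th)."""
    try:
        comparisons = GROUP_COMPARISONS[group]
    except KeyError:
        raise ValueError(f"group must be 'C' or 'L', got {group!r}") from None
    for pair in comparisons:
        for label in pair:
            if label not in ics_sweep.values:
                raise ValueError(f"sweep is missing relationship {label!r}")
    grid = ics_sweep.th_grid
    component: dict[tuple[str, str], np.ndarray] = {}
    for closer, farther in comparisons:
        xs = ics_sweep.values[closer]
        ys = ics_sweep.values[farther]
        component[(closer, farther)] = np.array(
            [auc(xs[:, t], ys[:, t]) for t in range(grid.size)]
        )
    mean_auc = np.mean(np.stack(list(component.values())), axis=0)
    best = int(np.argmax(mean_auc))  # argmax returns the first (smallest Th) tie
    return ThresholdResult(
        group=group,
        th_grid=grid,
        mean_auc=mean_auc,
        component_auc=component,
        selected_th=float(grid[best]),
    )
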