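"""Model/Results interface for ICS kinship calibration and classification.

:class:`KinshipModel` holds per-relationship ICS observations (typically
from a simulated calibration cohort); ``fit()`` estimates the three
candidate ICS distribution families for every relationship, selects one by
group AIC, and returns a :class:`KinshipResults` carrying the fitted
densities, a summary table, and the probabilistic machinery (posteriors,
likelihood ratios, Hummel verdicts, predicate ranges and masses).

Typical use::

    cohort = simulate_cohort(panel, n_families=200, seed=7)
    model = KinshipModel.from_cohort(cohort, threshold=4.0, group="C")
    results = model.fit()
    print(results.summary())
    verdict = results.classify(observed_ics)
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import distributions as dist
from . import inference as inf
from .genomap import GeneticMap
from .ibs import IbsTrack, IcsValue, detect_shared_segments, ibs_states_from_dosages, ics
from .pedigree import Cohort, relationship_pairs

#: Hypotheses evaluated per group.  L-1 is excluded from the lineal set:
#: its error-free ICS is constant at the map total (every locus shares an
#: allele with a parent), so it is screened by `l1_precheck` instead of a
#: density.
GROUP_HYPOTHESES: dict[str, tuple[str, ...]] = {
    "C": ("C-1", "C-2", "C-3", "C-4", "C-5", "UN"),
    "L": ("L-2", "L-3", "UN"),
}


class KinshipModel:
    """ICS calibration data for one relationship group (C or L).

    Parameters
    ----------
    ics_values : mapping of relationship label to ICS observations (cM).
        Must cover the group's hypothesis set (including "UN").
    group : "C" (collateral) or "L" (lineal).
    max_ics : total genetic map length in cM; the ICS domain bound and the
        truncation upper limit for the truncated-normal candidate.
    threshold : the segment-length threshold (C-Th or L-Th) that produced
        the ICS values; carried for bookkeeping.
    priors : optional prior probabilities per hypothesis (default flat).
    """

    def __init__(
        self,
        ics_values: Mapping[str, Sequence[float]],
        group: str,
        max_ics: float,
        threshold: float | None = None,
        priors: Mapping[str, float] | None = None,
    ) -> None:
        if group not in GROUP_HYPOTHESES:
            raise ValueError(f"group must be 'C' or 'L', got {group!r}")
        missing = [h for h in GROUP_HYPOTHESES[group] if h not in ics_values]
        if missing:
            raise ValueError(f"missing ICS values for {missing}")
        self.ics_values = {
            h: np.asarray(ics_values[h], dtype=float) for h in GROUP_HYPOTHESES[group]
        }
        self.group = group
        self.max_ics = float(max_ics)
        self.threshold = None if threshold is None else float(threshold)
        self.priors = dict(priors) if priors is not None else None

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        threshold: float,
        group: str,
        n_unrelated: int | None = None,
        seed: int | None = None,
        priors: Mapping[str, float] | None = None,
    ) -> "KinshipModel":
        """Compute ICS for every labelled pair of a simulated cohort."""
        labels = [h for h in GROUP_HYPOTHESES[group] if h != "UN"]
        pairs = relationship_pairs(
            cohort, relationships=labels + ["UN"], n_unrelated=n_unrelated, seed=seed
        )
        gmap = cohort.gmap
        values = {
            label: np.array(
                [
                    ics(
                        detect_shared_segments(ibs_states_from_dosages(a, b, gmap)),
                        threshold,
                    )
                    for a, b in pair_list
                ]
            )
            for label, pair_list in pairs.items()
        }
        return cls(
            values, group, max_ics=gmap.total_length(), threshold=threshold,
            priors=priors,
        )

    def fit(self, families: Sequence[str] = dist.FAMILIES) -> "KinshipResults":
        """MLE-fit candidate families, select by group AIC."""
        selection = dist.select_model(
            self.ics_values, self.group, bounds=(0.0, self.max_ics),
            families=families,
        )
        hs = inf.HypothesisSet(
            group=self.group,
            fits=selection.fits,
            max_ics=self.max_ics,
            priors=self.priors,
        )
        return KinshipResults(self, selection, hs)


class KinshipResults:
    """Fitted ICS distributions and the inference operations they support."""

    def __init__(
        self,
        model: KinshipModel,
        selection: dist.ModelSelection,
        hypothesis_set: inf.HypothesisSet,
    ) -> None:
        self.model = model
        self.selection = selection
        self.hypothesis_set = hypothesis_set

    @property
    def family(self) -> str:
        return self.selection.chosen_family

    @property
    def fits(self) -> dict[str, dist.FittedDistribution]:
        return dict(self.selection.fits)

    @property
    def params(self) -> pd.DataFrame:
        """Location/scale estimates of the chosen family per relationship."""
        rows = [
            {
                "relationship": rel,
                "family": f.family,
                "mu": f.mu,
                "sigma": f.sigma,
                "n": f.n_fit,
                "log_likelihood": f.log_likelihood,
                "aic": dist.aic(f),
            }
            for rel, f in self.selection.fits.items()
        ]
        return pd.DataFrame(rows).set_index("relationship")

    def summary(self) -> str:
        """Human-readable fit report (group AICs and chosen-family params)."""
        lines = [
            f"ICS kinship model — group {self.model.group}",
            f"  threshold Th : {self.model.threshold} cM",
            f"  max ICS      : {self.model.max_ics:.3f} cM",
            "",
            "Group AIC by candidate family:",
        ]
        for fam, a in self.selection.aic_by_family.items():
            marker = "  <- selected" if fam == self.family else ""
            lines.append(f"  {fam:<10s} {a:14.3f}{marker}")
        lines.append("")
        lines.append(f"Chosen family: {self.family}")
        lines.append(self.params.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------
    def posteriors(self, ics_value: IcsValue | float) -> inf.KinshipResult:
        return inf.posteriors(ics_value, self.hypothesis_set)

    def classify(
        self,
        ics_value: IcsValue | float,
        track: IbsTrack | None = None,
        l1_tolerance: float = 1e-3,
    ) -> inf.KinshipResult:
        """Verdict for one pair; L-group pairs are screened for L-1 first."""
        if self.model.group == "L" and track is not None:
            if inf.l1_precheck(track, tolerance=l1_tolerance):
                x = ics_value.value if isinstance(ics_value, IcsValue) else ics_value
                return inf.KinshipResult(
                    ics=ics_value,
                    log_densities={},
                    posteriors={"L-1": 1.0},
                    best_hypothesis="L-1",
                    predicate="practically proven",
                )
        return inf.posteriors(ics_value, self.hypothesis_set)

    def likelihood_ratio(
        self, ics_value: float, h1: str, h2: str = "UN"
    ) -> inf.LikelihoodRatio:
        fits = self.selection.fits
        return inf.likelihood_ratio(ics_value, fits[h1], fits[h2])

    def predicate_ranges(self, target: str, grid_step: float = 0.1):
        return inf.predicate_ranges(self.hypothesis_set, target, grid_step)

    def predicate_mass(
        self, target: str, threshold: float, grid_step: float = 0.1
    ) -> float:
        return inf.predicate_mass(self.hypothesis_set, target, threshold, grid_step)

    def predicate_table(self, grid_step: float = 0.1) -> pd.DataFrame:
        """Distribution mass per relationship at each reporting level."""
        rows = {}
        for rel in self.hypothesis_set.labels:
            rows[rel] = {
                f">={t}": self.predicate_mass(rel, t, grid_step)
                for t in inf.PREDICATE_THRESHOLDS
            }
        return pd.DataFrame(rows).T

    def z_test(self, observed: Sequence[float], relationship: str) -> dist.ZTestResult:
        return dist.z_test(observed, self.selection.fits[relationship])

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize the fitted model set as JSON (the calibration contract)."""
        payload = {
            "group": self.model.group,
            "threshold": self.model.threshold,
            "max_ics": self.model.max_ics,
            "family": self.family,
            "aic_by_family": self.selection.aic_by_family,
            "models": [
                dist.serialize_fit(f) for f in self.selection.fits.values()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def load_results(path: str | Path) -> KinshipResults:
    """Rehydrate a saved model set into a usable :class:`KinshipResults`.

    The rehydrated object supports all inference operations; the raw
    calibration ICS values are not stored, so refitting is not possible.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    fits = {
        obj["relationship"]: dist.deserialize_fit(obj) for obj in payload["models"]
    }
    model = KinshipModel.__new__(KinshipModel)
    model.ics_values = {}
    model.group = payload["group"]
    model.max_ics = float(payload["max_ics"])
    model.threshold = payload.get("threshold")
    model.priors = None
    selection = dist.ModelSelection(
        group=payload["group"],
        aic_by_family=payload.get("aic_by_family", {}),
        fits_by_family={payload["family"]: fits},
        chosen_family=payload["family"],
    )
    hs = inf.HypothesisSet(
        group=payload["group"], fits=fits, max_ics=float(payload["max_ics"])
    )
    return KinshipResults(model, selection, hs)
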