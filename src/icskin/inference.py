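"""Probabilistic kinship evaluation from an ICS value.

Given per-relationship fitted ICS densities f(ICS|H), this module computes
likelihood ratios f(ICS|H1)/f(ICS|H2), Bayesian posterior probabilities
over a hypothesis set (flat priors by default), Hummel-predicate verdicts,
and two distribution-level summaries: the ICS ranges mapped to each
predicate and the probability mass of a relationship's own distribution
that achieves a given posterior level.

All density arithmetic is done in log space: with ~10^5 SNP panels the
likelihood ratios of close relatives against unrelated pairs reach 10^90.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .distributions import FittedDistribution
from .ibs import IbsTrack, IcsValue

#: Hummel's predicates: verbal verdicts for posterior-probability bands.
PREDICATE_BANDS: tuple[tuple[str, float], ...] = (
    ("practically proven", 0.998),
    ("highly likely", 0.99),
    ("very likely", 0.95),
    ("likely", 0.90),
    ("undetermined", 0.0),
)

#: The four reporting levels conventionally tabulated.
PREDICATE_THRESHOLDS: tuple[float, ...] = (0.998, 0.99, 0.95, 0.90)


class InferenceError(ValueError):
    """The hypothesis set cannot evaluate the supplied ICS value."""


def predicate(posterior: float) -> str:
    """Map a posterior probability to its Hummel predicate."""
    if not 0.0 <= posterior <= 1.0 + 1e-12:
        raise ValueError("posterior must lie in [0, 1]")
    for name, lo in PREDICATE_BANDS:
        if posterior >= lo:
            return name
    return "undetermined"


@dataclass(frozen=True)
class HypothesisSet:
    """Competing relationship hypotheses with densities and priors.

    For collateral analysis the set is {C-1..C-5, UN}; for lineal analysis
    {L-2, L-3, UN}, with parent–child (L-1) handled by the deterministic
    pre-check :func:`l1_precheck` since its error-free ICS is a point mass
    at the maximum.  ``max_ics`` bounds the ICS domain (total map length).
    """

    group: str
    fits: Mapping[str, FittedDistribution]
    max_ics: float
    priors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.fits) < 1:
            raise InferenceError("empty hypothesis set")
        if self.priors is not None:
            if set(self.priors) != set(self.fits):
                raise InferenceError("priors must cover exactly the hypotheses")
            total = sum(self.priors.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise InferenceError(f"priors sum to {total}, not 1")
            if any(p <= 0 for p in self.priors.values()):
                raise InferenceError("priors must be > 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.fits)

    def log_priors(self) -> np.ndarray:
        if self.priors is None:
            return np.full(len(self.fits), -math.log(len(self.fits)))
        return np.log([self.priors[l] for l in self.labels])


@dataclass(frozen=True)
class LikelihoodRatio:
    """LR = f(ICS|H1) / f(ICS|H2), kept as log10 alongside the linear value."""

    log10: float
    value: float
    infinite: bool = False


@dataclass(frozen=True)
class KinshipResult:
    """Full probabilistic evaluation of one ICS value."""

    ics: IcsValue | float
    log_densities: dict[str, float]
    posteriors: dict[str, float]
    best_hypothesis: str
    predicate: str
    log10_lr_vs_un: dict[str, float] | None = None


def likelihood_ratio(
    ics_value: float, h1: FittedDistribution, h2: FittedDistribution
) -> LikelihoodRatio:
    """Eq-style density ratio of one ICS value under two hypotheses."""
    l1 = float(h1.logpdf(ics_value))
    l2 = float(h2.logpdf(ics_value))
    if l1 == -math.inf and l2 == -math.inf:
        raise InferenceError(
            f"both densities are 0 at ICS={ics_value}; the LR is undefined"
        )
    if l2 == -math.inf:
        return LikelihoodRatio(log10=math.inf, value=math.inf, infinite=True)
    log10 = (l1 - l2) / math.log(10.0)
    try:
        value = 10.0 ** log10
    except OverflowError:
        value = math.inf
    return LikelihoodRatio(log10=log10, value=value, infinite=not math.isfinite(value))


def _log_posteriors(x: float | np.ndarray, hs: HypothesisSet) -> np.ndarray:
    """Log posteriors, shape (n_hyp,) or (n_hyp, n_x)."""
    logd = np.stack([np.atleast_1d(f.logpdf(x)) for f in hs.fits.values()])
    logw = logd + hs.log_priors()[:, None]
    norm = logsumexp(logw, axis=0)
    return logw - norm


def posteriors(ics_value: IcsValue | float, hs: HypothesisSet) -> KinshipResult:
    """Normalized posterior probabilities Pr(H_i | ICS) with verdict.

    With flat priors this reduces to f(ICS|H_i) / sum_j f(ICS|H_j); the
    normalisation is carried out on log densities with max subtraction.
    """
    x = ics_value.value if isinstance(ics_value, IcsValue) else float(ics_value)
    if len(hs.fits) < 2:
        raise InferenceError("posterior evaluation needs at least 2 hypotheses")
    logd = np.array([float(f.logpdf(x)) for f in hs.fits.values()])
    if np.all(np.isneginf(logd)) and x == 0.0:
        # ICS of exactly 0 with (0, inf)-supported families (lognormal):
        # take the limit from above, which assigns the mass to the
        # hypothesis with the heaviest lower tail (in practice UN)
        logd = np.array(
            [float(f.logpdf(hs.max_ics * 1e-12)) for f in hs.fits.values()]
        )
    if np.all(np.isneginf(logd)):
        raise InferenceError(
            f"all hypothesis densities are 0 at ICS={x}; check the L-1 "
            "pre-check or whether the value lies outside the ICS domain"
        )
    logw = logd + hs.log_priors()
    post = np.exp(logw - logsumexp(logw))
    post = post / post.sum()
    labels = hs.labels
    post_map = dict(zip(labels, map(float, post)))
    best = labels[int(np.argmax(post))]
    lr_map = None
    if "UN" in hs.fits:
        ln10 = math.log(10.0)
        l_un = float(hs.fits["UN"].logpdf(x))
        lr_map = {
            label: (float(f.logpdf(x)) - l_un) / ln10
            for label, f in hs.fits.items()
            if label != "UN"
        }
    return KinshipResult(
        ics=ics_value,
        log_densities=dict(zip(labels, map(float, logd))),
        posteriors=post_map,
        best_hypothesis=best,
        predicate=predicate(post_map[best]),
        log10_lr_vs_un=lr_map,
    )


def l1_precheck(track: IbsTrack, tolerance: float = 1e-3) -> bool:
    """Parent–child screen: nearly all called loci share >= 1 allele.

    A true parent–child pair shares at least one allele at every locus;
    the tolerance (default 0.1%) absorbs array typing errors.  When true,
    the verdict is L-1 and the density machinery is bypassed.
    """
    if len(track) == 0:
        raise InferenceError("empty IBS track")
    frac = float(np.mean(track.states >= 1))
    return frac > 1.0 - tolerance


def _band_of(p: float) -> int:
    for i, (_, lo) in enumerate(PREDICATE_BANDS):
        if p >= lo:
            return i
    return len(PREDICATE_BANDS) - 1


def predicate_ranges(
    hs: HypothesisSet,
    target: str,
    grid_step: float = 0.1,
) -> list[tuple[str, list[tuple[float, float]]]]:
    """ICS intervals of each Hummel predicate for ``target``'s posterior.

    The posterior of ``target`` is scanned over (0, max_ics] at
    ``grid_step`` resolution and consecutive grid points in the same band
    are merged into intervals.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if target not in hs.fits:
        raise InferenceError(f"unknown target {target!r}")
    xs = np.arange(grid_step, hs.max_ics + grid_step / 2, grid_step)
    if len(hs.fits) == 1:
        return [("practically proven", [(float(xs[0]), float(xs[-1]))])]
    t_idx = list(hs.labels).index(target)
    post = np.exp(_log_posteriors(xs, hs))[t_idx]
    bands = np.array([_band_of(float(p)) for p in post])
    intervals: dict[int, list[tuple[float, float]]] = {}
    start = 0
    for i in range(1, len(xs) + 1):
        if i == len(xs) or bands[i] != bands[start]:
            intervals.setdefault(int(bands[start]), []).append(
                (float(xs[start]), float(xs[i - 1]))
            )
            start = i
    return [
        (PREDICATE_BANDS[b][0], intervals[b]) for b in sorted(intervals)
    ]


def _qualifying_intervals(
    hs: HypothesisSet, target: str, threshold: float, grid_step: float
) -> list[tuple[float, float]]:
    """Maximal ICS intervals where Pr(target|ICS) >= threshold.

    Grid scan plus root refinement of each boundary crossing, so interval
    endpoints are accurate far beyond the grid step.  The scan domain is
    extended past max_ics when the target's fitted density carries mass
    there (a fitted lognormal is not hard-bounded by the map length).
    """
    upper = float(max(hs.max_ics, hs.fits[target].frozen.ppf(1.0 - 1e-9)))
    xs = np.arange(grid_step, upper + grid_step / 2, grid_step)
    t_idx = list(hs.labels).index(target)

    def post_at(x) -> np.ndarray:
        return np.exp(_log_posteriors(x, hs))[t_idx]

    mask = post_at(xs) >= threshold
    if not mask.any():
        return []

    def crossing(inside: float, outside: float) -> float:
        f = lambda x: float(post_at(float(x))[0]) - threshold
        a, b = min(inside, outside), max(inside, outside)
        try:
            return float(optimize.brentq(f, a, b, xtol=1e-10))
        except ValueError:  # no sign change at the grid endpoints
            return inside

    intervals: list[tuple[float, float]] = []
    idx = np.flatnonzero(mask)
    run_start = idx[0]
    prev = idx[0]
    runs: list[tuple[int, int]] = []
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    for s, e in runs:
        lo = 0.0 if s == 0 else crossing(xs[s], xs[s - 1])
        hi = upper if e == len(xs) - 1 else crossing(xs[e], xs[e + 1])
        if hi < lo:
            lo, hi = hi, lo
        intervals.append((lo, hi))
    return intervals


def predicate_mass(
    hs: HypothesisSet,
    target: str,
    threshold: float,
    grid_step: float = 0.1,
) -> float:
    """Mass of ``target``'s own distribution with posterior >= threshold.

    This is the "percentage of the distribution" achieving a posterior
    level: the integral of f(ICS|target) over the ICS region where
    Pr(target|ICS) >= threshold, evaluated exactly via CDF differences on
    root-refined region boundaries.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if target not in hs.fits:
        raise InferenceError(f"unknown target {target!r}")
    if len(hs.fits) == 1:
        return 1.0
    fit = hs.fits[target]
    mass = 0.0
    for lo, hi in _qualifying_intervals(hs, target, threshold, grid_step):
        mass += float(fit.cdf(hi) - fit.cdf(lo))
    return mass
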