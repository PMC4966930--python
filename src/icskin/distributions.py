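"""Per-relationship ICS distribution models: MLE fits, AIC selection, z test.

Three two-parameter families are candidates for the ICS distribution of a
relationship: a normal, a normal truncated to [0, max ICS], and a
log-normal (mu, sigma on the log scale).  Each relationship is fitted by
maximum likelihood with its own (mu, sigma); families are compared per
group (collateral or lineal) by summing AIC = 2k - 2 log ML over the
group's relationships, and the family with the lowest group AIC is adopted.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = ("normal", "truncnorm", "lognormal")

#: Free parameters per fitted relationship (mu, sigma) in every family.
K_PARAMS = 2

#: Deterministic preference when group AICs tie to within this tolerance.
_TIE_TOL = 1e-6
_TIE_ORDER = {"lognormal": 0, "truncnorm": 1, "normal": 2}


class FitError(RuntimeError):
    """Maximum-likelihood fitting failed or the data are inadmissible."""


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted ICS density f(ICS | relationship) in one family.

    ``mu``/``sigma`` are the location and scale: natural scale for normal
    and truncnorm, log scale for lognormal.  ``lower``/``upper`` bound the
    truncnorm support (0 to the maximum ICS).
    """

    relationship: str
    family: str
    mu: float
    sigma: float
    n_fit: int
    log_likelihood: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise FitError(f"sigma must be > 0, got {self.sigma}")
        if self.family not in FAMILIES:
            raise FitError(f"unknown family {self.family!r}")
        if self.family == "truncnorm" and (self.lower is None or self.upper is None):
            raise FitError("truncnorm requires lower and upper bounds")

    @property
    def frozen(self):
        """The scipy frozen distribution carrying this fit."""
        if self.family == "normal":
            return stats.norm(loc=self.mu, scale=self.sigma)
        if self.family == "lognormal":
            return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def pdf(self, x) -> np.ndarray | float:
        return self.frozen.pdf(x)

    def logpdf(self, x) -> np.ndarray | float:
        return self.frozen.logpdf(x)

    def cdf(self, x) -> np.ndarray | float:
        return self.frozen.cdf(x)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.frozen.rvs(size=size, random_state=rng)


def pdf(fit: FittedDistribution, x) -> np.ndarray | float:
    """Density f(ICS | H) at x (module-level convenience)."""
    return fit.pdf(x)


def _normal_mle(values: np.ndarray) -> tuple[float, float, float]:
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma <= 0:
        raise FitError("degenerate sample: zero variance")
    ll = float(stats.norm(mu, sigma).logpdf(values).sum())
    return mu, sigma, ll


def fit_mle(
    values: Sequence[float],
    family: str,
    bounds: tuple[float, float] | None = None,
    relationship: str = "",
    max_zero_fraction: float = 0.05,
) -> FittedDistribution:
    """Fit one family to ICS values by maximum likelihood.

    Normal and lognormal use the closed-form MLE (lognormal = normal MLE of
    the log values); truncnorm maximises the truncated likelihood
    numerically from the untruncated start.  Lognormal fitting drops exact
    zeros (support is (0, inf)) with a logged count and refuses if they
    exceed ``max_zero_fraction`` of the sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise FitError(f"need at least 10 values to fit, got {x.size}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "normal":
        mu, sigma, ll = _normal_mle(x)
        return FittedDistribution(relationship, "normal", mu, sigma, x.size, ll)
    if family == "lognormal":
        if np.any(x < 0):
            raise FitError(f"{int((x < 0).sum())} negative values under lognormal")
        zeros = int((x == 0).sum())
        if zeros:
            if zeros > max_zero_fraction * x.size:
                raise FitError(
                    f"{zeros}/{x.size} zero ICS values: too many for a "
                    "lognormal fit"
                )
            logger.info(
                "excluding %d zero ICS values from lognormal fit of %s",
                zeros, relationship or "(unnamed)",
            )
            x = x[x > 0]
        mu, sigma, _ = _normal_mle(np.log(x))
        ll = float(
            stats.lognorm(s=sigma, scale=math.exp(mu)).logpdf(x).sum()
        )
        return FittedDistribution(relationship, "lognormal", mu, sigma, x.size, ll)
    # truncated normal
    if bounds is None:
        raise ValueError("truncnorm requires bounds=(lower, upper)")
    lower, upper = float(bounds[0]), float(bounds[1])
    if np.any(x < lower) or np.any(x > upper):
        raise FitError("values outside the truncation bounds")
    mu0, sigma0, _ = _normal_mle(x)
    n = x.size

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # negative log-likelihood over (mu, log sigma) with analytic gradient
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        b = (upper - mu) / sigma
        if b >= 0:
            z = float(stats.norm.cdf(b) - stats.norm.cdf(a))
        else:  # reflect for numerical stability deep in the lower tail
            z = float(stats.norm.cdf(-a) - stats.norm.cdf(-b))
        z = max(z, 1e-300)
        log_z = math.log(z)
        resid = (x - mu) / sigma
        nll = (
            n * (math.log(sigma) + 0.5 * math.log(2 * math.pi))
            + 0.5 * float((resid ** 2).sum())
            + n * log_z
        )
        phi_a = stats.norm.pdf(a)
        phi_b = stats.norm.pdf(b)
        a_phi_a = 0.0 if not math.isfinite(a) else a * phi_a
        b_phi_b = 0.0 if not math.isfinite(b) else b * phi_b
        d_mu = -float(resid.sum()) / sigma + n * (phi_a - phi_b) / (sigma * z)
        d_sigma = (
            n / sigma
            - float((resid ** 2).sum()) / sigma
            + n * (a_phi_a - b_phi_b) / (sigma * z)
        )
        return nll, np.array([d_mu, sigma * d_sigma])

    res = optimize.minimize(
        nll_grad,
        x0=np.array([mu0, math.log(sigma0)]),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success or not np.isfinite(res.fun):
        raise FitError(f"truncnorm optimisation failed: {res.message}")
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return FittedDistribution(
        relationship, "truncnorm", mu, sigma, x.size, -float(res.fun),
        lower=lower, upper=upper,
    )


def aic(fit: FittedDistribution) -> float:
    """Akaike information criterion 2k - 2 log ML with k = 2."""
    return 2.0 * K_PARAMS - 2.0 * fit.log_likelihood


@dataclass(frozen=True)
class ModelSelection:
    """Group-level AIC comparison of the three candidate families."""

    group: str
    aic_by_family: dict[str, float]
    fits_by_family: dict[str, dict[str, FittedDistribution]]
    chosen_family: str

    @property
    def fits(self) -> dict[str, FittedDistribution]:
        """Per-relationship fits of the chosen family."""
        return self.fits_by_family[self.chosen_family]


def select_model(
    values_by_relationship: Mapping[str, Sequence[float]],
    group: str,
    bounds: tuple[float, float],
    families: Sequence[str] = FAMILIES,
) -> ModelSelection:
    """Fit every family to every relationship; adopt the lowest group AIC.

    The group AIC of a family is the sum of per-relationship AICs (each
    relationship keeps its own mu, sigma).  Near-exact ties — normal and
    truncnorm coincide when the data sit far from the bounds — are resolved
    deterministically in the order lognormal, truncnorm, normal.

    A family whose support excludes part of the data (lognormal when a
    class contains many exact-zero ICS values) has maximum likelihood zero;
    it receives an infinite group AIC and drops out of the comparison
    rather than aborting it.
    """
    fits_by_family: dict[str, dict[str, FittedDistribution]] = {}
    aic_by_family: dict[str, float] = {}
    for family in families:
        try:
            fits = {
                rel: fit_mle(vals, family, bounds=bounds, relationship=rel)
                for rel, vals in values_by_relationship.items()
            }
        except FitError as exc:
            logger.info("family %s disqualified for group %s: %s",
                        family, group, exc)
            aic_by_family[family] = math.inf
            continue
        fits_by_family[family] = fits
        aic_by_family[family] = float(sum(aic(f) for f in fits.values()))
    if not fits_by_family:
        raise FitError(
            f"no candidate family could be fitted to group {group}"
        )
    best_aic = min(aic_by_family.values())
    tied = [f for f, a in aic_by_family.items() if a - best_aic < _TIE_TOL]
    if len(tied) > 1:
        logger.info("AIC tie between %s; preferring %s",
                    tied, min(tied, key=_TIE_ORDER.__getitem__))
    chosen = min(tied, key=_TIE_ORDER.__getitem__)
    return ModelSelection(
        group=group,
        aic_by_family=aic_by_family,
        fits_by_family=fits_by_family,
        chosen_family=chosen,
    )


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p_value: float
    n: int


def z_test(observed: Sequence[float], fit: FittedDistribution) -> ZTestResult:
    """Two-sided z test of observed ICS values against a fitted distribution.

    The fitted distribution is the null: on its natural scale (log scale
    for lognormal) z = (sample mean - mu) / (sigma / sqrt(n)).  Used to
    check that ICS values from held-out real pairs are consistent with the
    simulation-calibrated distribution.
    """
    x = np.asarray(observed, dtype=float)
    if x.size == 0:
        raise ValueError("z test needs at least one observation")
    if fit.family == "lognormal":
        if np.any(x <= 0):
            raise ValueError("lognormal z test requires positive observations")
        x = np.log(x)
    z = float((x.mean() - fit.mu) / (fit.sigma / math.sqrt(x.size)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ZTestResult(z=z, p_value=p, n=int(x.size))


def serialize_fit(fit: FittedDistribution) -> dict:
    return {
        "relationship": fit.relationship,
        "family": fit.family,
        "mu": fit.mu,
        "sigma": fit.sigma,
        "lower": fit.lower,
        "upper": fit.upper,
        "n_fit": fit.n_fit,
        "log_likelihood": fit.log_likelihood,
    }


def deserialize_fit(obj: Mapping) -> FittedDistribution:
    return FittedDistribution(
        relationship=obj["relationship"],
        family=obj["family"],
        mu=float(obj["mu"]),
        sigma=float(obj["sigma"]),
        n_fit=int(obj.get("n_fit", 0)),
        log_likelihood=float(obj.get("log_likelihood", math.nan)),
        lower=None if obj.get("lower") is None else float(obj["lower"]),
        upper=None if obj.get("upper") is None else float(obj["upper"]),
    )
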