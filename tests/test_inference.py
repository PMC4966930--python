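"""Likelihood ratios, posteriors, Hummel predicates, ranges and masses."""
import math

import numpy as np
import pytest

from icskin.distributions import FittedDistribution
from icskin.ibs import IbsTrack
from icskin.inference import (
    PREDICATE_THRESHOLDS,
    HypothesisSet,
    InferenceError,
    l1_precheck,
    likelihood_ratio,
    posteriors,
    predicate,
    predicate_mass,
    predicate_ranges,
)

from conftest import make_map


def lognorm_fit(rel, mu, sigma):
    return FittedDistribution(rel, "lognormal", mu=mu, sigma=sigma,
                              n_fit=100, log_likelihood=0.0)


@pytest.fixture()
def two_separated():
    """Two well-separated lognormals plus their hypothesis set."""
    fits = {"C-1": lognorm_fit("C-1", 8.0, 0.1), "UN": lognorm_fit("UN", 5.0, 0.3)}
    return HypothesisSet(group="C", fits=fits, max_ics=3662.5)


@pytest.fixture()
def six_hypotheses():
    mus = {"C-1": 8.1, "C-2": 7.7, "C-3": 7.1, "C-4": 6.7, "C-5": 6.4, "UN": 5.8}
    fits = {rel: lognorm_fit(rel, mu, 0.12) for rel, mu in mus.items()}
    return HypothesisSet(group="C", fits=fits, max_ics=3662.5)


class TestPredicate:
    @pytest.mark.parametrize(
        "p, name",
        [
            (0.999, "practically proven"),
            (0.998, "practically proven"),
            (0.995, "highly likely"),
            (0.96, "very likely"),
            (0.92, "likely"),
            (0.1, "undetermined"),
            (0.0, "undetermined"),
        ],
    )
    def test_band_mapping(self, p, name):
        assert predicate(p) == name

    def test_bands_partition_unit_interval(self):
        grid = np.linspace(0, 1, 10001)
        names = {predicate(float(p)) for p in grid}
        assert names == {"practically proven", "highly likely", "very likely",
                         "likely", "undetermined"}


class TestLikelihoodRatio:
    def test_identity(self):
        f = lognorm_fit("X", 6.0, 0.2)
        lr = likelihood_ratio(500.0, f, f)
        assert lr.value == pytest.approx(1.0)
        assert lr.log10 == pytest.approx(0.0)

    def test_reciprocity(self, two_separated):
        f1 = two_separated.fits["C-1"]
        f2 = two_separated.fits["UN"]
        a = likelihood_ratio(800.0, f1, f2)
        b = likelihood_ratio(800.0, f2, f1)
        assert a.log10 == pytest.approx(-b.log10, abs=1e-9)

    def test_closed_form_lognormal_ratio(self):
        f1 = lognorm_fit("A", 7.0, 0.2)
        f2 = lognorm_fit("B", 6.0, 0.5)
        x = 900.0

        def logpdf(mu, s):
            return (-math.log(x * s * math.sqrt(2 * math.pi))
                    - (math.log(x) - mu) ** 2 / (2 * s * s))

        expected_log10 = (logpdf(7.0, 0.2) - logpdf(6.0, 0.5)) / math.log(10)
        lr = likelihood_ratio(x, f1, f2)
        assert lr.log10 == pytest.approx(expected_log10, rel=1e-12)

    def test_zero_denominator_flags_infinite(self):
        f1 = FittedDistribution("A", "normal", 0.0, 1.0, 10, 0.0)
        f2 = lognorm_fit("B", 5.0, 0.2)  # density 0 at x = 0
        lr = likelihood_ratio(0.0, f1, f2)
        assert lr.infinite and lr.value == math.inf

    def test_both_zero_is_an_error(self):
        f1 = lognorm_fit("A", 5.0, 0.2)
        f2 = lognorm_fit("B", 6.0, 0.2)
        with pytest.raises(InferenceError, match="undefined"):
            likelihood_ratio(0.0, f1, f2)


class TestPosteriors:
    def test_equal_densities_split_evenly(self):
        f = {"A": lognorm_fit("A", 6.0, 0.2), "B": lognorm_fit("B", 6.0, 0.2)}
        hs = HypothesisSet(group="C", fits=f, max_ics=1000.0)
        res = posteriors(400.0, hs)
        assert res.posteriors["A"] == pytest.approx(0.5, abs=1e-12)
        assert res.posteriors["B"] == pytest.approx(0.5, abs=1e-12)

    def test_flat_prior_form_equals_general_form(self, six_hypotheses):
        # Pr = f_i Pr_i / sum f_j Pr_j reduces to f_i / sum f_j for flat priors
        flat = HypothesisSet(
            group="C", fits=six_hypotheses.fits, max_ics=3662.5,
            priors={rel: 1 / 6 for rel in six_hypotheses.fits},
        )
        for x in (300.0, 900.0, 2500.0):
            a = posteriors(x, six_hypotheses).posteriors
            b = posteriors(x, flat).posteriors
            for rel in a:
                assert a[rel] == pytest.approx(b[rel], abs=1e-12)

    def test_matches_brute_force_with_arbitrary_priors(self, six_hypotheses):
        priors = {rel: p for rel, p in zip(
            six_hypotheses.fits, (0.4, 0.2, 0.15, 0.12, 0.08, 0.05))}
        hs = HypothesisSet(group="C", fits=six_hypotheses.fits,
                           max_ics=3662.5, priors=priors)
        x = 1200.0
        res = posteriors(x, hs)
        dens = {rel: float(f.pdf(x)) for rel, f in hs.fits.items()}
        norm = sum(dens[rel] * priors[rel] for rel in dens)
        for rel in dens:
            assert res.posteriors[rel] == pytest.approx(
                dens[rel] * priors[rel] / norm, abs=1e-12)

    def test_normalization(self, six_hypotheses):
        for x in np.geomspace(50, 3500, 25):
            res = posteriors(float(x), six_hypotheses)
            assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    def test_two_hypothesis_posterior_equals_lr_transform(self, two_separated):
        x = 1500.0
        res = posteriors(x, two_separated)
        lr = likelihood_ratio(x, two_separated.fits["C-1"],
                              two_separated.fits["UN"])
        assert res.posteriors["C-1"] == pytest.approx(
            lr.value / (lr.value + 1.0), rel=1e-9)

    def test_zero_ics_resolved_in_the_limit(self, two_separated):
        # all lognormal densities vanish at exactly 0; the limit from above
        # assigns the pair to the heavier-lower-tail hypothesis (UN)
        res = posteriors(0.0, two_separated)
        assert res.best_hypothesis == "UN"
        assert res.posteriors["UN"] == pytest.approx(1.0, abs=1e-9)

    def test_out_of_domain_densities_error(self, two_separated):
        with pytest.raises(InferenceError, match="all hypothesis densities"):
            posteriors(-1.0, two_separated)

    def test_bad_priors_rejected(self, two_separated):
        with pytest.raises(InferenceError):
            HypothesisSet(group="C", fits=two_separated.fits, max_ics=3662.5,
                          priors={"C-1": 0.7, "UN": 0.2})


class TestL1Precheck:
    def test_full_sharing_true(self):
        gmap = make_map({"1": list(map(float, range(100)))})
        track = IbsTrack(gmap, np.arange(100), np.full(100, 1, dtype=np.int8))
        assert l1_precheck(track) is True

    def test_opposite_homozygotes_false(self):
        gmap = make_map({"1": list(map(float, range(100)))})
        states = np.full(100, 2, dtype=np.int8)
        states[[10, 50, 90]] = 0
        track = IbsTrack(gmap, np.arange(100), states)
        assert l1_precheck(track) is False

    def test_small_error_rate_tolerated(self):
        gmap = make_map({"1": list(map(float, range(10000)))})
        states = np.full(10000, 2, dtype=np.int8)
        states[:5] = 0  # 0.05% typing errors
        track = IbsTrack(gmap, np.arange(10000), states)
        assert l1_precheck(track, tolerance=1e-3) is True

    def test_empty_track_error(self):
        gmap = make_map({"1": [0.0]})
        track = IbsTrack(gmap, np.arange(0), np.array([], dtype=np.int8))
        with pytest.raises(InferenceError):
            l1_precheck(track)


class TestPredicateRanges:
    def test_single_hypothesis_whole_domain_proven(self):
        hs = HypothesisSet(group="C", fits={"UN": lognorm_fit("UN", 5.0, 0.3)},
                           max_ics=1000.0)
        ranges = predicate_ranges(hs, "UN", grid_step=1.0)
        assert len(ranges) == 1
        assert ranges[0][0] == "practically proven"

    def test_separated_target_bulk_is_proven(self, two_separated):
        ranges = dict(predicate_ranges(two_separated, "C-1", grid_step=1.0))
        proven = ranges["practically proven"]
        fit = two_separated.fits["C-1"]
        mass = sum(float(fit.cdf(b) - fit.cdf(a)) for a, b in proven)
        assert mass > 0.95

    def test_intervals_consistent_with_midpoint_posteriors(self, six_hypotheses):
        target = "C-3"
        t_idx = list(six_hypotheses.labels).index(target)
        for band, intervals in predicate_ranges(six_hypotheses, target,
                                                grid_step=2.0):
            for a, b in intervals:
                mid = 0.5 * (a + b)
                res = posteriors(mid, six_hypotheses)
                assert predicate(res.posteriors[target]) == band

    def test_stable_under_grid_refinement(self, two_separated):
        coarse = dict(predicate_ranges(two_separated, "C-1", grid_step=2.0))
        fine = dict(predicate_ranges(two_separated, "C-1", grid_step=1.0))
        for band in coarse:
            assert band in fine
            for (a1, b1), (a2, b2) in zip(coarse[band], fine[band]):
                assert abs(a1 - a2) <= 2.0 and abs(b1 - b2) <= 2.0


class TestPredicateMass:
    def test_single_hypothesis_mass_one(self):
        hs = HypothesisSet(group="C", fits={"UN": lognorm_fit("UN", 5.0, 0.3)},
                           max_ics=1000.0)
        assert predicate_mass(hs, "UN", 0.998) == 1.0

    def test_monotone_in_threshold(self, six_hypotheses):
        for rel in six_hypotheses.labels:
            masses = [predicate_mass(six_hypotheses, rel, t, grid_step=2.0)
                      for t in PREDICATE_THRESHOLDS]
            assert masses == sorted(masses)

    def test_matches_monte_carlo(self, two_separated):
        rng = np.random.default_rng(21)
        fit = two_separated.fits["C-1"]
        draws = fit.rvs(200_000, rng)
        dens = {rel: f.pdf(draws) for rel, f in two_separated.fits.items()}
        post = dens["C-1"] / (dens["C-1"] + dens["UN"])
        for t in (0.90, 0.998):
            mc = float(np.mean(post >= t))
            quad = predicate_mass(two_separated, "C-1", t, grid_step=1.0)
            assert quad == pytest.approx(mc, abs=0.005)

    def test_bad_threshold(self, two_separated):
        with pytest.raises(ValueError):
            predicate_mass(two_separated, "C-1", 0.0)
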