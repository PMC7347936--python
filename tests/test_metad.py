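"""Meta-d' likelihood, MLE and Bayesian fits, and efficiency."""

import numpy as np
import pytest
from scipy.stats import norm

from metaface import (
    ContractError,
    DataError,
    EstimationError,
    MCMCConfig,
    RatingCounts,
    SDTEstimate,
    dprime_type1,
    efficiency,
    fit_metad_bayes,
    fit_metad_mle,
    type2_likelihood,
)
from tests.conftest import ideal_observer_counts

ANCHOR = SDTEstimate(dprime=2.0, criterion=0.2, hit_rate=0.8, fa_rate=0.2,
                     adjustment_applied=False)


def _criteria(meta_c, gaps=(0.5, 0.5, 0.5)):
    lower = meta_c - np.cumsum(gaps)
    upper = meta_c + np.cumsum(gaps)
    return np.stack([lower, upper])


class TestType2Likelihood:
    def test_matches_hand_oracle(self):
        # independent re-derivation: sum count * log(p), p = normal-CDF areas
        # between adjacent criteria normalized by the response-region mass
        counts = RatingCounts(np.array(
            [[[3, 2, 1, 0], [1, 1, 1, 1]], [[1, 0, 1, 2], [0, 1, 2, 5]]]))
        meta_d = 1.4
        meta_c = ANCHOR.criterion * meta_d / ANCHOR.dprime
        criteria = _criteria(meta_c, gaps=(0.4, 0.5, 0.6))
        got = type2_likelihood(counts, meta_d, criteria, ANCHOR)

        cut = np.array([-np.inf, *criteria[0][::-1], meta_c, *criteria[1], np.inf])
        expected = 0.0
        for s, mu in enumerate((-meta_d / 2, meta_d / 2)):
            areas = np.diff(norm.cdf(cut, loc=mu))
            p_lo, p_hi = areas[:4].sum(), areas[4:].sum()
            for conf in range(4):
                expected += counts.counts[s, 0, conf] * np.log(areas[3 - conf] / p_lo)
                expected += counts.counts[s, 1, conf] * np.log(areas[4 + conf] / p_hi)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_degenerate_saturation_approaches_zero(self):
        # all mass in the outermost confidence cell per response, criteria
        # pushed toward meta_c: each trial probability tends to 1
        counts = RatingCounts(np.array(
            [[[0, 0, 0, 30], [0, 0, 0, 10]], [[0, 0, 0, 10], [0, 0, 0, 30]]]))
        criteria = _criteria(ANCHOR.criterion * 1.0, gaps=(1e-7, 1e-7, 1e-7))
        ll = type2_likelihood(counts, 2.0, criteria, ANCHOR)
        assert -1e-3 < ll <= 0.0

    def test_ordering_violation_rejected(self):
        meta_c = ANCHOR.criterion
        bad = _criteria(meta_c)
        bad[1] = bad[1][::-1]
        with pytest.raises(DataError):
            type2_likelihood(RatingCounts(np.ones((2, 2, 4), dtype=int)),
                             2.0, bad, ANCHOR)

    def test_zero_probability_region_gives_minus_inf(self):
        counts = RatingCounts(np.array(
            [[[0, 0, 0, 5], [0, 0, 0, 0]], [[0, 0, 0, 0], [0, 0, 0, 5]]]))
        # huge meta-d' makes the wrong-side response region vanish while an
        # extreme-confidence error cell still holds counts
        counts2 = RatingCounts(np.array(
            [[[0, 0, 0, 5], [5, 0, 0, 0]], [[0, 0, 0, 0], [0, 0, 0, 5]]]))
        crit = _criteria(0.0, gaps=(0.5, 0.5, 0.5))
        anchor = SDTEstimate(dprime=2.0, criterion=0.0, hit_rate=0.8,
                             fa_rate=0.2, adjustment_applied=False)
        ll_ok = type2_likelihood(counts, 2.0, crit, anchor)
        assert np.isfinite(ll_ok)
        ll_far = type2_likelihood(counts2, 60.0, crit, anchor)
        assert ll_far == -np.inf


class TestFitMetaDMLE:
    def test_recovers_generative_optimum(self):
        counts = ideal_observer_counts(dprime=2.0)
        fit = fit_metad_mle(counts)
        assert fit.meta_dprime == pytest.approx(2.0, abs=0.05)
        assert fit.method == "mle"

    def test_shuffled_confidence_gives_near_zero_metad(self):
        # confidence distribution identical for every (stimulus, response)
        # cell: ratings carry no type-2 information
        cell = np.array([8, 6, 4, 2])
        counts = RatingCounts(np.tile(cell, (2, 2, 1)).astype(int) *
                              np.array([[[3], [1]], [[1], [3]]]))
        fit = fit_metad_mle(counts)
        assert abs(fit.meta_dprime) < 0.2

    def test_criteria_ordered_outward(self):
        fit = fit_metad_mle(ideal_observer_counts(dprime=1.2))
        lower, upper = fit.type2_criteria
        assert np.all(np.diff(lower) < 0) and lower[0] < fit.meta_criterion
        assert np.all(np.diff(upper) > 0) and upper[0] > fit.meta_criterion
        assert np.isfinite(fit.loglik)

    def test_insufficient_confidence_variation_rejected(self):
        counts = RatingCounts(np.array(
            [[[0, 0, 0, 10], [0, 0, 0, 4]], [[0, 0, 0, 4], [0, 0, 0, 10]]]))
        with pytest.raises(EstimationError):
            fit_metad_mle(counts)

    def test_all_correct_rejected(self):
        counts = RatingCounts(np.array(
            [[[5, 0, 0, 5], [0, 0, 0, 0]], [[0, 0, 0, 0], [5, 0, 0, 5]]]))
        with pytest.raises(EstimationError):
            fit_metad_mle(counts)


class TestFitMetaDBayes:
    def test_agrees_with_mle_on_large_counts(self):
        counts = ideal_observer_counts(dprime=1.6, n_per_class=400)
        mle = fit_metad_mle(counts)
        bayes = fit_metad_bayes(counts, mcmc=MCMCConfig(seed=11))
        assert bayes.meta_dprime == pytest.approx(mle.meta_dprime, abs=0.1)
        ps = bayes.posterior_summary
        assert ps["ci95_low"] < bayes.meta_dprime < ps["ci95_high"]
        assert ps["rhat"] < 1.05

    def test_deterministic_under_fixed_seed(self):
        counts = ideal_observer_counts(dprime=1.0, n_per_class=60)
        cfg = MCMCConfig(seed=5, n_warmup=200, n_draws=200)
        a = fit_metad_bayes(counts, mcmc=cfg)
        b = fit_metad_bayes(counts, mcmc=cfg)
        assert a.meta_dprime == b.meta_dprime
        assert a.posterior_summary == b.posterior_summary

    def test_tolerates_zero_cells_without_correction(self):
        counts = RatingCounts(np.array(
            [[[6, 3, 0, 0], [2, 1, 1, 0]], [[3, 1, 0, 0], [2, 4, 5, 2]]]))
        fit = fit_metad_bayes(counts, mcmc=MCMCConfig(seed=2, n_warmup=200,
                                                      n_draws=200))
        assert np.isfinite(fit.meta_dprime)
        assert fit.posterior_summary["n_draws"] > 0


class TestEfficiency:
    def test_ideal_observer_is_zero(self):
        counts = ideal_observer_counts(dprime=2.0)
        fit = fit_metad_mle(counts)
        anchor = dprime_type1(counts)
        assert efficiency(fit, anchor).difference == pytest.approx(0.0, abs=0.05)

    def test_exact_subtraction_in_hyper_regime(self):
        from metaface import MetaDFit

        fit = MetaDFit(meta_dprime=2.5, meta_criterion=0.0,
                       type2_criteria=np.zeros((2, 3)), loglik=-1.0, method="mle")
        anchor = SDTEstimate(dprime=1.2, criterion=0.0, hit_rate=0.8,
                             fa_rate=0.2, adjustment_applied=False)
        assert efficiency(fit, anchor).difference == pytest.approx(1.3)

    def test_second_stage_noise_drives_difference_negative(self):
        from metaface import CohortConfig, ObserverParams, simulate_subject
        from metaface import tabulate_counts
        from metaface.observer import with_uniform_meta_noise

        params = with_uniform_meta_noise(
            ObserverParams(dprime_max=3.0, c50=0.015, slope=4.0), 2.0)
        config = CohortConfig(trials_per_contrast=4000, contrasts=(0.015,),
                              site_effect=(0.0,), tasks=("orientation",))
        trials = simulate_subject(params, config, "s01", rng=21)
        cell = trials[(trials["site"] == "S1")]
        counts = tabulate_counts(cell)
        fit = fit_metad_mle(counts)
        anchor = dprime_type1(counts)
        assert efficiency(fit, anchor).difference < -0.2

    def test_provenance_mismatch_rejected(self):
        counts = ideal_observer_counts(dprime=1.5, n_per_class=200)
        anchor_a = dprime_type1(counts, label=("s01", "LPFC", "orientation", 0.015))
        anchor_b = dprime_type1(counts, label=("s02", "S1", "orientation", 0.023))
        fit = fit_metad_mle(counts, anchor=anchor_a)
        with pytest.raises(ContractError):
            efficiency(fit, anchor_b)
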