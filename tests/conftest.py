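"""Shared fixtures: analytic ideal-observer count tensors and small cohorts."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metaface import CohortConfig, ObserverParams, RatingCounts, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def ideal_observer_counts(
    dprime: float = 2.0,
    cutpoints=(-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5),
    n_per_class: int = 10_000,
) -> RatingCounts:
    """Count tensor of a metacognitively ideal observer.

    Cell probabilities are normal-CDF areas between the 2K-1 interior
    cutpoints (type-1 criterion at the center), scaled by n_per_class and
    rounded -- the generative optimum for a meta-d' fit, with meta-d' = d'.
    """
    cut = np.concatenate([[-np.inf], cutpoints, [np.inf]])
    k = (len(cutpoints) + 1) // 2
    counts = np.zeros((2, 2, k), dtype=int)
    for s, mu in enumerate((-dprime / 2.0, dprime / 2.0)):
        probs = np.diff(norm.cdf(cut, loc=mu))
        counts[s, 0] = np.round(probs[:k][::-1] * n_per_class).astype(int)
        counts[s, 1] = np.round(probs[k:] * n_per_class).astype(int)
    return RatingCounts(counts)


def random_fittable_counts(rng: np.random.Generator, n_max: int = 40) -> RatingCounts:
    """Random 2x2x4 tensor guaranteed to satisfy the meta-d' preconditions."""
    while True:
        c = rng.integers(0, n_max, size=(2, 2, 4))
        rc = RatingCounts(np.asarray(c, dtype=int))
        correct = c[0, 0].sum() + c[1, 1].sum()
        incorrect = c[0, 1].sum() + c[1, 0].sum()
        occupied = np.count_nonzero(c.sum(axis=(0, 1)))
        both_classes = c[0].sum() > 0 and c[1].sum() > 0
        if correct > 0 and incorrect > 0 and occupied >= 2 and both_classes:
            return rc


def trials_from_outcomes(correct_pas, incorrect_pas) -> pd.DataFrame:
    """Tiny trial table with prescribed PAS ratings per accuracy stratum."""
    rows = []
    for pas in correct_pas:
        rows.append({"subject": "s01", "site": "LPFC", "task": "orientation",
                     "contrast": 0.015, "stimulus": 1, "response": 1,
                     "correct": True, "pas": int(pas)})
    for pas in incorrect_pas:
        rows.append({"subject": "s01", "site": "LPFC", "task": "orientation",
                     "contrast": 0.015, "stimulus": 1, "response": -1,
                     "correct": False, "pas": int(pas)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with the default design (both tasks, both sites)."""
    config = CohortConfig(n_subjects=6, seed=1234)
    trials, truth = simulate_cohort(config)
    return config, trials, truth


@pytest.fixture()
def default_params() -> ObserverParams:
    return ObserverParams(dprime_max=3.0, c50=0.015, slope=4.0)
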