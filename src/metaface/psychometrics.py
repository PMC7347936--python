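"""Method-of-constant-stimuli summaries and threshold-based subject selection.

Accuracy is summarised per tested contrast with exact binomial confidence
intervals; the "near-threshold" contrast is the tested contrast whose
accuracy is closest to 75% (no psychometric-function interpolation).  A
subject enters the near-threshold analysis only if the 95% CI of accuracy
covers 75% at one or more contrasts -- subjects at ceiling or floor across
the whole contrast range are excluded.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError

__all__ = [
    "accuracy_by_contrast",
    "nearest_threshold_contrast",
    "inclusion_filter",
    "pas_by_accuracy",
    "THRESHOLD_ACCURACY",
]

#: Target threshold performance of the two-choice tasks.
THRESHOLD_ACCURACY = 0.75

CIMethod = Literal["clopper-pearson", "wilson"]

_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}

#: Columns of the per-contrast summary table.
SUMMARY_COLUMNS = (
    "contrast", "n_trials", "n_correct", "accuracy", "ci_low", "ci_high",
)


def accuracy_by_contrast(
    trials: pd.DataFrame,
    ci_method: CIMethod = "clopper-pearson",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-contrast accuracy with a two-sided binomial CI.

    Proportions are exact trial-table proportions (no smoothing); the
    default CI is Clopper-Pearson ("exact"), Wilson available as an option.
    Trials are expected to come from one subject and task (pooled across
    sites or not, at the caller's choice).
    """
    if ci_method not in _CI_METHODS:
        raise DataError(f"unknown ci_method {ci_method!r}")
    if len(trials) == 0:
        raise DataError("no trials supplied")
    rows = []
    for contrast, grp in trials.groupby("contrast", sort=True):
        n = len(grp)
        x = int(grp["correct"].sum())
        lo, hi = proportion_confint(
            x, n, alpha=1 - ci_level, method=_CI_METHODS[ci_method]
        )
        rows.append(
            {
                "contrast": float(contrast),
                "n_trials": n,
                "n_correct": x,
                "accuracy": x / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def nearest_threshold_contrast(
    summary: pd.DataFrame, target: float = THRESHOLD_ACCURACY
) -> float:
    """Tested contrast whose accuracy is closest to ``target``.

    Ties are broken toward the *lower* contrast (the rising limb of the
    psychometric function).  ``summary`` should already pool counts across
    whatever factors the caller wants collapsed (e.g. TMS sites).
    """
    rows = summary.dropna(subset=["accuracy"])
    if len(rows) == 0:
        raise DataError("no valid accuracy rows")
    rows = rows.sort_values("contrast", kind="stable")
    dist = (rows["accuracy"] - target).abs().to_numpy()
    return float(rows["contrast"].to_numpy()[int(np.argmin(dist))])


def inclusion_filter(
    summary: pd.DataFrame, target: float = THRESHOLD_ACCURACY
) -> bool:
    """True iff the CI of accuracy covers ``target`` at >= 1 contrast."""
    ok = (summary["ci_low"] <= target) & (target <= summary["ci_high"])
    return bool(ok.any())


def pas_by_accuracy(trials: pd.DataFrame) -> dict[str, float]:
    """Mean subjective visibility (PAS) separately for correct and
    incorrect trials; an empty stratum yields NaN for its mean."""
    ok = np.asarray(trials["correct"], dtype=bool)
    pas = np.asarray(trials["pas"], dtype=float)
    n_c, n_i = int(ok.sum()), int((~ok).sum())
    return {
        "mean_pas_correct": float(pas[ok].mean()) if n_c else float("nan"),
        "mean_pas_incorrect": float(pas[~ok].mean()) if n_i else float("nan"),
        "n_correct": n_c,
        "n_incorrect": n_i,
    }
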