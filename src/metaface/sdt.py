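"""Type-1 signal detection summaries and the nonparametric Type 2 ROC.

Trial tables (see :mod:`metaface.observer`) are cross-tabulated into a
2 (stimulus) x 2 (response) x K (confidence) count tensor -- the standard
nR_S1/nR_S2 structure of the meta-d' literature -- from which type-1 d'/c
and the Type 2 area under the ROC are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError, EstimationError

__all__ = [
    "RatingCounts",
    "SDTEstimate",
    "Type2ROC",
    "tabulate_counts",
    "zero_cell_summary",
    "dprime_type1",
    "type2_auc",
]

AdjustmentPolicy = Literal["none", "half_count", "loglinear"]

#: stimulus/response axis order of the count tensor: index 0 is class -1,
#: index 1 is class +1.
CLASS_ORDER: tuple[int, int] = (-1, 1)


@dataclass(frozen=True)
class RatingCounts:
    """2 x 2 x K confidence-rating count tensor.

    ``counts[s, r, k]`` is the number of trials with stimulus class
    ``CLASS_ORDER[s]``, response class ``CLASS_ORDER[r]`` and confidence
    level ``k + 1``.

    The serialization convention follows the nR_S1/nR_S2 layout: for each
    true stimulus class, a length-2K vector ordered [response "-1" with
    confidence K..1, then response "+1" with confidence 1..K].
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[:2] != (2, 2):
            raise DataError(f"counts must be 2x2xK, got shape {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise DataError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return self.counts.shape[2]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_nr_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(nR_S1, nR_S2): per-stimulus length-2K vectors, resp -1 conf K..1
        then resp +1 conf 1..K."""
        out = []
        for s in range(2):
            out.append(
                np.concatenate([self.counts[s, 0, ::-1], self.counts[s, 1, :]])
            )
        return out[0], out[1]

    @classmethod
    def from_nr_vectors(cls, nr_s1: Iterable[int], nr_s2: Iterable[int]) -> "RatingCounts":
        nr_s1 = np.asarray(list(nr_s1), dtype=int)
        nr_s2 = np.asarray(list(nr_s2), dtype=int)
        if nr_s1.shape != nr_s2.shape or nr_s1.size % 2:
            raise DataError("nR vectors must share an even length")
        k = nr_s1.size // 2
        counts = np.empty((2, 2, k), dtype=int)
        for s, nr in enumerate((nr_s1, nr_s2)):
            counts[s, 0] = nr[:k][::-1]
            counts[s, 1] = nr[k:]
        return cls(counts)


@dataclass(frozen=True)
class SDTEstimate:
    """Type-1 sensitivity and criterion from hit/false-alarm rates."""

    dprime: float
    criterion: float
    hit_rate: float
    fa_rate: float
    adjustment_applied: bool
    label: tuple | None = field(default=None, compare=False)


@dataclass(frozen=True)
class Type2ROC:
    """Type 2 ROC points and trapezoidal area.

    ``hit_rates``/``fa_rates`` include the (0,0) and (1,1) endpoints and are
    sorted by false-alarm rate.  ``auc`` is NaN when either accuracy stratum
    is empty (flagged by ``defined``).
    """

    hit_rates: np.ndarray
    fa_rates: np.ndarray
    auc: float
    n_correct: int
    n_incorrect: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.auc)


def tabulate_counts(trials: pd.DataFrame, k: int = 4) -> RatingCounts:
    """Exact stimulus x response x confidence cross-tabulation.

    ``trials`` must carry ``stimulus``, ``response`` (each in {-1, +1}) and
    ``pas`` in 1..k; all trials are assumed to come from one analysis cell.
    """
    counts = np.zeros((2, 2, k), dtype=int)
    if len(trials) == 0:
        return RatingCounts(counts)
    stim = np.asarray(trials["stimulus"], dtype=int)
    resp = np.asarray(trials["response"], dtype=int)
    pas = np.asarray(trials["pas"], dtype=int)
    if not np.isin(stim, CLASS_ORDER).all() or not np.isin(resp, CLASS_ORDER).all():
        raise DataError("stimulus/response classes must be -1 or +1")
    if pas.min() < 1 or pas.max() > k:
        raise DataError(f"pas ratings must lie in 1..{k}")
    np.add.at(counts, ((stim + 1) // 2, (resp + 1) // 2, pas - 1), 1)
    return RatingCounts(counts)


def zero_cell_summary(counts: RatingCounts) -> int:
    """Number of zero cells in the 2 x 2 x K tensor."""
    return int(np.count_nonzero(counts.counts == 0))


def _rates_from_counts(counts: RatingCounts) -> tuple[float, float, int, int]:
    c2 = counts.counts.sum(axis=2)  # stimulus x response
    n_noise, n_signal = int(c2[0].sum()), int(c2[1].sum())
    if n_signal == 0 or n_noise == 0:
        raise EstimationError("both stimulus classes must be present")
    hr = c2[1, 1] / n_signal  # P(resp +1 | stim +1)
    far = c2[0, 1] / n_noise  # P(resp +1 | stim -1)
    return hr, far, n_signal, n_noise


def dprime_type1(
    data: RatingCounts | pd.DataFrame,
    adjustment: AdjustmentPolicy = "half_count",
    label: tuple | None = None,
) -> SDTEstimate:
    """Type-1 d' and criterion: d' = z(HR) - z(FAR), c = -(z(HR)+z(FAR))/2.

    ``adjustment`` handles extreme proportions:

    - ``"half_count"`` (default): replace 0 with 1/(2N) and 1 with 1 - 1/(2N),
      leaving interior proportions untouched;
    - ``"loglinear"``: add 0.5 to each response count and 1 to each class
      total, always;
    - ``"none"``: no correction (d' may be infinite).
    """
    counts = data if isinstance(data, RatingCounts) else tabulate_counts(data)
    hr, far, n_signal, n_noise = _rates_from_counts(counts)
    applied = False
    if adjustment == "loglinear":
        c2 = counts.counts.sum(axis=2)
        hr = (c2[1, 1] + 0.5) / (n_signal + 1)
        far = (c2[0, 1] + 0.5) / (n_noise + 1)
        applied = True
    elif adjustment == "half_count":
        for name, rate, n in (("hr", hr, n_signal), ("far", far, n_noise)):
            if rate in (0.0, 1.0):
                rate = 1 / (2 * n) if rate == 0.0 else 1 - 1 / (2 * n)
                applied = True
            if name == "hr":
                hr = rate
            else:
                far = rate
    elif adjustment != "none":
        raise DataError(f"unknown adjustment policy {adjustment!r}")
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return SDTEstimate(
        dprime=float(zh - zf),
        criterion=float(-(zh + zf) / 2),
        hit_rate=float(hr),
        fa_rate=float(far),
        adjustment_applied=applied,
        label=label,
    )


def _conf_counts_by_accuracy(data: RatingCounts | pd.DataFrame, k: int = 4):
    if isinstance(data, RatingCounts):
        c = data.counts
        correct = c[0, 0] + c[1, 1]
        incorrect = c[0, 1] + c[1, 0]
    else:
        pas = np.asarray(data["pas"], dtype=int)
        ok = np.asarray(data["correct"], dtype=bool)
        correct = np.bincount(pas[ok] - 1, minlength=k)
        incorrect = np.bincount(pas[~ok] - 1, minlength=k)
    return np.asarray(correct, dtype=float), np.asarray(incorrect, dtype=float)


def type2_auc(data: RatingCounts | pd.DataFrame, k: int = 4) -> Type2ROC:
    """Nonparametric Type 2 ROC area from confidence ratings.

    Treating each confidence level j in {2..K} as a criterion gives
    type-2 hit rate P(pas >= j | correct) and false-alarm rate
    P(pas >= j | incorrect); the AUC is the trapezoidal area over these
    points plus the (0,0) and (1,1) endpoints, sorted by false-alarm rate.
    Raw conditional proportions are used -- no smoothing; with no correct or
    no incorrect trials the AUC is undefined and returned as NaN.
    """
    correct, incorrect = _conf_counts_by_accuracy(data, k=k)
    n_c, n_i = int(correct.sum()), int(incorrect.sum())
    if n_c == 0 or n_i == 0:
        return Type2ROC(
            hit_rates=np.array([0.0, 1.0]),
            fa_rates=np.array([0.0, 1.0]),
            auc=float("nan"),
            n_correct=n_c,
            n_incorrect=n_i,
        )
    # P(pas >= j | .) for j = K, K-1, ..., 2  (ascending rates)
    hr = np.cumsum(correct[::-1])[:-1] / n_c
    far = np.cumsum(incorrect[::-1])[:-1] / n_i
    hr = np.concatenate([[0.0], hr, [1.0]])
    far = np.concatenate([[0.0], far, [1.0]])
    order = np.lexsort((hr, far))
    hr, far = hr[order], far[order]
    auc = float(np.trapezoid(hr, far))
    return Type2ROC(hit_rates=hr, fa_rates=far, auc=auc, n_correct=n_c, n_incorrect=n_i)
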