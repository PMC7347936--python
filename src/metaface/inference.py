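"""Group-level inference for the within-subjects design.

Covers the statistical toolbox of the analysis: paired t-tests with the
paired effect size dz = mean(diff)/sd(diff) (= |t|/sqrt(n)), power and
sample-size calculations for the paired design via the noncentral t
distribution, the Wald-type statistic (WTS) for factorial repeated measures
with a permutation null distribution, within-subject (Cousineau-Morey)
standard errors, and exact / chi-square contingency-table comparisons.

The WTS on an n x M matrix of subject cell vectors y_i is

    W = n * (H ybar)' (H S H')^+ (H ybar),

with ybar the cell-mean vector, S the empirical covariance of the y_i, H the
hypothesis contrast built from Kronecker products of centering matrices
P_k = I_k - J_k/k, and ^+ the Moore-Penrose pseudoinverse.  It requires
neither sphericity nor compound symmetry.  Its small-sample p-value comes
from pooling all observations and randomly reassigning them across cells and
subjects; the asymptotic chi-square(rank H) p-value is reported as a
cross-check, and a partial eta squared from the companion classical
repeated-measures ANOVA accompanies it as a descriptive effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from math import lgamma

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError, EstimationError

__all__ = [
    "PairedTestResult",
    "PowerSpec",
    "WTSResult",
    "paired_ttest",
    "dz_from_t",
    "power_paired_t",
    "build_hypothesis_matrix",
    "wts_statistic",
    "wts_permutation_test",
    "within_subject_se",
    "contingency_tests",
    "rm_anova_partial_eta_sq",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test with the paired effect size dz."""

    t: float
    df: int
    p: float
    dz: float
    n: int
    mean_diff: float


@dataclass(frozen=True)
class PowerSpec:
    """Paired t-test power specification; exactly one of n/power is None
    on input and filled in by :func:`power_paired_t`."""

    d: float
    alpha: float = 0.05
    n: int | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n is None and self.power is None:
            raise ConfigError("one of n and power must be given")
        if self.n is not None and self.n < 2:
            raise ConfigError("n must be >= 2")


@dataclass(frozen=True)
class WTSResult:
    """Wald-type statistic with permutation and asymptotic p-values."""

    W: float
    df_effect: int
    p_perm: float
    p_asymp: float
    eta_p2: float
    n_perm: int
    seed: int
    effect: str
    n_subjects: int


def paired_ttest(x, y) -> PairedTestResult:
    """Two-tailed paired t-test on x - y with dz = mean(diff)/sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D paired vectors")
    n = x.size
    if n < 2:
        raise DataError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance of differences")
    res = stats.ttest_rel(x, y)
    dz = float(d.mean() / sd)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        dz=dz,
        n=n,
        mean_diff=float(d.mean()),
    )


def dz_from_t(t: float, n: int) -> float:
    """Paired effect size |t| / sqrt(n)."""
    if n < 2:
        raise DataError("need n >= 2 pairs")
    return abs(t) / np.sqrt(n)


def _power_at(n: int, d: float, alpha: float) -> float:
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ncp = d * np.sqrt(n)
    return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_paired_t(spec: PowerSpec, max_n: int = 1_000_000) -> PowerSpec:
    """Complete a paired-design power spec via the noncentral t.

    Exactly one of ``n``/``power`` must be unset on input.  With ``n``
    given, fills in achieved two-tailed power; with a target ``power``
    given, returns the smallest integer n whose power meets it.  ``d`` is
    the paired effect size dz.
    """
    if (spec.n is None) == (spec.power is None):
        raise ConfigError("exactly one of n and power must be None on input")
    if spec.n is not None:
        return replace(spec, power=_power_at(spec.n, spec.d, spec.alpha))
    if not spec.alpha < spec.power < 1:
        raise ConfigError("target power must lie in (alpha, 1)")
    if spec.d == 0:
        raise EstimationError("no finite n reaches power above alpha when d = 0")
    # power is monotone increasing in n for d != 0: scan with doubling bracket
    lo, hi = 2, 2
    while _power_at(hi, spec.d, spec.alpha) < spec.power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise EstimationError(f"required n exceeds {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if _power_at(mid, spec.d, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return replace(spec, n=int(lo))


# ---------------------------------------------------------------------------
# Wald-type statistic for factorial repeated measures


_EFFECT_ALIASES = {
    "site": (0,),
    "contrast": (1,),
    "interaction": (0, 1),
}


def _effect_factors(effect, n_factors: int) -> tuple[int, ...]:
    if isinstance(effect, str):
        if effect not in _EFFECT_ALIASES:
            raise ConfigError(f"unknown effect {effect!r}")
        factors = _EFFECT_ALIASES[effect]
    else:
        factors = tuple(effect)
    if not factors or any(f < 0 or f >= n_factors for f in factors):
        raise ConfigError(f"effect factors {factors} out of range")
    return factors


def build_hypothesis_matrix(levels, effect) -> np.ndarray:
    """Kronecker contrast matrix for one effect of a factorial design.

    ``levels`` gives the number of levels per within-subject factor in
    cell-vector order (first factor slowest-varying).  Each factor in the
    effect contributes its centering matrix P_k = I_k - J_k/k; factors not
    in the effect are averaged out with a (1/k) row of ones.
    """
    levels = tuple(int(v) for v in levels)
    factors = _effect_factors(effect, len(levels))
    h = np.ones((1, 1))
    for i, k in enumerate(levels):
        if i in factors:
            blk = np.eye(k) - np.ones((k, k)) / k
        else:
            blk = np.ones((1, k)) / k
        h = np.kron(h, blk)
    return h


def wts_statistic(data, effect, levels=(2, 6)) -> tuple[float, int]:
    """Wald-type statistic and its effect rank for one within design.

    ``data`` is n_subjects x prod(levels), cell order matching ``levels``
    (first factor slowest; the default (2, 6) is site-major with 6 contrasts
    per site).
    """
    y = np.asarray(data, dtype=float)
    m = int(np.prod(levels))
    if y.ndim != 2 or y.shape[1] != m:
        raise DataError(f"data must be n x {m}")
    n = y.shape[0]
    if n < 2:
        raise DataError("need >= 2 subjects")
    if np.any(~np.isfinite(y)):
        raise DataError("data contains missing cells")
    h = build_hypothesis_matrix(levels, effect)
    ybar = y.mean(axis=0)
    sigma = np.cov(y, rowvar=False, ddof=1)
    df = int(np.linalg.matrix_rank(h))
    w = _quadratic_form(n, h @ ybar, h @ sigma @ h.T, sigma)
    return w, df


def _quadratic_form(n: int, hy: np.ndarray, core: np.ndarray,
                    sigma: np.ndarray) -> float:
    """n * hy' core^+ hy with a pseudoinverse cutoff tied to the covariance
    scale, so exactly-degenerate directions (e.g. pure subject offsets)
    yield 0 instead of amplified float noise."""
    scale = max(float(np.abs(np.diag(sigma)).max()), 1e-300)
    u, s, vt = np.linalg.svd((core + core.T) / 2)
    keep = s > 1e-12 * scale
    if not np.any(keep):
        return 0.0
    inv = (vt[keep].T / s[keep]) @ u[:, keep].T
    return max(float(n * hy @ inv @ hy), 0.0)


def rm_anova_partial_eta_sq(data, effect, levels=(2, 6)) -> float:
    """Partial eta squared from the classical balanced within-subjects ANOVA.

    SS_effect = n * ||C ybar||^2 and SS_error = sum_i ||C (y_i - ybar)||^2,
    where C is the square Kronecker centering projection of the effect
    (P_k for factors in the effect, J_k/k otherwise); eta_p^2 =
    SS_effect / (SS_effect + SS_error).
    """
    y = np.asarray(data, dtype=float)
    levels = tuple(int(v) for v in levels)
    factors = _effect_factors(effect, len(levels))
    c = np.ones((1, 1))
    for i, k in enumerate(levels):
        if i in factors:
            blk = np.eye(k) - np.ones((k, k)) / k
        else:
            blk = np.ones((k, k)) / k
        c = np.kron(c, blk)
    ybar = y.mean(axis=0)
    ss_effect = y.shape[0] * float(np.sum((c @ ybar) ** 2))
    resid = (y - ybar) @ c.T
    ss_error = float(np.sum(resid ** 2))
    if ss_effect + ss_error == 0:
        return 0.0
    return ss_effect / (ss_effect + ss_error)


def wts_permutation_test(
    data,
    effect,
    levels=(2, 6),
    n_perm: int = 10_000,
    seed: int = 0,
    warn_small_n: bool = True,
) -> WTSResult:
    """Permutation-resampled Wald-type test for one within-subject effect.

    The null distribution pools all n x M observations and randomly
    reassigns them across cells and subjects (reshaping to n x M each
    draw), recomputing W; p_perm = (1 + #{W* >= W_obs}) / (n_perm + 1).
    The asymptotic chi-square p-value and the companion RM-ANOVA partial
    eta squared are reported alongside.
    """
    y = np.asarray(data, dtype=float)
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    w_obs, df = wts_statistic(y, effect, levels)
    n, m = y.shape
    if warn_small_n and n <= 12:
        import warnings

        warnings.warn(
            f"WTS with n={n} subjects is unreliable; permutation p retained",
            RuntimeWarning,
            stacklevel=2,
        )
    h = build_hypothesis_matrix(levels, effect)
    pooled = y.ravel().copy()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled).reshape(n, m)
        ybar = perm.mean(axis=0)
        sigma = np.cov(perm, rowvar=False, ddof=1)
        w_star = _quadratic_form(n, h @ ybar, h @ sigma @ h.T, sigma)
        if w_star >= w_obs:
            count += 1
    p_perm = (1 + count) / (n_perm + 1)
    p_asymp = float(stats.chi2.sf(w_obs, df))
    eta = rm_anova_partial_eta_sq(y, effect, levels)
    name = effect if isinstance(effect, str) else "x".join(map(str, effect))
    return WTSResult(
        W=w_obs,
        df_effect=df,
        p_perm=float(p_perm),
        p_asymp=p_asymp,
        eta_p2=float(eta),
        n_perm=n_perm,
        seed=seed,
        effect=name,
        n_subjects=n,
    )


def within_subject_se(data) -> np.ndarray:
    """Within-subject (Cousineau-Morey) per-cell standard errors.

    Each subject's data are centered on their own mean (the grand mean is
    added back), per-cell SDs are divided by sqrt(n), and the k/(k-1)
    small-sample bias correction is applied with k the number of cells.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise DataError("data must be n_subjects x n_cells")
    n, k = y.shape
    centered = y - y.mean(axis=1, keepdims=True) + y.mean()
    if n == 1:
        return np.zeros(k)
    se = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return se * np.sqrt(k / (k - 1))


# ---------------------------------------------------------------------------
# Contingency tables


def _log_table_prob(table: np.ndarray, row_tot, col_tot, n: int) -> float:
    lg = lambda v: lgamma(v + 1)
    return (
        sum(lg(r) for r in row_tot)
        + sum(lg(c) for c in col_tot)
        - lg(n)
        - sum(lg(v) for v in table.ravel())
    )


def _freeman_halton_2xm(table: np.ndarray, max_tables: int = 5_000_000) -> float:
    """Exact p for a 2 x M table: sum of probabilities of all tables with
    the same margins whose probability does not exceed the observed one."""
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n = int(table.sum())
    n_tables = 1
    for c in col_tot:
        n_tables *= c + 1
        if n_tables > max_tables:
            raise EstimationError("table too large for exact enumeration")
    logp_obs = _log_table_prob(table, row_tot, col_tot, n)
    r1 = int(row_tot[0])
    p = 0.0
    for cells in product(*[range(c + 1) for c in col_tot]):
        if sum(cells) != r1:
            continue
        cand = np.array([cells, col_tot - np.array(cells)])
        lp = _log_table_prob(cand, row_tot, col_tot, n)
        if lp <= logp_obs + 1e-9:
            p += np.exp(lp)
    return min(p, 1.0)


def contingency_tests(table) -> dict[str, float]:
    """Exact test and Pearson chi-square on a 2 x M count table.

    Returns ``{"p_exact", "p_chi2", "chi2"}``.  The exact test is Fisher's
    for 2 x 2 and the Freeman-Halton extension (full enumeration) for wider
    tables; the chi-square is Pearson's without continuity correction.
    Columns whose total is zero carry no information and are dropped first.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or np.any(t < 0):
        raise DataError("table must be a nonnegative 2 x M count table")
    if t.sum() == 0:
        raise DataError("empty table")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2:
        return {"p_exact": 1.0, "p_chi2": 1.0, "chi2": 0.0}
    if t.shape[1] == 2:
        p_exact = float(stats.fisher_exact(t)[1])
    else:
        p_exact = float(_freeman_halton_2xm(t))
    if np.any(t.sum(axis=1) == 0):
        chi2, p_chi2 = 0.0, 1.0
    else:
        chi2, p_chi2 = stats.chi2_contingency(t, correction=False)[:2]
    return {"p_exact": p_exact, "p_chi2": float(p_chi2), "chi2": float(chi2)}
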