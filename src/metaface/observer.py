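"""Synthetic signal-detection observers for a two-site TMS psychophysics design.

The generative model is a two-stage Gaussian SDT observer.  On each trial a
binary stimulus class S in {-1, +1} produces first-stage evidence

    x ~ Normal(S * d'(contrast) / 2, 1),

where sensitivity follows a Naka-Rushton (hyperbolic-ratio) contrast response

    d'(c) = dprime_max * c**slope / (c**slope + c50**slope).

The type-1 response is sign(x - c1) with decision criterion ``c1``.  The
confidence (PAS) report is driven by second-stage evidence y = x + eta with
eta ~ Normal(0, sigma_m); sigma_m is the metacognitive noise, which may differ
by stimulation site and contrast.  PAS = 1 + #{k : |y - c1| > theta_k} for
three ordered thresholds theta_1 < theta_2 < theta_3.

A site "effect" is an additive per-contrast increase of sigma_m at one site
(LPFC) only: second-stage noise degrades confidence-accuracy coupling while
leaving type-1 accuracy untouched, which is the dissociation the design is
built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DEFAULT_CONTRASTS",
    "SITES",
    "TASKS",
    "STIMULUS_LABELS",
    "TRIAL_COLUMNS",
    "ObserverParams",
    "CohortConfig",
    "TrialRecord",
    "psychometric_dprime",
    "simulate_subject",
    "simulate_cohort",
]

#: RMS contrasts of the face stimuli under the method of constant stimuli.
DEFAULT_CONTRASTS: tuple[float, ...] = (0.009, 0.012, 0.013, 0.015, 0.023, 0.035)

#: Stimulation sites: LPFC (experimental) and S1 (active control).
SITES: tuple[str, str] = ("LPFC", "S1")

#: Two-choice discrimination tasks.
TASKS: tuple[str, str] = ("orientation", "emotion")

#: Meaning of the numeric stimulus classes per task (labels only; the
#: generative model is identical across tasks).
STIMULUS_LABELS: dict[str, dict[int, str]] = {
    "orientation": {1: "upright", -1: "inverted"},
    "emotion": {1: "happy", -1: "fearful"},
}

#: Fixed column order of the tidy trial table.
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject", "site", "task", "contrast", "stimulus", "response", "correct", "pas",
)

#: Recorded for provenance only -- PsychoPy opacity values matched to the
#: contrast set; never used in computation.
OPACITY_METADATA: tuple[float, ...] = (0.08125, 0.10, 0.113, 0.127, 0.198, 0.30)


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation with its objective and subjective outcome."""

    subject: str
    site: str
    task: str
    contrast: float
    stimulus: int
    response: int
    correct: bool
    pas: int

    def __post_init__(self) -> None:
        if self.stimulus not in (-1, 1) or self.response not in (-1, 1):
            raise ConfigError("stimulus and response must be -1 or +1")
        if self.pas not in (1, 2, 3, 4):
            raise ConfigError(f"pas must be in 1..4, got {self.pas}")
        if self.correct != (self.stimulus == self.response):
            raise ConfigError("correct flag inconsistent with stimulus/response")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one two-stage SDT observer.

    Parameters
    ----------
    dprime_max
        Asymptotic sensitivity in d' units; > 0.
    c50
        Semi-saturation contrast (RMS units); must lie strictly inside the
        simulated contrast range.
    slope
        Naka-Rushton exponent; > 0.
    type1_criterion
        Decision criterion c1 in evidence units (0 = unbiased).
    conf_thresholds
        Three strictly increasing nonnegative offsets from c1 mapping
        absolute second-stage evidence to PAS 1-4.
    meta_noise_by_site
        Per-site second-stage noise SD sigma_m >= 0; each entry a scalar or
        a per-contrast sequence.
    """

    dprime_max: float
    c50: float
    slope: float
    type1_criterion: float = 0.0
    conf_thresholds: tuple[float, float, float] = (0.5, 1.0, 1.5)
    meta_noise_by_site: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {s: 0.0 for s in SITES}
    )

    def __post_init__(self) -> None:
        if not self.dprime_max > 0:
            raise ConfigError(f"dprime_max must be > 0, got {self.dprime_max}")
        if not self.slope > 0:
            raise ConfigError(f"slope must be > 0, got {self.slope}")
        if not self.c50 > 0:
            raise ConfigError(f"c50 must be > 0, got {self.c50}")
        th = np.asarray(self.conf_thresholds, dtype=float)
        if th.shape != (3,) or np.any(th < 0) or np.any(np.diff(th) <= 0):
            raise ConfigError(
                "conf_thresholds must be 3 strictly increasing nonnegative offsets"
            )
        for site, sm in self.meta_noise_by_site.items():
            if np.any(np.asarray(sm, dtype=float) < 0):
                raise ConfigError(f"meta noise for site {site!r} must be >= 0")

    def meta_noise(self, site: str, contrast_index: int, n_contrasts: int) -> float:
        """Resolve sigma_m for one (site, contrast) cell."""
        sm = np.broadcast_to(
            np.asarray(self.meta_noise_by_site[site], dtype=float), (n_contrasts,)
        )
        return float(sm[contrast_index])


#: Population means and SDs used when drawing a cohort.  Means put threshold
#: (75% accuracy, d' ~ 1.35) inside the contrast range; SDs give realistic
#: between-subject spread without leaving the valid parameter space.
DEFAULT_POPULATION: dict[str, tuple[float, float]] = {
    "dprime_max": (3.0, 0.5),
    "c50": (0.015, 0.003),
    "slope": (4.0, 0.8),
    "type1_criterion": (0.0, 0.15),
    "theta1": (0.5, 0.10),
    "theta2": (1.0, 0.15),
    "theta3": (1.6, 0.20),
    "meta_noise": (0.3, 0.1),
}

#: Default additive sigma_m increase at LPFC, peaked at intermediate
#: contrasts (a site-by-contrast interaction on metacognition only).
DEFAULT_SITE_EFFECT: tuple[float, ...] = (0.0, 0.1, 0.4, 0.4, 0.1, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Design and population description for a simulated cohort."""

    n_subjects: int = 28
    trials_per_contrast: int = 24
    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS
    sites: tuple[str, str] = SITES
    tasks: tuple[str, ...] = TASKS
    population: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION)
    )
    site_effect: tuple[float, ...] = DEFAULT_SITE_EFFECT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.trials_per_contrast < 1 or self.trials_per_contrast % 2:
            raise ConfigError("trials_per_contrast must be a positive even count")
        if len(self.contrasts) < 1 or list(self.contrasts) != sorted(self.contrasts):
            raise ConfigError("contrasts must be sorted ascending")
        se = np.asarray(self.site_effect, dtype=float)
        if se.shape != (len(self.contrasts),):
            raise ConfigError("site_effect must give one value per contrast")
        if np.any(se < 0):
            raise ConfigError("site_effect must be >= 0 elementwise")
        for key, (mu, sd) in self.population.items():
            if sd < 0:
                raise ConfigError(f"population SD for {key!r} is negative")

    @property
    def trials_per_task_site(self) -> int:
        return self.trials_per_contrast * len(self.contrasts)


def psychometric_dprime(contrast: float, params: ObserverParams) -> float:
    """Naka-Rushton contrast-response function on d'.

    d'(c) = dprime_max * c**slope / (c**slope + c50**slope); nonnegative and
    monotone nondecreasing in contrast, with d'(c50) = dprime_max / 2.
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0):
        raise ConfigError("contrast must be nonnegative")
    cs = np.power(c, params.slope)
    out = params.dprime_max * cs / (cs + params.c50 ** params.slope)
    return float(out) if np.isscalar(contrast) else out


def _simulate_cell(
    params: ObserverParams,
    config: CohortConfig,
    subject: str,
    site: str,
    task: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """All trials of one (subject, site, task) cell, balanced per contrast."""
    m = config.trials_per_contrast
    n_contrasts = len(config.contrasts)
    frames = []
    for ci, contrast in enumerate(config.contrasts):
        dprime = psychometric_dprime(contrast, params)
        # balanced classes: m/2 each, presented in shuffled order
        stim = np.repeat([1, -1], m // 2)
        rng.shuffle(stim)
        x = rng.normal(loc=stim * dprime / 2.0, scale=1.0)
        c1 = params.type1_criterion
        resp = np.where(x > c1, 1, -1)
        sigma_m = params.meta_noise(site, ci, n_contrasts)
        y = x + (rng.normal(0.0, sigma_m, size=m) if sigma_m > 0 else 0.0)
        th = np.asarray(params.conf_thresholds)
        pas = 1 + (np.abs(y - c1)[:, None] > th[None, :]).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "site": site,
                    "task": task,
                    "contrast": contrast,
                    "stimulus": stim.astype(int),
                    "response": resp.astype(int),
                    "correct": resp == stim,
                    "pas": pas.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_subject(
    params: ObserverParams,
    config: CohortConfig,
    subject_id: str | int = "s01",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate every (site, task) cell for one observer.

    Returns a tidy trial table with columns :data:`TRIAL_COLUMNS`;
    ``trials_per_contrast * len(contrasts)`` rows per (site, task) cell
    (144 at the defaults).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    subject = str(subject_id)
    frames = [
        _simulate_cell(params, config, subject, site, task, rng)
        for site in config.sites
        for task in config.tasks
    ]
    return pd.concat(frames, ignore_index=True)[list(TRIAL_COLUMNS)]


def _draw_params(config: CohortConfig, rng: np.random.Generator) -> ObserverParams:
    """Draw one observer from the population, respecting parameter bounds."""
    pop = config.population
    lo_c, hi_c = min(config.contrasts), max(config.contrasts)

    def draw(key: str, low: float | None = None, high: float | None = None) -> float:
        mu, sd = pop[key]
        v = float(rng.normal(mu, sd))
        if low is not None:
            v = max(v, low)
        if high is not None:
            v = min(v, high)
        return v

    eps = 1e-6
    thetas = sorted(draw(k, low=eps) for k in ("theta1", "theta2", "theta3"))
    # enforce strict ordering in the (measure-zero) event of ties
    for i in (1, 2):
        if thetas[i] <= thetas[i - 1]:
            thetas[i] = thetas[i - 1] + eps
    base_sm = draw("meta_noise", low=0.0)
    lpfc_sm = base_sm + np.asarray(config.site_effect, dtype=float)
    meta_noise = {}
    for site in config.sites:
        meta_noise[site] = tuple(lpfc_sm) if site == "LPFC" else base_sm
    return ObserverParams(
        dprime_max=draw("dprime_max", low=0.1),
        c50=draw("c50", low=lo_c * (1 + 1e-3), high=hi_c * (1 - 1e-3)),
        slope=draw("slope", low=0.5),
        type1_criterion=draw("type1_criterion"),
        conf_thresholds=tuple(thetas),
        meta_noise_by_site=meta_noise,
    )


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Per-subject parameters are drawn from the population distributions in
    ``config.population``; the additive site effect raises sigma_m at LPFC
    only.  Subject RNG streams derive deterministically from
    ``(config.seed, subject index)`` so individual subjects are reproducible
    in isolation.

    Returns
    -------
    trials, truth
        ``trials``: tidy trial table; ``truth``: one row per subject with the
        ground-truth generative parameters (for recovery testing).
    """
    trial_frames = []
    truth_rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, i])
        params = _draw_params(config, rng)
        subject = f"s{i + 1:02d}"
        trial_frames.append(simulate_subject(params, config, subject, rng))
        row: dict[str, object] = {
            "subject": subject,
            "dprime_max": params.dprime_max,
            "c50": params.c50,
            "slope": params.slope,
            "type1_criterion": params.type1_criterion,
        }
        for j, th in enumerate(params.conf_thresholds, start=1):
            row[f"theta{j}"] = th
        for site in config.sites:
            sm = np.broadcast_to(
                np.asarray(params.meta_noise_by_site[site], dtype=float),
                (len(config.contrasts),),
            )
            for ci, contrast in enumerate(config.contrasts):
                row[f"sigma_m_{site}_c{ci + 1}"] = sm[ci]
        truth_rows.append(row)
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def with_uniform_meta_noise(
    params: ObserverParams, sigma_m: float, sites: Sequence[str] = SITES
) -> ObserverParams:
    """Copy of ``params`` with the same sigma_m at every site and contrast."""
    return replace(params, meta_noise_by_site={s: float(sigma_m) for s in sites})
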