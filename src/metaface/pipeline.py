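"""End-to-end analysis orchestration.

Two entry points mirror the sequencing of the study design:

- :func:`run_threshold_analysis` -- the primary analysis.  Per subject and
  task, the near-threshold contrast is chosen from accuracy pooled across
  TMS sites; metacognition metrics (Type 2 AUC, meta-d', meta-d' - d') plus
  d' and mean PAS are computed per site at that contrast, and the two sites
  are compared with paired t-tests.  Subjects whose accuracy CI never covers
  75% (ceiling/floor) are excluded with a per-subject reason.
- :func:`run_contrast_analysis` -- the secondary analysis.  Metric grids
  over every (site, contrast) cell enter permutation Wald-type tests of the
  site and contrast main effects and their interaction, with within-subject
  standard errors for plotting.

Both return a :class:`ResultsBundle` that serializes to plain CSV + text and
is byte-identical for identical configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .inference import paired_ttest, within_subject_se, wts_permutation_test
from .metad import MCMCConfig, efficiency, fit_metad_bayes, fit_metad_mle
from .observer import DEFAULT_CONTRASTS, SITES, TASKS
from .psychometrics import (
    THRESHOLD_ACCURACY,
    accuracy_by_contrast,
    inclusion_filter,
    nearest_threshold_contrast,
    pas_by_accuracy,
)
from .sdt import dprime_type1, tabulate_counts, type2_auc, zero_cell_summary

__all__ = ["AnalysisConfig", "ResultsBundle", "run_threshold_analysis",
           "run_contrast_analysis", "run_full_analysis", "report"]

#: Metrics the pipeline can compute per (subject, site, task, contrast) cell.
ALL_METRICS: tuple[str, ...] = ("type2_auc", "meta_d", "m_diff", "dprime", "pas")


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one analysis run.

    ``seed`` propagates to every stochastic stage (permutation tests and the
    Bayesian sampler); ``metrics`` selects which per-cell quantities are
    computed ("meta_d"/"m_diff" require a meta-d' fit and dominate runtime).
    """

    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS
    sites: tuple[str, str] = SITES
    tasks: tuple[str, ...] = TASKS
    metrics: tuple[str, ...] = ALL_METRICS
    ci_method: str = "clopper-pearson"
    adjustment: str = "half_count"
    metad_method: str = "mle"
    mcmc: Mapping[str, float] = field(default_factory=dict)
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.metrics) - set(ALL_METRICS)
        if bad:
            raise ConfigError(f"unknown metrics: {sorted(bad)}")
        if self.metad_method not in ("mle", "bayes"):
            raise ConfigError(f"unknown metad_method {self.metad_method!r}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if len(self.sites) != 2:
            raise ConfigError("exactly two sites required")

    @property
    def needs_metad(self) -> bool:
        return bool({"meta_d", "m_diff"} & set(self.metrics))

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(self.contrasts)
        d["sites"] = list(self.sites)
        d["tasks"] = list(self.tasks)
        d["metrics"] = list(self.metrics)
        d["mcmc"] = dict(self.mcmc)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("analysis config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
        for key in ("contrasts", "sites", "tasks", "metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ResultsBundle:
    """All tables of one analysis run plus provenance.

    ``tables`` maps short names to tidy DataFrames; every number carries its
    (subject, site, task, contrast) provenance in explicit columns.
    """

    tables: dict[str, pd.DataFrame]
    provenance: dict[str, object]
    log: list[str] = field(default_factory=list)

    def to_bytes(self) -> bytes:
        """Canonical byte serialization (CSV per table, sorted names)."""
        parts = [json.dumps(self.provenance, sort_keys=True)]
        for name in sorted(self.tables):
            parts.append(f"## {name}")
            parts.append(self.tables[name].to_csv(index=False))
        return "\n".join(parts).encode()

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, sort_keys=True, indent=2)
        )
        (out / "summary.txt").write_text(render_summary(self))

    @staticmethod
    def read_tables(outdir: str | Path) -> dict[str, pd.DataFrame]:
        out = Path(outdir)
        return {
            p.stem: pd.read_csv(p, float_precision="round_trip")
            for p in sorted(out.glob("*.csv"))
        }


def _derived_seed(seed: int, *parts) -> int:
    """Deterministic stream seed below 2**31 for one labelled stage."""
    tag = zlib.crc32("|".join(map(str, parts)).encode())
    return int((seed * 2654435761 + tag) % (2**31 - 1))


def _cell_metrics(cell: pd.DataFrame, config: AnalysisConfig, label: tuple) -> dict:
    """All configured metrics for one (subject, site, task, contrast) cell."""
    counts = tabulate_counts(cell)
    out: dict[str, object] = {"n_trials": len(cell), "zero_cells": zero_cell_summary(counts)}
    anchor = dprime_type1(counts, adjustment=config.adjustment, label=label)
    if "dprime" in config.metrics:
        out["dprime"] = anchor.dprime
        out["criterion"] = anchor.criterion
    if "type2_auc" in config.metrics:
        out["type2_auc"] = type2_auc(counts).auc
    if "pas" in config.metrics:
        out["pas"] = float(cell["pas"].mean())
        out.update(pas_by_accuracy(cell))
    if config.needs_metad:
        if config.metad_method == "bayes":
            mcfg = MCMCConfig(seed=_derived_seed(config.seed, "bayes", *label),
                              **dict(config.mcmc))
            fit = fit_metad_bayes(counts, anchor=anchor, mcmc=mcfg)
        else:
            fit = fit_metad_mle(counts, anchor=anchor)
        out["meta_d"] = fit.meta_dprime
        out["m_diff"] = efficiency(fit, anchor).difference
        if fit.posterior_summary is not None:
            out["meta_d_ci_low"] = fit.posterior_summary["ci95_low"]
            out["meta_d_ci_high"] = fit.posterior_summary["ci95_high"]
    return out


def _exclusion_reason(summary: pd.DataFrame, target: float) -> str:
    if (summary["ci_low"] > target).all():
        return "ceiling"
    if (summary["ci_high"] < target).all():
        return "floor"
    return "threshold not captured"


def run_threshold_analysis(trials: pd.DataFrame, config: AnalysisConfig) -> ResultsBundle:
    """Near-threshold metacognition analysis with paired site comparisons."""
    log: list[str] = []
    metric_rows, exclusion_rows, threshold_rows = [], [], []
    for task in config.tasks:
        t_task = trials[trials["task"] == task]
        subjects = sorted(t_task["subject"].unique())
        log.append(f"[threshold/{task}] {len(subjects)} subjects in")
        included = []
        for subj in subjects:
            t_subj = t_task[t_task["subject"] == subj]
            pooled = accuracy_by_contrast(t_subj, ci_method=config.ci_method)
            if not inclusion_filter(pooled):
                reason = _exclusion_reason(pooled, THRESHOLD_ACCURACY)
                exclusion_rows.append(
                    {"task": task, "subject": subj, "reason": reason}
                )
                continue
            near = nearest_threshold_contrast(pooled)
            threshold_rows.append(
                {"task": task, "subject": subj, "near_threshold_contrast": near}
            )
            included.append(subj)
            for site in config.sites:
                cell = t_subj[(t_subj["site"] == site) & (t_subj["contrast"] == near)]
                if len(cell) == 0:
                    raise DataError(
                        f"no trials for {subj}/{task}/{site} at contrast {near}"
                    )
                label = (subj, site, task, near)
                row = {"task": task, "subject": subj, "site": site, "contrast": near}
                row.update(_cell_metrics(cell, config, label))
                metric_rows.append(row)
        log.append(
            f"[threshold/{task}] {len(included)} included, "
            f"{len(subjects) - len(included)} excluded"
        )
    metrics_df = pd.DataFrame(metric_rows)
    paired_rows = []
    site_a, site_b = config.sites
    for task in config.tasks:
        sub = metrics_df[metrics_df["task"] == task] if len(metrics_df) else metrics_df
        for metric in [m for m in config.metrics if m in getattr(sub, "columns", [])]:
            wide = sub.pivot(index="subject", columns="site", values=metric).dropna()
            if len(wide) < 2:
                log.append(f"[threshold/{task}] {metric}: <2 complete pairs, skipped")
                continue
            res = paired_ttest(wide[site_a].to_numpy(), wide[site_b].to_numpy())
            paired_rows.append(
                {
                    "task": task,
                    "metric": metric,
                    "comparison": f"{site_a}-{site_b}",
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "dz": res.dz,
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                }
            )
    if not exclusion_rows and metrics_df.empty:
        raise DataError("no subjects passed the inclusion filter")
    bundle = ResultsBundle(
        tables={
            "threshold_metrics": metrics_df,
            "threshold_contrasts": pd.DataFrame(
                threshold_rows, columns=["task", "subject", "near_threshold_contrast"]
            ),
            "exclusions": pd.DataFrame(
                exclusion_rows, columns=["task", "subject", "reason"]
            ),
            "paired_tests": pd.DataFrame(
                paired_rows,
                columns=["task", "metric", "comparison", "t", "df", "p", "dz", "n",
                         "mean_diff"],
            ),
        },
        provenance=_provenance(config, "threshold"),
        log=log,
    )
    return bundle


def run_contrast_analysis(trials: pd.DataFrame, config: AnalysisConfig) -> ResultsBundle:
    """Across-contrast metric grids with permutation Wald-type tests."""
    log: list[str] = []
    grid_rows, wts_rows, se_rows = [], [], []
    contrasts = list(config.contrasts)
    m = 2 * len(contrasts)
    for task in config.tasks:
        t_task = trials[trials["task"] == task]
        subjects = sorted(t_task["subject"].unique())
        # standard contrast set only
        usable = []
        for subj in subjects:
            got = sorted(t_task.loc[t_task["subject"] == subj, "contrast"].unique())
            if not np.allclose(got, contrasts):
                log.append(
                    f"[contrast/{task}] {subj} dropped: non-standard contrast set"
                )
                continue
            usable.append(subj)
        log.append(f"[contrast/{task}] {len(usable)}/{len(subjects)} subjects usable")
        per_metric: dict[str, dict[str, list[float]]] = {}
        for subj in usable:
            t_subj = t_task[t_task["subject"] == subj]
            cells = {}
            for site in config.sites:
                for contrast in contrasts:
                    cell = t_subj[
                        (t_subj["site"] == site) & (t_subj["contrast"] == contrast)
                    ]
                    label = (subj, site, task, contrast)
                    vals = _cell_metrics(cell, config, label)
                    cells[(site, contrast)] = vals
                    row = {"task": task, "subject": subj, "site": site,
                           "contrast": contrast}
                    row.update(vals)
                    grid_rows.append(row)
            for metric in config.metrics:
                if metric not in next(iter(cells.values())):
                    continue
                vec = [cells[(s, c)][metric] for s in config.sites for c in contrasts]
                per_metric.setdefault(metric, {})[subj] = vec
        for metric, by_subj in per_metric.items():
            mat, kept = [], []
            for subj, vec in by_subj.items():
                if np.all(np.isfinite(vec)):
                    mat.append(vec)
                    kept.append(subj)
                else:
                    log.append(
                        f"[contrast/{task}] {subj} dropped from {metric} WTS: "
                        "undefined cell"
                    )
            if len(mat) < 3:
                log.append(f"[contrast/{task}] {metric}: too few subjects for WTS")
                continue
            mat = np.asarray(mat)
            for effect in ("site", "contrast", "interaction"):
                res = wts_permutation_test(
                    mat, effect, levels=(2, len(contrasts)),
                    n_perm=config.n_perm,
                    seed=_derived_seed(config.seed, "wts", task, metric, effect),
                    warn_small_n=False,
                )
                wts_rows.append(
                    {"task": task, "metric": metric, "effect": effect, "W": res.W,
                     "df": res.df_effect, "p_perm": res.p_perm,
                     "p_asymp": res.p_asymp, "eta_p2": res.eta_p2,
                     "n_perm": res.n_perm, "n": res.n_subjects, "seed": res.seed}
                )
            ses = within_subject_se(mat)
            for j, (site, contrast) in enumerate(
                [(s, c) for s in config.sites for c in contrasts]
            ):
                se_rows.append(
                    {"task": task, "metric": metric, "site": site,
                     "contrast": contrast,
                     "mean": float(mat[:, j].mean()), "within_se": float(ses[j]),
                     "n": len(kept)}
                )
    bundle = ResultsBundle(
        tables={
            "contrast_grids": pd.DataFrame(grid_rows),
            "wts_tests": pd.DataFrame(
                wts_rows,
                columns=["task", "metric", "effect", "W", "df", "p_perm", "p_asymp",
                         "eta_p2", "n_perm", "n", "seed"],
            ),
            "cell_means": pd.DataFrame(
                se_rows,
                columns=["task", "metric", "site", "contrast", "mean", "within_se",
                         "n"],
            ),
        },
        provenance=_provenance(config, "contrast"),
        log=log,
    )
    return bundle


def run_full_analysis(trials: pd.DataFrame, config: AnalysisConfig) -> ResultsBundle:
    """Threshold and across-contrast analyses in one bundle."""
    thr = run_threshold_analysis(trials, config)
    con = run_contrast_analysis(trials, config)
    tables = {**thr.tables, **con.tables}
    return ResultsBundle(
        tables=tables,
        provenance=_provenance(config, "full"),
        log=thr.log + con.log,
    )


def _provenance(config: AnalysisConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config": config.canonical_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }


def render_summary(bundle: ResultsBundle) -> str:
    """Human-readable account of every test and exclusion in a bundle."""
    lines = [
        "metaface analysis summary",
        f"stage: {bundle.provenance['stage']}",
        f"config hash: {bundle.provenance['config_hash']} "
        f"(seed {bundle.provenance['seed']})",
        "",
    ]
    excl = bundle.tables.get("exclusions")
    if excl is not None:
        if len(excl):
            lines.append("Excluded subjects:")
            for _, r in excl.iterrows():
                lines.append(f"  {r['task']}/{r['subject']}: {r['reason']}")
        else:
            lines.append("Excluded subjects: none")
        lines.append("")
    paired = bundle.tables.get("paired_tests")
    if paired is not None:
        if len(paired):
            lines.append("Paired site comparisons (two-tailed, uncorrected):")
            for _, r in paired.iterrows():
                lines.append(
                    f"  {r['task']}/{r['metric']} {r['comparison']}: "
                    f"t({r['df']}) = {r['t']:.3f}, p = {r['p']:.4f}, "
                    f"dz = {r['dz']:.3f}, n = {r['n']}"
                )
        else:
            lines.append("Paired site comparisons: skipped (no complete pairs)")
        lines.append("")
    wts = bundle.tables.get("wts_tests")
    if wts is not None:
        if len(wts):
            lines.append("Permutation Wald-type tests (two-tailed, uncorrected):")
            for _, r in wts.iterrows():
                lines.append(
                    f"  {r['task']}/{r['metric']} {r['effect']}: "
                    f"W = {r['W']:.3f} (df {r['df']}), perm p = {r['p_perm']:.4f} "
                    f"({r['n_perm']} perms, seed {r['seed']}), "
                    f"asymp p = {r['p_asymp']:.4f}, eta_p2 = {r['eta_p2']:.3f}, "
                    f"n = {r['n']}"
                )
        else:
            lines.append("Across-contrast section: skipped")
        lines.append("")
    if bundle.log:
        lines.append("Log:")
        lines.extend(f"  {entry}" for entry in bundle.log)
    return "\n".join(lines) + "\n"


def report(bundle: ResultsBundle, outdir: str | Path) -> str:
    """Write machine-readable tables and the text summary; returns the
    summary string."""
    bundle.write(outdir)
    return render_summary(bundle)
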