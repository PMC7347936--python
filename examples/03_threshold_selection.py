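"""Psychometric summaries, near-threshold contrast, and subject inclusion.

For one simulated subject: per-contrast accuracy with exact binomial CIs
(pooled across TMS sites), the contrast closest to 75% accuracy, and the
inclusion decision (the CI must cover 75% somewhere in the tested range).
"""

from metaface import (
    CohortConfig,
    ObserverParams,
    accuracy_by_contrast,
    inclusion_filter,
    nearest_threshold_contrast,
    pas_by_accuracy,
    simulate_subject,
)

params = ObserverParams(dprime_max=3.0, c50=0.015, slope=4.0)
config = CohortConfig(n_subjects=1)
trials = simulate_subject(params, config, "s01", rng=11)
task = trials[trials.task == "orientation"]

summary = accuracy_by_contrast(task)  # pooled across both sites
print(summary.to_string(index=False,
                        formatters={"accuracy": "{:.3f}".format,
                                    "ci_low": "{:.3f}".format,
                                    "ci_high": "{:.3f}".format}))

near = nearest_threshold_contrast(summary)
print(f"\nnear-threshold contrast (accuracy closest to 75%): {near}")
print(f"included in the threshold analysis: {inclusion_filter(summary)}")

cell = task[task.contrast == near]
pas = pas_by_accuracy(cell)
print(f"\nmean PAS at threshold: correct = {pas['mean_pas_correct']:.2f} "
      f"(n={pas['n_correct']}), incorrect = {pas['mean_pas_incorrect']:.2f} "
      f"(n={pas['n_incorrect']})")
print("Higher visibility ratings after correct than incorrect responses "
      "indicate intact metacognitive access.")
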