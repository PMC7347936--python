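"""Simulate a cohort of two-stage SDT observers and inspect the design.

Builds the default within-subject design -- 2 TMS sites x 2 tasks x
6 contrasts x 24 trials -- for a small cohort and prints the trial counts
plus the ground-truth generative parameters of the first subject.
"""

from metaface import CohortConfig, simulate_cohort

config = CohortConfig(n_subjects=4, seed=1)
trials, truth = simulate_cohort(config)

print(f"{len(trials)} trials total "
      f"({config.n_subjects} subjects x 2 sites x 2 tasks x 144 trials)")
print("\nTrials per (site, task) for subject s01:")
print(trials[trials.subject == "s01"].groupby(["site", "task"]).size())

print("\nGround truth for s01 (the parameters the fits should recover):")
row = truth.iloc[0]
print(f"  max sensitivity d'_max = {row.dprime_max:.2f}, "
      f"semi-saturation c50 = {row.c50:.4f}, slope = {row.slope:.2f}")
print(f"  metacognitive noise sigma_m at S1 = {row.sigma_m_S1_c3:.2f}, "
      f"at LPFC mid-contrast = {row.sigma_m_LPFC_c3:.2f}")
print("\nThe LPFC/S1 sigma_m gap is the injected 'TMS lesion': it degrades "
      "confidence-accuracy coupling without touching type-1 accuracy.")
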