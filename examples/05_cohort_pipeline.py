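"""End-to-end cohort analysis on a simulated 24-h study.

Simulates the default study design (24 myopes, 20 non-myopes, 7 sessions)
with the reported group rhythm parameters, then runs the full pipeline:
per-subject Fourier fits, circular summaries, repeated-measures ANOVA with
Bonferroni pairwise session contrasts, and refractive-group contrasts.
"""

import tempfile
from pathlib import Path

import pandas as pd

from chorodiurnal import default_cohort_config, generate_diurnal_cohort, run_pipeline

cohort, truth = generate_diurnal_cohort(default_cohort_config(seed=20))
print(f"simulated {cohort['subject_id'].nunique()} subjects, "
      f"{len(cohort)} measurements")

out = Path(tempfile.mkdtemp()) / "report"
paths = run_pipeline(cohort, out, n_perm=999, seed=20)

summary = pd.read_csv(paths["summary"])
cols = ["index", "daily_mean_mean", "amplitude_mean", "amplitude_percent_of_mean",
        "acrophase_clock", "rayleigh_r", "rayleigh_p", "anova_time_p"]
print(summary[cols].round(3).to_string(index=False))

contrasts = pd.read_csv(paths["contrasts"])
print(contrasts[["index", "mannwhitney_p", "watson_p"]].round(4).to_string(index=False))
# Row 1: the flow-deficit-density rhythm peaks in the early morning and its
# acrophases cluster (small Rayleigh p). The contrast table tests whether
# myopes and non-myopes differ in amplitude (Mann-Whitney) and in acrophase
# (Watson U2) - at these effect sizes significance is expected only in a
# fraction of simulated cohorts.
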