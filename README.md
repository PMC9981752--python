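# chorodiurnal

Diurnal rhythmometry of choroidal OCT angiography (OCT-A) indices.

The choroid — the vascular layer feeding the outer retina — varies over the
24-hour day, and that variation differs between myopic and non-myopic eyes.
`chorodiurnal` implements the full analysis chain for 24-h studies in which
each subject is imaged every 4 h at 7 sessions (starting 9 AM):

1. **En-face quantification** (`chorodiurnal.quantify`): binarized
   choriocapillaris slabs yield *flow-deficit* number, average size (µm²,
   magnification-corrected as size × factor²) and density (%); binarized
   deep-choroid slabs yield *perfusion density* (%). Indices are measured
   inside a modified ETDRS grid (sub-foveal 1 mm, sub-parafoveal 2.5 mm,
   sub-perifoveal 5 mm) whose pixel radii are scaled per eye by an
   axial-length magnification correction, with large-vessel projection
   masks excluded from numerator and denominator and sessions co-registered
   by phase correlation.
2. **Per-subject Fourier rhythmometry** (`chorodiurnal.rhythm`): a
   two-harmonic least-squares fit
   `y(t) = a₀ + Σₖ [aₖ cos(2πkt/24) + bₖ sin(2πkt/24)]`
   gives the daily mean, the diurnal amplitude (fitted peak-to-trough) and
   the acrophase (clock time of the fitted peak).
3. **Circular statistics** (`chorodiurnal.circstats`): Rayleigh test
   (`p ≈ exp(√(1+4n+4(n²−R²)) − (1+2n))`, R = n·r), circular deviation,
   two-sample Watson U² with a seeded permutation null, Fisher–Lee circular
   correlation, the ±2 h in-phase/antiphase rule, plus Mann–Whitney U and
   Spearman's ρ for linear contrasts.
4. **Cohort inference** (`chorodiurnal.pipeline`): repeated-measures ANOVA
   (time, group, time × group; uncorrected dfs) with Bonferroni pairwise
   session contrasts, and a summary table per index × region.

A first-class synthetic-data module (`chorodiurnal.synthetic`) generates
en-face images with exact pixel-level ground truth and cohorts with known
rhythm parameters, so every stage is testable without raw scans.

## Worked example

Simulate the default study design (24 myopes, 20 non-myopes, 7 sessions
over 24 h) and run the whole pipeline (`examples/05_cohort_pipeline.py`):

```python
from chorodiurnal import default_cohort_config, generate_diurnal_cohort, run_pipeline

cohort, truth = generate_diurnal_cohort(default_cohort_config(seed=20))
paths = run_pipeline(cohort, "report", n_perm=999, seed=20)
```

which prints (via the example script):

```
simulated 44 subjects, 616 measurements
                 index  daily_mean_mean  amplitude_mean  amplitude_percent_of_mean acrophase_clock  rayleigh_r  rayleigh_p  anova_time_p
  flow_deficit_density           14.146           3.019                      21.34         3:35 AM       0.587       0.000         0.000
deep_perfusion_density           56.789           1.995                       3.51         4:01 AM       0.222       0.113         0.001
                 index  mannwhitney_p  watson_p
  flow_deficit_density         0.0052     0.091
deep_perfusion_density         0.0190     0.625
```

Reading the first row: across the cohort the sub-foveal
choriocapillaris flow-deficit density averages 14.1 % with a fitted
peak-to-trough diurnal amplitude of 3.0 percentage points (21 % of the
daily mean), peaking in the early morning (circular mean acrophase
3:35 AM); acrophases cluster significantly across subjects (Rayleigh
r = 0.59, p < 0.001) and the time-of-day effect is significant in the
repeated-measures ANOVA. The contrast table then asks whether myopes and
non-myopes differ in amplitude (Mann–Whitney) and peak time (Watson U²).

The other example scripts each exercise one capability — image simulation,
ETDRS-grid quantification, a single rhythm fit, and circular statistics:

```bash
python examples/01_simulate_enface_images.py
python examples/02_quantify_enface.py
python examples/03_rhythm_fit.py
python examples/04_circular_stats.py
```

A thin CLI mirrors the stages:

```bash
chorodiurnal simulate --out-dir sim --seed 4
chorodiurnal run --measurements sim/cohort.csv --out-dir report --seed 4
```

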