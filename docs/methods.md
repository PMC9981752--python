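# Methods

This note documents the models, conventions and numerical choices behind
`chorodiurnal`, and what the synthetic-data generators do and do not emulate.

## Study design assumed throughout

The package targets 24-hour diurnal studies of choroidal OCT-A indices: each
subject is measured at 7 sessions every 4 h starting at 9 AM, so session
times are expressed as hours since 9 AM (0, 4, …, 24) and the first and last
sessions share a circadian phase. Reported clock times are 9 AM + t mod 24,
formatted on a 12-hour clock. The reference cohort design is two refractive
groups of 24 (myopes) and 20 (non-myopes) subjects.

## En-face quantification

**Indices.** In a binarized choriocapillaris en-face image, flow deficits are
the dark (below-threshold) pixels; an unconnected dark pixel is a single
deficit. Per region we report: flow-deficit number (8-connected components
intersecting the region), average flow-deficit size (mean component area ×
pixel area × correction factor², µm²), and flow-deficit density (dark
in-region pixels / non-excluded region pixels × 100). In the deep choroid the
vasculature itself appears dark; perfusion density is the dark fraction of
the region, in percent.

**Binarization.** The original analysis pipeline's thresholding algorithm is
not published, so the defaults here are implementation choices, recorded in
the output's `params`: choriocapillaris uses a local adaptive threshold
(Gaussian-weighted local mean, window 51 px) with a fixed bias — a pixel is a
deficit when it is more than 25 intensity units (on a 0–255 scale) below its
local mean; the deep choroid uses a global Otsu threshold with dark-pixel
polarity. A constant image binarizes to an empty foreground with a warning.

**ETDRS grid.** Zones are fixed on the retina: sub-foveal disk of radius
500 µm, sub-parafoveal annulus to 1250 µm, sub-perifoveal annulus to 2500 µm,
with quadrants split along the ±45° diagonals (right-eye convention, nasal =
image left). Pixel radii are physical radius / (nominal pitch × correction
factor); membership is by pixel-center distance, boundary pixels belonging to
the inner zone. Inner zones are measured on 3 mm scans, the perifoveal
annulus on 6 mm scans. Rasterized zone areas converge to the analytic
circle/annulus areas (relative error < 1 % at ≥ 512 px per side; Gauss-circle
error is O(r^⅔)).

**Magnification correction.** Transverse image scale varies with ocular
biometry. The default model scales linearly with axial length against a
24.46 mm reference eye (factor = AL / 24.46); a Bennett reduced-eye variant
(factor = (AL − 1.82) / (24.46 − 1.82)) is selectable. Corneal radius is
accepted and validated for schematic-eye extensions but enters neither
default. Deficit areas are corrected as size × factor²; number and density
are dimensionless and need no correction. Axial lengths outside a 20–30 mm
sanity band are rejected.

**Vessel masking and registration.** A binary mask of large superficial
vessel projections is removed from both numerator and denominator of every
density. Sessions are registered by translation-only phase correlation
(rotation/scale between sessions assumed negligible); the confidence score is
the Pearson correlation between reference and registered image, and results
below a configurable floor (default 0.5) are flagged for exclusion.
Replicate scans of a session are averaged field-wise; a session with one
usable replicate is used as-is and flagged.

**Boundary rule.** A deficit straddling a zone boundary is counted in every
zone it intersects; only its in-zone pixels contribute to that zone's
density, while its full area enters the size average. No minimum deficit
size is imposed by default (configurable).

## Rhythmometry

Each series is fitted by least squares with a truncated Fourier basis at the
24-h fundamental, default two harmonics (K = 2; 5 parameters from 7 points —
the convention in the diurnal ocular literature; K is configurable). The
**diurnal amplitude** is the fitted curve's peak-to-trough range and the
**acrophase** the time of the fitted maximum. Both are located on a 1-minute
grid (earliest time on ties) and then polished by bounded scalar
minimization within one grid step, which removes grid-quantization error
(noiseless in-class curves are recovered to ~1e-14). The **daily mean** is
the arithmetic mean of all recorded sessions, including both duplicate-phase
9 AM sessions (configurable by dropping t = 24 upstream). Amplitude is also
reported as 100 × amplitude / daily mean, rounded to 2 decimals. A constant
series yields amplitude 0 and an undefined acrophase (`flat_fit` flag).
Auxiliary formulas: pulse pressure = SBP − DBP; MAP = (SBP − DBP)/3 + DBP.

## Circular statistics

Acrophases convert to angles at 2π/24 rad/h. Implemented directly:

- mean resultant length r = |Σe^{iθ}|/n and circular mean;
- Rayleigh uniformity p ≈ exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·r —
  accurate for n ≥ 4 and calibrated here against simulation (type-I error
  0.05 and uniform null p-distribution at n = 44);
- circular deviation in hours, default angular deviation √(2(1−r)); the
  √(−2 ln r) convention is selectable — neither is claimed to reproduce any
  particular published dispersion exactly;
- Watson's two-sample U² with a seeded permutation null,
  p = (1 + #{U²_perm ≥ U²_obs}) / (1 + n_perm), default n_perm = 9999 —
  preferred over asymptotic tables at group sizes of ~20;
- Fisher–Lee circular–circular correlation with permutation p (two-sided);
- phase relation: two acrophases are *in phase* when their circular
  separation is ≤ 2 h and *antiphase* when within 2 h of 12 h.

Subjects with undefined (flat-fit) acrophases are excluded from circular
summaries, with the retained n reported. Linear group contrasts use
Mann–Whitney U (exact enumeration when both groups ≤ 8 and untied, normal
approximation with tie correction otherwise) and Spearman's rank
correlation.

## Cohort-level inference

The time-of-day effect is reported from the one-group repeated-measures
ANOVA over all complete subjects — error df (s−1)(N−1), i.e. (6, 258) at
N = 44, s = 7 — while the between-group effect (1, N−2) and time × group
interaction ((s−1)(N−g), i.e. (6, 252)) come from the mixed model. No
sphericity correction is applied by default, matching the uncorrected df
convention; Greenhouse–Geisser is available via the `correction` argument.
Bonferroni pairwise session contrasts use paired t-tests over all session
pairs (21 for 7 sessions) with p × 21, capped at 1. Subjects missing any
session are excluded listwise from ANOVA but retained in rhythm and circular
summaries. The summary table's "daily mean ± SD" is computed across
subjects' daily means, and its amplitude-% column is recomputed from the
row's own mean amplitude and mean daily mean.

## Synthetic data: what it emulates, and what it does not

**Images.** Choriocapillaris fields are Gaussian speckle (mean 180, SD 10 on
a 0–255 scale) with non-overlapping, non-adjacent dark elliptical deficits
whose areas are drawn uniformly in µm² and rasterized exactly; the truth
records every blob's pixel set, so densities are exact pixel counts.
Deep-choroid fields are random-walk vessel strokes stamped until a target
dark fraction is reached (achieved value stored exactly, within ±2
percentage points of target). Projection masks are thick near-straight
strokes. These fixtures have controllable, known truth but are *not*
physically realistic OCT-A speckle: no depth-dependent signal roll-off,
projection tails, motion artifacts, or segmentation error. Passing
end-to-end tests therefore demonstrates correctness of the measurement
pipeline, not robustness to real acquisition artifacts.

**Cohorts.** Each subject's series is a single 24-h cosine:
value(t) = mesor_s + (amplitude_s/2)·cos(2π(t − acrophase_s)/24) + ε, with
subject parameters drawn from group-level normals (amplitude truncated at 0,
acrophase wrapped modulo 24 h) and ε i.i.d. Gaussian. The default
configuration encodes the reference study's design (24/20 split, 7 sessions)
and its reported group parameters for sub-foveal flow-deficit density
(myopes: amplitude 3.16 ± 1.92 %, acrophase 1:31 AM ± 3.58 h; non-myopes:
2.02 ± 1.10 %, 5:14 AM ± 3.97 h) and deep perfusion density (1.76 ± 0.90 vs
1.25 ± 0.53 %, shared acrophase 4:48 AM). The within-subject
session-to-session noise SD is not reported anywhere; the default of 0.5
index units (≈ ⅙ of the between-subject SD of flow-deficit density) is a
simulator choice, documented as such. Real series need not follow a single
cosine; the two-harmonic fit tolerates this, the generator does not model it.

A consequence worth stating plainly: with the reported effect sizes at
n = 24/20, the refractive-group contrasts are only moderately powered —
simulation here gives ≈ 0.5 for the Mann–Whitney amplitude contrast and
≈ 0.3 for the Watson U² acrophase contrast at α = 0.05 (≈ 0.6 / 0.45 even
with noise-free parameter recovery). Single significant findings at these
effect sizes are fragile, and the package reports the measured power rather
than asserting replication.

## Problem sizes and tolerances

Default validation sizes: morphometry oracle on 1,000 random 64×64 binary
maps (exact agreement required); rhythm recovery on 500 simulated subjects
(noiseless ≤ 1e-6 amplitude error, noisy median acrophase error < 30 min at
5 %-of-amplitude noise); Rayleigh null calibration on 10,000 samples of
n = 44; Watson U² calibration on 2,000 replicates with 499 permutations;
group-contrast power on 200 simulated cohorts with 999 permutations. All
simulations are seeded; permutation p-values are reproducible given the
seed. Registration recovers integer shifts exactly on noiseless fixtures;
subpixel accuracy is available via the upsampling factor.

## Known limitations

- No slab extraction or B-scan segmentation: inputs are already-exported
  en-face images.
- Registration is translation-only; ocular torsion or scale drift between
  sessions is not corrected.
- The binarization defaults are not tuned to any particular device's
  intensity statistics; window and bias should be revisited for real
  exports.
- Rhythm fitting assumes a 24-h period; free-running or multi-day designs
  are out of scope.
- Mixed-effects alternatives to the RM ANOVA, and multiplicity control
  across indices/regions, are deliberately not provided.
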