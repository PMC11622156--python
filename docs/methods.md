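# Methods

## The measurement problem

Static automated perimetry estimates a light-sensitivity threshold, in
perimetric dB (attenuation of maximum stimulus luminance), at each of the
54 locations of the 24-2 grid; the two locations on the physiologic blind
spot are excluded, leaving 52 per eye.  The Goldmann size III stimulus
(~0.43°) loses repeatability once sensitivity drops below roughly the
high-teens-to-low-twenties dB: responses there are noise-dominated.  The
size V stimulus (~1.72°) reads higher (spatial summation) and remains
usable deeper into damaged fields.  To compare fields taken with the two
stimuli, the pipeline censors each stimulus's sensitivities at a
stimulus-specific threshold and converts to age-corrected total deviation
(TD), then treats the pointwise TD pair as two measurements of the same
quantity.

## Censoring and TD conversion

Censoring replaces every raw sensitivity strictly below threshold *t* with
*t* (equality is not censored).  Censoring precedes TD conversion because
the threshold lives on the sensitivity scale; the resulting TD is

    TD(p) = max(S(p), t_s) − N_s(p, age).

A point *pair* is flagged censored when at least one of its two raw
sensitivities fell below its threshold; the flag always refers to the raw
value, never to the TD.  TDs are kept at floating precision since the
statistics of interest are sub-dB.

The normative expectation is linear in age:
N_s(p, age) = mean_ref_s(p) + slope_s(p)·(age − age_ref)/10.  Proprietary
instrument databases are unavailable, so the default table is a parametric
hill of vision — peak 34 dB at fixation falling 0.25 dB/deg of
eccentricity, −0.7 dB/decade, reference age 45 — with stimulus V offset
uniformly **+3 dB**.  The offset equals the spacing of the two stimulus
noise floors used throughout (21 and 24 dB), which is the configuration in
which a zero mean censored TD difference is attainable: for points deep
below both floors the censored difference is exactly
t_V − t_III − offset, so a threshold pair can only zero it when its gap
matches the normative offset.  A 3 dB summation offset is within the range
reported for size III→V in the mid-periphery.  Any table with the same
schema can be substituted from CSV; every statistic downstream is agnostic
to the source of the table.  Tables are stored in right-eye coordinates
and mirrored in x for left-eye lookups, as perimetry software does.

## Threshold selection

The search evaluates every (t_III, t_V) on a 15–30 dB integer grid (both
axes), bracketing the debated useful-dynamic-range cutoffs with margin.
For each cell it computes the mean and sample SD (n−1) of
d = TD_V − TD_III over the censored point pairs, and selects the cell with
|mean| closest to zero.  Cells with fewer than `min_count` (default 30)
censored pairs are ineligible, so the argmin cannot land on a tiny noisy
subset.

**Tie handling.**  On stochastic data two cells' means never tie exactly,
yet cells can differ by far less than their own sampling error; a strict
argmin would then flip between statistically equivalent cells from seed to
seed.  The selector therefore treats every eligible cell whose |mean| lies
within 2 standard errors (of the argmin cell's mean) of the minimal |mean|
as tied, and resolves the tied set to the lowest SD, then the lower t_III,
then the lower t_V.  With exact arithmetic the rule degenerates to
exact-equality ties, so deterministic toy examples behave as a plain
argmin with lexicographic tie-breaks.  This "closest to zero, preferring
stable cells" reading is also how the selection is described in the
perimetry literature this pipeline follows (lowest mean difference with
low standard deviation).

## Agreement battery

On the pooled point pairs at fixed thresholds: subgroup mean ± SD of d for
censored, uncensored and all pairs; a two-sided one-sample t-test of d
against 0 with df = n − 1 (undefined and flagged NaN at zero variance);
OLS of TD_V (y) on TD_III (x) with r² = 1 − SSE/SST; and Bland–Altman
per-point means/differences with limits of agreement at mean ± k·SD,
k = 2 by default (1.96 available).  Point pairs are treated as independent
observations — the 52 points of a field and repeated sessions of an eye
are correlated, so p-values are anti-conservative; a cluster bootstrap
resampling whole sessions is provided as a labelled robustness check, not
part of the primary battery.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
not any instrument's staircase:

- **One disease, two stimuli.**  A per-session deficit field D(p) ≥ 0 is
  subtracted from both stimuli's normative expectations; the stimuli
  differ only through their normals, floors and noise.  True sensitivity
  is clamped to [0, 50] dB.
- **Patterns.**  NAION: altitudinal loss — one hemifield (random side)
  depressed by the session's severity with a linear ramp (default width
  4°) across the horizontal meridian.  Glaucoma: arcuate loss — full
  severity in the Bjerrum annulus (10–21° eccentricity) of one hemifield,
  a nasal step at 60 % severity, and an optional diffuse component
  (default off).
- **Severity.**  Drawn per session, truncated normal on [0, 40] dB:
  24 ± 5 (glaucoma), 20 ± 5 (NAION).  These produce the bimodal
  moderate/severe mix characteristic of the target cohorts: affected
  regions sit at or below the size III floor while spared regions stay
  well inside both stimuli's reliable ranges.  A large unimodal mass of
  borderline points just above the floor would instead let near-floor
  noise dips dominate the censored subset and bias the threshold search
  upward; visual fields in moderate-to-severe optic neuropathy are
  regionally bimodal in exactly this way.
- **Noise.**  Above a stimulus's floor, Gaussian retest noise with SD
  interpolating linearly from 1.3 dB (III) / 1.2 dB (V) at 30 dB to
  3.0 / 2.0 dB at the floor (published pointwise retest ranges), rounded
  to integer dB and clamped to [0, 50].  Below the floor (21 dB for III,
  24 dB for V) the default `uniform` mode draws from the integers
  [0, floor): the response carries no signal.  This sub-floor regime is
  what makes the floors recoverable: at threshold pairs on or just below
  the floors all sub-floor observations clamp exactly, giving a censored
  mean of zero with near-zero SD, while cells below that shelf inherit
  residual uniform noise (higher SD) and cells above it accumulate biased
  gaussian dips.  A `clamp` mode without the sub-floor regime exists to
  show the optimizer's behaviour when no noise floor is present.
- **Demographics.**  Ages are participant-level truncated normals on
  [19, 90] (67.8 ± 9.3 glaucoma, 61.3 ± 7.7 NAION); sessions distribute
  round-robin over participants (1053 pairs / 120 participants and
  939 / 586, matching the source cohorts' repeated-measures ratios);
  sessions are treated as independent, as no within-subject correlation
  is available to calibrate (an explicit limitation).  Eye, severity and
  pattern side are drawn per session.  All draws flow from one integer
  seed; identical seeds give bit-identical cohorts.

What passing tests on these cohorts does **not** show: fidelity to SITA
staircase behaviour, fixation losses/false responses, learning and media
artefacts, real spatial correlation of deficits, or the true proprietary
normative surfaces.  Conclusions about the *method* (threshold recovery,
variance reduction, agreement geometry) transfer; absolute numbers (e.g.
censored fractions) need not.

## Problem sizes and numerical choices

- Library-scale checks run on 500-pair mixed cohorts (≈26 000 point
  pairs), where the threshold search is stable seed to seed; full-scale
  runs (1992 pairs → 103 584 point pairs) are used for the counting and
  demographic checks.  The search grid is 16 × 16 cells evaluated by
  vectorised array arithmetic on a precomputed (pairs × 52) matrix.
- Degenerate inputs are flagged, not silently absorbed: empty censored
  subsets report NaN means; single-element subsets report NaN SD;
  zero-variance t-tests report NaN; all-identical x rejects the OLS fit;
  a grid with no eligible cell raises with advice.
- The recovered threshold pair typically lands at (20, 23) — one grid
  step below the floors on the exactly-clamped shelf, within the 1 dB
  resolution the grid supports; (20, 23) and (21, 24) are
  indistinguishable by construction in the deep regime (every sub-floor
  draw clamps to the threshold in both cells), and the SD tie-break
  prefers the shelf over its noisier neighbours.

## Known limitations

- The pointwise t-test and OLS ignore within-field and within-subject
  correlation (by design, to match the standard pooled analysis); use the
  cluster bootstrap for honest intervals.
- The hill-of-vision surrogate is rotationally symmetric and linear in
  eccentricity and age; real normative surfaces are neither.  Parameter
  estimates that depend only on *differences* of TDs are insensitive to
  this; absolute TD levels are not.
- Censoring thresholds are searched on an integer grid; sub-dB optima are
  out of scope, as are cross-validated or gradient-based selectors.
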