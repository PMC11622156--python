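# vfcensor

Tools for making standard automated perimetry (SAP) visual fields acquired
with Goldmann stimulus **size III** and **size V** directly comparable.

Size III is the clinical default for 24-2 perimetry, but in eyes with
moderate-to-severe loss from glaucoma or non-arteritic anterior ischemic
optic neuropathy (NAION) many locations fall below its useful dynamic
range, where measurements are noise-dominated and unrepeatable.  The larger
size V stimulus reads several dB more sensitive and stays reliable deeper
into damaged fields.  `vfcensor` implements a censoring-based pipeline that
puts the two stimuli on one scale:

1. **Censor** raw sensitivities: every value below a stimulus-specific
   threshold *t<sub>s</sub>* is replaced by *t<sub>s</sub>*, removing the
   noise-dominated sub-floor range.
2. **Convert** to age-corrected total deviation,
   TD(p) = max(S(p), t<sub>s</sub>) − N<sub>s</sub>(p, age), where
   N<sub>s</sub> is the stimulus's normative expectation.
3. **Search** an exhaustive threshold grid for the pair
   (t<sub>III</sub>, t<sub>V</sub>) whose mean censored-pair TD difference
   d = TD<sub>V</sub> − TD<sub>III</sub> is closest to zero (statistical
   ties resolve to the lower SD, then the lower thresholds).
4. **Quantify agreement**: subgroup means/SDs of d by censorship, a paired
   t-test of d against 0, OLS of TD<sub>V</sub> on TD<sub>III</sub> versus
   the line of unity y = x, and Bland–Altman limits of agreement at
   mean(d) ± 2·SD(d).

Because the clinical datasets that motivate this pipeline are not publicly
available, the package ships a seeded synthetic-cohort generator
(`vfcensor.simulate`) that emulates their structure — glaucoma (120
participants, 1053 same-day III/V pairs, age 67.8 ± 9.3 y, arcuate
defects) and NAION (586 participants, 939 pairs, age 61.3 ± 7.7 y,
altitudinal defects) — with stimulus-specific noise floors and
heteroscedastic retest noise.  It also provides a parametric
hill-of-vision surrogate for the proprietary normative databases, with a
CSV override path for real tables.

## Worked example

```python
from vfcensor import (generate_combined, default_norms, grid_search,
                      make_point_pairs, analyze)

norms = default_norms()                      # hill-of-vision surrogates, III and V
pairs = generate_combined(500, seed=7)       # mixed glaucoma + NAION cohort
result = grid_search(pairs, *norms)          # 15-30 dB grid, both stimuli
df = make_point_pairs(pairs, result.best, *norms)
s = analyze(df)
```

prints (via the obvious f-strings):

```
optimal thresholds: III=20 dB, V=23 dB
mean censored TD difference at optimum: +0.004 dB
censored pairs:   +0.00 ± 0.18 dB  (n=9210)
uncensored pairs: +0.02 ± 2.08 dB  (n=16790)
line of best fit: y = -0.26 + 0.91x  (r² = 0.86)
Bland-Altman limits of agreement: [-3.34, +3.36] dB
```

The search recovers the generator's noise floors (21 and 24 dB) to within
1 dB: the selected pair sits on the exactly-clamped shelf one grid step
below the floors, where the censored-pair mean difference is zero and its
SD minimal.  After censoring, the censored subgroup's differences collapse
(± 0.18 dB here versus several dB uncensored at the same points), and the
pooled fit hugs the line of unity — the behaviour that makes size III and
size V TDs interchangeable in practice.

The same pipeline runs from the shell:

```bash
vfcensor report --cohort combined --n-pairs 500 --seed 7 --out out/
vfcensor simulate --cohort naion --n-pairs 100 --seed 1 --out sim/
vfcensor optimize --fields sim/fields.csv --out opt/
vfcensor agree --fields sim/fields.csv --t-iii 21 --t-v 24 --plot --out agr/
```

Every command writes a JSON sidecar with its full configuration and seed,
so outputs regenerate byte for byte.

## Reading real data

`read_fields` ingests a long-format CSV (one row per tested location:
`subject_id, cohort, eye, session_id, stimulus, age_years, x_deg, y_deg,
sensitivity_db`); `<0` tokens map to 0 dB and blind-spot rows are dropped.
`pair_same_day` matches III/V fields within a session.  Normative tables
load from CSV via `read_normative` (columns `stimulus, x_deg, y_deg,
mean_sensitivity_ref_db, age_slope_db_per_decade` plus a
`# reference_age=` header line).

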