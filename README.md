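# nirspulse

Cerebrovascular stiffness and compliance indices from near-infrared
spectroscopy (NiRS) pulse waveforms.

## The problem

Arterial stiffening is a primary marker of vascular ageing. In the brain it
is usually assessed with transcranial Doppler (TCD) or phase-contrast MRI,
both of which are costly or operator-intensive. Optical intensity recorded
by a NiRS montage over the scalp pulses with every heartbeat, because
cortical blood volume does; that cardiac waveform carries the same incident
and reflected pressure-wave structure as peripheral PPG. `nirspulse` turns
multi-channel NiRS recordings (plus simultaneous ECG R-peak times) into
scalar vascular-health indices per subject:

- **Timing index (TI)** — the reciprocal of the reflection time,

  `TI = 1 / (t_refl − t_sys)`  [1/s],

  where `t_sys` and `t_refl` are the systolic and reflected-wave fiducials
  of the epoch-averaged arterial pulsation signal *s*. Reflected waves
  travel faster in stiff arteries, so the reflection time shortens and TI
  rises with stiffness. Fiducials are located automatically from the zero
  crossings of the second derivative `s₂`: `t_sys = min(t_p1, t_zc2)`, and
  `t_refl` is the first positive local maximum of *s* between `t_zc3` and
  `t_zc4`, falling back to the `s₂` minimum in that window when the
  reflected wave appears only as a shoulder. Channels with fewer than four
  zero crossings, `t_sys < 125 ms`, `t_refl > 500 ms`, or values outside
  the per-subject mean ± 1.5 SD are excluded; a subject needs ≥ 10
  surviving channels.

- **Pulse relaxation function (PReFx)** — an area-ratio compliance index of
  the systolic-to-diastolic relaxation segment,

  `PReFx = A/B − 0.5`,

  where `A` is the area enclosed between *s* and the second diastolic
  level over `[t_S, t_D2]` and `B` is the bounding rectangle with those
  fiducials at its diagonal. A linear decline gives exactly 0; a bulging
  (late reflected wave, compliant) segment gives positive values. Channels
  outside `[−0.1, 0.4]` or whose peak-picker chose the reflected peak as
  systole are rejected; a subject needs > 10 surviving channels.

- **Comparators** — TCD augmentation index
  `AI = (V_refl − V_dia)/(V_sys − V_dia)`, MRI pulsatility index
  `PI = (F_max − F_min)/F̄`, and a non-exercise cardiorespiratory fitness
  estimate (CRF; eCRF drops the sex term).

- **Cohort statistics** — Lilliefors normality gating, Pearson/Spearman
  choice per variable pair, Benjamini–Hochberg FDR over the reported
  correlation family at α = 0.05.

A synthetic-data module generates composite arterial pulses (forward +
reflected + re-reflected bells, optional dicrotic notch, heart-period
jitter, noise) and whole multi-channel cohorts with known ground truth, so
the entire chain is validated against signals whose answers are known.

## Worked example

Simulate a 12-subject cohort, run the full pipeline, and print the
correlation report:

```bash
nirspulse run --n-subjects 12 --n-channels 16 --seed 0 --out-dir out/
```

```
12 subjects analysed; outputs in out
index factor         r        p   method  n  significant_after_fdr ...
   TI    age  0.932954 0.000716 spearman  8                   True
   TI AI_TCD  0.896127 0.002588 spearman  8                   True
   TI PI_MRI  0.896127 0.002588 spearman  8                   True
PReFx    age -0.972935 0.001089  pearson  6                   True
...
```

The simulated cohort links the reflection delay to a synthetic age
covariate, so the stiffness index TI correlates positively with age while
the compliance index PReFx correlates negatively — opposite signs on the
same factor, as expected from their definitions. Subjects whose waveforms
are too fused for ≥ 10 channels to survive the exclusion cascade get no
index (`n` < 12 in the report), mirroring how the method behaves on real
cohorts. `out/` contains the per-subject index table, the report, and an
audit log listing every channel's fate (kept or excluded, with the rule).

The same analysis is available per stage (`simulate`, `preprocess`, `ti`,
`prefx`, `indices`, `stats`) and as library functions
(`nirspulse.analyze_session`, `nirspulse.run_cohort`).

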