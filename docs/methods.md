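# Methods

## Signal model and preprocessing

Input is raw optical intensity per channel at a nominal 39.0625 Hz, with
simultaneous ECG R-peak times. Channels are selected by source–detector
distance (default 20–60 mm; 25–50 mm is the preset most likely to yield
usable cortical waveforms), divided by their mean (so downstream amplitudes
are dimensionless and raw gain cancels exactly), band-passed to 0.5–5.0 Hz,
epoch-averaged time-locked to the R peaks, and sign-flipped so systole — an
intensity trough in raw data — appears as a positive peak. The result is
the arterial pulsation signal *s* with its origin at the R peak.

Filter realization: 3rd-order Butterworth applied forward–backward
(`sosfiltfilt`). The band alone does not fix the realization; zero phase is
required because any group delay would bias the fiducial times that are the
package's outputs. Epochs start at the nearest sample to each R-peak time
(no sub-sample interpolation — at ~25 ms sampling the added precision would
be spurious) and must lie fully inside the recording. Epoch length defaults
to 1.8 × the median R-R interval: long enough to contain the diastolic
minima of two consecutive cycles (needed by PReFx), short enough to exclude
a third.

The manual pulse-shape screen used with real recordings is replaced by an
automated rule triple: the first-cycle maximum must be strictly interior,
both cycle endpoints must lie below the cycle mean, and the cardiac-band
SNR (power at harmonics 1–4 of the cardiac fundamental vs. the rest of the
spectrum) must be ≥ 3 dB. Every rejection carries a rule identifier so a
human can audit the cascade.

## Timing index

The second derivative s₂ of the first cardiac cycle is computed by central
differences after optional Savitzky–Golay smoothing (window 7, order 3,
default on). Raw second differences at 39 Hz ring on residual noise;
smoothing is switchable and both paths are tested. One caveat is inherent
to local polynomial smoothing: at an idealized, exactly-flat segment
followed by a sharp onset (which occurs in noise-free synthetic pulses but
not in averaged physiological data) the smoother rings and can insert
spurious zero-crossing pairs; tests of such constructed signals use the
unsmoothed path.

Zero crossings are sign changes between consecutive samples, timed by
linear interpolation; exact zeros belong to the crossing at that sample.
With fewer than four crossings in the first cycle the channel is excluded.
Fiducials:

- `t_sys = min(t_p1, t_zc2)` — the earlier of the first local maximum of
  *s* (plateaus resolved to their left edge, ties to the earliest time) and
  the second zero crossing. On waveforms whose systole survives only as an
  inflection on the rising edge of a dominant reflected wave, `t_zc2` lands
  on that inflection.
- `t_refl` — within the open window `(t_zc3, t_zc4)`: the earliest local
  maximum of *s* with positive value, else the s₂ minimum in the window
  (the point of maximal concavity marking a reflected shoulder).

Exclusion cascade, in a fixed order: the hard thresholds first
(`t_sys < 125 ms`, `t_refl > 500 ms`, both measured from the R peak, the
only origin defined for *s*), then a single pass of the mean ± 1.5 SD fence
with the statistics computed once over the threshold survivors (sample SD,
ddof = 1). A single pass is reproducible and auditable; iterating the fence
to a fixed point would remove ~13 % of any Gaussian sample per round. As a
consequence, idempotence of the cascade holds for well-clustered fiducial
sets but is not a theorem for arbitrary inputs. Subject-level TI is the
mean of per-channel `1/(t_refl − t_sys)` (mean of inverses) over ≥ 10
surviving channels; with fewer channels the subject has no TI. TI is
reported in 1/s.

## PReFx

Cycle boundaries sit at multiples of the median R-R interval within the
epoch. `t_D1`, `t_D2` are the minima of cycles 1 and 2, `t_S` the first
local maximum after `t_D1`. `A` is the trapezoidal integral of
`s − s(t_D2)` over `[t_S, t_D2]` at native sampling (no resampling), `B`
the rectangle `(t_D2 − t_S) · (s(t_S) − s(t_D2))`, and PReFx = A/B − 0.5.
The interval screen `[−0.1, 0.4]` is treated as closed at both ends. The
documented failure mode — `t_S` landing on the reflected peak when the true
systole is an inflection — is flagged automatically by comparing `t_S` with
the timing module's `t_sys`: a disagreement of more than one sample marks
the channel, replacing the manual screen used with real data. The range
rule is applied before the flag rule and both are logged. Subject-level
PReFx is the mean over strictly more than 10 surviving channels ("more than
ten", versus "ten or more" for TI — the two phrasings are implemented
literally as > 10 and ≥ 10).

PReFx is exactly invariant to positive amplitude scaling and vertical
offset of *s*, and a linear relaxation segment gives exactly 0 (the
trapezoid rule is exact on linear segments); both are regression-tested.

## Comparator indices

`PI = (F_max − F_min)/F̄` per artery, averaged over sides when both middle
cerebral arteries are available. `AI = (V_refl − V_dia)/(V_sys − V_dia)` on
a diastolic-peak-locked averaged velocity waveform; fiducials may be
supplied externally (mirroring manual placement) or proposed by the
detector with a review flag. The CRF non-exercise model is a linear
combination of sex, age, BMI, resting heart rate and an activity score;
the shipped coefficients are provisional defaults in the style of the
published non-exercise regressions and are configuration values — every
output records the coefficient set used. eCRF is the same combination with
the sex term dropped, hence exactly sex-independent.

## Statistics

Each variable is gated once for normality on all its available values
(Lilliefors at the 5 % level, as provided by statsmodels); a pair is
correlated with Pearson iff both variables pass, else Spearman, two-sided.
Missing cells use pairwise deletion, so n differs per cell. The
Benjamini–Hochberg step-up runs over the 8-cell family of the reported
(index × factor) matrix at α = 0.05 (family membership is configurable). A
constant vector is reported non-normal rather than raising: it carries no
distributional evidence. An independent brute-force step-up implementation
exists solely as a test oracle.

## Synthetic data

A beat is the pointwise sum of phenomenological bell components — incident
forward wave, reflected wave, optional re-reflected wave, optional negative
dicrotic notch. The default bell is a gamma-density-shaped curve (shape
k = 4, mode exactly at `peak_time`, peak value exactly `amplitude`,
`width` acting as a standard-deviation-like scale) because arterial pulses
rise fast and decay slowly; a pure Gaussian is available. No
transmission-line or Windkessel physics is implied.

Sessions repeat the composite at jittered heart periods (Gaussian jitter,
default SD 20 ms), invert polarity so systole is an intensity trough,
modulate a baseline intensity of 100 a.u. by 1 % per unit pulse amplitude
with a per-channel gain in [0.9, 1.1], and add white Gaussian noise
(`noise_sd` is expressed in units of the forward-wave amplitude; a pink
option is deliberately absent from the defaults). Source–detector
distances are spaced evenly over 25–50 mm.

Ground truth is defined on the noise-free composite restricted to ± one
component width around each component's peak, so that under partial overlap
the target is the composite's local extremum — what any detector could at
best find — rather than the isolated bell's peak. When components fuse
completely the truth collapses and the generator refuses to define it.

Three documented morphology presets cover the canonical waveform classes:
`distinct-peaks` (both peaks visible; reflected found as a positive peak),
`shoulder` (reflected visible only as an inflection after band-pass and
averaging; found via the s₂ minimum), and `systolic-inflection` (dominant
reflected peak; systole found via `t_zc2`). Preset parameters are package
choices selected so that each class is realized *and* the composite retains
a well-defined ground truth; fully fused waveforms, whose truth is
ambiguous, are represented in the cohort generator instead, where they
exercise the exclusion cascade rather than recovery accuracy.

The cohort generator draws ages uniformly over 20–70 years and maps age
linearly to the reflection delay (default 0.25 s at age 20 down to 0.10 s
at age 70). With stiffening, the reflected wave also fuses into systole,
modelled as its amplitude shrinking from 0.70 to 0.45 over that range; a
fixed broad re-reflected mound (amplitude 0.35, peak 0.60 s, width 0.12 s)
fills the relaxation segment the way peripheral re-reflections do in vivo.
Heart periods are uniform in 0.75–1.0 s per subject, sessions default to
60 s at 10 % noise, and demographics (sex, BMI, resting HR, activity) are
drawn independently. At the stiff end of the gradient the composite is
single-peaked and many channels are honestly removed by the `t_refl`
threshold, so the oldest subjects often have no TI/PReFx — the same
behaviour the method shows on real cohorts, and the cohort-level
correlations are computed over the subjects that retain an index.

What the generator does not emulate: motion artefacts, optode coupling
drift, heart-rate variability beyond white jitter, respiratory and Mayer
waves, channel-to-channel waveform heterogeneity beyond gain, and the
frequency-domain (AC/DC/phase) structure of the acquisition. Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not field performance on real recordings.

## Problem sizes and numerical choices

Validation runs use 1-channel 255 s sessions (~250 averaged epochs) for
noisy recovery, 100 seeded runs per preset; cohort properties use 40
subjects × 16 channels × 60 s sessions and 50 seeded cohorts. These sizes
give stable statistics while keeping the full suite in the low minutes on
one CPU. Trapezoidal integration is used everywhere an area is needed;
zero-crossing times interpolate linearly between bracketing samples; all
times are reported in seconds with sample-accurate provenance (nearest-
sample epoch alignment). Degenerate inputs (zero-mean channel, empty
`(t_zc3, t_zc4)` window, one-cycle epochs, zero-height PReFx rectangle)
raise typed errors or excluded-channel records rather than propagating
NaNs.

## Known limitations

- The automated quality screen and reflected-as-systole flag are principled
  stand-ins for manual steps used with real recordings; their pass rates
  are not comparable to manually screened data.
- The fiducial algorithm is sensitive to spurious second-derivative
  structure near the epoch origin; on real data this is mitigated by
  averaging, and on synthetic data by the simulator producing a convex
  leading diastolic segment.
- CRF coefficients are provisional configuration defaults, not values
  validated against any cohort.
- Human-cohort correlation magnitudes are not reproducible from synthetic
  data; only procedure-level and sign-level properties are validated.
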