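# gaitdmo

Digital mobility outcomes (DMOs) from a single lower-back triaxial
accelerometer: gait sequence detection, initial contact (IC) detection,
cadence and stride length estimation, together with the technical-validation
and ranking machinery needed to compare the algorithms against a reference
system — exercisable end-to-end on synthetic recordings with exact ground
truth.

## What is implemented

| module | contents |
|---|---|
| `gaitdmo.io` | data model (`ImuRecording`, `GaitSequence`, `Stride`, `WalkingBout`, `SubjectInfo`), CSV/JSON/YAML readers and writers, walking-bout validity rules (strides 0.2–3 s and ≥ 0.15 m, ≥ 2 strides per foot, 3 s break rule) |
| `gaitdmo.gsd` | three gait-sequence detectors: a frequency/convolution detector on the vertical + AP axes and a step-grouping detector on the acceleration norm with 0.1 g / 0.15 g peak thresholds and an adaptive step-duration threshold |
| `gaitdmo.icd` | four IC detectors: integrate-then-CWT on the vertical axis (scale 9, second-derivative-of-Gaussian), an AP-axis variant with a signal-adapted first-derivative wavelet scale, a symmetry-index-dispatched variant with extra smoothing for impaired gait, and a norm zero-crossing detector; plus sequence refinement (first IC − 1 s, last IC + 1 s) |
| `gaitdmo.cad` | cadence = 2 × stride frequency from alternating-IC stride durations, a per-second cadence profile, and a dedicated wavelet + morphological step segmenter |
| `gaitdmo.sl` | stride-length estimators: inverted pendulum `k·√(2lh − h²)` with double-integrated vertical excursion (two calibration constants, cohort-specific for MS), an intensity model `t·∛(mean|a_v|) + p`, and a hybrid AP-integration/geometric model |
| `gaitdmo.validate` | 0.1 s window classification for detection (majority-overlap rule), IC matching inside a centred 0.5 s tolerance window, accuracy/sensitivity/specificity/PPV, Bland–Altman bias and limits of agreement, ICC(2,1) with F-based CI, and weighted exponential fits of median error vs walking speed (0.05 m/s bins) or bout duration (2 s bins) |
| `gaitdmo.rank` | benefit/cost decision matrix with min–max cost inversion and a weighted performance index in [0, 1] |
| `gaitdmo.simgait` | synthetic signal generator: per-bout sinusoidal vertical acceleration from the inverted-pendulum relation, biphasic impact transients at the ICs, AP/ML components, asymmetry via alternating step amplitudes, seeded noise, and exact ground truth (ICs, strides, cadence, speed); a factorial standard fixture suite over cadence × duration × asymmetry × noise |
| `gaitdmo.pipeline` | end-to-end technical validation: detectors get the full recording, IC/cadence/stride-length estimators get the reference bouts, all statistics aggregated and ranked into a JSON report |

## CLI

```bash
# synthesise a recording plus ground truth from a YAML protocol
gaitdmo simulate --protocol protocol.yaml --out rec.csv --truth ref.json

# detect gait sequences, then ICs, cadence, stride length
gaitdmo gsd --algo b --in rec.csv --out gs.json
gaitdmo icd --algo a --in rec.csv --gs gs.json --out ics.json
gaitdmo cad --algo a --in rec.csv --gs gs.json --out cad.json
gaitdmo sl  --algo a --in rec.csv --ics ics.json --subject subject.yaml --out sl.json

# full technical validation over recording/reference pairs + ranking
gaitdmo run --pairs pairs.yaml --out report.json
gaitdmo rank --report report.json [--weights weights.yaml]
```

Protocol YAML example:

```yaml
bouts:
  - {start_s: 5.0, n_strides: 12, cadence_spm: 100, stride_length_m: 0.9}
seed: 1
noise_sd_g: 0.02
```

Subject YAML: `leg_length_m`, `foot_length_m`, optional `cohort`
(HA/PD/MS/COPD/CHF/PFF — selects the MS-specific pendulum constant for the
second pendulum variant).

Recording CSV: header `time_s,acc_v,acc_ap,acc_ml` (aliases
`acc_is`/`acc_pa` accepted), units g by default; an optional
`<file>.csv.yaml` sidecar can declare `units: m/s^2`, a sampling rate, axis
remapping and sign flips.

## Notes

- All filters are zero-phase; event timing is validated with a 0.25 s
  half-tolerance, so group delay matters.
- The single-scale Gaussian-derivative CWT is implemented in
  `gaitdmo._dsp.cwt_gauss` (SciPy removed `signal.cwt` in 1.15).
- Times are seconds from recording start; sample index = round(t × fs).
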