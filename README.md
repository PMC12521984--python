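# emfl

A tested re-implementation of the analysis pipeline behind an *efficient
multifunction fMRI localizer*: a single 274-second-per-run experiment in which
five visual conditions (faces, scenes, objects, bodies, words on scrambled
backgrounds) are crossed with five simultaneously presented auditory
conditions (false-belief stories, false-photo stories, non-words, quilted
audio, spoken arithmetic), so that one short scan localizes 14 of the most
widely studied functional regions — category-selective visual areas, speech
and language regions, the theory-of-mind network, and the multiple-demand
system — in each participant individually.

The package is aimed at cognitive-neuroscience methodologists who want a
fully synthetic, ground-truth-controlled testbed for this class of localizer
analysis: every stage from design generation to the final ANOVA runs on
simulated brains with known per-voxel condition amplitudes, so the
statistical machinery can be validated end to end without any data download.

## What it implements

- **Design** (`emfl.design`): the counterbalanced crossed block design — per
  274 s run, ten 22 s stimulus blocks (seven 3 s clips + 20.5 s audio + 1.5 s
  response window) and three 18 s fixation blocks; visual conditions twice
  per run in palindromic order, auditory conditions twice in
  semi-palindromic order; all 25 (visual, auditory) pairings exactly twice
  across five runs. Includes an exhaustive counterbalance validator and
  BIDS-style events TSV I/O.
- **Simulation** (`emfl.simulate`): ground-truth phantoms (14 anatomical
  constraint parcels with graded condition selectivity: a strong core and a
  weaker periphery, preferred/non-preferred amplitude ratio fixed per
  parcel) and BOLD sessions: boxcar ⊗ canonical HRF signal, linear drift,
  motion-like nuisance leakage, AR(1) noise, and a per-session voxel gain
  field modelling session-to-session pattern variability. Also simulates
  single-modality "standard localizer" sessions for cross-validation.
- **GLM** (`emfl.glm`): concatenated-run voxelwise least squares with 10
  condition regressors, 6 nuisance regressors, and per-run intercept +
  linear drift; contrasts `t = c'β̂ / √(σ̂² c'(X'X)⁺c)` with two-sided p and
  signed log-p maps `−log₁₀(p)·sgn(t)` (threshold 3 ⇔ p < 0.001). The
  crossed design is structurally rank-deficient (the visual and auditory
  boxcars share their sum), so the fit is minimum-norm with rank-aware
  degrees of freedom and an estimability check on contrasts.
- **fROIs** (`emfl.froi`): top-10 %-of-parcel selection with deterministic
  tie-breaking, the fixed-threshold detection rule (p < 0.001, ≥ 10 voxels),
  split-half cross-validated 10-condition response profiles with the
  same-modality baseline rule, and growing-window selectivity curves.
- **Validation** (`emfl.validation`): Dice overlap of fROI masks within and
  between localizers (with the analytic chance level k/N), voxelwise pattern
  correlation, and the 2×2×2(×14) selectivity ANOVA
  (contrast × definer × measurer × parcel).
- **Pipeline** (`emfl.pipeline`, `emfl` CLI): end-to-end simulated cohorts
  with one root seed, provenance sidecars, and Monte-Carlo study helpers.

## Worked example

```python
import emfl

schedule = emfl.generate_schedule(5, seed=1)
report = emfl.validate_counterbalance(schedule)
print(report.passed, report.pair_counts.to_numpy().min(),
      report.pair_counts.to_numpy().max())
# True 2 2

phantom = emfl.make_phantom(seed=2)           # 14 parcels, ratio 3, CNR ~ 1
mask = phantom.parcels > 0
session = emfl.simulate_session(phantom, schedule, seed=3, mask=mask)
fit = emfl.fit_session(session, mask=mask)

parcel = emfl.parcels_from_phantom(phantom)[0]      # FFA, Faces>Objects
res = emfl.compute_contrast(fit, parcel.defining_contrast)
det = emfl.detect_fixed_threshold(res, parcel)
print(det.detected, det.n_significant)
# True 20

profile = emfl.crossval_profile(session, parcel, mask=mask)
print({c: round(float(v), 2) for c, v in profile.response.items()
       if c in ("faces", "objects", "scenes")}, round(profile.baseline, 2))
# {'faces': 0.86, 'scenes': 0.43, 'objects': 0.18} 0.39
```

The FFA-like parcel is detected with 20 voxels beyond p < 0.001, and its
held-out response profile shows the designed selectivity: ~0.9 % signal to
faces against ~0.2–0.4 % for the other visual conditions, with the
same-modality baseline (0.39) marking the reference level for the auditory
conditions (which fold in the mean visual response under the crossed
design).

Running a full simulated cohort:

```bash
emfl run --config examples/cohort.yaml   # or: emfl design / simulate / fit / froi / validate
```

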