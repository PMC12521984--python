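# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data experiments do and do not establish.

## The design

A run lasts 274 s: three 18 s fixation blocks (run start, mid-run after the
fifth stimulus slot, run end) and ten 22 s stimulus blocks, each pairing one
visual condition (seven 3 s clips) with one auditory condition (20.5 s of
audio followed by a 1.5 s silent response window). The counterbalance
construction is deterministic given a seed: the visual order of a run is a
random permutation of the five conditions followed by its reversal (a
positional palindrome), and the auditory label of the block with visual
index *v* is (v + r) mod 5 in the first half of run *r* (0-based) and
(v + r + 1) mod 5 in the reversed half. This Latin-square offset scheme
yields every one of the 25 (visual, auditory) pairings exactly twice across
five runs, each condition exactly twice per run, and the two occurrences of
any visual condition paired with two different auditory conditions — all of
which `validate_counterbalance` rechecks exhaustively by brute-force
recounting. The mid-run and run-end fixation placement is a design choice
(the timing arithmetic does not constrain it); any placement preserves the
274 s total.

## The signal model and phantom

Each voxel's time course is simulated at TR = 2 s (137 volumes per run) as

    y(t) = B · (1 + Σ_c (a_c g / 100) · x_c(t) + drift(t) + leak(t)) + ε(t)

where `B` is the baseline intensity (default 100, so one intensity unit is
1 % signal), `x_c` is the condition boxcar convolved with the canonical HRF,
`a_c` the condition amplitude in percent signal, `g` a per-session voxel
gain, `drift` a per-run linear trend with random slope (max excursion 0.5 %),
`leak` a small coupling (sd 0.05 % per unit) to the six smoothed,
zero-mean, unit-sd motion-like nuisance time courses, and `ε` stationary
AR(1) Gaussian noise (marginal sd 1.0 intensity units, lag-1 coefficient
0.3 by default).

The HRF is the canonical double gamma: response gamma with shape 6 and unit
dispersion, undershoot gamma with shape 16 scaled by 1/6, 32 s support,
shape normalized to unit peak. Regressors are built on a 0.1 s grid and the
convolution kernel is scaled to unit sum, so a sustained block drives the
regressor to a plateau of 1 and betas read directly as sustained
percent-signal block responses. Simulation and fitting share the same
regressor code, which is what makes the noiseless-recovery tests exact.

The default phantom is a 24³ grid (2 mm isotropic in the NIfTI affine)
holding 14 disjoint compact 60-voxel parcels that mirror the localizer's
fROI inventory (three face-, three scene-selective parcels, LOC, EBA, VWFA,
rTPJ, a language parcel, a speech parcel, frontal and parietal
multiple-demand parcels). Inside a parcel every voxel responds to all ten
conditions; the preferred condition (both story conditions for the language
parcel) responds `ratio` (default 3) times the non-preferred amplitude
(default 0.5 % signal). Amplitudes are graded radially: the ceil(10 % · N)
voxels nearest the parcel centre form a full-amplitude core (flagged in the
ground truth), and the periphery steps down to 0.5 of the core amplitude
and ramps linearly to 0.2 at the parcel edge. The published figures do not
tabulate per-region effect sizes in percent signal, so these amplitudes are
free parameters of the phantom, calibrated once against two design targets:
a block-level contrast-to-noise ratio of about 1 (preferred minus
non-preferred = 1 % signal against unit noise; full-session core t ≈ 6.7)
and recovery of ≥ 80 % of core voxels by the top-10 % rule (measured 0.84
over 15 subjects). They were then frozen.

**Session-to-session variability.** Each simulated session draws an
independent multiplicative voxel gain field `g ~ 1 + N(0, 0.15)` (clipped
at 0.05). Splits *within* a session share the field; different sessions do
not. This is the mechanism by which within-localizer fROI overlap exceeds
between-localizer overlap, as observed in real data: with bitwise-identical
signal across sessions the two expectations would coincide. The value 0.15
is in the range implied by reported within-subject fMRI pattern
reliabilities and is part of the frozen generator conditions.

**Standard localizer sessions** use the same phantom amplitudes with a
single-modality alternating design: per run, 18 s fixation, five
preferred/baseline block pairs of 18 s with a mid-run fixation, and a final
fixation (234 s, 117 volumes); four runs by default so even/odd splits
exist. The composite "english" condition responds with the mean of the
false-belief and false-photo amplitudes.

## The GLM and its identifiability

All runs of a session are concatenated and fitted jointly per voxel:
condition regressors shared across runs, the six nuisance time courses
(demeaned per run), and per-run intercept + linear drift columns
(10 + 6 + 2·5 = 26 columns, 685 rows for five runs). Betas are rescaled to
percent signal by dividing by the fitted per-run baseline (the intercept),
which makes the noiseless recovery exact rather than approximate (scaling
by the empirical run mean would fold a fraction of the signal into the
scale factor).

The fully crossed design is structurally rank-deficient: every stimulus
block carries exactly one visual and one auditory condition, so the five
visual boxcars and the five auditory boxcars sum to the identical
"any stimulus" time course and exactly one rank is lost. Only the split of
the shared stimulus response between the modality means is unidentifiable;
every within-modality contrast is estimable. The fit is therefore
minimum-norm least squares (pseudoinverse) with dof = T − rank(X);
`build_design_matrix` recognizes this specific one-dimensional null space
and raises on any *other* collinearity, naming the offending columns, and
`compute_contrast` rejects inestimable contrasts. A practical consequence,
matching what the crossed paradigm shows in real data: each condition's
reported response folds in the average response to the simultaneously
presented opposite modality, which is why response profiles use the mean of
the five same-modality conditions as the baseline against which
opposite-modality responses are read. In the noiseless phantom this
identity is exact: the same-modality baseline equals the response to every
opposite-modality condition, and preferred − non-preferred =
(ratio − 1) × amplitude exactly.

Inference is ordinary least squares without prewhitening:
t = c'β̂ / √(σ̂² c'(X'X)⁺c), two-sided p at the residual dof, and signed
log-p maps −log₁₀(p)·sgn(t) computed via the log survival function so
extreme voxels stay finite; the map threshold 3 corresponds to p < 0.001 in
the positive direction, the same criterion as the fixed-threshold detection
rule (≥ 10 parcel voxels at p < 0.001, positive t). Under serially
independent noise these p-values are exact, and the null-calibration study
verifies the p < 0.001 rate inside its binomial band over 2×10⁵ voxel
tests. Under the default AR(1) noise (0.3) the unwhitened block-design test
is anticonservative — measured inflation of the nominal 0.001 rate by
roughly an order of magnitude — which is a known property of unwhitened
first-level pipelines. The calibration claims in this package therefore
refer to the serially independent regime; selectivity and overlap analyses
(which compare effect estimates, not nominal error rates) are run at the
default autocorrelated noise.

## fROIs, splits and validation statistics

Top-fraction selection ranks parcel voxels by signed log-p (descending)
with ties broken by linear voxel index (ascending), and keeps
round-half-away-from-zero(fraction · N), at least 1, voxels — only the
positive direction of the defining contrast is ever selected. The canonical
cross-validation split is odd runs {1,3,5} against even runs {2,4}; a
first-three/last-two split is also provided. Profiles are the average of
the two split directions; growing-window curves compute held-out means of
the top-k training-ranked voxels incrementally for k = 1..N and equal the
from-scratch means identically.

Dice overlap 2|A∩B|/(|A|+|B|) is compared within sessions (even vs. odd
halves), between sessions on the four matched half pairings (equivalent
statistical power), and between sessions using all runs; the chance level
for two independent size-k subsets of an N-voxel parcel is k/N (0.10 for
the top-10 % rule), with a Monte-Carlo estimator as cross-check. The
selectivity ANOVA is a fixed-effects factorial
(contrast × definer × measurer, optionally × parcel) fitted by OLS with
sequential sums of squares — identical to the classic cell-mean
decomposition on the balanced tables the pipeline produces (balance is
checked and violations name the missing cells); the residual pools over
subject replicates.

## Problem sizes and reproducibility

The Monte-Carlo studies are sized for a desk machine: the cohort study uses
50 simulated subjects (14 parcels each for selectivity cells; one parcel
per modality family — FFA, PPA, Language, FrontalMD — for the Dice
comparison), null calibration uses ten 20 736-voxel signal-free sessions
(207 360 voxel tests), and the interaction type-I study uses 400
table-level simulations of ten subjects with main effects but no
contrast × definer interaction — table-level because the quantity under
test is the ANOVA's error calibration, not the upstream estimator, and the
generating model matches the statistical structure the pipeline produces.
All randomness flows from one root seed through a fixed-order PCG64 draw of
per-subject (schedule, phantom, session A, session B) seeds, so every run
is bit-reproducible.

## What passing tests do and do not show

The phantom validates the machinery: estimator correctness (closed-form
oracles, exact noiseless recovery), error calibration under the stated
noise model, selection/overlap arithmetic, and the qualitative structure of
the published analyses (held-out selectivity, within > between overlap,
selectivity declining with fROI size, no spurious contrast × definer
interaction). It does not model spatial smoothness of real BOLD noise,
motion artifacts beyond linear leakage, anatomical variability beyond
parcel placement jitter, surface geometry, or inter-subject amplitude
heterogeneity; real-data effect sizes and participant counts from the
published tables are not reproduced here, and conclusions about real brains
require the real dataset.
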