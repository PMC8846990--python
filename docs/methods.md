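# Methods

This note documents the models, algorithms and design choices behind
`pulsentropy`: what each stage computes, which defaults were chosen where
the field's conventions leave room, and what the synthetic validation does
and does not establish.

## Signal model and preprocessing

A wrist-pulse recording is modelled as a quasi-periodic pressure waveform
(fundamental at the heart rate, 1–1.5 Hz, with harmonics essentially
confined below 10 Hz) superimposed on slow baseline wander (< 0.5 Hz,
respiration and sensor drift) and broadband measurement noise.

**Low-pass denoising.** A zero-phase Butterworth low-pass at 40 Hz
(order 12, applied forward–backward with `sosfiltfilt`). Zero-phase
filtering is used so that no phase distortion leaks into the ordinal and
template structure the entropy estimators measure. The order was chosen so
that the *two-pass* magnitude response keeps the passband within 1 % below
0.8 × cutoff while a 60 Hz mains tone is attenuated by more than 80 dB;
lower even orders are configurable.

**Baseline removal.** The record is decomposed with the discrete Meyer
wavelet to level `L = floor(log2(fs/0.5))` (L = 8 at 200 Hz), putting the
approximation band below ~0.5 Hz and hence below the pulse fundamental.
This is deeper than the conservative maximum level suggested by the
62-tap filter length; the decomposition remains well-defined (with
symmetric boundary handling) and the resulting approximation is used only
as a slow-trend estimate, which the subsequent smoothing makes robust to
boundary effects. The drift level is the energy ratio of the approximation
reconstruction to the whole record; if it exceeds 0.05 the baseline is
estimated by a cubic spline through the approximation sampled at 0.5 s
knots and subtracted, otherwise the record passes through untouched. The
0.05 threshold is a package default (clean z-scored pulses sit well below
it; visible wander trips it), not a literature constant.

**Trimming and normalization.** Beat onsets are the local minima preceding
systolic peaks (peaks ≥ 0.3 s apart with prominence ≥ ¼ of the robust
amplitude range); samples before the first and after the last onset are
dropped so only complete cycles remain. Records with fewer than two
detectable onsets raise a quality error and are excluded — an automated,
reproducible replacement for manual artifact inspection. Finally the
record is z-scored, which makes the relative tolerance `r = 0.15·σ` equal
to the absolute 0.15 and renders all downstream measures invariant to the
recording's original amplitude scale.

## Entropy estimators

Parameters (defaults): embedding dimension `m = 3`, tolerance factor
`r = 0.15·SD`, fuzzy exponent `n = 2`, `c = 6` dispersion classes, delay
`d = 1`, scales `τ = 1..10`. All Shannon sums use natural logarithms with
`0·ln 0 = 0`; PeEn and DiEn are normalized by `ln(m!)` and `ln(c^m)`.

- **Sample entropy** uses pooled pair counts: both template sets run over
  `i = 1..N−m` so the length-`m` and length-`m+1` pair sets are comparable,
  and the estimate is `−ln(ΣA/ΣB)`. A per-template averaged-log variant
  (approximate-entropy style) exists behind a flag for comparison but is
  not used by the pipeline. An undefined estimate (zero matches at either
  length) is a first-class `nan` return, not an exception: short
  coarse-grained series produce it legitimately, and the refined composite
  framework exists to reduce its incidence.
- **Fuzzy entropy** replaces the crisp threshold by `exp(−(d/r)^n)` on raw
  (uncentered) templates; per-template local-mean removal is available as
  an option but off by default. Membership sums are accumulated with the
  self-pair excluded *before* summation — subtracting the diagonal
  afterwards cancels catastrophically when memberships are tiny.
- **Permutation entropy** breaks amplitude ties by original index order
  (stable sort), the common deterministic convention.
- **Dispersion entropy** maps amplitudes through the normal CDF of the
  series' own mean and SD into `c` classes via `round(c·y + 0.5)` (half
  rounds up) clipped to `[1, c]`; for Gaussian data the classes are
  equiprobable by construction.

The O(N²) pairwise template matching dominates the pipeline's runtime and
is JIT-compiled (numba), with an early-exit in the crisp distance loop.
The vectorized/brute-force reference paths live in the test suite and are
used to verify the kernels to 1e-10.

## Refined composite multiscale framework

At scale `τ`, element `j` of the offset-`k` coarse-grained series is the
mean of `x` over the window `(j−1)τ+k .. jτ+k−1` (1-based), `j` running
while the window is complete — `floor((N−k+1)/τ)` elements, so offsets
`k > 1` never index past the end of the record.

For SaEn/FuEn the match counts are pooled over all `τ` offset series and
the entropy is `−ln(Σ_k A_k / Σ_k B_k)`; for PeEn/DiEn the pattern
distributions are averaged over offsets before the Shannon entropy is
taken. At `τ = 1` every refined composite measure reduces exactly to its
single-scale estimator.

Two quantities are deliberately frozen at full resolution across scales:
the tolerance `r` (standard multiscale-entropy convention — this is what
makes the decreasing white-noise profile emerge, since coarse-graining
shrinks white-noise variance relative to a fixed `r`) and the dispersion
class mapping's `(μ, σ)` (the convention of the refined composite
multiscale dispersion literature, keeping class identities comparable
across scales). The pattern measures are normalized to `[0, 1]` at every
scale, matching how per-scale values are conventionally tabulated; raw
nats are available via a flag. A traditional single-offset multiscale
variant is kept behind `refined=False` purely for comparison — it is used
to demonstrate that refined composite counting produces no more undefined
sample-entropy values at deep scales.

## Group comparison

Per (measure, hand, scale) cell the per-subject entropies are summarized
as mean ± SD (sample SD, ddof = 1) and compared with an independent
two-sample pooled-variance t-test at α = 0.05 — the literal reading of
the conventional protocol; Welch's test is a flag. Each group's normality
is checked with Shapiro–Wilk and logged; an optional fallback switches the
cell to Mann–Whitney U when either group fails the check. Per-scale
p-values are reported unadjusted, as is conventional for these tables, but
because 4 measures × 10 scales × 2 hands is a real multiplicity burden a
Holm-corrected column is emitted alongside, clearly separated. Undefined
entropy values are dropped from their cell with the count logged. Two
degenerate groups with zero variance and equal means give p = 1 by
convention; unequal means raise an error. Left and right hands are
analyzed separately throughout; no paired test is run.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets: two
groups of subjects, one 10 s record per subject and hand at 200 Hz
(2000 samples), resting heart rates in the 60–90 bpm band.

Each beat is a sum of three positive Gaussian lobes — percussion, tidal
and dicrotic waves — with amplitude ratios 1 : 0.4 : 0.25, centres at
15 %, 40 % and 65 % of the beat's RR interval, and widths 5–8 % of RR.
These constants were chosen once to visually resemble a radial pressure
pulse and are configurable defaults, not literature values. Beat-to-beat
intervals are `60/HR + ε`, `ε ~ N(0, rr_jitter_sd²)` truncated to keep
RR > 0.3 s; per-subject heart rate varies as `N(75, 6²)` bpm clipped to
[50, 100]. Baseline wander is a sinusoid (amplitude 0.3, frequency drawn
from [0.05, 0.5] Hz) and measurement noise is white Gaussian
(SD 0.03 ≈ 10 % of the waveform SD). Defaults: `rr_jitter_sd = 0.04 s`
(a typical resting SDNN), `n_per_group = 100` mirroring the target study
design (reduced explicitly in tests).

The group difference knob `effect` multiplies group B's `rr_jitter_sd` and
`noise_sd` by `1 + effect` — the simplest mechanism that measurably shifts
all four entropy measures in the same direction. `effect = 0` makes the
groups exchangeable by construction, which is what the type-I-error
calibration relies on. Per-record seeds are spawned from the root seed via
a counter, so enlarging a cohort never reshuffles existing records.

What the generator does *not* emulate: real pulse morphology variability
(no Windkessel hemodynamics, no pathological classes, no respiratory
amplitude modulation, no sensor-pressure dependence). Passing the
synthetic validation therefore shows the *pipeline* is correct and
calibrated — not that any particular physiological effect exists in real
recordings.

## Validation design and problem sizes

- Estimator correctness is established against independent brute-force
  enumerations (explicit double loops, full pattern counting, explicit
  offset-series construction) on ≥ 50 random series per estimator, to
  1e-10.
- The multiscale signatures use 30 replicates of N = 2000: white-noise
  RC_MSE strictly decreasing over τ = 1..10; 1/f-noise RC_MSE varying by
  < 25 % over τ = 2..10; refined composite counting yields no more
  undefined values than single-offset coarse-graining at τ = 10.
- The statistical calibration uses cohorts of 30 subjects per group with
  3 s records (the study-level properties under test — exchangeability,
  test level, power ordering — do not depend on record length, and the
  shorter records let the Monte-Carlo use 100 null cohorts and 100
  alternative cohorts): the per-cell rejection rate at α = 0.05 must lie
  in the binomial band [0.03, 0.07], detection of `effect = 1` must reach
  ≥ 80 % of cohorts, and power must be nondecreasing in
  `effect ∈ {0, 0.25, 0.5, 1}`.
- The acceptance script re-runs one full-size null study (10 s records,
  both hands) plus a reduced calibration, all seeded from the command
  line.

## Known limitations

- The baseline-removal threshold (0.05) and the onset-detector's
  prominence constant (¼ of the robust range) are heuristics tuned for
  pulse-like waveforms; pathological or very-low-amplitude records may
  need different values.
- Crisp sample entropy remains occasionally undefined at deep scales on
  short records even with refined composite counting; the study layer
  drops and logs such values rather than imputing them.
- The Shapiro–Wilk gate is informative, not gating, by default: the
  pooled t-test is always reported unless the Mann–Whitney fallback is
  explicitly enabled.
- Entropy differences between groups are assessed per cell; the Holm
  column guards the family per table, not across tables.
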