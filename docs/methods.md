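# Methods

This note documents the models, parameter choices and numerical decisions
behind `fearsense`, and what the synthetic-data tests do and do not
demonstrate about real sensor data.

## Camera registration (`fearsense.geometry`)

The visible→thermal mapping is the 8-parameter bilinear transform
`(x, y) ↦ (a·x + b·y + c·xy + d, e·x + f·y + g·xy + h)`. Four
correspondences determine it exactly: the x- and y-coefficient quadruples
solve two 4-unknown linear systems over the shared design rows
`(x, y, x·y, 1)`. A configuration is declared degenerate when the design
matrix's condition number exceeds 1e12 (three collinear points, repeated
points). The bilinear family handles translation, scale, shear and a mild
non-projective warp; it is not a homography and no lens distortion is
modelled — adequate for a parallel-axis, small-baseline rig.

Registration error is the per-probe Euclidean distance between a manually
marked thermal position and the transform-mapped position, and the report's
summary is the arithmetic mean of those distances. The embedded reference
probe table reproduces all nine published distances and their printed
average of 1.18 px under exactly this definition.

Calibration blobs are localized by thresholding at image mean + 3 SD
(configurable), 8-connected component grouping, and intensity-weighted
centroids, returned in row-major order (rows grouped within 5% of the image
height). The original system used NIR illuminators but did not describe the
localization; this procedure is deterministic and sub-pixel accurate on the
synthetic scenes (< 0.5 px).

## Facial temperature (`fearsense.thermal_face`)

Face/eye/nose boxes come from an external detector behind a plain data
interface (`FacialFeatureSet`); the cascade-style detector cited by the
original system is deliberately out of scope, and synthetic scenes supply
ground-truth features. Nostrils are refined inside the nose box by Otsu
binarization (dark foreground), keeping the two largest components;
parameter-free, since no method was published.

Region layout is parameterized on the inter-eye distance (IOD), making it
scale-equivariant and mirror-symmetric. Defaults (all configurable): region
size 0.5 × 0.35 IOD; forehead centre 0.6 IOD above the eye line; cheek
centres 0.45 IOD below the eye line and ±0.55 IOD lateral of the nose
centre. The published figure shows the layout but no dimensions; these
defaults are stated so results are reproducible.

Regions are mapped to thermal coordinates corner-by-corner and replaced by
the axis-aligned bounding box, clipped to the frame. Temperature is the
arithmetic mean of raw 14-bit counts (0–16383) over the region and over all
session frames; the "all regions" value is the unweighted mean of the five
session means. No count→°C conversion is applied: the published values are
on the raw-count scale (≈15,000), and absolute radiometric calibration is a
non-goal.

## Blink detection (`fearsense.eyeblink`)

Per frame: (1) corneal glints are pixels in the top 0.5% of the frame's
intensity range (8-connected, up to two components, left-to-right); (2) a
square search region (half-size 48 px default) is anchored on each glint;
(3) the sub-block template slides a 3×3 grid of sub-blocks over the region
at one-sub-block stride (trailing edge included), scoring
`mean(surround) − mean(centre)` so the locally darkest block wins, ties to
the smallest (y, x); mask side defaults to three nominal pupil radii rounded
to a multiple of 3; (4) the region is Otsu-binarized, the dark component at
(or nearest) the coarse centre is boundary-traced and fitted with a
least-squares ellipse. The fit succeeds only with ≥ 20 boundary points, axis
ratio ≤ 3 and both semi-axes in [4, 36] px — the bounds are what reject the
ragged large components that Otsu produces on eyelid-occluded or noise-only
regions. A frame is *open* iff either eye yields a successful fit
(robustness to unilateral glint loss).

A blink is an open→closed transition whose closed run lasts ≥ 2 frames
(debouncing single-frame detector flicker); a long closure counts once. The
rate is transitions × 60 / duration, with duration taken from timestamps
(span + one median frame interval), not from a nominal camera rate — the
hardware's advertised 150 fps was not achieved in practice, so rate math
never assumes it. Sessions with > 50% closed frames carry no usable blink
signal and are flagged for exclusion; the threshold is a package default
(none was published).

## EEG band powers (`fearsense.eeg_bands`)

Channels are min-max scaled to [−1, 1] per session (the power *ratio* is
scale-invariant, so normalization mostly matters for downstream plotting and
clipping behaviour; a constant channel normalizes to zeros with a warning).
Windows are non-overlapping rectangular 128-sample segments — 1 s at 128 Hz,
1 Hz bin spacing; a trailing partial window is discarded. The one-sided
periodogram is normalized so bin powers sum to the window's mean squared
amplitude (Parseval, verified to 1e−9). Band power sums bins with
`low ≤ f < high`; delta is 0.5–4 Hz (the DC bin can never enter), beta is
13–30 Hz. The source definition of beta is open-ended (">13 Hz"); the 30 Hz
default cap is the conventional beta upper edge and keeps line noise and
high-frequency artifacts out of the denominator — it is configurable up to
Nyquist. The session index is the mean of per-window delta/beta ratios;
windows with beta power below 1e−12 are skipped and counted. The alternative
(ratio of window-mean powers) is available behind `aggregate=` for
sensitivity analysis; for stationary signals the two coincide.

No artifact rejection (EOG/EMG, ICA) is performed — out of scope, matching
the original chain, and one stated reason the EEG modality ranks below FT/SE.

## Reliability statistics (`fearsense.reliability`)

*Welch's t-test* accepts raw vectors or (mean, sd, n) summaries; two-tailed
p from the t distribution with Welch–Satterthwaite df. The pre/post
comparison uses the *unpaired* unequal-variance test although the groups are
the same subjects — reproduced as the original protocol ran it, not
endorsed; a paired option exists but is not the default. No multiple-testing
correction is applied, likewise matching the protocol.

*Cohen's d* is `|m₂ − m₁| / sqrt((s₁² + s₂²)/2)` — for equal group sizes
this equals the classic pooled-SD form — reported as a magnitude. From the
published (rounded) group summaries this form reproduces all four published
d values to three decimals (e.g. 1.8677 vs 1.8675 for the subjective score);
the fourth-decimal residual of ≤ 3×10⁻⁴ is consistent with the original
values having been computed from unrounded raw data that was never released.
The facial-temperature d uses the right-cheek summaries and the EEG d the O1
electrode — in both cases the measurement the original analysis selected for
its lowest p-value. Labels use a nearest-anchor rule over {0.2, 0.5, 0.8}
(ties to the larger; d ≥ 0.8 always Large), which matches every published
label and fills the gap the published range rule leaves between 0.3 and 0.5.

*Correlations.* Per-subject (post − pre) changes are sign-aligned (FT and
EEG negated, since they fall under fear while BR and SE rise), correlated
pairwise (Pearson), and each modality is scored by the sum of its
off-diagonal correlations. Ranking reports the order by d, the order by
correlation sum, and the modalities in the top two of both. Neutral-clip
compensation subtracts each subject's neutral-condition change from the
fear-condition change.

## Synthetic data (`fearsense.synthetic`)

All generators are pure functions of their spec; randomness is numpy PCG64
(`default_rng`) seeded from the spec, so identical specs give bit-identical
output.

* **Calibration scene**: Gaussian blobs (σ 2.5 px, amplitude 200 over
  background 20) at four commanded centres; the thermal view holds the same
  blobs at transform-mapped positions, so the generated correspondences are
  exact by construction.
* **Face scene**: uniform skin with two dark nostril ellipses; the thermal
  frame holds a commanded constant count level on each region footprint
  (regions must not overlap, keeping levels unambiguous) plus optional
  Gaussian noise.
* **Eye sequence**: two eyes per frame, dark elliptical pupils (semi-axes
  15 × 12 px) with bright glints; a blink replaces the frame with a flat
  eyelid fill at skin intensity — the simplest stimulus that defeats both
  glint detection and ellipse fitting. Sequences default to 60 s at 5 fps on
  96×384 frames: a quarter-scale version of the real 512×2048 eye crop, at a
  rate where a 0.6 s blink still spans three frames — small enough that full
  blink-recovery sweeps (k = 0..30 blinks) run in the test suite while
  exercising every detector stage.
* **EEG**: sums of sinusoids at exact 1 Hz analysis bins (2 Hz delta tone,
  20 Hz beta tone by default) plus white noise; the analytic delta/beta
  ratio is the amplitude-squared ratio, returned with the recording. Real
  EEG's 1/f background and artifacts are deliberately not modelled.
* **Cohort**: independent Gaussian draws per subject × modality × phase ×
  condition. Defaults are the published 16-subject group parameters; the
  neutral condition uses the published neutral means with the fear-condition
  SDs, which were never published. Because cells are independent, simulated
  cohorts carry *no* between-modality correlation: the published correlation
  matrix is not a simulation target (an optional latent-factor parameter
  exists for stress-testing the statistics layer and is labelled
  non-physiological).

**What passing tests show — and don't.** Exact blink recovery, sub-pixel
blob localization and 2% EEG-ratio recovery on these stimuli validate the
*algorithmic chain* (thresholds, template scoring, windowing, band
accounting), not robustness to real-world nuisances: head motion, eyelash
occlusion, specular clutter, EEG artifacts and thermal drift are all outside
the generators' vocabulary.

## Known statistical limitations

Two properties of the published-parameter simulation are worth stating
because they are easy to over-read:

* `|d̂|` is biased upward for near-null effects: with a true blink-rate d of
  ≈0.16 and a sampling SD of ≈0.35 at n = 16, the magnitude estimator's
  expectation is ≈0.3 (folded-normal), so simulated cohorts do *not* centre
  on the small published value. The very unequal subjective-score SDs
  (0.272 vs 2.208) similarly add a few percent of multiplicative bias.
* The strict per-cohort ordering of all four effect sizes is unstable: the
  subjective-score and facial-temperature effects are close (≈1.87 vs
  ≈1.69) relative to their sampling spread, so their order flips in roughly
  a third of replicates. What *is* stable (≈96–97% of replicates) — and what
  the underlying analysis actually concluded — is the set statement: both
  large-effect modalities outrank both small-effect ones. The test suite and
  acceptance script report both statistics.

Problem sizes used by the test suite and acceptance script (500 simulated
cohorts, 60 s sensor sessions, 100-scene matcher oracles) are the package's
own choices, large enough that the Monte-Carlo error bands quoted above are
meaningful.
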