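# Methods

## Scope and model

`pawpress` implements static posturography for a quadruped standing with
its two forelimbs on a pressure platform. The measured object is a time
series of calibrated pressure frames $p_t(r,c)$ (kPa) on a regular grid of
1 cm² sensors. From it the pipeline derives, per limb: the percentage load
share, contact area, mean and maximum pressure, the limb centre of
pressure (COP) and the maximal-pressure point; and for the body as a
whole: the COP trajectory, its statokinesiogram (90% coverage ellipse) and
stabilogram (per-axis COP traces). Cohort aggregation and the group
contrasts operate on these derived parameters.

Platform coordinates put the origin at the grid centre, x latero-lateral
(animal's left negative), y craniocaudal (cranial positive); the sensor at
cell $(r,c)$ sits at $((c-\tfrac{cols-1}{2})\,\delta,\ (\tfrac{rows-1}{2}-r)\,\delta)$
with pitch $\delta = 10$ mm. Defaults describe a 48 × 48 cm, 100 Hz
platform with a 30–400 kPa sensitivity range. The device's manual display
calibration of 212 kPa bounds the rendering colour scale; it is treated as
a display setting, not an acquisition clip, because standing-trial maximum
pressures routinely exceed it. An optional flag applies it as a hard
saturation cap instead.

## Segmentation and validity

Active sensors are those at or above the 30 kPa floor (inclusive).
Connected components of the activation mask (8-connectivity, since digital
pads can touch diagonally at 1 cm resolution) are clustered into limbs by
splitting the x-sorted component centroids at their largest latero-lateral
gap. The split is accepted only when that gap is at least 30 mm (three
pitches) and no second comparable gap exists; otherwise the frame is
flagged (≠ 2 clusters) and its sensors left unassigned. Unassigned sensors
are excluded from per-limb statistics but included in the body COP, which
is limb-agnostic.

The immobility rule — only trials with the animal completely still are
valid — is quantified as: every frame resolves into exactly two limb
clusters; each limb's footprint centroid stays within 10 mm (one pitch) of
its trial mean; and each limb's contact area has a coefficient of
variation ≤ 0.15. The numeric thresholds are this package's declared
defaults; the underlying acquisition software's criteria are not public.

## Per-limb parameters

Load share per frame is the limb's pressure sum over the two-limb total,
× 100; the trial value is the unweighted mean over cleanly segmented
frames, so the two shares sum to exactly 100. Contact area is the active-
sensor count × 1 cm², frame-averaged (hence possibly non-integer). Mean
pressure averages only active sensors (pedobarographic convention; keeps
mean ≥ floor), frame-averaged; maximum pressure is peak-hold — the single
highest reading over the whole trial, consistent with reported maxima
approaching the sensor range. Limb COP is the pressure-weighted centroid,
frame-averaged; the maximal-pressure point is the location of the peak
sensor (ties broken by first occurrence in frame/row/column order).

Asymmetry indices compare the limbs per subject. The load-distribution
difference is the absolute difference of shares (percentage points); area
and mean-pressure differences are $|a-b| / \frac{a+b}{2} \times 100$,
normalised by the two-limb mean — of the candidate formulas this is the
one consistent with published summary tables of this design (up to
per-subject vs group-mean averaging). Published maximum-pressure
differences are not consistent with any single candidate formula applied
to group means, so that formula is selectable (`mean_normalized` default,
`ll_normalized`, `absolute`) rather than silently resolved. Indices are
reported as absolute values (the field convention compares the
lesser-value and higher-value limb); the sound limb is identified as the
one with the higher load share. Subject-level values are unweighted means
over the (typically three) valid trials.

## COP sway

The body COP per frame is $\sum_i p_i x_i / \sum_i p_i$ over all active
sensors. The statokinesiogram is the 90% **prediction ellipse** under a
bivariate-normal model — the standard posturographic estimator of an
ellipse "containing 90% of the points": with sample covariance $\Sigma$
(n−1 denominator) and eigenvalues $\lambda_1 \ge \lambda_2$,

$$\text{semi-axes} = \sqrt{\chi^2_{0.90,2}\,\lambda_i}, \qquad
\text{area} = \pi\,\chi^2_{0.90,2}\sqrt{\lambda_1\lambda_2},
\qquad \chi^2_{0.90,2} \approx 4.60517 .$$

An empirical variant (covariance-shaped ellipse rescaled to cover exactly
⌈0.9 n⌉ points) is available for sensitivity analysis. Fewer than three
points or a rank-deficient covariance produce a *degenerate* fit — a
flagged zero-area result rather than an exception — so plotting a
constant trajectory cannot crash. Trials are pooled over their full
duration at the native sampling rate (no sub-blocking, no resampling).
Stabilogram summaries are per-axis mean, SD (n−1) and peak-to-peak range.

## The synthetic standing-dog generator

No real recordings are distributed, so the generator is first-class: it
defines the study conditions every downstream result is validated under.

* **Footprints.** Each forepaw is five isotropic Gaussian pressure bumps —
  one metacarpal pad (radius 13 mm, relative amplitude 1.0) and four
  digital pads (radius 7 mm, amplitude 0.45) in a cranial arc — at fixed
  positions: a standing dog keeps its paws planted, so sway is produced by
  re-weighting, never by translating footprints. Default paw centres are
  (±80, 0) mm.
* **Load.** The limbs divide `total_force_N` (default 900 N) according to
  `load_split`. The default force reproduces the pressure/area magnitudes
  a platform of this class reports for large-breed dogs (mean pressures
  ≈ 90–125 kPa over ≈ 35–50 cm²); it is a device-scale emulation choice,
  not the animals' scale weight. `load_split` governs the **measured**
  (post-floor) force division: after sampling and floor-zeroing, each
  limb's field is renormalised (three fixed-point iterations) so its
  quadrature force $10^{-3}\sum p_i \cdot 100\,\text{mm}^2$ matches the
  target exactly. Without this, floor truncation of the Gaussian tails
  biases recovered shares by up to ~0.5 percentage points.
* **Pad elasticity.** Pads spread under load: pad radii scale as
  $(F_\text{limb}/(F_\text{total}/2))^{\gamma}$ with $\gamma = 0.25$ by
  default — a qualitative law (no quantitative one is published) that
  makes the loaded limb's contact area strictly larger.
* **Sway.** Body-COP sway is an Ornstein–Uhlenbeck process per axis,
  $dX = -\theta X\,dt + \sigma\,dW$, exact discretisation, stationary SD
  $\sigma/\sqrt{2\theta}$ (θ = 1 s⁻¹ default; a `filtered-noise` i.i.d.
  variant exists for convergence tests). Latero-lateral sway is realised
  as a weight shift between the limbs ($\Delta s = dx / \text{span}$);
  craniocaudal sway and per-limb COP jitter linearly re-weight each paw's
  pads about their mass centroid. Because the sensor floor amplifies
  measured centroid shifts (truncated tails move asymmetrically), the
  simulator probes each limb's measured-COP response to a ±1 mm tilt and
  divides requested displacements by that gain, so imposed sway
  dispersions are faithful (gain ≈ 1.2 uncorrected on the craniocaudal
  axis).
* **Sensor model.** Sample at sensor centres, add i.i.d. Gaussian noise
  (2 kPa SD — unpublished; small against the 30 kPa floor), zero below
  the floor, clip at the 400 kPa ceiling, quantise to 0.5 kPa, zero
  outside the active mask. Identical config + seed is bit-reproducible.
* **Defaults as study conditions.** The default single-trial config is a
  *sound* dog: 50/50 split and sway stationary SDs (0.5, 0.3) mm —
  reverse-engineered from the sound-cohort ellipse area 2.17 mm² via
  area $= \pi\,\chi^2\,\sigma_x\sigma_y$, since no per-axis sway SDs are
  published. The cohort generator draws per-dog load asymmetry and
  sway-ellipse area from the three study conditions (asymmetry
  20.56 ± 5.00 → 8.51 ± 5.25 pp for the lame group at day 0 → 90,
  3.63 ± 2.48 pp for controls; ellipse areas 44.71 ± 26.82, 13.91 ± 4.12,
  2.17 ± 1.10 mm²) at a fixed 5:3 sway-axis ratio. The same physical dog
  underlies a lame subject's two sessions: day-0 and day-90 draws share a
  latent severity with correlation 0.9, making treatment contrasts paired
  (marginal means/SDs are unchanged). 5 dogs per group, three 10-s trials
  each.

What the generator does **not** emulate: hindlimb or four-limb scenes,
gait, real pad shapes and inter-dog conformation differences, spatially
correlated sensor noise, drift/creep of the sensors, or genuine
biomechanics of balance (no inverted-pendulum dynamics). Passing
recovery tests therefore shows the *pipeline* is correct and unbiased
under plausible stance statistics — not that the physiological model of
lameness is validated on real dogs.

## Group statistics

The cohort table is long-form (subject, group, day, parameter, limb role);
limb roles LL/SL are the lesser/higher-value limbs (lame/sound in the lame
group). Summaries report mean ± SD and the t-based 95% CI
(mean ± t₀.₉₇₅,ₙ₋₁·SD/√n). Three contrast designs cover the study's
reported tests: limb (LL vs SL) as a within-subject factor via
repeated-measures ANOVA; day (0 vs 90) within the lame group, also
repeated-measures; and day-90 lame vs control as a one-way between-group
ANOVA with Tukey-HSD-adjusted pairwise p-values. Shapiro–Wilk (residual
normality) and Levene (homoscedasticity) accompany every contrast, flagged
at α = 0.05. The exact factor structure of the original analysis is not
published; this layout reproduces each reported contrast individually and
is a documented modelling choice. Standard library routines (statsmodels
`AnovaRM`, `pairwise_tukeyhsd`; scipy tests) provide the machinery — the
statistics here are supporting apparatus, not the package's contribution.

## Numerical choices and problem sizes

* Floor comparison is inclusive (≥ 30 kPa); CSV bundles store repr-precision
  floats and are re-read with round-trip parsing, so write→read is the
  identity on frames.
* Sample covariance uses the n−1 denominator everywhere (documented for
  reproducibility); ellipse orientation is reported modulo π.
* Degenerate inputs: all-empty recordings raise; empty frames are dropped
  from trajectories with a warning; zero-variance cells yield zero-width
  CIs; the Tukey/ANOVA layer refuses singular designs by naming the
  missing cells.
* Test problem sizes are chosen for desk-scale runs: property tests use
  0.05–2 s trials; end-to-end recovery uses the full 10 s × 100 Hz trial;
  ellipse convergence uses 20,000-point samples; the null-calibration
  check runs 500 simulated cohorts. The analysis scripts run the full
  45-trial cohort at 10 s per trial.

## Known limitations

* The largest-gap limb split assumes a two-print scene; four-limb stances
  are out of scope and fail loudly.
* Pad-level anatomy is ordinal only (pad positions in the template); no
  per-pad pressure decomposition is attempted beyond peak localisation.
* The generator's elasticity exponent, noise SD, sway axis ratio and
  mean-reversion rate are plausibility choices, not fitted values; all are
  configurable.
* With 1 cm² sensors, contact area is quantised; monotonicity of area in
  load holds at elasticity-resolving load steps (a 2–4 pp change in load
  fraction per step).
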