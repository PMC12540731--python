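# Methods

This package re-implements, as tested and reusable code, the quantitative
pipeline of a chromosome-congression study: spindle-frame geometry on 2D
maximum-projection tracks, polar/aligned classification and congression
kinematics, immunofluorescence intensity normalization and ratio
statistics, the study's statistical toolkit, and a synthetic spindle
generator that encodes the underlying biological model so that every stage
can be exercised against known ground truth without raw microscopy data.

## Coordinate frame and geometry

All live-cell quantities are computed in 2D, matching analysis of maximum
intensity projections. Per frame, the spindle axis is the line through the
two pole positions (poles are annotated at the centriole pair, or at the
Aurora A signal centre on acentriolar poles); the equatorial (metaphase)
plane is the line through the midpoint of the pole–pole segment,
perpendicular to the axis. A kinetochore pair is represented by the
midpoint of its two sister centres. Distances to the nearest pole, to the
spindle midpoint ("centre of the equatorial plane") and to the plane are
measured from that midpoint; the pair–axis angle is taken at the nearest
pole between the axis and the pole→pair line. Exact nearest-pole ties are
broken toward the lexicographically smaller pole identifier. Units are µm,
minutes and degrees throughout.

## Classification and kinematics

* **Polar vs aligned.** A pair is *aligned* if either sister is within
  3 µm of the equatorial plane, or if its midpoint is at least as close to
  the spindle centre as to the nearest pole; otherwise it is *polar*. The
  two aligned rules are combined as a union, so the classification is a
  partition and is monotone in the 3-µm threshold.
* **Alignment event.** The first frame at which the pair midpoint comes
  within 2 µm of the plane. Pairs that never cross are censored, with the
  reason (anaphase or end of track) recorded.
* **Congression velocity.** Net Euclidean displacement of the pair
  midpoint over the last 6 min before the 2-µm crossing, divided by the
  window. If pre-crossing coverage is shorter than 6 but at least 3 min,
  the available window is used and flagged; below 3 min the velocity is
  undefined. A summed path-length variant is reported alongside. The
  window is interpreted as wall-clock time before the crossing, so for
  pairs that initiate late it includes pre-movement dwell; this is a
  property of the definition, not an estimator bias (the recovery tests
  use tracks that move through the whole window).
* **Residence time.** Bipolarization to alignment; censored at anaphase
  onset (or at the last observed frame) for pairs that never align.
  Alignment annotated before bipolarization is clamped to zero with a
  warning.
* **Polar count.** Number of polar pairs at the frame nearest a query
  time — by convention 5 min after bipolarization — reported in total and
  per nearest pole. The same classifier applied to a single snapshot
  reproduces fixed-cell counting.
* **Mitosis duration.** NEBD to one frame before anaphase onset; censored
  at the last frame when anaphase is not reached.
* **Initiation vs distance.** Per pair, the time from the first tracked
  frame to alignment is regressed (OLS) on the pair's initial distance to
  the nearest centrosome, censored pairs listed but excluded from the fit.
  The fit is reported only when at least three uncensored pairs exist.

Missing track frames: gaps of at most 2 frames are closed by per-sister
linear interpolation; longer gaps split the usable window of whichever
metric encounters them. Leading/trailing gaps are never extrapolated.

## Intensity quantification

ROI means are corrected by subtracting the cytoplasmic background of the
same cell; integrated sum-projection values are first divided by the
number of z-planes. Corrected values are clamped at zero with a flag
(downstream ratios must remain interpretable). Kinetochore signals are
normalized to the corrected CENP-A reference of the same ROI, making all
ratios invariant to overall intensity scale. Kinetochore pairs within the
circular pole signal (≤ 1 µm from the centrosome, boundary excluded —
"outside" is read strictly) are removed before any kinetochore statistic,
to avoid the non-specific pole staining of phospho-antibodies; a radius of
0 disables the filter. Per cell the pipeline computes the
centriolar/acentriolar pole ratio (for same-class pole pairs, the max/min
"maximum difference" readout, flagged), the polar-vs-aligned mean
normalized kinetochore ratio, and the OLS regression of normalized
intensity on pole distance (the gradient signature).

## Statistics

Group scatter is summarized as mean and sample SD with 95% confidence
intervals for both (t interval for the mean, chi-square interval for the
SD). Multi-group comparisons use the classical one-way ANOVA
decomposition followed by pairwise two-sided Tukey HSD at the 5% level,
with the Tukey–Kramer standard error for unbalanced groups
(q = |mᵢ−mⱼ| / √(MSW·(1/nᵢ+1/nⱼ)/2), p from the studentized-range
distribution with k groups and the within-group df; evaluated via scipy's
`studentized_range`, cross-checked in the tests against a 10⁶-draw
Monte-Carlo oracle). Stars follow the ∗ <0.05, ∗∗ <0.01, ∗∗∗ <0.001,
∗∗∗∗ <0.0001 convention. Trends use OLS with a two-tailed slope t-test
(df = n−2) and R²; an exactly-fitting line is reported with p = 0 and an
exact-fit flag, and x without variance is an error. Censored residence
times are excluded from ANOVA input by default (an
include-censored-at-anaphase variant can be built from the per-pair
table, which labels censoring explicitly).

## The synthetic spindle generator

The generator encodes the model the analyses are designed to detect:
**Aurora A forms a pole-centred activity gradient whose amplitude scales
with centriole content; when CENP-E is inactive, local Aurora activity
above a threshold blocks congression initiation.**

* Activity: A(d) = A_pole · exp(−d²/2σ²) with σ = 1.5 µm, so activity
  falls below 14% of the pole value beyond 3 µm (the "~3 µm radius"
  gradient). Centriolar poles have amplitude A₀ = 1; acentriolar poles
  ρ·A₀ with ρ = 0.25, matching the ~4-fold pole asymmetry.
* Initiation hazard: h(d) = h_max with CENP-E active;
  h_max·max(0, 1 − α·A(d)/A_thr) without it (h_max = 0.55 min⁻¹,
  A_thr = 0.4; α ≤ 1 models acute Aurora A inhibition). Near a centriolar
  pole the hazard is exactly 0 for d ≤ ~2 µm; it recovers smoothly with
  distance, which is what makes time-to-alignment decrease with initial
  pole distance in the initiation analysis.
* Cells: a 12-µm spindle along x, elongating linearly from 1 µm at NEBD
  (t = 0) to full length at bipolarization (t = 10 min). Per pole,
  Poisson(4) initially-polar pairs (capped so the total stays within the
  23 pairs resolvable per projection) are placed on a 3D sphere of radius
  d ~ U(0.5, 2) µm around the pole, biased toward the spindle interior
  (±45° in-plane, small out-of-plane elevation so the hazard's distance
  is exactly d); the remaining pairs start at the plate (axial SD
  0.75 µm clipped at ±2 µm, lateral radius ≤ 3 µm). Sisters sit 0.8 µm
  apart along the axis.
* Dynamics: from bipolarization each polar pair waits an exponential time
  under its hazard (exact cumulative-hazard inversion with the hazard
  piecewise-constant per 1-min frame — this reproduces the 1/h mean delay
  exactly, which an end-of-frame Bernoulli approximation does not), then
  moves in a straight line toward a drawn plate point (lateral radius
  ≤ 1.5 µm) at a drawn speed ~N(1.5, 0.3) µm/min. Control cells enter
  anaphase at 60 min provided every pair has reached the plate; otherwise
  observation continues to the 120-min window end with anaphase absent.
  Aurora-inhibitor presets apply α from drug addition (5 min after
  bipolarization) and end emission at fixation 8 min later, emulating the
  fixed-cell assay.
* Emission: simulation is 3D; positions are projected to 2D and emitted
  with isotropic 0.05-µm Gaussian localization noise. Kinetochore pair
  tracks start at bipolarization (on the ~1-µm pre-bipolar spindle the
  polar/aligned geometry is meaningless and tracking of the emulated
  assays begins at pseudo-metaphase); pole tracks span the whole
  recording.
* Intensities: a fixed-cell snapshot at the preset's readout time. Pole
  ROIs (pAurA) have true mean κ·A_pole (κ = 1000 a.u.); kinetochore ROIs
  have true mean I₀ + β·α·A(d) (I₀ = 50, β = 500) with d the measured
  distance to the nearest pole; CENP-A reference ~N(200, 20) and
  cytoplasmic background ~N(30, 5) are drawn per ROI, with multiplicative
  noise CV 5% (poles) / 10% (kinetochores). The drawn background enters
  both the signal and the recorded background field, so correction is
  unbiased by construction; a `zero_noise()` preset variant switches all
  four noise terms off, making the 1:0 pole ratio exactly 1/ρ = 4.
* Determinism: everything is a function of (preset, seed); cohort child
  seeds derive from the root seed via `numpy` SeedSequence, and all CSV
  output uses fixed 6-significant-digit formatting, so identical
  configurations produce byte-identical files.

### Calibration and what the generator does not emulate

The hazard/gradient constants above are model parameters chosen once and
verified by Monte-Carlo to recapitulate the headline cohort statistics
(mean polar counts of ≈8 / <1 / ≈4 / ≈1 and the pole-intensity ratio of
≈4) before release; the placement and plate-target geometry are part of
that calibration. Under these parameters the acute Aurora-attenuation arm
(α = 0.5, fixation 8 min post-drug) predicts a polar-count fold change of
≈1.5–1.7 rather than a full 2-fold: a third of initially-polar pairs sit
within 1 µm of the pole, where attenuated Aurora activity still exceeds
the hazard threshold. This is the model's honest output and is reported
as computed.

The generator does not emulate: pre-initiation poleward oscillation
(polar pairs are static until initiation), microtubule dynamics, fibrous
corona mass, SAC signalling, monopolar intermediates of single-centriole
spindles, z-dependent tracking loss (tracks are complete; the analysis'
gap handling is tested with synthetic gaps), or image formation. Passing
tests therefore demonstrate that the measurement pipeline recovers known
generative truth under realistic noise and geometry — not that the
biological model itself is correct.

## Problem sizes and numerical choices

Simulated recapitulation checks use 20-cell cohorts (the typical
per-condition cell numbers of such experiments) at 1-min frames over a
120-min window; property suites use 100–1000 random configurations or
tracks and a 10⁶-draw studentized-range oracle. Degenerate inputs fail
loudly: coincident poles name the frame, non-positive corrected
references name the ROI, zero within-group variance and zero x-variance
are explicit errors. Boundary conventions: the 3-µm aligned rule and 2-µm
crossing rule are inclusive (≤); the 1-µm pole exclusion is exclusive
(samples at exactly the radius are removed); the polar count is taken at
the frame nearest the query time.
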