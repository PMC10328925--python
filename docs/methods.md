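# Methods

## The morphomigrational description

`morphomig` characterises a single migrating cell, frame by frame, by four
coupled quantities derived from a time-lapse sequence of binary masks:

- **Elongation** ε = 1 − a/b, where a and b are the full minor and major
  axis lengths of the ellipse with the same centroid and central second
  moments as the mask. ε = 0 is a perfect circle; ε → 1 an infinitely
  elongated shape.
- **Turning angle** α(n): the signed angle between consecutive centroid
  displacement vectors d(n−1) and d(n), where d(n) runs from the centroid
  at frame n to the centroid at frame n+1. Defined for interior steps only.
- **Major-axis dynamics** Δϕ(n): the signed angle between the fitted major
  axes at frames n and n+1, bounded to [−90°, 90°] by axis-continuity
  tracking. It measures in-plane re-orientation of the shape.
- **Signed morphomigrational angle** sMM(n): the acute angle between the
  major axis at frame n and d(n) (the unsigned value uMM ∈ [0°, 90°]),
  given a sign that records *which side* of the axis the displacement falls
  on relative to the first frame. It is the quantity that couples shape to
  motion: |sMM| ≈ 0 is movement along the axis (lateral), |sMM| ≈ 90° is
  movement across it (perpendicular, the keratocyte archetype).

All angles are computed in screen coordinates (x = column, rightward;
y = row, downward), under which a rotation that appears clockwise on screen
is positive. This matches how microscopy images are displayed and fixes the
handedness of α unambiguously.

## Ellipse fit

Foreground pixels are treated as unit point masses at their integer centers
— the convention of standard region-property implementations. With
normalized central second moments mu20, mu11, mu02, the orientation is
φ = ½·atan2(2·mu11, mu20 − mu02) mapped into [0°, 180°), and the full axis
lengths are 4√λ of the two eigenvalues of [[mu20, mu11], [mu11, mu02]].
This "same second moments" normalisation makes ε = 1 − a/b independent of
any length-scale convention. The fit is deterministic and parameter-free;
tests require agreement with an independent eigendecomposition of the
pixel-coordinate covariance to 1e-9.

Numerical choices:

- Moments are accumulated relative to the mask's bounding-box corner, and
  step displacements are computed from the (integer origin, local centroid)
  split. Because all intermediate sums are then exactly invariant under
  integer translation of the mask, every step descriptor is bit-identical
  when the whole sequence is shifted — a property the test suite asserts
  exactly rather than approximately.
- A mask whose second moment vanishes along an axis (single pixel,
  1-pixel-wide line) has its semi-axes clamped to half a pixel and is
  flagged `degenerate`; downstream steps inherit the low-elongation flag.

## Sign tracking for sMM

The fitted axis is undirected, so "side of the axis" needs a consistent
axis direction along the track. Directions are propagated by u₁ =
(cos φ₁, sin φ₁) and uₙ = ±(cos φₙ, sin φₙ) with the sign chosen so
uₙ·uₙ₋₁ ≥ 0; an exact 90° tie resolves to Δϕ = +90°. This continuity
guarantees Δϕ ∈ [−90°, 90°].

The side of a step is the sign of the 2-D cross product uₙ × d(n); the
reference side is frozen at the first valid step whose displacement is not
exactly on the axis, and sMM is +uMM on the reference side, −uMM on the
other, with a +0 convention for motion exactly along the axis. Steps before
a reference exists are flagged `no_reference_side`. The published
description of the sign rule is verbal (the side must match "the first
frame"); the cross-product construction used here is a faithful
reconstruction of that rule, not a transcription of the original authors'
code, and is documented as such.

Flipping every propagated direction flips all sides together with the
reference, so the sMM sign pattern — and uMM always — is invariant to the
arbitrary initial direction choice.

The handedness of Δϕ is not fixed by its definition; the package defaults
to clockwise-on-screen positive (same as α) and exposes
`dphi_clockwise_positive` in the configuration for the opposite convention.

## Validity flags

- `zero_displacement`: |d| below `min_displacement_px` (default 0.25 px).
  Sub-quarter-pixel centroid shifts are segmentation noise; such steps
  carry no uMM/sMM, and α is undefined on steps adjacent to them.
- `low_elongation`: frame ε below `low_elongation_cutoff` (default 0.1,
  the upper edge of the low-ε band). A near-circular shape orients its
  fitted axis essentially at random, so sMM and Δϕ are computed but marked
  unreliable.

Frames with no foreground abort the run: the per-frame descriptor chain
(n−1, n, n+1) has no gap semantics.

## Coarse-grain bands

Numeric values are mapped to categorical labels by lower-exclusive /
upper-inclusive bands on |v|, with the sign reported separately:

| parameter | bands (upper edges) | labels |
|---|---|---|
| sMM | 15, 45, 70, 90 (°) | very_low, low, moderate, high |
| α | 60, 90, 135, 180 (°) | low, moderate, high, very_high |
| Δϕ | 10, 20, 45, 60, 90 (°) | very_low, low, moderate, high, very_high |
| ε | 0.1, 0.6, 1.0 | low, moderate, high |

The bands partition each domain exactly (property-tested on a fine grid)
and are memoryless. They live in the configuration so users can redefine
the coarse-graining; the defaults are frozen to the published table.

## Behaviour rules

Behaviours are verbal categories; the annotator encodes them as one
consistent rule set over the coarse labels, applied per step in priority
order (window rules pre-computed over maximal runs):

1. ROUNDED_CHAOTIC — ε band low. Dominates everything: no orientation-based
   label is trustworthy on a near-circular frame.
2. REAR_RETRACTION — |sMM| jumps very_low → high in one step, α low, Δϕ
   high/very_high at the jump. The re-orientation happens *between* the two
   steps, so Δϕ is accepted at the preceding or the current step.
3. LATERAL_U_TURN — sMM very_low/low with α high/very_high.
4. PERPENDICULAR_STRETCHING — window ≥ 3 steps of moderate/high sMM with ≥ 1
   sign change and increasing ε (protrusions thrown on both sides).
5. LATERAL_STRETCHING — window ≥ 3 steps of very_low/low sMM containing ≥ 2
   high-α steps, ε non-decreasing (repeated reversals along the axis while
   elongating).
6. GRADUAL_REDIRECTION — ≥ 2 consecutive steps of moderate sMM, constant
   sign, with low/moderate α of one consistent sign.
7. PERPENDICULAR_DISPLACEMENT — high sMM, sign constant vs the previous
   step, low α.
8. ASKEW_DISPLACEMENT — moderate sMM, low α.
9. LATERAL_DISPLACEMENT — very_low/low sMM, low α.

Design notes:

- Because rule 3 outranks rule 5, the individual reversal steps inside a
  lateral-stretching window are labelled U-turns and the surrounding steps
  stretching. That is deliberate: each reversal *is* a turn-back, and the
  window context is preserved by the neighbouring labels.
- "Constant sign" checks tolerate sMM sign flips while |sMM| ≤ 15°
  (`smm_sign_tolerance_deg`): the side of a displacement nearly parallel to
  the axis is noise-dominated.
- Rule 6 additionally requires |α| > `alpha_sign_min_deg` (default 5°) on
  every step: a track moving at a constant askew heading has α ≈ 0 of
  arbitrary sign, which is not a gradual redirection. Without this guard,
  rule 6 would absorb every steady askew mover.
- All windows, run lengths and the priority order are configuration; the
  defaults were chosen to reproduce the published frame annotations
  qualitatively on matching synthetic scenarios. The inverse mapping from
  values to behaviours is under-determined (behaviours were originally
  identified by visual inspection), so this encoding is one consistent
  choice rather than a canonical algorithm.

## Synthetic generator

Scenarios render rasterized ellipses (plus an ellipse–triangle composite
for tail retraction) by a pixel-center inclusion test on a 512×512 canvas,
with major axes ≥ 40 px so that moment-fit errors (< 1° orientation,
< 0.01 ε) are negligible against the band widths. Each scenario records
its programmed centroid, orientation, elongation and per-step behaviour;
reversals, rounding and retraction events are marked by frame. The
`tail_retraction` ground-truth centroid is derived from the rendered mask
(the composite has no closed-form moments) and its orientation is left
undefined; analytic parameter-recovery checks therefore use the purely
elliptical scenarios. Boundary noise perturbs the mask's signed distance
to its own boundary with per-pixel uniform noise, giving a seeded,
amplitude-controlled roughening that preserves area to within a few
percent at ≤ 2 px.

What the generator does *not* emulate: membrane protrusion dynamics,
intensity/texture, segmentation bias, shape irregularity beyond boundary
noise, and multi-cell fields. Passing tests therefore demonstrate that the
descriptor chain recovers known shape–motion couplings exactly as defined;
they do not validate segmentation quality or biological realism of the
motion models.

Default problem sizes — 25–31 frames per scenario, 50 random masks for the
oracle suite, 100 random ellipses for parameter recovery — keep the whole
verification suite under a minute while leaving rasterization error an
order of magnitude below every tolerance asserted.

## Interval dependence

sMM and Δϕ are step-based and therefore sampling-interval dependent.
`resample_track` keeps every k-th frame and rescales the frame interval so
the dependence can be explored; descriptors are always recomputed from the
resampled track rather than aggregated. Choosing the interval is left to
the user: it trades protrusion-scale detail against whole-cell translocation.

## Known limitations

- The sMM sign algorithm is a reconstruction (see above); tracks whose
  first sided step is itself noise-dominated inherit a fragile reference
  side. The `no_reference_side` flag and the low-ε flag mark the affected
  steps.
- One connected component is enforced per frame; touching or dividing
  cells are out of scope, as is segmentation of raw images.
- Behaviour labels are memoryless apart from the explicit window rules; no
  hysteresis or smoothing is applied across frames.
- Mean ± SD summaries are computed over valid steps only, and flagged
  steps are excluded with their counts reported (`n_valid`).
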