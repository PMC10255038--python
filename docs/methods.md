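# Methods

SparseShape models the transformation of a silhouette image into V4-like
shape selectivity in five stages: oriented filtering (model V1), an
inside–outside signal (border ownership), endstopped curvature cells,
signed local-curvature maps, and a supervised sparse-coding read-out.
This note records the model's assumptions, the parameters that matter,
the numerical choices made where the design was genuinely open, and the
known limits of what the test suite demonstrates.

## Stimuli

Stimuli are filled white silhouettes (foreground 1, background 0) on a
400×400 px canvas at 32 px/deg, so the 4° V4 receptive field spans
128×128 px centered on the canvas.

Closed contours are parametric radial profiles r(φ) about the RF center:
a periodic cubic-spline baseline through the control-point radii plus one
wrapped-Gaussian bump per control point. Each control point carries a
categorical curvature class that sets the bump's amplitude (fraction of
the local radius) and angular half-width (radians):

| class           | amplitude | width |
|-----------------|-----------|-------|
| sharp-convex    | +0.55     | 0.18  |
| medium-convex   | +0.45     | 0.35  |
| broad-convex    | +0.35     | 0.60  |
| flat            | 0         | —     |
| medium-concave  | −0.35     | 0.35  |
| sharp-concave   | −0.45     | 0.18  |

Amplitudes and widths were chosen once so that (a) concave classes are
genuinely concave in the differential-geometric sense (r·r″ > r² + 2r′²
at the dent apex), (b) profiles stay positive (the contour, being a
single-valued function of angle, can then never self-intersect), and
(c) the four acuteness levels are visually distinct at the rendered
scale. Rasterization tests each pixel center's polar radius against the
interpolated profile, which is exact for this star-shaped family;
anti-aliasing (2× supersampling) is available but off by default.

The standard boundary-conformation set expands a 49-base catalog over
45° rotations and removes rotationally symmetric duplicates: 3 bases with
90° symmetry contribute 2 rotations each, 2 bases with 180° symmetry 4
each, and 44 asymmetric bases 8 each — 6 + 8 + 352 = 366 unique stimuli.
The asymmetric bases are the first 44 canonical (lexicographically
minimal, aperiodic) four-class sequences over the six curvature classes,
placed at the four cardinal angles; the catalog ships as versioned JSON
(`data/catalog.json`) so the count is auditable. Every standard-set shape
is scaled so its maximum contour distance from the RF center equals
0.75 × the RF side (96 px at the default RF), i.e. shapes extend beyond
the RF half-width.

The invariance set holds three contour parts fixed (medium convex) and
sweeps the fourth through five curvature levels, crossed with whole-shape
scale factors and/or RF-position offsets (full factorial). A scale that
would push the contour outside the canvas is an error.

## V1 front end

Twelve orientations θ_j = (j−1)π/12 in (0, π) and four octave-spaced
scales (Gabor wavelengths 4, 8, 16, 32 px; envelope σ ≈ 0.56 λ from a
1-octave bandwidth; aspect ratio 0.5). Simple cells are half-wave
rectified quadrature Gabor outputs (the stack stores the strongest of
the four rectified phase units; the signed odd/even maps ride along for
the energy stage); complex cells are the quadrature energy
√(odd² + even²), hence contrast-polarity invariant. Responses are scaled
so the peak energy per image is 1. Kernels for orientations ≥ 90° are
exact 90° array rotations of the first six, so rotating an image by 90°
shifts the orientation index by exactly 6 channels — a property the test
suite exploits. Convolution uses FFTs with reflect padding; responses
within half a filter width of the canvas edge are flagged via
`valid_margin`.

## Border ownership

For the simple closed filled stimuli used here, the inside–outside
assignment is computed geometrically rather than by a recurrent network:
the inward normal is the gradient of a lightly smoothed (σ = 2 px)
signed distance transform of the mask, and each of the 24 direction
channels (θ_j ± π/2) carries the rectified dot product of its direction
with that normal, gated by the complex-cell contour energy at the
matching orientation and scale. The winner at a boundary point therefore
always points toward the interior — exact for this stimulus class — and
the module is swappable for a recurrent implementation with the same
array contract. Consequences: no response time-course, no illusory
contours, no occlusion handling.

## Endstopped cells

**Curvature degree.** Per orientation and scale, a simple cell is
inhibited by two complex cells displaced by Δ = σ_s along the preferred
orientation. The inhibition weight w_s is calibrated once per filter
configuration so that an infinite straight edge yields exactly zero, and
cached. Straight contours vanish; response at a contour point grows with
its curvature at the matched scale (the finest scale resolves the
sharpest bends; broad bends register at coarser scales).

**Curvature direction.** Per orientation, two opposed channels
(θ + π/2 vs θ − π/2) compete. Each channel is inhibited by complex-cell
flanks displaced toward the side it points away from, at ±2σ_s along the
tangent and σ_s perpendicular, with the complex maps pooled by an
isotropic Gaussian of σ_s. Both ±45°-rotated flank orientations
contribute at each flank position. This mirror-symmetric arrangement was
chosen after a chiral variant (one orientation per flank) showed
position-dependent winner errors: the asymmetric orientation assignment
interacts with which way the contour rotates around a closed shape. With
the symmetric flanks, the channel pointing toward the bend (the tangent
derivative's direction) wins at every sampled boundary point on discs of
radius 10–90 px and on ellipses, and straight contours tie by
construction.

A physical limit matters downstream: a flank pair whose geometry spans
~σ_s cannot detect a bend of radius ≫ σ_s, so the per-scale winner is
meaningless where scale and curvature are mismatched (measured ~50%
winner accuracy for fine scales on gentle arcs). The direction signal is
therefore read out from the scale-pooled channel difference: coarse
scales supply the sign for gentle curvature, fine scales for sharp
curvature.

## Curvature sign and signed curvature maps

Convexity is decided by agreement between the curvature-direction winner
and the border-ownership winner:

    convex  = ϕ( ΔEsDir · ΔBO ),   concave = ϕ( −ΔEsDir · ΔBO ),

where Δ is the (θ+π/2) − (θ−π/2) channel difference, ΔEsDir is pooled
over scales (see above), ΔBO is per scale, and ϕ is half-wave
rectification — so at most one of the pair is positive anywhere.

Signed local-curvature maps gate curvature magnitude with the strict
sign comparison and take the max over orientations, per scale:

    pos(x,y) = max_j EsDeg(x,y,θ_j)·[convex > concave at θ_j]

and analogously for neg with `<`. Ties zero both maps, so straight
segments vanish. Because different orientations can in principle
disagree (in practice only at numerical-residue level off the contour),
the weaker member of the pos/neg pair is silenced per pixel, making
mutual exclusivity exact on any input. The eight channels are ordered
(scale1-pos, scale1-neg, …, scale4-pos, scale4-neg), finest scale first.

Demonstrated properties: on a rendered disc ≥ 95% of boundary curvature
energy falls in the convex maps; a convex bump and a concave dent built
from the *same* circular arc — which curvature-direction cells cannot
tell apart at the apex — are cleanly separated into the pos and neg
maps. Straight lines and inflection points have no representation by
design.

## Part vectors and sparse coding

A fixed 3×3 grid of isotropic Gaussian kernels covers the RF (centers at
side fractions {1/6, 1/2, 5/6}; σ = RF/6; unit sum). Pooling each of
the 8 maps through each of the 9 kernels gives the 72-dimensional
part-based vector d_t, index i = (k−1)·9 + j. Under this grid the
largest possible center-to-center part distance is 2√2/3 ≈ 0.943 of the
RF side (diagonal corner cells).

Per neuron, signed weights γ minimize

    Σ_t ½‖R_t − d_tᵀγ‖² + αρ‖γ‖₁ + α(1−ρ)/2 ‖γ‖₂²

— the residual carries ½ and no 1/τ factor. The coordinate-descent
solver's per-sample convention is rescaled (its alpha = α/τ) so this
literal objective is minimized; solutions are then refined by an
active-set Newton step (the stationarity system on a fixed-sign support
is linear) with a LARS-homotopy fallback for degenerate pure-lasso
vertices. Final fits agree with an independent projected convex solver
to better than 1e−8 relative objective. Cross-validation fits use a
relaxed tolerance; final fits always run at full precision. α = 0
reduces to least squares (or NNLS in facilitatory-only mode).

Raw part-vector columns span ~60× in scale (concave and fine-scale maps
carry less energy over the standard set), which would make the penalties
weigh parts inequitably, so penalized fitting operates on unit-RMS-scaled
features (`standardize_parts`); support and signs are unaffected by
column scaling.

Per-neuron procedure: stratified 60/40 train/test split (response
quartile bins, each split at the training fraction; deterministic per
seed; undersized bins merge with a neighbor), 5-fold cross-validation
over 13 log-spaced alphas spanning 6 decades up to the data-dependent
α_max and ρ ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1.0}, ties broken toward the
smallest α then the largest ρ, then a full-precision refit on all
training stimuli. Predictions R = dᵀγ are reported unrectified. Neurons
with constant responses are skipped (Pearson r undefined) and logged in
the metrics table. The facilitatory-only ablation re-runs the same
procedure with γ ≥ 0.

## Synthetic ground-truth neurons

The generator emulates the model's own read-out assumption: responses
linear in the (standardized) part vectors with K-sparse signed weights
plus additive Gaussian noise. Support is drawn with a configurable
convex-map probability; each weight is positive with probability
`sign_mix`; magnitudes are uniform in [0.3, 1] — the floor keeps true
effects well above solver tolerance, and drawing magnitudes in the
standardized basis makes each chosen part contribute comparably to the
response. Noise is set per neuron to a target signal-to-noise ratio
(variance ratio; SNR 10 in the recovery experiments). One global seed
branches into independent per-neuron streams, so populations are
reproducible piecewise. Responses are left unrectified by default to
stay matched to the linear read-out; a flag floors them at zero.

What passing recovery tests do and do not show: they demonstrate that
the fitting machinery recovers the *signs* of true contributions
(median sign agreement 1.0) and predicts held-out responses well
(median r ≈ 0.95 at SNR 10, ~220 training stimuli), under the
generator's idealized linearity. They do not show trial-to-trial noise
robustness, response nonlinearity tolerance, or — see below — exact
support identification. Real recordings also violate the generator's
assumption that the model's curvature maps are the true stimulus
encoding.

### A known identifiability limit

Same-grid-cell features at adjacent scales are nearly collinear over the
standard set (|correlation| up to 0.99, mean ≈ 0.89 between neighboring
scale maps of the same sign and cell): the four acuteness channels
respond together on these stimuli once Gaussian-pooled. Exact support
recovery of a 5-sparse γ is therefore not attainable at Jaccard ≥ 0.6 by
*any* point on the elastic-net path (an oracle scan over α tops out at
median Jaccard ≈ 0.4; cross-validated fits reach ≈ 0.2 because the
prediction-optimal α admits small compensating weights). The true parts
are consistently the largest-magnitude weights with correct signs; they
are accompanied by small spillover onto their scale neighbors. This is a
property of the feature geometry, not of the solver, and it mirrors the
moderate (≈ 0.5) nonzero fractions seen when fitting real-shaped
response data.

## Analysis conventions

- RF visualization: per map, the standard-set contour fragment driving
  that map hardest (strongest summed response within one grid-cell
  window) is tiled at the 9 cells, windowed by each Gaussian kernel
  (peak-normalized profile), weighted by the corresponding γ entry and
  summed. The image is linear in γ; facilitatory parts render red,
  inhibitory blue.
- "Nonzero" means |γ_i| > 1e−8 (the solver tolerance floor).
- Contribution sums normalize γ by its maximum absolute entry (so the
  largest-magnitude weight maps to ±1 even for inhibition-dominated
  neurons) and sum positive and |negative| entries separately within the
  convex-map and concave-map index groups.
- Tuning centroids are response-weighted mean curvature levels with
  responses rectified before weighting (weights must be nonnegative);
  the slope of centroid against scale (or position) is ordinary least
  squares, returned as exactly 0 when all centroids are identical, and
  NaN (neuron flagged) when any condition's tuning curve is all zero.

## Problem sizes and determinism

The shipped experiments run the full 366-stimulus set through the
hierarchy (≈ 0.7 s/stimulus single-threaded), fit 50 synthetic neurons
for recovery and 20 paired neurons for the ablation. All splits, folds,
supports and noise draws derive from explicit integer seeds; rerunning
with the same seeds is bit-reproducible. Filter banks, calibration
weights and pooling kernels are cached per configuration within a
process.

## Known limitations

- Border ownership is exact-by-construction for filled simple shapes;
  nothing is claimed for occlusion, outlines, or texture.
- Zero curvature (straight lines, inflections) is unrepresented; shapes
  whose discrimination rests on straight segments are outside the
  model's reach.
- The acuteness dimension is weakly identified after pooling (see the
  identifiability note); analyses that need exact per-scale attribution
  should aggregate scale pairs.
- Curvature maps are kept at full resolution; no downsampling before
  pooling.
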