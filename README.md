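# sparseshape

A mechanistic model of how the primate ventral stream turns oriented-edge
responses into the signed-curvature shape selectivity recorded in area
V4, for computational neuroscientists who want an explicit, testable
hierarchy rather than an end-to-end network.

Mid-level vision encodes *boundary conformation*: V4 neurons respond to
convex projections and concave indentations at particular positions on a
closed shape. Curvature **magnitude** alone does not determine such a
response, and neither does curvature **direction** (the side a contour
bends toward) — the same arc is a bump on one shape and a dent on
another. SparseShape composes the missing ingredient explicitly:

1. **V1 front end** — quadrature Gabor simple/complex cells, 12
   orientations θ_j = (j−1)π/12 in (0, π), 4 octave-spaced scales.
2. **Border ownership** — a paired inside–outside signal R_BO(x, y, θ±π/2)
   whose winner points toward the figure interior (computed geometrically
   from the signed distance transform for these filled stimuli).
3. **Endstopping** — curvature-degree cells (center simple cell minus
   collinear complex flanks, calibrated to null on straight edges) and
   opposed curvature-direction channels.
4. **Curvature sign** — agreement between the direction and
   border-ownership winners:
   `convex = ϕ(ΔEsDir·ΔBO)`, `concave = ϕ(−ΔEsDir·ΔBO)`.
5. **Signed curvature maps** — per scale,
   `pos(x,y) = max_j EsDeg(x,y,θ_j)·[convex > concave]` (and `neg` with
   `<`): 8 maps = 4 acuteness levels × 2 signs.
6. **V4 read-out** — each of the 8 maps is pooled through a fixed 3×3
   grid of Gaussian kernels into a 72-dimensional part vector d_t, and a
   signed weight vector γ per neuron minimizes the elastic net

       Σ_t ½‖R_t − d_tᵀγ‖² + αρ‖γ‖₁ + α(1−ρ)/2‖γ‖₂²

   with α, ρ set by cross-validation on a stratified 60/40 split.
   Predicted responses are R = d_sᵀγ; positive weights are facilitatory
   shape parts, negative ones inhibitory.

Stimuli are generated parametrically: a 366-shape boundary-conformation
standard set (49 bases × 45° rotations, symmetric duplicates removed,
every shape scaled so its contour reaches 0.75 × RF from the center) and
single-varying-part series for scale/position invariance tests. A
synthetic-neuron generator (sparse signed weights over the part vectors
plus calibrated noise) supports the full analysis suite — receptive-field
visualization, convex/concave sparsity, facilitatory/inhibitory
contribution sums, part-distance statistics, tuning-centroid invariance
slopes — without any recorded data. Recorded responses in the same CSV
layout (`neuron_id, stimulus_id, response`) drop straight in.

## Worked example

`examples/02_signed_curvature.py` runs two silhouettes sharing an
identical circular arc — a disc (the arc is a convex bump) and a larger
disc with a bite taken by the same circle (the arc is a concave dent) —
through the hierarchy:

```
$ python examples/02_signed_curvature.py
bump (convex)    direction winner at apex: up     map energy: pos 0.296  neg 0.007
dent (concave)   direction winner at apex: up     map energy: pos 0.042  neg 0.154
```

The curvature-direction winner is identical for both shapes (the arc
bends the same way), so direction cells alone cannot separate them; the
signed maps, which fold in the inside–outside signal, put the bump's
energy into the convex channels and the dent's into the concave
channels. The other examples cover the standard set
(`01_standard_stimuli.py`: 366 unique stimuli, contour extent
96 ± 1 px), sparse-code fitting on synthetic neurons
(`03_fit_synthetic_neurons.py`) and invariance slopes
(`04_invariance_slopes.py`).

There is also a CLI for batch use:
`sparseshape {stimuli,maps,simulate,fit,analyze,run}` — see
`sparseshape --help`.

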