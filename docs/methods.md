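# Methods

## Imaging model

Fan-beam CT is discretized as the linear system `A f = p`. The image
`f` is an n × n grid of linear-attenuation-like densities (water ≈ 1.0)
with square pixels of side h cm; the physical origin is at the grid
centre, x points right, y up, row 0 is the top row. The measurement `p`
holds one ray sum per (view, detector-bin) pair, ordered view-major. The
matrix entry a_ij is the intersection length in cm of ray i with pixel j,
computed exactly (to floating tolerance) by Siddon's parametric
traversal: the ray is clipped to the grid bounding box, its crossing
parameters with all pixel-boundary planes are merged and sorted, and each
inter-crossing segment is assigned to the pixel containing its midpoint.
Rays that miss the grid keep their (empty) rows so that M = views × bins
always. Per-ray row sums therefore equal the analytic chord length of the
ray inside the grid box — a property the test suite checks against an
independent polygon-clipping oracle.

The scanner is a point source on a circle of radius `source_to_axis`
(default 293.1 cm) with an equi-distance *virtual* detector: a uniformly
sampled line through the rotation axis, perpendicular to the source-axis
direction, with `detector_bins` bins (default 1025) of `bin_aperture`
(default 0.05 cm). One ray per bin centre is traced (no sub-ray
averaging, matching the one-weight-per-ray-and-pixel model). View angles
are uniform over the full circle starting at 0. The default detector span
(51.25 cm at the axis) covers the 51.2 cm field of view of the default
512² × 0.1 cm grid. These defaults mirror the study conditions the
package reproduces; all are configuration fields.

## Phantom

The ground truth is an analytic head-phantom slice in the style of the
public FORBILD head phantom: an ordered list of elliptical primitives
with *additive* signed densities (skull bone 1.800, brain 1.050,
subarachnoid CSF 1.045, air cavities 0.0), plus low-contrast lesions at
+0.005/+0.010 above brain — inside the conventional [1.03, 1.08] display
window — and a fine, high-contrast petrous/inner-ear bone-air structure
on each side, which is what drives the streak artifacts few-view
reconstruction must suppress. The original FORBILD definition mixes
ellipses with drop shapes and clipped solids that cannot be expressed as
ellipses; this table is a synthetic elliptical transcription that keeps
the documented densities and anatomy (see the docstring of
`fewviewct.phantom.FORBILD_HEAD_SLICE`). Only *relative* algorithm
comparisons are insensitive to the exact slice; absolute metric values
are not.

Rasterization averages supersample² sub-sample points per pixel
(default 4, anti-aliasing the ellipse boundaries; interior pixels are
exact for any supersample). Projection data are generated by applying the
same system matrix used for reconstruction to this discrete phantom — a
deliberate inverse crime that makes the noise-free data exactly
consistent, so differences between reconstructions reflect the algorithms
and not the forward model.

## Noise model

Measurement noise is i.i.d. zero-mean Gaussian with standard deviation
`percent_of_max × max(p)` over the global sinogram maximum (default
0.05 %). Noise is not clipped to nonnegative values. The RNG is numpy's
PCG64 generator; the seed is recorded with saved sinograms so noisy
experiments replay exactly.

## Regularizers and the filtering step

With D₁…D₄ the horizontal, vertical and two diagonal partial-difference
operators (differences referencing out-of-grid pixels are 0):

    TD(f)  = Σ |D₁f| + |D₂f|
    WTD(f) = TD(f) + α ( Σ |D₃f| + |D₄f| )

The axial terms measure gradient sparsity; the diagonal terms measure
directional gradient continuity; α balances them (default 1.0, equal
weight). Diagonal differences carry no 1/√2 length normalization.

The regularizer is decreased by soft-threshold filtering through a
pseudo-inverse of the difference transform: every neighbour n of a pixel
proposes the candidate g_n = f_n + S_w(f − f_n), with
S_w(x) = sign(x)·max(|x| − w, 0); the output pixel is the weighted mean
of the candidates, weight 1 for the four axial neighbours and α for the
four diagonal ones, normalized at borders by the weights of the
neighbours actually present. Limiting behaviour used as test oracles:
w = 0 is the identity; w → ∞ is the α-weighted 8-neighbourhood mean;
α = 0 is exactly the 4-neighbour TD filter.

The threshold follows a geometric schedule w_k = w₀ c^k with defaults
w₀ = 0.02 (the scale of soft-tissue contrast) and c = 0.995, both
configuration fields. Geometric decay is the standard realization of a
decreasing-threshold scheme; the defaults were fixed as the declared
study conditions. A sensitivity sweep (see "Known limitations") shows the
comparison magnitudes depend on this choice.

## Reconstruction loop

All three algorithms start from a zero image and share one loop per
iteration:

1. **Data constraint** — one SART pass: for each view v in angle order,
   f_j += λ [Σ_{i∈v} a_ij (p_i − ⟨a_i, f⟩)/rowsum_i] / colsum_j^v, with
   zero-sum rays and pixels skipped; λ ∈ (0, 2), default 1.0. A
   `simultaneous` all-views mode is available behind a flag.
2. **Filtering** (skipped by SART) — one soft-threshold filtering step at
   the current w_k, with α = 0 for TDM-STF and α = 1 for WTDM-STF. The
   two variants share one code path, so WTDM-STF with α = 0 is
   bit-identical to TDM-STF.
3. **Acceleration** (skipped by SART) — FISTA momentum:
   t_{k+1} = (1 + √(1 + 4t_k²))/2, y = x_k + ((t_k − 1)/t_{k+1})(x_k − x_{k−1});
   the next SART pass is applied to the extrapolated y, the reported
   image is always the filtered iterate x_k. No momentum restart.

The loop stops at `max_iterations` (default 400). A nonnegativity clamp
is available but off by default. Noise-free runs are bit-reproducible.

## Evaluation

RMSE, PSNR (peak = max of the truth), and Herman's NRMSD and NMAD, all
over the whole image by default (an ROI mask is accepted; NRMSD = 1 for a
uniform image at the correct mean, NMAD = 1 for a zero image). Relative
gains of the WTD variant over the TD variant are
(m_TD − m_WTD)/m_TD × 100 for the error measures and sign-flipped for
PSNR. Profile extraction uses 1-based row/column indices to match the
usual "240th row" phrasing.

## Problem sizes and numerics

The full-scale study is the 512² phantom, 40 views × 1025 bins and 400
iterations; the system matrix (~25 M nonzeros) is stored in float32 CSR
(intersection lengths are exact to ~1e-7 relative at that precision,
far below reconstruction error scales) with per-view blocks and their
transposes cached for the sequential sweep, and is built once and shared
across algorithms and noise seeds. The scaled-down smoke study uses the
same anatomy at 128² (0.4 cm pixels) with 257 bins of 0.2 cm. Unit tests
use float64 matrices at dense-oracle scales (≤ 16²). Ties where a ray
runs exactly along a pixel-boundary plane are assigned to the pixel
containing the segment midpoint (the boundary-touching pixel on the +x/−y
side); such rays have measure zero in the test geometries, which offset
view angles from the grid symmetry axes.

## Synthetic-data scope

The generator emulates a monochromatic, noise-consistent 2-D fan-beam
acquisition of a piecewise-constant analytic phantom, with the same
discrete forward model used for reconstruction. It does not emulate
polychromatic beam hardening, scatter, detector blur, photon-statistics
(Poisson) noise, patient motion, or forward-model mismatch. Passing tests
therefore demonstrate correctness of the algorithms and their relative
merits under matched-model conditions, not clinical image quality.

## Known limitations and open choices

* The head-slice table is an elliptical transcription, not the original
  FORBILD definition; absolute metric values (e.g. the SART RMSE at 400
  iterations, measured here at 0.1015) depend on the slice content and on
  the relaxation parameter λ, for which 1.0 is the declared default.
* The comparison magnitude between the TD and WTD variants depends on the
  threshold schedule. Under the default schedule (w₀ = 0.02, c = 0.995)
  the noise-free gains measure ≈ 57 % (RMSE/NRMSD), ≈ 59 % (NMAD) and
  ≈ 15 % (PSNR); with noise, ≈ 35/35/41/7 %. Faster-decaying schedules
  reach much lower absolute errors for both variants but smaller relative
  gaps (e.g. c = 0.97 gives TD RMSE 2.8e-4 and a ≈ 35 % gain). The WTD
  variant beats the TD variant for every schedule examined except
  strongly over-aggressive decay (c = 0.95), where both collapse.
* NRMSD/NMAD are reported over the whole image; a different ROI changes
  their absolute values (not the algorithm ordering).
* Equi-angular detectors, cone-beam and limited-angle geometries are out
  of scope.
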