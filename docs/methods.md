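# Methods

## The model and what is being validated

`pivbench` asks a measurement-theory question: given an image sequence of
agents whose true velocities are known, how faithful is the velocity field
that particle image velocimetry (PIV) reports?  The ground truth comes from
the Vicsek model, the minimal flocking model in which coherent motion is an
emergent, noise-controlled property rather than a prescribed flow — the
relevant regime for cell types that migrate as coupled stochastic agents
rather than in a viscous continuum.

### Vicsek dynamics

N agents in a periodic square box of side L move at constant speed v₀.  The
synchronous discrete-time update, both rules reading the complete time-t
configuration, is

    r_i(t+1) = r_i(t) + v0 (cos θ_i(t), sin θ_i(t)) Δt
    θ_i(t+1) = ⟨θ_i(t)⟩_r + Δθ_i,   Δθ_i ~ U[−η0/2, η0/2] i.i.d. per agent

with ⟨θ⟩_r the direction of the summed heading unit vectors over all agents
within minimum-image distance r of agent i, itself included.  The mean
direction is evaluated with the two-argument arctangent atan2(Σsin, Σcos):
a plain arctan of the ratio is wrong in quadrants II/III.  In the
measure-zero event that both sums are exactly zero the agent keeps its
heading.  One independent noise draw per agent per step; a single shared
draw would be a different (and much stiffer) model.

Neighbor search is available as an O(N²) minimum-image distance matrix and
as a cell list (cell size ≥ r, 3×3 scan).  Both paths fill the same boolean
adjacency matrix before a shared reduction, so their outputs are bitwise
identical (tested); the matrix path is the default below ~600 agents where
it is faster in practice.

Defaults are the study conditions: L = 5 units imaged at 123 px/unit
(Γ = 615 px), N = 300, v₀ = 0.03 units/step (3.69 px/frame), r = 0.5 units
(61.5 px), Δt = 1.  η₀ defaults to π/6, the low-noise reference case;
experiments sweep it explicitly.

### Rendering

Each agent becomes a filled ellipse of 8 × 6 px (major axis along the
heading) at foreground intensity 0 on background 255.  Rasterization is
deliberately binary — a pixel is foreground iff its center lies inside the
rotated ellipse — because the image model has exactly two intensity levels;
no anti-aliasing is applied.  Agent centers keep continuous sub-pixel pixel
coordinates (rounding them would quantize the 3.69-px/frame displacement
that PIV is supposed to measure).  Ellipses wrap periodically, consistent
with the box.  The coordinate convention (x → column, y → row, origin
top-left, pixel (row, col) sampled at the point (row, col)) is defined once
in `render.py` and recorded in frame metadata; PIV and the metrics consume
the same convention.

### PIV

The image is tiled into γ × γ interrogation grids (vector spacing = γ; the
γ-lattice anchors are the grid centers).  "Step size 32 px (50 % of the
grid)" is interpreted as the search-zone enlargement — search side
N_g = γ + 32, margin m = 16 px per side — not as grid overlap, since the
vector spacing is separately fixed at γ.  For each grid the Z×Z patch at
time t is compared against every Z×Z window of the search zone at t+1 via
the normalized cross-correlation (mean-subtracted product sum over the
patch, normalized by both patch norms), evaluated at every integer offset
|k|, |l| ≤ m.  Implementation: the numerator for all offsets at once by FFT
correlation of the mean-subtracted template with the search zone, the
per-window norms by integral images.  This is numerically equivalent to the
longhand per-offset formula (the test suite enforces identical argmax
against a literal scalar implementation); offsets whose window has zero
variance are undefined and excluded from the argmax.

Peak selection is deterministic: correlation values within 1e-9 of the
maximum count as tied, and the tie with the smallest |offset| (then
lexicographically smallest) wins.  Sub-pixel refinement (default on) fits a
three-point Gaussian per axis around the integer peak — appropriate because
the true displacement, 3.69 px/frame, is non-integer — with a parabolic
fallback when a neighboring sample is non-positive, clamped to ±0.5 px;
integer-peak mode is retained because rigid-shift recovery is then exact
and testable.  Patches and search zones read pixels periodically to match
the periodic world; `PIVParams(periodic=False)` disables this for external,
non-periodic images (border grids are then skipped).

A grid yields no vector when its patch at t, or its search region at t+1,
contains no foreground ("empty-grid rule"), or when every offset is
undefined.  Outlier removal is a single-pass normalized-median test: the
residual of each vector from the component-wise median of its ≤ 8 valid
lattice neighbors, normalized by the median neighbor residual plus
ε = 0.1 px, must not exceed 2.0; vectors with fewer than two valid
neighbors are kept.  This is a documented, standard substitute for the
unspecified validation step of GUI PIV tools.

### Metrics

All distances in metric computations use the periodic minimum-image rule in
pixel space (period L·px_per_unit).  The global order parameter v_a is the
magnitude of the mean heading unit vector.  Local order v_a^{x_j,R} is the
same magnitude over the agents within R of a circle center x_j; circles are
centered on the anchors of the *valid* PIV vectors, and empty circles are
excluded from the mean v_a^R (never counted as zero).  The alignment score
A^R averages, over the M valid vectors with at least one enclosed agent,
the mean cosine between the vector and the enclosed agents' velocities; it
uses the agent state at the *earlier* frame of the PIV pair.  Vectors whose
displacement is exactly zero have no direction and are likewise excluded
from M.  The coherence difference D^R applies the v_a^R formula once to
agent headings and once to unit-normalized valid PIV vectors at the same
centers and radius, and takes the absolute difference.

For recording step τ > 1, PIV vectors are displacements per recorded
interval and agent velocities are the headings at the earlier recorded
frame; all scored quantities compare directions only, so no rescaling is
needed.

Characteristic scales: γ₀(N) = Γ/√N (grid side holding one agent on
average) and R₀(N) = γ₀/√π (circle radius with the same property under a
uniform spatial law).  For N = 300, Γ = 615 these give 35.5 px and 20.0 px.
The literature also uses the convention R₀ = γ₀ (so that R/R₀ = 1 matches
the grid side, 35.5 px for these parameters); both appear in published
normalizations and they disagree by √π.  The package implements the
defining formula and exposes `r0_convention: {formula | grid}` on
`ExperimentConfig`; every experiment row records the active convention, and
the two are never silently reconciled.

## Experiments and problem sizes

Experiments derive per-trial seeds as base seed + trial index (recorded per
output row) and return tidy DataFrames; undefined metric values are NaN.
Default problem sizes were chosen so that a full experiment is minutes, not
hours, on one CPU, while keeping the study's own parameter values intact:

- time series: PIV on every consecutive pair over the configured window
  (the low-noise convergence check uses t ∈ [150, 300], N = 300);
- single-time landscapes: PIV on the pair (t_eval − τ, t_eval) only, with
  t_eval = 300 where the order parameter is stationary at every noise
  level; the (γ/γ₀, R/R₀) landscape uses grid sides at the requested
  multiples of γ₀ rounded to even integers (step = γ/2, margin = γ/4),
  with border grids handled by the periodic patch rule;
- trial replication defaults to 5 for the shape checks (the rank ordering
  across cells is stable between 5 and 30 trials; 30 remains one flag away);
- the transition sweep uses 7 noise levels in [π/2, 3π/2], 5 trials, and the
  stationary window t ∈ [200, 300]; the critical noise is reported where the
  trial-averaged stationary v_a crosses 0.5 (a convention: 0.5 is the
  customary midpoint marker for this finite-size crossover), by linear
  interpolation between the bracketing sweep points.

## Numerical choices

- Peak ties: resolved toward the smallest displacement for determinism.
- Zero-variance windows: excluded via an absolute sum-of-squared-deviation
  threshold of 1e-3, eight orders below the smallest nonzero value an
  8-bit image can produce (a single differing pixel contributes ≥ 255²·(1−1/Z²)).
- "Exact" dynamical invariants (zero-noise heading cohesion, speed
  conservation) are asserted at 1e-9 absolute tolerance: sin/cos/atan2
  round trips are correct only to ~1 ulp per step, so bitwise equality is
  not attainable and not claimed.
- Angle averages use atan2 throughout; headings are stored wrapped to
  [0, 2π), positions to [0, L).

## What the generator emulates — and what it does not

The synthetic images share with real live-cell recordings the features that
matter for interrogation-window statistics: elongated oriented particles,
binary-contrast texture, finite density, and motion that decorrelates with
a noise-controlled length scale.  They deliberately omit photometric noise,
blur and out-of-focus artifacts, intensity gradients, cell division and
death, and shape change.  Passing results therefore certify the PIV
estimator's ability to recover *agent motion from ideal images of it* at
the right (γ, R) scales; they do not certify robustness to optical
degradation, which must be assessed on real data.  Likewise the Vicsek
model's constant speed and metric interaction are idealizations: the
conclusions about γ₀ and R₀ rest on the agents being approximately
uniformly distributed, and clustering at low noise already shows up here as
empty grids producing no vectors.

## Known limitations

- The correlation search is exhaustive within ±m; there is no multi-pass or
  window-deformation scheme, so displacements beyond the margin saturate
  (a warning is emitted when τ·v₀ exceeds it).
- The outlier test is one fixed, documented rule; GUI PIV packages differ
  here, and results near the validation threshold can differ accordingly.
- Landscape grid sides must tile the image only approximately; wrapped
  border grids slightly overweight the image edges for γ that do not divide
  Γ.
- At very low agent counts most grids are empty and the metrics are
  undefined for many frames; the NaN discipline propagates this honestly
  rather than imputing zeros.
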