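# Methods

## The measurement problem

A hair-cell kinocilium is a single microtubule-based filament, 25–40 µm
long in the lateral crista of larval zebrafish, imaged live as a confocal
Z-stack with strongly anisotropic voxels (0.064 µm lateral pitch, optical
sections every 0.6–0.7 µm; the package default axial spacing is 0.65 µm,
the midpoint of that range). Two quantities are of interest per filament:
its length, and the distribution of a tagged protein's fluorescence along
its arc. Group-level questions — does overexpression shorten kinocilia, is
a protein proximally or distally enriched — are answered on per-larva
summaries and tip-registered ensemble averages.

## Synthetic scenes

The generator replaces transgenic imaging with a forward model whose ground
truth is known exactly.

**Geometry.** A filament is a straight axis with a single-arch sinusoidal
lateral displacement (amplitude = `curvature_amp`, µm) in a seed-chosen
azimuth of the plane normal to the axis, rescaled so the returned polyline's
arc length equals the requested length exactly. This is a deliberate
minimal model of the mild/severe bending phenotypes; real kinocilia can
bend non-sinusoidally.

**Intensity patterns.** Along-arc emitter brightness follows one of four
classes, parameterized here since the source observations are qualitative:
`uniform` (constant 1), `proximal` (logistic shoulder, knot 0.45 of arc
length, width 0.06 — bright plateau, then monotone fall-off), `distal`
(logistic rise, knot 0.60, width 0.08, floor 0.05 — middle-proximal
depletion), and `bulbed` (distal plus a Gaussian tip bump of physical
sigma 1.5 µm, renormalized to peak 1). All values lie in [0, 1] and scale
the per-curve `amplitude` (default 3000 gray on a 100-gray background,
giving a realistic 30:1 peak signal-to-background).

**Rendering.** Each filament is a max-composited anisotropic Gaussian tube:
the curve is sampled every half-voxel, and every voxel within 3σ takes the
maximum over samples of `amplitude × pattern(s) × exp(−d²_lat/2σ²_xy −
d²_ax/2σ²_z)` (defaults σ_xy = 0.15 µm, σ_z = 0.50 µm). Max-composition
(rather than summed line-spread) keeps the on-axis brightness exactly equal
to the pattern value, so rendered profiles are interpretable as ground
truth and doubling the amplitude doubles the above-background signal
everywhere. Background is added, then optional Poisson shot noise and/or
additive Gaussian read noise (the default noise model; the acquisition's
true noise is not modelled further), then clipping to [0, 65535] and
quantization to uint16 (skippable for exact-arithmetic tests). All
randomness flows through one manifest seed; manifests serialize to JSON and
re-render bit-identically.

**What the generator does not emulate:** stereocilia and cell bodies,
spherical aberration, depth-dependent attenuation, photobleaching,
puncta motility, and multi-filament crossings. Passing tests therefore
demonstrate correctness of the measurement chain under a clean forward
model, not robustness to every confound of real neuromast images.

**Length studies.** Per-larva kinocilium lengths are simulated
hierarchically: larva offset ~ N(0, sd_between), within-larva scatter
~ N(0, sd_within), truncated at zero. The default design mirrors the
published overexpression series — group means 35.4 / 35.3 / 32.1 / 26.1 µm
with 8 / 8 / 7 / 5 larvae — with variance components sd_between = 1 µm and
sd_within = 2 µm chosen as realistic since raw scatter is unpublished, and
10 kinocilia per larva so the top-5 rule has room to select.

## Tracing and length

Tracing is seeded and automatic: given base and tip voxels, the filament is
the minimum-cost path on the 26-connected voxel graph with edge cost =
physical step length × mean of (I_max − I + 1) at the two endpoints
(Dijkstra search via scikit-image's geometric MCP, with anisotropic
sampling). The interactive plugin workflow this replaces is not
reproducible programmatically; seeds come from scene manifests in tests or
a seed TSV in real use. Masked (or non-finite) voxels are impassable;
coincident seeds yield a single-point path with a warning.

Two length metrics are reported. The default is the base-to-tip Euclidean
chord on anisotropically scaled coordinates — the literal reading of
length-by-Pythagoras on traced endpoints — with the polyline arc length
alongside. A raw voxel path staircases, inflating its naive segment sum by
5–20 % (worst in z, where each unavoidable 0.65 µm slice step lies nearly
perpendicular to the filament); the arc metric therefore resamples the
physical polyline at 0.1 µm, Gaussian-smooths the coordinates along arc
length (σ = 2 µm, endpoints pinned to base and tip), and sums the smoothed
segments. σ = 2 µm sits well above the voxel pitch and well below the
~35 µm bend radius of even strongly curved filaments; on noise-free scenes
it recovers generated arc lengths to ~0.1 %. Because the smoothed polyline
still joins base to tip, chord ≤ arc is preserved. `path_length` with
smoothing disabled returns the exact raw segment sum.

"Unambiguously traceable" is operationalized as: minimum intensity along
the path ≥ background + 2 × noise SD. Failing kinocilia are flagged
non-measurable; larvae with fewer than five measurable kinocilia are
excluded from per-larva aggregation (with a logged warning) rather than
averaged over fewer, since the five-tallest rule presumes five exist.

## Intensity profiles

Profiles are measured on the maximum Z-projection (the plot-profile
convention of the original workflow; 3D sampling is out of scope). The
traced 3D path is flattened to (y, x) and resampled at 0.5 µm to remove
pixel-scale jaggedness before sampling. Values are read every 0.064 µm of
arc length; each value is the mean of 2 bilinear samples spaced one pixel
apart, centered perpendicular to the local direction — the common raster
reading of a "2-pixel" segmented-line width, stated explicitly since the
dialect varies between tools.

Kinocilia shorter than 32 µm are excluded (boundary inclusive). Remaining
profiles are registered at their distal tips over a 32 µm window: each
contributes its distal-most 501 samples (32/0.064 + 1, endpoints
inclusive), discarding proximal overhang of longer filaments. Column means
are min–max rescaled to exactly [0, 100] — each ensemble against its own
extrema, which removes overall brightness differences between transgenes —
then transformed as log2(1 + x) (the +1 handles the exact zero at the
minimum, which the source presentation leaves unspecified), and smoothed
with a Loess curve (statsmodels lowess: degree 1, tricube weights, default
span 0.75; the span used in the original figures is unreported, so
recovered curves may differ in smoothness).

The regionalization index is the normalized intensity centroid
s̄ = Σ sᵢwᵢ / Σ wᵢ over the window (s ∈ [0, 1]); classes are proximal
(s̄ < 0.45), distal (s̄ > 0.55), else uniform (τ = 0.05). In the end-to-end
pipeline the per-kinocilium row is shifted by its minimum before computing
s̄, which removes the background pedestal that would otherwise pull every
centroid toward 0.5. On synthetic scenes at moderate noise (Gaussian SD 60
on amplitude 3000) the three patterns separate by centroid margins of
≥ 0.2, and classification is correct for ≥ 95 % of kinocilia.

## Statistics

Welch's two-tailed t-test and the Welch–Satterthwaite df are computed from
their defining formulas, with p-values from scipy's t distribution; the
one-way ANOVA is the explicit sum-of-squares decomposition with p from the
F distribution. Pairwise comparisons after ANOVA default to Tukey–Kramer
HSD (studentized-range distribution, unequal-n standard errors); the
alternative is Holm-adjusted pairwise Welch tests. The adjustment behind
the original pairwise p-values is unnamed in the source analysis; Tukey is
assumed because all groups are compared after an ANOVA, and the choice is a
config knob, not an assertion. Degenerate inputs are handled explicitly:
zero variance in both groups raises (equal means) or warns with p = 0
(distinct means); zero within-group variance yields an infinite-F warning.

Self-validation simulates the null (`validate_type_i`): at n = 8 per group
and 5000 replicates the empirical type-I error is within 0.05 ± 0.01.
`simulate_anova_power` draws per-larva means directly (common SD 1 µm, the
published group sizes); a severe-group deficit of ≥ 5 µm is detected at
p < 0.001 in ≥ 99 % of 1000 replicates. The published test statistics
themselves (t, F = 193.3, exact p) are not reproducible because the raw
per-larva values are unpublished; only design bookkeeping (df₂ = 24) and
power behaviour are checked.

## Locus mapping

Intervals are 1-based inclusive; BED input is converted (start + 1, end)
and a leading "chr" is stripped for comparison. The gap between disjoint
same-chromosome intervals is the plain difference of nearest boundaries (no
±1 adjustment, matching the MB arithmetic of the source comparison), 0 for
touching or overlapping intervals, and undefined across chromosomes
(raised as incomparable). MB values are rounded to one decimal for report
parity. The bundled fixture carries the GRCh38.p13 gene coordinates and the
marker-defined critical regions; marker positions that were never printed
(D19S592, D19S586, D15S1004) are deliberately absent, so distances quoted
against them elsewhere are out of scope.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to single-CPU
runs: single-filament stacks of ~12 × 160 × 540 voxels, 42 kinocilia for
pattern recovery, 1000 ANOVA replicates, 5000 Welch null replicates, and a
10⁶-draw Monte-Carlo check of the studentized-range tail (tolerance 0.005).
Oracle comparisons use 1e-10 (t statistics), 1e-8 (F vs squared pooled t),
and 1e-3 µm (arc-length construction). Floating-point boundaries are
handled with a 1e-9 tolerance (the 32 µm length filter, the 501-sample
count) so binary representation of 0.064 never drops a sample.

## Known limitations

Single-filament scenes only (no crossing or touching kinocilia); seeded
tracing, no automatic detection; profile sampling on projections, not
slices; no mixed-effects modelling beyond per-larva averaging; no liftover
or marker-database lookups; the two-channel competition experiments of the
source system are renderable but not quantified.
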