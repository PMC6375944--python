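# Methods

## The scientific problem

Noëlaerhabdaceae coccoliths (produced by *Emiliania*, *Gephyrocapsa* and
*Reticulofenestra*) are micrometre-scale calcite plates: two elliptical
shields joined by a tube of `n` radial calcite segments surrounding a
perforated central grid. Their mass `m` (1–30 pg) scales with the
peripheral grid perimeter `p` and the segment number `n`:

    m = k_p · p^β            (mass vs grid perimeter)
    p = w · n                (one segment every w ≈ 110–120 nm)
    m = k_n · n^β,           k_n = k_p · w^β

which supports the idea that the organic base plate scale (OBPS) sets
the number of calcite nucleation sites — one per ~112 nm of its
perimeter — and thereby the final coccolith mass.

`coccomorph` packages this analysis as testable code: a voxel phantom
generator with analytic ground truth, a desk-scale coherent-diffraction
imaging (CXDI) forward model with iterative phase retrieval, morphometric
measurement operators, and the allometric fits. Because the raw
synchrotron volumes are not part of the test loop, every operator is
scored against phantoms whose true `m, p, n, L, t, α` are known exactly.

## Phantom model (`coccomorph.phantom`)

A coccolith is parametrized by full axes: shield outline `(a, b)`, grid
ellipse `(a_g, b_g)`, segment count `n`, tube height `t`, proximal rim
length `L`, shield inclinations `α_major / α_minor`, and a `grid_fill`
fraction. The construction:

* **Tube** — an elliptic annulus between the grid ellipse and an offset
  outer ellipse (radial wall width, default 0.18 µm), of height `t`,
  cut into `n` wedges by radial gaps. Gaps are 1.5 voxels wide — the
  smallest gap that reliably survives voxelization — and keep a constant
  physical width at every radius so a morphological closing can seal
  them during measurement.
* **Shields** — plates of constant vertical thickness (default `0.25 t`)
  whose mid-surfaces rise conically from the tube edge,
  `z(r) ∝ r` with slope `tan α` along each principal axis. The distal
  shield spans tube edge → `(a, b)`; the proximal rim extends `L` beyond
  the tube but is clipped to stay under the distal shield (the distal
  shield is the wider one in this family); ground truth reports the
  effective (clipped) `L`.
* **Grid** — radial laths on the outer half of the central area,
  centered mid-segment so they stay attached to the tube, with angular
  width chosen to preserve `grid_fill` of the full central area and to
  never taper below ~2 voxels.

**Analytic mass.** Shield plates have exact area × thickness volumes;
tube and grid, whose wedges are defined in the arc-length
parametrization of the grid ellipse, are integrated by 1-D quadrature
over the parametric angle. Multiplying by 2.71 pg/µm³ (calcite) gives
the ground-truth mass; voxel-counted masses agree within ~1.5 % at
32.5 nm voxels.

**Voxelization fairness.** Binary occupancy is sampled at voxel
centers. The flat tube slab would otherwise quantize coherently (all
columns gain or lose a layer together), so the grid is shifted so the
tube base plane coincides with a voxel boundary; the sampled tube height
then rounds to the nearest voxel count.

**Populations.** `sample_population` draws `p ~ U(p_range)`, sets
`n = round(p/w)` (round-half-even), `m = k_p p^β e^ε` with
`ε ~ N(0, σ_log²)`, `L = (L/p)·p`, `t = (t/p)·p`. Defaults are the
fitted coefficients `k_p = 4.92×10⁻²`, `β = 3.175`, `w = 0.112 µm`,
`p ∈ [3, 7] µm` — the observed range — with `t/p = 0.18` and
`L/p = 0.12` chosen so that the default geometry's analytic mass tracks
the mass law (the in-plane dimensions and `t, L` scale isometrically,
giving a β = 3 core; the tube wall width absorbs the residual).
`geometry_for_mass` solves for the wall width that makes the analytic
mass match each record's generated mass exactly, yielding walls of
0.1–0.4 µm across the population.

**Coccospheres.** Coccoliths are placed tangentially (distal side
outward) at Fibonacci-lattice directions on a sphere of diameter
`Φ_CS` (observed range 4.1–7.3 µm, 10–24 coccoliths), with a random
global rotation and per-coccolith jitter on collision, a 1-voxel
clearance, and a bounded retry count before `PackingError`. A companion
integer label volume records each voxel's source coccolith.

## Measurement operators (`coccomorph.morphometrics`)

All measurements binarize at an **isovalue** (default 0.5 of solid
calcite; the concept follows the imaging analysis, the value is our
choice and a mass sensitivity over isovalue ∈ [0.3, 0.7] is reported by
the pipeline alongside every mass).

* **Segmentation** emulates iterative extract-and-subtract: connected
  components (face connectivity), peeled largest-first. Components
  anomalously large versus the population median are split by
  marker-based watershed on the distance transform. Components below
  `min_coccolith_voxels`, or failing a plate-flatness test
  (`sqrt(λ_min/λ_max)` of the positional covariance > 0.5 — merged or
  broken objects), are reported but flagged for exclusion, mirroring
  the exclusion of broken or incorrectly extracted coccoliths from mass
  statistics.
* **Orientation**: the plane normal is the eigenvector of the largest
  voxel-inertia eigenvalue; the volume is resampled with the major axis
  first and the normal third. The translation is snapped to whole
  voxels — at exactly half-voxel offsets the interpolated edge values of
  a binary volume tie at the isovalue and the strict threshold would
  erode every surface by half a voxel. The distal side is mapped to +z
  using the sign of the radius–height covariance (the shields rise
  distally with radius); this is degenerate, and irrelevant, for a
  perfectly flat object.
* **Mass**: above-isovalue voxel count × voxel volume × 2.71 pg/µm³.
* **Thickness map**: per column, voxel edge × above-isovalue count
  along the normal; maximal over the tube.
* **Ellipses**: the tube annulus is the set of columns thicker than
  0.72 × the maximum (above two stacked shield plates ≈ 0.5 t plus
  quantization, below the tube height). Slits are sealed by closing;
  hole-filling yields the grid boundary (inner tube edge) and the tube
  outer edge. The grid boundary is refined to sub-voxel accuracy by
  locating, along 720 rays, the half-height crossing of the
  grey-closed thickness map (unbiased for a sharp sampled edge), with a
  trimmed ellipse refit. Shield and grid outlines are fitted with the
  direct least-squares ellipse method; axes are reported as FULL axes,
  the convention forced by the circle limit of the perimeter formula
  `p = π√((a_g²+b_g²)/2 − (a_g−b_g)²/8)` (which equals πd for a circle
  and matches numerical arc length to <0.5 % for e ≤ 0.85).
* **Segment count**: the thickness profile is sampled on the tube wall
  at positions uniform in *grid-ellipse* arc length (the
  parametrization in which segments are laid down), averaged over a
  radial band. The dominant FFT harmonic over [8, 120] is cross-checked
  against direct counting of prominent profile minima; disagreement or
  modulation below 20 % peak-to-peak returns *unresolved* — the same
  outcome as for a gap-free tube or segments finer than the voxel grid
  (the *G. muellerae* situation).
* **Rim and tube**: `t` is the median column thickness over the tube
  annulus; `L` is the median over angular rays (±20° sectors about the
  major and minor axes, averaged) of the radial extent of columns
  crossed by both shields beyond the tube outer edge.
* **Inclination**: the mid-surface height of two-run columns (midpoint
  of top and bottom filled voxels; the two plate offsets cancel) is
  regressed against radius in ±12° sectors about each axis;
  `α = atan(slope)`, averaged over opposite sectors. Rimless coccoliths
  fall back to the top-surface slope. Columns within 5 % of the shield
  rim are excluded (partial columns corrupt the surface).
* When the central area is as thick as the tube, no interior hole
  survives thresholding and the grid boundary, hence `p`, is reported
  unresolved (the *E. huxleyi P41* exclusion).

## CXDI simulation (`coccomorph.cxdi`)

The forward model is the flat-Ewald (central-slice) approximation,
appropriate for the small-angle geometry of a multi-metre detector
distance at hard-X-ray energies: the pattern at tilt θ (rotation about
y, beam along z) is the squared magnitude of the central slice of the
3-D Fourier transform perpendicular to the rotated beam axis, sampled
with cubic spline interpolation. All transforms are unitary
(`norm="ortho"`), DC at `N//2`; the zero-tilt pattern equals
|2-D unitary FT of the beam-axis projection|²/N (tested, with the
Parseval identity). Optional Poisson noise and a circular beamstop are
applied per pattern.

Patterns over a −80°…+80° tilt series are splatted onto the 3-D Fourier
grid with trilinear weights and normalized by the accumulated weight;
unhit voxels (the 10° half-angle missing wedge, beamstop shadow) are
flagged unmeasured. Phase retrieval alternates HIO (feedback 0.9) and
ER with shrinkwrap support updates (Gaussian blur σ 3.0 decaying to
1.5, threshold 10 % of max), starting from random phases and an
autocorrelation support; unmeasured amplitudes are left unconstrained;
divergence flags the result rather than raising. Ensembles (default 20
in the pipeline; fewer in tests) are aligned by upsampled
cross-correlation with inversion-twin resolution and averaged. The PRTF
is Σ|F_avg| / Σ√I per shell over measured voxels — the averaged
reconstruction supplies the phases, consistent with averaging before
PRTF — and the resolution is read at the first downward 0.5 crossing
(linearly interpolated), or reported as the voxel size when the PRTF
never drops below 0.5, as for the best experimental datasets.
Background flattening fits an isotropic Gaussian centered at the mass
center by least squares on the background voxels (the compact object,
thresholded at half maximum and dilated, is masked out) and clips
negatives to zero.

## Allometric fits (`coccomorph.allometry`)

Power laws are fitted by OLS of ln y on ln x — the multiplicative
scatter makes the log scale the natural one, and the quoted 95 %
confidence bounds are consistent with t-based intervals there (exponent
CI direct, prefactor CI by the delta method on the intercept). R² is
reported on the log scale and is invariant under unit rescaling. A
linear-space nonlinear refinement is available but the log-space fit is
the default and is used everywhere. `fit_through_origin` implements
`p = w·n` with slope Σnp/Σn²; a single pair is accepted (the 6.92 µm /
61-segment specimen alone gives w = 113 nm) with an infinite CI.
Flag-based exclusion (unresolved grid or segment count) removes records
from the fits and lists them in the report, reproducing the published
exclusions.

## What the phantoms do and do not show

The generator reproduces the *geometric and statistical* structure of
the measured coccoliths: elliptical shields with the observed
eccentricity bands, ~30°/25° shield inclinations, 29–61 segments of
110–120 nm width, masses following the fitted power law. It does not
model crystallographic units (R/V c-axis orientations), organic
base-plate material, two-layered coccospheres, mechanical deformation,
partial coherence or detector physics. Passing tests therefore
demonstrate that the measurement operators and fits recover known
parameters under realistic geometry and sampling — not that they would
be unbiased on arbitrary experimental data.

## Problem sizes and numerical choices

Test phantoms use the real voxel sizes (28.8 / 32.5 nm) on volumes up
to ~320³; CXDI tests run on 64³ grids with an ellipsoid or ball test
object oversampled ~3×, 321-angle tilt series for assembly accuracy and
coarser series elsewhere; population closures use 20–50 phantoms over
p ∈ [3, 7] µm. Monte-Carlo CI coverage uses 100 replicate seeds.
Reported tolerances: phantom mass 3 %, perimeter 5 %, segment count
exact, inclination ±3–5°, rim/tube within 1–2 voxels; noiseless
fully-sampled phase retrieval reaches NRMSE < 10⁻², and assembled
intensities match the direct transform within 5 % at 0.5° steps.
Degenerate inputs (empty volumes, flat or spherical objects, collinear
points, non-positive fit data) raise typed exceptions; ties and flips
(inversion twin, distal-side ambiguity of flat objects) are resolved by
correlation or documented conventions. All stochastic stages are seeded
and bit-reproducible.
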