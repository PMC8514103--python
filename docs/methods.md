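# Methods

## Model

The tissue is a thin epithelial sheet treated as a 2D linear elastic
continuum on a rigid substrate to which it couples through a bed of
independent springs (Winkler foundation). Displacement **u** (μm) obeys the
quasi-static Cauchy equation ∇·σ + f = 0 with the adhesion force
f = α k **u** and the stress

σ = λ tr(εᵉ) I + 2μ εᵉ,  εᵉ = ε + ε_c I,

where ε is the linearized strain of **u** and ε_c ≥ 0 the prescribed
isotropic *contraction magnitude*: the baseline prestrain ε0c in the central
subdomain Ω1 and ε0c + εc in the peripheral annulus Ω2. The sign of the
eigenstrain term is fixed by physics: a fully clamped tissue must be under
tension, a free tissue must shrink stress-free, and the resulting substrate
tractions T = α k **u** must point centripetally. (Writing the elastic
strain as observable strain *minus* a positive contraction would instead
make the tissue expand; we treat that reading as a sign ambiguity and
implement the tension-generating convention.)

Assumptions: small strains, linear elasticity, quasi-static motion (inertia
and — by default — substrate viscosity neglected), rigid substrate (the
foundation spring ends are fixed in space), uniform isotropic material in
both subdomains.

### Constitutive matrix

Two modes are available.

* `printed_lame` (default): the 3D Lamé constants
  λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν)) used directly in the 2D stress
  formula. This is a plane-strain-type matrix.
* `plane_stress`: the standard plane-stress matrix E/(1−ν²)·[[1, ν, 0],
  [ν, 1, 0], [0, 0, (1−ν)/2]], physically natural for a thin sheet.

The default keeps the λ, μ formulas as printed in the modeling literature
this package follows; the alternative is one config switch. Every
verification in this repository (oracle comparison, round trips) uses the
same matrix on both sides, so the choice does not affect any validity check.

### Discretization

Structured mesh of square bilinear elements, side h = 2R/n_diameter,
axis-aligned and centered on the disk center. An element is kept iff its
center lies within the disk (inclusive boundary). This inclusion rule is an
inference — the published element count (7860 at 100 elements across the
diameter) is stated without the rule — but it is the unique convention among
the natural candidates (center in/out, strict/inclusive, node-based, grid
offset by half a cell) that reproduces that count, as the test suite checks
by brute force. Element stiffness uses 2×2 Gauss quadrature; the foundation
matrix is the consistent form α·k·∫NᵀN dΩ (a lumped diagonal would converge
to the same limit; the consistent form is what the assembled-matrix
formulation of the equilibrium equation describes, and it passes the patch
test cleanly). The eigenstrain load per element is ε_c·∫BᵀD{1,1,0}ᵀdΩ with
the sign convention above. The linear system is solved by sparse LU
(SuperLU); the relative residual must be ≤ 1e−10 or the solve raises.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| E | 1.0 | kPa | nanoindentation-scale stiffness of a pre-transformation epithelium |
| ν | 0.46 | – | quasi-incompressible tissue |
| R | 200 | μm | 400-μm circular micropatterns |
| n_diameter | 100 | – | canonical resolution (7860 elements) |
| k | 5e−3 | kPa/μm | places the traction boundary layer ℓ = √((λ+2μ)/k) ≈ 30 μm ≈ 15% of R, matching rim-concentrated experimental traction maps; not reported in the source material, config-exposed |
| c | 0 | kPa·h/μm | Kelvin–Voigt viscosity of the adhesion; the printed equilibrium law is purely elastic, so viscosity is an option (backward-Euler stepping), default off |
| ε0c | 0.05 | – | baseline prestrain; its absolute value cancels from every normalized trend (the model is linear), it only sets the absolute area change (~5% at default) |

Units: μm, kPa, hours; traction in kPa (≡ nN/μm²). The absolute traction
scale is uncalibrated; all headline comparisons use trends normalized to the
pre-induction timepoint t = −4 h.

### Induction schedules

Time courses are piecewise linear between endpoint constraints, on an hourly
grid from −4 h to 48 h (53 timepoints, induction at t = 0):

* **α(t)**: 1 until t = 0, then linear to α_min = 0.4 at 24 h, constant
  after. The 24-h span mirrors the experimental loss of integrin-mediated
  adhesion within a day of induction; the floor value is not published and
  0.4 is our reconstruction (config-exposed).
* **εc(t)**: 0 until t = 8 h, then linear until the total peripheral
  contraction ε0c + εc doubles the baseline at 48 h. The 8-h onset mirrors
  the experimental timing (traction minimum around 8 h, peripheral
  actomyosin buildup after); the doubling endpoint follows the measured
  ~2× pMLC2 intensity.
* **r_inner(t)**: R until 8 h, then linear to R/3 at 48 h, shrinking the
  baseline-only core as the active annulus grows.

`adhesion_only` freezes contractility at baseline; `contractility_only`
freezes α ≡ 1. The staggering of the α drop (early) and the contraction ramp
(later) is what produces the interior traction minimum in the combined run;
with fully simultaneous linear ramps the product α-effect × ε-effect is
monotone-then-monotone in the wrong order and no dip-recovery appears.
Arbitrary tabulated schedules can be passed directly via
`InductionSchedule`.

Per-timepoint observables: deformed area (shoelace sum over displaced
element quadrilaterals) and the area-weighted mean of |T| over the
undeformed domain (the experimental trend being emulated is a single
whole-island magnitude trace; rim-restricted statistics are available in the
pixel pipeline).

## Verification

An independent axisymmetric oracle solves the radial ODE
(λ+2μ)(u″ + u′/r − u/r²) = α k u with u(0) = 0 and σrr(R) = 0 by
second-order central finite differences — a 1D code path sharing nothing
with the 2D solver — and is itself checked against the closed-form modified
Bessel solution u ∝ I₁(r/ℓ). At the canonical resolution the 2D solution
matches the oracle to well under 2% relative L2.

The mesh-convergence study (n_diameter = 25, 50, 100) uses a deliberately
soft foundation (k_eff = 1e−4 kPa/μm, ℓ ≈ R) so the displacement varies
smoothly on the coarsest mesh: with the physical default k the boundary
layer spans only ~2 elements at n = 25 and the sequence is not yet
asymptotic. The observed order is ≈ 1.8 — slightly below the nominal 2
because the staircase approximation of the circular boundary perturbs the
traction-free edge at O(h) amplitude on an O(h) wavelength, contributing an
O(h^1.5)-type rim error that the nodal L2 norm feels. The error at fixed n
is dominated by the outermost element ring.

## Pixel-grid analysis conventions

* Grids are row-major; x = column, y = row; pixel centers at integer
  coordinates; foreground connectivity 8, ring erosion 4 (single-pixel
  rings). None of these conventions are published with the procedures being
  reproduced; they are fixed here and tested.
* **Perimeter** comes from the sub-pixel marching-squares contour smoothed
  by a 5-point circular moving average. The raw contour's pixel-scale
  staircase overestimates a smooth perimeter by ~5%, which circularity =
  4πA/P² amplifies to ~10%; the 5-point window brings disks and squares of
  ≥ 400 px diameter within 1% of their closed forms without erasing
  features larger than a few pixels. The window is skipped for contours
  shorter than 10 points.
* **Inward normals**: each tissue pixel takes the local normal of the
  nearest point of the (densely resampled) edge contour, oriented inward by
  probing which side of the contour is tissue. Using the direction *to* the
  nearest contour point instead is unstable for pixels a fraction of a
  pixel from the edge. Masks are zero-padded before contour extraction so
  border-touching tissues still yield closed contours.
* **Equal-pixel split**: the cut ring m minimizes |outer − inner| pixel
  counts, ties toward smaller m; the imbalance is bounded by one ring.
* **FEM-to-grid resampling** places one pixel per element (pixel centers at
  element centers, bilinear nodal interpolation), so forward fields map
  onto the pixel pipeline without regridding artifacts.

## Monolayer stress recovery

The substrate reaction −T must be equilibrated by the internal stress of
the monolayer. The mask footprint is meshed with one square element per
pixel, −T applied as an element-wise constant body load, the boundary left
traction-free, and the auxiliary elastic problem solved with rigid modes
removed by pinning three displacement components (two translations + one
rotation blocker). Because the load is balanced the pin reactions vanish and
the recovered stress is independent of both the pin choice and the nominal
modulus (both asserted by test; the modulus only rescales the auxiliary
displacement). Inputs with a net-force imbalance within 1% of the total
magnitude are projected onto the balanced subspace by subtracting the mean
vector; larger imbalances raise an error. The round-trip test against the
forward model is run on the homeostatic (uniform-prestrain) state — the
regime in which the monolayer assumption behind the method holds; with
piecewise eigenstrains the forward stress additionally contains a
self-equilibrated eigenstress near the Ω1/Ω2 interface that no
traction-based recovery can see. Recovered values are stress per unit sheet
thickness (kPa).

## Synthetic data

The generators emulate the statistical structure the analysis stages assume:
star-convex islands r(θ) = R + a·Σ cos(kθ + φ_k) with low wavenumbers
(default k ∈ {2, 3, 5}) and seeded phases; traction magnitude decaying
exponentially from the edge over a rim_fraction·R = 30 μm boundary layer at
a few hundred Pa peak (TFM scale), directed toward the island centroid so a
symmetric island balances exactly; additive Gaussian component noise of
configurable sd (no noise statistics are published for the source data);
and time series in which control islands are stationary while transformed
islands shrink (radius → 0.6 R), elongate (aspect ratio → 1.5 via
area-preserving anisotropic scaling over the late frames), and follow a
dip-then-recover traction-magnitude template. A single top-level seed fans
out to fixed per-stream `SeedSequence` substreams (mask phases, per-frame
field noise), so every output is bit-reproducible and new generators cannot
perturb existing fixtures.

What passing on synthetic data does *not* show: robustness to real
segmentation errors, non-star-convex or multiply-connected footprints,
spatially correlated traction noise, PIV windowing artifacts, or finite
substrate compliance — none of which the generators model.

## Known limitations

* Small-strain, linear elasticity: late dewetting (large deformation,
  3D aggregation) is outside the model's validity; the simulated area loss
  (~5% at default prestrain) is deliberately in the linear regime, so the
  simulated trends are qualitative analogues, not fits, of the experimental
  curves.
* The foundation density k, the α floor, and the schedule tabulations are
  reconstructions constrained by endpoints and monotonicity only.
* The staircase disk boundary limits the observable convergence order of
  rim-dominated solutions (see Verification).
* Stress recovery assumes a flat monolayer; it is not applicable after
  bilayering.
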