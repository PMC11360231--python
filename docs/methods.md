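# Methods

## The model

`tumorperf` models steady fluid exchange between two overlapping
continuum domains on a shared 2D mesh of the tumor section: the
capillary network (domain 1) and the extracellular space (domain 2).
Instead of resolving individual vessels, the capillary bed is *smeared*
into nodal fields — a volumetric fraction `r_Vcap`, a mean diameter
`d_cap`, and a wall hydraulic coefficient `h_cap` — so anisotropy of the
real vasculature enters through the spatial variation of these fields,
not through explicit vessel geometry.

Each domain obeys Darcy's law, `v = −k_D ∇p` (superficial velocity
convention: volume flux per total cross-section). The element
conductivity is

    K_IJ = ∫_V  r_V · kD_ij · N_I,i N_J,j  dV

over 4-node bilinear quadrilaterals (2 × 2 Gauss) and, at the mesh
center, 3-node linear triangles (1-point rule), with unit out-of-plane
thickness `h_z = 1 µm`. Transmural exchange is a nodal two-point
"connectivity element" coupling the capillary and extracellular pressure
at the same node with conductance

    k_J = (4 · r_Vcap,J · V_J / d_J) · h_cap,J        [µm³/(Pa·s)]

where `V_J` is the nodal tributary volume (`Σ_J V_J` = mesh volume).
The factor `4/d` is a cylinder's surface-to-volume ratio, so `4 r V/d`
is exactly the capillary wall area inside `V`; a literal product
`4·d·r·V·h` would carry µm⁵/(Pa·s) and cannot be a volumetric
conductance. This surface-area reading is the one implemented.

Boundary conditions follow the physiological setting: the capillary
pressure is prescribed everywhere at an effective 10 mmHg (1333.22 Pa,
folding hydrostatic and oncotic contributions together), and the
extracellular pressure is zero on the tumor contour (perfusion balanced
by reabsorption outside). Only the extracellular field is then unknown;
a general two-field solve (capillary Dirichlet only where the user says
so) is kept behind `fix_capillary_everywhere=False`. There is no storage
term, so each configuration is a single linear steady solve; the
"incremental" form `K ΔP = Q − K P₀` is retained because the time
course transfers the previous step's field as `P₀`.

With uniform parameters this reduces to a screened Poisson problem,
`∇·(r_ex k_t ∇p) = (4 r_Vcap h_cap / d)(p − p_c)`, with decay length

    λ = sqrt( r_ex · k_t · d / (4 · r_Vcap · h_cap) )  ≈ 56.4 µm

at the defaults below. The disc solution
`p(r) = p_c [1 − I₀(r/λ)/I₀(R/λ)]` and the strip solution
`p(x) = p_c [1 − cosh(x/λ)/cosh(L/λ)]` are the package's verification
oracles (relative L2 error 8.8×10⁻⁴ on a 32×64 polar mesh, observed
convergence order 2.0; see `analysis/04_verification_benchmarks.py`).

## From images to parameters

Per channel, a pixel is positive when its intensity exceeds a fixed
fraction of full scale — 0.95 for the vascular stain, 0.79 for the
perfusion stain. These mirror an over/under display threshold with a
"minimum below" setting; whether such settings mean intensity fraction
or histogram percentile is ambiguous, so both are implemented
(`threshold_mode`), fraction being the default. A 9 × 9 grid is laid
over the frame; per cell we record percent coverage of each channel and
the mean width of up to six randomly sampled (seeded) connected
components, where a component's width is twice the median
distance-transform value along its skeleton times the pixel size — the
automated analogue of a manual caliper across a stained vessel,
unbiased within ~6% across orientations on constant-width synthetic
bands. Components are attributed to the cell containing their centroid.

Cell-center values are carried to mesh nodes by inverse-distance
weighting (power 2), then per node:

    r_Vcap = d · A_cap% / (400 · h_z)
    r_Vcell = perfusion% / 100
    r_ex   = 1 − r_Vcap − r_Vcell

A node where the fractions over-fill the volume raises an error naming
the node. Because the perfusion stain is only a proxy for cell area and
saturates near dense vasculature, the drivers instead pass
`min_r_ex = 0.05`, which guarantees a 5% interstitial fraction by
capping `r_Vcell` — solid tissues do not compress their extracellular
space to nothing, and without the floor a sufficiently unlucky cell
renders the whole cohort infeasible.

## Geometry over time

Tumor outlines are treated as star-shaped about their centroid: radii
are single-valued in the polar angle. This gives a deterministic
correspondence for averaging replicate outlines (centroid-aligned,
per-angle mean radius; optional size normalization before averaging,
since how replicate sizes should be normalized is a modelling choice),
for linear interpolation between time knots (per-angle radius and
centroid), and for meshing (polar transfinite quads with a center
triangle fan). Four knots — days 7, 10, 13, 16, about 15/25/60/80% of
final growth — bound the simulation; geometry and heatmaps interpolate
linearly *within* the three knot intervals and are never extrapolated
outside them. (A phrase like "interpolation between the three data
points" with four configurations is read as the three intervals.)
Remeshing happens every substep, and pressures transfer to the new mesh
by k-nearest IDW (k = 4, power 2 — neither is experimentally
constrained; IDW cannot overshoot the sample extrema, which is why it
was preferred over polynomial transfer).

Resampling a smooth outline at n sector angles loses O(n⁻²) of its
area (an inscribed 32-gon of a circle loses 0.64%). By default the
resampled boundary is scaled radially so the mesh area matches the
polygon area to machine precision, keeping remeshing area-conservative
at any angular resolution; `preserve_area=False` pins boundary nodes
exactly on the contour instead (the Bessel benchmarks use this so the
analytic radius is exact).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| p_c | effective capillary pressure | 10 mmHg = 1333.22 Pa | Pa |
| h_cap | wall hydraulic coefficient | 1.57×10⁻³ | µm/(Pa·s) |
| h_z | section thickness | 1 | µm |
| k_t | tissue Darcy coefficient | 1.0 | µm²/(Pa·s) |
| µ | blood/plasma viscosity | 3×10⁻³ | Pa·s |
| d | capillary diameter | from images (~5) | µm |

`k_t` and `µ` are not pinned by measurements; `k_t` sets λ directly
(reported by `bessel_length` so its effect is visible) and `µ` only
enters the capillary Darcy tensor `d²/(32µ)·(t⊗t)` (aligned) or
`d²/(64µ)·I` (isotropic in-plane) — which is irrelevant under the
fixed-capillary-pressure boundary condition but implemented for the
general two-field mode. The volumetric source `Q` in the balance
equation has no concrete definition in this setting and defaults to
zero; transmural flux enters through the connectivity matrix.

## Synthetic data: what it does and does not establish

The generators emulate (i) star-shaped outlines whose cross-section
areas scale as volume^(2/3) along the exponential fit
`y = 59.98·exp(0.1874·t)` (a section of a self-similar growing mass;
the paper-scale link between 2D slices and 3D volumes is not measured,
so the 2/3 power is a choice), (ii) smooth-plus-noise heatmap fields,
and (iii) two-channel images of straight constant-width vessel bands
with perfusion halos, rendered so truth coverage is an exact pixel
count. They do **not** emulate staining texture, illumination
gradients, vessel curvature or branching, or 3D stacks. A green
image-stage test therefore establishes that thresholding, gridding, and
width estimation recover a known rasterized truth — not that the 0.95 /
0.79 settings are optimal for real micrographs.

Default synthetic magnitudes are chosen once to match the measured
world: vascular coverage of a few percent declining with age
(angiogenesis early, necrosis late), capillary diameters ~5 µm,
perfusion coverage tens of percent. Replicates are three per time point
in the analysis drivers (scaled down from the experimental six for
runtime; the averaging logic is identical).

## Numerical choices

- Sparse direct factorization (SuperLU via `scipy.sparse`) on the
  Dirichlet-reduced symmetric system; relative residuals are ~10⁻¹⁴.
- Conservation is checked per solve: total transmural influx
  `Σ k_J (p_cap − p_ex)` equals the boundary outflux recovered from
  Dirichlet-node reactions to machine precision (~10⁻¹⁵ relative).
- The discrete maximum principle (0 ≤ p_ex ≤ p_c) holds on the polar
  meshes used here; strongly distorted non-convex quads would raise a
  Jacobian error at meshing time rather than solve incorrectly.
- IDW exactness at samples is enforced by a nearest-sample snap within
  10⁻¹² of the coordinate scale; duplicate samples with conflicting
  values are rejected.
- Ray-polygon radius extraction tolerates sub-percent multivaluedness
  (outermost crossing wins) so that blended outlines, star-shaped about
  the blend of the resampling centers but queried about their area
  centroid, do not spuriously fail; genuinely folded boundaries still
  raise.

## Known limitations

- 2D only: flow is assumed identical in all planes parallel to the
  section; no stacked-slice 3D reconstruction.
- No solute/drug transport, no poroelastic deformation, no lymphatic
  sink; oncotic effects are folded into the single effective capillary
  pressure.
- The perfusion-stain-as-cell-fraction assumption is taken as given,
  with the `min_r_ex` guard as the only protection against its failure
  mode.
- Velocities are reported for the extracellular domain in the
  superficial (Darcy) convention; intrinsic pore velocities would be
  larger by 1/r_ex.
- Group summaries are mean ± s.e.m. only; no hypothesis testing.
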