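# Methods

`delfmap` reconstructs the inner (WM/GM) and pial (GM/CSF) cortical
surfaces from tissue-class probability volumes and a topology-corrected
white-matter segmentation. The pipeline consolidates every stage around
one physical model: the electrostatic potential of a charged conductor
(the WM) insulated by an inhomogeneous dielectric layer (the GM).

## 1. Model

### Permittivity and potential

With per-voxel WM and GM class probabilities `P_w`, `P_g` in [0, 1], the
permittivity is

    eps = 1 + (eps_max - 1) * (C_d * P_w + P_g),   clamped to [1, eps_max]

where `C_d` gates the WM term to within `d_min_eps` (default 1 mm, the
lower bound on cortical thickness) of the WM object, so that boundary
voxels classified WM rather than GM still carry the high-permittivity
layer. `eps_max = 100` by default; the skeleton is insensitive to this
choice over at least an order of magnitude (verified at 1000).

The potential solves the source-free inhomogeneous-dielectric equation

    div(eps grad phi) = 0,    phi = 1 on the WM region, phi = 0 on the
                              image border (Dirichlet),

equivalently a steady-state diffusion with diffusivity `eps`. Because
flux concentrates where `eps` is large, streamlines of `grad phi` run
through the GM layer before exiting into background — the property that
lets the field find the mid-sulcal collision surfaces. With `eps = 1`
the model reduces to the classical Laplace mapping; on an
asymmetric-bank sulcus phantom the dielectric ridge sits measurably
closer to the CSF centre line than the Laplace ridge (tested).

**Discretisation.** Conservative (flux) form on the voxel grid with
*harmonic* averaging of `eps` at cell faces. Harmonic averaging
reproduces the exact piecewise-linear solution across axis-aligned
permittivity jumps (asserted against the two-layer-slab closed form).
Solvers: Jacobi fixed point (reference) and red-black SOR (default,
same fixed point; over-relaxation factor `2/(1 + sin(pi/N))`, with the
effective `N` doubled when zero-flux faces mirror the domain).
Convergence: largest per-voxel update below `tol` (default 1e-6);
non-convergence raises an error carrying the residual.

**Boundary options.** Border faces are grounded by default; faces can
be declared zero-flux (`neumann_faces`), the natural condition for
phantoms extruded through the volume. When the Dirichlet boundary is
known at subvoxel accuracy — the WM model may be supplied as a level
set rather than a binary mask — optional signed-distance inputs
(`wm_sdf`, `zero_sdf`) place the boundary with ghost-value stencils
(face conductance scaled by 1/theta, theta clamped to [0.1, 1]). This
removes the half-voxel staircase error that otherwise dominates
accuracy near curved boundaries (2% vs ~10% worst-case on the spherical
capacitor closed form).

### Distance and correspondence transport

Let `N = grad phi / ||grad phi||`. Streamline arc length `d` from the
WM boundary and the source-point coordinates `psi_i` solve

    (-N) . grad d = 1,  d = 0 on the WM boundary
    (-N) . grad psi_i = 0,  psi_i = x_i on the WM boundary.

(The potential is 1 on WM and decays outward, so arc length grows along
`-N`; the sign is fixed accordingly.) Both are discretised with
first-order upwind differences selected per axis by the sign of the
tangent component — voxel value = weighted average of its up-streamline
neighbours plus the source term — and iterated with full-grid Jacobi
sweeps to a fixed point (tolerance 1e-4 mm; the dependency graph
follows the monotone potential, so sweeps converge in about the length
of the longest streamline). Voxels with no usable upwind stencil
(`||grad phi||` below 1e-8 of its maximum, or all upwind weights zero)
are flagged degenerate, excluded from the convergence test, filled with
a neighbour average, and later absorbed into the shock set.

An independent Lagrangian route — batched RK4 integration of
streamlines at quarter-voxel steps with trilinear interpolation of the
tangent field, bisected at the WM entry — is part of the package and is
used to verify the Eulerian solutions (agreement within one voxel at
more than 99% of GM voxels on slab and shell phantoms).

### Sulcal skeleton

Streamlines from opposing banks collide inside sulci; two detectors
mark the collision locus S:

* **Shocks**: voxels with `d > d_min_skel` (1 mm) where the
  centred-difference `||grad d||` falls below `T = 0.8` (it is close to
  1 elsewhere). Transport-degenerate voxels are added unconditionally.
* **Correspondence discontinuities**: voxels where the source point
  jumps by more than `D_min = 4` voxels (converted to mm by the grid
  spacing) across any of the 6 face neighbours. This detector needs no
  minimum-distance cutoff: near the WM boundary neighbouring
  streamlines originate close together, and we assert zero detections
  within one voxel of WM.

S is used raw (no thinning) as a barrier mask. On the fused symmetric
sulcus phantom the correspondence skeleton is a one-voxel-wide sheet on
the analytic medial plane; under probability noise sigma = 0.1 its
Hausdorff drift stays within 2 voxels, and it has at most as many
26-connected components as the shock skeleton on the same noisy
phantom.

A geometric caveat found while building the phantoms: in a *resolved*
sulcus (open CSF slit), potential decreases from the fundus toward the
opening, so the slit CSF is fundus-sourced and the detector flags the
GM/CSF interface sheets on both banks in addition to the mid-slit
plane. That widens S to ~3 voxels — harmless for its barrier role (the
extra voxels are at the GM/CSF interface where the pial surface stops
anyway), but it is why the medial-plane *accuracy* statement is made on
the fused (gap 0) variant, where the medial surface passes through
tissue.

### Deformable model

The surface is the zero level set of `phi_ls` (negative inside),
evolved by

    phi_t + w_a V . grad phi_ls = w_k kappa ||grad phi_ls||

* `V = -beta * grad phi / ||grad phi||` (advection down-potential, i.e.
  outward, where `beta > 0`).
* `beta = 2/(1 + exp(-K [P_gw - P0])) - 1` — logistic
  stopping/direction-reversal factor of the combined class probability;
  `K = 40`, set-point `P0 = 0.8`.
* `P_gw` is a weighted average of `P_g + P_w` over the closed
  neighbourhood (centre weight 0.5, the rest shared by 18 neighbours),
  with skeleton voxels contributing zero — the barrier also cuts the
  probability support across sulci.
* Optionally `beta` is composed with the distance-constraining factor
  `gamma = 2/(1 + exp(-K [1/2 - min(d, 2 d_max)/(2 d_max)])) - 1`
  (`d_max = 6` mm, above the anatomical thickness bound) through the
  OR-sign rule `beta1 = |beta| |gamma| sgn`, `sgn = -1` if either
  factor is negative: the surface retreats if either criterion says so.

Numerics: first-order upwind advection, central-difference mean
curvature (sum-of-principal-curvatures convention; clamped to 1/h),
CFL time step `dt = 0.5 h / (w_a max||V||_1 + 6 w_k / h)`, narrow band
of 6 voxels, redistancing every 5 iterations.

**Topology preservation.** A binary inside-set shadow of the level set
is maintained. Any voxel whose update would flip its sign is processed
in raster order: the flip is vetoed (value clamped to +-1e-6 with the
old sign) if the voxel belongs to S, or if it is not a *simple point*
of the current inside set under the (26-foreground, 6-background)
connectivity pair (topological numbers T26 = T6 = 1 on the punctured
neighbourhood; implementation verified against a brute-force
Betti-number oracle on 1e5 random configurations). Consequently the
foreground-26 / background-6 component counts and the Euler number of
the inside set are invariant for any number of steps, and redistancing
is also forbidden from flipping signs.

**Redistancing.** Upwind (Godunov) sweeps restore `||grad phi_ls|| = 1`
in the band while the interface-adjacent layer is kept *frozen* up to a
single global gradient-scale factor — a common rescaling of the near
layer leaves every linear zero crossing `a/(a-b)` exactly in place.
This choice matters: rebuilding near-interface values from subcell
estimates (the usual redistancing) nudged the interface by
~0.005 voxel per application, which over a few hundred steps breaks the
curvature-flow law; with the frozen near layer a shrinking sphere obeys
`R(t)^2 = R0^2 - 4t` to better than 1% down to R = 5 voxels (the test
tolerance is 5%).

### Pipeline

1. **Inner surface** — signed distance of the WM mask (exact EDT;
   zero level on the voxel-cube boundary), then 3 curvature-only
   iterations with the topology guard.
2. **Field** — permittivity and potential with the smoothed inner
   region as the phi = 1 Dirichlet set.
3. **Transport + skeleton** — `d`, `psi`, and S (correspondence
   detector by default; `shock` and `union` available).
4. **Pial surface** — advection-only evolution until the mean
   reinitialised-SDF change per iteration falls below 1e-4 (or 300
   steps), then 3 curvature-only smoothing iterations with the barrier
   still active; meshes by marching cubes and per-vertex thickness by
   closest orthogonal projection of pial vertices onto the white mesh.

With `supersample = 2` the PDE stages (including the level set) run on
a half-voxel grid (linear interpolation for probabilities, nearest for
masks). All stages are deterministic; the only randomness in the
package is the phantom noise, seeded explicitly.

## 2. Surface measures

Meshes are extracted by marching cubes at subvoxel resolution, oriented
outward, and are watertight with Euler characteristic 2 for genus-0
reconstructions. Closest-point queries use exact point-to-triangle
projection with a KD-tree candidate filter (24 candidate triangles per
query). Signed inter-surface distance is negative when the query
vertex lies inside the reference mesh (sign of the projection residual
against the reference's outward normal); summaries report
signed/absolute mean and standard deviation and the percentage of
vertices beyond 1 mm and 2 mm. Inflation is iterative umbrella
Laplacian smoothing (step 0.5, default 20 iterations); convexity is the
accumulated displacement along the current outward normal, positive in
sulcal fundi and negative on gyral crowns. Map association uses the
Pearson correlation over all vertices.

## 3. The phantom generator

Three families with closed-form ground truth, all on isotropic 0.5 mm
grids by default:

* **slab** — WM half-space capped by a GM layer (default 2 mm):
  straight streamlines, constant thickness.
* **spheres** — WM ball R1 = 8 mm in a GM shell to R2 = 10.5 mm:
  radial streamlines, thickness 2.5 mm, all fields closed-form.
* **sulcus** — a GM-coated WM block with a vertical slit (default CSF
  gap 1 mm, banks 2 mm, depth 12 mm) whose rounded fundus is a circular
  arc of 10 mm curvature radius clipped to the slit. Variant flags
  produce an unresolved fundus (GM fills the bottom 4 mm of the slit),
  a GM bridge partway up the slit, a fully fused slit (gap 0), and
  asymmetric bank thicknesses. The slit is symmetric about the exact
  mirror plane of the grid, so the symmetric configuration is
  mirror-symmetric to machine precision.

Hard labels become probabilities by a 0.5-voxel Gaussian blur
(partial-volume emulation), optional i.i.d. Gaussian noise, clipping to
[0, 1] and renormalisation where `P_w + P_g` would exceed 1. The
ground-truth record includes the analytic medial plane and a
region-of-interest box for skeleton checks: the slit interior, one bank
thickness clear of the fundus and rim, because the banks are
anatomically continuous around the fundus, over the rim and at the open
sulcus ends, so no separation claim holds there (or should).

What the phantoms do *not* emulate: MR intensity statistics, bias
fields, anisotropic voxels, curvature-varying cortical thickness, and
classifier-specific probability profiles. Passing tests therefore
demonstrate the correctness of the geometry/PDE machinery under
idealised soft classification, not segmentation robustness on real MR
data.

## 4. Known limitations

* **Set-point bias.** The advection equilibrium is the `P_gw = P0`
  isosurface (verified: the pial zero level tracks that isosurface to
  within half a voxel). On a blurred step edge, the 0.8 level lies
  `0.84 sigma_eff` inside the half-maximum boundary; with the
  generator's 0.5-voxel blur composed with the neighbourhood averaging
  of `P_gw`, that is about 0.6 voxel (0.3 mm at 0.5 mm spacing). The
  recovered shell thickness is therefore biased low by that amount:
  within one voxel of truth at >99% of vertices, but not within half a
  voxel. On real data this bias is absorbed by tuning `P0` to the
  classifier; the phantom suite reports it honestly instead.
* Problem sizes in the test-suite and acceptance runs (64^3-scale
  grids, 0.5 mm spacing) are chosen so the full suite completes in
  minutes; all tolerances are stated at those sizes.
* The marching cubes used is the standard scikit-image implementation,
  not a connectivity-consistent variant; on all phantoms tested the
  extracted meshes match the digital topology of the inside set, but
  this is checked, not guaranteed by construction.
* First-order upwind transport smears `d` and `psi` by O(h) near
  shocks; the skeleton detectors operate on exactly that smeared field,
  as intended.
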