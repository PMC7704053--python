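# Methods

## Model and assumptions

A single activated molecule is released at the inner cell membrane and
diffuses (diffusivity `D`, default 10 µm²/s — a typical cytosolic protein)
through the free cytosol of a voxelized cell until it first enters a
nucleus voxel.  Organelle surfaces, the cell membrane and the exterior are
reflecting; the nuclear surface is absorbing.  The state space is the set of
cytosol voxels only: absorption enters through the sink term of the
6-point finite-volume Laplacian (a face shared with a nucleus voxel
contributes `−1/h²` to that voxel's diagonal), and reflecting boundaries
are simply absent couplings.  Molecules are independent and non-interacting;
inactivation is first-order with a constant rate λ, which factorizes the
killed density as `e^{−λt}` times the unkilled one — the identity every
conditional statistic in the package is built on.  Time is in seconds,
length in micrometres throughout.

Assumptions worth keeping in mind: the continuous-time random walk on the
lattice approximates continuum diffusion only on timescales long compared
with the hop time `h²/6D`; statistics dominated by shorter times (i.e. very
large λ) are properties of the lattice model, not of continuum diffusion.
That is precisely the regime the scaling dichotomy quantifies (below).

## Voxel conventions

Voxel `(i,j,k)` has centre `((i+½)h, (j+½)h, (k+½)h)`; adjacency is
6-neighbor (faces) for the stencil, the flood fills and the BFS distances
alike, so the diffusion operator, connectivity and geodesics live on the
same graph.  Flat ordering is x-fastest.  The nucleus is the union of all
nucleus-component classes (heterochromatin, euchromatin, ...).  Nucleus
voxels that touch the exterior are rejected as a segmentation error rather
than silently reinterpreted.  Cytosol voxels with no path to the nucleus
are retained and flagged: conditional statistics remain well defined for
sources with unreachable support, the MFPT there is infinite.

Geometry variants: `physiological` (all organelles reflect), `no_ER`
(ER voxels opened to diffusion), `no_organelles` (every organelle opened).
The variant cytosols are nested, which is what makes the barrier-ratio
analyses meaningful.

## Release densities

`uniform_shell_init` spreads the unit of probability uniformly over the
membrane shell (cytosol voxels with an exterior face) — the voxel analogue
of activation at a uniformly random membrane point.  `patch_init` restricts
to shell voxels within a Euclidean radius of a centre voxel; `point_init`
is a single voxel.  All satisfy `Σ g h³ = 1` to 1e-12.

## Time integration and the hybrid tail

The semi-discrete system is linear with a constant matrix, so the package
advances it with a Krylov matrix-exponential stepper
(`scipy.sparse.linalg.expm_multiply`) between samples of an adaptive
geometric time grid: `t = 0`, then log-spaced points from
`1e-4 / max-rate` to the end time.  Each step is accurate to near machine
precision, so trajectory error is dominated by the sampling of the
quadratures, not the ODE solve.  The sample density (default 320 points per
decade) was set from the analytic trapezoid-error estimate on a log grid,
`relative error ≈ (ln10 / ppd)² / 12 ≈ 9e-6`, so that the survival identity
`S = 1 − ∫f` holds to 1e-5 and cross-route statistics agree to 1e-4; the
measured corridor worst case matches the estimate.

For long times the density is replaced by a truncated eigenvector
expansion of `D Δ_h`, retaining all modes with `|μ| <` a cutoff (default
1 s⁻¹, a configurable maximum of 200 modes, shift-invert Lanczos on large
grids, dense `eigh` below 600 voxels), orthonormal under the h³-weighted
inner product.  The switch time is the first sample in a scan window
(default 1–10 s) where integrator and tail agree to 1e-5 absolute and 1%
relative; if the retained tail is empty or agreement never occurs the
trajectory stays integrator-only with a logged warning.  Note the stepping
cost is proportional to elapsed physical time times the fastest rate
(`~12D/h²`), so on large cells the tail is not an optimization but the only
practical route to the 10 s horizon; desk-scale runs shrink the window
instead.

## Flux convention

The absorbed flux is `f_h = D·h·Σ n_i p_i`.  With `p` a density in µm⁻³
this is the unique prefactor for which `f_h = −dS_h/dt` exactly, and it is
validated by the conservation test `∫f dt = 1` on connected geometries.
(A per-voxel-mass convention would instead carry `D/h²`; the package uses
densities everywhere.)

## Conditional statistics: two routes

*Time-domain*: cumulative trapezoid of `t^k e^{−λt} f_h` on the sample
grid, plus closed-form integrals of the eigen tail beyond the switch time.
Medians come from bisection (Brent) on the conditional CDF with a bracket
grown from the conditional mean, relative tolerance 1e-8.  This route
underflows for λ well above 1e3 s⁻¹ (the integrand concentrates below the
first sample times), so:

*Resolvent*: `z = (λI − DΔ_h)⁻¹ (D/h²) n` gives the per-voxel splitting
probabilities (`Z = Σ g z h³`), and two further solves give the conditional
mean and second moment.  Solvers are chosen by regime: sparse LU below
60k unknowns, Jacobi-preconditioned CG above, and — crucially — for λ above
the fastest hop rate a Jacobi-series summation for the M-matrix, whose
terms are all nonnegative.  The series preserves *componentwise* relative
accuracy for far-field entries that are tens of orders of magnitude below
the solution norm (e.g. `Z ~ 1e-86` at λ = 1e9), which normwise Krylov
residual tests silently truncate to zero.  At λ = 0 the system is solved on
the nucleus-connected component only; sources with unreachable support are
directed to the time-domain route.

The two routes agree to 1e-4 relative on the test fixtures for
λ ∈ [0.1, 10³] and serve as each other's oracle.

## Graph distances and asymptotic machinery

Distances to the nucleus are multi-source BFS on the cytosol graph
(nucleus-adjacent voxels at distance 1), cross-checked against unit-weight
Dijkstra.  The Laplacian power sums `Σ_i (Δ_h)^k g` are computed by
repeated sparse application of `Δ_h`, with the final summation using the
exact column-sum identity `Σ_i (Δ_h v)_i = −h⁻² Σ_j n_j v_j` (the discrete
divergence theorem for the absorbing stencil).  This makes the sub-geodesic
sums *structural* floating-point zeros — the support of `(Δ_h)^{k−1} g` has
not reached a nucleus-adjacent voxel — instead of `O(ε·12^k)` cancellation
noise, which for geodesic distances beyond ~5 would swamp the 1e-10
relative test.  A direct compensated-summation route is kept as a
cross-check.  The asymptotic splitting probability
`−h³ D^{d_g} λ^{−d_g} Σ (Δ_h)^{d_g} g` is derived for `d_g > 1` but agrees
with the exact single-voxel closed form at `d_g = 1`, so it is applied for
all `d_g ≥ 1`.  Scaling exponents are least-squares slopes in log-log.

## Continuum sphere oracle

For an absorbing sphere of radius `a` inside a reflecting sphere of radius
`R`, the MFPT closed form is integrated by hand; the splitting probability
solves `D(z'' + 2z'/r) = λz`, `z(a)=1`, `z'(R)=0` via `v = rz`, written in
overflow-safe exponentials valid to arbitrary λ and verified against an
independent `solve_bvp` collocation to 1e-6.  The conditional mean is
`−d lnZ/dλ` by Richardson-extrapolated central differences (step `1e-4·λ`,
one halving) — deliberately numerical so the oracle is independent of
algebra slips.  Its large-λ decay is `λ^{−1/2}`; the lattice decay is
`λ^{−1}`, and on the same geometry (a=1, R=2, h=0.05) the two conditional
means agree within 5% up to λ ≈ 10², after which the lattice law takes
over — the package's quantitative statement of where the semi-discrete
model stops describing continuum diffusion.

## Synthetic cells

`random_cell` emulates the structure of segmented SXT reconstructions at
desk scale: an ellipsoidal cell (default semi-axes 1.5×1.3×1.2 µm — a
shrunken lymphocyte that voxelizes to ~64³ at the default h = 0.05 µm, kept
deliberately below imaging scale so full analyses run in seconds), an
offset ellipsoidal nucleus, and random ellipsoidal organelle blobs
(semi-axes 0.08–0.3 µm) placed by rejection sampling until they occlude 30%
of the cytosolic candidate volume (±20% relative; the ER dominates real
occlusion budgets).  A blob is rejected if it would overlap the nucleus or
strand any cytosol voxel from the nucleus, so generated cytosols are always
fully connected — a property the real cells have implicitly.  All
randomness flows through one seeded `numpy` generator; identical parameters
give bit-identical volumes.

What the generator does *not* emulate: organelle shape statistics (real ER
is a connected reticulum, not convex blobs), membrane curvature
distributions, LAC intensities, or imaging noise.  Tests passing on these
cells therefore validate the *mathematics* (operators, statistics, limits)
on SXT-like voxel structure; they are not evidence about real organelle
morphology.  Notably, on such small cells with scattered convex blobs the
per-voxel barrier slowdown is weaker than in real B cells: removing
organelles lowers the MFPT for >90% of membrane start points but can raise
it for start points near the nucleus (opening barrier volume adds space to
get lost in — domain monotonicity is not a theorem for reflecting
obstacles), whereas imaged B cells show ratios ≥ 2 almost everywhere.

## Known numerical limitations

* **Lattice absorption bias.**  The discrete absorbing surface sits
  effectively ~0.3h inside the voxelized nuclear surface (in 1D, exactly at
  the nucleus-voxel centre), so voxel MFPTs exceed the continuum value by
  an O(h) margin — measured 9.1% → 4.6% → 2.2% mean shell error at
  h = 0.1 / 0.05 / 0.025 on the a=1, R=2 sphere (clean first order).  At
  h = (R−a)/20 the bias floor is ~3–5% for any radius ratio; halve h to
  halve it.
* **Trapezoid quadrature** limits time-domain statistics to ~1e-5 relative;
  the resolvent route is exact to solver tolerance and preferred whenever a
  sampled density is not otherwise needed.
* **Large-λ conditional statistics are lattice properties** (`λ^{−1}`
  regime); interpret them as such rather than as continuum predictions.
* The eigen tail needs modes below the cutoff to exist; small desk-scale
  geometries decay faster than 1 s⁻¹ and run integrator-only (by design,
  with a warning).
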