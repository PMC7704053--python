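# fptcell

First-passage times of signaling molecules from the cell membrane to the
nucleus, in voxelized single-cell geometries with organelle barriers and
first-order signal inactivation.

## The problem

Many signaling proteins (NICD in Notch signaling is the textbook case) are
activated at the inner cell membrane and then simply diffuse through the
cytosol until they first touch the nuclear membrane.  The cytosol is not
empty: the ER, mitochondria, Golgi and other organelles act as reflecting
barriers that force detours, and the molecule may be inactivated
(dephosphorylated, degraded) before it ever arrives.  `fptcell` is for
quantitative cell biologists and modelers who have a segmented 3D label
field of a single cell — e.g. from soft X-ray tomography, one integer class
per cubic voxel — and want the arrival-time statistics this geometry
implies, and for methodologists studying how inactivation reshapes them.

## The model

On the cytosol voxels `C_h` (edge `h`, µm) the probability density
`p_h(x_i, t)` of a diffusing molecule obeys the semi-discrete diffusion
equation

    dp_h/dt = D Δ_h p_h,
    (Δ_h p)(x_i) = h⁻² [ Σ_{j∈N(V_i;C_h)} (p_j − p_i) − n_i p_i ],

where the first sum runs over the face neighbors within the cytosol
(organelles, the cell membrane and the exterior reflect by carrying no
coupling) and `n_i = |N(V_i; N_h)|` counts faces shared with nucleus voxels,
through which the molecule is absorbed.  The first-passage-time density and
survival probability are

    f_h(t) = D h Σ_i n_i p_h(x_i, t) = −dS_h/dt,      S_h(t) = Σ_i p_h h³.

With first-order inactivation at rate λ (s⁻¹) the killed density is exactly
`e^{−λt} p_h`, so every conditional statistic is a Laplace-type integral of
`f_h`: the splitting probability `Z_λ = ∫ e^{−λt} f_h dt`, the conditional
MFPT `⟨T_λ⟩ = −d ln Z_λ/dλ`, the conditional CDF, variance and median.  The
package computes these by two independent routes — time-domain quadrature of
the solved trajectory (with an eigenvector-expansion tail at large times)
and resolvent solves `(λI − DΔ_h) z = (D/h²) n` — and implements the
strong-inactivation asymptotics governed by the 6-neighbor graph geodesic
distance `d_g` from the release set to the nucleus:

    Z_λ ∼ −h³ D^{d_g} λ^{−d_g} Σ_i (Δ_h)^{d_g} g (x_i),
    ⟨T_λ⟩ ∼ d_g / λ,          ⟨T_λ⟩_phys / ⟨T_λ⟩_no-org → d_g,phys / d_g,no-org,

resting on the cancellation `Σ_i (Δ_h)^k g = 0` for all `k < d_g`.  A
continuum concentric-spheres module provides closed-form oracles (MFPT,
splitting probability, conditional MFPT with its `λ^{−1/2}` tail, against
the lattice `λ^{−1}` tail).

## Worked example

```python
import fptcell as fc

grid = fc.concentric_spheres_grid(r_nuc=1.0, r_cell=2.0, h=0.1)
masks = fc.build_masks(grid, "physiological")
op = fc.assemble_operator(masks, D=10.0)          # D in um^2/s
release = fc.uniform_shell_init(masks)            # activation at the membrane

field = fc.mfpt_field(op)                         # per-voxel MFPT, seconds
shell_mfpt = float(release.values @ field.u) * op.h**3
print(f"membrane-averaged MFPT: {shell_mfpt:.4f} s "
      f"(closed form at r0=R: {fc.sphere_mfpt(fc.SphereModel(1.0, 2.0, 2.0, 10.0)):.4f} s)")
for lam in (1e2, 1e4, 1e6):
    st = fc.resolvent_stats(op, release, lam)
    print(f"lambda={lam:8.0f} /s   Z={st['Z']:.3e}   <T|arrival>={st['mean']:.3e} s")
d_g = fc.graph_distance(masks, masks.shell).d_g
print(f"graph distance shell->nucleus: {d_g} hops; lambda*<T> at lambda=1e8: "
      f"{1e8 * fc.resolvent_stats(op, release, 1e8)['mean']:.3f}")
```

prints:

```
membrane-averaged MFPT: 0.0908 s (closed form at r0=R: 0.0833 s)
lambda=     100 /s   Z=4.481e-02   <T|arrival>=1.696e-02 s
lambda=   10000 /s   Z=4.048e-12   <T|arrival>=9.034e-04 s
lambda= 1000000 /s   Z=8.247e-31   <T|arrival>=9.095e-06 s
graph distance shell->nucleus: 9 hops; lambda*<T> at lambda=1e8: 9.001
```

Reading: without inactivation a membrane-released molecule needs ~0.09 s on
average to find the nucleus (the 9% excess over the continuum value is the
O(h) lattice absorption bias at this coarse h).  Raising λ filters out the
long searches — the conditional arrival time falls as the arrival
probability collapses — and in the strong-inactivation limit λ·⟨T⟩
approaches the graph distance (9 hops), the geodesic-filtering effect that
makes arrival times robust to organelle barriers.

A CLI wraps the same layers:

```sh
fptcell make-geometry --kind random --h 0.05 --seed 0 --out cell.nrrd
fptcell mfpt --geometry cell.nrrd --out mfpt.csv
fptcell stats --geometry cell.nrrd --lambdas 0.1,10,1000,1e5 --out stats.csv
fptcell run --config cfg.json --out results/
```

## Layout

| module | contents |
|---|---|
| `fptcell.geometry` | label volumes, masks, membrane shell, release densities |
| `fptcell.synthetic_geometry` | sphere / corridor / random-cell generators |
| `fptcell.operator` | discrete Laplacian, trajectories, eigen tail, FPT density |
| `fptcell.fpt_stats` | MFPT fields, conditional statistics (two routes) |
| `fptcell.asymptotics` | BFS distances, power sums, large-λ limits, exponent fits |
| `fptcell.analytic_reference` | concentric-spheres continuum closed forms |
| `fptcell.pipeline` / `fptcell.cli` | configuration-driven runs, `fptcell` CLI |

See `docs/methods.md` for the numerical choices and known limitations.
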