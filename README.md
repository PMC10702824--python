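# eisosim

Lattice Monte Carlo simulation of BAR-domain-driven plasma-membrane furrow
formation — and of its suppression by tetraspanner proteins that stabilize
the furrow-edge angle — together with the fluorescence-microscopy
quantifications used to characterize these membrane domains (network
factor, masked Pearson colocalization, sub-pixel radial peak distances,
strand-gap widths, PM/cytosol ratios) and a ground-truthed synthetic image
generator that makes every quantification testable without external data.

## Who this is for

MCC/eisosomes are stable furrows in the yeast plasma membrane, shaped by a
coat of BAR-domain proteins (Pil1/Lsp1) at the base and bounded by strands
of Sur7-family tetraspanners at their upper edges. This package is for
researchers studying how the balance of negative curvature (BAR coat) and
positive edge curvature (tetraspanners) decides between a stable furrow and
runaway invagination into a membrane tube, and for anyone who needs the
accompanying image metrics on their own two-channel micrographs.

## The model

A membrane patch is a lattice of `Lx x Ly = 25 x 49` nodes with positions
`(x, y = j, z <= 0)`; the outer two rings are height-pinned (`z = 0`).
The energy (in kBT) is

    E = sum_bonds k_harm(r) (r^2 - 1)^2                       springs
      + sum_j [ k_drag x(0, j) - k_drag x(Lx-1, j) ]          membrane drag
      + sum_nodes k_elast (phi_x^2 + phi_y^2)                 bending
      | BAR nodes: k_curv (phi_x - phi_0)^2 + k_elast phi_y^2

with `k_harm = 100 000 / 20 000` (compression/stretch), `k_drag = 800`,
`k_elast = 80 000`, `k_curv = 1 200 000` and a preferred BAR bending angle
`phi_0 = -28 deg` per node. `phi_x`, `phi_y` are the discrete turning
angles along the two lattice directions (positive = bending toward the cell
interior). `N` consecutive BAR columns x 29 rows emulate the eisosome
scaffold. Dynamics are single-node Metropolis moves (`dx, dz` uniform in
`+/- 0.001`, temperature 1) under hard constraints: bond lengths in
`(0.5, 2]`, a left/right boundary-angle symmetry filter (< 10 deg), and an
optional tetraspanner latch that irreversibly fixes a furrow-edge angle at
`60 +/- 5 deg` once it exceeds 60 deg.

Small `N` yields furrows whose edges meet the surface at shallow angles;
`N = 7` wraps the BAR-covered membrane by ~196 deg ("basically a half
circle"); large `N` drives a re-entrant omega neck that resolves into a
deep half-toroidal tube — unless the latch engages first and stabilizes the
furrow. See `docs/methods.md` for the full model account, conventions and
limitations.

## Worked example

```python
import numpy as np
from eisosim import build_config, run_simulation
from eisosim.observables import classify_shape, mean_boundary_angle

cfg = build_config(N=7, seed=1, sweep_budget=60_000)
traj = run_simulation(cfg)
state = traj.final_state
report = classify_shape(state, cfg)
print(f"mean outward boundary angle: {mean_boundary_angle(state, cfg):.1f} deg")
print(f"turning across BAR columns:  {report.turning_sum:.0f} deg")
print(f"invagination depth:          {report.depth:.2f} lattice units")
print(f"shape class:                 {report.shape}")
```

prints

```
mean outward boundary angle: 16.7 deg
turning across BAR columns:  -188 deg
invagination depth:          6.76 lattice units
shape class:                 half_circle
```

i.e. seven BAR domains bend the covered membrane by ~190 deg — close to the
prescribed `7 x (-28) = -196 deg` half circle — while the furrow edges meet
the flat membrane at ~17 deg (still relaxing toward its equilibrium near
13 deg at this sweep budget). The quantification side works the same way on
synthetic ground truth:

```python
from eisosim.synthetic import make_medial_cell
from eisosim.quant import radial_peak_distance

fa, fb, gt = make_medial_cell(delta_r_nm=50.0, seed=1)
pairs, n_rej = radial_peak_distance(fa, fb, gt.puncta_rc[:12], gt.center_px)
seps = [p.separation_nm for p in pairs]
print(f"recovered {np.mean(seps):.1f} +/- {np.std(seps):.1f} nm")
```

```
recovered 49.6 +/- 6.6 nm
```

— a 50 nm radial offset between two markers, imaged at widefield
resolution (PSF sigma 110 nm, 65 nm pixels), is recovered well within the
25 nm resolution bracket of the peak-fitting method.

Command-line wrappers cover the common workflows:

```sh
eisosim run -N 7 --latch --seed 17 --out run1/     # simulate
eisosim analyze run1/ --report report.json --ply final.ply
eisoquant simulate medial --seed 3 --out scene/    # synthetic microscopy
eisoquant coloc a.tif b.tif --pixel-size-nm 65
```

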