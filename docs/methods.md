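# Methods

## The membrane model

The plasma membrane patch is a rectangular lattice of `Lx x Ly` nodes
(default 25 x 49). Node `(i, j)` has an in-plane position `x(i,j)`
(equilibrium `x = i`), a fixed transverse coordinate `y = j`, and a height
`z(i,j) <= 0`: the cell wall caps the membrane at `z = 0`, so the patch can
only deform into the cell. The two outer rings of nodes
(`i in {0, 1, Lx-2, Lx-1}` and `j in {0, 1, Ly-2, Ly-1}`) have their height
pinned at 0, which embeds the patch into an implied larger flat membrane.
All energies are expressed in units of kBT and the Metropolis temperature is
fixed at 1.

Four energy terms act on the lattice:

* **Springs.** Nearest neighbors interact through
  `V_harm(r) = k_harm(r) (r^2 - 1)^2` with a stiffer compression branch
  (`k = 100 000` for `0.5 < r <= 1`, `k = 20 000` for `1 < r <= 2`).
  Bond lengths outside `(0.5, 2]` are forbidden outright.  The printed form
  of the potential is typographically ambiguous; the quadratic alternative
  `k (r - 1)^2` is available through `spring_form="quadratic"` but the
  quartic form (minimum at `r = 1`, harmonic curvature `4k` there) is the
  default and is used everywhere in the tests.
* **Drag.** The surrounding membrane pulls the two edge columns outward:
  `V_drag = +k_drag x(0, j)` and `-k_drag x(Lx-1, j)` with `k_drag = 800`,
  summed over all rows (corners included).  Only differences of this linear
  potential matter to the dynamics.
* **Bending.** Each interior node carries a discrete curvature energy
  `k_elast (phi_x^2 + phi_y^2)` with `k_elast = 80 000`, where `phi_x` is
  the signed turning angle of the chain `(i-1, j), (i, j), (i+1, j)`
  measured in the x-z plane and `phi_y` the (unsigned) analog along `j`.
  Angles are radians internally; every configured or reported angle is in
  degrees.
* **BAR domains.** On a central patch of `N` columns x 29 rows (both
  centered; `N` odd) the `phi_x` term is replaced by
  `k_curv (phi_x - phi_curv)^2` with `k_curv = 1 200 000` and
  `phi_curv = -28 deg`.  The anisotropy (only `phi_x` is biased) encodes the
  parallel orientation of the BAR scaffold.

**Sign convention.** `phi_x` is positive when the chain bends toward
`z < 0` (toward the cell interior) and negative when it bends back toward
the surface. Under this convention the base of a furrow — the membrane
wrapped around the BAR coat — carries negative angles, matching the
negative preferred angle of the BAR term, while the furrow's upper edges
carry positive angles. The boundary angle of a configuration is `phi_x`
evaluated at the first columns outside the BAR patch (`imin - 1` and
`imax + 1`); mirror-symmetric shapes give equal left and right values
because mirroring reverses both the traversal order and the x-axis.

## Monte Carlo scheme

One sweep is `Lx * Ly` attempted moves. A move picks a node uniformly at
random and displaces its `x` and `z` by independent uniform amounts in
`[-0.001, +0.001]`; for nodes on the z-pinned boundary rings only the `x`
component is applied (otherwise those nodes could never move and the drag
term would be inert). Moves are screened by hard constraints before the
Metropolis test:

* `z <= 0` everywhere and `z = 0` on the frozen rings;
* every incident bond stays inside `(0.5, 2]`;
* the symmetry filter `|phi_L(j) - phi_R(j)| < 10 deg` on every BAR row,
  which prevents the relaxation from wandering into high-energy asymmetric
  local minima (checked event-driven, only for moves that touch a
  boundary-angle stencil);
* when the tetraspanner latch is enabled and a (side, row) has latched, its
  boundary angle must stay inside `[55, 65] deg`.

Accepted moves use the standard criterion (accept if `dE <= 0`, else with
probability `exp(-dE)`). The move energy is evaluated incrementally — only
the four incident bonds, the three `phi_x` and three `phi_y` stencils, and
the drag term of the moved node are recomputed — in a compiled (numba)
kernel; the full-lattice recomputation exists independently and serves as
the test oracle (agreement to 1e-9 relative on random moves, with the
oracle evaluated in extended precision because full-lattice totals reach
~5e7 kBT while move deltas can be orders of magnitude smaller).

**Tetraspanner latch.** When enabled, any BAR row whose outward boundary
angle exceeds 60 deg on either side becomes latched there, irreversibly
within the run, and subsequent moves must keep that angle within
60 +/- 5 deg. The window is centered on the threshold, not on the angle at
latch time ("fixed with a maximum deviation of 5 deg" reads as a window
around the fixed value). Because the post-transient relaxation pulls the
boundary angle down, latched rows settle against the window floor and
time-average near 55 deg.

**Stopping.** The run ends at `sweep_budget` (default 2e5) sweeps, or
earlier when the windowed mean boundary angle (both sides, central 15 BAR
rows) changes by less than 0.1% between consecutive 2000-sweep windows on
five consecutive checks (single coincidences during slow relaxation would
otherwise stop the run prematurely). The check starts after 20 000 sweeps
so the non-monotonic growth transient cannot trigger it. `N = 0` runs have
no boundary angle and always use the full budget. Identical
(config, seed) pairs give bitwise-identical trajectories: all randomness
comes from one `numpy` PCG64 generator seeded from the config.

## Equilibrium phenomenology

With the default parameters the model reproduces the regime structure that
motivates it (values from seeded runs; see `tests/test_acceptance.py` and
`scripts/acceptance.py`):

* `N = 0`: flat membrane; bond lengths fluctuate around 1 with RMS ~3e-3
  and heights with RMS ~5e-3 (the 0.01 fluctuation scale);
* `N = 5`: a deep invagination whose flanks approach the surface gradually;
  equilibrium boundary angles ~9 deg (< 20 deg); turning sum across the BAR
  columns ~ -137 deg ~ `N * phi_curv`;
* `N = 7`: boundary angles peak near 53 deg during a non-monotonic growth
  transient before relaxing to ~13 deg; the BAR-covered area turns by
  ~ -190 deg, essentially a half circle (-196 deg is the prescribed value,
  approached within 5% — exactly, in the stiffness-quenched limit);
* `N = 7`, latch on: the transient pushes individual rows past 60 deg, the
  latch fires, and latched rows hold 60 +/- 5 deg while the rest of the
  membrane relaxes — the stable-furrow mechanism;
* `N = 11`: a re-entrant omega neck forms near the surface (central-row
  boundary angles peak at ~70 deg around sweep 1e4) and then resolves:
  the edge columns slide inward and the invagination deepens into a
  half-toroidal tube (depth ~8 lattice units, neck narrower than the
  belly below it, turning sum ~ -290 deg).  The omega is a transient of
  the relaxation, not a local energy minimum: the final state still
  classifies as omega by its re-entrant neck, but its boundary angles
  (~27-30 deg at plateau) are far below the ~90 deg the near-surface omega
  would carry.  This is the model's account of tube formation; a
  turgor-pressure term pressing the flanks onto the wall, which the model
  deliberately omits, would be required to hold the omega at the surface.

## Shape classification

`classify_shape` works on the central-row cross-section:

* *omega* if the maximum outward boundary angle exceeds 90 deg **or** the
  cross-section has a neck — scanning 50 evenly spaced depths, some shallow
  width (horizontal distance between the outermost polyline crossings) is
  less than 95% of a deeper width;
* *half_circle* if the turning sum over the BAR columns is within 20 deg of
  -180 deg and there is no neck (the +/-20 deg tolerance separates `N = 7`
  from `N = 5` and `N = 9`; it is a heuristic, not a measured quantity);
* *furrow* if the invagination depth exceeds 5x the thermal height RMS
  (default 0.01 lattice units);
* *flat* otherwise.

Reported boundary angles average the central 15 BAR rows; the tip rows show
end effects and are excluded from scalar summaries (the per-row vector is
always available).

## Image quantification

All distances are converted to nm through the pixel size carried by each
image; pixel centers sit at integer (row, col) coordinates.

* **Preprocessing**: rolling-ball background subtraction (default radius
  12.5 px, i.e. a 25 px diameter ball) followed by Richardson-Lucy
  deconvolution (20 iterations, Gaussian PSF).
* **Network factor**: the fraction of cell-mask pixels above Otsu's
  threshold computed within the mask. The score is invariant to positive
  affine rescaling and separates punctate (<= 0.15) from dispersed (> 0.15)
  patterns. The exact formula used in earlier work on this metric is not
  public; this definition is a stand-in that preserves the documented
  semantics and decision boundary, and should not be read as a
  reimplementation of the original. A near-uniform image has no signal/
  background split and returns the fully dispersed limit 1.0.
* **Colocalization**: Otsu mask per channel, AND-combined; Pearson
  correlation over the intersection; fewer than 10 overlapping pixels is
  reported as undefined rather than returning a meaningless coefficient.
* **Periphery linearization**: bilinear resampling of an annulus along arc
  length (strip length `round(2 pi r)` px); used for visualization, and
  round-trips annulus intensities within 2% RMS on smooth images.
* **Radial peak distance**: per anchor, a line profile is sampled radially
  (perpendicular to the periphery) in both registered channels and a single
  Gaussian plus constant offset is fitted per channel (least squares,
  sub-pixel center, uncertainty from the covariance). Profiles with
  R^2 < 0.8 in either channel are dropped and counted. The 25 nm figure is
  treated as the acceptance resolution of the method, not as a fit
  parameter. A rigid-shift estimator (phase cross-correlation) is provided
  for upstream channel registration.
* **PM/cytosol ratio**: mean over the annulus between two concentric
  circles, minus background, over the mean of the eroded inner disk, minus
  background; adding a constant to the whole image cancels.
* **Strand gap**: perpendicular profiles averaged along the strand axis,
  then a two-Gaussian model with shared width and common offset is fitted
  with multiple starting separations (the merged profile of two strands
  60 nm apart at STED resolution is barely bimodal, so a single start is
  unreliable); collapsed fits (centers < 1 px apart or one amplitude < 20%
  of the other) signal "no gap".

## Synthetic microscopy

The generator provides ground-truthed inputs for every quantification:

* *medial cells*: two channels of puncta on concentric rings separated by a
  known radial offset (default 50 nm), widefield-like PSF sigma 110 nm,
  65 nm pixels;
* *top-view patterns*: clustered 200-400 nm strand-like objects vs a
  homogeneous field with mild smooth texture, total intensity matched
  across classes (a `clustering_parameter` in [0, 1] mixes the recipes);
* *double strands*: two parallel lines with a known center-to-center gap
  (default 60 nm over a 300 nm length), STED-like PSF sigma 30 nm, 25 nm
  pixels.

Expected images are sums of analytic Gaussians evaluated at pixel centers
(lines are dense point chains at 0.2 px spacing); noise is Poisson on the
expected photon count plus additive Gaussian read noise (sd 2) over a
constant background (5 photons). Identical seeds reproduce images bitwise.
The generator does **not** model vectorial or depletion PSFs, axial
structure, autofluorescence, or segmentation difficulty: quantification
tests passing on these images demonstrate correct measurement geometry and
robustness at realistic SNR, not performance on raw micrographs.

## Problem sizes and tolerances

The test suite and the acceptance script run the full 25 x 49 lattice with
up to 2e5 sweeps per condition (about 1.5-2 minutes per run with the
compiled kernel) and 5 seeds x 5e4 sweeps for the BAR-free baseline; the
quantification checks use 6-8 seeds per recovery target and 100 seeded
pattern pairs for the network-factor separation. Incremental-vs-full energy
agreement is asserted at 1e-9 relative (with a 1e-9 kBT absolute floor) on
1000 random feasible moves.

## Known limitations

* The near-surface omega with > 90 deg boundary angles is transient under
  this Hamiltonian (see above); holding it would need a wall-adhesion or
  pressure term that the published parameterization does not include.
* `N` is prescribed, not recruited: the positive feedback of BAR-domain
  attraction to curved edges is discussed, not simulated.
* Single-node Metropolis dynamics gives a physical-looking but not
  literally hydrodynamic relaxation path; "time" is sweep count.
* The latch windows constrain angles only through move rejection; a row
  latched during a fast transient can therefore sit against the window
  edge rather than at its center.
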