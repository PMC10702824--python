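"""Metropolis Monte Carlo dynamics for the lattice membrane.

One *sweep* is ``Lx * Ly`` attempted single-node moves.  A move displaces the
x- and z-coordinates of one node by independent uniform amounts in
``[-step_size, +step_size]`` and is accepted with the standard Metropolis
criterion at temperature 1 (energies in kBT).  Hard constraints -- non-positive
height, the frozen boundary rings, the bond-length bounds, the left/right
boundary-angle symmetry filter, and the tetraspanner latch windows -- are
enforced by move rejection, never by penalty terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _kernel
from .model import (
    InfeasibleMoveError,
    LatticeState,
    SimulationConfig,
    bar_region,
    delta_energy,
    init_lattice,
    total_energy,
)

__all__ = [
    "Move",
    "Trajectory",
    "propose_move",
    "is_feasible",
    "metropolis_accept",
    "metropolis_step",
    "update_latch",
    "run_simulation",
]

# sweeps over which the windowed plateau criterion is evaluated; the
# criterion must hold on several consecutive checks so that a single noise
# coincidence during slow relaxation cannot stop the run
PLATEAU_WINDOW_SWEEPS = 2000
PLATEAU_REL_TOL = 1e-3
PLATEAU_MIN_SWEEPS = 20_000
PLATEAU_CONSECUTIVE = 5


class Move(NamedTuple):
    """Single-node displacement proposal."""

    i: int
    j: int
    dx: float
    dz: float


def propose_move(rng: np.random.Generator, state: LatticeState, config: SimulationConfig) -> Move:
    """Uniform random node with uniform displacements in [-step, +step].

    For nodes on the z-frozen boundary rings the z-component of the proposal
    is zeroed (only x moves there); a frozen node with dz != 0 would otherwise
    never move at all and the edge-column drag term would be inert.
    """
    Lx, Ly = state.shape
    idx = int(rng.integers(0, Lx * Ly))
    i, j = idx // Ly, idx % Ly
    s = config.step_size
    dx = float(rng.uniform(-s, s))
    dz = float(rng.uniform(-s, s))
    if state.frozen_z[i, j]:
        dz = 0.0
    return Move(i, j, dx, dz)


def _outward_angles(state: LatticeState, config: SimulationConfig, j: int) -> tuple[float, float]:
    cols, _ = bar_region(config)
    imin, imax = int(cols[0]), int(cols[-1])
    left, right = _kernel.boundary_angles_nb(state.x, state.z, imin, imax, j, j)
    return float(left[0]), float(right[0])


def is_feasible(state: LatticeState, move: Move, config: SimulationConfig) -> tuple[bool, str]:
    """Check every hard constraint for a move; returns (feasible, reason)."""
    try:
        delta_energy(state, move, config)
    except InfeasibleMoveError as exc:
        return False, exc.reason
    if config.N == 0:
        return True, "ok"
    cols, rows = bar_region(config)
    imin, imax = int(cols[0]), int(cols[-1])
    jmin, jmax = int(rows[0]), int(rows[-1])
    i, j = move.i, move.j
    if not (jmin <= j <= jmax):
        return True, "ok"
    if not (imin - 2 <= i <= imin or imax <= i <= imax + 2):
        return True, "ok"
    trial = state.copy()
    trial.x[i, j] += move.dx
    trial.z[i, j] += move.dz
    phi_l, phi_r = _outward_angles(trial, config, j)
    if abs(phi_l - phi_r) >= math.radians(config.symmetry_limit):
        return False, "symmetry"
    if config.latch_enabled:
        lo = math.radians(config.latch_threshold - config.latch_halfwidth)
        hi = math.radians(config.latch_threshold + config.latch_halfwidth)
        if state.latched_left[j] and not (lo <= phi_l <= hi):
            return False, "latch"
        if state.latched_right[j] and not (lo <= phi_r <= hi):
            return False, "latch"
    return True, "ok"


def metropolis_accept(delta_e: float, rng: np.random.Generator, temperature: float = 1.0) -> bool:
    """Standard Metropolis rule: accept iff dE <= 0 or u < exp(-dE/T)."""
    if delta_e <= 0.0:
        return True
    return float(rng.random()) < math.exp(-delta_e / temperature)


def metropolis_step(state: LatticeState, move: Move, rng: np.random.Generator,
                    config: SimulationConfig) -> bool:
    """Apply one feasible move with the Metropolis criterion.

    The caller guarantees feasibility (``is_feasible``); an infeasible move
    raises.  On acceptance the state is mutated in place and the latch
    registry refreshed.
    """
    feasible, reason = is_feasible(state, move, config)
    if not feasible:
        raise InfeasibleMoveError(reason)
    de = delta_energy(state, move, config)
    if not metropolis_accept(de, rng, config.temperature):
        return False
    state.x[move.i, move.j] += move.dx
    state.z[move.i, move.j] += move.dz
    if config.latch_enabled and config.N != 0:
        update_latch(state, config)
    return True


def update_latch(state: LatticeState, config: SimulationConfig) -> list[tuple[str, int]]:
    """Latch any (side, BAR row) whose outward boundary angle exceeds the
    threshold; irreversible within a run.  No-op when the latch is disabled.
    """
    if not config.latch_enabled or config.N == 0:
        return []
    cols, rows = bar_region(config)
    imin, imax = int(cols[0]), int(cols[-1])
    jmin, jmax = int(rows[0]), int(rows[-1])
    left, right = _kernel.boundary_angles_nb(state.x, state.z, imin, imax, jmin, jmax)
    thr = math.radians(config.latch_threshold)
    events: list[tuple[str, int]] = []
    for k, j in enumerate(range(jmin, jmax + 1)):
        if left[k] > thr and not state.latched_left[j]:
            state.latched_left[j] = True
            events.append(("left", j))
        if right[k] > thr and not state.latched_right[j]:
            state.latched_right[j] = True
            events.append(("right", j))
    return events


@dataclass
class Trajectory:
    """Recorded time series and snapshots of one simulation run."""

    config: SimulationConfig
    sweeps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    energy_total: np.ndarray = field(default_factory=lambda: np.empty(0))
    energy_spring: np.ndarray = field(default_factory=lambda: np.empty(0))
    energy_drag: np.ndarray = field(default_factory=lambda: np.empty(0))
    energy_elastic_plain: np.ndarray = field(default_factory=lambda: np.empty(0))
    energy_elastic_bar: np.ndarray = field(default_factory=lambda: np.empty(0))
    acceptance: np.ndarray = field(default_factory=lambda: np.empty(0))
    # outward-positive boundary angles (degrees), one column per BAR row
    phi_left: np.ndarray | None = None
    phi_right: np.ndarray | None = None
    snapshots: list[tuple[int, LatticeState]] = field(default_factory=list)
    events: list[tuple[str, int, int]] = field(default_factory=list)
    final_state: LatticeState | None = None
    plateau_sweep: int | None = None

    def mean_boundary_angle(self, n_central: int = 15) -> np.ndarray:
        """Per-record mean outward angle over both sides and the central BAR
        rows (tip rows excluded to avoid end effects)."""
        if self.phi_left is None or self.phi_left.size == 0:
            raise ValueError("trajectory has no boundary-angle series")
        n_rows = self.phi_left.shape[1]
        n_c = min(n_central, n_rows)
        lo = (n_rows - n_c) // 2
        sel = slice(lo, lo + n_c)
        return 0.5 * (self.phi_left[:, sel].mean(axis=1) + self.phi_right[:, sel].mean(axis=1))


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run the Metropolis dynamics for up to ``sweep_budget`` sweeps.

    Records energies, acceptance rate, boundary angles and snapshots every
    ``record_every`` sweeps, and stops early once the windowed mean boundary
    angle has plateaued (relative change < 1e-3 over 2000 consecutive
    sweeps).  Identical (config, seed) gives a bitwise-identical trajectory.
    """
    state = init_lattice(config)
    rng = np.random.default_rng(config.seed)
    Lx, Ly = config.Lx, config.Ly
    per_sweep = Lx * Ly
    s = config.step_size

    if config.N != 0:
        cols, rows = bar_region(config)
        imin, imax = int(cols[0]), int(cols[-1])
        jmin, jmax = int(rows[0]), int(rows[-1])
    else:
        imin = imax = jmin = jmax = -1

    params = _kernel.energy_params(config)
    sym_lim = math.radians(config.symmetry_limit)
    latch_lo = math.radians(config.latch_threshold - config.latch_halfwidth)
    latch_hi = math.radians(config.latch_threshold + config.latch_halfwidth)
    latch_thr = math.radians(config.latch_threshold)

    traj = Trajectory(config=config)
    rec_sweeps: list[int] = []
    rec_energy: list = []
    rec_acc: list[float] = []
    rec_left: list[np.ndarray] = []
    rec_right: list[np.ndarray] = []
    mean_angle_series: list[float] = []

    win_records = max(1, int(round(PLATEAU_WINDOW_SWEEPS / config.record_every)))
    plateau_hits = 0

    sweep = 0
    while sweep < config.sweep_budget:
        chunk = min(config.record_every, config.sweep_budget - sweep)
        n_att = chunk * per_sweep
        nodes = rng.integers(0, per_sweep, size=n_att)
        dxs = rng.uniform(-s, s, size=n_att)
        dzs = rng.uniform(-s, s, size=n_att)
        with np.errstate(divide="ignore"):  # u == 0.0 -> log -inf -> accept
            log_us = np.log(rng.random(size=n_att))
        ev_side = np.empty(2 * Ly, dtype=np.int64)
        ev_row = np.empty(2 * Ly, dtype=np.int64)
        ev_sweep = np.empty(2 * Ly, dtype=np.int64)
        accepted, n_ev = _kernel.run_sweeps_nb(
            state.x, state.z, state.frozen_z, state.bar,
            state.latched_left, state.latched_right,
            nodes, dxs, dzs, log_us,
            imin, imax, jmin, jmax,
            *params,
            sym_lim, config.latch_enabled, latch_lo, latch_hi, latch_thr,
            1.0 / config.temperature, sweep,
            ev_side, ev_row, ev_sweep,
        )
        sweep += chunk
        for k in range(n_ev):
            side = "left" if ev_side[k] == _kernel.EVENT_LEFT else "right"
            traj.events.append((side, int(ev_row[k]), int(ev_sweep[k])))

        eb = total_energy(state, config)
        if not math.isfinite(eb.total):
            traj.final_state = state
            raise RuntimeError(f"non-finite energy at sweep {sweep}: {eb}")
        rec_sweeps.append(sweep)
        rec_energy.append(eb)
        rec_acc.append(accepted / n_att)
        if config.N != 0:
            left, right = _kernel.boundary_angles_nb(state.x, state.z, imin, imax, jmin, jmax)
            rec_left.append(np.degrees(left))
            rec_right.append(np.degrees(right))
        traj.snapshots.append((sweep, state.copy()))

        # plateau criterion on the windowed mean boundary angle
        if config.N != 0:
            n_rows = jmax - jmin + 1
            n_c = min(15, n_rows)
            lo = (n_rows - n_c) // 2
            mean_angle_series.append(
                0.5 * (rec_left[-1][lo:lo + n_c].mean() + rec_right[-1][lo:lo + n_c].mean())
            )
            if sweep >= PLATEAU_MIN_SWEEPS and len(mean_angle_series) >= 2 * win_records:
                m1 = float(np.mean(mean_angle_series[-win_records:]))
                m0 = float(np.mean(mean_angle_series[-2 * win_records:-win_records]))
                if abs(m1 - m0) < PLATEAU_REL_TOL * max(abs(m0), 1e-12):
                    plateau_hits += 1
                    if plateau_hits >= PLATEAU_CONSECUTIVE:
                        traj.plateau_sweep = sweep
                        break
                else:
                    plateau_hits = 0

    traj.sweeps = np.asarray(rec_sweeps, dtype=np.int64)
    traj.energy_total = np.asarray([e.total for e in rec_energy])
    traj.energy_spring = np.asarray([e.spring for e in rec_energy])
    traj.energy_drag = np.asarray([e.drag for e in rec_energy])
    traj.energy_elastic_plain = np.asarray([e.elastic_plain for e in rec_energy])
    traj.energy_elastic_bar = np.asarray([e.elastic_bar for e in rec_energy])
    traj.acceptance = np.asarray(rec_acc)
    if config.N != 0:
        traj.phi_left = np.vstack(rec_left)
        traj.phi_right = np.vstack(rec_right)
    traj.final_state = state
    return traj
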