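"""Coarse-grained lattice membrane model: geometry and energies.

The membrane patch is a rectangular lattice of ``Lx x Ly`` nodes.  Node
``(i, j)`` carries a variable in-plane position ``x`` (equilibrium ``x = i``),
a fixed transverse position ``y = j`` and a variable non-positive height
``z <= 0`` (the cell wall caps the membrane at ``z = 0``).  The two outer
rings of nodes have their height frozen at 0, emulating the embedding of the
patch into a larger flat membrane.

Energies (all in units of kBT):

* **springs** between nearest neighbors, piecewise-stiff around the unit
  equilibrium spacing, ``V = k_harm(r) * (r^2 - 1)^2``;
* **drag** of the surrounding membrane acting on the two edge columns,
  ``V = +k_drag * x(0, j)`` and ``-k_drag * x(Lx-1, j)``;
* **bending** in the Cahn--Hilliard spirit, penalizing the squared turning
  angles ``phi_x`` / ``phi_y`` formed by three consecutive nodes along each
  lattice direction;
* **BAR-domain bias** on a central patch of nodes, replacing the ``phi_x``
  term by ``k_curv * (phi_x - phi_curv)^2`` with a preferred (negative,
  i.e. invaginating) angle ``phi_curv``.

A BAR domain spans ``N`` consecutive columns (one banana-shaped protein seen
in cross-section); ``bar_rows`` of them are stacked along ``j`` to emulate
the elongated Seg1/Pil1 scaffold of an MCC/eisosome furrow.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from . import _kernel

__all__ = [
    "ConfigurationError",
    "InfeasibleMoveError",
    "DegenerateGeometryError",
    "InconsistentStateError",
    "SimulationConfig",
    "LatticeState",
    "EnergyBreakdown",
    "build_config",
    "bar_region",
    "init_lattice",
    "spring_potential",
    "drag_energy",
    "bend_angle_x",
    "bend_angle_y",
    "node_elastic_energy",
    "total_energy",
    "delta_energy",
]


class ConfigurationError(ValueError):
    """Invalid or inconsistent simulation configuration."""


class InfeasibleMoveError(Exception):
    """A proposed move violates a hard constraint (used as a signal)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class DegenerateGeometryError(ValueError):
    """Angle requested for coincident / zero-length segments."""


class InconsistentStateError(RuntimeError):
    """Lattice state violates an invariant (e.g. bond-length bounds)."""


# reason codes shared with the compiled kernel
_REASONS = {
    _kernel.OK: "ok",
    _kernel.INFEASIBLE_Z: "z_positive",
    _kernel.INFEASIBLE_FROZEN: "frozen",
    _kernel.INFEASIBLE_BOND: "bond_bounds",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All model constants, geometry, thresholds, seed and budgets.

    Angles are in degrees, energies/stiffnesses in kBT, lengths in lattice
    units (the equilibrium neighbor spacing is 1).
    """

    Lx: int = 25
    Ly: int = 49
    N: int = 7
    bar_rows: int = 29
    k_harm_compress: float = 100_000.0
    k_harm_stretch: float = 20_000.0
    k_drag: float = 800.0
    k_elast: float = 80_000.0
    k_curv: float = 1_200_000.0
    phi_curv: float = -28.0
    r_min: float = 0.5
    r_max: float = 2.0
    latch_threshold: float = 60.0
    latch_halfwidth: float = 5.0
    symmetry_limit: float = 10.0
    step_size: float = 0.001
    temperature: float = 1.0
    seed: int = 0
    sweep_budget: int = 200_000
    latch_enabled: bool = False
    record_every: int = 200
    spring_form: str = "quartic"  # "quartic": k (r^2-1)^2 ; "quadratic": k (r-1)^2

    def validate(self) -> None:
        c = self
        if c.Lx < 7 or c.Ly < 7:
            raise ConfigurationError("lattice must be at least 7x7")
        if c.Lx % 2 == 0 or c.Ly % 2 == 0:
            raise ConfigurationError("Lx and Ly must be odd (centered BAR patch)")
        if c.N != 0 and (c.N % 2 == 0 or c.N < 0):
            raise ConfigurationError("N must be odd (or 0 for no BAR domains)")
        if c.N > c.Lx - 4:
            raise ConfigurationError("N must satisfy N <= Lx - 4")
        if c.N != 0:
            if c.bar_rows % 2 == 0 or c.bar_rows < 1:
                raise ConfigurationError("bar_rows must be odd and positive")
            if c.bar_rows > c.Ly - 4:
                raise ConfigurationError("bar_rows must satisfy bar_rows <= Ly - 4")
        if not (c.r_min < 1.0 < c.r_max):
            raise ConfigurationError("must have r_min < 1 < r_max")
        if not (0 < c.latch_halfwidth < c.latch_threshold):
            raise ConfigurationError("need 0 < latch_halfwidth < latch_threshold")
        for name in ("k_harm_compress", "k_harm_stretch", "k_drag", "k_elast", "k_curv"):
            if getattr(c, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if c.step_size <= 0:
            raise ConfigurationError("step_size must be > 0")
        if c.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if c.symmetry_limit <= 0:
            raise ConfigurationError("symmetry_limit must be > 0")
        if c.sweep_budget < 1 or c.record_every < 1:
            raise ConfigurationError("sweep_budget and record_every must be >= 1")
        if c.spring_form not in ("quartic", "quadratic"):
            raise ConfigurationError("spring_form must be 'quartic' or 'quadratic'")


_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def build_config(overrides: Mapping[str, Any] | None = None, **kwargs: Any) -> SimulationConfig:
    """Construct a validated configuration from the defaults plus overrides."""
    merged: dict[str, Any] = {}
    for src in (overrides or {}), kwargs:
        for key, val in src.items():
            if key not in _FIELDS:
                raise ConfigurationError(f"unknown configuration key: {key!r}")
            merged[key] = val
    cfg = SimulationConfig(**merged)
    cfg.validate()
    if cfg.N != 0:
        bar_region(cfg)  # raises if the BAR patch touches the frozen rings
    return cfg


def bar_region(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Column and row index sets covered by BAR domains.

    ``N`` consecutive columns centered on the lattice midline ``(Lx-1)/2``
    and ``bar_rows`` consecutive rows centered on ``(Ly-1)/2``.
    """
    if config.N == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ci, cj = (config.Lx - 1) // 2, (config.Ly - 1) // 2
    hw_i, hw_j = (config.N - 1) // 2, (config.bar_rows - 1) // 2
    cols = np.arange(ci - hw_i, ci + hw_i + 1, dtype=np.int64)
    rows = np.arange(cj - hw_j, cj + hw_j + 1, dtype=np.int64)
    # boundary-angle stencils need two plain columns outside the patch and
    # the patch itself must stay clear of the z-frozen rings
    if cols[0] < 2 or cols[-1] > config.Lx - 3 or rows[0] < 2 or rows[-1] > config.Ly - 3:
        raise ConfigurationError("BAR region touches the frozen boundary rings")
    return cols, rows


@dataclass
class LatticeState:
    """Mutable per-node state of the membrane lattice.

    ``x`` and ``z`` are ``(Lx, Ly)`` float arrays; ``y(i, j) = j`` is implicit
    and never mutated.  ``frozen_z`` marks the two outer rings (z pinned at 0),
    ``bar`` marks BAR-domain nodes.  ``latched_left/right[j]`` record the
    irreversible tetraspanner latch per boundary side and BAR row.
    """

    x: np.ndarray
    z: np.ndarray
    frozen_z: np.ndarray
    bar: np.ndarray
    latched_left: np.ndarray
    latched_right: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape  # type: ignore[return-value]

    def y(self) -> np.ndarray:
        Lx, Ly = self.shape
        return np.broadcast_to(np.arange(Ly, dtype=float), (Lx, Ly)).copy()

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.x.copy(), self.z.copy(), self.frozen_z.copy(), self.bar.copy(),
            self.latched_left.copy(), self.latched_right.copy(),
        )

    def point(self, i: int, j: int) -> np.ndarray:
        return np.array([self.x[i, j], float(j), self.z[i, j]])

    def check_invariants(self, config: SimulationConfig) -> None:
        """Raise :class:`InconsistentStateError` on any violated invariant."""
        if np.any(self.z > 0):
            raise InconsistentStateError("z > 0 somewhere")
        if np.any(self.z[self.frozen_z] != 0.0):
            raise InconsistentStateError("frozen node moved in z")
        rx, ry = _bond_lengths(self)
        for r in (rx, ry):
            if np.any(r <= config.r_min) or np.any(r > config.r_max):
                raise InconsistentStateError("bond length outside (r_min, r_max]")


def init_lattice(config: SimulationConfig) -> LatticeState:
    """Flat ground state: ``x(i,j) = i``, ``z = 0``, everything unlatched."""
    Lx, Ly = config.Lx, config.Ly
    x = np.repeat(np.arange(Lx, dtype=float)[:, None], Ly, axis=1)
    z = np.zeros((Lx, Ly))
    frozen = np.zeros((Lx, Ly), dtype=bool)
    frozen[[0, 1, Lx - 2, Lx - 1], :] = True
    frozen[:, [0, 1, Ly - 2, Ly - 1]] = True
    bar = np.zeros((Lx, Ly), dtype=bool)
    if config.N != 0:
        cols, rows = bar_region(config)
        bar[np.ix_(cols, rows)] = True
    return LatticeState(
        x=x, z=z, frozen_z=frozen, bar=bar,
        latched_left=np.zeros(Ly, dtype=bool),
        latched_right=np.zeros(Ly, dtype=bool),
    )


# --------------------------------------------------------------------------
# energy terms


def spring_potential(r, config: SimulationConfig):
    """Nearest-neighbor spring energy at bond length ``r`` (scalar or array).

    Piecewise stiffness: ``k_harm_compress`` for r <= 1, ``k_harm_stretch``
    for r > 1.  Lengths outside ``(r_min, r_max]`` are infeasible by
    construction and raise :class:`InfeasibleMoveError`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= config.r_min) or np.any(r > config.r_max):
        raise InfeasibleMoveError("bond_bounds")
    k = np.where(r <= 1.0, config.k_harm_compress, config.k_harm_stretch)
    if config.spring_form == "quartic":
        e = k * (r * r - 1.0) ** 2
    else:
        e = k * (r - 1.0) ** 2
    return e if e.ndim else float(e)


def drag_energy(state: LatticeState, config: SimulationConfig) -> float:
    """Drag of the surrounding membrane on the two edge columns."""
    return float(config.k_drag * (state.x[0, :].sum() - state.x[-1, :].sum()))


def _segments(p_prev, p, p_next) -> tuple[np.ndarray, np.ndarray]:
    p_prev, p, p_next = (np.asarray(q, dtype=float) for q in (p_prev, p, p_next))
    v1, v2 = p - p_prev, p_next - p
    if np.allclose(v1, 0) or np.allclose(v2, 0):
        raise DegenerateGeometryError("zero-length segment")
    return v1, v2


def bend_angle_x(p_prev, p, p_next) -> float:
    """Signed turning angle (degrees) between consecutive segments, in the
    x-z plane.

    The sign follows the membrane-curvature convention of the model:
    *positive* when the chain bends toward ``z < 0`` (toward the cell
    interior), *negative* when it bends back toward the surface.  The base
    of a furrow (below the BAR coat) therefore carries negative angles and
    its upper edges positive ones.
    """
    v1, v2 = _segments(p_prev, p, p_next)
    cross = v1[2] * v2[0] - v1[0] * v2[2]
    dot = v1[0] * v2[0] + v1[2] * v2[2]
    if cross == 0.0 and dot == 0.0:
        raise DegenerateGeometryError("segments degenerate in the x-z plane")
    return math.degrees(math.atan2(cross, dot))


def bend_angle_y(p_prev, p, p_next) -> float:
    """Unsigned turning angle (degrees) between consecutive 3D segments.

    Used along the j-direction, where the preferred angle is always 0 so only
    the magnitude enters the energy.
    """
    v1, v2 = _segments(p_prev, p, p_next)
    cross = np.linalg.norm(np.cross(v1, v2))
    dot = float(np.dot(v1, v2))
    return math.degrees(math.atan2(cross, dot))


def _interior(i: int, j: int, Lx: int, Ly: int) -> bool:
    return 1 <= i <= Lx - 2 and 1 <= j <= Ly - 2


def node_elastic_energy(state: LatticeState, i: int, j: int, config: SimulationConfig) -> float:
    """Bending energy carried by interior node ``(i, j)``.

    Plain nodes: ``k_elast (phi_x^2 + phi_y^2)``; BAR nodes:
    ``k_curv (phi_x - phi_curv)^2 + k_elast phi_y^2`` (radians internally).
    """
    Lx, Ly = state.shape
    if not _interior(i, j, Lx, Ly):
        raise ValueError("elastic energy is defined for interior nodes only")
    phi_x = math.radians(bend_angle_x(state.point(i - 1, j), state.point(i, j), state.point(i + 1, j)))
    phi_y = math.radians(bend_angle_y(state.point(i, j - 1), state.point(i, j), state.point(i, j + 1)))
    if state.bar[i, j]:
        return float(config.k_curv * (phi_x - math.radians(config.phi_curv)) ** 2
                     + config.k_elast * phi_y ** 2)
    return float(config.k_elast * (phi_x ** 2 + phi_y ** 2))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Total lattice energy decomposed into its physical terms (kBT)."""

    spring: float
    drag: float
    elastic_plain: float
    elastic_bar: float

    @property
    def total(self) -> float:
        return self.spring + self.drag + self.elastic_plain + self.elastic_bar


def _bond_lengths(state: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    """Bond lengths along i (shape (Lx-1, Ly)) and along j (shape (Lx, Ly-1))."""
    dx = np.diff(state.x, axis=0)
    dzx = np.diff(state.z, axis=0)
    rx = np.sqrt(dx * dx + dzx * dzx)
    dy = np.diff(state.x, axis=1)
    dzy = np.diff(state.z, axis=1)
    ry = np.sqrt(dy * dy + 1.0 + dzy * dzy)
    return rx, ry


def _phi_grids(state: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    """Turning angles (radians) phi_x for i=1..Lx-2 (all j) and phi_y for
    j=1..Ly-2 (all i)."""
    x, z = state.x, state.z
    v1x, v1z = x[1:-1, :] - x[:-2, :], z[1:-1, :] - z[:-2, :]
    v2x, v2z = x[2:, :] - x[1:-1, :], z[2:, :] - z[1:-1, :]
    phi_x = np.arctan2(v1z * v2x - v1x * v2z, v1x * v2x + v1z * v2z)

    u1x, u1z = x[:, 1:-1] - x[:, :-2], z[:, 1:-1] - z[:, :-2]
    u2x, u2z = x[:, 2:] - x[:, 1:-1], z[:, 2:] - z[:, 1:-1]
    # segment vectors are (ux, 1, uz); unsigned angle via |cross| and dot
    cx = u1z - u2z  # actually (1*u2z - u1z*1) sign is irrelevant under the norm
    cy = u1z * u2x - u1x * u2z
    cz = u1x - u2x
    cross = np.sqrt(cx * cx + cy * cy + cz * cz)
    dot = u1x * u2x + 1.0 + u1z * u2z
    phi_y = np.arctan2(cross, dot)
    return phi_x, phi_y


def total_energy(state: LatticeState, config: SimulationConfig) -> EnergyBreakdown:
    """Full (non-incremental) energy of a lattice state.

    Springs sum over every nearest-neighbor bond once, drag over the two edge
    columns, bending over interior nodes (both turning angles defined).
    Raises :class:`InconsistentStateError` if any bond is outside bounds.
    """
    rx, ry = _bond_lengths(state)
    try:
        spring = float(np.sum(spring_potential(rx, config)) + np.sum(spring_potential(ry, config)))
    except InfeasibleMoveError as exc:
        raise InconsistentStateError("bond length outside (r_min, r_max]") from exc

    drag = drag_energy(state, config)

    phi_x, phi_y = _phi_grids(state)
    # align on interior nodes: i in 1..Lx-2, j in 1..Ly-2
    px = phi_x[:, 1:-1]
    py = phi_y[1:-1, :]
    bar = state.bar[1:-1, 1:-1]
    phic = math.radians(config.phi_curv)
    e_plain = config.k_elast * (np.where(bar, 0.0, px ** 2) + py ** 2)
    e_bar = np.where(bar, config.k_curv * (px - phic) ** 2, 0.0)
    return EnergyBreakdown(
        spring=spring,
        drag=drag,
        elastic_plain=float(np.sum(e_plain)),
        elastic_bar=float(np.sum(e_bar)),
    )


def delta_energy(state: LatticeState, move, config: SimulationConfig) -> float:
    """Incremental energy change of a single-node move.

    Touches only the bonds and turning-angle stencils incident to the moved
    node.  ``move`` is anything with fields/entries ``(i, j, dx, dz)``.
    Raises :class:`InfeasibleMoveError` if the move violates ``z <= 0``, the
    frozen mask, or the bond-length bounds.
    """
    if hasattr(move, "i"):
        i, j, dx, dz = move.i, move.j, move.dx, move.dz
    else:
        i, j, dx, dz = move
    de, status = _kernel.delta_energy_nb(
        state.x, state.z, state.frozen_z, state.bar, int(i), int(j),
        float(dx), float(dz), *_kernel.energy_params(config),
    )
    if status != _kernel.OK:
        raise InfeasibleMoveError(_REASONS.get(status, str(status)))
    return float(de)
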