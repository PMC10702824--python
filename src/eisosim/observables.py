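"""Readouts from lattice states and trajectories.

Boundary angles at the edge of the BAR-covered region, line profiles
parallel/orthogonal to the BAR domains, shape classification (flat, furrow,
half-circle, omega), bond/height fluctuation statistics, and PLY surface
export of the simulated point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model import LatticeState, SimulationConfig, bar_region, bend_angle_x

__all__ = [
    "NoBarRegionError",
    "ProfileCurve",
    "ShapeReport",
    "boundary_angles",
    "mean_boundary_angle",
    "profile",
    "classify_shape",
    "fluctuation_stats",
    "export_surface",
    "read_surface",
]

# central BAR rows used for reported (tip-effect-free) boundary angles
N_CENTRAL_ROWS = 15
# tolerances of the shape heuristics, in degrees / relative width
OMEGA_ANGLE_DEG = 90.0
HALF_CIRCLE_TOL_DEG = 20.0
NECK_REL_MARGIN = 0.95
N_DEPTH_SCANS = 50


class NoBarRegionError(ValueError):
    """Operation requires BAR domains but the configuration has N = 0."""


def boundary_angles(state: LatticeState, config: SimulationConfig) -> dict:
    """Signed outward-positive boundary angles (degrees) per BAR row.

    The angle is the turning angle phi_x at the first column outside the
    BAR region (``imin - 1`` on the left, ``imax + 1`` on the right).
    Positive values mean positively curved membrane at the furrow edge (the
    bend where the membrane leaves the flat surface), as opposed to the
    negative curvature imposed below the BAR domains; a mirror-symmetric
    state gives equal left and right values.
    """
    if config.N == 0:
        raise NoBarRegionError("boundary angles require N >= 1 BAR columns")
    cols, rows = bar_region(config)
    left, right = _kernel.boundary_angles_nb(
        state.x, state.z, int(cols[0]), int(cols[-1]), int(rows[0]), int(rows[-1])
    )
    return {"rows": rows.copy(), "left": np.degrees(left), "right": np.degrees(right)}


def central_row_slice(n_rows: int, n_central: int = N_CENTRAL_ROWS) -> slice:
    n_c = min(n_central, n_rows)
    lo = (n_rows - n_c) // 2
    return slice(lo, lo + n_c)


def mean_boundary_angle(state: LatticeState, config: SimulationConfig,
                        n_central: int = N_CENTRAL_ROWS) -> float:
    """Mean outward boundary angle (degrees) over both sides and the central
    BAR rows."""
    ba = boundary_angles(state, config)
    sel = central_row_slice(len(ba["rows"]), n_central)
    return float(0.5 * (ba["left"][sel].mean() + ba["right"][sel].mean()))


@dataclass(frozen=True)
class ProfileCurve:
    """Ordered 3D points along one lattice line."""

    axis: str  # "along_bar" (varying i at fixed row) or "along_furrow" (varying j)
    index: int
    points: np.ndarray  # (n, 3) array of (x, y, z)


def profile(state: LatticeState, axis: str, index: int | None = None) -> ProfileCurve:
    """Extract a line profile through the lattice.

    ``along_bar`` runs across the BAR columns at row ``index`` (default: the
    central row) -- the cross-section in which the invagination curls.
    ``along_furrow`` runs along the furrow axis at column ``index`` (default:
    the central column).
    """
    Lx, Ly = state.shape
    if axis == "along_bar":
        j = (Ly - 1) // 2 if index is None else int(index)
        if not 0 <= j < Ly:
            raise IndexError(f"row index {j} outside lattice")
        pts = np.column_stack([state.x[:, j], np.full(Lx, float(j)), state.z[:, j]])
        return ProfileCurve("along_bar", j, pts)
    if axis == "along_furrow":
        i = (Lx - 1) // 2 if index is None else int(index)
        if not 0 <= i < Lx:
            raise IndexError(f"column index {i} outside lattice")
        pts = np.column_stack([state.x[i, :], np.arange(Ly, dtype=float), state.z[i, :]])
        return ProfileCurve("along_furrow", i, pts)
    raise ValueError("axis must be 'along_bar' or 'along_furrow'")


@dataclass(frozen=True)
class ShapeReport:
    """Classification of an equilibrated membrane cross-section."""

    shape: str  # flat | furrow | half_circle | omega
    max_boundary_angle: float  # degrees, outward-positive
    depth: float  # lattice units, -min z
    turning_sum: float  # degrees, summed phi_x over BAR columns, central row
    neck_width: float | None = None  # lattice units (omega only)
    max_interior_width: float | None = None


def _cross_section_widths(xs: np.ndarray, zs: np.ndarray,
                          n_depths: int = N_DEPTH_SCANS) -> tuple[np.ndarray, np.ndarray]:
    """Width of the invagination (outermost arm distance) at scanned depths.

    The cross-section is treated as a polyline; the width at depth d is the
    horizontal distance between the outermost crossings of the line z = d.
    Depths are returned shallow to deep.
    """
    zmin = float(zs.min())
    depths = np.linspace(0.05 * zmin, 0.95 * zmin, n_depths)
    widths = np.full(n_depths, np.nan)
    for k, d in enumerate(depths):
        crossings = []
        for a in range(len(xs) - 1):
            z0, z1 = zs[a], zs[a + 1]
            if (z0 - d) * (z1 - d) <= 0 and z0 != z1:
                t = (d - z0) / (z1 - z0)
                crossings.append(xs[a] + t * (xs[a + 1] - xs[a]))
        if len(crossings) >= 2:
            widths[k] = max(crossings) - min(crossings)
    return depths, widths


def classify_shape(state: LatticeState, config: SimulationConfig,
                   thermal_z_rms: float = 0.01) -> ShapeReport:
    """Classify the membrane shape of an (equilibrated) state.

    omega: max outward boundary angle > 90 deg, or the central cross-section
    is re-entrant (some shallow width strictly smaller than a deeper width);
    half_circle: total turning across the BAR columns within +/-20 deg of
    -180 deg and no neck; furrow: invagination depth above 5x the thermal
    height fluctuation; flat otherwise.
    """
    if config.N == 0:
        zmin = float(-state.z.min())
        return ShapeReport("furrow" if zmin > 5 * thermal_z_rms else "flat",
                           0.0, zmin, 0.0)
    ba = boundary_angles(state, config)
    max_angle = float(max(ba["left"].max(), ba["right"].max()))
    cols, rows = bar_region(config)
    jc = int(rows[len(rows) // 2])
    cross = profile(state, "along_bar", jc)
    xs, zs = cross.points[:, 0], cross.points[:, 2]
    depth = float(-zs.min())
    turning = sum(
        bend_angle_x(cross.points[i - 1], cross.points[i], cross.points[i + 1])
        for i in range(int(cols[0]), int(cols[-1]) + 1)
    )

    neck_width = None
    max_interior = None
    has_neck = False
    if depth > 5 * thermal_z_rms:
        _, widths = _cross_section_widths(xs, zs)
        ok = np.isfinite(widths)
        if ok.sum() >= 2:
            w = widths[ok]
            k_max = int(np.argmax(w))
            if k_max > 0:  # widest level is below some shallower level
                neck = float(w[:k_max].min())
                if neck < NECK_REL_MARGIN * w[k_max]:
                    has_neck = True
                    neck_width = neck
                    max_interior = float(w[k_max])

    if max_angle > OMEGA_ANGLE_DEG or has_neck:
        shape = "omega"
    elif abs(turning + 180.0) <= HALF_CIRCLE_TOL_DEG:
        shape = "half_circle"
    elif depth > 5 * thermal_z_rms:
        shape = "furrow"
    else:
        shape = "flat"
    return ShapeReport(shape, max_angle, depth, float(turning), neck_width, max_interior)


def fluctuation_stats(trajectory, burn_in: int) -> dict:
    """Bond-length and height fluctuation statistics over a trajectory.

    Uses the snapshots recorded at sweep >= ``burn_in``.  Returns the mean
    nearest-neighbor distance, the RMS deviation of bond lengths from that
    mean, and the RMS height of z-movable nodes.
    """
    snaps = [st for sw, st in trajectory.snapshots if sw >= burn_in]
    if not snaps:
        raise ValueError("burn_in leaves no snapshots")
    from .model import _bond_lengths  # local import to keep the namespace tidy

    bonds = []
    zs = []
    for st in snaps:
        rx, ry = _bond_lengths(st)
        bonds.append(np.concatenate([rx.ravel(), ry.ravel()]))
        zs.append(st.z[~st.frozen_z].ravel())
    all_bonds = np.concatenate(bonds)
    all_z = np.concatenate(zs)
    nn_mean = float(all_bonds.mean())
    return {
        "nn_mean": nn_mean,
        "nn_rms": float(np.sqrt(np.mean((all_bonds - nn_mean) ** 2))),
        "z_rms": float(np.sqrt(np.mean(all_z ** 2))),
    }


def export_surface(state: LatticeState, path) -> None:
    """Write the lattice as an ASCII PLY mesh.

    Vertices in row-major order (i outer, j inner) with an ``is_bar`` flag;
    each lattice cell is split into two triangles, giving
    ``2 (Lx-1) (Ly-1)`` faces.
    """
    Lx, Ly = state.shape
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {Lx * Ly}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar is_bar\n")
        fh.write(f"element face {2 * (Lx - 1) * (Ly - 1)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for i in range(Lx):
            for j in range(Ly):
                fh.write(f"{state.x[i, j]:.9g} {j} {state.z[i, j]:.9g} "
                         f"{int(state.bar[i, j])}\n")
        for i in range(Lx - 1):
            for j in range(Ly - 1):
                v = i * Ly + j
                fh.write(f"3 {v} {v + 1} {v + Ly}\n")
                fh.write(f"3 {v + 1} {v + Ly + 1} {v + Ly}\n")


def read_surface(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back an exported PLY: (vertices (n,3), is_bar (n,), faces (m,3))."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline().strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.empty((n_vert, 3))
        flags = np.empty(n_vert, dtype=np.uint8)
        for k in range(n_vert):
            parts = fh.readline().split()
            verts[k] = [float(p) for p in parts[:3]]
            flags[k] = int(parts[3])
        faces = np.empty((n_face, 3), dtype=np.int64)
        for k in range(n_face):
            parts = fh.readline().split()
            faces[k] = [int(p) for p in parts[1:4]]
    return verts, flags, faces
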