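"""Compiled inner loops for the lattice Monte Carlo.

Everything here is numba ``@njit`` code operating on plain arrays; the
public API lives in :mod:`eisosim.model` and :mod:`eisosim.engine`.  The
incremental energy evaluation touches only the four bonds and the six
turning-angle stencils incident to a moved node, which is what makes sweeps
over the full lattice affordable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

OK = 0
INFEASIBLE_Z = 1
INFEASIBLE_FROZEN = 2
INFEASIBLE_BOND = 3

EVENT_LEFT = 0
EVENT_RIGHT = 1


def energy_params(config) -> tuple:
    """Pack the energy-relevant config fields for the jitted functions."""
    return (
        config.k_harm_compress,
        config.k_harm_stretch,
        1.0 if config.spring_form == "quartic" else 0.0,
        config.k_drag,
        config.k_elast,
        config.k_curv,
        math.radians(config.phi_curv),
        config.r_min,
        config.r_max,
    )


@njit(cache=True)
def _spring(r, kc, ks, quartic):
    k = kc if r <= 1.0 else ks
    if quartic != 0.0:
        q = r * r - 1.0
    else:
        q = r - 1.0
    return k * q * q


@njit(cache=True)
def _phi_x(x, z, i, j):
    # signed turning angle in the x-z plane; positive when the chain bends
    # toward z < 0 (the cell interior), matching the membrane-curvature sign
    # convention of the model (BAR domains below the furrow: negative)
    v1x = x[i, j] - x[i - 1, j]
    v1z = z[i, j] - z[i - 1, j]
    v2x = x[i + 1, j] - x[i, j]
    v2z = z[i + 1, j] - z[i, j]
    return math.atan2(v1z * v2x - v1x * v2z, v1x * v2x + v1z * v2z)


@njit(cache=True)
def _phi_y(x, z, i, j):
    u1x = x[i, j] - x[i, j - 1]
    u1z = z[i, j] - z[i, j - 1]
    u2x = x[i, j + 1] - x[i, j]
    u2z = z[i, j + 1] - z[i, j]
    cx = u1z - u2z
    cy = u1z * u2x - u1x * u2z
    cz = u1x - u2x
    cross = math.sqrt(cx * cx + cy * cy + cz * cz)
    dot = u1x * u2x + 1.0 + u1z * u2z
    return math.atan2(cross, dot)


@njit(cache=True)
def _local_energy(x, z, bar, i, j, kc, ks, quartic, kdrag, kelast, kcurv, phic):
    """Energy of all terms that involve node (i, j)."""
    Lx, Ly = x.shape
    e = 0.0
    xi = x[i, j]
    zi = z[i, j]
    # springs to up to four neighbors
    if i > 0:
        dx = xi - x[i - 1, j]
        dz = zi - z[i - 1, j]
        e += _spring(math.sqrt(dx * dx + dz * dz), kc, ks, quartic)
    if i < Lx - 1:
        dx = x[i + 1, j] - xi
        dz = z[i + 1, j] - zi
        e += _spring(math.sqrt(dx * dx + dz * dz), kc, ks, quartic)
    if j > 0:
        dx = xi - x[i, j - 1]
        dz = zi - z[i, j - 1]
        e += _spring(math.sqrt(dx * dx + 1.0 + dz * dz), kc, ks, quartic)
    if j < Ly - 1:
        dx = x[i, j + 1] - xi
        dz = z[i, j + 1] - zi
        e += _spring(math.sqrt(dx * dx + 1.0 + dz * dz), kc, ks, quartic)
    # phi_x stencils centered at (i-1, j), (i, j), (i+1, j); interior nodes only
    if 1 <= j <= Ly - 2:
        for ii in range(i - 1, i + 2):
            if 1 <= ii <= Lx - 2:
                p = _phi_x(x, z, ii, j)
                if bar[ii, j]:
                    e += kcurv * (p - phic) * (p - phic)
                else:
                    e += kelast * p * p
    # phi_y stencils centered at (i, j-1), (i, j), (i, j+1)
    if 1 <= i <= Lx - 2:
        for jj in range(j - 1, j + 2):
            if 1 <= jj <= Ly - 2:
                p = _phi_y(x, z, i, jj)
                e += kelast * p * p
    # drag on the edge columns
    if i == 0:
        e += kdrag * xi
    elif i == Lx - 1:
        e -= kdrag * xi
    return e


@njit(cache=True)
def _bonds_feasible(x, z, i, j, xnew, znew, rmin, rmax):
    Lx, Ly = x.shape
    if i > 0:
        dx = xnew - x[i - 1, j]
        dz = znew - z[i - 1, j]
        r = math.sqrt(dx * dx + dz * dz)
        if r <= rmin or r > rmax:
            return False
    if i < Lx - 1:
        dx = x[i + 1, j] - xnew
        dz = z[i + 1, j] - znew
        r = math.sqrt(dx * dx + dz * dz)
        if r <= rmin or r > rmax:
            return False
    if j > 0:
        dx = xnew - x[i, j - 1]
        dz = znew - z[i, j - 1]
        r = math.sqrt(dx * dx + 1.0 + dz * dz)
        if r <= rmin or r > rmax:
            return False
    if j < Ly - 1:
        dx = x[i, j + 1] - xnew
        dz = z[i, j + 1] - znew
        r = math.sqrt(dx * dx + 1.0 + dz * dz)
        if r <= rmin or r > rmax:
            return False
    return True


@njit(cache=True)
def delta_energy_nb(x, z, frozen, bar, i, j, dx, dz,
                    kc, ks, quartic, kdrag, kelast, kcurv, phic, rmin, rmax):
    """(delta_E, status) for a single-node move; state is left untouched."""
    zo = z[i, j]
    xo = x[i, j]
    znew = zo + dz
    if znew > 0.0:
        return 0.0, INFEASIBLE_Z
    if frozen[i, j] and dz != 0.0:
        return 0.0, INFEASIBLE_FROZEN
    xnew = xo + dx
    if not _bonds_feasible(x, z, i, j, xnew, znew, rmin, rmax):
        return 0.0, INFEASIBLE_BOND
    e0 = _local_energy(x, z, bar, i, j, kc, ks, quartic, kdrag, kelast, kcurv, phic)
    x[i, j] = xnew
    z[i, j] = znew
    e1 = _local_energy(x, z, bar, i, j, kc, ks, quartic, kdrag, kelast, kcurv, phic)
    x[i, j] = xo
    z[i, j] = zo
    return e1 - e0, OK


@njit(cache=True)
def run_sweeps_nb(x, z, frozen, bar, latch_left, latch_right,
                  nodes, dxs, dzs, log_us,
                  imin, imax, jmin, jmax,
                  kc, ks, quartic, kdrag, kelast, kcurv, phic, rmin, rmax,
                  sym_lim, latch_on, latch_lo, latch_hi, latch_thr,
                  inv_temp, sweep0,
                  ev_side, ev_row, ev_sweep):
    """Run ``len(nodes) / (Lx*Ly)`` sweeps of single-node Metropolis moves.

    Mutates x, z and the latch registries in place.  Returns
    (accepted_moves, n_events) where latch events were appended to the
    ``ev_*`` arrays (side, BAR row, sweep index).

    Boundary-angle bookkeeping (symmetry filter, tetraspanner latch) is
    event-driven: it runs only for moves that touch a boundary-angle stencil
    of a BAR row.  The raw signed turning angle is already outward-positive
    on both sides (mirroring a state about the midline reverses both the
    traversal order and the x-axis, so the two sign flips cancel and a
    mirror-symmetric membrane gives equal left/right angles).
    """
    Lx, Ly = x.shape
    per_sweep = Lx * Ly
    accepted = 0
    n_ev = 0
    have_bar = imin >= 0
    for t in range(nodes.shape[0]):
        idx = nodes[t]
        i = idx // Ly
        j = idx - i * Ly
        dx = dxs[t]
        dz = 0.0 if frozen[i, j] else dzs[t]

        xo = x[i, j]
        zo = z[i, j]
        znew = zo + dz
        if znew > 0.0:
            continue
        xnew = xo + dx
        if not _bonds_feasible(x, z, i, j, xnew, znew, rmin, rmax):
            continue

        e0 = _local_energy(x, z, bar, i, j, kc, ks, quartic, kdrag, kelast, kcurv, phic)
        x[i, j] = xnew
        z[i, j] = znew
        e1 = _local_energy(x, z, bar, i, j, kc, ks, quartic, kdrag, kelast, kcurv, phic)

        reject = False
        touches_left = False
        touches_right = False
        phi_l = 0.0
        phi_r = 0.0
        if have_bar and jmin <= j <= jmax:
            touches_left = imin - 2 <= i <= imin
            touches_right = imax <= i <= imax + 2
            if touches_left or touches_right:
                phi_l = _phi_x(x, z, imin - 1, j)
                phi_r = _phi_x(x, z, imax + 1, j)
                if abs(phi_l - phi_r) >= sym_lim:
                    reject = True
                if not reject and latch_on:
                    if latch_left[j] and (phi_l < latch_lo or phi_l > latch_hi):
                        reject = True
                    if latch_right[j] and (phi_r < latch_lo or phi_r > latch_hi):
                        reject = True

        if not reject:
            de = e1 - e0
            if de > 0.0 and log_us[t] >= -de * inv_temp:
                reject = True

        if reject:
            x[i, j] = xo
            z[i, j] = zo
            continue

        accepted += 1
        if latch_on and (touches_left or touches_right):
            sweep = sweep0 + t // per_sweep
            if (not latch_left[j]) and phi_l > latch_thr:
                latch_left[j] = True
                ev_side[n_ev] = EVENT_LEFT
                ev_row[n_ev] = j
                ev_sweep[n_ev] = sweep
                n_ev += 1
            if (not latch_right[j]) and phi_r > latch_thr:
                latch_right[j] = True
                ev_side[n_ev] = EVENT_RIGHT
                ev_row[n_ev] = j
                ev_sweep[n_ev] = sweep
                n_ev += 1
    return accepted, n_ev


@njit(cache=True)
def boundary_angles_nb(x, z, imin, imax, jmin, jmax):
    """Outward-positive boundary angles (radians) per BAR row, both sides."""
    n = jmax - jmin + 1
    left = np.empty(n)
    right = np.empty(n)
    for k in range(n):
        j = jmin + k
        left[k] = _phi_x(x, z, imin - 1, j)
        right[k] = _phi_x(x, z, imax + 1, j)
    return left, right
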