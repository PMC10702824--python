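"""Unit tests for the lattice model: configuration, geometry, energies."""

import math

import numpy as np
import pytest

from eisosim import build_config, init_lattice, total_energy
from eisosim.engine import Move
from eisosim.model import (
    ConfigurationError,
    InconsistentStateError,
    InfeasibleMoveError,
    DegenerateGeometryError,
    bar_region,
    bend_angle_x,
    bend_angle_y,
    delta_energy,
    drag_energy,
    node_elastic_energy,
    spring_potential,
)

# independently computed: k_curv * (28 deg in rad)^2
FLAT_BAR_NODE_ENERGY = 286584.0685353354


# --------------------------------------------------------------------------
# configuration


class TestConfig:
    def test_defaults_match_model_constants(self):
        cfg = build_config()
        assert (cfg.Lx, cfg.Ly) == (25, 49)
        assert cfg.k_harm_compress == 100_000
        assert cfg.k_harm_stretch == 20_000
        assert cfg.k_drag == 800
        assert cfg.k_elast == 80_000
        assert cfg.k_curv == 1_200_000
        assert cfg.phi_curv == -28.0
        assert (cfg.r_min, cfg.r_max) == (0.5, 2.0)
        assert cfg.step_size == 0.001
        assert cfg.bar_rows == 29
        assert cfg.latch_threshold == 60.0 and cfg.latch_halfwidth == 5.0
        assert cfg.symmetry_limit == 10.0

    def test_override_passthrough(self):
        cfg = build_config(step_size=0.002)
        assert cfg.step_size == 0.002
        assert cfg.Lx == 25  # everything else untouched

    @pytest.mark.parametrize("bad", [
        {"N": 4},                 # even
        {"N": 23},                # > Lx - 4
        {"bar_rows": 2},          # even
        {"unknown_key": 1},
        {"r_min": 1.5},           # violates r_min < 1
        {"latch_halfwidth": 70},  # wider than threshold
        {"k_elast": -1},
        {"spring_form": "cubic"},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            build_config(bad)

    def test_n_zero_allowed(self):
        cfg = build_config(N=0)
        cols, rows = bar_region(cfg)
        assert cols.size == 0 and rows.size == 0


class TestBarRegion:
    def test_n7_columns_centered(self):
        cols, rows = bar_region(build_config(N=7))
        assert cols.tolist() == list(range(9, 16))
        assert rows.tolist() == list(range(10, 39))

    def test_n1_center_column(self):
        cols, _ = bar_region(build_config(N=1))
        assert cols.tolist() == [12]

    def test_region_clear_of_frozen_rings(self):
        with pytest.raises(ConfigurationError):
            build_config(Lx=9, N=7)  # columns would hit the frozen ring


class TestInitLattice:
    def test_flat_ground_state_energies(self, default_config):
        state = init_lattice(build_config(N=0))
        eb = total_energy(state, build_config(N=0))
        assert eb.spring == 0.0
        assert eb.elastic_plain == 0.0
        assert eb.elastic_bar == 0.0
        # drag of the flat state is a constant offset; only differences matter
        assert eb.drag == pytest.approx(-940_800.0)

    def test_frozen_ring_count(self, default_config):
        state = init_lattice(default_config)
        assert state.x.size == 25 * 49 == 1225
        assert int(state.frozen_z.sum()) == 280  # 2*(2*49) + 2*(2*21)

    def test_small_lattice_movable_core(self):
        cfg = build_config(Lx=7, Ly=7, N=1, bar_rows=1)
        state = init_lattice(cfg)
        movable = ~state.frozen_z
        assert movable.sum() == 9
        assert movable[2:5, 2:5].all()


# --------------------------------------------------------------------------
# energy terms


class TestSpring:
    def test_zero_at_unit_spacing(self, default_config):
        assert spring_potential(1.0, default_config) == 0.0

    def test_stretch_value(self, default_config):
        assert spring_potential(1.1, default_config) == pytest.approx(882.0)

    def test_out_of_bounds_infeasible(self, default_config):
        with pytest.raises(InfeasibleMoveError):
            spring_potential(0.4, default_config)
        with pytest.raises(InfeasibleMoveError):
            spring_potential(2.5, default_config)

    def test_piecewise_stiffness(self, default_config):
        # compression side uses the 5x stiffer constant
        e_comp = spring_potential(0.9, default_config)
        e_str = spring_potential(1.0 / 0.9, default_config)
        assert e_comp > e_str

    def test_quadratic_form_switch(self):
        cfg = build_config(spring_form="quadratic")
        assert spring_potential(1.1, cfg) == pytest.approx(20000 * 0.1 ** 2)


class TestDrag:
    def test_flat_value(self, default_config):
        state = init_lattice(default_config)
        assert drag_energy(state, default_config) == pytest.approx(-940_800.0)

    @pytest.mark.parametrize("col,sign", [(0, +1), (-1, -1)])
    def test_edge_column_shift_linear(self, default_config, col, sign):
        state = init_lattice(default_config)
        e0 = drag_energy(state, default_config)
        state.x[col, :] += 0.01
        assert drag_energy(state, default_config) - e0 == pytest.approx(sign * 392.0)


class TestBendAngles:
    def test_collinear_zero(self):
        assert bend_angle_x((0, 0, 0), (1, 0, 0), (2, 0, 0)) == 0.0
        assert bend_angle_y((0, 0, 0), (0, 1, 0), (0, 2, 0)) == 0.0

    def test_downward_bend_is_positive(self):
        # membrane-curvature convention: bending toward the cell interior
        # (z < 0) is positive
        assert bend_angle_x((0, 0, 0), (1, 0, 0), (2, 0, -1)) == pytest.approx(45.0)

    def test_antisymmetric_under_z_mirror(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(3, 3))
            pts[:, 1] = 0.0
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            a = bend_angle_x(*pts)
            b = bend_angle_x(*mirrored)
            assert a == pytest.approx(-b, abs=1e-12)

    def test_bend_angle_y_unsigned_3d_oracle(self, rng):
        # brute-force: angle between segment vectors via arccos
        for _ in range(50):
            pts = rng.normal(size=(3, 3))
            v1, v2 = pts[1] - pts[0], pts[2] - pts[1]
            expect = math.degrees(math.acos(np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
            assert bend_angle_y(*pts) == pytest.approx(expect, abs=1e-8)
            # symmetric under z-mirror
            assert bend_angle_y(*(pts * np.array([1, 1, -1.0]))) == pytest.approx(
                bend_angle_y(*pts), abs=1e-10)

    def test_y_bend_value(self):
        assert bend_angle_y((0, 0, 0), (0, 1, 0), (0, 2, -1)) == pytest.approx(45.0)

    def test_degenerate_segment_raises(self):
        with pytest.raises(DegenerateGeometryError):
            bend_angle_x((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestNodeElastic:
    def test_flat_plain_node_zero(self, default_config):
        state = init_lattice(default_config)
        assert node_elastic_energy(state, 5, 5, default_config) == 0.0

    def test_flat_bar_node_value(self, default_config):
        state = init_lattice(default_config)
        assert node_elastic_energy(state, 12, 24, default_config) == pytest.approx(
            FLAT_BAR_NODE_ENERGY)

    def test_bar_node_at_preferred_angle_zero(self, default_config):
        # build a 3-point kink of exactly -28 deg (toward z < 0 is positive,
        # so the preferred BAR angle bends back toward the surface... the
        # energy only needs phi_x == phi_curv, achieved by a +z kink)
        state = init_lattice(default_config)
        i, j = 12, 24
        phi = math.radians(28.0)
        # kink the x-chain so the turning at (i, j) equals -28 deg: raise z of
        # the next node; z must stay <= 0, so lower the previous two instead
        state.z[i - 1, j] = -math.tan(phi)
        state.z[i, j] = -math.tan(phi)
        # segments: (1, tan phi) then (1, 0) => turning = -phi (toward z > 0)
        e = node_elastic_energy(state, i, j, default_config)
        # phi_y contributions from the kinked nodes are nonzero; isolate phi_x
        # by comparing with the same geometry at a plain node
        phi_x = math.radians(bend_angle_x(state.point(i - 1, j), state.point(i, j),
                                          state.point(i + 1, j)))
        assert phi_x == pytest.approx(math.radians(-28.0))
        phi_y = math.radians(bend_angle_y(state.point(i, j - 1), state.point(i, j),
                                          state.point(i, j + 1)))
        expect = default_config.k_elast * phi_y ** 2  # BAR phi_x term vanishes
        assert e == pytest.approx(expect, rel=1e-9)

    def test_boundary_node_rejected(self, default_config):
        state = init_lattice(default_config)
        with pytest.raises(ValueError):
            node_elastic_energy(state, 0, 5, default_config)


# --------------------------------------------------------------------------
# total and incremental energy


def total_energy_longdouble(state, config):
    """Independent full-energy oracle in extended precision."""
    x = state.x.astype(np.longdouble)
    z = state.z.astype(np.longdouble)
    kc, ks = config.k_harm_compress, config.k_harm_stretch

    def spring(r):
        k = np.where(r <= 1.0, kc, ks)
        if config.spring_form == "quartic":
            return k * (r * r - 1.0) ** 2
        return k * (r - 1.0) ** 2

    rx = np.sqrt(np.diff(x, axis=0) ** 2 + np.diff(z, axis=0) ** 2)
    ry = np.sqrt(np.diff(x, axis=1) ** 2 + 1.0 + np.diff(z, axis=1) ** 2)
    e = np.sum(spring(rx)) + np.sum(spring(ry))
    e += config.k_drag * (np.sum(x[0, :]) - np.sum(x[-1, :]))

    phic = np.longdouble(math.radians(config.phi_curv))
    Lx, Ly = state.shape
    for i in range(1, Lx - 1):
        for j in range(1, Ly - 1):
            v1x, v1z = x[i, j] - x[i - 1, j], z[i, j] - z[i - 1, j]
            v2x, v2z = x[i + 1, j] - x[i, j], z[i + 1, j] - z[i, j]
            phi_x = np.arctan2(v1z * v2x - v1x * v2z, v1x * v2x + v1z * v2z)
            u1x, u1z = x[i, j] - x[i, j - 1], z[i, j] - z[i, j - 1]
            u2x, u2z = x[i, j + 1] - x[i, j], z[i, j + 1] - z[i, j]
            cross = np.sqrt((u1z - u2z) ** 2 + (u1z * u2x - u1x * u2z) ** 2
                            + (u1x - u2x) ** 2)
            phi_y = np.arctan2(cross, u1x * u2x + 1.0 + u1z * u2z)
            if state.bar[i, j]:
                e += config.k_curv * (phi_x - phic) ** 2 + config.k_elast * phi_y ** 2
            else:
                e += config.k_elast * (phi_x ** 2 + phi_y ** 2)
    return e


class TestTotalEnergy:
    def test_flat_default_lattice_breakdown(self, default_config):
        state = init_lattice(default_config)
        eb = total_energy(state, default_config)
        assert eb.spring == 0.0
        assert eb.elastic_plain == 0.0
        assert eb.elastic_bar == pytest.approx(29 * 7 * FLAT_BAR_NODE_ENERGY, rel=1e-12)
        assert eb.total == pytest.approx(eb.spring + eb.drag + eb.elastic_plain
                                         + eb.elastic_bar)

    def test_matches_longdouble_oracle(self, small_config, perturbed_state):
        eb = total_energy(perturbed_state, small_config)
        oracle = float(total_energy_longdouble(perturbed_state, small_config))
        assert eb.total == pytest.approx(oracle, rel=1e-10)

    def test_linearity_in_stiffness(self, small_config, perturbed_state):
        doubled = build_config(
            Lx=small_config.Lx, Ly=small_config.Ly, N=small_config.N,
            bar_rows=small_config.bar_rows,
            k_harm_compress=2 * small_config.k_harm_compress,
            k_harm_stretch=2 * small_config.k_harm_stretch,
            k_drag=2 * small_config.k_drag,
            k_elast=2 * small_config.k_elast,
            k_curv=2 * small_config.k_curv,
        )
        e1 = total_energy(perturbed_state, small_config)
        e2 = total_energy(perturbed_state, doubled)
        for name in ("spring", "drag", "elastic_plain", "elastic_bar"):
            assert getattr(e2, name) == pytest.approx(2 * getattr(e1, name), rel=1e-12)

    def test_translation_invariance(self, small_config, perturbed_state):
        e0 = total_energy(perturbed_state, small_config)
        shifted = perturbed_state.copy()
        shifted.x += 0.37
        e1 = total_energy(shifted, small_config)
        # drag difference cancels between the two edge columns; elastic and
        # spring terms are exactly translation invariant
        assert e1.total == pytest.approx(e0.total, rel=1e-9)
        assert e1.elastic_plain == pytest.approx(e0.elastic_plain, rel=1e-9, abs=1e-9)

    def test_bond_out_of_bounds_raises(self, small_config):
        state = init_lattice(small_config)
        state.x[4, 5] += 1.7  # stretches a bond beyond r_max
        with pytest.raises(InconsistentStateError):
            total_energy(state, small_config)


class TestDeltaEnergy:
    def test_null_move_zero(self, small_config, perturbed_state):
        assert delta_energy(perturbed_state, Move(4, 5, 0.0, 0.0), small_config) == 0.0

    def test_matches_full_recompute(self, small_config, perturbed_state, rng):
        state = perturbed_state
        e_before = total_energy_longdouble(state, small_config)
        Lx, Ly = state.shape
        checked = 0
        while checked < 200:
            i = int(rng.integers(0, Lx))
            j = int(rng.integers(0, Ly))
            dx = float(rng.uniform(-0.01, 0.01))
            dz = 0.0 if state.frozen_z[i, j] else float(rng.uniform(-0.01, 0.01))
            move = Move(i, j, dx, dz)
            try:
                de = delta_energy(state, move, small_config)
            except InfeasibleMoveError:
                continue
            after = state.copy()
            after.x[i, j] += dx
            after.z[i, j] += dz
            de_full = float(total_energy_longdouble(after, small_config) - e_before)
            assert de == pytest.approx(de_full, rel=1e-9, abs=1e-9)
            checked += 1

    def test_frozen_node_z_move_infeasible(self, default_config):
        state = init_lattice(default_config)
        with pytest.raises(InfeasibleMoveError, match="frozen"):
            delta_energy(state, Move(0, 5, 0.0, -0.0005), default_config)

    def test_positive_z_infeasible(self, default_config):
        state = init_lattice(default_config)
        with pytest.raises(InfeasibleMoveError, match="z_positive"):
            delta_energy(state, Move(12, 24, 0.0, +0.0005), default_config)
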