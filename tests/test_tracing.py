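"""Overdamped particle advection, stick boundaries and trap counting."""

import dataclasses

import numpy as np
import pytest

from aceodep.core import (
    ChamberGeometry2D,
    ConfigError,
    Medium,
    ParticleSpec,
    SolverError,
    SolverSettings,
)
from aceodep.dep import DEPForceField
from aceodep.stokesflow import FlowField
from aceodep.tracing import (
    BilinearSampler,
    count_trapped,
    release_grid,
    trace,
)

GEOM = ChamberGeometry2D(height=160e-6, electrode_width=100e-6, gap=200e-6)
MEDIUM = Medium.kcl(1e-3)
BEAD = ParticleSpec(radius=0.5e-6)


def still_flow(geometry=GEOM, n=21):
    """A quiescent FlowField on a uniform grid."""
    x = np.linspace(0, geometry.cell_width, n)
    y = np.linspace(0, geometry.height, n)
    z = np.zeros((n, n))
    return FlowField(x=x, y=y, u=z, v=z.copy(), p=z.copy(), psi=z.copy(),
                     divergence_norm=0.0, geometry=geometry)


def uniform_force(flow, fy, fx=0.0):
    shape = flow.psi.shape
    return DEPForceField(x=flow.x, y=flow.y,
                         fx=np.full(shape, fx), fy=np.full(shape, fy), re_fcm=0.5)


class TestReleaseGrid:
    def test_baseline_lattice_is_20_by_10(self):
        """300 x 160 um cell at 15 um pitch with half-pitch wall offsets."""
        pts = release_grid(GEOM, 15e-6)
        assert pts.shape == (200, 2)
        assert np.unique(np.round(pts[:, 0] * 1e9)).size == 20
        assert np.unique(np.round(pts[:, 1] * 1e9)).size == 10
        assert pts[:, 0].min() == pytest.approx(7.5e-6)
        assert pts[:, 1].max() == pytest.approx(142.5e-6)

    def test_row_major_ordering_from_origin(self):
        pts = release_grid(GEOM, 15e-6)
        assert pts[0, 1] == pts[19, 1]  # first 20 points share the bottom row
        assert (np.diff(pts[:20, 0]) > 0).all()

    def test_pitch_equal_to_height_gives_single_row(self):
        g = ChamberGeometry2D(height=100e-6, electrode_width=100e-6, gap=200e-6)
        pts = release_grid(g, 99e-6)
        assert np.unique(pts[:, 1]).size == 1

    def test_mirror_symmetric_lattice(self):
        pts = release_grid(GEOM, 15e-6)
        xs = np.sort(np.unique(pts[:, 0]))
        np.testing.assert_allclose(xs + xs[::-1], GEOM.cell_width, rtol=1e-12)

    def test_oversized_pitch_rejected(self):
        with pytest.raises(ConfigError, match="release_pitch"):
            release_grid(GEOM, 1.0)


class TestTrace:
    def test_quiescent_fluid_leaves_particles_in_place(self):
        flow = still_flow()
        starts = release_grid(GEOM, 50e-6)
        trajs = trace(flow, None, BEAD, MEDIUM, starts, 5.0)
        np.testing.assert_array_equal(trajs.final_positions(), starts)
        assert count_trapped(trajs).proportion_trapped == 0.0

    def test_overdamped_fall_time_matches_closed_form(self):
        """Uniform downward force F: settling speed F/(6 pi eta r), so a
        particle at height y0 reaches the wall at t = (y0 - r) 6 pi eta r / F."""
        flow = still_flow()
        fy = -1e-14
        force = uniform_force(flow, fy)
        mobility = 1.0 / (6 * np.pi * MEDIUM.viscosity * BEAD.radius)
        y0 = 100e-6
        t_exact = (y0 - BEAD.radius) / (abs(fy) * mobility)
        st = SolverSettings(dt=0.02, output_stride=1, dep_drift_cap=1e9)
        trajs = trace(flow, force, BEAD, MEDIUM, np.array([[150e-6, y0]]),
                      duration=2 * t_exact, settings=st)
        assert trajs.status[0] == 1
        assert trajs.stick_wall[0] == "bottom-electrode"
        assert trajs.stick_time[0] == pytest.approx(t_exact, rel=0.02)

    def test_starts_within_one_radius_stick_immediately(self):
        flow = still_flow()
        starts = np.array([[150e-6, 0.3e-6], [150e-6, GEOM.height - 0.2e-6], [20e-6, 0.4e-6]])
        trajs = trace(flow, None, BEAD, MEDIUM, starts, 1.0)
        assert (trajs.status == 1).all()
        assert list(trajs.stick_wall) == ["bottom-electrode", "top-electrode", "bottom-wall"]
        assert (trajs.stick_time == 0).all()

    def test_oversized_explicit_step_rejected(self):
        flow = still_flow()
        flow.u[:] = 1e-3  # 1 mm/s everywhere
        with pytest.raises(SolverError, match="smaller"):
            trace(flow, None, BEAD, MEDIUM, np.array([[150e-6, 80e-6]]), 1.0,
                  SolverSettings(dt=1.0))

    def test_side_planes_reflect(self):
        """A particle advected across a symmetry plane re-enters mirrored."""
        flow = still_flow()
        flow.psi[:] = -2e-5 * flow.y[:, None]  # uniform u = -20 um/s via psi
        flow.u[:] = -2e-5
        starts = np.array([[10e-6, 80e-6]])
        trajs = trace(flow, None, BEAD, MEDIUM, starts, 2.0,
                      SolverSettings(dt=0.01, output_stride=1))
        xs = trajs.positions[:, 0, 0]
        assert xs.min() >= 0.0
        assert trajs.status[0] == 0  # symmetry planes are not sticky walls


class TestBaselineTracing:
    def test_particles_accumulate_on_bottom_electrode(self, baseline_case):
        """ACEO vortices plus positive DEP capture a substantial fraction of
        the released beads on the bottom electrode within 60 s."""
        trap = baseline_case.trap
        assert trap.per_wall["bottom-electrode"] > 0.1 * trap.n_released
        assert trap.n_trapped_electrode == trap.per_wall["bottom-electrode"] + trap.per_wall["top-electrode"]
        assert 0.0 < trap.proportion_trapped < 1.0

    def test_streamline_conservation_without_dep(self, baseline_fields, baseline_cfg):
        """With DEP off, advected particles stay on streamlines: the stream
        function along each path varies < 1% of its cell-wide range over 10 s."""
        flow = baseline_fields.flow
        starts = np.array([[60e-6, 80e-6], [220e-6, 80e-6], [40e-6, 40e-6], [75e-6, 120e-6]])
        st = dataclasses.replace(baseline_cfg.solver, output_stride=10)
        trajs = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 10.0, st)
        psi_samp = BilinearSampler(flow.x, flow.y, flow.psi)
        rng = flow.psi.max() - flow.psi.min()
        for k in range(starts.shape[0]):
            assert trajs.status[k] == 0
            along = psi_samp(trajs.positions[:, k, :])[0]
            assert (along.max() - along.min()) / rng < 0.01

    def test_halved_time_step_moves_free_particles_less_than_1um(
        self, baseline_fields, baseline_cfg
    ):
        flow = baseline_fields.flow
        starts = np.array([[60e-6, 80e-6], [220e-6, 80e-6], [140e-6, 100e-6]])
        st1 = dataclasses.replace(baseline_cfg.solver, output_stride=10**9)
        st2 = dataclasses.replace(st1, cfl=st1.cfl / 2)
        t1 = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 10.0, st1)
        t2 = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 10.0, st2)
        d = np.linalg.norm(t1.final_positions() - t2.final_positions(), axis=1)
        assert d.max() < 1e-6

    def test_deterministic_repeat_is_bit_identical(self, baseline_fields, baseline_cfg):
        flow = baseline_fields.flow
        dep = baseline_fields.dep
        starts = release_grid(baseline_cfg.chamber, 30e-6)
        a1 = trace(flow, dep, baseline_cfg.particle, baseline_cfg.medium, starts, 5.0,
                   baseline_cfg.solver)
        a2 = trace(flow, dep, baseline_cfg.particle, baseline_cfg.medium, starts, 5.0,
                   baseline_cfg.solver)
        np.testing.assert_array_equal(a1.positions, a2.positions)
        assert a1.to_dataframe().equals(a2.to_dataframe())

    def test_stick_positions_mirror_symmetric(self, baseline_case, baseline_cfg):
        """The baseline cell is mirror-symmetric, so stick sites pair up
        about x = W/2 within a grid cell."""
        trajs = baseline_case.trajectories
        stuck = trajs.status == 1
        xs = np.sort(trajs.final_positions()[stuck, 0])
        mirrored = np.sort(baseline_cfg.chamber.cell_width - xs)
        assert np.abs(xs - mirrored).max() < baseline_cfg.solver.target_spacing

    def test_brownian_option_is_seeded_and_reproducible(self, baseline_fields, baseline_cfg):
        flow = baseline_fields.flow
        starts = np.array([[150e-6, 80e-6]])
        st = dataclasses.replace(baseline_cfg.solver, brownian=True, seed=7)
        b1 = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 2.0, st)
        b2 = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 2.0, st)
        np.testing.assert_array_equal(b1.positions, b2.positions)
        st3 = dataclasses.replace(st, seed=8)
        b3 = trace(flow, None, baseline_cfg.particle, baseline_cfg.medium, starts, 2.0, st3)
        assert not np.array_equal(b1.positions, b3.positions)


class TestCountTrapped:
    def test_proportion_definition(self):
        flow = still_flow()
        starts = np.array([[150e-6, 0.3e-6], [150e-6, 80e-6], [50e-6, 0.2e-6], [250e-6, 80e-6]])
        trajs = trace(flow, None, BEAD, MEDIUM, starts, 1.0)
        res = count_trapped(trajs)
        assert res.n_released == 4
        assert res.n_trapped_electrode == 1  # only the electrode stick counts
        assert res.proportion_trapped == pytest.approx(0.25)
        assert res.per_wall["bottom-wall"] == 1

    def test_all_near_electrode_start_trapped(self):
        flow = still_flow()
        xl, xr = GEOM.electrode_span
        xs = np.linspace(xl + 1e-6, xr - 1e-6, 8)
        starts = np.column_stack([xs, np.full(8, 0.4e-6)])
        trajs = trace(flow, None, BEAD, MEDIUM, starts, 0.5)
        assert count_trapped(trajs).proportion_trapped == 1.0
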