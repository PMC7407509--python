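"""Particle stepping, seeding, ensemble integration and outlet accounting."""

import numpy as np
import pytest

from centrisim import flow as F
from centrisim import forces as Fo
from centrisim import tracking as T
from centrisim import geometry as G

UM = 1e-6


@pytest.fixture(scope="module")
def still_field(duct_mesh, fluid):
    return F.solve_flow(
        duct_mesh, fluid, F.RotatingFrame(0.0), max_steps=200, min_steps=5
    )


@pytest.fixture(scope="module")
def duct_pressure_flow(duct_mesh, fluid):
    return F.solve_flow(
        duct_mesh, fluid, F.RotatingFrame(0.0),
        bc={"inlet": 500.0, "outlet": 0.0}, tol_rate=0.02, max_steps=8000,
    )


class TestStepParticle:
    def test_free_motion(self):
        p = Fo.Particle(10 * UM)
        st = T.ParticleState(p, np.zeros(3), np.array([0.1, 0.0, 0.0]))
        out = T.step_particle(st, np.zeros(3), 1e-4)
        np.testing.assert_allclose(out.velocity, [0.1, 0, 0])
        np.testing.assert_allclose(out.position, [1e-5, 0, 0])
        assert out.time == pytest.approx(1e-4)

    def test_explicit_euler_velocity_update(self):
        p = Fo.Particle(10 * UM)
        st = T.ParticleState(p, np.zeros(3), np.zeros(3))
        force = np.array([1e-10, 0, 0])
        out = T.step_particle(st, force, 5e-5)
        np.testing.assert_allclose(
            out.velocity, force / p.mass * 5e-5, rtol=1e-12
        )

    def test_terminal_velocity_under_drag(self, fluid):
        """Constant body force + Stokes drag settles on F/(3 pi mu d_p)."""
        p = Fo.Particle(10 * UM)
        st = T.ParticleState(p, np.zeros(3), np.zeros(3))
        force = np.array([0.0, 2e-12, 0.0])
        for _ in range(200):
            st = T.step_particle(
                st, force, 5e-5, fluid=fluid, fluid_velocity=np.zeros(3)
            )
        v_term = 2e-12 / (3 * np.pi * fluid.viscosity * p.diameter)
        assert st.velocity[1] == pytest.approx(v_term, rel=1e-3)

    def test_rejects_nonpositive_dt(self):
        p = Fo.Particle(10 * UM)
        st = T.ParticleState(p, np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            T.step_particle(st, np.zeros(3), 0.0)


class TestTotalForce:
    def test_neutral_particle_at_rest_in_still_fluid(
        self, still_field, fluid, lift_model
    ):
        p = Fo.Particle(10 * UM, density=fluid.density)
        st = T.ParticleState(
            p, np.array([250 * UM, 50 * UM, 25 * UM]), np.zeros(3)
        )
        f = T.total_force(st, still_field, lift_model, still_field.frame,
                          fluid)
        np.testing.assert_allclose(f, 0.0, atol=1e-25)

    def test_comoving_centerline_particle_feels_only_body_forces(
        self, short_separator_flow, fluid, lift_model
    ):
        """Moving with the fluid at the duct center (beta = 0): drag and
        lift vanish; centrifugal + Coriolis remain."""
        frame = short_separator_flow.frame
        geo = short_separator_flow.geometry
        pos = np.array([300 * UM, 25 * UM, 25 * UM])  # contraction center
        u_f = T._fluid_velocity_3d(short_separator_flow, pos[None, :])[0]
        p = Fo.Particle(20 * UM)
        st = T.ParticleState(p, pos, u_f)
        total = T.total_force(st, short_separator_flow, lift_model, frame,
                              fluid)
        r_disk = np.array(
            [geo.placement.radial_offset + pos[0], pos[1] - geo.y_ref, 0.0]
        )
        expected = Fo.centrifugal_force(p, fluid, frame, r_disk) + \
            Fo.coriolis_force(p, fluid, frame, u_f)
        np.testing.assert_allclose(total, expected, rtol=1e-6, atol=1e-16)

    def test_requires_in_transit(self, still_field, fluid, lift_model):
        p = Fo.Particle(10 * UM)
        st = T.ParticleState(
            p, np.array([250 * UM, 50 * UM, 25 * UM]), np.zeros(3),
            status="exited:outlet",
        )
        with pytest.raises(ValueError):
            T.total_force(st, still_field, lift_model, still_field.frame,
                          fluid)


class TestSeeding:
    def test_reproducible_under_seed(self, separator_geometry,
                                     default_populations):
        a = T.seed_inlet_ensemble(separator_geometry, default_populations, 7)
        b = T.seed_inlet_ensemble(separator_geometry, default_populations, 7)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.position, sb.position)
        c = T.seed_inlet_ensemble(separator_geometry, default_populations, 8)
        assert any(
            not np.array_equal(sa.position, sc.position)
            for sa, sc in zip(a, c)
        )

    def test_counts_and_clearance(self, separator_geometry,
                                  default_populations):
        states = T.seed_inlet_ensemble(
            separator_geometry, default_populations, 3
        )
        assert len(states) == 40
        H = separator_geometry.height
        port = separator_geometry.inlets[0]
        for st in states:
            d = st.particle.diameter
            assert port.span[0] + d / 2 <= st.position[1] <= port.span[1] - d / 2
            assert d / 2 <= st.position[2] <= H - d / 2
            assert separator_geometry.contains(st.position[:2])

    def test_oversized_particle_rejected(self, separator_geometry):
        with pytest.raises(G.GeometryError):
            T.seed_inlet_ensemble(
                separator_geometry, [(Fo.Particle(60 * UM), 1)], 1
            )

    def test_initial_velocity_is_local_fluid(
        self, short_separator_geometry, short_separator_flow
    ):
        states = T.seed_inlet_ensemble(
            short_separator_geometry, [(Fo.Particle(10 * UM), 5)], 11,
            flow_field=short_separator_flow,
        )
        for st in states:
            u_f = T._fluid_velocity_3d(
                short_separator_flow, st.position[None, :]
            )[0]
            np.testing.assert_allclose(st.velocity, u_f)


@pytest.fixture(scope="module")
def short_run(short_separator_geometry, short_separator_flow, fluid,
              lift_model):
    pops = [
        (Fo.Particle(10 * UM, label="WBC"), 6),
        (Fo.Particle(20 * UM, label="CTC"), 6),
    ]
    states = T.seed_inlet_ensemble(
        short_separator_geometry, pops, 21, flow_field=short_separator_flow
    )
    return T.simulate_ensemble(
        states, short_separator_flow, lift_model,
        short_separator_flow.frame, fluid,
    )


class TestEnsemble:
    def test_particle_conservation(self, short_run):
        counts = short_run.status_counts()
        assert sum(counts.values()) == short_run.n_particles == 12

    def test_all_terminate(self, short_run):
        for st in short_run.states:
            assert not st.in_transit

    def test_wall_clearance_on_exit_states(self, short_run,
                                           short_separator_geometry):
        H = short_separator_geometry.height
        for st in short_run.states:
            d = st.particle.diameter
            assert d / 2 - 1e-12 <= st.position[2] <= H - d / 2 + 1e-12

    def test_bitwise_determinism(
        self, short_separator_geometry, short_separator_flow, fluid,
        lift_model, short_run
    ):
        pops = [
            (Fo.Particle(10 * UM, label="WBC"), 6),
            (Fo.Particle(20 * UM, label="CTC"), 6),
        ]
        states = T.seed_inlet_ensemble(
            short_separator_geometry, pops, 21,
            flow_field=short_separator_flow,
        )
        rerun = T.simulate_ensemble(
            states, short_separator_flow, lift_model,
            short_separator_flow.frame, fluid,
        )
        assert [s.status for s in rerun.states] == [
            s.status for s in short_run.states
        ]
        for a, b in zip(rerun.states, short_run.states):
            np.testing.assert_array_equal(a.position, b.position)

    def test_centerline_particle_stays_centered_without_rotation(
        self, duct_pressure_flow, fluid, lift_model
    ):
        p = Fo.Particle(10 * UM, density=fluid.density)
        pos = np.array([20 * UM, 50 * UM, 25 * UM])
        st = T.ParticleState(
            p, pos, T._fluid_velocity_3d(duct_pressure_flow, pos[None, :])[0]
        )
        res = T.simulate_ensemble(
            [st], duct_pressure_flow, lift_model, duct_pressure_flow.frame,
            fluid,
        )
        final = res.states[0]
        assert final.exit_label == "outlet"
        assert final.position[1] == pytest.approx(50 * UM, abs=0.5 * UM)
        assert final.position[2] == pytest.approx(25 * UM, abs=0.5 * UM)

    def test_time_step_refinement_bounds_exit_shift(
        self, short_separator_geometry, short_separator_flow, fluid,
        lift_model
    ):
        """Halving the reporting step moves each final lateral exit
        coordinate by at most d_p/2."""
        pops = [(Fo.Particle(20 * UM, label="CTC"), 4)]
        finals = []
        for dt in (5e-5, 2.5e-5):
            states = T.seed_inlet_ensemble(
                short_separator_geometry, pops, 5,
                flow_field=short_separator_flow,
            )
            res = T.simulate_ensemble(
                states, short_separator_flow, lift_model,
                short_separator_flow.frame, fluid, dt=dt,
            )
            finals.append([s.position[1] for s in res.states])
        for a, b in zip(*finals):
            assert abs(a - b) <= 10 * UM


class TestEfficiency:
    def _fabricate(self, tallies):
        """tallies: list of (label, status) pairs."""
        states = []
        for label, status in tallies:
            st = T.ParticleState(
                Fo.Particle(10 * UM, label=label), np.zeros(3), np.zeros(3),
                status=status,
            )
            states.append(st)
        return T.TrajectoryResult(
            states=states, history=[np.zeros((1, 7))] * len(states),
            settings={},
        )

    def test_ninety_percent_case(self):
        res = self._fabricate(
            [("CTC", "exited:outlet_lower")] * 18
            + [("CTC", "exited:outlet_upper")] * 2
        )
        assert T.separation_efficiency(res, "CTC", "outlet_lower") == 90.0

    def test_all_and_none(self):
        res = self._fabricate([("CTC", "exited:outlet_lower")] * 5)
        assert T.separation_efficiency(res, "CTC", "outlet_lower") == 100.0
        assert T.separation_efficiency(res, "CTC", "outlet_upper") == 0.0

    def test_stalled_counts_in_denominator(self):
        res = self._fabricate(
            [("CTC", "exited:outlet_lower")] * 3 + [("CTC", T.STALLED)]
        )
        assert T.separation_efficiency(res, "CTC", "outlet_lower") == 75.0

    def test_empty_population_rejected(self):
        res = self._fabricate([("CTC", "exited:outlet_lower")])
        with pytest.raises(ValueError):
            T.separation_efficiency(res, "WBC", "outlet_lower")

    def test_brute_force_equivalence(self, short_run):
        for label in ("WBC", "CTC"):
            for outlet in ("outlet_lower", "outlet_upper"):
                manual = sum(
                    1
                    for s in short_run.states
                    if s.particle.label == label
                    and s.exit_label == outlet
                )
                total = sum(
                    1 for s in short_run.states if s.particle.label == label
                )
                assert T.separation_efficiency(
                    short_run, label, outlet
                ) == pytest.approx(100.0 * manual / total)


class TestSweep:
    def test_single_point_sweep_report(
        self, short_separator_mesh, fluid, default_populations
    ):
        reports = T.rpm_sweep(
            short_separator_mesh, fluid,
            [(p, 3) for p, _ in default_populations],
            [2000.0], seed=2,
            solver_options=dict(tol_rate=0.05, max_steps=8000),
        )
        assert len(reports) == 1
        rep = reports[0]
        assert rep.error is None
        assert rep.ensemble_size == 6
        assert set(rep.efficiency) == {"WBC", "CTC"}
        for eff in rep.efficiency.values():
            assert 0.0 <= eff <= 100.0

    def test_failures_recorded_and_sweep_continues(
        self, short_separator_mesh, fluid, default_populations
    ):
        reports = T.rpm_sweep(
            short_separator_mesh, fluid,
            [(p, 2) for p, _ in default_populations],
            [2000.0], seed=2,
            solver_options=dict(tol_rate=1e-9, max_steps=3),
        )
        assert len(reports) == 1
        assert reports[0].error is not None

    def test_empty_rpm_list_rejected(self, short_separator_mesh, fluid):
        with pytest.raises(ValueError):
            T.rpm_sweep(short_separator_mesh, fluid, [], [], seed=1)
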