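"""Integrator and gradient machinery: oracle values, symmetries, convergence."""

import math

import numpy as np
import pytest

from gfuncsim import (
    BasicGrowthModel,
    BasicGrowthParams,
    CommunityState,
    DrugParams,
    DrugResistanceModel,
    SimulationSpec,
    Trajectory,
    eco_evo_rhs,
    fitness_gradient,
    simulate,
)
from gfuncsim.exceptions import CapabilityError, StructuralError

CTRL = BasicGrowthParams(r=0.25, K_m=100.0, sigma_k2=12.5)


def logistic(t, x0, r, K):
    """Closed-form logistic growth solution (independent oracle)."""
    return K * x0 * np.exp(r * t) / (K + x0 * (np.exp(r * t) - 1.0))


class TestFitnessGradient:
    def test_zero_at_capacity_peak(self, basic_model):
        comm = CommunityState.from_arrays([0.0], [42.0], [0.2])
        assert fitness_gradient(basic_model, comm, 0) == 0.0

    def test_control_value(self, basic_model, control_community):
        # -r u x exp(u^2/(2 sk2)) / (K_m sk2) at (u=3, x=10)
        expected = -0.25 * 3 * 10 * math.exp(9 / 25) / (100 * 12.5)
        got = fitness_gradient(basic_model, control_community, 0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.0086000, abs=5e-8)

    def test_analytic_matches_central_difference(self, basic_model, narrow_competition, drug_model):
        rng = np.random.default_rng(7)
        for model in (basic_model, narrow_competition, drug_model):
            for _ in range(25):
                u = rng.uniform(0.5, 3.0, size=2) * rng.choice([-1, 1], size=2)
                x = rng.uniform(5.0, 95.0, size=2)
                comm = CommunityState.from_arrays(u, x, [0.2, 0.2], t=700.0)
                for i in range(2):
                    a = fitness_gradient(model, comm, i, method="analytic")
                    fd = fitness_gradient(model, comm, i, method="central_difference")
                    assert fd == pytest.approx(a, rel=1e-6, abs=1e-10)

    def test_symmetric_community_has_antisymmetric_gradients(self, narrow_competition):
        comm = CommunityState.from_arrays([2.0, -2.0], [30.0, 30.0], [0.2, 0.2])
        g0 = fitness_gradient(narrow_competition, comm, 0)
        g1 = fitness_gradient(narrow_competition, comm, 1)
        assert g0 == pytest.approx(-g1, rel=1e-12)

    def test_capability_error_without_analytic_form(self, basic_model, control_community):
        class NoGrad(BasicGrowthModel):
            has_analytic_gradient = False

        model = NoGrad(CTRL)
        with pytest.raises(CapabilityError):
            fitness_gradient(model, control_community, 0, method="analytic")
        # fallback route still works
        fd = fitness_gradient(model, control_community, 0, method="central_difference")
        assert fd == pytest.approx(fitness_gradient(basic_model, control_community, 0), rel=1e-6)

    def test_bad_clone_index(self, basic_model, control_community):
        with pytest.raises(StructuralError):
            fitness_gradient(basic_model, control_community, 5)


class TestRhs:
    def test_control_point_values(self, basic_model, control_community):
        dx, du = eco_evo_rhs(basic_model, control_community)
        g = 0.25 * (1 - 10 / (100 * math.exp(-9 / 25)))
        grad = -0.25 * 3 * 10 * math.exp(9 / 25) / (100 * 12.5)
        assert dx[0] == pytest.approx(10 * g, rel=1e-12)         # 2.1417
        assert du[0] == pytest.approx(0.2 * grad, rel=1e-12)     # -0.0017200

    def test_extinct_clone_is_stationary(self, basic_model):
        comm = CommunityState.from_arrays([1.0], [0.0], [0.2])
        dx, _ = eco_evo_rhs(basic_model, comm)
        assert dx[0] == 0.0

    def test_joint_equilibrium(self, basic_model):
        comm = CommunityState.from_arrays([0.0], [100.0], [0.2])
        dx, du = eco_evo_rhs(basic_model, comm)
        assert abs(dx[0]) < 1e-13 and du[0] == 0.0


class TestSimulate:
    def test_control_reaches_capacity_and_optimum(self, basic_model, control_community):
        traj = simulate(basic_model, control_community, SimulationSpec(t_end=5000.0))
        assert traj.x[-1, 0] == pytest.approx(100.0, abs=1e-4)
        assert traj.u[-1, 0] == pytest.approx(0.0, abs=1e-4)
        assert traj.metadata["final_rhs_norm"] < 1e-6

    def test_frozen_strategy_matches_logistic_closed_form(self, basic_model):
        # k=0, v0=0: pure logistic growth; compare to the analytic solution
        init = CommunityState.from_arrays([0.0], [10.0], [0.0])
        spec = SimulationSpec(t_end=40.0, output_times=np.linspace(0, 40, 81))
        traj = simulate(basic_model, init, spec)
        expected = logistic(traj.times, 10.0, 0.25, 100.0)
        np.testing.assert_allclose(traj.x[:, 0], expected, rtol=1e-6)
        assert float(np.interp(10.0, traj.times, traj.x[:, 0])) == pytest.approx(57.512, abs=5e-4)

    def test_mirror_symmetry(self, narrow_competition, two_clone_community):
        spec = SimulationSpec(t_end=200.0, output_times=np.linspace(0, 200, 201))
        fwd = simulate(narrow_competition, two_clone_community, spec)
        neg = CommunityState.from_arrays([-3.0, 3.0], [10.0, 10.0], [0.2, 0.2])
        mir = simulate(narrow_competition, neg, spec)
        np.testing.assert_allclose(mir.u, -fwd.u, atol=1e-9)
        np.testing.assert_allclose(mir.x, fwd.x, atol=1e-7)

    def test_densities_stay_nonnegative_and_bounded(self, basic_model, control_community):
        traj = simulate(basic_model, control_community, SimulationSpec(t_end=1500.0))
        assert np.all(traj.x >= 0)
        assert np.all(traj.x <= 100.0 + 1e-6)  # never exceeds max_v K(v) without a drug

    def test_drug_without_kill_matches_basic(self, basic_model, drug_model, control_community):
        p = DrugResistanceModel(
            DrugParams(base=CTRL, s_m=0.0, u_opt=0.0, sigma_t2=0.8, time_G=600.0)
        )
        spec = SimulationSpec(t_end=1500.0)
        a = simulate(basic_model, control_community, spec)
        b = simulate(p, control_community, spec)
        # the drug run splits at time_G, so the step sequences differ;
        # agreement is to integration accuracy, not bitwise
        np.testing.assert_allclose(a.x, b.x, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(a.u, b.u, rtol=1e-5, atol=1e-7)

    def test_treatment_onset_splits_segments(self, drug_model, control_community):
        traj = simulate(drug_model, control_community, SimulationSpec(t_end=1500.0))
        spans = [s["span"] for s in traj.metadata["segments"]]
        assert len(spans) == 2 and spans[0][1] == 600.0 and spans[1][0] == 600.0

    def test_tolerance_halving_changes_endpoint_negligibly(self, drug_model, control_community):
        base = simulate(drug_model, control_community, SimulationSpec(t_end=1500.0))
        tight = simulate(
            drug_model,
            control_community,
            SimulationSpec(t_end=1500.0, rel_tol=5e-9, abs_tol=5e-11),
        )
        assert abs(base.u[-1, 0] - tight.u[-1, 0]) < 1e-8
        assert abs(base.x[-1, 0] - tight.x[-1, 0]) < 1e-6

    def test_analytic_and_fd_gradient_trajectories_agree(self, basic_model, control_community):
        spec = SimulationSpec(t_end=500.0, output_times=np.linspace(0, 500, 251))
        a = simulate(basic_model, control_community, spec, gradient_method="analytic")
        b = simulate(basic_model, control_community, spec, gradient_method="central_difference")
        np.testing.assert_allclose(a.u, b.u, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(a.x, b.x, rtol=1e-6)

    def test_strategy_bounds_are_respected(self, basic_model):
        init = CommunityState.from_arrays([3.0], [10.0], [0.2])
        spec = SimulationSpec(t_end=500.0, strategy_bounds=(1.5, 5.0))
        traj = simulate(basic_model, init, spec)
        assert np.all(traj.u >= 1.5 - 1e-12) and np.all(traj.u <= 5.0 + 1e-12)
        # pinned at the lower bound, density equilibrates to K(1.5)
        assert traj.u[-1, 0] == pytest.approx(1.5, abs=1e-9)
        assert traj.x[-1, 0] == pytest.approx(100 * math.exp(-1.5**2 / 25), rel=1e-4)

    def test_extinction_threshold_floors_density(self):
        # a clone held above carrying capacity shrinks; with a decaying
        # population the floor triggers and the density is exactly zeroed
        model = BasicGrowthModel(CTRL)
        init = CommunityState.from_arrays([4.0], [5.0], [0.0])
        # strategy far off-peak: K(4) ~ 52.7; start below it so x grows.
        # Instead force decay with x0 above K(4).
        init = CommunityState.from_arrays([4.0], [80.0], [0.0])
        spec = SimulationSpec(t_end=400.0, extinction_threshold=55.0)
        traj = simulate(model, init, spec)
        assert traj.x[-1, 0] == 0.0

    def test_determinism(self, drug_model, control_community):
        spec = SimulationSpec(t_end=800.0)
        a = simulate(drug_model, control_community, spec)
        b = simulate(drug_model, control_community, spec)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.x, b.x)


class TestTrajectorySerialization:
    def test_json_round_trip_is_bit_exact(self, basic_model, control_community):
        traj = simulate(basic_model, control_community, SimulationSpec(t_end=100.0))
        text = traj.to_json()
        back = Trajectory.from_json(text)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.u, traj.u)
        assert np.array_equal(back.x, traj.x)
        assert back.metadata == traj.metadata

    def test_csv_long_format(self, basic_model, control_community, tmp_path):
        import pandas as pd

        traj = simulate(basic_model, control_community, SimulationSpec(t_end=50.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "clone_id", "u", "x"]
        assert len(df) == len(traj.times) * traj.n_clones

    def test_community_interpolation_range_check(self, basic_model, control_community):
        traj = simulate(basic_model, control_community, SimulationSpec(t_end=50.0))
        with pytest.raises(ValueError):
            traj.community_at(60.0)
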