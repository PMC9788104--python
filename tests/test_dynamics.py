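"""Coupled ODE system: term structure, integration, supplementation mechanics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from reefrescue import (
    CoralParams,
    IntegratorSettings,
    InterventionPlan,
    MacroalgaeParams,
    SystemState,
    apply_supplementation_hook,
    attach_nurseries,
    baseline_gradient,
    build_ring_lattice,
    competition_preset,
    coral_fitness,
    fitness_curvature,
    fitness_gradient,
    immigrant_trait,
    integrate_years,
    larval_input,
    macroalgal_fitness,
    selection_attenuation,
    system_rhs,
    verify_regime,
)


@pytest.fixture
def net():
    return build_ring_lattice(20, 4, 0.2)


@pytest.fixture
def base():
    return baseline_gradient(20, 27.0, 3.0)


def make_state(n=20, C=0.25, M=0.1, z=None):
    return SystemState(
        C=np.full(n, float(C)),
        M=np.full(n, float(M)),
        z=np.asarray(z, dtype=float) if z is not None else np.full(n, 27.0),
    )


class TestSystemRhs:
    def test_empty_network_is_absorbing(self, net, base, coral, macroalgae, bistable):
        state = make_state(C=0.0, M=0.0, z=base)
        dC, dM, dz = system_rhs(state, base, net, coral, macroalgae, bistable)
        np.testing.assert_array_equal(dC, 0.0)
        np.testing.assert_array_equal(dM, 0.0)
        np.testing.assert_array_equal(dz, 0.0)

    def test_rhs_matches_term_by_term_assembly(self, net, base, macroalgae, bistable, rng):
        """The fused RHS equals the dynamics assembled from the public operations."""
        cp = CoralParams(V=0.08, beta=0.01)
        state = SystemState(
            C=rng.uniform(1e-5, 0.5, 20),
            M=rng.uniform(0.0, 0.4, 20),
            z=rng.uniform(25.0, 30.0, 20),
        )
        T = base + rng.uniform(-1.0, 2.0, 20)
        dC, dM, dz = system_rhs(state, T, net, cp, macroalgae, bistable)

        l = larval_input(net, state.C, cp.beta)
        zi = immigrant_trait(net, state.C, state.z, cp.beta, l)
        F = np.clip(1.0 - state.C - state.M, 0.0, 1.0)
        gC = coral_fitness(T, state.z, state.C, state.M, cp, bistable)
        curv = fitness_curvature(T, state.z, state.C, state.M, cp, bistable)
        grad = fitness_gradient(T, state.z, state.C, state.M, cp, bistable)
        q = selection_attenuation(state.C, cp.C_min)
        expect_dC = gC * state.C + l * F + 0.5 * cp.V * curv * state.C
        expect_dz = (zi - state.z) * l * F / np.maximum(state.C, cp.C_min) + q * cp.V * grad
        expect_dM = macroalgal_fitness(state.C, state.M, macroalgae, bistable) * state.M

        np.testing.assert_allclose(dC, expect_dC, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(dz, expect_dz, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(dM, expect_dM, rtol=1e-9, atol=1e-12)

    def test_zero_variance_reduces_trait_dynamics_to_gene_flow(
        self, net, base, macroalgae, bistable
    ):
        cp = CoralParams(V=0.0, beta=0.01)
        state = make_state(C=0.3, M=0.1, z=base)
        T = base + 2.0  # strong selection pressure if V > 0
        _, _, dz = system_rhs(state, T, net, cp, macroalgae, bistable)
        l = larval_input(net, state.C, cp.beta)
        zi = immigrant_trait(net, state.C, state.z, cp.beta, l)
        F = 1.0 - state.C - state.M
        np.testing.assert_allclose(
            dz, (zi - state.z) * l * F / np.maximum(state.C, cp.C_min), rtol=1e-9
        )

    def test_isolated_patch_equilibrium_matches_root_finding(self, macroalgae, bistable):
        """Single self-connected patch at T = z: dC/dt = 0 at the root of
        g_C(C) C + beta C (1 - C) = 0 located by an independent bisection."""
        net1 = build_ring_lattice(3, 2, 0.2)  # smallest ring; equal covers
        cp = CoralParams(V=0.0, beta=0.01)
        row_sum = float(net1.D[0].sum())

        def dcdt(c):
            g = coral_fitness(27.0, 27.0, c, 0.0, cp, bistable)
            return g * c + cp.beta * row_sum * c * (1 - c)

        c_star = brentq(dcdt, 0.5, 1.0 - 1e-12)
        state = SystemState(
            C=np.full(3, c_star), M=np.zeros(3), z=np.full(3, 27.0)
        )
        dC, _, _ = system_rhs(
            state, np.full(3, 27.0), net1, cp, macroalgae, bistable
        )
        np.testing.assert_allclose(dC, 0.0, atol=1e-12)


class TestIntegrateYears:
    def test_zero_years_returns_initial_state(self, net, base, coral, macroalgae, bistable):
        state = make_state(z=base)
        traj = integrate_years(
            state, np.empty((0, 20)), 0, net, coral, macroalgae, bistable
        )
        assert len(traj) == 1
        np.testing.assert_array_equal(traj[0].C, state.C)

    def test_stable_equilibrium_persists_without_forcing_noise(
        self, macroalgae, bistable
    ):
        """Starting from the certified coral-dominated equilibrium (adjusted for
        self-recruitment), 100 quiet years leave the state unchanged."""
        cp = CoralParams(V=0.0, beta=0.01)
        report = verify_regime(bistable, cp, macroalgae)
        (c_eq,) = {round(eq[0], 9) for eq in report.stable_equilibria if eq[0] > eq[1]}

        def dcdt(c):
            g = coral_fitness(27.0, 27.0, c, 0.0, cp, bistable)
            return g * c + cp.beta * c * max(0.0, 1 - c)

        c_star = brentq(dcdt, max(c_eq - 0.2, 0.3), 1.0 - 1e-12)
        net = build_ring_lattice(20, 4, 0.2)
        state = SystemState(
            C=np.full(20, c_star), M=np.zeros(20), z=np.full(20, 27.0)
        )
        forcing = np.full((100, 20), 27.0)
        traj = integrate_years(state, forcing, 100, net, cp, macroalgae, bistable)
        np.testing.assert_allclose(traj[-1].C, c_star, atol=1e-6)

    def test_adaptive_solver_matches_fixed_step_reference(
        self, net, base, macroalgae, bistable
    ):
        """LSODA and a fine fixed-step RK4 agree on a decade of warming."""
        cp = CoralParams(V=0.05, beta=0.01)
        state = make_state(C=0.4, M=0.1, z=base)
        forcing = base[None, :] + np.linspace(0.0, 1.5, 10)[:, None]
        lsoda = integrate_years(
            state, forcing, 10, net, cp, macroalgae, bistable,
            settings=IntegratorSettings(method="lsoda"),
        )
        rk4 = integrate_years(
            state, forcing, 10, net, cp, macroalgae, bistable,
            settings=IntegratorSettings(method="rk4", max_step=1e-3),
        )
        np.testing.assert_allclose(lsoda[-1].C, rk4[-1].C, atol=1e-4)
        np.testing.assert_allclose(lsoda[-1].M, rk4[-1].M, atol=1e-4)
        np.testing.assert_allclose(lsoda[-1].z, rk4[-1].z, atol=1e-4)

    def test_cover_bounds_hold_under_strong_forcing(self, net, base, macroalgae, bistable):
        cp = CoralParams(V=0.1, beta=0.01)
        state = make_state(C=0.5, M=0.45, z=base)
        forcing = base[None, :] + np.linspace(0, 4, 60)[:, None]
        traj = integrate_years(state, forcing, 60, net, cp, macroalgae, bistable)
        for s in traj:
            assert np.all(s.C >= 0) and np.all(s.M >= 0)
            assert np.all(s.C + s.M <= 1 + 1e-8)

    def test_trait_confined_to_initial_hull_without_selection(
        self, net, base, macroalgae, bistable
    ):
        cp = CoralParams(V=0.0, beta=0.01)
        state = make_state(C=0.3, M=0.1, z=base)
        forcing = base[None, :] + np.linspace(0, 3, 80)[:, None]
        traj = integrate_years(state, forcing, 80, net, cp, macroalgae, bistable)
        lo, hi = base.min(), base.max()
        for s in traj:
            assert np.all(s.z >= lo - 1e-9) and np.all(s.z <= hi + 1e-9)


class TestSupplementationHook:
    def test_nursery_cover_set_from_rate_and_beta(self, net, base):
        netn = attach_nurseries(net, [16, 17, 18, 19])
        plan = InterventionPlan(strategy="hot", rate=1e-4, delta_Z=2.0, duration=100)
        state = SystemState(
            C=np.full(20, 0.3), M=np.zeros(20), z=base.copy(),
            nursery_C=np.zeros(4), nursery_z=np.zeros(4),
        )
        out = apply_supplementation_hook(state, plan, year=0, net=netn, beta=0.01)
        np.testing.assert_allclose(out.nursery_C, 1e-4 / 0.01)  # C_s = 0.01
        np.testing.assert_allclose(out.nursery_z, base[[16, 17, 18, 19]] + 2.0)

    def test_zero_enhancement_tracks_target_trait(self, net, base):
        netn = attach_nurseries(net, [5])
        plan = InterventionPlan(strategy="cold", rate=1e-5, delta_Z=0.0, duration=50)
        state = SystemState(
            C=np.full(20, 0.3), M=np.zeros(20), z=base.copy(),
            nursery_C=np.zeros(1), nursery_z=np.zeros(1),
        )
        out = apply_supplementation_hook(state, plan, year=10, net=netn, beta=0.01)
        assert out.nursery_z[0] == base[5]

    def test_expired_plan_zeroes_nursery_cover(self, net, base):
        netn = attach_nurseries(net, [5])
        plan = InterventionPlan(strategy="cold", rate=1e-5, delta_Z=1.0, duration=50)
        state = SystemState(
            C=np.full(20, 0.3), M=np.zeros(20), z=base.copy(),
            nursery_C=np.full(1, 1e-3), nursery_z=np.zeros(1),
        )
        out = apply_supplementation_hook(state, plan, year=50, net=netn, beta=0.01)
        assert out.nursery_C[0] == 0.0

    def test_full_reef_receives_no_settlement(self, base, macroalgae, bistable):
        """Free-space gating: a fully occupied target gains no supplementation."""
        net = attach_nurseries(build_ring_lattice(20, 4, 0.2), [7])
        cp = CoralParams(V=0.0, beta=0.01)
        C = np.zeros(20)
        C[7] = 0.6
        M = np.zeros(20)
        M[7] = 0.4  # C + M = 1 at the target
        state = SystemState(
            C=C, M=M, z=base.copy(),
            nursery_C=np.full(1, 0.01), nursery_z=np.array([base[7] + 3.0]),
        )
        dC, _, dz = system_rhs(state, base, net, cp, macroalgae, bistable)
        l7 = 0.01 * (0.2 * C[[5, 6, 7, 8, 9]].sum() + 1.0 * 0.01)
        assert l7 > 0  # larvae do arrive...
        assert dC[7] == pytest.approx(
            coral_fitness(base[7], base[7], 0.6, 0.4, cp, bistable) * 0.6
        )  # ...but none settle, and gene flow exerts no pull
        assert dz[7] == 0.0
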