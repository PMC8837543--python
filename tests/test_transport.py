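"""Method-of-lines solver: grid, stencils vs analytic/brute-force oracles,
conservation audits, coupled-run invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thrombolyze.fixtures import integrate_tracer, make_minimal_clot, make_tracer_problem
from thrombolyze.kinetics import IB, IM
from thrombolyze.parameters import get_scenario
from thrombolyze.systemic import solve_systemic
from thrombolyze.transport import (
    CoupledSolver,
    apply_initial_conditions,
    bound_rhs,
    boundary_fluxes,
    build_grid,
    mobile_transport_rhs,
    platelet_transport_rhs,
    run_simulation,
    species_rhs,
)


class TestGrid:
    def test_default_spacing_gives_301_nodes_for_distal_clot(self, params):
        grid = build_grid(get_scenario("S1"), 2.0e-5)
        assert grid.n == 301
        assert grid.clot_start == 100
        assert grid.clot_end == 300

    def test_proximal_clot_starts_at_node_zero(self):
        grid = build_grid(get_scenario("S3"), 2.0e-5)
        assert grid.clot_start == 0

    def test_misaligned_spacing_snaps_with_warning(self):
        with pytest.warns(UserWarning, match="snap"):
            grid = build_grid(get_scenario("S3"), 3.1e-5)
        assert grid.x[-1] == pytest.approx(4.0e-3)

    def test_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            build_grid(get_scenario("S3"), 0.0)


class TestInitialConditions:
    def test_baseline_plasma_everywhere(self, params):
        scen = get_scenario("S1")
        grid = build_grid(scen, 1e-4)
        state = apply_initial_conditions(grid, scen, params)
        assert np.allclose(state.mobile[IM["PLG"]], params.baseline("PLG"))
        assert np.allclose(state.mobile[IM["tPA"]], params.baseline("tPA"))

    def test_platelets_and_sites_confined_to_clot(self, params):
        scen = get_scenario("S1")
        grid = build_grid(scen, 1e-4)
        state = apply_initial_conditions(grid, scen, params)
        span = grid.clot_slice
        assert np.allclose(state.platelets[0][span], params.c_plt0(scen.phi_plt0))
        assert np.all(state.platelets[0][: grid.clot_start] == 0)
        assert np.allclose(state.bound[IB["n_FBR"]][span], params.n_fbr0(scen.phi_fbr0))
        # vesicle-bound platelets and bound drug species start at zero
        assert np.all(state.platelets[1:] == 0)
        assert np.all(state.bound[:4] == 0)


class TestTransportStencils:
    def test_null_transport_null_derivative(self):
        n = 20
        c = np.full((1, n), 0.7)
        out = mobile_transport_rhs(c, np.zeros(n), np.array([0.0]), 1e-5,
                                   np.array([0.7]), 0.01)
        assert np.allclose(out, 0.0)

    def test_brute_force_assembly_oracle(self, rng):
        """On a 10-node toy the vectorised stencils match an independently
        written loop assembly to machine precision."""
        n, dx, tau = 10, 2e-5, 0.02
        c = rng.uniform(0, 1, (3, n))
        u = rng.uniform(0, 1e-4, n)
        d = np.array([1e-10, 5e-11, 0.0])
        inlet = rng.uniform(0, 1, 3)
        out = mobile_transport_rhs(c, u, d, dx, inlet, tau)
        ref = np.zeros_like(c)
        for j in range(3):
            ref[j, 0] = (inlet[j] - c[j, 0]) / tau
            for i in range(1, n):
                adv = -(u[i] * c[j, i] - u[i - 1] * c[j, i - 1]) / dx
                if i < n - 1:
                    lap = (c[j, i + 1] - 2 * c[j, i] + c[j, i - 1]) / dx**2
                else:
                    lap = (c[j, i - 1] - c[j, i]) / dx**2
                ref[j, i] = adv + d[j] * lap
        assert np.allclose(out, ref, rtol=1e-13, atol=1e-16)

        mob = rng.uniform(0, 1, n)
        p = rng.uniform(0, 1, (2, n))
        out_p = platelet_transport_rhs(p, u, mob, 1e-12, dx)
        ref_p = np.zeros_like(p)
        for j in range(2):
            for i in range(n):
                up = u[i - 1] * p[j, i - 1] if i > 0 else 0.0
                adv = -(u[i] * p[j, i] - up) / dx
                if i == 0:
                    lap = (p[j, 1] - p[j, 0]) / dx**2
                elif i < n - 1:
                    lap = (p[j, i + 1] - 2 * p[j, i] + p[j, i - 1]) / dx**2
                else:
                    lap = (p[j, i - 1] - p[j, i]) / dx**2
                ref_p[j, i] = mob[i] * (adv + 1e-12 * lap)
        assert np.allclose(out_p, ref_p, rtol=1e-13, atol=1e-16)

    def test_advected_step_moves_at_u(self):
        prob = make_tracer_problem("advection-step")
        t_end = 8.0
        c = integrate_tracer(prob, t_end)
        # front position = first crossing of C = 0.5 (upwind smears the jump
        # symmetrically, so the half-height point tracks the exact front)
        front = np.interp(0.5, c[::-1], prob.x[::-1])
        exact = prob.x[len(prob.x) // 4] + prob.u * t_end
        assert front == pytest.approx(exact, abs=2 * prob.dx)

    def test_gaussian_variance_grows_as_2dt(self):
        prob = make_tracer_problem("diffusion-gaussian")
        t_end = 100.0
        c = integrate_tracer(prob, t_end)
        mass = np.trapezoid(c, prob.x)
        mean = np.trapezoid(prob.x * c, prob.x) / mass
        var = np.trapezoid((prob.x - mean) ** 2 * c, prob.x) / mass
        sigma0 = 1.0e-4
        assert var == pytest.approx(sigma0**2 + 2 * prob.d * t_end, rel=0.01)

    def test_advection_diffusion_erfc_profile(self):
        """The smoothed-step solution: the half-height point of the computed
        profile tracks the analytic erfc front, and the plateaus match; the
        front itself is wider by the scheme's numerical diffusion u·dx/2."""
        prob = make_tracer_problem("advection-diffusion")
        t_end = 6.0
        c = integrate_tracer(prob, t_end)
        exact = prob.solution(t_end)
        front = np.interp(0.5, c[::-1], prob.x[::-1])
        front_exact = np.interp(0.5, exact[::-1], prob.x[::-1])
        assert front == pytest.approx(front_exact, abs=1.5 * prob.dx)
        far = np.abs(prob.x - front_exact) > 20 * prob.dx
        assert np.abs(c - exact)[far].max() < prob.tolerance

    def test_tracer_mass_balance_against_boundary_fluxes(self):
        """Interior tracer mass change equals the net discrete boundary flux
        to < 0.1% per reporting interval."""
        prob = make_tracer_problem("advection-diffusion")
        n = len(prob.x)
        u = np.full(n, prob.u)
        d = np.array([prob.d])

        def rhs(t, y):
            return mobile_transport_rhs(
                y[None, :], u, d, prob.dx, np.array([prob.inlet]), 1e-3
            ).ravel()

        y = prob.c0.copy()
        t = 0.0
        for _ in range(5):
            sol = solve_ivp(rhs, (t, t + 4.0), y, method="LSODA",
                            rtol=1e-10, atol=1e-14, dense_output=True)
            y_new = sol.y[:, -1]
            ts = np.linspace(t, t + 4.0, 81)
            flux_net = np.array([
                boundary_fluxes(sol.sol(tt)[None, :], u, d, prob.dx)
                for tt in ts
            ])
            net = np.trapezoid(flux_net[:, 0, 0] - flux_net[:, 1, 0], ts)
            dm = (y_new[1:].sum() - y[1:].sum()) * prob.dx
            assert dm == pytest.approx(net, rel=1e-3, abs=1e-12)
            y, t = y_new, t + 4.0


class TestCoupledRunInvariants:
    def test_toy_recanalises_and_covers_all_fields(self, toy_run):
        scen, p, res = toy_run
        assert res.recanalised
        assert res.recanalisation_time is not None and res.recanalisation_time > 0
        active = [i for i in range(18) if np.any(res.snapshots[:, :, i] > 0)]
        assert len(active) == 18  # every kinetic pathway produced material

    def test_lysis_extent_monotone_in_time(self, toy_run):
        _, _, res = toy_run
        assert np.all(np.diff(res.e_l_min) >= -1e-9)
        assert np.all(np.diff(res.e_l_max) >= -1e-9)

    def test_flowrate_nondecreasing_during_lysis(self, toy_run):
        """While the occlusion spans its full initial length, resistance can
        only fall, so the Darcy flowrate can only rise.  (Once the remaining
        length shrinks, the driving head ΔP_x·L_rem shrinks with it, and the
        flowrate law permits small dips.)"""
        _, _, res = toy_run
        full = res.l_rem >= res.l_rem[0] * (1 - 1e-12)
        q_full = res.q[full.nonzero()[0]]
        assert np.all(np.diff(q_full) >= -1e-18)
        assert res.q.max() > res.q[0]  # lysis did accelerate the flow

    def test_platelets_retained_while_occlusive(self, toy_run):
        """Total platelet content of the clot is constant (< 1% drift) until
        the occlusion is dissolved — platelets only leave after breakthrough."""
        _, p, res = toy_run
        plt_tot = res.snapshots[:, :, 10].sum(axis=1)
        pre = res.snapshot_times < res.recanalisation_time
        assert np.all(np.abs(plt_tot[pre] / plt_tot[0] - 1.0) < 0.01)

    def test_bound_species_never_appear_outside_clot(self, params):
        scen, p = make_minimal_clot()
        scen = scen.model_copy(update={"d_clot": 1.0e-4, "l_clot": 1.0e-4})
        res = run_simulation(scen, p, t_max=10.0)
        outside = slice(0, res.grid.clot_start)
        for k in range(13, 18):
            assert np.all(res.snapshots[:, outside, k] == 0.0)

    def test_immediate_recanalisation_without_fibrin(self):
        scen, p = make_minimal_clot(phi_fbr=0.0)
        res = run_simulation(scen, p, t_max=5.0)
        assert res.recanalised
        assert res.recanalisation_time == 0.0

    def test_nv_pathway_inert_without_platelets(self):
        scen, p = make_minimal_clot(phi_plt=0.0)
        res = run_simulation(scen, p, t_max=20.0)
        assert np.all(res.snapshots[:, :, 11] == 0.0)  # no vesicle ever binds
        assert res.e_l_max[-1] > 0.0  # leakage tPA still lyses fibrin

    def test_grid_convergence_of_recanalisation_time(self):
        scen1, p1 = make_minimal_clot(n_nodes=11)
        scen2, p2 = make_minimal_clot(n_nodes=21)
        t1 = run_simulation(scen1, p1).recanalisation_time
        t2 = run_simulation(scen2, p2).recanalisation_time
        assert abs(t2 - t1) / t1 < 0.05

    def test_hemodynamic_refresh_cadence_converges(self):
        """The quasi-static flow refresh converges first-order in cadence;
        at cadences well below the run duration the result is insensitive.
        (The production cadence/duration ratio is ~10× smaller again.)"""
        scen, p = make_minimal_clot()
        t1 = run_simulation(scen, p, dt_report=0.25).recanalisation_time
        t2 = run_simulation(scen, p, dt_report=0.125).recanalisation_time
        assert abs(t2 - t1) / t1 < 0.01

    def test_one_way_coupling_systemic_series_unaffected_by_clot(self, params):
        """Perturbing clot parameters leaves the systemic solution
        bit-identical (the coupling is strictly one-way)."""
        reg = get_scenario("S13").regimen
        sol_a = solve_systemic(params, reg, 120.0, drug="tPA")
        perturbed = params.model_copy(update={
            "hemodynamics": params.hemodynamics.model_copy(update={"n_fbr_0": 3.0})
        })
        sol_b = solve_systemic(perturbed, reg, 120.0, drug="tPA")
        assert np.array_equal(sol_a.values, sol_b.values)

    def test_spec_rhs_views_consistent(self, toy_run):
        scen, p, _ = toy_run
        from thrombolyze.transport import _constant_inlet

        solver = CoupledSolver(scen, p, _constant_inlet(scen, p))
        full = solver.rhs(0.0, solver.state.arr.ravel()).reshape(-1, 18)
        assert np.allclose(species_rhs(solver).T, full[:, :10])
        assert np.allclose(bound_rhs(solver).T, full[:, 13:])
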