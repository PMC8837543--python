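"""Reaction network: stoichiometry, conservation, positivity, gating laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from thrombolyze.kinetics import (
    IB,
    IM,
    IP,
    StateError,
    bound_phase_rates,
    extent_of_lysis,
    extent_of_platelets,
    mobility,
    nv_platelet_rates,
    plasma_reaction_rates,
    platelet_bookkeeping,
)

N_M, N_B, N_P = 10, 5, 3

conc_arrays = st.lists(st.floats(0.0, 10.0), min_size=N_M, max_size=N_M).map(np.array)


def _state(rng, scale=1.0):
    c = rng.uniform(0, 2, N_M) * scale
    b = rng.uniform(0, 0.2, N_B)
    b[IB["n_FBR"]] = b[:3].sum() + rng.uniform(0.1, 1.0)  # site balance holds
    plt = np.array([1e-5, 1e-6, 1e-6])
    return c, b, plt


class TestPlasmaPhase:
    def test_null_state_null_rates(self, params):
        r = plasma_reaction_rates(np.zeros(N_M), params)
        assert np.all(r == 0.0)

    def test_leakage_stoichiometry(self, params):
        c = np.zeros(N_M)
        c[IM["NV"]] = 0.5
        r = plasma_reaction_rates(c, params)
        k = params.kinetics
        assert r[IM["tPA"]] == pytest.approx(k.v_rel * k.k_leak * 0.5)
        assert r[IM["NV"]] == pytest.approx(-k.k_leak * 0.5)
        assert r[IM["NVemp"]] == pytest.approx(k.k_leak * 0.5)

    @given(c=conc_arrays)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_antiplasmin_stoichiometry_audit(self, c):
        """AP consumption, AP-PLS production and the AP term of the PLS rate
        are one and the same flux, for any state."""
        p = default_params()
        r = plasma_reaction_rates(c, p)
        k = p.kinetics
        ap_flux = k.k_ap * c[IM["PLS"]] * c[IM["AP"]]
        assert r[IM["AP_PLS"]] == pytest.approx(-r[IM["AP"]], rel=1e-12, abs=1e-300)
        assert r[IM["AP"]] == pytest.approx(-ap_flux, rel=1e-12, abs=1e-300)

    @given(c=conc_arrays)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_no_rate_pushes_empty_pool_negative(self, c):
        p = default_params()
        r = plasma_reaction_rates(c, p)
        assert np.all(r[c == 0.0] >= -1e-15)

    def test_negative_input_rejected(self, params):
        c = np.zeros(N_M)
        c[IM["PLG"]] = -0.1
        with pytest.raises(ValueError):
            plasma_reaction_rates(c, params)


def default_params():
    from thrombolyze import default_parameters

    return default_parameters()


class TestBoundPhase:
    def test_no_sites_no_adsorption_but_desorption(self, params):
        c = np.zeros(N_M)
        c[IM["tPA"]] = 1.0
        b = np.zeros(N_B)  # n_FBR = 0
        rb, feedback, r_deg = bound_phase_rates(c, b, params)
        assert np.all(rb == 0.0) and np.all(feedback == 0.0)
        # existing bound material still desorbs when plasma is empty
        b2 = np.zeros(N_B)
        b2[IB["tPA_F"]] = 0.3
        b2[IB["n_FBR"]] = 0.3
        rb2, fb2, _ = bound_phase_rates(np.zeros(N_M), b2, params)
        k = params.kinetics
        assert rb2[IB["tPA_F"]] == pytest.approx(-k.k_off_tpa * 0.3)
        assert fb2[IM["tPA"]] == pytest.approx(k.k_off_tpa * 0.3)

    def test_site_balance_violation_raises(self, params):
        b = np.zeros(N_B)
        b[IB["tPA_F"]] = 1.0
        b[IB["n_FBR"]] = 0.5  # occupied > intact sites
        with pytest.raises(StateError):
            bound_phase_rates(np.zeros(N_M), b, params)

    def test_degradation_needs_fibrin_bound_plasmin(self, params, rng):
        """r_deg vanishes whenever no plasmin is associated with the fibrin
        (neither on intact sites nor on lysed fragments)."""
        for _ in range(10):
            c, b, _ = _state(rng)
            b[IB["PLS_F"]] = 0.0
            b[IB["PLS_F_lysed"]] = 0.0
            _, _, r_deg = bound_phase_rates(c, b, params)
            assert r_deg == pytest.approx(0.0, abs=1e-300)

    def test_sites_only_decrease(self, params, rng):
        for _ in range(10):
            c, b, _ = _state(rng)
            rb, _, _ = bound_phase_rates(c, b, params)
            assert rb[IB["n_FBR"]] <= 0.0


class TestConservationUnderKineticsOnly:
    """Quadrature audit: with transport and clearance off, conserved protein
    pools are flat over a 600 s stiff integration.

    Pools follow the network's routing: displaced tPA/PLG leave with the
    degradation products (tracked by quadrature, like the MG-inactivated
    plasmin pool and the PAI-neutralised tPA pool).
    """

    def _rhs(self, t, y, p):
        c, b, plt = y[:N_M], y[N_M : N_M + N_B], y[N_M + N_B : N_M + N_B + N_P]
        c, b, plt = np.maximum(c, 0), np.maximum(b, 0), np.maximum(plt, 0)
        k = p.kinetics
        r_c = plasma_reaction_rates(c, p, check=False)
        rb, fb, r_deg = bound_phase_rates(c, b, p, check=False)
        r_nv, r_plt = nv_platelet_rates(c, plt, p, check=False)
        inv = 1.0 / max(b[IB["n_FBR"]], 1e-30)
        aux = np.array(
            [
                k.k_mg * c[IM["PLS"]] * c[IM["MG"]],  # MG-inactivated plasmin
                k.k_pai * c[IM["tPA"]] * c[IM["PAI"]],  # PAI-neutralised tPA
                r_deg * b[IB["tPA_F"]] * inv,  # tPA leaving with FDPs
                r_deg * b[IB["PLG_F"]] * inv,  # PLG leaving with FDPs
            ]
        )
        return np.concatenate([r_c + fb + r_nv, rb, r_plt, aux])

    def _pools(self, y, p):
        c, b, plt = y[:N_M], y[N_M : N_M + N_B], y[N_M + N_B : N_M + N_B + N_P]
        mg_pool, pai_pool, fdp_tpa, fdp_plg = y[N_M + N_B + N_P :]
        v = p.kinetics.v_rel
        tpa = (
            c[IM["tPA"]] + b[IB["tPA_F"]] + pai_pool + fdp_tpa
            + v * (c[IM["NV"]] + plt[IP["PLT_NV"]])
        )
        plg_pls = (
            c[IM["PLG"]] + c[IM["PLS"]] + c[IM["AP_PLS"]]
            + b[IB["PLG_F"]] + b[IB["PLS_F"]] + b[IB["PLS_F_lysed"]]
            + mg_pool + fdp_plg
        )
        nv = c[IM["NV"]] + c[IM["NVemp"]] + plt[IP["PLT_NV"]] + plt[IP["PLT_NVemp"]]
        return tpa, plg_pls, nv

    def test_pools_flat_over_600s(self, params):
        c0 = np.array([0.02, 2.2, 0.01, 1.0, 0.0, 8.0, 3.0, 4e-4, 3.5e-4, 1e-5])
        b0 = np.array([0.05, 0.1, 0.02, 0.01, 1.7])
        plt0 = np.array([5.5e-6, 1e-6, 1e-7])
        y0 = np.concatenate([c0, b0, plt0, np.zeros(4)])
        start = self._pools(y0, params)
        sol = solve_ivp(
            self._rhs, (0, 600.0), y0, args=(params,), method="LSODA",
            rtol=1e-10, atol=1e-14,
        )
        assert sol.success
        end = self._pools(sol.y[:, -1], params)
        for a, b_ in zip(start, end):
            assert b_ == pytest.approx(a, rel=1e-6)


class TestNanovesiclePlateletPathway:
    def test_no_platelets_no_binding_or_release(self, params):
        c = np.zeros(N_M)
        c[IM["NV"]] = 1.0
        r_m, r_p = nv_platelet_rates(c, np.zeros(N_P), params)
        assert np.all(r_m == 0.0) and np.all(r_p == 0.0)

    def test_binding_linear_in_free_platelets(self, params):
        c = np.zeros(N_M)
        c[IM["NV"]] = 1.0e-3
        plt1 = np.array([1e-5, 0.0, 0.0])
        plt2 = np.array([2e-5, 0.0, 0.0])
        _, r1 = nv_platelet_rates(c, plt1, params)
        _, r2 = nv_platelet_rates(c, plt2, params)
        assert r2[IP["PLT_NV"]] == pytest.approx(2 * r1[IP["PLT_NV"]], rel=1e-12)

    def test_release_only_state(self, params):
        c = np.zeros(N_M)
        plt = np.array([1e-5, 2e-6, 0.0])
        r_m, r_p = nv_platelet_rates(c, plt, params)
        k = params.kinetics
        c_free, _ = platelet_bookkeeping(plt, params)
        rate = k.k_trig_base + k.k_trig * min((c_free / k.c_plt_ref) ** (k.hill_release - 1), 1.0)
        expected = k.v_rel * rate * plt[IP["PLT_NV"]]
        assert r_m[IM["tPA"]] == pytest.approx(expected, rel=1e-12)

    @given(
        nv=st.floats(0, 1e-2), plt_tot=st.floats(0, 1e-4),
        plt_nv=st.floats(0, 1e-5), plt_nvemp=st.floats(0, 1e-5),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_vesicle_pool_conserved_algebraically(self, nv, plt_tot, plt_nv, plt_nvemp):
        """Binding/unbinding/release only shuffles vesicles between the four
        NV pools; the net rate of their sum is identically zero."""
        p = default_params()
        c = np.zeros(N_M)
        c[IM["NV"]] = nv
        plt = np.array([plt_tot, plt_nv, plt_nvemp])
        r_m, r_p = nv_platelet_rates(c, plt, p)
        total = r_m[IM["NV"]] + r_m[IM["NVemp"]] + r_p[IP["PLT_NV"]] + r_p[IP["PLT_NVemp"]]
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_site_exclusion_limits_binding(self, params):
        n_int = params.hemodynamics.n_int
        plt_tot = 1e-5
        # all integrin sites occupied by bound vesicles -> no free sites
        plt = np.array([plt_tot, n_int * plt_tot / 2, n_int * plt_tot / 2])
        c_free, c_int_free = platelet_bookkeeping(plt, params)
        assert c_free == 0.0 and c_int_free == 0.0


class TestLysisExtentAndMobility:
    @pytest.mark.parametrize("n, expected", [(1.7, 0.0), (0.0, 1.0), (0.425, 0.75)])
    def test_extent_of_lysis_linear(self, n, expected):
        assert extent_of_lysis(n, 1.7) == pytest.approx(expected)

    def test_extent_domain_error(self):
        with pytest.raises(ValueError):
            extent_of_lysis(0.5, 0.0)

    def test_mobility_branches(self):
        assert mobility(0.99, 10.0, 0.95) == 1.0  # above critical extent
        assert mobility(0.95, 10.0, 0.95) == pytest.approx(1.0)  # continuity
        assert mobility(0.0, 10.0, 0.95) == pytest.approx(1 - np.tanh(10.0), rel=1e-9)
        assert mobility(0.0, 10.0, 0.95) == pytest.approx(4.1e-9, rel=0.02)

    @given(
        e1=st.floats(0, 1), e2=st.floats(0, 1),
        m=st.floats(1, 20), crit=st.floats(0.5, 0.99),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_mobility_monotone_and_bounded(self, e1, e2, m, crit):
        lo, hi = sorted([e1, e2])
        m_lo, m_hi = mobility(lo, m, crit), mobility(hi, m, crit)
        assert m_lo <= m_hi + 1e-12
        assert 1 - np.tanh(m) - 1e-12 <= m_lo <= 1.0 + 1e-12

    @pytest.mark.parametrize("c, expected", [(5.0, 1.0), (0.0, 0.0), (2.5, 0.5)])
    def test_extent_of_platelets(self, c, expected):
        assert extent_of_platelets(c, 5.0) == pytest.approx(expected)

    def test_extent_of_platelets_domain_error(self):
        with pytest.raises(ValueError):
            extent_of_platelets(1.0, 0.0)
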