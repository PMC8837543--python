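"""Deterministic toy inputs and oracle problems for solver verification.

Tracer problems carry closed-form solutions (translating step, spreading
Gaussian, advected error-function profile) against which the semi-
discrete transport operator is verified.  The minimal clot is a tiny,
fast end-to-end problem with round-number constants — deliberately not
the physiological values — that exercises every kinetic pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erfc

from .parameters import (
    HemodynamicsParams,
    KineticsParams,
    ParameterSet,
    PKParams,
    Scenario,
    SolverParams,
    SpeciesParams,
)
from .transport import mobile_transport_rhs

__all__ = ["ToyProblem", "make_tracer_problem", "integrate_tracer", "make_minimal_clot"]


@dataclass
class ToyProblem:
    """A 1D tracer problem with a known closed-form solution."""

    kind: str
    x: np.ndarray  # node coordinates, m
    dx: float
    u: float  # uniform velocity, m/s
    d: float  # diffusivity, m²/s
    c0: np.ndarray  # initial profile
    inlet: float  # Dirichlet inlet value
    solution: Callable[[float], np.ndarray]  # analytic C(x, t)
    tolerance: float


def make_tracer_problem(kind: str, n: int = 101, length: float = 2.0e-3) -> ToyProblem:
    """Build one of the closed-form tracer problems.

    kinds: ``advection-step`` (translating front), ``diffusion-gaussian``
    (variance grows as 2Dt), ``advection-diffusion`` (erfc profile).
    """
    x = np.linspace(0.0, length, n)
    dx = x[1] - x[0]
    if kind == "diffusion-gaussian":
        d, u = 1.0e-10, 0.0
        x0, sigma0 = length / 2.0, 1.0e-4

        def solution(t: float) -> np.ndarray:
            var = sigma0**2 + 2.0 * d * t
            return sigma0 / np.sqrt(var) * np.exp(-((x - x0) ** 2) / (2.0 * var))

        return ToyProblem(kind, x, dx, u, d, solution(0.0), 0.0, solution, 0.01)
    if kind == "advection-step":
        u, d = 1.0e-4, 0.0
        x0 = length / 4.0

        def solution(t: float) -> np.ndarray:
            return np.where(x <= x0 + u * t, 1.0, 0.0)

        return ToyProblem(kind, x, dx, u, d, solution(0.0), 1.0, solution, 0.01)
    if kind == "advection-diffusion":
        u, d = 1.0e-4, 1.0e-10
        x0 = length / 4.0

        def solution(t: float) -> np.ndarray:
            if t == 0.0:
                return np.where(x <= x0, 1.0, 0.0)
            return 0.5 * erfc((x - x0 - u * t) / np.sqrt(4.0 * d * t))

        return ToyProblem(kind, x, dx, u, d, solution(0.0), 1.0, solution, 0.02)
    raise ValueError(f"unknown tracer problem kind {kind!r}")


def integrate_tracer(
    problem: ToyProblem,
    t_end: float,
    *,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-12,
    tau_bc: float = 1.0e-3,
) -> np.ndarray:
    """Integrate a tracer problem with the production transport stencil."""
    n = len(problem.x)
    u_node = np.full(n, problem.u)
    d_coef = np.array([problem.d])

    def rhs(t, y):
        return mobile_transport_rhs(
            y[None, :], u_node, d_coef, problem.dx, np.array([problem.inlet]), tau_bc
        ).ravel()

    sol = solve_ivp(rhs, (0.0, t_end), problem.c0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"tracer integration failed: {sol.message}")
    return sol.y[:, -1]


def make_minimal_clot(
    n_nodes: int = 11,
    phi_fbr: float = 0.05,
    phi_plt: float = 0.05,
    drug: str = "NV",
) -> tuple[Scenario, ParameterSet]:
    """A tiny end-to-end problem (sub-second run) with round-number
    constants exercising every kinetic pathway.

    ``phi_plt = 0`` degenerates to the pure-fibrin model (NV pathway
    inert except passive leakage); ``phi_fbr = 0`` leaves nothing to lyse
    and recanalises immediately.
    """
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    length = 2.0e-4  # 0.2 mm clot occupying the whole domain
    scen = Scenario(
        name="toy",
        description="minimal clot fixture",
        d_clot=0.0,
        l_clot=length,
        phi_fbr0=phi_fbr,
        phi_plt0=phi_plt,
        drug=drug,
        inlet_mode="constant",
    )
    p = ParameterSet(
        species=SpeciesParams(
            d_tpa=1.0e-10, d_plg=1.0e-10, d_pls=1.0e-10, d_ap=1.0e-10,
            d_ap_pls=1.0e-10, d_fbg=1.0e-10, d_mg=1.0e-10, d_pai=1.0e-10,
            d_nv=1.0e-11, d_nvemp=1.0e-11, d_plt=1.0e-12,
            mw_tpa=5.0e4, mw_fbg=3.0e5,
        ),
        kinetics=KineticsParams(
            k_cat_plg_plasma=0.1, km_plg_plasma=10.0,
            k_ap=1.0, k_mg=0.1, k_pai=1.0,
            k_cat_fbg=0.1, km_fbg=10.0,
            k_leak=1.0e-3,
            k_on_nv=1.0, k_off_nv=0.01, k_off_nvemp=0.01, k_trig=1.0,
            k_on_tpa=0.1, k_off_tpa=0.1, k_on_plg=0.1, k_off_plg=0.1,
            k_on_pls=0.1, k_off_pls=0.1,
            k_cat_plg_bound=5.0, km_plg_bound=1.0,
            k_deg=5.0, k_deg_sat=0.05, k_rel_lysed=0.1,
            v_rel=10.0,
        ),
        hemodynamics=HemodynamicsParams(
            mu=1.0e-3, dpdx=1.0e4, area=1.0e-6, r_f=1.0e-6, r_p=1.0e-6,
            platelet_volume=1.0e-17, n_int=1.0e4, n_fbr_0=5.0,
            m_mobility=10.0, e_l_crit=0.95,
        ),
        pk=PKParams(
            v_c=1.0, body_weight=70.0, inlet_tpa=0.1,
            t_half_tpa=240.0, t_half_nv=6000.0, t_half_plg=1.0e5,
            t_half_pls=1.0e4, t_half_ap=1.0e5, t_half_ap_pls=1.0e4,
            t_half_fbg=1.0e5, t_half_mg=1.0e5, t_half_pai=1.0e3,
            c0_tpa=0.0, c0_plg=2.0, c0_pls=0.0, c0_ap=1.0, c0_ap_pls=0.0,
            c0_fbg=10.0, c0_mg=1.0, c0_pai=1.0e-3,
        ),
        solver=SolverParams(
            dx=length / (n_nodes - 1), dt_report=1.0, rtol=1.0e-6, atol=1.0e-10,
            t_max=120.0, u_max=0.1, snapshot_interval=10.0, bc_relax_tau=0.01,
        ),
    )
    return scen, p
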