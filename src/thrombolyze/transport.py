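"""Method-of-lines solver for the coupled 1D transport–reaction system.

The occluded artery is a uniform 1D grid from the inlet (x = 0) to the
distal clot end (x = d_clot + L_clot).  Eighteen fields live on it: ten
mobile plasma species (advected with the permeation velocity and
diffusing), three platelet fields (same operators scaled by the
lysis-gated mobility coefficient), four fibrin-bound species and the
intact binding-site field (purely local ODEs).

Discretisation: conservative first-order upwind advection (the permeation
velocity is uniformly non-negative), second-order central diffusion,
Dirichlet inlet for plasma species (imposed by fast relaxation), zero-
gradient outlet, zero platelet influx at the inlet.  For nanovesicle runs
a zero-gradient condition on plasma tPA is imposed at the clot front by
mirroring the upstream ghost value, which keeps the profile smooth under
triggered release.

Time integration is stiff adaptive (LSODA with a banded Jacobian,
bandwidth 18).  The hemodynamics (flowrate, velocity, porosity, mobility)
are quasi-static: refreshed once per reporting interval rather than
inside the integrator, which is accurate because the velocity evolves on
the lysis timescale, orders of magnitude slower than the chemistry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.integrate import ode

from . import kinetics as kin
from .hemodynamics import EPS_OPEN, ClotState, darcy_velocity, flowrate, update_clot_geometry
from .kinetics import IB, IM, IP, mobility
from .parameters import (
    ALL_FIELDS,
    BOUND_SPECIES,
    MOBILE_SPECIES,
    PLATELET_SPECIES,
    ParameterSet,
    Scenario,
)
from .systemic import SystemicSolution, solve_systemic

__all__ = [
    "Grid1D",
    "FieldState",
    "SimulationResult",
    "SolverError",
    "build_grid",
    "apply_initial_conditions",
    "mobile_transport_rhs",
    "platelet_transport_rhs",
    "boundary_fluxes",
    "species_rhs",
    "platelet_rhs",
    "bound_rhs",
    "CoupledSolver",
    "run_simulation",
]

N_MOBILE = len(MOBILE_SPECIES)
N_PLT = len(PLATELET_SPECIES)
N_BOUND = len(BOUND_SPECIES)
N_FIELDS = N_MOBILE + N_PLT + N_BOUND  # 18


class SolverError(RuntimeError):
    """Time integration failed; carries diagnostics about the stiff field."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1D grid with the index span of the initial clot."""

    x: np.ndarray  # node coordinates, m
    dx: float
    clot_start: int  # first node inside the initial clot
    clot_end: int  # last node inside the initial clot (inclusive)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def clot_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[self.clot_start : self.clot_end + 1] = True
        return mask

    @property
    def clot_slice(self) -> slice:
        return slice(self.clot_start, self.clot_end + 1)


def build_grid(scen: Scenario, dx: float) -> Grid1D:
    """Uniform grid over [0, d_clot + L_clot] with spacing ``dx``.

    A spacing that does not divide the domain length is snapped (with a
    warning) so that the clot front and end align to nodes.
    """
    if dx <= 0:
        raise ValueError("dx must be > 0")
    length = scen.domain_length
    n_cells = length / dx
    if abs(n_cells - round(n_cells)) > 1.0e-6 * n_cells:
        warnings.warn(
            f"dx={dx:g} does not divide the domain length {length:g}; snapping",
            stacklevel=2,
        )
    n = int(round(n_cells)) + 1
    dx_eff = length / (n - 1)
    x = np.linspace(0.0, length, n)
    clot_start = int(round(scen.d_clot / dx_eff))
    return Grid1D(x=x, dx=dx_eff, clot_start=clot_start, clot_end=n - 1)


@dataclass
class FieldState:
    """Gridded state: (n_nodes, 18) array plus scalars.

    Column layout: ``MOBILE_SPECIES`` (0–9), ``PLATELET_SPECIES`` (10–12),
    ``BOUND_SPECIES`` (13–17).
    """

    arr: np.ndarray  # (N, 18)
    t: float = 0.0
    q: float = 0.0
    clot: ClotState | None = None

    @property
    def mobile(self) -> np.ndarray:
        """(10, N) view of the mobile plasma concentrations."""
        return self.arr[:, :N_MOBILE].T

    @property
    def platelets(self) -> np.ndarray:
        """(3, N) view of the platelet fields."""
        return self.arr[:, N_MOBILE : N_MOBILE + N_PLT].T

    @property
    def bound(self) -> np.ndarray:
        """(5, N) view of the bound-phase fields."""
        return self.arr[:, N_MOBILE + N_PLT :].T


def apply_initial_conditions(grid: Grid1D, scen: Scenario, p: ParameterSet) -> FieldState:
    """Baseline plasma everywhere; platelets and intact fibrin sites
    homogeneously distributed over the clot span; bound drug species zero."""
    arr = np.zeros((grid.n, N_FIELDS))
    for j, name in enumerate(MOBILE_SPECIES):
        arr[:, j] = p.baseline(name)
    span = grid.clot_slice
    arr[span, N_MOBILE + IP["PLT_tot"]] = p.c_plt0(scen.phi_plt0)
    arr[span, N_MOBILE + N_PLT + IB["n_FBR"]] = p.n_fbr0(scen.phi_fbr0)
    state = FieldState(arr=arr, t=0.0)
    state.clot = update_clot_geometry(state.bound, state.platelets, scen, p, grid)
    return state


# ---------------------------------------------------------------------------
# semi-discrete operators


def mobile_transport_rhs(
    c: np.ndarray,
    u_node: np.ndarray,
    d_coef: np.ndarray,
    dx: float,
    inlet: np.ndarray,
    tau_bc: float,
    front_idx: int | None = None,
    front_rows: tuple[int, ...] = (),
) -> np.ndarray:
    """Advection–diffusion right-hand side for mobile plasma species.

    Parameters
    ----------
    c : (S, N) concentrations; u_node : (N,) velocity; d_coef : (S,) or
    (S, 1) diffusivities; inlet : (S,) Dirichlet values imposed by
    relaxation at node 0.  ``front_idx``/``front_rows`` mirror the
    upstream ghost for the given rows at the clot-front node.
    """
    c = np.atleast_2d(c)
    d_coef = np.reshape(d_coef, (-1, 1))
    flux = u_node[None, :] * c
    out = np.empty_like(c)
    out[:, 1:] = -(flux[:, 1:] - flux[:, :-1]) / dx
    lap = np.zeros_like(c)
    lap[:, 1:-1] = (c[:, 2:] - 2.0 * c[:, 1:-1] + c[:, :-2]) / dx**2
    lap[:, -1] = (c[:, -2] - c[:, -1]) / dx**2
    if front_idx is not None and 0 < front_idx < c.shape[1] - 1:
        for row in front_rows:
            lap[row, front_idx] = (c[row, front_idx + 1] - c[row, front_idx]) / dx**2
    out[:, 1:] += (d_coef * lap)[:, 1:]
    out[:, 0] = (np.asarray(inlet) - c[:, 0]) / tau_bc
    return out


def platelet_transport_rhs(
    c: np.ndarray,
    u_node: np.ndarray,
    mob: np.ndarray,
    d_plt: float,
    dx: float,
) -> np.ndarray:
    """Mobility-gated advection–diffusion for platelet fields.

    No platelet influx at the inlet; zero-gradient outlet.  Both transport
    terms are scaled node-wise by the mobility coefficient M(E_L).
    """
    c = np.atleast_2d(c)
    flux = u_node[None, :] * c
    adv = np.empty_like(c)
    adv[:, 0] = -flux[:, 0] / dx
    adv[:, 1:] = -(flux[:, 1:] - flux[:, :-1]) / dx
    lap = np.empty_like(c)
    lap[:, 0] = (c[:, 1] - c[:, 0]) / dx**2
    lap[:, 1:-1] = (c[:, 2:] - 2.0 * c[:, 1:-1] + c[:, :-2]) / dx**2
    lap[:, -1] = (c[:, -2] - c[:, -1]) / dx**2
    return mob[None, :] * (adv + d_plt * lap)


def boundary_fluxes(
    c: np.ndarray, u_node: np.ndarray, d_coef: np.ndarray, dx: float
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete boundary fluxes consistent with the interior stencil.

    Returns (influx, outflux) per species for the interior-mass balance
    over nodes 1..N−1: influx = u₀C₀ + D(C₀−C₁)/dx, outflux = u_{N−1}C_{N−1}.
    """
    c = np.atleast_2d(c)
    d_coef = np.reshape(d_coef, (-1,))
    influx = u_node[0] * c[:, 0] + d_coef * (c[:, 0] - c[:, 1]) / dx
    outflux = u_node[-1] * c[:, -1]
    return influx, outflux


# ---------------------------------------------------------------------------
# coupled solver


class CoupledSolver:
    """Advances the 18-field semi-discrete system for one scenario.

    The inlet provider maps time to the ten mobile-species inlet
    concentrations (a constant vector for S1–S12, the systemic PKPD
    solution for S13–S16).
    """

    def __init__(
        self,
        scen: Scenario,
        p: ParameterSet,
        inlet: Callable[[float], np.ndarray],
        grid: Grid1D | None = None,
    ) -> None:
        self.scen = scen
        self.p = p
        self.grid = grid if grid is not None else build_grid(scen, p.solver.dx)
        self.inlet = inlet
        self.d_mobile = np.array([p.diffusivity(s) for s in MOBILE_SPECIES])
        self.d_plt = p.species.d_plt
        self.state = apply_initial_conditions(self.grid, scen, p)
        self.u_node = np.zeros(self.grid.n)
        self.mob = np.ones(self.grid.n)
        self.front_idx: int | None = None
        self.q: float = 0.0
        self.recanalised = False
        self.warning_counters = {"negative_clips": 0, "snapped_dx": 0}
        self._refresh(self.state.arr)

    # -- quasi-static hemodynamics -----------------------------------------

    def _refresh(self, arr: np.ndarray) -> ClotState:
        """Recompute clot geometry, flowrate, velocity and mobility."""
        bound = arr[:, N_MOBILE + N_PLT :].T
        plts = arr[:, N_MOBILE : N_MOBILE + N_PLT].T
        clot = update_clot_geometry(np.maximum(bound, 0.0), np.maximum(plts, 0.0),
                                    self.scen, self.p, self.grid)
        h = self.p.hemodynamics
        if clot.recanalised:
            self.recanalised = True  # freeze Q at its last clot-bearing value
        else:
            q = flowrate(h.dpdx, clot, h.area, h.mu, self.grid)
            self.q = min(q, self.p.solver.u_max * h.area)
        self.u_node = darcy_velocity(self.q, h.area, clot.eps)
        # platelet mobility is a single coefficient M(t) gated by the least
        # lysed part of the clot; while the clot is still occlusive there is
        # no breakthrough path, so platelets cannot move at all — they are
        # released together once the occlusion is dissolved
        span = self.grid.clot_slice
        e_l_gate = float(clot.e_l[span].min())
        m_scalar = float(mobility(e_l_gate, h.m_mobility, h.e_l_crit))
        if not clot.recanalised:
            m_scalar = 0.0
        self.mob = np.full(self.grid.n, m_scalar)
        clot.mobility_m = self.mob
        if self.scen.drug == "NV":
            occl = np.nonzero(clot.eps < 1.0 - EPS_OPEN)[0]
            self.front_idx = int(occl[0]) if len(occl) else None
        else:
            self.front_idx = None
        self.state.clot = clot
        self.state.q = self.q
        return clot

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        arr = y.reshape(self.grid.n, N_FIELDS)
        c = np.maximum(arr[:, :N_MOBILE].T, 0.0)
        plts = np.maximum(arr[:, N_MOBILE : N_MOBILE + N_PLT].T, 0.0)
        bound = np.maximum(arr[:, N_MOBILE + N_PLT :].T, 0.0)

        r_plasma = kin.plasma_reaction_rates(c, self.p, check=False)
        rb, feedback, _ = kin.bound_phase_rates(c, bound, self.p, check=False)
        r_nv, r_plt = kin.nv_platelet_rates(c, plts, self.p, check=False)

        dc = mobile_transport_rhs(
            arr[:, :N_MOBILE].T, self.u_node, self.d_mobile, self.grid.dx,
            self.inlet(t), self.p.solver.bc_relax_tau,
            front_idx=self.front_idx, front_rows=(IM["tPA"],),
        )
        r_tot = r_plasma + feedback + r_nv
        dc[:, 1:] += r_tot[:, 1:]
        if self.front_idx is not None and 0 < self.front_idx < self.grid.n - 1:
            # zero-gradient tPA at the clot front: mirror the upstream ghost
            # in both the advective and diffusive flux so triggered release
            # is not washed off the face faster than it is resupplied
            j, f = IM["tPA"], self.front_idx
            c_tpa = arr[:, j]
            adv_f = -(self.u_node[f] - self.u_node[f - 1]) * c_tpa[f] / self.grid.dx
            lap_f = (c_tpa[f + 1] - c_tpa[f]) / self.grid.dx**2
            dc[j, f] = adv_f + self.d_mobile[j] * lap_f + r_tot[j, f]
        if self.front_idx == 0:
            # clot front at the inlet (proximal clot, NV run): the zero-
            # gradient tPA condition replaces the Dirichlet value so that
            # locally released tPA is not clamped away
            j = IM["tPA"]
            c_tpa = arr[:, j]
            dc[j, 0] = (
                self.d_mobile[j] * (c_tpa[1] - c_tpa[0]) / self.grid.dx**2
                + r_tot[j, 0]
            )
        dp = platelet_transport_rhs(
            arr[:, N_MOBILE : N_MOBILE + N_PLT].T, self.u_node, self.mob,
            self.d_plt, self.grid.dx,
        )
        dp += r_plt
        out = np.empty_like(arr)
        out[:, :N_MOBILE] = dc.T
        out[:, N_MOBILE : N_MOBILE + N_PLT] = dp.T
        out[:, N_MOBILE + N_PLT :] = rb.T
        return out.ravel()

    # -- time stepping ------------------------------------------------------

    def run(
        self,
        t_max: float | None = None,
        dt_report: float | None = None,
        progress: Callable[[float], None] | None = None,
    ) -> "SimulationResult":
        sp = self.p.solver
        t_max = sp.t_max if t_max is None else t_max
        dt = sp.dt_report if dt_report is None else dt_report
        thr = sp.lysis_complete_threshold
        span = self.grid.clot_slice

        integ = ode(self.rhs)
        integ.set_integrator(
            "lsoda", rtol=sp.rtol, atol=sp.atol, uband=N_FIELDS, lband=N_FIELDS,
            nsteps=100000,
        )
        integ.set_initial_value(self.state.arr.ravel().copy(), 0.0)

        rec = _Recorder(self, thr)
        t = 0.0
        e_l_prev = self.state.clot.e_l.copy()
        rec.record(t, self.state.arr, self.state.clot)
        while t < t_max and not self.recanalised:
            integ.integrate(t + dt)
            if not integ.successful():
                arr = integ.y.reshape(self.grid.n, N_FIELDS)
                worst = ALL_FIELDS[int(np.argmax(np.abs(self.rhs(t, integ.y)
                                                        .reshape(-1, N_FIELDS)).max(axis=0)))]
                raise SolverError(
                    f"stiff integration failed at t={t:.1f}s "
                    f"(largest residual in field {worst!r})"
                )
            t += dt
            arr = integ.y.reshape(self.grid.n, N_FIELDS).copy()
            neg = arr < -10.0 * sp.atol
            if np.any(neg):
                self.warning_counters["negative_clips"] += int(np.count_nonzero(neg))
            np.clip(arr, 0.0, None, out=arr)
            clot = self._refresh(arr)
            rec.update_completion(t - dt, t, e_l_prev, clot.e_l, span, thr)
            e_l_prev = clot.e_l.copy()
            rec.record(t, arr, clot)
            self.state.arr = arr
            self.state.t = t
            if progress is not None:
                progress(t)
        return rec.finalise(t_max)


class _Recorder:
    """Accumulates report-cadence series and sparse field snapshots."""

    def __init__(self, solver: CoupledSolver, threshold: float) -> None:
        self.s = solver
        self.threshold = threshold
        self.times: list[float] = []
        self.clot_avg: list[np.ndarray] = []
        self.q: list[float] = []
        self.l_rem: list[float] = []
        self.e_l_min: list[float] = []
        self.e_l_max: list[float] = []
        self.c_front: list[np.ndarray] = []
        self.influx: list[np.ndarray] = []
        self.outflux: list[np.ndarray] = []
        self.u_clot: list[float] = []
        self.max_plasma = np.zeros(N_MOBILE)
        self.t_complete = np.full(solver.grid.n, np.nan)
        self.snap_times: list[float] = []
        self.snapshots: list[np.ndarray] = []
        self._last_avg = np.zeros(N_FIELDS)
        self._next_snap = 0.0

    def record(self, t: float, arr: np.ndarray, clot: ClotState) -> None:
        s = self.s
        span = s.grid.clot_slice
        occl = clot.occlusive
        if np.any(occl):
            w = clot.eps[occl] * s.grid.dx
            avg = (arr[occl, :] * w[:, None]).sum(axis=0) / w.sum()
            self._last_avg = avg
            u_in_clot = float(s.u_node[occl][0])
        else:
            avg = self._last_avg
            u_in_clot = float(s.u_node[span][0])
        self.times.append(t)
        self.clot_avg.append(avg)
        self.q.append(s.q)
        self.l_rem.append(clot.l_clot_rem)
        self.e_l_min.append(float(clot.e_l[span].min()))
        self.e_l_max.append(float(clot.e_l[span].max()))
        self.c_front.append(arr[s.grid.clot_start, :N_MOBILE].copy())
        self.u_clot.append(u_in_clot)
        np.maximum(self.max_plasma, arr[:, :N_MOBILE].max(axis=0), out=self.max_plasma)
        inf, outf = boundary_fluxes(arr[:, :N_MOBILE].T, s.u_node, s.d_mobile, s.grid.dx)
        self.influx.append(inf)
        self.outflux.append(outf)
        if t >= self._next_snap - 1.0e-9 or self.s.recanalised:
            self.snap_times.append(t)
            self.snapshots.append(arr.copy())
            self._next_snap = t + self.s.p.solver.snapshot_interval

    def update_completion(self, t0, t1, e_prev, e_cur, span, thr) -> None:
        idx = np.arange(len(self.t_complete))[span]
        for i in idx:
            if np.isnan(self.t_complete[i]) and e_cur[i] >= thr:
                de = e_cur[i] - e_prev[i]
                frac = 1.0 if de <= 0 else np.clip((thr - e_prev[i]) / de, 0.0, 1.0)
                self.t_complete[i] = t0 + frac * (t1 - t0)

    def finalise(self, t_max: float) -> "SimulationResult":
        s = self.s
        span = s.grid.clot_slice
        if s.recanalised:
            # nodes already complete at the first record (e.g. nothing to
            # lyse) never produced a crossing; stamp them with the current time
            e_now = s.state.clot.e_l
            fill = np.isnan(self.t_complete) & (e_now >= self.threshold)
            self.t_complete[fill] = self.times[-1]
        recan_time = None
        if s.recanalised and not np.any(np.isnan(self.t_complete[span])):
            recan_time = float(np.nanmax(self.t_complete[span]))
        return SimulationResult(
            scenario=s.scen,
            grid=s.grid,
            times=np.asarray(self.times),
            clot_avg=np.vstack(self.clot_avg),
            q=np.asarray(self.q),
            l_rem=np.asarray(self.l_rem),
            e_l_min=np.asarray(self.e_l_min),
            e_l_max=np.asarray(self.e_l_max),
            c_front=np.vstack(self.c_front),
            u_clot=np.asarray(self.u_clot),
            influx=np.vstack(self.influx),
            outflux=np.vstack(self.outflux),
            max_plasma=self.max_plasma,
            t_complete=self.t_complete,
            recanalised=s.recanalised,
            recanalisation_time=recan_time,
            snapshot_times=np.asarray(self.snap_times),
            snapshots=np.asarray(self.snapshots),
            final_state=s.state,
            warning_counters=dict(s.warning_counters),
            metadata={
                "dx": s.grid.dx,
                "rtol": s.p.solver.rtol,
                "atol": s.p.solver.atol,
                "dt_report": s.p.solver.dt_report,
                "t_max": t_max,
                "lysis_complete_threshold": s.p.solver.lysis_complete_threshold,
            },
        )


@dataclass
class SimulationResult:
    """Bundle of report-cadence series, snapshots and scalars for one run."""

    scenario: Scenario
    grid: Grid1D
    times: np.ndarray  # (T,), s
    clot_avg: np.ndarray  # (T, 18) porosity-volume-weighted averages, μM
    q: np.ndarray  # (T,), m³/s
    l_rem: np.ndarray  # (T,), m
    e_l_min: np.ndarray
    e_l_max: np.ndarray
    c_front: np.ndarray  # (T, 10) plasma concentrations at the clot front node
    u_clot: np.ndarray  # (T,) interstitial velocity at the first occlusive node
    influx: np.ndarray  # (T, 10) discrete inlet flux, μM·m/s
    outflux: np.ndarray  # (T, 10)
    max_plasma: np.ndarray  # (10,) running max over space and time
    t_complete: np.ndarray  # (N,) per-node completion time, s (NaN if never)
    recanalised: bool
    recanalisation_time: float | None  # s
    snapshot_times: np.ndarray
    snapshots: np.ndarray  # (S, N, 18)
    final_state: FieldState
    warning_counters: dict
    metadata: dict
    systemic: SystemicSolution | None = None

    def field_index(self, name: str) -> int:
        return ALL_FIELDS.index(name)

    def avg_series(self, name: str) -> np.ndarray:
        """Clot-averaged time series of any of the 18 fields."""
        return self.clot_avg[:, self.field_index(name)]

    @property
    def recanalisation_minutes(self) -> float | None:
        return None if self.recanalisation_time is None else self.recanalisation_time / 60.0


# ---------------------------------------------------------------------------
# spec-level operation wrappers (thin views over CoupledSolver internals)


def species_rhs(solver: CoupledSolver, t: float = 0.0) -> np.ndarray:
    """Time derivatives of the ten mobile plasma species, shape (10, N)."""
    full = solver.rhs(t, solver.state.arr.ravel()).reshape(-1, N_FIELDS)
    return full[:, :N_MOBILE].T


def platelet_rhs(solver: CoupledSolver, t: float = 0.0) -> np.ndarray:
    full = solver.rhs(t, solver.state.arr.ravel()).reshape(-1, N_FIELDS)
    return full[:, N_MOBILE : N_MOBILE + N_PLT].T


def bound_rhs(solver: CoupledSolver, t: float = 0.0) -> np.ndarray:
    full = solver.rhs(t, solver.state.arr.ravel()).reshape(-1, N_FIELDS)
    return full[:, N_MOBILE + N_PLT :].T


def _constant_inlet(scen: Scenario, p: ParameterSet) -> Callable[[float], np.ndarray]:
    values = np.array([p.baseline(s) for s in MOBILE_SPECIES])
    if scen.drug == "tPA":
        values[IM["tPA"]] = (
            scen.inlet_concentration if scen.inlet_concentration is not None else p.pk.inlet_tpa
        )
    else:
        values[IM["NV"]] = (
            scen.inlet_concentration if scen.inlet_concentration is not None else p.inlet_nv()
        )
    return lambda t: values


def run_simulation(
    scen: Scenario,
    p: ParameterSet,
    *,
    t_max: float | None = None,
    dx: float | None = None,
    dt_report: float | None = None,
    progress: Callable[[float], None] | None = None,
) -> SimulationResult:
    """Run one scenario end-to-end.

    For systemic-PKPD inlet mode the compartment ODEs are solved first and
    interpolated as the inlet boundary (one-way coupling); for constant
    inlet the therapeutic drug level is imposed directly (0.035 μM tPA, or
    0.035/v_rel μM NV).  The run terminates at recanalisation or t_max.
    """
    overrides = {}
    if dx is not None:
        overrides["dx"] = dx
    if dt_report is not None:
        overrides["dt_report"] = dt_report
    if t_max is not None:
        overrides["t_max"] = t_max
    if overrides:
        p = p.model_copy(
            update={"solver": p.solver.model_copy(update=overrides)}
        )
    systemic = None
    if scen.inlet_mode == "systemic-PKPD":
        # solve the compartment model over the whole regimen (plus washout)
        # so the bleeding-risk readout covers the full infusion even when
        # the local model recanalises early
        regimen_end = scen.regimen.bolus_duration + scen.regimen.infusion_duration
        t_end_sys = max(p.solver.t_max + p.solver.dt_report, regimen_end + 1800.0)
        systemic = solve_systemic(p, scen.regimen, t_end_sys, drug=scen.drug)
        inlet = systemic.interp
    else:
        inlet = _constant_inlet(scen, p)
    solver = CoupledSolver(scen, p, inlet)
    result = solver.run(progress=progress)
    result.systemic = systemic
    return result
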