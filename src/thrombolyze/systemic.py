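"""Systemic one-compartment pharmacokinetics/pharmacodynamics.

Ten species (tPA, PLG, PLS, AP, AP-PLS, FBG, MG, PAI, NV, NVemp) evolve in
a single well-mixed plasma compartment under intravenous dosing, first-
order hepatic elimination, homeostatic secretion and the plasma-phase
fibrinolysis reactions.  Secretion balances clearance at baseline, so the
drug-free system is stationary.

The solved time series doubles as the inlet boundary condition of the 1D
occluded-artery model (one-way coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import IM, plasma_reaction_rates
from .parameters import MOBILE_SPECIES, DoseRegimen, ParameterSet

__all__ = [
    "InfusionSchedule",
    "make_infusion",
    "systemic_rhs",
    "solve_systemic",
    "SystemicSolution",
]


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion rate I(t) in mg/s for the dosed species."""

    species: str  # "tPA" or "NV"
    breakpoints: np.ndarray  # segment edges, s (first is 0)
    rates: np.ndarray  # mg/s on each segment

    def rate(self, t: float) -> float:
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        if idx < 0 or idx >= len(self.rates):
            return 0.0
        return float(self.rates[idx])

    @property
    def total_mass(self) -> float:
        """∫ I dt in mg."""
        widths = np.diff(self.breakpoints)
        return float(np.sum(widths * self.rates))

    @property
    def end_time(self) -> float:
        return float(self.breakpoints[-1])


def make_infusion(regimen: DoseRegimen, species: str = "tPA") -> InfusionSchedule:
    """Build the top-hat bolus + constant infusion schedule of a regimen."""
    if species not in ("tPA", "NV"):
        raise ValueError("dosed species must be 'tPA' or 'NV'")
    total = regimen.total_mass  # mg
    bolus_mass = regimen.bolus_fraction * total
    infusion_mass = total - bolus_mass
    edges = [0.0, regimen.bolus_duration]
    rates = [bolus_mass / regimen.bolus_duration]
    if infusion_mass > 0:
        edges.append(regimen.bolus_duration + regimen.infusion_duration)
        rates.append(infusion_mass / regimen.infusion_duration)
    return InfusionSchedule(
        species=species, breakpoints=np.asarray(edges), rates=np.asarray(rates)
    )


def _clearance_and_secretion(
    p: ParameterSet, reactions: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Elimination constants and homeostatic secretion rates.

    Secretion balances clearance at baseline; with the reaction network
    active it additionally compensates the baseline reaction losses (e.g.
    continuous tPA neutralisation by PAI-1, PLG turnover by baseline tPA),
    so the drug-free system is stationary up to trace plasmin turnover.
    """
    k_el = np.array([p.k_el(s) for s in MOBILE_SPECIES])
    sec = np.array([p.secretion(s) for s in MOBILE_SPECIES])
    if reactions:
        c0 = np.array([p.baseline(s) for s in MOBILE_SPECIES])
        r0 = plasma_reaction_rates(c0, p, check=False)
        sec = sec - np.minimum(r0, 0.0) * (sec > 0)  # only secreted species
    return k_el, sec


def systemic_rhs(
    t: float,
    c: np.ndarray,
    sched: InfusionSchedule | None,
    p: ParameterSet,
    *,
    reactions: bool = True,
) -> np.ndarray:
    """dC/dt (μM/s) for the 10 systemic species.

    Dosing enters as I(t)/(V_c·Mw) for the dosed species; every species is
    cleared at k_el,i and secreted at its homeostatic rate; plasma
    reactions are delegated to the kinetics module.
    """
    k_el, sec = _clearance_and_secretion(p, reactions)
    dc = -k_el * np.maximum(c, 0.0) + sec
    if sched is not None:
        mw = p.species.mw_tpa if sched.species == "tPA" else p.mw_nv
        # mg/s → μM/s: (I·1e-3 g/s) / (Mw g/mol · V_c L) · 1e6
        dc[IM[sched.species]] += sched.rate(t) * 1.0e3 / (mw * p.pk.v_c)
    if reactions:
        dc += plasma_reaction_rates(np.maximum(c, 0.0), p, check=False)
    return dc


@dataclass
class SystemicSolution:
    """Systemic concentration time series on a uniform reporting grid."""

    times: np.ndarray  # s
    values: np.ndarray  # (T, 10) μM, columns ordered as MOBILE_SPECIES
    schedule: InfusionSchedule | None

    def interp(self, t: float) -> np.ndarray:
        """Linear-in-time inlet concentrations at time t, shape (10,)."""
        if t <= self.times[0]:
            return self.values[0]
        if t >= self.times[-1]:
            return self.values[-1]
        i = int(np.searchsorted(self.times, t) - 1)
        w = (t - self.times[i]) / (self.times[i + 1] - self.times[i])
        return (1.0 - w) * self.values[i] + w * self.values[i + 1]

    def series(self, species: str) -> np.ndarray:
        return self.values[:, IM[species]]

    def dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(MOBILE_SPECIES))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Tidy tabular text: one row per time, units row under the header."""
        df = self.dataframe()
        units = ["s"] + ["uM"] * (df.shape[1] - 1)
        with open(path, "w") as fh:
            fh.write(",".join(df.columns) + "\n")
            fh.write(",".join(units) + "\n")
            df.to_csv(fh, header=False, index=False)


def solve_systemic(
    p: ParameterSet,
    regimen: DoseRegimen | None,
    t_end: float,
    *,
    drug: str = "tPA",
    reactions: bool = True,
    report_dt: float = 1.0,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-14,
) -> SystemicSolution:
    """Integrate the systemic ODEs segment-wise over the dosing schedule.

    The schedule breakpoints are integration restart points (the top-hat
    inputs are known a priori, so no event detection is needed); output is
    sampled on a uniform grid suitable for inlet interpolation.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    sched = make_infusion(regimen, drug) if regimen is not None else None
    c0 = np.array([p.baseline(s) for s in MOBILE_SPECIES])

    edges = [0.0, t_end]
    if sched is not None:
        edges += [float(b) for b in sched.breakpoints if 0.0 < b < t_end]
    edges = sorted(set(edges))

    times = [np.array([0.0])]
    values = [c0[None, :]]
    c = c0.copy()
    for a, b in zip(edges[:-1], edges[1:]):
        n_pts = max(int(round((b - a) / report_dt)), 1)
        t_eval = np.linspace(a, b, n_pts + 1)[1:]
        sol = solve_ivp(
            lambda t, y: systemic_rhs(t, y, sched, p, reactions=reactions),
            (a, b), c, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"systemic PK integration failed on [{a}, {b}]: {sol.message}")
        times.append(sol.t)
        values.append(sol.y.T)
        c = sol.y[:, -1].copy()
    return SystemicSolution(
        times=np.concatenate(times), values=np.vstack(values), schedule=sched
    )
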