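"""Clot microstructure → hydraulic closure and Darcy flow.

The lysing clot is treated as a porous medium whose resistance is the sum
of a fibrous-network contribution (Davies closure for the fibrin fibres)
and a granular contribution (Kozeny–Carman closure for the activated
platelets).  The volumetric flowrate through the occluded segment follows
Darcy's law with a fixed pressure gradient; the permeation (interstitial)
velocity is the flowrate divided by the open area ``A·ε``.

Resistances are inverse permeabilities (1/m²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import IB, IP, extent_of_lysis, extent_of_platelets
from .parameters import ParameterSet, Scenario

__all__ = [
    "ClotState",
    "fibre_resistance",
    "platelet_resistance",
    "total_resistance",
    "flowrate",
    "darcy_velocity",
    "update_clot_geometry",
]

#: nodes with porosity below 1 − EPS_OPEN count as clot-bearing
EPS_OPEN = 1.0e-6


def fibre_resistance(phi_fbr: np.ndarray | float, r_f: float) -> np.ndarray | float:
    """Fibrin-fibre network resistance via the Davies fibrous-medium closure.

    Permeability ``k = r_f² / (16 φ^1.5 (1 + 56 φ³))``; resistance is 1/k,
    zero at φ = 0.
    """
    phi = np.asarray(phi_fbr, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("fibrin volume fraction must satisfy 0 <= phi < 1")
    if r_f <= 0:
        raise ValueError("fibre radius must be > 0")
    res = 16.0 * phi**1.5 * (1.0 + 56.0 * phi**3) / r_f**2
    return float(res) if res.ndim == 0 else res


def platelet_resistance(phi_plt: np.ndarray | float, r_p: float) -> np.ndarray | float:
    """Platelet-aggregate resistance via a Kozeny–Carman sphere packing.

    Permeability ``k = (2 r_p)² (1 − φ)³ / (180 φ²)``; resistance 1/k, zero
    at φ = 0.
    """
    phi = np.asarray(phi_plt, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("platelet volume fraction must satisfy 0 <= phi < 1")
    if r_p <= 0:
        raise ValueError("platelet radius must be > 0")
    res = 180.0 * phi**2 / ((2.0 * r_p) ** 2 * (1.0 - phi) ** 3)
    return float(res) if res.ndim == 0 else res


def total_resistance(phi_fbr, phi_plt, r_f: float, r_p: float):
    """Node-wise total clot resistance R_tot = R_FBR + R_PLT."""
    return fibre_resistance(phi_fbr, r_f) + platelet_resistance(phi_plt, r_p)


@dataclass
class ClotState:
    """Per-node clot microstructure and derived hydraulics."""

    phi_fbr: np.ndarray
    phi_plt: np.ndarray
    eps: np.ndarray
    r_fbr: np.ndarray
    r_plt: np.ndarray
    r_tot: np.ndarray
    e_l: np.ndarray
    e_plt: np.ndarray
    occlusive: np.ndarray  # within the initial clot span and not yet fully lysed
    l_clot_rem: float
    mobility_m: np.ndarray = field(default=None)  # filled by the solver

    @property
    def recanalised(self) -> bool:
        return self.l_clot_rem <= 0.0


def update_clot_geometry(
    bound: np.ndarray,
    platelets: np.ndarray,
    scen: Scenario,
    p: ParameterSet,
    grid,
) -> ClotState:
    """Recompute volume fractions, porosity, resistances and lysis extent.

    φ_FBR scales with the remaining intact binding sites,
    φ_PLT with the extent of platelets; ε = 1 − φ_FBR − φ_PLT.
    The remaining clot length counts initial-clot nodes whose extent of
    lysis is below the completion threshold.
    """
    h = p.hemodynamics
    n = grid.n
    span = grid.clot_mask
    n_fbr0 = p.n_fbr0(scen.phi_fbr0)
    c_plt0 = p.c_plt0(scen.phi_plt0)

    n_fbr = np.maximum(bound[IB["n_FBR"]], 0.0)
    if n_fbr0 > 0:
        phi_fbr = scen.phi_fbr0 * np.clip(n_fbr / n_fbr0, 0.0, 1.0)
    else:  # nothing to lyse: clot counts as fully lysed from the start
        phi_fbr = np.zeros(n)
    if c_plt0 > 0:
        e_plt = np.maximum(extent_of_platelets(platelets[IP["PLT_tot"]], c_plt0), 0.0)
    else:
        e_plt = np.zeros(n)
    phi_plt = np.clip(scen.phi_plt0 * e_plt, 0.0, 0.5)
    eps = np.clip(1.0 - phi_fbr - phi_plt, 1.0e-3, 1.0)

    e_l = np.ones(n)
    if n_fbr0 > 0:
        e_l[span] = extent_of_lysis(n_fbr[span], n_fbr0)

    r_fbr = fibre_resistance(phi_fbr, h.r_f)
    r_plt = platelet_resistance(phi_plt, h.r_p)
    r_tot = r_fbr + r_plt

    thr = p.solver.lysis_complete_threshold
    occlusive = span & (e_l < thr)
    # remaining length as the occlusive fraction of the initial clot span
    # (node counting would overstate the physical length by one cell)
    n_span = int(np.count_nonzero(span))
    l_rem = scen.l_clot * float(np.count_nonzero(occlusive)) / n_span
    return ClotState(
        phi_fbr=phi_fbr, phi_plt=phi_plt, eps=eps,
        r_fbr=r_fbr, r_plt=r_plt, r_tot=r_tot,
        e_l=e_l, e_plt=np.asarray(e_plt, dtype=float),
        occlusive=occlusive, l_clot_rem=l_rem,
    )


def flowrate(dpdx: float, clot: ClotState, area: float, mu: float, grid) -> float:
    """Darcy flowrate through the occluded segment.

    ``Q = ΔP_x · L_clot,rem · A / (μ ∫ R_tot/ε dx)`` with the integral
    evaluated by the trapezoid rule on the grid.  Q is spatially constant
    (incompressible 1D flow).  Raises if no clot-bearing node remains —
    the caller handles the recanalised branch.
    """
    if clot.recanalised:
        raise ValueError("no occlusive clot remains; Darcy's law does not apply")
    integrand = clot.r_tot / clot.eps
    denom = mu * np.trapezoid(integrand, dx=grid.dx)
    if denom <= 0:
        raise ValueError("zero hydraulic resistance with clot present")
    return dpdx * clot.l_clot_rem * area / denom


def darcy_velocity(q: float, area: float, eps_local: np.ndarray | float) -> np.ndarray | float:
    """Interstitial (permeation) velocity u = Q/(A·ε), node-wise."""
    eps = np.asarray(eps_local, dtype=float)
    if np.any(eps <= 0) or np.any(eps > 1):
        raise ValueError("porosity must lie in (0, 1]")
    u = q / (area * eps)
    return float(u) if u.ndim == 0 else u
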