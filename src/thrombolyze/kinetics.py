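"""Reaction source terms of the fibrinolysis + nanovesicle network.

Three groups of reactions are modelled, following the classical
fibrinolysis model family (Michaelis–Menten plasminogen activation,
mass-action adsorption onto a shared pool of fibrin binding sites,
second-order irreversible inhibition) extended with the targeted
nanovesicle (NV) pathway:

plasma phase
    PLG → PLS activation by free tPA (Michaelis–Menten); PLS inhibition
    by α2-antiplasmin (AP, second order, producing the AP-PLS complex);
    PLS inactivation by α2-macroglobulin (MG); tPA inhibition by PAI-1;
    fibrinogen (FBG) degradation by PLS; passive tPA leakage from
    circulating NV.

fibrin-bound phase
    Reversible adsorption of tPA/PLG/PLS onto free intact binding sites;
    Michaelis–Menten conversion of bound PLG to bound PLS catalysed by
    bound tPA; site degradation driven by bound PLS; proportional
    displacement of bound species from degraded sites (bound PLS moves to
    the lysed-site pool and is then released back to plasma).

NV–platelet pathway
    NV binding to free α_IIbβ3 integrin sites on activated platelets,
    optional unbinding, and triggered tPA release upon contact.
    ``PLT_NV`` and ``PLT_NVemp`` are vesicle-equivalent concentrations
    (μM of platelet-bound vesicles); each bound vesicle occupies one
    integrin site, so the free site pool is
    ``C_INT,free = N_INT·C_PLT,tot − C_PLT,NV − C_PLT,NVemp``.

All concentrations are in μM; all rates in μM/s.  Functions are
vectorised: species arrays have shape ``(n_species,)`` or
``(n_species, n_nodes)``.
"""

from __future__ import annotations

import numpy as np

from .parameters import BOUND_SPECIES, MOBILE_SPECIES, ParameterSet

__all__ = [
    "IM",
    "IB",
    "IP",
    "StateError",
    "plasma_reaction_rates",
    "bound_phase_rates",
    "nv_platelet_rates",
    "platelet_bookkeeping",
    "extent_of_lysis",
    "mobility",
    "extent_of_platelets",
]

#: index of each mobile species in the plasma concentration array
IM = {name: i for i, name in enumerate(MOBILE_SPECIES)}
#: index of each bound species (n_FBR last)
IB = {name: i for i, name in enumerate(BOUND_SPECIES)}
#: index of each platelet field
IP = {"PLT_tot": 0, "PLT_NV": 1, "PLT_NVemp": 2}

_SITE_EPS = 1.0e-30


class StateError(ValueError):
    """A state vector violates a structural invariant (e.g. site balance)."""


def _check_nonneg(arr: np.ndarray, what: str) -> None:
    if np.any(np.asarray(arr) < 0):
        raise ValueError(f"negative {what} concentration")


def plasma_reaction_rates(c: np.ndarray, p: ParameterSet, *, check: bool = True) -> np.ndarray:
    """Net plasma-phase reaction rate for each of the 10 mobile species.

    Parameters
    ----------
    c : array, shape (10,) or (10, n)
        Plasma concentrations in μM, ordered as ``MOBILE_SPECIES``.
    """
    c = np.asarray(c, dtype=float)
    if check:
        _check_nonneg(c, "plasma")
    k = p.kinetics
    tpa, plg, pls = c[IM["tPA"]], c[IM["PLG"]], c[IM["PLS"]]
    ap, mg, pai = c[IM["AP"]], c[IM["MG"]], c[IM["PAI"]]
    fbg, nv = c[IM["FBG"]], c[IM["NV"]]

    r_act = k.k_cat_plg_plasma * tpa * plg / (k.km_plg_plasma + plg)
    r_ap = k.k_ap * pls * ap
    r_mg = k.k_mg * pls * mg
    r_pai = k.k_pai * tpa * pai
    r_fbg = k.k_cat_fbg * pls * fbg / (k.km_fbg + fbg)
    r_leak = k.k_leak * nv

    r = np.zeros_like(c)
    r[IM["tPA"]] = -r_pai + k.v_rel * r_leak
    r[IM["PLG"]] = -r_act
    r[IM["PLS"]] = r_act - r_ap - r_mg
    r[IM["AP"]] = -r_ap
    r[IM["AP_PLS"]] = r_ap
    r[IM["FBG"]] = -r_fbg
    r[IM["MG"]] = -r_mg
    r[IM["PAI"]] = -r_pai
    r[IM["NV"]] = -r_leak
    r[IM["NVemp"]] = r_leak
    return r


def bound_phase_rates(
    c: np.ndarray,
    b: np.ndarray,
    p: ParameterSet,
    *,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fibrin-bound-phase rates and the matching plasma feedback terms.

    Parameters
    ----------
    c : array (10,) or (10, n)
        Plasma concentrations, μM.
    b : array (5,) or (5, n)
        Bound concentrations ``(tPA_F, PLG_F, PLS_F, PLS_F_lysed, n_FBR)``, μM.

    Returns
    -------
    rb : array like ``b``
        Bound-phase rates; ``rb[4] = -r_deg`` (intact sites only decrease).
    feedback : array like ``c``
        Source/sink terms for the plasma phase so that reactions alone
        conserve total (plasma + bound) protein mass.
    r_deg : array
        Fibrin binding-site degradation rate, μM/s (also the FDP source).
    """
    c = np.asarray(c, dtype=float)
    b = np.asarray(b, dtype=float)
    if check:
        _check_nonneg(c, "plasma")
        _check_nonneg(b, "bound")
    n_tpa, n_plg, n_pls = b[IB["tPA_F"]], b[IB["PLG_F"]], b[IB["PLS_F"]]
    n_lys, n_fbr = b[IB["PLS_F_lysed"]], b[IB["n_FBR"]]
    occupied = n_tpa + n_plg + n_pls
    if check and np.any(occupied > n_fbr * (1.0 + 1.0e-9) + 1.0e-12):
        raise StateError("bound species exceed intact fibrin binding sites")

    k = p.kinetics
    n_free = np.maximum(n_fbr - occupied, 0.0)

    ads_tpa = k.k_on_tpa * c[IM["tPA"]] * n_free
    ads_plg = k.k_on_plg * c[IM["PLG"]] * n_free
    ads_pls = k.k_on_pls * c[IM["PLS"]] * n_free
    des_tpa = k.k_off_tpa * n_tpa
    des_plg = k.k_off_plg * n_plg
    des_pls = k.k_off_pls * n_pls
    conv = k.k_cat_plg_bound * n_tpa * n_plg / (k.km_plg_bound + n_plg)
    # degradation is driven by all fibrin-associated plasmin (on intact
    # sites and on already-cut fragments, which remain in the gel until
    # released); the saturation factor switches cutting off smoothly as
    # the last intact sites disappear
    r_deg = k.k_deg * (n_pls + n_lys) * n_fbr / (n_fbr + k.k_deg_sat)

    # bound species sitting on degraded sites are displaced in proportion
    # to their occupancy; displaced PLS stays fibrin-associated on lysed
    # fragments (PLS_F_lysed) before first-order release to plasma, while
    # displaced tPA and PLG remain complexed with the solubilised
    # degradation products and are carried away with them (no plasma return)
    inv_fbr = 1.0 / np.maximum(n_fbr, _SITE_EPS)
    disp_tpa = r_deg * n_tpa * inv_fbr
    disp_plg = r_deg * n_plg * inv_fbr
    disp_pls = r_deg * n_pls * inv_fbr
    rel_lys = k.k_rel_lysed * n_lys

    rb = np.zeros_like(b)
    rb[IB["tPA_F"]] = ads_tpa - des_tpa - disp_tpa
    rb[IB["PLG_F"]] = ads_plg - des_plg - conv - disp_plg
    rb[IB["PLS_F"]] = ads_pls - des_pls + conv - disp_pls
    rb[IB["PLS_F_lysed"]] = disp_pls - rel_lys
    rb[IB["n_FBR"]] = -r_deg

    feedback = np.zeros_like(c)
    feedback[IM["tPA"]] = des_tpa - ads_tpa
    feedback[IM["PLG"]] = des_plg - ads_plg
    feedback[IM["PLS"]] = des_pls - ads_pls + rel_lys
    return rb, feedback, r_deg


def platelet_bookkeeping(plt: np.ndarray, p: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Free-platelet equivalents and free integrin-site concentration.

    Returns ``(C_PLT_free, C_INT_free)`` in μM.  ``C_PLT_free`` is the
    platelet-equivalent carrying capacity still available,
    ``C_INT_free / N_INT``.
    """
    plt = np.asarray(plt, dtype=float)
    n_int = p.hemodynamics.n_int
    c_int_free = np.maximum(
        n_int * plt[IP["PLT_tot"]] - plt[IP["PLT_NV"]] - plt[IP["PLT_NVemp"]], 0.0
    )
    return c_int_free / n_int, c_int_free


def nv_platelet_rates(
    c: np.ndarray,
    plt: np.ndarray,
    p: ParameterSet,
    *,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """NV–platelet binding, unbinding and triggered-release rates.

    Returns ``(r_mobile, r_platelet)`` where ``r_mobile`` holds the
    contributions to tPA/NV/NVemp and ``r_platelet`` those to
    ``(PLT_tot, PLT_NV, PLT_NVemp)``.
    """
    c = np.asarray(c, dtype=float)
    plt = np.asarray(plt, dtype=float)
    if check:
        _check_nonneg(c, "plasma")
        _check_nonneg(plt, "platelet")
    k = p.kinetics
    c_plt_free, c_int_free = platelet_bookkeeping(plt, p)

    bind = k.k_on_nv * c[IM["NV"]] * c_int_free
    unbind = k.k_off_nv * plt[IP["PLT_NV"]]
    unbind_emp = k.k_off_nvemp * plt[IP["PLT_NVemp"]]
    # platelet-dependent release: a passive contact component plus a
    # cooperative component that scales with local platelet availability
    # below the reference density and saturates above it (multivalent
    # contacts no longer limiting)
    rate = k.k_trig_base
    if k.hill_release != 1.0:
        factor = np.minimum(
            np.power(np.maximum(c_plt_free, 0.0) / k.c_plt_ref, k.hill_release - 1.0),
            1.0,
        )
        rate = rate + k.k_trig * factor
    else:
        rate = rate + k.k_trig
    trig = rate * plt[IP["PLT_NV"]]

    r_mobile = np.zeros_like(c)
    r_mobile[IM["NV"]] = unbind - bind
    r_mobile[IM["NVemp"]] = unbind_emp
    r_mobile[IM["tPA"]] = k.v_rel * trig

    r_plt = np.zeros_like(plt)
    r_plt[IP["PLT_NV"]] = bind - unbind - trig
    r_plt[IP["PLT_NVemp"]] = trig - unbind_emp
    return r_mobile, r_plt


def extent_of_lysis(n_tot: np.ndarray | float, n_tot0: float) -> np.ndarray | float:
    """Extent of lysis E_L = 1 − n_tot/n_tot,0, clipped to [0, 1]."""
    if np.any(np.asarray(n_tot0) <= 0):
        raise ValueError("n_tot0 must be > 0")
    return np.clip(1.0 - np.asarray(n_tot, dtype=float) / n_tot0, 0.0, 1.0)


def mobility(e_l: np.ndarray | float, m: float, e_l_crit: float) -> np.ndarray | float:
    """Lysis-gated platelet mobility coefficient.

    M = 1 for E_L > E_L,crit, else 1 − tanh(m·(1 − E_L/E_L,crit));
    continuous at the critical extent of lysis.
    """
    e_l = np.asarray(e_l, dtype=float)
    m_val = np.where(e_l > e_l_crit, 1.0, 1.0 - np.tanh(m * (1.0 - e_l / e_l_crit)))
    return float(m_val) if m_val.ndim == 0 else m_val


def extent_of_platelets(c_plt_tot: np.ndarray | float, c_plt0: float) -> np.ndarray | float:
    """Extent of activated platelets E_PLT = C_PLT,tot / C_PLT,0."""
    if c_plt0 <= 0:
        raise ValueError("c_plt0 must be > 0")
    return np.asarray(c_plt_tot, dtype=float) / c_plt0
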