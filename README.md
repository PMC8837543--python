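# thrombolyze

A 1D multiphysics simulator of intravenous thrombolysis in an occluded
artery, for two thrombolytics: conventional free tissue plasminogen
activator (tPA) and an activated-platelet-targeted, tPA-loaded nanovesicle
(tPA-NV).  It is written for researchers in computational haemodynamics
and targeted drug delivery who want to compare dosing regimens and clot
conditions on two readouts: **recanalisation time** (treatment efficacy)
and the **systemic fibrinogen nadir** (a bleeding-risk surrogate — plasma
fibrinogen below 150 mg/dL ≈ 4.4 μM signals increased bleeding risk).

## The model

Three coupled sub-models (one-way coupled, systemic → local):

* **Systemic PK/PD** — a one-compartment model of ten plasma species
  (tPA, plasminogen PLG, plasmin PLS, α₂-antiplasmin AP, the AP–PLS
  complex, fibrinogen FBG, α₂-macroglobulin MG, PAI-1, loaded and empty
  vesicles), with bolus + infusion dosing
  `dC_i/dt = I(t)/(V_c·Mw) − k_el,i C_i + S_i + r_i`,
  homeostatic secretion and the plasma fibrinolysis reactions.
* **Clot hydraulics** — Darcy flow through the lysing porous clot,
  `Q = ΔP_x L_rem A / (μ ∫ R_tot/ε dx)`, with a Davies closure for the
  fibrin-fibre resistance and a Kozeny–Carman closure for the platelet
  fraction; the permeation velocity `u = Q/(A·ε)` stays below ~4×10⁻⁵ m/s.
* **Local PD + transport** — eighteen fields on a 1D grid: mobile species
  advect and diffuse with the permeation flow; tPA/PLG/PLS adsorb onto
  fibrin binding sites; fibrin-bound plasmin degrades the sites
  (`∂n_FBR/∂t = −r_deg`, extent of lysis `E_L = 1 − n_FBR/n_FBR,0`);
  vesicles bind platelet integrins and release their payload on contact,
  with the release rate increasing with local platelet density.  Platelet
  fields are immobilised until the occlusion dissolves
  (`M = 1 − tanh(m(1 − E_L/E_L,crit))`, m = 10, E_L,crit = 0.95).

Sixteen built-in treatment scenarios vary clot position, composition
(dense ε₀ = 0.95 vs coarse ε₀ = 0.98), drug and dosing regimen, including
the recommended stroke regimen (0.9 mg/kg, 10% bolus + 1 h infusion).
See `docs/methods.md` for the full equations, parameter provenance and
calibration, numerical scheme and limitations.

## Worked example

Systemic pharmacokinetics of the four dosing regimens
(`python examples/systemic_regimens.py`):

```
bleeding-risk threshold: 150 mg/dL = 4.41 uM fibrinogen
baseline FBG: 8.0 uM, baseline tPA: 5.0e-05 uM

S13 (tPA, 0.9 mg/kg, bolus fraction 0.1):
  tPA during infusion: 0.0323 uM   FBG nadir: 7.38 uM (7.7% drop)   PLG nadir: 0.61 uM
S14 ( NV, 0.9 mg/kg, bolus fraction 0.1):
  tPA during infusion: 0.0001 uM   FBG nadir: 8.00 uM (0.0% drop)   PLG nadir: 2.19 uM
S15 ( NV, 0.09 mg/kg, bolus fraction 1.0):
  tPA during infusion: 0.0001 uM   FBG nadir: 8.00 uM (0.0% drop)   PLG nadir: 2.20 uM
S16 ( NV, 0.45 mg/kg, bolus fraction 0.1):
  tPA during infusion: 0.0001 uM   FBG nadir: 8.00 uM (0.0% drop)   PLG nadir: 2.20 uM
```

The free-tPA regimen (S13) holds circulating tPA at its ~0.035 μM
therapeutic level for the infusion hour, at the cost of depleting
systemic plasminogen (2.2 → 0.61 μM) and depressing fibrinogen — for a
patient starting near the low end of the normal 5–13 μM range that drop
crosses the bleeding threshold.  The vesicle regimens keep the enzyme
encapsulated in circulation (free tPA barely doubles its 5×10⁻⁵ μM
baseline through passive leakage), leaving both proteins untouched; the
payload is released only inside the clot.

A full occluded-artery run (`python examples/single_scenario.py`, ~1 min)
prints, for the proximal coarse clot S7:

```
initial permeation velocity: 3.88e-05 m/s
recanalisation at 8.97 min
peak clot-averaged free tPA: 0.0346 uM (inlet level 0.035 uM)
```

With the free drug the clot-averaged tPA never exceeds the inlet level —
there is no local amplification, so lysis is paced by permeation.  On the
platelet-bearing dense clot (`python examples/drug_comparison.py`) the
vesicle reverses that: its payload is released inside the clot, local tPA
overshoots the inlet more than tenfold, and recanalisation moves from
12.2 min (free tPA, S3) to 9.5 min (vesicle, S4).

`examples/toy_clot.py` (sub-second) and `examples/drug_comparison.py`
(free tPA vs vesicle head-to-head) cover the remaining workflows, and the
same functionality is scriptable from the shell:

```
thrombolyze list-scenarios
thrombolyze run S7 --dx 4e-5 --out out/
thrombolyze batch all --dx 4e-5 --out out/
thrombolyze validate-config my_parameters.yaml
```

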