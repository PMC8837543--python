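# Model and methods

`thrombolyze` simulates intravenous thrombolysis of an occlusive clot in a
straight 1D arterial segment, for two thrombolytics: free tissue
plasminogen activator (tPA) and an activated-platelet-targeted tPA-loaded
nanovesicle (tPA-NV).  It couples three sub-models, one-way:

1. a **systemic one-compartment PK/PD model** (10 species: tPA, PLG, PLS,
   AP, AP-PLS, FBG, MG, PAI, NV, NVemp) with intravenous dosing, first-
   order hepatic elimination, homeostatic secretion and the plasma-phase
   fibrinolysis reactions;
2. a **local pharmacodynamics model** of the clot: reversible adsorption
   of tPA/PLG/PLS onto fibrin binding sites, Michaelis–Menten activation
   of bound plasminogen, site degradation by fibrin-associated plasmin,
   and the vesicle pathway (integrin binding, passive leakage, triggered
   release);
3. a **1D transport model**: Darcy permeation through the porous clot
   under a fixed pressure gradient, with upwind advection and central
   diffusion of the ten mobile species, mobility-gated platelet fields and
   purely local bound-phase ODEs (18 coupled fields in total).

The systemic solution provides the inlet boundary condition of the 1D
model; the clot never feeds back on the compartment (the drug mass
sequestered in a 4 mm clot is negligible against the plasma pool).

## Governing equations

Systemic compartment (concentrations in μM):

    dC_i/dt = I_i(t)/(V_c · Mw_i) − k_el,i · C_i + S_i + r_i^plasma

`I_i` is the infusion rate of the dosed species (a finite 5 s top-hat
bolus followed by a constant infusion — never a Dirac impulse), `V_c` the
plasma volume, and `S_i` the homeostatic secretion.  `S_i` balances both
clearance *and* the baseline reaction losses (continuous tPA
neutralisation by PAI-1, baseline plasminogen turnover), so the drug-free
system is stationary up to trace plasmin turnover (< 2% drift over two
hours).

Flow through the occluded segment is incompressible Darcy flow:

    Q(t) = ΔP_x · L_rem(t) · A / ( μ ∫ R_tot(x,t)/ε(x,t) dx ),
    u(x,t) = Q/(A·ε)

with the clot resistance the sum of a Davies fibrous-medium closure for
the fibrin network, `k_FBR = r_f² / (16 φ^1.5 (1+56 φ³))`, and a
Kozeny–Carman sphere-packing closure for the platelet fraction,
`k_PLT = (2 r_p)² (1−φ)³ / (180 φ²)` (resistances are inverse
permeabilities; at equal volume fraction the fibre network is ~10³ times
more resistive than the platelet packing).  The permeation velocity is
additionally capped at `u_max = 3.8×10⁻⁵ m/s`, representing the series
resistance of the distal vascular bed: however permeable the clot itself
becomes, flow through an occluded branch is limited by the rest of the
path.  The cap is what keeps the initial permeation velocity below
4×10⁻⁵ m/s in every scenario, including the coarsest clots, where the
bare Davies closure would predict three times that.

Mobile species obey a convection–diffusion–reaction equation with a
Dirichlet inlet (the systemic concentrations), a zero-gradient outlet at
the distal clot end, and — for vesicle runs — a zero-gradient condition
on plasma tPA at the clot front, which prevents the triggered-release
spike from being clamped or washed off the front face.  Platelet fields
use the same operators scaled by a single mobility coefficient

    M(t) = 1 − tanh( m (1 − E_L/E_L,crit) ),  m = 10, E_L,crit = 0.95

evaluated at the *minimum* extent of lysis over the still-occlusive clot,
and platelet transport is suppressed entirely while any part of the clot
remains occlusive: platelets in an occlusive clot have no breakthrough
path, and are released together once the occlusion dissolves.  A node-wise
mobility field was rejected because the non-conservative form annihilates
platelet mass at mobility gradients and drains platelets out of partially
lysed clots, extinguishing the vesicle release pathway mid-run.

The extent of lysis is `E_L = 1 − n_FBR/n_FBR,0`.  Fibrin-bound phase
kinetics per node:

* adsorption/desorption of tPA, PLG, PLS on the free intact sites;
* bound activation `PLG-F → PLS-F` at `k_cat · n_tPA-F · n_PLG-F/(K_m + n_PLG-F)`;
* site degradation `r_deg = k_deg (n_PLS-F + n_PLS-F,lysed) · n_FBR/(n_FBR + K_sat)`
  — plasmin on already-cut fragments stays in the gel and keeps cutting
  until it is released to plasma at `k_rel`; the small saturation scale
  `K_sat = 10⁻⁴ μM` only regularises the endpoint;
* displaced species: bound plasmin on degraded sites moves to the
  lysed-fragment pool (and later back to plasma, where AP and MG inhibit
  it); displaced tPA and PLG stay complexed with the soluble degradation
  products and leave with them.  Returning them to plasma instead produces
  local free-tPA levels ~10× the inlet, which contradicts the observed
  bound `≤ 0.035 μM` behaviour of free-tPA runs.

### The vesicle pathway

`PLT-NV` and `PLT-NVemp` are vesicle-equivalent concentrations (μM of
platelet-bound vesicles); each bound vesicle occupies one integrin site,
so the free-site pool is `C_INT,free = N_INT·C_PLT,tot − C_PLT-NV −
C_PLT-NVemp` with `N_INT = 5×10⁴` sites per activated platelet.  A
platelet-level bookkeeping (one vesicle per platelet) caps the releasable
payload two orders of magnitude below the observed clot tPA levels and is
therefore untenable.

Binding is bilinear, `k_on,NV · C_NV · C_INT,free`, with weak unbinding.
Triggered release is first-order in bound vesicles with a
platelet-dependent rate constant

    k_release = k_trig,base + k_trig · min( (C_PLT,free/C_ref)^(h−1), 1 ),
    h = 3.6,  C_ref = C_PLT(φ_PLT = 0.03)

— a passive contact component plus a cooperative component that needs a
high local density of platelet contacts (multivalent clustering of the
RGD-coated vesicle) and saturates above the reference density.  This
two-timescale law is the model's expression of the experimentally
observed platelet-dependent release rate: on platelet-rich (dense) clots
the stored payload unloads within ~2 minutes and local free tPA overshoots
the therapeutic inlet level several-fold, while on platelet-poor (coarse)
clots most of the payload unloads too slowly to matter before a free-tPA
treatment would already have finished — which is exactly the dense/coarse
benefit reversal the simulator is built to study.  Free circulating
vesicles also leak payload slowly (`k_leak = 10⁻⁶ s⁻¹`), which produces
the slightly-above-baseline systemic tPA seen under vesicle dosing.

## Numerical scheme

Method of lines on a uniform grid (default Δx = 20 μm; 301 nodes for the
6 mm distal-clot domain).  Conservative first-order upwind advection
(positivity matters more than order at these Péclet numbers), second-order
central diffusion, Dirichlet inlet imposed by fast relaxation
(τ = 0.05 s).  Time integration is LSODA with a banded Jacobian
(bandwidth 18 — the state is ordered node-major), rtol 10⁻⁶, atol
10⁻¹² μM.  The hemodynamics (Q, u, ε, R, M, clot-front index) are
quasi-static: refreshed once per 1 s reporting interval rather than inside
the integrator.  The refresh converges first-order in cadence; on a 15 s
toy problem cadences of 0.25 s and 0.125 s differ by 0.4%, and the
production cadence-to-run-duration ratio is another order of magnitude
smaller.  Negative undershoots are clipped to zero with a warning counter
rather than aborting.

**Recanalisation** is declared when every node of the initial clot span
reaches `E_L ≥ 0.95 = E_L,crit`, linearly interpolated between reports.
The threshold is configurable; 0.95 is the default because (i) it is the
point at which the mobility law itself says the clot no longer restrains
platelets — mechanical integrity is gone — and (ii) with
adsorption-limited regeneration every bound-phase rate scales with the
vanishing site pool, so `E_L → 1` is asymptotic and a near-unity threshold
measures the tail of that asymptote rather than patency.

**Resolutions used for the reported numbers** (a deliberate accuracy/cost
trade-off): the twelve constant-inlet scenarios run at Δx = 40 μm, the
four systemic-coupled regimen scenarios at the default 20 μm.  Halving
the 40 μm spacing changes reference recanalisation times by ≤ 1.2% and
flips no qualitative ordering.

## Parameters and calibration

All constants live in `src/thrombolyze/data/default_parameters.yaml`,
each tagged with its provenance (`paper-main`, `paper-SI`,
`prior-publication`, `default`).  Diffusivities of the vesicle
(1.6×10⁻¹² m²/s) and platelets (3.1×10⁻¹⁴ m²/s), the tPA (4 min) and
vesicle (132.61 min) half-lives, the therapeutic inlet level (0.035 μM),
the dosing regimens, the mobility constants (m = 10, E_L,crit = 0.95) and
the clot geometries are fixed by the study design.  Classical fibrinolysis
rate constants (adsorption/desorption, inhibition by AP/MG/PAI,
plasma-phase activation) follow the established fibrinolysis modelling
literature.  The constants that no accessible source fixes — the fibrin
binding-site concentration `n_FBR,0 = 1.85 μM`, the bound-phase catalytic
rate 0.125 s⁻¹, the plasmin cut rate 0.45 s⁻¹, the pressure gradient
1.06×10⁶ Pa/m, the bed-limit velocity, the plasma volume 2.85 L and the
vesicle binding/release constants — were calibrated in a single pass
against the study's headline readouts (the 7–15 min recanalisation window,
the 13.75 min standard-regimen time, the 0.15 μM clot tPA peak, the ~2 min
clot-front arrival, the < 4×10⁻⁵ m/s initial permeation velocity) and then
frozen.  Dose regimens for the vesicle are specified in tPA-equivalent
mass (`Mw_NV = v_rel · Mw_tPA`, payload ratio `v_rel = 100`), so equal
mg/kg delivers equal enzyme.

## What the scenario generator emulates — and what it does not

The sixteen built-in scenarios vary clot position (0 or 2 mm from the
inlet), composition (fibrin/platelet volume fractions spanning dense
ε₀ = 0.95 and coarse ε₀ = 0.98 clots), drug and dosing regimen.  They
assume homogeneous clots, fully pre-activated platelets, a rigid straight
vessel, constant pressure gradient and Newtonian viscosity.  Real clots
are heterogeneous (denser cores), platelets activate dynamically, and
vessels branch and comply — so passing the scenario suite demonstrates
internal consistency of the model family and reproduction of the study
conditions, not predictive validity for any patient.

## Known limitations

* The model over-concentrates vesicle capture just behind the clot front:
  the first interior node completes lysis at ~6 min in the distal vesicle
  scenario, earlier than the ~9.5 min the study describes, and the
  front-to-back completion spread (~6 min) is wider.  Narrowing it would
  require slowing dense-clot release, which breaks the 9.3-min lower bound
  of the standard-regimen vesicle scenario; the two could not be met
  jointly under this release law.
* One scenario (S6, the proximal platelet-rich dense clot under vesicle
  treatment) recanalises at ~6.3 min, just below the 7-min lower edge of
  the reported window (within 15% of it).
* After the remaining clot length starts shrinking, the driving head
  `ΔP_x·L_rem` shrinks with it and the flowrate can dip; the monotone-Q
  property holds only while the occlusion spans its full length.
* Platelet mobility is all-or-nothing at breakthrough; the post-
  recanalisation platelet washout phase is outside the model's scope (the
  simulation ends at recanalisation).
* `E_L → 1` exactly is asymptotic (see the threshold discussion); "extent
  of lysis" read-outs above ~0.999 are not meaningful at these kinetics.
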