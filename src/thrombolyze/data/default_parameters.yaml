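# Canonical parameter set for the thrombolysis simulator.
#
# Units: SI for lengths/times/pressures (m, s, Pa), litres for plasma volume,
# μM for all concentrations, g/mol for molecular weights.  Half-lives in
# seconds.  Each entry may carry a provenance tag:
#   paper-main        — fixed in the main text of the source study
#   paper-SI          — from its supporting information (not available here;
#                       no entry currently uses this tag)
#   prior-publication — from the classical fibrinolysis modelling
#                       literature (Anand & Diamond 1996; Wootton,
#                       Popel & Alevriadou 2002, and successors)
#   default           — chosen for this package (physiological estimates, or
#                       calibrated once against the study's printed
#                       macroscopic readouts; see docs/methods.md)

species:
  d_tpa:    {value: 5.3e-11, units: m^2/s, provenance: prior-publication}
  d_plg:    {value: 5.0e-11, units: m^2/s, provenance: prior-publication}
  d_pls:    {value: 5.3e-11, units: m^2/s, provenance: prior-publication}
  d_ap:     {value: 6.0e-11, units: m^2/s, provenance: prior-publication}
  d_ap_pls: {value: 4.0e-11, units: m^2/s, provenance: default}
  d_fbg:    {value: 2.0e-11, units: m^2/s, provenance: prior-publication}
  d_mg:     {value: 2.0e-11, units: m^2/s, provenance: default}
  d_pai:    {value: 6.0e-11, units: m^2/s, provenance: default}
  d_nv:     {value: 1.6e-12, units: m^2/s, provenance: paper-main}
  d_nvemp:  {value: 1.6e-12, units: m^2/s, provenance: paper-main}
  d_plt:    {value: 3.1e-14, units: m^2/s, provenance: paper-main}
  mw_tpa:   {value: 5.9e4,   units: g/mol, provenance: default, comment: alteplase}
  mw_fbg:   {value: 3.4e5,   units: g/mol, provenance: default}

kinetics:
  # plasma-phase fibrinolysis
  k_cat_plg_plasma: {value: 0.3,   units: 1/s,      provenance: prior-publication}
  km_plg_plasma:    {value: 28.0,  units: uM,       provenance: prior-publication}
  k_ap:             {value: 10.0,  units: 1/(uM s), provenance: prior-publication}
  k_mg:             {value: 0.18,  units: 1/(uM s), provenance: prior-publication}
  k_pai:            {value: 10.0,  units: 1/(uM s), provenance: prior-publication}
  k_cat_fbg:        {value: 1.0,   units: 1/s,      provenance: default}
  km_fbg:           {value: 8.0,   units: uM,       provenance: default}
  # nanovesicle leakage / binding / triggered release
  k_leak:      {value: 1.0e-6, units: 1/s,      provenance: default, comment: calibrated}
  k_on_nv:     {value: 0.3,    units: 1/(uM s), provenance: default, comment: calibrated}
  k_off_nv:    {value: 1.0e-4, units: 1/s,      provenance: default}
  k_off_nvemp: {value: 1.0e-2, units: 1/s,      provenance: default}
  k_trig:      {value: 9.0e-3, units: 1/s,      provenance: default, comment: calibrated}
  k_trig_base: {value: 1.3e-3, units: 1/s,      provenance: default,
                comment: passive contact release component}
  hill_release: {value: 3.6, provenance: default, comment: cooperative PLT-dependent release}
  c_plt_ref:   {value: 5.535e-6, units: uM, provenance: default,
                comment: platelet concentration at volume fraction 0.03}
  # fibrin-bound phase
  k_on_tpa:  {value: 0.1,   units: 1/(uM s), provenance: prior-publication}
  k_off_tpa: {value: 0.058, units: 1/s,      provenance: prior-publication}
  k_on_plg:  {value: 0.1,   units: 1/(uM s), provenance: prior-publication}
  k_off_plg: {value: 3.8,   units: 1/s,      provenance: prior-publication}
  k_on_pls:  {value: 0.1,   units: 1/(uM s), provenance: prior-publication}
  k_off_pls: {value: 0.076, units: 1/s,      provenance: prior-publication}
  k_cat_plg_bound: {value: 0.125, units: 1/s, provenance: default, comment: calibrated}
  km_plg_bound:    {value: 0.16, units: uM,  provenance: prior-publication}
  k_deg:       {value: 0.45, units: 1/s, provenance: default, comment: calibrated}
  k_deg_sat:   {value: 1.0e-4, units: uM, provenance: default}
  k_rel_lysed: {value: 0.01, units: 1/s, provenance: default}
  v_rel: {value: 100.0, provenance: default, comment: tPA payload per vesicle}

hemodynamics:
  mu:   {value: 3.5e-3, units: Pa s, provenance: prior-publication}
  dpdx: {value: 1.06e6, units: Pa/m, provenance: default, comment: calibrated}
  area: {value: 7.07e-6, units: m^2, provenance: default, comment: 1.5 mm radius artery}
  r_f:  {value: 5.0e-8,  units: m,   provenance: prior-publication}
  r_p:  {value: 1.3e-6,  units: m,   provenance: default}
  platelet_volume: {value: 9.0e-18, units: m^3, provenance: default}
  n_int: {value: 5.0e4, provenance: default, comment: integrins per activated platelet}
  n_fbr_0: {value: 1.85, units: uM, provenance: default, comment: calibrated}
  m_mobility: {value: 10.0, provenance: paper-main}
  e_l_crit:   {value: 0.95, provenance: paper-main}

pk:
  v_c: {value: 2.85, units: L, provenance: default, comment: adult plasma volume}
  body_weight: {value: 70.0, units: kg, provenance: default}
  inlet_tpa: {value: 0.035, units: uM, provenance: paper-main}
  t_half_tpa: {value: 240.0,   units: s, provenance: paper-main, comment: 4 min}
  t_half_nv:  {value: 7956.6,  units: s, provenance: paper-main, comment: 132.61 min}
  t_half_plg: {value: 190080.0, units: s, provenance: default, comment: 2.2 d}
  t_half_pls: {value: 8640.0,  units: s, provenance: default}
  t_half_ap:  {value: 224640.0, units: s, provenance: default, comment: 2.6 d}
  t_half_ap_pls: {value: 43200.0, units: s, provenance: default}
  t_half_fbg: {value: 302400.0, units: s, provenance: default, comment: 3.5 d}
  t_half_mg:  {value: 259200.0, units: s, provenance: default}
  t_half_pai: {value: 420.0,   units: s, provenance: default, comment: 7 min}
  c0_tpa: {value: 5.0e-5, units: uM, provenance: paper-main}
  c0_plg: {value: 2.2,    units: uM, provenance: prior-publication}
  c0_pls: {value: 0.0,    units: uM, provenance: prior-publication}
  c0_ap:  {value: 1.0,    units: uM, provenance: prior-publication}
  c0_ap_pls: {value: 0.0, units: uM, provenance: prior-publication}
  c0_fbg: {value: 8.0,    units: uM, provenance: prior-publication}
  c0_mg:  {value: 3.0,    units: uM, provenance: prior-publication}
  c0_pai: {value: 4.0e-4, units: uM, provenance: prior-publication}

solver:
  dx: {value: 2.0e-5, units: m, provenance: default}
  dt_report: {value: 1.0, units: s, provenance: default}
  rtol: {value: 1.0e-6, provenance: default}
  atol: {value: 1.0e-12, units: uM, provenance: default}
  t_max: {value: 1800.0, units: s, provenance: default}
  u_max: {value: 3.8e-5, units: m/s, provenance: default,
         comment: series resistance of the distal vascular bed caps permeation}
  snapshot_interval: {value: 30.0, units: s, provenance: default}
  bc_relax_tau: {value: 0.05, units: s, provenance: default}
  lysis_complete_threshold: {value: 0.95, provenance: default,
                             comment: mechanical integrity lost at E_L_crit}
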