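# Bovine-liver reference standard, nominal certified values (editable).
# Concentrations in mg/kg with 1-sigma absolute uncertainties; the organic
# residual is a protein-like C/H/N/O mix scaled so all mass fractions sum to 1.
# The pellet areal mass corresponds to 17.4 mg pressed into a self-supporting
# disc (13.1 mg/cm^2).
name: SRM-1577C-bovine-liver
areal_mass_g_per_cm2: 0.0131
certified_mg_per_kg:
  P:  {value: 11750.0, uncertainty: 270.0}
  S:  {value: 7490.0,  uncertainty: 340.0}
  Cl: {value: 2870.0,  uncertainty: 60.0}
  K:  {value: 10230.0, uncertainty: 640.0}
  Ca: {value: 131.0,   uncertainty: 10.0}
  Mn: {value: 10.46,   uncertainty: 0.47}
  Fe: {value: 197.94,  uncertainty: 0.65}
  Co: {value: 0.300,   uncertainty: 0.018}
  Ni: {value: 0.0445,  uncertainty: 0.0092}
  Cu: {value: 275.2,   uncertainty: 4.6}
  Zn: {value: 181.1,   uncertainty: 1.0}
  Se: {value: 2.031,   uncertainty: 0.045}
  Br: {value: 9.7,     uncertainty: 1.0}
  Rb: {value: 35.3,    uncertainty: 1.1}
  Sr: {value: 0.0953,  uncertainty: 0.0042}
  Pb: {value: 0.0628,  uncertainty: 0.0010}
organic_residual:
  H: 0.07
  C: 0.50
  N: 0.16
  O: 0.27
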