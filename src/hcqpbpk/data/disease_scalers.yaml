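# Disease-stage physiology scalers.
# Multipliers apply to the healthy individual's value; *_override entries are
# absolute replacements.  Magnitudes are editable defaults in the spirit of the
# staged hepatic-impairment physiology of Edginton & Willmann (2008) and
# Johnson et al. (2010) for Child-Pugh classes, and of published CKD physiology
# compilations for renal stages; only their DIRECTION is load-bearing for the
# package's qualification tests.
# hepatic_flow scales the whole splanchnic inflow (hepatic artery + gut + spleen),
# i.e. total hepatic blood flow QH.  enzyme_activity scales hepatic intrinsic
# clearance per CYP.  binding_protein scales the alpha-1 acid glycoprotein
# concentration (unbound fraction rises as 1/scalar).  GFR_override is in
# mL/min/1.73 m^2.  gastric_emptying_time / small_intestinal_transit_time are
# multipliers on the healthy times.
healthy: {}
CP-A:
  hepatic_flow: 0.60
  liver_volume: 0.90
  binding_protein: 0.88
  hematocrit: 0.95
  gfr: 0.90
  organ_flow: {kidney: 0.85, muscle: 0.90, skin: 0.90, adipose: 0.90}
  enzyme_activity: {CYP3A4: 0.60, CYP2C8: 0.70, CYP2D6: 0.85}
CP-B:
  hepatic_flow: 0.40
  liver_volume: 0.80
  binding_protein: 0.75
  hematocrit: 0.90
  gfr: 0.70
  organ_flow: {kidney: 0.70, muscle: 0.80, skin: 0.80, adipose: 0.80}
  enzyme_activity: {CYP3A4: 0.40, CYP2C8: 0.55, CYP2D6: 0.60}
CP-C:
  hepatic_flow: 0.25
  liver_volume: 0.67
  binding_protein: 0.50
  hematocrit: 0.85
  gfr: 0.50
  organ_flow: {kidney: 0.55, muscle: 0.70, skin: 0.70, adipose: 0.70}
  enzyme_activity: {CYP3A4: 0.25, CYP2C8: 0.40, CYP2D6: 0.40}
CKD-moderate:
  GFR_override: 45.0
  hematocrit: 0.92
  gastric_emptying_time: 1.40
  small_intestinal_transit_time: 1.15
CKD-severe:
  GFR_override: 20.0
  hematocrit: 0.82
  gastric_emptying_time: 1.80
  small_intestinal_transit_time: 1.30
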