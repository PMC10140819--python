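# Reference adult physiology (ICRP-89-style reference man/woman).
# Organ volumes in L at the reference body weight; blood flows are expressed as
# fractions of cardiac output and must sum to 1 exactly.  Values are rounded
# composites of ICRP Publication 89 and Brown et al. (1997) compilations, the
# standard sources for whole-body PBPK physiology.  An individual at weight W is
# obtained by multiplying volumes and flows by (W / body_weight)**allometric_exponent
# (default exponent 1; see physiology.build_reference_adult).
# GFR is body-surface-normalised (mL/min/1.73 m^2) and is not weight-scaled.
allometric_exponent: 1.0
reference:
  M:
    body_weight: 73.0        # kg
    cardiac_output: 360.0    # L/h (~6 L/min at rest)
    hematocrit: 0.45
    GFR: 110.0               # mL/min/1.73 m^2
    gastric_emptying_time: 15.0          # min, fasted
    small_intestinal_transit_time: 210.0 # min
    organ_volumes:           # L
      lung: 0.50
      liver: 1.80
      kidney: 0.31
      gut: 1.20
      muscle: 29.0
      adipose: 14.5
      skin: 3.30
      bone: 10.5
      brain: 1.45
      heart: 0.33
      spleen: 0.15
      rest: 3.90
      arterial_blood: 1.70
      venous_blood: 3.90
  F:
    body_weight: 60.0
    cardiac_output: 330.0
    hematocrit: 0.40
    GFR: 110.0
    gastric_emptying_time: 15.0
    small_intestinal_transit_time: 210.0
    organ_volumes:
      lung: 0.42
      liver: 1.40
      kidney: 0.275
      gut: 1.10
      muscle: 17.5
      adipose: 18.0
      skin: 2.30
      bone: 7.80
      brain: 1.30
      heart: 0.25
      spleen: 0.13
      rest: 3.50
      arterial_blood: 1.32
      venous_blood: 3.08
# Fraction of cardiac output perfusing each organ (arterial side).  'liver' is
# the hepatic ARTERY only; total hepatic blood flow QH = liver + gut + spleen
# (portal vein drains gut and spleen through the liver).
flow_fractions:
  liver: 0.065
  gut: 0.150
  spleen: 0.030
  kidney: 0.190
  muscle: 0.170
  adipose: 0.050
  skin: 0.050
  bone: 0.050
  brain: 0.120
  heart: 0.040
  rest: 0.085
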