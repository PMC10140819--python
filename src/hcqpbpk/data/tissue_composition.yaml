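# Tissue composition for mechanistic partition-coefficient calculation
# (Rodgers & Rowland scheme for ionised bases; Poulin & Theil alternative).
# f_ew / f_iw: fractional extracellular / intracellular water (v/v)
# f_nl / f_np: fractional neutral lipid / neutral phospholipid (v/v)
# ap:          acidic phospholipid content (mg/g tissue)
# Values are rounded composites of the published rat/human composition tables
# commonly used with these schemes; 'rest' (carcass remainder) uses muscle-like
# composition.  Bone water is taken at the upper end of published ranges so the
# aqueous limiting case stays near unity.
pH_plasma: 7.4
pH_intracellular: 7.0
pH_blood_cell: 7.22
blood_cells:
  f_iw: 0.603
  f_nl: 0.0017
  f_np: 0.0029
  ap: 0.50
tissues:
  adipose: {f_ew: 0.135, f_iw: 0.017, f_nl: 0.853, f_np: 0.0016, ap: 0.40}
  bone:    {f_ew: 0.120, f_iw: 0.400, f_nl: 0.017, f_np: 0.0017, ap: 0.67}
  brain:   {f_ew: 0.162, f_iw: 0.620, f_nl: 0.039, f_np: 0.0015, ap: 0.40}
  gut:     {f_ew: 0.282, f_iw: 0.475, f_nl: 0.038, f_np: 0.0125, ap: 2.41}
  heart:   {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014, f_np: 0.0111, ap: 2.25}
  kidney:  {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012, f_np: 0.0240, ap: 5.03}
  liver:   {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014, f_np: 0.0240, ap: 4.56}
  lung:    {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022, f_np: 0.0128, ap: 3.91}
  muscle:  {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010, f_np: 0.0072, ap: 1.53}
  skin:    {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060, f_np: 0.0044, ap: 1.32}
  spleen:  {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap: 3.18}
  rest:    {f_ew: 0.150, f_iw: 0.600, f_nl: 0.012, f_np: 0.0072, ap: 1.53}
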