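# Hydroxychloroquine (HCQ) drug record.
# Physicochemical and ADME inputs trace to the primary HCQ literature
# (Tett et al. 1988/1989/1992 whole-blood PK; McLachlan 1993 binding;
# Warhurst 2003 pKa).  logP and intestinal Peff are model-optimised values,
# treated here as fixed inputs.
name: hydroxychloroquine
molecular_weight: 335.87          # g/mol (free base)
logP: 2.4                         # optimised lipophilicity
pKa_values: [9.67, 8.27]          # diprotic base (most basic first)
fu_plasma: 0.48                   # fraction unbound in plasma (AGP-bound)
blood_to_plasma_ratio: 7.2        # whole blood : plasma, healthy reference
binding_partner: AGP              # alpha-1 acid glycoprotein
solubility_mg_per_ml: 5.0         # sulfate salt, phosphate buffer pH 7.2
solubility_pH: 7.2
intestinal_permeability_Peff: 1.06e-5   # cm/min, optimised
renal_plasma_clearance_CLR: 12.7  # L/h at reference GFR
salt_to_base_factor: 0.775        # 200 mg sulfate == 155 mg base

# Hepatic clearance block.  hepatic_blood_clearance is not a printed model
# input; default 4.0 L/h = total HCQ blood clearance ~5.76 L/h (96 mL/min,
# Tett 1988) minus renal blood clearance 12.7/7.2 = 1.76 L/h.  Intrinsic
# clearance is back-calculated from it with the well-stirred liver model.
clearance:
  hepatic_blood_clearance: 4.0    # L/h, CLH (whole blood)
  eq_form: as_printed             # as_printed | standard_well_stirred
  # Fractional CYP contributions to hepatic metabolism (editable defaults;
  # HCQ is de-alkylated mainly by CYP2D6/3A4 with a CYP2C8 component).
  enzyme_contributions: {CYP2D6: 0.45, CYP3A4: 0.35, CYP2C8: 0.20}
  # Typical adult hepatic abundances, pmol per mg microsomal protein.
  enzyme_abundance_pmol_per_mg: {CYP3A4: 137.0, CYP2C8: 24.0, CYP2D6: 8.0}
  mppgl_mg_per_g: 40.0            # microsomal protein per g liver
  liver_density_g_per_ml: 1.05

# Reference in-vitro clearances as reported for the source PBPK model
# (uL/min/pmol); recorded for comparison only, never used in simulation.
reported_invitro_clearance: {CYP2C8: 0.0078, CYP2D6: 0.025, CYP3A4: 0.002}

# Formulation / absorption defaults (oral route).
formulation:
  release_model: lint80
  dissolution_time_min: 300.0     # time to 80% released after lag
  lag_time_min: 60.0
  cap_release_at_80pct: false     # default: linear continuation to 100%
absorption:
  smooth_surface_area_cm2: 2200.0 # smooth small-intestine cylinder
  mucosal_amplification: 240.0    # folds/villi amplification; calibrated once
                                  # so oral bioavailability ~0.75 (Tett 1989)
  lumen_volume_ml: 350.0

partition_scheme: rodgers_rowland  # rodgers_rowland | poulin_theil
adipose_oil_correction: false
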