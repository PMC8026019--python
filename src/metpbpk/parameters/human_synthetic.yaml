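# Reference parameterization of the human (21-compartment) metformin PBPK model
# for a 70 kg subject. SYNTHETIC reference assembly: volumes follow standard
# human physiology (muscle 27.9 L, adipose 14.9 L, liver 1.8 L, ...); carrier
# kinetics are inherited from the mouse model and rescaled by intestinal surface
# area (71 m^2) times the absorption coefficient (0.7) for the five absorption
# reactions, and by the elimination coefficient (320) for the two renal
# secretion reactions. Partition coefficients are taken unchanged from the
# mouse model. Units: mL, mL/h, nmol, nmol/mL, 1/h, kg.
species: human
body_weight_kg: 70.0

physiology:
  total_volume_mL: 7.0e+4
  cardiac_output_plasma_mL_h: 184800.0   # 5.6 L/min blood x (1 - hct)
  gfr_mL_h: 7200.0                       # 120 mL/min
  urine_flow_mL_h: 60.0
  gastric_emptying_per_h: 3.0
  intestinal_transit_per_h: 0.4
  hematocrit: 0.45
  intestinal_surface_area_cm2: 7.1e+5    # 71 m^2
  protein_per_area_mg_cm2: 0.2           # "Proctor coefficient"
  volumes_mL:
    lungs: 510.0
    heart: 356.0
    brain: 1420.0
    muscle: 27900.0
    adipose: 14900.0
    stomach: 160.0
    stomach_lumen: 250.0
    liver: 1800.0
    portal_vein: 70.0
    arterial_plasma: 1000.0
    venous_plasma: 1900.0
    kidney_plasma: 25.0
    kidney: 306.0
    kidney_tubular: 15.0
    intestine_vascular: 150.0
    enterocytes: 712.0
    intestine_lumen: 25.0
    rbc: 2320.0
  flows_mL_h:
    heart: 7400.0
    brain: 22200.0
    muscle: 31400.0
    adipose: 9250.0
    stomach: 4600.0
    kidney: 35100.0
    intestine: 27700.0
    liver_arterial: 12000.0

scale_up:
  absorption_coef: 0.7
  elimination_coef: 320.0

kinetics_local:   # human whole-organ passive permeabilities and RBC exchange
  passive:
    enterocyte_exchange_Kd: 1000.0
    kidney_exchange_Kd: 800.0
  rbc:
    kin_mL_h: 64.0    # plasma -> RBC uptake clearance
    kout_mL_h: 72.0   # RBC -> plasma release clearance (sets ~22 h RBC washout)
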