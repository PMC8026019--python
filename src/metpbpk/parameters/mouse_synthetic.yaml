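# Reference parameterization of the mouse (20-compartment) metformin PBPK model.
#
# SYNTHETIC reference assembly: physiological volumes and plasma flows follow
# standard rodent physiology compendia for a 25 g mouse; partition coefficients
# are the fitted tissue:plasma values of the deposited model; intestinal carrier
# kinetics are expressed per mg of Caco-2 monolayer protein and rescaled to the
# whole organ via surface area x 0.2 mg protein/cm^2. Units: mL, mL/h, nmol,
# nmol/mL, 1/h, kg.
species: mouse
body_weight_kg: 0.025

physiology:
  total_volume_mL: 25.0
  cardiac_output_plasma_mL_h: 462.0
  gfr_mL_h: 15.0
  urine_flow_mL_h: 0.06
  gastric_emptying_per_h: 3.0
  intestinal_transit_per_h: 0.35
  hematocrit: null
  intestinal_surface_area_cm2: 3.0e+4   # 3 m^2
  protein_per_area_mg_cm2: 0.2
  volumes_mL:
    lungs: 0.175
    heart: 0.125
    brain: 0.425
    muscle: 9.5
    adipose: 1.75
    stomach: 0.15
    stomach_lumen: 0.3
    liver: 1.375
    portal_vein: 0.1
    arterial_plasma: 0.35
    venous_plasma: 0.5
    kidney_plasma: 0.05
    kidney: 0.34
    kidney_tubular: 0.05
    intestine_vascular: 0.25
    enterocytes: 0.35
    intestine_lumen: 1.0
  flows_mL_h:          # plasma flows; remainder = cardiac output - named
    heart: 30.0
    brain: 15.0
    muscle: 74.0
    adipose: 32.0
    stomach: 5.0
    kidney: 74.0
    intestine: 60.0
    liver_arterial: 10.0

partition_coefficients:   # fitted (estimated) tissue:plasma values
  intestine: 4.6
  stomach: 3.2
  liver: 5.5
  lungs: 3.0
  brain: 0.8
  muscle: 4.1
  adipose: 0.7
  heart: 2.5
  remainder: 0.8
  kidney: 4.5

kinetics:
  intestinal_per_mg_protein:   # Caco-2 monolayer values, per mg protein
    "03.2": {Vf: 0.02, Km: 2000.0}      # lumen -> enterocytes (PMAT/OCT3)
    "03.3": {Vmax: 0.0825, Km: 1500.0}  # enterocytes -> vascular (OCT1); whole-organ 495
    "03.4": {Vmax: 0.0233, Km: 2000.0}  # lumen -> vascular, saturable paracellular
    "03.6": {Kd: 3.2e-5}              # lumen -> enterocytes, diffusion
    "03.7": {Kd: 5.5e-5}              # lumen -> vascular, paracellular diffusion
  renal:                       # whole-organ active secretion
    "13.4": {Vmax: 12000.0, Km: 18.0}   # kidney plasma -> kidney tissue (OCT2)
    "13.5": {Vmax: 1700.0, Km: 40.0}    # kidney tissue -> tubular lumen (MATE1/2K, OCT1)
  passive:
    enterocyte_exchange_Kd: 2.0         # 03.8 vascular <-> enterocytes
    kidney_exchange_Kd: 4.0             # 13.6 kidney plasma <-> kidney tissue
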