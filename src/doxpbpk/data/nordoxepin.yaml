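# N-desmethyldoxepin (nordoxepin) compound parameterization (active metabolite).
# total_hepatic_clearance_L_min is an intrinsic clearance referenced to the
# unbound liver water concentration (lumps the non-CYP2D6 routes).
name: nordoxepin
molecular_weight: 265.35
log_p: 3.60
pka: 10.47
compound_type: base
fraction_unbound: 0.21
solubility_mg_per_L: 0.00361
solubility_ph: 7.0
intestinal_permeability_cm_min: 7.87e-4
organ_permeability_cm_min: 0.33
partition_method: schmitt
blood_plasma_ratio: 1.0
total_hepatic_clearance_L_min: 2.50
pathways:
  - enzyme: CYP2D6
    km_uM: 40.0
    kcat_per_min: 160.0
    reference_concentration_uM: 0.40
    product: inactive
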