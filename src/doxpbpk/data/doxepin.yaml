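# Doxepin compound parameterization (parent drug).
# Units: molecular_weight g/mol; km_uM umol/L; kcat_per_min 1/min;
# reference_concentration_uM umol/L; solubility mg/L; permeabilities cm/min.
name: doxepin
molecular_weight: 279.37
log_p: 3.70
pka: 9.76
compound_type: base
fraction_unbound: 0.20
solubility_mg_per_L: 31.60
solubility_ph: 7.0
intestinal_permeability_cm_min: 7.86e-4
organ_permeability_cm_min: 0.30
partition_method: rodgers_rowland
blood_plasma_ratio: 1.0
pathways:
  - enzyme: CYP2C19
    km_uM: 5.0
    kcat_per_min: 28.0
    reference_concentration_uM: 0.76
    product: metabolite
  - enzyme: CYP2D6
    km_uM: 88.0
    kcat_per_min: 260.0
    reference_concentration_uM: 0.40
    product: inactive
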