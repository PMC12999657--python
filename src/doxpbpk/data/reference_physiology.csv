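organ,volume_L,flow_L_per_min
lung,0.50,
brain,1.45,0.700
heart,0.33,0.240
kidney,0.31,1.240
liver,1.80,0.300
gut,1.10,0.900
spleen,0.15,0.077
stomach,0.15,0.038
muscle,26.0,0.750
adipose,13.0,0.260
skin,3.30,0.300
bone,9.00,0.250
rest,2.40,0.300
arterial_blood,1.70,
venous_blood,3.90,
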