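compound,study,cyp2d6,n,female_percent,age_min,age_max,weight_min,weight_max,dose_mg,formulation
doxepin,geister,non-genotyped,30,63,22,50,55,90,75,capsule_immediate
doxepin,kirchheiner,NM,19,0,23,35,50,93,75,tablet_weibull
doxepin,kirchheiner,IM,8,0,26,42,63.0,87.4,75,tablet_weibull
doxepin,kirchheiner,PM,11,0,28,56,69.4,86.2,75,tablet_weibull
doxepin,kirchheiner,UM,11,0,22,44,65.9,92.1,75,tablet_weibull
nordoxepin,geister,non-genotyped,30,63,22,50,55,90,75,capsule_immediate
nordoxepin,kirchheiner,NM,19,0,23,35,50,93,75,tablet_weibull
nordoxepin,kirchheiner,IM,8,0,26,42,63.0,87.4,75,tablet_weibull
nordoxepin,kirchheiner,PM,11,0,32,60,69.4,86.2,75,tablet_weibull
nordoxepin,kirchheiner,UM,11,0,22,44,65.9,92.1,75,tablet_weibull
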