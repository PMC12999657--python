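label,compound,cyp2d6,metric,observed,predicted,unit
geister,doxepin,non-genotyped,AUC,692.47,709.02,nmol*hr/L
geister,doxepin,non-genotyped,Cmax,57.13,55.85,nmol/L
geister,doxepin,non-genotyped,Tmax,1.98,1.40,h
kirchheiner,doxepin,NM,AUC,398.00,504.66,nmol*hr/L
kirchheiner,doxepin,NM,Cmax,35.00,43.97,nmol/L
kirchheiner,doxepin,IM,AUC,933.00,1031.62,nmol*hr/L
kirchheiner,doxepin,IM,Cmax,62.00,60.26,nmol/L
kirchheiner,doxepin,PM,AUC,2291.00,2315.53,nmol*hr/L
kirchheiner,doxepin,PM,Cmax,100.00,78.72,nmol/L
kirchheiner,doxepin,UM,AUC,331.00,379.95,nmol*hr/L
kirchheiner,doxepin,UM,Cmax,26.00,36.19,nmol/L
geister,nordoxepin,non-genotyped,AUC,1121.40,955.80,nmol*hr/L
geister,nordoxepin,non-genotyped,Cmax,24.64,25.10,nmol/L
geister,nordoxepin,non-genotyped,Tmax,4.52,5.55,h
kirchheiner,nordoxepin,NM,AUC,562.00,628.00,nmol*hr/L
kirchheiner,nordoxepin,NM,Cmax,25.00,19.14,nmol/L
kirchheiner,nordoxepin,IM,AUC,912.00,1194.33,nmol*hr/L
kirchheiner,nordoxepin,IM,Cmax,28.00,28.42,nmol/L
kirchheiner,nordoxepin,PM,AUC,1820.00,4640.32,nmol*hr/L
kirchheiner,nordoxepin,PM,Cmax,42.00,49.53,nmol/L
kirchheiner,nordoxepin,UM,AUC,200.00,342.48,nmol*hr/L
kirchheiner,nordoxepin,UM,Cmax,16.00,13.42,nmol/L
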