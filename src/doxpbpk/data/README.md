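# Bundled reference data

- `doxepin.yaml`, `nordoxepin.yaml` — compound parameter files (physicochemistry,
  ADME, Michaelis–Menten pathway constants) for the parent drug and its active
  metabolite, in the printed literature units.
- `tissue_composition.csv` — per-tissue fractional composition (extracellular /
  intracellular water, neutral lipid, neutral phospholipid volume fractions and
  acidic phospholipid concentration in mg/g) used by the Rodgers–Rowland and
  Schmitt-style tissue:plasma partition calculations. Values are representative
  entries from the published Rodgers–Rowland (2005/2006) composition lineage;
  `stomach` carries gut-like surrogate values and `rest` a muscle-like average,
  since the original tables do not enumerate those lumped compartments.
- `reference_physiology.csv` — organ volumes (L) and regional blood flows
  (L/min) for a 70 kg reference adult, ICRP-style rounded values. The `liver`
  flow is the hepatic-artery flow; portal inflow is the sum of gut, spleen and
  stomach outflows. The lung receives the whole cardiac output and has no
  arterial flow entry.
- `study_demographics.csv` — demographic and dose characteristics of the
  clinical study groups (non-genotyped development group and the four CYP2D6
  genotype groups) used to parameterize virtual populations.
- `observed_predicted.csv` — observed and reported-predicted AUC(0–inf)
  (nmol·hr/L), Cmax (nmol/L) and Tmax (h) per study group and compound; the
  fixture the fold-error / GMFE evaluation arithmetic is checked against.
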