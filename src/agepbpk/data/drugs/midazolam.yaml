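# Midazolam — short-acting benzodiazepine, prototypical hepatic + intestinal
# CYP3A4 substrate.  Values assembled from published clinical-pharmacology
# data for healthy adults; the whole-liver and whole-gut intrinsic
# clearances are in-vivo values calibrated so the reference adult model
# reproduces observed systemic clearance (~0.4-0.5 L/min) and oral
# bioavailability (~0.3).
name: midazolam
molecular_weight: 325.77          # g/mol
peff: 4.5                         # effective jejunal permeability, 1e-4 cm/s
fu_p_adult: 0.032                 # unbound fraction in plasma
rb: 0.66                          # blood:plasma concentration ratio
binding_protein: ALB
clint_l_adult: 360.0              # uL/min/mg microsomal protein (in vivo)
clint_i_adult: 500.0              # L/h, whole-intestine intrinsic clearance
cyp3a_abundance_intestine_adult: 70500.0   # pmol, total mucosal CYP3A
intestinal_abundance_fraction: {duodenum: 0.20, jejunum: 0.57, ileum: 0.23}
renal_cl_adult: 0.1               # L/h (renal excretion of parent is minor)
ktp:                              # tissue:plasma partition coefficients
  lung: 1.0
  brain: 1.3
  heart: 1.7
  muscle: 1.3
  adipose: 3.0
  skin: 1.5
  spleen: 1.6
  kidney: 2.0
  liver: 2.5
  duodenum: 2.0
  jejunum: 2.0
  ileum: 2.0
  cecum: 2.0
  colon: 2.0
  rest: 1.1
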