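# Fentanyl — high-extraction synthetic opioid, hepatic CYP3A4 substrate,
# extensive tissue distribution (Vss ~4 L/kg).  AAG is the dominant binding
# protein.  Whole-liver intrinsic clearance calibrated to an adult systemic
# clearance of ~0.8 L/min.
name: fentanyl
molecular_weight: 336.47
peff: 4.0
fu_p_adult: 0.16
rb: 1.0
binding_protein: AAG
clint_l_adult: 141.0
clint_i_adult: 40.0
cyp3a_abundance_intestine_adult: 70500.0
intestinal_abundance_fraction: {duodenum: 0.20, jejunum: 0.57, ileum: 0.23}
renal_cl_adult: 3.0
ktp:
  lung: 3.0
  brain: 4.0
  heart: 3.0
  muscle: 3.5
  adipose: 10.0
  skin: 3.0
  spleen: 3.5
  kidney: 4.5
  liver: 4.5
  duodenum: 4.0
  jejunum: 4.0
  ileum: 4.0
  cecum: 4.0
  colon: 4.0
  rest: 2.5
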