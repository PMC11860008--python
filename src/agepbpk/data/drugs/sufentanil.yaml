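# Sufentanil — highly potent, highly lipophilic opioid (Vss ~2.5-3 L/kg),
# AAG-bound CYP3A4 substrate.  Whole-liver intrinsic clearance calibrated to
# an adult systemic clearance of ~0.75 L/min.
name: sufentanil
molecular_weight: 386.55
peff: 4.0
fu_p_adult: 0.075
rb: 0.75
binding_protein: AAG
clint_l_adult: 380.0
clint_i_adult: 40.0
cyp3a_abundance_intestine_adult: 70500.0
intestinal_abundance_fraction: {duodenum: 0.20, jejunum: 0.57, ileum: 0.23}
renal_cl_adult: 0.5
ktp:
  lung: 3.0
  brain: 3.0
  heart: 3.0
  muscle: 2.5
  adipose: 6.0
  skin: 2.5
  spleen: 3.0
  kidney: 3.5
  liver: 3.0
  duodenum: 3.0
  jejunum: 3.0
  ileum: 3.0
  cecum: 3.0
  colon: 3.0
  rest: 2.0
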