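# Alfentanil — low-extraction opioid with a small distribution volume
# (Vss ~0.4-0.6 L/kg) and rapid onset; AAG-bound CYP3A4 substrate.
# Whole-liver intrinsic clearance calibrated to an adult systemic clearance
# of ~0.25 L/min.
name: alfentanil
molecular_weight: 416.52
peff: 4.0
fu_p_adult: 0.10
rb: 0.63
binding_protein: AAG
clint_l_adult: 46.0
clint_i_adult: 25.0
cyp3a_abundance_intestine_adult: 70500.0
intestinal_abundance_fraction: {duodenum: 0.20, jejunum: 0.57, ileum: 0.23}
renal_cl_adult: 0.3
ktp:
  lung: 0.5
  brain: 0.3
  heart: 0.5
  muscle: 0.5
  adipose: 0.15
  skin: 0.4
  spleen: 0.5
  kidney: 0.6
  liver: 0.7
  duodenum: 0.5
  jejunum: 0.5
  ileum: 0.5
  cecum: 0.5
  colon: 0.5
  rest: 0.5
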