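# Age-resolved human physiology tables for the whole-body PBPK model.
#
# Units are stated per block.  Organ volumes are expressed as fractions of
# body weight (organ density ~1 g/mL) interpolated linearly in age between
# the listed reference ages (newborn, 1, 5, 10, 15 y and adult); perfusion
# is expressed as fractions of cardiac output on the same grid.  The values
# are assembled from standard reference-anatomy compilations for healthy
# subjects (ICRP-style reference individuals, sex-averaged).

adult_reference_age: 30.0

# Rational growth curves Y = (a + b*A)/(1 + c*A + d*A^2), fitted to
# sex-averaged reference anthropometry; separate coefficient sets per age
# segment (infancy, childhood/adolescence, adulthood/senescence).
growth:
  body_weight:          # kg
    - {max_age: 3.0,  a: 3.4699174,  b: 14.426092,   c: 0.88413959,   d: -0.039668451}
    - {max_age: 18.0, a: 10.439141,  b: 0.29644179,  c: -0.079974109, d: 0.0020900732}
    - {max_age: .inf, a: 58.156661,  b: 0.39542883,  c: -0.0033982936, d: 9.9316666e-05}
  height:               # cm
    - {max_age: 3.0,  a: 50.218974,  b: 122.12432,   c: 1.3960488,    d: -0.096889829}
    - {max_age: 18.0, a: 79.594688,  b: 2.4897092,   c: -0.037235807, d: 0.0012104783}
    - {max_age: .inf, a: 169.71708,  b: -0.30401807, c: -0.0025758052, d: 1.2839764e-05}

cardiac_output:
  adult_L_h: 390.0        # ~6.5 L/min at the 70-kg reference adult
  reference_bw: 70.0      # kg
  allometric_exponent: 0.75

body_volume_per_kg: 0.952   # L/kg; whole-body density ~1.05 g/mL
liver_density_g_per_ml: 1.0
arterial_blood_fraction: 0.333333   # of total blood volume

# Senescence beyond age 40: cardiac output declines ~0.7 %/y; hepatic and
# renal perfusion carry small organ-specific extras on top of the CO
# decline so that, combined, hepatic flow reaches ~57 % and renal flow
# ~70 % of the young-adult value by ~age 90; liver volume declines to
# ~70 % over the same span.
elderly:
  onset_age: 40.0
  cardiac_output_decline_per_year: 0.0070
  liver_volume_decline_per_year: 0.0060
  hepatic_flow_decline_per_year: 0.0022
  renal_flow_decline_per_year: 0.0010
  floor: 0.40

# Tissues drained by the portal vein (their venous outflow enters the liver).
hepatic_inflow_tissues: [spleen, duodenum, jejunum, ileum, cecum, colon]

hepatic_artery_flow_fraction:
  ages: [0, 1, 5, 10, 15, 20]
  values: [0.065, 0.065, 0.065, 0.065, 0.065, 0.065]

tissues:
  liver:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0370, 0.0330, 0.0300, 0.0260, 0.0235, 0.0257]}
  kidney:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0071, 0.0070, 0.0058, 0.0056, 0.0045, 0.0044]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.080, 0.140, 0.170, 0.180, 0.190, 0.190]}
  spleen:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0027, 0.0029, 0.0026, 0.0025, 0.0023, 0.0026]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.030, 0.030, 0.030, 0.030, 0.030, 0.030]}
  heart:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0057, 0.0050, 0.0045, 0.0044, 0.0041, 0.0047]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.030, 0.035, 0.040, 0.040, 0.040, 0.040]}
  brain:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.1090, 0.0950, 0.0690, 0.0440, 0.0254, 0.0207]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.140, 0.180, 0.220, 0.180, 0.130, 0.120]}
  muscle:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.220, 0.190, 0.280, 0.330, 0.400, 0.400]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.100, 0.100, 0.130, 0.150, 0.170, 0.170]}
  adipose:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.140, 0.230, 0.200, 0.220, 0.210, 0.193]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.030, 0.050, 0.050, 0.050, 0.050, 0.050]}
  skin:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.050, 0.040, 0.040, 0.040, 0.045, 0.047]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.050, 0.050, 0.050, 0.050, 0.050, 0.050]}
  lung:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0150, 0.0130, 0.0110, 0.0090, 0.0080, 0.0076]}
  blood:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.080, 0.080, 0.078, 0.077, 0.077, 0.077]}
  stomach:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0021, 0.0021, 0.0021, 0.0021, 0.0021, 0.0021]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.010, 0.010, 0.010, 0.010, 0.010, 0.010]}
  duodenum:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0010, 0.0010, 0.0010, 0.0010, 0.0010, 0.0010]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.015, 0.015, 0.015, 0.015, 0.015, 0.015]}
  jejunum:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0050, 0.0050, 0.0050, 0.0050, 0.0050, 0.0050]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.045, 0.045, 0.045, 0.045, 0.045, 0.045]}
  ileum:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0036, 0.0036, 0.0036, 0.0036, 0.0036, 0.0036]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.035, 0.035, 0.035, 0.035, 0.035, 0.035]}
  cecum:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0011, 0.0011, 0.0011, 0.0011, 0.0011, 0.0011]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.015, 0.015, 0.015, 0.015, 0.015, 0.015]}
  colon:
    volume_fraction: {ages: [0, 1, 5, 10, 15, 20], values: [0.0057, 0.0057, 0.0057, 0.0057, 0.0057, 0.0057]}
    flow_fraction:   {ages: [0, 1, 5, 10, 15, 20], values: [0.035, 0.035, 0.035, 0.035, 0.035, 0.035]}

# Gastric emptying: band midpoints of reported mean residence times.
gastric_emptying:
  - {max_age: 0.0767, minutes: 68.0}    # newborns (0-27 days)
  - {max_age: 2.0,    minutes: 41.0}    # infants
  - {max_age: 12.0,   minutes: 41.0}    # children
  - {max_age: 19.0,   minutes: 75.0}    # adolescents
  - {max_age: .inf,   minutes: 62.5}    # adults

# Mean segmental residence times (min); age-invariant by assumption.
intestinal_transit_min:
  duodenum: 15.0
  jejunum: 95.0
  ileum: 110.0
  cecum: 270.0
  colon: 810.0
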