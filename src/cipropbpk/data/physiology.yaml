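# Reference physiology: organ volumes as fractions of body weight and blood
# flows as fractions of cardiac output, by sex.
#
# These are synthetic stand-in defaults assembled from standard
# reference-man / reference-woman compilations; the modelling code never
# hard-codes them, so the table can be swapped for any preferred source.
#
# Conventions:
#   * flow fractions refer to the parallel systemic circuit and must sum to 1
#     per sex; the lung sits in series and carries the whole cardiac output.
#   * "liver" flow is total hepatic perfusion. In this all-parallel topology
#     the gut and spleen drain directly into the venous pool (no portal
#     chaining), so their fractions are trimmed to keep the circuit closed.
#   * "rest" lumps everything not named (bone, connective tissue, ...); its
#     volume and flow close the mass and flow balances exactly.
reference:
  cardiac_output_ref: {male: 390.0, female: 330.0}   # l/h at ref_weight
  ref_weight: {male: 73.0, female: 60.0}             # kg
  co_exponent: 0.75                                  # allometric CO scaling
  arterial_fraction: 0.3333333333333333              # arterial:venous = 1:2
blood:
  volume_fraction: {male: 0.079, female: 0.065}
tissues:
  lung:    {volume_fraction: {male: 0.0076, female: 0.0073}, flow_fraction: {male: 1.0,   female: 1.0}}
  brain:   {volume_fraction: {male: 0.0200, female: 0.0210}, flow_fraction: {male: 0.114, female: 0.120}}
  heart:   {volume_fraction: {male: 0.0047, female: 0.0042}, flow_fraction: {male: 0.040, female: 0.050}}
  skin:    {volume_fraction: {male: 0.0371, female: 0.0388}, flow_fraction: {male: 0.050, female: 0.050}}
  muscle:  {volume_fraction: {male: 0.4000, female: 0.2900}, flow_fraction: {male: 0.160, female: 0.120}}
  adipose: {volume_fraction: {male: 0.2100, female: 0.3200}, flow_fraction: {male: 0.050, female: 0.075}}
  spleen:  {volume_fraction: {male: 0.0026, female: 0.0024}, flow_fraction: {male: 0.025, female: 0.025}}
  git:     {volume_fraction: {male: 0.0171, female: 0.0176}, flow_fraction: {male: 0.130, female: 0.140}}
  liver:   {volume_fraction: {male: 0.0257, female: 0.0240}, flow_fraction: {male: 0.215, female: 0.215}}
  kidney:  {volume_fraction: {male: 0.0044, female: 0.0044}, flow_fraction: {male: 0.180, female: 0.170}}
  rest:    {volume_fraction: {male: 0.1918, female: 0.2053}, flow_fraction: {male: 0.036, female: 0.035}}
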