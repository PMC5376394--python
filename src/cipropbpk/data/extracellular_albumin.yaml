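# Ratio of albumin concentration in extracellular (interstitial) fluid to
# plasma, E/P, per tissue. Used to convert total tissue concentrations to
# unbound extracellular concentrations:
#     fue = 1 / (1 + E/P * (1 - fu_plasma) / fu_plasma)
#
# Synthetic stand-in defaults patterned on rodent interstitial-albumin data;
# brain and lung use the albumin-poor CSF / epithelial-lining-fluid side of
# the reported ranges. Replace freely; all conversions read this file.
e_over_p:
  lung: 0.20
  brain: 0.40
  heart: 0.60
  skin: 0.87
  muscle: 0.56
  adipose: 0.42
  spleen: 0.85
  git: 0.70
  liver: 0.85
  kidney: 0.60
  rest: 0.60
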