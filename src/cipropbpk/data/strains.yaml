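# E. coli strain panel for time-kill simulation.
#
# MICs marked source: reported come from the published strain panel
# (LM347 0.023, LM625 0.50, LM707 48 mg/l); the remaining MICs are
# documented defaults placed inside the reported 0.023-48 mg/l range.
# All kill-rate parameters (emax_kill, the MIC->EC50 scaling, hill,
# resistant-subpopulation EC50 multiplier) are reconstruction defaults,
# not published values; scenario outputs that depend on them are
# qualitative.
defaults:
  emax_kill: 6.0            # h^-1, maximal drug-induced kill rate
  ec50_per_mic: 1.0         # EC50 = ec50_per_mic * MIC
  hill: 1.0
  resistant_ec50_factor: 10.0
strains:
  LM347: {mic: 0.023, source: reported}
  LM202: {mic: 0.125, source: default}
  LM378: {mic: 0.25,  source: default}
  LM625: {mic: 0.50,  source: reported}
  LM693: {mic: 32.0,  source: default}
  LM707: {mic: 48.0,  source: reported}
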