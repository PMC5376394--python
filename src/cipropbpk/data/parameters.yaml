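# Default drug-specific parameter set for ciprofloxacin.
#
# "priors" are the literature-informed typical values (with log-scale
# uncertainty expressed as a fractional SD) used to penalize the population
# fit; "estimates" are the published population estimates used as the default
# simulation parameter set. The rest-compartment prior is derived at load time
# as the arithmetic mean of the ten tissue priors and is therefore not listed.
drug:
  fu_plasma: 0.65          # unbound fraction in plasma
  crcl_to_clr: 0.06        # ml/min -> l/h conversion in the renal model
priors:
  cl_nr:       {mode: 7.17,  cv: 0.25}   # l/h
  f_secretion: {mode: 0.57,  cv: 0.25}
  kp_lung:     {mode: 3.3,   cv: 0.25}
  kp_brain:    {mode: 0.771, cv: 0.25}
  kp_heart:    {mode: 3.67,  cv: 0.25}
  kp_skin:     {mode: 0.718, cv: 0.25}
  kp_muscle:   {mode: 1.6,   cv: 0.25}
  kp_adipose:  {mode: 0.449, cv: 0.25}
  kp_spleen:   {mode: 1.954, cv: 0.25}
  kp_git:      {mode: 3.39,  cv: 0.25}
  kp_liver:    {mode: 3.67,  cv: 0.25}
  kp_kidney:   {mode: 8.2,   cv: 0.25}
estimates:
  log_scale:
    cl_nr: 2.60
    kp_lung: 1.20
    kp_brain: -0.257
    kp_heart: 1.30
    kp_skin: -0.335
    kp_muscle: -0.0229
    kp_adipose: -0.885
    kp_spleen: 0.668
    kp_git: 1.21
    kp_liver: 1.27
    kp_kidney: 2.09
    kp_rest: 1.35
  normal_scale:
    cl_nr: 13.5
    f_secretion: 0.674
    kp_lung: 3.32
    kp_brain: 0.773
    kp_heart: 3.67
    kp_skin: 0.715
    kp_muscle: 0.977
    kp_adipose: 0.413
    kp_spleen: 1.95
    kp_git: 3.35
    kp_liver: 3.56
    kp_kidney: 8.09
    kp_rest: 3.86
variability:
  iiv_cl_cv: 0.56          # inter-individual CV on total clearance
  iiv_kp_cv: 0.55          # shared inter-individual CV on all Kp
  sigma_log: 0.33          # additive residual SD on log concentration
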