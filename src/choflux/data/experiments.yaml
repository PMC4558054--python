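# Reference culture definitions: two media (Biogro-CHO, PowerCHO-2),
# each as a batch and a daily-fed fed-batch, inoculated at 0.2e6 cells/mL.
# The PowerCHO base glucose level is a reconstructed value.
media:
  Biogro:
    base_state:
      GLC: 25.0
      LAC: 2.0
      NH4: 0.3
      GLN: 4.0
      GLU: 0.5
      ALA: 0.3
      ASP: 0.4
      ASN: 1.0
      SER: 1.0
      GLY: 0.7
      ARG: 1.2
      HIS: 0.4
      ILE: 1.6
      LYS: 1.0
      MET: 0.4
      PHE: 0.6
      PRO: 0.8
      THR: 1.0
      TRP: 0.15
      TYR: 0.5
      VAL: 1.2
      G6P: 1.0e-07
      F6P: 3.0e-08
      FBP: 3.0e-08
      PEP: 1.0e-08
      PYR: 1.0e-07
      CIT: 5.0e-07
      AKG: 5.0e-08
      MAL: 3.0e-07
      R5P: 2.0e-08
      EGLU: 4.0e-06
      ATP: 2.0e-05
      ADP: 5.0e-06
      AMP: 1.0e-06
      NAD: 2.0e-06
      NADH: 2.0e-07
      NADP: 2.0e-07
      NADPH: 1.0e-07
      Xv: 0.2
      mAb: 0.0
      V: 1.0
  PowerCHO:
    base_state:
      GLC: 30.0
      LAC: 1.5
      NH4: 0.3
      GLN: 6.5
      GLU: 0.6
      ALA: 0.4
      ASP: 1.2
      ASN: 3.0
      SER: 2.8
      GLY: 0.9
      ARG: 2.4
      HIS: 0.6
      ILE: 3.2
      LYS: 1.4
      MET: 0.6
      PHE: 0.9
      PRO: 1.1
      THR: 1.4
      TRP: 0.25
      TYR: 0.8
      VAL: 1.8
      G6P: 1.0e-07
      F6P: 3.0e-08
      FBP: 3.0e-08
      PEP: 1.0e-08
      PYR: 1.0e-07
      CIT: 5.0e-07
      AKG: 5.0e-08
      MAL: 3.0e-07
      R5P: 2.0e-08
      EGLU: 4.0e-06
      ATP: 2.0e-05
      ADP: 5.0e-06
      AMP: 1.0e-06
      NAD: 2.0e-06
      NADH: 2.0e-07
      NADP: 2.0e-07
      NADPH: 1.0e-07
      Xv: 0.2
      mAb: 0.0
      V: 1.0
cultures:
- name: biogro-batch
  medium: Biogro
  mode: batch
  duration_h: 144
  sampling_interval_h: 12
  initial_state:
    GLC: 25.0
    GLN: 4.0
- name: biogro-fedbatch
  medium: Biogro
  mode: fed-batch
  duration_h: 192
  sampling_interval_h: 24
  initial_state:
    GLC: 10.0
    GLN: 2.4
  feed:
    GLU: 0.5
    ALA: 0.3
    ASP: 0.4
    ASN: 1.0
    SER: 1.0
    GLY: 0.7
    ARG: 1.2
    HIS: 0.4
    ILE: 1.6
    LYS: 1.0
    MET: 0.4
    PHE: 0.6
    PRO: 0.8
    THR: 1.0
    TRP: 0.15
    TYR: 0.5
    VAL: 1.2
    GLC: 130.0
    GLN: 25.0
  policy:
    interval_h: 24.0
    first_feed_h: 24.0
    glucose_floor_mM: 10.0
    mode: daily
- name: powercho-batch
  medium: PowerCHO
  mode: batch
  duration_h: 216
  sampling_interval_h: 24
  initial_state:
    GLC: 30.0
    GLN: 6.5
- name: powercho-fedbatch
  medium: PowerCHO
  mode: fed-batch
  duration_h: 360
  sampling_interval_h: 24
  initial_state:
    GLC: 30.0
    GLN: 6.5
  feed:
    GLU: 1.5
    ALA: 1.0
    ASP: 3.0
    ASN: 7.5
    SER: 7.0
    GLY: 2.25
    ARG: 6.0
    HIS: 1.5
    ILE: 8.0
    LYS: 3.5
    MET: 1.5
    PHE: 2.25
    PRO: 2.75
    THR: 3.5
    TRP: 0.625
    TYR: 2.0
    VAL: 4.5
    GLC: 100.0
    GLN: 16.0
  policy:
    interval_h: 24.0
    first_feed_h: 24.0
    glucose_floor_mM: 10.0
    mode: daily
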