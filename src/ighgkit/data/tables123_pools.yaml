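schema: ighgkit-sim-pools/1
comment: 'Default ''tables123'' cohort structure: per-population multigene haplotype
  pools transcribed from the printed allotype frequency tables (renormalized) and
  coupled to reproduce the published haplotype counts and sharing pattern.'
member_splits:
  IGHG1*02:
    IGHG1*02: 0.7
    IGHG1*05: 0.2
    IGHG1*09: 0.1
  IGHG2*03:
    IGHG2*03: 0.8
    IGHG2*05: 0.2
populations:
  EA:
    n_samples: 95
    haplotypes:
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*03
      freq: 0.33
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*02
      freq: 0.25
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*02
      freq: 0.08
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*03
      freq: 0.04
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.13
    - g3: IGHG3*07
      hinge_exons: 4
      g1: IGHG1*07
      g2: IGHG2*02
      freq: 0.066
    - g3: IGHG3*07
      hinge_exons: 4
      g1: IGHG1*07
      g2: IGHG2*03
      freq: 0.023
    - g3: IGHG3*12
      hinge_exons: 3
      g1: IGHG1*07
      g2: IGHG2*03
      freq: 0.037
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*02
      freq: 0.028
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*08
      g2: IGHG2*11
      freq: 0.011
    - g3: IGHG3*11
      hinge_exons: 5
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.005
  AA:
    n_samples: 94
    haplotypes:
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.11
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.103
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n3
      freq: 0.09
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*02
      freq: 0.0746
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n1
      freq: 0.0051
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*n3
      g2: IGHG2*03
      freq: 0.0112
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*n4
      g2: IGHG2*06
      freq: 0.0112
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*08
      g2: IGHG2*06
      freq: 0.0052
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0678
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*n3
      freq: 0.0719
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0373
    - g3: IGHG3*07
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0524
    - g3: IGHG3*13
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0388
    - g3: IGHG3*16
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0335
    - g3: IGHG3*17
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0335
    - g3: IGHG3*22
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n3
      freq: 0.009
    - g3: IGHG3*22
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0088
    - g3: IGHG3*08
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0094
    - g3: IGHG3*04
      hinge_exons: 2
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0052
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*03
      freq: 0.11
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*02
      freq: 0.038
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*08
      g2: IGHG2*n1
      freq: 0.006
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*03
      freq: 0.0211
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0255
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*07
      g2: IGHG2*03
      freq: 0.0095
    - g3: IGHG3*12
      hinge_exons: 3
      g1: IGHG1*07
      g2: IGHG2*03
      freq: 0.012
  SA:
    n_samples: 94
    haplotypes:
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.13
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.1821
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n3
      freq: 0.0757
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n9
      freq: 0.0461
    - g3: IGHG3*01
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*15
      freq: 0.007
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0699
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0594
    - g3: IGHG3*03
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*15
      freq: 0.0053
    - g3: IGHG3*13
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0692
    - g3: IGHG3*n3
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n3
      freq: 0.0606
    - g3: IGHG3*17
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0567
    - g3: IGHG3*01m
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0423
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0279
    - g3: IGHG3*14
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*02
      freq: 0.0154
    - g3: IGHG3*n5
      hinge_exons: 3
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0356
    - g3: IGHG3*26
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*03
      freq: 0.0356
    - g3: IGHG3*22
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n10
      freq: 0.0288
    - g3: IGHG3*08
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*06
      freq: 0.0221
    - g3: IGHG3*n7
      hinge_exons: 4
      g1: IGHG1*02
      g2: IGHG2*n12
      freq: 0.0154
    - g3: IGHG3*11
      hinge_exons: 4
      g1: IGHG1*03
      g2: IGHG2*03
      freq: 0.0149
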