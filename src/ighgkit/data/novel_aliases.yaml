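schema: ighgkit-novel-aliases/1
comment: Published names for allotypes outside the IMGT catalog; Gm strings as-published.
aliases:
- gene: IGHG1
  published_name: IGHG1*n3
  gm: 17, 1, 27
  vector: SIKDLDLIA
  gm_provenance: as-published
  nt:
    G1_CH1_290: A
    G1_CH2_146: T
    G1_CH2_178: T
    G1_CH3_47: T
    G1_CH3_51: C
    G1_CH3_243: A
    G1_CH3_271: C
- gene: IGHG1
  published_name: IGHG1*n4
  gm: 17, 1
  vector: SIKEPDLVA
  gm_provenance: as-published
  nt:
    G1_CH1_290: A
    G1_CH2_146: A
    G1_CH2_178: C
    G1_CH3_47: T
    G1_CH3_51: C
    G1_CH3_243: G
    G1_CH3_271: C
- gene: IGHG1
  published_name: IGHG1*1K1
  gm: '17'
  vector: SIKDPEMVA
  gm_provenance: as-published
  nt:
    G1_CH1_290: A
    G1_CH2_146: T
    G1_CH2_178: C
    G1_CH3_47: G
    G1_CH3_51: A
    G1_CH3_243: G
    G1_CH3_271: C
- gene: IGHG1
  published_name: IGHG1*1K2
  gm: 17, 2
  vector: SIKDPEMVG
  gm_provenance: as-published
  nt:
    G1_CH1_290: A
    G1_CH2_146: T
    G1_CH2_178: C
    G1_CH3_47: G
    G1_CH3_51: A
    G1_CH3_243: G
    G1_CH3_271: G
- gene: IGHG1
  published_name: IGHG1*1K3
  gm: '3'
  vector: CIRDPEMVA
  gm_provenance: as-published
- gene: IGHG1
  published_name: IGHG1*1K4
  gm: '3'
  vector: STRDPEMVA
  gm_provenance: as-published
- gene: IGHG1
  published_name: IGHG1*1K5
  gm: '3'
  vector: STRDPDLVA
  gm_provenance: as-published
- gene: IGHG2
  published_name: IGHG2*n1
  gm: '23'
  vector: TSLKMVAKVV
  gm_provenance: as-published
  nt:
    G2_CH1_214: A
    G2_CH1_224: G
    G2_CH1_226: C
    G2_CH1_286: A
    G2_CH2_150: A
    G2_CH2_231: G
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: G
- gene: IGHG2
  published_name: IGHG2*n3
  gm: ..
  vector: PNFKVVAKVI
  gm_provenance: as-published
  nt:
    G2_CH1_214: C
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: A
    G2_CH2_150: G
    G2_CH2_231: G
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: A
- gene: IGHG2
  published_name: IGHG2*n9
  gm: ..
  vector: PNFKVMAKVV
  gm_provenance: as-published
  nt:
    G2_CH1_214: C
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: A
    G2_CH2_150: G
    G2_CH2_231: A
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: G
- gene: IGHG2
  published_name: IGHG2*n10
  gm: ..
  vector: PNFEVMAKVV
  gm_provenance: as-published
  nt:
    G2_CH1_214: C
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: G
    G2_CH2_150: G
    G2_CH2_231: A
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: G
- gene: IGHG2
  published_name: IGHG2*n12
  gm: ..
  vector: PNFEVMAKMV
  gm_provenance: as-published
  nt:
    G2_CH1_214: C
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: G
    G2_CH2_150: G
    G2_CH2_231: A
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: A
    G2_CH3_243: G
- gene: IGHG2
  published_name: IGHG2*1K1
  gm: '23'
  vector: PNFKMVAKVV
  gm_provenance: as-published
  nt:
    G2_CH1_214: C
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: A
    G2_CH2_150: A
    G2_CH2_231: G
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: G
- gene: IGHG2
  published_name: IGHG2*1K2
  gm: ..
  vector: TNFKVVAKVV
  gm_provenance: as-published
  nt:
    G2_CH1_214: A
    G2_CH1_224: A
    G2_CH1_226: T
    G2_CH1_286: A
    G2_CH2_150: G
    G2_CH2_231: G
    G2_CH3_111: G
    G2_CH3_155: G
    G2_CH3_213: G
    G2_CH3_243: G
- gene: IGHG3
  published_name: IGHG3*n3
  gm: 5*
  vector: SLFQPRYATVSNMKQIRF
  gm_provenance: as-published
  hinge_exons: 4
  nt:
    G3_CH1_224: G
    G3_CH1_226: C
    G3_CH2_4: T
    G3_CH2_176: C
    G3_CH2_191: A
    G3_CH2_284: C
    G3_CH2_319: A
    G3_CH3_114: G
    G3_CH3_130: G
    G3_CH3_155: T
    G3_CH3_168: A
    G3_CH3_205: A
    G3_CH3_234: C
    G3_CH3_243: A
    G3_CH3_283: G
    G3_CH3_286: T
- gene: IGHG3
  published_name: IGHG3*01m
  gm: 6*
  vector: SLLQPRYATVSNMKEIRF
  gm_provenance: as-published
  hinge_exons: 4
  nt:
    G3_CH1_224: G
    G3_CH1_226: C
    G3_CH2_4: C
    G3_CH2_176: C
    G3_CH2_191: A
    G3_CH2_284: C
    G3_CH2_319: A
    G3_CH3_114: G
    G3_CH3_130: G
    G3_CH3_155: T
    G3_CH3_168: A
    G3_CH3_205: A
    G3_CH3_234: G
    G3_CH3_243: A
    G3_CH3_283: G
    G3_CH3_286: T
- gene: IGHG3
  published_name: IGHG3*n5
  gm: 15*
  vector: SLLQPRYATMSKVKQIHY
  gm_provenance: as-published
  hinge_exons: 3
  nt:
    G3_CH1_224: G
    G3_CH1_226: C
    G3_CH2_4: C
    G3_CH2_176: C
    G3_CH2_191: A
    G3_CH2_284: C
    G3_CH2_319: A
    G3_CH3_114: A
    G3_CH3_130: G
    G3_CH3_155: A
    G3_CH3_168: G
    G3_CH3_205: A
    G3_CH3_234: C
    G3_CH3_243: A
    G3_CH3_283: A
    G3_CH3_286: A
- gene: IGHG3
  published_name: IGHG3*n7
  gm: 5, 14, 21, 26, 27
  vector: SLLQLRYATVNNMRQIRF
  gm_provenance: as-published
  hinge_exons: 4
  nt:
    G3_CH1_224: G
    G3_CH1_226: C
    G3_CH2_4: C
    G3_CH2_176: T
    G3_CH2_191: A
    G3_CH2_284: C
    G3_CH2_319: A
    G3_CH3_114: G
    G3_CH3_130: A
    G3_CH3_155: T
    G3_CH3_168: A
    G3_CH3_205: G
    G3_CH3_234: C
    G3_CH3_243: A
    G3_CH3_283: G
    G3_CH3_286: T
- gene: IGHG3
  published_name: IGHG3*1K1
  gm: 5, 11, 13, 24, 26
  vector: SLLQPRYATVSNVRQVRF
  gm_provenance: as-published
  hinge_exons: 3
  nt:
    G3_CH1_224: G
    G3_CH1_226: C
    G3_CH2_4: C
    G3_CH2_176: C
    G3_CH2_191: A
    G3_CH2_284: C
    G3_CH2_319: A
    G3_CH3_114: G
    G3_CH3_130: G
    G3_CH3_155: T
    G3_CH3_168: G
    G3_CH3_205: G
    G3_CH3_234: C
    G3_CH3_243: G
    G3_CH3_283: G
    G3_CH3_286: T
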