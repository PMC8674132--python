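schema: ighgkit-gene-model/1
synthetic_reconstruction: true
comment: Synthetic IMGT-style reference reconstruction; regenerate with scripts/build_reference_fixtures.py
gene: IGHG3
hinge_first_exon_aa: 17
hinge_repeat_exon_aa: 15
exons:
- name: CH1
  phase_offset: 0
  eu_start: 118
  callable: true
  sequence: CGCGTGCTACTCTCACGGCTTCCGGCAGTTCCGCTCACACTGTCAGGGGCGGGTCCTGCCTCAGGGTCGGCTGCTCGGACAACCCTTTCGGCCACGCGTTCACTTACACCGGGGCCCCCGGGACCACCTGGGTCATCCGGACTAACAACTGTAGTCACTCTCCCTACCTCACCTTCTGGACGGGCAGCGACTACACGGTCAACCGCTTCCTCGCGACCCGCGAGCCTTGTCGCCTCTGGCCCCTCTTCCCTCGGCGTCACGCTGCGGCGCGTATCGCCGGGGACCGCACTGCGC
- name: H1
  phase_offset: 0
  eu_start: null
  callable: false
  sequence: CCTCCAGTCCTAGTCGCGGGCCCAACTGTGGTCCTTACCCTGACCGCAGCA
- name: H2
  phase_offset: 0
  eu_start: null
  callable: false
  sequence: CGTGGACTTACACGTACTTCCACTACCACAGTTTCCGGGCGAGTT
- name: H3
  phase_offset: 0
  eu_start: null
  callable: false
  sequence: TCCTCGGTCCCGGCGACCCTACTAGCAGCACGGCCCTCTCCGGGG
- name: H4
  phase_offset: 0
  eu_start: null
  callable: false
  sequence: CCTCGACTACTCTCCTCCCGCCGGACACGATCCTCGCGAGTCGGT
- name: CH2
  phase_offset: 0
  eu_start: 233
  callable: true
  sequence: ACCCTTTCGCGGGTGTCTGTACCAACCCTATCATCCGGCCGTCTGGTCTCCTCACTCCGTGGAGTGCGTCCTTCCGGTCCGCTTCTCGTCTCAACTACAACTCGACCTCGTGGTCTACGCTCCCAAGCTGCCTCCGTCGGCTCACCGACAGTACTTGGAGGCGTCACCTCGTCACCGCGGCTAGTCGTTTATCTAGCCCGAGTGCGCGGAGTGACCGGGGGCCGGGGAGGTCGCGCACGAGTCCCGGTATCACTGCGTTCGCCAGCGTCAGGCTCGTCCCGTGCAGTACTCGGCCGACGAGGGGCTTCCCTGACTACTACTCGAC
- name: CH3
  phase_offset: 2
  eu_start: 342
  callable: true
  sequence: TTACGCTAGTCACCCCGGTCCGATCCACGGTACCTGTGCTTGTTCTCTCCACAGCTGGACTTCTACGTCTAGGGCCAACGGCACCAGGCGCACGGCTAGTTGCCACACGTACCGTGCGAGTGCTACCCAGTGTCCCAGCTGTGTCGCCAGGAAATGTGGTGCCTCCCATGGTACCTGCAGTAGCTCGTGGCACTGCTGCATCCAAAGGCCTGTCTCTACCGCTGCGCGCCCCGCAACCTCTCATTGTGGGTTCTTCAGCGCCAGCTCCTGGCGTCGGACTACGCTTTGCCCTGGCTGCGCTTCTAACCCCCTCCACCCCCTGA
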