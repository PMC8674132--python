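schema: ighgkit-gene-model/1
synthetic_reconstruction: true
comment: Synthetic IMGT-style reference reconstruction; regenerate with scripts/build_reference_fixtures.py
gene: IGHG2
hinge_first_exon_aa: null
hinge_repeat_exon_aa: null
exons:
- name: CH1
  phase_offset: 0
  eu_start: 118
  callable: true
  sequence: CTCCCAGCGTCTCTAGTGGTCGGTACAGCCCTTGTGGGGCCACCGTCCTCAGCGGGTCCTCTTGTCACAACTACCTCAGGTGCGCCCTCGACCACGGGCCCCCGTGTGTCCGGAGGCCGCTCAGTAACATCATCGCTGACGCCTCCACCATCGCGATCTGCAACTCTCTCACCGTCTCTCCGGGGCCCGGCTTCCCGGGCTCTTACCTCACCCACTGGTGCAAACTTCACACCTGCGTCTCTCCGCCGGCCGCGTACTTCGCCGTCACTCGGGGTACCATCCTCGAAGTCTC
- name: H
  phase_offset: 2
  eu_start: 216
  callable: true
  sequence: GGCCGGTTCCCCTCTCACTCCTCGCATCCCTCTCGCCCCGGGCGTCGCGGC
- name: CH2
  phase_offset: 2
  eu_start: 233
  callable: true
  sequence: TAACCTCTGGTGCACGCTCTTCCGTAGTGCTTGTCCTCCCTGCACCGTCACGAGGACTAGCTCCGGTCCTTGGAGGCCTGGGAGGACCGTCAGTGACGGCTACTCCGGTCCTCGCCCGAGGACGAGTTGTGGCACCCCCCTCAACCGCAATGCTAACTGCACTGACTCGTCTAACCTCCACCACGCTGGTTGTCCCAGGTCCGCTTACAACTCGCGGGGTCACCCGGGGGGTGTCCACTTCCGTAGTAGGCACCTCGTCTCCACGACGCCGCGCTTCGTCTGCTACGGCTGTCCTTGGCTCAACGGTATCGCTAGTTCGAGCCACCG
- name: CH3
  phase_offset: 2
  eu_start: 342
  callable: true
  sequence: CCACTCCGGTACGAGGTTCGGGCGCTGTTACGCCGCGAACTGGTCGCCGTCGTCGGTCCCGCACGGTTCTGCCAGTGTCGCGCGGCCCGGCTTCGACGCCCTCTTCACGAGCTACCCCACTGCCGCGCGTATCAGTCGGACGGACCGTTCCCAAGCGGGCCGGACCTGTTACACTGCGCGCCACTACCCTGACGTCCCTTTCACGTACACGTGTGGTGACTGCCGTGCGCCTGGTCGCTACAGTTACGCTGGTACGAGCCCGGGGTGTTGGTCCTGTGACTTCACCACGATCCCGTCGAGCGCGGCGAGCAGTACCGGTGTGA
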