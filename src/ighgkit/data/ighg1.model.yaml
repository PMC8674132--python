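schema: ighgkit-gene-model/1
synthetic_reconstruction: true
comment: Synthetic IMGT-style reference reconstruction; regenerate with scripts/build_reference_fixtures.py
gene: IGHG1
hinge_first_exon_aa: null
hinge_repeat_exon_aa: null
exons:
- name: CH1
  phase_offset: 0
  eu_start: 118
  callable: true
  sequence: GGACTACTATCACTCGGTACCGTGCTTCTACCGACAGGTTCCGCGACGACCCCGCTGGCAGTACTCGCTGCAGCCACCGTCCTGCGTTCAGTCCCCGCCCTCCCTCGGGCGCCGGGGTCCCGGGCTACGGTTACGGCACCGCTCCTGTCGACGTCCCGACGGCTGTCACCAACACCATCGGTAGGCCGGCTACTCGCTCGGCTTGTAGCTGCCCGGCTAACCGCTGCGGTCGCTGCCACGCTGATCCTGACGACCCCAGGAGCCTCCGGTCTACTATCTGGCGCTCCTAAAG
- name: H
  phase_offset: 2
  eu_start: 216
  callable: true
  sequence: GTCGTCTACGCTCGGGGTCCGGCCCATCACGACGACGTGTAGGTGGTCTGT
- name: CH2
  phase_offset: 2
  eu_start: 233
  callable: true
  sequence: CTTCCCGCGTAGGTCCCCTCGGCGGCACTGCGACCACGCTCGCCCCGACACCAACTGGCGGGGTGTCCCGGCTCCCACTAGTGGCCCCCGTTCTGTCGACAGTGGGCCTGCGGGGGCGGTCTCTCGGTGGGGGTGTAACACTCGATGCCGGCGTCCGTCCCACTGGGCGAACCCTTCCTGCGTCCGGCGTTTCCACTCCCTCCCGCGGGACGCTCGTTGCTCCACGGTCTCTGGCATCGTCCCGGTCAACCCGACTTGTCGCTTCTCTTCTGCTCGGCTCGCGGGCTGGCTCGGTCGCCCGAGGCCTTGGCTCAACAGCGCCAGCGG
- name: CH3
  phase_offset: 2
  eu_start: 342
  callable: true
  sequence: CTGTAACGTCCCGTCCCGTTGGCTCAGTACGAGTCTCCGGTCCTGATCTACTGACACGTGCATCGTCTGTACGGCGAGCACGGCTGGCTCCGACACTGTCCACTACCCGTGGCCGACTGGTTGGGGTTTCTGGCTCCACTTCGCTTGCAGTCCGGCGCCCCGCGACCGCCGTCGTGGCCGCTCTAGGGGGGCTAGGGACCGTGGGACTTGGGCTGCTACCGGCCGGGGTCCGTGGACTGCGTGTCCTGCGAGGTGGTTCTACCCGTCGTGCACCTCCCGGCGGGGCGGTCACCGTCTCGGTAGTCCGTCTAGGCGTGCGCTGA
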