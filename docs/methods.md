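# Methods

## Scope and data model

The package analyses coding-region polymorphism of the three IgG subclass
constant genes IGHG1, IGHG2 and IGHG3 (IGHG4 is excluded because of its
known copy-number variation). Inputs are unphased diploid genotypes at
named coding-exon SNPs, IGHG3 hinge amplicon lengths, and static
configuration: gene models, an allele catalog, and (optionally) a second
variant set for concordance. Genotypes are stored as unordered base pairs
throughout — Sanger-style typing has no phase, and any phase in a VCF input
is discarded deliberately so that phasing is exclusively the EM module's
job. Missing calls are excluded pairwise (per SNP), not listwise; cohorts
of ~94 samples cannot afford listwise deletion.

## Reference reconstruction

No machine-readable reference exon sequences or Eu maps ship with the
published tables, so the packaged gene models are **synthetic
reconstructions**, generated by `scripts/build_reference_fixtures.py` and
marked as such in their file headers. The reconstruction is constrained by
every available anchor tying exon-local nucleotide coordinates to Eu
amino-acid positions:

| anchor | constraint |
|---|---|
| `G3_CH3_283` = Eu 435 (R/H) | CH3 phase offset 2, first full codon Eu 342 |
| `G3_CH3_234` = Eu 419 (Q/E) | same layout, position-1 codon change |
| `G2_CH3_243` = Eu 422 (V/I) | same CH3 layout in IGHG2 |
| `G2_CH2_231` = Eu 309 (V/L/M) | CH2 phase offset 2, first full codon Eu 233 |

These four anchors are mutually consistent under exactly one layout (CH2/CH3
exons begin with two nucleotides completing the upstream codon), which the
reconstruction adopts uniformly; CH1 starts in frame at Eu 118. Exon-local
coordinates are 1-based inclusive. Everything outside the constrained codons
is deterministic seeded filler drawn from four-fold-degenerate codon
families (guaranteeing no stop codons and synonymous third-position sites
where needed). Codon phase offsets are explicit per exon in the YAML schema,
and the Eu map is validated to be injective per gene. IGHG3 hinge exons are
representable but flagged non-callable: heterozygous exon copy number makes
their sequence unreadable in practice, so no hinge SNPs are analysed.

The allele catalog transcribes the published per-gene allotype tables
(residue vectors over the variable Eu positions, dash notation resolved at
load time against the first-listed allele), with nucleotide states derived
from the reconstruction where the variation lies inside the study panel.
Synonymous member alleles (IGHG1\*05/\*09 under IGHG1\*02, IGHG2\*05 under
IGHG2\*03) exercise the collapsing step. Allotypes outside the IMGT-style
catalog — the study's own "n" allotypes, IGHG3\*01m, and 1kGP-only "1K"
entries — live in a packaged alias file keyed by residue vector; their Gm
strings are carried as-published and flagged as such. IGHG3\*04's CH-domain
vector is not printed anywhere (it is a sub-1% allotype); it received a
unique synthetic vector so that the documented rule "every unique CH
sequence associates with one hinge length, except IGHG3\*11/\*12" holds in
the reconstruction. Where the printed frequency columns were ambiguous in
the extracted table text, cells were assigned to the population keeping each
column sum nearest 1 and the columns renormalized; the simulation pools are
therefore close to, but not digit-identical with, the printed values.

## EM phasing

Haplotype frequencies are maximum-likelihood estimates under multinomial
sampling. For each sample all haplotype pairs consistent with its genotype
are enumerated; a missing genotype at a locus expands over the alleles
*observed* at that locus in the population (never all four bases — the only
multi-allelic site is the documented IGHG2 Eu 309 trimorphism, handled as a
three-allele locus). The E-step weights pair (h₁,h₂) by
f(h₁)f(h₂)(2−[h₁=h₂]); the M-step re-estimates frequencies from expected
pair counts. Numerical choices: convergence when the largest absolute
frequency change drops below 1e-8; at most 5000 iterations; 10 restarts
(uniform start, then seeded Dirichlet draws) guarding against local maxima,
best final log-likelihood retained. The log-likelihood trace is recorded and
asserted non-decreasing. Frequencies are estimated per population, never
pooled implicitly.

Above 12 loci per block the diplotype expansion is bounded by
**partition–ligation**: per-gene blocks first (genes larger than 12 loci
split into halves recursively), block haplotypes with frequency > 1e-4
retained, then an EM over blocks in which each "allele" is a retained block
haplotype and each sample's candidates are the consistent block-haplotype
pairs. Samples whose genotype is consistent only with discarded
(sub-threshold) block haplotypes drop out of the ligation step; at the
retention threshold used this affects at most rare-recombinant carriers.

Most-probable diplotypes maximise f(h₁)f(h₂)(2−[h₁=h₂]) over consistent
pairs, with the posterior reported against the sum over all consistent
pairs; ties break lexicographically for determinism; samples whose every
consistent pair has zero probability are flagged unassigned rather than
forced.

## Allotyping and naming

Each variant codon is rebuilt on the reference background and the whole
coding sequence translated; a premature stop is an error (no catalog allele
truncates). Alleles with identical residue vectors collapse into one
allotype whose frequency is the member sum and whose name is the most
frequent member's (ties: lexicographically smallest). Naming against the
catalog is by exact residue-vector match among allotype representatives;
IGHG3\*11 vs \*12 differ only in hinge exon count, so a vector matching both
yields the dual label `IGHG3*11/IGHG3*12` unless a hinge count
disambiguates. Unmatched vectors receive the published alias name when the
vector is in the alias file (this is how the study's own novel allotypes,
e.g. IGHG2\*n3, keep their numbers), otherwise a run-local `GENE*n<k>` label
persisted in a JSON registry so re-runs are stable; registry numbering skips
published n-numbers. Novel allotypes carry a Gm designation only when the
catalog explicitly marks serological indistinguishability (e.g.
IGHG3\*01/\*11, which differ only at Eu 296); otherwise the component is
`unassigned` — serological identity is never inferred from sequence
distance. Human-readable tables print residues with the dash convention
relative to the top row; machine output is always explicit.

## Hinge copy number

Predicted amplicon length for k hinge exons is
`flank_bp + 3·(17 + 15·(k−1))`, a 45 bp ladder over k = 2..5 (hinge protein
lengths 32/47/62/77 aa). `flank_bp` defaults to 300 bp — a placeholder,
since the real value depends on unpublished primer positions — and the
calling tolerance defaults to 10 bp (chip sizing accuracy); both are
configuration. One band is read as a copy-number homozygote (no
allele-dropout model; this matches how fragment-analyzer data are read),
two bands as a heterozygote, three or more as an anomaly consistent with a
gene duplication: excluded from allele frequencies and counted separately.

## FST and the empirical null

Per-SNP two-population Weir–Cockerham θ = a/(a+b+c) is computed from the
1984 variance components (sample sizes, allele frequencies, observed
heterozygosities); negative estimates are reported as-is and sites
monomorphic across the pair are excluded as undefined. Multi-allelic sites
decompose as global-minor-allele vs rest. Significance uses a one-sided
upper-tail empirical p against θ at 1000 randomly sampled genome SNPs for
the same population pair, with the add-one rule
p = (1+#{θ_null ≥ θ})/(1+n_null): a zero p-value from 1000 draws is
statistically indefensible. Bonferroni multiplies by #SNPs × #pairs
(default α 0.05). The scan takes non-synonymous SNPs with global minor
allele frequency strictly above 10% (frequency pooled over the requested
populations). When no genome-wide VCF is available the null comes from the
Balding–Nichols neutral-pair simulator at a configurable background F; an
asymptotic fallback is never silently substituted.

For calibration against a known simulated F the package uses the
estimator's own multi-locus combination (`multi_locus_theta`: ratio of
summed components). The mean of per-site ratios is *not* used for
calibration: the per-site ratio is strongly skewed and its mean sits well
below F (≈0.34 at F = 0.6) even at enormous sample sizes. Per-site scans
report per-site θ, as the tabled analysis does.

## Synthetic cohorts

`simulate_cohort` draws two multigene haplotypes per sample i.i.d. from the
sample's population pool (optionally a mixture over pools — admixture acts
per chromosome), expands allotypes to nucleotide haplotypes over the 87-SNP
study panel (with configured synonymous member splits), emits unordered
genotypes, flips each emitted allele with the error rate (symmetric flip
among the site's declared alleles — deliberately not a chromatogram error
model), drops calls at the missing rate, and emits hinge band lengths
predicted from the haplotypes' linked exon counts. Same seed, byte-identical
outputs; a truth log records pool of origin, allotypes, member alleles and
nucleotide haplotypes per chromosome, and regenerates the pre-error matrix
exactly.

The default `tables123` configuration encodes the published study structure:
three cohorts (95/94/94), per-population pools whose per-gene marginals
match the printed allotype frequency columns (renormalized), whose coupling
reproduces the published multigene-haplotype structure (10 EA / 18 AA / 18
SA haplotypes above 1%, 9 shared AA–SA, 4 shared AA–EA, exactly 1 shared
EA–SA), and whose hinge-length linkage reproduces the printed ladder
frequencies including the single 2-exon (AA) and 5-exon (EA) alleles.
LD between synonymous variants within an allotype is unknown from the
printed record; member expansion assigns them deterministically. What
passing tests on these cohorts show is that the pipeline recovers known
structure of this shape at these sample sizes; they do not probe
chromatogram-level artefacts, primer dropout, or population substructure
within a cohort.

`simulate_bn_pair` draws ancestral frequencies uniform on [0.1, 0.9] and
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) (F = 0 degenerates to
identical frequencies), then genotypes under within-population
Hardy–Weinberg proportions.

## QC

The Hardy–Weinberg test is the standard conditional exact test (sum of
probabilities of heterozygote counts of matching parity with conditional
probability ≤ observed), computed in log-gamma space; cohorts of ~94 and
rare variants make chi-square asymptotics unsafe, so exact is the default
and chi-square an option. HWE is computed per population only — pooling
differentiated populations manufactures Wahlund disequilibrium. The exact
test is verified against a full-enumeration rational-arithmetic oracle for
all genotype tables up to 30 individuals.

## Problem sizes used in checks

The shipped checks run the full pipeline at the study's own scale (three
cohorts of ~95; EM over 34 non-synonymous loci via per-gene
partition–ligation), estimator calibrations at 400–500 simulated SNPs with
200–660 diploids per population, exhaustive oracles up to 30 individuals
(HWE) and 12 per population (θ), and 1000 random haplotypes per gene for
the translation oracle. Frequency comparisons use three binomial standard
errors at the simulated cohort size; haplotype *counts* above the 1%
threshold wobble by a few units because several pool haplotypes sit at
1–1.5%, and the count checks allow that threshold-crossing noise.

## Known limitations

* The reference sequences and Eu maps are reconstructions; exon filler
  sequence and synonymous-site placement are synthetic, so nucleotide-level
  outputs (haplotype strings) are not comparable with real IGHG sequence.
* The 1kGP comparison panels are packaged key sets with transcribed
  presence flags and frequencies, not re-extracted call sets; the
  concordance machinery accepts any VCF-derived variant set for real use.
* Phasing accuracy degrades for rare haplotypes (below ~1% at N≈95) and in
  admixed cohorts; the most-probable diplotype is reported with its
  posterior, and downstream frequency estimates come from the EM
  frequencies, not from hard diplotype calls.
* Hinge `flank_bp` is assay-dependent; the default is a placeholder.
* The empirical-p tie handling (upper tail, add-one) and the exact-test
  flavour are this package's documented choices; alternatives (mid-p,
  two-sided empirical p) are not implemented.
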