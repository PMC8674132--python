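"""Per-SNP quality statistics used as analysis gates.

Allele frequencies, global minor allele frequency (MAF), call rate, and an
exact test for Hardy-Weinberg equilibrium.  The HWE test is the standard
conditional exact test (sum of probabilities of heterozygote counts whose
conditional probability does not exceed the observed one, conditioning on
the allele counts); small cohorts of ~94 diploids and rare variants make the
chi-square asymptotics unsafe, so the exact test is the default and the
chi-square variant is an option.  HWE is always computed within a population,
never pooled: pooling differentiated populations manufactures Wahlund
disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from ighgkit.genotype_io import GenotypeMatrix
from ighgkit.reference import SnpDef


class UndefinedFrequencyError(ValueError):
    """All calls missing in the requested sample subset."""


def allele_freqs(
    matrix: GenotypeMatrix, snp: SnpDef | str, populations: Sequence[str] | None = None
) -> dict[str, float]:
    """Allele frequencies at one SNP over a population subset.

    Frequency = allele count / (2 x non-missing samples); missing calls are
    excluded pairwise.
    """
    snp_id = snp if isinstance(snp, str) else snp.snp_id
    counts: dict[str, int] = {}
    n = 0
    for sample in matrix.samples_in(populations):
        call = matrix.call(sample, snp_id)
        if call is None:
            continue
        n += 1
        for base in call:
            counts[base] = counts.get(base, 0) + 1
    if n == 0:
        raise UndefinedFrequencyError(f"{snp_id}: no non-missing calls in subset")
    return {base: c / (2 * n) for base, c in sorted(counts.items())}


def genotype_counts(
    matrix: GenotypeMatrix, snp: SnpDef | str, populations: Sequence[str] | None = None
) -> tuple[int, int, int]:
    """(ref-hom, het, alt-hom) counts; multi-allelic alts pool as non-reference."""
    snp_id = snp if isinstance(snp, str) else snp.snp_id
    ref = matrix.snp(snp_id).ref_base
    a = b = c = 0
    for sample in matrix.samples_in(populations):
        call = matrix.call(sample, snp_id)
        if call is None:
            continue
        n_ref = sum(1 for base in call if base == ref)
        if n_ref == 2:
            a += 1
        elif n_ref == 1:
            b += 1
        else:
            c += 1
    return a, b, c


def hwe_exact(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for biallelic genotype counts.

    Conditions on the observed allele counts; returns the summed probability
    of all heterozygote counts (of matching parity) whose conditional
    probability is at most that of the observed configuration.  Degenerate
    totals (monomorphic or empty) return 1.
    """
    if min(n_refhom, n_het, n_althom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_refhom + n_het + n_althom
    if n == 0:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_refhom + n_het, 2 * n_althom + n_het)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log multinomial weight x 2^het  (normalizing constant cancels)
    logw = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_het)[0][0]]
    # tolerance guards against float ties at the observed configuration
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Chi-square (1 df) HWE test; offered for parity with array-era tooling."""
    n = n_refhom + n_het + n_althom
    if n == 0:
        raise ValueError("at least one genotype required")
    p = (2 * n_refhom + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_refhom, n_het, n_althom])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


@dataclass(frozen=True)
class SnpQc:
    snp_id: str
    freqs: Mapping[str, Mapping[str, float]]  # population -> base -> frequency
    global_freqs: Mapping[str, float]
    maf: float
    hwe_p: Mapping[str, float]  # per population
    callrate: float


def snp_qc(
    matrix: GenotypeMatrix,
    snp: SnpDef | str,
    populations: Sequence[str] | None = None,
    exact: bool = True,
) -> SnpQc:
    snp_id = snp if isinstance(snp, str) else snp.snp_id
    pops = list(populations) if populations else matrix.population_labels()
    freqs = {}
    hwe_p = {}
    for pop in pops:
        try:
            freqs[pop] = allele_freqs(matrix, snp_id, [pop])
        except UndefinedFrequencyError:
            freqs[pop] = {}
            hwe_p[pop] = 1.0
            continue
        test = hwe_exact if exact else hwe_chisq
        hwe_p[pop] = test(*genotype_counts(matrix, snp_id, [pop]))
    global_freqs = allele_freqs(matrix, snp_id, pops)
    maf = 0.0 if len(global_freqs) < 2 else 1.0 - max(global_freqs.values())
    n_called = sum(
        1 for s in matrix.samples_in(pops) if matrix.call(s, snp_id) is not None
    )
    n_total = len(matrix.samples_in(pops))
    return SnpQc(
        snp_id=snp_id,
        freqs=freqs,
        global_freqs=global_freqs,
        maf=maf,
        hwe_p=hwe_p,
        callrate=n_called / n_total if n_total else 0.0,
    )


def qc_table(
    matrix: GenotypeMatrix, populations: Sequence[str] | None = None, exact: bool = True
) -> pd.DataFrame:
    """QC report over every SNP in the matrix (one row per SNP)."""
    pops = list(populations) if populations else matrix.population_labels()
    rows = []
    for snp in matrix.snps:
        q = snp_qc(matrix, snp, pops, exact=exact)
        row: dict = {"snp_id": q.snp_id, "maf": q.maf, "callrate": q.callrate}
        for pop in pops:
            alt_f = sum(f for b, f in q.freqs[pop].items() if b != snp.ref_base)
            row[f"alt_freq_{pop}"] = alt_f
            row[f"hwe_p_{pop}"] = q.hwe_p[pop]
        rows.append(row)
    return pd.DataFrame(rows)


def maf_filter(qcs: Iterable[SnpQc], threshold: float) -> list[str]:
    """SNP ids with global MAF strictly above ``threshold``; order preserved."""
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    return [q.snp_id for q in qcs if q.maf > threshold]
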