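"""Pairwise per-SNP Weir-Cockerham FST with an empirical genome-sampled null.

The estimator is the 1984 variance-components theta for two populations and
a biallelic site: theta = a / (a + b + c) with ``a`` the among-population,
``b`` the among-individual-within-population and ``c`` the within-individual
component, computed from sample sizes, allele frequencies and observed
heterozygosities.  Negative estimates are reported as-is; sites monomorphic
in both populations have no defined theta and are excluded from scans.

Significance is assessed against an empirical null of theta values from
randomly sampled genome SNPs for the same population pair (size 1000 by
default), with the add-one rule p = (1 + #{null >= observed}) / (1 + n_null)
-- a zero p-value from a finite null sample is indefensible.  Bonferroni
correction multiplies by the number of SNPs x pairs scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ighgkit.genotype_io import GenotypeMatrix
from ighgkit.reference import SnpDef

Counts = tuple[int, int, int]  # (hom-common, het, hom-minor) per population


def weir_cockerham_components(
    counts1: Counts, counts2: Counts
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for two populations at a biallelic site."""
    counts = (counts1, counts2)
    r = 2
    n_i = [sum(c) for c in counts]
    if min(n_i) < 1:
        raise ValueError("both populations need at least one genotype")
    p_i = [(2 * c[0] + c[1]) / (2 * n) for c, n in zip(counts, n_i)]
    h_i = [c[1] / n for c, n in zip(counts, n_i)]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    if nbar <= 1:
        raise ValueError("theta undefined for single-individual populations")
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def weir_cockerham_theta(counts1: Counts, counts2: Counts) -> float:
    """Per-site theta; NaN when both populations are monomorphic (a+b+c = 0)."""
    a, b, c = weir_cockerham_components(counts1, counts2)
    denom = a + b + c
    if denom == 0:
        return math.nan
    return a / denom


def multi_locus_theta(count_pairs: Iterable[tuple[Counts, Counts]]) -> float:
    """Combined theta over loci: ratio of summed variance components.

    This is the estimator's own multi-locus combination (sum the a, b, c
    components over loci, then form a/(a+b+c)); averaging per-site ratios
    instead is downward-biased because the per-site ratio is strongly
    skewed.  Used for calibration against a known simulated F.
    """
    A = B = C = 0.0
    for c1, c2 in count_pairs:
        a, b, c = weir_cockerham_components(c1, c2)
        A += a
        B += b
        C += c
    denom = A + B + C
    if denom == 0:
        return math.nan
    return A / denom


def empirical_p(observed_theta: float, null_thetas: Sequence[float]) -> float:
    """One-sided upper-tail empirical p with the add-one rule."""
    null = [t for t in null_thetas if not math.isnan(t)]
    if not null:
        raise ValueError("empirical null is empty")
    exceed = sum(1 for t in null if t >= observed_theta)
    return (1 + exceed) / (1 + len(null))


@dataclass(frozen=True)
class FstResult:
    snp_id: str
    rsid: str | None
    pair: tuple[str, str]
    theta: float
    empirical_p: float
    p_bonferroni: float
    significant: bool
    n_tests: int


def pair_genotype_counts(
    matrix: GenotypeMatrix, snp: SnpDef | str, pair: tuple[str, str]
) -> tuple[Counts, Counts] | None:
    """Biallelic genotype counts for a population pair.

    Multi-allelic sites decompose as global-minor-allele vs rest; returns
    None when fewer than two alleles segregate across the pair.
    """
    snp_id = snp if isinstance(snp, str) else snp.snp_id
    calls = {
        pop: [matrix.call(s, snp_id) for s in matrix.samples_in([pop])]
        for pop in pair
    }
    tally: dict[str, int] = {}
    for pop_calls in calls.values():
        for call in pop_calls:
            if call:
                for base in call:
                    tally[base] = tally.get(base, 0) + 1
    if len(tally) < 2:
        return None
    minor = min(tally, key=lambda b: (tally[b], b))
    out = []
    for pop in pair:
        a = b = c = 0
        for call in calls[pop]:
            if call is None:
                continue
            m = sum(1 for base in call if base == minor)
            if m == 0:
                a += 1
            elif m == 1:
                b += 1
            else:
                c += 1
        out.append((a, b, c))
    return out[0], out[1]


class NullSourceError(RuntimeError):
    """No empirical null available; an asymptotic fallback is never substituted."""


def null_from_bn_simulation(
    pair_counts: Mapping[tuple[str, str], tuple[int, int]],
    n_null: int = 1000,
    seed: int = 0,
    fst: float = 0.1,
) -> dict[tuple[str, str], np.ndarray]:
    """Neutral-pair empirical null from Balding-Nichols simulated SNPs.

    ``pair_counts`` maps each population pair to its per-population sample
    sizes; ``fst`` sets the background differentiation of the simulated
    genome SNPs.
    """
    from ighgkit import synthetic_data

    out = {}
    rng = np.random.default_rng(seed)
    for pair, (n1, n2) in pair_counts.items():
        sim = synthetic_data.simulate_bn_pair(
            n_snps=n_null, F=fst, n_per_pop=(n1, n2),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        thetas = np.array(
            [weir_cockerham_theta(c1, c2) for c1, c2 in zip(sim.counts1, sim.counts2)]
        )
        out[pair] = thetas[~np.isnan(thetas)]
    return out


def null_from_vcf(
    path: str,
    sample_pops: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    n_null: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Theta null from uniformly sampled autosomal biallelic VCF SNPs."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    pop_of = [sample_pops.get(s) for s in samples]
    records = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        chrom = rec.CHROM.removeprefix("chr")
        if chrom in {"X", "Y", "MT", "M"}:
            continue
        records.append(rec.genotype.array()[:, :2].copy())
    if not records:
        raise NullSourceError(f"{path}: no autosomal biallelic SNPs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=min(n_null, len(records)), replace=False)
    out: dict[tuple[str, str], np.ndarray] = {}
    for pair in pairs:
        thetas = []
        for i in idx:
            gt = records[i]
            counts = []
            for pop in pair:
                sel = [j for j, p in enumerate(pop_of) if p == pop]
                sub = gt[sel]
                ok = (sub >= 0).all(axis=1)
                alt = sub[ok].sum(axis=1)
                counts.append((int((alt == 0).sum()), int((alt == 1).sum()),
                               int((alt == 2).sum())))
            t = weir_cockerham_theta(counts[0], counts[1])
            if not math.isnan(t):
                thetas.append(t)
        out[pair] = np.array(thetas)
    return out


def fst_scan(
    matrix: GenotypeMatrix,
    snp_ids: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    null_thetas: Mapping[tuple[str, str], Sequence[float]],
    alpha: float = 0.05,
) -> list[FstResult]:
    """Per pair x SNP theta with empirical p and Bonferroni correction.

    ``snp_ids`` should already be restricted to non-synonymous SNPs passing
    the global-MAF gate (qc.maf_filter); the Bonferroni factor is
    #SNPs x #pairs.
    """
    if not null_thetas:
        raise NullSourceError(
            "no empirical null provided; supply --null-vcf or --null-simulate"
        )
    m = len(snp_ids) * len(pairs)
    out: list[FstResult] = []
    for pair in pairs:
        if pair not in null_thetas:
            raise NullSourceError(f"no null distribution for pair {pair}")
        for snp_id in snp_ids:
            snp = matrix.snp(snp_id)
            counts = pair_genotype_counts(matrix, snp, pair)
            if counts is None:
                continue
            theta = weir_cockerham_theta(*counts)
            if math.isnan(theta):
                continue
            p = empirical_p(theta, null_thetas[pair])
            p_bonf = min(1.0, p * m)
            out.append(
                FstResult(
                    snp_id=snp_id,
                    rsid=snp.rsid,
                    pair=tuple(pair),
                    theta=theta,
                    empirical_p=p,
                    p_bonferroni=p_bonf,
                    significant=p_bonf < alpha,
                    n_tests=m,
                )
            )
    return out


def fst_table(results: Iterable[FstResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "rsid": r.rsid or "",
                "pair": "-".join(r.pair),
                "theta": round(r.theta, 4),
                "empirical_p": r.empirical_p,
                "p_bonferroni": r.p_bonferroni,
                "significant": r.significant,
            }
            for r in results
        ]
    )
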