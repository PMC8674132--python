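"""EM estimation of haplotype frequencies from unphased diploid genotypes.

This is the maximum-likelihood multilocus EM under multinomial sampling
(the classic Excoffier-Slatkin / Haploview-style algorithm): for every
sample, all haplotype pairs consistent with its unphased genotype are
enumerated (missing loci expand over the alleles observed at that locus);
the E-step weights each pair by current haplotype frequencies, the M-step
re-estimates frequencies from expected pair counts.  The log-likelihood is
non-decreasing across iterations and is recorded per iteration.

Loci counts above a configured block size are estimated by
partition-ligation: per-block EM first (per-gene blocks are the natural
partition), then EM over combinations of retained block haplotypes.

Frequencies are estimated per population separately; pooling across
populations is never implicit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ighgkit.genotype_io import GenotypeMatrix
from ighgkit.reference import SnpDef

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 5000
DEFAULT_RESTARTS = 10
MAX_BLOCK_LOCI = 12
LIGATION_KEEP = 1e-4
MAX_PAIR_EXPANSION = 65536

Hap = tuple[str, ...]  # one allele string per locus (multi-character in ligation)


class EMExpansionError(RuntimeError):
    """Diplotype expansion exceeded the configured bound.

    Raised when too many loci are phased in one EM block; use the
    partition-ligation mode (multigene_haplotypes) instead.
    """


@dataclass
class HaplotypeFrequencySet:
    loci: list[SnpDef]
    haplotypes: dict[str, float]  # allele string (one base per locus) -> frequency
    loglik: float
    n_iter: int
    converged: bool
    population: str | None = None
    trace: list[float] = field(default_factory=list, repr=False)

    def marginal(self, locus_index: int) -> dict[str, float]:
        """Allele frequencies at one locus implied by the haplotype frequencies."""
        out: dict[str, float] = defaultdict(float)
        for hap, f in self.haplotypes.items():
            out[hap[locus_index]] += f
        return dict(out)

    def filtered(self, threshold: float) -> dict[str, float]:
        return {h: f for h, f in self.haplotypes.items() if f > threshold}


@dataclass(frozen=True)
class DiplotypeAssignment:
    sample: str
    haplotypes: tuple[str, str] | None  # lexicographically ordered pair
    posterior: float
    unassigned: bool = False


# ---------------------------------------------------------------------------
# Generic EM core: loci are abstract; per sample, each locus offers a list of
# candidate unordered allele pairs (1 candidate when the genotype is observed,
# several when it is missing or when the "locus" is a ligation block).
# ---------------------------------------------------------------------------

def _expand_pairs(
    per_locus: Sequence[Sequence[tuple[str, str]]], max_pairs: int = MAX_PAIR_EXPANSION
) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs consistent with per-locus candidates."""
    pairs: set[tuple[Hap, Hap]] = {((), ())}
    for candidates in per_locus:
        nxt: set[tuple[Hap, Hap]] = set()
        for h1, h2 in pairs:
            for a, b in candidates:
                nxt.add(tuple(sorted(((*h1, a), (*h2, b)))))
                if a != b:
                    nxt.add(tuple(sorted(((*h1, b), (*h2, a)))))
        pairs = nxt
        if len(pairs) > max_pairs:
            raise EMExpansionError(
                f"diplotype expansion exceeded {max_pairs} pairs; phase this "
                "region with partition-ligation (multigene_haplotypes)"
            )
    return sorted(pairs)


def _em_core(
    pair_sets: list[list[tuple[Hap, Hap]]],
    tol: float,
    max_iter: int,
    n_restarts: int,
    rng: np.random.Generator,
) -> tuple[dict[Hap, float], float, int, bool, list[float]]:
    universe: list[Hap] = sorted({h for pairs in pair_sets for p in pairs for h in p})
    index = {h: i for i, h in enumerate(universe)}
    k = len(universe)
    if k == 0:
        raise ValueError("no haplotypes to estimate (all samples fully missing?)")
    # integer views of the pair lists for fast numpy E-steps
    views = [
        (np.array([index[a] for a, _ in pairs]),
         np.array([index[b] for _, b in pairs]),
         np.array([1.0 if a == b else 2.0 for a, b in pairs]))
        for pairs in pair_sets
    ]
    n = len(pair_sets)
    best: tuple | None = None
    for restart in range(n_restarts):
        f = (np.full(k, 1.0 / k) if restart == 0
             else rng.dirichlet(np.ones(k)))
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            new = np.zeros(k)
            ll = 0.0
            for ia, ib, mult in views:
                w = f[ia] * f[ib] * mult
                tot = w.sum()
                if tot <= 0:
                    # degenerate start: spread over candidates
                    w = mult / mult.sum()
                    tot = 1.0
                    ll += -745.0  # log of ~double-underflow likelihood
                else:
                    w = w / tot
                    ll += float(np.log(tot))
                np.add.at(new, ia, w)
                np.add.at(new, ib, w)
            new /= 2.0 * n
            trace.append(ll)
            delta = float(np.abs(new - f).max())
            f = new
            if delta < tol:
                converged = True
                break
        # final log-likelihood at the converged frequencies
        ll_final = 0.0
        for ia, ib, mult in views:
            tot = float((f[ia] * f[ib] * mult).sum())
            ll_final += float(np.log(tot)) if tot > 0 else -np.inf
        trace.append(ll_final)
        cand = (ll_final, {h: float(f[i]) for h, i in index.items()}, it, converged, trace)
        if best is None or cand[0] > best[0]:
            best = cand
    ll_final, freqs, it, converged, trace = best
    return freqs, ll_final, it, converged, trace


# ---------------------------------------------------------------------------
# Candidate-pair construction from a GenotypeMatrix
# ---------------------------------------------------------------------------

def _locus_candidates(
    matrix: GenotypeMatrix, loci: Sequence[SnpDef], population: str | None
) -> tuple[list[str], list[list[list[tuple[str, str]]]]]:
    """Per-sample, per-locus candidate unordered allele pairs.

    Missing genotypes expand over the alleles observed at that locus in the
    population (never over all four bases); samples missing at every locus
    are dropped.
    """
    pops = None if population is None else [population]
    samples = matrix.samples_in(pops)
    observed = {}
    for snp in loci:
        alleles = matrix.observed_alleles(snp.snp_id, pops)
        observed[snp.snp_id] = alleles if alleles else [snp.ref_base]
    kept: list[str] = []
    out: list[list[list[tuple[str, str]]]] = []
    for sample in samples:
        per_locus: list[list[tuple[str, str]]] = []
        any_called = False
        for snp in loci:
            call = matrix.call(sample, snp.snp_id)
            if call is not None:
                any_called = True
                per_locus.append([call])
            else:
                alleles = observed[snp.snp_id]
                per_locus.append(
                    [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
                )
        if any_called:
            kept.append(sample)
            out.append(per_locus)
    return kept, out


def _resolve_loci(matrix: GenotypeMatrix, loci: Sequence[SnpDef | str]) -> list[SnpDef]:
    return [matrix.snp(l) if isinstance(l, str) else l for l in loci]


def em_haplotypes(
    matrix: GenotypeMatrix,
    loci: Sequence[SnpDef | str],
    population: str | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_block_loci: int = MAX_BLOCK_LOCI,
) -> HaplotypeFrequencySet:
    """ML haplotype frequencies for one EM block (<= ``max_block_loci`` loci)."""
    snps = _resolve_loci(matrix, loci)
    if not snps:
        raise ValueError("at least one locus required")
    if len(snps) > max_block_loci:
        raise EMExpansionError(
            f"{len(snps)} loci exceed the {max_block_loci}-locus EM block bound; "
            "use partition-ligation (multigene_haplotypes)"
        )
    kept, per_sample = _locus_candidates(matrix, snps, population)
    if not kept:
        raise ValueError("no sample with a non-missing call at these loci")
    pair_sets = [_expand_pairs(pl) for pl in per_sample]
    rng = np.random.default_rng(seed)
    freqs, ll, n_iter, converged, trace = _em_core(
        pair_sets, tol, max_iter, n_restarts, rng
    )
    return HaplotypeFrequencySet(
        loci=snps,
        haplotypes={"".join(h): f for h, f in freqs.items()},
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        population=population,
        trace=trace,
    )


def assign_diplotypes(
    freqs: HaplotypeFrequencySet,
    matrix: GenotypeMatrix,
    population: str | None = None,
) -> list[DiplotypeAssignment]:
    """Most-probable consistent haplotype pair per sample.

    The pair maximizes f(h1) f(h2) (2 - [h1 == h2]); the posterior is that
    weight over the sum across all consistent pairs.  Ties break
    lexicographically; samples whose every consistent pair has zero
    probability are flagged unassigned.
    """
    kept, per_sample = _locus_candidates(matrix, freqs.loci, population)
    f = freqs.haplotypes
    out: list[DiplotypeAssignment] = []
    for sample, per_locus in zip(kept, per_sample):
        pairs = _expand_pairs(per_locus)
        weights = []
        for h1, h2 in pairs:
            s1, s2 = "".join(h1), "".join(h2)
            w = f.get(s1, 0.0) * f.get(s2, 0.0) * (1.0 if s1 == s2 else 2.0)
            weights.append((w, (s1, s2)))
        total = sum(w for w, _ in weights)
        if total <= 0:
            out.append(DiplotypeAssignment(sample, None, 0.0, unassigned=True))
            continue
        # max weight; ties broken by lexicographic order of the pair
        w_best = max(w for w, _ in weights)
        pair_best = min(p for w, p in weights if w >= w_best * (1 - 1e-12))
        out.append(DiplotypeAssignment(sample, pair_best, w_best / total))
    return out


# ---------------------------------------------------------------------------
# Partition-ligation
# ---------------------------------------------------------------------------

def _split_blocks(snps: list[SnpDef], max_block: int) -> list[list[SnpDef]]:
    """Per-gene blocks first; genes larger than the bound split into halves."""
    by_gene: list[list[SnpDef]] = []
    for snp in snps:
        if by_gene and by_gene[-1][0].gene == snp.gene:
            by_gene[-1].append(snp)
        else:
            by_gene.append([snp])
    blocks: list[list[SnpDef]] = []
    for gene_block in by_gene:
        stack = [gene_block]
        while stack:
            blk = stack.pop(0)
            if len(blk) <= max_block:
                blocks.append(blk)
            else:
                mid = len(blk) // 2
                stack = [blk[:mid], blk[mid:]] + stack
    return blocks


def _consistent_block_pairs(
    matrix: GenotypeMatrix,
    block: list[SnpDef],
    haplotypes: list[str],
    sample: str,
) -> list[tuple[str, str]]:
    calls = [matrix.call(sample, snp.snp_id) for snp in block]
    out = []
    for i, g in enumerate(haplotypes):
        for h in haplotypes[i:]:
            ok = True
            for j, call in enumerate(calls):
                if call is not None and (g[j], h[j]) != call and (h[j], g[j]) != call:
                    ok = False
                    break
            if ok:
                out.append((g, h))
    return out


def multigene_haplotypes(
    matrix: GenotypeMatrix,
    loci: Sequence[SnpDef | str],
    population: str | None = None,
    threshold: float = 0.01,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_block_loci: int = MAX_BLOCK_LOCI,
    ligation_keep: float = LIGATION_KEEP,
    require_nonsynonymous: bool = True,
) -> HaplotypeFrequencySet:
    """Partition-ligation EM across genes; report keeps frequencies > threshold.

    Loci are expected to be amino-acid-changing SNPs (the multigene haplotype
    analysis is defined on those); pass ``require_nonsynonymous=False`` to
    phase arbitrary panels.
    """
    snps = _resolve_loci(matrix, loci)
    if require_nonsynonymous:
        bad = [s.snp_id for s in snps if not s.is_nonsynonymous]
        if bad:
            raise ValueError(f"loci must be non-synonymous; offending: {bad[:3]}")
    if len(snps) <= max_block_loci:
        full = em_haplotypes(
            matrix, snps, population, tol, max_iter, n_restarts, seed, max_block_loci
        )
        return HaplotypeFrequencySet(
            loci=full.loci,
            haplotypes=full.filtered(threshold),
            loglik=full.loglik,
            n_iter=full.n_iter,
            converged=full.converged,
            population=population,
            trace=full.trace,
        )
    blocks = _split_blocks(snps, max_block_loci)
    block_haps: list[list[str]] = []
    for b_i, block in enumerate(blocks):
        sub = multigene_haplotypes(
            matrix, block, population, threshold=ligation_keep, tol=tol,
            max_iter=max_iter, n_restarts=n_restarts, seed=seed + 1000 * (b_i + 1),
            max_block_loci=max_block_loci, ligation_keep=ligation_keep,
            require_nonsynonymous=False,
        )
        block_haps.append(sorted(sub.haplotypes))
    pops = None if population is None else [population]
    samples = matrix.samples_in(pops)
    pair_sets: list[list[tuple[Hap, Hap]]] = []
    kept: list[str] = []
    for sample in samples:
        per_block = []
        feasible = True
        for block, haps in zip(blocks, block_haps):
            cands = _consistent_block_pairs(matrix, block, haps, sample)
            if not cands:
                feasible = False
                break
            per_block.append(cands)
        if not feasible:
            continue  # genotype carries a sub-ligation-threshold haplotype
        kept.append(sample)
        pair_sets.append(_expand_pairs(per_block))
    if not kept:
        raise ValueError("no sample consistent with retained block haplotypes")
    rng = np.random.default_rng(seed)
    freqs, ll, n_iter, converged, trace = _em_core(
        pair_sets, tol, max_iter, n_restarts, rng
    )
    joined = {"".join(h): f for h, f in freqs.items()}
    return HaplotypeFrequencySet(
        loci=snps,
        haplotypes={h: f for h, f in joined.items() if f > threshold},
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        population=population,
        trace=trace,
    )
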