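"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators:

* ``simulate_cohort`` draws diploid samples from population-specific
  multigene haplotype pools (IGHG3-IGHG1-IGHG2 allotypes with linked hinge
  exon counts, expanded to nucleotide haplotypes over the study SNP panel),
  with optional admixture between pools, symmetric genotyping error, missing
  calls and hinge amplicon lengths.  The packaged ``tables123`` configuration
  encodes the published per-population allotype and hinge frequency columns,
  so end-to-end runs produce reports directly comparable to the printed
  tables.

* ``simulate_bn_pair`` draws biallelic SNPs for two populations under the
  Balding-Nichols model (population frequencies Beta-distributed around an
  ancestral frequency with parameter F) for FST estimator calibration and
  empirical nulls.

Same seed, same outputs, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ighgkit import hinge as hinge_mod
from ighgkit.genotype_io import GenotypeMatrix, HingeLengthTable, as_call
from ighgkit.reference import (
    GeneModel,
    SnpDef,
    _data_path,
    load_catalog,
    load_gene_models,
    load_novel_aliases,
    study_snp_defs,
)


@dataclass(frozen=True)
class PoolHaplotype:
    g3: str
    hinge_exons: int
    g1: str
    g2: str
    freq: float

    @property
    def names(self) -> tuple[str, str, str]:
        return (self.g3, self.g1, self.g2)


@dataclass
class SimConfig:
    seed: int
    pools: dict[str, list[PoolHaplotype]]  # pool label -> haplotypes
    cohorts: dict[str, tuple[int, dict[str, float]]]  # pop -> (N, pool weights)
    member_splits: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    error_rate: float = 0.0
    hinge_config: hinge_mod.HingeConfig = field(default_factory=hinge_mod.HingeConfig)

    def validate(self) -> None:
        for label, pool in self.pools.items():
            if not pool:
                raise ValueError(f"pool {label!r} is empty")
            s = sum(h.freq for h in pool)
            if abs(s - 1.0) > 1e-3:
                raise ValueError(f"pool {label!r} frequencies sum to {s:.4f}, not 1")
        for pop, (n, weights) in self.cohorts.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"cohort {pop!r} mixture weights do not sum to 1")
            for label in weights:
                if label not in self.pools:
                    raise ValueError(f"cohort {pop!r} references unknown pool {label!r}")
        for rate in (self.missing_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthSet:
    diplotypes: dict[str, tuple[dict, dict]]  # sample -> two haplotype records
    pool_freqs: dict[str, dict[tuple[str, str, str], float]]
    bn_F: float | None = None


@dataclass
class BnPairSim:
    counts1: list[tuple[int, int, int]]
    counts2: list[tuple[int, int, int]]
    ancestral_p: np.ndarray
    pop_freqs: np.ndarray  # (n_snps, 2)
    F: float


# ---------------------------------------------------------------------------
# Nucleotide expansion of allotype-level pools
# ---------------------------------------------------------------------------

class HaplotypeExpander:
    """Allotype names -> nucleotide haplotype strings over the study panel."""

    def __init__(self, panel: Sequence[SnpDef], catalog=None, aliases=None):
        self.panel = list(panel)
        catalog = catalog or load_catalog()
        aliases = aliases if aliases is not None else load_novel_aliases()
        self.nt: dict[str, dict[str, str]] = {}
        for entry in catalog.entries:
            if entry.nt_states is not None:
                self.nt[entry.name] = dict(entry.nt_states)
        for alias in aliases:
            if "nt" in alias:
                self.nt[alias["published_name"]] = dict(alias["nt"])

    def expand(self, names: Sequence[str]) -> str:
        states: dict[str, str] = {}
        for name in names:
            if name not in self.nt:
                raise KeyError(f"no nucleotide states for allele {name!r}")
            states.update(self.nt[name])
        return "".join(states.get(s.snp_id, s.ref_base) for s in self.panel)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _choose_member(allotype: str, splits: Mapping[str, Mapping[str, float]],
                   rng: np.random.Generator) -> str:
    split = splits.get(allotype)
    if not split:
        return allotype
    names = sorted(split)
    probs = np.array([split[n] for n in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_cohort(
    config: SimConfig,
    models: Mapping[str, GeneModel] | None = None,
    panel: Sequence[SnpDef] | None = None,
) -> tuple[GenotypeMatrix, HingeLengthTable, TruthSet]:
    """Draw diploid cohorts from the configured haplotype pools.

    Per sample: a pool of origin is drawn per chromosome from the cohort's
    mixture weights, a multigene haplotype from that pool, and a synonymous
    member allele per gene; genotypes are emitted as unordered base pairs,
    then each emitted allele is flipped with the error rate and dropped to
    missing with the missing rate.  Hinge bands are the predicted amplicon
    lengths of the two hinge exon counts.
    """
    config.validate()
    models = models or load_gene_models()
    panel = list(panel) if panel is not None else study_snp_defs(models)
    expander = HaplotypeExpander(panel)
    rng = np.random.default_rng(config.seed)

    samples: list[str] = []
    populations: dict[str, str] = {}
    calls: dict[str, dict[str, tuple[str, str] | None]] = {s.snp_id: {} for s in panel}
    hinge_lengths: dict[str, tuple[float, ...]] = {}
    truth: dict[str, tuple[dict, dict]] = {}

    pool_sorted = {label: sorted(pool, key=lambda h: h.names)
                   for label, pool in config.pools.items()}

    for pop in sorted(config.cohorts):
        n, weights = config.cohorts[pop]
        pool_labels = sorted(weights)
        pool_probs = np.array([weights[l] for l in pool_labels])
        for i in range(n):
            sample = f"{pop}_{i + 1:03d}"
            samples.append(sample)
            populations[sample] = pop
            records = []
            for _chrom in range(2):
                label = pool_labels[rng.choice(len(pool_labels), p=pool_probs)]
                pool = pool_sorted[label]
                probs = np.array([h.freq for h in pool])
                hap = pool[rng.choice(len(pool), p=probs / probs.sum())]
                members = tuple(
                    _choose_member(name, config.member_splits, rng)
                    for name in hap.names
                )
                nt = expander.expand(members)
                records.append(
                    {
                        "pool": label,
                        "allotypes": hap.names,
                        "members": members,
                        "hinge_exons": hap.hinge_exons,
                        "nt": nt,
                    }
                )
            truth[sample] = (records[0], records[1])
            # genotypes with error/missing injection
            for j, snp in enumerate(panel):
                b1, b2 = records[0]["nt"][j], records[1]["nt"][j]
                if config.error_rate > 0:
                    b1 = _flip(b1, snp, config.error_rate, rng)
                    b2 = _flip(b2, snp, config.error_rate, rng)
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    calls[snp.snp_id][sample] = None
                else:
                    calls[snp.snp_id][sample] = as_call(b1, b2)
            lengths = sorted(
                {
                    config.hinge_config.predicted_length(r["hinge_exons"])
                    for r in records
                }
            )
            hinge_lengths[sample] = tuple(lengths)

    matrix = GenotypeMatrix(
        samples=samples,
        populations=populations,
        snps=panel,
        calls=calls,
        provenance=f"simulated:seed={config.seed}",
    )
    table = HingeLengthTable(
        samples=samples, populations=dict(populations), lengths=hinge_lengths
    )
    pool_freqs = {
        label: {h.names: h.freq for h in pool} for label, pool in config.pools.items()
    }
    return matrix, table, TruthSet(diplotypes=truth, pool_freqs=pool_freqs)


def _flip(base: str, snp: SnpDef, rate: float, rng: np.random.Generator) -> str:
    if rng.random() >= rate:
        return base
    others = [b for b in snp.alleles if b != base]
    if not others:
        return base
    return others[rng.choice(len(others))]


def regenerate_matrix_from_truth(
    truth: TruthSet, matrix: GenotypeMatrix
) -> GenotypeMatrix:
    """Pre-error genotype matrix implied by the truth diplotypes."""
    calls: dict[str, dict[str, tuple[str, str] | None]] = {
        s.snp_id: {} for s in matrix.snps
    }
    for sample, (rec1, rec2) in truth.diplotypes.items():
        for j, snp in enumerate(matrix.snps):
            calls[snp.snp_id][sample] = as_call(rec1["nt"][j], rec2["nt"][j])
    return GenotypeMatrix(
        samples=list(matrix.samples),
        populations=dict(matrix.populations),
        snps=list(matrix.snps),
        calls=calls,
        provenance="truth",
    )


# ---------------------------------------------------------------------------
# Packaged tables123 configuration
# ---------------------------------------------------------------------------

def tables123_config(
    seed: int = 0,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    path: str | Path | None = None,
) -> SimConfig:
    """The default study-structure configuration (three cohorts of ~95)."""
    p = Path(path) if path is not None else _data_path("tables123_pools.yaml")
    doc = yaml.safe_load(p.read_text())
    if doc.get("schema") != "ighgkit-sim-pools/1":
        raise ValueError(f"{p}: unsupported pools schema {doc.get('schema')!r}")
    pools = {}
    cohorts = {}
    for pop, block in doc["populations"].items():
        pools[pop] = [
            PoolHaplotype(
                g3=h["g3"], hinge_exons=int(h["hinge_exons"]), g1=h["g1"],
                g2=h["g2"], freq=float(h["freq"]),
            )
            for h in block["haplotypes"]
        ]
        cohorts[pop] = (int(block["n_samples"]), {pop: 1.0})
    return SimConfig(
        seed=seed,
        pools=pools,
        cohorts=cohorts,
        member_splits=doc.get("member_splits", {}),
        missing_rate=missing_rate,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# Balding-Nichols divergent-population SNPs
# ---------------------------------------------------------------------------

def simulate_bn_pair(
    n_snps: int,
    F: float,
    n_per_pop: int | tuple[int, int],
    seed: int = 0,
    p_range: tuple[float, float] = (0.1, 0.9),
) -> BnPairSim:
    """Genotype counts for two populations under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``p_range``; each population's
    frequency is Beta(p (1-F)/F, (1-p)(1-F)/F) around the ancestral p
    (F = 0 degenerates to both populations sharing p exactly); genotypes are
    drawn under within-population Hardy-Weinberg proportions.
    """
    if not 0 <= F < 1:
        raise ValueError("F must lie in [0, 1)")
    if isinstance(n_per_pop, int):
        n_per_pop = (n_per_pop, n_per_pop)
    rng = np.random.default_rng(seed)
    p = rng.uniform(p_range[0], p_range[1], size=n_snps)
    if F == 0:
        freqs = np.stack([p, p], axis=1)
    else:
        k = (1 - F) / F
        freqs = np.stack(
            [rng.beta(p * k, (1 - p) * k) for _ in range(2)], axis=1
        )
    counts1, counts2 = [], []
    for i in range(n_snps):
        row = []
        for pop, n in enumerate(n_per_pop):
            q = freqs[i, pop]
            geno = rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
            row.append((int((geno == 0).sum()), int((geno == 1).sum()),
                        int((geno == 2).sum())))
        counts1.append(row[0])
        counts2.append(row[1])
    return BnPairSim(
        counts1=counts1, counts2=counts2, ancestral_p=p, pop_freqs=freqs, F=F
    )
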