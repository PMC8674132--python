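"""Nucleotide haplotypes to amino-acid allotypes.

Allotypes (protein variants of the IgG constant heavy chain) are obtained by
translating phased nucleotide haplotypes in the reference codon context.
Alleles encoding the same amino-acid sequence -- i.e. differing only by
synonymous changes -- are grouped, and the group is named after its most
frequent member allele.  Residue vectors with no catalog match receive a
stable novel label (``GENE*n<k>``); labels the study itself published for
such vectors are reproduced through the packaged alias file.  Gm serological
designations (G1m/G2m/G3m) are attached from the catalog.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ighgkit import phasing
from ighgkit.genotype_io import GenotypeMatrix
from ighgkit.reference import (
    CODON_TABLE,
    AlleleCatalog,
    GeneModel,
    SnpDef,
    load_novel_aliases,
    translate,
)


class PrematureStopError(ValueError):
    """A haplotype introduces a stop codon inside the coding region."""


def mutated_cds(model: GeneModel, snps: Sequence[SnpDef], haplotype: str) -> str:
    """Reference CDS with one substitution per SNP according to the haplotype."""
    if len(haplotype) != len(snps):
        raise ValueError(f"haplotype length {len(haplotype)} != {len(snps)} loci")
    cds = list(model.cds)
    for snp, base in zip(snps, haplotype):
        if base not in snp.alleles:
            raise ValueError(f"{snp.snp_id}: base {base!r} not among {snp.alleles}")
        cds[model.cds_pos(snp.exon, snp.exon_pos)] = base
    return "".join(cds)


def translate_haplotype(
    model: GeneModel,
    snps: Sequence[SnpDef],
    haplotype: str,
    positions: Sequence[int] | None = None,
) -> str:
    """Residue vector over ``positions`` (default: the haplotype's non-synonymous
    Eu positions, ascending) encoded by a nucleotide haplotype.

    Each variant codon is rebuilt on the reference background and the whole
    coding sequence is translated; a premature stop is an error (no catalog
    allele truncates the constant region).
    """
    cds = mutated_cds(model, snps, haplotype)
    protein = translate(cds)
    stop = protein.find("*")
    if stop != -1 and stop != len(protein) - 1:
        raise PrematureStopError(
            f"{model.gene_name}: haplotype creates a stop at codon {stop + 1}"
        )
    if positions is None:
        positions = sorted(
            {s.eu_pos for s in snps if s.is_nonsynonymous and s.eu_pos is not None}
        )
    out = []
    for eu in positions:
        idx = model.codon_index_of_eu(eu)
        out.append(protein[idx])
    return "".join(out)


@dataclass
class AlleleCall:
    """A phased nucleotide haplotype of one gene with its catalog identity."""

    gene: str
    haplotype: str  # one base per SnpDef of the phased panel
    allele_name: str  # catalog allele, published novel name, or run-local label
    freq: dict[str, float] = field(default_factory=dict)  # population -> frequency


@dataclass
class AllotypeCall:
    gene: str
    residues: str  # explicit residue vector over the gene's catalog positions
    name: str
    members: list[str]
    gm: str | None
    freq: dict[str, float] = field(default_factory=dict)
    hinge_exons: int | None = None


@dataclass(frozen=True)
class GmString:
    g3m: str
    g1m: str
    g2m: str

    def __str__(self) -> str:  # concatenated serological designation
        return f"G3m{self.g3m} G1m{self.g1m} G2m{self.g2m}"


class NovelNameRegistry:
    """Stable run-local novel-allotype labels, persisted as a JSON manifest."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.names: dict[str, str] = {}  # "GENE:VECTOR[:hinge]" -> label
        if self.path and self.path.exists():
            self.names = json.loads(self.path.read_text())

    def save(self) -> None:
        if self.path:
            self.path.write_text(json.dumps(self.names, indent=2, sort_keys=True))

    @staticmethod
    def key(gene: str, vector: str, hinge: int | None = None) -> str:
        return f"{gene}:{vector}" + (f":{hinge}" if hinge is not None else "")


def _alias_index(aliases: list[dict] | None):
    idx = {}
    for a in aliases or []:
        idx[(a["gene"], a["vector"])] = a
    return idx


def name_vector(
    gene: str,
    vector: str,
    catalog: AlleleCatalog,
    aliases: list[dict] | None = None,
    registry: NovelNameRegistry | None = None,
    hinge_exons: int | None = None,
) -> tuple[str, str | None]:
    """(name, gm) for a residue vector.

    Exact match against catalog allotype representatives wins; if several
    representatives share the vector and differ only in hinge length (the
    IGHG3*11 / IGHG3*12 situation), the hinge count disambiguates when
    available and a dual label is returned otherwise.  Unmatched vectors get
    the published alias name when one exists, else a registry label.
    """
    reps = [
        e for e in catalog.gene_entries(gene)
        if e.is_allotype_representative and "".join(e.residues) == vector
    ]
    if len(reps) > 1 and hinge_exons is not None:
        narrowed = [e for e in reps if e.hinge_exons == hinge_exons]
        reps = narrowed or reps
    if len(reps) == 1:
        return reps[0].name, reps[0].gm
    if len(reps) > 1:
        names = sorted(e.name for e in reps)
        gms = {e.gm for e in reps}
        return "/".join(names), gms.pop() if len(gms) == 1 else None
    alias = _alias_index(aliases).get((gene, vector))
    if alias is not None:
        return alias["published_name"], alias.get("gm")
    if registry is not None:
        key = registry.key(gene, vector)
        if key not in registry.names:
            taken = {v for k, v in registry.names.items() if k.startswith(gene + ":")}
            taken |= {a["published_name"] for a in aliases or [] if a["gene"] == gene}
            k = 1
            while f"{gene}*n{k}" in taken:
                k += 1
            registry.names[key] = f"{gene}*n{k}"
            registry.save()
        return registry.names[key], None
    return f"{gene}*novel[{vector}]", None


def match_allele(
    gene: str,
    snps: Sequence[SnpDef],
    haplotype: str,
    catalog: AlleleCatalog,
    aliases: list[dict] | None = None,
) -> str | None:
    """Catalog allele whose nucleotide states exactly match a phased haplotype."""
    candidates = []
    entries = list(catalog.gene_entries(gene))
    for alias in aliases or []:
        if alias["gene"] == gene and "nt" in alias:
            candidates.append((alias["published_name"], alias["nt"]))
    for e in entries:
        if e.nt_states is not None:
            candidates.append((e.name, e.nt_states))
    ref_states = {s.snp_id: s.ref_base for s in snps}
    best = None
    for name, nt in candidates:
        ok = all(
            nt.get(s.snp_id, ref_states[s.snp_id]) == base
            for s, base in zip(snps, haplotype)
        )
        # an exact match must also not require alts outside the panel
        extra = [k for k, v in nt.items() if k not in ref_states]
        if ok and not extra:
            if best is None or name < best:
                best = name
    return best


def collapse_to_allotypes(
    gene: str,
    model: GeneModel,
    snps: Sequence[SnpDef],
    allele_calls: Sequence[AlleleCall],
    catalog: AlleleCatalog,
    aliases: list[dict] | None = None,
    registry: NovelNameRegistry | None = None,
    hinge_of_allele: Mapping[str, int] | None = None,
) -> list[AllotypeCall]:
    """Group alleles encoding the same protein; name each group.

    The allotype frequency is the sum of member frequencies per population;
    the group is named after the member with the highest pooled frequency
    (ties break to the lexicographically smallest member name), then mapped
    against the catalog for its serological (Gm) designation.
    """
    positions = catalog.positions[gene]
    groups: dict[str, list[AlleleCall]] = defaultdict(list)
    for call in allele_calls:
        vec = translate_haplotype(model, snps, call.haplotype, positions)
        groups[vec].append(call)
    out: list[AllotypeCall] = []
    for vec, members in groups.items():
        freq: dict[str, float] = defaultdict(float)
        for m in members:
            for pop, f in m.freq.items():
                freq[pop] += f
        pooled = {m.allele_name: sum(m.freq.values()) for m in members}
        top = max(pooled.values())
        rep = min(n for n, f in pooled.items() if f >= top * (1 - 1e-12))
        hinge = (hinge_of_allele or {}).get(rep)
        name, gm = name_vector(gene, vec, catalog, aliases, registry, hinge)
        # groups whose representative member is itself a named catalog allele
        # keep that name (most-frequent-member rule)
        if rep in {e.name for e in catalog.gene_entries(gene)}:
            entry = catalog.by_name(rep)
            target = entry.allotype_of or rep
            name = target
            gm = catalog.by_name(target).gm
        out.append(
            AllotypeCall(
                gene=gene,
                residues=vec,
                name=name,
                members=sorted(pooled, key=lambda n: (-pooled[n], n)),
                gm=gm,
                freq=dict(freq),
                hinge_exons=hinge,
            )
        )
    out.sort(key=lambda a: -sum(a.freq.values()))
    return out


def gm_of(
    g3_name: str,
    g1_name: str,
    g2_name: str,
    catalog: AlleleCatalog,
    aliases: list[dict] | None = None,
) -> GmString:
    """Serological Gm designation of an (IGHG3, IGHG1, IGHG2) allotype triple.

    Novel allotypes inherit the Gm of a catalog neighbour only when the
    catalog marks them serologically indistinguishable (an explicit field);
    otherwise the component is ``unassigned``.
    """
    alias_by_name = {a["published_name"]: a for a in aliases or []}

    def component(name: str) -> str:
        try:
            gm = catalog.by_name(name).gm
            return gm if gm is not None else "unassigned"
        except KeyError:
            pass
        if name in alias_by_name:
            gm = alias_by_name[name].get("gm")
            return gm if gm else "unassigned"
        if "/" in name:  # dual label (hinge-ambiguous): components share Gm
            first = name.split("/")[0]
            return component(first)
        return "unassigned"

    return GmString(g3m=component(g3_name), g1m=component(g1_name), g2m=component(g2_name))


# ---------------------------------------------------------------------------
# Frequency reports (human-readable tables)
# ---------------------------------------------------------------------------

def allotype_calls_for_gene(
    matrix: GenotypeMatrix,
    gene: str,
    model: GeneModel,
    catalog: AlleleCatalog,
    populations: Sequence[str] | None = None,
    aliases: list[dict] | None = None,
    registry: NovelNameRegistry | None = None,
    seed: int = 0,
    loci: Sequence[SnpDef] | None = None,
    **em_kwargs,
) -> list[AllotypeCall]:
    """EM-phase one gene's amino-acid-changing SNPs and collapse to allotypes."""
    if loci is None:
        loci = [s for s in matrix.snps if s.gene == gene and s.is_nonsynonymous
                and s.callable]
    loci = list(loci)
    pops = list(populations) if populations else matrix.population_labels()
    calls: dict[str, AlleleCall] = {}
    for pop in pops:
        freqs = phasing.multigene_haplotypes(
            matrix, loci, population=pop, threshold=0.0, seed=seed,
            require_nonsynonymous=False, **em_kwargs,
        )
        for hap, f in freqs.haplotypes.items():
            if f <= 0:
                continue
            if hap not in calls:
                name = match_allele(gene, loci, hap, catalog, aliases) or hap
                calls[hap] = AlleleCall(gene=gene, haplotype=hap, allele_name=name)
            calls[hap].freq[pop] = calls[hap].freq.get(pop, 0.0) + f
    return collapse_to_allotypes(
        gene, model, loci, list(calls.values()), catalog, aliases, registry
    )


def allotype_frequency_report(
    matrix: GenotypeMatrix,
    models: Mapping[str, GeneModel],
    catalog: AlleleCatalog,
    populations: Sequence[str] | None = None,
    min_freq: float = 0.01,
    aliases: list[dict] | None = None,
    registry: NovelNameRegistry | None = None,
    seed: int = 0,
    **em_kwargs,
) -> pd.DataFrame:
    """Per-gene allotype table: name, Gm, residues, per-population frequency.

    Frequencies come from EM phasing of non-synonymous loci per population;
    rows are kept when any population frequency strictly exceeds ``min_freq``.
    """
    if aliases is None:
        aliases = load_novel_aliases()
    pops = list(populations) if populations else matrix.population_labels()
    rows = []
    for gene in ("IGHG3", "IGHG1", "IGHG2"):
        if gene not in models or not any(s.gene == gene for s in matrix.snps):
            continue
        allotypes = allotype_calls_for_gene(
            matrix, gene, models[gene], catalog, pops, aliases, registry, seed,
            **em_kwargs,
        )
        baseline = None
        for a in allotypes:
            if not any(a.freq.get(p, 0.0) > min_freq for p in pops):
                continue
            if baseline is None:
                baseline = a.residues
            display = "".join(
                "-" if r == b else r for r, b in zip(a.residues, baseline)
            )
            row = {
                "gene": gene,
                "allotype": a.name,
                "gm": a.gm if a.gm is not None else "",
                "residues": a.residues,
                "residues_vs_top": display,
                "members": ",".join(a.members),
            }
            for p in pops:
                row[f"freq_{p}"] = round(a.freq.get(p, 0.0), 4)
            rows.append(row)
    return pd.DataFrame(rows)


def multigene_haplotype_report(
    matrix: GenotypeMatrix,
    models: Mapping[str, GeneModel],
    catalog: AlleleCatalog,
    populations: Sequence[str] | None = None,
    threshold: float = 0.01,
    aliases: list[dict] | None = None,
    registry: NovelNameRegistry | None = None,
    seed: int = 0,
    **em_kwargs,
) -> pd.DataFrame:
    """IGHG3-IGHG1-IGHG2 multigene haplotypes above ``threshold``, with Gm."""
    if aliases is None:
        aliases = load_novel_aliases()
    pops = list(populations) if populations else matrix.population_labels()
    gene_order = ("IGHG3", "IGHG1", "IGHG2")
    loci = [s for g in gene_order for s in matrix.snps
            if s.gene == g and s.is_nonsynonymous and s.callable]
    spans = {}
    start = 0
    for g in gene_order:
        n = sum(1 for s in loci if s.gene == g)
        spans[g] = (start, start + n)
        start += n
    rows = []
    for pop in pops:
        freqs = phasing.multigene_haplotypes(
            matrix, loci, population=pop, threshold=threshold, seed=seed, **em_kwargs
        )
        for hap, f in sorted(freqs.haplotypes.items(), key=lambda kv: -kv[1]):
            names = {}
            for g in gene_order:
                lo, hi = spans[g]
                sub_loci = loci[lo:hi]
                vec = translate_haplotype(
                    models[g], sub_loci, hap[lo:hi], catalog.positions[g]
                )
                names[g], _ = name_vector(g, vec, catalog, aliases, registry)
            gm = gm_of(names["IGHG3"], names["IGHG1"], names["IGHG2"], catalog, aliases)
            rows.append(
                {
                    "population": pop,
                    "haplotype": " ".join(names[g] for g in gene_order),
                    "IGHG3": names["IGHG3"],
                    "IGHG1": names["IGHG1"],
                    "IGHG2": names["IGHG2"],
                    "gm": str(gm),
                    "freq": round(f, 4),
                }
            )
    return pd.DataFrame(rows)
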