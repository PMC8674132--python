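"""Cohort genotype I/O.

Normalizes heterogeneous inputs (wide genotype tables, VCF, hinge amplicon
length lists) into one in-memory representation.  Genotypes are stored as
unordered diploid base pairs: Sanger-style genotyping carries no phase, so
any phase present in a VCF is deliberately discarded and phasing is left to
the EM module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ighgkit.reference import GeneModel, SnpDef, parse_snp_id, classify_snp

log = logging.getLogger("ighgkit")

Call = tuple[str, str]  # unordered, stored sorted


def as_call(b1: str, b2: str) -> Call:
    return (b1, b2) if b1 <= b2 else (b2, b1)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs unphased diploid calls with population labels."""

    samples: list[str]
    populations: dict[str, str]  # sample -> population label (free strings)
    snps: list[SnpDef]
    calls: dict[str, dict[str, Call | None]]  # snp_id -> sample -> call
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for snp in self.snps:
            valid = set(snp.alleles)
            for sample, call in self.calls.get(snp.snp_id, {}).items():
                if call is None:
                    continue
                bad = [b for b in call if b not in valid]
                if bad:
                    raise ValueError(
                        f"sample {sample}, SNP {snp.snp_id}: base {bad[0]!r} not in "
                        f"{sorted(valid)}"
                    )

    # -- access ------------------------------------------------------------

    def snp(self, snp_id: str) -> SnpDef:
        for snp in self.snps:
            if snp.snp_id == snp_id:
                return snp
        raise KeyError(snp_id)

    def call(self, sample: str, snp_id: str) -> Call | None:
        return self.calls.get(snp_id, {}).get(sample)

    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            pop = self.populations[s]
            if pop not in seen:
                seen.append(pop)
        return seen

    def samples_in(self, populations: Sequence[str] | None = None) -> list[str]:
        if populations is None:
            return list(self.samples)
        pops = set(populations)
        return [s for s in self.samples if self.populations[s] in pops]

    def observed_alleles(self, snp_id: str, populations: Sequence[str] | None = None) -> list[str]:
        out: set[str] = set()
        for s in self.samples_in(populations):
            call = self.call(s, snp_id)
            if call:
                out.update(call)
        return sorted(out)

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        wanted = list(snp_ids)
        return GenotypeMatrix(
            samples=list(self.samples),
            populations=dict(self.populations),
            snps=[self.snp(sid) for sid in wanted],
            calls={sid: dict(self.calls.get(sid, {})) for sid in wanted},
            provenance=self.provenance,
        )

    def missingness(self) -> dict[str, float]:
        out = {}
        for snp in self.snps:
            miss = sum(1 for s in self.samples if self.call(s, snp.snp_id) is None)
            out[snp.snp_id] = miss / len(self.samples) if self.samples else 0.0
        return out


@dataclass
class HingeLengthTable:
    """Per-sample IGHG3 hinge amplicon band lengths (bp)."""

    samples: list[str]
    populations: dict[str, str]
    lengths: dict[str, tuple[float, ...]]  # 1-3 observed band sizes

    def __post_init__(self) -> None:
        for sample, bands in self.lengths.items():
            if not 1 <= len(bands) <= 3:
                raise ValueError(f"{sample}: expected 1-3 bands, got {len(bands)}")


# ---------------------------------------------------------------------------
# Wide genotype table (one row per sample; sample_id, population, snp columns)
# ---------------------------------------------------------------------------

def _classify_or_passthrough(models: Mapping[str, GeneModel], snp_id: str,
                             calls: Iterable[str],
                             declared_alts: Sequence[str] | None = None) -> SnpDef:
    """Build a SnpDef for a table column.

    The reference base comes from the gene model; alternative bases come from
    the packaged panel when the site is declared there (so out-of-domain
    calls are rejected), else they are inferred from the observed calls.
    """
    skel = parse_snp_id(snp_id)
    model = models[skel.gene]
    ref = model.cds[model.cds_pos(skel.exon, skel.exon_pos)]
    if declared_alts is not None:
        alts = sorted(declared_alts)
    else:
        alts = sorted({b for call in calls for b in call if b != ref})
    if not alts:
        # monomorphic column: keep a degenerate def with the model ref only
        exon = model.exon_by_name(skel.exon)
        from dataclasses import replace
        return replace(skel, ref_base=ref, alt_bases=(), is_nonsynonymous=False,
                       callable=exon.callable)
    return classify_snp(model, skel, ref, alts)


def read_genotype_table(path: str | Path, models: Mapping[str, GeneModel]) -> GenotypeMatrix:
    """Read a wide CSV/TSV genotype table (delimiter auto-detected).

    Grammar: header ``sample_id,population,<snp_id>...``; calls are ``X/Y``
    with ``.`` (or ``./.``) for missing.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["sample_id", "population"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    snp_cols = [c for c in df.columns if c not in required]
    samples = df["sample_id"].tolist()
    populations = dict(zip(samples, df["population"]))

    from ighgkit.reference import load_study_variants

    panel_df = load_study_variants()
    rsid_of = dict(
        panel_df[["snp_id", "rsid"]].dropna().itertuples(index=False)
    )
    declared_alts = {
        row.snp_id: tuple(str(row.alt).split(","))
        for row in panel_df.itertuples()
    }

    snps: list[SnpDef] = []
    calls: dict[str, dict[str, Call | None]] = {}
    for col in snp_cols:
        parsed: dict[str, Call | None] = {}
        for sample, raw in zip(samples, df[col]):
            raw = (raw or ".").strip()
            if raw in {".", "./.", ""}:
                parsed[sample] = None
                continue
            parts = raw.replace("|", "/").split("/")
            if len(parts) != 2 or not all(p in "ACGT" for p in parts):
                raise ValueError(f"{path}: invalid call {raw!r} at sample "
                                 f"{sample!r}, column {col!r}")
            parsed[sample] = as_call(*parts)
        observed = [c for c in parsed.values() if c is not None]
        snp = _classify_or_passthrough(models, col, observed, declared_alts.get(col))
        if snp.rsid is None and rsid_of.get(col):
            from dataclasses import replace
            snp = replace(snp, rsid=rsid_of[col])
        snps.append(snp)
        calls[snp.snp_id] = parsed
    matrix = GenotypeMatrix(samples=samples, populations=populations, snps=snps,
                            calls=calls, provenance=f"table:{path}")
    miss = matrix.missingness()
    worst = max(miss.values(), default=0.0)
    log.info("read %d samples x %d SNPs from %s (max per-SNP missingness %.3f)",
             len(samples), len(snps), path, worst)
    return matrix


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path, sep: str = ",") -> None:
    rows = []
    for sample in matrix.samples:
        row = {"sample_id": sample, "population": matrix.populations[sample]}
        for snp in matrix.snps:
            call = matrix.call(sample, snp.snp_id)
            row[snp.snp_id] = "." if call is None else f"{call[0]}/{call[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    models: Mapping[str, GeneModel],
    sample_pop_map: Mapping[str, str],
    site_map: Mapping[str, str],
) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF.

    ``site_map`` maps VCF sites to SNP ids, keyed either by rsid or by
    ``"<contig>:<pos>"`` (1-based); unmapped sites are skipped with a logged
    count.  Phased separators are accepted, but phase is discarded — the
    pipeline re-phases.  Multi-allelic records beyond the declared alts are
    skipped with a warning; non-diploid genotypes are an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_pops = [s for s in samples if s not in sample_pop_map]
    if missing_pops:
        raise ValueError(f"no population label for samples: {missing_pops[:5]}")
    snps: list[SnpDef] = []
    calls: dict[str, dict[str, Call | None]] = {}
    skipped = 0
    for rec in vcf:
        key = rec.ID if rec.ID and rec.ID in site_map else f"{rec.CHROM}:{rec.POS}"
        snp_id = site_map.get(key)
        if snp_id is None:
            skipped += 1
            continue
        skel = parse_snp_id(snp_id)
        model = models[skel.gene]
        alts = [a for a in rec.ALT if a and len(a) == 1 and a in "ACGT"]
        if len(alts) != len(rec.ALT):
            log.warning("%s: non-SNP or invalid alts at %s; site skipped", path, key)
            skipped += 1
            continue
        try:
            snp = classify_snp(model, skel, rec.REF, alts, rsid=rec.ID)
        except ValueError as exc:
            log.warning("%s: %s; site skipped", path, exc)
            skipped += 1
            continue
        alleles = (rec.REF, *alts)
        parsed: dict[str, Call | None] = {}
        for sample, gt in zip(samples, rec.genotypes):
            *allele_idx, _phased = gt
            if len(allele_idx) != 2:
                raise ValueError(f"{path}: sample {sample} not diploid at {key}")
            if -1 in allele_idx:
                parsed[sample] = None
            else:
                parsed[sample] = as_call(alleles[allele_idx[0]], alleles[allele_idx[1]])
        snps.append(snp)
        calls[snp.snp_id] = parsed
    log.info("read %d mapped sites from %s (%d sites skipped)", len(snps), path, skipped)
    return GenotypeMatrix(
        samples=samples,
        populations={s: sample_pop_map[s] for s in samples},
        snps=snps,
        calls=calls,
        provenance=f"vcf:{path}",
    )


# ---------------------------------------------------------------------------
# Hinge amplicon lengths
# ---------------------------------------------------------------------------

def read_hinge_table(path: str | Path) -> HingeLengthTable:
    """CSV with columns sample_id, population, lengths_bp (semicolon-separated)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "population", "lengths_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    samples = df["sample_id"].tolist()
    lengths = {
        s: tuple(float(x) for x in raw.split(";") if x.strip())
        for s, raw in zip(samples, df["lengths_bp"])
    }
    return HingeLengthTable(
        samples=samples,
        populations=dict(zip(samples, df["population"])),
        lengths=lengths,
    )


def write_hinge_table(table: HingeLengthTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": table.samples,
            "population": [table.populations[s] for s in table.samples],
            "lengths_bp": [";".join(f"{x:g}" for x in table.lengths[s]) for s in table.samples],
        }
    ).to_csv(path, index=False)
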