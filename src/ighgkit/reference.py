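"""Gene models, SNP naming and the IMGT/Gm allele catalog.

The three IgG heavy-chain constant genes (IGHG1, IGHG2, IGHG3) are modelled
as ordered coding exons (CH1, hinge, CH2, CH3; IGHG3 carries up to four hinge
exons).  Polymorphic sites are named ``GENE_EXON_POS`` -- e.g. ``G1_CH1_68``
is the 68th nucleotide of the IGHG1 CH1 exon -- and amino-acid positions use
the Eu numbering system.

The packaged gene models and catalog are synthetic reconstructions built from
IMGT-style records and the published allotype tables; they are regenerated by
``scripts/build_reference_fixtures.py`` and carry a ``synthetic_reconstruction``
flag in their headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

GENES = ("IGHG1", "IGHG2", "IGHG3")
GENE_TOKENS = {"G1": "IGHG1", "G2": "IGHG2", "G3": "IGHG3"}
TOKEN_OF_GENE = {v: k for k, v in GENE_TOKENS.items()}
EXON_NAMES = ("CH1", "H", "H1", "H2", "H3", "H4", "CH2", "CH3")
BASES = ("A", "C", "G", "T")

_SNP_ID_RE = re.compile(r"^(G[123])_(CH1|H[1-4]?|CH2|CH3)_([1-9]\d*)$")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence; ``*`` marks stop codons."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


class SnpIdError(ValueError):
    """Raised when a SNP identifier does not follow the GENE_EXON_POS grammar."""


class ReferenceMismatchError(ValueError):
    """Raised when a declared reference base disagrees with the gene model."""


@dataclass(frozen=True)
class SnpDef:
    """A polymorphic site on one gene, in exon-local 1-based coordinates."""

    snp_id: str
    gene: str
    exon: str
    exon_pos: int
    ref_base: str | None = None
    alt_bases: tuple[str, ...] = ()
    rsid: str | None = None
    eu_pos: int | None = None
    is_nonsynonymous: bool | None = None
    callable: bool = True

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_base, *self.alt_bases) if self.ref_base else self.alt_bases

    @property
    def key(self) -> tuple:
        """Identity used for cross-dataset comparison (strict: includes alts)."""
        return (self.gene, self.exon, self.exon_pos, tuple(sorted(self.alt_bases)))


def parse_snp_id(snp_id: str) -> SnpDef:
    """Parse ``G1_CH1_68``-style identifiers into a SnpDef skeleton."""
    m = _SNP_ID_RE.match(snp_id)
    if not m:
        # identify the offending token for the error message
        parts = snp_id.split("_")
        if len(parts) != 3:
            raise SnpIdError(f"malformed SNP id {snp_id!r}: expected GENE_EXON_POS")
        gene_tok, exon_tok, pos_tok = parts
        if gene_tok not in GENE_TOKENS:
            raise SnpIdError(f"malformed SNP id {snp_id!r}: unknown gene token {gene_tok!r}")
        if exon_tok not in EXON_NAMES:
            raise SnpIdError(f"malformed SNP id {snp_id!r}: unknown exon token {exon_tok!r}")
        raise SnpIdError(f"malformed SNP id {snp_id!r}: bad position token {pos_tok!r}")
    gene_tok, exon, pos = m.groups()
    return SnpDef(snp_id=snp_id, gene=GENE_TOKENS[gene_tok], exon=exon, exon_pos=int(pos))


def format_snp_id(gene: str, exon: str, exon_pos: int) -> str:
    return f"{TOKEN_OF_GENE[gene]}_{exon}_{exon_pos}"


@dataclass(frozen=True)
class Exon:
    name: str
    sequence: str
    phase_offset: int  # leading nucleotides that complete the upstream codon
    eu_start: int | None  # Eu position of the first full codon (None: no Eu map)
    callable: bool = True

    @property
    def n_full_codons(self) -> int:
        return (len(self.sequence) - self.phase_offset) // 3

    @property
    def trailing(self) -> int:
        return (len(self.sequence) - self.phase_offset) % 3


@dataclass
class GeneModel:
    """Exon-structured reference coding sequence with an Eu-position map."""

    gene_name: str
    exons: list[Exon]
    hinge_first_exon_aa: int | None = None
    hinge_unit_aa: int | None = None
    _cds: str = field(init=False, repr=False)
    _exon_cds_offset: dict[str, int] = field(init=False, repr=False)
    _codon_eu: list[int | None] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._exon_cds_offset = {}
        pieces: list[str] = []
        pos = 0
        for exon in self.exons:
            self._exon_cds_offset[exon.name] = pos
            pieces.append(exon.sequence)
            pos += len(exon.sequence)
        self._cds = "".join(pieces)
        if len(self._cds) % 3:
            raise ValueError(f"{self.gene_name}: spliced CDS length not divisible by 3")
        # Assign an Eu position (or None) to every codon of the spliced CDS.
        codon_eu: list[int | None] = [None] * (len(self._cds) // 3)
        for exon in self.exons:
            off = self._exon_cds_offset[exon.name]
            if exon.phase_offset and (off + exon.phase_offset) % 3:
                raise ValueError(f"{self.gene_name}/{exon.name}: phase offset inconsistent with splice")
            if exon.phase_offset and exon.eu_start is not None:
                codon_eu[off // 3] = exon.eu_start - 1  # boundary codon split across exons
            if exon.eu_start is not None:
                first = (off + exon.phase_offset) // 3
                for k in range(exon.n_full_codons):
                    codon_eu[first + k] = exon.eu_start + k
        self._codon_eu = codon_eu
        seen = [e for e in codon_eu if e is not None]
        if len(seen) != len(set(seen)):
            raise ValueError(f"{self.gene_name}: Eu map is not injective")

    # -- coordinate helpers ------------------------------------------------

    @property
    def cds(self) -> str:
        return self._cds

    def exon_by_name(self, name: str) -> Exon:
        for exon in self.exons:
            if exon.name == name:
                return exon
        raise KeyError(f"{self.gene_name} has no exon {name!r}")

    def cds_pos(self, exon: str, exon_pos: int) -> int:
        """0-based CDS offset of the 1-based ``exon_pos`` within ``exon``."""
        ex = self.exon_by_name(exon)
        if not 1 <= exon_pos <= len(ex.sequence):
            raise ValueError(
                f"{format_snp_id(self.gene_name, exon, exon_pos)}: position outside "
                f"exon of length {len(ex.sequence)}"
            )
        return self._exon_cds_offset[exon] + exon_pos - 1

    def codon_context(self, exon: str, exon_pos: int) -> tuple[int, int, str]:
        """(codon index, 0-based offset within codon, codon string) for a site."""
        cpos = self.cds_pos(exon, exon_pos)
        idx = cpos // 3
        return idx, cpos % 3, self._cds[3 * idx : 3 * idx + 3]

    def eu_of_codon(self, codon_index: int) -> int | None:
        return self._codon_eu[codon_index]

    @property
    def eu_map(self) -> dict[tuple[str, int], int]:
        """Mapping (exon name, 1-based full-codon index within exon) -> Eu."""
        out: dict[tuple[str, int], int] = {}
        for exon in self.exons:
            if exon.eu_start is None:
                continue
            for k in range(exon.n_full_codons):
                out[(exon.name, k + 1)] = exon.eu_start + k
        return out

    def codon_index_of_eu(self, eu: int) -> int:
        for idx, e in enumerate(self._codon_eu):
            if e == eu:
                return idx
        raise KeyError(f"{self.gene_name}: Eu position {eu} not in map")

    def residue_at_eu(self, eu: int) -> str:
        idx = self.codon_index_of_eu(eu)
        return CODON_TABLE[self._cds[3 * idx : 3 * idx + 3]]

    def protein(self) -> str:
        aa = translate(self._cds)
        return aa[:-1] if aa.endswith("*") else aa


def classify_snp(
    model: GeneModel,
    snp: SnpDef,
    ref_base: str,
    alt_bases: str | Sequence[str],
    rsid: str | None = None,
) -> SnpDef:
    """Fill in Eu position and synonymous/non-synonymous status for a site.

    The codon carrying the site is rebuilt on the reference background; the
    variant is non-synonymous iff any alternative codon translates to a
    different residue, in which case ``eu_pos`` is taken from the Eu map.
    """
    if isinstance(alt_bases, str):
        alt_bases = (alt_bases,)
    alt_bases = tuple(alt_bases)
    for b in (ref_base, *alt_bases):
        if b not in BASES:
            raise ValueError(f"{snp.snp_id}: invalid base {b!r}")
    if any(a == ref_base for a in alt_bases):
        raise ValueError(f"{snp.snp_id}: alt base equals ref base {ref_base!r}")
    if len(set(alt_bases)) != len(alt_bases):
        raise ValueError(f"{snp.snp_id}: duplicate alt bases")
    exon = model.exon_by_name(snp.exon)
    cpos = model.cds_pos(snp.exon, snp.exon_pos)
    if model.cds[cpos] != ref_base:
        raise ReferenceMismatchError(
            f"{snp.snp_id}: declared ref {ref_base!r} but model has {model.cds[cpos]!r}"
        )
    idx, within, codon = model.codon_context(snp.exon, snp.exon_pos)
    ref_aa = CODON_TABLE[codon]
    nonsyn = False
    for alt in alt_bases:
        alt_codon = codon[:within] + alt + codon[within + 1 :]
        if CODON_TABLE[alt_codon] != ref_aa:
            nonsyn = True
    eu = model.eu_of_codon(idx) if nonsyn else None
    return replace(
        snp,
        ref_base=ref_base,
        alt_bases=alt_bases,
        rsid=rsid if rsid is not None else snp.rsid,
        eu_pos=eu,
        is_nonsynonymous=nonsyn,
        callable=exon.callable,
    )


# ---------------------------------------------------------------------------
# Allele catalog
# ---------------------------------------------------------------------------

_GM_RE = re.compile(r"^(\.\.|[0-9]{1,2}\*?)(,\s*[0-9]{1,2}\*?)*$")


def gm_is_valid(gm: str) -> bool:
    """Comma-separated Gm marker grammar (Lefranc nomenclature).

    Markers are small integers, optionally starred for the abbreviated marker
    series (e.g. G3m ``5*``); ``..`` denotes absence of the G2m 23 marker.
    """
    return bool(_GM_RE.match(gm.strip()))


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    gene: str
    residues: tuple[str, ...]  # one residue per catalog position, dash-resolved
    gm: str | None = None
    nt_states: Mapping[str, str] | None = None  # snp_id -> base, where known
    hinge_exons: int | None = None
    allotype_of: str | None = None  # set for synonymous member alleles
    serologically_same_as: tuple[str, ...] = ()

    @property
    def is_allotype_representative(self) -> bool:
        return self.allotype_of is None


@dataclass
class AlleleCatalog:
    positions: dict[str, tuple[int, ...]]  # gene -> variable Eu positions
    entries: list[CatalogEntry]
    source: str | None = None

    def gene_entries(self, gene: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.gene == gene]

    def by_name(self, name: str) -> CatalogEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def residue_vector(self, name: str) -> str:
        return "".join(self.by_name(name).residues)


def _resolve_dashes(vector: str, baseline: str) -> str:
    if len(vector) != len(baseline):
        raise ValueError(f"vector length {len(vector)} != baseline {len(baseline)}")
    return "".join(b if v == "-" else v for v, b in zip(vector, baseline))


def _data_path(name: str) -> Path:
    return Path(resources.files("ighgkit").joinpath("data", name))


def load_gene_model(gene_or_path: str | Path) -> GeneModel:
    """Load a gene model from YAML (packaged model when given a gene name)."""
    if isinstance(gene_or_path, str) and gene_or_path in GENES:
        path = _data_path(f"{gene_or_path.lower()}.model.yaml")
    else:
        path = Path(gene_or_path)
    doc = yaml.safe_load(path.read_text())
    if doc.get("schema") != "ighgkit-gene-model/1":
        raise ValueError(f"{path}: unsupported gene-model schema {doc.get('schema')!r}")
    exons = [
        Exon(
            name=e["name"],
            sequence=e["sequence"].upper(),
            phase_offset=int(e.get("phase_offset", 0)),
            eu_start=e.get("eu_start"),
            callable=bool(e.get("callable", True)),
        )
        for e in doc["exons"]
    ]
    return GeneModel(
        gene_name=doc["gene"],
        exons=exons,
        hinge_first_exon_aa=doc.get("hinge_first_exon_aa"),
        hinge_unit_aa=doc.get("hinge_repeat_exon_aa"),
    )


def load_gene_models() -> dict[str, GeneModel]:
    return {g: load_gene_model(g) for g in GENES}


def load_catalog(path: str | Path | None = None) -> AlleleCatalog:
    """Load the allele catalog; dash notation is resolved at load time."""
    p = Path(path) if path is not None else _data_path("allele_catalog.yaml")
    doc = yaml.safe_load(p.read_text())
    if doc.get("schema") != "ighgkit-allele-catalog/1":
        raise ValueError(f"{p}: unsupported catalog schema {doc.get('schema')!r}")
    positions: dict[str, tuple[int, ...]] = {}
    entries: list[CatalogEntry] = []
    for gene, block in doc["genes"].items():
        positions[gene] = tuple(int(x) for x in block["positions"])
        alleles = block["alleles"]
        if not alleles:
            continue
        baseline = alleles[0]["vector"]
        if "-" in baseline:
            raise ValueError(f"{gene}: first-listed allele vector may not contain dashes")
        for a in alleles:
            vec = _resolve_dashes(a["vector"], baseline)
            entries.append(
                CatalogEntry(
                    name=a["name"],
                    gene=gene,
                    residues=tuple(vec),
                    gm=a.get("gm"),
                    nt_states=a.get("nt") or None,
                    hinge_exons=a.get("hinge_exons"),
                    allotype_of=a.get("allotype_of"),
                    serologically_same_as=tuple(a.get("serologically_same_as", ())),
                )
            )
    return AlleleCatalog(positions=positions, entries=entries, source=str(p))


def validate_catalog(catalog: AlleleCatalog, models: Mapping[str, GeneModel]) -> list[str]:
    """Check catalog invariants against the gene models; returns violations."""
    violations: list[str] = []
    seen: set[str] = set()
    for entry in catalog.entries:
        if entry.name in seen:
            violations.append(f"{entry.name}: duplicate allele name")
        seen.add(entry.name)
        pos = catalog.positions.get(entry.gene)
        if pos is None:
            violations.append(f"{entry.name}: unknown gene {entry.gene}")
            continue
        if len(entry.residues) != len(pos):
            violations.append(
                f"{entry.name}: residue vector length {len(entry.residues)} != "
                f"{len(pos)} declared positions"
            )
        model = models.get(entry.gene)
        if model is not None:
            known = {e for e in model._codon_eu if e is not None}
            for eu in pos:
                if eu not in known:
                    violations.append(f"{entry.gene}: Eu position {eu} absent from model Eu map")
                    break
        if entry.gm is not None and not gm_is_valid(entry.gm):
            violations.append(f"{entry.name}: Gm designation {entry.gm!r} fails grammar")
        if entry.allotype_of is not None and entry.allotype_of not in {
            e.name for e in catalog.entries
        }:
            violations.append(f"{entry.name}: allotype_of {entry.allotype_of!r} not in catalog")
    # Representatives must be unique per (vector, hinge length)
    reps: dict[tuple, str] = {}
    for entry in catalog.entries:
        if not entry.is_allotype_representative:
            continue
        key = (entry.gene, entry.residues, entry.hinge_exons)
        if key in reps:
            violations.append(
                f"{entry.name}: residue vector duplicates representative {reps[key]}"
            )
        else:
            reps[key] = entry.name
    return violations


def load_study_variants(path: str | Path | None = None):
    """Packaged variant panel: the study's SNPs plus external-dataset records.

    Returns a pandas DataFrame with presence flags (study / 1kGP-ph3 /
    1kGP-30X) and per-population non-reference allele frequencies.
    """
    import pandas as pd

    p = Path(path) if path is not None else _data_path("study_variants.tsv")
    return pd.read_csv(p, sep="\t", dtype={"present_study": int, "present_ph3": int,
                                           "present_30x": int})


def study_snp_defs(
    models: Mapping[str, GeneModel],
    dataset: str = "study",
    path: str | Path | None = None,
) -> list[SnpDef]:
    """Classified SnpDefs for one dataset's panel (``study``/``ph3``/``30x``)."""
    df = load_study_variants(path)
    col = {"study": "present_study", "ph3": "present_ph3", "30x": "present_30x"}[dataset]
    out = []
    for _, row in df[df[col] == 1].iterrows():
        skel = parse_snp_id(row["snp_id"])
        rsid = row["rsid"] if isinstance(row["rsid"], str) and row["rsid"] else None
        alts = tuple(str(row["alt"]).split(","))
        out.append(classify_snp(models[skel.gene], skel, str(row["ref"]), alts, rsid=rsid))
    return out


def load_novel_aliases(path: str | Path | None = None) -> list[dict]:
    """Published names for allotypes outside the IMGT catalog (``n``/``1K`` labels)."""
    p = Path(path) if path is not None else _data_path("novel_aliases.yaml")
    doc = yaml.safe_load(p.read_text())
    if doc.get("schema") != "ighgkit-novel-aliases/1":
        raise ValueError(f"{p}: unsupported alias schema {doc.get('schema')!r}")
    return list(doc["aliases"])
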