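"""Cross-dataset variant concordance.

Which SNPs found in one dataset are present in another, with frequency
deltas for shared sites and flags for common variants exclusive to one
dataset.  Matching is by exon-local key -- (gene, exon, exon position,
sorted alternative alleles) in strict mode -- so call sets on different
genome builds compare once their site maps are normalized; a lenient
position-only mode ignores the alternative alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ighgkit.reference import GeneModel, load_study_variants, parse_snp_id

Key = tuple  # (gene, exon, exon_pos[, alts])


@dataclass
class VariantSet:
    label: str
    records: dict[Key, dict]  # key -> {"snp_id", "rsid", "freqs": {pop: f}}

    @classmethod
    def build(
        cls,
        label: str,
        rows: Sequence[Mapping],
        freq_cols: Sequence[str],
        strict: bool = True,
    ) -> "VariantSet":
        records: dict[Key, dict] = {}
        for row in rows:
            skel = parse_snp_id(row["snp_id"])
            key: Key = (skel.gene, skel.exon, skel.exon_pos)
            if strict:
                key = key + (tuple(sorted(str(row["alt"]).split(","))),)
            if key in records:
                raise ValueError(f"{label}: duplicate variant key {key}")
            freqs = {}
            for col in freq_cols:
                v = row.get(col)
                if v is not None and v == v and v != "":
                    freqs[col.removeprefix("freq_")] = float(v)
            records[key] = {
                "snp_id": row["snp_id"],
                "rsid": row.get("rsid") or "",
                "freqs": freqs,
            }
        return cls(label=label, records=records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> set:
        return set(self.records)


@dataclass
class ConcordanceResult:
    set_a: str
    set_b: str
    shared: int
    a_only: int
    b_only: int
    table: pd.DataFrame


def concordance(a: VariantSet, b: VariantSet) -> ConcordanceResult:
    """Exact set algebra on variant keys, with frequency deltas for shared keys."""
    shared = a.keys & b.keys
    a_only = a.keys - b.keys
    b_only = b.keys - a.keys
    rows = []
    for key in sorted(a.keys | b.keys):
        rec = a.records.get(key) or b.records[key]
        fa = a.records.get(key, {}).get("freqs", {})
        fb = b.records.get(key, {}).get("freqs", {})
        max_a = max(fa.values(), default=float("nan"))
        max_b = max(fb.values(), default=float("nan"))
        rows.append(
            {
                "snp_id": rec["snp_id"],
                "rsid": rec["rsid"],
                f"in_{a.label}": key in a.records,
                f"in_{b.label}": key in b.records,
                f"max_freq_{a.label}": max_a,
                f"max_freq_{b.label}": max_b,
                "freq_delta": max_a - max_b
                if key in shared and fa and fb
                else float("nan"),
            }
        )
    return ConcordanceResult(
        set_a=a.label,
        set_b=b.label,
        shared=len(shared),
        a_only=len(a_only),
        b_only=len(b_only),
        table=pd.DataFrame(rows),
    )


def flag_discrepant_common(result: ConcordanceResult, freq_threshold: float) -> pd.DataFrame:
    """Exclusive SNPs whose frequency in their own dataset exceeds the threshold."""
    if not 0 < freq_threshold < 1:
        raise ValueError("frequency threshold must lie in (0, 1)")
    t = result.table
    a_col, b_col = f"in_{result.set_a}", f"in_{result.set_b}"
    fa, fb = f"max_freq_{result.set_a}", f"max_freq_{result.set_b}"
    a_excl = t[t[a_col] & ~t[b_col] & (t[fa] > freq_threshold)]
    b_excl = t[t[b_col] & ~t[a_col] & (t[fb] > freq_threshold)]
    return pd.concat([a_excl, b_excl], ignore_index=True)


def load_packaged_variant_sets(strict: bool = True, path=None) -> dict[str, VariantSet]:
    """The packaged panels: this study's SNPs and the two 1kGP extracts."""
    df = load_study_variants(path)
    rows = df.to_dict("records")
    sets = {}
    for label, flag, cols in [
        ("study", "present_study", ["freq_ea", "freq_aa", "freq_sa"]),
        ("ph3", "present_ph3", ["freq_afr", "freq_eur", "freq_eas"]),
        ("30x", "present_30x", ["freq_afr", "freq_eur", "freq_eas"]),
    ]:
        subset = [r for r in rows if r[flag] == 1]
        sets[label] = VariantSet.build(label, subset, cols, strict=strict)
    return sets
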