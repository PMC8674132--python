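"""IGHG3 hinge exon copy-number calls from amplicon fragment lengths.

The IgG3 hinge is encoded by a variable number of exons (2-5 across
chromosomes): an invariant first exon of 17 amino acids plus 15 amino acids
per additional exon, so hinge protein lengths run 32/47/62/77 aa for 2/3/4/5
exons and consecutive copy numbers differ by 45 bp of amplicon length.
A sample showing one band is read as a copy-number homozygote (no
allele-dropout model; LabChip-style sizing), two bands as a heterozygote,
and three or more bands as an anomaly (e.g. a gene duplication) that is
excluded from allele frequencies and counted separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ighgkit.genotype_io import HingeLengthTable


@dataclass(frozen=True)
class HingeConfig:
    """Amplicon geometry for the hinge fragment.

    ``flank_bp`` is the constant non-hinge portion of the amplicon; its
    default is a placeholder (the real value depends on primer positions)
    and should be set from the assay design.
    """

    flank_bp: float = 300.0
    first_exon_aa: int = 17
    repeat_exon_aa: int = 15
    min_exons: int = 2
    max_exons: int = 5
    tolerance_bp: float = 10.0

    def protein_length(self, n_exons: int) -> int:
        return self.first_exon_aa + (n_exons - 1) * self.repeat_exon_aa

    def predicted_length(self, n_exons: int) -> float:
        return self.flank_bp + 3 * self.protein_length(n_exons)

    @property
    def rung_spacing(self) -> float:
        return 3.0 * self.repeat_exon_aa


@dataclass(frozen=True)
class HingeCall:
    sample: str
    exon_counts: tuple[int, int] | None  # sorted pair; None when uncallable
    anomaly: bool = False
    uncallable: bool = False


class UncallableLengthError(ValueError):
    pass


def exon_count_from_length(
    length_bp: float, config: HingeConfig = HingeConfig(), tolerance_bp: float | None = None
) -> int:
    """Exon count whose predicted amplicon length is nearest within tolerance."""
    if length_bp <= 0:
        raise ValueError(f"amplicon length must be positive, got {length_bp}")
    tol = config.tolerance_bp if tolerance_bp is None else tolerance_bp
    best = None
    for count in range(config.min_exons, config.max_exons + 1):
        dev = abs(length_bp - config.predicted_length(count))
        if best is None or dev < best[0]:
            best = (dev, count)
    if best[0] > tol:
        raise UncallableLengthError(
            f"length {length_bp} bp is {best[0]:.1f} bp from the nearest rung "
            f"(count {best[1]}); tolerance {tol} bp"
        )
    return best[1]


def call_sample(
    sample: str, bands: Sequence[float], config: HingeConfig = HingeConfig()
) -> HingeCall:
    if len(bands) >= 3:
        return HingeCall(sample, None, anomaly=True)
    try:
        counts = sorted(exon_count_from_length(b, config) for b in bands)
    except UncallableLengthError:
        return HingeCall(sample, None, uncallable=True)
    if len(counts) == 1:
        counts = counts * 2  # single band: copy-number homozygote
    return HingeCall(sample, tuple(counts))


def call_table(
    table: HingeLengthTable, config: HingeConfig = HingeConfig()
) -> list[HingeCall]:
    return [call_sample(s, table.lengths[s], config) for s in table.samples]


def hinge_allele_freqs(
    calls: Iterable[HingeCall],
) -> tuple[dict[int, float], int, int]:
    """(per-count allele frequencies, n anomalies, n uncallable).

    Single-band samples contribute two alleles of their count; two-band
    samples one of each; anomalies and uncallable samples are excluded.
    """
    counter: Counter[int] = Counter()
    anomalies = uncallable = 0
    for call in calls:
        if call.anomaly:
            anomalies += 1
        elif call.uncallable or call.exon_counts is None:
            uncallable += 1
        else:
            counter.update(call.exon_counts)
    total = sum(counter.values())
    if total == 0:
        raise ValueError("no callable sample")
    freqs = {count: n / total for count, n in sorted(counter.items())}
    return freqs, anomalies, uncallable


def hinge_report(
    table: HingeLengthTable, config: HingeConfig = HingeConfig()
) -> pd.DataFrame:
    """Summary table: exon count, hinge aa length, per-population allele
    frequency."""
    pops: dict[str, list[HingeCall]] = {}
    for sample in table.samples:
        pops.setdefault(table.populations[sample], []).append(
            call_sample(sample, table.lengths[sample], config)
        )
    rows: dict[int, dict] = {}
    meta = []
    for pop, calls in pops.items():
        freqs, anomalies, uncallable = hinge_allele_freqs(calls)
        meta.append({"population": pop, "anomalies": anomalies, "uncallable": uncallable})
        for count, f in freqs.items():
            row = rows.setdefault(
                count,
                {"n_hinge_exons": count, "hinge_aa": config.protein_length(count)},
            )
            row[f"freq_{pop}"] = round(f, 4)
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["n_hinge_exons"]))
    df.attrs["per_population"] = meta
    return df.fillna(0.0)
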