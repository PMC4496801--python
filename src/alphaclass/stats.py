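"""Summary statistics over annotation tracks.

Covers the per-SF base-pair accounting of an annotated sequence set, the
complete-monomer (>= 140 bp) filter, WGS-style normalization to a haploid
genome of 3x10^9 bp, and the double-filter proportion correction: total
alpha-satellite detection is taken from the unfiltered sample while the
per-SF split is taken from the filtered one, which removes most of the
unclassed monomers created by read fragmentation without sacrificing
detection.  Region statistics (e.g. R2% and B-box% of a pericentromeric
interval) are monomer-count fractions with the region size corrected by
subtracting user-supplied mask intervals (non-satellite insertions, gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotator import AnnotationRecord
from .classifier import sf_of
from .consensus_model import ALL_LABELS

SF_ORDER = ("SF1", "SF2", "SF3", "SF5", "SF4+", "none")


@dataclass
class SFSummary:
    total_bp: int                      # size of the analyzed input
    per_sf_bp: dict[str, int] = field(default_factory=dict)
    per_class_bp: dict[str, int] = field(default_factory=dict)
    per_sf_count: dict[str, int] = field(default_factory=dict)
    per_class_count: dict[str, int] = field(default_factory=dict)
    n_monomers: int = 0
    total_as_bp: int = 0
    unclassed_fraction: float = 0.0    # (Um + Xm) monomers / all monomers
    mean_monomer_length: float = 0.0

    @property
    def as_fraction(self) -> float:
        return self.total_as_bp / self.total_bp if self.total_bp else 0.0

    def sf_proportions(self) -> dict[str, float]:
        tot = self.total_as_bp or 1
        return {sf: bp / tot for sf, bp in self.per_sf_bp.items()}


def summarize(records: list[AnnotationRecord], total_bp: int) -> SFSummary:
    s = SFSummary(
        total_bp=total_bp,
        per_sf_bp={sf: 0 for sf in SF_ORDER},
        per_class_bp={c: 0 for c in ALL_LABELS},
        per_sf_count={sf: 0 for sf in SF_ORDER},
        per_class_count={c: 0 for c in ALL_LABELS},
    )
    total_len = 0
    unclassed = 0
    for r in records:
        sf = sf_of(r.label)
        s.per_sf_bp[sf] += r.length
        s.per_class_bp[r.label] += r.length
        s.per_sf_count[sf] += 1
        s.per_class_count[r.label] += 1
        total_len += r.length
        if r.label in ("Um", "Xm"):
            unclassed += 1
    s.n_monomers = len(records)
    s.total_as_bp = total_len
    s.unclassed_fraction = unclassed / len(records) if records else 0.0
    s.mean_monomer_length = total_len / len(records) if records else 0.0
    return s


def filter_complete(
    records: list[AnnotationRecord], min_len: int = 140
) -> list[AnnotationRecord]:
    """Keep only complete monomers (the uppercase records of the track)."""
    return [r for r in records if r.length >= min_len]


def corrected_profile(raw: SFSummary, filtered: SFSummary) -> SFSummary:
    """Split the raw (unfiltered) AS total by the filtered SF proportions.

    Conserves ``raw.total_as_bp`` exactly while adopting the cleaner class
    composition of the filtered sample; the unclassed fraction is likewise
    taken from the filtered sample.
    """
    if filtered.total_as_bp <= 0:
        raise ValueError("filtered summary has zero alpha-satellite content")
    out = SFSummary(
        total_bp=raw.total_bp,
        n_monomers=raw.n_monomers,
        total_as_bp=raw.total_as_bp,
        unclassed_fraction=filtered.unclassed_fraction,
        mean_monomer_length=raw.mean_monomer_length,
    )
    props = filtered.sf_proportions()
    remaining = raw.total_as_bp
    sfs = [sf for sf in SF_ORDER if sf in props]
    for sf in sfs[:-1]:
        bp = int(round(raw.total_as_bp * props[sf]))
        out.per_sf_bp[sf] = bp
        remaining -= bp
    out.per_sf_bp[sfs[-1]] = remaining  # absorb rounding; total conserved
    return out


@dataclass(frozen=True)
class ReadSetSummary:
    """WGS read-set statistics normalized to a haploid genome."""

    n_reads: int
    n_monomers: int
    mean_monomer_length: float
    total_read_bp: int
    genome_size: float = 3e9

    @property
    def mb_per_genome(self) -> float:
        """Mb of alpha satellite per haploid genome equivalent."""
        if self.total_read_bp == 0:
            return 0.0
        return (
            self.n_monomers
            * self.mean_monomer_length
            * (self.genome_size / self.total_read_bp)
            / 1e6
        )


def read_set_summary(
    records: list[AnnotationRecord],
    n_reads: int,
    total_read_bp: int,
    genome_size: float = 3e9,
) -> ReadSetSummary:
    mean_len = (
        sum(r.length for r in records) / len(records) if records else 0.0
    )
    return ReadSetSummary(n_reads, len(records), mean_len, total_read_bp, genome_size)


def end_trim(read: str, qualities: list[int] | None = None, n_bases: int = 0,
             min_quality: int = 20) -> str:
    """Remove ``n_bases`` from each read end (simple bad-end trimming).

    With ``qualities`` given, additionally extends the trim inward past
    any bases below ``min_quality``.  Returns the empty string when the
    trim exhausts the read.
    """
    if n_bases < 0:
        raise ValueError("n_bases must be >= 0")
    lo, hi = n_bases, len(read) - n_bases
    if qualities is not None:
        while lo < hi and qualities[lo] < min_quality:
            lo += 1
        while hi > lo and qualities[hi - 1] < min_quality:
            hi -= 1
    return read[lo:hi] if hi > lo else ""


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def region_stats(
    records: list[AnnotationRecord],
    regions: list[tuple[str, int, int]],
    mask: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-region composition table (Table-style R2% / B-box% / SF% columns).

    A record belongs to a region when it overlaps it; percentages are
    monomer-count fractions.  ``corrected_size_bp`` subtracts the masked
    bp (e.g. LINE insertions and gaps) from the region length.
    """
    mask = mask or []
    rows = []
    for seq_id, r0, r1 in regions:
        masked = sum(
            _overlap(r0, r1, m0, m1) for mid, m0, m1 in mask if mid == seq_id
        )
        recs = [
            r for r in records
            if r.seq_id == seq_id and _overlap(r.start, r.end, r0, r1) > 0
        ]
        n = len(recs)
        classes = {c: sum(1 for r in recs if r.label == c) for c in ALL_LABELS}
        sfs = {
            sf: sum(1 for r in recs if sf_of(r.label) == sf) for sf in SF_ORDER
        }
        rows.append(
            {
                "seq_id": seq_id,
                "start": r0,
                "end": r1,
                "corrected_size_bp": (r1 - r0) - masked,
                "n_monomers": n,
                "r2_pct": 100.0 * classes["R2"] / n if n else 0.0,
                "bbox_pct": (
                    100.0 * sum(1 for r in recs if r.box == "B") / n if n else 0.0
                ),
                **{
                    f"{sf.lower().replace('+', 'plus')}_pct":
                        100.0 * sfs[sf] / n if n else 0.0
                    for sf in ("SF1", "SF2", "SF3", "SF5", "SF4+")
                },
            }
        )
    return pd.DataFrame(rows)
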