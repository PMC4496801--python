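"""Monomer extraction by repeated local alignment to the ASC consensus.

A confirmed alpha-satellite segment is decomposed into consecutive ~171 bp
monomers: the best local Smith-Waterman-Gotoh alignment of the segment to
the ASC consensus is recorded as a monomer, the aligned span is removed
from further consideration, and the process repeats on the remaining
stretches.  Extraction stops when the best remaining alignment has a
relative score rs <= 0.29, where

    rs = score / (match_reward * alignment_length)

and alignment length counts all columns (matches + mismatches + gapped
bases), or when the raw score falls to the level reachable by chance
(``min_score``), which is what terminates the loop on non-satellite
sequence where short spurious alignments can still carry a high rs.

Adjacent monomers are typically separated by small (<= 5 bp) unassigned
gaps left by imprecise alignment of monomer ends; these bases belong to no
monomer.  Incomplete monomers (< 140 bp) are flagged and later rendered in
lowercase in the annotation track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import encode, swg_core
from .config import ScoringParams
from .consensus_model import AscConsensus, BOX_START, BOX_END


@dataclass
class Alignment:
    """One local alignment of a (sub)sequence against ASC."""

    score: int
    seq_start: int
    seq_end: int
    asc_start: int       # 0-based half-open on ASC
    asc_end: int
    n_match: int
    n_mismatch: int
    n_gap_open: int
    n_gap_bases: int
    seq_cols: np.ndarray  # aligned (non-gap) columns, sequence side
    asc_cols: np.ndarray  # same columns, ASC side
    match_reward: int = 1

    @property
    def ncols(self) -> int:
        return self.n_match + self.n_mismatch + self.n_gap_bases

    @property
    def rs(self) -> float:
        if self.ncols == 0:
            return 0.0
        return self.score / (self.match_reward * self.ncols)


@dataclass
class Monomer:
    """One extracted alpha-satellite monomer (segment-frame coordinates)."""

    start: int
    end: int
    asc_start: int
    asc_end: int
    rs: float
    score: int
    seq_cols: np.ndarray = field(repr=False)
    asc_cols: np.ndarray = field(repr=False)
    strand: str = "+"
    seq_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_complete(self) -> bool:
        return self.length >= 140

    @property
    def box_present(self) -> bool:
        """True if the alignment spans the full A/B box (ASC 35-51, 1-based)."""
        return self.asc_start <= BOX_START - 1 and self.asc_end >= BOX_END


def swg_align(
    seq: str | np.ndarray,
    asc: AscConsensus | str | np.ndarray,
    params: ScoringParams | None = None,
) -> Alignment:
    """Best local alignment of ``seq`` against the ASC consensus."""
    params = params or ScoringParams()
    a = encode(seq) if isinstance(seq, str) else seq
    if isinstance(asc, AscConsensus):
        b = encode(asc.sequence)
    elif isinstance(asc, str):
        b = encode(asc)
    else:
        b = asc
    (
        score,
        s0,
        s1,
        a0,
        a1,
        nm,
        nx,
        ngo,
        ngb,
        seq_cols,
        asc_cols,
    ) = swg_core(a, b, params.match, params.mismatch, params.gap_open, params.gap_extend)
    return Alignment(
        score, s0, s1, a0, a1, nm, nx, ngo, ngb, seq_cols, asc_cols, params.match
    )


def asc_register(monomer: Monomer) -> int:
    """1-based ASC coordinate aligned to the monomer's first base.

    The register anchors the monomer in the traditional coordinate frame
    (position 1 = first base of the BamHI site) so the A/B box columns can
    be read through the alignment; :attr:`Monomer.box_present` is False
    when the register places the monomer past the box region.
    """
    return monomer.asc_start + 1


def decompose(
    seq: str,
    asc: AscConsensus | str,
    params: ScoringParams | None = None,
    rs_stop: float = 0.29,
    min_score: int = 25,
    offset: int = 0,
    strand: str = "+",
    seq_id: str = "",
) -> list[Monomer]:
    """Greedy repeated-alignment decomposition of a segment into monomers.

    Alignments are extracted best-score-first (ties to the leftmost start);
    each extraction splits its free interval, and remaining intervals are
    re-aligned independently so monomers can never overlap.  ``offset``
    shifts reported coordinates into a parent frame.
    """
    params = params or ScoringParams()
    a_full = encode(seq)
    b = encode(asc.sequence if isinstance(asc, AscConsensus) else asc)
    intervals: list[tuple[int, int]] = [(0, len(seq))] if len(seq) > 0 else []
    cache: dict[tuple[int, int], Alignment] = {}
    monomers: list[Monomer] = []
    while intervals:
        best_key = None
        best_iv = None
        for iv in intervals:
            if iv not in cache:
                cache[iv] = swg_align(a_full[iv[0] : iv[1]], b, params)
            aln = cache[iv]
            if aln.score <= 0:
                continue
            key = (aln.score, -(iv[0] + aln.seq_start))
            if best_key is None or key > best_key:
                best_key = key
                best_iv = iv
        if best_iv is None:
            break
        aln = cache[best_iv]
        if aln.score < min_score or aln.rs <= rs_stop:
            break
        s0 = best_iv[0]
        monomers.append(
            Monomer(
                start=offset + s0 + aln.seq_start,
                end=offset + s0 + aln.seq_end,
                asc_start=aln.asc_start,
                asc_end=aln.asc_end,
                rs=aln.rs,
                score=aln.score,
                seq_cols=aln.seq_cols + offset + s0,
                asc_cols=aln.asc_cols,
                strand=strand,
                seq_id=seq_id,
            )
        )
        intervals.remove(best_iv)
        del cache[best_iv]
        for piece in (
            (s0, s0 + aln.seq_start),
            (s0 + aln.seq_end, best_iv[1]),
        ):
            # a piece shorter than min_score bases can never reach min_score
            if piece[1] - piece[0] >= min_score:
                intervals.append(piece)
    monomers.sort(key=lambda m: m.start)
    return monomers
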