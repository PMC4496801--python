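"""Dot-matrix higher-order repeat (HOR) evaluation.

A region is compared against itself: for every off-diagonal offset d the
number of exact word matches between the sequence and its own copy shifted
by d is counted.  Tandem HORs with period P produce strong diagonals at
offsets P, 2P, 3P, ...; divergent monomeric arrays show only the weak
~171 bp monomeric self-similarity.  A HOR is called at the smallest
offset above 1.5 monomer lengths whose diagonal coverage clears the
threshold, provided its multiple also peaks and at least three repeat
units fit in the region (two high-identity copies are reported as a
duplication, not a HOR).  Inter-unit identity comes from global alignment
of adjacent period-length units.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np


@dataclass
class DotProfile:
    """Word-match counts of a sequence against itself, per offset."""

    seq_len: int
    word: int
    counts: np.ndarray    # counts[d] = word matches at offset d (d >= 1)

    def coverage(self) -> np.ndarray:
        """Fraction of available diagonal cells matched, per offset."""
        n_words = self.seq_len - self.word + 1
        avail = np.maximum(n_words - np.arange(len(self.counts)), 1)
        return self.counts / avail


@dataclass(frozen=True)
class HORCall:
    region: str
    has_hor: bool
    period_bp: int | None
    identity_pct: float | None
    note: str = ""

    def __str__(self) -> str:
        if self.has_hor:
            return (
                f"{self.region}: HOR {self.period_bp/1000:.1f} kb, "
                f"identity {self.identity_pct:.1f}%"
            )
        return f"{self.region}: No HOR" + (f", {self.note}" if self.note else "")


def self_dotmatrix(seq: str, word: int = 11, max_word_hits: int = 2000) -> DotProfile:
    """Per-offset exact word-match counts of ``seq`` against itself.

    Only the upper triangle (offset >= 1) is counted.  ``max_word_hits``
    caps the occurrence list per word to bound the cost on extremely
    repetitive input; the cap is far above anything a caller at the
    intended region sizes (1 kb - ~150 kb) will hit.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * word:
        return DotProfile(n, word, np.zeros(1, dtype=np.int64))
    positions: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        w = seq[i : i + word]
        if "N" in w:
            continue
        lst = positions.setdefault(w, [])
        if len(lst) < max_word_hits:
            lst.append(i)
    counts = np.zeros(n, dtype=np.int64)
    for lst in positions.values():
        if len(lst) < 2:
            continue
        arr = np.asarray(lst)
        diffs = (arr[None, :] - arr[:, None]).ravel()
        diffs = diffs[diffs > 0]
        counts += np.bincount(diffs, minlength=n)[:n]
    return DotProfile(n, word, counts)


def unit_identity(seq: str, period: int) -> float:
    """Mean percent identity of adjacent period-length units (global)."""
    units = [
        seq[i * period : (i + 1) * period]
        for i in range(len(seq) // period)
    ]
    if len(units) < 2:
        raise ValueError("need at least 2 full periods for unit identity")
    idents = []
    for u, v in zip(units, units[1:]):
        res = edlib.align(u, v, task="path")
        cols = sum(
            int(num)
            for num, op in _cigar_ops(res["cigar"])
        )
        idents.append(100.0 * (1.0 - res["editDistance"] / cols))
    return float(np.mean(idents))


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def call_hor(
    profile: DotProfile,
    seq: str,
    monomer_len: int = 171,
    coverage_threshold: float = 0.30,
    min_units: int = 3,
    region: str = "",
) -> HORCall:
    """Call a HOR (or duplication, or nothing) from a self dot matrix.

    The candidate period is the smallest offset above 1.5 monomer lengths
    with diagonal coverage >= threshold whose double is also elevated
    (when in range); the local coverage maximum around it is reported.
    """
    cov = profile.coverage()
    n = profile.seq_len
    min_period = int(1.5 * monomer_len)
    max_period = (n - profile.word) // 2  # need at least 2 units to see a diagonal
    candidates = [
        d
        for d in range(min_period, max_period + 1)
        if cov[d] >= coverage_threshold
    ]
    for d in candidates:
        # refine to the local coverage peak
        lo, hi = max(1, d - profile.word), min(len(cov) - 1, d + profile.word)
        period = int(lo + np.argmax(cov[lo : hi + 1]))
        # the second multiple must also be elevated when it fits
        d2 = 2 * period
        if d2 <= max_period:
            w = profile.word
            near = cov[max(1, d2 - w) : min(len(cov), d2 + w + 1)]
            if near.max() < 0.5 * coverage_threshold:
                continue
        n_units = n // period
        identity = unit_identity(seq, period)
        if n_units >= min_units:
            return HORCall(region, True, period, identity)
        return HORCall(
            region,
            False,
            None,
            None,
            note=f"duplication {period} bp, identity {identity:.1f}%",
        )
    return HORCall(region, False, None, None)


def scan_region(
    seq: str,
    word: int = 11,
    monomer_len: int = 171,
    coverage_threshold: float = 0.30,
    min_units: int = 3,
    region: str = "",
) -> HORCall:
    """Convenience wrapper: dot matrix + HOR call for one region."""
    if len(seq) < 1000:
        raise ValueError("HOR evaluation needs at least 1 kb of sequence")
    profile = self_dotmatrix(seq, word)
    return call_hor(profile, seq, monomer_len, coverage_threshold, min_units, region)
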