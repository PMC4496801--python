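"""Numba kernel for Smith-Waterman-Gotoh local alignment with traceback.

The scoring follows the additive scheme used throughout the package:
matches earn ``match``; mismatches, gap openings and gapped bases pay
``mismatch``, ``gap_open`` and ``gap_extend`` respectively (a gap of
length g costs gap_open + g*gap_extend in total).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (never matches)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def swg_core(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Full Gotoh DP + traceback.

    Returns (score, seq_start, seq_end, asc_start, asc_end, n_match,
    n_mismatch, n_gap_open, n_gap_bases, seq_cols, asc_cols) where the
    coordinate pairs are 0-based half-open and seq_cols/asc_cols list the
    aligned (non-gap) columns in left-to-right order.
    """
    n, m = a.shape[0], b.shape[0]
    NEG = np.int32(-(10 ** 9))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    go = np.int32(gap_open + gap_extend)  # cost of a gap's first base
    ge = np.int32(gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else -mismatch
            mx = H[i - 1, j - 1]
            p = np.uint8(1)
            if E[i - 1, j - 1] > mx:
                mx = E[i - 1, j - 1]
                p = np.uint8(2)
            if F[i - 1, j - 1] > mx:
                mx = F[i - 1, j - 1]
                p = np.uint8(3)
            v = mx + s
            if v > 0:
                H[i, j] = v
                ptrH[i, j] = p
                if v > best:
                    best = v
                    bi = i
                    bj = j
            # E: gap in the query a, consuming b[j-1]
            eo = H[i, j - 1] - go
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
            else:
                E[i, j] = ee
                ptrE[i, j] = np.uint8(1)
            # F: gap in the reference b, consuming a[i-1]
            fo = H[i - 1, j] - go
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
            else:
                F[i, j] = fe
                ptrF[i, j] = np.uint8(1)

    cap = n + m + 2
    seq_cols = np.empty(cap, dtype=np.int64)
    asc_cols = np.empty(cap, dtype=np.int64)
    k = 0
    n_match = 0
    n_mismatch = 0
    n_gap_open = 0
    n_gap_bases = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            seq_cols[k] = i - 1
            asc_cols[k] = j - 1
            k += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                n_match += 1
            else:
                n_mismatch += 1
            i -= 1
            j -= 1
            state = 0 if p == 1 else (1 if p == 2 else 2)
        elif state == 1:
            n_gap_bases += 1
            if ptrE[i, j] == 0:
                n_gap_open += 1
                state = 0
            j -= 1
        else:
            n_gap_bases += 1
            if ptrF[i, j] == 0:
                n_gap_open += 1
                state = 0
            i -= 1
    return (
        int(best),
        i,
        bi,
        j,
        bj,
        n_match,
        n_mismatch,
        n_gap_open,
        n_gap_bases,
        seq_cols[:k][::-1].copy(),
        asc_cols[:k][::-1].copy(),
    )
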