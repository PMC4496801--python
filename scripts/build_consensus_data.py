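"""Regenerate the bundled synthetic consensus-model data set.

The classifier needs a ~171 bp alpha-satellite consensus (ASC) plus one
position count matrix per monomer class.  The original per-class matrices
are not redistributable, so the package ships a *synthetic* stand-in set
built by this script: a fixed base consensus, class consensuses derived
from it by class-specific substitutions, and an A/B box region (positions
35-51, 1-based) set per ancestral type.  The set is valid input for every
algorithm in the package (which must work for any well-formed matrix set);
accuracy tests are calibrated against this bundled set.

Run from the repository root:

    python scripts/build_consensus_data.py

Output is written to src/alphaclass/data/ and is deterministic.
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parent.parent / "src" / "alphaclass" / "data"

ALPHABET = "ACGT"
L = 171  # monomer length
BOX_START, BOX_END = 35, 51  # 1-based inclusive
# 17 bp box consensuses. The B box carries a CENP-B-box-like motif; the A box
# is the ancestral (non-CENP-B-binding) configuration, differing at 7 sites.
B_BOX = "TTCGTTGGAAACGGGAA"
A_BOX = "TTCGTTTCAAACACTCT"

# class -> (ancestral type, suprachromosomal family)
CLASSES = {
    "J1": ("A", "SF1"),
    "J2": ("B", "SF1"),
    "D1": ("B", "SF2"),
    "D2": ("A", "SF2"),
    "W1": ("B", "SF3"),
    "W2": ("B", "SF3"),
    "W3": ("B", "SF3"),
    "W4": ("A", "SF3"),
    "W5": ("A", "SF3"),
    "R1": ("B", "SF5"),
    "R2": ("A", "SF5"),
    "M1": ("A", "SF4+"),
}

N_SUBS = 20          # class-specific substitutions outside the box
TOTAL_COUNT = 100    # column total in every count matrix
MAJOR = 88           # count of the consensus base (others get 4)
N_SOFT = 15          # positions per class with a softer 64/20/8/8 column


def base_consensus(rng: np.random.Generator) -> str:
    """AT-rich random 171-mer used as the common ancestor of all classes."""
    probs = [0.30, 0.20, 0.20, 0.30]  # A C G T
    return "".join(rng.choice(list(ALPHABET), size=L, p=probs))


def with_box(seq: str, box: str) -> str:
    return seq[: BOX_START - 1] + box + seq[BOX_END:]


def mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in ALPHABET if b != s[p]])
    return "".join(s)


def count_matrix(consensus: str, rng: np.random.Generator) -> np.ndarray:
    mat = np.full((L, 4), (TOTAL_COUNT - MAJOR) // 3, dtype=int)
    for i, b in enumerate(consensus):
        mat[i, ALPHABET.index(b)] = MAJOR
    soft = rng.choice(L, size=N_SOFT, replace=False)
    for i in soft:
        major = ALPHABET.index(consensus[i])
        second = rng.choice([k for k in range(4) if k != major])
        col = np.full(4, 8)
        col[major], col[second] = 64, 20
        mat[i] = col
    assert (mat.sum(axis=1) == TOTAL_COUNT).all()
    return mat


def main() -> None:
    rng = np.random.default_rng(4141)
    base = base_consensus(rng)
    asc = with_box(base, A_BOX)

    non_box = np.array(
        [i for i in range(L) if not (BOX_START - 1 <= i < BOX_END)]
    )
    consensi: dict[str, str] = {}
    for label, (ab, _sf) in CLASSES.items():
        while True:
            pos = rng.choice(non_box, size=N_SUBS, replace=False)
            cons = mutate(with_box(base, A_BOX if ab == "A" else B_BOX), pos, rng)
            # keep classes well separated (>= 18 mismatches pairwise)
            if all(
                sum(a != b for a, b in zip(cons, other)) >= 18
                for other in consensi.values()
            ):
                break
        consensi[label] = cons

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "classes").mkdir(exist_ok=True)

    with open(OUT / "asc.synthetic.fa", "w") as fh:
        fh.write(">ASC synthetic alpha-satellite consensus, A-box at 35-51\n")
        fh.write(asc + "\n")

    for label, (ab, _sf) in CLASSES.items():
        mat = count_matrix(consensi[label], rng)
        with open(OUT / "classes" / f"{label}.synthetic_counts.txt", "w") as fh:
            fh.write(f">{label} {ab} {L}\n")
            for i in range(L):
                fh.write(f"{i + 1} " + " ".join(str(c) for c in mat[i]) + "\n")

    with open(OUT / "README.txt", "w") as fh:
        fh.write(
            "Synthetic consensus-model data set (stand-in; see docs/methods.md).\n"
            "Generated by scripts/build_consensus_data.py; do not edit by hand.\n"
            "Format of classes/*.synthetic_counts.txt: header '>LABEL TYPE LENGTH',\n"
            "then one line per position: pos countA countC countG countT.\n"
        )
    print(f"wrote {len(CLASSES)} class matrices + ASC to {OUT}")


if __name__ == "__main__":
    main()
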