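"""Consensus models: the ASC test sequence, per-class matrices, box models.

Alpha satellite monomers fall into 12 standard classes (J1, J2, D1, D2,
W1-W5, R1, R2, M1) which map onto five suprachromosomal families and two
ancestral types distinguished by the A/B box region at monomer positions
35-51 (1-based; the B configuration is the CENP-B binding motif).  Each
class is modelled as a position count matrix over {A,C,G,T}; a uniform
"random" model serves as the null hypothesis.  Position 1 of the monomer
follows the convention that anchors it to the first base of the BamHI site
in the DXZ1 higher-order repeat.

The bundled data set under ``alphaclass/data`` is a synthetic stand-in
(see ``data/README.txt``); every algorithm in the package works for any
well-formed matrix set loaded through :func:`load_models`.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

BOX_START = 35  # 1-based, inclusive
BOX_END = 51
BOX_LEN = BOX_END - BOX_START + 1

#: class label -> (ancestral A/B type, suprachromosomal family)
CLASS_TABLE: dict[str, tuple[str, str]] = {
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

#: the two residual labels for unclassed and random monomers
EXTRA_LABELS = ("Um", "Xm")
ALL_LABELS = tuple(CLASS_TABLE) + EXTRA_LABELS

A_TYPE_CLASSES = tuple(c for c, (t, _) in CLASS_TABLE.items() if t == "A")
B_TYPE_CLASSES = tuple(c for c, (t, _) in CLASS_TABLE.items() if t == "B")

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


class ModelLoadError(Exception):
    """A model data file is missing or ill-formed."""


@dataclass(frozen=True)
class AscConsensus:
    """The alpha-satellite consensus test sequence used for monomerization."""

    sequence: str
    origin_note: str = "position 1 = first base of the BamHI site (DXZ1 convention)"

    def __post_init__(self) -> None:
        if not (165 <= len(self.sequence) <= 175):
            raise ModelLoadError(
                f"ASC length {len(self.sequence)} outside [165, 175]"
            )
        if set(self.sequence) - set(ALPHABET):
            raise ModelLoadError("ASC contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClassModel:
    """Position count/probability matrix for one monomer class."""

    label: str
    ab_type: str                      # "A", "B", or "" for the random model
    counts: np.ndarray                # (L, 4) int
    probs: np.ndarray = field(init=False)      # Laplace-smoothed, rows sum to 1
    log_probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ModelLoadError(f"{self.label}: negative count in matrix")
        smoothed = self.counts.astype(float) + 1.0  # Laplace pseudocount
        self.probs = smoothed / smoothed.sum(axis=1, keepdims=True)
        self.log_probs = np.log(self.probs)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def sf(self) -> str:
        return CLASS_TABLE[self.label][1] if self.label in CLASS_TABLE else "none"

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass
class BoxModel:
    """A/B box matrices over monomer positions 35-51 (17 columns).

    Each matrix is the position-wise renormalized sum of the count matrices
    of all class models of the corresponding ancestral type, restricted to
    the box columns.  The random row is uniform.
    """

    a_counts: np.ndarray  # (17, 4)
    b_counts: np.ndarray

    def __post_init__(self) -> None:
        for name, c in (("A", self.a_counts), ("B", self.b_counts)):
            if c.shape != (BOX_LEN, 4):
                raise ModelLoadError(f"box matrix {name} must be {BOX_LEN}x4")
        self.a_probs = self._norm(self.a_counts)
        self.b_probs = self._norm(self.b_counts)
        self.a_log = np.log(self.a_probs)
        self.b_log = np.log(self.b_probs)

    @staticmethod
    def _norm(c: np.ndarray) -> np.ndarray:
        s = c.astype(float) + 1.0
        return s / s.sum(axis=1, keepdims=True)


def random_model(length: int) -> ClassModel:
    """Uniform null model: probability 0.25 for every base at every position."""
    # counts chosen so the Laplace-smoothed probabilities are exactly 0.25
    return ClassModel("Xm", "", np.full((length, 4), 24, dtype=int))


def parse_class_file(path: str) -> ClassModel:
    try:
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith(">"):
                raise ModelLoadError(f"{path}: missing '>' header")
            parts = header[1:].split()
            if len(parts) != 3:
                raise ModelLoadError(f"{path}: header must be '>LABEL TYPE LENGTH'")
            label, ab_type, length_s = parts
            length = int(length_s)
            rows = []
            for line in fh:
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 5:
                    raise ModelLoadError(f"{path}: bad row {line!r}")
                rows.append([int(x) for x in fields[1:]])
    except OSError as exc:
        raise ModelLoadError(f"{path}: {exc}") from exc
    counts = np.array(rows, dtype=int)
    if counts.shape[0] != length:
        raise ModelLoadError(
            f"{path}: header says {length} positions, file has {counts.shape[0]}"
        )
    totals = counts.sum(axis=1)
    if len(set(totals.tolist())) != 1:
        raise ModelLoadError(f"{path}: rows do not sum to a common column total")
    try:
        return ClassModel(label, ab_type, counts)
    except ModelLoadError as exc:
        raise ModelLoadError(f"{path}: {exc}") from exc


def derive_box_models(models: list[ClassModel]) -> BoxModel:
    """Sum count matrices of all A-type (B-type) classes over the box columns."""
    a_sum = np.zeros((BOX_LEN, 4), dtype=int)
    b_sum = np.zeros((BOX_LEN, 4), dtype=int)
    seen = {"A": False, "B": False}
    for m in models:
        if m.ab_type not in ("A", "B"):
            raise ModelLoadError(f"class {m.label} lacks an A/B type")
        block = m.counts[BOX_START - 1 : BOX_END]
        if block.shape[0] != BOX_LEN:
            raise ModelLoadError(f"class {m.label} shorter than the box region")
        if m.ab_type == "A":
            a_sum += block
        else:
            b_sum += block
        seen[m.ab_type] = True
    if not (seen["A"] and seen["B"]):
        raise ModelLoadError("need at least one class of each ancestral type")
    return BoxModel(a_sum, b_sum)


def load_asc(data_dir: str | None = None) -> AscConsensus:
    data_dir = data_dir or _DATA_DIR
    matches = glob.glob(os.path.join(data_dir, "asc*.fa"))
    if not matches:
        raise ModelLoadError(f"no ASC fasta found in {data_dir}")
    with open(matches[0]) as fh:
        lines = [ln.strip() for ln in fh if not ln.startswith(">")]
    return AscConsensus("".join(lines).upper())


def load_models(
    data_dir: str | None = None,
) -> tuple[AscConsensus, list[ClassModel], BoxModel]:
    """Load the ASC consensus, the 12 class models and the derived box model.

    The returned class list ends with the uniform random model (label
    ``Xm``), giving the 13 hypotheses of the Bayesian classifier.
    """
    data_dir = data_dir or _DATA_DIR
    asc = load_asc(data_dir)
    class_dir = os.path.join(data_dir, "classes")
    files = sorted(glob.glob(os.path.join(class_dir, "*.txt")))
    models = [parse_class_file(p) for p in files]
    labels = {m.label for m in models}
    missing = set(CLASS_TABLE) - labels
    if missing:
        raise ModelLoadError(f"missing class matrices: {sorted(missing)}")
    # canonical class order, then the random model
    order = {c: i for i, c in enumerate(CLASS_TABLE)}
    models.sort(key=lambda m: order[m.label])
    box = derive_box_models(models)
    models.append(random_model(len(asc)))
    return asc, models, box
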