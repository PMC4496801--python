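"""Bayesian classification of monomers and of the A/B box region.

Each extracted monomer is scored under 13 hypotheses: the 12 class
position-probability matrices and a uniform random model, with a uniform
prior.  The likelihood is the product of per-position probabilities read
along the ASC-registered alignment columns; alignment gap columns are
skipped as uninformative.  The winning hypothesis is assigned when its
posterior reaches the threshold (default 0.9); otherwise the monomer is
unclassed (Um), or random (Xm) when the random model itself wins at
threshold.  Monomers aligning to fewer than ``min_model_cols`` model
positions are Um by construction.

The A/B box (monomer positions 35-51) is typed independently with the
summed A-type and B-type matrices: A, B, X (random), U (unclassed), or Q
when the truncated monomer does not contain the box region at all.  Box
and monomer calls may legitimately disagree (hybrid monomers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import encode
from .consensus_model import (
    BOX_END,
    BOX_START,
    CLASS_TABLE,
    BoxModel,
    ClassModel,
)
from .monomerizer import Monomer


@dataclass(frozen=True)
class ClassCall:
    label: str          # one of the 12 classes, "Um" or "Xm"
    posterior: float    # posterior of the winning hypothesis
    sf: str
    n_cols: int         # informative model columns used
    flag: str = ""      # diagnostic, e.g. "too_few_columns"


@dataclass(frozen=True)
class BoxCall:
    box: str            # "A", "B", "X", "U" or "Q"
    posterior: float


def sf_of(label: str) -> str:
    """Suprachromosomal family of a monomer class; Um/Xm map to 'none'."""
    if label in CLASS_TABLE:
        return CLASS_TABLE[label][1]
    if label in ("Um", "Xm"):
        return "none"
    raise ValueError(f"unknown monomer class {label!r}")


class BayesClassifier:
    """Vectorized classifier over a fixed model set.

    Models whose native length differs from the ASC length contribute
    uniform (uninformative) probabilities at the missing positions, which
    keeps likelihoods comparable across hypotheses.
    """

    def __init__(
        self,
        models: list[ClassModel],
        box: BoxModel,
        asc_len: int = 171,
        threshold: float = 0.9,
        min_model_cols: int = 30,
    ):
        self.labels = [m.label for m in models]
        self.threshold = threshold
        self.min_model_cols = min_model_cols
        self.asc_len = asc_len
        stack = np.full((len(models), asc_len, 4), np.log(0.25))
        for k, m in enumerate(models):
            L = min(m.length, asc_len)
            stack[k, :L, :] = m.log_probs[:L, :]
        self.log_stack = stack
        self.box_log = np.stack(
            [box.a_log, box.b_log, np.full((BOX_END - BOX_START + 1, 4), np.log(0.25))]
        )

    @staticmethod
    def _posterior(logliks: np.ndarray) -> np.ndarray:
        z = logliks - logliks.max()
        w = np.exp(z)
        return w / w.sum()

    def _columns(self, monomer: Monomer, seq_codes: np.ndarray):
        bases = seq_codes[monomer.seq_cols]
        ok = (bases < 4) & (monomer.asc_cols < self.asc_len)
        return monomer.asc_cols[ok], bases[ok]

    def classify_monomer(self, monomer: Monomer, seq: str | np.ndarray) -> ClassCall:
        codes = encode(seq) if isinstance(seq, str) else seq
        asc_cols, bases = self._columns(monomer, codes)
        n = len(asc_cols)
        if n < self.min_model_cols:
            return ClassCall("Um", 0.0, "none", n, flag="too_few_columns")
        logliks = self.log_stack[:, asc_cols, bases].sum(axis=1)
        post = self._posterior(logliks)
        k = int(post.argmax())
        label, p = self.labels[k], float(post[k])
        if p < self.threshold:
            return ClassCall("Um", p, "none", n)
        if label == "Xm":
            return ClassCall("Xm", p, "none", n)
        return ClassCall(label, p, sf_of(label), n)

    def classify_box(self, monomer: Monomer, seq: str | np.ndarray) -> BoxCall:
        if not monomer.box_present:
            return BoxCall("Q", 0.0)
        codes = encode(seq) if isinstance(seq, str) else seq
        asc_cols, bases = self._columns(monomer, codes)
        inside = (asc_cols >= BOX_START - 1) & (asc_cols <= BOX_END - 1)
        rows = asc_cols[inside] - (BOX_START - 1)
        b = bases[inside]
        logliks = self.box_log[:, rows, b].sum(axis=1)
        post = self._posterior(logliks)
        k = int(post.argmax())
        p = float(post[k])
        if p < self.threshold:
            return BoxCall("U", p)
        return BoxCall(("A", "B", "X")[k], p)


def classify_monomer(
    m: Monomer,
    seq: str,
    models: list[ClassModel],
    box: BoxModel,
    threshold: float = 0.9,
    min_model_cols: int = 30,
    asc_len: int = 171,
) -> ClassCall:
    """One-shot convenience wrapper around :class:`BayesClassifier`."""
    clf = BayesClassifier(models, box, asc_len, threshold, min_model_cols)
    return clf.classify_monomer(m, seq)


def classify_box(
    m: Monomer,
    seq: str,
    models: list[ClassModel],
    box: BoxModel,
    threshold: float = 0.9,
    asc_len: int = 171,
) -> BoxCall:
    clf = BayesClassifier(models, box, asc_len, threshold)
    return clf.classify_box(m, seq)
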