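"""Windowed whole-sequence annotation and BED track assembly.

Long sequences are processed in consecutive 5 kb windows overlapping by
about 200 bp; each window that clears both detection phases is decomposed
into monomers on the better-matching strand, every monomer is classified
(class + independent A/B box call), and window-local coordinates are
lifted to sequence coordinates.  Duplicate monomers from the window
overlaps are resolved by the rule used for the published track: of two
overlapping monomers the longer remains intact and the shorter is trimmed
to its non-overlapping remainder (dropped when fully contained; on equal
lengths the earlier record stays intact).

Records render as BED9 rows: the name is ``<CLASS>/<boxcode>`` with the
class in lowercase for incomplete (< 140 bp) monomers, the score is
round(1000 * posterior), and the color encodes the monomeric type hued by
suprachromosomal family (SF1 reds, SF2 blues, SF3 greens, SF5 oranges,
SF4+ purple, Um/Xm grays).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, replace

from .classifier import BayesClassifier
from .config import AlphaConfig
from .consensus_model import AscConsensus, BoxModel, ClassModel, load_models
from .detector import Phase1Screen, detect, revcomp
from .monomerizer import decompose

logger = logging.getLogger("alphaclass")

#: itemRgb per monomeric type
CLASS_COLORS: dict[str, str] = {
    "J1": "178,34,34",
    "J2": "255,99,71",
    "D1": "0,0,180",
    "D2": "30,144,255",
    "W1": "0,100,0",
    "W2": "34,139,34",
    "W3": "60,179,113",
    "W4": "0,160,120",
    "W5": "152,205,100",
    "R1": "255,140,0",
    "R2": "255,190,40",
    "M1": "148,0,211",
    "Um": "128,128,128",
    "Xm": "190,190,190",
}


@dataclass
class AnnotationRecord:
    """One BED-ready monomer row."""

    seq_id: str
    start: int
    end: int
    label: str       # class label in canonical case (J1 .. M1, Um, Xm)
    box: str         # A, B, X, U or Q
    strand: str
    posterior: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        cased = self.label if self.length >= 140 else self.label.lower()
        return f"{cased}/{self.box}"

    @property
    def score(self) -> int:
        return int(round(1000 * self.posterior))

    @property
    def color(self) -> str:
        return CLASS_COLORS[self.label]


def make_windows(
    seq_len: int, size: int = 5000, overlap: int = 200
) -> list[tuple[int, int]]:
    """Tile [0, seq_len) with windows of ``size`` overlapping by ``overlap``."""
    if size <= overlap or overlap < 0:
        raise ValueError("need size > overlap >= 0")
    if seq_len <= 0:
        return []
    windows = []
    start = 0
    while True:
        end = min(start + size, seq_len)
        windows.append((start, end))
        if end >= seq_len:
            break
        start += size - overlap
    return windows


def dedup_overlaps(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Resolve overlapping records: longer intact, shorter trimmed/dropped."""
    out: list[AnnotationRecord] = []
    for rec in sorted(records, key=lambda r: (r.seq_id, r.start, r.end)):
        rec = replace(rec)
        while out and out[-1].seq_id == rec.seq_id and out[-1].end > rec.start:
            prev = out[-1]
            if rec.length > prev.length:
                # later record is longer: keep it intact, trim the earlier one
                prev.end = rec.start
                if prev.length <= 0:
                    out.pop()
                    continue
                break
            # earlier record intact (also on ties); trim the later one
            rec.start = prev.end
            break
        if rec.length > 0:
            out.append(rec)
    return out


class Annotator:
    """Full pipeline over in-memory sequences; deterministic given config."""

    def __init__(
        self,
        asc: AscConsensus | None = None,
        models: list[ClassModel] | None = None,
        box: BoxModel | None = None,
        config: AlphaConfig | None = None,
    ):
        if asc is None or models is None or box is None:
            asc, models, box = load_models()
        self.asc = asc
        self.config = config or AlphaConfig()
        self.screen = Phase1Screen(asc, self.config)
        self.classifier = BayesClassifier(
            models,
            box,
            asc_len=len(asc),
            threshold=self.config.bayes_threshold,
            min_model_cols=self.config.min_model_cols,
        )

    def annotate_window(
        self, seq_id: str, seq: str, start: int, end: int
    ) -> list[AnnotationRecord]:
        cfg = self.config
        segment = detect(seq_id, seq, start, end, self.screen)
        if segment is None:
            return []
        window = seq[start:end]
        work = window if segment.strand == "+" else revcomp(window)
        monomers = decompose(
            work,
            self.asc,
            cfg.scoring,
            rs_stop=cfg.rs_stop,
            min_score=cfg.min_score,
            strand=segment.strand,
            seq_id=seq_id,
        )
        records = []
        for m in monomers:
            call = self.classifier.classify_monomer(m, work)
            boxcall = self.classifier.classify_box(m, work)
            if segment.strand == "+":
                g0, g1 = start + m.start, start + m.end
            else:
                g0 = start + (len(window) - m.end)
                g1 = start + (len(window) - m.start)
            records.append(
                AnnotationRecord(
                    seq_id, g0, g1, call.label, boxcall.box, segment.strand,
                    call.posterior,
                )
            )
        return records

    def annotate_sequence(self, seq_id: str, seq: str) -> list[AnnotationRecord]:
        cfg = self.config
        records: list[AnnotationRecord] = []
        windows = make_windows(len(seq), cfg.window_size, cfg.window_overlap)
        for i, (start, end) in enumerate(windows):
            records.extend(self.annotate_window(seq_id, seq, start, end))
            if (i + 1) % 50 == 0:
                logger.info("%s: %d/%d windows", seq_id, i + 1, len(windows))
        return dedup_overlaps(records)

    def annotate(self, sequences: dict[str, str]) -> list[AnnotationRecord]:
        records: list[AnnotationRecord] = []
        for seq_id, seq in sequences.items():
            records.extend(self.annotate_sequence(seq_id, str(seq)))
        return records


def annotate_fasta(
    fasta_path: str,
    config: AlphaConfig | None = None,
    data_dir: str | None = None,
) -> list[AnnotationRecord]:
    """Annotate every record of a FASTA file; returns deduplicated records."""
    from Bio import SeqIO

    asc, models, box = load_models(data_dir)
    ann = Annotator(asc, models, box, config)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    return ann.annotate(seqs)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
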