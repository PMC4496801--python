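"""Synthetic alpha-satellite genomes with known per-monomer truth.

The generator emulates the documented organization of the five
suprachromosomal families: SF1 and SF2 arrays with J1J2 / D1D2 dimeric
periodicity, SF3 arrays with W1-W5 pentameric order, SF5 arrays with
irregular R1/R2 alternation (including pure-R2 clusters), monomeric M1
(SF4+) arrays, and mixed new-family/SF5 regions.  Monomers are drawn from
the bundled class consensus matrices at a controlled divergence
(substitutions at the given rate, indels at a tenth of it), optionally
organized into higher-order repeats: a unit of ``hor_period_monomers``
monomers is sampled once and then reiterated with a small inter-copy
divergence (1 - identity).  Arrays are embedded in uniform-random flanks
and the exact coordinates, class, ancestral box type and strand of every
monomer are emitted as a truth track.

Everything is reproducible from the layout seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .consensus_model import CLASS_TABLE, ClassModel, load_models

#: array type -> monomer class layout ("cycle" repeats, "random" draws)
ARRAY_TYPES: dict[str, tuple[str, tuple[str, ...]]] = {
    "dimeric_sf1": ("cycle", ("J1", "J2")),
    "dimeric_sf2": ("cycle", ("D1", "D2")),
    "pentameric_sf3": ("cycle", ("W1", "W2", "W3", "W4", "W5")),
    "monomeric_sf4": ("cycle", ("M1",)),
    "irregular_sf5": ("random", ("R1", "R2")),
    "pure_r2": ("cycle", ("R2",)),
    "mixed_sf1_sf5": ("random", ("J1", "J2", "R1", "R2")),
    "mixed_sf2_sf5": ("random", ("D1", "D2", "R1", "R2")),
}

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class BlockSpec:
    """One tandem array block."""

    array_type: str
    n_monomers: int
    divergence_pct: float = 10.0
    hor_period_monomers: int | None = None
    hor_identity_pct: float = 99.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.array_type not in ARRAY_TYPES:
            raise ValueError(f"unknown array type {self.array_type!r}")
        if not 0 <= self.divergence_pct <= 30:
            raise ValueError("divergence_pct must be within [0, 30]")


@dataclass
class LayoutSpec:
    """Ordered blocks with flanking/spacer random DNA and a seed."""

    blocks: list[BlockSpec]
    flank_len: int = 5000
    spacer_len: int = 2000
    seq_id: str = "synth"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class TruthMonomer:
    start: int
    end: int
    label: str
    box: str     # ancestral type of the generating class
    strand: str


@dataclass
class TruthTrack:
    seq_id: str
    monomers: list[TruthMonomer] = field(default_factory=list)

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for m in self.monomers:
                fh.write(
                    f"{self.seq_id}\t{m.start}\t{m.end}\t{m.label}/{m.box}\t0\t"
                    f"{m.strand}\n"
                )


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length > 0 else ""


def sample_monomer(
    model: ClassModel, divergence_pct: float, rng: np.random.Generator
) -> str:
    """Draw the consensus of ``model`` and degrade it to the target divergence.

    Substitutions occur at divergence_pct/100 per base (to a uniformly
    chosen different base); indels at a tenth of that rate, split evenly
    between single-base deletions and insertions, which keeps lengths near
    the canonical ~171 bp.
    """
    if not 0 <= divergence_pct <= 30:
        raise ValueError("divergence_pct must be within [0, 30]")
    cons = model.consensus()
    p_sub = divergence_pct / 100.0
    p_indel = p_sub / 10.0
    out = []
    for b in cons:
        r = rng.random()
        if r < p_indel / 2:
            continue  # deletion
        if r < p_indel:
            out.append(rng.choice(_BASES))  # insertion before the base
        if rng.random() < p_sub:
            out.append(rng.choice([x for x in "ACGT" if x != b]))
        else:
            out.append(b)
    return "".join(out)


def _mutate_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation (preserves coordinates)."""
    chars = list(seq)
    for i in np.nonzero(rng.random(len(chars)) < rate)[0]:
        chars[i] = rng.choice([x for x in "ACGT" if x != chars[i]])
    return "".join(chars)


def _class_sequence(spec: BlockSpec, n: int, rng: np.random.Generator) -> list[str]:
    mode, classes = ARRAY_TYPES[spec.array_type]
    if mode == "cycle":
        return [classes[i % len(classes)] for i in range(n)]
    return [classes[rng.integers(len(classes))] for i in range(n)]


def build_block(
    spec: BlockSpec,
    models: dict[str, ClassModel],
    rng: np.random.Generator,
) -> tuple[str, list[TruthMonomer]]:
    """Generate one array block (plus-strand frame, then flipped if needed)."""
    labels = _class_sequence(spec, spec.n_monomers, rng)
    pieces: list[str] = []
    truth: list[TruthMonomer] = []
    if spec.hor_period_monomers:
        period = spec.hor_period_monomers
        unit_labels = labels[:period]
        unit = [
            sample_monomer(models[lab], spec.divergence_pct, rng)
            for lab in unit_labels
        ]
        # each copy drifts from the master unit at half the target rate, so
        # *adjacent copies* differ by ~(100 - identity)% as observed on dot plots
        rate = (100.0 - spec.hor_identity_pct) / 100.0 / 2.0
        n_units = -(-spec.n_monomers // period)
        pos = 0
        for _u in range(n_units):
            for lab, mono in zip(unit_labels, unit):
                if len(truth) >= spec.n_monomers:
                    break
                m = _mutate_subs(mono, rate, rng)
                pieces.append(m)
                truth.append(
                    TruthMonomer(pos, pos + len(m), lab, CLASS_TABLE[lab][0], "+")
                )
                pos += len(m)
    else:
        pos = 0
        for lab in labels:
            m = sample_monomer(models[lab], spec.divergence_pct, rng)
            pieces.append(m)
            truth.append(
                TruthMonomer(pos, pos + len(m), lab, CLASS_TABLE[lab][0], "+")
            )
            pos += len(m)
    seq = "".join(pieces)
    if spec.strand == "-":
        L = len(seq)
        seq = seq.translate(_COMP)[::-1]
        truth = [
            TruthMonomer(L - t.end, L - t.start, t.label, t.box, "-")
            for t in reversed(truth)
        ]
    return seq, truth


def build_genome(
    spec: LayoutSpec,
    models: dict[str, ClassModel] | None = None,
) -> tuple[str, TruthTrack]:
    """Assemble flanks, blocks and spacers into one sequence plus truth."""
    if models is None:
        _, model_list, _ = load_models()
        models = {m.label: m for m in model_list if m.label in CLASS_TABLE}
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = [random_dna(spec.flank_len, rng)]
    pos = spec.flank_len
    truth = TruthTrack(spec.seq_id)
    for i, block in enumerate(spec.blocks):
        if i > 0:
            parts.append(random_dna(spec.spacer_len, rng))
            pos += spec.spacer_len
        seq, block_truth = build_block(block, models, rng)
        parts.append(seq)
        truth.monomers.extend(
            TruthMonomer(pos + t.start, pos + t.end, t.label, t.box, t.strand)
            for t in block_truth
        )
        pos += len(seq)
    parts.append(random_dna(spec.flank_len, rng))
    return "".join(parts), truth


def write_genome(
    spec: LayoutSpec, prefix: str, models: dict[str, ClassModel] | None = None
) -> tuple[str, TruthTrack]:
    """Emit prefix.fa, prefix.truth.bed and prefix.spec.json."""
    seq, truth = build_genome(spec, models)
    with open(f"{prefix}.fa", "w") as fh:
        fh.write(f">{spec.seq_id}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    truth.write_bed(f"{prefix}.truth.bed")
    with open(f"{prefix}.spec.json", "w") as fh:
        fh.write(spec.to_json())
    return seq, truth


def simulate_reads(
    genome: str,
    n_reads: int,
    read_len: int = 700,
    rng: np.random.Generator | int = 0,
    end_error_len: int = 60,
    end_error_rate: float = 0.25,
) -> list[str]:
    """WGS-style reads: uniform starts, degraded base quality at read ends.

    Emulates the two artifacts that inflate unclassed monomer calls in
    shotgun data: monomers truncated at read boundaries and noisy
    low-quality read ends (``end_error_rate`` substitutions over the last
    ``end_error_len`` bases of both ends).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(0, max(1, len(genome) - read_len)))
        read = list(genome[start : start + read_len])
        for i in range(len(read)):
            dist_from_end = min(i, len(read) - 1 - i)
            if dist_from_end < end_error_len and rng.random() < end_error_rate:
                read[i] = rng.choice([x for x in "ACGT" if x != read[i]])
        reads.append("".join(read))
    return reads
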