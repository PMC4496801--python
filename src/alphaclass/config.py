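"""Runtime configuration for the annotation pipeline.

All tunables that affect detection, monomer extraction, classification and
HOR calling live here so that a run is fully described by one object.
Defaults are the operating point the package is calibrated for; the
alignment scoring scheme in particular fixes the meaning of the relative
score (rs) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap local alignment scoring (all values are magnitudes).

    score = match*n_match - mismatch*n_mismatch
            - gap_open*n_gap_opens - gap_extend*n_gap_bases

    Note the opening of a gap pays both ``gap_open`` and, for each gapped
    base, ``gap_extend``; a gap of length g therefore costs
    gap_open + g*gap_extend.
    """

    match: int = 1
    mismatch: int = 1
    gap_open: int = 2
    gap_extend: int = 1


@dataclass
class AlphaConfig:
    # -- phase-1 octamer dictionary screen --
    ro_threshold: float = 0.6     # ro above this = not alpha satellite
    frag_len: int = 342           # sub-fragment length for the screen
    frag_stride: int = 171        # stride; <= frag_len - monomer length is safe
    f_random_samples: int = 500   # Monte-Carlo samples for f(random)
    # -- phase-2 dot matrix confirmation --
    dot_word: int = 8
    dot_sig: float = 1e-3         # Bonferroni-corrected diagonal significance
    # -- monomerizer --
    scoring: ScoringParams = field(default_factory=ScoringParams)
    rs_stop: float = 0.29         # stop extraction at relative score <= this
    min_score: int = 25           # chance-score floor for accepting a monomer
    max_inter_gap: int = 5        # expected slack between adjacent monomers
    min_complete_len: int = 140   # complete-monomer length (uppercase in BED)
    # -- Bayesian classifier --
    bayes_threshold: float = 0.9
    min_model_cols: int = 30      # fewer aligned model columns -> Um
    # -- windowing --
    window_size: int = 5000
    window_overlap: int = 200
    # -- statistics --
    genome_size: float = 3e9      # haploid genome size for WGS normalization
    # -- HOR scan --
    hor_word: int = 11
    hor_coverage: float = 0.30    # diagonal coverage needed to call a period
    hor_min_units: int = 3        # fewer repeats = duplication, not HOR
    # -- misc --
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "AlphaConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        scoring = ScoringParams(**raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
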