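# Methods

## Scope and model

`alphaclass` annotates alpha satellite (AS) DNA monomer by monomer. The
underlying model is the standard one for human centromeric satellite:
~171 bp monomers belonging to 12 diagnostic classes (J1, J2, D1, D2,
W1–W5, R1, R2, M1) that map onto five suprachromosomal families (SF1,
SF2, SF3, SF5, SF4+), with an independent ancestral A/B dichotomy
readable from monomer positions 35–51 (the A/B box; B is the CENP-B
binding configuration, though typing asserts ancestry, not binding
functionality). Monomer coordinates use the traditional register in
which position 1 is the first base of the BamHI site of the X-chromosome
HOR. Sub-layers within the SF4+ umbrella are deliberately not annotated.

## Consensus data

The classifier is driven entirely by data files: an ASC consensus
(FASTA) and one integer count matrix per class (`>LABEL TYPE LENGTH`
header, then `pos countA countC countG countT` rows). The bundled set is
**synthetic** — a stand-in with the documented structure, generated by
`scripts/build_consensus_data.py`: a fixed 171 bp AT-rich base consensus;
per class, 20 class-specific substitutions outside the box plus the
type-specific box (a CENP-B-box-like B configuration vs an A
configuration differing at 7 sites); count columns of 88/4/4/4 with 15
softer (64/20/8/8) columns per class. Classes are kept ≥ 18 mismatches
apart, comparable to the ~75–90% inter-class identities of the real
families. Matrices are Laplace-smoothed (+1 per cell) at load so no
likelihood is ever zero; the random model is uniform 0.25. The A/B box
matrices are derived, not stored: position-wise sums of the count
matrices of the six A-type and six B-type classes over columns 35–51,
renormalized.

Consequence of the stand-in: classification *accuracy* numbers quoted by
the tests certify the algorithms against this matrix set, not against
the historical one; any well-formed matrix set in the same format can be
substituted via `load_models(data_dir)`.

## Detection

**Phase 1 (dictionary screen).** Distance between a fragment and ASC:
`ro = f / f_random`, `f = log((N1+N2)/(2·nc))` over distinct-octamer
dictionaries. `f_random` is the Monte-Carlo mean of f for uniform-random
fragments of the same length (default 500 samples, seeded); samples
sharing no octamer with ASC enter through a continuity correction
`nc_eff = max(nc, 1/2)`, without which f is undefined. The acceptance
threshold is ro ≤ 0.6 on either strand.

Because a lone monomer is a ~3% minority of a 5 kb window, the screen is
applied to overlapping sub-fragments (default 342 bp, stride 171 — every
171 bp monomer is fully contained in some sub-fragment); the window
passes if any sub-fragment passes. Screening the whole 5 kb dictionary
instead would push ro for a single-monomer window to ~0.8–1.0 and blind
the detector to sparse AS.

Sensitivity bound: at 20% divergence from ASC a monomer occasionally
(order 1%) retains too few intact octamers for any framing to reach
ro ≤ 0.6 — this is a property of the printed statistic and threshold,
not of the implementation. Detection is empirically complete through
15% divergence (property-tested); the end-to-end recovery guarantees are
stated at ≤ 10%.

**Phase 2 (dot-matrix confirmation).** Word matches (default word 8)
between the window and ASC are grouped by diagonal and collapsed into
maximal runs — r consecutive word hits are one exact match of r+7 bases,
not r independent events (treating them as independent makes a single
chance ~12 bp match look astronomically significant). Each diagonal gets
two chance probabilities: a binomial tail on its number of distinct runs
(Bonferroni-corrected over diagonals) and the expected count of chance
exact matches at least as long as its longest run (per-base match
probability from the two base compositions). The window statistic is the
minimum; windows with statistic ≤ 1e-3 are confirmed. Both strands are
evaluated and the more significant orientation is recorded as the
segment's strand.

## Monomerization

Local alignment uses an affine-gap Smith–Waterman–Gotoh DP (numba
kernel) under the additive score

    score = n_match·match − n_mismatch·mismatch
            − n_gap_opens·gap_open − n_gap_bases·gap_extend

with defaults match 1, mismatch 1, gap open 2, gap extend 1 (a gap of
length g costs 2 + g). With match reward 1, the relative score
`rs = score / alignment_columns` lies in (−∞, 1] and the printed
stopping threshold rs ≤ 0.29 is directly interpretable (≈ 35% divergence
for a full-length gapless monomer). Alignment length counts columns:
matches + mismatches + gapped bases.

Extraction is greedy best-score-first (ties to the leftmost start). Each
accepted alignment splits its free interval and the remainders are
re-aligned independently, so monomers can never overlap and the result
is deterministic. Two stopping rules apply: the rs ≤ 0.29 rule, and a
raw-score floor (`min_score`, default 25) — needed because rs alone
cannot terminate on non-satellite sequence, where a chance 10 bp perfect
local match carries rs = 1.0 while genuine chance scores for a
5 kb × 171 bp problem plateau around 16. Imperfect alignment of monomer
ends leaves small unassigned gaps (typically ≤ 5 bp, occasionally ~10 at
15% divergence) between adjacent monomers; these bases belong to no
monomer. Monomers < 140 bp are flagged incomplete.

Correctness of the DP is pinned to an independent oracle (biopython's
`PairwiseAligner`, local mode, `open_gap_score = −(gap_open+gap_extend)`)
with exact score agreement on randomized suites.

## Classification

Thirteen hypotheses (12 classes + uniform random), uniform prior,
per-position independent likelihoods read along the ASC-registered
alignment columns. Gap columns are skipped as uninformative, which keeps
truncated monomers classifiable; completeness is tracked separately by
the 140 bp flag. A model shorter than ASC contributes uniform
probabilities at missing positions. The winner is assigned at posterior
≥ 0.9 (`bayes_threshold`); if the random model wins at threshold the
call is Xm; every sub-threshold case is Um; monomers covering < 30 model
columns (`min_model_cols`) are Um by construction. Box typing repeats
the procedure over columns 35–51 with the summed A/B matrices
(A/B/X/U), except that a monomer whose alignment does not span the full
box region is Q. Monomer and box calls are deliberately independent —
hybrid monomers (e.g. an R2 body with a B box) surface as discordant
calls.

## Track assembly

Windows default to 5000 bp with 200 bp overlap (the overlap exceeds one
monomer, so every monomer is complete in at least one window). Records
are BED9, 0-based half-open: name `<CLASS>/<boxcode>` (lowercase class
when < 140 bp), score = round(1000·posterior), strand from the detector,
itemRgb fixed per class and hued by SF (SF1 reds, SF2 blues, SF3 greens,
SF5 oranges, SF4+ purple, Um/Xm grays). Duplicates from window overlaps:
of two overlapping monomers the longer remains intact and the shorter is
trimmed to its non-overlapping remainder (dropped when contained); equal
lengths keep the earlier record intact. Casing is rendered from the
final record length.

## Statistics

Per-SF and per-class bp/counts, the unclassed fraction (Um+Xm monomers
over all monomers), and the ≥ 140 bp completeness filter. WGS-style
normalization: monomer count × mean monomer length × (genome size /
total read bp), genome size 3×10⁹ bp (configurable). The double-filter
correction takes total AS bp from the unfiltered sample but splits it by
the SF proportions of the filtered sample (conserving the total
exactly), mirroring the protocol that combines maximal detection with
cleaner composition. Bad-end trimming is a simple configurable end trim
with an optional quality-aware mode; the read simulator shows that
trimming *plus* filtering raises the mean monomer length, while trimming
alone can lower it (moderately noisy ends are still locally alignable
and pad raw monomer calls). Region statistics (R2%, B-box%, per-SF %)
are monomer-count fractions over user intervals, with region size
corrected by subtracting user-supplied mask intervals (e.g. LINE
insertions, gaps).

## HOR scan

The self dot matrix counts exact word matches (default word 11) per
offset; coverage is matches over available diagonal cells. A HOR is
called at the smallest offset ≥ 1.5 monomer lengths with coverage ≥ 0.30
whose doubled offset is also elevated, refined to the local coverage
peak, provided ≥ 3 units fit in the region; exactly-2-unit repeats are
reported as duplications. Inter-unit identity is the mean adjacent-unit
global-alignment identity (edlib). With word 11, the 0.30 threshold sits
between the inter-unit identity floor of variant HORs (~93%, coverage
≈ 0.45) and the monomer-level background of homogeneous arrays (≤ ~8%
monomer divergence keeps same-class lag coverage below ~0.17). Note that
an extremely homogeneous dimeric array is reported as a ~342 bp-period
HOR — the dimer *is* its repeating unit in that regime.

## Synthetic genomes

The generator emulates the documented array organizations: J1J2 / D1D2
dimeric, W1–W5 pentameric, irregular R1/R2 (and pure-R2) SF5, monomeric
M1, and mixed new-family/SF5 blocks, on either strand, embedded in
uniform-random flanks/spacers. Monomers are drawn from the class
consensus with substitutions at the requested divergence and indels at a
tenth of that rate (AS divergence is substitution-dominated; lengths stay
near 171 bp). HOR blocks sample one unit and reiterate it, each copy
drifting from the master at half the (100 − identity)% rate so *adjacent*
copies differ by the nominal amount. The read simulator draws uniform
read starts and degrades both read ends (default 25% substitutions over
the last 60 bp) to emulate truncation plus low-quality Sanger ends.

What the generator does not emulate: real class phylogeny (classes are
equidistant mutants of one base consensus), large indels/transposon
insertions, gradients of divergence across dead layers, CpG or strand
composition bias, and assembly artifacts. Passing recovery tests
therefore certify the pipeline's statistical machinery, not performance
on real centromeres.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `ro_threshold` | 0.6 | phase-1 dictionary distance cutoff |
| `frag_len` / `frag_stride` | 342 / 171 | phase-1 sub-fragment framing |
| `f_random_samples` | 500 | Monte-Carlo calibration size |
| `dot_word` / `dot_sig` | 8 / 1e-3 | phase-2 word size / significance |
| match/mismatch/open/extend | 1/1/2/1 | SWG scoring |
| `rs_stop` | 0.29 | extraction stop on relative score |
| `min_score` | 25 | chance-score floor for a monomer |
| `min_complete_len` | 140 bp | complete-monomer (uppercase) cutoff |
| `bayes_threshold` | 0.9 | posterior needed for a class/box call |
| `min_model_cols` | 30 | fewer aligned columns ⇒ Um |
| `window_size` / `window_overlap` | 5000 / 200 bp | processing windows |
| `genome_size` | 3×10⁹ bp | WGS normalization constant |
| `hor_word` / `hor_coverage` / `hor_min_units` | 11 / 0.30 / 3 | HOR scan |

Test and acceptance problem sizes are chosen for single-CPU runs: the
planted-genome recovery check uses a ~1 Mb genome with ~2 450 monomers
across all array types; classifier recovery uses 1 000 draws per class;
the detector null rate uses 1 000 random 5 kb windows.

## Known limitations

- The bundled matrices are a synthetic stand-in (above); absolute
  agreement with historical annotations of real genomes is out of scope.
- Phase-1 sensitivity decays beyond ~15% divergence from ASC for
  *isolated* monomers (dense arrays are unaffected).
- One strand is chosen per 5 kb window; a strand switch inside a single
  window keeps only the better-matching orientation.
- The HOR caller reports the smallest qualifying period; nested or
  interleaved periodicities yield the innermost unit.
- Full-assembly statistics (tens of Mbp of AS) are supported by the code
  path but not exercised in CI.
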