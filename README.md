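# alphaclass

Monomer-by-monomer annotation of alpha satellite (AS) DNA — the tandemly
repeated ~171 bp family of primate centromeres — in arbitrary sequence:
assembly contigs, centromeric reference models, or shotgun reads.

Alpha satellite is organized in classes of monomers that diagnose five
suprachromosomal families (SFs): the "new" families of live higher-order
repeat (HOR) centromeres — SF1 (J1/J2 dimers), SF2 (D1/D2 dimers), SF3
(W1–W5 pentamers) — and the "dead" pericentromeric layers SF5 (irregular
R1/R2) and the SF4+ umbrella (M1). Each class also carries an ancestral
A/B box type at monomer positions 35–51; the B configuration is the
CENP-B binding motif. `alphaclass` detects AS, cuts it into monomers,
classifies every monomer, emits a color-coded BED9 browser track, and
provides per-SF statistics plus a dot-matrix HOR caller.

## Method

1. **Detection.** Phase 1 is an octanucleotide-dictionary screen: for a
   fragment vs the AS consensus (ASC), with dictionary sizes N1, N2 and
   intersection nc,

       ro = f / f(random),   f = log((N1 + N2) / (2·nc)),

   where f(random) is calibrated on length-matched random sequence;
   ro = 0 for identical sequences and fragments with ro ≤ 0.6 pass.
   Phase 2 confirms candidates by an automated dot matrix against ASC,
   scoring the best diagonal's match runs against a chance model.
2. **Monomerization.** Repeated Smith–Waterman–Gotoh local alignment to
   ASC (match +1, mismatch −1, gap open −2, gap extend −1). Each best
   alignment becomes a monomer, its span is removed, and extraction stops
   when the relative score rs = score / (match_reward × alignment_length)
   drops to 0.29 or below. Monomer position 1 follows the BamHI-site
   convention of DXZ1.
3. **Classification.** A Bayesian classifier scores each monomer under the
   12 class position-probability matrices plus a uniform random model
   (uniform prior); the winner is assigned at posterior ≥ 0.9, otherwise
   the monomer is unclassed (Um) or random (Xm). The A/B box is typed
   independently (A/B/X/U, or Q when the box region is missing).
4. **Track assembly.** 5 kb windows with ~200 bp overlap; duplicate calls
   from the overlaps are resolved by keeping the longer monomer intact and
   trimming the shorter. Monomers < 140 bp are rendered in lowercase.
5. **HOR scan.** A region's self dot matrix is searched for periodic
   diagonals; ≥ 3 units above the coverage threshold is a HOR call with
   the inter-unit identity from global alignment of adjacent units
   (2 units report as a duplication).

The bundled consensus data set (ASC + 12 count matrices) is a synthetic
stand-in with the documented structure (see `docs/methods.md`); every
algorithm works with any well-formed matrix set dropped into the same
plain-text format.

## Worked example

Generate a synthetic chromosome with a known truth track — an SF1 dimeric
array and a pure-R2 HOR (8-monomer unit, 99% identity) in random flanks —
then annotate it and scan the HOR:

```
$ alphaclass synth --spec layout.yaml --out demo
19236 bp, 54 monomers -> demo.fa

$ alphaclass annotate --fasta demo.fa --out demo.bed --quiet
54 monomers -> demo.bed

$ head -4 demo.bed
track name="AS-SF" itemRgb="On"
demo  4000  4168  J1/A  1000  +  4000  4168  178,34,34
demo  4170  4340  J2/B  1000  +  4170  4340  255,99,71
demo  4342  4510  J1/A  1000  +  4342  4510  178,34,34

$ alphaclass stats --track demo.bed --out demo.tsv && cat demo.tsv
metric              raw    filtered_140bp
n_monomers          54     54
total_as_bp         9071   9071
unclassed_fraction  0.0000 0.0000
SF1_bp              5063   5063
SF5_bp              4008   4008
...

$ alphaclass hor --fasta r2block.fa --out hor.tsv && cat hor.tsv
region   has_hor  period_bp  identity_pct
r2block  True     1370       99.1
```

Reading the output: every record is one monomer — `J1/A` means class J1
(SF1), A-type box; uppercase names are complete (≥ 140 bp) monomers; the
score is 1000 × the classifier posterior; colors are hued by SF (SF1
reds, SF2 blues, SF3 greens, SF5 oranges, SF4+ purple, Um/Xm grays). All
54 planted monomers are recovered with their generating classes
(`J1J2...` alternation in SF1; the stats table splits the 9071 annotated
bp into the two planted families). The HOR caller reports the planted
8-monomer period (1370 bp ≈ 8 × 171) at 99.1% inter-unit identity.

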