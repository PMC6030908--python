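# Methods

This note records the models, conventions, parameter choices and known
limitations behind guidescout, in the order the pipeline runs.

## Coordinates and sequence normalisation

All internal coordinates are 0-based half-open; the only 1-based inclusive
values are human-facing TSV columns, whose names carry a `1` suffix
(`start1`). Sequences are uppercased on ingest, `U` maps to `T`, and any
letter outside A/C/G/T/N (including IUPAC ambiguity codes in genomes) maps
to `N` with a logged warning. `N` means "masked/variant position": it
matches no IUPAC class, so PAMs are never called over an N, guides whose
protospacer or PAM covers an N carry the `OVERLAPS_N` flag and are excluded
from default output, and candidate off-target sites containing N are
dropped. This is the conservative reading of N-masking as a variant mask;
treating ambiguity codes as matchable was the alternative and was rejected
to keep "masked" a single concept.

## Nuclease profiles

A profile is (PAM pattern, PAM side, guide length, cut offset, blunt flag,
alternative PAMs). Built-ins:

| name   | PAM    | side | guide | cut                            | alt PAMs |
|--------|--------|------|-------|--------------------------------|----------|
| SpCas9 | NGG    | 3'   | 20    | blunt, between positions 17/18 | NAG, NGA |
| SaCas9 | NNGRRT | 3'   | 20    | blunt, −3 from PAM             | —        |
| Cpf1   | TTTV   | 5'   | 23    | staggered, after position 18   | —        |

Cut offsets are stored in the profile (signed bases from the PAM-proximal
protospacer end), not hard-coded: −3 for both Cas9s, +18 for Cpf1. The
Cpf1 staggered cut is represented by its PAM-distal nick position, which is
what primer placement and microhomology windows need; the second nick of
the cohesive cut is not modelled. Cpf1 guide length is 23 by default and
configurable (21-base spacers are in use as well).

## Guide scanning and identifiers

Both strands are scanned for PAM occurrences whose full protospacer fits
inside the input. A guide's identifier is
`<1-based plus-strand position of the PAM's 5' base><forw|rev>` (e.g.
`171forw`) and later names primers and pool oligos. Warning flags: HIGH_GC
(> 75 % GC in the protospacer), LOW_GC (< 25 %), TTTT (homopolymer that
terminates pol III transcription), OVERLAPS_N. The GC cutoffs are not
prescribed anywhere authoritative; 25/75 match common practice and are
CLI-configurable. A 50-base guide-oriented context window centred on the
cut is stored when it fits in the input; restriction screening and the
out-of-frame score report "unavailable" (`NA`) rather than 0 without it.

Restriction screening keeps enzymes whose recognition site (either strand)
spans the cut junction and occurs exactly once in the 50-base window —
uniqueness is what makes a digest informative. The shipped table lists 16
common 6–8-cutters; users can substitute their own 2-column TSV.

## Off-target search

The contract: every genomic site on either strand where (a) the PAM matches
the canonical pattern or, when enabled (default on), an alternative pattern
(NAG/NGA for SpCas9), and (b) the protospacer Hamming distance is at most
`max_mm` (default 4, hard cap 5). Two implementations ship:

* `enumerate_offtargets` — numpy-vectorized: per-base boolean masks locate
  PAM-compatible positions, a sliding-window byte comparison counts
  mismatches, and a cumulative-sum table excludes N-containing windows.
* `brute_force_scan` — the obvious pure-Python position-by-position loop,
  kept deliberately free of vectorisation or indexing shortcuts.

The two must agree exactly (all fields, all orderings); the test suite and
the acceptance script assert this on hundreds of randomized genomes. A
seed-and-extend index was considered and rejected: with a 4-mismatch budget
over a 20-mer no practical contiguous seed is mismatch-free by pigeonhole,
so an exact-seed filter would silently drop hits; at the package's design
scale (≤ a few Mb) the vectorized full scan is fast enough and provably
complete. Hits are sorted by (mismatches, CFD descending, contig, start).
Written reports cap at the 1000 highest-CFD hits per guide; the full
histogram (`mmCounts`) is always computed from the complete hit list.

When the input sequence occurs exactly once in the genome, each guide's
perfect-match hit at that locus is flagged on-target and excluded from
specificity aggregation and the off-target table; duplicated perfect sites
elsewhere count as off-targets. Inputs with masked positions, or absent
from the genome, are not locatable and then no hit is excluded.

## Scores

**MIT hit score** (see README for the formula): position weights ship in
`data/mit_weights.tsv`, position 1 = PAM-distal. The shipped vector is the
widely reproduced experimental 20-mer weight matrix, several of whose
PAM-distal entries are exactly 0 — under that table a single mismatch at
such a position scores 100, so the sharper law "hit = 100 iff no mismatch"
holds only for strictly positive weight tables (e.g. the uniform synthetic
tables, `ScoreTables.uniform`, used throughout the property tests). The
pairwise-distance denominator generalises 19 to `guide_len − 1` for
non-20-mer guides.

**CFD**: product of per-(position, guide base, off base) penalties and a
PAM-class penalty keyed by the two bases after the N of NGG-type PAMs. The
shipped penalty tables are constructed stand-ins (filenames and headers say
`synthetic`): mismatch penalties decay linearly toward the PAM-proximal
end (0.96 → 0.20) with transversions penalised 0.65× versus 0.9× for
transitions, and the PAM table has canonical GG = 1.0, AG = 0.259,
GA = 0.069 and near-zero elsewhere. Published tables drop in via
`ScoreTables.from_files`. For guide lengths without shipped tables (Cpf1),
uniform synthetic tables are generated, with non-canonical PAM penalty 0.25.

**Specificity** `100·100/(100 + Σ hits)` is permutation-invariant and
strictly decreasing per added hit. Colour classes: green ≥ 50, red < 30,
yellow between (boundary value 30 is yellow); both thresholds configurable.

**Efficiency** is a pluggable registry. The default, fully specified model
`pam_proximal_gc` is `100·(0.2 + 0.6·GC10/10 + 0.2·[terminal base = G])`
over the ten PAM-proximal bases — it captures the two sequence features
with the most consistent empirical support (proximal GC content, G adjacent
to the PAM) and is deliberately simple enough to verify by hand. Published
linear coefficient sets load from a documented TSV (`intercept`,
`score_min`, `score_max` meta rows plus `position/base/weight` rows;
min-max scaled to [0, 100] and clamped). Trained neural models are out of
scope. A model that needs missing context reports "unavailable", never 0.

**Out-of-frame**: microhomology patterns are identical substring pairs of
length ≥ 2 with the left copy ending at or before the cut junction and the
right copy starting at or after it, both within 30 bases of the cut (all
three constants configurable). The junction convention: `cut` is the
0-based between-base offset; a copy ending exactly at the junction counts
as left, one starting exactly there as right. Patterns positionally
contained in a longer pattern with the same deletion length are suppressed
(sub-patterns of a repeat describe the same deletion event). Pattern weight
is `100 · round(exp(−deletion/20), 3) · (2·#GC + #AT)`; the score is the
percentage of weight on deletions with length % 3 ≠ 0, "unavailable" when
no pattern exists. The exponential rounding to 3 decimals is part of the
weight definition (it makes hand-checking exact), not numerical sloppiness.

## Primers, manifests, cloning oligos

Melting temperatures use a nearest-neighbor ΔH/ΔS sum over the unified
duplex parameter set (shipped in `data/nn_params.tsv`, reverse-complement
stacks folded), initiation terms included:
`Tm = ΔH/(ΔS + R·ln(C/4)) − 273.15 + 16.6·log10([Na+])`, defaults C = 50 nM
primer, 50 mM Na+. The implementation is cross-checked in the tests against
an independent nearest-neighbor implementation to 1e-9 °C.

Primer search is an in-house deterministic greedy (no external engine) so
identical inputs give identical primers: candidates of length 18–27 are
scanned outward from the site, filtered by Tm within tolerance (default
60 ± 3 °C), no AAAA/TTTT/GGGG/CCCC run, and a G/C 3' end; up to 200
candidates per side are collected and the pair minimising summed Tm
deviation within the product range wins, ties broken by (product length,
left start, oligo lengths). Defaults: 600–1000 bp validation products
(Sanger-friendly), 200–280 bp off-target products (amplicon sequencing).
Off-target batches never raise per hit: infeasible hits go to a skip list
with the binding constraint, and pairs + skips always partition the hits.
Cross-dimer checking and adapter tailing are out of scope.

CRISPResso manifests are `name / amplicon_seq / guide_seq` TSV rows; the
amplicon is the plus-strand genomic product and `guide_seq` is the sequence
the amplicon actually contains — the protospacer for the on-target row, the
(mismatched) site sequence for off-target rows — validated by containment
before writing.

Cloning oligos: `fwd_overhang + insert` and `rev_overhang + revcomp(insert)`
where the insert is the protospacer after the promoter prefix rule
(`add_G_if_absent` for U6-type vectors, `require_GG` — G's prepended — for
T7 in-vitro templates; rules add bases rather than substituting so the
genomic match is preserved). Built-in profiles: `bbsI_U6` with the standard
ACCG/AAAC BbsI overhangs; `t7_invitro` with generic Golden-Gate-style
overhangs (TAGG/AAAC) as a placeholder for any user vector — overhangs are
freely configurable per profile.

## Saturating-mutagenesis pools

Selection keeps scored guides with specificity and efficiency at or above
the thresholds and no N overlap, ordered along the region; the coverage
report states the largest gap between adjacent retained cut sites. Oligo
layout is fixed and decodable:
`fwd_barcode + left_adapter + insert + right_adapter + revcomp(rev_barcode)`
— the reverse barcode is appended reverse-complemented so both barcodes
read as PCR primer landing sites on the synthesised strand. Barcodes must
be ≥ 6 nt, pairwise distinct and (forward set) prefix-free, which makes
decoding injective; default adapters are the common U6 vector arm tail and
sgRNA scaffold head, both overridable. Unequal insert lengths within a
subpool (a 21st G added to some inserts) produce a validation warning
listing offenders rather than an error. Gene-identifier-driven library
lookup against published human/mouse collections is out of scope — it is
curated data, not algorithm; region-driven design covers the computation.

## Synthetic fixtures

`generate_toy_genome` draws an i.i.d. uniform A/C/G/T background from a
seeded generator and plants guide+canonical-PAM sites mutated at exactly
*m* protospacer positions (PAM instantiated to a concrete canonical
sequence), at non-overlapping positions round-robin across contigs, on
either strand; *m* up to 5 is allowed so the over-budget behaviour of the
search can be exercised. After planting, a brute-force scan with
alternative PAMs enabled and budget `max(4, max planted m)` must find
exactly the planted sites; otherwise the background is regenerated, up to
20 times, then the generator fails loudly. The generator is a pure function
of its arguments including the seed.

What the fixtures emulate: local sequence composition and exact-distance
off-target structure. What they do not: real genome repeat structure,
chromatin, GC-skewed isochores, or the empirical distribution of off-target
activity — so green tests demonstrate the engine's contracts (completeness,
exactness, determinism), not wet-lab predictive performance, which is
bounded by the score tables supplied.

## Problem sizes in the shipped checks

The test suite verifies oracle equivalence on 100 random (guide, 50 kb
genome) pairs across budgets 0–4 and planted-site recovery over 50 seeded
fixtures of ten sites each; the acceptance script re-measures the same
properties end-to-end at 30 pairs × 20 kb and 25 fixtures × 2 × 10 kb,
plus 5000 score-law cases and 200 out-of-frame contexts — sizes chosen so a
full from-scratch run completes in seconds on a laptop while every property
is exercised across both strands, all mismatch classes and all PAM classes.

## Known limitations

* Bulge/indel off-targets and variant-aware (population SNP) off-target
  search are not modelled; only Hamming-distance sites are found.
* Efficiency scoring ships no trained published model; the default is a
  transparent two-feature surrogate and real coefficient tables must be
  supplied by the user.
* The CFD tables are constructed stand-ins; absolute CFD values are not
  comparable to published ones until real tables are dropped in (orderings
  by mismatch count and PAM class are preserved).
* The Tm model covers monovalent salt only (no Mg2+/dNTP correction).
* Exon-overlap filtering is a linear scan per hit — adequate for desk-scale
  annotations, not for whole-transcriptome BED files.
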