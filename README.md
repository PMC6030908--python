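# guidescout

CRISPR guide-RNA selection for genome editing experiments: scan a target
sequence for nuclease-specific PAM sites, enumerate every potential
off-target in a genome within a mismatch budget, score specificity (MIT
aggregate, CFD), on-target efficiency and microhomology out-of-frame
propensity, and design the downstream wet-lab materials — cloning oligos,
validation and off-target PCR primers, CRISPResso amplicon manifests and
barcoded saturating-mutagenesis oligo pools.

It is written for bench scientists and screen builders who need reproducible,
scriptable guide design against their own FASTA genomes (engineered strains,
non-model organisms, synthetic constructs) rather than a hosted web service.

## The scores

For a 20-nt protospacer and an off-target site differing at the mismatch
position set *P* (positions numbered 1 = PAM-distal to 20 = PAM-proximal),
the per-hit **MIT score** is

```
hit = 100 · Π_{p∈P} (1 − W[p]) · 1 / (((19 − d̄)/19)·4 + 1) · 1/|P|²
```

with position weights *W* and d̄ the mean pairwise distance between
mismatches (the last two factors apply only for |P| ≥ 2). The guide-level
**specificity score** aggregates all off-targets:

```
spec = 100 · 100 / (100 + Σ hits)    ∈ (0, 100]
```

— 100 with no off-targets, strictly decreasing with every additional hit.
Guides are classed green (≥ 50), yellow, or red (< 30).

The **CFD score** of a single site is a product of per-(position, guide
base, off base) penalties times a PAM-class penalty, exactly 1.0 only for a
perfect match with a canonical PAM. Both scores are table-driven; the CFD
tables shipped in `src/guidescout/data/` are constructed stand-ins (marked
`_synthetic`) in a documented format that published tables drop into.

The **out-of-frame score** enumerates microhomologies — identical sequence
pairs flanking the cut that can template a deletion — weights each pattern
by `exp(−deletion/20)` and GC-weighted length, and reports the percentage
of weight on deletions whose length is not a multiple of 3 (higher = more
likely frameshift knockout).

Off-target search honours the classic contract: all sites with up to four
mismatches (configurable to 5), on both strands, canonical plus alternative
PAMs (NAG/NGA for SpCas9). A pure-Python brute-force scanner ships alongside
the vectorized engine and the two are asserted equal in the test suite.

## Worked example

Generate a synthetic two-contig genome with one perfect site and planted
off-targets at 1, 2 and 3 mismatches, then design guides against a window
around the on-target:

```
$ guidescout fixture --out fx --seed 11 --guide GTACGTTCAGGATCAGGTAC \
      --plan "0:+,1:-,2:+,3:-" --contig-len 8000 --n-contigs 2
genome.fa: 2 contig(s), 4 planted site(s)

$ guidescout design --genome fx/genome.fa --input fx/input.fa --out run
guides.tsv: 29 guide(s)
offtargets.tsv: 5 off-target row(s)
```

`run/guides.tsv` is sorted by specificity (ties: position, then strand):

```
guideId  targetSeq                 strand  start1  specScore  effScore  outOfFrameScore  mmCounts
7rev     GGGATCTTACGACAGTGGTG CGG  -       8       100        76        NA               0-0-0-0-0
12rev    CGCGTGGGATCTTACGACAG TGG  -       13      100        70        NA               0-0-0-0-0
...
171forw  GTACGTTCAGGATCAGGTAC TGG  +       151     49         50        51               0-1-1-1-0
```

The planted guide `171forw` sees exactly the three planted off-targets
(`mmCounts` 0-1-1-1-0: one each at 1, 2 and 3 mismatches) and its
specificity drops to 49 — yellow. Guides with no genomic near-matches score
100. `run/offtargets.tsv` lists each hit with its coordinates, MIT and CFD
scores:

```
guideId  contig  start1  strand  siteSeq               pamSeq  mismatches  mitHit  cfd
171forw  c2      5501    -       GTACGTTCATGATCAGGTAC  GGG     1           92.10   0.3900
171forw  c1      6538    +       ATACGTTCAGGATCAGGTAG  TGG     2           10.43   0.1123
```

From there, `guidescout primers --guide-id 171forw ...` writes validation
primers (600–1000 bp product, Tm 60 ± 3 °C), one primer pair per off-target
(200–280 bp, amplicon-sequencing friendly) and a CRISPResso manifest;
`guidescout satmut --subpools subpools.tsv ...` emits a barcoded oligo pool
over all guides passing specificity/efficiency thresholds. Every output
directory contains a `run.json` from which the run reproduces byte-for-byte.

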