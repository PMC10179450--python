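# Methods

## The recombination model

A plant mitogenome assembled as a single circle may coexist in vivo with
alternative conformations produced by homologous recombination between the
two copies of a large direct repeat. For a repeat `R` with copies embedded
as `...X·R·Y...` and `...U·R·V...` on the master circle, recombination
exchanges the flank pairings: the native junctions `X·R·Y` and `U·R·V` are
replaced by `X·R·V` and `U·R·Y`. On a circle, a single direct-repeat
exchange splits the molecule into two smaller circles; exchanging at both
of two repeats yields a second master circle with the inter-repeat
segments swapped. With two independent two-copy direct repeats this gives
`2^2 = 4` conformations: masters A and B and sub-circle pairs C and D.

`enumerate_isomers` formalizes this on an assembly graph whose repeat
nodes have in/out degree 2: each repeat admits two entry→exit pairings,
every combination is decomposed into circles, and results are
deduplicated up to rotation and reverse-complement of each circle (a DNA
circle has no intrinsic origin or strand). Graphs with inverted ('-')
links are rejected with an explicit error: inverted-repeat recombination
produces segment inversions rather than splits and is an extension point,
not a supported classification.

## Junction-spanning read support

Because the two copies of a repeat are (near-)identical, only reads
covering *repeat plus both flanks* discriminate conformations. For each
repeat, four references `left flank + repeat + right flank` (default
flank 500 bp) are built — two native, two flank-swapped — and labelled by
a fixed convention: `p1`/`p2` native in master-circle order, `p3`/`p4`
recombinant (`p5..p8` for the second repeat). The figure-defined labels
of any particular published study may be a permutation of this
convention.

A read supports a path when the reference window
`[max_end_slack, |ref| - max_end_slack)` aligns semi-globally (edlib,
infix mode) within the read at identity ≥ `min_identity` (default 0.80,
`max_end_slack` default 0), **and** the alignment holds the same identity
within each flank window separately. The per-flank requirement is what
makes "completely spanned" informative: the flanks are a small fraction
of a reference built around a multi-kilobase repeat, so an overall
identity threshold alone cannot reject a read carrying the wrong flank,
while a score-maximising local aligner would simply not extend across it.
Flank errors are attributed by walking the alignment CIGAR; indels are
charged to the reference position at which they occur. Both read strands
are tried; a (read, path) pair counts at most once. In the error-free
limit with `min_identity = 1` the criterion reduces to exact substring
containment, which is the oracle the tests enforce.

A repeat is called *recombinationally active* when all four paths have at
least `min_support` (default 1) spanning reads. The recombinant fraction
`(p3+p4) / (p1+p2+p3+p4)` is reported with a Clopper–Pearson binomial
confidence interval (exact, conservative; the counts are small).

Raising `min_identity` never increases a count (the acceptance threshold
only tightens), and counts are invariant to rotation of the circular
genome coordinates because references are extracted with wrapping
arithmetic.

## Synthetic study system

The generator's defaults are the study conditions the package models:

| parameter | default | note |
|---|---|---|
| genome_length | 515,187 bp | circular |
| repeat_lengths | 9026, 7040 bp | two-copy direct repeats, copies 100% identical |
| gc_target | 0.4405 | bases drawn i.i.d.; realized GC within 0.5 pp for ≥ 100 kb |
| segment_fractions | 0.40/0.25/0.20/0.15 | split of the non-repeat residue over S1..S4 |
| read_mean_length | 17,520 bp | truncated normal, sd 5,000, min 200 |
| target_depth | 75× | `n_reads` overrides |
| error_rate | 0.05 | substitution:insertion:deletion = 2:1:1 |
| isomer_weights | 0.55/0.15/0.15/0.15 | majority master A |
| truth_flank | 500 bp | junction windows recorded in truth labels |

The layout is `S1·R1·S2·R2·S3·R1·S4·R2`, so each repeat copy has distinct
flanks (the six-contig topology of a collapsed assembly graph). The
unique-segment lengths and the isomer mixture are stand-ins chosen once —
published assemblies report the repeat lengths and that the principal
master circle dominates, not the unitig lengths or mixture proportions.
The read-length standard deviation and the 2:1:1 error split are likewise
package defaults: a study typically reports only mean length and N50, and
a truncated normal does not attempt to match an empirical N50. Reads are
drawn per isomer by weight, per circle within an isomer by length, with
uniform start, random strand, and per-base errors; truth labels record
the pre-error source interval and every junction window it fully
contains.

What the simulator does **not** emulate: basecaller-specific error
profiles (homopolymer compression, quality strings), chimeric reads,
heteroplasmy below the isomer level, and biological base composition
(genes, codon structure). Tests passing on this system therefore
demonstrate correctness of the algorithms under the stated model, not
performance on real Nanopore data.

## Repeat finders

**SSRs.** Maximal perfect tandem runs of 1–6 bp motifs with copy-number
thresholds 10/5/4/3/3/3 (mono→hexa). A run is anchored at its leftmost
start; `copies` counts complete motif copies; motifs that are themselves
periodic (e.g. `ATAT`) are reported at the smaller unit only; any window
containing N fails to match. Overlapping SSRs of different unit sizes are
all reported. Published MISA tallies may count compound microsatellites
differently; this implementation reports simple runs only.

**Dispersed repeats.** Maximal ungapped pairs of four kinds — forward
(copy = copy), reverse (= reversed), palindromic (= reverse complement),
complementary (= complement) — with ≤ `max_mismatch` Hamming mismatches
(default 3) and length ≥ `min_len` (default 30). Maximality: no
simultaneous extension of both copies in either direction stays within
the budget. Search: exact k-mer seeds with
`k = min(min_len // (max_mismatch + 1), 32)` locate candidate
(anti-)diagonals (the floor makes the pigeonhole guarantee exact), then
each seeded diagonal is scanned exhaustively, so on sequences small
enough for the brute-force oracle the output is provably identical to it.
Self-pairs (a window equal to its own image) are excluded; pairs are
stored with `interval_a.start <= interval_b.start`.

E-value model: `E = n² · C(l, m) · (1/4)^(l-m) · (3/4)^m` (two-position
Bonferroni on the binomial match probability), filtered at `1e-5` by
default. Note the model's consequence: on a ~515 kb genome an exact
30-mer pair passes (E ≈ 2e-7) but a 30 bp pair with 3 mismatches does not
(E ≈ 2.5e-2) — mismatched pairs must be longer to survive the filter.
Published REPuter outputs may differ in borderline records because
REPuter's exact statistic is not reproduced here.

Both finders scan linearly; repeats spanning the circle's origin are
found by rotating the sequence first. This matches the behaviour of the
linear reference tools and keeps record coordinates simple. Note that
decreasing the mismatch budget does not literally shrink the record
*set*: a wide maximal window at budget 3 may split into several maximal
sub-windows at budget 1. What holds, and what the tests assert, is that
increasing `min_len` never adds records and that every stricter-budget
record nests inside a looser-budget record.

The end-to-end pipeline stage runs the dispersed-repeat finder at
`min_len 1000, max_mismatch 0` — the recombination-scale question — while
the standalone `repeats` command defaults to the descriptive 30/3/1e-5
setting. Full descriptive settings on a multi-hundred-kilobase genome are
inherently near-quadratic and are left to an explicit invocation.

## Codon usage

CDS features (including `join(...)`/`complement(...)` locations and
duplicated gene copies) are extracted with Biopython;
`RSCU(c) = count(c) · k / Σ counts` over each amino acid's `k` synonymous
codons. Stop codons are excluded by default (the convention of the common
desktop tools; a flag includes them — they shift values at the second
decimal). RNA-edited codons are counted as written in DNA, since the
statistic operates on the deposited genomic sequence. Codons containing N
and trailing partial codons are skipped; zero-count families get NaN.
Invariants enforced by tests: family mean RSCU = 1 (when the family is
observed), invariance to CDS order and to duplicating every CDS.

## MTPT detection

Plastid-to-mitochondrion transfers are local BLASTN alignments
(`-task blastn -word_size 7 -evalue 1e-10`, plastome as query) — the
canonical implementation of word seeding with Karlin–Altschul statistics.
Because the plastome's inverted repeat produces two query hits on one
mitogenome insertion, hits whose mitogenome intervals overlap by ≥ 95% of
the shorter are collapsed, keeping the better E-value. Fragments are
ranked `MTPT1, MTPT2, ...` by descending alignment length. The summary
reports the fragment count, summed length (over unique mitogenome
locations, not a positional union) and its percentage of the mitogenome,
identity bins (>90 / 80–90 / <80%), and the count above 1 kb. Annotating
genes inside MTPTs requires a plastome annotation and is out of scope.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally and wrap through the
  origin on circles; TSV reports are 1-based inclusive.
* All randomness flows from explicit `numpy` generators seeded from the
  configuration; fixed seed ⇒ byte-identical FASTA/FASTQ/TSV outputs.
* `flank_len = 0` degenerates all four path references to the bare repeat
  and is flagged with a warning; a reference shorter than
  `2 × max_end_slack` is a parameter error; an all-zero support table is
  "no coverage", not an error.
* Isomer FASTA records are linearized at the lexicographically smallest
  rotation (Booth's algorithm) so equal circles serialize identically.
* An all-N sequence has undefined GC and raises; N never matches anything
  in either repeat finder, including another N.

## Problem sizes used in the checks

The test suite and the acceptance script run the full-size default genome
for structure statistics (515 kb generation and planted-repeat recovery
take a few seconds) and scaled-down systems elsewhere: recombinant-
fraction recovery uses a 50 kb circle with 3/2 kb repeats and 800 reads
of mean 12 kb (≈ 550 junction-spanning reads, CI half-width ≈ 0.06), and
oracle-equivalence checks use ≤ 2 kb sequences where the brute-force
scans are exact. These sizes preserve the geometry that matters — reads
several times longer than `repeat + 2 × flank`, repeats large relative to
read length — while keeping each check to seconds.

## Known limitations

* Only direct (same-orientation) two-copy repeats are classified;
  inverted repeats and higher-multiplicity repeats are rejected
  explicitly.
* Short-repeat, low-frequency recombination detection would require far
  deeper coverage and is out of scope.
* The spanning criterion counts secondary occurrences implicitly (a read
  may support several paths when slack > 0); no tie-breaking is applied.
* REPuter- and MISA-exact output reconciliation (compound SSRs,
  borderline E-values) is documented above rather than reproduced.
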