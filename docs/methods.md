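# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each module.  Coordinates are 1-based inclusive
throughout; the majority coding strand is called J and the minority strand
N, and a feature on N is stored on J coordinates and reverse-complemented on
extraction.

## Genome and annotation model

A `MitoGenome` is a circular DNA string plus a sorted feature list; a
feature may wrap the origin (start > end) only on a circular genome.  The J
strand is defined operationally as the strand carrying *cox1*: a GenBank
record whose plus strand does not carry *cox1* is reverse-complemented on
load, with a logged notice, so all skew statistics refer to the same strand
convention.  N bases are preserved in sequences but excluded from every
composition count (the excluded count is reported).

The two bundled gene tables transcribe the published annotation of
KC467055/KC467056: name, strand, 1-based span, the spacer to the next
feature (negative = overlap), and start/stop codons and anticodons where
applicable.  `read_gene_table` recomputes every spacer from the coordinates
and attaches a discrepancy report instead of silently correcting; the
bundled *S. longifissa* table carries one such discrepancy (trnM's printed
spacer −3 versus the recomputed 0), faithfully mirroring its source.  The
final spacer closes the circle and therefore fixes the genome length
(18,133 bp and 17,209 bp for the two tables).

## Composition and skew

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed on the J strand;
whole-strand statistics include the control region.  Fourfold-degenerate
third codon positions (P_4fd) are identified from the genetic code table
itself: a codon family is fourfold degenerate when all four third bases give
the same amino acid and none is a stop.  Under the invertebrate
mitochondrial code (NCBI table 5) this yields nine families — CTN, GTN,
TCN, CCN, ACN, GCN, CGN, GGN and additionally AGN, which is fully
Ser-degenerate in this code although it is often omitted from older
eight-family lists.  Deriving the set from the code keeps the finder
consistent with the exhaustive-substitution oracle used in tests.  P_4fd
skews pool third bases of J-strand protein-coding genes only (an option
projects N-strand genes onto J).  Truncated stop codons are excluded from
codon iteration.  Reports print skews to 4 decimals and percentages to 2.

## Codon calls

The start codon is the first three bases in reading orientation.  A CDS
whose length mod 3 is 1 or 2 and whose trailing bases read T or TA is called
a truncated stop (completed to UAA by polyadenylation in vivo); otherwise
the final triplet must be TAA/TAG or a warning is raised.  Starts are
classified standard (ATN) or nonstandard (covering the TCT serine start of
*cox1* and the CTG/TTG starts of *nad6*).

## Gene order and TDRL

Orders are signed circular token sequences over the 38-token alphabet
(37 genes + CR), rotation-normalized at *trnI*.  Breakpoints are counted on
orientation-respecting adjacencies, where a junction and its
reverse-complement reading are identical.  A TDRL event duplicates a
contiguous block in tandem and deletes exactly one copy of each duplicated
token; `tdrl_search` enumerates all blocks × keep-masks exhaustively for
single events (multi-event search is capped at two events for combinatorial
cost).  Inversions are representable but never generated by TDRL moves,
matching the duplication/loss model.  A scenario is classified
`non_random_polarity_consistent` when every maximal run of deleted copies
shares one transcriptional polarity (the CR, which has none, is neutral);
this encodes the transcription-coupled deletion hypothesis for the derived
katydid order.

## Tandem repeats

The detector targets near-perfect minisatellites: (1) exact 8-mer matches
vote for candidate periods via their offset histogram; (2) each candidate
period p is scored by the match array m[i] = (s[i] == s[i+p]) with a sliding
period-length window at the identity threshold (default 80%); (3) the
consensus is the per-column majority over full units (ties to the
lexicographically smallest base; the partial unit never votes); (4) the
trailing partial copy is trimmed/extended against the consensus phase;
(5) the reported period is the smallest candidate meeting the threshold, so
harmonics (2p) are never reported when p explains the array.  Copy number is
fractional (span/period).  There is deliberately no wraparound indel
alignment: the arrays this targets are colinear 175-mers with point
mutations, and the simplification keeps every output reproducible by hand.
This is the main deviation from alignment-based repeat finders: repeats with
internal indels will fragment into multiple hits.

ORF scanning translates all six frames of the doubled motif (so
junction-spanning frames are caught) with the invertebrate mitochondrial
code, reporting maximal stop-free runs ≥ 30 aa; the run's first codon is its
start (any codon — the repeat ORF of interest starts at AAA/Lys), with an
option restricting starts to ATN/GTG/TTG.

## Structure scanning

T-stretches are maximal pure T runs; variants are T runs interrupted by at
most two isolated C's, each flanked by at least one T, reported as the best
window within each maximal chain (leftmost, then longest).  Hairpins are
perfect inverted repeats — A·T and G·C arm pairing only, no mismatches,
bulges or wobble, stem ≥ 3, loop 3–15 depending on preset — enumerated
exhaustively; "hairpin length" means total length 2·stem + loop.  Minority-
strand scans run on the reverse complement with coordinates mapped back.
Tie-break everywhere: leftmost, then longest, then most GC pairs.

Replication-origin classification returns `long_T_stretch_type` when a pure
T-stretch at the preset threshold lies in or within 20 bp of a hairpin
(katydid preset threshold 10, since reported katydid stretches start at
10 bp), `T_variant_in_stem_loop_type` when an interrupted variant overlaps a
hairpin span (cricket preset 13+, grasshopper 16+), else `none`.  The 20-bp
adjacency radius is a package choice; published descriptions say "in or
adjacent to" without a distance.

## Alignment, distances, rate test, ME trees

Global alignment is Needleman–Wunsch with linear gap penalty (default
+1/−1/−2) and the deterministic traceback preference diagonal > up > left;
identity counts identical columns over all alignment columns (a gap-excluded
variant is provided).  Gap-containing columns can be stripped before
distance estimation, with surviving and parsimony-informative site counts
reported.

Jukes–Cantor: d = −(3/4)·ln(1 − 4p/3), Var(d) = p(1−p)/(L(1−4p/3)²).

The relative-rate test contrasts two lineages against a shared outgroup.
Lineage rates are distances to the inferred common ancestor,
rate_i = (d12 + d_iO − d_jO)/2, with means over taxa at equal weight.  The
statistic is z = (rate1 − rate2)/SD with
Var = Var(d1O) + Var(d2O) − 2·Cov(d1O, d2O); the covariance arises from the
shared outgroup→ancestor path and is computed by the delta method from the
exact Jukes–Cantor joint-mismatch probability on the 3-branch star implied
by the three mean distances.  Simulation at 1,000 sites shows empirical
size ≈ 0.05 at α = 0.05 and power ≈ 1 against a 2× rate ratio (the
pseudogene-vs-functional contrast of interest); both are recomputed by the
test suite and the acceptance script, not quoted.  Because lineage rates
depend on taxon weighting choices inside rate-test software, decimal-exact
agreement with any particular tool's output is not claimed — only direction
and significance.

Minimum-evolution trees enumerate all unrooted topologies (capped at 8 taxa;
10,395 topologies), fit OLS branch lengths by least squares on the
path-indicator system, and select the minimal total length with ties broken
by canonical newick encoding.  Branch lengths are not constrained
non-negative; on additive matrices the fit is exact.

## Synthetic data

The generator's defaults are the published study conditions: genome-wide
J-strand targets A+T 69.05%, AT skew 0.0017, GC skew −0.2983 (the *S.
retrolateralis* preset uses 70.08% / 0.0063 / −0.3218); ATR at 75.70% A+T
with a planted T-stretch (19 bp for the *S. longifissa* preset, 21 bp for
*S. retrolateralis*) and three planted hairpins (stem 8, loop 9, 4 GC pairs)
just 5′ of it; a GC-rich TR section (55.52% A+T) tiled with a 175-bp motif —
nine full copies plus a partial on the 1,729-bp span of the *S. longifissa*
table — mutated at 2% per unit, the motif carrying a 58-aa ORF from AAA
(Lys) to GTG (Val) terminated by the junction codon; and a *trnS(UCN)*
pseudogene placed in the spacer before *nad1*, evolved from the same
ancestor as the functional copy at twice its Jukes–Cantor branch length
(0.3 vs 0.6), with a THYTHDA-matching literal planted downstream of *nad1*.

Non-control-region ("coding") base frequencies are solved so the mixture of
background + ATR + TR hits the genome-wide targets exactly in expectation;
the realized coding-strand targets are recorded in the truth record, since
P_4fd skews recover the coding-strand pressure, not the genome-wide mixture.
Regions are filled by exact-count shuffles, so composition targets are met
to rounding; protein-coding genes are then rewritten codon-by-codon
(rejection-sampled against stops, constraint-aware across the −7 bp gene
overlaps, with printed start/stop codons planted), which adds roughly half a
percent of sampling drift to genome-wide A+T — visible as ~68.2% measured
versus the 69.05% target.  Unplanned T (and A) homopolymers at or above the
planted length are broken so the planted stretch is the unique longest
signal.  Everything is deterministic under the config seed, including the
GenBank output byte-for-byte.

What the generator does **not** emulate: real tRNA/rRNA secondary structure,
codon usage beyond base frequencies, selection, indels, and heteroplasmy.
Passing recovery tests therefore demonstrates correctness of the scanners
and estimators under the stated composition/architecture model, not
robustness to every feature of real sequencing data.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 18-kb
genomes, 1,000-site rate-test alignments with 500 null and 200 alternative
replicates, brute-force oracle comparisons on sequences ≤ 20 nt (hairpins),
≤ 6 tokens (TDRL), and 300-codon CDSs.  The full suite completes in a few
seconds.
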