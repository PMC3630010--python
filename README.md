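# mitocomp

Comparative analysis of insect mitochondrial genomes, built around the two
unusually large katydid (bush-katydid, genus *Sinochlora*) mitogenomes
deposited as GenBank KC467055 (*S. longifissa*, 18,133 bp) and KC467056
(*S. retrolateralis*, 17,209 bp).  These genomes combine a derived gene order
(*rrnS*–*trnI*–*trnM*–*nad2*–CR–*trnQ*–*trnW* instead of the ancestral
*rrnS*–CR–*trnI*–*trnQ*–*trnM*–*nad2*–*trnW*), a control region split into an
A+T-rich section (ATR) and a GC-rich ~175-bp tandem-repeat section (TR), a
fast-evolving *trnS(UCN)* pseudogene, and replication-origin recognition
sequences of two kinds (a long T-stretch near a hairpin, or a (T)nC(T)n
variant inside one).

The package is for molecular evolution researchers who want each of those
analyses as tested, reusable functions rather than a chain of one-off GUI
tools:

- **genome_io** — GenBank/FASTA/gene-table (TSV) reading and writing on
  1-based inclusive coordinates; strand-aware region extraction on a circular
  genome; gene-name normalization (ND2/COI/12S → nad2/cox1/rrnS).  The two
  published annotation tables ship with the package
  (`mitocomp.packaged_table("sl" | "sr")`).
- **composition** — base counts, A+T content, and strand skews
  (AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C)), including skew at
  fourfold-degenerate third codon positions (P_4fd), the standard proxy for
  neutral mutational pressure.
- **annotation_geometry** — intergenic spacers and overlaps (the −7 bp
  atp8/atp6 and nad4L/nad4 overlaps), plus start/stop codon extraction and
  classification (standard ATN vs TCT/CTG/TTG starts; complete TAA/TAG vs
  truncated T/TA stops).
- **gene_order** — signed circular gene orders over the canonical 37-gene +
  CR alphabet, breakpoint counts, and an exhaustive tandem-duplication /
  random-loss (TDRL) scenario search with transcription-polarity
  classification of the lost copies.
- **repeats** — deterministic tandem-repeat detection (k-mer offset
  candidates → period scoring → majority consensus → fractional copy
  number) and six-frame ORF scanning of repeat motifs in tandem context.
- **structure_scan** — T-stretch and (T)nC(T)n-variant scanners, a
  constraint-based perfect inverted-repeat (hairpin) enumerator, IUPAC
  degenerate-motif search (e.g. the THYTHDA mtTERM candidate), and
  replication-origin signature classification with katydid / cricket /
  grasshopper presets.
- **pseudogene_rates** — Needleman–Wunsch global alignment, Jukes–Cantor
  distances with sampling variances, a two-lineage relative-rate test
  against an outgroup, and exhaustive minimum-evolution trees (≤ 8 taxa,
  OLS branch lengths).
- **synthetic_data** — a seeded generator that emits fully annotated
  synthetic mitogenomes on the published coordinates, with planted skews,
  T-stretches, hairpins, tandem repeats, a repeat ORF, and a pseudogene
  evolving at a configurable rate multiple — so every stage is testable
  with known truth and no downloads.

## Worked example

```python
import mitocomp as mc

# a synthetic S. longifissa-style genome with known ground truth
genome, truth = mc.build_genome(mc.preset_config("sl", seed=1))

stats = mc.base_composition(genome.sequence)
print(len(genome), round(stats.at_content, 2), round(stats.gc_skew, 4))
# 18133 68.2 -0.3007     <- genome length; A+T %; strong C skew on J

order = mc.order_signature(genome.features)
scenarios = mc.tdrl_search(mc.ANCESTRAL_ORDER, order, max_block_len=6)
best = [s for s in scenarios if s.block_len == 5][0]
print([t[0] for t in best.block_tokens], mc.classify_loss_pattern(best))
# ['CR', 'trnI', 'trnQ', 'trnM', 'nad2'] non_random_polarity_consistent

tr = mc.extract_region(genome, genome.feature("CR_TR"))
hit = mc.find_tandem_repeats(tr)[0]
print(hit.period, hit.full_copies, hit.copy_number)
# 175 9 9.88              <- nine full 175-bp copies plus a partial copy

orf = [o for o in mc.consensus_orf_scan(hit.consensus) if o.aa_length == 58][0]
print(orf.protein[0], orf.protein[-1])
# K V                     <- repeat ORF starts with lysine, ends with valine
```

The one-event TDRL scenario above is the duplication of the
CR–*trnI*–*trnQ*–*trnM*–*nad2* block followed by loss of one copy of each
gene; every deleted run shares transcriptional polarity, i.e. the loss
pattern is consistent with transcription-coupled (non-random) deletion.

A command-line interface mirrors the library
(`mitocomp simulate | stats | codons | order | repeats | scan | rates | all`).

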