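"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
majority (J) strand.  Skew at fourfold-degenerate third codon positions
(P_4fd) isolates mutational pressure from selection: at those sites any of
the four bases is synonymous under the invertebrate mitochondrial code, so
their composition approximates the neutral equilibrium of each strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

from .genome_io import GeneFeature, MitoGenome, extract_region

INVERT_MITO_TABLE_ID = 5


@dataclass
class CompositionStats:
    a: int
    c: int
    g: int
    t: int
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        """Percent A+T of counted (non-N) bases."""
        return 100.0 * (self.a + self.t) / self.total

    @property
    def at_skew(self) -> float:
        at = self.a + self.t
        if at == 0:
            raise ZeroDivisionError("AT skew undefined: no A or T bases")
        return (self.a - self.t) / at

    @property
    def gc_skew(self) -> float:
        gc = self.g + self.c
        if gc == 0:
            raise ZeroDivisionError("GC skew undefined: no G or C bases")
        return (self.g - self.c) / gc

    def report_row(self) -> dict:
        """Printed at the field's customary precision: skews to 4 decimals,
        percentages to 2."""
        return {
            "A": self.a, "C": self.c, "G": self.g, "T": self.t,
            "n_excluded": self.n_excluded,
            "at_content": round(self.at_content, 2),
            "at_skew": round(self.at_skew, 4),
            "gc_skew": round(self.gc_skew, 4),
        }


def base_composition(seq: str) -> CompositionStats:
    """Counts and skews for a DNA string; N bases are excluded from counts."""
    seq = seq.upper()
    stats = CompositionStats(seq.count("A"), seq.count("C"),
                             seq.count("G"), seq.count("T"),
                             n_excluded=seq.count("N"))
    if stats.total == 0:
        raise ValueError("sequence contains no countable (non-N) bases")
    return stats


def _fourfold_prefixes(code_id: int = INVERT_MITO_TABLE_ID) -> frozenset[str]:
    """Codon-family prefixes (first two bases) whose four codons all encode
    the same amino acid under the given code (no stop among them)."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    prefixes = set()
    for a in "ACGT":
        for b in "ACGT":
            aas = set()
            for c in "ACGT":
                codon = a + b + c
                if codon in table.stop_codons:
                    aas.add("*")
                else:
                    aas.add(table.forward_table[codon])
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(a + b)
    return frozenset(prefixes)


def fourfold_third_positions(cds: str, code_id: int = INVERT_MITO_TABLE_ID) -> list[int]:
    """0-based codon indices whose family is fourfold degenerate.

    ``cds`` is read in its own orientation; a trailing incomplete codon (the
    truncated T/TA stop) is ignored.  An internal stop before the final codon
    triggers a warning (the annotation is suspect), not an error.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    table = CodonTable.unambiguous_dna_by_id[code_id]
    prefixes = _fourfold_prefixes(code_id)
    n_codons = len(cds) // 3
    hits: list[int] = []
    internal_stops: list[int] = []
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in table.stop_codons and i < n_codons - 1:
            internal_stops.append(i)
        if codon[:2] in prefixes:
            hits.append(i)
    if internal_stops:
        warnings.warn(f"internal stop codon(s) at codon index {internal_stops}")
    return hits


def skew_at_p4fd(genome: MitoGenome, genes: list[GeneFeature] | None = None,
                 include_n_strand: bool = False,
                 code_id: int = INVERT_MITO_TABLE_ID) -> CompositionStats:
    """Pooled composition of the third bases of fourfold-degenerate codons,
    read on the J strand.

    By default only J-strand protein-coding genes contribute (the standard
    way P_4fd skews are reported for mitogenomes); ``include_n_strand``
    additionally projects minority-strand genes onto J, for exploration.
    """
    if genes is None:
        genes = [f for f in genome.features if f.category == "PCG"]
    pooled: list[str] = []
    for f in genes:
        if f.category != "PCG":
            continue
        if f.strand == "N" and not include_n_strand:
            continue
        cds = extract_region(genome, f)
        for i in fourfold_third_positions(cds, code_id):
            base = cds[3 * i + 2]
            if f.strand == "N":
                base = {"A": "T", "T": "A", "G": "C", "C": "G"}[base]
            pooled.append(base)
    if not pooled:
        raise ValueError("no fourfold-degenerate sites in the selected genes")
    return base_composition("".join(pooled))


def composition_report(genome: MitoGenome) -> list[dict]:
    """One composition row per feature plus a whole-J-strand row (the whole
    strand, control region included)."""
    rows = [{"region": "whole_J_strand",
             **base_composition(genome.sequence).report_row()}]
    for f in genome.features:
        stats = base_composition(extract_region(genome, f))
        rows.append({"region": f.name, **stats.report_row()})
    return rows
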