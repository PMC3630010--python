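"""Replication-origin recognition-sequence scanners.

Insect mtDNA replication origins are marked either by a long thymine
homopolymer (T-stretch) in or next to a stem-loop, or by a T-stretch variant
— a (T)nC(T)n run with isolated T->C transitions — inside a stem-loop.
This module provides the corresponding scanners: maximal T runs, interrupted
T runs, a constraint-based inverted-repeat (hairpin) enumerator with perfect
Watson-Crick stems, and degenerate IUPAC motif search on both strands.

All coordinates are 1-based inclusive on the supplied sequence; minority-
strand (N) hits are found on the reverse complement and mapped back.
Tie-breaking everywhere is leftmost, then longest, then most GC pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .genome_io import revcomp


@dataclass
class TStretchHit:
    start: int
    length: int
    strand: str
    kind: str     # pure | variant
    pattern: str  # matched text (J-strand reading for J, N reading for N)


@dataclass
class HairpinHit:
    arm1_start: int
    arm2_start: int
    stem_len: int
    loop_len: int
    gc_pairs: int

    @property
    def total_len(self) -> int:
        return 2 * self.stem_len + self.loop_len

    @property
    def span(self) -> tuple[int, int]:
        return self.arm1_start, self.arm2_start + self.stem_len - 1


@dataclass
class MotifHit:
    start: int
    strand: str
    matched: str
    pattern: str


def _map_back(start0: int, length: int, n: int) -> int:
    """1-based start on the forward sequence of a hit found at 0-based
    ``start0`` on the reverse complement."""
    return n - (start0 + length) + 1


def find_t_stretches(seq: str, min_len: int = 8, strand: str = "J") -> list[TStretchHit]:
    """Maximal pure T runs of at least ``min_len`` on the requested strand."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = seq.upper()
    scan = seq if strand == "J" else revcomp(seq)
    hits = []
    for m in re.finditer(rf"T{{{min_len},}}", scan):
        length = m.end() - m.start()
        start = m.start() + 1 if strand == "J" else _map_back(m.start(), length, len(seq))
        hits.append(TStretchHit(start, length, strand, "pure", m.group()))
    hits.sort(key=lambda h: (h.start, -h.length))
    return hits


def find_t_variants(seq: str, min_total: int = 13, max_interruptions: int = 2,
                    min_flank_run: int = 1, strand: str = "J") -> list[TStretchHit]:
    """(T)nC(T)n-style runs: T runs interrupted by isolated single C's.

    Within each maximal chain of T runs separated by single C's, the best
    window using at most ``max_interruptions`` C's is reported (leftmost,
    then longest).  Each interrupting C must carry at least
    ``min_flank_run`` T's on both sides.  Pure runs that meet ``min_total``
    are reported with kind ``pure``.
    """
    if min_total < 3:
        raise ValueError("min_total must be >= 3")
    seq = seq.upper()
    scan = seq if strand == "J" else revcomp(seq)
    hits: list[TStretchHit] = []
    for chain in re.finditer(r"T+(?:CT+)*", scan):
        runs = [len(r) for r in chain.group().split("C")]
        # best window of consecutive runs joined by <= max_interruptions C's
        best: tuple[int, int] | None = None  # (start_run_idx, end_run_idx)
        best_len = 0
        for i in range(len(runs)):
            for j in range(i, min(len(runs), i + max_interruptions + 1)):
                if any(runs[k] < min_flank_run for k in range(i, j + 1)) and j > i:
                    continue
                total = sum(runs[i:j + 1]) + (j - i)
                if total > best_len:
                    best_len, best = total, (i, j)
        if best is None or best_len < min_total:
            continue
        i, j = best
        offset = sum(runs[:i]) + i  # bases before the window within the chain
        start0 = chain.start() + offset
        text = scan[start0:start0 + best_len]
        kind = "pure" if "C" not in text else "variant"
        start = start0 + 1 if strand == "J" else _map_back(start0, best_len, len(seq))
        hits.append(TStretchHit(start, best_len, strand, kind, text))
    hits.sort(key=lambda h: (h.start, -h.length))
    return hits


_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_hairpins(seq: str, stem_min: int = 3, stem_max: int = 12,
                  loop_min: int = 3, loop_max: int = 11,
                  min_gc_pairs: int = 0, max_hits: int = 10000) -> list[HairpinHit]:
    """Exhaustive perfect inverted-repeat scan within the stated bounds.

    Arms must pair base-for-base (A.T and G.C only; no mismatches, bulges or
    wobble).  Results are sorted by arm1 position, then total length
    descending, then GC pairs descending, and truncated at ``max_hits``.
    """
    if stem_min < 3 or loop_min < 3:
        raise ValueError("stem_min and loop_min must be >= 3")
    seq = seq.upper()
    n = len(seq)
    hits: list[HairpinHit] = []
    for i in range(n):
        for s in range(stem_min, stem_max + 1):
            if i + s > n:
                break
            arm1 = seq[i:i + s]
            for l in range(loop_min, loop_max + 1):
                j = i + s + l
                if j + s > n:
                    break
                arm2 = seq[j:j + s]
                if all(_PAIR.get(a) == b for a, b in zip(arm1, reversed(arm2))):
                    gc = sum(1 for b in arm1 if b in "GC")
                    if gc >= min_gc_pairs:
                        hits.append(HairpinHit(i + 1, j + 1, s, l, gc))
    hits.sort(key=lambda h: (h.arm1_start, -h.total_len, -h.gc_pairs))
    return hits[:max_hits]


_IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


def _iupac_regex(pattern: str) -> str:
    out = []
    for ch in pattern.upper():
        if ch not in _IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {ch!r}")
        exp = ambiguous_dna_values[ch]
        out.append(ch if len(exp) == 1 else f"[{exp}]")
    return "".join(out)


def iupac_find(seq: str, pattern: str) -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC degenerate pattern on
    both strands."""
    seq = seq.upper()
    rx = re.compile(f"(?=({_iupac_regex(pattern)}))")
    hits = []
    m_len = len(pattern)
    for m in rx.finditer(seq):
        hits.append(MotifHit(m.start() + 1, "J", m.group(1), pattern))
    rc = revcomp(seq)
    for m in rx.finditer(rc):
        hits.append(MotifHit(_map_back(m.start(), m_len, len(seq)), "N",
                             m.group(1), pattern))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


#: scanner parameter bundles for the three orthopteran CR styles
PRESETS = {
    # katydids: long pure T-stretch (>= 10 nt) in or adjacent to a hairpin
    "katydid": {"t_stretch_min": 10, "variant_min_total": 13,
                "max_interruptions": 2, "stem_min": 3, "stem_max": 12,
                "loop_min": 3, "loop_max": 11, "min_gc_pairs": 1,
                "gap_max": 20},
    # crickets: 13-19 nt (T)nC(T)n variant inside a stem-loop
    "cricket": {"t_stretch_min": 13, "variant_min_total": 13,
                "max_interruptions": 2, "stem_min": 3, "stem_max": 12,
                "loop_min": 3, "loop_max": 15, "min_gc_pairs": 1,
                "gap_max": 20},
    # grasshoppers: 16-18 nt variants inside a stem-loop
    "grasshopper": {"t_stretch_min": 16, "variant_min_total": 16,
                    "max_interruptions": 2, "stem_min": 3, "stem_max": 12,
                    "loop_min": 3, "loop_max": 15, "min_gc_pairs": 1,
                    "gap_max": 20},
}


def classify_or_signature(cr_seq: str, preset: str | dict = "katydid") -> str:
    """Classify the replication-origin recognition signature of a control
    region (or its A+T-rich section).

    Returns ``long_T_stretch_type`` if a pure T-stretch of preset length
    lies inside or within ``gap_max`` bp of a hairpin; ``T_variant_in_
    stem_loop_type`` if an interrupted (T)nC(T)n variant overlaps a hairpin
    span; otherwise ``none``.  Both strands are scanned.
    """
    p = PRESETS[preset] if isinstance(preset, str) else preset
    pins = find_hairpins(cr_seq, p["stem_min"], p["stem_max"],
                         p["loop_min"], p["loop_max"], p["min_gc_pairs"])
    spans = [h.span for h in pins]

    def near(start: int, length: int, gap: int) -> bool:
        lo, hi = start, start + length - 1
        return any(lo <= b + gap and hi >= a - gap for a, b in spans)

    for strand in ("J", "N"):
        for t in find_t_stretches(cr_seq, p["t_stretch_min"], strand):
            if near(t.start, t.length, p["gap_max"]):
                return "long_T_stretch_type"
    for strand in ("J", "N"):
        for t in find_t_variants(cr_seq, p["variant_min_total"],
                                 p["max_interruptions"], strand=strand):
            if t.kind == "variant" and near(t.start, t.length, 0):
                return "T_variant_in_stem_loop_type"
    return "none"
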