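"""Tandem-repeat detection and ORF scanning in repeat motifs.

The detector targets the near-perfect minisatellite arrays found in insect
mitochondrial control regions (here, an ~175-bp GC-rich unit repeated in
tandem).  It proposes candidate periods from exact k-mer offset statistics,
scores a period by direct seq[i] == seq[i+p] agreement, builds a per-column
majority consensus over the full units, and reports fractional copy number.
There is no wraparound indel alignment: units are assumed colinear, which is
exact for the near-identical arrays this targets and keeps every result
reproducible by hand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .composition import INVERT_MITO_TABLE_ID
from .genome_io import revcomp


@dataclass
class TandemRepeatHit:
    start: int   # 1-based inclusive
    end: int
    period: int
    copy_number: float
    consensus: str
    identity: float  # mean per-unit % identity against the consensus

    @property
    def full_copies(self) -> int:
        return (self.end - self.start + 1) // self.period


@dataclass
class OrfHit:
    frame: int          # 0..2 within the scanned sequence
    strand: str         # J or N
    start: int          # 1-based nt position of the first codon (mod period
    aa_length: int      # in tandem context)
    start_codon: str
    stop_codon: str | None  # None = open-ended run
    protein: str


def _candidate_periods(seq: str, k: int, min_period: int, max_period: int) -> list[int]:
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i:i + k]].append(i)
    offsets: Counter[int] = Counter()
    for plist in pos.values():
        for a, b in zip(plist, plist[1:]):
            d = b - a
            if min_period <= d <= max_period:
                offsets[d] += 1
    # smallest periods first so the fundamental period wins over multiples
    return sorted(p for p, c in offsets.items() if c >= 2)


def _region_at_period(seq: str, p: int, min_identity: float) -> list[tuple[int, int]]:
    """Maximal intervals [i, j) where a sliding period-length window of the
    match array m[i] = (seq[i] == seq[i+p]) stays at or above min_identity."""
    n = len(seq)
    if n < 2 * p:
        return []
    m = [seq[i] == seq[i + p] for i in range(n - p)]
    win = sum(m[:p])
    good = []
    thresh = min_identity / 100.0 * p
    for i in range(len(m) - p + 1):
        if i:
            win += m[i + p - 1] - m[i - 1]
        good.append(win >= thresh)
    regions = []
    i = 0
    while i < len(good):
        if good[i]:
            j = i
            while j + 1 < len(good) and good[j + 1]:
                j += 1
            # matched pairs run i..j+p-1; array spans both copies
            regions.append((i, j + p - 1 + p + 1))  # [start, end) in sequence
            i = j + 1
        else:
            i += 1
    return regions


def _consensus(seq: str, start: int, end: int, p: int) -> tuple[str, float]:
    units = [seq[start + j * p:start + (j + 1) * p]
             for j in range((end - start) // p)]
    units = [u for u in units if len(u) == p]
    cols = []
    for c in range(p):
        counts = Counter(u[c] for u in units)
        top = max(counts.values())
        cols.append(min(b for b, n in counts.items() if n == top))
    cons = "".join(cols)
    ident = 100.0 * sum(sum(a == b for a, b in zip(u, cons)) for u in units) \
        / (len(units) * p)
    return cons, ident


def _trim_partial(seq: str, start: int, end: int, p: int, cons: str) -> int:
    """Extend/trim the trailing partial unit to the last base matching the
    consensus phase."""
    j = end
    while j < len(seq) and seq[j] == cons[(j - start) % p]:
        j += 1
    while j > start + p and seq[j - 1] != cons[(j - 1 - start) % p]:
        j -= 1
    return j


def find_tandem_repeats(seq: str, min_period: int = 10, max_period: int = 500,
                        min_copies: float = 1.9, min_identity: float = 80.0,
                        k: int = 8) -> list[TandemRepeatHit]:
    """Deterministic tandem-repeat scan (leftmost-longest tie-break).

    The reported period is the smallest candidate whose consensus tiling
    meets ``min_identity``, so a 2x-period harmonic is never reported when
    the fundamental period explains the array.
    """
    seq = seq.upper()
    hits: list[TandemRepeatHit] = []
    claimed: list[tuple[int, int]] = []
    for p in _candidate_periods(seq, k, min_period, max_period):
        for start, end in _region_at_period(seq, p, min_identity):
            cons, ident = _consensus(seq, start, end, p)
            if ident < min_identity:
                continue
            end = _trim_partial(seq, start, end, p, cons)
            copy = (end - start) / p
            if copy < min_copies:
                continue
            # leftmost-longest: drop hits subsumed by an earlier (smaller-
            # period or leftward) accepted hit
            if any(start >= a and end <= b for a, b in claimed):
                continue
            hits.append(TandemRepeatHit(start + 1, end, p, round(copy, 3),
                                        cons, round(ident, 2)))
            claimed.append((start, end))
    hits.sort(key=lambda h: (h.start, -(h.end - h.start)))
    return hits


def rotations(s: str) -> set[str]:
    return {s[i:] + s[:i] for i in range(len(s))}


# ---------------------------------------------------------------------------
# ORF scanning


def consensus_orf_scan(motif: str, code_id: int = INVERT_MITO_TABLE_ID,
                       min_aa: int = 30, tandem_context: bool = True,
                       restrict_starts: bool = False) -> list[OrfHit]:
    """Maximal stop-free runs >= min_aa in all six frames of a repeat motif.

    With ``tandem_context`` the motif is doubled before scanning so frames
    spanning the unit junction are caught, and start coordinates are mapped
    back modulo the period.  An ORF here is a maximal stop-free run whose
    first codon is the start (any codon, matching the AAA-initiated repeat
    ORF usage); ``restrict_starts`` limits starts to ATN/GTG/TTG.
    """
    motif = motif.upper()
    p = len(motif)
    table = CodonTable.unambiguous_dna_by_id[code_id]
    hits: list[OrfHit] = []
    seen: set[tuple] = set()
    for strand in ("J", "N"):
        s = motif if strand == "J" else revcomp(motif)
        scan = s + s if tandem_context else s
        for frame in range(3):
            i = frame
            run_start = i
            run: list[str] = []
            while i + 3 <= len(scan):
                codon = scan[i:i + 3]
                if codon in table.stop_codons:
                    _emit(hits, seen, run, run_start, codon, frame, strand,
                          p, min_aa, restrict_starts, table)
                    run = []
                    run_start = i + 3
                else:
                    run.append(codon)
                i += 3
            _emit(hits, seen, run, run_start, None, frame, strand,
                  p, min_aa, restrict_starts, table)
    hits.sort(key=lambda h: (h.strand, h.frame, h.start))
    return hits


_START_SET_PREFIXES = ("AT",)
_ALT_STARTS = ("GTG", "TTG")


def _emit(hits, seen, run, run_start, stop, frame, strand, period, min_aa,
          restrict_starts, table) -> None:
    if len(run) < min_aa:
        return
    if restrict_starts:
        while run and not (run[0].startswith(_START_SET_PREFIXES)
                           or run[0] in _ALT_STARTS):
            run = run[1:]
            run_start += 3
        if len(run) < min_aa:
            return
    protein = str(Seq("".join(run)).translate(table=table.id))
    start_1 = run_start % period + 1
    key = (strand, start_1, len(run))
    if key in seen:
        return
    seen.add(key)
    hits.append(OrfHit(frame, strand, start_1, len(run), run[0],
                       stop, protein))
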