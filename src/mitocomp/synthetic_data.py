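"""Synthetic mitogenomes with known ground truth for every pipeline stage.

The generator emulates the architecture of large katydid mitogenomes: a
compact gene complement laid out on printed annotation coordinates, a
control region split into an A+T-rich section (ATR, ~75% A+T) carrying a
long T-stretch and hairpins, and a GC-rich tandem-repeat section (TR) built
from an ~175-bp unit repeated in tandem with a trailing partial copy, plus
a pseudogenized tRNA paralog evolving at an elevated rate in the spacer
between trnS(UCN) and nad1.  Default parameters are the measured properties
of the two deposited genomes (KC467055 / KC467056); every random draw is
fixed by the config seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from .composition import INVERT_MITO_TABLE_ID
from .genome_io import (GeneFeature, GeneTable, MitoGenome, packaged_table,
                        revcomp)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}


def base_freqs(at_content: float, at_skew: float = 0.0,
               gc_skew: float = 0.0) -> np.ndarray:
    """Per-strand base frequencies (A, C, G, T) realizing the given A+T
    content (fraction) and skews."""
    if not 0 < at_content < 1:
        raise ValueError("at_content must be a fraction in (0,1)")
    at, gc = at_content, 1.0 - at_content
    f = np.array([at * (1 + at_skew) / 2, gc * (1 - gc_skew) / 2,
                  gc * (1 + gc_skew) / 2, at * (1 - at_skew) / 2])
    if (f < 0).any():
        raise ValueError("skew targets imply negative frequencies")
    return f


def sample_sequence(length: int, freqs: np.ndarray | tuple,
                    rng: np.random.Generator, exact: bool = False) -> str:
    """Random DNA of the given composition: i.i.d. draws by default, or an
    exact-count shuffle (``exact``) whose realized composition matches the
    target to rounding."""
    freqs = np.asarray(freqs, dtype=float)
    if length <= 0:
        raise ValueError("length must be positive")
    if exact:
        counts = np.floor(freqs / freqs.sum() * length).astype(int)
        while counts.sum() < length:
            counts[np.argmax(freqs * length - counts)] += 1
        arr = np.repeat(BASES, counts)
        rng.shuffle(arr)
    else:
        arr = rng.choice(BASES, size=length, p=freqs / freqs.sum())
    return arr.tobytes().decode()


def mutate_jc(seq: str, d: float, rng: np.random.Generator) -> str:
    """Evolve a sequence to Jukes-Cantor distance d: each site substitutes
    with probability (3/4)(1 - e^(-4d/3)), uniformly to another base."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    hit = rng.random(arr.size) < p_change
    if hit.any():
        idx = np.array([_IDX.get(chr(b), 0) for b in arr[hit]], dtype=int)
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


@dataclass
class HairpinSpec:
    stem: int = 8
    loop: int = 9
    gc_pairs: int = 4


@dataclass
class SynthConfig:
    """Study-condition defaults (the S. longifissa architecture)."""

    seed: int = 0
    table: str | GeneTable = "sl"
    # genome-wide J-strand targets (fractions / dimensionless)
    genome_at: float = 0.6905
    genome_at_skew: float = 0.0017
    genome_gc_skew: float = -0.2983
    # A+T-rich CR section
    atr_at: float = 0.7570
    t_stretch_len: int = 19
    n_hairpins: int = 3
    hairpin: HairpinSpec = field(default_factory=HairpinSpec)
    # GC-rich tandem-repeat CR section
    tr_at: float = 0.5552
    motif_len: int = 175
    per_unit_mut: float = 0.02
    plant_orf: bool = True
    orf_aa: int = 58
    # pseudogene paralog of trnS(UCN)
    pseudo_d_func: float = 0.3
    pseudo_rate_multiplier: float = 2.0
    code_id: int = INVERT_MITO_TABLE_ID


def preset_config(which: str = "sl", seed: int = 0) -> SynthConfig:
    if which == "sl":
        return SynthConfig(seed=seed)
    if which == "sr":
        return SynthConfig(seed=seed, table="sr", genome_at=0.7008,
                           genome_at_skew=0.0063, genome_gc_skew=-0.3218,
                           atr_at=0.7561, t_stretch_len=21, tr_at=0.5826,
                           plant_orf=False)
    raise KeyError(which)


@dataclass
class TruthRecord:
    """Everything planted, for truth-vs-recovered regression tests."""

    genome_at: float
    genome_at_skew: float
    genome_gc_skew: float
    # realized coding-strand (background) targets, which differ from the
    # genome-wide ones because the CR sections have their own compositions
    coding_at: float
    coding_at_skew: float
    coding_gc_skew: float
    atr_span: tuple[int, int]
    tr_span: tuple[int, int]
    atr_at: float
    t_stretch: tuple[int, int]          # (1-based start, length), J strand
    hairpins: list[tuple[int, int, int]]  # (arm1_start, stem, loop)
    motif: str
    n_full_copies: int
    partial_len: int
    copy_number: float
    orf: tuple[int, int] | None         # (codon offset in motif, aa length)
    pseudogene_span: tuple[int, int] | None
    rate_multiplier: float
    or_signature: str = "long_T_stretch_type"


# ---------------------------------------------------------------------------
# building blocks


def _make_hairpin(spec: HairpinSpec, rng: np.random.Generator) -> str:
    pos = rng.choice(spec.stem, size=spec.gc_pairs, replace=False)
    arm = ["A" if rng.random() < 0.5 else "T" for _ in range(spec.stem)]
    for p in pos:
        arm[p] = "G" if rng.random() < 0.5 else "C"
    arm = "".join(arm)
    # an A+T loop with one C so the loop cannot extend a T run into the stem
    loop = "C" + sample_sequence(spec.loop - 1, base_freqs(0.9), rng)
    return arm + loop + revcomp(arm)


def _build_atr(length: int, cfg: SynthConfig, rng: np.random.Generator
               ) -> tuple[str, dict]:
    """A+T-rich section: hairpins, then the long J-strand T-stretch in the
    initial quarter, mirroring the conserved katydid ATR layout."""
    seq = np.frombuffer(
        sample_sequence(length, base_freqs(cfg.atr_at), rng, exact=True).encode(),
        dtype=np.uint8).copy()
    hairpins = []
    cursor = max(0, length // 4 - cfg.n_hairpins * (cfg.hairpin.stem * 2
                                                    + cfg.hairpin.loop + 6) - cfg.t_stretch_len - 10)
    for _ in range(cfg.n_hairpins):
        hp = _make_hairpin(cfg.hairpin, rng)
        seq[cursor:cursor + len(hp)] = np.frombuffer(hp.encode(), dtype=np.uint8)
        hairpins.append((cursor + 1, cfg.hairpin.stem, cfg.hairpin.loop))
        cursor += len(hp) + 3 + int(rng.integers(0, 3))
    t_start = cursor + 2
    t = cfg.t_stretch_len
    if t_start + t + 1 >= length:
        raise ValueError("ATR too short for the configured hairpins + T-stretch")
    seq[t_start:t_start + t] = ord("T")
    seq[t_start - 1] = ord("A")          # keep the run maximal
    seq[t_start + t] = ord("A")
    protected = set(range(max(0, t_start - 1), t_start + t + 1))
    for a, s, l in hairpins:
        protected |= set(range(a - 1, a - 1 + 2 * s + l))
    _scrub_runs(seq, "T", t, protected, rng)
    _scrub_runs(seq, "A", t, protected, rng)
    truth = {"t_stretch": (t_start + 1, t), "hairpins": hairpins}
    return seq.tobytes().decode(), truth


def _scrub_runs(arr: np.ndarray, base: str, max_len: int, protected: set[int],
                rng: np.random.Generator) -> None:
    """Break unplanned homopolymer runs of ``base`` reaching ``max_len`` so
    planted stretches stay the unique longest signal."""
    s = arr.tobytes().decode()
    for m in re.finditer(f"{base}{{{max_len},}}", s):
        span = range(m.start(), m.end())
        free = [i for i in span if i not in protected]
        if not free:
            continue
        for i in free[::max_len - 1] if max_len > 1 else free:
            arr[i] = ord("C") if base in "TA" else ord("A")


def _make_motif(cfg: SynthConfig, rng: np.random.Generator
                ) -> tuple[str, tuple[int, int] | None]:
    """One tandem-repeat unit; optionally carrying an ORF that spans nearly
    the whole unit (first codon AAA/Lys, last GTG/Val, junction stop)."""
    p = cfg.motif_len
    if not cfg.plant_orf:
        return sample_sequence(p, base_freqs(cfg.tr_at), rng, exact=True), None
    table = CodonTable.unambiguous_dna_by_id[cfg.code_id]
    n_aa = cfg.orf_aa
    if 3 * n_aa + 1 > p:
        raise ValueError("ORF does not fit in the repeat unit")
    codons = ["AAA"]
    while len(codons) < n_aa - 1:
        c = sample_sequence(3, base_freqs(cfg.tr_at), rng)
        if c not in table.stop_codons:
            codons.append(c)
    codons.append("GTG")
    tail_len = p - 3 * n_aa
    tail = ""
    if tail_len:
        tail = "T" + (sample_sequence(tail_len - 1, base_freqs(cfg.tr_at), rng)
                      if tail_len > 1 else "")
    # the frame-0 codon after the ORF is motif[3*n_aa..] starting with T, or
    # (tail-less) the junction codon T+AA = TAA; either way the run stops
    motif = "".join(codons) + tail
    return motif, (0, n_aa)


def _build_tr(length: int, cfg: SynthConfig, rng: np.random.Generator
              ) -> tuple[str, dict]:
    motif, orf = _make_motif(cfg, rng)
    p = cfg.motif_len
    n_full, partial = divmod(length, p)
    parts = []
    for _ in range(n_full):
        parts.append(mutate_jc_point(motif, cfg.per_unit_mut, rng))
    parts.append(motif[:partial])
    truth = {"motif": motif, "n_full_copies": n_full, "partial_len": partial,
             "copy_number": round(length / p, 3), "orf": orf}
    return "".join(parts), truth


def mutate_jc_point(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at a flat rate (no multiple hits) — the 'a few
    point mutations per repeat unit' regime."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.array([_IDX.get(chr(b), 0) for b in arr[hit]], dtype=int)
    arr[hit] = BASES[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# protein-coding genes on fixed coordinates


def _positions(f: GeneFeature, L: int) -> list[int]:
    """0-based genome positions of a feature in reading orientation."""
    if f.start <= f.end:
        pos = list(range(f.start - 1, f.end))
    else:
        pos = list(range(f.start - 1, L)) + list(range(f.end))
    return pos if f.strand == "J" else pos[::-1]


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _write_oriented(arr: np.ndarray, positions: list[int], text: str,
                    strand: str) -> None:
    for pos, ch in zip(positions, text):
        arr[pos] = ord(ch if strand == "J" else _COMP[ch])


def _read_oriented(arr: np.ndarray, positions: list[int], strand: str) -> str:
    s = "".join(chr(arr[p]) for p in positions)
    return s if strand == "J" else "".join(_COMP[c] for c in s)


def _sample_codon(freqs: np.ndarray, fixed: dict[int, str], positions: list[int],
                  strand: str, stops: set[str], rng: np.random.Generator,
                  force: str | None = None) -> str:
    """A codon consistent with already-fixed genome positions; never a stop
    unless ``force`` says otherwise."""
    constraint = []
    for pos in positions:
        if pos in fixed:
            b = fixed[pos]
            constraint.append(b if strand == "J" else _COMP[b])
        else:
            constraint.append(None)
    if force is not None:
        if any(c is not None and c != f for c, f in zip(constraint, force)):
            raise ValueError(f"planted codon {force} conflicts with an "
                             "overlapping feature's fixed bases")
        return force
    for _ in range(64):
        cand = sample_sequence(3, freqs, rng)
        if cand in stops:
            continue
        if all(c is None or c == x for c, x in zip(constraint, cand)):
            return cand
    # exhaustive fallback
    opts = [a + b + c
            for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if (a + b + c) not in stops
            and all(q is None or q == x for q, x in zip(constraint, a + b + c))]
    if not opts:
        raise ValueError("no stop-free codon satisfies overlap constraints")
    return opts[int(rng.integers(len(opts)))]


def _write_pcgs(arr: np.ndarray, table: GeneTable, freqs: np.ndarray,
                cfg: SynthConfig, rng: np.random.Generator) -> None:
    code = CodonTable.unambiguous_dna_by_id[cfg.code_id]
    stops = set(code.stop_codons)
    L = len(arr)
    fixed: dict[int, str] = {}
    pcgs = [f for f in table.features if f.category == "PCG"]
    for f in pcgs:
        # composition targets are J-strand properties: genes read on N draw
        # their codons from the complemented frequency vector (A<->T, C<->G
        # is exactly a reversal of the (A,C,G,T) vector)
        gfreqs = freqs if f.strand == "J" else freqs[::-1]
        pos = _positions(f, L)
        n_codons, rem = divmod(len(pos), 3)
        stop = f.stop_codon or ("TAA" if rem == 0 else "T" * 0)
        for i in range(n_codons):
            cp = pos[3 * i:3 * i + 3]
            if i == 0:
                codon = _sample_codon(gfreqs, fixed, cp, f.strand, stops, rng,
                                      force=f.start_codon or "ATG")
            elif i == n_codons - 1 and rem == 0:
                codon = _sample_codon(gfreqs, fixed, cp, f.strand, stops, rng,
                                      force=stop if stop in stops else "TAA")
            else:
                codon = _sample_codon(gfreqs, fixed, cp, f.strand, stops, rng)
            _write_oriented(arr, cp, codon, f.strand)
        if rem:
            trunc = (f.stop_codon or "T" * rem)[:rem]
            _write_oriented(arr, pos[3 * n_codons:], trunc, f.strand)
        # freeze this gene's start and stop bases against later overwrites
        for p in pos[:3] + pos[-3:]:
            fixed[p] = chr(arr[p])
    _repair_internal_stops(arr, pcgs, fixed, stops, L, rng)


def _repair_internal_stops(arr, pcgs, fixed, stops, L, rng, max_rounds=60):
    for _ in range(max_rounds):
        dirty = False
        for f in pcgs:
            pos = _positions(f, L)
            n_codons = len(pos) // 3
            for i in range(1, n_codons - 1):
                cp = pos[3 * i:3 * i + 3]
                codon = _read_oriented(arr, cp, f.strand)
                if codon in stops:
                    free = [p for p in cp if p not in fixed]
                    if not free:
                        raise ValueError(
                            f"{f.name}: internal stop pinned by overlaps")
                    p = free[int(rng.integers(len(free)))]
                    arr[p] = BASES[int(rng.integers(4))]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("internal-stop repair did not converge")


# ---------------------------------------------------------------------------


def _background_freqs(cfg: SynthConfig, L: int, atr_len: int, tr_len: int
                      ) -> np.ndarray:
    """Background (non-CR) frequencies chosen so the genome-wide mixture of
    background + ATR + TR hits the configured whole-strand targets."""
    want = base_freqs(cfg.genome_at, cfg.genome_at_skew, cfg.genome_gc_skew) * L
    want -= base_freqs(cfg.atr_at) * atr_len
    want -= base_freqs(cfg.tr_at) * tr_len
    rest = L - atr_len - tr_len
    f = want / rest
    if (f <= 0).any():
        raise ValueError("CR composition targets incompatible with genome target")
    return f / f.sum()


#: degenerate motif proposed as the mitochondrial transcription-termination
#: factor binding site downstream of nad1 (IUPAC THYTHDA); planted literal
MTTERM_LITERAL = "TACTAGA"


def build_genome(config: SynthConfig) -> tuple[MitoGenome, TruthRecord]:
    """Emit a fully annotated synthetic mitogenome plus its truth record."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    table = packaged_table(cfg.table) if isinstance(cfg.table, str) else cfg.table
    L = table.genome_length
    atr = table.features[[f.name for f in table.features].index("CR_ATR")]
    tr = table.features[[f.name for f in table.features].index("CR_TR")]
    atr_len, tr_len = atr.length(L), tr.length(L)

    arr = np.frombuffer(
        sample_sequence(L, _background_freqs(cfg, L, atr_len, tr_len), rng,
                        exact=True).encode(), dtype=np.uint8).copy()

    atr_seq, atr_truth = _build_atr(atr_len, cfg, rng)
    arr[atr.start - 1:atr.end] = np.frombuffer(atr_seq.encode(), np.uint8)
    tr_seq, tr_truth = _build_tr(tr_len, cfg, rng)
    arr[tr.start - 1:tr.end] = np.frombuffer(tr_seq.encode(), np.uint8)

    _write_pcgs(arr, table, _background_freqs(cfg, L, atr_len, tr_len), cfg, rng)

    # functional trnS(UCN) + faster-evolving pseudogene copy in the big IGS
    features = [replace(f) for f in table.features]
    pseudo_span = None
    names = [f.name for f in table.features]
    if "trnS_UCN" in names and "nad1" in names:
        fs = table.features[names.index("trnS_UCN")]
        n1 = table.features[names.index("nad1")]
        igs_len = n1.start - fs.end - 1
        t_len = fs.length(L)
        if igs_len >= t_len + len(MTTERM_LITERAL) + 6:
            anc = sample_sequence(t_len, base_freqs(cfg.genome_at), rng)
            func = mutate_jc(anc, cfg.pseudo_d_func, rng)
            pseudo = mutate_jc(anc, cfg.pseudo_d_func * cfg.pseudo_rate_multiplier, rng)
            _write_oriented(arr, _positions(fs, L), func, fs.strand)
            p_start = fs.end + 3  # 1-based
            arr[p_start - 1:p_start - 1 + t_len] = np.frombuffer(
                pseudo.encode(), np.uint8)
            pseudo_span = (p_start, p_start + t_len - 1)
            features.append(GeneFeature("ptrnS_UCN", "pseudogene", fs.strand,
                                        *pseudo_span))
            # mtTERM motif just downstream of nad1 (N-strand gene: before its
            # J-start)
            m_start = n1.start - 1 - len(MTTERM_LITERAL) - 3
            arr[m_start:m_start + len(MTTERM_LITERAL)] = np.frombuffer(
                MTTERM_LITERAL.encode(), np.uint8)

    atr_off = atr.start - 1
    bf = _background_freqs(cfg, L, atr_len, tr_len)
    truth = TruthRecord(
        genome_at=cfg.genome_at, genome_at_skew=cfg.genome_at_skew,
        genome_gc_skew=cfg.genome_gc_skew,
        coding_at=float(bf[0] + bf[3]),
        coding_at_skew=float((bf[0] - bf[3]) / (bf[0] + bf[3])),
        coding_gc_skew=float((bf[2] - bf[1]) / (bf[2] + bf[1])),
        atr_span=(atr.start, atr.end), tr_span=(tr.start, tr.end),
        atr_at=cfg.atr_at,
        t_stretch=(atr_truth["t_stretch"][0] + atr_off,
                   atr_truth["t_stretch"][1]),
        hairpins=[(a + atr_off, s, l) for a, s, l in atr_truth["hairpins"]],
        motif=tr_truth["motif"], n_full_copies=tr_truth["n_full_copies"],
        partial_len=tr_truth["partial_len"],
        copy_number=tr_truth["copy_number"], orf=tr_truth["orf"],
        pseudogene_span=pseudo_span,
        rate_multiplier=cfg.pseudo_rate_multiplier,
    )
    gid = f"synthetic_{cfg.table if isinstance(cfg.table, str) else 'custom'}_seed{cfg.seed}"
    genome = MitoGenome(gid, arr.tobytes().decode(), True, features)
    return genome, truth


def build_cricket_cr(length: int = 800, seed: int = 0,
                     variant: tuple[int, int] = (8, 4)) -> tuple[str, dict]:
    """Synthetic cricket-style control region: a (T)nC(T)m variant forming
    one hairpin arm plus the adjacent loop, with no long pure T-stretch —
    the second replication-origin signature kind."""
    rng = np.random.default_rng(seed)
    n, m = variant
    arr = np.frombuffer(sample_sequence(length, base_freqs(0.70), rng,
                                        exact=True).encode(), np.uint8).copy()
    arm1 = "G" + "T" * n          # one GC pair anchors the stem
    loop = "C" + "T" * m
    hp = arm1 + loop + revcomp(arm1)
    start = length // 2
    arr[start:start + len(hp)] = np.frombuffer(hp.encode(), np.uint8)
    arr[start - 1] = ord("G")
    arr[start + len(hp)] = ord("G")
    protected = set(range(start - 1, start + len(hp) + 1))
    _scrub_runs(arr, "T", n + 1, protected, rng)
    _scrub_runs(arr, "A", n + 1, protected, rng)
    truth = {"variant_start": start + 2, "variant_len": n + 1 + m,
             "hairpin": (start + 1, len(arm1), len(loop)),
             "or_signature": "T_variant_in_stem_loop_type"}
    return arr.tobytes().decode(), truth
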