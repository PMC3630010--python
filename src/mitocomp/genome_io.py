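"""Mitogenome records, annotation tables, and strand-aware sequence access.

Coordinates are 1-based inclusive throughout, following the convention of
published mitogenome annotation tables.  The majority coding strand is called
J and the minority strand N; a feature on N is stored with ``start <= end``
on the J strand and is reverse-complemented on extraction.  Features may wrap
the origin of a circular genome, in which case ``start > end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR_part", "pseudogene", "spacer")

#: canonical feature tokens for the standard insect mitogenome (37 genes + CR)
PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cob", "nad1",
)
TRNA_NAMES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL_UUR", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS_AGN", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS_UCN", "trnL_CUN", "trnV",
)
RRNA_NAMES = ("rrnL", "rrnS")
GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES  # 37 genes

# synonym table: annotation spellings seen in GenBank records -> canonical
_SYNONYMS = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "cox i": "cox1", "cox ii": "cox2", "cox iii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cytb": "cob", "cob": "cob", "cyt b": "cob",
    "atpase6": "atp6", "atpase8": "atp8",
    "12s": "rrnS", "16s": "rrnL", "srrna": "rrnS", "lrrna": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "12s rrna": "rrnS", "16s rrna": "rrnL",
    "12s ribosomal rna": "rrnS", "16s ribosomal rna": "rrnL",
    "d-loop": "CR", "control region": "CR", "a+t rich region": "CR",
    "trnl1": "trnL_CUN", "trnl2": "trnL_UUR",
    "trns1": "trnS_AGN", "trns2": "trnS_UCN",
    "trnl(cun)": "trnL_CUN", "trnl(uur)": "trnL_UUR",
    "trns(agn)": "trnS_AGN", "trns(ucn)": "trnS_UCN",
}
_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_name(raw: str) -> str:
    """Map a gene-name synonym (ND2, COI, 12S rRNA, tRNA-Ser(UCN)...) to its
    canonical token.  Unrecognized names are returned stripped, not rejected,
    so non-standard features survive a round trip."""
    name = raw.strip()
    key = name.lower().replace("-", "").replace("_", "").replace(" ", "")
    flat = {k.replace("-", "").replace("_", "").replace(" ", ""): v
            for k, v in _SYNONYMS.items()}
    if key in flat:
        return flat[key]
    canon = {g.lower(): g for g in GENE_NAMES + ("CR", "CR_ATR", "CR_TR")}
    if name.lower() in canon:
        return canon[name.lower()]
    low = name.lower()
    if low.startswith("trna-") and len(low) >= 8:
        aa = low[5:8]
        if aa in _AA3:
            one = _AA3[aa]
            rest = low[8:].strip("()- ")
            if one == "L":
                return "trnL_CUN" if "cun" in rest else "trnL_UUR"
            if one == "S":
                return "trnS_AGN" if "agn" in rest else "trnS_UCN"
            return f"trn{one}"
    return name


def category_for(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES or (name.startswith("trn") and len(name) > 3):
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in ("CR", "CR_ATR", "CR_TR"):
        return "CR_part"
    if name.startswith("p") and name[1:] in TRNA_NAMES:
        return "pseudogene"
    return "spacer"


@dataclass
class GeneFeature:
    """One annotated feature with 1-based inclusive J-strand coordinates."""

    name: str
    category: str
    strand: str  # "J" or "N"
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def length(self, genome_length: int | None = None) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} wraps the origin; genome length needed")
        return genome_length - self.start + 1 + self.end

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class MitoGenome:
    """A (typically circular) mitochondrial genome plus its feature list."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        for f in self.features:
            for pos in (f.start, f.end):
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(
                        f"feature {f.name}: position {pos} outside [1, {len(self.sequence)}]")
            if f.wraps and not self.circular:
                raise ValueError(f"feature {f.name} wraps a linear genome")
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class GeneTable:
    """Rows of GeneFeature plus each row's printed spacer-to-next value.

    ``discrepancies`` lists rows whose stored spacer disagrees with the one
    recomputed from the coordinates (printed tables do contain typos)."""

    features: list[GeneFeature]
    spacers: list[int]
    genome_length: int | None = None
    discrepancies: list[dict] = field(default_factory=list)

    def recomputed_spacers(self, genome_length: int | None = None) -> list[int]:
        """spacer_i = next.start - this.end - 1; the final row wraps to the
        first feature when a genome length is known (circular accounting)."""
        L = genome_length or self.genome_length
        out = []
        feats = self.features
        for i, f in enumerate(feats):
            if i + 1 < len(feats):
                out.append(feats[i + 1].start - f.end - 1)
            elif L is not None:
                out.append(feats[0].start + L - f.end - 1)
            else:
                out.append(0)
        return out


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a gene-coordinate TSV (columns name, category, strand, start, end,
    spacer, start_codon, stop_codon, anticodon; '.' for missing)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return GeneTable([], [])
    if df.empty:
        return GeneTable([], [])
    feats: list[GeneFeature] = []
    spacers: list[int] = []
    for i, row in df.iterrows():
        strand = row["strand"].strip()
        if strand not in ("J", "N"):
            raise ValueError(f"row {i}: unknown strand token {strand!r}")
        try:
            start, end = int(row["start"]), int(row["end"])
            spacer = int(row["spacer"])
        except ValueError as exc:
            raise ValueError(f"row {i}: non-integer coordinate: {exc}") from exc
        name = normalize_name(row["name"])
        cat = row.get("category", "").strip() or category_for(name)

        def opt(col: str) -> str | None:
            v = row.get(col, ".").strip()
            return None if v in (".", "") else v

        feats.append(GeneFeature(name, cat, strand, start, end,
                                 opt("start_codon"), opt("stop_codon"),
                                 opt("anticodon")))
        spacers.append(spacer)
    # the final printed spacer closes the circle: it fixes the genome length
    genome_length = feats[-1].end + spacers[-1] if feats else None
    table = GeneTable(feats, spacers, genome_length)
    for f, stored, recomp in zip(feats, spacers, table.recomputed_spacers()):
        if stored != recomp:
            table.discrepancies.append(
                {"name": f.name, "stored": stored, "recomputed": recomp})
    return table


def genome_length_from_table(table: GeneTable) -> int:
    """Genome length implied by the final feature's end plus its wrap spacer."""
    if table.genome_length is None:
        raise ValueError("table has no features")
    return table.genome_length


def extract_region(genome: MitoGenome, feature: GeneFeature) -> str:
    """Feature sequence in reading orientation: J verbatim, N reverse-
    complemented; wrapping features are concatenated across the origin."""
    seq = genome.sequence
    if feature.wraps:
        if not genome.circular:
            raise ValueError(f"{feature.name}: wrapping feature on linear genome")
        raw = seq[feature.start - 1:] + seq[:feature.end]
    else:
        raw = seq[feature.start - 1:feature.end]
    return raw if feature.strand == "J" else revcomp(raw)


# ---------------------------------------------------------------------------
# GenBank / FASTA


def _feature_name(bf: SeqFeature) -> str | None:
    for key in ("gene", "product", "note"):
        if key in bf.qualifiers:
            return normalize_name(bf.qualifiers[key][0])
    if bf.type in ("D-loop", "misc_feature"):
        return "CR"
    return None


def read_genbank(path: str | Path) -> MitoGenome:
    """Read a single-record GenBank flat file into a MitoGenome.

    The J strand is operationally the strand carrying cox1: if the record's
    plus strand does not, the whole record is reverse-complemented on load
    (with a logged notice) so downstream skew statistics refer to J.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    seq = str(record.seq).upper()
    feats: list[GeneFeature] = []
    keep_types = {"gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}
    seen: set[str] = set()
    for bf in record.features:
        # 'gene' features duplicate CDS/tRNA/rRNA entries; keep the typed ones
        if bf.type == "gene" or bf.type not in keep_types:
            continue
        name = _feature_name(bf)
        if name is None or name in seen:
            continue
        seen.add(name)
        strand = "J" if (bf.location.strand or 1) >= 0 else "N"
        start = int(bf.location.start) + 1
        end = int(bf.location.end)
        cat = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(
            bf.type, category_for(name))
        feats.append(GeneFeature(name, cat, strand, start, end,
                                 anticodon=bf.qualifiers.get("anticodon", [None])[0]))
    if not feats:
        warnings.warn(f"{path}: record has no usable features")
    genome = MitoGenome(record.id or path.stem, seq, circular, feats)
    cox1 = next((f for f in genome.features if f.name == "cox1"), None)
    if cox1 is not None and cox1.strand == "N":
        log.info("%s: cox1 on minus strand; reverse-complementing record to J", path)
        L = len(seq)
        flipped = [replace(f, strand=("N" if f.strand == "J" else "J"),
                           start=L - f.end + 1, end=L - f.start + 1)
                   for f in genome.features]
        genome = MitoGenome(genome.id, revcomp(seq), circular, flipped)
    return genome


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in genome.features:
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "CR_part": "D-loop", "pseudogene": "misc_feature",
                 "spacer": "misc_feature"}[f.category]
        loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "J" else -1)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


def read_fasta(path: str | Path) -> MitoGenome:
    record = SeqIO.read(str(path), "fasta")
    return MitoGenome(record.id, str(record.seq), circular=True, features=[])


def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
                str(path), "fasta")


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    rows = []
    for f, sp in zip(table.features, table.spacers):
        rows.append({"name": f.name, "category": f.category, "strand": f.strand,
                     "start": f.start, "end": f.end, "spacer": sp,
                     "start_codon": f.start_codon or ".",
                     "stop_codon": f.stop_codon or ".",
                     "anticodon": f.anticodon or "."})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_table(which: str) -> GeneTable:
    """Load one of the bundled annotation tables: 'sl' (S. longifissa,
    KC467055 geometry) or 'sr' (S. retrolateralis, KC467056 geometry)."""
    here = Path(__file__).parent / "data"
    fname = {"sl": "gene_table_sl.tsv", "sr": "gene_table_sr.tsv"}[which]
    return read_gene_table(here / fname)
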