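"""Feature geometry: intergenic spacers / overlaps and start-stop codon calls.

Insect mitogenomes are compact: adjacent genes frequently abut or overlap
(e.g. the seven-nucleotide atp8-atp6 and nad4L-nad4 overlaps), and several
protein-coding genes end on truncated stop codons (T or TA) completed to UAA
by post-transcriptional polyadenylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

from .composition import INVERT_MITO_TABLE_ID
from .genome_io import GeneFeature, MitoGenome, extract_region


@dataclass
class SpacerRecord:
    upstream: str
    downstream: str
    length: int  # negative = overlap, 0 = abutting, positive = spacer
    cr_adjacent: bool = False  # pair touches a control-region part


@dataclass
class CodonCall:
    gene: str
    start_codon: str
    start_class: str  # standard_ATN | nonstandard
    stop_codon: str   # TAA, TAG, TA or T
    stop_class: str   # complete | truncated


def spacer_table(features: list[GeneFeature], genome_length: int,
                 circular: bool = True) -> list[SpacerRecord]:
    """One record per adjacent feature pair (sorted by start), plus the
    wrap-around pair on a circular genome."""
    feats = sorted(features, key=lambda f: (f.start, f.end))
    seen: set[tuple[int, int]] = set()
    for f in feats:
        if (f.start, f.end) in seen:
            warnings.warn(f"duplicate feature coordinates {f.start}-{f.end} ({f.name})")
        seen.add((f.start, f.end))
    records: list[SpacerRecord] = []
    n = len(feats)
    for i in range(n - 1 + (1 if circular and n > 1 else 0)):
        up, down = feats[i % n], feats[(i + 1) % n]
        if i == n - 1:  # wrap pair
            length = down.start + genome_length - up.end - 1
        else:
            length = down.start - up.end - 1
        records.append(SpacerRecord(
            up.name, down.name, length,
            cr_adjacent="CR_part" in (up.category, down.category)))
    return records


def accounting_identity(features: list[GeneFeature], genome_length: int) -> int:
    """Sum of feature lengths plus all spacer lengths on the circle; equals
    the genome length when the annotation tiles it consistently."""
    total = sum(f.length(genome_length) for f in features)
    total += sum(r.length for r in spacer_table(features, genome_length, True))
    return total


def codon_calls(genome: MitoGenome, pcg_features: list[GeneFeature] | None = None,
                code_id: int = INVERT_MITO_TABLE_ID) -> list[CodonCall]:
    """Extract and classify initiation and termination codons for each
    protein-coding gene.

    The start codon is the first three bases in reading orientation.  The
    stop is the trailing ``len mod 3`` bases when they read T or TA
    (truncated stop), otherwise the final in-frame triplet, which is checked
    against the code's stop set.
    """
    table = CodonTable.unambiguous_dna_by_id[code_id]
    if pcg_features is None:
        pcg_features = [f for f in genome.features if f.category == "PCG"]
    calls: list[CodonCall] = []
    for f in pcg_features:
        cds = extract_region(genome, f)
        if len(cds) < 6:
            raise ValueError(f"{f.name}: CDS shorter than 6 nt")
        start = cds[:3]
        start_class = "standard_ATN" if start.startswith("AT") else "nonstandard"
        rem = len(cds) % 3
        if rem and cds[-rem:] in ("T", "TA"):
            stop, stop_class = cds[-rem:], "truncated"
        else:
            stop, stop_class = cds[-3:], "complete"
            if rem:
                warnings.warn(f"{f.name}: trailing {cds[-rem:]!r} is not a "
                              "truncated stop; reporting final full codon")
                stop = cds[len(cds) - rem - 3:len(cds) - rem]
            if stop not in table.stop_codons:
                warnings.warn(f"{f.name}: final codon {stop} is not a stop codon")
        calls.append(CodonCall(f.name, start, start_class, stop, stop_class))
    return calls


def geometry_report(genome: MitoGenome) -> dict[str, list]:
    spacers = spacer_table(genome.features, len(genome), genome.circular)
    calls = codon_calls(genome)
    return {"spacers": [vars(r) for r in spacers],
            "codon_calls": [vars(c) for c in calls]}
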