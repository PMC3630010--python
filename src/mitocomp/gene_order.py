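"""Gene-order signatures and tandem-duplication random-loss (TDRL) analysis.

Mitochondrial gene rearrangements are predominantly explained by tandem
duplication of a contiguous block followed by loss of one copy of each
duplicated gene.  When the lost copies form runs of uniform transcriptional
polarity the loss is "non-random" (transcription-coupled), which is the
model proposed for the derived katydid order
rrnS-trnI-trnM-nad2-CR-trnQ-trnW arising from the ancestral insect order
rrnS-CR-trnI-trnQ-trnM-nad2-trnW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .genome_io import GENE_NAMES, GeneFeature

Token = tuple[str, str]  # (name, orientation "+" or "-")

#: the canonical 38-token alphabet: 37 genes plus the control region
CANONICAL_ALPHABET = frozenset(GENE_NAMES) | {"CR"}


@dataclass(frozen=True)
class GeneOrder:
    tokens: tuple[Token, ...]
    circular: bool = True

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    def normalized(self, anchor: str | None = None) -> "GeneOrder":
        """Rotate a circular order so the anchor token (trnI by default, else
        the lexicographically smallest name) comes first."""
        if not self.circular or len(set(self.names)) != len(self.names):
            return self
        names = self.names
        if anchor is None:
            anchor = "trnI" if "trnI" in names else min(names)
        i = names.index(anchor)
        return GeneOrder(self.tokens[i:] + self.tokens[:i], True)

    def __str__(self) -> str:
        return " ".join(("-" if o == "-" else "") + n for n, o in self.tokens)


def order_signature(features: list[GeneFeature]) -> GeneOrder:
    """Signed gene order over the canonical 38-token alphabet, anchored at
    trnI.  CR parts (ATR/TR) collapse to a single CR token; pseudogenes and
    spacers are ignored.  Missing or duplicated canonical tokens are errors.
    """
    tokens: list[Token] = []
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        if f.category in ("pseudogene", "spacer"):
            continue
        name = "CR" if f.category == "CR_part" else f.name
        orient = "+" if f.strand == "J" else "-"
        if name == "CR" and tokens and tokens[-1][0] == "CR":
            continue  # ATR + TR -> one CR token
        tokens.append((name, orient))
    names = [t[0] for t in tokens]
    dupes = sorted({n for n in names if names.count(n) > 1})
    missing = sorted(CANONICAL_ALPHABET - set(names))
    extra = sorted(set(names) - CANONICAL_ALPHABET)
    if dupes or missing or extra:
        raise ValueError(f"non-canonical gene order: duplicates={dupes} "
                         f"missing={missing} extra={extra}")
    return GeneOrder(tuple(tokens), True).normalized()


def _adjacencies(order: GeneOrder) -> set[tuple[Token, Token]]:
    """Orientation-respecting adjacency set on the circle; an adjacency and
    its reverse-complement reading are the same physical junction."""
    toks = order.tokens
    n = len(toks)
    adj = set()
    last = n if order.circular else n - 1
    for i in range(last):
        a, b = toks[i % n], toks[(i + 1) % n]
        flip = ((b[0], "-" if b[1] == "+" else "+"),
                (a[0], "-" if a[1] == "+" else "+"))
        adj.add(min((a, b), flip))
    return adj


def breakpoint_count(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (symmetric for equal
    alphabets; zero iff the circular orders match up to rotation)."""
    if set(a.names) != set(b.names):
        raise ValueError("orders are over different token alphabets")
    return len(_adjacencies(a) - _adjacencies(b))


@dataclass
class TdrlScenario:
    """One tandem-duplication / loss event: ``block`` is the duplicated span
    (as source-order indices), ``keep_mask[i]`` says whether the first copy
    of the i-th duplicated token is the one retained."""

    block_start: int
    block_len: int
    keep_mask: tuple[bool, ...]
    n_events: int = 1
    block_tokens: tuple[Token, ...] = field(default_factory=tuple)


def tdrl_apply(order: GeneOrder, block_start: int, block_len: int,
               keep_mask: tuple[bool, ...] | list[bool]) -> GeneOrder:
    """Duplicate the contiguous block in tandem, then delete the non-kept
    copy of each duplicated token."""
    n = len(order.tokens)
    if not 1 <= block_len <= n:
        raise ValueError("block length out of range")
    if len(keep_mask) != block_len:
        raise ValueError("keep_mask length does not match block length")
    # rotate so the block starts at index 0 (legal on a circle)
    rot = order.tokens[block_start:] + order.tokens[:block_start]
    block, rest = rot[:block_len], rot[block_len:]
    doubled = [(tok, 0) for tok in block] + [(tok, 1) for tok in block] + \
              [(tok, None) for tok in rest]
    kept = []
    for tok, copy in doubled:
        if copy is None:
            kept.append(tok)
        else:
            idx = block.index(tok)  # tokens are unique within the block
            if (copy == 0) == bool(keep_mask[idx]):
                kept.append(tok)
    out = GeneOrder(tuple(kept), order.circular)
    return out.normalized() if order.circular else out


def tdrl_search(source: GeneOrder, target: GeneOrder,
                max_block_len: int | None = None) -> list[TdrlScenario]:
    """Exhaustively enumerate single-TDRL scenarios turning ``source`` into
    ``target`` (all contiguous blocks x all keep masks).  Scenarios whose
    result equals the source itself are reported with n_events 0."""
    if set(source.names) != set(target.names):
        raise ValueError("orders are over different token alphabets")
    n = len(source.tokens)
    if max_block_len is None:
        max_block_len = n
    src = source.normalized()
    tgt_norm = target.normalized()
    results: list[TdrlScenario] = []
    seen: set[tuple] = set()
    for start in range(n if source.circular else 1):
        for length in range(1, max_block_len + 1):
            if not source.circular and start + length > n:
                continue
            block = tuple((src.tokens[start:] + src.tokens[:start])[:length])
            for mask in product((True, False), repeat=length):
                out = tdrl_apply(src, start, length, mask)
                if out.tokens != tgt_norm.tokens:
                    continue
                n_events = 0 if out.tokens == src.tokens else 1
                key = (block, mask, n_events)
                if key in seen:
                    continue
                seen.add(key)
                results.append(TdrlScenario(start, length, mask, n_events, block))
    return results


def deleted_runs(scenario: TdrlScenario) -> list[list[Token]]:
    """Maximal contiguous runs of deleted copies in the doubled intermediate."""
    block, mask = scenario.block_tokens, scenario.keep_mask
    doubled = [(tok, 0) for tok in block] + [(tok, 1) for tok in block]
    runs: list[list[Token]] = []
    cur: list[Token] = []
    for tok, copy in doubled:
        idx = block.index(tok)
        deleted = (copy == 0) != bool(mask[idx])
        if deleted:
            cur.append(tok)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def classify_loss_pattern(scenario: TdrlScenario,
                          polarity: dict[str, str] | None = None) -> str:
    """Label a scenario ``non_random_polarity_consistent`` when every run of
    deleted copies shares one transcriptional polarity (tokens without an
    entry in ``polarity`` — the CR — are neutral), else ``random``."""
    if polarity is None:
        polarity = {}
    for run in deleted_runs(scenario):
        pols = set()
        for name, orient in run:
            if name in polarity:
                pols.add(polarity[name])
            elif name == "CR":
                continue  # the control region has no transcriptional polarity
            else:
                pols.add("J" if orient == "+" else "N")
        if len(pols) > 1:
            return "random"
    return "non_random_polarity_consistent"


# ---------------------------------------------------------------------------
# Named order presets

def _order(tokens: list[tuple[str, str]]) -> GeneOrder:
    return GeneOrder(tuple(tokens), True).normalized()


#: gene order of the putative insect ancestor (and most orthopterans),
#: anchored at trnI: ... rrnS - CR - trnI ...
ANCESTRAL_ORDER = _order([
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("nad2", "+"), ("trnW", "+"),
    ("trnC", "-"), ("trnY", "-"), ("cox1", "+"), ("trnL_UUR", "+"),
    ("cox2", "+"), ("trnK", "+"), ("trnD", "+"), ("atp8", "+"), ("atp6", "+"),
    ("cox3", "+"), ("trnG", "+"), ("nad3", "+"), ("trnA", "+"), ("trnR", "+"),
    ("trnN", "+"), ("trnS_AGN", "+"), ("trnE", "+"), ("trnF", "-"),
    ("nad5", "-"), ("trnH", "-"), ("nad4", "-"), ("nad4L", "-"), ("trnT", "+"),
    ("trnP", "-"), ("nad6", "+"), ("cob", "+"), ("trnS_UCN", "+"),
    ("nad1", "-"), ("trnL_CUN", "-"), ("rrnL", "-"), ("trnV", "-"),
    ("rrnS", "-"), ("CR", "+"),
])

#: derived katydid order: ... rrnS - trnI - trnM - nad2 - CR - trnQ - trnW ...
SINOCHLORA_ORDER = _order([
    ("trnI", "+"), ("trnM", "+"), ("nad2", "+"), ("CR", "+"), ("trnQ", "-"),
    ("trnW", "+"), ("trnC", "-"), ("trnY", "-"), ("cox1", "+"),
    ("trnL_UUR", "+"), ("cox2", "+"), ("trnK", "+"), ("trnD", "+"),
    ("atp8", "+"), ("atp6", "+"), ("cox3", "+"), ("trnG", "+"), ("nad3", "+"),
    ("trnA", "+"), ("trnR", "+"), ("trnN", "+"), ("trnS_AGN", "+"),
    ("trnE", "+"), ("trnF", "-"), ("nad5", "-"), ("trnH", "-"), ("nad4", "-"),
    ("nad4L", "-"), ("trnT", "+"), ("trnP", "-"), ("nad6", "+"), ("cob", "+"),
    ("trnS_UCN", "+"), ("nad1", "-"), ("trnL_CUN", "-"), ("rrnL", "-"),
    ("trnV", "-"), ("rrnS", "-"),
])

ORDER_PRESETS = {"ancestral": ANCESTRAL_ORDER, "sinochlora": SINOCHLORA_ORDER}


def read_order(path) -> GeneOrder:
    """Order file: one token per line, '-' prefix for minority-strand genes."""
    tokens = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("-"):
            tokens.append((line[1:], "-"))
        else:
            tokens.append((line, "+"))
    return GeneOrder(tuple(tokens), True).normalized()


def write_order(order: GeneOrder, path) -> None:
    with open(path, "w") as fh:
        for name, orient in order.tokens:
            fh.write(("-" if orient == "-" else "") + name + "\n")
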