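"""Gene-order comparison, rearrangement classification, and the
tandem-duplication-random-loss (TDRL) model.

A gene order is a circular, strand-signed sequence of gene/CR/OL/NC tokens.
Rearrangement reports compare an order against the canonical vertebrate
arrangement; TDRL reachability asks whether a single
duplicate-block-then-delete event explains an observed order.  A one-event
TDRL product of a block is kept(copy 1) ++ kept(copy 2): the rearranged
block image must split into a prefix and a suffix that are each in the
original block order, with duplicated genes occupying both halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .genome_model import Mitogenome
from .refdata import (
    ALL_LABELS,
    CANONICAL_ORDER,
    CANONICAL_STRAND,
    HOTSPOT_REGIONS,
    NC_MIN_BP,
)

Token = tuple[str, int]  # (label, strand sign)


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed arrangement of gene/CR/OL/NC tokens.

    Rotation-equivalent orders compare equal; NC tokens participate in the
    token sequence but are ignored by rearrangement arithmetic.
    """

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        for label, strand in self.tokens:
            if label not in ALL_LABELS:
                raise ValueError(f"unknown label in gene order: {label!r}")
            if strand not in (1, -1):
                raise ValueError(f"strand sign must be +-1, got {strand!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def rotate(self, k: int) -> "GeneOrder":
        k %= len(self.tokens)
        return GeneOrder(self.tokens[k:] + self.tokens[:k])

    def _normal_form(self) -> tuple[Token, ...]:
        toks = self.tokens
        anchors = [i for i, (lab, _) in enumerate(toks) if lab == "Phe"]
        if len(anchors) == 1:
            k = anchors[0]
            return toks[k:] + toks[:k]
        return min(toks[k:] + toks[:k] for k in range(len(toks)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self._normal_form() == other._normal_form()

    def __hash__(self) -> int:
        return hash(self._normal_form())

    def without_nc(self) -> "GeneOrder":
        return GeneOrder(tuple(t for t in self.tokens if t[0] != "NC"))

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.tokens)


CANONICAL = GeneOrder(CANONICAL_ORDER)


def extract_order(genome: Mitogenome, nc_min: int = NC_MIN_BP) -> GeneOrder:
    """Gene order of an annotated genome, with intergenic NC tokens.

    Features are sorted circularly starting from tRNA-Phe when present;
    intergenic spans of at least ``nc_min`` bp become NC tokens.  The
    canonical-strand sign convention is applied (H = +1, L = -1).
    """
    feats = genome.sorted_features()
    if not feats:
        raise ValueError("genome has no features")
    L = len(genome)
    start_idx = next((k for k, f in enumerate(feats) if f.label == "Phe"), 0)
    feats = feats[start_idx:] + feats[:start_idx]
    tokens: list[Token] = []
    for k, f in enumerate(feats):
        tokens.append((f.label, 1 if f.strand == "H" else -1))
        nxt = feats[(k + 1) % len(feats)]
        # circular gap between this feature's end and the next one's start
        gap = (nxt.start - (f.end % L)) % L
        # overlapping features produce large modular "gaps"; only count true
        # intergenic spacers (shorter than half the genome)
        if nc_min <= gap < L // 2:
            tokens.append(("NC", 1))
    return GeneOrder(tuple(tokens))


# ---------------------------------------------------------------------------
# Comparison against the canonical order
# ---------------------------------------------------------------------------

@dataclass
class RearrangementReport:
    status: str  # typical | rearranged
    classes: set[str] = field(default_factory=set)
    displaced: set[str] = field(default_factory=set)
    hotspots: set[str] = field(default_factory=set)
    nc_tokens: int = 0
    tdrl_reachable: bool | None = None
    tdrl_witness: tuple[int, int] | None = None


def _successor_map(tokens: tuple[Token, ...]) -> dict[str, set[str]]:
    """Label -> set of successor labels (NC ignored), circular."""
    labs = [lab for lab, _ in tokens if lab != "NC"]
    out: dict[str, set[str]] = {}
    for k, lab in enumerate(labs):
        out.setdefault(lab, set()).add(labs[(k + 1) % len(labs)])
    return out


_CANON_POSITIONS = {lab: k for k, (lab, _) in enumerate(CANONICAL_ORDER)}
_REGION_OF = {lab: reg for reg, labs in HOTSPOT_REGIONS.items() for lab in labs}


def _within_window(labels: set[str], window: int) -> bool:
    """True when all labels sit inside one circular canonical window."""
    pos = sorted(_CANON_POSITIONS[lab] for lab in labels)
    if len(pos) <= 1:
        return True
    n = len(CANONICAL_ORDER)
    # smallest circular arc covering all positions
    gaps = [(pos[(k + 1) % len(pos)] - pos[k]) % n for k in range(len(pos))]
    return n - max(gaps) + 1 <= window


SHUFFLE_WINDOW = 5


def compare_to_canonical(order: GeneOrder,
                         shuffle_window: int = SHUFFLE_WINDOW) -> RearrangementReport:
    """Classify an order's deviation from the canonical arrangement.

    Displaced labels are those whose successor (NC ignored) differs from
    canonical.  Classes: inversion on any strand-sign flip; duplication on
    label multiplicity; OL_shift when the O_L is displaced; a displaced CR
    is classed translocation; displaced genes confined to one canonical
    window of at most ``shuffle_window`` positions give shuffling, anything
    wider translocation.
    """
    report = RearrangementReport(status="typical")
    report.nc_tokens = sum(1 for lab, _ in order.tokens if lab == "NC")
    succ = _successor_map(order.tokens)
    canon_succ = _successor_map(CANONICAL.tokens)
    for lab, successors in succ.items():
        if lab not in canon_succ:
            raise ValueError(f"label {lab!r} not in canonical order")
        if successors != canon_succ[lab]:
            report.displaced.add(lab)
    labs = [lab for lab, _ in order.tokens]
    dup = {lab for lab in set(labs) if lab != "NC" and labs.count(lab) > 1}
    if dup:
        report.classes.add("duplication")
        report.displaced |= dup
    for lab, strand in order.tokens:
        if lab != "NC" and CANONICAL_STRAND.get(lab) not in (None, strand):
            report.classes.add("inversion")
            report.displaced.add(lab)
    if "OL" in report.displaced:
        report.classes.add("OL_shift")
    genes = {lab for lab in report.displaced if lab not in ("CR", "OL", "NC")}
    if "CR" in report.displaced:
        report.classes.add("translocation")
    if genes:
        if _within_window(genes, shuffle_window) and "translocation" not in report.classes:
            report.classes.add("shuffling")
        else:
            report.classes.add("translocation")
    report.hotspots = {
        _REGION_OF.get(lab, "other") for lab in report.displaced
    }
    if report.classes or report.displaced:
        report.status = "rearranged"
    flag, witness = tdrl_reachable(order)
    report.tdrl_reachable = flag
    report.tdrl_witness = witness
    return report


# ---------------------------------------------------------------------------
# TDRL
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TDRLEvent:
    """A tandem duplication of ``block`` followed by per-gene copy loss.

    ``block`` is (start index, length) in the origin order; ``losses`` maps
    each block label to the kept copy: 'first', 'second' or 'both'.
    """

    block: tuple[int, int]
    losses: dict[str, str]

    def __hash__(self):
        return hash((self.block, tuple(sorted(self.losses.items()))))


def apply_tdrl(order: GeneOrder, block: tuple[int, int],
               losses: dict[str, str], emit_nc: bool = True
               ) -> tuple[GeneOrder, TDRLEvent]:
    """Duplicate a contiguous block in tandem, then delete copies.

    ``losses`` maps each block label to 'first' | 'second' | 'both'; labels
    omitted keep both copies.  Deleting both copies of a gene is an error.
    Each deleted copy leaves an NC remnant token at its own position when
    ``emit_nc`` (the sequence-level remnant crosses the >= 50 bp threshold).
    """
    s, b = block
    n = len(order)
    if not 1 <= b <= n:
        raise ValueError(f"block length {b} outside [1, {n}]")
    idx = [(s + k) % n for k in range(b)]
    block_tokens = [order.tokens[i] for i in idx]
    block_labels = [lab for lab, _ in block_tokens]
    for lab, kept in losses.items():
        if lab not in block_labels:
            raise ValueError(f"loss pattern names {lab!r} outside the block")
        if kept not in ("first", "second", "both"):
            raise ValueError(f"invalid copy choice {kept!r} for {lab!r}")
    new_block: list[Token] = []
    for copy_name in ("first", "second"):
        for tok in block_tokens:
            kept = losses.get(tok[0], "both")
            if kept in (copy_name, "both"):
                new_block.append(tok)
            elif emit_nc:
                new_block.append(("NC", 1))
    rest = [order.tokens[(s + b + k) % n] for k in range(n - b)]
    event = TDRLEvent(block=(s, b), losses=dict(losses))
    return GeneOrder(tuple(new_block + rest)), event


def _splits_into_two_runs(ranks: list[int], n_ranks: int) -> bool:
    """Can ``ranks`` be cut into a prefix and suffix, each strictly
    increasing, jointly covering every rank (duplicates in both halves)?"""
    for cut in range(len(ranks) + 1):
        a, b = ranks[:cut], ranks[cut:]
        if all(x < y for x, y in zip(a, a[1:])) and \
           all(x < y for x, y in zip(b, b[1:])) and \
           len(set(a) | set(b)) == n_ranks:
            return True
    return False


def tdrl_reachable(order: GeneOrder, origin: GeneOrder = CANONICAL
                   ) -> tuple[bool, tuple[int, int] | None]:
    """Is ``order`` one TDRL event away from ``origin``?

    NC tokens are ignored; any strand-sign difference is immediately
    unreachable (TDRL cannot invert).  Returns the minimal witness block
    (start, length in origin coordinates), the empty event for identical
    orders.
    """
    target = [t for t in order.tokens if t[0] != "NC"]
    source = [t for t in origin.tokens if t[0] != "NC"]
    src_strand = {lab: sg for lab, sg in source}
    seen = set()
    for lab, sg in target:
        if lab not in src_strand:
            return False, None
        if src_strand[lab] != sg:
            return False, None
        seen.add(lab)
    if seen != set(src_strand):
        return False, None
    m, k = len(source), len(target)
    if k < m:
        return False, None
    if GeneOrder(tuple(target)) == GeneOrder(tuple(source)):
        return True, (0, 0)
    # rotations of the target, indexed by first token label
    tgt_labels = [lab for lab, _ in target]
    for b in range(1, m + 1):
        for s in range(m):
            block = [source[(s + i) % m][0] for i in range(b)]
            outside = [source[(s + b + i) % m][0] for i in range(m - b)]
            rank = {lab: i for i, lab in enumerate(block)}
            image_len = k - len(outside)
            # candidate rotations: the image must be followed by `outside`
            for r in range(k):
                rot = tgt_labels[r:] + tgt_labels[:r]
                if rot[image_len:] != outside:
                    continue
                image = rot[:image_len]
                if any(lab not in rank for lab in image):
                    continue
                if _splits_into_two_runs([rank[lab] for lab in image], b):
                    return True, (s, b)
    return False, None


def replay_witness(order: GeneOrder, witness: tuple[int, int],
                   origin: GeneOrder = CANONICAL) -> GeneOrder | None:
    """Find a loss pattern over the witness block reproducing ``order``.

    Returns the replayed order (NC-free) or None; used to validate
    reachability witnesses.
    """
    s, b = witness
    if b == 0:
        return origin.without_nc()
    source = [t for t in origin.tokens if t[0] != "NC"]
    target = [t for t in order.tokens if t[0] != "NC"]
    block = [source[(s + i) % len(source)][0] for i in range(b)]
    rank = {lab: i for i, lab in enumerate(block)}
    outside = [source[(s + b + i) % len(source)][0] for i in range(len(source) - b)]
    tgt_labels = [lab for lab, _ in target]
    image_len = len(target) - len(outside)
    for r in range(len(target)):
        rot = tgt_labels[r:] + tgt_labels[:r]
        if rot[image_len:] != outside:
            continue
        image = rot[:image_len]
        if any(lab not in rank for lab in image):
            continue
        ranks = [rank[lab] for lab in image]
        for cut in range(len(ranks) + 1):
            a, c = ranks[:cut], ranks[cut:]
            if not (all(x < y for x, y in zip(a, a[1:]))
                    and all(x < y for x, y in zip(c, c[1:]))
                    and len(set(a) | set(c)) == b):
                continue
            losses = {}
            for i, lab in enumerate(block):
                first, second = i in a, i in c
                losses[lab] = ("both" if first and second
                               else "first" if first else "second")
            replayed, _ = apply_tdrl(GeneOrder(tuple(source)), (s, b),
                                     losses, emit_nc=False)
            if replayed == order.without_nc():
                return replayed
    return None


# ---------------------------------------------------------------------------
# Tree-based sharing of derived orders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyVerdict:
    order_class: str
    verdict: str  # monophyletic | polyphyletic
    n_species: int
    smallest_clade: int


def shared_order_monophyly(tree: dendropy.Tree,
                           assignment: dict[str, str]) -> list[MonophylyVerdict]:
    """Monophyly of each gene-order class on a rooted species tree.

    A class is monophyletic when its species set equals the full tip set of
    some clade; otherwise the smallest containing clade is reported.
    Species missing from the tree raise an error listing them.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(assignment) - tips)
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    classes: dict[str, set[str]] = {}
    for sp, cls in assignment.items():
        classes.setdefault(cls, set()).add(sp)
    out = []
    for cls, species in sorted(classes.items()):
        if len(species) == len(tips):
            out.append(MonophylyVerdict(cls, "monophyletic", len(species),
                                        len(tips)))
            continue
        mrca = tree.mrca(taxon_labels=sorted(species))
        clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        verdict = "monophyletic" if clade == species else "polyphyletic"
        out.append(MonophylyVerdict(cls, verdict, len(species), len(clade)))
    return out
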