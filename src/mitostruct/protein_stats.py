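"""Protein-coding gene statistics.

Start/stop codon usage (vertebrate mitochondrial code, including the
positional reading of incomplete stops completed by polyadenylation),
gene-length statistics with maximum percentage variation (MPV), circular
overlap detection, per-codon-position base composition, and amino-acid
conservation profiling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_model import (
    BaseComposition,
    GeneFeature,
    Mitogenome,
    extract_gene_sequence,
)
from .refdata import MT_STOP_CODONS


def detect_start_codon(gene_seq: str) -> str:
    """First in-frame triplet of a sense-strand gene sequence, verbatim."""
    if len(gene_seq) < 3:
        raise ValueError("gene sequence shorter than one codon")
    return gene_seq[:3].upper()


@dataclass(frozen=True)
class CodonRecord:
    gene: str
    start_codon: str
    stop_codon: str  # TAA/TAG/AGA/AGG or TA-/T--/AG-
    complete: bool
    flagged: bool  # residue matched no recognized stop pattern
    followed_by_same_strand_trna: bool | None


def _next_feature(genome: Mitogenome, gene: GeneFeature) -> GeneFeature | None:
    """Feature whose span starts soonest after the gene's 3' genomic end."""
    L = len(genome)
    others = [f for f in genome.features if f is not gene]
    if not others:
        return None
    if gene.strand == "H":
        anchor = gene.end % L
        return min(others, key=lambda f: (f.start - anchor) % L)
    anchor = gene.start
    return min(others, key=lambda f: (anchor - (f.end % L)) % L)


def detect_stop_codon(gene: GeneFeature, genome: Mitogenome) -> CodonRecord:
    """Classify the stop codon of a protein-coding gene.

    Purely positional: a span length divisible by three must end in a
    complete vertebrate-mt stop; a remainder of one or two nucleotides with
    a trailing T / TA / AG is read as an incomplete stop completed by
    polyadenylation.  Unrecognized residues yield a flagged record.  The
    punctuation context (whether the next same-strand feature is a tRNA)
    is reported alongside.
    """
    if gene.kind != "protein":
        raise ValueError(f"{gene.label} is not protein-coding")
    seq = extract_gene_sequence(genome, gene)
    start = detect_start_codon(seq)
    rem = len(seq) % 3
    flagged = False
    if rem == 0:
        stop = seq[-3:]
        complete = True
        if stop not in MT_STOP_CODONS:
            flagged = True
    elif rem == 1:
        stop, complete = "T--", False
        if seq[-1] != "T":
            flagged = True
            stop = seq[-1] + "--"
    else:
        tail = seq[-2:]
        complete = False
        if tail == "TA":
            stop = "TA-"
        elif tail == "AG":
            stop = "AG-"
        else:
            stop = tail + "-"
            flagged = True
    nxt = _next_feature(genome, gene)
    followed = None
    if nxt is not None:
        followed = nxt.kind == "trna" and nxt.strand == gene.strand
    return CodonRecord(
        gene=gene.label, start_codon=start, stop_codon=stop,
        complete=complete, flagged=flagged,
        followed_by_same_strand_trna=followed,
    )


# ---------------------------------------------------------------------------
# Length statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthStats:
    gene: str
    modal: int
    smallest: int
    largest: int
    mpv: float  # (largest - smallest) / modal * 100
    fraction_modal: float


def length_stats(lengths, gene: str = "") -> LengthStats:
    """Modal length and maximum percentage variation of a length multiset.

    MPV = (largest - smallest) / modal * 100.  Modal ties break toward the
    smallest value for deterministic reporting.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length multiset")
    counts = Counter(lengths)
    top = max(counts.values())
    modal = min(v for v, c in counts.items() if c == top)
    smallest, largest = min(lengths), max(lengths)
    return LengthStats(
        gene=gene, modal=modal, smallest=smallest, largest=largest,
        mpv=(largest - smallest) / modal * 100.0,
        fraction_modal=counts[modal] / len(lengths),
    )


# ---------------------------------------------------------------------------
# Overlaps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    length: int
    strand_relation: str  # same | opposite


def _circular_intersection(f1: GeneFeature, f2: GeneFeature, L: int) -> int:
    """Number of genome positions covered by both features."""
    total = 0
    for shift in (-L, 0, L):
        lo = max(f1.start, f2.start + shift)
        hi = min(f1.end, f2.end + shift)
        if hi > lo:
            total += hi - lo
    return min(total, L)


def detect_overlaps(genome: Mitogenome) -> list[OverlapRecord]:
    """Every feature pair with positive span intersection on the circle."""
    feats = genome.sorted_features()
    L = len(genome)
    out = []
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            n = _circular_intersection(feats[a], feats[b], L)
            if n > 0:
                out.append(OverlapRecord(
                    gene_a=feats[a].label, gene_b=feats[b].label, length=n,
                    strand_relation=("same" if feats[a].strand == feats[b].strand
                                     else "opposite"),
                ))
    return out


# ---------------------------------------------------------------------------
# Codon-position composition
# ---------------------------------------------------------------------------

def codon_position_composition(genes: list[str]) -> dict[str, BaseComposition]:
    """Base composition at codon positions 1-3 plus total, frame from 0.

    Trailing partial codons (incomplete stops) contribute to the positions
    they cover.
    """
    counters = {1: Counter(), 2: Counter(), 3: Counter()}
    total = Counter()
    for seq in genes:
        for idx, base in enumerate(seq.upper()):
            counters[idx % 3 + 1][base] += 1
            total[base] += 1
    out = {str(pos): BaseComposition.from_counts(c) for pos, c in counters.items()}
    out["total"] = BaseComposition.from_counts(total)
    return out


# ---------------------------------------------------------------------------
# Amino-acid conservation
# ---------------------------------------------------------------------------

def conservation_profile(aa_rows: list[str], gap_cap: float = 0.0
                         ) -> tuple[list[bool], float]:
    """Per-column invariability of an amino-acid alignment.

    A column is invariable when all non-gap residues are identical and the
    gap fraction does not exceed ``gap_cap`` (default strict: no gaps).
    Returns (per-column flags, fraction of invariable columns).
    """
    if len(aa_rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    lengths = {len(r) for r in aa_rows}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    n_cols = next(iter(lengths))
    flags = []
    for c in range(n_cols):
        col = [row[c] for row in aa_rows]
        residues = [x for x in col if x != "-"]
        gap_frac = (len(col) - len(residues)) / len(col)
        flags.append(bool(residues) and len(set(residues)) == 1
                     and gap_frac <= gap_cap)
    return flags, sum(flags) / n_cols
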