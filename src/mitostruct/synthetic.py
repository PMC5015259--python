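"""Seeded generator of annotated synthetic mitogenomes and alignments.

The generator emits fully annotated circular genomes with the canonical
vertebrate gene order and the marginal statistics observed across fish
mitogenomes: per-gene codon-position composition, start/stop codon usage
(incomplete stops only before same-strand tRNAs), the three canonical
reading-frame overlaps, tRNAs that fold uniquely into their planted
cloverleafs, GC-rich stems with A-rich loops, a control region carrying
the four CSBs and a poly-T tract, and an O_L hairpin with its replication
motif inside the WANCY cluster.  Planted ground truth is recorded next to
every genome so that downstream detectors can be validated exactly.

The generator validates each planted structural element against the
corresponding detector and resamples on ambiguity, so emitted structures
are uniquely recoverable by construction.  It targets marginal statistics,
not phylogenetically realistic sequence evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import refdata as R
from .gene_order import CANONICAL, GeneOrder, TDRLEvent, apply_tdrl
from .genome_model import GeneFeature, Mitogenome, revcomp
from .noncoding import find_ol
from .rrna_struct import Alignment, eligible_pairs, max_nested_pairing
from .trna_struct import (
    AA_STEM,
    Architecture,
    TRNAFold,
    _pair_indices,
    classify_pair,
    fold_trna,
)

_BASES = np.array(list("ACGT"))
_WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


def _weights(comp: dict[str, float]) -> np.ndarray:
    w = np.array([comp[b] for b in "ACGT"], dtype=float)
    return w / w.sum()

_STEM_W = _weights(R.STEM_COMPOSITION)
_LOOP_W = _weights(R.LOOP_COMPOSITION)


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-mitogenome generator.

    Defaults are the study conditions: composition targets per codon
    position, canonical overlap lengths, tRNA architectures within the
    observed loop ranges, CR length range, poly-T length, O_L stem/loop
    sizes, and per-strand wobble rates.
    """

    seed: int = 0
    codon_composition: dict = field(default_factory=lambda: dict(R.CODON_COMPOSITION))
    protein_plan: dict = field(default_factory=lambda: dict(R.PROTEIN_PLAN))
    start_codons: dict = field(default_factory=lambda: dict(R.START_CODON_PLAN))
    overlaps: dict = field(default_factory=lambda: dict(R.CANONICAL_OVERLAPS))
    trna_architecture: dict = field(default_factory=lambda: dict(R.TRNA_ARCHITECTURE))
    wobble_rate_h: float = 0.035
    wobble_rate_l: float = 0.133
    csb_refs: dict = field(default_factory=lambda: dict(R.CSB_REFERENCES))
    cr_length_range: tuple[int, int] = R.CR_LENGTH_RANGE
    polyt_length: int = 10
    ol_stem: int = 12
    ol_loop: int = 12
    nc_remnant: int = 60
    gap_range: tuple[int, int] = (1, 3)
    rrna_lengths: dict = field(default_factory=lambda: {"12S": 950, "16S": 1650})

    def __post_init__(self) -> None:
        if not R.OL_STEM_RANGE[0] <= self.ol_stem <= R.OL_STEM_RANGE[1]:
            raise ValueError(f"O_L stem {self.ol_stem} outside observed range")
        if not R.OL_LOOP_RANGE[0] <= self.ol_loop <= R.OL_LOOP_RANGE[1]:
            raise ValueError(f"O_L loop {self.ol_loop} outside observed range")
        for label, (d, dl, v, tl) in self.trna_architecture.items():
            if d != 0 and not R.D_STEM_RANGE[0] <= d <= R.D_STEM_RANGE[1]:
                raise ValueError(f"{label}: D stem {d} outside range")
            for val, rng in ((dl, R.D_LOOP_RANGE), (v, R.V_LOOP_RANGE),
                             (tl, R.T_LOOP_RANGE)):
                if not rng[0] <= val <= rng[1]:
                    raise ValueError(f"{label}: loop size {val} outside {rng}")


DEFAULT_PARAMS = GeneratorParams()


@dataclass
class PlantedRRNA:
    """Ancestral rRNA sequence with its planted consensus structure."""

    seq: str
    stems: list[list[tuple[int, int]]]
    invariable: set[int]
    hypervariable: tuple[int, int] | None = None

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for s in self.stems for p in s]


@dataclass
class GroundTruth:
    """Planted structures recorded alongside a generated genome."""

    trna_folds: dict[str, TRNAFold] = field(default_factory=dict)
    rrna: dict[str, PlantedRRNA] = field(default_factory=dict)
    csb_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    polyt: tuple[int, int] | None = None
    ol_stem: int = 0
    ol_loop: int = 0
    ol_offset: int = 0  # hairpin offset within the Asn..Cys region
    mterf_offset: int = -1
    order: GeneOrder | None = None
    tdrl_events: list[TDRLEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tRNA generation
# ---------------------------------------------------------------------------

def _sample(rng: np.random.Generator, weights: np.ndarray, n: int = 1) -> str:
    return "".join(rng.choice(_BASES, size=n, p=weights))


def generate_trna(label: str, rng: np.random.Generator,
                  params: GeneratorParams = DEFAULT_PARAMS,
                  max_tries: int = 200) -> TRNAFold:
    """One tRNA gene sequence folding uniquely into its planted cloverleaf.

    Stems are Watson-Crick with per-strand wobble planting; loops follow
    the A-rich loop composition; the anticodon is the vertebrate one; the
    mTERF tridecamer is planted across the D arm of tRNA-Leu(UUR).
    Candidates whose best fold differs from the plant are resampled.
    """
    arch = Architecture(*params.trna_architecture[label])
    strand = R.CANONICAL_STRAND.get(label, 1)
    wobble = params.wobble_rate_l if strand == -1 else params.wobble_rate_h
    pair_idx = _pair_indices(arch)
    spans_probe = TRNAFold(seq="N" * arch.length, arch=arch)
    spans = spans_probe.spans()
    ac_loop_start = spans["ac_loop"][0]
    for _ in range(max_tries):
        seq = list(_sample(rng, _LOOP_W, arch.length))
        for i, j in pair_idx:
            if rng.random() < wobble:
                seq[i], seq[j] = ("G", "T") if rng.random() < 0.5 else ("T", "G")
            else:
                seq[i] = _sample(rng, _STEM_W)
                seq[j] = _WC_PARTNER[seq[i]]
        anticodon = R.ANTICODONS[label]
        for k in range(3):
            seq[ac_loop_start + 2 + k] = anticodon[k]
        if label == "Leu(UUR)":
            # tridecamer spans the linker, D stem 5' arm and D-loop start
            motif = R.MTERF_TRIDECAMER
            for k, base in enumerate(motif):
                seq[7 + k] = base
            d5_lo, d5_hi = spans["d_stem5"]
            d3_lo, d3_hi = spans["d_stem3"]
            for k in range(arch.d_stem):  # re-complement the 3' D arm
                seq[d3_hi - 1 - k] = _WC_PARTNER[seq[d5_lo + k]]
        s = "".join(seq)
        pairs = [(i, j, classify_pair(s[i], s[j])) for i, j in pair_idx]
        planted = TRNAFold(seq=s, arch=arch, pairs=pairs,
                           score=2 * sum(1 for *_, c in pairs if c != "mismatch"))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                recovered = fold_trna(s, label)
            except ValueError:
                continue
        if recovered.arch == arch:
            return planted
    raise RuntimeError(f"could not generate an unambiguous tRNA-{label} "
                       f"in {max_tries} tries")


def mutate_trna(fold: TRNAFold, sub_rate: float, rng: np.random.Generator,
                compensatory: float = 0.8) -> str:
    """One mutated copy of a tRNA sequence.

    Paired positions mutate compensatorily (to a different Watson-Crick
    pair) with the given probability, otherwise one-sidedly; loop positions
    substitute freely at ``sub_rate``.
    """
    seq = list(fold.seq)
    paired = {i for i, _, _ in fold.pairs} | {j for _, j, _ in fold.pairs}
    for i, j, _ in fold.pairs:
        if rng.random() < sub_rate:
            if rng.random() < compensatory:
                choices = [p for p in _WC_PAIRS if p != (seq[i], seq[j])]
                seq[i], seq[j] = choices[rng.integers(len(choices))]
            else:
                seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
    for k in range(len(seq)):
        if k not in paired and rng.random() < sub_rate:
            seq[k] = str(rng.choice([b for b in "ACGT" if b != seq[k]]))
    return "".join(seq)


# ---------------------------------------------------------------------------
# Protein gene generation
# ---------------------------------------------------------------------------

def _codon_weights(label: str, params: GeneratorParams) -> list[np.ndarray]:
    rows = params.codon_composition[label]
    # rows: (total, 1st, 2nd, 3rd), each (A, T, G, C)
    out = []
    for a, t, g, c in rows[1:]:
        out.append(_weights({"A": a, "T": t, "G": g, "C": c}))
    return out


def generate_protein(label: str, rng: np.random.Generator,
                     params: GeneratorParams = DEFAULT_PARAMS,
                     prefix: str | None = None,
                     suffix: str | None = None) -> str:
    """Sense-strand protein gene with planted start/stop and composition.

    Interior codons are sampled per-position from the gene's composition
    targets, rejecting in-frame stops; ``prefix``/``suffix`` override the
    gene's ends (used to realize the canonical overlaps).
    """
    length, stop = params.protein_plan[label]
    if prefix is None:
        prefix = params.start_codons[label]
    w = _codon_weights(label, params)
    seq = list(prefix)
    stop_tail = stop.rstrip("-")
    tail = list(suffix if suffix else stop_tail)
    body_end = length - len(tail)
    if body_end > len(seq):
        pos_idx = np.arange(len(seq), body_end) % 3
        draws = np.empty(len(pos_idx), dtype="<U1")
        for p in range(3):
            mask = pos_idx == p
            draws[mask] = rng.choice(_BASES, size=int(mask.sum()), p=w[p])
        seq.extend(draws.tolist())
    seq = seq + tail
    assert len(seq) == length
    # repair in-frame stops (none of TAA/TAG/AGA/AGG contains C, so setting
    # any free position of an offending codon to C is always sufficient);
    # positions inside the designed prefix/suffix stay untouched
    last_codon_start = (length // 3 - 1) * 3 if length % 3 == 0 else None
    for c in range(0, length - 2, 3):
        if c == last_codon_start:
            continue
        if "".join(seq[c : c + 3]) in R.MT_STOP_CODONS:
            free = [k for k in (c, c + 1, c + 2)
                    if len(prefix) <= k < body_end]
            if free:
                seq[free[-1]] = "C"
    return "".join(seq)


# ---------------------------------------------------------------------------
# rRNA generation
# ---------------------------------------------------------------------------

# rRNA/O_L ancestors: arms draw only G/C, loops and spacers only A.  This
# makes the planted pairing the provably unique maximum nested pairing of
# the ancestor (A cannot pair without T, and every G/C column is consumed
# by its planted partner); mutation noise then reintroduces the remaining
# bases in the emitted alignments.
_ARM_W = _weights({"A": 0.0, "T": 0.0, "G": 50.0, "C": 50.0})
_RLOOP_W = _weights({"A": 100.0, "T": 0.0, "G": 0.0, "C": 0.0})


def generate_rrna_structure(rng: np.random.Generator, length: int,
                            arm_range: tuple[int, int] = (4, 7),
                            loop_range: tuple[int, int] = (4, 6),
                            spacer_range: tuple[int, int] = (3, 6),
                            invariable_frac: float = 0.4,
                            hypervariable_len: int = 16,
                            max_tries: int = 60) -> PlantedRRNA:
    """Ancestral rRNA sequence of hairpin stems with recorded ground truth.

    Stem arms are GC-biased with exact reverse-complement 3' arms; loops
    and spacers avoid G/T so they cannot pair with each other.  A fraction
    of the unpaired columns is designated invariable, and one loop is
    widened into a hypervariable region.  The plant is validated by
    re-deriving the maximum nested pairing on the ancestor; ambiguous
    drafts are resampled.
    """
    for _ in range(max_tries):
        seq_parts: list[str] = []
        stems: list[list[tuple[int, int]]] = []
        unpaired: list[int] = []
        pos = 0

        def spacer(n):
            nonlocal pos
            seq_parts.append(_sample(rng, _RLOOP_W, n))
            unpaired.extend(range(pos, pos + n))
            pos += n

        spacer(int(rng.integers(*spacer_range)))
        hyper = None
        placed_hyper = False
        while pos < length - 40:
            arm = int(rng.integers(arm_range[0], arm_range[1] + 1))
            if not placed_hyper and pos > length // 2:
                loop = hypervariable_len
                placed_hyper = True
            else:
                loop = int(rng.integers(loop_range[0], loop_range[1] + 1))
            arm5 = _sample(rng, _ARM_W, arm)
            seq_parts.append(arm5)
            a_start = pos
            pos += arm
            if loop == hypervariable_len and placed_hyper and hyper is None:
                hyper = (pos, pos + loop)
            spacer_like = _sample(rng, _RLOOP_W, loop)
            seq_parts.append(spacer_like)
            unpaired.extend(range(pos, pos + loop))
            pos += loop
            seq_parts.append(revcomp(arm5))
            stems.append([(a_start + k, pos + arm - 1 - k) for k in range(arm)])
            pos += arm
            spacer(int(rng.integers(*spacer_range)))
        if pos < length:
            spacer(length - pos)
        seq = "".join(seq_parts)
        assert len(seq) == length
        hyper_cols = set(range(*hyper)) if hyper else set()
        candidates = [c for c in unpaired if c not in hyper_cols]
        n_inv = int(invariable_frac * len(candidates))
        invariable = set(
            rng.choice(np.array(candidates), size=n_inv, replace=False).tolist()
        )
        planted = PlantedRRNA(seq=seq, stems=stems, invariable=invariable,
                              hypervariable=hyper)
        # validate: the noiseless maximum nested pairing must equal the plant
        aln = Alignment(ids=["a", "b"], rows=[seq, seq])
        elig = eligible_pairs(aln)
        recovered = max_nested_pairing(elig, len(seq))
        if sorted(recovered) == sorted(planted.all_pairs()):
            return planted
    raise RuntimeError("could not generate an unambiguous rRNA structure")


def generate_alignment(structure, n: int, sub_rate: float, seed=None,
                       compensatory: float = 0.8,
                       rng: np.random.Generator | None = None):
    """Simulate an alignment (or sequence set) from a planted structure.

    For a :class:`PlantedRRNA`, returns an :class:`Alignment` whose rows
    derive from the ancestor; paired columns mutate compensatorily often
    enough to preserve the 75 % pairing rule at sub_rate <= 0.1, designated
    invariable sites never mutate, and the hypervariable region receives
    elevated substitution plus gaps.  Every mutable column is guaranteed at
    least one variant row (so the planted invariable set is exactly
    recoverable).  For a :class:`TRNAFold`, returns a list of mutated
    sequences.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(structure, TRNAFold):
        return [mutate_trna(structure, sub_rate, rng, compensatory)
                for _ in range(n)]
    planted: PlantedRRNA = structure
    L = len(planted.seq)
    rows = [list(planted.seq) for _ in range(n)]
    pairs = planted.all_pairs()
    paired_cols = {c for p in pairs for c in p}
    hyper = set(range(*planted.hypervariable)) if planted.hypervariable else set()

    def compensate(row, i, j):
        choices = [p for p in _WC_PAIRS if p != (row[i], row[j])]
        row[i], row[j] = choices[rng.integers(len(choices))]

    for i, j in pairs:
        for row in rows:
            if rng.random() < sub_rate:
                if rng.random() < compensatory:
                    compensate(row, i, j)
                else:
                    row[i] = str(rng.choice([b for b in "ACGT" if b != row[i]]))
    for c in range(L):
        if c in paired_cols or c in planted.invariable:
            continue
        in_hyper = c in hyper and sub_rate > 0
        rate = max(sub_rate * 4, 0.3) if in_hyper else sub_rate
        for row in rows:
            if in_hyper and rng.random() < 0.5:
                row[c] = "-"
            elif rng.random() < rate:
                row[c] = str(rng.choice([b for b in "ACGT" if b != row[c]]))
    if sub_rate > 0:
        # every mutable column must differ from the ancestor in at least one
        # row, so the planted invariable set is exactly the constant set; a
        # forced one-sided change in a paired column costs at most 1/n of
        # that pair's eligibility
        for c in range(L):
            if c in planted.invariable:
                continue
            if any(row[c] != planted.seq[c] for row in rows):
                continue
            row = rows[rng.integers(n)]
            row[c] = str(rng.choice([b for b in "ACGT" if b != row[c]]))
    return Alignment(ids=[f"seq{k}" for k in range(n)],
                     rows=["".join(r) for r in rows])


# ---------------------------------------------------------------------------
# Control region and O_L
# ---------------------------------------------------------------------------

_CR_W = _weights({"A": 33.0, "T": 30.0, "G": 15.0, "C": 22.0})


def _cr_filler(rng: np.random.Generator, n: int) -> str:
    """AT-rich filler with T-runs capped at 8 (no accidental poly-T)."""
    out = []
    run = 0
    for _ in range(n):
        b = _sample(rng, _CR_W)
        if b == "T":
            run += 1
            if run > 8:
                b, run = "A", 0
        else:
            run = 0
        out.append(b)
    return "".join(out)


def generate_cr(rng: np.random.Generator,
                params: GeneratorParams = DEFAULT_PARAMS
                ) -> tuple[str, dict[str, tuple[int, int]], tuple[int, int]]:
    """Control region with planted CSBs (order D < I < II < III) and a
    poly-T tract directly upstream of CSB-I."""
    total = int(rng.integers(params.cr_length_range[0],
                             params.cr_length_range[1] + 1))
    refs = params.csb_refs
    blocks = [refs[b] for b in R.CSB_ORDER]
    polyt = "T" * params.polyt_length
    fixed = sum(map(len, blocks)) + len(polyt)
    n_gaps = 5
    slack = total - fixed - 8 * n_gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [slack]])) + 8
    parts, spans = [], {}
    pos = 0

    def add(s):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    add(_cr_filler(rng, int(gap_lens[0])))
    spans["D"] = (pos, pos + len(refs["D"]))
    add(refs["D"])
    add(_cr_filler(rng, int(gap_lens[1])))
    polyt_span = (pos, pos + len(polyt))
    add(polyt)
    spans["I"] = (pos, pos + len(refs["I"]))
    add(refs["I"])
    add(_cr_filler(rng, int(gap_lens[2])))
    spans["II"] = (pos, pos + len(refs["II"]))
    add(refs["II"])
    add(_cr_filler(rng, int(gap_lens[3])))
    spans["III"] = (pos, pos + len(refs["III"]))
    add(refs["III"])
    add(_cr_filler(rng, int(gap_lens[4])))
    cr = "".join(parts)
    assert len(cr) == total
    return cr, spans, polyt_span


def generate_ol(rng: np.random.Generator,
                params: GeneratorParams = DEFAULT_PARAMS,
                max_tries: int = 200) -> tuple[str, int]:
    """O_L hairpin sequence (stem-loop with the GCCGG motif on the 3' arm).

    Returns (hairpin sequence, motif offset).  Validated against
    :func:`find_ol` so the planted stem/loop is the unique best hairpin.
    """
    s, loop = params.ol_stem, params.ol_loop
    for _ in range(max_tries):
        arm5 = _sample(rng, _ARM_W, s)
        arm3 = revcomp(arm5)
        # plant the motif inside the 3' arm, keeping the stem paired:
        # overwrite arm3 and re-derive arm5 as its reverse complement
        m_off = int(rng.integers(0, s - len(R.OL_MOTIF) + 1))
        arm3 = arm3[:m_off] + R.OL_MOTIF + arm3[m_off + len(R.OL_MOTIF):]
        arm5 = revcomp(arm3)
        loop_seq = _sample(rng, _RLOOP_W, loop)
        hairpin = arm5 + loop_seq + arm3
        hit = find_ol(hairpin)
        if (hit is not None and hit.start == 0 and hit.stem_len == s
                and hit.loop_len == loop and hit.motif_identity == 5):
            return hairpin, s + loop + m_off
    raise RuntimeError("could not generate an unambiguous O_L hairpin")


# ---------------------------------------------------------------------------
# Whole-genome assembly
# ---------------------------------------------------------------------------

def generate_canonical_genome(params: GeneratorParams = DEFAULT_PARAMS
                              ) -> tuple[Mitogenome, GroundTruth]:
    """A canonical-order synthetic mitogenome plus its ground truth.

    Same params (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth(order=CANONICAL)

    # 1. component sequences -------------------------------------------------
    trna_seqs: dict[str, str] = {}
    for label in R.TRNA_LABELS:
        fold = generate_trna(label, rng, params)
        truth.trna_folds[label] = fold
        trna_seqs[label] = fold.seq
    truth.mterf_offset = 7

    rrna_seqs: dict[str, str] = {}
    for label, length in params.rrna_lengths.items():
        planted = generate_rrna_structure(rng, length)
        truth.rrna[label] = planted
        rrna_seqs[label] = planted.seq

    # overlap-aware protein construction (shared sequence blocks designed so
    # both reading frames carry valid codons and stops)
    shared_atp = "ATGCACCTAA"   # ATP6 start; last 10 nt of ATP8 (stop TAA)
    shared_nd4 = "ATGCTAA"      # ND4 start; last 7 nt of ND4L (stop TAA)
    protein_seqs = {
        "ATP6": generate_protein("ATP6", rng, params, prefix=shared_atp),
        "ATP8": generate_protein("ATP8", rng, params, suffix=shared_atp),
        "ND4": generate_protein("ND4", rng, params, prefix=shared_nd4),
        "ND4L": generate_protein("ND4L", rng, params, suffix=shared_nd4),
        "ND5": generate_protein("ND5", rng, params, suffix="TTAA"),
        "ND6": generate_protein("ND6", rng, params, suffix="TTAA"),
    }
    for label in R.PROTEIN_LABELS:
        if label not in protein_seqs:
            protein_seqs[label] = generate_protein(label, rng, params)

    cr_seq, csb_spans, polyt_span = generate_cr(rng, params)
    truth.csb_spans = csb_spans
    truth.polyt = polyt_span
    ol_seq, ol_motif_off = generate_ol(rng, params)
    truth.ol_stem, truth.ol_loop = params.ol_stem, params.ol_loop

    # 2. assembly along the canonical order ----------------------------------
    genomic: dict[str, str] = {}
    for label, strand in R.CANONICAL_ORDER:
        kind = R.kind_of(label)
        if kind == "trna":
            sense = trna_seqs[label]
        elif kind == "rrna":
            sense = rrna_seqs[label]
        elif kind == "protein":
            sense = protein_seqs[label]
        elif label == "CR":
            sense = cr_seq
        else:
            sense = ol_seq
        genomic[label] = revcomp(sense) if strand == -1 else sense

    # overlap map: label -> nt shared with the previous feature
    overlap_prev = {"ATP6": params.overlaps[("ATP8", "ATP6")],
                    "ND4": params.overlaps[("ND4L", "ND4")],
                    "ND6": params.overlaps[("ND5", "ND6")]}
    zero_gap_after = {"ATP8", "ND4L", "ND5", "ATP6"}  # overlaps + ATP6|COIII abut

    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    prev_label = None
    for label, strand in R.CANONICAL_ORDER:
        frag = genomic[label]
        ov = overlap_prev.get(label, 0)
        if ov:
            assert seq_parts and "".join(seq_parts)[-ov:] == frag[:ov], \
                f"overlap mismatch at {label}"
            start = pos - ov
            seq_parts.append(frag[ov:])
            pos = start + len(frag)
        else:
            if prev_label is not None and prev_label not in zero_gap_after:
                gap = int(rng.integers(params.gap_range[0],
                                       params.gap_range[1] + 1))
                # A-only spacers flank the O_L so no competing hairpin can
                # extend the planted stem into the intergenic gap
                if label == "OL" or prev_label == "OL":
                    seq_parts.append("A" * gap)
                else:
                    seq_parts.append(_sample(rng, _CR_W, gap))
                pos += gap
            start = pos
            seq_parts.append(frag)
            pos += len(frag)
        features.append(GeneFeature(label, R.kind_of(label),
                                    "H" if strand == 1 else "L",
                                    start, start + len(frag)))
        if label == "OL":
            truth.ol_offset = 0  # refined below once flanks are known
        prev_label = label

    sequence = "".join(seq_parts)
    genome = Mitogenome(
        accession=f"SYN{params.seed:07d}",
        taxon=f"Synthetomichthys exemplaris seed{params.seed}",
        sequence=sequence,
        features=features,
    )
    # record the O_L hairpin offset within the Asn..Cys intergenic region
    asn = genome.get("Asn")
    ol_f = genome.get("OL")
    truth.ol_offset = ol_f.start - asn.end
    return genome, truth


# ---------------------------------------------------------------------------
# Genome-level TDRL
# ---------------------------------------------------------------------------

def generate_rearranged_genome(genome: Mitogenome, block_labels: tuple[str, ...],
                               losses: dict[str, str],
                               params: GeneratorParams = DEFAULT_PARAMS
                               ) -> tuple[Mitogenome, TDRLEvent]:
    """Apply one sequence-level TDRL event to an annotated genome.

    The block is a contiguous run of features (named by label) that must
    not overlap their neighbours; each deleted copy leaves its 5'-most
    ``nc_remnant`` bp behind as an unannotated NC spacer.
    """
    feats = genome.sorted_features()
    labels = [f.label for f in feats]
    try:
        i0 = labels.index(block_labels[0])
    except ValueError:
        raise ValueError(f"block label {block_labels[0]!r} not in genome")
    idx = list(range(i0, i0 + len(block_labels)))
    if [labels[i % len(feats)] for i in idx] != list(block_labels):
        raise ValueError(f"block {block_labels} is not a contiguous run")
    block = [feats[i % len(feats)] for i in idx]
    if any(f.wraps(len(genome)) for f in block):
        raise ValueError("origin-wrapping blocks are not supported")
    lo, hi = block[0].start, block[-1].end
    for f in feats:
        if f in block:
            continue
        if f.start < hi and f.end > lo:
            raise ValueError("block boundary splits an overlapping feature pair")
    seq = genome.sequence
    pieces: list[tuple[str, GeneFeature | None]] = []
    cursor = lo
    for f in block:
        if f.start > cursor:
            pieces.append((seq[cursor : f.start], None))
        pieces.append((seq[f.start : f.end], f))
        cursor = f.end

    new_mid: list[str] = []
    new_feats_mid: list[tuple[int, GeneFeature]] = []
    offset = lo
    for copy_name in ("first", "second"):
        for frag, f in pieces:
            if f is None:
                new_mid.append(frag)
                offset += len(frag)
                continue
            kept = losses.get(f.label, "both")
            if kept in (copy_name, "both"):
                new_feats_mid.append((offset, f))
                new_mid.append(frag)
                offset += len(frag)
            else:
                remnant = frag[: params.nc_remnant]
                new_mid.append(remnant)
                offset += len(remnant)
    new_seq = seq[:lo] + "".join(new_mid) + seq[hi:]
    shift = len(new_seq) - len(seq)
    new_features = []
    for f in genome.features:
        if f in block:
            continue
        if f.start >= hi:
            new_features.append(replace(f, start=f.start + shift,
                                        end=f.end + shift))
        else:
            new_features.append(f)
    for start, f in new_feats_mid:
        new_features.append(replace(f, start=start, end=start + f.length))
    order_block_start = next(
        k for k, (lab, _) in enumerate(CANONICAL.tokens) if lab == block_labels[0]
    )
    event = TDRLEvent(block=(order_block_start, len(block_labels)),
                      losses=dict(losses))
    return Mitogenome(genome.accession + "_tdrl", genome.taxon, new_seq,
                      sorted(new_features, key=lambda f: f.start)), event


def generate_genome_set(n: int, seed: int,
                        rearranged_fraction: float = 0.2,
                        params: GeneratorParams = DEFAULT_PARAMS
                        ) -> list[tuple[Mitogenome, GroundTruth]]:
    """A set of synthetic genomes, a fraction carrying one hotspot TDRL."""
    rng = np.random.default_rng(seed)
    out = []
    events = [
        (("Ile", "Gln", "Met"),
         {"Ile": "first", "Gln": "second", "Met": "first"}),
        (("Trp", "Ala", "Asn"),
         {"Trp": "first", "Ala": "second", "Asn": "first"}),
        (("Thr", "Pro", "CR"),
         {"Thr": "first", "Pro": "second", "CR": "first"}),
    ]
    for k in range(n):
        p = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        genome, truth = generate_canonical_genome(p)
        if rng.random() < rearranged_fraction:
            block, losses = events[int(rng.integers(len(events)))]
            genome, event = generate_rearranged_genome(genome, block, losses, p)
            truth.tdrl_events.append(event)
            order, _ = apply_tdrl(CANONICAL, event.block, event.losses)
            truth.order = order
        out.append((genome, truth))
    return out
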