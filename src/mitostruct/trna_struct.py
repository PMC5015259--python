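"""Constraint-based tRNA cloverleaf folding and position numbering.

The fold search enumerates every partition of the gene sequence into the
cloverleaf architecture (acceptor stem 7 bp, D arm, anticodon arm with a
fixed 7-nt loop, variable loop, T arm, discriminator) within the loop-size
ranges observed across fish mitogenomes, and returns the partition with the
most paired positions (Watson-Crick + G:T wobble).  No thermodynamics is
involved; the search space is small enough to be exhaustive.

Position numbering follows the extended 1-83 scheme in which each loop has
a fixed slot range sized for its maximum observed length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import mannwhitneyu

from .refdata import (
    AA_STEM,
    AC_LOOP,
    AC_STEM,
    ANTICODONS,
    D_LOOP_RANGE,
    D_STEM_RANGE,
    MTERF_TRIDECAMER,
    T_LOOP_RANGE,
    T_STEM,
    V_LOOP_RANGE,
)

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


def classify_pair(b1: str, b2: str) -> str:
    """Classify a base pair as watson_crick, wobble, or mismatch (symmetric)."""
    if b1 not in "ACGT" or b2 not in "ACGT":
        raise ValueError(f"ambiguous base in pair ({b1!r}, {b2!r})")
    if (b1, b2) in WATSON_CRICK:
        return "watson_crick"
    if (b1, b2) in WOBBLE:
        return "wobble"
    return "mismatch"


def is_paired(b1: str, b2: str) -> bool:
    return (b1, b2) in WATSON_CRICK or (b1, b2) in WOBBLE


@dataclass(frozen=True)
class FoldParams:
    """Architecture constraints for the fold search.

    Linkers follow the standard tRNA convention: 2 nt between the acceptor
    stem and the D arm (positions 8-9) and 1 nt between the D arm and the
    anticodon arm (position 26).
    """

    linker1: int = 2
    linker2: int = 1
    d_stem_options: tuple[int, ...] = D_STEM_RANGE
    d_loop_range: tuple[int, int] = D_LOOP_RANGE
    v_loop_range: tuple[int, int] = V_LOOP_RANGE
    t_loop_range: tuple[int, int] = T_LOOP_RANGE
    # identities allowed to replace the D arm by a single loop (D stem = 0)
    d_replacement_identities: tuple[str, ...] = ("Ser(AGY)",)
    min_length: int = 55
    max_length: int = 95


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass(frozen=True)
class Architecture:
    d_stem: int
    d_loop: int
    v_loop: int
    t_loop: int

    @property
    def length(self) -> int:
        # AA 7 + linker 2 + D arm + linker 1 + AC arm 17 + V + T arm 15 + disc 1
        return 45 + 2 * self.d_stem + self.d_loop + self.v_loop + self.t_loop


@dataclass
class TRNAFold:
    """A cloverleaf decomposition of one tRNA gene sequence."""

    seq: str
    arch: Architecture
    pairs: list[tuple[int, int, str]] = field(default_factory=list)  # (i, j, class)
    score: int = 0

    @property
    def anticodon(self) -> str:
        i = self.spans()["ac_loop"][0]
        return self.seq[i + 2 : i + 5]

    def spans(self) -> dict[str, tuple[int, int]]:
        """0-based half-open spans of every architectural element."""
        a = self.arch
        p = 0
        out = {}

        def take(name, n):
            nonlocal p
            out[name] = (p, p + n)
            p += n

        take("aa_stem5", AA_STEM)
        take("linker1", 2)
        take("d_stem5", a.d_stem)
        take("d_loop", a.d_loop)
        take("d_stem3", a.d_stem)
        take("linker2", 1)
        take("ac_stem5", AC_STEM)
        take("ac_loop", AC_LOOP)
        take("ac_stem3", AC_STEM)
        take("v_loop", a.v_loop)
        take("t_stem5", T_STEM)
        take("t_loop", a.t_loop)
        take("t_stem3", T_STEM)
        take("aa_stem3", AA_STEM)
        take("discriminator", 1)
        assert p == len(self.seq)
        return out

    def d_arm_span(self) -> tuple[int, int]:
        s = self.spans()
        return s["d_stem5"][0], s["d_stem3"][1]

    def stem_pairs(self, stem: str) -> list[tuple[int, int, str]]:
        """Pairs of one stem: 'aa', 'd', 'ac' or 't'."""
        s = self.spans()
        lo, hi = s[f"{stem}_stem5"]
        return [p for p in self.pairs if lo <= p[0] < hi]

    def dot_bracket(self) -> str:
        out = ["." for _ in self.seq]
        for i, j, cls in self.pairs:
            if cls != "mismatch":
                out[i], out[j] = "(", ")"
        return "".join(out)


def _pair_indices(arch: Architecture) -> list[tuple[int, int]]:
    """(5', 3') paired position indices for an architecture."""
    a = arch
    pairs = []
    L = a.length
    # acceptor stem: 0..6 with L-2..L-8 (discriminator is L-1)
    pairs += [(k, L - 2 - k) for k in range(AA_STEM)]
    # D stem
    d5 = AA_STEM + 2
    d3_end = d5 + 2 * a.d_stem + a.d_loop
    pairs += [(d5 + k, d3_end - 1 - k) for k in range(a.d_stem)]
    # AC stem
    ac5 = d3_end + 1
    ac3_end = ac5 + 2 * AC_STEM + AC_LOOP
    pairs += [(ac5 + k, ac3_end - 1 - k) for k in range(AC_STEM)]
    # T stem
    t5 = ac3_end + a.v_loop
    t3_end = t5 + 2 * T_STEM + a.t_loop
    pairs += [(t5 + k, t3_end - 1 - k) for k in range(T_STEM)]
    return pairs


def enumerate_architectures(length: int, identity: str | None,
                            params: FoldParams = DEFAULT_FOLD_PARAMS):
    d_opts = list(params.d_stem_options)
    if identity in params.d_replacement_identities:
        d_opts = [0] + d_opts
    archs = []
    for d in d_opts:
        for dl in range(params.d_loop_range[0], params.d_loop_range[1] + 1):
            for v in range(params.v_loop_range[0], params.v_loop_range[1] + 1):
                tl = length - 45 - 2 * d - dl - v
                if params.t_loop_range[0] <= tl <= params.t_loop_range[1]:
                    archs.append(Architecture(d, dl, v, tl))
    return archs


def fold_trna(seq: str, identity: str | None = None,
              params: FoldParams = DEFAULT_FOLD_PARAMS) -> TRNAFold:
    """Fold a sense-strand tRNA gene sequence into its best cloverleaf.

    Exhaustive over the constrained partition space; the partition with the
    highest paired-position count wins, ties broken by larger D stem, then
    smaller D loop, then 5'-most anticodon stem.  An anticodon disagreeing
    with ``identity`` triggers a warning, not an error.
    """
    seq = seq.upper()
    L = len(seq)
    if not params.min_length <= L <= params.max_length:
        raise ValueError(f"sequence length {L} outside [{params.min_length}, "
                         f"{params.max_length}]")
    archs = enumerate_architectures(L, identity, params)
    if not archs:
        raise ValueError(
            f"no feasible cloverleaf partition for length {L}: loop-range "
            f"constraints cannot be satisfied"
        )
    best = None
    for arch in archs:
        idx = _pair_indices(arch)
        pairs = [(i, j, classify_pair(seq[i], seq[j])) for i, j in idx]
        n_paired = sum(1 for _, _, c in pairs if c != "mismatch")
        score = 2 * n_paired
        mismatches = len(pairs) - n_paired
        ac5_start = 10 + 2 * arch.d_stem + arch.d_loop
        # fewer mismatched stem positions breaks score ties before the
        # larger-D-stem rule: otherwise a 4-bp D stem with one mismatched
        # pair would always shadow a clean 3-bp stem of equal score
        key = (score, -mismatches, arch.d_stem, -arch.d_loop, -ac5_start)
        if best is None or key > best[0]:
            best = (key, arch, pairs, score)
    _, arch, pairs, score = best
    if score == 0:
        raise ValueError("no stem can pair: every candidate partition scores 0")
    fold = TRNAFold(seq=seq, arch=arch, pairs=pairs, score=score)
    if identity is not None and identity in ANTICODONS:
        if fold.anticodon != ANTICODONS[identity]:
            warnings.warn(
                f"anticodon {fold.anticodon} does not match expected "
                f"{ANTICODONS[identity]} for tRNA-{identity}",
                stacklevel=2,
            )
    return fold


# ---------------------------------------------------------------------------
# 1-83 position numbering
# ---------------------------------------------------------------------------

# slot ranges (inclusive) for each element in the extended numbering
_SLOTS = {
    "aa_stem5": (1, 7), "linker1": (8, 9), "d_stem5": (10, 13),
    "d_loop": (14, 27), "d_stem3": (28, 31), "linker2": (32, 32),
    "ac_stem5": (33, 37), "ac_loop": (38, 44), "ac_stem3": (45, 49),
    "v_loop": (50, 55), "t_stem5": (56, 60), "t_loop": (61, 70),
    "t_stem3": (71, 75), "aa_stem3": (76, 82), "discriminator": (83, 83),
}

MAX_POSITION = 83


@dataclass
class PositionMap:
    """Mapping from 0-based fold positions to 1-83 slot numbers."""

    numbers: dict[int, int]
    fold: TRNAFold

    def pair_sites(self) -> list[tuple[int, int]]:
        """Numbered pair-site labels, e.g. (2, 81)."""
        return [(self.numbers[i], self.numbers[j]) for i, j, _ in self.fold.pairs]

    @property
    def max_index(self) -> int:
        return max(self.numbers.values())


def number_positions(fold: TRNAFold) -> PositionMap:
    """Assign 1-83 numbers to every fold position.

    Loops fill their slot ranges from the 5' side, unused slots skipped.
    Shortened D stems keep the pairing symmetry: a 3-bp D stem occupies
    10-12 on the 5' side and 29-31 on the 3' side.
    """
    spans = fold.spans()
    numbers: dict[int, int] = {}
    for name, (lo, hi) in spans.items():
        n = hi - lo
        slo, shi = _SLOTS[name]
        if name == "d_stem3":
            # fill from the 3' end of the slot so pairs mirror the 5' side
            nums = range(shi - n + 1, shi + 1)
        else:
            nums = range(slo, slo + n)
        for pos, num in zip(range(lo, hi), nums):
            numbers[pos] = num
    return PositionMap(numbers=numbers, fold=fold)


# ---------------------------------------------------------------------------
# Wobble statistics
# ---------------------------------------------------------------------------

_STEM_SIZES = {"aa": AA_STEM, "d": None, "ac": AC_STEM, "t": T_STEM}


def wobble_stats(folds: list[tuple[str, str, TRNAFold]]) -> pd.DataFrame:
    """Occurrence of wobble pairings per tRNA x stem.

    ``folds`` is a list of (trna_label, strand, fold).  Returns a table with
    wobble counts, pair denominators (pairs x genes) and percentages per
    stem, plus per-row strand; percentages are recomputed from counts.
    """
    if not folds:
        raise ValueError("at least one fold required")
    rows: dict[tuple[str, str], dict] = {}
    for label, strand, fold in folds:
        key = (label, strand)
        row = rows.setdefault(
            key,
            {"trna": label, "strand": strand, "n_genes": 0,
             **{f"{s}_wobble": 0 for s in _STEM_SIZES},
             **{f"{s}_pairs": 0 for s in _STEM_SIZES}},
        )
        row["n_genes"] += 1
        for stem in _STEM_SIZES:
            pairs = fold.stem_pairs(stem)
            row[f"{stem}_pairs"] += len(pairs)
            row[f"{stem}_wobble"] += sum(1 for _, _, c in pairs if c == "wobble")
    out = pd.DataFrame(rows.values())
    for stem in _STEM_SIZES:
        out[f"{stem}_pct"] = 100.0 * out[f"{stem}_wobble"] / out[f"{stem}_pairs"].where(
            out[f"{stem}_pairs"] > 0
        )
    total_w = sum(out[f"{s}_wobble"] for s in _STEM_SIZES)
    total_p = sum(out[f"{s}_pairs"] for s in _STEM_SIZES)
    out["total_wobble"] = total_w
    out["total_pairs"] = total_p
    out["total_pct"] = 100.0 * total_w / total_p.where(total_p > 0)
    return out.sort_values(["strand", "trna"]).reset_index(drop=True)


def strand_wobble_test(table: pd.DataFrame) -> dict:
    """Mann-Whitney U comparison of per-tRNA wobble rates between strands."""
    l_rates = table.loc[table.strand == "L", "total_pct"].dropna()
    h_rates = table.loc[table.strand == "H", "total_pct"].dropna()
    stat, p = mannwhitneyu(l_rates, h_rates, alternative="greater")
    return {
        "l_mean_pct": float(l_rates.mean()),
        "h_mean_pct": float(h_rates.mean()),
        "u_statistic": float(stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# mTERF tridecamer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    offset: int
    matched: str
    identity: int  # matching positions out of 13
    present: bool
    overlaps_d_arm: bool | None


def find_mterf_motif(seq: str, fold: TRNAFold | None = None,
                     threshold: int = 10) -> MotifHit:
    """Best ungapped alignment of the human mTERF tridecamer in ``seq``.

    Absence (best identity below ``threshold`` of 13) is a result, not an
    error.  When a fold is supplied, reports whether the hit overlaps the
    D arm.
    """
    motif = MTERF_TRIDECAMER
    k = len(motif)
    if len(seq) < k:
        return MotifHit(-1, "", 0, False, None)
    best_off, best_id = 0, -1
    for off in range(len(seq) - k + 1):
        ident = sum(1 for a, b in zip(seq[off : off + k], motif) if a == b)
        if ident > best_id:
            best_off, best_id = off, ident
    overlaps = None
    if fold is not None:
        lo, hi = fold.d_arm_span()
        overlaps = best_off < hi and best_off + k > lo
    return MotifHit(
        offset=best_off,
        matched=seq[best_off : best_off + k],
        identity=best_id,
        present=best_id >= threshold,
        overlaps_d_arm=overlaps,
    )
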