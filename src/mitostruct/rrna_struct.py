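"""Consensus rRNA stem inference from multiple sequence alignments.

A column pair is *eligible* when at least a threshold fraction (default
75 %) of the aligned sequences form a Watson-Crick or G:U wobble pair at
those two columns.  A maximum-cardinality nested pairing over eligible
pairs is computed by dynamic programming (Nussinov-style, sparse over the
eligible partner lists) and segmented into stems: unilateral bulges up to a
cap are absorbed, bilateral interior gaps of two or more columns on both
sides delimit stems.  Pseudoknots are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

# base encoding: A=0 C=1 G=2 T=3 N=4 -=5
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4, "-": 5, ".": 5}
# pairing lookup over codes 0..5 (RNA-style: WC + G:U wobble; N/gap never pair)
_PAIR_OK = np.zeros((6, 6), dtype=bool)
for _a, _b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _PAIR_OK[_a, _b] = True


@dataclass
class Alignment:
    """Equal-length gapped sequences over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise ValueError("alignment needs at least 1 column")
        self._codes = np.array(
            [[_ENC[c] for c in row.upper()] for row in self.rows], dtype=np.int8
        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        aln = AlignIO.read(str(path), fmt)
        return cls(ids=[r.id for r in aln], rows=[str(r.seq) for r in aln])


def pairing_fraction(aln: Alignment, i: int, j: int,
                     count_gapped_rows: bool = True) -> float:
    """Fraction of rows whose (i, j) bases form a WC or wobble pair.

    Rows with a gap or N at either column never count as paired; under the
    default conservative reading they stay in the denominator.
    """
    if i == j:
        raise ValueError("columns must differ")
    ci, cj = aln.codes[:, i], aln.codes[:, j]
    paired = _PAIR_OK[ci, cj]
    if count_gapped_rows:
        return float(paired.sum()) / aln.n_rows
    defined = (ci < 4) & (cj < 4)
    n = int(defined.sum())
    return float(paired[defined].sum()) / n if n else 0.0


@dataclass
class Stem:
    """A run of nested column pairs forming one stem."""

    pairs: list[tuple[int, int]]  # i ascending, j descending
    eligibility: list[float]
    bulges: list[int] = field(default_factory=list)  # absorbed unilateral columns

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def span5(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0] + 1

    @property
    def span3(self) -> tuple[int, int]:
        return self.pairs[-1][1], self.pairs[0][1] + 1


@dataclass
class ConsensusStructure:
    stems: list[Stem]
    invariable: set[int] = field(default_factory=set)
    variability: np.ndarray | None = None
    hypervariable: set[int] = field(default_factory=set)

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for s in self.stems for p in s.pairs]

    def dot_bracket(self, n_cols: int) -> str:
        out = ["." for _ in range(n_cols)]
        for i, j in self.all_pairs():
            out[i], out[j] = "(", ")"
        return "".join(out)


MIN_SEPARATION = 3  # minimum unpaired columns enclosed by a pair


def eligible_pairs(aln: Alignment, threshold: float = 0.75,
                   count_gapped_rows: bool = True,
                   allow_wobble: bool = True,
                   min_separation: int = MIN_SEPARATION) -> dict[tuple[int, int], float]:
    """All column pairs (i < j) meeting the pairing-fraction threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    codes = aln.codes
    n_rows, n_cols = codes.shape
    table = _PAIR_OK.copy()
    if not allow_wobble:
        table[2, 3] = table[3, 2] = False
    out: dict[tuple[int, int], float] = {}
    for i in range(n_cols - min_separation - 1):
        ci = codes[:, i]
        js = np.arange(i + min_separation + 1, n_cols)
        paired = table[ci[:, None], codes[:, js]]  # (rows, len(js))
        if count_gapped_rows:
            fracs = paired.sum(axis=0) / n_rows
        else:
            defined = (ci[:, None] < 4) & (codes[:, js] < 4)
            denom = defined.sum(axis=0)
            with np.errstate(invalid="ignore"):
                fracs = np.where(denom > 0,
                                 (paired & defined).sum(axis=0) / np.maximum(denom, 1),
                                 0.0)
        for j, frac in zip(js[fracs >= threshold], fracs[fracs >= threshold]):
            out[(i, int(j))] = float(frac)
    return out


def max_nested_pairing(eligible: dict[tuple[int, int], float],
                       n_cols: int) -> list[tuple[int, int]]:
    """Maximum-cardinality nested (non-crossing) pairing over eligible pairs.

    Deterministic tie-break: at every interval the 5'-most column is paired
    whenever pairing it preserves the maximum, with the smallest admissible
    partner.
    """
    partners: list[list[int]] = [[] for _ in range(n_cols)]
    for (i, j) in sorted(eligible):
        partners[i].append(j)
    # M[i][j] over half-open interval [i, j); filled for i descending with
    # the inner maximization vectorized over j
    M = np.zeros((n_cols + 1, n_cols + 1), dtype=np.int32)
    for i in range(n_cols - 1, -1, -1):
        row = M[i + 1].copy()
        for k in partners[i]:
            cand = 1 + M[i + 1][k] + M[k + 1, k + 1:]
            np.maximum(row[k + 1:], cand, out=row[k + 1:])
        M[i] = row
    pairs: list[tuple[int, int]] = []
    stack = [(0, n_cols)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 or M[i][j] == 0:
            continue
        chosen = None
        for k in partners[i]:
            if k >= j:
                break
            if 1 + M[i + 1][k] + M[k + 1][j] == M[i][j]:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen))
            stack.append((chosen + 1, j))
    return sorted(pairs)


BULGE_CAP = 3  # maximum absorbed unilateral bulge (columns)


def _segment_stems(pairs: list[tuple[int, int]],
                   eligible: dict[tuple[int, int], float],
                   bulge_cap: int = BULGE_CAP) -> list[Stem]:
    """Split a nested pairing into stems.

    Consecutive nested pairs extend a stem; a unilateral skip of up to
    ``bulge_cap`` columns on one side is absorbed as an internal bulge; a
    bilateral interior gap of >= 2 columns on both sides (or a skip beyond
    the cap) terminates the stem.  Stems of fewer than 2 pairs drop out.
    """
    stems: list[Stem] = []
    current: list[tuple[int, int]] = []
    bulges: list[int] = []

    def flush():
        nonlocal current, bulges
        if len(current) >= 2:
            stems.append(Stem(
                pairs=current,
                eligibility=[eligible[p] for p in current],
                bulges=bulges,
            ))
        current, bulges = [], []

    # group by nesting chains: sort by i; a pair (i2, j2) continues (i1, j1)
    # when i1 < i2 and j2 < j1 with small gaps
    for pair in pairs:
        if not current:
            current = [pair]
            continue
        i1, j1 = current[-1]
        i2, j2 = pair
        if not (i2 > i1 and j2 < j1):
            flush()
            current = [pair]
            continue
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a == 0 and b == 0:
            current.append(pair)
        elif (a >= 2 and b >= 2) or a > bulge_cap or b > bulge_cap:
            flush()
            current = [pair]
        else:
            bulges.extend(range(i1 + 1, i2))
            bulges.extend(range(j2 + 1, j1))
            current.append(pair)
    flush()
    return stems


def invariable_sites(aln: Alignment, allow_gaps: bool = False) -> set[int]:
    """Columns where every row shares a single base (gaps disallowed by default)."""
    codes = aln.codes
    out = set()
    for col in range(aln.n_cols):
        c = codes[:, col]
        if allow_gaps:
            c = c[c < 4]
            if c.size == 0:
                continue
        if np.all(c == c[0]) and c[0] < 4:
            out.add(col)
    return out


def variability_profile(aln: Alignment, window: int = 10,
                        quantile: float = 0.9,
                        gap_frac_flag: float = 0.5) -> tuple[np.ndarray, set[int]]:
    """Per-column variability score plus hypervariable flags.

    Score = fraction of rows differing from the column consensus, smoothed
    with a centred moving average.  Columns whose smoothed score exceeds the
    given quantile of the profile are flagged, as are gap-rich columns.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = aln.codes
    n_rows, n_cols = codes.shape
    scores = np.empty(n_cols)
    gap_rich = set()
    for col in range(n_cols):
        c = codes[:, col]
        vals, counts = np.unique(c, return_counts=True)
        consensus = vals[np.argmax(counts)]
        scores[col] = float(np.sum(c != consensus)) / n_rows
        if float(np.sum(c == 5)) / n_rows >= gap_frac_flag:
            gap_rich.add(col)
    kernel = np.ones(window) / window
    smoothed = np.convolve(scores, kernel, mode="same")
    cut = np.quantile(smoothed, quantile)
    flags = {c for c in range(n_cols) if smoothed[c] > cut} | gap_rich
    return smoothed, flags


def find_consensus_stems(aln: Alignment, threshold: float = 0.75,
                         seed_structure: ConsensusStructure | None = None,
                         count_gapped_rows: bool = True,
                         bulge_cap: int = BULGE_CAP,
                         min_separation: int = MIN_SEPARATION) -> ConsensusStructure:
    """Infer the consensus secondary structure of an rRNA alignment.

    With ``seed_structure`` only pairs within +-2 columns of a seed pair are
    considered (re-evaluation of a prior model under the threshold rule);
    otherwise the search is de novo over all eligible pairs.
    """
    elig = eligible_pairs(aln, threshold=threshold,
                          count_gapped_rows=count_gapped_rows,
                          min_separation=min_separation)
    if seed_structure is not None:
        seeds = seed_structure.all_pairs()
        elig = {
            (i, j): f for (i, j), f in elig.items()
            if any(abs(i - si) <= 2 and abs(j - sj) <= 2 for si, sj in seeds)
        }
    pairs = max_nested_pairing(elig, aln.n_cols)
    stems = _segment_stems(pairs, elig, bulge_cap=bulge_cap)
    inv = invariable_sites(aln)
    scores, flags = variability_profile(aln)
    return ConsensusStructure(
        stems=stems, invariable=inv, variability=scores,
        hypervariable=flags - inv,
    )


def stems_table(structure: ConsensusStructure):
    import pandas as pd

    rows = []
    for k, s in enumerate(structure.stems, 1):
        rows.append({
            "stem": k,
            "span5_start": s.span5[0], "span5_end": s.span5[1],
            "span3_start": s.span3[0], "span3_end": s.span3[1],
            "n_pairs": s.n_pairs,
            "mean_eligibility": float(np.mean(s.eligibility)),
            "n_bulge_cols": len(s.bulges),
        })
    return pd.DataFrame(rows)
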