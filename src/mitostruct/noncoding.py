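"""Control-region and origin-of-light-strand-replication feature detection.

The control region (CR) is scanned for the four conserved sequence blocks
(CSB-D, -I, -II, -III) by best ungapped sliding-window identity against
shared reference sequences, and for poly-T homopolymer runs longer than
eight nucleotides.  The O_L is located inside the WANCY tRNA cluster as the
inverted repeat maximizing paired positions within the observed stem/loop
bounds, with its replication motif (5'-GCCGG-3') scored separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import BaseComposition, base_composition
from .refdata import (
    CSB_ORDER,
    CSB_REFERENCES,
    OL_LOOP_RANGE,
    OL_MOTIF,
    OL_STEM_RANGE,
)
from .trna_struct import classify_pair, is_paired

PRESENT_IDENTITY = 0.7
PARTIAL_IDENTITY = 0.5


@dataclass(frozen=True)
class CSBHit:
    block: str  # D, I, II, III
    start: int
    end: int
    matched: str
    identity: float
    status: str  # present | partial | absent


@dataclass
class CSBScan:
    hits: list[CSBHit]
    order_ok: bool

    def hit(self, block: str) -> CSBHit:
        return next(h for h in self.hits if h.block == block)


def _best_window(seq: str, ref: str) -> tuple[int, float]:
    k = len(ref)
    best_off, best_id = 0, -1.0
    for off in range(len(seq) - k + 1):
        ident = sum(1 for a, b in zip(seq[off : off + k], ref) if a == b) / k
        if ident > best_id:
            best_off, best_id = off, ident
    return best_off, best_id


def find_csbs(cr: str, refs: dict[str, str] | None = None,
              present_identity: float = PRESENT_IDENTITY,
              partial_identity: float = PARTIAL_IDENTITY) -> CSBScan:
    """Locate the four CSBs within a control-region sequence.

    Each block's best ungapped window is classified present/partial/absent
    by identity.  A violation of the canonical D < I < II < III ordering of
    the present blocks is reported as ``order_ok=False``, not an error.
    """
    if not cr:
        raise ValueError("empty control-region sequence")
    refs = dict(CSB_REFERENCES if refs is None else refs)
    missing = [b for b in CSB_ORDER if not refs.get(b)]
    if missing:
        raise ValueError(f"missing CSB reference(s): {missing}")
    hits = []
    for block in CSB_ORDER:
        ref = refs[block]
        if len(cr) < len(ref):
            hits.append(CSBHit(block, 0, 0, "", 0.0, "absent"))
            continue
        off, ident = _best_window(cr, ref)
        status = ("present" if ident >= present_identity
                  else "partial" if ident >= partial_identity else "absent")
        hits.append(CSBHit(block, off, off + len(ref), cr[off : off + len(ref)],
                           ident, status))
    present = [h for h in hits if h.status == "present"]
    starts = [h.start for h in present]
    return CSBScan(hits=hits, order_ok=starts == sorted(starts))


def find_polyt(cr: str, min_run: int = 9) -> list[tuple[int, int]]:
    """Maximal runs of T longer than eight nucleotides: (offset, length)."""
    runs = []
    i, L = 0, len(cr)
    while i < L:
        if cr[i] == "T":
            j = i
            while j < L and cr[j] == "T":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# O_L stem-loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OLHit:
    start: int  # offset of the hairpin within the searched region
    end: int
    stem_len: int
    loop_len: int
    n_paired: int  # paired positions (2 per intact pair)
    pair_classes: tuple[str, ...]
    motif_offset: int
    motif_matched: str
    motif_identity: int  # out of 5

    @property
    def loop_span(self) -> tuple[int, int]:
        return self.start + self.stem_len, self.start + self.stem_len + self.loop_len


def _motif_scan(region: str, motif: str = OL_MOTIF) -> tuple[int, int]:
    k = len(motif)
    best_off, best_id = 0, -1
    for off in range(max(len(region) - k + 1, 1)):
        window = region[off : off + k]
        ident = sum(1 for a, b in zip(window, motif) if a == b)
        if ident > best_id:
            best_off, best_id = off, ident
    return best_off, max(best_id, 0)


def find_ol(region: str,
            stem_range: tuple[int, int] = OL_STEM_RANGE,
            loop_range: tuple[int, int] = OL_LOOP_RANGE,
            mismatch_per_10bp: int = 1) -> OLHit | None:
    """Best stem-loop hairpin in the region between tRNA-Asn and tRNA-Cys.

    Scans every (offset, stem, loop) candidate; a stem of s bp tolerates
    ``s // 10 * mismatch_per_10bp`` internal mismatches (terminal pairs must
    pair).  Returns the hit maximizing paired positions, ties broken by
    longer stem then 5'-most offset; ``None`` when no stem of at least the
    minimum length exists.
    """
    L = len(region)
    best = None
    best_key = None
    for s in range(stem_range[0], stem_range[1] + 1):
        allowed_mm = (s // 10) * mismatch_per_10bp
        for loop in range(loop_range[0], loop_range[1] + 1):
            span = 2 * s + loop
            if span > L:
                continue
            for off in range(L - span + 1):
                arm5 = region[off : off + s]
                arm3 = region[off + s + loop : off + span]
                mm = 0
                ok = True
                for k in range(s):
                    if not is_paired(arm5[k], arm3[s - 1 - k]):
                        if k == 0 or k == s - 1:  # terminal pairs must hold
                            ok = False
                            break
                        mm += 1
                        if mm > allowed_mm:
                            ok = False
                            break
                if not ok:
                    continue
                n_paired = 2 * (s - mm)
                key = (n_paired, s, -off)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (off, s, loop, mm)
    if best is None:
        return None
    off, s, loop, mm = best
    span = 2 * s + loop
    arm5 = region[off : off + s]
    arm3 = region[off + s + loop : off + span]
    classes = tuple(classify_pair(arm5[k], arm3[s - 1 - k]) for k in range(s))
    m_off, m_id = _motif_scan(region[off : off + span])
    return OLHit(
        start=off, end=off + span, stem_len=s, loop_len=loop,
        n_paired=2 * (s - mm), pair_classes=classes,
        motif_offset=off + m_off,
        motif_matched=region[off + m_off : off + m_off + len(OL_MOTIF)],
        motif_identity=m_id,
    )


def ol_region_composition(hit: OLHit, region: str) -> tuple[BaseComposition, BaseComposition]:
    """Base composition of the hairpin stem (both arms) and of the loop."""
    s = hit.stem_len
    stem_seq = (region[hit.start : hit.start + s]
                + region[hit.start + s + hit.loop_len : hit.end])
    loop_seq = region[hit.loop_span[0] : hit.loop_span[1]]
    return base_composition(stem_seq), base_composition(loop_seq)
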