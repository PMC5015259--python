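"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 0-based half-open internally.  A feature span is stored as
``(start, end)`` with ``0 <= start < L`` and ``start < end <= start + L``;
an ``end`` beyond the genome length encodes a feature wrapping the origin
of the circular molecule.  GenBank 1-based inclusive coordinates are
converted at the I/O boundary.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .refdata import ALL_LABELS, SYNONYMS, kind_of

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A typed, stranded gene feature on a circular genome.

    ``strand`` is ``"H"`` (heavy) or ``"L"`` (light).  ``end`` may exceed
    the genome length to represent a feature wrapping the origin.
    """

    label: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown gene label: {self.label!r}")
        if kind_of(self.label) != self.kind:
            raise ValueError(
                f"label {self.label!r} implies kind {kind_of(self.label)!r}, "
                f"got {self.kind!r}"
            )
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not self.end > self.start >= 0:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class Mitogenome:
    """Circular DNA sequence plus typed gene features."""

    accession: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            if f.length > L or f.start >= L or f.end > f.start + L:
                raise ValueError(
                    f"feature {f.label} span [{f.start},{f.end}) does not fit "
                    f"genome of length {L}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def get(self, label: str) -> GeneFeature:
        hits = [f for f in self.features if f.label == label]
        if not hits:
            raise KeyError(label)
        if len(hits) > 1:
            raise KeyError(f"label {label!r} is duplicated; use .features")
        return hits[0]


@dataclass(frozen=True)
class BaseComposition:
    """Base percentages over non-N sites."""

    a: float
    c: float
    g: float
    t: float
    n_sites: int

    @classmethod
    def from_counts(cls, counts: Counter) -> "BaseComposition":
        n = sum(counts[b] for b in "ACGT")
        if n == 0:
            return cls(float("nan"), float("nan"), float("nan"), float("nan"), 0)
        return cls(
            a=100.0 * counts["A"] / n,
            c=100.0 * counts["C"] / n,
            g=100.0 * counts["G"] / n,
            t=100.0 * counts["T"] / n,
            n_sites=n,
        )

    @property
    def defined(self) -> bool:
        return self.n_sites > 0

    def as_dict(self) -> dict[str, float]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}


def base_composition(seq: str) -> BaseComposition:
    """Base composition of ``seq``; N sites excluded from the denominator."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    return BaseComposition.from_counts(Counter(seq))


def extract_gene_sequence(genome: Mitogenome, feature: GeneFeature) -> str:
    """Sense (coding-strand) sequence of ``feature``.

    L-strand features are returned reverse-complemented; origin wrapping is
    handled by slicing the doubled sequence.
    """
    if feature not in genome.features:
        raise ValueError(f"feature {feature.label} does not belong to genome")
    doubled = genome.sequence + genome.sequence
    sub = doubled[feature.start : feature.end]
    return revcomp(sub) if feature.strand == "L" else sub


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_FEATURE_TYPE = {"protein": "CDS", "trna": "tRNA", "rrna": "rRNA"}


def _resolve_label(names: list[str], synonyms: dict[str, str]) -> str | None:
    for name in names:
        key = name.strip().lower()
        if key in synonyms:
            return synonyms[key]
        if name.strip() in ALL_LABELS:
            return name.strip()
    return None


def _span_from_location(loc, L: int) -> tuple[int, int]:
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 1:
        return int(loc.start), int(loc.end)
    if len(parts) == 2:
        by_start = sorted(parts, key=lambda p: int(p.start))
        hi, lo = by_start[1], by_start[0]
        if int(hi.end) == L and int(lo.start) == 0:
            return int(hi.start), L + int(lo.end)
    raise ValueError(f"unsupported compound location: {loc}")


def read_genbank(path, synonyms: dict[str, str] | None = None) -> Mitogenome:
    """Read one annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop/rep_origin features are mapped to the controlled
    label vocabulary through the synonym table; an unmappable label raises
    ``ValueError`` naming the offending qualifier.
    """
    table = dict(SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    record = SeqIO.read(str(path), "genbank")
    L = len(record.seq)
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type in ("source", "gene", "misc_feature"):
            continue
        if feat.type == "D-loop":
            label = "CR"
        elif feat.type == "rep_origin":
            label = "OL"
        elif feat.type in ("CDS", "tRNA", "rRNA"):
            names = feat.qualifiers.get("gene", []) + feat.qualifiers.get("product", [])
            label = _resolve_label(names, table)
            if label is None:
                raise ValueError(
                    f"unmappable gene label in {feat.type} feature: "
                    f"qualifiers {names!r}"
                )
        else:
            continue
        start, end = _span_from_location(feat.location, L)
        if end > start + L or start >= L or end <= start:
            raise ValueError(f"feature {label} outside sequence: [{start},{end})")
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(GeneFeature(label, kind_of(label), strand, start, end))
    return Mitogenome(
        accession=record.id,
        taxon=record.annotations.get("organism", record.description),
        sequence=str(record.seq).upper(),
        features=features,
    )


def to_seqrecord(genome: Mitogenome) -> SeqRecord:
    L = len(genome.sequence)
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16],
        description=f"{genome.taxon} mitochondrion, complete genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["organism"] = genome.taxon
    record.annotations["date"] = "01-JAN-2000"  # fixed for byte determinism
    for f in genome.sorted_features():
        strand = -1 if f.strand == "L" else 1
        if f.end <= L:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:
            p1 = SimpleLocation(f.start, L, strand=strand)
            p2 = SimpleLocation(0, f.end - L, strand=strand)
            loc = CompoundLocation([p1, p2] if strand == 1 else [p2, p1])
        if f.kind == "noncoding":
            ftype = "D-loop" if f.label == "CR" else "rep_origin"
            qualifiers = {"note": ["control region" if f.label == "CR"
                                   else "origin of L-strand replication"]}
        else:
            ftype = _FEATURE_TYPE[f.kind]
            if f.kind == "trna":
                qualifiers = {"product": [f"tRNA-{f.label}"]}
            elif f.kind == "rrna":
                qualifiers = {"product": [f"{f.label} ribosomal RNA"]}
            else:
                qualifiers = {"gene": [f.label]}
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=qualifiers))
    return record


def write_genbank(genome: Mitogenome, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(to_seqrecord(genome), fh, "genbank")


def genbank_bytes(genome: Mitogenome) -> bytes:
    buf = io.StringIO()
    SeqIO.write(to_seqrecord(genome), buf, "genbank")
    return buf.getvalue().encode()


def feature_table(genome: Mitogenome) -> pd.DataFrame:
    """TSV-ready feature table (accession, label, kind, strand, start, end, length)."""
    rows = [
        {
            "accession": genome.accession,
            "label": f.label,
            "kind": f.kind,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "length": f.length,
        }
        for f in genome.sorted_features()
    ]
    return pd.DataFrame(rows)


def write_feature_table(genome: Mitogenome, path_or_buffer) -> None:
    feature_table(genome).to_csv(path_or_buffer, sep="\t", index=False)
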