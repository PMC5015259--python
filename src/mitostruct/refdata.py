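"""Reference data for the vertebrate mitochondrial genome.

Controlled label vocabulary, the canonical (typical) vertebrate gene order,
anticodons, per-gene codon-position composition targets, tRNA architecture
ranges, and the synthetic control-region CSB reference sequences shared by
the generator and the detector.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Label vocabulary
# ---------------------------------------------------------------------------

PROTEIN_LABELS = (
    "ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cyt b",
)

TRNA_LABELS = (
    "Phe", "Val", "Leu(UUR)", "Ile", "Gln", "Met", "Trp", "Ala", "Asn",
    "Cys", "Tyr", "Ser(UCN)", "Asp", "Lys", "Gly", "Arg", "His",
    "Ser(AGY)", "Leu(CUN)", "Glu", "Thr", "Pro",
)

RRNA_LABELS = ("12S", "16S")

NONCODING_LABELS = ("CR", "OL", "NC")

ALL_LABELS = PROTEIN_LABELS + TRNA_LABELS + RRNA_LABELS + NONCODING_LABELS


def kind_of(label: str) -> str:
    """Feature kind implied by a canonical label."""
    if label in PROTEIN_LABELS:
        return "protein"
    if label in TRNA_LABELS:
        return "trna"
    if label in RRNA_LABELS:
        return "rrna"
    if label in NONCODING_LABELS:
        return "noncoding"
    raise ValueError(f"unknown label: {label!r}")


# Synonym table used when reading GenBank qualifiers.  User-extensible via
# a YAML mapping passed to read_genbank.  Keys are lowercase.
SYNONYMS = {
    # proteins
    "nd1": "ND1", "nadh1": "ND1", "nadh dehydrogenase subunit 1": "ND1",
    "nd2": "ND2", "nadh2": "ND2", "nadh dehydrogenase subunit 2": "ND2",
    "nd3": "ND3", "nadh3": "ND3", "nadh dehydrogenase subunit 3": "ND3",
    "nd4": "ND4", "nadh4": "ND4", "nadh dehydrogenase subunit 4": "ND4",
    "nd4l": "ND4L", "nadh4l": "ND4L",
    "nadh dehydrogenase subunit 4l": "ND4L",
    "nd5": "ND5", "nadh5": "ND5", "nadh dehydrogenase subunit 5": "ND5",
    "nd6": "ND6", "nadh6": "ND6", "nadh dehydrogenase subunit 6": "ND6",
    "coi": "COI", "cox1": "COI", "co1": "COI",
    "cytochrome c oxidase subunit i": "COI",
    "cytochrome c oxidase subunit 1": "COI",
    "coii": "COII", "cox2": "COII", "co2": "COII",
    "cytochrome c oxidase subunit ii": "COII",
    "cytochrome c oxidase subunit 2": "COII",
    "coiii": "COIII", "cox3": "COIII", "co3": "COIII",
    "cytochrome c oxidase subunit iii": "COIII",
    "cytochrome c oxidase subunit 3": "COIII",
    "atp6": "ATP6", "atpase6": "ATP6", "atpase 6": "ATP6",
    "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atpase 8": "ATP8",
    "atp synthase f0 subunit 8": "ATP8",
    "cytb": "Cyt b", "cyt b": "Cyt b", "cob": "Cyt b",
    "cytochrome b": "Cyt b",
    # rRNAs
    "12s": "12S", "12s rrna": "12S", "12s ribosomal rna": "12S",
    "s-rrna": "12S", "rrns": "12S", "small subunit ribosomal rna": "12S",
    "16s": "16S", "16s rrna": "16S", "16s ribosomal rna": "16S",
    "l-rrna": "16S", "rrnl": "16S", "large subunit ribosomal rna": "16S",
    # noncoding
    "d-loop": "CR", "control region": "CR", "cr": "CR",
    "ol": "OL", "origin of l-strand replication": "OL",
    "l-strand origin": "OL", "rep_origin": "OL",
}

# tRNA product-name synonyms; Leu/Ser isoacceptors distinguished by the
# codon family or (trnX-anticodon) style names.
_TRNA_SYNONYMS = {
    "trna-phe": "Phe", "trnf": "Phe", "trnf-gaa": "Phe",
    "trna-val": "Val", "trnv": "Val", "trnv-tac": "Val",
    "trna-leu(uur)": "Leu(UUR)", "trna-leu (uur)": "Leu(UUR)",
    "trnl-taa": "Leu(UUR)", "trnl2": "Leu(UUR)", "trnl-uaa": "Leu(UUR)",
    "trna-leu(cun)": "Leu(CUN)", "trna-leu (cun)": "Leu(CUN)",
    "trnl-tag": "Leu(CUN)", "trnl1": "Leu(CUN)", "trnl-uag": "Leu(CUN)",
    "trna-ile": "Ile", "trni": "Ile", "trni-gat": "Ile",
    "trna-gln": "Gln", "trnq": "Gln", "trnq-ttg": "Gln",
    "trna-met": "Met", "trnm": "Met", "trnm-cat": "Met",
    "trna-trp": "Trp", "trnw": "Trp", "trnw-tca": "Trp",
    "trna-ala": "Ala", "trna-ala ": "Ala", "trna-tgc": "Ala",
    "trna-asn": "Asn", "trnn": "Asn", "trnn-gtt": "Asn",
    "trna-cys": "Cys", "trnc": "Cys", "trnc-gca": "Cys",
    "trna-tyr": "Tyr", "trny": "Tyr", "trny-gta": "Tyr",
    "trna-ser(ucn)": "Ser(UCN)", "trna-ser (ucn)": "Ser(UCN)",
    "trns-tga": "Ser(UCN)", "trns1": "Ser(UCN)", "trns-uga": "Ser(UCN)",
    "trna-ser(agy)": "Ser(AGY)", "trna-ser (agy)": "Ser(AGY)",
    "trns-gct": "Ser(AGY)", "trns2": "Ser(AGY)", "trns-gcu": "Ser(AGY)",
    "trna-asp": "Asp", "trnd": "Asp", "trnd-gtc": "Asp",
    "trna-lys": "Lys", "trnk": "Lys", "trnk-ttt": "Lys",
    "trna-gly": "Gly", "trng": "Gly", "trng-tcc": "Gly",
    "trna-arg": "Arg", "trnr": "Arg", "trnr-tcg": "Arg",
    "trna-his": "His", "trnh": "His", "trnh-gtg": "His",
    "trna-thr": "Thr", "trnt": "Thr", "trnt-tgt": "Thr",
    "trna-pro": "Pro", "trnp": "Pro", "trnp-tgg": "Pro",
    "trna-glu": "Glu", "trne": "Glu", "trne-ttc": "Glu",
}
SYNONYMS.update(_TRNA_SYNONYMS)

# single-letter amino-acid code for tRNA labels (gene-order shorthand)
TRNA_SINGLE_LETTER = {
    "Phe": "F", "Val": "V", "Leu(UUR)": "L1", "Ile": "I", "Gln": "Q",
    "Met": "M", "Trp": "W", "Ala": "A", "Asn": "N", "Cys": "C",
    "Tyr": "Y", "Ser(UCN)": "S1", "Asp": "D", "Lys": "K", "Gly": "G",
    "Arg": "R", "His": "H", "Ser(AGY)": "S2", "Leu(CUN)": "L2",
    "Glu": "E", "Thr": "T", "Pro": "P",
}

# ---------------------------------------------------------------------------
# Canonical (typical vertebrate) gene order, strand-signed.
# +1 = heavy (H) strand, -1 = light (L) strand.  ND6 and eight tRNAs
# (Gln, Ala, Asn, Cys, Tyr, Ser(UCN), Glu, Pro) are L-strand encoded.
# ---------------------------------------------------------------------------

CANONICAL_ORDER = (
    ("Phe", 1), ("12S", 1), ("Val", 1), ("16S", 1), ("Leu(UUR)", 1),
    ("ND1", 1), ("Ile", 1), ("Gln", -1), ("Met", 1), ("ND2", 1),
    ("Trp", 1), ("Ala", -1), ("Asn", -1), ("OL", 1), ("Cys", -1),
    ("Tyr", -1), ("COI", 1), ("Ser(UCN)", -1), ("Asp", 1), ("COII", 1),
    ("Lys", 1), ("ATP8", 1), ("ATP6", 1), ("COIII", 1), ("Gly", 1),
    ("ND3", 1), ("Arg", 1), ("ND4L", 1), ("ND4", 1), ("His", 1),
    ("Ser(AGY)", 1), ("Leu(CUN)", 1), ("ND5", 1), ("ND6", -1),
    ("Glu", -1), ("Cyt b", 1), ("Thr", 1), ("Pro", -1), ("CR", 1),
)

CANONICAL_STRAND = {label: strand for label, strand in CANONICAL_ORDER}

# Rearrangement hotspot regions (canonical membership).
HOTSPOT_REGIONS = {
    "IQM": ("Ile", "Gln", "Met"),
    "WANCY": ("Trp", "Ala", "Asn", "OL", "Cys", "Tyr"),
    "K-ATP8-ATP6": ("Lys", "ATP8", "ATP6"),
    "ND5-CR": ("ND5", "ND6", "Glu", "Cyt b", "Thr", "Pro", "CR"),
}

# ---------------------------------------------------------------------------
# Vertebrate mitochondrial genetic code: stop codons and anticodons
# ---------------------------------------------------------------------------

MT_STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")

# Anticodon written 5'->3' on the DNA sense strand of the tRNA gene.
ANTICODONS = {
    "Phe": "GAA", "Val": "TAC", "Leu(UUR)": "TAA", "Ile": "GAT",
    "Gln": "TTG", "Met": "CAT", "Trp": "TCA", "Ala": "TGC",
    "Asn": "GTT", "Cys": "GCA", "Tyr": "GTA", "Ser(UCN)": "TGA",
    "Asp": "GTC", "Lys": "TTT", "Gly": "TCC", "Arg": "TCG",
    "His": "GTG", "Ser(AGY)": "GCT", "Leu(CUN)": "TAG", "Glu": "TTC",
    "Thr": "TGT", "Pro": "TGG",
}

# mTERF binding-site tridecamer (human reference), found within the
# tRNA-Leu(UUR) gene D arm.
MTERF_TRIDECAMER = "TGGCAGAGCCCGG"

# ---------------------------------------------------------------------------
# Average base composition (%) of the 13 protein-coding genes, per codon
# position, over 250 fish mitogenomes.  Row order: (A, T, G, C) for total,
# 1st, 2nd, 3rd positions.  Used by the generator as sampling targets.
# ---------------------------------------------------------------------------

CODON_COMPOSITION = {
    #         total                 1st                  2nd                  3rd
    "ND1":  ((25.0, 28.3, 15.5, 31.3), (23.8, 20.8, 26.3, 29.1), (17.1, 41.7, 11.6, 29.7), (33.8, 22.4, 8.5, 35.3)),
    "ND2":  ((27.2, 25.9, 13.2, 33.7), (30.4, 18.1, 20.6, 31.0), (15.6, 39.0, 11.1, 34.4), (35.7, 20.4, 8.1, 35.8)),
    "COI":  ((24.7, 29.7, 18.4, 27.2), (24.9, 22.0, 30.9, 22.2), (18.1, 40.5, 15.0, 26.3), (30.8, 26.7, 9.3, 33.2)),
    "COII": ((28.6, 27.3, 16.6, 27.5), (23.8, 18.7, 31.2, 26.3), (27.6, 37.8, 11.0, 23.6), (34.3, 25.4, 7.3, 33.0)),
    "ATP8": ((30.6, 26.2, 11.5, 31.7), (29.8, 23.9, 15.2, 31.0), (22.7, 31.8, 11.4, 34.1), (37.4, 22.6, 8.3, 31.8)),
    "ATP6": ((25.6, 29.4, 13.5, 31.5), (28.0, 16.0, 21.1, 34.9), (14.2, 47.1, 11.4, 27.3), (34.4, 24.9, 8.2, 32.5)),
    "COIII": ((24.9, 28.0, 17.3, 29.9), (20.0, 25.0, 28.6, 26.5), (20.8, 36.5, 16.7, 26.0), (33.7, 22.2, 6.6, 37.4)),
    "ND3":  ((22.3, 31.0, 15.5, 31.3), (19.1, 24.4, 25.2, 31.3), (15.7, 44.9, 12.6, 26.8), (32.2, 23.0, 8.8, 36.0)),
    "ND4L": ((22.7, 28.4, 15.6, 33.3), (19.8, 24.1, 24.5, 31.5), (13.5, 40.1, 14.7, 31.8), (33.5, 20.8, 8.2, 37.5)),
    "ND4":  ((26.6, 27.7, 15.0, 30.8), (28.8, 20.1, 21.0, 30.1), (16.1, 41.1, 15.0, 27.9), (34.8, 21.7, 9.1, 34.4)),
    "ND5":  ((28.0, 27.5, 14.0, 30.5), (32.6, 19.8, 22.4, 25.2), (19.5, 39.7, 12.2, 28.6), (31.7, 22.9, 7.8, 37.6)),
    "Cyt b": ((24.8, 29.5, 15.3, 30.5), (24.1, 24.2, 25.8, 25.9), (20.0, 41.2, 13.5, 25.3), (31.1, 22.1, 6.7, 40.1)),
    "ND6":  ((15.4, 37.8, 32.8, 14.0), (12.8, 32.0, 42.8, 12.4), (12.0, 44.1, 23.1, 20.9), (21.3, 37.1, 32.3, 9.4)),
}

# RNA-gene stem/loop base composition targets (%, A/T/G/C).
STEM_COMPOSITION = {"A": 23.7, "T": 23.0, "G": 26.4, "C": 26.9}
LOOP_COMPOSITION = {"A": 40.7, "T": 27.8, "G": 13.3, "C": 18.2}

# ---------------------------------------------------------------------------
# tRNA cloverleaf architecture: fixed stems and observed loop ranges.
# AA stem 7 bp, AC stem 5 bp, T stem 5 bp; D stem 3-4 bp (absent only in
# the Ser(AGY) D-arm-replacement-loop variant); AC loop fixed at 7 nt.
# ---------------------------------------------------------------------------

D_STEM_RANGE = (3, 4)
D_LOOP_RANGE = (3, 14)
V_LOOP_RANGE = (3, 6)
T_LOOP_RANGE = (3, 10)
AA_STEM = 7
AC_STEM = 5
T_STEM = 5
AC_LOOP = 7

# Default per-tRNA architecture (d_stem, d_loop, v_loop, t_loop) used by the
# generator; modal-like values inside the observed ranges.
TRNA_ARCHITECTURE = {
    "Phe": (4, 8, 4, 7), "Val": (4, 8, 5, 7), "Leu(UUR)": (4, 9, 5, 7),
    "Ile": (4, 8, 5, 7), "Gln": (4, 8, 5, 7), "Met": (4, 8, 5, 7),
    "Trp": (4, 8, 5, 7), "Ala": (4, 8, 4, 7), "Asn": (4, 8, 5, 7),
    "Cys": (4, 7, 4, 7), "Tyr": (4, 8, 5, 7), "Ser(UCN)": (4, 8, 5, 7),
    "Asp": (4, 8, 4, 7), "Lys": (4, 8, 4, 7), "Gly": (4, 8, 4, 7),
    "Arg": (4, 7, 4, 7), "His": (4, 8, 4, 7), "Ser(AGY)": (3, 7, 5, 7),
    "Leu(CUN)": (4, 8, 5, 7), "Glu": (4, 8, 4, 7), "Thr": (4, 8, 4, 7),
    "Pro": (4, 8, 4, 7),
}

# ---------------------------------------------------------------------------
# Protein gene lengths (bp, annotated span incl. stop residue) and stop-codon
# plan for the canonical synthetic genome.  Genes whose 3' neighbour is a
# same-strand tRNA may carry incomplete stops (T-- / TA-); genes followed by
# an opposite-strand gene carry complete stops.
# ---------------------------------------------------------------------------

PROTEIN_PLAN = {
    # label: (length_bp, stop)  stop in {TAA, TAG, AGA, AGG, TA-, T--}
    "ND1": (975, "TAA"),
    "ND2": (1045, "T--"),
    "COI": (1551, "TAA"),
    "COII": (691, "T--"),
    "ATP8": (168, "TAA"),
    "ATP6": (684, "TAA"),
    "COIII": (785, "TA-"),
    "ND3": (349, "T--"),
    "ND4L": (297, "TAA"),
    "ND4": (1381, "T--"),
    "ND5": (1839, "TAA"),
    "ND6": (522, "TAA"),
    "Cyt b": (1141, "T--"),
}

START_CODON_PLAN = {label: "ATG" for label in PROTEIN_LABELS}
START_CODON_PLAN["COI"] = "GTG"  # GTG heavily used only in COI

# Canonical reading-frame overlaps (nt) between adjacent protein genes.
CANONICAL_OVERLAPS = {("ATP8", "ATP6"): 10, ("ND4L", "ND4"): 7, ("ND5", "ND6"): 4}

# ---------------------------------------------------------------------------
# Control region: CSB reference sequences.  The four blocks below are
# SYNTHETIC references constructed to match the reported modal lengths
# (D 18, I 22, II 17, III 19 nt) and base-composition biases (D T-rich,
# I AT-rich, II C-rich, III AC-rich); they are not the study's sequences.
# Generator and detector share this fixture.
# ---------------------------------------------------------------------------

CSB_REFERENCES = {
    # 18 nt, T-rich (A 1, T 8, G 4, C 5)
    "D": "TTCTGGTCTTACGTTCTG",
    # 22 nt, AT-rich (A 9, T 7, G 3, C 3)
    "I": "ATATGAATTAACTAGCATACAA",
    # 17 nt, C-rich (A 4, T 2, G 0, C 11)
    "II": "CAAACCCCCCTTCCCCA",
    # 19 nt, AC-rich (A 8, T 2, G 2, C 7)
    "III": "ACACAGCCAACATCACCAT",
}

CSB_ORDER = ("D", "I", "II", "III")

# Control-region total length range observed across fishes (nt).
CR_LENGTH_RANGE = (724, 1401)

# O_L hairpin search / generation bounds.
OL_STEM_RANGE = (8, 39)
OL_LOOP_RANGE = (3, 23)
OL_MOTIF = "GCCGG"

# Intergenic spacers of at least this many bp count as NC regions.
NC_MIN_BP = 50
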