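# Methods

This note records the models, conventions and numerical choices behind
mitostruct, and what the synthetic-data experiments do and do not show.

## Coordinates and the genome model

Spans are 0-based half-open internally; GenBank's 1-based inclusive
coordinates are converted at the I/O boundary. A circular genome is a
linear string with wrap-aware arithmetic: a feature crossing the origin is
stored as `(start, end)` with `end > L`, and extraction slices the doubled
sequence. Display rotation anchors on tRNA-Phe. The label vocabulary is
closed (13 proteins, 22 tRNAs with both Leu and Ser isoacceptors
distinguished, 2 rRNAs, CR, O_L, NC); GenBank qualifiers map through a
user-extensible synonym table, and an unmappable label is an error rather
than a silently retained string. N bases are excluded from composition
denominators.

## Protein-coding genes

Start codons are read verbatim from the first in-frame triplet; no
translation model is assumed. Stop-codon classification is purely
positional, following the punctuation reading of mitochondrial transcript
processing: a span length ≡ 0 (mod 3) must end in TAA/TAG/AGA/AGG;
remainders of 1 or 2 with trailing T or TA/AG are incomplete stops (T--,
TA-, AG-) completed by polyadenylation; anything else is flagged, never
silently dropped. The punctuation context — whether the next same-strand
feature is a tRNA — is reported with each record. MPV uses the modal
length as denominator; ties break toward the smaller mode so reports are
deterministic. Overlap detection computes exact circular span
intersections for every feature pair. The genetic code is fixed to the
vertebrate mitochondrial code. Amino-acid conservation uses a strict gap
cap of 0 % by default (a column with any gap is not invariable);
configurable.

## tRNA cloverleaf model

Folding is an exhaustive search over the constrained partition space:
linkers fixed at 2 nt (positions 8–9) and 1 nt (position 26, the standard
tRNA convention, configurable), stems fixed at 7/3–4/5/5 bp, the
anticodon loop at 7 nt, D/V/T loops in 3–14/3–6/3–10 nt. The product of
loop ranges is small (tens of candidates per sequence), so the optimum is
guaranteed. The objective is the number of paired positions (WC + G:T
wobble). Ties break by *fewer mismatched stem positions*, then larger D
stem, then smaller D loop, then 5'-most anticodon stem. The mismatch
criterion comes first by design: with fixed linkers, a 4-bp D stem
carrying one mismatched pair always ties a clean 3-bp stem on paired
count, so preferring the larger stem alone would make every genuine 3-bp
D stem unreportable. The D-arm-replacement loop (stem absent) is allowed
only for tRNA-Ser(AGY) by default. Position numbering extends the
classical 1–73 scheme to 83 by sizing each loop's slot range at its
observed maximum; loops fill slots from the 5' side, a 3-bp D stem
occupies 10–12/29–31, and the discriminator is always 83.

## Consensus rRNA structure

The pairing-fraction (75 %) rule is applied conservatively: rows with a
gap or N at either column stay in the denominator and count as unpaired
(an exclude-gapped-rows mode exists). Eligible pairs require a minimum
hairpin separation of 3 columns — the standard steric constraint; the
source survey is silent here. The maximum-cardinality nested pairing is
computed by Nussinov-style DP, sparse over per-column eligible partner
lists; the traceback pairs the 5'-most column whenever doing so preserves
the maximum, with the smallest admissible partner, which totalizes the
order and makes results reproducible. Stems are segmented by the
bilateral-bulge rule: a gap of ≥ 2 columns on both sides ends a stem; a
unilateral skip of ≤ 3 columns is absorbed as an internal bulge (the cap
prevents pathological stems and is configurable); stems need ≥ 2 pairs.
Pseudoknots and tertiary interactions are out of model; long-range
eligible pairs simply never enter stems. A seeded re-evaluation mode
restricts the search to ± 2 columns around a prior model's pairs.

## Noncoding features

CSB references are synthetic fixtures matching the reported modal lengths
(D 18, I 22, II 17, III 19 nt) and composition biases (T-, AT-, C-,
AC-rich respectively); the survey's own consensus sequences are not
printed in its text, so detector and generator share this fixture and the
identity thresholds (present ≥ 0.7, partial ≥ 0.5) are configuration, not
claims about absolute conservation. Note the null behaviour: the best of
~900 windows against a ~20-nt reference lands near 0.55–0.6 identity, so
random sequence typically scores "partial", rarely "present", never
biologically meaningful — present/partial calls should be read together
with the identity value. Poly-T runs must exceed eight nucleotides. The
O_L search enumerates every (offset, stem, loop) candidate within the
observed bounds (stem 8–39 bp, loop 3–23 nt), requires terminal pairs to
hold, tolerates one internal mismatch per 10 bp of stem — a package
choice; the survey says only "stable stem-loop" — and maximizes paired
positions with ties to the longer stem, then the 5'-most offset. The
GCCGG motif is scored as the best 5-mer window anywhere in the hairpin,
since its strand and position are not fixed by the source.

## Gene orders and TDRL

Orders are circular and strand-signed; rotation-equivalent orders compare
equal, anchored on tRNA-Phe when present. NC tokens (intergenic spacers
≥ 50 bp) are carried in the order but ignored by displacement arithmetic —
under the TDRL reading they are by-products, not participants. A label is
displaced when its successor (NC ignored) differs from canonical.
Classes: inversion on any sign flip; duplication on multiplicity; O_L
shift when the O_L itself is displaced; a displaced CR is always
translocation (control-region relocations are what the field's
translocation examples describe, and a window rule would misfile them);
displaced genes confined to one canonical window of ≤ 5 positions are
shuffling, wider patterns translocation. The window width is
configurable; the source classifies qualitatively by example.

Single-event TDRL reachability: duplicating a block in tandem and
deleting one copy of each gene leaves kept(copy 1) ++ kept(copy 2), so an
order is one event from the origin iff, for some block, the orders agree
outside it and the block image splits into a prefix and a suffix that are
each strictly increasing in origin block order (a label kept twice must
appear in both halves). The checker returns the minimal witness
(shortest block, then 5'-most) and a replay facility reconstructs a loss
pattern and verifies it. Multi-event search is deliberately out of scope
(exponential); unreachable orders are reported as not single-event
explainable. Monophyly of a shared order class on a rooted tree is MRCA
tip-set equality, with the smallest containing clade reported otherwise.

## The synthetic-mitogenome generator

The generator emits annotated canonical-order genomes whose marginal
statistics follow the surveyed values: per-gene, per-codon-position base
composition (sampled per position with in-frame stop repair), start/stop
codon plans (ATG everywhere but GTG in COI; incomplete stops exactly in
the genes followed by a same-strand tRNA; complete stops in ND5, ND6,
COI, which are followed by opposite-strand genes), the three canonical
overlaps realized by shared sequence blocks valid in both reading frames,
tRNA architectures inside the observed ranges with per-strand wobble
rates (L 13.3 %, H 3.5 %), a control region of 724–1,401 nt with the four
CSBs in order and a 10-nt poly-T directly upstream of CSB-I, and an O_L
hairpin (stem 12 bp, loop 12 nt, GCCGG on the 3' arm) inside the WANCY
cluster. One integer seed drives a single explicit RNG stream; the same
parameters give byte-identical GenBank output.

Identifiability is engineered, then verified: rRNA and O_L ancestors draw
stem arms from {G,C} and loops/spacers from {A} only, which makes the
planted pairing the provably unique maximum nested pairing of the
ancestor (A cannot pair without T; every G/C column is consumed by its
planted partner); substitution noise reintroduces the other bases in
emitted alignments. Each tRNA, the O_L, and each rRNA ancestor is
validated against its detector at generation time and resampled on
ambiguity, honouring the contract that planted ground truth is exactly
recoverable. Alignment simulation mutates paired columns compensatorily
80 % of the time (pair failure 0.2 × rate, keeping planted pairs above
the 75 % rule for rates ≤ 0.1), never touches designated invariable
sites, inflates one loop into a hypervariable region (4× rate plus 50 %
gaps), and forces at least one variant row in every mutable column so the
planted invariable set is exactly the constant set. TDRL events duplicate
a contiguous feature block at the sequence level and leave the deleted
copy's 5'-most 60 bp as an NC remnant, crossing the 50-bp threshold.

What passing recovery tests shows — and does not. The generator targets
marginal statistics, not phylogenetically realistic evolution: there are
no branch lengths, no among-site rate variation beyond the hypervariable
region, no indels outside it, and loop composition in the rRNA ancestors
is intentionally degenerate. Exact recovery on this data demonstrates
correctness of the detectors under their own model assumptions; it does
not predict stem counts or CSB calls on real 250-species alignments,
which depend on alignment quality and real covariation.

## Problem sizes and defaults

The analysis cohort is 10 genomes (seed 42, 30 % rearranged), a size
chosen so every script re-derives its tables in seconds while exercising
both typical and rearranged paths; recovery experiments use 100-sequence
alignments at 5 % substitution, 1,000 tRNA folds, and 1,000 simulated
TDRL events, matching the scale at which the corresponding statistics
stabilize. Genome-level defaults (12S 950 nt, 16S 1,650 nt, ~16.9 kb
total) sit inside the observed vertebrate range.

## Known limitations

De novo annotation is out of scope: inputs are annotated genomes.
Thermodynamic folding, modified nucleotides, pseudoknots and
transmembrane-topology prediction are not modelled. Multi-event TDRL
histories and ancestral gene-order reconstruction over the tree are not
attempted. Genome-level TDRL blocks may not cut through overlapping gene
pairs (the event would have to split a shared reading frame); the
token-level operator has no such restriction.
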