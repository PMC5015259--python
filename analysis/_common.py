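"""Shared study conditions for the analysis scripts.

A fixed 10-genome synthetic cohort (seed 42, 30 % carrying one hotspot
TDRL event) stands in for a curated genome set.  Script 01 materializes
the cohort as GenBank files under scratch/; later scripts re-read those
files through the ordinary parser, or regenerate the cohort if the cache
is absent, so every script is independently runnable.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "genomes"
RESULTS = ROOT / "results"

COHORT_N = 10
COHORT_SEED = 42
REARRANGED_FRACTION = 0.3


def build_cohort():
    from mitostruct.synthetic import generate_genome_set

    return generate_genome_set(COHORT_N, seed=COHORT_SEED,
                               rearranged_fraction=REARRANGED_FRACTION)


def materialize_cohort():
    from mitostruct.genome_model import write_genbank

    SCRATCH.mkdir(parents=True, exist_ok=True)
    pairs = build_cohort()
    for genome, _ in pairs:
        write_genbank(genome, SCRATCH / f"{genome.accession}.gb")
    return pairs


def load_cohort():
    from mitostruct.genome_model import read_genbank

    paths = sorted(SCRATCH.glob("*.gb"))
    if len(paths) == COHORT_N:
        return [read_genbank(p) for p in paths]
    return [g for g, _ in materialize_cohort()]
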