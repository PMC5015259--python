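#!/usr/bin/env python
"""Control-region and O_L features across the cohort.

Scans each control region for the four conserved sequence blocks and the
poly-T tract, and the WANCY cluster for the O_L stem-loop and its GCCGG
replication motif.  Writes the noncoding feature table to results/.
"""

from _common import RESULTS, load_cohort

from mitostruct.pipeline import noncoding_table


def main():
    genomes = load_cohort()
    RESULTS.mkdir(exist_ok=True)
    df = noncoding_table(genomes)
    df.to_csv(RESULTS / "noncoding.tsv", sep="\t", index=False)
    with_cr = df[df.cr_present]
    print(f"CR present in {len(with_cr)}/{len(df)} genomes "
          f"(lengths {int(with_cr.cr_length.min())}-"
          f"{int(with_cr.cr_length.max())} nt)")
    for block in ("D", "I", "II", "III"):
        n = (with_cr[f"csb_{block}_status"] == "present").sum()
        print(f"  CSB-{block}: present in {n}/{len(with_cr)}")
    ol = df[df.ol_present.fillna(False)]
    print(f"O_L found in {len(ol)}/{len(df)} genomes, stem GC "
          f"{ol.ol_stem_gc.mean():.0f} %, loop A {ol.ol_loop_a.mean():.0f} % "
          f"(motif identity {ol.ol_motif_identity.mean():.1f}/5)")


if __name__ == "__main__":
    main()
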