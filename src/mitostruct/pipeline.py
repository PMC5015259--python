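"""Orchestration: run every analysis stage over a genome set and emit the
table suite (composition, codon usage, lengths, overlaps, tRNA structure,
noncoding features, gene order) as TSV files plus a machine-readable
manifest.

All numeric cells are recomputed from module outputs; the pipeline is
idempotent for a fixed configuration and input set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import refdata as R
from .gene_order import compare_to_canonical, extract_order
from .genome_model import Mitogenome, extract_gene_sequence
from .noncoding import find_csbs, find_ol, find_polyt, ol_region_composition
from .protein_stats import (
    codon_position_composition,
    detect_overlaps,
    detect_stop_codon,
    length_stats,
)
from .trna_struct import find_mterf_motif, fold_trna, wobble_stats

log = logging.getLogger("mitostruct")


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run."""

    out_dir: str = "results"
    pairing_threshold: float = 0.75
    csb_present_identity: float = 0.7
    csb_partial_identity: float = 0.5
    nc_min: int = R.NC_MIN_BP
    polyt_min: int = 9
    shuffle_window: int = 5
    seed: int = 0
    genome_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.pairing_threshold <= 1.0:
            raise ValueError("pairing_threshold outside (0, 1]")
        if not 0.0 <= self.csb_partial_identity <= self.csb_present_identity <= 1.0:
            raise ValueError("CSB identity thresholds inconsistent")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ---------------------------------------------------------------------------
# per-stage tables
# ---------------------------------------------------------------------------

def composition_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Per-gene, per-codon-position base composition across genomes."""
    rows = []
    for label in R.PROTEIN_LABELS:
        seqs = []
        for g in genomes:
            try:
                seqs.append(extract_gene_sequence(g, g.get(label)))
            except KeyError:
                continue
        if not seqs:
            continue
        comp = codon_position_composition(seqs)
        row = {"gene": label, "n_genomes": len(seqs)}
        for pos in ("total", "1", "2", "3"):
            for base, val in comp[pos].as_dict().items():
                row[f"pos{pos}_{base}"] = round(val, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def codon_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    records = []
    for g in genomes:
        for f in g.sorted_features():
            if f.kind != "protein":
                continue
            rec = detect_stop_codon(f, g)
            records.append({"accession": g.accession, **asdict(rec)})
    df = pd.DataFrame(records)
    return (
        df.groupby(["gene", "start_codon", "stop_codon", "complete"])
        .size().rename("count").reset_index()
        .sort_values(["gene", "count"], ascending=[True, False])
        .reset_index(drop=True)
    )


def length_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for label in R.PROTEIN_LABELS:
        lengths = []
        for g in genomes:
            try:
                lengths.append(g.get(label).length)
            except KeyError:
                continue
        if lengths:
            stats = length_stats(lengths, gene=label)
            rows.append({**asdict(stats), "mpv": round(stats.mpv, 3)})
    return pd.DataFrame(rows)


def overlap_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        for rec in detect_overlaps(g):
            rows.append({"accession": g.accession, **asdict(rec)})
    return pd.DataFrame(rows)


def trna_tables(genomes: list[Mitogenome]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(arm-length table, wobble occurrence table, mTERF table)."""
    import warnings

    arm_rows, folds, mterf_rows = [], [], []
    for g in genomes:
        for label in R.TRNA_LABELS:
            try:
                f = g.get(label)
            except KeyError:
                continue
            seq = extract_gene_sequence(g, f)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold = fold_trna(seq, label)
            folds.append((label, f.strand, fold))
            arm_rows.append({
                "accession": g.accession, "trna": label, "strand": f.strand,
                "length": len(seq), "d_stem": fold.arch.d_stem,
                "d_loop": fold.arch.d_loop, "v_loop": fold.arch.v_loop,
                "t_loop": fold.arch.t_loop, "anticodon": fold.anticodon,
            })
            if label == "Leu(UUR)":
                hit = find_mterf_motif(seq, fold)
                mterf_rows.append({
                    "accession": g.accession, "offset": hit.offset,
                    "identity": hit.identity, "present": hit.present,
                    "overlaps_d_arm": hit.overlaps_d_arm,
                })
    return pd.DataFrame(arm_rows), wobble_stats(folds), pd.DataFrame(mterf_rows)


def noncoding_table(genomes: list[Mitogenome],
                    config: RunConfig | None = None) -> pd.DataFrame:
    config = config or RunConfig()
    rows = []
    for g in genomes:
        row: dict = {"accession": g.accession}
        try:
            cr_feat = g.get("CR")
            cr = extract_gene_sequence(g, cr_feat)
        except KeyError:
            # unsequenced / absent control region
            row.update({"cr_present": False})
            rows.append(row)
            continue
        row["cr_present"] = True
        row["cr_length"] = len(cr)
        scan = find_csbs(cr, present_identity=config.csb_present_identity,
                         partial_identity=config.csb_partial_identity)
        for h in scan.hits:
            row[f"csb_{h.block}_status"] = h.status
            row[f"csb_{h.block}_start"] = h.start
            row[f"csb_{h.block}_identity"] = round(h.identity, 3)
        row["csb_order_ok"] = scan.order_ok
        runs = find_polyt(cr, min_run=config.polyt_min)
        row["polyt_runs"] = len(runs)
        row["polyt_longest"] = max((n for _, n in runs), default=0)
        try:
            asn, cys = g.get("Asn"), g.get("Cys")
            region = g.sequence[asn.end : cys.start]
            hit = find_ol(region)
        except KeyError:
            hit = None
        if hit is None:
            row["ol_present"] = False
        else:
            stem_c, loop_c = ol_region_composition(hit, region)
            row.update({
                "ol_present": True, "ol_stem": hit.stem_len,
                "ol_loop": hit.loop_len, "ol_motif": hit.motif_matched,
                "ol_motif_identity": hit.motif_identity,
                "ol_stem_gc": round(stem_c.g + stem_c.c, 2),
                "ol_loop_a": round(loop_c.a, 2),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def gene_order_table(genomes: list[Mitogenome],
                     config: RunConfig | None = None) -> pd.DataFrame:
    config = config or RunConfig()
    rows = []
    for g in genomes:
        order = extract_order(g, nc_min=config.nc_min)
        rep = compare_to_canonical(order, shuffle_window=config.shuffle_window)
        rows.append({
            "accession": g.accession,
            "status": rep.status,
            "classes": ",".join(sorted(rep.classes)),
            "displaced": ",".join(sorted(rep.displaced)),
            "hotspots": ",".join(sorted(rep.hotspots)),
            "nc_tokens": rep.nc_tokens,
            "tdrl_reachable": rep.tdrl_reachable,
            "tdrl_witness": (f"{rep.tdrl_witness[0]}+{rep.tdrl_witness[1]}"
                             if rep.tdrl_witness else ""),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    manifest: dict
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


_STAGES = {
    "composition": composition_table,
    "codons": codon_table,
    "lengths": length_table,
    "overlaps": overlap_table,
    "noncoding": noncoding_table,
    "gene_order": gene_order_table,
}


def run_pipeline(genomes: list[Mitogenome], config: RunConfig | None = None
                 ) -> ReportBundle:
    """Run every stage over the genome set and write the TSV suite.

    Per-genome/stage failures are logged and recorded; the pipeline
    continues past them.
    """
    if not genomes:
        raise ValueError("at least one genome required")
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}
    for name, fn in _STAGES.items():
        try:
            tables[name] = (fn(genomes, config)
                            if name in ("noncoding", "gene_order")
                            else fn(genomes))
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            log.error("stage %s failed: %s", name, exc)
            failures[name] = str(exc)
    try:
        arms, wobble, mterf = trna_tables(genomes)
        tables["trna_arms"] = arms
        tables["trna_wobble"] = wobble
        tables["trna_mterf"] = mterf
    except Exception as exc:  # noqa: BLE001
        log.error("stage trna failed: %s", exc)
        failures["trna"] = str(exc)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.2f")
    manifest = {
        "package": "mitostruct",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            g.accession: hashlib.sha256(g.sequence.encode()).hexdigest()
            for g in genomes
        },
        "tables": sorted(tables),
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(tables=tables, manifest=manifest, failures=failures)


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(name)s %(levelname)s: %(message)s")
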