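"""End-to-end run: simulate -> junctions -> isomers -> repeat/codon/MTPT reports."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import io as mio
from .codons import compute_rscu, extract_cds
from .core import gc_content
from .isomers import isomer_to_fasta
from .junctions import build_all_path_references, count_spanning_reads, summarize_recombination
from .mtpt import find_homologous_fragments, summarize_mtpt
from .repeats import find_dispersed_repeats, find_ssrs, summarize_repeats
from .simulate import SimulationConfig, simulate
from .isomers import circle_sequence


def isomer_table(isomers, graph) -> pd.DataFrame:
    rows = []
    for label, iso in isomers.items():
        for i, circle in enumerate(iso.circles, start=1):
            rows.append(
                {
                    "isomer": label,
                    "classification": iso.classification,
                    "circle": f"{label}{i}" if len(iso.circles) > 1 else label,
                    "length_bp": sum(graph.segments[sid].length for sid, _ in circle),
                    "segments": ",".join(f"{sid}{o}" for sid, o in circle),
                    "recombined_at": ",".join(sorted(iso.recombined_at)) or "-",
                }
            )
    return pd.DataFrame(rows)


def support_tables_to_df(tables) -> pd.DataFrame:
    rows = []
    for rid, table in sorted(tables.items()):
        for plabel in sorted(table.read_ids, key=lambda p: int(p.lstrip("p"))):
            ids = table.read_ids[plabel]
            rows.append(
                {
                    "repeat_id": rid,
                    "path_label": plabel,
                    "n_spanning": len(ids),
                    "read_ids": ",".join(ids),
                }
            )
    return pd.DataFrame(rows)


def ssr_table(records) -> pd.DataFrame:
    # 1-based inclusive coordinates in reports
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "unit_size": r.unit_size,
                "copies": r.copies,
                "start": r.interval.start + 1,
                "end": r.interval.end,
            }
            for r in records
        ]
    )


def dispersed_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "start_a": r.interval_a.start + 1,
                "end_a": r.interval_a.end,
                "start_b": r.interval_b.start + 1,
                "end_b": r.interval_b.end,
                "length": r.length,
                "mismatches": r.mismatches,
                "evalue": r.evalue,
            }
            for r in records
        ]
    )


def mtpt_table(fragments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank_id": f.rank_id,
                "mito_start": f.mito_interval.start + 1,
                "mito_end": f.mito_interval.end,
                "plastid_start": f.plastid_interval.start + 1,
                "plastid_end": f.plastid_interval.end,
                "plastid_strand": f.plastid_interval.strand,
                "length": f.length,
                "identity": f.identity,
                "evalue": f.evalue,
            }
            for f in fragments
        ]
    )


def run_full_pipeline(
    config: SimulationConfig,
    outdir,
    genbank=None,
    plastid_fasta=None,
    flank: int = 500,
    min_identity: float = 0.80,
    max_end_slack: int = 0,
    repeat_min_len: int = 1000,
    repeat_max_mismatch: int = 0,
) -> Path:
    """Simulate the study system and run every analysis stage on it.

    The dispersed-repeat stage defaults to recombination-scale parameters
    (min_len 1000, exact copies); RSCU and MTPT stages run only when a
    GenBank annotation / plastome FASTA is supplied. Writes per-stage TSVs
    plus an aggregate ``summary.tsv`` and returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, repeats, graph, isomers, reads = simulate(config)

    mio.write_fasta(outdir / "master.fasta", [genome])
    iso_records = []
    for label, iso in isomers.items():
        for i, circle in enumerate(iso.circles, start=1):
            rid = label if len(iso.circles) == 1 else f"{label}{i}"
            iso_records.append((rid, circle_sequence(circle, graph, canonical=False)))
    mio.write_fasta(outdir / "isomers.fasta", iso_records)
    mio.write_fastq(outdir / "reads.fastq", reads)
    mio.write_bed(
        outdir / "repeats.bed",
        [
            (genome.id, iv, rp.id)
            for rp in repeats
            for iv in (rp.copy_a, rp.copy_b)
        ],
    )
    truth_rows = [
        {
            "read_id": r.label.read_id,
            "source_isomer": r.label.source_isomer,
            "start": r.label.source_interval.start,
            "end": r.label.source_interval.end,
            "strand": r.label.source_interval.strand,
            "circle_length": r.label.source_circle_length,
            "junction_paths": ",".join(sorted(r.label.junction_paths_covered)) or "-",
        }
        for r in reads
    ]
    mio.write_tsv(outdir / "truth.tsv", pd.DataFrame(truth_rows))
    mio.write_gfa(outdir / "graph.gfa", graph)

    summary_rows = [
        ("genome_length_bp", len(genome)),
        ("gc_percent", round(gc_content(genome), 2)),
        ("n_reads", len(reads)),
        ("n_isomers", len(isomers)),
    ]

    mio.write_tsv(outdir / "isomers.tsv", isomer_table(isomers, graph))

    refs = build_all_path_references(genome, repeats, flank_len=flank)
    tables = count_spanning_reads(refs, reads, min_identity=min_identity, max_end_slack=max_end_slack)
    mio.write_tsv(outdir / "junctions.tsv", support_tables_to_df(tables))
    summary_rows.append(("n_junction_paths", sum(len(t.read_ids) for t in tables.values())))
    for rid, table in sorted(tables.items()):
        summ = summarize_recombination(table)
        summary_rows.append((f"{rid}_status", summ.status))
        if summ.recombinant_fraction is not None:
            summary_rows.append((f"{rid}_recombinant_fraction", round(summ.recombinant_fraction, 4)))

    ssrs = find_ssrs(genome)
    mio.write_tsv(outdir / "ssr.tsv", ssr_table(ssrs))
    dispersed = find_dispersed_repeats(
        genome, min_len=repeat_min_len, max_mismatch=repeat_max_mismatch
    )
    mio.write_tsv(outdir / "dispersed_repeats.tsv", dispersed_table(dispersed))
    rep_summary = summarize_repeats(ssrs, dispersed, len(genome))
    summary_rows.append(("n_ssrs", rep_summary["n_ssrs"]))
    summary_rows.append(("n_dispersed_pairs", rep_summary["n_dispersed_pairs"]))

    if genbank is not None:
        cds = extract_cds(genbank)
        if cds:
            mio.write_tsv(outdir / "rscu.tsv", compute_rscu(cds))
            summary_rows.append(("n_cds", len(cds)))
    if plastid_fasta is not None:
        plastid = mio.read_fasta(plastid_fasta)[0]
        frags = find_homologous_fragments(genome, plastid)
        mio.write_tsv(outdir / "mtpt.tsv", mtpt_table(frags))
        msum = summarize_mtpt(frags, len(genome))
        summary_rows.append(("n_mtpt_fragments", msum["n_fragments"]))

    mio.write_tsv(
        outdir / "summary.tsv",
        pd.DataFrame(summary_rows, columns=["metric", "value"]),
    )
    mio.write_manifest(
        outdir,
        {
            "config": dataclasses.asdict(config),
            "flank": flank,
            "min_identity": min_identity,
            "max_end_slack": max_end_slack,
            "repeat_min_len": repeat_min_len,
            "repeat_max_mismatch": repeat_max_mismatch,
        },
    )
    return outdir
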