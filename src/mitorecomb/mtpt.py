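"""Mitochondrial plastid DNA (MTPT) detection.

Plant mitogenomes routinely carry segments transferred from the plastome.
This module finds them as local BLASTN alignments between the two organelle
genomes (plastome as query, mitogenome as database; ``-task blastn
-word_size 7 -evalue 1e-10``), collapses the double hits produced by the
plastome's inverted repeat to unique mitogenome locations, ranks fragments
by length (MTPT1 = longest), and summarizes counts, total transferred
length and identity bins.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import CircularSequence, Interval

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class BlastNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class MTPTFragment:
    rank_id: str  # "MTPT<n>" assigned by descending length
    mito_interval: Interval
    plastid_interval: Interval
    length: int  # alignment length (BLAST outfmt 6 semantics)
    identity: float  # percentage
    evalue: float


def _require_blast() -> None:
    for tool in ("makeblastdb", "blastn"):
        if shutil.which(tool) is None:
            raise BlastNotFoundError(f"{tool} not found on PATH")


def _write_fasta(path: Path, g: CircularSequence) -> None:
    with open(path, "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, len(g.seq), 70):
            fh.write(g.seq[i : i + 70] + "\n")


def run_blastn(
    mito: CircularSequence,
    plastid: CircularSequence,
    word_size: int = 7,
    max_evalue: float = 1e-10,
) -> pd.DataFrame:
    """Raw tabular hits, plastome query vs mitogenome database."""
    _require_blast()
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        mito_fa = tmpdir / "mito.fasta"
        cp_fa = tmpdir / "plastid.fasta"
        _write_fasta(mito_fa, mito)
        _write_fasta(cp_fa, plastid)
        subprocess.run(
            ["makeblastdb", "-in", str(mito_fa), "-dbtype", "nucl"],
            check=True,
            capture_output=True,
        )
        res = subprocess.run(
            [
                "blastn",
                "-task", "blastn",
                "-query", str(cp_fa),
                "-db", str(mito_fa),
                "-word_size", str(word_size),
                "-evalue", str(max_evalue),
                "-outfmt", "6",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    rows = [line.split("\t") for line in res.stdout.splitlines() if line.strip()]
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    if not df.empty:
        for col in ("pident", "evalue", "bitscore"):
            df[col] = df[col].astype(float)
        for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
            df[col] = df[col].astype(int)
    return df


def _hit_intervals(row) -> tuple[Interval, Interval]:
    """BLAST 1-based inclusive coordinates -> 0-based half-open Intervals."""
    qs, qe = sorted((row.qstart, row.qend))
    ss, se = sorted((row.sstart, row.send))
    strand = "+" if row.sstart <= row.send else "-"
    return Interval(ss - 1, se), Interval(qs - 1, qe, strand)


def find_homologous_fragments(
    mito: CircularSequence,
    plastid: CircularSequence,
    word_size: int = 7,
    max_evalue: float = 1e-10,
    dedupe_overlap: float = 0.95,
) -> list[MTPTFragment]:
    """Unique-location MTPT fragments, longest first.

    Hits whose mitogenome intervals overlap by >= ``dedupe_overlap`` of the
    shorter interval are considered the same insertion (typically the two
    inverted-repeat copies of a plastome region hitting one mitogenome
    locus); only the hit with the better E-value (ties: higher bitscore) is
    kept. Fragments are ranked MTPT1, MTPT2, ... by descending alignment
    length.
    """
    df = run_blastn(mito, plastid, word_size=word_size, max_evalue=max_evalue)
    if df.empty:
        return []
    df = df.sort_values(["evalue", "bitscore"], ascending=[True, False])
    kept: list[tuple[Interval, Interval, int, float, float]] = []
    for row in df.itertuples(index=False):
        miv, piv = _hit_intervals(row)
        dup = False
        for kmiv, *_ in kept:
            ov = min(miv.end, kmiv.end) - max(miv.start, kmiv.start)
            shorter = min(miv.end - miv.start, kmiv.end - kmiv.start)
            if ov > 0 and shorter > 0 and ov / shorter >= dedupe_overlap:
                dup = True
                break
        if not dup:
            kept.append((miv, piv, row.length, row.pident, row.evalue))
    kept.sort(key=lambda t: (-t[2], t[0].start))
    return [
        MTPTFragment(
            rank_id=f"MTPT{i + 1}",
            mito_interval=miv,
            plastid_interval=piv,
            length=length,
            identity=pident,
            evalue=evalue,
        )
        for i, (miv, piv, length, pident, evalue) in enumerate(kept)
    ]


def summarize_mtpt(fragments: list[MTPTFragment], mito_length: int) -> dict:
    """Count, summed length/percentage, identity bins, fragments > 1 kb.

    Total length is the sum of fragment lengths over unique mitogenome
    locations (not a positional union). Identity bins follow the >90 /
    80-90 / <80 percent convention.
    """
    total = sum(f.length for f in fragments)
    bins = {">90": 0, "80-90": 0, "<80": 0}
    for f in fragments:
        if f.identity > 90:
            bins[">90"] += 1
        elif f.identity >= 80:
            bins["80-90"] += 1
        else:
            bins["<80"] += 1
    return {
        "n_fragments": len(fragments),
        "total_length_bp": total,
        "percent_of_mitogenome": 100.0 * total / mito_length if mito_length else 0.0,
        "identity_bins": bins,
        "n_over_1kb": sum(1 for f in fragments if f.length > 1000),
        "longest_bp": max((f.length for f in fragments), default=0),
    }
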