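"""Readers/writers for the formats the pipeline touches, plus the pipeline.

FASTA/FASTQ/GenBank go through Biopython; BED is 0-based half-open; GFA 1.0
S/L lines carry the assembly graph. All reports are TSV (tab, UTF-8,
header row); every run writes a JSON parameter manifest next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CircularSequence, Interval
from .isomers import AssemblyGraph, Segment
from .junctions import RepeatPair
from .simulate import SimulationConfig


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[CircularSequence]:
    """All records; id is the first whitespace-delimited header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CircularSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path, sequences) -> None:
    """Sequences wrapped at 70 columns; accepts CircularSequence or (id, seq)."""
    with open(path, "w") as fh:
        for s in sequences:
            sid, seq = (s.id, s.seq) if hasattr(s, "seq") else s
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads) -> None:
    """Reads as (id, seq) or objects with .id/.seq; dummy 'I' qualities."""
    with open(path, "w") as fh:
        for r in reads:
            rid, seq = (r.id, r.seq) if hasattr(r, "seq") else r
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_genbank(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "genbank"))


# ---------------------------------------------------------------------------
# BED (0-based half-open)


def read_bed(path) -> list[tuple[str, Interval, str]]:
    """(chrom, interval, name) per line; strand from column 6 when present."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((parts[0], Interval(start, end, strand), name))
    return out


def write_bed(path, entries) -> None:
    """entries: iterable of (chrom, Interval, name)."""
    with open(path, "w") as fh:
        for chrom, iv, name in entries:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def repeats_from_bed(path, genome: CircularSequence) -> list[RepeatPair]:
    """Pair up BED entries sharing a name column into RepeatPair records."""
    by_name: dict[str, list[Interval]] = {}
    for chrom, iv, name in read_bed(path):
        by_name.setdefault(name or chrom, []).append(iv)
    pairs = []
    for name, ivs in by_name.items():
        if len(ivs) != 2:
            raise FormatError(f"repeat {name}: expected exactly 2 copies, got {len(ivs)}")
        a, b = sorted(ivs, key=lambda iv: iv.start)
        pairs.append(
            RepeatPair(id=name, copy_a=a, copy_b=b, length=a.span(len(genome)))
        )
    pairs.sort(key=lambda rp: -rp.length)
    return pairs


# ---------------------------------------------------------------------------
# GFA 1.0


def read_gfa(path) -> AssemblyGraph:
    segments: dict[str, Segment] = {}
    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line[0] in "#H":
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: bad S line")
                name, seq = parts[1], parts[2]
                tags = parts[3:]
                is_repeat = any(t == "RC:i:2" or t.startswith("DP:f:2") for t in tags)
                if seq == "*":
                    length = None
                    for t in tags:
                        if t.startswith("LN:i:"):
                            length = int(t[5:])
                    segments[name] = Segment(name, length=length, is_repeat=is_repeat)
                else:
                    segments[name] = Segment(name, seq=seq.upper(), is_repeat=is_repeat)
            elif parts[0] == "L":
                if len(parts) < 5:
                    raise FormatError(f"{path}:{lineno}: bad L line")
                links.append((parts[1], parts[2], parts[3], parts[4]))
    if not segments:
        raise FormatError(f"{path}: no S lines")
    return AssemblyGraph(segments=segments, links=links)


def write_gfa(path, graph: AssemblyGraph) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for sid, seg in graph.segments.items():
            seq = seg.seq if seg.seq is not None else "*"
            tags = [f"LN:i:{seg.length}"]
            if seg.is_repeat:
                tags.append("RC:i:2")
            fh.write("\t".join(["S", sid, seq, *tags]) + "\n")
        for u, uo, v, vo in graph.links:
            fh.write(f"L\t{u}\t{uo}\t{v}\t{vo}\t0M\n")


# ---------------------------------------------------------------------------
# TSV + config + manifest


def write_tsv(path, df: pd.DataFrame, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_sim_config(path=None, **overrides) -> SimulationConfig:
    """SimulationConfig from a YAML/key=value file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
        else:  # flat key=value lines
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = line.split("=", 1)
                data[key.strip()] = yaml.safe_load(val.strip())
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"unknown simulation parameters: {sorted(unknown)}")
    for key in ("repeat_lengths", "segment_fractions", "isomer_weights"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def write_manifest(outdir, params: dict, name: str = "manifest.json") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name

    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return str(obj)

    path.write_text(json.dumps(params, indent=2, sort_keys=True, default=default) + "\n")
    return path
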