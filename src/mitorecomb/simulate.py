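"""Synthetic study system: a repeat-bearing circular mitogenome plus long reads.

The generator emulates a cactus-like plant mitogenome: a ~515 kb circle at
~44% GC carrying two pairs of large direct repeats (defaults 9026 bp and
7040 bp, copies 100% identical) whose recombination produces four isomers —
two master circles (A, B) and two pairs of sub-genomic circles (C, D).
Nanopore-like long reads (mean ~17.5 kb at ~75x depth) are drawn from a
weighted mixture of those isomers, with per-read truth labels recording the
source circle, the source interval, and which repeat junctions the read
spans. Every downstream stage of the package is testable against these
planted truths without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CircularSequence, Interval, circular_substring, reverse_complement
from .isomers import AssemblyGraph, Isomer, Link, Segment, circle_sequence, enumerate_isomers
from .junctions import RepeatPair

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


class UnsupportedOrientation(ValueError):
    """Inverted repeat orientation: recombination outcome not enumerated."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mitogenome and read set.

    Defaults encode the sequenced system this package models: a 515,187 bp
    circle, direct repeats of 9026 and 7040 bp, GC 44.05%, long reads of
    mean length 17,520 bp at 75-fold depth. The error rate is a coarse
    Nanopore-like 5% split substitution:insertion:deletion = 2:1:1, and the
    isomer mixture defaults to a majority of master circle A with the
    alternative conformations as minority species.
    """

    genome_length: int = 515_187
    repeat_lengths: tuple[int, ...] = (9026, 7040)
    gc_target: float = 0.4405
    # fractions of the non-repeat residue allotted to the unique segments
    segment_fractions: tuple[float, ...] = (0.40, 0.25, 0.20, 0.15)
    read_mean_length: int = 17_520
    read_length_sd: int = 5_000
    read_min_length: int = 200
    target_depth: float = 75.0
    n_reads: int | None = None
    error_rate: float = 0.05
    isomer_weights: tuple[float, ...] = (0.55, 0.15, 0.15, 0.15)
    truth_flank: int = 500  # flank width for junction windows in truth labels
    seed: int = 0

    def validate(self) -> None:
        reps = [r for r in self.repeat_lengths if r > 0]
        if any(r < 0 for r in self.repeat_lengths):
            raise ConfigError("negative repeat length")
        if any(r >= self.genome_length / 4 for r in reps):
            raise ConfigError("repeat lengths must be < genome_length / 4")
        n_seg = max(1, 2 * len(reps))
        residue = self.genome_length - 2 * sum(reps)
        if residue < n_seg:
            raise ConfigError("repeats leave no room for unique segments")
        if not 0 <= self.gc_target <= 1:
            raise ConfigError("gc_target must be a fraction")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if len(self.isomer_weights) != 4 or any(w < 0 for w in self.isomer_weights):
            raise ConfigError("isomer_weights: 4 non-negative floats")
        if sum(self.isomer_weights) <= 0:
            raise ConfigError("isomer_weights must not all be zero")
        if self.read_min_length < 1 or self.read_mean_length < self.read_min_length:
            raise ConfigError("read length parameters inconsistent")

    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.isomer_weights, dtype=float)
        return w / w.sum()

    def expected_n_reads(self) -> int:
        if self.n_reads is not None:
            return self.n_reads
        return max(1, round(self.target_depth * self.genome_length / self.read_mean_length))


@dataclass(frozen=True)
class TruthLabel:
    read_id: str
    source_isomer: str  # A, B, C1, C2, D1, D2 (circle within pair isomers)
    source_interval: Interval  # on the source circle, pre-error; '-' = RC read
    source_circle_length: int
    junction_paths_covered: frozenset[str] = frozenset()


@dataclass
class SimulatedRead:
    id: str
    seq: str
    label: TruthLabel | None = None


@dataclass
class ReadSet:
    reads: list[SimulatedRead] = field(default_factory=list)

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def mean_length(self) -> float:
        return float(np.mean([len(r.seq) for r in self.reads]))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode("ascii")


def _segment_lengths(config: SimulationConfig, n_segments: int) -> list[int]:
    residue = config.genome_length - 2 * sum(r for r in config.repeat_lengths if r > 0)
    fracs = list(config.segment_fractions)[:n_segments]
    if len(fracs) < n_segments:
        fracs += [fracs[-1] if fracs else 1.0] * (n_segments - len(fracs))
    total = sum(fracs)
    lengths = [max(1, int(residue * f / total)) for f in fracs]
    lengths[0] += residue - sum(lengths)
    if min(lengths) < 1:
        raise ConfigError("segment fractions leave an empty segment")
    return lengths


def generate_master_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CircularSequence, list[RepeatPair], AssemblyGraph]:
    """Build the master circle with planted identical direct repeats.

    Layout with two repeats: S1·R1·S2·R2·S3·R1·S4·R2 — exactly two copies
    of each repeat, four unique segments so that every repeat copy has
    distinct flanks (the six-contig topology of a collapsed assembly
    graph). Bases are drawn i.i.d. at the GC target. Returns the circle,
    the repeat annotations, and the matching assembly graph (segments carry
    sequence; ``graph.master_order`` records the input circle's traversal).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reps = [r for r in config.repeat_lengths if r > 0]
    if not reps:
        seq = _random_dna(rng, config.genome_length, config.gc_target)
        genome = CircularSequence("synthetic_master", seq)
        graph = AssemblyGraph(
            segments={"S1": Segment("S1", seq=seq)},
            links=[("S1", "+", "S1", "+")],
        )
        graph.master_order = ["S1"]
        return genome, [], graph

    n_segments = 2 * len(reps)
    seg_lengths = _segment_lengths(config, n_segments)
    repeat_seqs = [_random_dna(rng, r, config.gc_target) for r in reps]
    seg_seqs = [_random_dna(rng, L, config.gc_target) for L in seg_lengths]

    order: list[tuple[str, str]] = []
    for half in range(2):
        for i in range(len(reps)):
            s_idx = half * len(reps) + i
            order.append((f"S{s_idx + 1}", seg_seqs[s_idx]))
            order.append((f"R{i + 1}", repeat_seqs[i]))

    pieces = []
    positions: dict[str, list[int]] = {}
    pos = 0
    for name, s in order:
        positions.setdefault(name, []).append(pos)
        pieces.append(s)
        pos += len(s)
    genome = CircularSequence("synthetic_master", "".join(pieces))
    assert len(genome) == config.genome_length

    repeat_pairs = []
    for i, r in enumerate(reps):
        a, b = positions[f"R{i + 1}"]
        repeat_pairs.append(
            RepeatPair(
                id=f"R{i + 1}",
                copy_a=Interval(a, a + r),
                copy_b=Interval(b, b + r),
                length=r,
                identity=1.0,
            )
        )

    segments = {f"S{i + 1}": Segment(f"S{i + 1}", seq=seg_seqs[i]) for i in range(n_segments)}
    for i, rs in enumerate(repeat_seqs):
        segments[f"R{i + 1}"] = Segment(f"R{i + 1}", seq=rs, is_repeat=True)
    names = [name for name, _ in order]
    links: list[Link] = [
        (names[j], "+", names[(j + 1) % len(names)], "+") for j in range(len(names))
    ]
    graph = AssemblyGraph(segments=segments, links=links)
    graph.master_order = names
    return genome, repeat_pairs, graph


def graph_from_repeats(genome: CircularSequence, repeats: list[RepeatPair]) -> AssemblyGraph:
    """Collapse a master circle with annotated two-copy repeats into a graph."""
    occs = []  # (start, end, repeat_id) in circle order
    for rp in repeats:
        for iv in (rp.copy_a, rp.copy_b):
            if iv.strand != "+":
                raise UnsupportedOrientation(rp.id)
            occs.append((iv.start, iv.start + iv.span(len(genome)), rp.id))
    occs.sort()
    n = len(genome)
    segments: dict[str, Segment] = {}
    order: list[str] = []
    for k, (start, end, rid) in enumerate(occs):
        if rid not in segments:
            segments[rid] = Segment(
                rid, seq=circular_substring(genome, start % n, end - start), is_repeat=True
            )
        sid = f"S{k + 1}"
        gap_start = end % n
        gap_span = (occs[(k + 1) % len(occs)][0] - gap_start) % n
        if gap_span == 0:
            raise ConfigError("adjacent repeat copies leave no unique segment")
        segments[sid] = Segment(sid, seq=circular_substring(genome, gap_start, gap_span))
        order.extend([rid, sid])
    links = [(order[j], "+", order[(j + 1) % len(order)], "+") for j in range(len(order))]
    graph = AssemblyGraph(segments=segments, links=links)
    graph.master_order = order
    graph.validate()
    return graph


def _master_triples(graph: AssemblyGraph) -> set[tuple[str, str, str]]:
    """(prev_segment, repeat, next_segment) triples of the master circle."""
    order = getattr(graph, "master_order", None)
    if order is None:
        raise ValueError("graph lacks master_order; build it with this module")
    m = len(order)
    return {
        (order[(j - 1) % m], sid, order[(j + 1) % m])
        for j, sid in enumerate(order)
        if graph.segments[sid].is_repeat
    }


def path_label_map(graph: AssemblyGraph, repeat_order: list[str]) -> dict[tuple[str, str, str], str]:
    """Fixed convention mapping flank triples to path labels.

    For the i-th repeat, labels ``p(4i+1)``/``p(4i+2)`` are the two pairings
    present in the master circle (in circle order), ``p(4i+3)``/``p(4i+4)``
    the flank-swapped recombinant pairings.
    """
    order = getattr(graph, "master_order", None)
    if order is None:
        raise ValueError("graph lacks master_order")
    m = len(order)
    mapping: dict[tuple[str, str, str], str] = {}
    for i, rid in enumerate(repeat_order):
        pairs = [
            (order[(j - 1) % m], order[(j + 1) % m])
            for j, sid in enumerate(order)
            if sid == rid
        ]
        if len(pairs) != 2:
            raise ValueError(f"repeat {rid}: expected 2 occurrences, got {len(pairs)}")
        (ea, xa), (eb, xb) = pairs
        base = 4 * i
        mapping[(ea, rid, xa)] = f"p{base + 1}"
        mapping[(eb, rid, xb)] = f"p{base + 2}"
        mapping[(ea, rid, xb)] = f"p{base + 3}"
        mapping[(eb, rid, xa)] = f"p{base + 4}"
    return mapping


def derive_isomers(
    genome: CircularSequence,
    repeats: list[RepeatPair],
    graph: AssemblyGraph | None = None,
) -> dict[str, Isomer]:
    """The conformations reachable by direct-repeat recombination.

    Keyed by label: 'A' is the input master circle, 'B' the
    double-recombinant master (inter-repeat segments exchanged), 'C'/'D'
    the sub-circle pairs from recombining at exactly the first/second
    repeat. A single repeat pair yields only 'A' and 'C'; no repeats yield
    just 'A'.
    """
    if graph is None:
        graph = graph_from_repeats(genome, repeats)
    isomers = enumerate_isomers(graph)
    master = _master_triples(graph)
    repeat_order = [rp.id for rp in repeats]
    labeled: dict[str, Isomer] = {}
    for iso in isomers:
        recombined = set()
        for circle in iso.circles:
            ncirc = len(circle)
            for j, (sid, _) in enumerate(circle):
                if graph.segments[sid].is_repeat:
                    trip = (circle[(j - 1) % ncirc][0], sid, circle[(j + 1) % ncirc][0])
                    if trip not in master:
                        recombined.add(sid)
        iso = Isomer(iso.circles, iso.classification, frozenset(recombined))
        if not recombined:
            label = "A"
        elif len(repeat_order) > 1 and len(recombined) == len(repeat_order):
            label = "B"
        else:
            label = "CD"[repeat_order.index(sorted(recombined)[0])] if len(repeat_order) > 1 else "C"
        labeled[label] = iso
    return dict(sorted(labeled.items()))


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class _SourceCircle:
    label: str  # A, B, C1, C2, D1, D2
    isomer_label: str
    seq: str
    junctions: tuple[tuple[str, Interval], ...]  # (path_label, window on circle)


def _source_circles(
    isomers: dict[str, Isomer], graph: AssemblyGraph, repeats: list[RepeatPair], flank: int
) -> dict[str, list[_SourceCircle]]:
    label_map = path_label_map(graph, [rp.id for rp in repeats]) if repeats else {}
    out: dict[str, list[_SourceCircle]] = {}
    for iso_label, iso in isomers.items():
        circles = []
        for ci, circle in enumerate(iso.circles, start=1):
            seq = circle_sequence(circle, graph, canonical=False)
            ncirc = len(circle)
            L = len(seq)
            # offsets of each traversal element within the emitted sequence
            offsets = []
            pos = 0
            for sid, _ in circle:
                offsets.append(pos)
                pos += graph.segments[sid].length
            junctions = []
            for j, (sid, _) in enumerate(circle):
                if not graph.segments[sid].is_repeat:
                    continue
                trip = (circle[(j - 1) % ncirc][0], sid, circle[(j + 1) % ncirc][0])
                plabel = label_map.get(trip)
                if plabel is None:
                    continue
                rep_len = graph.segments[sid].length
                w_start = (offsets[j] - flank) % L
                w_end = (offsets[j] + rep_len + flank) % L
                junctions.append((plabel, Interval(w_start, w_end)))
            name = iso_label if len(iso.circles) == 1 else f"{iso_label}{ci}"
            circles.append(_SourceCircle(name, iso_label, seq, tuple(junctions)))
        out[iso_label] = circles
    return out


def _covers(read_start: int, read_span: int, window: Interval, L: int) -> bool:
    w_span = window.span(L)
    if w_span > read_span:
        return False
    return (window.start - read_start) % L + w_span <= read_span


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base errors, substitution:insertion:deletion = 2:1:1."""
    if rate <= 0:
        return seq
    n = len(seq)
    err_pos = np.flatnonzero(rng.random(n) < rate)
    if err_pos.size == 0:
        return seq
    kinds = rng.choice(3, size=err_pos.size, p=[0.5, 0.25, 0.25])  # 0 sub, 1 ins, 2 del
    rand_bases = BASES[rng.integers(0, 4, size=err_pos.size)]
    pieces = []
    prev = 0
    for pos, kind, rb in zip(err_pos.tolist(), kinds.tolist(), rand_bases.tolist()):
        pieces.append(seq[prev:pos])
        base = chr(rb)
        if kind == 0:  # substitute with a different base
            cur = seq[pos]
            sub = base if base != cur else "ACGT"[("ACGT".index(cur) + 1) % 4]
            pieces.append(sub)
        elif kind == 1:  # insert before the base, keep the base
            pieces.append(base + seq[pos])
        # kind == 2: deletion, emit nothing
        prev = pos + 1
    pieces.append(seq[prev:])
    return "".join(pieces)


def simulate_reads(
    isomers: dict[str, Isomer],
    graph: AssemblyGraph,
    repeats: list[RepeatPair],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Draw long reads from the weighted isomer mixture.

    Each read's source isomer follows ``isomer_weights`` (missing isomers
    with zero weight are allowed); within a two-circle isomer the circle is
    chosen proportional to its length. Start positions are uniform on the
    circle, lengths are truncated-normal (minimum ``read_min_length``,
    capped at the circle length), errors are applied per base and the read
    is emitted on a uniformly random strand. Truth labels record the
    pre-error source interval and all junction windows it fully contains.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    weights = config.normalized_weights()
    iso_labels = ["A", "B", "C", "D"]
    available = [l for l in iso_labels if l in isomers]
    w = np.array([weights[iso_labels.index(l)] for l in available])
    if w.sum() <= 0:
        raise ConfigError("all weight assigned to isomers that do not exist")
    w = w / w.sum()
    circles_by_iso = _source_circles(isomers, graph, repeats, config.truth_flank)

    n_reads = config.expected_n_reads()
    reads = []
    for k in range(n_reads):
        iso_label = available[rng.choice(len(available), p=w)]
        circles = circles_by_iso[iso_label]
        if len(circles) == 1:
            circ = circles[0]
        else:
            lens = np.array([len(c.seq) for c in circles], dtype=float)
            circ = circles[rng.choice(len(circles), p=lens / lens.sum())]
        L = len(circ.seq)
        raw = rng.normal(config.read_mean_length, config.read_length_sd)
        span = int(min(max(raw, config.read_min_length), L))
        start = int(rng.integers(0, L))
        source = circular_substring(CircularSequence(circ.label, circ.seq), start, span)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _apply_errors(source, config.error_rate, rng)
        if strand == "-":
            seq = reverse_complement(seq)
        covered = frozenset(
            p for p, window in circ.junctions if _covers(start, span, window, L)
        )
        rid = f"read{k:06d}"
        label = TruthLabel(
            read_id=rid,
            source_isomer=circ.label,
            source_interval=Interval(start, (start + span) % L, strand),
            source_circle_length=L,
            junction_paths_covered=covered,
        )
        reads.append(SimulatedRead(rid, seq, label))
    return ReadSet(reads)


def simulate(config: SimulationConfig):
    """One-call simulation: genome, repeats, graph, isomers, reads."""
    rng = np.random.default_rng(config.seed)
    genome, repeats, graph = generate_master_genome(config, rng)
    isomers = derive_isomers(genome, repeats, graph)
    reads = simulate_reads(isomers, graph, repeats, config, rng)
    return genome, repeats, graph, isomers, reads
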