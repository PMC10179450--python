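"""Junction-spanning long-read support for repeat-mediated recombination.

Around each two-copy direct repeat there are four possible flank pairings
("paths"): the two present in the master circle and the two produced by
recombination (left flank of one copy joined to the right flank of the
other). For each path a reference of ``left flank + repeat + right flank``
is built; a long read supports a path when it aligns across the entire
reference. Because the two copies are (near-)identical, only reads spanning
repeat plus both flanks are informative, and the per-path spanning-read
counts measure which conformations coexist in the sequenced tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
from scipy.stats import binomtest

from .core import CircularSequence, Interval, circular_substring, reverse_complement


@dataclass(frozen=True)
class RepeatPair:
    """A two-copy repeat annotation; both copies on the '+' strand."""

    id: str
    copy_a: Interval
    copy_b: Interval
    length: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("repeat length must be >= 1")
        if self.copy_a.strand != "+" or self.copy_b.strand != "+":
            raise ValueError("direct repeats only: both copies on '+'")


@dataclass(frozen=True)
class PathReference:
    repeat_id: str
    path_label: str
    left_flank_src: str  # "a" or "b": which copy contributed the left flank
    right_flank_src: str
    seq: str
    flank_len: int


@dataclass
class SupportTable:
    """Spanning-read counts per junction path for one repeat."""

    repeat_id: str
    read_ids: dict[str, list[str]]  # path_label -> supporting read ids
    min_identity: float
    max_end_slack: int

    @property
    def counts(self) -> dict[str, int]:
        return {p: len(ids) for p, ids in self.read_ids.items()}

    def total(self) -> int:
        return sum(len(ids) for ids in self.read_ids.values())


@dataclass(frozen=True)
class RecombinationSummary:
    repeat_id: str
    status: str  # "active", "inactive", or "no coverage"
    recombinant_fraction: float | None
    ci_low: float | None
    ci_high: float | None
    majority_conformation: str | None  # "native" or "recombinant"
    counts: dict[str, int]


def build_path_references(
    genome: CircularSequence,
    repeat: RepeatPair,
    flank_len: int = 500,
    first_label: int = 1,
) -> list[PathReference]:
    """The four flank-pairing references for one repeat.

    Labels ``p{first_label}``/``p{first_label+1}`` are the two native
    pairings (flanks of copy a; of copy b), the next two the flank-swapped
    recombinant pairings (left of a + right of b; left of b + right of a).
    With default 500 bp flanks and a repeat of length L each reference is
    L + 1000 bp.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    if flank_len == 0:
        warnings.warn("flank_len 0: all four references degenerate to the repeat")
    n = len(genome)

    def flanks(iv: Interval) -> tuple[str, str, str]:
        span = iv.span(n)
        rep = circular_substring(genome, iv.start, span)
        if flank_len == 0:
            return "", rep, ""
        left_start = (iv.start - flank_len) % n if genome.circular else iv.start - flank_len
        if genome.circular:
            left = circular_substring(genome, left_start, flank_len)
            right = circular_substring(genome, (iv.start + span) % n, min(flank_len, n - span))
        else:
            lo = max(0, iv.start - flank_len)
            left = genome.seq[lo : iv.start]
            right = genome.seq[iv.start + span : iv.start + span + flank_len]
            if len(left) < flank_len or len(right) < flank_len:
                warnings.warn(f"{iv}: flank truncated by sequence end")
        return left, rep, right

    la, rep_a, ra = flanks(repeat.copy_a)
    lb, rep_b, rb = flanks(repeat.copy_b)
    # the two copies may differ slightly; each reference uses the repeat
    # body of the copy providing the left flank
    for iv, other in ((repeat.copy_a, repeat.copy_b), (repeat.copy_b, repeat.copy_a)):
        ov = _flank_overlaps(iv, other, flank_len, n)
        if ov:
            warnings.warn(f"{repeat.id}: {ov} flank overlaps the other copy")

    combos = [
        ("a", "a", la + rep_a + ra),
        ("b", "b", lb + rep_b + rb),
        ("a", "b", la + rep_a + rb),
        ("b", "a", lb + rep_b + ra),
    ]
    return [
        PathReference(
            repeat_id=repeat.id,
            path_label=f"p{first_label + i}",
            left_flank_src=left,
            right_flank_src=right,
            seq=seq,
            flank_len=flank_len,
        )
        for i, (left, right, seq) in enumerate(combos)
    ]


def _circular_overlap(a_start: int, a_span: int, b_start: int, b_span: int, n: int) -> bool:
    return (b_start - a_start) % n < a_span or (a_start - b_start) % n < b_span


def _flank_overlaps(iv: Interval, other: Interval, flank_len: int, n: int) -> str | None:
    if not flank_len:
        return None
    o_start, o_span = other.start, other.span(n)
    if _circular_overlap((iv.start - flank_len) % n, flank_len, o_start, o_span, n):
        return "left"
    end = (iv.start + iv.span(n)) % n
    if _circular_overlap(end, flank_len, o_start, o_span, n):
        return "right"
    return None


def build_all_path_references(
    genome: CircularSequence, repeats: list[RepeatPair], flank_len: int = 500
) -> list[PathReference]:
    """References for every repeat, labelled p1..p4, p5..p8, ... in order."""
    refs = []
    for i, rp in enumerate(repeats):
        refs.extend(build_path_references(genome, rp, flank_len, first_label=4 * i + 1))
    return refs


def _read_items(reads) -> list[tuple[str, str]]:
    items = []
    for r in reads:
        if isinstance(r, tuple):
            items.append((r[0], r[1]))
        else:
            items.append((r.id, r.seq))
    return items


def _flank_errors(cigar: str, core_len: int, flank: int) -> tuple[int, int] | None:
    """Edit operations attributed to the first/last ``flank`` reference bp.

    Walks edlib's extended CIGAR ('='/'X'/'I'/'D'); indels are charged to
    the reference position where they occur. Returns None on an empty path.
    """
    if not cigar:
        return None
    left = right = 0
    qpos = 0  # position in the reference (edlib query)
    right_start = core_len - flank
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            qpos += n
            continue
        if ch in ("X", "I"):  # 'X' mismatch, 'I' unmatched reference base
            span_start, span_end = qpos, qpos + n
            left += max(0, min(span_end, flank) - span_start)
            right += max(0, span_end - max(span_start, right_start))
            qpos += n
        else:  # 'D': extra read base; charge to the current reference position
            if qpos < flank:
                left += n
            if qpos >= right_start:
                right += n
    return left, right


def _spans(core: str, rseq: str, max_dist: int, flank: int, min_identity: float) -> bool:
    core_len = len(core)
    aln = edlib.align(core, rseq, mode="HW", task="path", k=max_dist)
    if aln["editDistance"] == -1:
        return False
    if flank <= 0:
        return True
    errs = _flank_errors(aln["cigar"], core_len, flank)
    if errs is None:
        return False
    max_flank_err = int(flank * (1.0 - min_identity))
    return errs[0] <= max_flank_err and errs[1] <= max_flank_err


def count_spanning_reads(
    refs: list[PathReference],
    reads,
    min_identity: float = 0.80,
    max_end_slack: int = 0,
) -> dict[str, SupportTable]:
    """Count reads that completely span each path reference.

    A read supports a path iff it contains a (semi-global) alignment of the
    reference window ``[max_end_slack, |ref| - max_end_slack)`` whose
    overall identity and whose identity within each flank window both reach
    ``min_identity``. The per-flank requirement is what makes "completely
    spanned" informative: a score-maximising local aligner would not extend
    across a non-matching flank, and the flanks are the only part of a path
    reference that distinguishes the four paths of a repeat. Both strands
    are tried; each (read, path) pair counts at most once. Returns one
    table per repeat, keyed by repeat id.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    tables: dict[str, SupportTable] = {}
    items = _read_items(reads)
    rc_cache: dict[str, str] = {}
    for ref in refs:
        core_len = len(ref.seq) - 2 * max_end_slack
        if core_len <= 0:
            raise ValueError(
                f"{ref.path_label}: reference shorter than 2 x max_end_slack"
            )
        core = ref.seq[max_end_slack : len(ref.seq) - max_end_slack]
        max_dist = int(core_len * (1.0 - min_identity))
        # flank portion remaining inside the core after trimming the slack
        flank = max(0, ref.flank_len - max_end_slack)
        table = tables.setdefault(
            ref.repeat_id,
            SupportTable(ref.repeat_id, {}, min_identity, max_end_slack),
        )
        supporters = table.read_ids.setdefault(ref.path_label, [])
        for rid, rseq in items:
            if len(rseq) < core_len - max_dist:
                continue
            hit = _spans(core, rseq, max_dist, flank, min_identity)
            if not hit:
                rc = rc_cache.get(rid)
                if rc is None:
                    rc = rc_cache[rid] = reverse_complement(rseq)
                hit = _spans(core, rc, max_dist, flank, min_identity)
            if hit:
                supporters.append(rid)
    return tables


def summarize_recombination(
    table: SupportTable, min_support: int = 1, confidence: float = 0.95
) -> RecombinationSummary:
    """Classify one repeat's junction support.

    The repeat is "recombinationally active" iff all four paths have at
    least ``min_support`` spanning reads. The recombinant fraction is
    (p3 + p4) / (p1 + p2 + p3 + p4) in label order, with a Clopper–Pearson
    binomial confidence interval.
    """
    labels = sorted(table.read_ids, key=lambda p: int(p.lstrip("p")))
    if len(labels) != 4:
        raise ValueError(f"expected 4 paths for {table.repeat_id}, got {labels}")
    counts = {p: len(table.read_ids[p]) for p in labels}
    native = counts[labels[0]] + counts[labels[1]]
    recomb = counts[labels[2]] + counts[labels[3]]
    total = native + recomb
    if total == 0:
        return RecombinationSummary(
            table.repeat_id, "no coverage", None, None, None, None, counts
        )
    status = (
        "active"
        if all(counts[p] >= min_support for p in labels)
        else "inactive"
    )
    ci = binomtest(recomb, total).proportion_ci(confidence_level=confidence)
    return RecombinationSummary(
        repeat_id=table.repeat_id,
        status=status,
        recombinant_fraction=recomb / total,
        ci_low=ci.low,
        ci_high=ci.high,
        majority_conformation="native" if native >= recomb else "recombinant",
        counts=counts,
    )
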