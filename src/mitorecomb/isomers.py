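"""Enumeration of circular genome conformations (isomers) from a repeat graph.

A plant mitogenome assembly typically collapses each large repeat into a
single graph node traversed twice. Homologous recombination between the two
copies of a direct repeat swaps which entry flank continues into which exit
flank, so each two-copy repeat node admits two entry->exit pairings. This
module enumerates every combination of pairings, decomposes each into
circles, and classifies the results: a single circle carrying all segments
is a "master circle"; recombination at a single direct repeat splits the
master into a pair of sub-genomic circles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import reverse_complement


class GraphStructureError(ValueError):
    """Graph violates the repeat-multiplicity / degree invariants."""


class UnsupportedOrientationError(NotImplementedError):
    """Graph contains inverted ('-') links; only direct repeats are handled."""


@dataclass
class Segment:
    id: str
    seq: str | None = None
    length: int | None = None
    is_repeat: bool = False

    def __post_init__(self) -> None:
        if self.seq is not None:
            self.length = len(self.seq)
        if self.length is None:
            raise ValueError(f"segment {self.id}: need seq or length")


# A link is (from_segment, from_orient, to_segment, to_orient), GFA L-line style.
Link = tuple[str, str, str, str]


@dataclass
class AssemblyGraph:
    """Segments plus oriented adjacencies; repeat nodes carry multiplicity 2+."""

    segments: dict[str, Segment]
    links: list[Link]
    # traversal order of the master circle the graph was built from, when known
    master_order: list[str] | None = None

    def validate(self) -> None:
        for u, uo, v, vo in self.links:
            if u not in self.segments or v not in self.segments:
                raise GraphStructureError(f"link references unknown segment: {(u, v)}")
            if uo != "+" or vo != "+":
                raise UnsupportedOrientationError(
                    "inverted-orientation links detected; only direct-repeat "
                    "graphs are classified"
                )
        outs: dict[str, int] = {s: 0 for s in self.segments}
        ins: dict[str, int] = {s: 0 for s in self.segments}
        for u, _, v, _ in self.links:
            outs[u] += 1
            ins[v] += 1
            if self.segments[u].is_repeat and self.segments[v].is_repeat:
                raise GraphStructureError(
                    f"adjacent repeat nodes ({u} -> {v}) are not supported"
                )
        for sid, seg in self.segments.items():
            expect = self.multiplicity(sid)
            if ins[sid] != expect or outs[sid] != expect:
                raise GraphStructureError(
                    f"segment {sid}: in/out degree ({ins[sid]}/{outs[sid]}) "
                    f"!= multiplicity {expect}"
                )

    def multiplicity(self, sid: str) -> int:
        if not self.segments[sid].is_repeat:
            return 1
        return max(1, sum(1 for u, _, v, _ in self.links if v == sid))

    def repeat_ids(self) -> list[str]:
        return [s for s, seg in self.segments.items() if seg.is_repeat]


@dataclass(frozen=True)
class Isomer:
    """One resolved conformation: a set of circles of (segment, orientation)."""

    circles: tuple[tuple[tuple[str, str], ...], ...]
    classification: str  # "master" or "sub_circle_pair"
    recombined_at: frozenset[str] = frozenset()

    def segment_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for circle in self.circles:
            for sid, _ in circle:
                counts[sid] = counts.get(sid, 0) + 1
        return counts

    def circle_lengths(self, graph: AssemblyGraph) -> list[int]:
        return [
            sum(graph.segments[sid].length for sid, _ in circle)
            for circle in self.circles
        ]


def _canonical_circle(circle: tuple[tuple[str, str], ...]) -> tuple:
    """Minimum over rotations and over reverse-complement traversal."""
    variants = []
    n = len(circle)
    flipped = tuple(
        (sid, "-" if o == "+" else "+") for sid, o in reversed(circle)
    )
    for form in (circle, flipped):
        for i in range(n):
            variants.append(form[i:] + form[:i])
    return min(variants)


def canonical_isomer_key(circles) -> tuple:
    return tuple(sorted(_canonical_circle(tuple(c)) for c in circles))


def enumerate_isomers(graph: AssemblyGraph) -> list[Isomer]:
    """All distinct circle decompositions over the repeat entry->exit pairings.

    For ``k`` independent two-copy direct repeats on one master circle this
    yields ``2**k`` combinations, deduplicated up to rotation and
    reverse-complement of each circle. Classification is "master" for a
    single circle containing every unique segment, otherwise
    "sub_circle_pair".
    """
    graph.validate()
    repeats = graph.repeat_ids()
    in_links: dict[str, list[Link]] = {r: [] for r in repeats}
    out_links: dict[str, list[Link]] = {r: [] for r in repeats}
    plain_next: dict[str, tuple[str, str]] = {}  # unique seg -> (via_repeat|None, next)
    for u, _, v, _ in graph.links:
        if v in in_links:
            in_links[v].append((u, "+", v, "+"))
        if u in out_links:
            out_links[u].append((u, "+", v, "+"))
        if u not in out_links and v not in in_links:
            plain_next[u] = (None, v)

    # Reference pairing (first matching) defines "not recombined"; for graphs
    # built from a master circle the caller recomputes recombined_at against
    # the master's flank adjacencies.
    matchings_per_repeat = []
    for r in repeats:
        ins = in_links[r]
        outs = out_links[r]
        if len(ins) != len(outs) or not ins:
            raise GraphStructureError(f"repeat {r}: unmatched entries/exits")
        matchings = [tuple(zip(ins, perm)) for perm in permutations(outs)]
        matchings_per_repeat.append(matchings)

    uniques = [s for s in graph.segments if not graph.segments[s].is_repeat]
    seen: dict[tuple, Isomer] = {}
    combos = product(*matchings_per_repeat) if repeats else [()]
    for combo in combos:
        # successor of unique segment u: possibly through a repeat r to v
        succ: dict[str, tuple[str | None, str]] = dict(plain_next)
        for r, matching in zip(repeats, combo):
            for (u, _, _, _), (_, _, v, _) in matching:
                succ[u] = (r, v)
        circles = []
        unused = set(uniques)
        while unused:
            start = min(unused)  # deterministic traversal order
            circle: list[tuple[str, str]] = []
            cur = start
            while True:
                circle.append((cur, "+"))
                unused.discard(cur)
                via, nxt = succ[cur]
                if via is not None:
                    circle.append((via, "+"))
                if nxt == start:
                    break
                cur = nxt
            circles.append(tuple(circle))
        key = canonical_isomer_key(circles)
        if key in seen:
            continue
        classification = "master" if len(circles) == 1 else "sub_circle_pair"
        seen[key] = Isomer(circles=tuple(circles), classification=classification)
    return list(seen.values())


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def circle_sequence(circle, graph: AssemblyGraph, canonical: bool = True) -> str:
    """Nucleotide sequence of one circle, linearized.

    With ``canonical=True`` the record starts at the lexicographically
    smallest rotation, so equal circles serialize identically regardless of
    traversal start.
    """
    parts = []
    for sid, orient in circle:
        seq = graph.segments[sid].seq
        if seq is None:
            raise ValueError(f"segment {sid} carries no sequence")
        parts.append(seq if orient == "+" else reverse_complement(seq))
    s = "".join(parts)
    if canonical and s:
        k = _least_rotation(s)
        s = s[k:] + s[:k]
    return s


def isomer_to_fasta(isomer: Isomer, graph: AssemblyGraph, name: str = "isomer") -> list[SeqRecord]:
    """One FASTA record per circle, canonical-rotation linearized."""
    records = []
    for i, circle in enumerate(isomer.circles, start=1):
        seq = circle_sequence(circle, graph)
        rid = name if len(isomer.circles) == 1 else f"{name}_circle{i}"
        desc = "circular " + ",".join(f"{sid}{o}" for sid, o in circle)
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    return records
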