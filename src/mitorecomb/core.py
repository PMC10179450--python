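"""Shared sequence and coordinate primitives.

Plant mitogenomes assemble as circles, so every coordinate in this package
is allowed to wrap through the origin of a :class:`CircularSequence`.
Internally all intervals are 0-based, half-open; report writers convert to
1-based inclusive (GenBank convention) at the edge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

DNA_ALPHABET = frozenset("ACGTN")
_DNA_RE = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


def _check_dna(seq: str) -> str:
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise AlphabetError(f"non-DNA characters in sequence: {bad!r}")
    return seq


def complement(seq: str) -> str:
    """Watson–Crick complement (N stays N)."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement; an involution on {A,C,G,T,N} strings."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval.

    On a circular sequence ``end <= start`` is legal and means the interval
    wraps through the origin; its span is ``(end - start) mod length``.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValueError("interval coordinates must be non-negative")

    def span(self, seq_length: int | None = None) -> int:
        """Number of bases covered; needs ``seq_length`` when wrapping."""
        if self.end > self.start:
            return self.end - self.start
        if seq_length is None:
            raise ValueError("wrapping interval needs the sequence length")
        n = (self.end - self.start) % seq_length
        if n == 0:
            raise ValueError("zero-span interval")
        return n

    def wraps(self) -> bool:
        return self.end <= self.start


@dataclass
class CircularSequence:
    """A (possibly circular) uppercase DNA sequence.

    All position arithmetic on a circular sequence is modulo ``len(self)``.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError("empty sequence")
        _check_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def substring(self, start: int, span: int) -> str:
        return circular_substring(self, start, span)

    def fetch(self, interval: Interval) -> str:
        """Sequence of an interval, reverse-complemented for '-' strand."""
        s = circular_substring(self, interval.start, interval.span(len(self)))
        return reverse_complement(s) if interval.strand == "-" else s


def circular_substring(g: CircularSequence, start: int, span: int) -> str:
    """``span`` bases starting at ``start``, wrapping the origin if circular.

    Raises on a linear sequence when the window would run off the end, and
    on any out-of-range ``start``/``span``.
    """
    n = len(g)
    if not 0 <= start < n:
        raise ValueError(f"start {start} out of range for length {n}")
    if not 0 < span <= n:
        raise ValueError(f"span {span} out of range for length {n}")
    end = start + span
    if end <= n:
        return g.seq[start:end]
    if not g.circular:
        raise ValueError(
            f"window [{start}, {end}) overruns linear sequence of length {n}"
        )
    return g.seq[start:] + g.seq[: end - n]


def gc_content(g: CircularSequence | str) -> float:
    """GC percentage over unambiguous bases (N excluded from denominator)."""
    seq = g.seq if isinstance(g, CircularSequence) else _check_dna(g)
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / acgt
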