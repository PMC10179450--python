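"""Descriptive repeat content: microsatellites and dispersed repeat pairs.

Two finders in the style of the field's standard tools:

* :func:`find_ssrs` — perfect tandem repeats of 1–6 bp motifs above
  per-unit-size copy-number thresholds (MISA-style; defaults 10/5/4/3/3/3
  for mono- through hexanucleotides).
* :func:`find_dispersed_repeats` — maximal non-tandem repeated pairs of
  four kinds (forward, reverse, palindromic, complementary) under a Hamming
  mismatch budget and a length/E-value filter (REPuter-style; defaults
  30 bp, 3 mismatches, E < 1e-5).

Both scan the sequence linearly; to probe repeats spanning the origin of a
circle, rotate the sequence first.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf

from .core import CircularSequence, Interval, complement, reverse_complement

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
REPEAT_KINDS = ("forward", "reverse", "palindromic", "complementary")


@dataclass(frozen=True)
class SSRRecord:
    motif: str
    unit_size: int
    copies: int
    interval: Interval

    def __post_init__(self) -> None:
        if self.interval.end - self.interval.start != self.unit_size * self.copies:
            raise ValueError("SSR interval length != unit_size * copies")


@dataclass(frozen=True)
class DispersedRepeat:
    kind: str
    interval_a: Interval  # stored with interval_a.start <= interval_b.start
    interval_b: Interval
    length: int
    mismatches: int
    evalue: float


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter motif."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def find_ssrs(
    g: CircularSequence | str,
    thresholds: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """Maximal perfect tandem runs of 1–6 bp motifs, sorted by start.

    A run of period ``u`` is reported once, anchored at its leftmost start,
    with ``copies`` the number of complete motif copies. Runs whose motif
    is itself periodic (e.g. "ATAT" at unit 4) are reported at the smaller
    unit only. Windows containing N never match. Overlapping SSRs of
    different unit sizes are all reported.
    """
    if thresholds is None:
        thresholds = DEFAULT_SSR_THRESHOLDS
    s = g.seq if isinstance(g, CircularSequence) else g
    n = len(s)
    records = []
    for u, min_copies in sorted(thresholds.items()):
        if u < 1:
            raise ValueError("unit sizes must be >= 1")
        min_run = u * min_copies
        i = 0
        while i + min_run <= n:
            # left-maximality: the period-u run must not start earlier
            if i > 0 and s[i - 1] == s[i + u - 1] and s[i - 1] != "N":
                i += 1
                continue
            j = i + u
            while j < n and s[j] == s[j - u] and s[j] != "N":
                j += 1
            copies = (j - i) // u
            motif = s[i : i + u]
            if (
                copies >= min_copies
                and "N" not in motif
                and _is_primitive(motif)
            ):
                records.append(
                    SSRRecord(motif, u, copies, Interval(i, i + u * copies))
                )
            # next candidate run of this period starts after the current run
            i = max(i + 1, j - u + 1)
    records.sort(key=lambda r: (r.interval.start, r.unit_size))
    return records


def repeat_evalue(length: int, mismatches: int, genome_length: int) -> float:
    """Expected pair count under a two-position Bonferroni binomial model.

    E = n^2 * C(l, m) * (1/4)^(l-m) * (3/4)^m for a pair of length ``l``
    with ``m`` mismatches in a genome of length ``n``.
    """
    return (
        genome_length**2
        * comb(length, mismatches)
        * 0.25 ** (length - mismatches)
        * 0.75**mismatches
    )


def _maximal_windows(mismatch_positions, lo, hi, max_mismatch):
    """Maximal sub-windows of [lo, hi) holding <= max_mismatch mismatches.

    Yields (start, end, n_mismatches). ``mismatch_positions`` must be the
    sorted mismatch coordinates inside [lo, hi).
    """
    p = list(mismatch_positions)
    q = len(p)
    m = max_mismatch
    if q <= m:
        yield lo, hi, q
        return
    for a in range(q - m + 1):
        start = lo if a == 0 else p[a - 1] + 1
        end = hi if a + m == q else p[a + m]
        yield start, end, m


def _diagonal_mismatches(s: str, t: str, d: int) -> tuple[int, int, list[int]]:
    """Mismatch positions (in s-coordinates) when aligning s[i] to t[i+d]."""
    n, nt = len(s), len(t)
    lo = max(0, -d)
    hi = min(n, nt - d)
    mism = [
        i
        for i in range(lo, hi)
        if s[i] != t[i + d] or s[i] == "N" or t[i + d] == "N"
    ]
    return lo, hi, mism


def _seed_diagonals(s: str, t: str, k: int) -> set[int]:
    """(s, t)-space diagonals j - i holding an exact shared k-mer."""
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if "N" not in w:
            index.setdefault(w, []).append(i)
    out: set[int] = set()
    for j in range(len(t) - k + 1):
        for i in index.get(t[j : j + k], ()):
            out.add(j - i)
    return out


def _window_records(
    s: str,
    t: str,
    kind: str,
    diagonals,
    min_len: int,
    max_mismatch: int,
) -> set[tuple]:
    """Canonical (kind, a_start, b_start, length, mismatches) tuples."""
    n = len(s)
    found: set[tuple] = set()
    for d in diagonals:
        if kind == "forward" and d == 0:
            continue  # trivial self-match
        lo, hi, mism = _diagonal_mismatches(s, t, d)
        if hi - lo < min_len:
            continue
        for start, end, nm in _maximal_windows(mism, lo, hi, max_mismatch):
            length = end - start
            if length < min_len:
                continue
            a = (start, end)
            if kind in ("forward", "complementary"):
                b = (start + d, end + d)
            else:  # t is a reversed transform: map back to s coordinates
                b = (n - (end + d), n - (start + d))
            if a == b:
                continue  # self-pair
            (a, b) = (a, b) if a <= b else (b, a)
            found.add((kind, a[0], b[0], length, nm))
    return found


def _transform(s: str, kind: str) -> str:
    if kind == "forward":
        return s
    if kind == "reverse":
        return s[::-1]
    if kind == "palindromic":
        return reverse_complement(s)
    if kind == "complementary":
        return complement(s)
    raise ValueError(f"unknown repeat kind: {kind}")


def find_dispersed_repeats(
    g: CircularSequence | str,
    min_len: int = 30,
    max_mismatch: int = 3,
    max_evalue: float | None = 1e-5,
    kinds: tuple[str, ...] = REPEAT_KINDS,
) -> list[DispersedRepeat]:
    """Maximal repeated pairs of each kind under a Hamming mismatch budget.

    A pair is maximal when no simultaneous extension of both copies in
    either direction keeps the mismatch count within ``max_mismatch``.
    Candidate alignments are located by exact k-mer seeding with
    k = min(min_len // (max_mismatch + 1), 32), which by the pigeonhole
    principle finds every qualifying pair, then enumerated exhaustively on
    each seeded (anti-)diagonal. ``max_evalue=None`` disables the E-value
    filter.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    s = g.seq if isinstance(g, CircularSequence) else g
    n = len(s)
    k = min(min_len // (max_mismatch + 1), 32)
    if k < 1:
        raise ValueError("mismatch budget too large for min_len")
    if max_evalue is None:
        max_evalue = inf
    records: list[DispersedRepeat] = []
    for kind in kinds:
        t = _transform(s, kind)
        diagonals = _seed_diagonals(s, t, k)
        for kind_, a0, b0, length, nm in sorted(
            _window_records(s, t, kind, diagonals, min_len, max_mismatch)
        ):
            ev = repeat_evalue(length, nm, n)
            if ev >= max_evalue:
                continue
            records.append(
                DispersedRepeat(
                    kind=kind_,
                    interval_a=Interval(a0, a0 + length),
                    interval_b=Interval(b0, b0 + length),
                    length=length,
                    mismatches=nm,
                    evalue=ev,
                )
            )
    records.sort(key=lambda r: (-r.length, r.interval_a.start, r.kind))
    return records


def summarize_repeats(
    ssrs: list[SSRRecord],
    dispersed: list[DispersedRepeat],
    genome_length: int,
) -> dict:
    """Aggregate counts plus union coverage of repeat-involved positions."""
    ssr_by_unit = {u: 0 for u in range(1, 7)}
    for r in ssrs:
        ssr_by_unit[r.unit_size] = ssr_by_unit.get(r.unit_size, 0) + 1
    by_kind = {kind: 0 for kind in REPEAT_KINDS}
    bins = {"30-49": 0, "50-99": 0, ">=100": 0}
    intervals = []
    for r in dispersed:
        by_kind[r.kind] += 1
        if r.length < 50:
            bins["30-49"] += 1
        elif r.length < 100:
            bins["50-99"] += 1
        else:
            bins[">=100"] += 1
        intervals.append((r.interval_a.start, r.interval_a.end))
        intervals.append((r.interval_b.start, r.interval_b.end))
    # union of interval coverage over both copies of every pair
    union = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                union += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        union += cur_end - cur_start
    return {
        "n_ssrs": len(ssrs),
        "ssr_by_unit_size": ssr_by_unit,
        "n_dispersed_pairs": len(dispersed),
        "dispersed_by_kind": by_kind,
        "dispersed_by_length_bin": bins,
        "dispersed_union_bp": union,
        "dispersed_union_fraction": union / genome_length if genome_length else 0.0,
    }
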