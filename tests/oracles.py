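"""Independent brute-force oracles used to validate the fast implementations.

These re-derive expected results from first principles (exhaustive scans,
direct string containment) and deliberately share no search code with the
package.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def comp(s: str) -> str:
    return s.translate(_COMP)


# ---------------------------------------------------------------------------
# SSRs


def _primitive(motif: str) -> bool:
    # classic rotation trick: a string is primitive iff it does not occur
    # inside (motif + motif) minus its ends
    return motif not in (motif + motif)[1:-1]


def brute_force_ssrs(s: str, thresholds: dict[int, int]) -> set[tuple]:
    """All (motif, unit, copies, start) for maximal perfect tandem runs."""
    n = len(s)
    out = set()
    for u, min_copies in thresholds.items():
        for i in range(n):
            motif = s[i : i + u]
            if len(motif) < u or "N" in motif or not _primitive(motif):
                continue
            # maximal number of complete copies starting at i
            c = 0
            while s[i + c * u : i + (c + 1) * u] == motif:
                c += 1
            if c < min_copies:
                continue
            if "N" in s[i : i + c * u]:
                continue
            # left-maximal: the same period must not extend one base left
            if i > 0 and s[i - 1] != "N" and s[i - 1] == s[i + u - 1]:
                continue
            out.add((motif, u, c, i))
    return out


# ---------------------------------------------------------------------------
# dispersed repeats


def _transform(s: str, kind: str) -> str:
    return {
        "forward": s,
        "reverse": s[::-1],
        "palindromic": rc(s),
        "complementary": comp(s),
    }[kind]


def _map_back(kind: str, n: int, d: int, start: int, end: int):
    a = (start, end)
    if kind in ("forward", "complementary"):
        b = (start + d, end + d)
    else:
        b = (n - (end + d), n - (start + d))
    if a == b:
        return None
    return (a, b) if a <= b else (b, a)


def brute_force_dispersed(
    s: str, min_len: int, max_mismatch: int, kinds=("forward", "reverse", "palindromic", "complementary")
) -> set[tuple]:
    """All canonical (kind, a_start, b_start, length, mismatches) tuples.

    Scans every (s, transform)-space diagonal with a sliding window: for
    each window start, the furthest end keeping <= max_mismatch mismatches;
    windows contained in a longer window on the same diagonal are dropped
    (non-maximal).
    """
    n = len(s)
    out = set()
    for kind in kinds:
        t = _transform(s, kind)
        for d in range(-(n - 1), n):
            if kind == "forward" and d == 0:
                continue
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            bad = [
                s[i] != t[i + d] or s[i] == "N" or t[i + d] == "N"
                for i in range(lo, hi)
            ]
            m = hi - lo
            windows = []
            j = 0
            mism = 0
            for i in range(m):
                if j < i:
                    j = i
                    mism = 0
                while j < m and mism + (1 if bad[j] else 0) <= max_mismatch:
                    mism += 1 if bad[j] else 0
                    j += 1
                windows.append((i, j))
                if i < j and bad[i]:
                    mism -= 1
            prev_end = -1
            for i, j in windows:
                if j <= prev_end:  # contained in an earlier window
                    continue
                prev_end = j
                if j - i < min_len:
                    continue
                pair = _map_back(kind, n, d, lo + i, lo + j)
                if pair is None:
                    continue
                (a0, _), (b0, _) = pair
                nm = sum(bad[i:j])
                out.add((kind, a0, b0, j - i, nm))
    return out


# ---------------------------------------------------------------------------
# spanning reads


def brute_force_spanning_counts(refs, reads) -> dict[str, int]:
    """Exact substring containment of each reference in each read (both strands)."""
    counts = {}
    for ref in refs:
        k = 0
        for r in reads:
            seq = r.seq if hasattr(r, "seq") else r[1]
            if ref.seq in seq or ref.seq in rc(seq):
                k += 1
        counts[ref.path_label] = k
    return counts
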