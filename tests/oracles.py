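"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: motif membership is decided
by decomposing each candidate substring with itertools.groupby, and overlap
counting is an all-pairs scan.
"""

from __future__ import annotations

from itertools import groupby


def _runs(s: str) -> list[tuple[str, int, int]]:
    out = []
    pos = 0
    for ch, grp in groupby(s):
        n = len(list(grp))
        out.append((ch, pos, pos + n))
        pos += n
    return out


def g4_substring_matches(
    s: str, min_tract: int = 3, loop_min: int = 1, loop_max: int = 7, min_tracts: int = 4
) -> bool:
    """Does the *whole* string match the motif grammar?

    Tracts are maximal G-runs of >= min_tract; the string must start and end
    with a tract, every gap between consecutive tracts must be a legal loop,
    and there must be >= min_tracts tracts.  N never matches.
    """
    if "N" in s:  # N never participates in a match, neither tract nor loop
        return False
    gruns = [(a, b) for c, a, b in _runs(s) if c == "G" and b - a >= min_tract]
    if len(gruns) < min_tracts:
        return False
    if gruns[0][0] != 0 or gruns[-1][1] != len(s):
        return False
    for (a1, b1), (a2, b2) in zip(gruns, gruns[1:]):
        gap = a2 - b1
        if not (loop_min <= gap <= loop_max):
            return False
    return True


def g4_brute_scan(
    s: str, min_tract: int = 3, loop_min: int = 1, loop_max: int = 7, min_tracts: int = 4
) -> list[tuple[int, int]]:
    """Leftmost-longest greedy non-overlapping matches by substring enumeration."""
    n = len(s)
    tract = "G" * min_tract
    min_len = min_tracts * min_tract + (min_tracts - 1) * loop_min
    out = []
    pos = 0
    while pos <= n - min_len:
        found = None
        for start in range(pos, n - min_len + 1):
            if s[start : start + min_tract] != tract:
                continue
            for end in range(n, start + min_len - 1, -1):
                if g4_substring_matches(s[start:end], min_tract, loop_min, loop_max, min_tracts):
                    found = (start, end)
                    break
            if found:
                break
        if not found:
            break
        out.append(found)
        pos = found[1]
    return out


def brute_overlap_hits(a_rows, b_rows, strand_mode="ignore", min_overlap=1):
    """All-pairs hit flags for rows (contig, start, end, strand)."""
    flip = {"+": "-", "-": "+"}
    hits = []
    for ac, as_, ae, astr in a_rows:
        hit = False
        for bc, bs, be, bstr in b_rows:
            if ac != bc:
                continue
            if strand_mode == "same" and bstr != astr:
                continue
            if strand_mode == "opposite" and bstr != flip[astr]:
                continue
            if min(ae, be) - max(as_, bs) >= min_overlap:
                hit = True
                break
        hits.append(hit)
    return hits
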