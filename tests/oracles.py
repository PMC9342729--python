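"""Independent reference implementations used to check the fast detectors.

These are deliberately written from the definitions, not from the package
internals: the SSR oracle enumerates every (start, unit) pair directly;
the dispersed-repeat oracle scans complete diagonals/antidiagonals with no
seeding step; the micro oracle checks window maximality by brute extension
on tiny strings; the alignment oracle is a plain-python Gotoh DP.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# SSRs


def _primitive(motif: str) -> bool:
    u = len(motif)
    return not any(
        u % p == 0 and motif == motif[:p] * (u // p) for p in range(1, u)
    )


def ssr_oracle(seq: str, min_by_unit: dict[int, int]) -> set[tuple]:
    """Every maximal primitive microsatellite run, by direct enumeration.

    Returns {(start, end, motif, n_repeats)} after the containment
    suppression rule (shorter-unit run inside a longer-unit run dropped).
    """
    n = len(seq)
    raw = []
    for u, min_rep in min_by_unit.items():
        for s in range(n - u + 1):
            motif = seq[s : s + u]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximal: position s-1 must not continue the period
            if s > 0 and s - 1 + u < n and seq[s - 1] == seq[s - 1 + u]:
                continue
            # periodic stretch length from s
            L = u
            while s + L < n and seq[s + L] == seq[s + L - u]:
                L += 1
            n_rep = L // u
            if n_rep >= min_rep:
                raw.append((s, s + n_rep * u, motif, n_rep))
    out = set()
    for h in raw:
        s, e, motif, _ = h
        contained = any(
            len(o[2]) > len(motif) and o[0] <= s and e <= o[1] for o in raw
        )
        if not contained:
            out.add(h)
    return out


# ---------------------------------------------------------------------------
# Dispersed repeats


def _windows_from_matches(match: np.ndarray, h: int) -> list[tuple[int, int, int]]:
    """Match-trimmed cores of all maximal <=h-mismatch windows of a
    diagonal's full match vector (local coordinates)."""
    L = len(match)
    marks = [-1] + list(np.flatnonzero(~match)) + [L]
    out = []
    for t in range(len(marks) - h - 1):
        a, b = marks[t] + 1, marks[t + h + 1]
        if b <= a:
            continue
        mm = sum(1 for q in marks[t + 1 : t + h + 1] if a <= q < b)
        while a < b and not match[a]:
            a += 1
            mm -= 1
        while b > a and not match[b - 1]:
            b -= 1
            mm -= 1
        if b > a:
            out.append((a, b, mm))
    return out


def dispersed_oracle(seq: str, min_len: int, max_hamming: int) -> set[tuple]:
    """All dispersed-repeat hits by scanning every (anti)diagonal in full.

    Returns {(kind, pos1, pos2, length, mismatches)} with intervals as
    (start, end) tuples, canonicalized exactly like the detector.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    carr = np.frombuffer(seq.translate(COMP).encode(), dtype=np.uint8)
    nmask = arr != ord("N")
    hits = set()
    for d in range(1, n - min_len + 1):
        match = (arr[:-d] == arr[d:]) & nmask[:-d] & nmask[d:]
        for a, b, mm in _windows_from_matches(match, max_hamming):
            if b - a >= min_len:
                hits.add(("forward", (a, b), (a + d, b + d), b - a, mm))
    for c in range(min_len - 1, 2 * n - min_len):
        lo, hi = max(0, c - n + 1), min(n, c + 1)
        p = np.arange(lo, hi)
        match = (arr[p] == carr[c - p]) & nmask[p] & nmask[c - p]
        for a, b, mm in _windows_from_matches(match, max_hamming):
            a, b = a + lo, b + lo
            if b - a < min_len:
                continue
            p2 = (c - b + 1, c - a + 1)
            if a > p2[0]:
                continue  # mirror; counted once
            hits.add(("palindromic", (a, b), p2, b - a, mm))
    return hits


def dispersed_micro_oracle(seq: str, min_len: int, h: int) -> set[tuple]:
    """Maximality checked by explicit window extension (tiny inputs only).

    A pair of windows is a maximal window iff neither end can move outward
    without exceeding the mismatch budget or leaving the sequence; hits are
    its match-trimmed core, like the detector reports.
    """
    n = len(seq)

    def col(kind, c_or_d, p):  # does alignment column p match?
        if kind == "forward":
            q = p + c_or_d
            if not (0 <= p < n and 0 <= q < n):
                return None
            return seq[p] == seq[q] and seq[p] != "N"
        q = c_or_d - p
        if not (0 <= p < n and 0 <= q < n):
            return None
        return seq[p] == seq[q].translate(COMP) and seq[p] != "N"

    hits = set()
    for kind in ("forward", "palindromic"):
        keys = range(1, n) if kind == "forward" else range(2 * n - 1)
        for key in keys:
            for a in range(n):
                if col(kind, key, a) is None:
                    continue
                for b in range(a + 1, n + 1):
                    cols = [col(kind, key, p) for p in range(a, b)]
                    if any(c is None for c in cols):
                        break
                    mm = cols.count(False)
                    if mm > h:
                        break
                    left = col(kind, key, a - 1)
                    right = col(kind, key, b)
                    left_ext = left is not None and (mm + (not left)) <= h
                    right_ext = right is not None and (mm + (not right)) <= h
                    if left_ext or right_ext:
                        continue
                    ta, tb, tmm = a, b, mm
                    while ta < tb and not col(kind, key, ta):
                        ta += 1
                        tmm -= 1
                    while tb > ta and not col(kind, key, tb - 1):
                        tb -= 1
                        tmm -= 1
                    if tb - ta < min_len:
                        continue
                    if kind == "forward":
                        hits.add((kind, (ta, tb), (ta + key, tb + key), tb - ta, tmm))
                    else:
                        p2 = (key - tb + 1, key - ta + 1)
                        if ta <= p2[0]:
                            hits.add((kind, (ta, tb), p2, tb - ta, tmm))
    return hits


# ---------------------------------------------------------------------------
# Global affine-gap alignment score (Gotoh, plain python)


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=10.0,
                gap_extend=2.0) -> float:
    """Optimal global alignment score; first gap base costs gap_open."""
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)
    return max(M[la][lb], X[la][lb], Y[la][lb])


# ---------------------------------------------------------------------------
# Exhaustive minimal set cover


def exhaustive_min_cover(site_pairs: list[frozenset], coverable: frozenset) -> int:
    """Size of the smallest subset of sites covering ``coverable``."""
    from itertools import combinations

    if not coverable:
        return 0
    for size in range(1, len(site_pairs) + 1):
        for combo in combinations(site_pairs, size):
            if frozenset().union(*combo) >= coverable:
                return size
    raise AssertionError("coverable set not coverable")
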