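"""Three repeat surveys over a plastome sequence.

* :func:`find_ssrs` — MISA-style microsatellites: maximal runs of a
  primitive 1-6 bp motif meeting per-unit-size minimum repeat counts.
* :func:`find_tandem_repeats` — a deliberately simplified tandem-repeat
  detector (period scan + consensus scoring).  It is an approximation of
  the classic stochastic-model finders, not a re-implementation: copies are
  compared to the consensus positionally, without intra-copy indels.
* :func:`find_dispersed_repeats` — all maximal repeated pairs (forward and
  palindromic/reverse-complement orientation) of length >= ``min_len`` with
  at most ``max_hamming`` mismatches, in the VMATCH ``-f -p -h -l`` sense.

A dispersed hit is the match-trimmed core of a *maximal window*: a paired
span that cannot be extended at either end without exceeding the mismatch
budget or running off the sequence.  Terminal mismatch columns are trimmed
from the window before reporting (so hits begin and end on matching
columns) and identical cores are reported once; without trimming, a
planted repeat in random background would be reported as several
overlapping windows, each padded by chance-matched columns soaking up the
unused mismatch budget.  Detection is exact: any qualifying hit contains
an exact match of length >= ceil((min_len - h) / (h + 1)), which is used
as the seed size, so seeding cannot miss a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import interval_intersects, revcomp

_COMP = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# SSRs


@dataclass
class SSRParams:
    """Minimum repeat count per motif unit size (1..6)."""

    min_repeats_by_unit: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats_by_unit) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("unit sizes must be exactly 1..6")
        if any(v < 2 for v in self.min_repeats_by_unit.values()):
            raise ValueError("minimum repeat counts must be >= 2")


@dataclass
class SSRHit:
    motif: str
    canonical_class: str
    start: int
    end: int
    n_repeats: int

    @property
    def unit(self) -> int:
        return len(self.motif)


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def canonical_ssr_class(motif: str) -> str:
    """MISA-style class label, e.g. A/T, AT/AT, AGG/CCT.

    The lexicographically smallest rotation of the motif and of its reverse
    complement, joined smallest-first.
    """
    rots = lambda m: {m[i:] + m[:i] for i in range(len(m))}
    x = min(rots(motif))
    y = min(rots(revcomp(motif)))
    return f"{min(x, y)}/{max(x, y)}"


def find_ssrs(seq: str, params: SSRParams | None = None) -> list[SSRHit]:
    """All maximal primitive-motif microsatellite runs meeting the
    per-unit-size thresholds; shorter-unit calls whose interval lies inside
    a longer-unit call are suppressed."""
    params = params or SSRParams()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits: list[SSRHit] = []
    for u, min_rep in sorted(params.min_repeats_by_unit.items()):
        if n < u * min_rep:
            continue
        m = arr[u:] == arr[:-u]  # m[t]: position u+t continues the period
        # maximal runs of True
        padded = np.concatenate(([False], m, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(edges[::2], edges[1::2]):
            # periodic stretch covers seq[a : b + u]
            stretch = b - a + u
            n_rep = stretch // u
            if n_rep < min_rep:
                continue
            motif = seq[a : a + u]
            if "N" in motif or not _is_primitive(motif):
                continue
            hits.append(
                SSRHit(
                    motif=motif,
                    canonical_class=canonical_ssr_class(motif),
                    start=a,
                    end=a + n_rep * u,
                    n_repeats=n_rep,
                )
            )
    # suppress shorter-unit hits contained within a longer-unit run
    keep = []
    for h in hits:
        contained = any(
            o.unit > h.unit and o.start <= h.start and h.end <= o.end
            for o in hits
        )
        if not contained:
            keep.append(h)
    keep.sort(key=lambda h: (h.start, h.unit))
    return keep


# ---------------------------------------------------------------------------
# Tandem repeats (simplified detector)


@dataclass
class TandemParams:
    match: int = 2
    mismatch: int = 7
    indel: int = 7
    pm: int = 80
    pi: int = 10
    min_score: int = 50
    max_period: int = 500
    report_min_unit: int = 30
    report_min_identity: float = 90.0

    def __post_init__(self) -> None:
        for name in ("match", "mismatch", "indel", "pm", "pi", "min_score",
                     "max_period", "report_min_unit", "report_min_identity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TandemHit:
    start: int
    end: int
    period: int
    n_copies: int
    consensus: str
    identity: float  # mean pairwise % identity among full copies
    score: int


def _mean_pairwise_identity(copies: list[str]) -> float:
    if len(copies) < 2:
        return 100.0
    tot, num = 0, 0
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            a, b = copies[i], copies[j]
            tot += sum(x == y for x, y in zip(a, b)) / len(a)
            num += 1
    return 100.0 * tot / num


def find_tandem_repeats(
    seq: str, params: TandemParams | None = None, report_all: bool = False
) -> list[TandemHit]:
    """Scan every candidate period up to ``max_period``.

    For each period ``d`` the sequence is compared against itself shifted
    by ``d``; long match runs seed tandem tracts which are greedily
    extended across isolated mismatch columns.  Copies are scored against
    the majority-rule consensus with (+match, -mismatch) weights; tracts
    scoring below ``min_score`` are dropped.  The returned report keeps
    only tracts with unit >= ``report_min_unit`` and mean copy identity >=
    ``report_min_identity`` unless ``report_all`` is set.
    """
    params = params or TandemParams()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    raw: list[TandemHit] = []
    claimed: list[tuple[int, int]] = []  # spans already explained by a smaller period
    for d in range(1, min(params.max_period, n // 2) + 1):
        m = arr[d:] == arr[:-d]
        padded = np.concatenate(([False], m, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        runs = list(zip(edges[::2], edges[1::2]))
        if not runs:
            continue
        min_seed = max(7, d // 2)
        used_upto = -1
        for ridx, (r0, r1) in enumerate(runs):
            if r1 - r0 < min_seed or r0 <= used_upto:
                continue
            # greedy extension across isolated mismatch columns; a
            # neighbouring run is absorbed only when it is substantial
            # relative to the gap (keeps 25%-identity background noise out)
            a, b = int(r0), int(r1)
            mism = 0
            gap_max = max(3, d // 5)
            j = ridx
            while j + 1 < len(runs):
                g0, g1 = runs[j + 1]
                gap = int(g0 - b)
                ok = (
                    gap <= gap_max
                    and g1 - g0 >= max(3, 2 * gap)
                    and (mism + gap) / (g1 - a) <= 0.2
                )
                if not ok:
                    break
                mism += gap
                b = int(g1)
                j += 1
            j = ridx
            while j - 1 >= 0:
                g0, g1 = runs[j - 1]
                gap = int(a - g1)
                ok = (
                    gap <= gap_max
                    and g1 - g0 >= max(3, 2 * gap)
                    and (mism + gap) / (b - g0) <= 0.2
                )
                if not ok:
                    break
                mism += gap
                a = int(g0)
                j -= 1
            used_upto = b
            # snap the tract to whole copies; a trailing mismatch column is
            # inside the last copy even though the period run stops before it
            start = a
            n_copies = int(round((b - a + d) / d))
            while start + n_copies * d > n:
                n_copies -= 1
            if n_copies < 2:
                continue
            end = start + n_copies * d
            if any(s <= start and end <= e for s, e in claimed):
                continue  # already explained by a smaller period
            copies = [seq[start + c * d : start + (c + 1) * d] for c in range(n_copies)]
            cols = list(zip(*copies))
            consensus = "".join(max(set(col), key=col.count) for col in cols)
            matches = sum(c == x for copy in copies for c, x in zip(copy, consensus))
            total = n_copies * d
            score = params.match * matches - params.mismatch * (total - matches)
            if score < params.min_score:
                continue
            identity = _mean_pairwise_identity(copies)
            raw.append(
                TandemHit(start, start + total, d, n_copies, consensus, identity, score)
            )
            claimed.append((start, end))
    raw.sort(key=lambda h: (h.start, h.period))
    if report_all:
        return raw
    return [
        h
        for h in raw
        if h.period >= params.report_min_unit
        and h.identity >= params.report_min_identity
    ]


# ---------------------------------------------------------------------------
# Dispersed (forward / palindromic) repeats


@dataclass
class DispersedParams:
    min_len: int = 30
    max_hamming: int = 3
    kinds: tuple[str, ...] = ("forward", "palindromic")

    def __post_init__(self) -> None:
        if self.min_len < 8:
            raise ValueError("min_len must be >= 8")
        if self.max_hamming < 0:
            raise ValueError("max_hamming must be >= 0")
        bad = set(self.kinds) - {"forward", "palindromic"}
        if bad:
            raise ValueError(f"unknown repeat kinds {bad}")

    @property
    def seed_k(self) -> int:
        """Exact-seed length guaranteeing no qualifying hit is missed."""
        return max(4, -(-(self.min_len - self.max_hamming) // (self.max_hamming + 1)))


@dataclass
class DispersedRepeatHit:
    kind: str  # 'forward' or 'palindromic'
    pos1: tuple[int, int]
    pos2: tuple[int, int]
    length: int
    mismatches: int

    def sort_key(self):
        return (self.pos1, self.pos2, self.kind)


def _in_mask(iv: tuple[int, int], mask: list[tuple[int, int]]) -> bool:
    return any(s <= iv[0] and iv[1] <= e for s, e in mask)


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _maximal_windows(
    match_at, lo: int, hi: int, seed: int, h: int
) -> list[tuple[int, int, int]]:
    """Maximal (start, end, n_mismatch) windows around ``seed``.

    ``match_at(p)`` answers whether column p matches, for p in [lo, hi).
    Collects up to h+1 mismatch columns on each side of the seed column and
    enumerates every span bounded by mismatches (or true sequence
    boundaries) containing at most h interior mismatches.  Any maximal
    window overlapping the scanned neighbourhood is produced; windows
    farther away are found from their own seeds.
    """
    left: list[int] = []  # mismatch columns < seed, descending
    p = seed - 1
    while p >= lo and len(left) <= h:
        if not match_at(p):
            left.append(p)
        p -= 1
    if len(left) <= h:
        left.append(lo - 1)  # boundary sentinel
    right: list[int] = []  # mismatch columns > seed, ascending
    p = seed + 1
    while p < hi and len(right) <= h:
        if not match_at(p):
            right.append(p)
        p += 1
    if len(right) <= h:
        right.append(hi)  # boundary sentinel
    marks = left[::-1] + right
    out = []
    for t in range(len(marks) - h - 1):
        a, b = marks[t] + 1, marks[t + h + 1]
        if b <= a:
            continue
        n_mm = sum(1 for q in marks[t + 1 : t + h + 1] if a <= q < b)
        # trim terminal mismatch columns so the core starts/ends on matches
        while a < b and not match_at(a):
            a += 1
            n_mm -= 1
        while b > a and not match_at(b - 1):
            b -= 1
            n_mm -= 1
        if b > a:
            out.append((a, b, n_mm))
    return out


def find_dispersed_repeats(
    seq: str,
    params: DispersedParams | None = None,
    mask: list[tuple[int, int]] | None = None,
) -> list[DispersedRepeatHit]:
    """All maximal forward and palindromic repeat pairs.

    ``mask`` intervals (typically one IR copy, so the giant IRa/IRb pair
    does not dominate the output) are excluded from seeding, and hits with
    a copy falling entirely inside the mask are suppressed.
    """
    params = params or DispersedParams()
    mask = mask or []
    n = len(seq)
    k = params.seed_k
    h = params.max_hamming
    if n < params.min_len:
        return []
    idx = _seed_index(seq, k)
    comp = seq.translate(_COMP)
    seen: set[tuple] = set()
    hits: list[DispersedRepeatHit] = []

    def mask_free(p: int) -> bool:
        return not any(s < p + k and p < e for s, e in mask)

    if "forward" in params.kinds:
        # per diagonal, remember exact-match runs already explored: any seed
        # inside the same exact run yields the same windows
        explored: dict[int, list[tuple[int, int]]] = {}
        for kmer, positions in idx.items():
            if "N" in kmer or len(positions) < 2:
                continue
            for ai in range(len(positions)):
                i = positions[ai]
                if not mask_free(i):
                    continue
                for bi in range(ai + 1, len(positions)):
                    j = positions[bi]
                    if not mask_free(j):
                        continue
                    d = j - i
                    if any(a <= i and i + k <= b for a, b in explored.get(d, ())):
                        continue
                    match_at = lambda p: seq[p] == seq[p + d] and seq[p] != "N"
                    lo_r, hi_r = i, i + k
                    while lo_r > 0 and match_at(lo_r - 1):
                        lo_r -= 1
                    while hi_r < n - d and match_at(hi_r):
                        hi_r += 1
                    explored.setdefault(d, []).append((lo_r, hi_r))
                    wins = _maximal_windows(match_at, 0, n - d, i, h)
                    for a, b, mm in wins:
                        if b - a < params.min_len:
                            continue
                        key = ("forward", d, a, b)
                        if key not in seen:
                            seen.add(key)
                            hits.append(
                                DispersedRepeatHit(
                                    "forward", (a, b), (a + d, b + d), b - a, mm
                                )
                            )

    if "palindromic" in params.kinds:
        explored_c: dict[int, list[tuple[int, int]]] = {}
        for kmer, positions in idx.items():
            if "N" in kmer:
                continue
            partners = idx.get(revcomp(kmer))
            if not partners:
                continue
            for i in positions:
                if not mask_free(i):
                    continue
                for j in partners:
                    if j < i or not mask_free(j):
                        continue
                    c = i + j + k - 1  # anti-diagonal: partner of p is c - p
                    if any(a <= i and i + k <= b for a, b in explored_c.get(c, ())):
                        continue
                    lo = max(0, c - n + 1)
                    hi = min(n, c + 1)
                    match_at = lambda p: seq[p] == comp[c - p] and seq[p] != "N"
                    lo_r, hi_r = i, i + k
                    while lo_r > lo and match_at(lo_r - 1):
                        lo_r -= 1
                    while hi_r < hi and match_at(hi_r):
                        hi_r += 1
                    explored_c.setdefault(c, []).append((lo_r, hi_r))
                    wins = _maximal_windows(match_at, lo, hi, i, h)
                    for a, b, mm in wins:
                        if b - a < params.min_len:
                            continue
                        p2 = (c - b + 1, c - a + 1)
                        if a > p2[0]:
                            continue  # mirror image; kept once
                        key = ("palindromic", c, a, b)
                        if key not in seen:
                            seen.add(key)
                            hits.append(
                                DispersedRepeatHit(
                                    "palindromic", (a, b), p2, b - a, mm
                                )
                            )

    if mask:
        hits = [
            hit
            for hit in hits
            if not (_in_mask(hit.pos1, mask) or _in_mask(hit.pos2, mask))
        ]
    hits.sort(key=DispersedRepeatHit.sort_key)
    return hits
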