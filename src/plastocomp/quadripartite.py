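"""Detection of the plastome quadripartite structure from sequence alone,
and an IRscope-style junction report.

The two inverted repeats of a plastome are, by definition here, the longest
pair of disjoint, exactly matching, inextensible inverted segments.  Exact
matching is intentional: plastome IR copies are maintained identical by
copy-correction, and near-identical IR detection with mismatches is a
different problem.  Detection is seed-and-extend over k-mer matches between
the genome and its reverse complement, with per-diagonal deduplication, so
a 38 kb IR costs one extension, not thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    PlastomeRecord,
    QuadripartitePartition,
    SequenceRecord,
    revcomp,
)

JUNCTION_ORDER = ("JLB", "JSB", "JSA", "JLA")


class NoQuadripartiteStructure(ValueError):
    """Raised when no inverted-repeat pair of the required size exists."""


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        d.setdefault(seq[i : i + k], []).append(i)
    return d


def longest_inverted_pair(
    seq: str, min_len: int = 1000, seed_k: int = 32
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Longest pair of disjoint intervals (A, B) with seq[B] == revcomp(seq[A]).

    Both intervals are maximal (inextensible at either end within the
    linear sequence).  Ties break to the leftmost A start.  Returns None
    when the best pair is shorter than ``min_len``.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    rc = revcomp(seq)
    # match seq[i..] against rc[j..]; rc position j maps to seq interval
    # ending at n - j, i.e. seq[n-j-L : n-j] is the inverted partner.
    index = _seed_positions(seq, seed_k)
    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    explored: dict[int, list[tuple[int, int]]] = {}  # diagonal d -> i ranges
    for j in range(0, n - seed_k + 1):
        kmer = rc[j : j + seed_k]
        for i in index.get(kmer, ()):  # seq[i:i+k] == rc[j:j+k]
            d = j - i  # constant along an extension (rc index = i + d)
            done = False
            for a, b in explored.get(d, ()):  # already inside an extension?
                if a <= i and i + seed_k <= b:
                    done = True
                    break
            if done:
                continue
            lo_i, hi_i = i, i + seed_k  # [lo_i, hi_i) matched in seq
            while lo_i > 0 and d + lo_i - 1 >= 0 and seq[lo_i - 1] == rc[d + lo_i - 1]:
                lo_i -= 1
            while hi_i < n and d + hi_i < n and seq[hi_i] == rc[d + hi_i]:
                hi_i += 1
            explored.setdefault(d, []).append((lo_i, hi_i))
            length = hi_i - lo_i
            a_int = (lo_i, hi_i)
            # partner: rc range [d+lo_i, d+hi_i) maps back into seq coords
            b_int = (n - (d + hi_i), n - (d + lo_i))
            first, second = sorted([a_int, b_int])
            if first[1] > second[0]:  # overlapping: self-palindrome, reject
                # trim to the largest disjoint sub-pair (split at midpoint)
                half = (second[0] + first[1]) // 2
                first = (first[0], min(first[1], half))
                second = (max(second[0], half), second[1])
                length = min(first[1] - first[0], second[1] - second[0])
                first = (first[0], first[0] + length)
                second = (second[1] - length, second[1])
                if length <= 0:
                    continue
            key = (length, -first[0])
            if best is None or key > (best[0], -best[1][0]):
                best = (length, first, second)
    if best is None or best[0] < min_len:
        return None
    return best[1], best[2]


def detect_inverted_repeat(
    seq: SequenceRecord, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Locate IRa/IRb and derive the LSC/IRb/SSC/IRa partition.

    The longer single-copy interval between the two IR copies is named LSC.
    IRb is the IR copy immediately downstream (clockwise) of the LSC.
    Raises :class:`NoQuadripartiteStructure` when nothing >= ``min_ir_len``
    is found.
    """
    pair = longest_inverted_pair(seq.residues, min_len=min_ir_len)
    if pair is None:
        raise NoQuadripartiteStructure(
            f"no inverted repeat pair >= {min_ir_len} bp: "
            "no quadripartite structure"
        )
    (a1, a2), (b1, b2) = pair
    n = len(seq.residues)
    gap_mid = (a2, b1)  # between the copies
    gap_wrap = (b2, a1)  # through the origin (modular)
    len_mid = gap_mid[1] - gap_mid[0]
    len_wrap = (gap_wrap[1] - gap_wrap[0]) % n
    if len_mid >= len_wrap:
        lsc, ssc = gap_mid, gap_wrap
        irb, ira = (b1, b2), (a1, a2)  # LSC -> (clockwise) second copy first
    else:
        lsc, ssc = gap_wrap, gap_mid
        irb, ira = (a1, a2), (b1, b2)

    def norm(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (s - n if s >= n else s, e - n if e > n else e)

    lsc, irb, ssc, ira = norm(lsc), norm(irb), norm(ssc), norm(ira)
    part = QuadripartitePartition(
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
        junctions={
            "JLB": irb[0],
            "JSB": ssc[0],
            "JSA": ira[0],
            "JLA": lsc[0],
        },
        genome_length=n,
    )
    part.validate()
    ira_seq = seq.fetch(*ira)
    irb_seq = seq.fetch(*irb)
    assert ira_seq == revcomp(irb_seq), "IR copies are not exact reverse complements"
    return part


@dataclass
class JunctionGene:
    name: str
    side: str  # 'upstream' or 'downstream' of the junction in genome order
    distance: int  # bp between gene end and the junction (0 = abutting)


@dataclass
class StraddlingGene:
    name: str
    split: dict[str, int]  # region name -> bp of the gene in that region


@dataclass
class JunctionReport:
    """Per junction: nearest flanking genes and genes split by the junction."""

    junctions: dict[str, dict] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        out = []
        for j in JUNCTION_ORDER:
            info = self.junctions.get(j, {})
            row = {"junction": j, "position": info.get("position")}
            for side in ("upstream", "downstream"):
                g = info.get(side)
                row[f"{side}_gene"] = g.name if g else None
                row[f"{side}_distance"] = g.distance if g else None
            row["straddling"] = ";".join(
                f"{s.name}:" + ",".join(f"{r}={bp}" for r, bp in s.split.items())
                for s in info.get("straddling", [])
            )
            out.append(row)
        return out


def _circular_distance_upstream(pos: int, junction: int, n: int) -> int:
    return (junction - pos) % n


def junction_report(
    rec: PlastomeRecord, part: QuadripartitePartition
) -> JunctionReport:
    """Nearest genes and split lengths at each of JLB/JSB/JSA/JLA.

    A junction sits between the last base of one region and the first base
    of the next; a gene whose genomic span contains that boundary is
    reported with the number of its bases falling in each region (the two
    split lengths sum to the gene's span).  Distances are measured from the
    gene end nearest the junction, 0 when the gene abuts it exactly.
    """
    n = part.genome_length
    genes = rec.gene_features()
    report = JunctionReport()
    for jname in JUNCTION_ORDER:
        jpos = part.junctions[jname]
        nearest_up: JunctionGene | None = None
        nearest_down: JunctionGene | None = None
        straddling: list[StraddlingGene] = []
        for g in genes:
            s, e = g.span
            # does the gene's span contain the junction (circular)?
            inside = (s < jpos < e) if s <= e else (jpos > s or jpos < e)
            if inside:
                before = (jpos - s) % n
                after = (e - jpos) % n
                r_before = part.region_of((jpos - 1) % n)
                r_after = part.region_of(jpos % n)
                straddling.append(
                    StraddlingGene(g.name_with_copy(), {r_before: before, r_after: after})
                )
                continue
            d_up = _circular_distance_upstream(e % n, jpos, n)
            d_down = (s - jpos) % n
            if nearest_up is None or d_up < nearest_up.distance:
                nearest_up = JunctionGene(g.name_with_copy(), "upstream", d_up)
            if nearest_down is None or d_down < nearest_down.distance:
                nearest_down = JunctionGene(g.name_with_copy(), "downstream", d_down)
        report.junctions[jname] = {
            "position": jpos,
            "upstream": nearest_up,
            "downstream": nearest_down,
            "straddling": straddling,
        }
    return report
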