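"""Pairwise whole-plastome synteny and inversion calling.

The comparison is anchor-based: k-mers that are unique in both genomes
(counting a k-mer and its reverse complement as one strand-equivalence
class) become anchors; anchors are chained into orientation-consistent
collinear blocks; an inverted block bounded by same-orientation blocks is
an inversion call.  Because anchor resolution is limited by local repeats
near the breakpoints, called endpoints are afterwards *snapped* to the
boundaries of a flanking palindromic (inverted) repeat pair when one is
found immediately outside the endpoints — the repeat copies then abut the
inversion exactly, reproducing the coordinate relationship expected of a
repeat-mediated inversion.

Reports use 1-based inclusive coordinates; everything internal is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .records import SequenceRecord, revcomp
from .repeats import DispersedParams, find_dispersed_repeats

log = logging.getLogger(__name__)


@dataclass
class AnchorMatch:
    ref_pos: int
    query_pos: int
    k: int
    orientation: str  # 'same' | 'inverted'


@dataclass
class SyntenyBlock:
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    orientation: str
    n_anchors: int


@dataclass
class FlankingRepeat:
    pos5: tuple[int, int]  # 0-based half-open, upstream copy
    pos3: tuple[int, int]  # downstream copy
    length: int
    mismatches: int


@dataclass
class InversionCall:
    ref_start: int  # 0-based half-open internally
    ref_end: int
    query_interval: tuple[int, int]
    n_anchors: int
    genes_contained: list[str] = field(default_factory=list)
    flanking_repeat: FlankingRepeat | None = None
    snapped: bool = False

    def report_coords(self) -> tuple[int, int]:
        """1-based inclusive endpoints for reports."""
        return self.ref_start + 1, self.ref_end


def _kmer_census(seq: str, k: int) -> dict[str, tuple[int, int, int]]:
    """canonical k-mer -> (count, first position, strand form 0/1)."""
    out: dict[str, tuple[int, int, int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = revcomp(w)
        canon, form = (w, 0) if w <= rc else (rc, 1)
        if canon in out:
            c, p, f = out[canon]
            out[canon] = (c + 1, p, f)
        else:
            out[canon] = (1, i, form)
    return out


def build_anchor_map(
    ref: SequenceRecord,
    query: SequenceRecord,
    k: int = 21,
    min_anchors: int = 50,
    ref_mask: list[tuple[int, int]] | None = None,
) -> list[AnchorMatch]:
    """Anchors at k-mers unique in both genomes, sorted by ref position.

    ``ref_mask`` intervals (typically the reference IRs, which are
    near-identical across related plastomes and would seed ambiguous
    anchors) exclude reference positions from anchoring.
    """
    if k < 15:
        raise ValueError("k must be >= 15 to make chance k-mer collisions negligible")
    cr = _kmer_census(ref.residues, k)
    cq = _kmer_census(query.residues, k)
    mask = ref_mask or []
    anchors = []
    for canon, (count_r, pos_r, form_r) in cr.items():
        if count_r != 1:
            continue
        hit = cq.get(canon)
        if hit is None or hit[0] != 1:
            continue
        if any(s < pos_r + k and pos_r < e for s, e in mask):
            continue
        orientation = "same" if form_r == hit[2] else "inverted"
        anchors.append(AnchorMatch(pos_r, hit[1], k, orientation))
    anchors.sort(key=lambda a: a.ref_pos)
    if len(anchors) < min_anchors:
        log.warning(
            "only %d unique anchors (min %d): genomes may be too repetitive",
            len(anchors), min_anchors,
        )
    return anchors


def chain_blocks(
    anchors: list[AnchorMatch], max_gap: int = 5000, min_anchors_per_block: int = 3
) -> list[SyntenyBlock]:
    """Greedy chaining of ref-sorted anchors into collinear blocks.

    Consecutive anchors extend a block when orientation is unchanged, the
    query coordinate moves in the direction the orientation dictates, and
    neither genome jumps more than ``max_gap``.
    """
    blocks: list[SyntenyBlock] = []
    run: list[AnchorMatch] = []

    def flush() -> None:
        if len(run) >= min_anchors_per_block:
            k = run[0].k
            qs = [a.query_pos for a in run]
            blocks.append(
                SyntenyBlock(
                    ref_interval=(run[0].ref_pos, run[-1].ref_pos + k),
                    query_interval=(min(qs), max(qs) + k),
                    orientation=run[0].orientation,
                    n_anchors=len(run),
                )
            )
        run.clear()

    for a in anchors:
        if run:
            prev = run[-1]
            dr = a.ref_pos - prev.ref_pos
            dq = a.query_pos - prev.query_pos
            ok = (
                a.orientation == prev.orientation
                and dr <= max_gap
                and abs(dq) <= max_gap
                and (dq > 0 if a.orientation == "same" else dq < 0)
            )
            if not ok:
                flush()
        run.append(a)
    flush()
    return blocks


def detect_inversions(
    anchors: list[AnchorMatch],
    min_block: int = 1000,
    max_gap: int = 5000,
) -> list[InversionCall]:
    """Inversion calls from the anchor map.

    Blocks shorter than ``min_block`` on the reference are ignored; an
    inverted block whose reference-adjacent surviving neighbours are both
    same-orientation (or which sits at the end of the block list) is
    emitted.  Endpoints are the inverted block's outermost anchor span and
    are meant to be refined by :func:`find_flanking_inverted_repeat`.
    """
    blocks = [
        b
        for b in chain_blocks(anchors, max_gap=max_gap)
        if b.ref_interval[1] - b.ref_interval[0] >= min_block
    ]
    calls: list[InversionCall] = []
    for idx, b in enumerate(blocks):
        if b.orientation != "inverted":
            continue
        prev_ok = idx == 0 or blocks[idx - 1].orientation == "same"
        next_ok = idx == len(blocks) - 1 or blocks[idx + 1].orientation == "same"
        if prev_ok and next_ok:
            calls.append(
                InversionCall(
                    ref_start=b.ref_interval[0],
                    ref_end=b.ref_interval[1],
                    query_interval=b.query_interval,
                    n_anchors=b.n_anchors,
                )
            )
    return calls


def find_flanking_inverted_repeat(
    seq: SequenceRecord,
    inversion: InversionCall,
    window: int = 500,
    params: DispersedParams | None = None,
) -> FlankingRepeat | None:
    """Search just outside the called endpoints for an inverted-repeat pair.

    Scans ``window`` bp around each endpoint for the longest maximal
    palindromic pair with one copy near each endpoint, then re-snaps the
    inversion so the repeat copies lie exactly outside it (5' copy end ==
    inversion start; inversion end == 3' copy start).  Returns None when no
    qualifying pair exists; the call is left unsnapped in that case.
    """
    params = params or DispersedParams()
    pal = DispersedParams(
        min_len=params.min_len,
        max_hamming=params.max_hamming,
        kinds=("palindromic",),
    )
    n = len(seq.residues)
    lo1 = max(0, inversion.ref_start - window)
    hi1 = min(n, inversion.ref_start + window)
    lo2 = max(0, inversion.ref_end - window)
    hi2 = min(n, inversion.ref_end + window)

    candidates: list[FlankingRepeat] = []
    if lo2 <= hi1:  # endpoint windows touch: scan the contiguous region
        for h in find_dispersed_repeats(seq.residues[lo1:hi2], pal):
            candidates.append(
                FlankingRepeat(
                    pos5=(h.pos1[0] + lo1, h.pos1[1] + lo1),
                    pos3=(h.pos2[0] + lo1, h.pos2[1] + lo1),
                    length=h.length,
                    mismatches=h.mismatches,
                )
            )
    else:
        # splice the two endpoint windows together and keep only pairs with
        # one copy on each side of the splice point
        sub = seq.residues[lo1:hi1] + seq.residues[lo2:hi2]
        boundary = hi1 - lo1
        shift = lo2 - hi1  # offset restoring genome coords right of the splice
        for h in find_dispersed_repeats(sub, pal):
            if h.pos1[1] <= boundary <= h.pos2[0]:
                candidates.append(
                    FlankingRepeat(
                        pos5=(h.pos1[0] + lo1, h.pos1[1] + lo1),
                        pos3=(h.pos2[0] + lo1 + shift, h.pos2[1] + lo1 + shift),
                        length=h.length,
                        mismatches=h.mismatches,
                    )
                )
    # copies must sit on the correct sides with the inversion between them
    candidates = [
        f for f in candidates
        if abs(f.pos5[1] - inversion.ref_start) <= window
        and abs(f.pos3[0] - inversion.ref_end) <= window
        and f.pos5[1] < f.pos3[0]
    ]
    if not candidates:
        return None
    flank = max(candidates, key=lambda f: f.length)
    inversion.ref_start = flank.pos5[1]
    inversion.ref_end = flank.pos3[0]
    inversion.flanking_repeat = flank
    inversion.snapped = True
    return flank


def search_repeat_homolog(
    unit: str,
    genome: SequenceRecord,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
    min_score: float = 20.0,
):
    """Best local alignment of ``unit`` (both strands) against a genome.

    Returns (interval, strand, percent identity, aligned length, score) or
    None when nothing reaches ``min_score``.
    """
    if len(unit) < 20:
        raise ValueError("unit must be >= 20 bp")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    best = None
    for strand, query in (("+", unit), ("-", revcomp(unit))):
        score = aligner.score(genome.residues, query)
        if best is None or score > best[0]:
            best = (score, strand, query)
    score, strand, query = best
    if score < min_score:
        return None
    aln = next(iter(aligner.align(genome.residues, query)))
    tgt = aln.aligned[0]
    interval = (int(tgt[0][0]), int(tgt[-1][1]))
    # identity over aligned columns from the aligned coordinate pairs
    matches = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        seg_t = genome.residues[ts:te]
        seg_q = query[qs:qe]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        aligned_len += te - ts
    identity = 100.0 * matches / aligned_len if aligned_len else 0.0
    return {
        "interval": interval,
        "strand": strand,
        "identity": identity,
        "aligned_length": aligned_len,
        "score": float(score),
    }
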