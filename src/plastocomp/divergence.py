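"""Hypervariable intergenic-spacer (IGS) scan.

The procedure: extract every spacer between genomically adjacent genes,
drop spacers that straddle a quadripartite junction, fall inside an
excluded region (e.g. a known inversion) or duplicate an IR-copy locus;
align each locus across genomes; compute pairwise Kimura two-parameter
(K2p) distances; rank loci by divergence.

K2p distance: with transition proportion P and transversion proportion Q
over compared (non-gap, non-N) columns,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

reported per 100 sites.  Pairs where a log argument is <= 0 are flagged
saturated instead of yielding a number.

Alignment: pairwise global alignment with affine gaps (match +1, mismatch
-1, gap open -10, gap extend -2) via Biopython; more than two sequences
are aligned progressively along a k-mer-distance guide tree with
profile-profile dynamic programming.  Columns only ever gain gaps, never
lose residues, so input residues are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .records import PlastomeRecord, QuadripartitePartition

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# IGS extraction


@dataclass
class IGSLocus:
    name: str  # "geneA-geneB", upstream gene first in genome order
    interval: tuple[int, int]  # in the source genome, 0-based half-open
    sequence: str
    genome_id: str


def extract_igs(
    rec: PlastomeRecord,
    part: QuadripartitePartition | None = None,
    exclude: list[tuple[int, int]] | None = None,
) -> list[IGSLocus]:
    """Spacers between adjacent genes, in circular genome order.

    Filters, in order: zero-length gaps (abutting genes), spacers spanning
    one of the four region junctions (when a partition is given), spacers
    intersecting an ``exclude`` interval, and IR-duplicate spacers (locus
    entirely inside IRb, whose IRa twin is identical by construction).
    Locus names keep the annotated gene labels, anticodon suffixes
    included (e.g. ``trnL-UAG-ccsA``).
    """
    part = part or rec.partition
    genes = rec.gene_features()
    if not genes:
        raise ValueError("record has no annotated genes")
    n = len(rec.seq.residues)
    spans = sorted({(f.span[0], f.span[1], f.gene_name) for f in genes})
    exclude = exclude or []
    junctions = list(part.junctions.values()) if part else []
    irb = part.irb if part else None

    loci: list[IGSLocus] = []
    for idx, (s, e, name) in enumerate(spans):
        nxt = spans[(idx + 1) % len(spans)]
        gap_start, gap_end = e, nxt[0]
        if idx == len(spans) - 1:
            gap_end += n  # wrap the origin
        if gap_end - gap_start < 1:
            continue
        if any(gap_start < j < gap_end or (gap_end > n and gap_start < j + n < gap_end)
               for j in junctions):
            continue
        g0, g1 = gap_start % n, gap_end % n
        if any(gap_start < ex_e + (n if gap_end > n and ex_s < g1 else 0)
               and ex_s + (n if gap_end > n and ex_e <= g1 else 0) < gap_end
               for ex_s, ex_e in exclude):
            continue
        if irb is not None and irb[0] <= gap_start and gap_end <= irb[1]:
            continue
        loci.append(
            IGSLocus(
                name=f"{name}-{nxt[2]}",
                interval=(gap_start, gap_end % n if gap_end > n else gap_end),
                sequence=rec.seq.fetch(gap_start, gap_end),
                genome_id=rec.id,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Alignment


def _pairwise_align(a: str, b: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = next(iter(aligner.align(a, b)))
    # reconstruct gapped rows from the aligned coordinate pairs
    out_a, out_b = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        out_a.append(a[pa:sa])
        out_b.append("-" * (sa - pa))
        out_a.append("-" * (sb - pb))
        out_b.append(b[pb:sb])
        out_a.append(a[sa:ea])
        out_b.append(b[sb:eb])
        pa, pb = ea, eb
    out_a.append(a[pa:])
    out_b.append("-" * (len(a) - pa))
    out_a.append("-" * (len(b) - pb))
    out_b.append(b[pb:])
    ra, rb = "".join(out_a), "".join(out_b)
    return ra, rb, float(aln.score)


def pairwise_alignment_score(a: str, b: str, gap_open: float = 10, gap_extend: float = 2) -> float:
    """Optimal global affine-gap score (match +1, mismatch -1)."""
    return _pairwise_align(a, b, gap_open, gap_extend)[2]


def _kmer_profile(seq: str, k: int = 4) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        prof[seq[i : i + k]] = prof.get(seq[i : i + k], 0) + 1
    return prof


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    shared = sum(min(pa.get(w, 0), pb.get(w, 0)) for w in pa)
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom if denom > 0 else 1.0


_GAP_IDX = 4
_CHAR_IDX = {c: i for i, c in enumerate(_BASES + "-")}


def _profile(rows: list[str]) -> np.ndarray:
    """Column base frequencies over A,C,G,T,gap; N spreads over ACGT."""
    L = len(rows[0])
    prof = np.zeros((L, 5))
    for r in rows:
        for j, c in enumerate(r):
            if c == "N":
                prof[j, :4] += 0.25
            else:
                prof[j, _CHAR_IDX[c]] += 1.0
    return prof / len(rows)


def _profile_align(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> list[str]:
    """Gotoh affine-gap DP between two alignment profiles (numpy rows)."""
    fa, fb = _profile(rows_a), _profile(rows_b)
    La, Lb = fa.shape[0], fb.shape[0]
    # expected match(+1)/mismatch(-1) score between columns, gaps neutral
    sub = np.full((4, 4), -1.0)
    np.fill_diagonal(sub, 1.0)
    fb_scored = (sub @ fb[:, :4].T)  # (4, Lb); row scores come cheap

    NEG = -1e9
    go, ge = float(gap_open), float(gap_extend)
    # score matrices kept two rows at a time; only int8 pointers are full
    prev_m = np.full(Lb + 1, NEG)
    prev_x = np.full(Lb + 1, NEG)
    prev_y = np.full(Lb + 1, NEG)
    prev_m[0] = 0.0
    prev_y[1:] = -go - ge * np.arange(Lb)
    ptr_m = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptr_x = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptr_y = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    ptr_x[2:, 0] = 1  # stay in the gap state along the borders
    ptr_y[0, 2:] = 2
    cols = np.arange(Lb)
    cur_m = np.empty(Lb + 1)
    cur_x = np.empty(Lb + 1)
    cur_y = np.empty(Lb + 1)
    for i in range(1, La + 1):
        col_score = fa[i - 1, :4] @ fb_scored  # (Lb,)
        stack = np.vstack((prev_m[:-1], prev_x[:-1], prev_y[:-1]))
        best = stack.argmax(axis=0)
        cur_m[1:] = stack[best, cols] + col_score
        cur_m[0] = NEG
        ptr_m[i, 1:] = best
        stack_x = np.vstack((prev_m[1:] - go, prev_x[1:] - ge, prev_y[1:] - go))
        bx = stack_x.argmax(axis=0)
        cur_x[1:] = stack_x[bx, cols]
        ptr_x[i, 1:] = bx
        # X in column 0
        sx0 = np.array([prev_m[0] - go, prev_x[0] - ge, prev_y[0] - go])
        ptr_x[i, 0] = int(sx0.argmax())
        cur_x[0] = sx0[ptr_x[i, 0]]
        # Y along the row depends on Y[i, j-1]; closed form via prefix max:
        # Y[i,j] = max_{k<j} (Z[k] - ge*(j-1-k)) with Z = max(M,X at k) - go
        z = np.maximum(cur_m[:-1], cur_x[:-1]) - go
        w = np.maximum.accumulate(z + ge * cols)
        cur_y[1:] = w - ge * cols
        cur_y[0] = NEG
        open_here = z >= cur_y[:-1] - ge
        ptr_y[i, 1:] = np.where(
            open_here, np.where(cur_m[:-1] >= cur_x[:-1], 0, 1), 2
        )
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    # traceback (prev_* now hold row La)
    i, j = La, Lb
    state = int(np.argmax([prev_m[Lb], prev_x[Lb], prev_y[Lb]]))
    cols_a: list[int] = []  # -1 = gap, else source column
    cols_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            nxt = ptr_m[i, j]
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif state == 1:
            nxt = ptr_x[i, j]
            cols_a.append(i - 1)
            cols_b.append(-1)
            i -= 1
        else:
            nxt = ptr_y[i, j]
            cols_a.append(-1)
            cols_b.append(j - 1)
            j -= 1
        state = int(nxt)
    cols_a.reverse()
    cols_b.reverse()
    out = []
    for rows, cols in ((rows_a, cols_a), (rows_b, cols_b)):
        for r in rows:
            out_r = "".join("-" if c < 0 else r[c] for c in cols)
            out.append(out_r)
    # keep input row order: rows_a first, then rows_b (already so)
    return out


def align_locus(
    seqs: dict[str, str], gap_open: float = 10, gap_extend: float = 2
) -> dict[str, str]:
    """Multiple alignment of one locus across genomes.

    Two sequences: optimal global affine-gap alignment.  More: progressive
    profile-profile alignment along an average-linkage guide tree built
    from k-mer distances.  Returns aligned rows keyed by genome id.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = list(seqs)
    for gid in ids:
        if not seqs[gid]:
            raise ValueError(f"empty sequence for {gid}")
    if len(ids) == 2:
        ra, rb, _ = _pairwise_align(seqs[ids[0]], seqs[ids[1]], gap_open, gap_extend)
        return {ids[0]: ra, ids[1]: rb}

    m = len(ids)
    dm = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    tree = to_tree(linkage(squareform(dm, checks=False), method="average"))

    def rec(node) -> tuple[list[str], list[int]]:
        if node.id < m:  # leaf
            return [seqs[ids[node.id]]], [node.id]
        rows_l, idx_l = rec(node.left)
        rows_r, idx_r = rec(node.right)
        merged = _profile_align(rows_l, rows_r, gap_open, gap_extend)
        return merged, idx_l + idx_r

    rows, order = rec(tree)
    return {ids[oid]: row for oid, row in zip(order, rows)}


# ---------------------------------------------------------------------------
# K2p distance


@dataclass
class PairwiseK2p:
    pair: tuple[str, str]
    P: float
    Q: float
    n_sites: int
    d: float | None  # per 100 sites; None when saturated
    saturated: bool = False


def k2p_distance(row_a: str, row_b: str, pair=("a", "b")) -> PairwiseK2p:
    """K2p distance between two aligned rows (pairwise deletion).

    Columns with a gap or N in either row are excluded.  Raises
    ``ValueError`` when no columns remain.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    n_sites = ts = tv = 0
    for x, y in zip(row_a, row_b):
        if x not in _BASES or y not in _BASES:
            continue
        n_sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n_sites == 0:
        raise ValueError("no comparable (non-gap, non-N) sites")
    P, Q = ts / n_sites, tv / n_sites
    arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        return PairwiseK2p(pair, P, Q, n_sites, None, saturated=True)
    d = 100.0 * (-0.5 * math.log(arg1) - 0.25 * math.log(arg2))
    return PairwiseK2p(pair, P, Q, n_sites, d)


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class LocusDivergence:
    name: str
    alignment: dict[str, str]
    pairwise: list[PairwiseK2p]
    summary_max: float | None = None
    summary_mean: float | None = None
    rank: int | None = None

    def summarize(self) -> None:
        ds = [p.d for p in self.pairwise if p.d is not None]
        self.summary_max = max(ds) if ds else None
        self.summary_mean = sum(ds) / len(ds) if ds else None


def score_locus(name: str, seqs: dict[str, str],
                gap_open: float = 10, gap_extend: float = 2) -> LocusDivergence:
    """Align one locus and compute all pairwise K2p distances."""
    aln = align_locus(seqs, gap_open, gap_extend)
    ids = list(aln)
    pw = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                pw.append(k2p_distance(aln[ids[i]], aln[ids[j]], (ids[i], ids[j])))
            except ValueError:
                continue
    ld = LocusDivergence(name=name, alignment=aln, pairwise=pw)
    ld.summarize()
    return ld


def rank_hypervariable(
    loci: list[LocusDivergence],
    top_n: int = 5,
    threshold: float = 5.0,
    statistic: str = "max",
) -> list[LocusDivergence]:
    """Rank loci by divergence; keep the top_n at or above the threshold.

    ``statistic`` selects the per-locus summary: ``max`` (default) or
    ``mean`` pairwise K2p, per 100 sites.
    """
    if not loci:
        raise ValueError("no loci to rank")
    if statistic not in ("max", "mean"):
        raise ValueError("statistic must be 'max' or 'mean'")
    key = (lambda l: l.summary_max) if statistic == "max" else (lambda l: l.summary_mean)
    scored = [l for l in loci if key(l) is not None]
    scored.sort(key=lambda l: (-key(l), l.name))
    for r, l in enumerate(scored, start=1):
        l.rank = r
    return [l for l in scored[:top_n] if key(l) >= threshold]


def igs_divergence_scan(
    genomes: list[PlastomeRecord],
    partitions: dict[str, QuadripartitePartition] | None = None,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
    top_n: int = 5,
    threshold: float = 5.0,
    gap_open: float = 10,
    gap_extend: float = 2,
) -> tuple[list[LocusDivergence], list[LocusDivergence]]:
    """Full scan: extract IGS per genome, keep loci present in every
    genome, score each, rank.  Returns (all scored loci, ranked top)."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    partitions = partitions or {}
    exclude = exclude or {}
    per_genome: list[dict[str, str]] = []
    for g in genomes:
        loci = extract_igs(g, partitions.get(g.id), exclude.get(g.id))
        table: dict[str, str] = {}
        for l in loci:
            table.setdefault(l.name, l.sequence)  # first copy wins
        per_genome.append(table)
    common = set(per_genome[0])
    for t in per_genome[1:]:
        common &= set(t)
    scored = []
    for name in sorted(common):
        seqs = {g.id: t[name] for g, t in zip(genomes, per_genome)}
        if any(not s for s in seqs.values()):
            continue
        scored.append(score_locus(name, seqs, gap_open, gap_extend))
    ranked = rank_hypervariable(scored, top_n=top_n, threshold=threshold)
    return scored, ranked
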