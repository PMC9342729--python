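"""Synthetic annotated plastomes with machine-readable planted truth.

The generator emulates the structures the analysis modules detect: a
circular quadripartite genome (LSC + IRb + SSC + IRa, IRa the exact
reverse complement of IRb), annotated genes (CDS/tRNA/rRNA, multi-exon,
both strands, IR-duplicated, one trans-spliced gene), planted
microsatellites, tandem repeats and dispersed/palindromic repeats, an
optional large single-copy inversion flanked by a palindromic repeat
pair, and a set of related genomes diverged under a two-parameter (K80)
substitution process with per-locus rate multipliers and indels.

Two properties make closed-loop testing exact rather than statistical:

* chance microsatellites are removed from the background by rejection
  (local resampling until the SSR scan reports exactly the planted set);
* planted repeat pairs are *sealed*: the h+1 alignment columns
  immediately outside each copy are forced to mismatch, so the maximal
  dispersed-repeat windows trim back to exactly the planted coordinates
  instead of wandering into chance-matched background.

All randomness flows from one ``numpy`` Generator per seed, consumed in
a fixed order, so output is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .records import (
    FeatureAnnotation,
    PlastomeRecord,
    QuadripartitePartition,
    SequenceRecord,
    revcomp,
)
from .repeats import DispersedParams, SSRParams, canonical_ssr_class, find_ssrs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# name pools for auto-generated gene sets (plastid-style labels; anticodon
# suffixes on tRNAs are kept because IGS locus names embed them)
_LSC_CDS_POOL = [
    "psbA", "matK", "rpoB", "rpoC1", "atpA", "atpB", "rbcL", "petA",
    "psaA", "psaB", "rpl36", "rps8", "rpl14", "rpl16", "ccsA", "rps16",
    "clpP", "rpoA", "atpH", "rps2", "cemA", "petD", "rpl20", "psbB",
]
_LSC_TRNA_POOL = ["trnL-UAG", "trnT-UGU", "trnH-GUG", "trnK-UUU"]
_SSC_CDS_POOL = ["ndhE", "ndhF", "psaC", "ndhG"]
_IR_RRNA_POOL = ["rrn23", "rrn16"]
_IR_TRNA_POOL = ["trnI-GAU", "trnA-UGC"]


# ---------------------------------------------------------------------------
# Specs


@dataclass
class GeneTemplate:
    name: str
    kind: str  # CDS | tRNA | rRNA
    length: int  # transcript length (CDS: multiple of 3)
    strand: int = 1
    n_exons: int = 1
    region: str = "LSC"  # LSC | SSC | IR
    trans_spliced: bool = False


@dataclass
class PlantedSSR:
    motif: str
    n_repeats: int


@dataclass
class PlantedTandem:
    unit_len: int
    n_copies: int
    mismatches: int = 0


@dataclass
class PlantedDispersed:
    kind: str  # forward | palindromic
    length: int
    mismatches: int = 0


@dataclass
class InversionSpec:
    length: int = 20_000
    flank_len: int = 164
    flank_mismatches: int = 0
    start: int | None = None  # LSC coordinate; auto-centred when None


def default_planted_ssrs() -> list[PlantedSSR]:
    """Full-scale SSR census: 19 mononucleotide, 8 di-, 3 trinucleotide runs,
    the census size typical of a single plastome."""
    out = [PlantedSSR("A" if i % 2 == 0 else "T", 10 + i % 4) for i in range(19)]
    out += [PlantedSSR("AT", 6 + i % 3) for i in range(8)]
    out += [PlantedSSR("AGG", 5), PlantedSSR("AGG", 6), PlantedSSR("AAG", 5)]
    return out


def auto_gene_templates(lsc_len: int, ssc_len: int, ir_len: int) -> list[GeneTemplate]:
    """A deterministic, region-size-scaled gene set.

    Includes single- and multi-exon CDS on both strands, tRNAs with
    anticodon-suffixed names, IR rRNA/tRNA genes (duplicated into IRa by
    construction) and one trans-spliced three-exon gene.
    """
    tpl: list[GeneTemplate] = []
    n_lsc = max(5, min(len(_LSC_CDS_POOL), lsc_len // 5500))
    # genes take roughly half the region; spacers need the rest
    cds_len = min(1200, max(150, (lsc_len // (n_lsc + 2)) * 6 // 10))
    cds_len = cds_len // 3 * 3
    for i in range(n_lsc):
        name = _LSC_CDS_POOL[i]
        strand = -1 if i % 3 == 2 else 1
        n_exons = 1
        if i == 1:
            n_exons = 2  # a cis-splicing gene
        if i == 3:
            n_exons = 3  # two introns
        if i == 5:
            n_exons = 2  # minus-strand cis-splicing gene
        tpl.append(GeneTemplate(name, "CDS", cds_len, strand, n_exons, "LSC"))
    for i, name in enumerate(_LSC_TRNA_POOL[: max(2, n_lsc // 4)]):
        tpl.append(GeneTemplate(name, "tRNA", 72 + 3 * i, 1 if i % 2 else -1, 1, "LSC"))
    if lsc_len >= 8000:
        tpl.append(GeneTemplate("rps12", "CDS", 372, 1, 3, "LSC", trans_spliced=True))
    n_ssc = max(1, min(len(_SSC_CDS_POOL), ssc_len // 2500))
    ssc_cds = min(900, max(150, (ssc_len // (n_ssc + 1)) // 2 // 3 * 3))
    for i in range(n_ssc):
        tpl.append(GeneTemplate(_SSC_CDS_POOL[i], "CDS", ssc_cds, -1 if i % 2 else 1, 1, "SSC"))
    rrna_len = min(2400, max(300, ir_len // 5))
    tpl.append(GeneTemplate(_IR_RRNA_POOL[0], "rRNA", rrna_len, 1, 1, "IR"))
    if ir_len >= 6000:
        tpl.append(GeneTemplate(_IR_RRNA_POOL[1], "rRNA", max(300, rrna_len // 2), 1, 1, "IR"))
    tpl.append(GeneTemplate(_IR_TRNA_POOL[0], "tRNA", 74, 1, 1, "IR"))
    return tpl


@dataclass
class PlastomeSpec:
    """Study conditions for one synthetic plastome.

    Defaults emulate the scale of a real ~170 kb plastome; tests use
    :meth:`scaled` for small fast genomes with identical structure.
    """

    lsc_len: int = 86_000
    ssc_len: int = 8_000
    ir_len: int = 38_000
    gc: float = 0.38
    gene_templates: list[GeneTemplate] | None = None
    planted_ssrs: list[PlantedSSR] = field(default_factory=default_planted_ssrs)
    planted_tandems: list[PlantedTandem] = field(
        default_factory=lambda: [PlantedTandem(35, 3, 0), PlantedTandem(42, 2, 1)]
    )
    planted_dispersed: list[PlantedDispersed] = field(
        default_factory=lambda: [
            PlantedDispersed("forward", 45, 1),
            PlantedDispersed("palindromic", 35, 0),
        ]
    )
    inversion: InversionSpec | None = None
    seed: int = 0
    suppress_chance_repeats: bool = True
    dispersed_params: DispersedParams = field(default_factory=DispersedParams)
    ssr_params: SSRParams = field(default_factory=SSRParams)

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    @classmethod
    def scaled(cls, lsc_len: int = 12_000, ssc_len: int = 3_000, ir_len: int = 4_000,
               **kw) -> "PlastomeSpec":
        """A small genome with the same quadripartite layout (test scale)."""
        ssrs = kw.pop("planted_ssrs", None)
        if ssrs is None:
            ssrs = [PlantedSSR("A", 11), PlantedSSR("T", 10), PlantedSSR("AT", 6),
                    PlantedSSR("AGG", 5), PlantedSSR("AAG", 6)]
        return cls(lsc_len=lsc_len, ssc_len=ssc_len, ir_len=ir_len,
                   planted_ssrs=ssrs, **kw)


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    seed: int
    genome_length: int
    regions: dict[str, tuple[int, int]]
    junctions: dict[str, int]
    genes: list[dict]
    ssrs: list[dict]  # motif, start, end, n_repeats, canonical_class
    tandems: list[dict]  # start, end, period, n_copies, mismatches
    dispersed: list[dict]  # kind, pos1, pos2, length, mismatches
    inversion: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimulatedPlastome:
    record: PlastomeRecord
    truth: GroundTruth
    #: record *before* the inversion was applied (None when no inversion)
    donor: PlastomeRecord | None = None


# ---------------------------------------------------------------------------
# Low-level helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _str_to_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).copy()


def _ssr_free(seq: str, params: SSRParams) -> bool:
    return not find_ssrs(seq, params)


def _random_unit(rng: np.random.Generator, length: int, gc: float,
                 params: SSRParams, max_tries: int = 50) -> str:
    """A random DNA unit with no qualifying SSR inside it."""
    for _ in range(max_tries):
        s = _arr_to_str(_random_dna(rng, length, gc))
        if _ssr_free(s, params):
            return s
    raise RuntimeError("could not draw an SSR-free unit")


def _random_cds(rng: np.random.Generator, length: int, params: SSRParams,
                max_tries: int = 50) -> str:
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    n_mid = length // 3 - 2
    for _ in range(max_tries):
        mid = "".join(rng.choice(_SENSE_CODONS, size=n_mid))
        tx = "ATG" + mid + "TAA"
        if _ssr_free(tx, params):
            return tx
    raise RuntimeError("could not draw an SSR-free CDS")


class _Layout:
    """Occupied-interval bookkeeping for non-overlapping placement."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.occupied.append((start, end))

    def place(self, length: int, lo: int, hi: int, margin: int = 8,
              max_tries: int = 200) -> int:
        """Random start in [lo, hi - length) clear of occupied intervals."""
        for _ in range(max_tries):
            s = int(self.rng.integers(lo, hi - length))
            iv = (s - margin, s + length + margin)
            if all(iv[1] <= a or b <= iv[0] for a, b in self.occupied):
                self.reserve(s - margin, s + length + margin)
                return s
        raise RuntimeError(f"no room to place a {length} bp element in [{lo}, {hi})")


def _break_period(genome: np.ndarray, pos: int, period_partner: int,
                  rng: np.random.Generator) -> None:
    """Force genome[pos] != genome[period_partner] (SSR run terminator)."""
    n = len(genome)
    if not (0 <= pos < n and 0 <= period_partner < n):
        return
    if genome[pos] == genome[period_partner]:
        choices = [b for b in _BASES if b != genome[period_partner]]
        genome[pos] = choices[int(rng.integers(len(choices)))]


def _force_neq(genome: np.ndarray, adjust: int, value: int,
               rng: np.random.Generator, also_not: int | None = None) -> None:
    """Force genome[adjust] != value (and != also_not) by resampling."""
    if not (0 <= adjust < len(genome)):
        return
    forbidden = {value} | ({also_not} if also_not is not None else set())
    if genome[adjust] in forbidden:
        choices = [b for b in _BASES if b not in forbidden]
        genome[adjust] = choices[int(rng.integers(len(choices)))]


_COMP_U8 = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_U8[_a] = _b


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_U8[arr][::-1]


# ---------------------------------------------------------------------------
# Gene construction


def _build_gene_piece(
    rng: np.random.Generator, tpl: GeneTemplate, ssr_params: SSRParams
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Genomic sequence of one (cis) gene plus parts relative to its start."""
    if tpl.kind == "CDS":
        tx = _random_cds(rng, tpl.length, ssr_params)
    else:
        tx = _random_unit(rng, tpl.length, 0.5, ssr_params)
    if tpl.n_exons == 1:
        piece = tx if tpl.strand == 1 else revcomp(tx)
        return _str_to_arr(piece), [(0, len(tx), tpl.strand)]
    for _ in range(50):
        bounds = np.linspace(0, len(tx), tpl.n_exons + 1).astype(int)
        exons = [tx[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        introns = [
            _random_unit(rng, int(80 + rng.integers(0, 60)), 0.35, ssr_params)
            for _ in range(tpl.n_exons - 1)
        ]
        pre = exons[0]
        rel_parts = [(0, len(exons[0]))]
        for intron, exon in zip(introns, exons[1:]):
            pre += intron
            rel_parts.append((len(pre), len(pre) + len(exon)))
            pre += exon
        # the exon/intron junctions must not assemble into a chance SSR
        if _ssr_free(pre, ssr_params):
            break
    else:
        raise RuntimeError("could not build an SSR-free multi-exon gene")
    if tpl.strand == 1:
        return _str_to_arr(pre), [(a, b, 1) for a, b in rel_parts]
    total = len(pre)
    flipped = [(total - b, total - a, -1) for a, b in rel_parts]
    return _str_to_arr(revcomp(pre)), flipped  # transcript order kept


# ---------------------------------------------------------------------------
# generate_plastome


def generate_plastome(spec: PlastomeSpec) -> SimulatedPlastome:
    """Build one synthetic plastome; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    L, S, I = spec.lsc_len, spec.ssc_len, spec.ir_len
    n = L + 2 * I + S
    templates = spec.gene_templates or auto_gene_templates(L, S, I)
    genome = _random_dna(rng, n, spec.gc)
    layout = _Layout(rng)
    region_bounds = {"LSC": (0, L), "IR": (L, L + I), "SSC": (L + I, L + I + S)}
    h = spec.dispersed_params.max_hamming

    inv_interval: tuple[int, int] | None = None
    if spec.inversion is not None:
        inv = spec.inversion
        s0 = inv.start if inv.start is not None else (L - inv.length) // 2
        if not (inv.flank_len + 12 <= s0 and s0 + inv.length + inv.flank_len + 12 <= L):
            raise ValueError("inversion interval (plus flanks) must fit inside the LSC")
        inv_interval = (s0, s0 + inv.length)
        layout.reserve(s0 - inv.flank_len - 10, s0 + 10)
        layout.reserve(s0 + inv.length - 10, s0 + inv.length + inv.flank_len + 10)

    # --- genes -------------------------------------------------------------
    features: list[FeatureAnnotation] = []
    truth_genes: list[dict] = []

    def add_feature(name: str, kind: str, parts, copy_index=1):
        features.append(FeatureAnnotation(name, kind, list(parts), copy_index))

    ir_local_features: list[tuple[str, str, list[tuple[int, int, int]]]] = []
    for tpl in templates:
        if tpl.trans_spliced:
            # exon 1 on the minus strand, exons 2..k elsewhere on plus
            e1_len = max(3, (tpl.length // 3) // 3 * 3)
            rest_len = tpl.length - e1_len
            # +3 so the truncation drops the terminal stop codon (the stop
            # belongs to the last exon of the trans-spliced transcript)
            tx1 = _random_cds(rng, e1_len + 3, spec.ssr_params)[:e1_len]
            lo, hi = region_bounds["LSC"]
            p1 = layout.place(e1_len, lo + 20, hi - 20)
            genome[p1 : p1 + e1_len] = _str_to_arr(revcomp(tx1))
            piece2, rel2 = _build_gene_piece(
                rng, GeneTemplate(tpl.name, "CDS", rest_len // 3 * 3, 1, 2, "LSC"),
                spec.ssr_params,
            )
            p2 = layout.place(len(piece2), lo + 20, hi - 20)
            genome[p2 : p2 + len(piece2)] = piece2
            parts = [(p1, p1 + e1_len, -1)] + [(p2 + a, p2 + b, st) for a, b, st in rel2]
            add_feature(tpl.name, "gene", parts)
            add_feature(tpl.name, "CDS", parts)
            truth_genes.append({"name": tpl.name, "kind": "CDS", "parts": parts,
                                "region": "LSC", "splicing": "trans"})
            continue
        piece, rel = _build_gene_piece(rng, tpl, spec.ssr_params)
        lo, hi = region_bounds[tpl.region]
        pos = layout.place(len(piece), lo + 20, hi - 20)
        genome[pos : pos + len(piece)] = piece
        parts = [(pos + a, pos + b, st) for a, b, st in rel]
        span = [(pos, pos + len(piece), tpl.strand)]
        if tpl.region == "IR":
            ir_local_features.append((tpl.name, tpl.kind, parts))
        add_feature(tpl.name, "gene", span)
        add_feature(tpl.name, tpl.kind, parts)
        splicing = "none" if tpl.n_exons == 1 else "cis"
        truth_genes.append({"name": tpl.name, "kind": tpl.kind, "parts": parts,
                            "region": tpl.region if tpl.region != "IR" else "IRb",
                            "splicing": splicing})

    # --- planted repeats (single-copy regions only) ------------------------
    truth_ssrs: list[dict] = []
    for idx, ssr in enumerate(spec.planted_ssrs):
        u = len(ssr.motif)
        tract = ssr.motif * ssr.n_repeats
        region = "SSC" if idx % 7 == 6 and S > 2 * len(tract) + 200 else "LSC"
        lo, hi = region_bounds[region]
        pos = layout.place(len(tract), lo + 12, hi - 12)
        genome[pos : pos + len(tract)] = _str_to_arr(tract)
        _break_period(genome, pos - 1, pos - 1 + u, rng)
        _break_period(genome, pos + len(tract), pos + len(tract) - u, rng)
        truth_ssrs.append({
            "motif": ssr.motif, "start": int(pos), "end": int(pos + len(tract)),
            "n_repeats": ssr.n_repeats,
            "canonical_class": canonical_ssr_class(ssr.motif),
        })

    truth_tandems: list[dict] = []
    for tan in spec.planted_tandems:
        unit = _random_unit(rng, tan.unit_len, spec.gc, spec.ssr_params)
        tract = _str_to_arr(unit * tan.n_copies)
        for _ in range(tan.mismatches):
            p = int(rng.integers(tan.unit_len, len(tract)))
            _force_neq(tract, p, int(tract[p]), rng)
        lo, hi = region_bounds["LSC"]
        pos = layout.place(len(tract), lo + 12, hi - 12)
        genome[pos : pos + len(tract)] = tract
        truth_tandems.append({"start": int(pos), "end": int(pos + len(tract)),
                              "period": tan.unit_len, "n_copies": tan.n_copies,
                              "mismatches": tan.mismatches})

    truth_dispersed: list[dict] = []
    for disp in spec.planted_dispersed:
        truth_dispersed.append(
            _plant_dispersed_pair(genome, layout, rng, disp, region_bounds, spec, h)
        )

    # --- mirror IRa, then remove chance SSRs -------------------------------
    def sync_ira():
        genome[n - I :] = _rc_arr(genome[L : L + I])
        # seal the IR boundaries so the *maximal* exact inverted pair is
        # exactly the planted IR: first SSC base must not pair with the
        # last SSC base, first LSC base must not pair with the last
        _force_neq(genome, L + I, int(_COMP_U8[genome[n - I - 1]]), rng)
        _force_neq(genome, 0, int(_COMP_U8[genome[L - 1]]), rng)

    sync_ira()
    if spec.suppress_chance_repeats:
        h_guard = h + 2
        protect: list[tuple[int, int]] = []
        for f in features:
            protect += [(ps, pe) for ps, pe, _ in f.parts]
        protect += [(t["start"] - 2, t["end"] + 2) for t in truth_ssrs]
        protect += [(t["start"] - 1, t["end"] + 1) for t in truth_tandems]
        for t in truth_dispersed:
            protect += [
                (t["pos1"][0] - h_guard, t["pos1"][1] + h_guard),
                (t["pos2"][0] - h_guard, t["pos2"][1] + h_guard),
            ]
        if inv_interval is not None:
            fl = spec.inversion.flank_len
            protect += [
                (inv_interval[0] - fl - h_guard, inv_interval[0] + h_guard),
                (inv_interval[1] - h_guard, inv_interval[1] + fl + h_guard),
            ]
        _suppress_chance_ssrs(genome, protect, rng, spec, truth_ssrs, L, I, n,
                              sync_ira)

    # --- IR duplicate features ---------------------------------------------
    for name, kind, parts in ir_local_features:
        mirrored = [(n + L - e, n + L - s, -st) for s, e, st in parts]
        span = [(min(p[0] for p in mirrored), max(p[1] for p in mirrored),
                 mirrored[0][2])]
        add_feature(name, "gene", span, copy_index=2)
        add_feature(name, kind, mirrored, copy_index=2)
        truth_genes.append({"name": name, "kind": kind, "parts": mirrored,
                            "region": "IRa", "splicing": "none"})

    partition = QuadripartitePartition(
        lsc=(0, L), irb=(L, L + I), ssc=(L + I, L + I + S), ira=(L + I + S, n),
        junctions={"JLB": L, "JSB": L + I, "JSA": L + I + S, "JLA": 0},
        genome_length=n,
    )
    features.sort(key=lambda f: (f.span[0], f.kind != "gene"))
    seq = SequenceRecord(f"synth{spec.seed}", _arr_to_str(genome), circular=True)
    base = PlastomeRecord(seq=seq, features=features, partition=partition)

    truth = GroundTruth(
        seed=spec.seed,
        genome_length=n,
        regions={"LSC": (0, L), "IRb": (L, L + I), "SSC": (L + I, L + I + S),
                 "IRa": (L + I + S, n)},
        junctions=dict(partition.junctions),
        genes=truth_genes,
        ssrs=truth_ssrs,
        tandems=truth_tandems,
        dispersed=truth_dispersed,
    )

    if spec.inversion is None:
        return SimulatedPlastome(record=base, truth=truth)

    donor, inverted, inv_truth = plant_inversion(
        base, inv_interval, spec.inversion.flank_len,
        spec.inversion.flank_mismatches, rng=rng,
        max_hamming=h, min_len=spec.dispersed_params.min_len,
    )
    truth.inversion = inv_truth
    truth.dispersed = truth.dispersed + [{
        "kind": "palindromic",
        "pos1": list(inv_truth["flank5"]), "pos2": list(inv_truth["flank3"]),
        "length": spec.inversion.flank_len,
        "mismatches": spec.inversion.flank_mismatches,
    }]
    return SimulatedPlastome(record=inverted, truth=truth, donor=donor)


def _spread_positions(length: int, m: int, min_len: int) -> list[int]:
    """Interior mismatch positions splitting a unit into fragments that are
    individually below the dispersed-repeat reporting length (keeps the
    planted pair's trimmed core unique when possible)."""
    return [round((k + 1) * length / (m + 1)) for k in range(m)]


def _plant_dispersed_pair(genome, layout, rng, disp: PlantedDispersed,
                          region_bounds, spec, h: int) -> dict:
    l = disp.length
    lo, hi = region_bounds["LSC"]
    unit = _random_unit(rng, l, spec.gc, spec.ssr_params)
    i = layout.place(l, lo + 12, hi - 12)
    j = layout.place(l, lo + 12, hi - 12)
    if j < i:
        i, j = j, i
    copy1 = _str_to_arr(unit)
    if disp.kind == "forward":
        copy2 = copy1.copy()
        for p in _spread_positions(l, disp.mismatches, spec.dispersed_params.min_len):
            _force_neq(copy2, p, int(copy1[p]), rng)
    else:
        copy2 = _rc_arr(copy1)
        for p in _spread_positions(l, disp.mismatches, spec.dispersed_params.min_len):
            # column p of the pair is copy2 position l-1-p
            _force_neq(copy2, l - 1 - p, int(_COMP_U8[copy1[p]]), rng)
    genome[i : i + l] = copy1
    genome[j : j + l] = copy2
    # seal: force the h+1 columns outside each end to mismatch
    if disp.kind == "forward":
        d = j - i
        for t in range(1, h + 2):
            _force_neq(genome, j - t, int(genome[i - t]), rng)
        for t in range(0, h + 1):
            _force_neq(genome, j + l + t, int(genome[i + l + t]), rng)
    else:
        for t in range(1, h + 2):
            _force_neq(genome, j + l + t - 1, int(_COMP_U8[genome[i - t]]), rng)
        for t in range(0, h + 1):
            _force_neq(genome, j - 1 - t, int(_COMP_U8[genome[i + l + t]]), rng)
    return {"kind": disp.kind, "pos1": [int(i), int(i + l)],
            "pos2": [int(j), int(j + l)], "length": l,
            "mismatches": disp.mismatches}


def _suppress_chance_ssrs(genome, protect, rng, spec, truth_ssrs, L, I, n,
                          sync_ira, max_iter: int = 60) -> None:
    """Rejection loop: resample background until the SSR scan reports
    exactly the planted set (IRa kept in sync with IRb).

    ``protect`` lists intervals that must not be rewritten: gene parts,
    planted repeats with their boundary-breaker/seal guards, and the
    inversion flank zones.
    """
    from .records import merge_intervals

    planted_keys = {(t["start"], t["end"], t["motif"]) for t in truth_ssrs}
    protected = merge_intervals(protect)
    ira_start = n - I

    def is_protected(p: int) -> bool:
        return any(s <= p < e for s, e in protected)

    for _ in range(max_iter):
        hits = find_ssrs(_arr_to_str(genome), spec.ssr_params)
        extra = [hh for hh in hits
                 if (hh.start, hh.end, hh.motif) not in planted_keys]
        if not extra:
            return
        for hh in extra:
            s, e = hh.start, hh.end
            if s >= ira_start:  # rewrite the IRb mirror instead
                s, e = n + L - e, n + L - s
            wrote = False
            for p in range(s, e):
                if not is_protected(p):
                    genome[p] = _BASES[int(rng.integers(4))]
                    wrote = True
            if not wrote:
                raise RuntimeError(
                    f"chance SSR at {hh.start}-{hh.end} overlaps only protected "
                    "sequence; respecify the plastome"
                )
        sync_ira()
    raise RuntimeError("could not suppress chance SSRs within iteration limit")


# ---------------------------------------------------------------------------
# Inversion planting


def plant_inversion(
    base: PlastomeRecord,
    interval: tuple[int, int],
    flank_len: int = 164,
    flank_mismatches: int = 0,
    rng: np.random.Generator | None = None,
    max_hamming: int = 3,
    min_len: int = 30,
) -> tuple[PlastomeRecord, PlastomeRecord, dict]:
    """Plant a palindromic flank pair and invert the enclosed interval.

    Returns (donor, inverted, truth): ``donor`` carries the flank pair with
    the interval still in original orientation; ``inverted`` additionally
    has the interval reverse-complemented, with contained features
    re-mapped.  The flank copies are written immediately outside the
    interval and sealed (mismatch walls) so detectors recover the planted
    length exactly.  Raises when the interval or its flank zones collide
    with the IR regions or with annotated features.
    """
    rng = rng or np.random.default_rng(0)
    s, e = interval
    n = len(base.seq.residues)
    part = base.partition
    if part is not None:
        lsc_s, lsc_e = part.lsc
        if not (lsc_s <= s - flank_len and e + flank_len <= lsc_e):
            raise ValueError("inversion plus flanks collides with the IR/SSC regions")
    zone5 = (s - flank_len - max_hamming - 2, s + max_hamming + 2)
    zone3 = (e - max_hamming - 2, e + flank_len + max_hamming + 2)
    for f in base.features:
        for ps, pe, _ in f.parts:
            for zs, ze in (zone5, zone3):
                if ps < ze and zs < pe:
                    raise ValueError(
                        f"feature {f.gene_name} overlaps an inversion endpoint zone"
                    )

    genome = _str_to_arr(base.seq.residues)
    ssr_params = SSRParams()
    unit = _random_unit(rng, flank_len, 0.38, ssr_params)
    copy1 = _str_to_arr(unit)
    copy2 = _rc_arr(copy1)
    for p in _spread_positions(flank_len, flank_mismatches, min_len):
        _force_neq(copy2, flank_len - 1 - p, int(_COMP_U8[copy1[p]]), rng)
    i, j = s - flank_len, e  # copy1 upstream, copy2 downstream
    genome[i:s] = copy1
    genome[j : j + flank_len] = copy2
    h = max_hamming
    # outer walls
    for t in range(1, h + 2):
        _force_neq(genome, j + flank_len + t - 1, int(_COMP_U8[genome[i - t]]), rng)
    # inner walls: interior columns must mismatch in the donor *and* stay
    # mismatching after the interior is reverse complemented
    for t in range(0, h + 1):
        a, b = s + t, e - 1 - t  # column (s+t) pairs with (e-1-t)
        forbidden = {int(_COMP_U8[genome[b]]), int(genome[b])}
        if int(genome[a]) in forbidden:
            choices = [int(x) for x in _BASES if int(x) not in forbidden]
            genome[a] = choices[int(rng.integers(len(choices)))]

    donor_seq = SequenceRecord(base.seq.id + "_donor", _arr_to_str(genome), True)
    donor = PlastomeRecord(seq=donor_seq, features=list(base.features),
                           partition=base.partition)

    inv = genome.copy()
    inv[s:e] = _rc_arr(genome[s:e])
    new_features = []
    for f in base.features:
        new_parts = []
        changed = False
        for ps, pe, st in f.parts:
            if pe <= s or ps >= e:
                new_parts.append((ps, pe, st))
            elif s <= ps and pe <= e:
                # mapping each part keeps transcript order (exon 1 first)
                new_parts.append((s + e - pe, s + e - ps, -st))
                changed = True
            else:
                raise ValueError(
                    f"feature {f.gene_name} straddles the inversion endpoint"
                )
        if changed:
            new_features.append(
                FeatureAnnotation(f.gene_name, f.kind, new_parts, f.copy_index)
            )
        else:
            new_features.append(f)
    inv_seq = SequenceRecord(base.seq.id, _arr_to_str(inv), True)
    inverted = PlastomeRecord(seq=inv_seq, features=new_features,
                              partition=base.partition)
    truth = {
        "start": int(s), "end": int(e),
        "flank5": [int(i), int(s)], "flank3": [int(j), int(j + flank_len)],
        "flank_len": int(flank_len), "flank_mismatches": int(flank_mismatches),
        "genes_contained": sorted({f.gene_name for f in base.features
                                   if s <= f.span[0] and f.span[1] <= e}),
    }
    return donor, inverted, truth


# ---------------------------------------------------------------------------
# Divergence simulation (K80 with per-locus rate multipliers and indels)


@dataclass
class DivergenceSpec:
    """Conditions for evolving related genomes from one ancestor.

    ``rate`` is the expected substitutions/site on each branch of a star
    topology (every derived genome is one branch away from the ancestor);
    multipliers rescale the branch length inside given intervals, which is
    how hypervariable spacers are emulated.  ``kappa`` is the
    transition/transversion *rate* ratio (alpha/beta) of the K80 process.
    Indels (length 1..max_indel_len) fall only in intergenic single-copy
    sequence so annotations stay liftable; IR copies receive identical
    substitutions (plastome copy-correction) by mutating IRb and
    rebuilding IRa as its reverse complement.
    """

    n_genomes: int = 3
    rate: float = 0.015
    kappa: float = 2.0
    indel_rate: float = 0.0005
    max_indel_len: int = 4
    topology: str = "star"
    branch_scales: list[float] | None = None
    rate_multipliers: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.topology != "star":
            raise ValueError("only the star topology is implemented")


@dataclass
class DivergenceTruth:
    branch_lengths: list[float]  # substitutions/site, ancestor -> genome g
    rate_multipliers: list[tuple[int, int, float]]
    realized_transitions: list[int]
    realized_transversions: list[int]
    n_indels: list[int]

    def expected_pairwise_d(self, g1: int, g2: int, multiplier: float = 1.0) -> float:
        """Expected K2p distance (per 100 sites) between two genomes.

        ``g == -1`` denotes the unmutated ancestor.
        """
        t1 = self.branch_lengths[g1] if g1 >= 0 else 0.0
        t2 = self.branch_lengths[g2] if g2 >= 0 else 0.0
        return 100.0 * (t1 + t2) * multiplier


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length t."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


_TS_MAP = np.zeros(256, dtype=np.uint8)
_TV1_MAP = np.zeros(256, dtype=np.uint8)
_TV2_MAP = np.zeros(256, dtype=np.uint8)
for _b, _ts, _tv in ((b"A", b"G", b"CT"), (b"G", b"A", b"CT"),
                     (b"C", b"T", b"AG"), (b"T", b"C", b"AG")):
    _TS_MAP[_b[0]] = _ts[0]
    _TV1_MAP[_b[0]] = _tv[0]
    _TV2_MAP[_b[0]] = _tv[1]


def diverge_genomes(
    base: PlastomeRecord, dspec: DivergenceSpec
) -> tuple[list[PlastomeRecord], DivergenceTruth]:
    """Evolve ``n_genomes`` descendants of ``base`` under K80."""
    part = base.partition
    if part is None:
        raise ValueError("base record needs a quadripartite partition")
    rng = np.random.default_rng(dspec.seed)
    n = len(base.seq.residues)
    L, LI = part.irb[0], part.irb[1]
    ssc_end = part.ssc[1]
    core_len = ssc_end  # LSC + IRb + SSC; IRa is rebuilt per genome
    base_arr = _str_to_arr(base.seq.residues)

    scales = dspec.branch_scales or [1.0] * dspec.n_genomes
    if len(scales) != dspec.n_genomes:
        raise ValueError("branch_scales length mismatch")

    # per-site branch-length multiplier over the mutable core
    mult = np.ones(core_len)
    for s, e, m in dspec.rate_multipliers:
        if not (0 <= s < e <= core_len):
            raise ValueError("rate multiplier interval outside the mutable core")
        mult[s:e] = m

    # intergenic single-copy zones eligible for indels; region boundaries and
    # the whole IRb are protected so deletions cannot cross them
    protected = np.zeros(core_len, dtype=bool)
    for f in base.features:
        for ps, pe, _ in f.parts:
            if ps < core_len:
                protected[ps : min(pe, core_len)] = True
    protected[L:LI] = True
    protected[max(0, L - 1)] = True
    protected[core_len - 1] = True
    eligible = np.flatnonzero(~protected)

    genomes: list[PlastomeRecord] = []
    truth = DivergenceTruth([], list(dspec.rate_multipliers), [], [], [])
    for g in range(dspec.n_genomes):
        t_branch = dspec.rate * scales[g]
        truth.branch_lengths.append(t_branch)
        arr = base_arr[:core_len].copy()
        n_ts = n_tv = 0
        for val in np.unique(mult):
            sites = np.flatnonzero(mult == val)
            p_ts, p_tv = _k80_probs(t_branch * val, dspec.kappa)
            u = rng.random(sites.size)
            ts_sites = sites[u < p_ts]
            tv_sites = sites[(u >= p_ts) & (u < p_ts + 2 * p_tv)]
            arr[ts_sites] = _TS_MAP[arr[ts_sites]]
            if tv_sites.size:
                pick = rng.random(tv_sites.size) < 0.5
                arr[tv_sites[pick]] = _TV1_MAP[arr[tv_sites[pick]]]
                arr[tv_sites[~pick]] = _TV2_MAP[arr[tv_sites[~pick]]]
            n_ts += int(ts_sites.size)
            n_tv += int(tv_sites.size)
        truth.realized_transitions.append(n_ts)
        truth.realized_transversions.append(n_tv)

        # indels in intergenic single-copy zones
        events: list[tuple[int, int]] = []  # (pos, +len insertion / -len deletion)
        if dspec.indel_rate > 0 and eligible.size:
            k = rng.binomial(eligible.size, dspec.indel_rate)
            pos = np.sort(rng.choice(eligible, size=k, replace=False))
            for p in pos:
                p = int(p)
                length = int(min(1 + rng.geometric(0.5), dspec.max_indel_len))
                if rng.random() < 0.5:
                    # shrink the deletion so it stays inside unprotected sequence
                    while length > 0 and protected[p : p + length].any():
                        length -= 1
                    if length > 0:
                        events.append((p, -length))
                else:
                    events.append((p, length))
        truth.n_indels.append(len(events))

        pieces = []
        cursor = 0
        breaks: list[tuple[int, int]] = []  # (orig pos, cumulative shift)
        shift = 0
        for p, ln in events:
            if p < cursor:  # swallowed by a previous deletion
                continue
            pieces.append(arr[cursor:p])
            if ln < 0:
                cursor = p - ln
                shift += ln
            else:
                pieces.append(_random_dna(rng, ln, 0.38))
                cursor = p
                shift += ln
            breaks.append((p, shift))
        pieces.append(arr[cursor:core_len])
        new_core = np.concatenate(pieces)

        def lift(x: int) -> int:
            s = 0
            for p, sh in breaks:
                if x > p:
                    s = sh
                else:
                    break
            return x + s

        new_L, new_LI, new_core_len = lift(L), lift(LI), len(new_core)
        full = np.concatenate((new_core, _rc_arr(new_core[new_L:new_LI])))
        new_n = len(full)

        feats = []
        for f in base.features:
            parts = [(lift(ps), lift(pe), st) for ps, pe, st in f.parts]
            feats.append(FeatureAnnotation(f.gene_name, f.kind, parts, f.copy_index))
        new_part = QuadripartitePartition(
            lsc=(0, new_L), irb=(new_L, new_LI),
            ssc=(new_LI, new_core_len), ira=(new_core_len, new_n),
            junctions={"JLB": new_L, "JSB": new_LI, "JSA": new_core_len, "JLA": 0},
            genome_length=new_n,
        )
        rec = PlastomeRecord(
            seq=SequenceRecord(f"{base.seq.id}_g{g + 1}", _arr_to_str(full), True),
            features=feats,
            partition=new_part,
        )
        genomes.append(rec)
    return genomes, truth


# ---------------------------------------------------------------------------
# A complete synthetic comparative study


@dataclass
class StudyBundle:
    """One reference genome with a planted inversion plus diverged relatives.

    ``reference`` carries the inversion; ``donor`` is the same genome in
    ancestral orientation (flank pair planted, interval not inverted);
    ``relatives`` are K80-diverged descendants of the donor.  ``hot_loci``
    maps IGS locus names to their planted rate multipliers.
    """

    reference: PlastomeRecord
    donor: PlastomeRecord
    relatives: list[PlastomeRecord]
    truth: GroundTruth
    divergence_truth: DivergenceTruth
    hot_loci: dict[str, float]


def default_study(
    seed: int = 0,
    spec: PlastomeSpec | None = None,
    n_relatives: int = 3,
    rate: float = 0.015,
    kappa: float = 2.0,
    indel_rate: float = 0.0005,
    hot_multipliers: tuple[float, ...] = (10.0, 4.6, 2.9, 2.0, 1.8),
) -> StudyBundle:
    """Generate the full comparative-study setup on synthetic data.

    The hot multipliers emulate a handful of hypervariable spacers whose
    divergence stands far above the genomic background, the situation the
    K2p ranking procedure is designed to detect.
    """
    from .divergence import extract_igs

    if spec is None:
        spec = PlastomeSpec(seed=seed, inversion=InversionSpec())
    elif spec.inversion is None:
        spec.inversion = InversionSpec(
            length=max(1000, spec.lsc_len // 4),
            flank_len=min(164, max(40, spec.lsc_len // 80)),
        )
    sim = generate_plastome(spec)
    donor, reference = sim.donor, sim.record
    inv = sim.truth.inversion

    # pick hypervariable spacers among donor IGS loci clear of the
    # inversion (the scan excludes the inverted region, as one would for a
    # genome carrying a rearrangement)
    loci = extract_igs(donor, donor.partition,
                       exclude=[(inv["start"], inv["end"])])
    loci = [l for l in loci
            if l.interval[1] > l.interval[0]
            and l.interval[1] - l.interval[0] >= 60
            and l.interval[1] <= donor.partition.lsc[1]]
    loci.sort(key=lambda l: l.interval[0] - l.interval[1])  # longest first
    hot = {}
    multipliers = []
    for l, m in zip(loci, hot_multipliers):
        hot[l.name] = m
        multipliers.append((l.interval[0], l.interval[1], m))

    dspec = DivergenceSpec(
        n_genomes=n_relatives, rate=rate, kappa=kappa, indel_rate=indel_rate,
        rate_multipliers=multipliers, seed=(seed * 7919 + 13) % (2**31),
    )
    relatives, dtruth = diverge_genomes(donor, dspec)
    return StudyBundle(
        reference=reference, donor=donor, relatives=relatives,
        truth=sim.truth, divergence_truth=dtruth, hot_loci=hot,
    )
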