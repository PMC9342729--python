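"""Genome summary statistics: region lengths, GC content, gene inventory,
codon usage and intron/splicing classification.

Gene counting supports two policies because plastome IRs duplicate genes:
``unique`` counts each (gene name, functional class) once regardless of IR
duplication (the convention most published gene inventories follow, with a
multiplicity column emitted alongside), ``all_copies`` counts every
annotated copy.  Codon usage likewise offers both policies; totals differ
by construction and both are reported rather than reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io import extract_feature_sequence
from .records import FeatureAnnotation, PlastomeRecord, QuadripartitePartition

log = logging.getLogger(__name__)

#: plastid / bacterial genetic code
_TABLE11 = unambiguous_dna_by_id[11]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def gc_content(seq: str) -> float:
    """GC percentage of a sequence, N's excluded from both numerator and
    denominator, reported to 2 decimals (half-up)."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return _round2(100.0 * (counts["G"] + counts["C"]) / denom)


@dataclass
class GenomeSummary:
    total_len: int
    region_lens: dict[str, int]
    gc_overall: float
    gc_by_region: dict[str, float]
    gc_by_class: dict[str, float]
    class_lens: dict[str, tuple[int, float]]  # class -> (bp, % of genome)
    gene_counts: dict[str, int]
    gene_multiplicity: dict[str, int] = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, object]]:
        rows: list[tuple[str, object]] = [("total_len", self.total_len)]
        rows += [(f"len_{k}", v) for k, v in self.region_lens.items()]
        rows += [("gc_overall", self.gc_overall)]
        rows += [(f"gc_{k}", v) for k, v in self.gc_by_region.items()]
        rows += [(f"gc_{k}", v) for k, v in self.gc_by_class.items()]
        for k, (bp, pct) in self.class_lens.items():
            rows += [(f"len_{k}", bp), (f"pct_{k}", pct)]
        rows += [(f"n_{k}", v) for k, v in self.gene_counts.items()]
        return rows


_CLASS_OF_KIND = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}


def _gene_classes(rec: PlastomeRecord) -> dict[str, str]:
    """Map gene name -> functional class from its typed features."""
    classes: dict[str, str] = {}
    for f in rec.features:
        cls = _CLASS_OF_KIND.get(f.kind)
        if cls and f.gene_name not in classes:
            classes[f.gene_name] = cls
    # gene-only annotations: fall back on naming conventions
    for f in rec.features_of_kind("gene"):
        if f.gene_name not in classes:
            low = f.gene_name.lower()
            if low.startswith("trn"):
                classes[f.gene_name] = "tRNA"
            elif low.startswith("rrn"):
                classes[f.gene_name] = "rRNA"
            else:
                classes[f.gene_name] = "protein_coding"
    return classes


def summarize_genome(
    rec: PlastomeRecord,
    partition: QuadripartitePartition | None = None,
    count_policy: str = "unique",
) -> GenomeSummary:
    """Region lengths, GC by region and by feature class, gene inventory."""
    partition = partition or rec.partition
    if partition is None:
        raise ValueError(
            "record has no quadripartite partition; run detect_inverted_repeat first"
        )
    if count_policy not in ("unique", "all_copies"):
        raise ValueError(f"unknown count_policy {count_policy!r}")

    n = len(rec.seq.residues)
    region_lens = partition.region_lengths()
    gc_by_region = {
        name: gc_content(rec.seq.fetch(*getattr(partition, name.lower())))
        for name in ("LSC", "SSC", "IRa", "IRb")
    }

    classes = _gene_classes(rec)
    class_seq: dict[str, list[str]] = {"CDS": [], "tRNA": [], "rRNA": []}
    for f in rec.features:
        if f.kind in class_seq:
            class_seq[f.kind].append(extract_feature_sequence(rec, f))
    gc_by_class = {
        k: gc_content("".join(v)) for k, v in class_seq.items() if v
    }
    class_lens = {
        k: (sum(map(len, v)), _round2(100.0 * sum(map(len, v)) / n))
        for k, v in class_seq.items()
    }

    multiplicity: dict[str, int] = {}
    for f in rec.gene_features():
        multiplicity[f.gene_name] = max(
            multiplicity.get(f.gene_name, 0), f.copy_index
        )
    if count_policy == "unique":
        tally = {name: 1 for name in multiplicity}
    else:
        tally = dict(multiplicity)
    counts = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
    for name, k in tally.items():
        counts[classes.get(name, "protein_coding")] += k
    counts["total"] = sum(counts.values())

    return GenomeSummary(
        total_len=n,
        region_lens=region_lens,
        gc_overall=gc_content(rec.seq.residues),
        gc_by_region=gc_by_region,
        gc_by_class=gc_by_class,
        class_lens=class_lens,
        gene_counts=counts,
        gene_multiplicity=multiplicity,
    )


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    by_amino_acid: dict[str, int]
    total_codons: int

    def most_abundant_aa(self) -> str:
        aa = {k: v for k, v in self.by_amino_acid.items() if k != "*"}
        return max(aa, key=aa.get)  # type: ignore[arg-type]

    def least_abundant_aa(self) -> str:
        aa = {k: v for k, v in self.by_amino_acid.items() if k != "*" and v > 0}
        return min(aa, key=aa.get)  # type: ignore[arg-type]


def codon_usage(rec: PlastomeRecord, dedup_policy: str = "all_copies") -> CodonUsageTable:
    """Codon counts over concatenated CDS transcripts (genetic code 11).

    ``dedup_policy='unique'`` counts one copy per gene name; the default
    counts every annotated CDS copy, IR duplicates included.  CDS lengths
    not divisible by 3 are logged and the trailing partial codon dropped;
    internal stop codons are counted as stops and logged, never fatal.
    """
    if dedup_policy not in ("unique", "all_copies"):
        raise ValueError(f"unknown dedup_policy {dedup_policy!r}")
    cds = rec.features_of_kind("CDS")
    if not cds:
        raise ValueError("no CDS features annotated")
    if dedup_policy == "unique":
        cds = [f for f in cds if f.copy_index == 1]

    counts: dict[str, int] = {}
    by_aa: dict[str, int] = {}
    total = 0
    for f in cds:
        tx = extract_feature_sequence(rec, f)
        if len(tx) % 3:
            log.warning(
                "CDS %s length %d not divisible by 3; trailing %d base(s) dropped",
                f.gene_name, len(tx), len(tx) % 3,
            )
            tx = tx[: len(tx) - len(tx) % 3]
        n_codons = len(tx) // 3
        for i in range(n_codons):
            codon = tx[3 * i : 3 * i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
            if codon in _TABLE11.stop_codons:
                aa = "*"
                if i < n_codons - 1:
                    log.warning("internal stop codon in CDS %s", f.gene_name)
            else:
                aa = _TABLE11.forward_table[codon]
            by_aa[aa] = by_aa.get(aa, 0) + 1
            total += 1
    return CodonUsageTable(counts=counts, by_amino_acid=by_aa, total_codons=total)


@dataclass
class SplicingReport:
    #: (gene_name, copy_index) -> (intron_count, splicing class)
    genes: dict[tuple[str, int], tuple[int, str]]

    def cis_spliced(self) -> list[tuple[str, int]]:
        return [g for g, (n, c) in self.genes.items() if c == "cis"]

    def trans_spliced(self) -> list[tuple[str, int]]:
        return [g for g, (n, c) in self.genes.items() if c == "trans"]


def _is_collinear(parts: list[tuple[int, int, int]]) -> bool:
    """True when transcript-ordered parts run monotonically along the
    genome on one strand (the cis-splicing geometry)."""
    strands = {p[2] for p in parts}
    if len(strands) != 1:
        return False
    starts = [p[0] for p in parts]
    if strands == {1}:
        return all(a < b for a, b in zip(starts, starts[1:]))
    return all(a > b for a, b in zip(starts, starts[1:]))


def classify_splicing(rec: PlastomeRecord) -> SplicingReport:
    """Per gene copy: intron count and none/cis/trans splicing class.

    Trans-splicing is called when annotated parts are non-collinear: their
    genome order differs from transcript order or their strands are mixed
    (the plastid rps12 geometry).
    """
    # prefer the spliced kinds (CDS/tRNA/rRNA); fall back to gene rows
    best: dict[tuple[str, int], FeatureAnnotation] = {}
    for f in rec.features:
        key = (f.gene_name, f.copy_index)
        have = best.get(key)
        if have is None or (have.kind == "gene" and f.kind != "gene"):
            best[key] = f
    genes = {}
    for key, f in best.items():
        introns = len(f.parts) - 1
        if introns == 0:
            cls = "none"
        elif _is_collinear(f.parts):
            cls = "cis"
        else:
            cls = "trans"
        genes[key] = (introns, cls)
    return SplicingReport(genes=genes)
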