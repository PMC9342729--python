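"""Core coordinate and feature model shared by every analysis module.

Internal convention: all coordinates are 0-based, half-open.  GenBank I/O
converts to/from the 1-based inclusive convention at the boundary.  Circular
genomes are stored linearized at the deposited origin; origin-spanning
intervals are handled by modular slicing, never by rotating the sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the closed alphabet {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(raw: str) -> str:
    """Uppercase and map IUPAC ambiguity codes other than N to N.

    Downstream counters (GC, codon usage, repeat scans) assume a closed
    five-letter alphabet; a warning is issued when any code is remapped.
    """
    seq = raw.upper().replace("U", "T")
    if set(seq) - _VALID:
        n_bad = sum(c not in _VALID for c in seq)
        warnings.warn(
            f"{n_bad} ambiguity code(s) beyond N mapped to N", stacklevel=2
        )
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


@dataclass
class SequenceRecord:
    """A (possibly circular) DNA sequence with accession-like id."""

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.residues = normalize_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Slice [start, end); for circular records the interval may wrap.

        ``end`` may exceed the length (modular arithmetic), or be smaller
        than ``start`` to denote an origin-spanning interval.
        """
        n = len(self.residues)
        if n == 0:
            raise ValueError("empty sequence")
        if not self.circular:
            if not (0 <= start <= end <= n):
                raise IndexError(f"interval [{start}, {end}) out of bounds")
            return self.residues[start:end]
        start %= n
        end = end % n if end % n or end == 0 else n
        if end > n:
            end -= n
        if start < end:
            return self.residues[start:end]
        if start == end:
            return ""
        return self.residues[start:] + self.residues[:end]

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id + "_rc", revcomp(self.residues), self.circular)


#: feature kinds the model captures
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")


@dataclass
class FeatureAnnotation:
    """An annotated gene/CDS/tRNA/rRNA with oriented exon parts.

    ``parts`` are (start, end, strand) triples in transcript order, 0-based
    half-open, strand +1/-1.  ``copy_index`` distinguishes IR duplicates of
    the same gene name (1-based, in order of appearance).
    """

    gene_name: str
    kind: str
    parts: list[tuple[int, int, int]]
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise ValueError(f"feature {self.gene_name}: empty parts")

    def name_with_copy(self) -> str:
        """Gene name, suffixed with the copy index for IR duplicates."""
        return self.gene_name if self.copy_index == 1 else f"{self.gene_name}({self.copy_index})"

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (min start, max end) over all parts."""
        return (min(p[0] for p in self.parts), max(p[1] for p in self.parts))

    @property
    def strand(self) -> int | None:
        strands = {p[2] for p in self.parts}
        return strands.pop() if len(strands) == 1 else None

    def total_part_length(self, genome_len: int | None = None) -> int:
        tot = 0
        for s, e, _ in self.parts:
            if e >= s:
                tot += e - s
            elif genome_len is not None:  # origin-spanning part
                tot += genome_len - s + e
            else:
                raise ValueError("wrapping part without genome length")
        return tot


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals plus the four junction coordinates.

    Intervals are 0-based half-open; a region containing the origin is
    stored with start > end and interpreted modularly.  Junctions are the
    positions *between* the last base of one region and the first base of
    the next (equal to the start coordinate of the downstream region).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    junctions: dict[str, int] = field(default_factory=dict)
    genome_length: int = 0

    def region_length(self, name: str) -> int:
        s, e = getattr(self, name.lower())
        if e >= s:
            return e - s
        return self.genome_length - s + e

    def region_lengths(self) -> dict[str, int]:
        return {r: self.region_length(r) for r in ("LSC", "SSC", "IRa", "IRb")}

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name in ("LSC", "IRb", "SSC", "IRa"):
            s, e = getattr(self, name.lower())
            if (s <= pos < e) if e >= s else (pos >= s or pos < e):
                return name
        raise ValueError(f"position {pos} not covered by partition")

    def validate(self) -> None:
        total = sum(self.region_lengths().values())
        if total != self.genome_length:
            raise ValueError(
                f"partition tiles {total} bp but genome is {self.genome_length} bp"
            )
        if self.region_length("LSC") < self.region_length("SSC"):
            raise ValueError("naming convention violated: LSC shorter than SSC")


@dataclass
class PlastomeRecord:
    """Annotated plastome: sequence + features + optional partition."""

    seq: SequenceRecord
    features: list[FeatureAnnotation] = field(default_factory=list)
    partition: QuadripartitePartition | None = None

    @property
    def id(self) -> str:
        return self.seq.id

    def features_of_kind(self, kind: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == kind]

    def gene_features(self) -> list[FeatureAnnotation]:
        """'gene'-kind features, or all features if no gene-level rows exist."""
        genes = self.features_of_kind("gene")
        return genes if genes else list(self.features)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (report convention)."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def interval_intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
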