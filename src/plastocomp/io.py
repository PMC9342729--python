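"""GenBank / FASTA input-output built on Biopython.

Reading converts GenBank's 1-based inclusive locations into the internal
0-based half-open convention and records gene/CDS/tRNA/rRNA features,
including compound (``join``) and minus-strand (``complement``) locations.
Features whose location cannot be interpreted are skipped with a warning
that is preserved in a load report rather than aborting the whole record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import (
    FEATURE_KINDS,
    FeatureAnnotation,
    PlastomeRecord,
    SequenceRecord,
    revcomp,
)


@dataclass
class LoadReport:
    """What happened while ingesting a GenBank record."""

    path: str = ""
    n_features: int = 0
    skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _feature_name(feat: SeqFeature) -> str | None:
    q = feat.qualifiers
    for key in ("gene", "locus_tag", "product"):
        if key in q and q[key]:
            return str(q[key][0]).strip()
    return None


def _location_parts(feat: SeqFeature) -> list[tuple[int, int, int]]:
    """Location parts in transcript order as (start, end, strand).

    Biopython normalizes ``complement(join(a..b, c..d))`` into a compound
    of per-part complements listed in transcript order, so its part order
    is taken as transcript order directly — this also covers mixed-strand
    locations (trans-spliced genes such as rps12), which GenBank writes
    part-by-part in transcript order.
    """
    loc = feat.location
    raw = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return [(int(p.start), int(p.end), int(p.strand or 1)) for p in raw]


def read_genbank(path: str | Path) -> tuple[PlastomeRecord, LoadReport]:
    """Read an annotated plastome from a GenBank flat file.

    Returns the record plus a :class:`LoadReport` listing any skipped
    features.  Raises ``ValueError`` if the file holds no sequence.
    """
    path = Path(path)
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None or len(rec.seq) == 0:
        raise ValueError(f"{path}: no sequence found in GenBank file")

    circular = rec.annotations.get("topology", "circular") == "circular"
    seq = SequenceRecord(rec.id or rec.name, str(rec.seq), circular=circular)

    report = LoadReport(path=str(path))
    features: list[FeatureAnnotation] = []
    copy_counter: dict[tuple[str, str], int] = {}
    n = len(seq.residues)
    for feat in rec.features:
        if feat.type not in FEATURE_KINDS:
            continue
        name = _feature_name(feat)
        if name is None:
            report.skipped.append(f"{feat.type} without gene/locus_tag qualifier")
            continue
        try:
            parts = _location_parts(feat)
        except Exception as exc:  # unparsable location
            report.skipped.append(f"{feat.type} {name}: {exc}")
            warnings.warn(f"skipping {feat.type} {name}: unparsable location")
            continue
        if any(not (0 <= s < n and 0 < e <= n) for s, e, _ in parts):
            report.skipped.append(f"{feat.type} {name}: location out of bounds")
            continue
        key = (name, feat.type)
        copy_counter[key] = copy_counter.get(key, 0) + 1
        features.append(
            FeatureAnnotation(name, feat.type, parts, copy_index=copy_counter[key])
        )
    report.n_features = len(features)
    return PlastomeRecord(seq=seq, features=features), report


def extract_feature_sequence(rec: PlastomeRecord, feat: FeatureAnnotation) -> str:
    """Spliced transcript sequence of a feature.

    Parts are concatenated in annotated transcript order; minus-strand
    parts are reverse complemented individually, so mixed-strand
    (trans-spliced) features come out in transcript orientation.  Parts
    spanning the origin of a circular genome are handled modularly.
    """
    if not feat.parts:
        raise ValueError("feature has no parts")
    chunks = []
    for start, end, strand in feat.parts:
        piece = rec.seq.fetch(start, end)
        chunks.append(revcomp(piece) if strand == -1 else piece)
    return "".join(chunks)


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column wrapping."""
    if not records:
        raise ValueError("no records to write")
    for r in records:
        if not r.id:
            raise ValueError("record with empty id")
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (assumed circular plastomes)."""
    out = [
        SequenceRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def _to_biopython(rec: PlastomeRecord) -> BioSeqRecord:
    """Convert to a Biopython SeqRecord with GenBank-writable features."""
    bio = BioSeqRecord(
        Seq(rec.seq.residues),
        id=rec.seq.id,
        name=rec.seq.id[:16].replace(".", "_"),
        description="synthetic annotated plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if rec.seq.circular else "linear",
        },
    )
    for feat in rec.features:
        # parts are kept in transcript order; Biopython renders a uniform
        # minus-strand compound back into complement(join(...)) form
        locs = []
        for s, e, strand in feat.parts:
            locs.append(SimpleLocation(s, e, strand))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        bio.features.append(
            SeqFeature(location, type=feat.kind, qualifiers={"gene": [feat.gene_name]})
        )
    return bio


def write_genbank(rec: PlastomeRecord, path: str | Path) -> None:
    """Write an annotated plastome as a GenBank flat file."""
    SeqIO.write([_to_biopython(rec)], str(path), "genbank")
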