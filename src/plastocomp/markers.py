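"""Diagnostic marker-site evaluation on per-locus alignments.

A diagnostic site is an alignment column whose residue pattern separates
at least one pair of taxa: a SNP column (all residues are bases) or an
indel column (some taxon carries a gap).  Columns where individuals of the
same taxon disagree are skipped — a diagnostic marker must be fixed within
taxon, not probabilistic.  Indel columns are treated as a fifth character
state per column; no merging of adjacent gap columns is attempted by
default (``merge_adjacent_indels`` opts in).

The minimal discriminating set is found greedily (largest-uncovered-first
set cover over taxon pairs) and then verified optimal by exhaustive search
whenever the site list is small enough to allow it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

log = logging.getLogger(__name__)


@dataclass
class SiteCall:
    column: int
    kind: str  # 'SNP' | 'indel'
    residues_by_taxon: dict[str, str]
    distinguishes: frozenset[tuple[str, str]]


@dataclass
class DiscriminationReport:
    sites: list[SiteCall]
    pairs_covered: frozenset[tuple[str, str]]
    minimal_set: list[int]  # columns
    fully_discriminating: bool
    uncovered_pairs: frozenset[tuple[str, str]] = frozenset()
    skipped_columns: list[int] = field(default_factory=list)


def call_diagnostic_sites(
    alignment: dict[str, str],
    taxon_of: dict[str, str] | None = None,
    merge_adjacent_indels: bool = False,
) -> tuple[list[SiteCall], list[int]]:
    """Classify every polymorphic column of the alignment.

    ``alignment`` maps row id -> aligned string; ``taxon_of`` maps row id
    -> taxon label (default: each row is its own taxon).  Returns the site
    calls plus the columns skipped for intra-taxon disagreement.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ids = list(alignment)
    L = len(alignment[ids[0]])
    if any(len(alignment[i]) != L for i in ids):
        raise ValueError("ragged alignment")
    taxon_of = taxon_of or {i: i for i in ids}
    taxa = sorted(set(taxon_of.values()))
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")

    sites: list[SiteCall] = []
    skipped: list[int] = []
    for col in range(L):
        residues: dict[str, str] = {}
        ok = True
        for row_id in ids:
            t = taxon_of[row_id]
            c = alignment[row_id][col].upper()
            if t in residues and residues[t] != c:
                ok = False
                break
            residues[t] = c
        if not ok:
            skipped.append(col)
            log.debug("column %d: intra-taxon disagreement, skipped", col)
            continue
        if len(set(residues.values())) < 2:
            continue  # monomorphic
        kind = "indel" if "-" in residues.values() else "SNP"
        pairs = frozenset(
            (a, b) for a, b in combinations(taxa, 2) if residues[a] != residues[b]
        )
        sites.append(SiteCall(col, kind, residues, pairs))

    if merge_adjacent_indels:
        merged: list[SiteCall] = []
        for s in sites:
            if (
                merged
                and s.kind == "indel"
                and merged[-1].kind == "indel"
                and s.column == merged[-1].column + 1
                and s.distinguishes == merged[-1].distinguishes
            ):
                continue  # same indel block, same signal
            merged.append(s)
        sites = merged
    return sites, skipped


def minimal_discriminating_set(
    sites: list[SiteCall],
    taxa: list[str],
    exhaustive_limit: int = 20,
) -> DiscriminationReport:
    """Smallest set of columns covering every distinguishable taxon pair.

    Greedy cover first; when ``len(sites) <= exhaustive_limit`` the greedy
    answer is replaced by the true optimum found by exhaustive search over
    subsets of smaller size.
    """
    all_pairs = frozenset(combinations(sorted(taxa), 2))
    coverable = frozenset().union(*(s.distinguishes for s in sites)) if sites else frozenset()
    uncovered_forever = all_pairs - coverable

    # greedy
    chosen: list[SiteCall] = []
    remaining = set(coverable)
    pool = list(sites)
    while remaining:
        best = max(pool, key=lambda s: len(s.distinguishes & remaining))
        gain = len(best.distinguishes & remaining)
        if gain == 0:
            break
        chosen.append(best)
        remaining -= best.distinguishes
        pool.remove(best)
    minimal = [s.column for s in chosen]

    if sites and len(sites) <= exhaustive_limit and len(chosen) > 1:
        for size in range(1, len(chosen)):
            found = None
            for combo in combinations(sites, size):
                cov = frozenset().union(*(s.distinguishes for s in combo))
                if cov >= coverable:
                    found = combo
                    break
            if found:
                minimal = [s.column for s in found]
                break

    return DiscriminationReport(
        sites=sites,
        pairs_covered=coverable,
        minimal_set=sorted(minimal),
        fully_discriminating=not uncovered_forever,
        uncovered_pairs=uncovered_forever,
    )
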