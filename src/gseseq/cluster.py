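"""Error-tolerant clustering of observed barcodes into canonical barcodes.

Sphere clustering in the starcode spirit: observed barcodes are visited in
descending abundance (ties broken lexicographically) and each either joins
the most abundant existing canonical within Levenshtein distance ``d`` whose
accumulated count is at least ``ratio`` times its own, or founds a new
canonical. Merging is single-level — satellites attach to canonicals only,
never chain — so every member is guaranteed within ``d`` of its canonical.

Candidate canonicals are found through a symmetric-deletion index (two
strings within edit distance d share a common string after at most d
deletions each), which avoids all-pairs scanning while producing exactly the
same table as the brute-force greedy pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import edlib

from .readparse import ParsedRead, STATUS_OK


@dataclass
class ClusterTable:
    """Observed barcode -> canonical barcode mapping with counts."""

    mapping: dict[str, str]  # observed -> canonical (canonical maps to itself)
    observed_counts: dict[str, int]
    canonical_counts: dict[str, int]  # accumulated, includes dropped clusters
    dropped: set[str]  # canonicals whose total count < min_reads
    d: int = 2
    ratio: float = 5.0
    min_reads: int = 10

    @property
    def kept_canonicals(self) -> list[str]:
        """Surviving canonical barcodes, most abundant first."""
        keep = [c for c in self.canonical_counts if c not in self.dropped]
        return sorted(keep, key=lambda c: (-self.canonical_counts[c], c))

    def to_rows(self) -> list[tuple[str, int, str]]:
        rows = [
            (obs, self.observed_counts[obs], canon)
            for obs, canon in self.mapping.items()
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("observed_barcode\tcount\tcanonical_barcode\tkept\n")
            for obs, count, canon in self.to_rows():
                fh.write(f"{obs}\t{count}\t{canon}\t{int(canon not in self.dropped)}\n")


def _deletion_variants(s: str, d: int) -> set[str]:
    out = {s}
    frontier = {s}
    for _ in range(d):
        nxt = set()
        for t in frontier:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1 :])
        out |= nxt
        frontier = nxt
    return out


def levenshtein(a: str, b: str, k: int = -1) -> int:
    return edlib.align(a, b, mode="NW", k=k)["editDistance"]


def cluster_barcodes(
    counts: Mapping[str, int],
    d: int = 2,
    ratio: float = 5.0,
    min_reads: int = 10,
) -> ClusterTable:
    """Greedy abundance-descending sphere clustering of barcode counts."""
    if d > 3:
        raise ValueError("d > 3 is not supported (complexity guard)")
    if d < 0:
        raise ValueError("d must be >= 0")
    if any(c < 1 for c in counts.values()):
        raise ValueError("counts must be >= 1")

    order = sorted(counts, key=lambda b: (-counts[b], b))
    mapping: dict[str, str] = {}
    canon_counts: dict[str, int] = {}
    index: dict[str, list[str]] = {}  # deletion variant -> canonicals

    for bc in order:
        c = counts[bc]
        cands: set[str] = set()
        for var in _deletion_variants(bc, d):
            hits = index.get(var)
            if hits:
                cands.update(hits)
        best: str | None = None
        for canon in cands:
            if canon_counts[canon] < ratio * c:
                continue
            dist = levenshtein(bc, canon, k=d)
            if dist < 0 or dist > d:
                continue
            # highest accumulated count wins; ties -> lexicographically smallest
            if (
                best is None
                or canon_counts[canon] > canon_counts[best]
                or (canon_counts[canon] == canon_counts[best] and canon < best)
            ):
                best = canon
        if best is not None:
            mapping[bc] = best
            canon_counts[best] += c
        else:
            mapping[bc] = bc
            canon_counts[bc] = c
            for var in _deletion_variants(bc, d):
                index.setdefault(var, []).append(bc)

    totals = canon_counts
    dropped = {c for c, t in totals.items() if t < min_reads}
    return ClusterTable(
        mapping=mapping,
        observed_counts=dict(counts),
        canonical_counts=totals,
        dropped=dropped,
        d=d,
        ratio=ratio,
        min_reads=min_reads,
    )


def barcode_counts(parsed: Iterable[ParsedRead]) -> dict[str, int]:
    """Observed-barcode counts over ok calls (short inserts still count)."""
    counts: dict[str, int] = {}
    for p in parsed:
        if p.call.status == STATUS_OK:
            counts[p.call.barcode] = counts.get(p.call.barcode, 0) + 1
    return counts


def assign_reads(
    parsed: Iterable[ParsedRead], table: ClusterTable
) -> tuple[dict[str, str], dict]:
    """Map every ok read to its SAG (canonical barcode) or leave unassigned.

    Returns (read_id -> canonical barcode, summary); reads whose barcode is
    absent from the table or whose cluster was dropped stay unassigned.
    """
    assignments: dict[str, str] = {}
    n_ok = 0
    unassigned = 0
    for p in parsed:
        if p.call.status != STATUS_OK:
            continue
        n_ok += 1
        canon = table.mapping.get(p.call.barcode)
        if canon is None or canon in table.dropped:
            unassigned += 1
            continue
        assignments[p.call.read_id] = canon
    summary = {
        "ok_reads": n_ok,
        "assigned": len(assignments),
        "unassigned": unassigned,
        "n_sags": len(table.kept_canonicals),
    }
    return assignments, summary


def sag_read_sets(
    parsed: Iterable[ParsedRead],
    assignments: Mapping[str, str],
    include_short: bool = False,
) -> dict[str, list[str]]:
    """Per-SAG insert sequences (short inserts excluded from binning by default)."""
    sags: dict[str, list[str]] = {}
    for p in parsed:
        if p.call.status != STATUS_OK:
            continue
        canon = assignments.get(p.call.read_id)
        if canon is None:
            continue
        if p.short and not include_short:
            continue
        sags.setdefault(canon, []).append(p.insert)
    return sags
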