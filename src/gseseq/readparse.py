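"""Barcode-cassette extraction from long reads.

Each read carries (in either orientation) a cassette of
``anchor5 + barcode + anchor3`` followed by the genomic insert. Both anchors
are located by semi-global (infix) edit-distance alignment against the read
and its reverse complement; the best joint placement whose anchors are each
within ``max_anchor_edits`` and whose inter-anchor gap is within
``barcode_length +/- indel_slack`` wins. Ties on total edits are broken
toward the plus strand and then the 5'-most placement; ties that would yield
different barcode strings are reported as ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import edlib

from ._util import read_seqs, revcomp
from .poolstats import BarcodeSpec

STATUS_OK = "ok"
STATUS_NO_ANCHOR = "no_anchor"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_LENGTH_FAIL = "length_fail"


@dataclass
class BarcodeCall:
    read_id: str
    barcode: str
    strand: str  # '+' read as-is, '-' reverse complement matched
    anchor5_edits: int
    anchor3_edits: int
    barcode_start: int  # 0-based offset in the oriented read
    status: str
    cassette_end: int = -1  # end (exclusive) of anchor3 in the oriented read


@dataclass
class ParseParams:
    max_anchor_edits: int = 2
    indel_slack: int = 1
    min_insert: int = 100
    layout: str = "single"  # "both-ends": cassette on both ends, barcodes must agree


def _locations(anchor: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """(start, end_inclusive, edits) placements of anchor at best distance <= k."""
    res = edlib.align(anchor, target, mode="HW", task="locations", k=k)
    d = res["editDistance"]
    if d < 0:
        return []
    out = []
    seen = set()
    for st, en in res["locations"]:
        st = 0 if st is None else st
        if (st, en) not in seen:
            seen.add((st, en))
            out.append((st, en, d))
    return out


def find_cassette(
    seq: str,
    spec: BarcodeSpec,
    max_anchor_edits: int = 2,
    indel_slack: int = 1,
    read_id: str = "",
    strands: tuple[str, ...] = ("+", "-"),
) -> BarcodeCall:
    """Locate the cassette and extract the barcode from one read."""
    if len(spec.anchor5) < 8 or len(spec.anchor3) < 8:
        raise ValueError("anchors must be >= 8 bases")
    bl = spec.barcode_length
    fail = BarcodeCall(read_id, "", "+", -1, -1, -1, STATUS_NO_ANCHOR)
    if len(seq) < len(spec.anchor5) + len(spec.anchor3):
        return fail

    candidates: list[tuple[int, int, int, str, int, int, int]] = []
    # (total_edits, strand_rank, barcode_start, barcode, e5, e3, cassette_end)
    saw_gap_fail = False
    for strand_rank, (strand, oriented) in enumerate(
        (("+", seq), ("-", revcomp(seq)))
    ):
        if strand not in strands:
            continue
        for st5, en5, e5 in _locations(spec.anchor5, oriented, max_anchor_edits):
            bc_start = en5 + 1
            # anchor3 must start within barcode_length +/- slack of anchor5's end
            win_lo = bc_start
            win_hi = min(
                len(oriented),
                bc_start + bl + indel_slack + len(spec.anchor3) + max_anchor_edits,
            )
            window = oriented[win_lo:win_hi]
            for st3, en3, e3 in _locations(spec.anchor3, window, max_anchor_edits):
                gap = st3  # bases between anchor5 end and anchor3 start
                if not (bl - indel_slack <= gap <= bl + indel_slack):
                    saw_gap_fail = True
                    continue
                barcode = oriented[bc_start : bc_start + gap]
                candidates.append(
                    (
                        e5 + e3,
                        strand_rank,
                        bc_start,
                        barcode,
                        e5,
                        e3,
                        win_lo + en3 + 1,
                    )
                )

    if not candidates:
        fail.status = STATUS_LENGTH_FAIL if saw_gap_fail else STATUS_NO_ANCHOR
        return fail
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best = candidates[0]
    ties = [c for c in candidates if c[0] == best[0]]
    if any(c[3] != best[3] for c in ties):
        return BarcodeCall(read_id, "", "+", -1, -1, -1, STATUS_AMBIGUOUS)
    total, strand_rank, bc_start, barcode, e5, e3, cass_end = best
    return BarcodeCall(
        read_id=read_id,
        barcode=barcode,
        strand="+" if strand_rank == 0 else "-",
        anchor5_edits=e5,
        anchor3_edits=e3,
        barcode_start=bc_start,
        status=STATUS_OK,
        cassette_end=cass_end,
    )


def extract_insert(
    seq: str, call: BarcodeCall, min_insert: int = 100
) -> tuple[str, bool]:
    """Cassette-trimmed, plus-oriented insert for an ok call.

    Returns (insert, short_flag); short inserts are flagged for exclusion
    from binning rather than dropped here.
    """
    if call.status != STATUS_OK:
        raise ValueError("extract_insert requires an ok call")
    if call.cassette_end <= call.barcode_start:
        raise ValueError("overlapping anchor placements")
    oriented = seq if call.strand == "+" else revcomp(seq)
    insert = oriented[call.cassette_end :]
    return insert, len(insert) < min_insert


@dataclass
class ParsedRead:
    call: BarcodeCall
    insert: str
    short: bool


def parse_records(
    records: Iterable[tuple[str, str]],
    spec: BarcodeSpec,
    params: ParseParams | None = None,
) -> tuple[list[ParsedRead], dict]:
    """Parse an iterable of (read_id, sequence); returns calls + a summary."""
    params = params or ParseParams()
    out: list[ParsedRead] = []
    counts = {STATUS_OK: 0, STATUS_NO_ANCHOR: 0, STATUS_AMBIGUOUS: 0, STATUS_LENGTH_FAIL: 0}
    short = 0
    for rid, seq in records:
        call = find_cassette(
            seq,
            spec,
            max_anchor_edits=params.max_anchor_edits,
            indel_slack=params.indel_slack,
            read_id=rid,
        )
        tail_trim = 0
        if call.status == STATUS_OK and params.layout == "both-ends":
            # The second cassette reads forward on the opposite orientation.
            oriented = seq if call.strand == "+" else revcomp(seq)
            second = find_cassette(
                revcomp(oriented),
                spec,
                max_anchor_edits=params.max_anchor_edits,
                indel_slack=params.indel_slack,
                strands=("+",),
            )
            if second.status != STATUS_OK:
                call = BarcodeCall(rid, "", "+", -1, -1, -1, STATUS_NO_ANCHOR)
            else:
                d = edlib.align(call.barcode, second.barcode, mode="NW", k=1)["editDistance"]
                if d < 0:
                    call = BarcodeCall(rid, "", "+", -1, -1, -1, STATUS_AMBIGUOUS)
                else:
                    tail_trim = second.cassette_end
        counts[call.status] += 1
        if call.status == STATUS_OK:
            insert, is_short = extract_insert(seq, call, min_insert=params.min_insert)
            if tail_trim:
                insert = insert[: len(insert) - tail_trim]
                is_short = len(insert) < params.min_insert
            short += is_short
            out.append(ParsedRead(call=call, insert=insert, short=is_short))
        else:
            out.append(ParsedRead(call=call, insert="", short=False))
    total = sum(counts.values())
    summary = {
        "n_reads": total,
        "counts_by_status": counts,
        "ok_rate": counts[STATUS_OK] / total if total else 0.0,
        "short_inserts": short,
    }
    return out, summary


def parse_fastq(
    path: str | Path, spec: BarcodeSpec, params: ParseParams | None = None
) -> tuple[list[ParsedRead], dict]:
    """Parse a FASTQ/FASTA file (optionally gzipped)."""
    return parse_records(read_seqs(path), spec, params)


def write_calls_tsv(parsed: Iterable[ParsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tbarcode\tstrand\tanchor5_edits\tanchor3_edits\tstatus\tshort\n")
        for p in parsed:
            c = p.call
            fh.write(
                f"{c.read_id}\t{c.barcode}\t{c.strand}\t{c.anchor5_edits}\t"
                f"{c.anchor3_edits}\t{c.status}\t{int(p.short)}\n"
            )


def iter_ok(parsed: Iterable[ParsedRead]) -> Iterator[ParsedRead]:
    for p in parsed:
        if p.call.status == STATUS_OK:
            yield p
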