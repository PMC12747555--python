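"""Shared sequence helpers: complements, k-mer encoding, FASTA/FASTQ I/O."""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit base codes; anything else maps to -1 and poisons the k-mers it touches
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to int8 codes A=0 C=1 G=2 T=3 (other symbols -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """All forward k-mers of ``seq`` as base-4 integers (int64), in order.

    k-mers containing non-ACGT symbols are dropped. Requires k <= 31 so the
    value fits in 62 bits.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    codes = encode_bases(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ weights
    ok = np.all(win >= 0, axis=1)
    return vals[ok]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) k-mer codes of ``seq``."""
    fwd = kmer_codes(seq, k)
    rev = kmer_codes(revcomp(seq), k)[::-1]
    if fwd.size != rev.size:
        # non-ACGT symbols were dropped asymmetrically; fall back to set logic
        both = np.concatenate([fwd, rev])
        return both
    return np.minimum(fwd, rev)


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, optionally gzipped.

    Format is sniffed from the first character; malformed records raise
    ValueError mentioning the record index.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "":
            return
        fmt = "fastq" if first == "@" else "fasta"
        idx = 0
        try:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
                idx += 1
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record at index {idx}: {exc}") from exc


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that pieces of length >= L hold at least half the bases."""
    arr = sorted(lengths, reverse=True)
    if not arr:
        return 0
    half = sum(arr) / 2
    acc = 0
    for ln in arr:
        acc += ln
        if acc >= half:
            return ln
    return arr[-1]
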