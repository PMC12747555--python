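"""Mock-community evaluation of demultiplexed SAGs.

Reads (or contigs) are compared against a set of reference genomes by
canonical k-mer containment: a read is assigned to the reference holding the
largest fraction of its canonical 21-mers, provided that fraction reaches
``min_kmer_frac``. From per-read assignments the module derives, per SAG:

* mapping ratio — fraction of reads assigned to any reference;
* purity — fraction of assigned reads on the majority reference, with
  external contamination defined as 1 - purity (a SAG is flagged
  high-purity when purity is strictly above 95% and low-contamination when
  contamination is strictly below 1%);
* completeness — fraction of the majority reference's canonical k-mers
  covered by the SAG's sequences;
* a quality tier: complete (100%), high (>90%), medium (50-90% with quality
  score completeness - 5 x contamination, on the percent scale, >= 10),
  draft (10-50%), else low.

k-mer containment stands in for read alignment so the evaluation is exact
and fast on synthetic data; ground-truth tables from the simulator provide
the independent comparison in tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import canonical_kmers


class ReferenceSet:
    """Reference genomes with per-genome canonical k-mer sets."""

    def __init__(self, genomes: Mapping[str, str], k: int = 21):
        if not (15 <= k <= 31) or k % 2 == 0:
            raise ValueError("k must be odd and within [15, 31]")
        self.k = k
        self.genomes = dict(genomes)
        self.kmers: dict[str, np.ndarray] = {
            name: np.unique(canonical_kmers(seq, k)) for name, seq in self.genomes.items()
        }
        self.names = sorted(self.kmers)


@dataclass
class SAGMetrics:
    sag_id: str
    n_reads: int
    mapping_ratio: float
    purity: float | None
    external_contamination: float | None
    majority_reference: str | None
    completeness: float
    tier: str
    high_purity: bool
    low_contamination: bool


def _contained_fraction(kmers: np.ndarray, ref: np.ndarray) -> float:
    if kmers.size == 0 or ref.size == 0:
        return 0.0
    idx = np.searchsorted(ref, kmers)
    idx[idx >= ref.size] = ref.size - 1
    return float(np.mean(ref[idx] == kmers))


def assign_read(seq: str, refset: ReferenceSet, min_kmer_frac: float = 0.5) -> str | None:
    """Assign one sequence to a reference by canonical k-mer containment."""
    if len(seq) < refset.k:
        return None
    kmers = canonical_kmers(seq, refset.k)
    best_name, best_score, tie = None, -1.0, False
    for name in refset.names:
        score = _contained_fraction(kmers, refset.kmers[name])
        if score > best_score:
            best_name, best_score, tie = name, score, False
        elif score == best_score:
            tie = True
    if tie or best_score < min_kmer_frac:
        return None
    return best_name


def completeness(seqs: Iterable[str], refset: ReferenceSet, reference: str) -> float:
    """Fraction of the reference's canonical k-mers covered by ``seqs``."""
    ref = refset.kmers[reference]
    if ref.size == 0:
        return 0.0
    parts = [canonical_kmers(s, refset.k) for s in seqs if len(s) >= refset.k]
    if not parts:
        return 0.0
    covered = np.unique(np.concatenate(parts))
    idx = np.searchsorted(ref, covered)
    idx[idx >= ref.size] = ref.size - 1
    return float(np.sum(ref[idx] == covered) / ref.size)


def tier(comp: float, contamination: float) -> str:
    """Quality tier from completeness and contamination (both in [0,1]).

    Bands are lower-bound inclusive and upper exclusive, except that the
    medium band closes at 0.90 (the high tier starts strictly above 90%, so
    exactly-90% genomes are medium-grade, matching the 50-90% convention).
    The medium band additionally requires the MIMAG-style quality score
    (completeness - 5 x contamination, percent scale) to reach 10.
    """
    if not (0.0 <= comp <= 1.0) or not (0.0 <= contamination <= 1.0):
        raise ValueError("completeness and contamination must be in [0,1]")
    if comp == 1.0:
        return "complete"
    if comp > 0.90:
        return "high"
    if 0.50 <= comp <= 0.90:
        score = comp * 100 - 5 * contamination * 100
        if score >= 10:
            return "medium"
    if 0.10 <= comp < 0.50:
        return "draft"
    return "low"


def sag_metrics(
    sag_id: str,
    reads: Sequence[str],
    refset: ReferenceSet,
    min_kmer_frac: float = 0.5,
) -> SAGMetrics:
    """Per-SAG evaluation from its read (or contig) sequences."""
    if not reads:
        raise ValueError("sag_metrics requires >= 1 read")
    assigned: dict[str, int] = {}
    n_any = 0
    for seq in reads:
        ref = assign_read(seq, refset, min_kmer_frac)
        if ref is not None:
            n_any += 1
            assigned[ref] = assigned.get(ref, 0) + 1
    mapping_ratio = n_any / len(reads)
    if n_any == 0:
        return SAGMetrics(
            sag_id, len(reads), 0.0, None, None, None, 0.0, "low", False, False
        )
    majority = max(assigned, key=lambda r: (assigned[r], r))
    purity = assigned[majority] / n_any
    contamination = 1.0 - purity
    comp = completeness(reads, refset, majority)
    return SAGMetrics(
        sag_id=sag_id,
        n_reads=len(reads),
        mapping_ratio=mapping_ratio,
        purity=purity,
        external_contamination=contamination,
        majority_reference=majority,
        completeness=comp,
        tier=tier(comp, contamination),
        high_purity=purity > 0.95,
        low_contamination=contamination < 0.01,
    )


def evaluate_sags(
    sag_reads: Mapping[str, Sequence[str]],
    refset: ReferenceSet,
    min_kmer_frac: float = 0.5,
) -> pd.DataFrame:
    """Metrics table over all SAGs (one row per SAG)."""
    rows = []
    for sag in sorted(sag_reads):
        m = sag_metrics(sag, list(sag_reads[sag]), refset, min_kmer_frac)
        rows.append(vars(m))
    return pd.DataFrame(rows)


def abundance_recovery(
    majority_refs: Sequence[str | None],
    expected: Mapping[str, float],
) -> tuple[pd.DataFrame, float]:
    """Observed vs expected per-genome fractions over classified SAGs.

    Observed fraction of genome g = SAGs with majority reference g divided by
    the number of classified SAGs; returns the table and the maximum
    absolute deviation from the expected proportions.
    """
    classified = [r for r in majority_refs if r is not None]
    if not classified:
        raise ValueError("no classified SAGs")
    total = len(classified)
    rows = []
    max_dev = 0.0
    for name in sorted(expected):
        obs = sum(1 for r in classified if r == name) / total
        dev = abs(obs - expected[name])
        max_dev = max(max_dev, dev)
        rows.append({"genome": name, "expected": expected[name], "observed": obs, "deviation": dev})
    return pd.DataFrame(rows), max_dev


def tier_histogram(tiers: Iterable[str]) -> dict[str, int]:
    out = {"complete": 0, "high": 0, "medium": 0, "draft": 0, "low": 0}
    for t in tiers:
        out[t] += 1
    return out
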