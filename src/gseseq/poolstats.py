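"""Statistics of a random droplet-barcode pool.

A droplet barcode here is a string of ``barcode_length`` random bases flanked
by two constant PCR handles (anchors). With 19 random bases over {A,C,G,T}
the sequence space holds 4^19 ~ 2.7e11 distinct barcodes, so a pool of a few
billion oligos drawn at random stays almost entirely collision-free. This
module quantifies that claim two ways:

* the closed-form expected fraction of drawn barcodes that are not unique
  under uniform sampling **with replacement** (random oligo synthesis draws
  with replacement, which is why the closed form below and not the
  permutation formula applies), and
* a Monte-Carlo estimate of the same fraction at desk scale, used as an
  independent check of the closed form.

A third view — how many realized barcode pairs sit within a small Levenshtein
radius of each other — measures how safely downstream error-tolerant
clustering can merge sequencing errors without merging distinct droplets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np

# Generic Illumina-style PCR handles used as default cassette anchors. Any
# pair of >=8 bp ACGT strings works; real runs supply their own.
DEFAULT_ANCHOR5 = "CTACACGACGCTCTTCCGATCT"
DEFAULT_ANCHOR3 = "AGATCGGAAGAGCGGTTCAGCA"

_MC_MAX_POOL = 10_000_000


@dataclass(frozen=True)
class BarcodeSpec:
    """Architecture of the barcode cassette shared by every pipeline stage."""

    barcode_length: int = 19
    alphabet: str = "ACGT"
    anchor5: str = DEFAULT_ANCHOR5
    anchor3: str = DEFAULT_ANCHOR3

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ValueError("alphabet must hold >= 2 distinct symbols")
        if "N" in self.alphabet:
            raise ValueError("N is not allowed in the alphabet")
        for name in ("anchor5", "anchor3"):
            anchor = getattr(self, name)
            if any(c not in self.alphabet for c in anchor):
                raise ValueError(f"{name} contains symbols outside the alphabet")

    @property
    def space_size(self) -> int:
        return space_size(self)

    @property
    def cassette_length(self) -> int:
        return len(self.anchor5) + self.barcode_length + len(self.anchor3)


@dataclass(frozen=True)
class PoolDesign:
    """A realized pool: ``pool_size`` barcodes drawn from the spec's space."""

    spec: BarcodeSpec = field(default_factory=BarcodeSpec)
    pool_size: int = 5_000_000_000
    edit_radius: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.pool_size <= self.spec.space_size:
            raise ValueError("pool_size must satisfy 0 < pool_size <= space_size")
        if self.edit_radius < 0:
            raise ValueError("edit_radius must be >= 0")


def space_size(spec: BarcodeSpec) -> int:
    """Exact number of distinct barcode sequences, |alphabet|^length.

    Computed in arbitrary-precision integer arithmetic; never a float.
    """
    return len(spec.alphabet) ** spec.barcode_length


def expected_collision_fraction(design: PoolDesign) -> float:
    """Expected fraction of drawn barcodes whose sequence is not unique.

    With N = space_size and n = pool_size drawn uniformly with replacement,
    the expected number of distinct sequences observed is N*(1-(1-1/N)^n),
    so the non-unique (collision) fraction is 1 - N*(1-(1-1/N)^n)/n.
    Evaluated via log1p/expm1 so it stays accurate for n/N << 1.
    """
    n = design.pool_size
    big_n = design.spec.space_size
    if n == 1:
        return 0.0
    t = n * math.log1p(-1.0 / big_n)
    # 1 - N*(1-e^t)/n  ==  1 + (N/n)*expm1(t)
    frac = 1.0 + (big_n / n) * math.expm1(t)
    return min(max(frac, 0.0), 1.0)


def collision_fraction_mc(
    design: PoolDesign, replicates: int = 20, seed: int = 1
) -> tuple[float, float]:
    """Monte-Carlo collision fraction: (mean, standard error) over replicates.

    Each replicate draws ``pool_size`` barcodes uniformly (as integers in the
    sequence space) and measures the collision fraction as the excess-draw
    fraction (n - #distinct)/n — i.e. the fraction of draws that repeat an
    already-drawn sequence. This is the empirical counterpart of the closed
    form in :func:`expected_collision_fraction` (counting every member of a
    duplicated value instead would double-count each collision and sit ~2x
    above the closed form).
    """
    n = design.pool_size
    big_n = design.spec.space_size
    if n > _MC_MAX_POOL:
        raise ValueError(
            f"pool_size {n} too large to sample; use expected_collision_fraction"
        )
    if big_n >= 2**63:
        raise ValueError("sequence space too large for integer sampling; use the analytic path")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    fracs = np.empty(replicates)
    for i in range(replicates):
        draws = rng.integers(0, big_n, size=n)
        n_distinct = np.unique(draws).size
        fracs[i] = (n - n_distinct) / n
    mean = float(fracs.mean())
    se = float(fracs.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
    return mean, se


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


def _lev(a: str, b: str, k: int | None = None) -> int:
    res = edlib.align(a, b, mode="NW", k=-1 if k is None else k)
    return res["editDistance"]


def min_pairwise_distance_profile(barcodes: list[str], radius: int) -> int:
    """Count unordered barcode pairs within Levenshtein distance <= radius.

    Candidate pairs are found through a symmetric-deletion neighborhood index
    (two strings within edit distance d always share a variant after at most
    d deletions each) and then verified exactly, so the count equals the
    all-pairs brute force without quadratic scanning.
    """
    if radius > 2:
        raise ValueError("radius > 2 is not supported (complexity guard)")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    index: dict[str, list[int]] = {}
    for i, bc in enumerate(barcodes):
        for var in _deletion_variants(bc, radius):
            index.setdefault(var, []).append(i)
    cand: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) > 1:
            for i, j in combinations(members, 2):
                cand.add((i, j) if i < j else (j, i))
    count = 0
    for i, j in sorted(cand):
        d = _lev(barcodes[i], barcodes[j], k=radius)
        if 0 <= d <= radius:
            count += 1
    return count


def pool_report(design: PoolDesign, mc: bool = False, replicates: int = 20, seed: int = 1) -> dict:
    """JSON-ready summary of a pool design."""
    report: dict = {
        "barcode_length": design.spec.barcode_length,
        "alphabet": design.spec.alphabet,
        "space_size": design.spec.space_size,
        "pool_size": design.pool_size,
        "expected_collision_fraction": expected_collision_fraction(design),
    }
    if mc:
        est, se = collision_fraction_mc(design, replicates=replicates, seed=seed)
        report["mc_estimate"] = est
        report["mc_se"] = se
        report["mc_replicates"] = replicates
    return report
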