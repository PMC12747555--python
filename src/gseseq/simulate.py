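"""Synthetic droplet-barcoded long-read library with full ground truth.

The generator emulates a mock-community single-entity sequencing experiment:
reference genomes are encapsulated into droplets (Poisson loading, so a small
fraction of droplets are doublets), whole-genome amplified with uneven,
heavy-tailed coverage (log-normal per-window weights standing in for MDA
bias), fragmented, barcoded with a cassette of two PCR handles flanking a
random barcode, and sequenced as HiFi-like reads (~Q30: low substitution and
indel rates) with a small ambient-DNA fraction whose reads carry the
droplet's barcode but a foreign genome's sequence.

Fragmentation is modeled as cutting linear amplicons: a fragment is anchored
at a bias-weighted window and extended by a log-normal length draw, truncated
at the genome ends, so terminal fragments that start or end exactly at the
genome boundary occur at a realistic rate. Read lengths are log-normal with
the location parameter set to ln(N50) - sigma^2, which makes the realized,
length-weighted median (the N50) land on the requested target.

Every read and droplet is recorded in a ground-truth table, which downstream
modules use for parameter-recovery checks.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp, write_fasta, write_fastq
from .poolstats import BarcodeSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_MIN_FRAGMENT = 50


@dataclass(frozen=True)
class GenomeSpec:
    """One community member: an explicit sequence, a FASTA path, or a
    (length, GC) recipe for a random genome."""

    name: str
    length: int | None = None
    gc: float = 0.5
    sequence: str | None = None
    path: str | None = None


@dataclass(frozen=True)
class CommunitySpec:
    genomes: tuple[GenomeSpec, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genome names")
        if len(self.abundances) != len(self.genomes):
            raise ValueError("abundances must match genomes")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be >= 0")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    Error-rate defaults (sub 1e-3, ins/del 3e-4) correspond to HiFi-like
    reads of which the large majority are >= Q30; the N50 target of 1.7 kb
    matches the library scale this simulator emulates. ``lambda_load=0`` is
    the zero-loading limit: every occupied droplet holds exactly one entity.
    """

    n_droplets: int = 300
    lambda_load: float = 0.1
    spec: BarcodeSpec = field(default_factory=BarcodeSpec)
    pool_size: int = 5_000_000_000
    reads_per_droplet_mean: float = 35.0
    wga_bias_sigma: float = 1.0
    wga_window: int = 500
    read_len_n50_target: int = 1700
    read_len_sigma: float = 0.45
    sub_rate: float = 0.001
    ins_rate: float = 0.0003
    del_rate: float = 0.0003
    barcode_error_rate: float = 0.005
    ambient_fraction: float = 0.01
    layout: str = "single"  # or "both-ends"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "barcode_error_rate", "ambient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.read_len_n50_target < 200:
            raise ValueError("read_len_n50_target must be >= 200")
        if self.layout not in ("single", "both-ends"):
            raise ValueError("layout must be 'single' or 'both-ends'")


@dataclass
class SimResult:
    reads: list[tuple[str, str, str]]  # (id, sequence, quality)
    read_truth: pd.DataFrame
    droplet_truth: pd.DataFrame
    genomes: dict[str, str]
    config: SimConfig
    community: CommunitySpec

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(outdir / "reads.fastq", self.reads)
        self.read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        self.droplet_truth.to_csv(outdir / "droplet_truth.tsv", sep="\t", index=False)
        write_fasta(outdir / "genomes.fasta", self.genomes.items())
        cfg = dataclasses.asdict(self.config)
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(cfg, fh, indent=2)


def _random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytes(_BASES[codes]).decode()


def generate_genomes(community: CommunitySpec, seed: int) -> dict[str, str]:
    """Materialize community genomes; random ones are deterministic per seed."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for g in community.genomes:
        if g.sequence is not None:
            seq = g.sequence.upper()
        elif g.path is not None:
            from ._util import read_seqs

            seq = "".join(s for _, s in read_seqs(g.path))
        else:
            if g.length is None:
                raise ValueError(f"genome {g.name}: need sequence, path, or length")
            if not 0.0 <= g.gc <= 1.0:
                raise ValueError(f"genome {g.name}: gc must be in [0,1]")
            seq = _random_genome(g.length, g.gc, rng)
        if len(seq) < 1000:
            raise ValueError(f"genome {g.name}: length must be >= 1 kb")
        out[g.name] = seq
    return out


def make_strain_community(
    n_strains: int = 3,
    ancestor_length: int = 12_000,
    divergence: float = 0.005,
    gc: float = 0.5,
    seed: int = 0,
    name_prefix: str = "strain",
) -> CommunitySpec:
    """Community of related strains: one random ancestor, each strain carrying
    independent substitutions at the given per-base rate. Emulates the
    within-community microdiversity that confounds pooled assembly."""
    rng = np.random.default_rng(seed)
    ancestor = _random_genome(ancestor_length, gc, rng)
    codes = _CODE[np.frombuffer(ancestor.encode(), dtype=np.uint8)].astype(np.int64)
    genomes = []
    for i in range(n_strains):
        mut = codes.copy()
        hit = rng.random(ancestor_length) < divergence
        shift = rng.integers(1, 4, size=ancestor_length)
        mut[hit] = (mut[hit] + shift[hit]) % 4
        genomes.append(
            GenomeSpec(name=f"{name_prefix}{i + 1}", sequence=bytes(_BASES[mut]).decode())
        )
    ab = tuple([1.0 / n_strains] * n_strains)
    return CommunitySpec(genomes=tuple(genomes), abundances=ab)


def _zt_poisson(lam: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson; lam=0 degenerates to exactly one entity."""
    if lam <= 0:
        return 1
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


def _apply_errors(
    seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> str:
    if sub == 0 and ins == 0 and dele == 0:
        return seq
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    L = codes.size
    keep = rng.random(L) >= dele
    do_sub = rng.random(L) < sub
    shift = rng.integers(1, 4, size=L)
    codes = np.where(do_sub, (codes + shift) % 4, codes)
    do_ins = rng.random(L) < ins
    counts = keep.astype(np.int64) + do_ins
    out = np.repeat(codes, counts)
    n_ins = int(do_ins.sum())
    if n_ins:
        ends = np.cumsum(counts) - 1
        out[ends[do_ins]] = rng.integers(0, 4, size=n_ins)
    return bytes(_BASES[out]).decode()


def _corrupt_barcode(bc: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return bc
    codes = _CODE[np.frombuffer(bc.encode(), dtype=np.uint8)].astype(np.int64)
    hit = rng.random(codes.size) < rate
    if not hit.any():
        return bc
    shift = rng.integers(1, 4, size=codes.size)
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return bytes(_BASES[codes]).decode()


def _random_barcode(spec: BarcodeSpec, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(spec.alphabet), size=spec.barcode_length)
    return "".join(spec.alphabet[i] for i in idx)


def simulate_droplets(
    community: CommunitySpec,
    config: SimConfig,
    genomes: dict[str, str] | None = None,
) -> SimResult:
    """Run the droplet simulation; deterministic given (community, config)."""
    if config.pool_size < config.n_droplets:
        raise ValueError("pool_size < n_droplets: each droplet draws a pool barcode")
    rng = np.random.default_rng(config.seed)
    if genomes is None:
        genomes = generate_genomes(community, seed=config.seed)
    names = [g.name for g in community.genomes]
    abund = np.asarray(community.abundances, dtype=float)
    abund = abund / abund.sum()
    spec = config.spec

    # Pool draw: each droplet picks a uniform pool slot; distinct slots get
    # i.i.d. uniform barcodes, so a slot collision reproduces a pool collision
    # without materializing billions of oligos.
    slots = rng.integers(0, config.pool_size, size=config.n_droplets)
    slot_barcodes: dict[int, str] = {}
    for s in sorted(set(slots.tolist())):
        slot_barcodes[s] = _random_barcode(spec, rng)
    droplet_barcodes = [slot_barcodes[int(s)] for s in slots]

    # Droplet composition + per-entity WGA window weights.
    droplet_entities: list[list[str]] = []
    droplet_weights: list[list[np.ndarray]] = []
    for _ in range(config.n_droplets):
        k = _zt_poisson(config.lambda_load, rng)
        ents = [names[i] for i in rng.choice(len(names), size=k, p=abund)]
        weights = []
        for gname in ents:
            nwin = math.ceil(len(genomes[gname]) / config.wga_window)
            if config.wga_bias_sigma > 0:
                w = rng.lognormal(0.0, config.wga_bias_sigma, size=nwin)
            else:
                w = np.ones(nwin)
            weights.append(w / w.sum())
        droplet_entities.append(ents)
        droplet_weights.append(weights)

    n_reads_per_droplet = rng.poisson(config.reads_per_droplet_mean, size=config.n_droplets)

    mu_len = math.log(config.read_len_n50_target) - config.read_len_sigma**2

    def sample_fragment(ents: list[str], weights: list[np.ndarray]) -> tuple[str, int, int]:
        ei = int(rng.integers(0, len(ents))) if len(ents) > 1 else 0
        gname = ents[ei]
        L = len(genomes[gname])
        w = weights[ei]
        j = int(rng.choice(w.size, p=w))
        lo = j * config.wga_window
        hi = min(L, lo + config.wga_window)
        length = max(_MIN_FRAGMENT, int(round(rng.lognormal(mu_len, config.read_len_sigma))))
        if rng.random() < 0.5:
            start = int(rng.integers(lo, hi))
            end = min(start + length, L)
        else:
            end = int(rng.integers(lo, hi)) + 1
            start = max(end - length, 0)
        if end - start < _MIN_FRAGMENT:
            start = max(0, end - _MIN_FRAGMENT)
            end = min(L, start + _MIN_FRAGMENT)
        return gname, start, end

    reads: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    read_counter = 0
    for d in range(config.n_droplets):
        bc_true = droplet_barcodes[d]
        for _ in range(int(n_reads_per_droplet[d])):
            is_ambient = (
                config.n_droplets > 1 and rng.random() < config.ambient_fraction
            )
            if is_ambient:
                o = int(rng.integers(0, config.n_droplets - 1))
                if o >= d:
                    o += 1
                gname, start, end = sample_fragment(droplet_entities[o], droplet_weights[o])
            else:
                gname, start, end = sample_fragment(droplet_entities[d], droplet_weights[d])
            frag = genomes[gname][start:end]
            strand = "+" if rng.random() < 0.5 else "-"
            insert = frag if strand == "+" else revcomp(frag)
            bc_obs = _corrupt_barcode(bc_true, config.barcode_error_rate, rng)
            cassette = spec.anchor5 + bc_obs + spec.anchor3
            if config.layout == "both-ends":
                molecule = cassette + insert + revcomp(cassette)
            else:
                molecule = cassette + insert
            molecule = _apply_errors(
                molecule, config.sub_rate, config.ins_rate, config.del_rate, rng
            )
            if rng.random() < 0.5:
                molecule = revcomp(molecule)
            rid = f"r{read_counter:07d}"
            read_counter += 1
            reads.append((rid, molecule, "?" * len(molecule)))
            truth_rows.append(
                (rid, d, bc_true, gname, start, end, strand, is_ambient)
            )

    read_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "droplet_id",
            "true_barcode",
            "source_genome",
            "source_start",
            "source_end",
            "strand",
            "is_ambient",
        ],
    )
    droplet_truth = pd.DataFrame(
        {
            "droplet_id": range(config.n_droplets),
            "true_barcode": droplet_barcodes,
            "genomes": [",".join(sorted(set(e))) for e in droplet_entities],
            "entity_count": [len(e) for e in droplet_entities],
            "n_reads": n_reads_per_droplet,
        }
    )
    return SimResult(
        reads=reads,
        read_truth=read_truth,
        droplet_truth=droplet_truth,
        genomes=genomes,
        config=config,
        community=community,
    )
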