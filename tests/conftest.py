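"""Shared fixtures: small communities and cached expensive simulation runs."""
from __future__ import annotations

import numpy as np
import pytest

import gseseq as g


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def mock_community() -> g.CommunitySpec:
    """Three unrelated 40 kb genomes at uneven abundances."""
    return g.CommunitySpec(
        genomes=tuple(g.GenomeSpec(name=f"phage{i + 1}", length=40_000, gc=0.5) for i in range(3)),
        abundances=(0.5, 0.3, 0.2),
    )


@pytest.fixture(scope="session")
def small_community() -> g.CommunitySpec:
    return g.CommunitySpec(
        genomes=(g.GenomeSpec(name="a", length=20_000, gc=0.5),),
        abundances=(1.0,),
    )


def _run_demux(community: g.CommunitySpec, cfg: g.SimConfig):
    res = g.simulate_droplets(community, cfg)
    parsed, summary = g.parse_records(((r, s) for r, s, _ in res.reads), cfg.spec)
    counts = g.barcode_counts(parsed)
    table = g.cluster_barcodes(counts)
    assignments, asg_summary = g.assign_reads(parsed, table)
    sags = g.sag_read_sets(parsed, assignments)
    return {
        "sim": res,
        "parsed": parsed,
        "parse_summary": summary,
        "table": table,
        "assignments": assignments,
        "assign_summary": asg_summary,
        "sags": sags,
    }


@pytest.fixture(scope="session")
def noisy_run(mock_community):
    """Default-error-rate mock run: 3 genomes, 300 droplets, seed 1."""
    cfg = g.SimConfig(n_droplets=300, seed=1)
    return _run_demux(mock_community, cfg)


@pytest.fixture(scope="session")
def zero_noise_run(mock_community):
    """Noise-free limit: no errors, no ambient DNA, single-entity droplets."""
    cfg = g.SimConfig(
        n_droplets=300,
        seed=1,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        barcode_error_rate=0.0,
        ambient_fraction=0.0,
        lambda_load=0.0,
    )
    return _run_demux(mock_community, cfg)


@pytest.fixture(scope="session")
def strategy_run(tmp_path_factory):
    """The mixed-strain strategy-comparison demo (DA vs BCA vs SAGb)."""
    outdir = tmp_path_factory.mktemp("strategy_demo")
    cfg = g.strategy_demo_config(outdir=str(outdir), seed=1)
    report = g.run_pipeline(cfg)
    return report
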