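"""Simulator: determinism, genome composition, droplet loading, read-length
and error-rate calibration, coverage uniformity in the no-bias limit."""
import math

import numpy as np
import pytest
from scipy.stats import chisquare

import gseseq as g
from gseseq._util import n50, revcomp


def single_genome_community(length=20_000, gc=0.5):
    return g.CommunitySpec(genomes=(g.GenomeSpec(name="a", length=length, gc=gc),), abundances=(1.0,))


class TestGenerateGenomes:
    def test_deterministic(self):
        comm = g.CommunitySpec(
            genomes=tuple(g.GenomeSpec(name=f"g{i}", length=40_000, gc=0.5) for i in range(3)),
            abundances=(1 / 3, 1 / 3, 1 / 3),
        )
        a = g.generate_genomes(comm, seed=7)
        b = g.generate_genomes(comm, seed=7)
        assert a == b
        c = g.generate_genomes(comm, seed=8)
        assert a != c

    def test_gc_zero_gives_at_only(self):
        comm = single_genome_community(gc=0.0)
        seq = g.generate_genomes(comm, seed=1)["a"]
        assert set(seq) <= {"A", "T"}

    def test_gc_fraction_recovered(self):
        comm = g.CommunitySpec(
            genomes=(g.GenomeSpec(name="a", length=50_000, gc=0.44),), abundances=(1.0,)
        )
        seq = g.generate_genomes(comm, seed=3)["a"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.42 <= gc <= 0.46

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            g.CommunitySpec(
                genomes=(g.GenomeSpec(name="a", length=2000), g.GenomeSpec(name="a", length=2000)),
                abundances=(0.5, 0.5),
            )

    def test_abundances_validated(self):
        with pytest.raises(ValueError):
            g.CommunitySpec(genomes=(g.GenomeSpec(name="a", length=2000),), abundances=(0.9,))


class TestSimulateDroplets:
    def test_byte_identical_on_same_seed(self):
        comm = single_genome_community()
        cfg = g.SimConfig(n_droplets=20, seed=9)
        r1 = g.simulate_droplets(comm, cfg)
        r2 = g.simulate_droplets(comm, cfg)
        assert r1.reads == r2.reads
        assert r1.read_truth.equals(r2.read_truth)
        assert r1.droplet_truth.equals(r2.droplet_truth)

    def test_read_counts_conserved(self):
        comm = single_genome_community()
        res = g.simulate_droplets(comm, g.SimConfig(n_droplets=50, seed=2))
        assert len(res.reads) == int(res.droplet_truth.n_reads.sum())
        assert len(res.read_truth) == len(res.reads)

    def test_pool_smaller_than_droplets_rejected(self):
        comm = single_genome_community()
        with pytest.raises(ValueError, match="pool_size"):
            g.simulate_droplets(comm, g.SimConfig(n_droplets=10, pool_size=5, seed=1))

    def test_zero_noise_reads_match_reference_exactly(self):
        comm = single_genome_community()
        cfg = g.SimConfig(
            n_droplets=10, seed=4, sub_rate=0, ins_rate=0, del_rate=0,
            barcode_error_rate=0, ambient_fraction=0, lambda_load=0,
        )
        res = g.simulate_droplets(comm, cfg)
        genome = res.genomes["a"]
        truth = res.read_truth.set_index("read_id")
        for rid, seq, _ in res.reads:
            t = truth.loc[rid]
            frag = genome[t.source_start : t.source_end]
            insert = frag if t.strand == "+" else revcomp(frag)
            mol = cfg.spec.anchor5 + t.true_barcode + cfg.spec.anchor3 + insert
            assert seq == mol or seq == revcomp(mol)

    def test_doublet_fraction_matches_truncated_poisson(self):
        comm = single_genome_community()
        lam = 0.1
        cfg = g.SimConfig(n_droplets=1000, lambda_load=lam, reads_per_droplet_mean=1, seed=4)
        res = g.simulate_droplets(comm, cfg)
        frac = float((res.droplet_truth.entity_count >= 2).mean())
        expect = (1 - math.exp(-lam) * (1 + lam)) / (1 - math.exp(-lam))
        se = math.sqrt(expect * (1 - expect) / 1000)
        assert abs(frac - expect) <= 3 * se

    def test_read_n50_within_ten_percent_of_target(self, noisy_run):
        lens = [len(s) for _, s, _ in noisy_run["sim"].reads]
        assert 1530 <= n50(lens) <= 1870

    def test_substitution_rate_recovered(self):
        comm = single_genome_community()
        cfg = g.SimConfig(
            n_droplets=60, seed=5, ins_rate=0, del_rate=0,
            barcode_error_rate=0, ambient_fraction=0, lambda_load=0,
        )
        res = g.simulate_droplets(comm, cfg)
        genome = res.genomes["a"]
        truth = res.read_truth.set_index("read_id")
        mism = tot = 0
        for rid, seq, _ in res.reads:
            t = truth.loc[rid]
            frag = genome[t.source_start : t.source_end]
            insert = frag if t.strand == "+" else revcomp(frag)
            mol = cfg.spec.anchor5 + t.true_barcode + cfg.spec.anchor3 + insert
            m = min(
                sum(a != b for a, b in zip(seq, mol)),
                sum(a != b for a, b in zip(revcomp(seq), mol)),
            )
            mism += m
            tot += len(mol)
        assert tot >= 1_000_000
        assert abs(mism / tot - cfg.sub_rate) <= 0.2 * cfg.sub_rate

    def test_unbiased_coverage_is_uniform_in_interior(self):
        """With wga_bias_sigma=0, fragment anchors are uniform; test interior
        windows (the truncation zone near genome ends is excluded because
        linear-genome edge effects are physical, not bias)."""
        comm = single_genome_community()
        cfg = g.SimConfig(
            n_droplets=1, seed=6, wga_bias_sigma=0, reads_per_droplet_mean=800,
            lambda_load=0, ambient_fraction=0,
        )
        res = g.simulate_droplets(comm, cfg)
        wins = res.read_truth.source_start.to_numpy() // cfg.wga_window
        counts = np.bincount(wins, minlength=40)
        _, p = chisquare(counts[8:32])
        assert p > 0.001

    def test_ambient_reads_flagged_and_foreign(self):
        comm = g.CommunitySpec(
            genomes=(g.GenomeSpec(name="a", length=20_000), g.GenomeSpec(name="b", length=20_000)),
            abundances=(0.5, 0.5),
        )
        cfg = g.SimConfig(n_droplets=100, seed=8, ambient_fraction=0.2, lambda_load=0)
        res = g.simulate_droplets(comm, cfg)
        amb = res.read_truth[res.read_truth.is_ambient]
        assert len(amb) > 0
        # ambient reads keep the droplet's barcode by construction
        bc = dict(zip(res.droplet_truth.droplet_id, res.droplet_truth.true_barcode))
        assert all(row.true_barcode == bc[row.droplet_id] for row in amb.itertuples())


class TestStrainCommunity:
    def test_divergence_scales_with_rate(self):
        comm = g.make_strain_community(n_strains=2, ancestor_length=10_000, divergence=0.01, seed=1)
        s1, s2 = (gs.sequence for gs in comm.genomes)
        diff = sum(a != b for a, b in zip(s1, s2)) / len(s1)
        # two independent 1% mutation loads: pairwise ~2% minus coincidences
        assert 0.01 <= diff <= 0.03
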