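"""End-to-end orchestration: simulate -> extract -> cluster -> assemble -> evaluate.

Stages hand data to each other through files (FASTQ/TSV/FASTA/JSON) written
under the run's output directory, so any stage can be re-run individually or
replaced by an external tool. The run report aggregates per-stage summaries:
read counts by parse status, SAG counts, tier histograms, and the DA/BCA/SAGb
strategy-comparison table. Re-running with the same config and seed
reproduces every output byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assemble as asm
from . import cluster as clu
from . import evaluate as ev
from . import readparse as rp
from . import simulate as sim
from ._util import n50 as _n50, write_fasta
from .poolstats import BarcodeSpec

log = logging.getLogger("gseseq")

ALL_STAGES = ("simulate", "extract", "cluster", "assemble", "evaluate")


@dataclass
class RunConfig:
    """Parameters for every stage plus run-level bookkeeping."""

    outdir: str = "gse_run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES

    # community (used when no external genomes are supplied)
    n_genomes: int = 3
    genome_length: int = 40_000
    gc: float = 0.5
    abundances: tuple[float, ...] | None = None
    strain_divergence: float | None = None  # if set, genomes are related strains

    # simulate
    n_droplets: int = 300
    lambda_load: float = 0.1
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
    layout: str = "single"

    # barcode spec
    barcode_length: int = 19
    anchor5: str | None = None
    anchor3: str | None = None

    # extract
    max_anchor_edits: int = 2
    indel_slack: int = 1
    min_insert: int = 100

    # cluster
    cluster_d: int = 2
    cluster_ratio: float = 5.0
    min_reads: int = 10

    # assemble
    strategies: tuple[str, ...] = ("DA", "BCA", "SAGb")
    assembler: str = "builtin"
    min_overlap: int = 40
    max_mismatch_frac: float = 0.02
    min_contig: int = 500

    # evaluate
    k: int = 21
    min_kmer_frac: float = 0.5

    def barcode_spec(self) -> BarcodeSpec:
        kw = {"barcode_length": self.barcode_length}
        if self.anchor5:
            kw["anchor5"] = self.anchor5
        if self.anchor3:
            kw["anchor3"] = self.anchor3
        return BarcodeSpec(**kw)

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(
            n_droplets=self.n_droplets,
            lambda_load=self.lambda_load,
            spec=self.barcode_spec(),
            pool_size=self.pool_size,
            reads_per_droplet_mean=self.reads_per_droplet_mean,
            wga_bias_sigma=self.wga_bias_sigma,
            wga_window=self.wga_window,
            read_len_n50_target=self.read_len_n50_target,
            read_len_sigma=self.read_len_sigma,
            sub_rate=self.sub_rate,
            ins_rate=self.ins_rate,
            del_rate=self.del_rate,
            barcode_error_rate=self.barcode_error_rate,
            ambient_fraction=self.ambient_fraction,
            layout=self.layout,
            seed=self.seed,
        )

    def community(self) -> sim.CommunitySpec:
        if self.strain_divergence is not None:
            return sim.make_strain_community(
                n_strains=self.n_genomes,
                ancestor_length=self.genome_length,
                divergence=self.strain_divergence,
                gc=self.gc,
                seed=self.seed,
            )
        genomes = tuple(
            sim.GenomeSpec(name=f"genome{i + 1}", length=self.genome_length, gc=self.gc)
            for i in range(self.n_genomes)
        )
        ab = self.abundances or tuple([1.0 / self.n_genomes] * self.n_genomes)
        return sim.CommunitySpec(genomes=genomes, abundances=ab)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "strategies", "abundances"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def compare_strategies(results: dict[str, asm.StrategyResult]) -> dict:
    """Fold-change table of aggregate stats for barcode-aware strategies vs DA."""
    if "DA" not in results:
        raise ValueError("strategy comparison requires a DA run")
    others = [s for s in results if s != "DA"]
    if not others:
        raise ValueError("strategy comparison requires >= 1 barcode-aware strategy")
    da = results["DA"].aggregate
    table = {}
    for name in sorted(others):
        st = results[name].aggregate

        def ratio(a: float, b: float) -> float | None:
            return a / b if b else None

        table[f"{name}/DA"] = {
            "max_len": ratio(st.max_len, da.max_len),
            "total_len": ratio(st.total_len, da.total_len),
            "n_contigs": ratio(st.n_contigs, da.n_contigs),
            "count_gt_2kb": ratio(st.count_gt_2kb, da.count_gt_2kb),
            "count_gt_10kb": ratio(st.count_gt_10kb, da.count_gt_10kb),
            "max_len_below_da": st.max_len < da.max_len,
        }
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    spec = config.barcode_spec()
    t0 = time.time()

    state: dict = {}
    try:
        if "simulate" in config.stages:
            log.info("stage: simulate")
            community = config.community()
            result = sim.simulate_droplets(community, config.sim_config())
            result.write(outdir)
            state["sim"] = result
            read_lens = [len(s) for _, s, _ in result.reads]
            report["stages"]["simulate"] = {
                "n_reads": len(result.reads),
                "n_droplets": config.n_droplets,
                "read_n50": _n50(read_lens),
                "genomes": {n: len(s) for n, s in result.genomes.items()},
            }

        if "extract" in config.stages:
            log.info("stage: extract")
            params = rp.ParseParams(
                max_anchor_edits=config.max_anchor_edits,
                indel_slack=config.indel_slack,
                min_insert=config.min_insert,
                layout=config.layout,
            )
            parsed, summary = rp.parse_fastq(outdir / "reads.fastq", spec, params)
            rp.write_calls_tsv(parsed, outdir / "barcode_calls.tsv")
            write_fasta(
                outdir / "inserts.fasta",
                ((p.call.read_id, p.insert) for p in rp.iter_ok(parsed) if not p.short),
            )
            state["parsed"] = parsed
            report["stages"]["extract"] = summary

        if "cluster" in config.stages:
            log.info("stage: cluster")
            parsed = state["parsed"]
            counts = clu.barcode_counts(parsed)
            table = clu.cluster_barcodes(
                counts, d=config.cluster_d, ratio=config.cluster_ratio, min_reads=config.min_reads
            )
            table.write_tsv(outdir / "clusters.tsv")
            assignments, summary = clu.assign_reads(parsed, table)
            sags = clu.sag_read_sets(parsed, assignments)
            sag_dir = outdir / "sags"
            sag_dir.mkdir(exist_ok=True)
            manifest_rows = []
            for i, canon in enumerate(table.kept_canonicals):
                sag_id = f"sag{i:05d}"
                reads = sags.get(canon, [])
                manifest_rows.append((sag_id, canon, len(reads)))
                write_fasta(
                    sag_dir / f"{sag_id}.fasta",
                    ((f"{sag_id}_r{j}", s) for j, s in enumerate(reads)),
                )
            with open(outdir / "sag_manifest.tsv", "w") as fh:
                fh.write("sag_id\tcanonical_barcode\tn_reads\n")
                for row in manifest_rows:
                    fh.write("\t".join(map(str, row)) + "\n")
            state["table"] = table
            state["sags"] = {
                f"sag{i:05d}": sags.get(canon, [])
                for i, canon in enumerate(table.kept_canonicals)
            }
            report["stages"]["cluster"] = summary

        if "assemble" in config.stages:
            log.info("stage: assemble")
            sags = state["sags"]
            results: dict[str, asm.StrategyResult] = {}
            for strategy in config.strategies:
                res = asm.run_strategy(
                    strategy,
                    sags,
                    assembler=config.assembler,
                    min_overlap=config.min_overlap,
                    max_mismatch_frac=config.max_mismatch_frac,
                    min_contig=config.min_contig,
                )
                results[res.strategy] = res
                cdir = outdir / "contigs" / res.strategy
                cdir.mkdir(parents=True, exist_ok=True)
                for unit, contigs in res.contigs_by_unit.items():
                    if contigs:
                        write_fasta(cdir / f"{unit}.fasta", ((c.id, c.sequence) for c in contigs))
            asm.write_stats_tsv(results, outdir / "assembly_stats.tsv")
            state["assembly"] = results
            report["stages"]["assemble"] = {
                name: dataclasses.asdict(res.aggregate) for name, res in results.items()
            }
            if "DA" in results and len(results) > 1:
                report["strategy_comparison"] = compare_strategies(results)

        if "evaluate" in config.stages:
            log.info("stage: evaluate")
            sags = state["sags"]
            genomes = state["sim"].genomes if "sim" in state else None
            if genomes is None:
                raise RuntimeError("evaluate stage requires simulated genomes in this run")
            refset = ev.ReferenceSet(genomes, k=config.k)
            metrics = ev.evaluate_sags(
                {s: r for s, r in sags.items() if r}, refset, config.min_kmer_frac
            )
            metrics.to_csv(outdir / "sag_metrics.tsv", sep="\t", index=False)
            tiers = ev.tier_histogram(metrics["tier"]) if len(metrics) else {}
            high_purity = float(metrics["high_purity"].mean()) if len(metrics) else 0.0
            report["stages"]["evaluate"] = {
                "n_sags": int(len(metrics)),
                "tier_histogram": tiers,
                "high_purity_fraction": high_purity,
                "mean_mapping_ratio": float(metrics["mapping_ratio"].mean())
                if len(metrics)
                else 0.0,
            }
            state["metrics"] = metrics
    except Exception as exc:
        report["error"] = {"stage": _current_stage(report), "message": str(exc)}
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise

    report["elapsed_sec"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _current_stage(report: dict) -> str:
    done = set(report.get("stages", {}))
    for stage in ALL_STAGES:
        if stage not in done:
            return stage
    return "unknown"


def demo_config(outdir: str = "gse_demo", seed: int = 1) -> RunConfig:
    """The standard mock-community demo: 3 genomes x 40 kb, 300 droplets."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        n_genomes=3,
        genome_length=40_000,
        n_droplets=300,
        reads_per_droplet_mean=12.0,
        strategies=("DA", "BCA", "SAGb"),
    )


def strategy_demo_config(outdir: str = "gse_strategy_demo", seed: int = 1) -> RunConfig:
    """Mixed community of related strains for the DA/BCA/SAGb comparison.

    Three strains of a 12 kb ancestor at ~1% pairwise divergence — below the
    assembler's mismatch tolerance, so pooled assembly collapses strains into
    consensus mosaics while per-droplet assembly keeps them apart. Droplets
    are sequenced deeply (~3-4x) so single-droplet assemblies can complete.
    """
    return RunConfig(
        outdir=outdir,
        seed=seed,
        n_genomes=3,
        genome_length=12_000,
        strain_divergence=0.005,
        n_droplets=64,
        reads_per_droplet_mean=35.0,
        read_len_n50_target=1700,
        strategies=("DA", "BCA", "SAGb"),
    )
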