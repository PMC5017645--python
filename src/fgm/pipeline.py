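"""End-to-end orchestration: simulate -> screen -> deconvolve -> contig -> anchor.

One :class:`RunConfig` drives every stage; per-stage seeds are spawned from
the single top-level seed so stages (and sweep cells) are reproducible and
order-independent.  The parameter-sweep experiments (sequencing depth,
pool coverage, pooling dimension) are expressed over the same machinery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anchor as anchor_mod
from . import deconvolve, features, io, physmap, pooling, simulate

__version__ = "0.1.0"

_SUPPORTED_P = (2, 3, 4, 5, 7, 8, 9, 11, 13, 16)


def default_pools_per_dim(d: int, n_clones: int) -> int:
    """Smallest supported pool count per dimension fitting d and n_clones."""
    for p in _SUPPORTED_P:
        if d <= pooling.max_dimensions(p) and n_clones <= p**3:
            return p
    raise ValueError(f"no supported pool count for d={d}, n={n_clones}")


@dataclass
class RunConfig:
    """All pipeline parameters plus the top-level seed."""

    # genome
    genome_length: int = 1_000_000
    repeat_fraction: float = 0.0
    n_chromosomes: int = 1
    # clone library (defaults are the full BAC law rescaled to megabase genomes)
    n_clones: int = 8
    mean_insert: float = 50_000.0
    # pooling
    dimension: int = 3
    pools_per_dim: int = 0  # 0 = choose automatically
    strategy: str = "solid"
    # sequencing
    depth: float = 20.0
    read_length: int = 100
    fragment_mean: int = 500
    fragment_sd: int = 30
    with_errors: bool = True
    # features
    prefixes: tuple = features.DEFAULT_PREFIXES
    fs_len: int = 31
    k: int = 31
    filter_freq: int = 1
    # deconvolution
    m_max: int = 4
    # physical map
    cutoff: float = 1e-12
    min_bands: int = 10
    max_q: int = 5
    dq_steps: int = 9
    # anchoring
    seq_mean_len: int = 10_000
    min_seq_len: int = 100
    min_frac: float = 0.5
    map_t: float = 0.9
    marker_spacing: int = 50_000
    gap: int = anchor_mod.GAP_BETWEEN_CONTIGS
    spacer: int = anchor_mod.SPACER_WITHIN_CONTIG
    # reproducibility
    seed: int = 0

    def feature_params(self) -> features.FeatureParams:
        return features.FeatureParams(tuple(self.prefixes), self.fs_len, self.k)

    def library_model(self) -> simulate.LibraryModel:
        return simulate.LibraryModel().scaled(self.mean_insert, self.n_clones)

    def resolved_p(self) -> int:
        return self.pools_per_dim or default_pools_per_dim(self.dimension, self.n_clones)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["prefixes"] = list(d["prefixes"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        if "prefixes" in data:
            data["prefixes"] = tuple(data["prefixes"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["genome", "library", "pooling", "reads", "seqs", "markers"]
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, ss)}


# ---------------------------------------------------------------------------
# Simulation + deconvolution core (shared by the full run and the sweeps)


@dataclass
class ResolvedRun:
    """Everything up to per-clone final F-sets, plus truth handles."""

    config: RunConfig
    genome: simulate.Genome
    clones: list[simulate.Clone]
    design: pooling.PoolDesign
    batches: list[simulate.ReadBatch]
    pool_fsets: dict[str, dict[str, features.FSet]]      # kind -> pool -> FSet (filtered)
    intersected: dict[str, dict[str, features.FSet]]     # kind -> clone -> FSet
    final: dict[str, dict[str, features.FSet]]           # kind -> clone -> FSet

    def true_fset(self, clone: simulate.Clone, kind: str) -> features.FSet:
        codes = self.genome.sequences[clone.chrom][clone.start:clone.end]
        return features.fset_of_sequence(codes, self.config.feature_params(), kind,
                                         owner=clone.id, stage="truth")

    def rate_frame(self, kinds=("FS",), stages=("intersected", "final")) -> pd.DataFrame:
        rows = []
        for kind in kinds:
            for clone in self.clones:
                truth = self.true_fset(clone, kind)
                for stage in stages:
                    fs = getattr(self, stage)[kind][clone.id]
                    rep = deconvolve.rates(fs, truth)
                    rows.append({"clone_id": clone.id, "kind": kind, "stage": stage,
                                 "detection": rep.detection_rate,
                                 "correct": rep.correct_rate})
        return pd.DataFrame(rows)


def resolve_run(config: RunConfig, *, kinds: tuple[str, ...] = ("FS", "KMER"),
                keep_reads: bool = False, refine: bool = True) -> ResolvedRun:
    """Simulate one design and resolve per-clone F-sets from pool reads."""
    seeds = _stage_seeds(config.seed)
    genome = simulate.generate_genome(config.genome_length, config.repeat_fraction,
                                      seeds["genome"], n_chromosomes=config.n_chromosomes)
    clones = simulate.simulate_library(genome, config.library_model(), seeds["library"])
    p = config.resolved_p()
    if config.strategy == "solid":
        design = pooling.build_solid_pools(clones, config.dimension, p)
    elif config.strategy == "random":
        design = pooling.build_random_pools(clones, config.dimension, p, seeds["pooling"])
    else:
        raise ValueError(f"unknown pooling strategy {config.strategy!r}")
    err = simulate.default_error_model(config.read_length) if config.with_errors else None
    params = config.feature_params()
    pool_fsets: dict[str, dict[str, features.FSet]] = {k: {} for k in kinds}
    batches = []
    for batch in simulate.simulate_pool_reads(
            design, clones, genome, config.depth, err,
            read_length=config.read_length, fragment_mean=config.fragment_mean,
            fragment_sd=config.fragment_sd, seed=seeds["reads"]):
        screened = features.screen_pool(batch, params, kinds=kinds)
        for kind in kinds:
            pool_fsets[kind][batch.pool_id] = features.filter_by_frequency(
                screened[kind], config.filter_freq)
        if keep_reads:
            batches.append(batch)
    intersected = {k: deconvolve.intersect_all(design, pool_fsets[k]) for k in kinds}
    if refine:
        final = {k: deconvolve.refine_all(intersected[k], design, pool_fsets[k],
                                          config.m_max) for k in kinds}
    else:
        final = {k: {c: dataclasses.replace(fs, stage="final")
                     for c, fs in intersected[k].items()} for k in kinds}
    return ResolvedRun(config, genome, clones, design, batches,
                       pool_fsets, intersected, final)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineResult:
    resolved: ResolvedRun
    contigs: list[physmap.PhysContig]
    singletons: list[str]
    clone_usage: float
    assembly: anchor_mod.AnchoredAssembly
    report: anchor_mod.EvaluationReport
    log: list[dict] = field(default_factory=list)
    out_dir: Path | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir=None, *, write_fastq: bool = False) -> PipelineResult:
    """Run every stage on one simulated design and score against truth."""
    log: list[dict] = []

    def stage(name, **counts):
        log.append({"stage": name, "time": time.time(), **counts})

    rr = resolve_run(config, keep_reads=True)
    stage("resolve", n_clones=len(rr.clones), n_pools=len(rr.design.membership),
          n_pairs=sum(b.n_pairs for b in rr.batches))

    bands, index, dropped = physmap.clone_bands(rr.final["FS"], min_bands=config.min_bands)
    sparams = physmap.SulstonParams(config.cutoff, len(index), config.min_bands)
    contigs, singletons, table = physmap.build_contigs(bands, sparams)
    contigs, more_singles = physmap.q_analysis(contigs, bands, table, sparams,
                                               max_q=config.max_q, steps=config.dq_steps)
    singletons += more_singles
    usage = physmap.clone_usage(contigs, len(bands))
    stage("contig", n_bands=len(index), n_imported=len(bands), n_dropped=dropped,
          n_contigs=len(contigs), n_singletons=len(singletons), clone_usage=usage)

    seeds = _stage_seeds(config.seed)
    raw_seqs, seq_truth = simulate.fragment_truth_contigs(
        rr.genome, config.seq_mean_len, seeds["seqs"], min_len=config.min_seq_len)
    seqs = {sid: anchor_mod.SeqContig(sid, s, k=config.k) for sid, s in raw_seqs.items()}
    bins_by_contig = {c.id: anchor_mod.split_into_bins(c, rr.final["KMER"])
                      for c in contigs}
    all_bins = [b for bs in bins_by_contig.values() for b in bs]
    allocations = {}
    for sid, sc in seqs.items():
        allocations[sid] = anchor_mod.allocate(sc, all_bins, config.min_frac)
    n_alloc = sum(a is not None for a in allocations.values())
    stage("allocate", n_seqs=len(seqs), n_allocated=n_alloc,
          n_bins=len(all_bins))

    links = anchor_mod.map_pairs(rr.batches, raw_seqs, k=config.k, t=config.map_t)
    scaffolds = anchor_mod.connect_and_orient(allocations, links, bins_by_contig,
                                              seqs, spacer=config.spacer)
    markers = simulate.generate_markers(rr.genome, rr.clones, config.marker_spacing,
                                        seeds["markers"])
    assembly = anchor_mod.anchor_contigs(contigs, scaffolds, markers, gap=config.gap)
    report = anchor_mod.evaluate(assembly, rr.genome, rr.clones, contigs)
    stage("anchor", n_links=int(links["n"].sum()) if len(links) else 0,
          n_markers=len(markers), n_placed=report.n_placed,
          mapped_fraction=report.mapped_fraction)

    result = PipelineResult(rr, contigs, singletons, usage, assembly, report, log)
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_artifacts(result, config, markers, bands, write_fastq)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig, markers, bands,
                     write_fastq: bool) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rr = result.resolved
    config.to_yaml(out / "config.yaml")
    io.write_genome_fasta(rr.genome, out / "genome.fasta")
    io.write_clones_tsv(rr.clones, out / "clones.tsv")
    io.write_design_tsv(rr.design, out / "design.tsv")
    io.write_markers_tsv(markers, out / "markers.tsv")
    if write_fastq:
        err = simulate.default_error_model(config.read_length) if config.with_errors else None
        for batch in rr.batches:
            io.write_pool_fastq(batch, out / "reads", err)
    fdir = out / "fsets"
    fdir.mkdir(exist_ok=True)
    for kind in rr.final:
        for cid, fs in rr.final[kind].items():
            io.write_fset_tsv(fs, fdir / f"{cid}.final.{kind}.tsv")
    physmap.write_size_file(bands, out / "clones.size")
    io.write_contig_tsv(result.contigs, result.singletons, out / "contigs.tsv")
    io.write_agp(result.assembly, out / "pseudomolecules.agp")
    io.write_fasta({c: p.sequence for c, p in result.assembly.pseudomolecules.items()},
                   out / "pseudomolecules.fasta")
    io.write_report_tsv(result.report, out / "report.tsv")
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "log": result.log,
        "checksums": {f.name: _checksum(f) for f in sorted(out.iterdir()) if f.is_file()},
    }
    (out / "run.json").write_text(json.dumps(manifest, indent=2, default=float))


# ---------------------------------------------------------------------------
# Parameter sweeps


@dataclass
class SweepResult:
    axis: str
    frame: pd.DataFrame

    def cell_means(self, value_col: str = "detection") -> pd.DataFrame:
        return (self.frame.groupby([self.axis, "dimension"])[value_col]
                .mean().reset_index())


def _replicate_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def sweep_depth(config: RunConfig, depths, dims, *, with_errors: bool | None = None,
                replicates: int = 3, kinds=("FS",), refine: bool = True) -> SweepResult:
    """Final F-set detection rate per (depth, dimension) cell, mean over seeds."""
    rows = []
    for d in dims:
        for depth in depths:
            for rep, seed in enumerate(_replicate_seeds(config.seed + 1000 * d, replicates)):
                cfg = dataclasses.replace(
                    config, depth=float(depth), dimension=d, pools_per_dim=0,
                    seed=seed,
                    with_errors=config.with_errors if with_errors is None else with_errors)
                if depth == 0:
                    for clone_i in range(cfg.n_clones):
                        rows.append({"depth": depth, "dimension": d, "replicate": rep,
                                     "stage": "final", "kind": kinds[0],
                                     "detection": 0.0, "correct": None})
                    continue
                rr = resolve_run(cfg, kinds=kinds, refine=refine)
                rf = rr.rate_frame(kinds=kinds, stages=("final",))
                for r in rf.itertuples():
                    rows.append({"depth": depth, "dimension": d, "replicate": rep,
                                 "stage": r.stage, "kind": r.kind,
                                 "detection": r.detection, "correct": r.correct})
    return SweepResult("depth", pd.DataFrame(rows))


def sweep_pool_coverage(config: RunConfig, coverages, dims, *, replicates: int = 2,
                        kinds=("FS",)) -> SweepResult:
    """Detection/correct rates and clone usage per (pool-coverage, dimension) cell.

    Pool coverage (pool insert bases over genome length) is steered through
    the clone count: n = coverage * p * genome_length / mean_insert.
    """
    rows = []
    for d in dims:
        for cov in coverages:
            for rep, seed in enumerate(_replicate_seeds(config.seed + 7000 * d, replicates)):
                p = default_pools_per_dim(d, 1)
                n = max(1, int(round(cov * p * config.genome_length / config.mean_insert)))
                p = default_pools_per_dim(d, n)
                cfg = dataclasses.replace(config, n_clones=n, dimension=d,
                                          pools_per_dim=p, seed=seed)
                rr = resolve_run(cfg, kinds=kinds)
                actual = float(np.mean(list(
                    deconvolve.pool_coverage(rr.design, rr.clones, rr.genome).values())))
                rf = rr.rate_frame(kinds=kinds, stages=("intersected", "final"))
                bands, index, _ = physmap.clone_bands(rr.final["FS"] if "FS" in rr.final
                                                      else rr.final[kinds[0]],
                                                      min_bands=config.min_bands)
                usage = float("nan")
                if len(bands) >= 2:
                    sparams = physmap.SulstonParams(config.cutoff, len(index), config.min_bands)
                    contigs, singles, table = physmap.build_contigs(bands, sparams)
                    contigs, more = physmap.q_analysis(contigs, bands, table, sparams,
                                                       max_q=config.max_q,
                                                       steps=config.dq_steps)
                    usage = physmap.clone_usage(contigs, len(bands))
                agg = rf.groupby("stage").agg(detection=("detection", "mean"),
                                              correct=("correct", "mean"))
                for stage, r in agg.iterrows():
                    rows.append({"pool_coverage": cov, "actual_coverage": actual,
                                 "dimension": d, "replicate": rep, "stage": stage,
                                 "detection": r.detection, "correct": r.correct,
                                 "clone_usage": usage})
    return SweepResult("pool_coverage", pd.DataFrame(rows))
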