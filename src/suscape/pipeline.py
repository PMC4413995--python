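"""End-to-end pipeline driver: simulate -> CN -> CNVR -> annotate -> trees.

A single :class:`PipelineConfig` (YAML on disk) holds every path, threshold
and seed; :func:`run_pipeline` executes the requested stages into a run
directory, writing a manifest with per-stage row counts so identical
config+seed reruns are byte-identical.  Stages degrade gracefully: without
a gene annotation the OR/non-OR partitions are skipped with a warning while
CNVR-ALL results are still produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import bayes as bayes_mod
from . import cnvr as cnvr_mod
from . import depth as depth_mod
from . import distances as dist_mod
from . import io as io_mod
from . import mkv as mkv_mod
from . import simulate as sim_mod

log = logging.getLogger("suscape")

ALL_STAGES = ("simulate", "cn", "cnvr", "annotate", "dist", "bayes")


@dataclass
class PipelineConfig:
    """Every printed threshold of the analysis in one place."""

    out_dir: str = "results/run"
    seed: int = 0
    # --- cohort simulation (active when no depth files are supplied)
    chrom_size: int = 20_000_000
    mask_density: float = 0.35
    n_regions: int = 60
    individuals_per_population: int = 2
    coverage: float | None = None  # None: per-individual coverages of the emulated cohort
    populations: list[str] = field(default_factory=lambda: list(sim_mod.POPULATIONS))
    # --- file inputs (override simulation when set)
    mask_bed: str | None = None
    depth_files: dict[str, list[str]] | None = None  # population -> per-individual TSVs
    seed_regions_bed: str | None = None
    genes_bed: str | None = None
    genotypes_tsv: str | None = None
    # --- thresholds (the analysis constants)
    bin_size: int = 1000
    min_unmasked: int = 300
    seed_cn: float = 2.5
    min_bins: int = 6
    sd_threshold: float = 0.7
    overlap_frac: float = 0.70
    cnd_threshold: float = 2.0
    chromosome_blacklist: list[str] = field(default_factory=list)
    gc_reference: str = "diploid"
    groups: dict[str, list[str]] = field(
        default_factory=lambda: {
            "scrofa": ["Sumatra", "China", "Europe"],
            "isea": ["Sbar", "Sceb", "Scel", "Sver"],
        }
    )
    # --- SNP comparison
    n_snp_sites: int = 200_000
    snp_rate: float = 0.02
    cn_event_rate: float = 0.05
    # --- Bayesian stage (reduced defaults keep the demo minutes-scale)
    bayes_steps: int = 10
    bayes_samples: int = 1_500
    bayes_models: list[str] = field(default_factory=lambda: ["null", "m1", "m2", "m3", "m4"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _simulate_stage(cfg: PipelineConfig, out: Path) -> dict:
    genome = sim_mod.simulate_genome(
        {"chr1": cfg.chrom_size}, mask_density=cfg.mask_density,
        bin_size=cfg.bin_size, seed=cfg.seed,
    )
    landscape = sim_mod.plant_cn_landscape(
        genome, cfg.populations, n_regions=cfg.n_regions,
        min_unmasked=cfg.min_unmasked, seed=cfg.seed + 1,
    )
    seeds = sim_mod.simulate_seed_regions(genome, min_unmasked=cfg.min_unmasked, seed=cfg.seed + 2)
    genes = sim_mod.simulate_genes(landscape, genome, seed=cfg.seed + 3)
    species = sim_mod.default_sus_tree()
    tracks: dict[str, list[dict[str, np.ndarray]]] = {}
    for pi, pop in enumerate(cfg.populations):
        tracks[pop] = []
        for ind in range(cfg.individuals_per_population):
            if cfg.coverage is not None:
                cov = cfg.coverage
            else:
                table = sim_mod.INDIVIDUAL_COVERAGE.get(pop, (9.0, 9.0))
                cov = table[ind % len(table)]
            rd_cfg = sim_mod.ReadDepthSimConfig(coverage=cov, seed=cfg.seed + 100 + pi * 10 + ind)
            tracks[pop].append(sim_mod.simulate_depth_track(genome, landscape, pop, rd_cfg))
    names, genotypes = sim_mod.simulate_genotypes(species, cfg.n_snp_sites, cfg.snp_rate, seed=cfg.seed + 4)

    io_mod.mask_to_bed(genome.mask, out / "mask.bed")
    io_mod.write_bed(seeds, out / "seed_regions.bed")
    io_mod.write_bed(genes, out / "genes.bed", columns=["chrom", "start", "end", "name", "cls"])
    truth = landscape.loci.copy()
    for j, pop in enumerate(landscape.populations):
        truth[pop] = landscape.cn[:, j]
    truth.to_csv(out / "truth_cn.tsv", sep="\t", index=False)
    for pop in cfg.populations:
        for ind, track in enumerate(tracks[pop]):
            io_mod.write_depth_tsv(track, cfg.bin_size, out / f"depth_{pop}_{ind + 1}.tsv")
    io_mod.write_genotypes_tsv(names, genotypes, out / "genotypes.tsv")
    io_mod.write_newick(species.tree, out / "species_tree.nwk")
    return {
        "genome": genome, "landscape": landscape, "seed_regions": seeds,
        "genes": genes, "depth": tracks, "genotypes": (names, genotypes),
        "species": species,
    }


def _cn_stage(cfg: PipelineConfig, out: Path, sim: dict | None) -> dict:
    if sim is not None:
        genome = sim["genome"]
        grid = depth_mod.build_bins(
            genome, min_unmasked=cfg.min_unmasked, blacklist=tuple(cfg.chromosome_blacklist)
        )
        seeds = sim["seed_regions"]
        depth_by_pop = {
            pop: [depth_mod.track_from_bins(grid, t, f"{pop}_{i + 1}") for i, t in enumerate(tracks)]
            for pop, tracks in sim["depth"].items()
        }
    else:
        if not (cfg.mask_bed and cfg.depth_files and cfg.seed_regions_bed):
            raise ValueError("cn stage needs mask_bed, depth_files and seed_regions_bed (or simulation)")
        mask = io_mod.bed_to_mask(cfg.mask_bed)
        sizes = {c: int(iv.max()) for c, iv in mask.items()}
        grid = depth_mod.build_bins(
            mask=mask, chrom_sizes=sizes, bin_size=cfg.bin_size,
            min_unmasked=cfg.min_unmasked, blacklist=tuple(cfg.chromosome_blacklist),
        )
        seeds = io_mod.read_bed(cfg.seed_regions_bed, names=("chrom", "start", "end"))
        depth_by_pop = {}
        for pop, paths in cfg.depth_files.items():
            depth_by_pop[pop] = [
                depth_mod.track_from_bins(
                    grid, io_mod.read_depth_tsv(p, sizes, cfg.bin_size), f"{pop}_{i + 1}"
                )
                for i, p in enumerate(paths)
            ]
    cn_tracks: dict[str, depth_mod.CNTrack] = {}
    for pop, tracks in depth_by_pop.items():
        result = depth_mod.depth_to_cn(tracks, grid, seeds, population=pop, gc_reference=cfg.gc_reference)
        cn_tracks[pop] = result.cn
        io_mod.write_cn_track(grid.bins, result.cn.cn, grid.bin_size, out / f"cn_{pop}.tsv")
        pd.DataFrame({"gc_low": result.gc_model.edges[:-1], "factor": result.gc_model.factors}).to_csv(
            out / f"gc_factors_{pop}.tsv", sep="\t", index=False, float_format="%.5f"
        )
    return {"grid": grid, "cn_tracks": cn_tracks}


def _cnvr_stage(cfg: PipelineConfig, out: Path, cn: dict) -> dict:
    res = cnvr_mod.cnvr_pipeline(
        cn["cn_tracks"], cn["grid"], seed_threshold=cfg.seed_cn,
        min_bins=cfg.min_bins, sd_threshold=cfg.sd_threshold,
    )
    pops = list(cn["cn_tracks"])
    cnvrs = res["cnvrs"]
    if len(cnvrs):
        bed = cnvrs[["chrom", "start", "end"]].copy()
        bed["name"] = [f"CNVR{i:05d}" for i in range(len(cnvrs))]
        bed["sd"] = cnvrs["sd"].round(4)
        io_mod.write_bed(bed, out / "cnvrs.bed")
        io_mod.write_cn_matrix(cnvrs, pops, out / "cnvr_cn_matrix.tsv")
        specific = cnvr_mod.population_specific(cnvrs, pops, threshold=cfg.seed_cn)
        io_mod.write_cn_matrix(specific, pops, out / "population_specific.tsv")
    groups = {}
    for gname, members in cfg.groups.items():
        if len(members) >= 2 and all(m in pops for m in members):
            groups[gname] = cnvr_mod.group_ascertain(
                cn["cn_tracks"], cn["grid"], members, seed_threshold=cfg.seed_cn,
                min_bins=cfg.min_bins, sd_threshold=cfg.sd_threshold,
            )
    if len(groups) == 2:
        a, b = list(groups)
        parts = cnvr_mod.compare_groups(groups[a], groups[b])
        for key, frame in parts.items():
            label = {"a": a, "b": b}[key.split("_")[1]]
            frame.to_csv(out / f"group_{key.split('_')[0]}_{label}.tsv", sep="\t", index=False)
    res["groups"] = groups
    return res


def _annotate_stage(cfg: PipelineConfig, out: Path, cnvr_res: dict, sim: dict | None) -> dict | None:
    if sim is not None:
        genes = sim["genes"]
    elif cfg.genes_bed:
        genes = io_mod.read_bed(cfg.genes_bed)
    else:
        warnings.warn("no gene annotation: OR/non-OR partitions skipped, CNVR-ALL still produced")
        return None
    cnvrs = cnvr_res["cnvrs"]
    pops = [c for c in cnvrs.columns if c not in ("chrom", "start", "end", "populations", "missing", "sd")]
    table = annotate_mod.overlap_genes(cnvrs, genes, pops, min_frac=cfg.overlap_frac)
    parts = annotate_mod.partition_by_class(cnvrs, table)
    table.to_csv(out / "gene_cn.tsv", sep="\t", index=False, float_format="%.4f")
    for name, frame in parts.items():
        Path(out / f"cnvr_ids_{name}.txt").write_text("\n".join(str(i) for i in frame.index) + "\n")
    return {"gene_table": table, "partitions": parts, "populations": pops}


def _dist_stage(cfg: PipelineConfig, out: Path, cnvr_res: dict, ann: dict | None, sim: dict | None) -> dict:
    cnvrs = cnvr_res["cnvrs"]
    pops = [c for c in cnvrs.columns if c not in ("chrom", "start", "end", "populations", "missing", "sd")]
    partitions = {"ALL": cnvrs}
    if ann is not None:
        partitions.update({k: v for k, v in ann["partitions"].items() if k != "ALL"})
    results = {}
    for name, frame in partitions.items():
        if len(frame) < 1:
            continue
        cn = frame[pops].to_numpy(float)
        counts = dist_mod.binary_cnd(cn, threshold=cfg.cnd_threshold)
        rates = dist_mod.cnd_rate(counts, len(frame), pops)
        io_mod.write_phylip(pops, rates.rates, out / f"cnd_rates_{name}.phy")
        if len(pops) >= 3:
            tree = dist_mod.nj_tree(rates)
            io_mod.write_newick(tree, out / f"nj_{name}.nwk")
            results[f"nj_{name}"] = tree
        results[f"rates_{name}"] = rates
    cluster = dist_mod.hierarchical_cluster(cnvrs[pops].to_numpy(float), pops)
    io_mod.write_newick(cluster, out / "hclust_ALL.nwk")
    results["hclust"] = cluster
    genotypes = None
    if sim is not None:
        genotypes = sim["genotypes"]
    elif cfg.genotypes_tsv:
        genotypes = io_mod.read_genotypes_tsv(cfg.genotypes_tsv)
    if genotypes is not None:
        names, gmat = genotypes
        snp = dist_mod.snp_rate(gmat, names)
        io_mod.write_phylip(names, snp.rates, out / "snp_rates.phy")
        if set(names) == set(pops):
            order = [names.index(p) for p in pops]
            snp_aligned = dist_mod.RateMatrix(pops, snp.rates[np.ix_(order, order)], snp.denominator)
            ratio = dist_mod.rate_ratio(results["rates_ALL"], snp_aligned)
            io_mod.write_manifest(out / "rate_ratio.json", **ratio)
            results["rate_ratio"] = ratio
            io_mod.write_newick(dist_mod.nj_tree(snp_aligned), out / "nj_SNP.nwk")
    return results


def _bayes_stage(cfg: PipelineConfig, out: Path, cnvr_res: dict, ann: dict | None) -> pd.DataFrame:
    cnvrs = cnvr_res["cnvrs"]
    pops = [c for c in cnvrs.columns if c not in ("chrom", "start", "end", "populations", "missing", "sd")]
    models = {k: v for k, v in bayes_mod.predefined_models().items() if k in cfg.bayes_models}
    frames = {"ALL": cnvrs}
    if ann is not None:
        frames.update({k: v for k, v in ann["partitions"].items() if k != "ALL"})
    rows = {}
    for pname, frame in frames.items():
        if len(frame) < 5:
            continue
        matrix = mkv_mod.discretize(frame[pops].to_numpy(float), pops)
        for mname, model in models.items():
            if not set().union(*[set(c) for c in model.clades]) <= set(pops):
                continue
            tag = sum(ord(c) for c in pname + mname)  # stable across runs
            est = bayes_mod.stepping_stone(
                matrix, [model], steps=cfg.bayes_steps, samples_per_step=cfg.bayes_samples,
                seed=cfg.seed + tag, model_name=f"{pname}:{mname}",
            )
            rows[(pname, mname)] = est
    tables = []
    for pname in frames:
        ests = {m: e for (p, m), e in rows.items() if p == pname}
        if ests:
            t = bayes_mod.compare_models(ests)
            t.insert(0, "partition", pname)
            tables.append(t)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    table.to_csv(out / "model_comparison.tsv", sep="\t", index=False, float_format="%.3f")
    return table


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in order; later stages reuse earlier ones'
    in-memory results.  Returns a dict of all stage outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    counts: dict[str, int] = {}
    try:
        if "simulate" in stages and not cfg.depth_files:
            state["sim"] = _simulate_stage(cfg, out)
            counts["planted_regions"] = len(state["sim"]["landscape"].loci)
        needs_cn = {"cn", "cnvr", "annotate", "dist", "bayes"} & set(stages)
        if needs_cn:
            state["cn"] = _cn_stage(cfg, out, state.get("sim"))
            counts["retained_bins"] = len(state["cn"]["grid"])
        if {"cnvr", "annotate", "dist", "bayes"} & set(stages):
            state["cnvr"] = _cnvr_stage(cfg, out, state["cn"])
            counts["cnvrs"] = len(state["cnvr"]["cnvrs"])
        if {"annotate", "dist", "bayes"} & set(stages):
            state["annotate"] = _annotate_stage(cfg, out, state["cnvr"], state.get("sim"))
            if state["annotate"] is not None:
                counts["genes_with_cn"] = len(state["annotate"]["gene_table"])
        if "dist" in stages:
            state["dist"] = _dist_stage(cfg, out, state["cnvr"], state.get("annotate"), state.get("sim"))
        if "bayes" in stages:
            state["bayes"] = _bayes_stage(cfg, out, state["cnvr"], state.get("annotate"))
            counts["bayes_rows"] = len(state["bayes"])
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err
    io_mod.write_manifest(out / "manifest.json", config=asdict(cfg), stage_counts=counts)
    return state
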