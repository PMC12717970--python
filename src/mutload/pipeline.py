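"""End-to-end orchestration from a single YAML config.

A config either points at real input files or carries a ``simulate``
block; the pipeline then runs io -> classify -> load stats -> windows ->
SV -> reports, writing every table as TSV with a provenance header
(config hash, seed, package version).  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as fc
from . import load_stats as ls
from . import simulate as sim
from . import sv as sva
from . import variant_io as vio
from . import windows as win
from .errors import ConfigError, MutloadError, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "max_missing": 0.25,
    "min_maf_snp": 0.001,
    "provean_threshold": -2.5,
    "sv_min_size": 30,
    "sv_max_dist": 100,
    "sv_min_overlap": 0.9,
    "sv_min_maf": 0.01,
    "diversity_window": 10_000,
    "load_window": 100_000,
    "alpha": 0.05,
    "correction": "bonferroni",
}


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    inputs: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "outdir" not in raw:
            raise ConfigError("config requires 'outdir'")
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            inputs=dict(raw.get("inputs", {})),
            simulate=raw.get("simulate"),
            thresholds={**DEFAULT_THRESHOLDS, **raw.get("thresholds", {})},
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.inputs and self.simulate is None:
            raise ConfigError("config needs either 'inputs' or a 'simulate' block")
        th = self.thresholds
        checks = [
            ("max_missing", 0.0, 1.0),
            ("min_maf_snp", 0.0, 0.5),
            ("sv_min_overlap", 0.0, 1.0),
            ("sv_min_maf", 0.0, 0.5),
            ("alpha", 0.0, 1.0),
        ]
        for key, lo, hi in checks:
            if not lo <= float(th[key]) <= hi:
                raise ConfigError(f"threshold {key}={th[key]} outside [{lo}, {hi}]")
        if self.inputs and "assignment" not in self.inputs:
            raise ConfigError("inputs require an 'assignment' table with an outgroup")

    def sha256(self) -> str:
        # outdir is a location, not an analysis parameter: leave it out so
        # identical analyses hash identically wherever they are written
        canon = json.dumps(
            {k: v for k, v in self.raw.items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# mutload {__version__}\n"
        f"# config_sha256={config.sha256()}\n"
        f"# seed={config.seed}\n"
    )


def write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _sim_config_from_block(block: dict[str, Any], seed: int) -> sim.SimConfig:
    block = dict(block)
    epochs = {
        pop: [sim.DemographyEpoch(**e) for e in eps]
        for pop, eps in block.pop("epochs").items()
    }
    block.setdefault("seed", seed)
    return sim.SimConfig(epochs=epochs, **block)


def default_simulate_block() -> dict[str, Any]:
    """A small illustrative two-step domestication scenario."""
    return {
        "n_sites": 2000,
        "n_generations": 120,
        "chrom_length": 1_000_000,
        "n_chromosomes": 4,
        "sel_coeff": -0.05,
        "dominance": 0.5,
        "mut_rate": 2e-4,
        "init_freq": 0.08,
        "epochs": {
            "wild": [{"start_gen": 0, "N": 120}],
            "semidom": [{"start_gen": 40, "N": 40, "source_pop": "wild"}],
            "domesticated": [{"start_gen": 80, "N": 15, "source_pop": "semidom"}],
        },
        "selfing_rate": {"wild": 0.1, "semidom": 0.5, "domesticated": 0.9},
        "n_sampled": {"wild": 12, "semidom": 12, "domesticated": 12},
    }


@dataclass
class StageInputs:
    matrix: vio.GenotypeMatrix
    assignment: vio.PopulationAssignment
    sift_path: Path
    provean_path: Path
    gene_models: pd.DataFrame
    genetic_map: pd.DataFrame
    sweep: pd.DataFrame
    sv_paths: dict[str, dict[str, Path]]
    chrom_sizes: dict[str, int]


def simulate_inputs(config: PipelineConfig, workdir: Path) -> StageInputs:
    """Generate the full synthetic input set under ``workdir``."""
    block = config.simulate or default_simulate_block()
    miscls = float(block.pop("miscls_rate", 0.0)) if "miscls_rate" in block else 0.0
    sim_cfg = _sim_config_from_block(block, config.seed)
    result = sim.simulate_populations(sim_cfg)
    matrix, assignment = vio.matrix_from_simulation(result)
    workdir.mkdir(parents=True, exist_ok=True)
    vio.write_vcf(matrix, workdir / "genotypes.vcf")
    vio.write_population_assignment(assignment, workdir / "populations.tsv")
    sift_path = workdir / "sift.tsv"
    provean_path = workdir / "provean.tsv"
    sim.emit_annotation_tables(
        result.truth, miscls, config.seed + 1, sift_path, provean_path
    )
    chrom_names = sorted(result.truth["chrom"].unique())
    chrom_sizes = {c: sim_cfg.chrom_length for c in chrom_names}
    gene_models = sim.generate_gene_models(
        n_genes=max(10, sim_cfg.n_sites // 50),
        seed=config.seed + 2,
        chrom_names=chrom_names,
        chrom_length=sim_cfg.chrom_length,
    )
    sim.write_gff(gene_models, workdir / "genes.gff3")
    genetic_map = sim.generate_genetic_map(
        n_markers=10 * len(chrom_names),
        cm_per_mb=2.0,
        seed=config.seed + 3,
        chrom_names=chrom_names,
        chrom_length=sim_cfg.chrom_length,
    )
    genetic_map.to_csv(workdir / "genetic_map.tsv", sep="\t", index=False)
    sweep = sim.generate_sweep_table(
        config.seed + 4, chrom_names=chrom_names, chrom_length=sim_cfg.chrom_length
    )
    sweep.to_csv(workdir / "sweep.tsv", sep="\t", index=False)
    sv_cfg = sim.SVFixtureConfig(
        accessions=matrix.accessions,
        outgroup=assignment.outgroup,
        chrom_names=chrom_names,
        chrom_length=sim_cfg.chrom_length,
        n_truth=12,
        false_positives={"callerA": 2, "callerB": 2, "callerC": 2},
    )
    _, sv_paths = sim.generate_sv_fixtures(sv_cfg, config.seed + 5, workdir / "sv")
    return StageInputs(
        matrix=matrix,
        assignment=assignment,
        sift_path=sift_path,
        provean_path=provean_path,
        gene_models=gene_models,
        genetic_map=genetic_map,
        sweep=sweep,
        sv_paths=sv_paths,
        chrom_sizes=chrom_sizes,
    )


def load_inputs(config: PipelineConfig) -> StageInputs:
    inp = config.inputs
    matrix = vio.read_vcf(inp["vcf"])
    assignment = vio.read_population_assignment(inp["assignment"])
    gene_models = sim.read_gff(inp["gene_models"]) if "gene_models" in inp else pd.DataFrame(
        columns=["chrom", "start", "end", "feature", "gene_id"]
    )
    genetic_map = (
        pd.read_csv(inp["genetic_map"], sep="\t")
        if "genetic_map" in inp
        else pd.DataFrame(columns=["chrom", "bp", "cM"])
    )
    sweep = (
        pd.read_csv(inp["sweep"], sep="\t")
        if "sweep" in inp
        else pd.DataFrame(columns=["chrom", "position", "likelihood"])
    )
    sv_paths = {
        acc: {c: Path(p) for c, p in callers.items()}
        for acc, callers in inp.get("sv_vcfs", {}).items()
    }
    chrom_sizes = inp.get("chrom_sizes") or win.chrom_sizes_from_sites(
        matrix.sites, int(config.thresholds["load_window"])
    )
    return StageInputs(
        matrix=matrix,
        assignment=assignment,
        sift_path=Path(inp["sift"]),
        provean_path=Path(inp["provean"]),
        gene_models=gene_models,
        genetic_map=genetic_map,
        sweep=sweep,
        sv_paths=sv_paths,
        chrom_sizes=chrom_sizes,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the mapping of written report tables.

    A stage failure raises :class:`PipelineError` naming the stage;
    partial outputs are retained alongside a FAILED marker file.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    th = config.thresholds
    stage = "io"
    t0 = time.time()
    try:
        if config.simulate is not None or not config.inputs:
            inputs = simulate_inputs(config, outdir / "inputs")
        else:
            inputs = load_inputs(config)
        logger.info("stage io done in %.1fs", time.time() - t0)

        stage = "filter"
        matrix = vio.filter_accessions(inputs.matrix, float(th["max_missing"]))
        matrix = vio.filter_sites(matrix)
        matrix = vio.impute_missing(matrix)
        polarized = vio.polarize(matrix, inputs.assignment)

        stage = "classify"
        sift = fc.read_sift_table(inputs.sift_path)
        provean = fc.read_provean_table(inputs.provean_path)
        categories = fc.classify_sites(sift, provean, polarized)
        write_table(categories, outdir / "site_categories.tsv", config)
        written["site_categories"] = outdir / "site_categories.tsv"

        stage = "load_stats"
        profiles = ls.per_genome_counts(polarized, categories, inputs.assignment)
        write_table(profiles, outdir / "load_profiles.tsv", config)
        written["load_profiles"] = outdir / "load_profiles.tsv"

        stats_json: dict[str, Any] = {}
        ratios = profiles.set_index("accession")["del_neutr_ratio"]
        try:
            comparison = ls.compare_populations(
                ratios, inputs.assignment, float(th["alpha"])
            )
            stats_json["del_neutr_ratio"] = {
                "test": "kruskal-wallis + dunn (bonferroni)",
                "statistic": comparison.statistic,
                "p_value": comparison.p_value,
                "letters": comparison.letters,
                "pairwise": comparison.dunn.to_dict(orient="records"),
            }
        except ConfigError as exc:
            stats_json["del_neutr_ratio"] = {"error": str(exc)}

        sfs = ls.sfs_and_adaf(
            polarized, categories, inputs.assignment, alpha=float(th["alpha"])
        )
        write_table(sfs.spectra, outdir / "sfs.tsv", config)
        write_table(sfs.comparisons, outdir / "sfs_comparisons.tsv", config)
        written["sfs"] = outdir / "sfs.tsv"
        written["sfs_comparisons"] = outdir / "sfs_comparisons.tsv"

        try:
            priv = ls.private_alleles(polarized, categories, inputs.assignment)
            write_table(priv.accession_table, outdir / "private_alleles.tsv", config)
            write_table(
                priv.population_table, outdir / "private_alleles_pop.tsv", config
            )
            written["private_alleles"] = outdir / "private_alleles.tsv"
            stats_json["private_vs_shared"] = priv.ttests.to_dict(orient="records")
        except ConfigError as exc:
            stats_json["private_vs_shared"] = {"error": str(exc)}

        del_mask = polarized.ok_mask & (
            categories["category"].to_numpy() == "deleterious"
        )
        gft = ls.genotype_frequency_table(polarized, inputs.assignment, del_mask)
        write_table(gft, outdir / "genotype_frequencies.tsv", config)
        written["genotype_frequencies"] = outdir / "genotype_frequencies.tsv"

        stage = "windows"
        maf_table = vio.maf_filter(polarized, float(th["min_maf_snp"]))
        dw = int(th["diversity_window"])
        lw = int(th["load_window"])
        pi_df = win.windowed_pi(
            maf_table, inputs.assignment, dw, inputs.chrom_sizes
        )
        d_df = win.windowed_tajimas_d(
            maf_table, inputs.assignment, dw, inputs.chrom_sizes
        )
        diversity = pi_df.merge(
            d_df[["chrom", "start0", "end", "population", "tajima_d", "n_segregating"]],
            on=["chrom", "start0", "end", "population"],
        )
        write_table(diversity, outdir / "diversity_windows.tsv", config)
        written["diversity_windows"] = outdir / "diversity_windows.tsv"

        acc_load, pop_load = win.window_relative_load(
            polarized, categories, inputs.assignment, lw, inputs.chrom_sizes
        )
        big = win.make_windows(inputs.chrom_sizes, lw)
        pi_big = win.windowed_pi(maf_table, inputs.assignment, lw, inputs.chrom_sizes)
        if len(inputs.genetic_map):
            big = win.interpolate_recombination(inputs.genetic_map, big)
        else:
            big["recomb_rate"] = np.nan
        if len(inputs.sweep):
            big = win.attach_sweep(inputs.sweep, big)
        else:
            big["sweep_stat"] = np.nan

        window_stats = pi_big.merge(
            big[["chrom", "start0", "end", "recomb_rate", "sweep_stat"]],
            on=["chrom", "start0", "end"],
        ).merge(
            pop_load, on=["chrom", "start0", "end", "population"], how="left"
        )
        write_table(window_stats, outdir / "window_stats.tsv", config)
        written["window_stats"] = outdir / "window_stats.tsv"

        acc_load = acc_load.assign(
            window=acc_load["chrom"]
            + ":"
            + acc_load["start0"].astype(str)
        )
        hl_rows = []
        for pop in inputs.assignment.populations():
            pop_stats = window_stats[window_stats["population"] == pop].assign(
                window=lambda d: d["chrom"] + ":" + d["start0"].astype(str)
            )
            loads = acc_load[acc_load["population"] == pop][
                ["window", "ratio"]
            ].rename(columns={"ratio": "value"})
            for statistic in ("pi", "recomb_rate", "sweep_stat"):
                stat = pop_stats.set_index("window")[statistic]
                try:
                    res = win.high_low_partition_test(
                        stat, loads, float(th["alpha"])
                    )
                    hl_rows.append(
                        {
                            "population": pop,
                            "statistic": statistic,
                            "mean_load_low": res.mean_load_low,
                            "mean_load_high": res.mean_load_high,
                            "p_value": res.p_value,
                            "verdict": res.verdict,
                        }
                    )
                except ConfigError as exc:
                    hl_rows.append(
                        {
                            "population": pop,
                            "statistic": statistic,
                            "mean_load_low": np.nan,
                            "mean_load_high": np.nan,
                            "p_value": np.nan,
                            "verdict": f"undefined ({exc})",
                        }
                    )
        write_table(pd.DataFrame(hl_rows), outdir / "highlow_table.tsv", config)
        written["highlow_table"] = outdir / "highlow_table.tsv"

        stage = "sv"
        if inputs.sv_paths:
            calls = sva.read_caller_vcfs(inputs.sv_paths)
            consensus = sva.consensus_per_accession(
                calls,
                int(th["sv_max_dist"]),
                float(th["sv_min_overlap"]),
                int(th["sv_min_size"]),
            )
            catalogue = sva.collapse_across_accessions(
                consensus, int(th["sv_max_dist"]), float(th["sv_min_overlap"])
            )
            catalogue = sva.sv_filter_and_polarize(
                catalogue,
                [a for a in inputs.matrix.accessions],
                inputs.assignment.outgroup,
                float(th["sv_min_maf"]),
            )
            write_table(catalogue, outdir / "sv_catalogue.tsv", config)
            written["sv_catalogue"] = outdir / "sv_catalogue.tsv"
            if len(inputs.gene_models):
                genome_size = int(sum(inputs.chrom_sizes.values()))
                overlap = sva.genic_feature_overlap(
                    catalogue, inputs.gene_models, genome_size
                )
                write_table(overlap, outdir / "sv_overlap_summary.tsv", config)
                written["sv_overlap_summary"] = outdir / "sv_overlap_summary.tsv"
                sv_acc, sv_tests = sva.load_in_sv_vs_outside(
                    catalogue, categories, polarized, inputs.assignment,
                    inputs.gene_models,
                )
                write_table(sv_acc, outdir / "sv_load.tsv", config)
                written["sv_load"] = outdir / "sv_load.tsv"
                stats_json["sv_load_ttest"] = sv_tests.to_dict(orient="records")

        stage = "report"
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_json, fh, indent=2, sort_keys=True, default=float)
        written["stats"] = outdir / "stats.json"
        logger.info("pipeline complete: %d tables", len(written))
        return written
    except MutloadError as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
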