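"""End-to-end orchestration: simulate -> sample -> offsets -> transplant ->
evaluation, with reproducible per-stage seeding and file outputs."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as olio
from .gf import GFModel, GFParams, fit_gf, gf_offset_matrix
from .landscape import env_table
from .metrics import OffsetMatrix, env_distance_matrix, fst_matrix
from .simulate import (
    SampleMatrix,
    ScenarioRun,
    SCENARIOS,
    desk_config,
    export_vcf,
    full_scale_config,
    run_scenario,
    sample_and_filter,
)
from .transplant import (
    cg_fitness_matrix,
    core_edge_summary,
    evaluate_offsets,
    local_adaptation,
    sympatric_advantage,
    q1_adjacent_offsets,
    q1_offset_vs_demesize,
)

__all__ = [
    "RunConfig",
    "stage_seed",
    "analyze_replicate",
    "run_all",
    "q1_run_config",
    "transplant_run_config",
]

#: GF offset variants: (label, loci subset, env subset)
GF_VARIANTS = {
    "gf_genome_all": ("genome", "all"),
    "gf_genome_causal": ("genome", "causal"),
    "gf_causal_all": ("causal", "all"),
    "gf_causal_causal": ("causal", "causal"),
}


def stage_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Deterministic sub-seed for a named stage of a named replicate."""
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, zlib.crc32(stage.encode()), replicate])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """One reproducible run: scenario, scale preset, replicate count, seeds."""

    scenario: str = "case1"
    preset: str = "desk"
    replicates: int = 1
    master_seed: int = 0
    out_dir: str = "results/run"
    n_trees: int = 30
    max_snps: int = 400
    gf_variants: tuple[str, ...] = ("gf_genome_all",)
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.preset not in ("desk", "full"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        unknown = set(self.gf_variants) - set(GF_VARIANTS)
        if unknown:
            raise ValueError(f"unknown GF variants: {sorted(unknown)}")

    def sim_config(self):
        base = desk_config() if self.preset == "desk" else full_scale_config()
        return replace(base, **self.sim_overrides)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "gf_variants" in data:
            data["gf_variants"] = tuple(data["gf_variants"])
        return cls(**data)


def q1_run_config(scheme: str, master_seed: int, replicates: int = 10,
                  out_dir: str = "results/q1") -> RunConfig:
    """Frozen desk-scale settings for the deme-size drift analysis.

    Calibrated once by pilot runs (see docs/methods.md): half-scale deme
    sizes (5..100 individuals, N=5000), mu=1e-7, 120 neutral generations,
    20 trees over at most 400 SNPs. At this scale the adjacent-shift GF
    Offset vs deme-size correlation is reliably negative; smaller demes
    lose the signal to sampling noise."""
    if scheme not in ("equal", "increasing", "decreasing"):
        raise ValueError(f"unknown deme-size scheme {scheme!r}")
    return RunConfig(
        scenario=f"q1_{scheme}",
        preset="desk",
        replicates=replicates,
        master_seed=master_seed,
        out_dir=out_dir,
        n_trees=20,
        max_snps=400,
        sim_overrides={"deme_size": 50, "mu": 1.0e-7, "generations": 120},
    )


def transplant_run_config(scenario: str, master_seed: int, replicates: int = 10,
                          out_dir: str = "results/transplant",
                          gf_variants: tuple[str, ...] = ("gf_genome_all",)) -> RunConfig:
    """Frozen desk-scale settings for the common-garden evaluation runs
    (selection scenarios; see docs/methods.md for the calibration pilots)."""
    return RunConfig(
        scenario=scenario,
        preset="desk",
        replicates=replicates,
        master_seed=master_seed,
        out_dir=out_dir,
        n_trees=30,
        max_snps=400,
        gf_variants=gf_variants,
    )


def _subsample_snps(freqs: np.ndarray, names: list[str], max_snps: int, seed: int):
    if freqs.shape[1] <= max_snps:
        return freqs, names
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(freqs.shape[1], size=max_snps, replace=False))
    return freqs[:, keep], [names[i] for i in keep]


def fit_gf_for_sample(
    sample: SampleMatrix,
    env_df: pd.DataFrame,
    loci_subset: str = "genome",
    n_trees: int = 30,
    max_snps: int = 400,
    seed: int = 0,
) -> GFModel:
    """Fit the turnover-function model on a sample's per-deme frequencies.

    ``loci_subset='causal'`` restricts to QTN loci. For speed, at most
    ``max_snps`` SNP columns are used (random but seed-stable subsample)."""
    if loci_subset == "causal":
        cols = np.nonzero(sample.sites.is_qtn)[0]
        if cols.size == 0:
            raise ValueError("no causal loci available")
    else:
        cols = np.arange(sample.freqs.shape[1])
    names = [f"site{sample.kept_loci[c]}" for c in cols]
    freqs, names = _subsample_snps(sample.freqs[:, cols], names, max_snps, seed)
    params = GFParams(n_trees=n_trees, seed=seed)
    return fit_gf(freqs, env_df, params, snp_names=names)


def compute_offsets(
    run: ScenarioRun,
    sample: SampleMatrix,
    config: RunConfig,
    replicate: int = 0,
) -> tuple[dict[str, OffsetMatrix], dict[str, GFModel]]:
    """All offset matrices for one replicate: the requested GF variants,
    Euclidean and Mahalanobis environmental distances (all/causal), and
    Weir-Cockerham F_ST (genome, and causal when QTNs exist)."""
    fields = run.all_fields(seed=stage_seed(config.master_seed, "decoys", replicate))
    all_df = pd.DataFrame({f.name: f.values for f in fields})
    causal_df = all_df[[f.name for f in fields if f.causal]]

    offsets: dict[str, OffsetMatrix] = {}
    models: dict[str, GFModel] = {}
    for label in config.gf_variants:
        loci, envsub = GF_VARIANTS[label]
        if loci == "causal" and not sample.sites.is_qtn.any():
            continue
        env_df = causal_df if envsub == "causal" else all_df
        model = fit_gf_for_sample(
            sample,
            env_df,
            loci_subset=loci,
            n_trees=config.n_trees,
            max_snps=config.max_snps,
            seed=stage_seed(config.master_seed, f"gf_{label}", replicate),
        )
        models[label] = model
        offsets[label] = OffsetMatrix(
            metric=label, subset=loci, values=gf_offset_matrix(model, env_df)
        )

    offsets["ed_all"] = env_distance_matrix(fields, "euclidean", "all")
    offsets["ed_causal"] = env_distance_matrix(fields, "euclidean", "causal")
    offsets["md_all"] = env_distance_matrix(fields, "mahalanobis", "all")
    offsets["md_causal"] = env_distance_matrix(fields, "mahalanobis", "causal")
    offsets["fst_genome"] = fst_matrix(sample, "genome")
    if sample.sites.is_qtn.any():
        offsets["fst_causal"] = fst_matrix(sample, "causal")
    return offsets, models


def analyze_replicate(config: RunConfig, replicate: int = 0) -> dict:
    """Simulate and fully analyze one replicate; returns in-memory results."""
    sim_cfg = config.sim_config()
    run = run_scenario(
        config.scenario, sim_cfg, seed=stage_seed(config.master_seed, "simulate", replicate)
    )
    sample = sample_and_filter(run, seed=stage_seed(config.master_seed, "sample", replicate))
    result: dict = {"run": run, "sample": sample, "replicate": replicate}

    if config.scenario.startswith("q1_"):
        env_df = pd.DataFrame({"env_1": run.causal_fields[0].values})
        model = fit_gf_for_sample(
            sample,
            env_df,
            n_trees=config.n_trees,
            max_snps=config.max_snps,
            seed=stage_seed(config.master_seed, "gf_q1", replicate),
        )
        adj = q1_adjacent_offsets(model, run.causal_fields[0].values, sim_cfg.nx, sim_cfg.ny)
        result["gf_model"] = model
        result["adjacent_offsets"] = adj
        result["pearson_r"] = q1_offset_vs_demesize(adj, run.grid.deme_sizes)
        return result

    offsets, models = compute_offsets(run, sample, config, replicate)
    cg = cg_fitness_matrix(run, sample)
    evaluation = evaluate_offsets(
        offsets, cg, sim_cfg.nx, sim_cfg.ny, replicate=replicate
    )
    result.update(
        offsets=offsets,
        gf_models=models,
        cg_fitness=cg,
        local_adaptation=local_adaptation(cg),
        sympatric_advantage=sympatric_advantage(cg),
        evaluation=evaluation,
    )
    return result


def run_all(config: RunConfig) -> Path:
    """Run every replicate, write all artifacts under ``config.out_dir`` and
    return the manifest path. Outputs per replicate: VCF of the sample, the
    environment table, offset matrices, turnover curves and the evaluation
    table; plus pooled evaluation and summary tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    sim_cfg = config.sim_config()

    eval_tables = []
    summary_rows = []
    for rep in range(config.replicates):
        rep_dir = out / f"rep{rep}"
        rep_dir.mkdir(exist_ok=True)
        res = analyze_replicate(config, rep)
        run: ScenarioRun = res["run"]
        sample: SampleMatrix = res["sample"]
        export_vcf(sample, sim_cfg, str(rep_dir / "sample.vcf"))
        fields = (
            run.all_fields(seed=stage_seed(config.master_seed, "decoys", rep))
            if not config.scenario.startswith("q1_")
            else run.causal_fields
        )
        olio.write_env_table(rep_dir / "environments.tsv", run.grid, fields)

        if config.scenario.startswith("q1_"):
            olio.write_turnover_curves(rep_dir / "turnover.tsv", res["gf_model"])
            pd.DataFrame(
                {
                    "deme_id": np.arange(run.grid.n_demes),
                    "deme_size": run.grid.deme_sizes,
                    "adjacent_gf_offset": res["adjacent_offsets"],
                }
            ).to_csv(rep_dir / "adjacent_offsets.tsv", sep="\t", index=False)
            summary_rows.append({"replicate": rep, "pearson_r": res["pearson_r"]})
        else:
            for name, om in res["offsets"].items():
                olio.write_offset_matrix(rep_dir / f"offset_{name}.tsv", om)
            for name, model in res["gf_models"].items():
                olio.write_turnover_curves(rep_dir / f"turnover_{name}.tsv", model)
            pd.DataFrame(res["cg_fitness"]).to_csv(
                rep_dir / "cg_fitness.tsv", sep="\t", index_label="source"
            )
            res["evaluation"].to_csv(rep_dir / "evaluation.tsv", sep="\t", index=False)
            eval_tables.append(res["evaluation"])
            summary_rows.append(
                {
                    "replicate": rep,
                    "local_adaptation": res["local_adaptation"],
                    "sympatric_advantage": res["sympatric_advantage"],
                }
            )

    if eval_tables:
        pooled = pd.concat(eval_tables, ignore_index=True)
        pooled.to_csv(out / "evaluation.tsv", sep="\t", index=False)
        core_edge_summary(pooled).to_csv(out / "core_edge_summary.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    return olio.write_manifest(out, extra={"scenario": config.scenario, "preset": config.preset})
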