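"""End-to-end orchestration: one declarative config, one manifest.

Stage order: ingest → batch QC → batch filter → log2 → completeness filter →
imputation → three normalization branches → attribute-weighting ensemble →
top-k → three-model RFE → subset combination → first-pass U test → merge →
second-pass validation → z-score/enrichment exports.

Every artifact is TSV; the manifest records per-stage counts, the config
hash and the seed, and is byte-identical across runs with the same config
and seed.  The RFE stage, the rank-based validation and the reported
effects run on the mean-normalized branch: per-sample baseline shifts are
technical variation, and leaving them in would both blunt true differences
and let sample-level offsets masquerade as group effects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import io, preprocess, reporting, rfe, simulate, stats, weighting

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
class PreprocessSettings(BaseModel):
    epsilon: float = Field(0.05, gt=0)
    log2_transform: bool = True
    min_observed_fraction: float = Field(0.5, ge=0, le=1)
    batches_keep: Optional[list[str]] = None  # None = keep all
    ratio_reference: str = "grand_mean"
    qc_missingness_margin: float = Field(0.15, gt=0)


class EnsembleSettings(BaseModel):
    top_k: int = Field(200, ge=1)
    vote_threshold: float = Field(0.5, gt=0, le=1)


class RFESettings(BaseModel):
    models: list[str] = list(rfe.RFE_MODELS)
    step: int | Literal["auto"] = "auto"
    # forest size for candidate refinement; importance ranking at n ≈ 10
    # samples is stable well below the usual library default
    n_estimators: int = Field(50, ge=10)
    combine_mode: Literal["intersection", "union"] = "union"

    @field_validator("models")
    @classmethod
    def _known_models(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(rfe.RFE_MODELS)
        if unknown:
            raise ValueError(f"unknown RFE model(s): {sorted(unknown)}")
        return v


class StatSettings(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    exact_limit: int = Field(12, ge=4)
    bh_correct: bool = False
    first_pass_scope: Literal["topk", "all"] = "topk"

    def to_config(self) -> stats.StatConfig:
        return stats.StatConfig(self.alpha, self.exact_limit, self.bh_correct)


class SyntheticSettings(BaseModel):
    n_proteins: int = 2000
    n_per_group: int = 5
    n_batches: int = 3
    dep_fraction: float = Field(0.05, ge=0, lt=1)
    log2_fc: float = Field(2.0, gt=0)
    base_mean: float = 20.0
    base_sd: float = 3.0
    replicate_sd: float = 0.3
    batch_shift_sd: float = 0.5
    mnar_midpoint: Optional[float] = 16.0
    mnar_slope: float = 1.0
    mcar_rate: float = Field(0.02, ge=0, lt=1)
    corrupted_batch: Optional[str] = None
    missingness_boost: float = 0.3

    def to_config(self, seed: int) -> simulate.SyntheticConfig:
        return simulate.SyntheticConfig(seed=seed, **self.model_dump())


class PipelineConfig(BaseModel):
    """Declarative description of one full run."""

    seed: int = 0
    outdir: str = "depselect_run"
    matrix_path: Optional[str] = None
    metadata_path: Optional[str] = None
    zero_as_missing: bool = True
    synthetic: Optional[SyntheticSettings] = None
    preprocess: PreprocessSettings = PreprocessSettings()
    ensemble: EnsembleSettings = EnsembleSettings()
    rfe: RFESettings = RFESettings()
    stats: StatSettings = StatSettings()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------
class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _auto_step(n_features: int) -> int:
    # keep the elimination path to ~12 evaluated sizes on large candidate sets
    return max(1, int(np.ceil(n_features / 12)))


def run_pipeline(
    config: PipelineConfig,
    matrix: io.IntensityMatrix | None = None,
    samples: io.SampleTable | None = None,
) -> dict:
    """Execute the full discovery procedure and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    counts = manifest["stages"]
    t_start = time.time()

    def _art(name: str, filename: str) -> Path:
        path = outdir / filename
        manifest["artifacts"][name] = filename
        return path

    stage = "ingest"
    try:
        if matrix is None:
            if config.synthetic is not None:
                syn = config.synthetic.to_config(stage_seed(config.seed, "synthetic"))
                matrix, samples, truth = simulate.simulate_dataset(syn)
                io.write_intensity_matrix(matrix, _art("input_matrix", "matrix.tsv"))
                io.write_table(samples.table, _art("sample_metadata", "samples.tsv"))
                io.write_table(truth.table, _art("truth", "truth.tsv"))
            elif config.matrix_path and config.metadata_path:
                matrix = io.read_protein_matrix(
                    config.matrix_path, zero_as_missing=config.zero_as_missing
                )
                samples = io.read_sample_metadata(config.metadata_path)
            else:
                raise ValueError(
                    "provide matrix/metadata paths or a synthetic block"
                )
        assert samples is not None
        io.check_samples_covered(matrix, samples)
        samples = samples.subset(matrix.samples)
        samples.two_group_labels()
        samples.validate_group_sizes(2)
        counts["proteins_in_input"] = matrix.n_proteins
        counts["samples_in_input"] = matrix.n_samples

        stage = "batch_qc"
        if len(set(samples.table["batch"])) >= 2:
            qc = preprocess.batch_qc(
                matrix, samples, config.preprocess.qc_missingness_margin
            )
            io.write_table(qc, _art("batch_qc", "batch_qc.tsv"))
            counts["batches_flagged"] = int(qc["flagged"].sum())

        stage = "filter_batches"
        if config.preprocess.batches_keep is not None:
            matrix, samples = preprocess.filter_batches(
                matrix, samples, set(config.preprocess.batches_keep)
            )
        counts["samples_after_batch_filter"] = matrix.n_samples

        stage = "log2_transform"
        if config.preprocess.log2_transform:
            matrix = preprocess.log2_transform(matrix)

        stage = "completeness_filter"
        matrix, dropped_incomplete = preprocess.completeness_filter(
            matrix, samples, config.preprocess.min_observed_fraction
        )
        counts["proteins_dropped_incomplete"] = len(dropped_incomplete)

        stage = "impute"
        matrix, dropped_allmissing = preprocess.impute_missing(
            matrix, config.preprocess.epsilon
        )
        counts["proteins_dropped_all_missing"] = len(dropped_allmissing)
        counts["proteins_after_filters"] = matrix.n_proteins
        io.write_intensity_matrix(matrix, _art("imputed_matrix", "imputed.tsv"))

        stage = "normalize"
        branch_mean = preprocess.mean_normalize(matrix)
        branch_ratio = preprocess.ratio_normalize(
            matrix, config.preprocess.ratio_reference, samples
        )
        branch_binomial = preprocess.binomial_transform(matrix)
        io.write_intensity_matrix(branch_mean, _art("mean_branch", "norm_mean.tsv"))
        io.write_intensity_matrix(branch_ratio, _art("ratio_branch", "norm_ratio.tsv"))
        codes = branch_binomial.as_labels()
        codes.index.name = "protein_id"
        io.write_table(codes.reset_index(), _art("binomial_branch", "norm_binomial.tsv"))

        stage = "attribute_weighting"
        labels = samples.groups.reindex(matrix.samples)
        y = labels.to_numpy()
        w_seed = stage_seed(config.seed, "weighting")
        tables = [
            weighting.compute_weight_table(
                branch_mean.values.T,
                y,
                weighting.CONTINUOUS_ALGORITHMS,
                config.ensemble.vote_threshold,
                w_seed,
                branch="mean",
            ),
            weighting.compute_weight_table(
                branch_ratio.values.T,
                y,
                weighting.CONTINUOUS_ALGORITHMS,
                config.ensemble.vote_threshold,
                w_seed,
                branch="ratio",
            ),
            weighting.compute_weight_table(
                branch_binomial.codes.T.astype(float),
                y,
                weighting.CATEGORICAL_ALGORITHMS,
                config.ensemble.vote_threshold,
                w_seed,
                branch="binomial",
            ),
        ]
        pooled = weighting.pool_weight_tables(tables)
        io.write_table(pooled.to_frame(), _art("weight_table", "weights.tsv"))
        counts["vote_columns"] = pooled.n_algorithms

        stage = "select_top_k"
        top_ids = pooled.top_k(config.ensemble.top_k)
        counts["top_k"] = len(top_ids)
        io.write_table(
            pd.DataFrame({"protein_id": top_ids}), _art("top_k", "top_candidates.tsv")
        )

        stage = "rfe"
        Xc = branch_mean.values.loc[top_ids].T  # samples x candidates
        step = (
            _auto_step(len(top_ids))
            if config.rfe.step == "auto"
            else int(config.rfe.step)
        )
        results = []
        for model in config.rfe.models:
            res = rfe.rfe_rank(
                Xc,
                y,
                model,
                seed=stage_seed(config.seed, f"rfe:{model}"),
                step=step,
                n_estimators=config.rfe.n_estimators,
            )
            io.write_table(res.order_frame(), _art(f"rfe_order_{model}", f"rfe_{model}_order.tsv"))
            io.write_table(res.curve_frame(), _art(f"rfe_curve_{model}", f"rfe_{model}_curve.tsv"))
            results.append(res)
        combined = rfe.combine_subsets(
            [r.optimal_subset for r in results], config.rfe.combine_mode
        )
        io.write_table(
            pd.DataFrame({"protein_id": combined.intersection}),
            _art("rfe_intersection", "rfe_intersection.tsv"),
        )
        io.write_table(
            pd.DataFrame({"protein_id": combined.union}),
            _art("rfe_union", "rfe_union.tsv"),
        )
        counts["rfe_intersection"] = len(combined.intersection)
        counts["rfe_union"] = len(combined.union)
        counts["rfe_fallback_to_union"] = combined.fallback_applied
        rfe_set = combined.selected

        stage = "first_pass_mwu"
        stat_cfg = config.stats.to_config()
        scope = (
            top_ids
            if config.stats.first_pass_scope == "topk"
            else list(branch_mean.values.index)
        )
        mwu_set, first_table = stats.first_pass_filter(
            branch_mean.values, labels, scope, stat_cfg
        )
        io.write_table(first_table, _art("first_pass", "mwu_first_pass.tsv"))
        counts["first_pass_significant"] = len(mwu_set)

        stage = "merge_candidates"
        merged = stats.merge_candidates(scope, rfe_set, mwu_set)
        io.write_table(merged, _art("merged", "merged_candidates.tsv"))
        counts["merged"] = len(merged)

        stage = "second_pass_mwu"
        dep_table = stats.second_pass_validate(
            branch_mean.values, labels, merged, first_table, stat_cfg, matrix.gene_symbols
        )
        io.write_table(dep_table, _art("dep_table", "dep_table.tsv"))
        counts["final_deps"] = int(dep_table["final"].sum())

        stage = "reporting"
        final_ids = list(dep_table.loc[dep_table["final"], "protein_id"])
        if final_ids:
            std = reporting.zscore_standardize(branch_mean.values.loc[final_ids])
            reporting.export_heatmap_table(
                std, samples, _art("heatmap_table", "heatmap.tsv")
            )
            export_counts = reporting.export_enrichment_inputs(
                dep_table, outdir / "enrichment"
            )
            manifest["artifacts"]["gene_list"] = "enrichment_genes.txt"
            manifest["artifacts"]["ranked_list"] = "enrichment_ranked.rnk"
            counts["genes_exported"] = export_counts["exported"]
        else:
            counts["genes_exported"] = 0
    except Exception as exc:  # noqa: BLE001 — re-raise with the failing stage named
        raise StageError(stage, exc) from exc

    manifest["runtime_seconds"] = round(time.time() - t_start, 2)
    reproducible = {k: v for k, v in manifest.items() if k != "runtime_seconds"}
    (outdir / "manifest.json").write_text(
        json.dumps(reproducible, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline finished in %.1fs", manifest["runtime_seconds"])
    return manifest


def recovery_benchmark(
    seeds: list[int],
    outdir: str | Path,
    synthetic: SyntheticSettings | None = None,
    **config_overrides,
) -> pd.DataFrame:
    """Run the full pipeline over several seeds and score spike-in recovery.

    Returns one row per seed with sensitivity and false-discovery
    proportion against the generator's ground truth.
    """
    outdir = Path(outdir)
    rows = []
    for seed in seeds:
        cfg = PipelineConfig(
            seed=seed,
            outdir=str(outdir / f"seed_{seed}"),
            synthetic=synthetic or SyntheticSettings(),
            **config_overrides,
        )
        manifest = run_pipeline(cfg)
        dep = io.read_table(outdir / f"seed_{seed}" / "dep_table.tsv")
        truth = io.read_table(outdir / f"seed_{seed}" / "truth.tsv")
        metrics = simulate.evaluate_recovery(dep, truth)
        rows.append(
            {
                "seed": seed,
                "sensitivity": metrics.sensitivity,
                "fdp": metrics.false_discovery_proportion,
                "n_final": metrics.n_called,
                "top_k": manifest["stages"]["top_k"],
            }
        )
    return pd.DataFrame(rows)
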