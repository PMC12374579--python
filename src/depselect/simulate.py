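"""Synthetic DIA-like proteome generator with known spiked effects.

Emulates the structure of a two-group, small-n label-free DIA experiment:
~2,000 protein groups with log-normal intensities, five biological
replicates per group acquired in three batches, a configurable fraction of
spiked differential proteins at a fixed |log2 fold change| (sign randomized
per protein, split symmetrically ±fc/2 across groups so sample-level
normalization cannot absorb it), additive per-sample batch shifts, and
missingness that rises as intensity falls (censoring at the detection
floor) on top of a small completely-at-random component.  One batch can be
deliberately corrupted with extra missingness to give the batch-QC stage a
positive control.

Everything is deterministic given the seed, and the ground truth table
supports sensitivity / false-discovery scoring of any downstream caller.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntensityMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study-like conditions.

    All intensity parameters are on the log2 scale; the exported matrix is
    raw-scale (2**log2) so the full ingest path is exercised.
    """

    n_proteins: int = 2000
    n_per_group: int = 5
    n_batches: int = 3
    dep_fraction: float = 0.05
    log2_fc: float = 2.0
    base_mean: float = 20.0
    base_sd: float = 3.0
    replicate_sd: float = 0.3  # per-replicate log2 noise
    batch_shift_sd: float = 0.5
    group_labels: tuple[str, str] = ("AL", "IF")
    # missingness model
    mnar_midpoint: float | None = 16.0  # log2 intensity of 50% MNAR dropout
    mnar_slope: float = 1.0
    mcar_rate: float = 0.02
    corrupted_batch: str | None = None
    missingness_boost: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.dep_fraction < 1:
            raise ValueError("dep_fraction must be in [0, 1)")
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must be in [0, 1)")
        if self.log2_fc <= 0:
            raise ValueError("log2_fc must be positive")

    @property
    def n_deps(self) -> int:
        return round(self.dep_fraction * self.n_proteins)


@dataclass
class SyntheticTruth:
    """Ground truth: spiked proteins, their signed effects, design labels."""

    table: pd.DataFrame  # protein_id, is_dep, true_log2_fc
    config: SyntheticConfig

    @property
    def dep_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_dep"], "protein_id"])


def _design(config: SyntheticConfig) -> SampleTable:
    rows = []
    for g in config.group_labels:
        for i in range(config.n_per_group):
            rows.append(
                {
                    "sample_id": f"{g}_{i + 1}",
                    "group": g,
                    "batch": str(i % config.n_batches + 1),
                    "timepoint": "",
                }
            )
    return SampleTable(pd.DataFrame(rows))


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[IntensityMatrix, SampleTable, SyntheticTruth]:
    """Complete (no-missingness) raw-scale matrix plus design and truth.

    Per protein p and sample s on the log2 scale:
    ``mu_p + group_effect(p, s) + batch_shift(batch(s)) + N(0, replicate_sd)``
    with ``mu_p ~ N(base_mean, base_sd)`` and group effects ±log2_fc/2 for
    spiked proteins.
    """
    rng = np.random.default_rng(config.seed)
    samples = _design(config)
    ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    genes = pd.Series([f"Gene{i + 1}" for i in range(config.n_proteins)], index=ids)

    n_dep = config.n_deps
    if config.dep_fraction > 0 and n_dep < 1:
        warnings.warn("dep_fraction too small for any spiked protein", UserWarning)
    dep_idx = rng.choice(config.n_proteins, size=n_dep, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_dep)
    true_fc = np.zeros(config.n_proteins)
    true_fc[dep_idx] = signs * config.log2_fc

    mu = rng.normal(config.base_mean, config.base_sd, size=config.n_proteins)
    group_of = samples.groups
    batch_of = samples.batches
    shifts = {
        b: rng.normal(0.0, config.batch_shift_sd)
        for b in sorted(batch_of.unique())
    }
    ga, gb = config.group_labels
    cols = {}
    for sid in samples.samples:
        # effect is +fc/2 in the second group, −fc/2 in the first
        half = np.where(group_of[sid] == gb, 0.5, -0.5)
        log2v = (
            mu
            + true_fc * half
            + shifts[batch_of[sid]]
            + rng.normal(0.0, config.replicate_sd, size=config.n_proteins)
        )
        cols[sid] = log2v
    log2_values = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))
    values = np.power(2.0, log2_values)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "protein_id": ids,
                "is_dep": true_fc != 0,
                "true_log2_fc": true_fc,
            }
        ),
        config,
    )
    return IntensityMatrix(values, mask, genes), samples, truth


def missingness_probability(
    log2_values: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """MNAR logistic dropout plus the MCAR floor, capped at 0.95."""
    p = np.full(log2_values.shape, float(config.mcar_rate))
    if config.mnar_midpoint is not None:
        z = (config.mnar_midpoint - log2_values) / config.mnar_slope
        p = p + 1.0 / (1.0 + np.exp(-z))
    return np.minimum(p, 0.95)


def inject_missingness(
    matrix: IntensityMatrix,
    samples: SampleTable,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Blank cells according to the intensity-dependent missingness model."""
    if matrix.missing_mask.to_numpy().any():
        raise ValueError("inject_missingness expects a complete matrix")
    rng = rng or np.random.default_rng(config.seed + 1)
    log2v = np.log2(matrix.values.to_numpy())
    p = missingness_probability(log2v, config)
    if config.corrupted_batch is not None:
        batch_of = samples.batches
        boost_cols = np.array(
            [batch_of[s] == str(config.corrupted_batch) for s in matrix.samples]
        )
        p = np.minimum(p + config.missingness_boost * boost_cols[None, :], 0.95)
    drop = rng.random(p.shape) < p
    values = matrix.values.mask(pd.DataFrame(drop, index=matrix.values.index,
                                             columns=matrix.values.columns))
    mask = matrix.missing_mask | drop
    return IntensityMatrix(values, mask, matrix.gene_symbols)


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[IntensityMatrix, SampleTable, SyntheticTruth]:
    """Generate and apply missingness in one deterministic call."""
    matrix, samples, truth = generate_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    return inject_missingness(matrix, samples, config, rng), samples, truth


@dataclass
class RecoveryMetrics:
    sensitivity: float
    false_discovery_proportion: float
    n_true: int
    n_called: int
    n_true_positive: int
    by_branch: dict[str, int] = field(default_factory=dict)


def evaluate_recovery(
    dep_table: pd.DataFrame, truth: SyntheticTruth | pd.DataFrame
) -> RecoveryMetrics:
    """Score a final DEP table against the spike-in ground truth.

    sensitivity = |called ∩ true| / |true|; FDP = |called \\ true| / |called|
    (0 when nothing is called).
    """
    truth_table = truth.table if isinstance(truth, SyntheticTruth) else truth
    true_ids = set(truth_table.loc[truth_table["is_dep"].astype(bool), "protein_id"])
    final = dep_table[dep_table["final"].astype(bool)]
    called = set(final["protein_id"])
    tp = len(called & true_ids)
    sens = tp / len(true_ids) if true_ids else 0.0
    fdp = (len(called) - tp) / max(len(called), 1)
    by_branch: dict[str, int] = {}
    if "selected_by" in final.columns:
        for flags in final["selected_by"]:
            for flag in str(flags).split(";"):
                if flag:
                    by_branch[flag] = by_branch.get(flag, 0) + 1
    return RecoveryMetrics(sens, fdp, len(true_ids), len(called), tp, by_branch)
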