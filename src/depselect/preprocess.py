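"""Imputation, the three normalization strategies, and batch handling.

The core operations are scikit-learn transformers working on the usual
``samples x features`` orientation (features = proteins), so they compose
with sklearn pipelines.  The module-level functions wrap them to operate on
:class:`~depselect.io.IntensityMatrix`, which is stored proteins x samples.

Missing values in DIA data are missing-not-at-random (low intensity is
censored), so imputation uses the per-protein observed minimum minus a small
offset: the imputed value sits just below everything that was quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OneToOneFeatureMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import IntensityMatrix, SampleTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sklearn-style transformers (samples x features)
# ---------------------------------------------------------------------------
class MinObservedImputer(OneToOneFeatureMixin, TransformerMixin, BaseEstimator):
    """Impute each feature's missing cells with its observed minimum − epsilon.

    Parameters
    ----------
    epsilon : float, default 0.05
        Positive offset subtracted from the per-feature observed minimum.
        On a log2 intensity scale this places imputed values just below the
        detection floor of that protein.
    """

    def __init__(self, epsilon: float = 0.05):
        self.epsilon = epsilon

    def fit(self, X, y=None):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float)
        observed_any = ~np.all(np.isnan(X), axis=0)
        if not observed_any.all():
            raise ValueError(
                "feature(s) with no observed values; drop them before imputation"
            )
        with np.errstate(all="ignore"):
            self.fill_values_ = np.nanmin(X, axis=0) - self.epsilon
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(
            self, X, ensure_all_finite="allow-nan", dtype=float, reset=False, copy=True
        )
        nan_rows, nan_cols = np.where(np.isnan(X))
        X[nan_rows, nan_cols] = self.fill_values_[nan_cols]
        return X


class SampleMeanNormalizer(OneToOneFeatureMixin, TransformerMixin, BaseEstimator):
    """Center every sample (row) on the grand mean of the training matrix.

    Removes per-sample baseline shifts (loading, acquisition drift) while
    preserving the overall intensity level: after the transform every
    sample's mean equals the grand mean.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        self.grand_mean_ = float(np.mean(X))
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return X - X.mean(axis=1, keepdims=True) + self.grand_mean_


class ReferenceRatioNormalizer(OneToOneFeatureMixin, TransformerMixin, BaseEstimator):
    """Subtract a per-feature reference profile (log-scale ratio normalization).

    The reference is the feature-wise mean over the fitted samples (or a
    supplied subset of samples), so each value becomes a log-ratio to the
    reference profile.
    """

    def __init__(self, reference_rows: np.ndarray | None = None):
        self.reference_rows = reference_rows

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        rows = (
            np.arange(X.shape[0])
            if self.reference_rows is None
            else np.asarray(self.reference_rows)
        )
        if rows.size == 0:
            raise ValueError("reference resolves to zero samples")
        self.reference_ = X[rows].mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return X - self.reference_


class MedianBinarizer(OneToOneFeatureMixin, TransformerMixin, BaseEstimator):
    """Dichotomize each feature at its median: 1 = over, 0 = under.

    Exact ties with the median go to "under", so the rule is deterministic
    and a constant feature maps to all-under.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        self.medians_ = np.median(X, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return (X > self.medians_).astype(np.int8)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
@dataclass
class CategoricalMatrix:
    """Proteins x samples over/under codes from the binomial transformation."""

    codes: pd.DataFrame  # int8, 1 = over, 0 = under
    categories: tuple[str, str] = ("under", "over")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def samples(self) -> list[str]:
        return list(self.codes.columns)

    def as_labels(self) -> pd.DataFrame:
        return self.codes.replace({0: self.categories[0], 1: self.categories[1]})


# ---------------------------------------------------------------------------
# IntensityMatrix-level operations
# ---------------------------------------------------------------------------
def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2 of observed intensities; missing cells stay missing."""
    observed = matrix.values.to_numpy()[~matrix.missing_mask.to_numpy()]
    if observed.size and (observed <= 0).any():
        raise ValueError("log2 transform requires strictly positive intensities")
    return IntensityMatrix(
        np.log2(matrix.values), matrix.missing_mask.copy(), matrix.gene_symbols
    )


def completeness_filter(
    matrix: IntensityMatrix, samples: SampleTable, min_fraction: float = 0.5
) -> tuple[IntensityMatrix, list[str]]:
    """Drop proteins observed in fewer than ``min_fraction`` of the samples of
    every group (kept if at least one group reaches the threshold)."""
    groups = samples.groups.reindex(matrix.samples)
    observed = ~matrix.missing_mask
    keep = pd.Series(False, index=matrix.values.index)
    for label in groups.unique():
        cols = groups.index[groups == label]
        keep |= observed[cols].mean(axis=1) >= min_fraction
    dropped = list(matrix.values.index[~keep])
    if dropped:
        logger.info("completeness filter dropped %d protein(s)", len(dropped))
    return matrix.subset_proteins(list(matrix.values.index[keep])), dropped


def impute_missing(
    matrix: IntensityMatrix, epsilon: float = 0.05
) -> tuple[IntensityMatrix, list[str]]:
    """Fill every missing cell of protein p with min(observed of p) − epsilon.

    Proteins with no observed value at all cannot be imputed and are dropped
    (returned in the second element so the removal is auditable).  The
    missingness mask is kept as provenance; observed cells are untouched.
    """
    observed_counts = (~matrix.missing_mask).sum(axis=1)
    dropped = list(matrix.values.index[observed_counts == 0])
    if dropped:
        logger.info("imputation dropped %d all-missing protein(s)", len(dropped))
        matrix = matrix.subset_proteins(
            list(matrix.values.index[observed_counts > 0])
        )
    imputer = MinObservedImputer(epsilon=epsilon)
    filled = imputer.fit_transform(matrix.values.to_numpy().T).T
    values = pd.DataFrame(
        filled, index=matrix.values.index, columns=matrix.values.columns
    )
    return (
        IntensityMatrix(values, matrix.missing_mask.copy(), matrix.gene_symbols),
        dropped,
    )


def _require_complete(matrix: IntensityMatrix, op: str) -> None:
    if matrix.values.isna().to_numpy().any():
        raise ValueError(f"{op} requires a complete matrix; impute first")


def mean_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    _require_complete(matrix, "mean normalization")
    out = SampleMeanNormalizer().fit_transform(matrix.values.to_numpy().T).T
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return IntensityMatrix(values, matrix.missing_mask.copy(), matrix.gene_symbols)


def ratio_normalize(
    matrix: IntensityMatrix,
    reference: str = "grand_mean",
    samples: SampleTable | None = None,
) -> IntensityMatrix:
    """Log-scale ratio to a reference profile.

    ``reference`` is ``"grand_mean"``, ``"reference_group:<label>"`` or
    ``"reference_sample:<id>"``.
    """
    _require_complete(matrix, "ratio normalization")
    if reference == "grand_mean":
        rows = None
    elif reference.startswith("reference_group:"):
        label = reference.split(":", 1)[1]
        if samples is None:
            raise ValueError("reference_group requires sample metadata")
        groups = samples.groups.reindex(matrix.samples)
        rows = np.flatnonzero((groups == label).to_numpy())
        if rows.size == 0:
            raise ValueError(f"reference group {label!r} has no samples")
    elif reference.startswith("reference_sample:"):
        sid = reference.split(":", 1)[1]
        if sid not in matrix.samples:
            raise ValueError(f"reference sample {sid!r} not in matrix")
        rows = np.array([matrix.samples.index(sid)])
    else:
        raise ValueError(f"unknown ratio reference {reference!r}")
    out = (
        ReferenceRatioNormalizer(reference_rows=rows)
        .fit_transform(matrix.values.to_numpy().T)
        .T
    )
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return IntensityMatrix(values, matrix.missing_mask.copy(), matrix.gene_symbols)


def binomial_transform(matrix: IntensityMatrix) -> CategoricalMatrix:
    """Per-protein median split into over/under categories."""
    _require_complete(matrix, "binomial transformation")
    codes = MedianBinarizer().fit_transform(matrix.values.to_numpy().T).T
    return CategoricalMatrix(
        pd.DataFrame(codes, index=matrix.values.index, columns=matrix.values.columns)
    )


def filter_batches(
    matrix: IntensityMatrix, samples: SampleTable, keep: set[str]
) -> tuple[IntensityMatrix, SampleTable]:
    """Retain only samples whose batch label is in ``keep``; re-validate groups."""
    keep = {str(b) for b in keep}
    observed = set(samples.table["batch"])
    unknown = keep - observed
    if unknown:
        raise ValueError(f"unknown batch label(s): {sorted(unknown)}")
    kept_ids = [
        s
        for s in matrix.samples
        if samples.batches.get(s) in keep
    ]
    sub_samples = samples.subset(kept_ids)
    before = set(samples.table["group"])
    after = set(sub_samples.table["group"])
    if before - after:
        raise ValueError(
            f"batch filter emptied group(s): {sorted(before - after)}"
        )
    sub_samples.validate_group_sizes(2)
    return matrix.subset_samples(kept_ids), sub_samples


def batch_qc(
    matrix: IntensityMatrix,
    samples: SampleTable,
    missingness_margin: float = 0.15,
) -> pd.DataFrame:
    """Per-batch quality summary supporting a manual batch-exclusion decision.

    Reports median observed intensity, missingness rate and the median
    within-batch pairwise Pearson correlation; a batch whose missingness rate
    exceeds the median of the other batches by more than
    ``missingness_margin`` is flagged.
    """
    batches = samples.batches.reindex(matrix.samples)
    labels = sorted(batches.unique())
    if len(labels) < 2:
        raise ValueError("batch QC needs at least 2 batches")
    rows = []
    for label in labels:
        cols = [s for s in matrix.samples if batches[s] == label]
        sub = matrix.values[cols]
        mask = matrix.missing_mask[cols]
        obs = sub.to_numpy()[~mask.to_numpy()]
        corr = sub.corr(min_periods=3)
        upper = corr.to_numpy()[np.triu_indices(len(cols), k=1)]
        rows.append(
            {
                "batch": label,
                "n_samples": len(cols),
                "median_intensity": float(np.median(obs)) if obs.size else np.nan,
                "missingness_rate": float(mask.to_numpy().mean()),
                "median_pairwise_correlation": float(np.nanmedian(upper))
                if upper.size
                else np.nan,
            }
        )
    qc = pd.DataFrame(rows)
    flags = []
    for i in range(len(qc)):
        others = qc["missingness_rate"].drop(index=i)
        flags.append(
            bool(qc.loc[i, "missingness_rate"] > others.median() + missingness_margin)
        )
    qc["flagged"] = flags
    return qc
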