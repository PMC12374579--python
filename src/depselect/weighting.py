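"""Ensemble attribute weighting: ten per-protein relevance criteria.

Each criterion scores how well a single protein separates the two sample
groups.  Entropy, chi-square, rule and Gini criteria reduce a continuous
feature to its best binary split, scanning the midpoints between consecutive
distinct sorted values and keeping the split that maximizes the criterion
itself; this makes them invariant under strictly monotone transforms of the
feature and lets every score be checked against small enumeration oracles.
Over/under categorical features (the binomial branch) pass through the same
machinery, where the single category boundary is the only admissible split.

Weights are binarized per algorithm by min-max scaling and thresholding
("selected" votes), votes are summed into a cumulative ensemble score across
algorithms (and, at the pipeline level, across normalization branches), and
the top-k proteins by score are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

#: criteria applicable to continuous intensities
CONTINUOUS_ALGORITHMS = (
    "information_gain",
    "information_gain_ratio",
    "chi_squared",
    "deviation",
    "rule",
    "gini_index",
    "relief",
    "svm",
    "uncertainty",
    "pca",
)
#: the subset that is well defined for categorical (over/under) features —
#: deviation, svm and pca need continuous geometry and are excluded
CATEGORICAL_ALGORITHMS = (
    "information_gain",
    "information_gain_ratio",
    "chi_squared",
    "rule",
    "gini_index",
    "relief",
    "uncertainty",
)


def _entropy(p: np.ndarray) -> np.ndarray:
    """Binary entropy in bits, elementwise, with 0·log0 = 0."""
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def _validate_two_class(y: np.ndarray) -> np.ndarray:
    classes, y01 = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, found {classes.size}")
    counts = np.bincount(y01)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y01.astype(np.int64)


def _split_tables(X: np.ndarray, y01: np.ndarray):
    """All-features split scan: class counts left of each admissible midpoint.

    Returns (k, n1_left, valid) arrays of shape (n-1, p): for split position
    k (left part = k smallest values), the number of class-1 samples on the
    left, and whether the split falls between two distinct values.
    """
    n, p = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    Ys = y01[order]
    c1 = np.cumsum(Ys, axis=0)[: n - 1]  # class-1 count in left part
    k = np.arange(1, n)[:, None].repeat(p, axis=1).astype(float)
    valid = Xs[1:] != Xs[:-1]
    return k, c1.astype(float), valid


def _best_over_splits(crit: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Maximum of a per-split criterion over admissible splits (0 if none)."""
    masked = np.where(valid, crit, -np.inf)
    best = masked.max(axis=0)
    return np.where(np.isfinite(best), best, 0.0)


def _split_criteria(X: np.ndarray, y01: np.ndarray) -> dict[str, np.ndarray]:
    """Compute every split-based criterion for all features in one scan."""
    n, p = X.shape
    n1 = float(y01.sum())
    n0 = float(n - n1)
    h_y = float(_entropy(np.array([n1 / n]))[0])
    gini_y = 1.0 - (n0 / n) ** 2 - (n1 / n) ** 2

    k, c1, valid = _split_tables(X, y01)
    kl = k
    kr = n - k
    n1l, n0l = c1, kl - c1
    n1r, n0r = n1 - c1, n0 - (kl - c1)

    with np.errstate(divide="ignore", invalid="ignore"):
        h_cond = (kl / n) * _entropy(n1l / kl) + (kr / n) * _entropy(n1r / kr)
        ig = h_y - h_cond
        h_split = _entropy(kl / n)
        igr = np.where(h_split > 0, ig / np.where(h_split > 0, h_split, 1.0), 0.0)
        su = 2.0 * ig / (h_split + h_y) if h_y > 0 else np.zeros_like(ig)
        # chi-square of the 2x2 split-vs-class table
        det = n0l * n1r - n1l * n0r
        denom = kl * kr * n0 * n1
        chi2 = np.where(denom > 0, n * det**2 / np.where(denom > 0, denom, 1.0), 0.0)
        gini_children = (kl / n) * (1 - (n0l / kl) ** 2 - (n1l / kl) ** 2) + (
            kr / n
        ) * (1 - (n0r / kr) ** 2 - (n1r / kr) ** 2)
        gini_red = gini_y - gini_children
        rule_acc = (np.maximum(n0l, n1l) + np.maximum(n0r, n1r)) / n
        rule_gain = rule_acc - max(n0, n1) / n

    return {
        "information_gain": _best_over_splits(ig, valid),
        "information_gain_ratio": _best_over_splits(igr, valid),
        "chi_squared": _best_over_splits(chi2, valid),
        "gini_index": _best_over_splits(gini_red, valid),
        "uncertainty": _best_over_splits(su, valid),
        "rule": _best_over_splits(rule_gain, valid),
    }


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    return np.where(rng > 0, (X - lo) / rng_safe, 0.0)


def relief_weights(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Relief with one nearest hit and one nearest miss per instance.

    Every instance is used; features are min-max scaled; distances are
    Manhattan on the scaled features (which coincides with the overlap
    metric on 0/1 categorical codes).  Nearest-neighbour ties break to the
    smallest sample index so the weights are deterministic.
    """
    Xs = _minmax_scale(np.asarray(X, dtype=float))
    n, p = Xs.shape
    diff = np.abs(Xs[:, None, :] - Xs[None, :, :])  # n x n x p
    dist = diff.sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    same = y01[:, None] == y01[None, :]
    w = np.zeros(p)
    for i in range(n):
        hit_pool = np.where(same[i] & (np.arange(n) != i))[0]
        miss_pool = np.where(~same[i])[0]
        hit = hit_pool[np.argmin(dist[i, hit_pool])]
        miss = miss_pool[np.argmin(dist[i, miss_pool])]
        w += diff[i, miss] - diff[i, hit]
    return w / n


def svm_weights(X: np.ndarray, y01: np.ndarray, random_state: int = 0) -> np.ndarray:
    """|coefficients| of a linear max-margin classifier on standardized data,
    trained on all features jointly (C = 1)."""
    Xz = StandardScaler().fit_transform(np.asarray(X, dtype=float))
    clf = SVC(kernel="linear", C=1.0, random_state=random_state)
    clf.fit(Xz, y01)
    return np.abs(np.asarray(clf.coef_).ravel())


def pca_weights(X: np.ndarray) -> np.ndarray:
    """|loading| of each feature on the first principal component of the
    standardized matrix."""
    Xz = StandardScaler().fit_transform(np.asarray(X, dtype=float))
    pca = PCA(n_components=1, svd_solver="full")
    pca.fit(Xz)
    return np.abs(pca.components_[0])


def weight_features(
    X, y, algorithm: str, random_state: int = 0
) -> np.ndarray:
    """One relevance weight per feature under the named criterion.

    ``X`` is samples x features (continuous intensities or 0/1 over/under
    codes); ``y`` holds exactly two class labels.
    """
    X = np.asarray(X, dtype=float)
    y01 = _validate_two_class(np.asarray(y))
    if X.shape[0] != y01.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if algorithm in (
        "information_gain",
        "information_gain_ratio",
        "chi_squared",
        "gini_index",
        "uncertainty",
        "rule",
    ):
        return _split_criteria(X, y01)[algorithm]
    if algorithm == "deviation":
        scaled = _minmax_scale(X)
        return scaled.std(axis=0, ddof=1)
    if algorithm == "relief":
        return relief_weights(X, y01)
    if algorithm == "svm":
        return svm_weights(X, y01, random_state)
    if algorithm == "pca":
        return pca_weights(X)
    raise ValueError(f"unknown weighting algorithm {algorithm!r}")


def binarize_weights(weights: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Min-max scale weights to [0, 1] and vote 1 where scaled >= threshold.

    All-equal weights carry no ranking information and yield all-zero votes.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    w = np.asarray(weights, dtype=float)
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros(w.shape, dtype=np.int8)
    scaled = (w - lo) / (hi - lo)
    return (scaled >= threshold).astype(np.int8)


def ensemble_score(votes: pd.DataFrame) -> pd.Series:
    """Cumulative score = row sum of the binary votes."""
    arr = votes.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("votes must be binary")
    return votes.sum(axis=1).astype(int)


def select_top_k(
    scores: pd.Series, k: int, tie_weight: pd.Series | None = None
) -> list[str]:
    """Top-k protein ids by score; boundary ties break by higher mean raw
    weight, then lexicographic id — fully deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} available proteins")
    if tie_weight is None:
        tie_weight = pd.Series(0.0, index=scores.index)
    frame = pd.DataFrame(
        {
            "score": scores.to_numpy(),
            "tie": tie_weight.reindex(scores.index).to_numpy(),
            "protein_id": scores.index.to_numpy(),
        }
    ).sort_values(
        by=["score", "tie", "protein_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    return list(frame["protein_id"].iloc[:k])


@dataclass
class WeightTable:
    """Raw weights, binary votes and cumulative score per protein.

    Columns are labelled ``<branch>:<algorithm>``; the same structure serves
    a single branch (branch name ``""``) or the pooled three-branch ensemble.
    """

    raw_weights: pd.DataFrame
    votes: pd.DataFrame
    scores: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if list(self.raw_weights.index) != list(self.votes.index):
            raise ValueError("raw_weights and votes index mismatch")
        if not np.isfinite(self.raw_weights.to_numpy()).all():
            raise ValueError("non-finite raw weight")
        self.scores = ensemble_score(self.votes)

    @property
    def n_algorithms(self) -> int:
        return self.votes.shape[1]

    def top_k(self, k: int) -> list[str]:
        return select_top_k(self.scores, k, self.raw_weights.mean(axis=1))

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.raw_weights.add_prefix("weight:"),
                self.votes.add_prefix("vote:"),
            ],
            axis=1,
        )
        out["score"] = self.scores
        out.index.name = "protein_id"
        return out.reset_index()


def compute_weight_table(
    X: pd.DataFrame,
    y,
    algorithms: tuple[str, ...] = CONTINUOUS_ALGORITHMS,
    vote_threshold: float = 0.5,
    random_state: int = 0,
    branch: str = "",
) -> WeightTable:
    """Run every algorithm on one branch (X: samples x proteins)."""
    prefix = f"{branch}:" if branch else ""
    raw = {}
    votes = {}
    for alg in algorithms:
        w = weight_features(X.to_numpy(), y, alg, random_state=random_state)
        raw[prefix + alg] = w
        votes[prefix + alg] = binarize_weights(w, vote_threshold)
    idx = pd.Index(X.columns, name="protein_id")
    return WeightTable(
        pd.DataFrame(raw, index=idx), pd.DataFrame(votes, index=idx)
    )


def pool_weight_tables(tables: list[WeightTable]) -> WeightTable:
    """Pool per-branch votes into one cumulative ensemble score."""
    if not tables:
        raise ValueError("no weight tables to pool")
    raw = pd.concat([t.raw_weights for t in tables], axis=1)
    votes = pd.concat([t.votes for t in tables], axis=1)
    if raw.isna().to_numpy().any():
        raise ValueError("branches disagree on the protein universe")
    return WeightTable(raw, votes.astype(np.int8))


class EnsembleAttributeWeighter(SelectorMixin, BaseEstimator):
    """Scikit-learn selector: ensemble attribute weighting with top-k support.

    Fits the configured weighting algorithms on (X, y), binarizes each
    algorithm's weights into votes, sums votes into a per-feature score and
    keeps the ``top_k`` features (ties broken by mean raw weight, then by
    feature name).

    Attributes
    ----------
    raw_weights_ : DataFrame, features x algorithms
    votes_ : DataFrame of 0/1 votes
    scores_ : Series of cumulative vote counts
    """

    def __init__(
        self,
        algorithms: tuple[str, ...] = CONTINUOUS_ALGORITHMS,
        vote_threshold: float = 0.5,
        top_k: int = 200,
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.vote_threshold = vote_threshold
        self.top_k = top_k
        self.random_state = random_state

    def fit(self, X, y):
        names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"f{i}" for i in range(np.asarray(X).shape[1])]
        )
        Xv, y = check_X_y(X, y)
        frame = pd.DataFrame(Xv, columns=names)
        table = compute_weight_table(
            frame,
            y,
            algorithms=tuple(self.algorithms),
            vote_threshold=self.vote_threshold,
            random_state=self.random_state,
        )
        self.weight_table_ = table
        self.raw_weights_ = table.raw_weights
        self.votes_ = table.votes
        self.scores_ = table.scores
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        selected = set(table.top_k(min(self.top_k, len(names))))
        self.support_ = np.array([n in selected for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
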