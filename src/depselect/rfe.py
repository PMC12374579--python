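"""Recursive feature elimination under three ranking models.

Each model repeatedly refits on the surviving features and discards the
lowest-ranked one(s): logistic regression and the linear max-margin
classifier rank by |coefficient| on standardized inputs, the random forest
by impurity-based (Gini) importance.  Leave-one-out accuracy is recorded at
each visited subset size — with n = 5 per group, k-fold splits are too
unstable to be meaningful — and the optimal subset is the smallest size
attaining the maximum of that curve (parsimony tie-break).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

RFE_MODELS = ("logistic", "forest", "linear_margin")


def _make_model(name: str, random_state: int, n_estimators: int):
    if name == "logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(penalty="l2", C=1.0, max_iter=2000)),
            ]
        )
    if name == "forest":
        return RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        )
    if name == "linear_margin":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="linear", C=1.0, random_state=random_state)),
            ]
        )
    raise ValueError(f"unknown RFE model {name!r}")


def _importances(fitted, name: str) -> np.ndarray:
    if name == "forest":
        return fitted.feature_importances_
    coef = fitted.named_steps["clf"].coef_
    return np.abs(np.asarray(coef)).ravel()


def _loo_accuracy(model, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy, refitting on each n−1 subset."""
    n = len(y)
    correct = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        m = clone(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[train], y[train])
            correct += int(m.predict(X[~train])[0] == y[i])
    return correct / n


@dataclass
class RFEResult:
    """Elimination order (first eliminated → last survivor), the accuracy
    curve over the visited subset sizes, and the optimal subset."""

    model_name: str
    elimination_order: list[str]
    performance_curve: dict[int, float]
    optimal_subset: list[str]

    def order_frame(self) -> pd.DataFrame:
        chosen = set(self.optimal_subset)
        return pd.DataFrame(
            {
                "model": self.model_name,
                "elimination_rank": np.arange(1, len(self.elimination_order) + 1),
                "protein_id": self.elimination_order,
                "in_optimal_subset": [
                    p in chosen for p in self.elimination_order
                ],
            }
        )

    def curve_frame(self) -> pd.DataFrame:
        sizes = sorted(self.performance_curve)
        return pd.DataFrame(
            {
                "model": self.model_name,
                "subset_size": sizes,
                "loo_accuracy": [self.performance_curve[s] for s in sizes],
            }
        )


class ModelRFE(BaseEstimator):
    """Scikit-learn-style recursive feature eliminator.

    Parameters
    ----------
    model : {"logistic", "forest", "linear_margin"}
    step : int, default 1
        Features removed per iteration.  The final iteration removes fewer
        so the order always ends at a single survivor.
    n_estimators : int, default 100
        Trees for the forest ranker; at the sample sizes this pipeline
        targets (n ≈ 10) the importance ranking is already stable here.
    random_state : int, default 0

    Attributes
    ----------
    elimination_order_ : list of feature names, worst-first
    performance_curve_ : dict size -> leave-one-out accuracy
    optimal_subset_ : list of feature names (smallest argmax of the curve)
    """

    def __init__(
        self,
        model: str = "logistic",
        step: int = 1,
        n_estimators: int = 100,
        random_state: int = 0,
    ):
        self.model = model
        self.step = step
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"f{i}" for i in range(np.asarray(X).shape[1])]
        )
        Xv, y = check_X_y(X, y)
        if len(np.unique(y)) != 2:
            raise ValueError("two-class labels required")
        if Xv.shape[1] < 2:
            raise ValueError("RFE needs at least 2 features")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        base = _make_model(self.model, self.random_state, self.n_estimators)

        remaining = list(names)
        name_to_col = {nm: j for j, nm in enumerate(names)}
        eliminated: list[str] = []
        curve: dict[int, float] = {}
        while True:
            cols = [name_to_col[nm] for nm in remaining]
            Xr = Xv[:, cols]
            curve[len(remaining)] = _loo_accuracy(base, Xr, y)
            if len(remaining) == 1:
                break
            m = clone(base)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(Xr, y)
            imp = _importances(m, self.model)
            # worst first; equal importances break lexicographically by name
            order = sorted(range(len(remaining)), key=lambda j: (imp[j], remaining[j]))
            n_drop = min(self.step, len(remaining) - 1)
            drop = [remaining[j] for j in order[:n_drop]]
            eliminated.extend(drop)
            dropset = set(drop)
            remaining = [nm for nm in remaining if nm not in dropset]

        self.elimination_order_ = eliminated + remaining
        self.performance_curve_ = curve
        best_size = optimal_size(curve)
        self.optimal_subset_ = sorted(self.elimination_order_[-best_size:])
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self)
        keep = set(self.optimal_subset_)
        if isinstance(X, pd.DataFrame):
            return X[[c for c in X.columns if c in keep]]
        idx = [i for i, nm in enumerate(self.feature_names_in_) if nm in keep]
        return np.asarray(X)[:, idx]


def optimal_size(curve: dict[int, float]) -> int:
    """Smallest subset size attaining the maximum accuracy."""
    if not curve:
        raise ValueError("empty performance curve")
    best = max(curve.values())
    return min(size for size, acc in curve.items() if acc == best)


def rfe_rank(
    X: pd.DataFrame,
    y,
    model: str,
    seed: int = 0,
    step: int = 1,
    n_estimators: int = 100,
) -> RFEResult:
    """Run one model's recursive elimination on samples x proteins data."""
    est = ModelRFE(
        model=model, step=step, n_estimators=n_estimators, random_state=seed
    )
    est.fit(X, y)
    return RFEResult(
        model_name=model,
        elimination_order=list(est.elimination_order_),
        performance_curve=dict(est.performance_curve_),
        optimal_subset=list(est.optimal_subset_),
    )


def optimal_subset(result: RFEResult) -> list[str]:
    size = optimal_size(result.performance_curve)
    return sorted(result.elimination_order[-size:])


@dataclass
class CombinedSubsets:
    """Intersection and union of the per-model optimal subsets; ``selected``
    is the configured one, after the empty-intersection fallback."""

    intersection: list[str]
    union: list[str]
    mode: str
    selected: list[str]
    fallback_applied: bool


def combine_subsets(sets: list[list[str]], mode: str = "union") -> CombinedSubsets:
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combination mode {mode!r}")
    if not sets:
        raise ValueError("no subsets to combine")
    inter = set(sets[0])
    union: set[str] = set()
    for s in sets:
        inter &= set(s)
        union |= set(s)
    selected = inter if mode == "intersection" else union
    fallback = False
    if mode == "intersection" and not inter:
        warnings.warn(
            "model subsets have an empty intersection; falling back to union",
            UserWarning,
            stacklevel=2,
        )
        selected = union
        fallback = True
    return CombinedSubsets(
        sorted(inter), sorted(union), mode, sorted(selected), fallback
    )
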