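"""Two-pass Mann-Whitney U validation of candidate proteins.

The exact two-sided p-value is computed by counting rank-sum outcomes over
all C(n1+n2, n1) group assignments: a dynamic-programming count of the
rank-sum distribution when the pooled values are tie-free, and direct
enumeration of assignments (with mid-ranks) when ties are present.  At the
sample sizes this pipeline targets (n = 5 vs 5) the exact null is coarse —
the smallest attainable two-sided p is 2/252 ≈ 0.0079 — which is why no
multiple-testing correction is applied by default: the raw p < alpha gate
mirrors the validation the pipeline reproduces, and a Benjamini-Hochberg
option is available for stricter use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class StatConfig:
    alpha: float = 0.05
    exact_limit: int = 12  # max n1+n2 for the exact null
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.exact_limit < 4:
            raise ValueError("exact_limit must be >= 4")


@dataclass
class UStatResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    direction: int  # sign of median(b) - median(a)


def _ranksum_counts(n: int, n1: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks {1..n} with rank sum s.

    Classic restricted-partition dynamic programme; the basis of the exact
    tie-free Mann-Whitney null.
    """
    max_sum = n1 * (2 * n - n1 + 1) // 2
    # iterate ranks, updating a (subset size, rank sum) count table
    table = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            table[k, r:] += table[k - 1, : max_sum + 1 - r]
    return table[n1]


def _exact_p_dp(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p from the tie-free rank-sum distribution."""
    n = n1 + n2
    counts = _ranksum_counts(n, n1)
    sums = np.arange(counts.size, dtype=float)
    u_all = sums - n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    extreme = np.abs(u_all - mid) >= np.abs(u - mid) - 1e-9
    return float(counts[extreme].sum() / comb(n, n1))


def _exact_p_enumerate(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating group assignments (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    n1, n = len(a), len(pooled)
    mid = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    count = 0
    total = 0
    target = abs(u_obs - mid) - 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        count += abs(u - mid) >= target
        total += 1
    return count / total


def mann_whitney(a, b, config: StatConfig | None = None) -> UStatResult:
    """Two-sided Mann-Whitney U test.

    Exact by full enumeration of rank assignments when n1 + n2 is within
    ``config.exact_limit``; otherwise the normal approximation with tie and
    continuity corrections.  Ties are handled by mid-ranks in both regimes.
    """
    config = config or StatConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite value in test input")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    direction = int(np.sign(np.median(b) - np.median(a)))
    if np.all(pooled == pooled[0]):
        return UStatResult(u, 1.0, "exact", 0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= config.exact_limit:
        if has_ties:
            p = _exact_p_enumerate(a, b)
        else:
            p = _exact_p_dp(u, n1, n2)
        return UStatResult(u, min(p, 1.0), "exact", direction)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return UStatResult(u, float(res.pvalue), "normal_approx", direction)


# ---------------------------------------------------------------------------
# pipeline gates
# ---------------------------------------------------------------------------
def _split_groups(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[list[str], list[str], str, str]:
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, found {len(groups)}")
    ga, gb = groups
    cols_a = [s for s in matrix.columns if labels[s] == ga]
    cols_b = [s for s in matrix.columns if labels[s] == gb]
    return cols_a, cols_b, ga, gb


def u_test_table(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features: list[str],
    config: StatConfig | None = None,
) -> pd.DataFrame:
    """Per-protein U test over ``features``; matrix is proteins x samples.

    Effect = median(group B) − median(group A) with groups in sorted label
    order, on the matrix's (log2) scale.
    """
    config = config or StatConfig()
    cols_a, cols_b, ga, gb = _split_groups(matrix, labels)
    rows = []
    for fid in features:
        a = matrix.loc[fid, cols_a].to_numpy(dtype=float)
        b = matrix.loc[fid, cols_b].to_numpy(dtype=float)
        res = mann_whitney(a, b, config)
        rows.append(
            {
                "protein_id": fid,
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
                "direction": res.direction,
                "log2_effect": float(np.median(b) - np.median(a)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "u_statistic",
            "p_value",
            "method",
            "direction",
            "log2_effect",
        ],
    )
    if config.bh_correct and len(out):
        out["p_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def first_pass_filter(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features: list[str],
    config: StatConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Proteins from ``features`` with p < alpha, plus the full test table."""
    config = config or StatConfig()
    if not features:
        warnings.warn("first-pass filter received an empty feature set", UserWarning)
        return [], u_test_table(matrix, labels, [], config)
    table = u_test_table(matrix, labels, features, config)
    kept = list(table.loc[table["p_value"] < config.alpha, "protein_id"])
    return kept, table


def merge_candidates(
    ensemble_set: list[str],
    rfe_set: list[str],
    mwu_set: list[str],
) -> pd.DataFrame:
    """Union of the RFE-refined and first-pass-significant sets with
    per-protein provenance flags."""
    universe = set(ensemble_set)
    bad_rfe = set(rfe_set) - universe
    bad_mwu = set(mwu_set) - universe
    if bad_rfe or bad_mwu:
        raise ValueError(
            "candidate set(s) not contained in the ensemble set: "
            f"{sorted(bad_rfe | bad_mwu)}"
        )
    if not rfe_set and not mwu_set:
        raise ValueError(
            "both the RFE subset and the first-pass significant set are empty; "
            "nothing to validate"
        )
    merged = sorted(set(rfe_set) | set(mwu_set))
    return pd.DataFrame(
        {
            "protein_id": merged,
            "from_rfe": [p in set(rfe_set) for p in merged],
            "from_mwu1": [p in set(mwu_set) for p in merged],
        }
    )


def second_pass_validate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    merged: pd.DataFrame,
    first_pass: pd.DataFrame,
    config: StatConfig | None = None,
    gene_symbols: pd.Series | None = None,
) -> pd.DataFrame:
    """Re-test the merged list; the final flag is p_second < alpha.

    On unchanged data the second pass reproduces the first-pass p for
    proteins tested in both (it is a re-test of the merged list, not a new
    statistic).  Returns the final DEP table sorted by (p_second, id).
    """
    config = config or StatConfig()
    if merged.empty:
        raise ValueError("merged candidate list is empty")
    features = list(merged["protein_id"])
    second = u_test_table(matrix, labels, features, config)
    p_first = first_pass.set_index("protein_id")["p_value"]
    out = second.rename(columns={"p_value": "p_second_pass"}).merge(
        merged, on="protein_id"
    )
    out["p_first_pass"] = out["protein_id"].map(p_first)
    out["gene_symbol"] = (
        out["protein_id"].map(gene_symbols).fillna("")
        if gene_symbols is not None
        else ""
    )
    out["selected_by"] = [
        ";".join(
            ["ensemble"]
            + (["rfe"] if r else [])
            + (["mwu1"] if m else [])
        )
        for r, m in zip(out["from_rfe"], out["from_mwu1"])
    ]
    out["final"] = out["p_second_pass"] < config.alpha
    out = out.sort_values(["p_second_pass", "protein_id"], kind="stable")
    cols = [
        "protein_id",
        "gene_symbol",
        "log2_effect",
        "direction",
        "u_statistic",
        "method",
        "p_first_pass",
        "p_second_pass",
        "selected_by",
        "final",
    ]
    return out[cols].reset_index(drop=True)
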