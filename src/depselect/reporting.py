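"""Heatmap-ready standardization and enrichment-tool exports.

Validated DEP intensities are z-scored per protein across samples
(mean 0, sd 1 with the n−1 denominator) for heatmap display; gene lists and
a signed ranked list (direction × −log10 p) are exported in the plain-text
layouts that network and rank-based enrichment tools ingest.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SampleTable, write_table

logger = logging.getLogger(__name__)


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x − mean) / sd with sample sd; constant rows map to zeros.

    ``matrix`` is proteins x samples and must have at least 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-score standardization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant protein row(s) standardized to zeros",
            UserWarning,
        )
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def export_heatmap_table(
    std: pd.DataFrame, samples: SampleTable, path: str | Path
) -> pd.DataFrame:
    """Write the standardized matrix with samples ordered by group then batch."""
    if std.empty:
        raise ValueError("nothing to export: standardized matrix is empty")
    meta = samples.table[samples.table["sample_id"].isin(std.columns)]
    ordered = list(
        meta.sort_values(["group", "batch", "sample_id"], kind="stable")["sample_id"]
    )
    out = std[ordered].copy()
    out.index.name = "protein_id"
    write_table(out.reset_index(), path)
    return out


def export_enrichment_inputs(
    dep_table: pd.DataFrame, path_prefix: str | Path
) -> dict[str, int]:
    """Write enrichment-tool inputs for the final (p_second < alpha) DEPs.

    ``<prefix>_genes.txt``: one gene symbol per line, for network tools.
    ``<prefix>_ranked.rnk``: gene <tab> direction × −log10(p_second), sorted
    descending, for rank-based enrichment.  Rows without a gene symbol are
    skipped and counted.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    final = dep_table[dep_table["final"].astype(bool)].copy()
    has_symbol = final["gene_symbol"].astype(str).str.len() > 0
    skipped = int((~has_symbol).sum())
    if skipped:
        logger.info("skipped %d final DEP(s) lacking a gene symbol", skipped)
    final = final[has_symbol]
    if final.empty:
        warnings.warn("no exportable genes; writing empty enrichment files")
    genes_path = prefix.parent / f"{prefix.name}_genes.txt"
    rnk_path = prefix.parent / f"{prefix.name}_ranked.rnk"
    genes_path.write_text("".join(f"{g}\n" for g in final["gene_symbol"]))
    p = np.clip(final["p_second_pass"].to_numpy(dtype=float), 1e-300, 1.0)
    score = final["direction"].to_numpy(dtype=float) * -np.log10(p)
    ranked = (
        pd.DataFrame({"gene": final["gene_symbol"], "score": score})
        .sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    )
    ranked.to_csv(rnk_path, sep="\t", index=False, header=False)
    return {"exported": int(len(final)), "skipped_no_symbol": skipped}
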