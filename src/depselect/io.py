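"""Reading and writing protein-group matrices, sample metadata and result tables.

All on-disk formats are plain text.  The protein matrix follows the wide
protein-group layout emitted by DIA search engines (one row per protein
group, identifier/annotation columns followed by per-sample intensity
columns).  Every result table the pipeline produces is TSV with a fixed
column order so that ``read(write(x)) == x``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: identifier column candidates, in precedence order (DIA-NN conventions)
ID_COLUMN_CANDIDATES = ("Protein.Group", "Protein.Ids", "protein_id")
GENE_COLUMN_CANDIDATES = ("Genes", "gene_symbol")
#: annotation columns that are never intensities
NON_VALUE_COLUMNS = {
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
    "protein_id",
    "gene_symbol",
}


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity table with an explicit missingness mask.

    ``values`` is indexed by protein id with one column per sample; cells that
    were never quantified hold ``NaN`` until imputation fills them.  The mask
    is kept separately so that imputed cells remain identifiable downstream.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate protein id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values shape")
        self.missing_mask = self.missing_mask.set_axis(idx, axis=0).set_axis(
            self.values.columns, axis=1
        )
        observed = self.values.to_numpy()[~self.missing_mask.to_numpy()]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value in an observed cell")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(idx)

    # -- conveniences -------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_proteins(self, ids: Sequence[str]) -> "IntensityMatrix":
        ids = list(ids)
        return IntensityMatrix(
            self.values.loc[ids],
            self.missing_mask.loc[ids],
            None if self.gene_symbols is None else self.gene_symbols.loc[ids],
        )

    def subset_samples(self, samples: Sequence[str]) -> "IntensityMatrix":
        samples = list(samples)
        return IntensityMatrix(
            self.values[samples], self.missing_mask[samples], self.gene_symbols
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            None if self.gene_symbols is None else self.gene_symbols.copy(),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: group (two-level downstream), batch, timepoint."""

    table: pd.DataFrame  # columns: sample_id, group, batch, timepoint

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample metadata lacks column(s): {sorted(missing)}")
        t = self.table.copy()
        if "batch" not in t.columns:
            t["batch"] = "1"
        if "timepoint" not in t.columns:
            t["timepoint"] = ""
        t = t[["sample_id", "group", "batch", "timepoint"]].astype(str)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    @property
    def batches(self) -> pd.Series:
        return self.table.set_index("sample_id")["batch"]

    def group_labels(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def two_group_labels(self) -> tuple[str, str]:
        """The two group labels in sorted order; errors on any other count."""
        labels = self.group_labels()
        if len(labels) != 2:
            raise ValueError(
                f"exactly 2 groups required, found {len(labels)}: {labels}"
            )
        return labels[0], labels[1]

    def validate_group_sizes(self, min_size: int = 2) -> None:
        counts = self.table["group"].value_counts()
        small = counts[counts < min_size]
        if len(small):
            raise ValueError(
                f"group(s) with fewer than {min_size} samples: "
                f"{sorted(small.index)}"
            )

    def subset(self, samples: Sequence[str]) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(samples))]
        return SampleTable(keep.reset_index(drop=True))


def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_protein_matrix(
    path: str | Path,
    id_column: str | None = None,
    value_columns: Sequence[str] | None = None,
    gene_column: str | None = None,
    zero_as_missing: bool = True,
) -> IntensityMatrix:
    """Read a wide protein-group quantification table.

    Blank cells, ``NA``/``NaN`` tokens and (by default) exact zeros are
    treated as missing — a zero in DIA output means "not quantified", not an
    abundance of zero.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if id_column is None:
        id_column = next(
            (c for c in ID_COLUMN_CANDIDATES if c in raw.columns), raw.columns[0]
        )
    if id_column not in raw.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    if gene_column is None:
        gene_column = next(
            (c for c in GENE_COLUMN_CANDIDATES if c in raw.columns), None
        )
    if value_columns is None:
        value_columns = [c for c in raw.columns if c not in NON_VALUE_COLUMNS]
    else:
        absent = [c for c in value_columns if c not in raw.columns]
        if absent:
            raise ValueError(f"value column(s) not found: {absent}")

    ids = raw[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate protein id {dup!r}")

    values = (
        raw[list(value_columns)]
        .apply(pd.to_numeric, errors="coerce")
        .set_axis(ids, axis=0)
        .astype(float)
    )
    mask = values.isna()
    if zero_as_missing:
        mask |= values == 0.0
    values = values.mask(mask)
    observed = values.to_numpy()[~mask.to_numpy()]
    if observed.size and (observed < 0).any():
        raise ValueError("negative intensity encountered")
    genes = None
    if gene_column is not None:
        genes = raw[gene_column].astype(str).set_axis(ids).replace({"nan": ""})
    return IntensityMatrix(values, mask, genes)


def read_sample_metadata(path: str | Path) -> SampleTable:
    path = Path(path)
    table = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    return SampleTable(table)


def check_samples_covered(matrix: IntensityMatrix, samples: SampleTable) -> None:
    """Every matrix sample must appear exactly once in the metadata."""
    absent = [s for s in matrix.samples if s not in set(samples.samples)]
    if absent:
        raise ValueError(f"matrix sample(s) absent from metadata: {absent}")


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any pipeline result table as TSV (round-trip stable)."""
    if table.shape[1] == 0 and not index:
        raise ValueError("refusing to write a table with no columns")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    if matrix.gene_symbols is not None:
        out.insert(0, "gene_symbol", matrix.gene_symbols.values)
    write_table(out.reset_index(), path)


def read_intensity_matrix(
    path: str | Path, zero_as_missing: bool = False
) -> IntensityMatrix:
    """Re-read a matrix previously written by :func:`write_intensity_matrix`.

    Defaults to keeping zeros: pipeline intermediates are on a log scale
    where zero is a legitimate value.
    """
    return read_protein_matrix(
        path, id_column="protein_id", zero_as_missing=zero_as_missing
    )
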