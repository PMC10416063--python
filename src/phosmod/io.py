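"""Readers and writers for the tabular formats the toolkit consumes.

All abundance tables are tab-delimited UTF-8 text with a header row.
Samples are columns; features (phosphosites or proteins) are rows.
Phosphosite rows are keyed by two columns (gene, site); protein rows by a
single gene column.  Empty cells denote missing values and become NaN.

In memory an abundance matrix is a :class:`pandas.DataFrame` with a
``MultiIndex`` (gene, site) for phosphopeptide tables or a plain gene
``Index`` for protein tables, and sample identifiers as columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHOSPHO_KEY_COLUMNS = ("gene", "site")
PROTEIN_KEY_COLUMNS = ("gene",)


class DuplicateKeyError(ValueError):
    """A row key occurs more than once in an abundance table."""


def read_abundance_table(path: str | Path, n_key_columns: int) -> pd.DataFrame:
    """Read a TSV abundance table into a DataFrame.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.  The first ``n_key_columns``
        columns are row keys; all remaining columns must be numeric or
        empty (missing).
    n_key_columns
        2 for phosphopeptide tables (gene, site), 1 for protein tables.

    Raises
    ------
    DuplicateKeyError
        If any row key occurs more than once; the message names the key.
    ValueError
        If a data cell is non-numeric; the message gives row and column.
    """
    if n_key_columns < 1:
        raise ValueError("n_key_columns must be >= 1")
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.shape[1] <= n_key_columns:
        raise ValueError(
            f"{path}: expected at least {n_key_columns + 1} columns, "
            f"found {raw.shape[1]}"
        )
    key_cols = list(raw.columns[:n_key_columns])
    sample_cols = list(raw.columns[n_key_columns:])
    if len(set(sample_cols)) != len(sample_cols):
        raise ValueError(f"{path}: duplicate sample columns")

    keys = raw[key_cols]
    for col in key_cols:
        if (keys[col].str.len() == 0).any():
            bad = int(np.argmax(keys[col].str.len().to_numpy() == 0))
            raise ValueError(f"{path}: empty key in column '{col}', row {bad + 2}")
    if n_key_columns == 1:
        index = pd.Index(keys.iloc[:, 0], name=key_cols[0])
    else:
        index = pd.MultiIndex.from_frame(keys)
    dup = index.duplicated(keep=False)
    if dup.any():
        first = index[dup][0]
        raise DuplicateKeyError(f"{path}: duplicate row key {first!r}")

    values = np.full((len(raw), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        cells = raw[col].to_numpy()
        nonempty = cells != ""
        try:
            values[nonempty, j] = cells[nonempty].astype(float)
        except ValueError:
            for i in np.flatnonzero(nonempty):
                try:
                    float(cells[i])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cells[i]!r} at row "
                        f"{i + 2}, column '{col}'"
                    ) from None
            raise
    return pd.DataFrame(values, index=index, columns=sample_cols)


def write_abundance_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an abundance DataFrame as TSV; NaN becomes the empty string."""
    matrix.to_csv(path, sep="\t", na_rep="")


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, group)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_annotation_table(
    path: str | Path, kinds_path: str | Path
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a samples x variables annotation table plus its kind sidecar.

    The sidecar is a two-column TSV (variable, kind) with kind in
    {"categorical", "continuous"}.  Continuous columns are coerced to float.
    """
    ann = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    kinds_df = pd.read_csv(kinds_path, sep="\t", header=0, dtype=str)
    kinds = dict(zip(kinds_df.iloc[:, 0], kinds_df.iloc[:, 1]))
    unknown = set(kinds.values()) - {"categorical", "continuous"}
    if unknown:
        raise ValueError(f"{kinds_path}: unknown variable kinds {sorted(unknown)}")
    missing = set(ann.columns) - set(kinds)
    if missing:
        raise ValueError(f"variables without a kind tag: {sorted(missing)}")
    ann = ann.replace("", np.nan)
    for var, kind in kinds.items():
        if kind == "continuous" and var in ann.columns:
            ann[var] = ann[var].astype(float)
    return ann, kinds


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file, ignoring blanks."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_two_column_table(path: str | Path) -> pd.DataFrame:
    """Read a generic two-column TSV with header (used for activation-loop
    sites and druggability annotations)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    return df


def read_site_mapping(path: str | Path) -> pd.DataFrame:
    """Read a site-to-protein mapping TSV.

    Columns: gene, site, protein_id, positions (comma-separated 1-based
    residue ordinals).  Returns a DataFrame with a parsed ``positions``
    column holding lists of ints.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = {"gene", "site", "protein_id", "positions"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: required columns {sorted(required)}")
    df = df.copy()
    df["positions"] = [
        [int(p) for p in str(cell).split(",") if p != ""] for cell in df["positions"]
    ]
    for _, row in df.iterrows():
        if any(p < 1 for p in row["positions"]):
            raise ValueError(
                f"{path}: non-positive residue ordinal for "
                f"{row['gene']} {row['site']}"
            )
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT set database: set name, description, then members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def site_key_strings(index: pd.Index) -> list[str]:
    """Harmonize phosphosite keys as 'gene_site' strings (for cross-cohort
    comparisons and set databases)."""
    if isinstance(index, pd.MultiIndex):
        return [f"{g}_{s}" for g, s in index]
    return [str(k) for k in index]
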