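"""Column normalization and row filtering ahead of module discovery.

Filtering drops rows with too many missing values, then keeps the
high-variance half of the survivors.  When several cohorts are combined
(e.g. tumor and normal of two cancer types), the filters are applied to
several sample combinations separately and the union of passing sites is
retained, so a site strongly varying in only one subgroup is not lost.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def column_normalize(matrix: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Normalize each sample column for loading on the log2 scale.

    ``method="median"`` subtracts the column median; ``"upper_quartile"``
    subtracts the column 75th percentile (linear interpolation between
    order statistics).  Missing entries are untouched.
    """
    if method not in ("median", "upper_quartile"):
        raise ValueError(f"unknown normalization method {method!r}")
    all_missing = matrix.isna().all(axis=0)
    if all_missing.any():
        bad = matrix.columns[all_missing][0]
        raise ValueError(f"sample {bad!r} has no non-missing values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "median":
            shift = np.nanmedian(matrix.to_numpy(), axis=0)
        else:
            shift = np.nanpercentile(matrix.to_numpy(), 75, axis=0)
    return matrix - shift


def _row_sd(values: np.ndarray) -> np.ndarray:
    """Per-row sample SD (ddof=1) over non-missing entries; rows with <2
    observations get SD 0."""
    n = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(values, axis=1, ddof=1)
    sd = np.where(n < 2, 0.0, sd)
    return np.nan_to_num(sd, nan=0.0)


def filter_rows(
    matrix: pd.DataFrame,
    max_missing_frac: float = 0.25,
    top_variance_frac: float = 0.5,
) -> pd.DataFrame:
    """Drop high-missingness rows, then keep the top-variance fraction.

    Rows with a missing fraction strictly greater than ``max_missing_frac``
    are removed first.  Among the survivors, rows whose standard deviation
    (non-missing entries, n-1 denominator) is at or above the
    ``1 - top_variance_frac`` quantile of survivor SDs are kept; ties at
    the threshold are kept.  The two steps run in this fixed order.
    """
    for name, frac in (("max_missing_frac", max_missing_frac),
                       ("top_variance_frac", top_variance_frac)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    values = matrix.to_numpy(dtype=float)
    missing_frac = np.mean(np.isnan(values), axis=1)
    survivors = matrix.loc[missing_frac <= max_missing_frac]
    if survivors.empty:
        warnings.warn("no rows pass the missingness filter; returning empty matrix")
        return survivors
    sds = _row_sd(survivors.to_numpy(dtype=float))
    threshold = np.quantile(sds, 1 - top_variance_frac)
    kept = survivors.loc[sds >= threshold]
    if kept.empty:
        warnings.warn("no rows pass the variance filter; returning empty matrix")
    return kept


def multi_group_filter_union(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_combinations: Sequence[Iterable[str]],
    max_missing_frac: float = 0.25,
    top_variance_frac: float = 0.5,
) -> set:
    """Union of row keys passing the filters in any sample combination.

    Each combination is a collection of group labels; the filters run on
    the matrix restricted to the samples of those groups, and the union of
    passing row keys over all combinations is returned.
    """
    known = set(groups.values())
    sample_by_group: dict[str, list[str]] = {}
    for sample, label in groups.items():
        sample_by_group.setdefault(label, []).append(sample)
    kept: set = set()
    for combo in group_combinations:
        labels = list(combo)
        unknown = set(labels) - known
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}")
        samples = [s for lab in labels for s in sample_by_group[lab]
                   if s in matrix.columns]
        if not samples:
            continue
        sub = filter_rows(matrix[samples], max_missing_frac, top_variance_frac)
        kept.update(sub.index)
    return kept
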