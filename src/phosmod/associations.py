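"""Association of module scores with clinical/sample annotations.

Categorical variables are split into one-vs-rest binary indicators; each
indicator is tested against each module score vector with a two-sided
Mann-Whitney rank-sum test.  Continuous variables use a Spearman
correlation test.  All (module x indicator/variable) p-values in a run
are corrected as one family, Benjamini-Hochberg by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_GROUP_SIZE = 3

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


@dataclass
class AssociationResult:
    module: object
    variable: str
    level: str | None
    statistic: float
    p: float
    adj_p: float = np.nan
    reason: str | None = None


def binarize_categorical(
    annotations: pd.DataFrame, kinds: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand categorical variables into one-vs-rest indicators.

    A variable with L observed levels becomes L binary columns named
    ``variable=level`` (both columns are kept for binary variables).
    A sample missing the variable is missing in every indicator.
    Single-level variables are dropped with a warning.  Continuous
    variables pass through unchanged.
    """
    out = {}
    out_kinds: dict[str, str] = {}
    for var in annotations.columns:
        kind = kinds.get(var)
        if kind == CONTINUOUS:
            out[var] = annotations[var].astype(float)
            out_kinds[var] = CONTINUOUS
            continue
        if kind != CATEGORICAL:
            raise ValueError(f"variable {var!r} has no categorical/continuous tag")
        col = annotations[var]
        levels = sorted(col.dropna().unique())
        if len(levels) < 2:
            warnings.warn(f"categorical variable {var!r} has <2 levels; dropped")
            continue
        for level in levels:
            name = f"{var}={level}"
            indicator = (col == level).astype(float)
            indicator[col.isna()] = np.nan
            out[name] = indicator
            out_kinds[name] = CATEGORICAL
    return pd.DataFrame(out, index=annotations.index), out_kinds


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def calculate_annotation_association(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    kinds: Mapping[str, str],
    correction: str = "benjamini_hochberg",
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Test every module against every annotation variable.

    ``scores`` is modules x samples; ``annotations`` samples x variables
    with a kind tag per variable.  Returns a DataFrame sorted by adjusted
    p with columns module, variable, level, statistic, p, adj_p, reason.
    Groups below ``min_group_size`` yield a missing p and a reason code.
    """
    if correction != "benjamini_hochberg":
        raise ValueError(f"unsupported correction {correction!r}")
    shared = [s for s in scores.columns if s in annotations.index]
    absent = [s for s in scores.columns if s not in annotations.index]
    if absent:
        warnings.warn(f"samples without annotations: {absent}")
    binarized, bin_kinds = binarize_categorical(annotations.loc[shared], kinds)

    results: list[AssociationResult] = []
    for module, score_row in scores[shared].iterrows():
        values = score_row.to_numpy(dtype=float)
        for col in binarized.columns:
            ann = binarized[col].to_numpy(dtype=float)
            ok = ~np.isnan(values) & ~np.isnan(ann)
            if bin_kinds[col] == CATEGORICAL:
                var, level = col.split("=", 1)
                in_group = values[ok & (ann == 1)]
                out_group = values[ok & (ann == 0)]
                if min(len(in_group), len(out_group)) < min_group_size:
                    results.append(AssociationResult(
                        module, var, level, np.nan, np.nan,
                        reason="group_below_min_size"))
                    continue
                stat, p = stats.mannwhitneyu(
                    in_group, out_group, alternative="two-sided"
                )
                results.append(AssociationResult(module, var, level,
                                                 float(stat), float(p)))
            else:
                if ok.sum() < min_group_size:
                    results.append(AssociationResult(
                        module, col, None, np.nan, np.nan,
                        reason="too_few_samples"))
                    continue
                rho, p = stats.spearmanr(values[ok], ann[ok])
                results.append(AssociationResult(module, col, None,
                                                 float(rho), float(p)))

    table = pd.DataFrame(
        {
            "module": [r.module for r in results],
            "variable": [r.variable for r in results],
            "level": [r.level for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "reason": [r.reason for r in results],
        }
    )
    table["adj_p"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "adj_p"] = benjamini_hochberg(
            table.loc[tested, "p"].to_numpy()
        )
    return table.sort_values("adj_p", na_position="last").reset_index(drop=True)
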