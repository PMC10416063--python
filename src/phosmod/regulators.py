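"""Nomination of candidate upstream regulators (kinases/phosphatases).

Protein and *raw* phosphopeptide rows for a user-supplied candidate gene
list are gathered into one feature table — raw rather than
protein-normalized phospho, so autophosphorylation signal survives the
earlier normalization.  Nearly collinear features (pairwise Pearson r
above a threshold, default 0.95) are collapsed to their per-sample mean
via connected components; remaining missing values are KNN-imputed.
Features are then associated with module scores either by rank
correlation (default Spearman) or by a ridge model per module with all
features as predictors.  Because log(kinase abundance) vs substrate
phosphorylation is often sigmoid, module scores can optionally be passed
through a logistic transform first (rank-preserving, so Spearman results
are unchanged by it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.impute import KNNImputer

from .associations import benjamini_hochberg
from .normalize import DEFAULT_ALPHAS, DEFAULT_CV_FOLDS

DEFAULT_CORR_THRESHOLD = 0.95


@dataclass
class RegulatorFeature:
    """One candidate-regulator feature after collapsing and imputation."""

    feature_id: str
    source: str  # "protein", "phospho" or "collapsed"
    member_ids: tuple[str, ...]
    genes: tuple[str, ...]
    values: pd.Series  # per-sample, no missing values


def _feature_rows(
    genes: Sequence[str],
    protein: pd.DataFrame,
    raw_phospho: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Stack protein and phospho rows for listed genes into one table."""
    rows, ids, sources, row_genes = [], [], [], []
    gene_set = set(genes)
    for gene in genes:
        if gene in protein.index:
            rows.append(protein.loc[gene])
            ids.append(f"{gene}-protein")
            sources.append("protein")
            row_genes.append(gene)
    if isinstance(raw_phospho.index, pd.MultiIndex):
        hits = raw_phospho.loc[
            raw_phospho.index.get_level_values(0).isin(gene_set)
        ]
        for (gene, site), row in hits.iterrows():
            rows.append(row)
            ids.append(f"{gene}-{site}-phospho")
            sources.append("phospho")
            row_genes.append(gene)
    absent = [g for g in genes
              if g not in protein.index
              and not (isinstance(raw_phospho.index, pd.MultiIndex)
                       and g in raw_phospho.index.get_level_values(0))]
    for g in absent:
        warnings.warn(f"candidate regulator {g!r} absent from both matrices")
    table = pd.DataFrame(rows, index=ids) if rows else pd.DataFrame()
    return table, sources, row_genes


def collect_possible_regulators(
    genes: Sequence[str],
    protein: pd.DataFrame,
    raw_phospho: pd.DataFrame,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    imputer_k: int = 5,
) -> list[RegulatorFeature]:
    """Gather, collapse and impute candidate-regulator features.

    Features with pairwise Pearson r strictly above ``corr_threshold``
    (signed, so anti-correlated features never merge) are joined into
    connected components and each component is replaced by its per-sample
    mean.  A threshold above 1 disables collapsing entirely.
    """
    if not genes:
        raise ValueError("candidate gene list is empty")
    table, sources, row_genes = _feature_rows(genes, protein, raw_phospho)
    if table.empty:
        return []
    n = len(table)
    if corr_threshold <= 1:
        corr = table.T.corr(method="pearson").to_numpy()
        adj = np.triu(np.nan_to_num(corr, nan=0.0) > corr_threshold, k=1)
        n_comp, comp = connected_components(
            csr_matrix(adj), directed=False
        )
    else:
        n_comp, comp = n, np.arange(n)

    grouped_values = np.empty((n_comp, table.shape[1]))
    features: list[RegulatorFeature] = []
    meta: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        block = table.iloc[members]
        grouped_values[c] = block.mean(axis=0, skipna=True).to_numpy()
        member_ids = tuple(table.index[members])
        member_genes = tuple(sorted({row_genes[m] for m in members}))
        if len(members) == 1:
            meta.append((member_ids[0], sources[members[0]],
                         member_ids, member_genes))
        else:
            meta.append(("|".join(member_ids), "collapsed",
                         member_ids, member_genes))

    keep = ~np.isnan(grouped_values).all(axis=1)
    grouped_values = grouped_values[keep]
    meta = [m for m, k in zip(meta, keep) if k]
    if np.isnan(grouped_values).any():
        grouped_values = KNNImputer(n_neighbors=imputer_k).fit_transform(
            grouped_values
        )
    for (fid, source, member_ids, member_genes), vals in zip(meta, grouped_values):
        features.append(RegulatorFeature(
            feature_id=fid,
            source=source,
            member_ids=member_ids,
            genes=member_genes,
            values=pd.Series(vals, index=table.columns),
        ))
    return features


def sigmoid_transform(scores: pd.DataFrame) -> pd.DataFrame:
    """Map each module's scores through z-standardization then the
    logistic function 1/(1+e^-z).  Strictly rank-preserving per module;
    a zero-variance module row becomes constant 0.5 with a warning."""
    out = {}
    for module, row in scores.iterrows():
        v = row.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        sd = np.std(v[ok]) if ok.sum() else 0.0
        if ok.sum() < 3:
            raise ValueError(f"module {module!r} has <3 non-missing scores")
        if sd == 0:
            warnings.warn(f"module {module!r} has zero variance; constant 0.5")
            z = np.where(ok, 0.0, np.nan)
        else:
            z = (v - np.mean(v[ok])) / sd
        out[module] = 1.0 / (1.0 + np.exp(-z))
    return pd.DataFrame(out, index=scores.columns).T


def _ridge_cv_multifeature(
    X: np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float],
    cv_folds: int,
    seed: int,
) -> np.ndarray:
    """Multi-feature ridge with CV alpha choice matching the
    protein-normalization conventions (seeded contiguous-block folds,
    ties to larger alpha).  Returns the coefficient vector."""
    from sklearn.linear_model import Ridge

    from .normalize import _cv_folds

    n = len(y)
    folds = _cv_folds(n, cv_folds, seed)
    best_alpha, best_mse = None, np.inf
    for alpha in alphas:
        errors = []
        for test_idx in folds:
            train = np.ones(n, dtype=bool)
            train[test_idx] = False
            if train.sum() < 2:
                continue
            model = Ridge(alpha=alpha).fit(X[train], y[train])
            errors.append(np.mean((y[test_idx] - model.predict(X[test_idx])) ** 2))
        mse = float(np.mean(errors)) if errors else np.inf
        if mse < best_mse or (mse == best_mse and best_alpha is not None
                              and alpha > best_alpha):
            best_mse, best_alpha = mse, alpha
    model = Ridge(alpha=best_alpha).fit(X, y)
    return model.coef_


def calculate_regulator_association(
    features: Sequence[RegulatorFeature],
    scores: pd.DataFrame,
    mode: str = "correlation",
    corr_method: str = "spearman",
    sigmoid: bool = False,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Associate each regulator feature with each module score vector.

    ``mode="correlation"`` reports a coefficient and p per (feature,
    module); ``mode="linear_model"`` fits one ridge model per module with
    all features as predictors and reports coefficients (no p-values:
    regularized coefficients lack a standard null).  ``sigmoid`` applies
    :func:`sigmoid_transform` to the scores first.
    """
    if mode not in ("correlation", "linear_model"):
        raise ValueError(f"unknown mode {mode!r}")
    if corr_method not in ("spearman", "pearson"):
        raise ValueError(f"unknown corr_method {corr_method!r}")
    if not features:
        return pd.DataFrame(
            columns=["module", "feature", "mode", "statistic", "p", "adj_p"]
        )
    feat_table = pd.DataFrame(
        {f.feature_id: f.values for f in features}
    )  # samples x features
    shared = [s for s in scores.columns if s in feat_table.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared by features and scores")
    scores = scores[shared]
    if sigmoid:
        scores = sigmoid_transform(scores)
    feat_table = feat_table.loc[shared]

    records = []
    if mode == "correlation":
        corr_fn = stats.spearmanr if corr_method == "spearman" else stats.pearsonr
        for module, score_row in scores.iterrows():
            y = score_row.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            for f in features:
                x = feat_table[f.feature_id].to_numpy(dtype=float)[ok]
                stat, p = corr_fn(x, y[ok])
                records.append((module, f.feature_id, mode,
                                float(stat), float(p)))
        table = pd.DataFrame(
            records, columns=["module", "feature", "mode", "statistic", "p"]
        )
        table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        X = feat_table.to_numpy(dtype=float)
        for module, score_row in scores.iterrows():
            y = score_row.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            coefs = _ridge_cv_multifeature(X[ok], y[ok], alphas, cv_folds, seed)
            for f, coef in zip(features, coefs):
                records.append((module, f.feature_id, mode, float(coef), np.nan))
        table = pd.DataFrame(
            records, columns=["module", "feature", "mode", "statistic", "p"]
        )
        table["adj_p"] = np.nan
    return table


def correlate_activation_loops(
    scores: pd.DataFrame,
    loop_sites: Sequence[tuple[str, str]],
    raw_phospho: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of known kinase activation-loop phosphosites
    with module scores.

    Activation-loop phosphorylation tracks kinase activity, so a loop
    site correlating with a module is direct evidence for that kinase.
    Sites absent from the phospho matrix are reported with status
    "absent".
    """
    records = []
    present = 0
    for gene, site in loop_sites:
        key = (gene, site)
        if key not in raw_phospho.index:
            records.append((gene, site, None, np.nan, np.nan, "absent"))
            continue
        present += 1
        x = raw_phospho.loc[key].to_numpy(dtype=float)
        for module, score_row in scores.iterrows():
            y = score_row.reindex(raw_phospho.columns).to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3:
                records.append((gene, site, module, np.nan, np.nan,
                                "too_few_samples"))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            records.append((gene, site, module, float(rho), float(p), "ok"))
    if present == 0:
        warnings.warn("no activation-loop site present in the phospho matrix")
    return pd.DataFrame(
        records, columns=["gene", "site", "module", "statistic", "p", "status"]
    )


def filter_druggable(
    associations: pd.DataFrame,
    features: Sequence[RegulatorFeature],
    druggability: pd.DataFrame,
) -> pd.DataFrame:
    """Keep associations whose feature involves a druggable gene.

    ``druggability`` is a two-column table (gene, flag/category).  A
    collapsed feature is retained if any member gene is flagged.  The
    druggability annotation is appended as a column.
    """
    flags = dict(zip(druggability.iloc[:, 0], druggability.iloc[:, 1]))
    by_id = {f.feature_id: f for f in features}
    keep_rows, annot = [], []
    for _, row in associations.iterrows():
        feat = by_id.get(row["feature"])
        genes = feat.genes if feat is not None else ()
        hits = [flags[g] for g in genes if g in flags and str(flags[g]).lower()
                not in ("0", "false", "no", "")]
        keep_rows.append(bool(hits))
        annot.append(";".join(str(h) for h in hits))
    out = associations.loc[keep_rows].copy()
    out["druggable"] = [a for a, k in zip(annot, keep_rows) if k]
    return out.reset_index(drop=True)
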