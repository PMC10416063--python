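"""Consensus discovery of co-regulated phosphosite modules.

The normalized phosphosite matrix is turned into a site-by-site
correlation matrix; each site's row of correlations is its feature vector.
A sweep of clustering algorithms and hyperparameters (density-based
clustering over a range of minimum cluster sizes, plus k-means and
agglomerative clustering over a small k range) produces candidate
labelings.  The consensus candidate is the one most similar to all the
others by mean pairwise adjusted Rand index (ARI); among near-ties the
candidate labeling the most phosphosites wins, so the consensus is both
reproducible and inclusive.  Density-based candidates may leave sites
unassigned (label -1); for ARI comparisons each unassigned site counts as
its own singleton cluster, which penalizes candidates that discard
everything without invalidating the partition.

A module's per-sample score is the mean normalized abundance of its
member sites in that sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.special import comb
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN, AgglomerativeClustering, KMeans
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

NOISE_LABEL = -1


def default_sweep_grid() -> list[tuple[str, dict]]:
    """Default hyperparameter sweep: density-based clustering over minimum
    cluster sizes 2..19, k-means and agglomerative over a small k range."""
    grid: list[tuple[str, dict]] = []
    grid += [("hdbscan", {"min_cluster_size": m}) for m in range(2, 20)]
    grid += [("kmeans", {"n_clusters": k}) for k in (5, 10, 15)]
    grid += [("agglomerative", {"n_clusters": k}) for k in (5, 10, 15)]
    return grid


@dataclass
class ClusteringCandidate:
    """One labeling from the sweep (-1 = unassigned/noise)."""

    algorithm: str
    hyperparameters: dict
    labels: pd.Series  # index = site keys, values = int labels
    n_labeled: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        self.n_labeled = int((self.labels != NOISE_LABEL).sum())

    @property
    def n_modules(self) -> int:
        return len(set(self.labels) - {NOISE_LABEL})


def pairwise_correlation(
    normalized: pd.DataFrame,
    method: str = "pearson",
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Site-by-site correlation over pairwise-complete samples.

    Pairs sharing fewer than ``min_overlap`` non-missing samples are set
    to 0 (and counted in the log); zero-variance sites get all-zero
    correlations.  The result is symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(normalized) < 2:
        raise ValueError("need at least 2 sites for pairwise correlation")
    corr = normalized.T.corr(method=method)
    observed = normalized.notna().to_numpy().astype(float)
    overlap = observed @ observed.T
    low = overlap < min_overlap
    np.fill_diagonal(low, False)
    n_low = int(low.sum() // 2)
    if n_low:
        logger.info("%d site pairs below min_overlap=%d set to 0", n_low, min_overlap)
    values = corr.to_numpy()
    values[low] = 0.0
    nan_mask = np.isnan(values)
    if nan_mask.any():
        zero_var = np.isnan(np.diag(values)) | (
            np.nansum(~np.isnan(values), axis=1) == 0
        )
        warnings.warn("zero-variance site(s); their correlations set to 0")
        values[nan_mask] = 0.0
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=corr.index, columns=corr.columns)


def _make_clusterer(algorithm: str, params: dict, seed: int):
    if algorithm == "hdbscan":
        return HDBSCAN(copy=True, **params)
    if algorithm == "kmeans":
        return KMeans(random_state=seed, n_init=10, **params)
    if algorithm == "agglomerative":
        return AgglomerativeClustering(**params)
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


def run_clustering_sweep(
    corr: pd.DataFrame,
    grid: Sequence[tuple[str, dict]] | None = None,
    seed: int = 0,
) -> list[ClusteringCandidate]:
    """Cluster the correlation matrix once per grid entry.

    Sites are embedded in correlation space: each site's feature vector is
    its row of correlations.  A failing grid entry is skipped with a
    logged reason rather than aborting the sweep.
    """
    if grid is None:
        grid = default_sweep_grid()
    if not grid:
        raise ValueError("sweep grid is empty")
    X = corr.to_numpy()
    candidates: list[ClusteringCandidate] = []
    for algorithm, params in grid:
        try:
            clusterer = _make_clusterer(algorithm, params, seed)
            raw = clusterer.fit_predict(X)
        except Exception as exc:  # noqa: BLE001 - sweep is fault tolerant
            logger.warning("skipping %s %r: %s", algorithm, params, exc)
            continue
        labels = pd.Series(np.asarray(raw, dtype=int), index=corr.index)
        candidates.append(ClusteringCandidate(algorithm, dict(params), labels))
    return candidates


def _noise_to_singletons(labels: np.ndarray) -> np.ndarray:
    """Replace each -1 with a unique fresh label so noise sites form
    singleton clusters."""
    labels = labels.copy()
    noise = labels == NOISE_LABEL
    if noise.any():
        start = labels.max() + 1 if labels.size else 0
        labels[noise] = np.arange(start, start + noise.sum())
    return labels


def adjusted_rand_index(
    a: Mapping | pd.Series,
    b: Mapping | pd.Series,
    noise_as_singletons: bool = True,
) -> float:
    """Permutation-model adjusted Rand index between two labelings.

    Both labelings must cover exactly the same keys.  With
    ``noise_as_singletons`` (default), every -1 site is first re-labeled
    as its own singleton cluster; with it off, the comparison is
    restricted to sites labeled (!= -1) in both.
    """
    a = pd.Series(dict(a)) if not isinstance(a, pd.Series) else a
    b = pd.Series(dict(b)) if not isinstance(b, pd.Series) else b
    if set(a.index) != set(b.index):
        raise ValueError("label maps cover different key domains")
    b = b.reindex(a.index)
    la = a.to_numpy(dtype=int)
    lb = b.to_numpy(dtype=int)
    if noise_as_singletons:
        la = _noise_to_singletons(la)
        lb = _noise_to_singletons(lb)
    else:
        keep = (la != NOISE_LABEL) & (lb != NOISE_LABEL)
        la, lb = la[keep], lb[keep]
        if la.size == 0:
            return 1.0
    n = la.size
    if n == 0:
        return 1.0
    # contingency table via joint label codes
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    joint = ia.astype(np.int64) * (ib.max() + 1) + ib
    nij = np.bincount(joint)
    ai = np.bincount(ia)
    bj = np.bincount(ib)
    sum_ij = comb(nij, 2).sum()
    sum_a = comb(ai, 2).sum()
    sum_b = comb(bj, 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def mean_pairwise_ari(
    candidates: Sequence[ClusteringCandidate],
    noise_as_singletons: bool = True,
) -> np.ndarray:
    """Mean ARI of each candidate against all the others."""
    k = len(candidates)
    ari = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ari[i, j] = ari[j, i] = adjusted_rand_index(
                candidates[i].labels, candidates[j].labels, noise_as_singletons
            )
    if k == 1:
        return np.array([1.0])
    return (ari.sum(axis=1) - 1.0) / (k - 1)


def select_consensus_labels(
    candidates: Sequence[ClusteringCandidate],
    rel_tol: float = 0.02,
    noise_as_singletons: bool = True,
) -> ClusteringCandidate:
    """Pick the candidate most similar to all others by mean pairwise ARI.

    Candidates within ``rel_tol`` (relative) of the maximum mean ARI form
    the top set — mean-ARI differences at the percent scale are sampling
    noise, not evidence — and from that set the candidate labeling the
    most phosphosites wins (the most inclusive reproducible labeling);
    remaining ties go to the earliest grid entry.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    if len(candidates) == 1:
        warnings.warn("single candidate; returning it as the consensus")
        return candidates[0]
    means = mean_pairwise_ari(candidates, noise_as_singletons)
    best = means.max()
    tol = abs(best) * rel_tol
    contenders = [i for i, m in enumerate(means) if m >= best - tol]
    winner = max(contenders, key=lambda i: (candidates[i].n_labeled, -i))
    return candidates[winner]


def drop_small_modules(labels: pd.Series, min_size: int = 2) -> pd.Series:
    """Demote modules with fewer than ``min_size`` members to noise."""
    counts = labels[labels != NOISE_LABEL].value_counts()
    small = counts[counts < min_size].index
    out = labels.copy()
    out[out.isin(small)] = NOISE_LABEL
    return out


def drop_incoherent_modules(
    labels: pd.Series, corr: pd.DataFrame, min_coherence: float = 0.25
) -> pd.Series:
    """Demote modules with near-zero internal correlation to noise.

    Clustering algorithms readily produce a spurious "module" out of the
    mutually uncorrelated sites that survive filtering (they form a dense
    blob near the origin of correlation space).  A real co-regulated
    module has substantial mean pairwise member correlation; any module
    whose mean off-diagonal correlation falls below ``min_coherence`` is
    demoted to unassigned.  The default of 0.25 sits above the magnitude
    of chance correlation at typical cohort sizes (roughly 3/sqrt(n) for
    n around 100-200 samples).  This automates the curation step
    otherwise done by eye on the per-module heatmaps.
    """
    out = labels.copy()
    for module in set(labels) - {NOISE_LABEL}:
        members = labels.index[labels == module]
        if len(members) < 2:
            continue
        block = corr.loc[members, members].to_numpy()
        n = len(members)
        mean_corr = (block.sum() - np.trace(block)) / (n * n - n)
        if mean_corr < min_coherence:
            logger.info(
                "module %s demoted: mean within-module correlation %.3f "
                "below %.3f", module, mean_corr, min_coherence,
            )
            out[out == module] = NOISE_LABEL
    return out


def calculate_module_scores(
    normalized: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-sample mean of each module's member sites (missing-excluded).

    Returns a modules x samples DataFrame; a cell is missing when every
    member is missing in that sample.  Noise sites are excluded.
    """
    labels = labels.reindex(normalized.index.intersection(labels.index))
    scores = {}
    for module in sorted(set(labels) - {NOISE_LABEL}):
        members = labels.index[labels == module]
        if len(members) == 0:
            warnings.warn(f"module {module} is empty; excluded")
            continue
        scores[module] = normalized.loc[members].mean(axis=0, skipna=True)
    out = pd.DataFrame(scores).T
    out.index.name = "module"
    return out


def impute_missing(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """K-nearest-neighbor imputation across rows (sites as observations).

    Distances are Euclidean over mutually non-missing columns; existing
    values are never altered.  Rows with no observed value are an error.
    """
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"row {matrix.index[all_missing][0]!r} has no non-missing values"
        )
    imputer = KNNImputer(n_neighbors=k)
    values = imputer.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def export_module_tables(
    normalized: pd.DataFrame,
    labels: pd.Series,
    out_dir,
    annotations: pd.DataFrame | None = None,
    heatmaps: bool = False,
) -> list:
    """Write one member-site x sample table per module for visual curation.

    Member rows are ordered by hierarchical-clustering leaf order
    (average linkage on Euclidean distances, missing as 0 for ordering
    only).  Sample annotation rows are appended below when provided.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for module in sorted(set(labels) - {NOISE_LABEL}):
        members = labels.index[labels == module]
        block = normalized.loc[members]
        if len(block) > 2:
            filled = block.fillna(0.0).to_numpy()
            order = leaves_list(linkage(pdist(filled), method="average"))
            block = block.iloc[order]
        table = block.copy()
        table.index = [
            "_".join(map(str, k)) if isinstance(k, tuple) else str(k)
            for k in table.index
        ]
        if annotations is not None:
            ann = annotations.reindex(table.columns).T
            table = pd.concat([table, ann])
        path = out_dir / f"module_{module}.tsv"
        table.to_csv(path, sep="\t", na_rep="")
        written.append(path)
        if heatmaps:
            _write_heatmap(block, out_dir / f"module_{module}.png")
    return written


def _write_heatmap(block: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * len(block))))
    ax.imshow(block.fillna(0.0).to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(block)))
    ax.set_yticklabels(
        ["_".join(map(str, k)) if isinstance(k, tuple) else str(k)
         for k in block.index],
        fontsize=6,
    )
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


class ModuleDiscovery(BaseEstimator, ClusterMixin):
    """Consensus module discovery over a clustering-hyperparameter sweep.

    ``fit`` takes the protein-normalized phosphosite matrix (sites x
    samples), builds the correlation matrix, runs the sweep, and selects
    the consensus labeling.

    Parameters
    ----------
    grid : list of (algorithm, params) or None
        Sweep grid; None uses :func:`default_sweep_grid`.
    corr_method : {"pearson", "spearman"}
        Site-site correlation flavor.
    min_overlap : int
        Minimum pairwise-complete samples for a correlation to count.
    min_module_size : int
        Modules smaller than this are demoted to noise after selection.
    min_module_coherence : float
        Modules whose mean within-module correlation falls below this are
        demoted to noise (automated spurious-module curation).
    noise_as_singletons : bool
        ARI noise handling during consensus selection.
    seed : int
        Seed for stochastic clusterers.

    Attributes
    ----------
    correlation_ : DataFrame, sites x sites.
    candidates_ : list of ClusteringCandidate.
    consensus_ : ClusteringCandidate actually selected.
    labels_ : ndarray of int, aligned with the input row order.
    module_scores_ : DataFrame, modules x samples.
    sweep_report_ : DataFrame with one row per candidate.
    """

    def __init__(
        self,
        grid: Sequence[tuple[str, dict]] | None = None,
        corr_method: str = "pearson",
        min_overlap: int = 5,
        min_module_size: int = 2,
        min_module_coherence: float = 0.25,
        consensus_rel_tol: float = 0.02,
        noise_as_singletons: bool = True,
        seed: int = 0,
    ):
        self.grid = grid
        self.corr_method = corr_method
        self.min_overlap = min_overlap
        self.min_module_size = min_module_size
        self.min_module_coherence = min_module_coherence
        self.consensus_rel_tol = consensus_rel_tol
        self.noise_as_singletons = noise_as_singletons
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.correlation_ = pairwise_correlation(
            X, self.corr_method, self.min_overlap
        )
        self.candidates_ = run_clustering_sweep(
            self.correlation_, self.grid, self.seed
        )
        if not self.candidates_:
            raise RuntimeError("every sweep entry failed; no candidates")
        # curate every candidate (size and coherence demotion) before the
        # consensus comparison, so candidates are ranked on genuine module
        # structure rather than on how they happen to carve up the
        # incoherent remainder
        self.curated_candidates_ = []
        for cand in self.candidates_:
            lab = drop_small_modules(cand.labels, self.min_module_size)
            lab = drop_incoherent_modules(
                lab, self.correlation_, self.min_module_coherence
            )
            self.curated_candidates_.append(
                ClusteringCandidate(cand.algorithm, cand.hyperparameters, lab)
            )
        means = mean_pairwise_ari(
            self.curated_candidates_, self.noise_as_singletons
        )
        self.consensus_ = select_consensus_labels(
            self.curated_candidates_,
            rel_tol=self.consensus_rel_tol,
            noise_as_singletons=self.noise_as_singletons,
        )
        labels = self.consensus_.labels
        self.label_series_ = labels
        self.labels_ = labels.to_numpy()
        self.module_scores_ = calculate_module_scores(X, labels)
        self.sweep_report_ = pd.DataFrame(
            {
                "algorithm": [c.algorithm for c in self.candidates_],
                "hyperparameters": [repr(c.hyperparameters) for c in self.candidates_],
                "n_modules": [c.n_modules for c in self.candidates_],
                "n_labeled": [c.n_labeled for c in self.candidates_],
                "mean_ari": means,
            }
        )
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
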