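"""Protein normalization of phosphopeptide abundance.

Phosphopeptide log2 relative abundance confounds two signals: how much of
the parent protein is present, and how phosphorylated it is.  To isolate
the phosphorylation signal, each phosphopeptide is regressed on its parent
protein with a one-feature ridge model (regularization chosen by k-fold
cross-validation over a fixed grid) and replaced by its residuals.
Regularization matters when a protein barely varies across the cohort: an
unregularized slope would then be dominated by noise.

The ridge slope has the closed form

    slope = S_xy / (S_xx + alpha),    intercept = ybar - slope * xbar

with the intercept unpenalized, so residuals over the training pairs
always have mean zero.

Note: for kinases and phosphatases that autophosphorylate, protein
abundance and phosphorylation are intertwined and this normalization
over-corrects; regulator nomination therefore works on raw phosphopeptide
data (see :mod:`phosmod.regulators`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Regularization grid: five-fold steps spanning 3.2e-4 .. 625.
DEFAULT_ALPHAS: tuple[float, ...] = (
    0.00032, 0.0016, 0.008, 0.04, 0.2, 1, 5, 25, 125, 625,
)
DEFAULT_CV_FOLDS = 3


@dataclass(frozen=True)
class RidgeFit:
    """One-feature ridge fit with an unpenalized intercept."""

    intercept: float
    slope: float
    alpha: float
    n_used: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def ridge_fit(x: np.ndarray, y: np.ndarray, alpha: float) -> RidgeFit:
    """Fit y ~ x with ridge penalty ``alpha`` on the slope only.

    ``x`` and ``y`` must already be restricted to pairwise non-missing
    entries of equal length >= 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("ridge fit requires at least 2 paired points")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("x and y must not contain missing values")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    denom = sxx + alpha
    slope = 0.0 if denom == 0 else sxy / denom
    intercept = ybar - slope * xbar
    return RidgeFit(intercept=intercept, slope=slope, alpha=alpha, n_used=len(x))


def _cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle of range(n), as k folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, k) if len(fold) > 0]


def cv_select_alpha(
    x: np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> float:
    """Pick the alpha minimizing mean squared CV prediction error.

    Folds are contiguous blocks of a seeded shuffle, so the choice is
    deterministic for a given seed.  Ties are broken toward the larger
    alpha (stronger regularization at equal error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < cv_folds:
        raise ValueError(f"need >= {cv_folds} paired points, got {n}")
    folds = _cv_folds(n, cv_folds, seed)
    best_alpha = None
    best_mse = np.inf
    for alpha in alphas:
        errors = []
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            if train_mask.sum() < 2:
                continue
            fit = ridge_fit(x[train_mask], y[train_mask], alpha)
            errors.append(np.mean((y[test_idx] - fit.predict(x[test_idx])) ** 2))
        mse = float(np.mean(errors)) if errors else np.inf
        if mse < best_mse or (mse == best_mse and best_alpha is not None
                              and alpha > best_alpha):
            best_mse = mse
            best_alpha = alpha
    assert best_alpha is not None
    return best_alpha


class ProteinNormalizer(BaseEstimator, TransformerMixin):
    """Remove parent-protein variation from phosphopeptide abundance.

    Parameters
    ----------
    alphas : sequence of float
        Ridge regularization grid searched by cross-validation.
    cv_folds : int
        Number of CV folds; peptides with fewer paired non-missing values
        than this are dropped (the step doubles as a missingness filter).
    seed : int
        Seed for the fold-assignment shuffle.
    keep_unmatched : bool
        If True (default), peptides whose gene has no protein row are
        passed through mean-centered instead of dropped.

    Attributes
    ----------
    residuals_ : pandas.DataFrame
        Protein-normalized phosphopeptide matrix (same TSV dialect as the
        input when written).
    dropped_ : list of tuple
        Row keys dropped for insufficient paired observations, with reason.
    fits_ : dict
        Row key -> :class:`RidgeFit` for peptides that were regressed.
    """

    def __init__(
        self,
        alphas: Sequence[float] = DEFAULT_ALPHAS,
        cv_folds: int = DEFAULT_CV_FOLDS,
        seed: int = 0,
        keep_unmatched: bool = True,
    ):
        self.alphas = alphas
        self.cv_folds = cv_folds
        self.seed = seed
        self.keep_unmatched = keep_unmatched

    def fit(self, X: pd.DataFrame, protein: pd.DataFrame | None = None):
        """Fit per-peptide ridge models and compute residuals.

        ``X`` is the phosphopeptide matrix (MultiIndex (gene, site));
        ``protein`` the protein matrix (gene index) over the same samples.
        """
        if protein is None:
            raise ValueError("a protein abundance matrix is required")
        missing_cols = [c for c in X.columns if c not in protein.columns]
        if missing_cols:
            raise ValueError(f"samples absent from protein matrix: {missing_cols}")
        protein = protein[X.columns]

        residual_rows: dict = {}
        dropped: list[tuple] = []
        fits: dict = {}
        for key, y_row in X.iterrows():
            gene = key[0] if isinstance(key, tuple) else key
            y = y_row.to_numpy(dtype=float)
            if gene not in protein.index:
                if self.keep_unmatched:
                    centered = y - np.nanmean(y) if np.any(~np.isnan(y)) else y
                    residual_rows[key] = centered
                    logger.debug("no protein row for %r; mean-centered", key)
                else:
                    dropped.append((key, "no_parent_protein"))
                continue
            x = protein.loc[gene].to_numpy(dtype=float)
            paired = ~np.isnan(x) & ~np.isnan(y)
            n_paired = int(paired.sum())
            if n_paired < self.cv_folds:
                dropped.append((key, "insufficient_paired_values"))
                continue
            alpha = cv_select_alpha(
                x[paired], y[paired], self.alphas, self.cv_folds, self.seed
            )
            fit = ridge_fit(x[paired], y[paired], alpha)
            fits[key] = fit
            resid = np.full_like(y, np.nan)
            resid[paired] = y[paired] - fit.predict(x[paired])
            residual_rows[key] = resid
        index = X.index[[k in residual_rows for k in X.index]]
        self.residuals_ = pd.DataFrame(
            [residual_rows[k] for k in index], index=index, columns=X.columns
        )
        self.dropped_ = dropped
        self.fits_ = fits
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the residual matrix computed during :meth:`fit`."""
        if not hasattr(self, "residuals_"):
            raise RuntimeError("ProteinNormalizer is not fitted")
        return self.residuals_

    def fit_transform(self, X, protein=None, **kwargs):  # noqa: D102
        return self.fit(X, protein=protein).transform(X)


def normalize_phospho_by_protein(
    phospho: pd.DataFrame,
    protein: pd.DataFrame,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    keep_unmatched: bool = True,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Functional wrapper over :class:`ProteinNormalizer`.

    Returns (residual matrix, dropped row keys with reasons).
    """
    est = ProteinNormalizer(alphas, cv_folds, seed, keep_unmatched)
    est.fit(phospho, protein=protein)
    return est.residuals_, est.dropped_


def normalize_by_subgroup(
    phospho: pd.DataFrame,
    protein: pd.DataFrame,
    groups: Mapping[str, str],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    keep_unmatched: bool = True,
) -> pd.DataFrame:
    """Run protein normalization independently within each sample subgroup.

    Combining cohorts (e.g. tumor and normal of two cancer types) on one
    scale hides non-linear scale differences; normalizing each subgroup
    separately and re-assembling the residual columns in the original
    sample order avoids this.  A peptide dropped in one subgroup is
    missing in that subgroup's columns but may survive in others.
    """
    labels = {groups.get(s) for s in phospho.columns}
    if None in labels:
        ungrouped = [s for s in phospho.columns if s not in groups]
        raise ValueError(f"samples without a group label: {ungrouped}")
    pieces: list[pd.DataFrame] = []
    for label in sorted(labels):  # type: ignore[arg-type]
        samples = [s for s in phospho.columns if groups[s] == label]
        if len(samples) < cv_folds:
            warnings.warn(
                f"group {label!r} has {len(samples)} samples < {cv_folds} "
                "CV folds; all residuals missing for this group"
            )
            pieces.append(pd.DataFrame(np.nan, index=phospho.index, columns=samples))
            continue
        resid, _ = normalize_phospho_by_protein(
            phospho[samples], protein[samples], alphas, cv_folds, seed,
            keep_unmatched,
        )
        pieces.append(resid.reindex(phospho.index))
    out = pd.concat(pieces, axis=1)
    out = out[phospho.columns]
    # drop rows that are all-missing everywhere (dropped in every group)
    return out.loc[~out.isna().all(axis=1)]
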