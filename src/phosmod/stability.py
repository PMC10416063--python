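"""Module stability under cohort down-sampling.

How many samples does module discovery need?  The full pipeline is
re-run on repeated random sample subsets at several cohort sizes; each
reference module is then compared with its best-matching module in every
subsampled run (percent phosphosite overlap), and the consistency of the
reference module's sites across repeats is summarized with the mean
pairwise adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .discovery import NOISE_LABEL, adjusted_rand_index

logger = logging.getLogger(__name__)


@dataclass
class SubsampleDesign:
    sizes: tuple[int, ...] = (25, 50, 75, 100)
    repeats: int = 15
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2")
        for size in self.sizes:
            if size > n_samples:
                raise ValueError(
                    f"subsample size {size} exceeds population {n_samples}"
                )


def subsample_cohorts(
    samples: Sequence[str], design: SubsampleDesign
) -> list[tuple[int, int, list[str]]]:
    """Uniform random subsets without replacement, reproducible from the
    design seed; repeats are drawn independently."""
    design.validate(len(samples))
    rng = np.random.default_rng(design.seed)
    out = []
    for size in design.sizes:
        for rep in range(design.repeats):
            chosen = set(rng.choice(list(samples), size=size, replace=False))
            # canonical cohort order: a subsample is a set of patients, and
            # downstream runs must not depend on draw order
            out.append((size, rep, [s for s in samples if s in chosen]))
    return out


def best_module_overlap(
    reference: pd.Series, run: pd.Series, reference_module: int
) -> float:
    """Max percent overlap of a reference module with any module of a run.

    overlap = max over run modules of |ref ∩ run| / |ref| * 100, computed
    on the shared site universe.  Run noise (-1) never counts as a module.
    """
    ref_sites = set(reference.index[reference == reference_module])
    if not ref_sites:
        raise ValueError(f"reference module {reference_module} is empty")
    run = run[run.index.isin(reference.index)]
    best = 0.0
    for module in set(run) - {NOISE_LABEL}:
        members = set(run.index[run == module])
        best = max(best, 100.0 * len(ref_sites & members) / len(ref_sites))
    return best


def cross_run_ari(
    reference_sites: set, runs: Sequence[pd.Series]
) -> float:
    """Mean pairwise ARI of the runs' labels restricted to the reference
    module's sites (how consistently those sites co-cluster)."""
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    values = []
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            shared = (reference_sites
                      & set(runs[i].index) & set(runs[j].index))
            if len(shared) < len(reference_sites):
                logger.info(
                    "restricting ARI to %d of %d reference sites",
                    len(shared), len(reference_sites),
                )
            if not shared:
                continue
            idx = sorted(shared)
            values.append(adjusted_rand_index(
                runs[i].loc[idx], runs[j].loc[idx]
            ))
    return float(np.mean(values)) if values else float("nan")


def run_stability_analysis(
    samples: Sequence[str],
    design: SubsampleDesign,
    rerun: Callable[[list[str]], pd.Series],
    reference_labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run discovery on every subsample and summarize per module.

    ``rerun`` maps a sample subset to a module assignment (site -> label)
    produced by the same configuration as the reference run.  Returns
    (per-run table: size, repeat, module, best_overlap_pct;
    summary table: size, module, mean, sd, cross_run_ari).
    """
    ref_modules = sorted(set(reference_labels) - {NOISE_LABEL})
    records = []
    runs_by_size: dict[int, list[pd.Series]] = {}
    for size, rep, subset in subsample_cohorts(samples, design):
        labels = rerun(subset)
        runs_by_size.setdefault(size, []).append(labels)
        for module in ref_modules:
            records.append((size, rep, module,
                            best_module_overlap(reference_labels, labels, module)))
    per_run = pd.DataFrame(
        records, columns=["size", "repeat", "module", "best_overlap_pct"]
    )
    summary_records = []
    for size in design.sizes:
        for module in ref_modules:
            sel = per_run[(per_run["size"] == size)
                          & (per_run["module"] == module)]
            ref_sites = set(
                reference_labels.index[reference_labels == module]
            )
            summary_records.append((
                size, module,
                float(sel["best_overlap_pct"].mean()),
                float(sel["best_overlap_pct"].std(ddof=1)),
                cross_run_ari(ref_sites, runs_by_size[size]),
            ))
    summary = pd.DataFrame(
        summary_records,
        columns=["size", "module", "mean_overlap_pct", "sd_overlap_pct",
                 "cross_run_ari"],
    )
    return per_run, summary
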