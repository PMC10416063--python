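# Methods

## Model and assumptions

The package treats a phosphoproteomic cohort as two log2
relative-abundance matrices over the same samples: phosphopeptides keyed
by (gene, site) and proteins keyed by gene. Three assumptions drive the
design:

1. A phosphopeptide's measured abundance is approximately linear in its
   parent protein's abundance; the residual after removing that linear
   component reflects phosphorylation state. The single-feature ridge
   model with unpenalized intercept,
   slope = Sxy/(Sxx + α), intercept = ȳ − slope·x̄,
   is deliberately minimal: with one feature, regularization matters
   only when the protein barely varies, which is exactly the case where
   an unregularized slope would chase noise. The known failure mode is
   autophosphorylation on kinases/phosphatases, where protein abundance
   and phosphorylation are causally coupled and normalization
   over-corrects; regulator nomination therefore uses raw phosphopeptide
   data.
2. Co-regulated sites covary across samples, so module structure lives
   in the site × site correlation matrix. Sites are clustered in
   correlation space (each site's feature vector is its row of
   correlations), not by a precomputed distance, so every clustering
   family in the sweep sees the same embedding.
3. No single clustering algorithm/hyperparameter setting is trustworthy
   a priori. Reproducibility across the sweep is the selection signal:
   the consensus labeling maximizes mean pairwise ARI against all other
   candidates, and within a tolerance band the most inclusive labeling
   (most sites assigned) wins.

## Parameters that matter

| parameter | default | units/range | why |
|---|---|---|---|
| `alphas` | 0.00032 … 625 (×5 steps) | ridge penalty | spans negligible to dominant regularization on log2 data |
| `cv_folds` | 3 | folds | also the minimum paired-observation count per peptide |
| `max_missing_frac` | 0.25 | fraction | rows with *more* than 25 % missing are dropped (strict inequality) |
| `top_variance_frac` | 0.5 | fraction | keep rows at/above the (1−frac) quantile of survivor SDs |
| `min_overlap` | 5 | samples | correlations on fewer pairwise-complete samples are set to 0 |
| `min_module_size` | 2 | sites | singleton modules are meaningless |
| `min_module_coherence` | 0.25 | mean within-module r | automated spurious-module curation; sits above chance correlation magnitude ≈3/√n for cohorts of 100–200 samples |
| `consensus_rel_tol` | 0.02 | relative | candidates within 2 % of the best mean ARI count as tied; mean-ARI differences at that scale are sampling noise, and the tie resolves toward inclusiveness |
| `corr_threshold` (regulators) | 0.95 | Pearson r | features above this collapse to their per-sample mean; >1 disables |
| `flank` | 7 | residues | 15-mer windows, the field's usual motif width |

## Numerical conventions

- Standard deviations use the n−1 denominator over non-missing entries;
  rows with fewer than 2 observations get SD 0. Quantiles/percentiles
  use linear interpolation between order statistics. Rows exactly at the
  variance threshold are kept. Because the variance cut is rank-based,
  re-filtering an already-filtered matrix tightens further; the filter
  is deterministic but not idempotent under composition.
- CV folds are contiguous blocks of a seeded shuffle of the paired
  sample indices (seed is a config parameter, default 0); alpha ties
  break toward the larger alpha. The CV score is mean squared
  prediction error (the natural choice for a least-squares model).
- Peptides whose gene has no protein row are retained mean-centered
  rather than dropped: silently shrinking the site universe would bias
  downstream stages, and centering matches the residual scale. This is
  logged and configurable (`keep_unmatched`).
- ARI is computed from the contingency-table permutation-model formula.
  Unassigned sites (−1) are re-labeled as singleton clusters before the
  formula: excluding them would reward candidates that discard
  everything, while singleton treatment penalizes over-discarding yet
  keeps a valid partition. The restricted alternative (sites labeled in
  both) is available.
- Candidate curation (minimum size, then minimum coherence) is applied
  to every sweep candidate *before* the consensus comparison, so
  candidates are ranked on genuine module structure rather than on how
  they happen to carve up the mutually uncorrelated remainder — those
  sites otherwise form a dense blob near the origin of correlation
  space that density-based clusterers happily call a module.
- Zero-variance sites get all-zero correlation rows (diagonal stays 1)
  with a warning; all-missing columns and rows are errors naming the
  offender.
- Regulator feature collapsing uses *signed* r > threshold (merging
  anti-correlated features by mean would cancel signal) and connected
  components (deterministic, order-independent). Collapsed component
  means are not re-checked against the threshold. In ridge
  (`linear_model`) mode no per-coefficient p-values are emitted —
  regularized coefficients have no standard null.
- The logistic option for regulator association z-standardizes each
  module's scores and applies 1/(1+e^−z). The transform is strictly
  monotone, so Spearman-mode results are provably unchanged; it only
  matters for Pearson or ridge modes. The curve family is motivated by
  the typical log(kinase abundance) vs substrate-saturation shape; the
  exact parameterization is a package choice.
- Motif counts exclude the pad character `-` (positions beyond a
  terminus are non-observations); enrichment and depletion get separate
  one-sided Fisher tests, covering both readings of "enrichment or
  depletion". Default background for a module is all clustered sites
  outside it (controls for acquisition bias); "all input sites" is
  available. No multiple-testing correction inside motif grids by
  default (displayed as −log10 p); BH is optional.
- Set over-representation intersects each database set with the
  universe first; the default universe is all sites that entered
  clustering. Cross-cohort overlap testing requires identifiers
  harmonized as `gene_site` strings and uses the same hypergeometric
  upper tail.
- BH correction treats all (module × indicator/variable) hypotheses in
  one run as a single family — the most conservative interpretable
  default. Minimum group size for rank tests is 3.
- Subsampling is plain uniform sampling without replacement; subsets
  are re-ordered to the original cohort order so a full-size subsample
  is bit-identical to the reference run. The variance-balanced
  splitting some pipelines use is approximated by seeding + repeats,
  since its balancing criterion is not quantitatively defined.

## The synthetic generator

`synthetic.generate_cohort` plants: per-module latent drivers d_m ~
N(0,1) over samples; member sites β·d_m + γ·protein + ε with β ∈
[0.8, 1.2], γ ∈ [0.3, 1.0], ε ~ N(0, 0.5); 300 pure protein+ε noise
sites; a binary subtype annotation shifting module 0's driver by 1.5 in
one subgroup; one true regulator gene per module (protein row = driver
+ N(0, 0.3), plus an activation-loop phosphosite) among 12 decoys; a
module-specific residue at offset +1 of each member's FASTA window; and
10 % missingness, completely at random by default (an optional
intensity-dependent mechanism preferentially drops low values). The
reference conditions are 150 samples and 8 modules of 5–30 sites.

What it does **not** emulate: TMT ratio compression, batch/plex
effects, peptide-level quantification error heterogeneity, co-eluting
multiply-phosphorylated peptide ambiguity, or instrument-specific
missingness. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated generative model, not
performance on any particular real cohort.

## Problem sizes in the test and acceptance runs

Unit and property tests use a reduced cohort (60 samples, 4 modules of
6–15 sites, 60 noise sites) and a reduced sweep grid (HDBSCAN
min-cluster-size 3–10, k-means/agglomerative k ∈ {4, 8}) so the whole
suite runs in a couple of minutes; full-size recovery (150 samples, 8
modules, the default grid) is exercised in the acceptance tests across
10 seeds. The stability analysis is run at cohort sizes
{15, 30, 45, 60} with 5 repeats (3 in the acceptance script) — the
same design, scaled to the reduced cohort.

## Known limitations

- One protein feature per peptide; isoform-aware or multi-protein
  normalization is out of scope.
- The sweep ships three clustering families; other scikit-learn
  clusterers can be added via the grid but are not defaulted.
- Hypergeometric over-representation replaces rank-based single-sample
  projection for set enrichment: exact, fast and desk-testable, but it
  ignores within-module effect-size ordering.
- Coherence-based curation uses a fixed threshold; very weak but real
  modules (mean within-correlation < 0.25) would be demoted and the
  threshold should be lowered for noisy small cohorts.
- Stability analysis re-runs the full pipeline per subsample and is the
  most expensive stage; budget accordingly on large cohorts.
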