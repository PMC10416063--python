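"""Synthetic phosphoproteomic cohorts with known ground truth.

Every downstream stage of the toolkit can be exercised without external
data by generating a cohort in which the answers are planted:

* each module m has a latent driver vector d_m ~ N(0, 1) over samples;
* a member site i of module m measures beta_i * d_m + gamma_i * protein_i
  + eps, where protein_i is that site's independently generated parent
  protein (the confound protein normalization must remove), beta_i the
  driver effect and eps ~ N(0, noise_sd);
* noise sites are pure protein + eps, so after normalization they carry
  no shared signal;
* a categorical annotation shifts one module's driver in a subgroup of
  samples (so annotation association has a planted hit);
* one candidate-regulator gene per module has a protein row equal to its
  module's driver plus noise (plus decoy regulator genes with unrelated
  rows), and an activation-loop phosphosite tracking the same driver;
* each module's member sites share a planted residue at offset +1 of
  their FASTA flanking sequence, so motif enrichment is recoverable;
* entries go missing completely at random at a configurable rate (an
  optional intensity-dependent mechanism drops low values preferentially,
  to stress-test the filters the way real phosphoproteomics data would).

What this generator does *not* emulate: TMT ratio compression, batch
effects, peptide-level quantification error structure, or the
abundance-correlated missingness patterns of specific instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODULE_MOTIF_RESIDUES = "PGKRLDEQ"  # residue planted at offset +1, per module
SITE_RESIDUES = "STY"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults define the reference conditions."""

    n_samples: int = 150
    n_modules: int = 8
    module_size_range: tuple[int, int] = (5, 30)
    n_noise_sites: int = 300
    driver_effect_range: tuple[float, float] = (0.8, 1.2)
    protein_slope_range: tuple[float, float] = (0.3, 1.0)
    noise_sd: float = 0.5
    missing_frac: float = 0.10
    missing_mechanism: str = "mcar"  # or "intensity"
    annotation_effect: float = 1.5
    n_decoy_regulators: int = 12
    regulator_noise_sd: float = 0.3
    protein_length: int = 40
    flank: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4 or self.n_modules < 1:
            raise ValueError("need >= 4 samples and >= 1 module")
        lo, hi = self.module_size_range
        if not (2 <= lo <= hi):
            raise ValueError("module sizes must be >= 2 and lo <= hi")
        if not 0 <= self.missing_frac <= 1:
            raise ValueError("missing_frac must be in [0, 1]")
        if self.missing_mechanism not in ("mcar", "intensity"):
            raise ValueError(f"unknown mechanism {self.missing_mechanism!r}")
        if 2 * self.flank + 1 > self.protein_length:
            raise ValueError("protein_length too short for the flank width")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    site_modules: pd.Series  # (gene, site) -> module id, -1 for noise
    module_drivers: pd.DataFrame  # modules x samples latent vectors
    regulator_genes: dict[int, str]  # module -> true driver gene
    decoy_genes: list[str]
    annotation_variable: str
    annotation_level: str
    affected_module: int
    annotation_effect: float
    module_motifs: dict[int, str]  # module -> planted residue at offset +1
    loop_sites: list[tuple[str, str]]  # (gene, site) activation-loop keys


@dataclass
class SyntheticCohort:
    protein: pd.DataFrame
    phospho: pd.DataFrame
    annotations: pd.DataFrame
    annotation_kinds: dict[str, str]
    fasta: dict[str, str]
    site_mapping: pd.DataFrame
    regulator_candidates: list[str]
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default=None)


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(_AA), size=length))


def _apply_missingness(
    values: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.missing_frac == 0:
        return values
    out = values.copy()
    if cfg.missing_mechanism == "mcar":
        mask = rng.random(values.shape) < cfg.missing_frac
    else:
        # intensity-dependent: low values are likelier to drop out, with
        # the marginal rate kept at missing_frac via rank-based weights
        ranks = np.argsort(np.argsort(values, axis=None)).reshape(values.shape)
        weights = 1.0 - ranks / ranks.size  # high weight for low values
        weights *= cfg.missing_frac * values.size / weights.sum()
        mask = rng.random(values.shape) < np.clip(weights, 0, 1)
    out[mask] = np.nan
    return out


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort with ground truth.

    All randomness flows from ``config.seed`` through one generator, so
    identical configs give bit-identical cohorts.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]

    # latent drivers, one per module
    drivers = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    # planted categorical annotation shifts module 0's driver in subgroup B
    subtype = np.where(rng.random(cfg.n_samples) < 0.5, "A", "B")
    affected = 0
    drivers[affected, subtype == "B"] += cfg.annotation_effect

    lo, hi = cfg.module_size_range
    module_sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    n_sites = int(module_sizes.sum()) + cfg.n_noise_sites
    genes = [f"G{i:04d}" for i in range(n_sites)]

    site_rows: dict[tuple[str, str], np.ndarray] = {}
    protein_rows: dict[str, np.ndarray] = {}
    truth_modules: dict[tuple[str, str], int] = {}
    fasta: dict[str, str] = {}
    mapping_records = []
    module_motifs = {
        m: MODULE_MOTIF_RESIDUES[m % len(MODULE_MOTIF_RESIDUES)]
        for m in range(cfg.n_modules)
    }

    site_idx = 0
    module_of_site = np.concatenate(
        [np.full(s, m) for m, s in enumerate(module_sizes)]
        + [np.full(cfg.n_noise_sites, -1)]
    )
    for module in module_of_site:
        gene = genes[site_idx]
        protein_row = rng.standard_normal(cfg.n_samples)
        protein_rows[gene] = protein_row
        gamma = rng.uniform(*cfg.protein_slope_range)
        eps = rng.normal(0, cfg.noise_sd, cfg.n_samples)
        if module >= 0:
            beta = rng.uniform(*cfg.driver_effect_range)
            values = beta * drivers[module] + gamma * protein_row + eps
        else:
            values = gamma * protein_row + eps

        # sequence context: random protein with the site centered where a
        # +/- flank window fits, motif residue planted at offset +1
        position = int(rng.integers(cfg.flank + 1,
                                    cfg.protein_length - cfg.flank))
        seq = _random_protein(rng, cfg.protein_length)
        residue = SITE_RESIDUES[rng.integers(len(SITE_RESIDUES))]
        seq[position - 1] = residue
        if module >= 0:
            seq[position] = module_motifs[int(module)]
        protein_id = f"P_{gene}"
        fasta[protein_id] = "".join(seq)
        site = f"{residue}{position}"
        key = (gene, site)
        site_rows[key] = values
        truth_modules[key] = int(module)
        mapping_records.append((gene, site, protein_id, str(position)))
        site_idx += 1

    # candidate regulators: one true driver gene per module, plus decoys
    regulator_genes: dict[int, str] = {}
    loop_sites: list[tuple[str, str]] = []
    for m in range(cfg.n_modules):
        gene = f"REG{m:02d}"
        regulator_genes[m] = gene
        protein_rows[gene] = drivers[m] + rng.normal(
            0, cfg.regulator_noise_sd, cfg.n_samples
        )
        loop_key = (gene, "T200")
        site_rows[loop_key] = drivers[m] + rng.normal(
            0, cfg.regulator_noise_sd, cfg.n_samples
        )
        truth_modules[loop_key] = -1
        loop_sites.append(loop_key)
    decoys = []
    for d in range(cfg.n_decoy_regulators):
        gene = f"DEC{d:02d}"
        decoys.append(gene)
        protein_rows[gene] = rng.standard_normal(cfg.n_samples)

    phospho_index = pd.MultiIndex.from_tuples(
        list(site_rows), names=["gene", "site"]
    )
    phospho = pd.DataFrame(
        _apply_missingness(np.vstack(list(site_rows.values())), cfg, rng),
        index=phospho_index, columns=samples,
    )
    protein = pd.DataFrame(
        _apply_missingness(np.vstack(list(protein_rows.values())), cfg, rng),
        index=pd.Index(list(protein_rows), name="gene"), columns=samples,
    )

    age = rng.uniform(30, 85, cfg.n_samples).round(1)
    annotations = pd.DataFrame(
        {"subtype": subtype, "age": age}, index=pd.Index(samples, name="sample")
    )
    truth = SyntheticTruth(
        site_modules=pd.Series(truth_modules).rename_axis(["gene", "site"]),
        module_drivers=pd.DataFrame(drivers, columns=samples),
        regulator_genes=regulator_genes,
        decoy_genes=decoys,
        annotation_variable="subtype",
        annotation_level="B",
        affected_module=affected,
        annotation_effect=cfg.annotation_effect,
        module_motifs=module_motifs,
        loop_sites=loop_sites,
    )
    mapping = pd.DataFrame(
        mapping_records, columns=["gene", "site", "protein_id", "positions"]
    )
    mapping["positions"] = [[int(p)] for p in mapping["positions"]]
    return SyntheticCohort(
        protein=protein,
        phospho=phospho,
        annotations=annotations,
        annotation_kinds={"subtype": "categorical", "age": "continuous"},
        fasta=fasta,
        site_mapping=mapping,
        regulator_candidates=list(regulator_genes.values()) + decoys,
        truth=truth,
        config=cfg,
    )


def generate_gmt_fixture(
    truth: SyntheticTruth, contamination: float = 0.0, seed: int = 0
) -> dict[str, set[str]]:
    """One named set per true module, partially contaminated.

    A fraction ``contamination`` of each set's slots is replaced by
    random identifiers drawn from outside the module, so at 0 the
    matching set is pure truth and at 1.0 it is entirely random.
    """
    if not 0 <= contamination <= 1:
        raise ValueError("contamination must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = pd.Series(
        [f"{g}_{s}" for g, s in truth.site_modules.index],
        index=truth.site_modules.index,
    )
    sets: dict[str, set[str]] = {}
    for module in sorted(set(truth.site_modules) - {-1}):
        members = list(ids[truth.site_modules == module])
        others = list(ids[truth.site_modules != module])
        n_replace = int(round(contamination * len(members)))
        kept = list(rng.choice(members, len(members) - n_replace, replace=False))
        noise = list(rng.choice(others, min(n_replace, len(others)),
                                replace=False))
        if kept or noise:
            sets[f"module_{module}_set"] = set(kept) | set(noise)
    return sets


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write a ready-to-run cohort directory in the pipeline's formats."""
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    io.write_abundance_table(cohort.phospho, out / "phospho.tsv")
    io.write_abundance_table(cohort.protein, out / "protein.tsv")
    cohort.annotations.to_csv(out / "annotations.tsv", sep="\t", na_rep="")
    pd.DataFrame(
        {"variable": list(cohort.annotation_kinds),
         "kind": list(cohort.annotation_kinds.values())}
    ).to_csv(out / "annotation_kinds.tsv", sep="\t", index=False)
    with open(out / "proteins.fasta", "w") as fh:
        for pid, seq in cohort.fasta.items():
            fh.write(f">{pid}\n{seq}\n")
    mapping = cohort.site_mapping.copy()
    mapping["positions"] = [",".join(map(str, p)) for p in mapping["positions"]]
    mapping.to_csv(out / "site_mapping.tsv", sep="\t", index=False)
    with open(out / "regulators.txt", "w") as fh:
        fh.write("\n".join(cohort.regulator_candidates) + "\n")
    pd.DataFrame(cohort.truth.loop_sites, columns=["gene", "site"]).to_csv(
        out / "activation_loops.tsv", sep="\t", index=False
    )
    io.write_gmt(generate_gmt_fixture(cohort.truth), out / "site_sets.gmt")
    truth_labels = cohort.truth.site_modules.rename("module").reset_index()
    truth_labels.to_csv(out / "truth_modules.tsv", sep="\t", index=False)
    for name in ["phospho.tsv", "protein.tsv", "annotations.tsv",
                 "annotation_kinds.tsv", "proteins.fasta", "site_mapping.tsv",
                 "regulators.txt", "activation_loops.tsv", "site_sets.gmt",
                 "truth_modules.tsv"]:
        paths[name] = str(out / name)
    return paths
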