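"""Single-process orchestration of the full workflow.

Stages: normalize -> filter (multi-group union) -> correlate -> sweep ->
consensus -> module scores, then (as toggled) annotation association,
regulator nomination, motif analysis, set enrichment and subsampling
sensitivity.  Every output is a TSV under the configured output
directory; a ``manifest.json`` records the schema version, parameters,
seeds and input checksums, and two runs with identical config and inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .associations import calculate_annotation_association
from .config import RunConfig
from .discovery import ModuleDiscovery, calculate_module_scores
from .enrichment import set_overrepresentation
from .motifs import (calculate_motif_enrichment, collect_flanking_sequences,
                     read_fasta)
from .normalize import normalize_by_subgroup, normalize_phospho_by_protein
from .preprocess import column_normalize, filter_rows, multi_group_filter_union
from .regulators import (calculate_regulator_association,
                         collect_possible_regulators,
                         correlate_activation_loops, filter_druggable)
from .stability import SubsampleDesign, run_stability_analysis
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_labels(labels: pd.Series, path: Path) -> None:
    table = labels.rename("module").reset_index()
    table.to_csv(path, sep="\t", index=False)


def discover_modules(
    phospho: pd.DataFrame,
    protein: pd.DataFrame,
    params: dict,
    sample_groups: dict | None = None,
    group_combinations: list | None = None,
) -> tuple[ModuleDiscovery, pd.DataFrame, list]:
    """Normalize, filter and cluster; the in-memory core of `run`.

    Returns (fitted ModuleDiscovery, normalized filtered matrix, drops).
    """
    if params.get("column_normalize"):
        phospho = column_normalize(phospho, params["column_normalize"])
        protein = column_normalize(protein, params["column_normalize"])
    if sample_groups:
        normalized = normalize_by_subgroup(
            phospho, protein, sample_groups,
            params["alphas"], params["cv_folds"], params["seed"],
        )
        dropped: list = []
    else:
        normalized, dropped = normalize_phospho_by_protein(
            phospho, protein, params["alphas"], params["cv_folds"],
            params["seed"],
        )
    if sample_groups and group_combinations:
        keys = multi_group_filter_union(
            normalized, sample_groups, group_combinations,
            params["max_missing_frac"], params["top_variance_frac"],
        )
        filtered = normalized.loc[sorted(keys)]
    else:
        filtered = filter_rows(
            normalized, params["max_missing_frac"], params["top_variance_frac"]
        )
    grid = params.get("sweep")
    if grid is not None:
        grid = [(entry[0], dict(entry[1])) for entry in grid]
    disco = ModuleDiscovery(
        grid=grid,
        corr_method=params["corr_method"],
        min_overlap=params["min_overlap"],
        min_module_size=params["min_module_size"],
        min_module_coherence=params["min_module_coherence"],
        consensus_rel_tol=params["consensus_rel_tol"],
        noise_as_singletons=params["noise_as_singletons"],
        seed=params["seed"],
    ).fit(filtered)
    return disco, filtered, dropped


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, writing artifacts and a manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters
    manifest: dict = {
        "schema_version": config.version,
        "parameters": params,
        "stages": config.stages,
        "inputs": {},
        "outputs": [],
    }
    for key, value in config.paths.items():
        if key == "output_dir" or value is None:
            continue
        for p in value if isinstance(value, list) else [value]:
            manifest["inputs"][str(p)] = _checksum(str(p))

    stage = "load"
    try:
        phospho = io.read_abundance_table(config.paths["phospho"], 2)
        protein = (io.read_abundance_table(config.paths["protein"], 1)
                   if config.paths.get("protein") else None)
        groups = config.sample_groups
        if isinstance(groups, str):
            groups = io.read_sample_groups(groups)

        stage = "discover"
        if protein is None:
            raise ValueError("a protein matrix is required for normalization")
        disco, normalized, dropped = discover_modules(
            phospho, protein, params, groups, config.group_combinations
        )
        labels = disco.label_series_
        io.write_abundance_table(normalized, out / "normalized_phospho.tsv")
        pd.DataFrame(
            [(k[0], k[1], reason) if isinstance(k, tuple) else (k, "", reason)
             for k, reason in dropped],
            columns=["gene", "site", "reason"],
        ).to_csv(out / "dropped_peptides.tsv", sep="\t", index=False)
        _write_labels(labels, out / "module_assignment.tsv")
        disco.sweep_report_.to_csv(out / "sweep_report.tsv", sep="\t",
                                   index=False)
        scores = disco.module_scores_
        scores.to_csv(out / "module_scores.tsv", sep="\t", na_rep="")
        for name in ["normalized_phospho.tsv", "dropped_peptides.tsv",
                     "module_assignment.tsv", "sweep_report.tsv",
                     "module_scores.tsv"]:
            manifest["outputs"].append(name)

        if config.stages.get("annotations") and config.paths.get("annotations"):
            stage = "annotations"
            ann, kinds = io.read_annotation_table(
                config.paths["annotations"], config.paths["annotation_kinds"]
            )
            assoc = calculate_annotation_association(scores, ann, kinds)
            assoc.to_csv(out / "annotation_association.tsv", sep="\t",
                         index=False, na_rep="")
            manifest["outputs"].append("annotation_association.tsv")

        features = None
        if config.stages.get("regulators") and config.paths.get("regulators"):
            stage = "regulators"
            genes = io.read_gene_list(config.paths["regulators"])
            features = collect_possible_regulators(
                genes, protein, phospho,
                params["corr_threshold"], params["imputer_k"],
            )
            reg = calculate_regulator_association(
                features, scores,
                mode=params["regulator_mode"],
                corr_method=params["regulator_corr_method"],
                sigmoid=params["sigmoid"],
                alphas=params["alphas"],
                cv_folds=params["cv_folds"],
                seed=params["seed"],
            )
            if config.paths.get("druggability"):
                drug = io.read_two_column_table(config.paths["druggability"])
                reg = filter_druggable(reg, features, drug)
            reg.to_csv(out / "regulator_association.tsv", sep="\t",
                       index=False, na_rep="")
            manifest["outputs"].append("regulator_association.tsv")
            if config.paths.get("activation_loops"):
                loops = io.read_two_column_table(
                    config.paths["activation_loops"]
                )
                loop_table = correlate_activation_loops(
                    scores,
                    list(loops.itertuples(index=False, name=None)),
                    phospho,
                )
                loop_table.to_csv(out / "activation_loop_association.tsv",
                                  sep="\t", index=False, na_rep="")
                manifest["outputs"].append("activation_loop_association.tsv")

        if config.stages.get("motifs") and config.paths.get("fasta"):
            stage = "motifs"
            fasta = read_fasta(config.paths["fasta"])
            mapping = io.read_site_mapping(config.paths["site_mapping"])
            by_module = collect_flanking_sequences(
                mapping, fasta, labels, params["flank"]
            )
            clustered = {m: peps for m, peps in by_module.items() if m != -1}
            for module, peps in clustered.items():
                background = [p for m, ps in clustered.items()
                              if m != module for p in ps]
                if not background:
                    continue
                table = calculate_motif_enrichment(peps, background)
                table.to_csv(out / f"motif_module_{module}.tsv", sep="\t",
                             index=False)
                manifest["outputs"].append(f"motif_module_{module}.tsv")

        if config.stages.get("enrichment") and config.paths.get("gmt"):
            stage = "enrichment"
            gmt_paths = config.paths["gmt"]
            if not isinstance(gmt_paths, list):
                gmt_paths = [gmt_paths]
            universe = set(io.site_key_strings(labels.index))
            keys = pd.Series(io.site_key_strings(labels.index),
                             index=labels.index)
            for gmt_path in gmt_paths:
                db = io.read_gmt(gmt_path)
                stem = Path(gmt_path).stem
                for module in sorted(set(labels) - {-1}):
                    query = set(keys[labels == module])
                    table = set_overrepresentation(query, db, universe)
                    name = f"enrichment_{stem}_module_{module}.tsv"
                    table.to_csv(out / name, sep="\t", index=False, na_rep="")
                    manifest["outputs"].append(name)

        if config.stages.get("sensitivity"):
            stage = "sensitivity"
            design = SubsampleDesign(
                sizes=tuple(params["sensitivity_sizes"]),
                repeats=int(params["sensitivity_repeats"]),
                seed=int(params["seed"]),
            )

            def rerun(subset: list) -> pd.Series:
                sub_groups = ({s: groups[s] for s in subset} if groups
                              else None)
                sub_disco, _, _ = discover_modules(
                    phospho[subset], protein[subset], params, sub_groups,
                    config.group_combinations,
                )
                return sub_disco.label_series_

            per_run, summary = run_stability_analysis(
                list(phospho.columns), design, rerun, labels
            )
            per_run.to_csv(out / "stability_runs.tsv", sep="\t", index=False)
            summary.to_csv(out / "stability_summary.tsv", sep="\t",
                           index=False, na_rep="")
            manifest["outputs"] += ["stability_runs.tsv",
                                    "stability_summary.tsv"]
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
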