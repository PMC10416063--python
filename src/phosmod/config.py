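"""YAML run configuration with a versioned, typo-rejecting schema."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = 1

_PATH_KEYS = {
    "phospho", "protein", "annotations", "annotation_kinds", "regulators",
    "fasta", "site_mapping", "gmt", "activation_loops", "druggability",
    "output_dir", "sample_groups",
}
_STAGE_KEYS = {
    "normalize", "discover", "annotations", "regulators", "motifs",
    "enrichment", "sensitivity",
}
_PARAM_DEFAULTS: dict[str, object] = {
    "column_normalize": None,  # None, "median" or "upper_quartile"
    "max_missing_frac": 0.25,
    "top_variance_frac": 0.5,
    "alphas": [0.00032, 0.0016, 0.008, 0.04, 0.2, 1, 5, 25, 125, 625],
    "cv_folds": 3,
    "seed": 0,
    "corr_method": "pearson",
    "min_overlap": 5,
    "sweep": None,  # None = default grid, else list of [algorithm, params]
    "min_module_size": 2,
    "min_module_coherence": 0.25,
    "consensus_rel_tol": 0.02,
    "noise_as_singletons": True,
    "corr_threshold": 0.95,
    "imputer_k": 5,
    "regulator_mode": "correlation",
    "regulator_corr_method": "spearman",
    "sigmoid": False,
    "flank": 7,
    "sensitivity_sizes": [25, 50, 75, 100],
    "sensitivity_repeats": 15,
}


@dataclass
class RunConfig:
    paths: dict[str, object]
    stages: dict[str, bool]
    parameters: dict[str, object]
    sample_groups: dict[str, str] | None = None
    group_combinations: list[list[str]] | None = None
    version: int = SCHEMA_VERSION

    @property
    def output_dir(self) -> Path:
        return Path(str(self.paths["output_dir"]))


def _reject_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {section}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere in the file are rejected, so a typo in a long
    scientific config fails loudly instead of silently using a default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown("config", raw, {
        "version", "paths", "stages", "parameters", "sample_groups",
        "group_combinations",
    })
    version = raw.get("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config version {version}")

    paths = dict(raw.get("paths") or {})
    _reject_unknown("paths", paths, _PATH_KEYS)
    if "phospho" not in paths or "output_dir" not in paths:
        raise ValueError("paths.phospho and paths.output_dir are required")
    base = Path(path).resolve().parent
    for key, value in list(paths.items()):
        if key == "output_dir" or value is None:
            continue
        values = value if isinstance(value, list) else [value]
        resolved = []
        for v in values:
            p = Path(str(v))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"paths.{key}: {p} does not exist")
            resolved.append(str(p))
        paths[key] = resolved if isinstance(value, list) else resolved[0]
    out_dir = Path(str(paths["output_dir"]))
    if not out_dir.is_absolute():
        paths["output_dir"] = str(base / out_dir)

    stages = {k: True for k in _STAGE_KEYS}
    stages["sensitivity"] = False
    given_stages = dict(raw.get("stages") or {})
    _reject_unknown("stages", given_stages, _STAGE_KEYS)
    stages.update({k: bool(v) for k, v in given_stages.items()})

    parameters = dict(_PARAM_DEFAULTS)
    given_params = dict(raw.get("parameters") or {})
    _reject_unknown("parameters", given_params, set(_PARAM_DEFAULTS))
    parameters.update(given_params)
    _validate_parameters(parameters)

    sample_groups = raw.get("sample_groups")
    group_combinations = raw.get("group_combinations")
    return RunConfig(
        paths=paths,
        stages=stages,
        parameters=parameters,
        sample_groups=sample_groups,
        group_combinations=group_combinations,
        version=version,
    )


def _validate_parameters(p: dict) -> None:
    if p["column_normalize"] not in (None, "median", "upper_quartile"):
        raise ValueError("column_normalize must be null, median or upper_quartile")
    for key in ("max_missing_frac", "top_variance_frac"):
        if not 0 <= float(p[key]) <= 1:
            raise ValueError(f"{key} must be in [0, 1]")
    if int(p["cv_folds"]) < 2:
        raise ValueError("cv_folds must be >= 2")
    if p["corr_method"] not in ("pearson", "spearman"):
        raise ValueError("corr_method must be pearson or spearman")
    if p["regulator_mode"] not in ("correlation", "linear_model"):
        raise ValueError("regulator_mode must be correlation or linear_model")
    if p["regulator_corr_method"] not in ("pearson", "spearman"):
        raise ValueError("regulator_corr_method must be pearson or spearman")
    if any(float(a) < 0 for a in p["alphas"]):
        raise ValueError("alphas must be >= 0")


def default_config_dict(phospho: str, protein: str, output_dir: str) -> dict:
    """A minimal config mapping, handy for tests and `phosmod init`."""
    return {
        "version": SCHEMA_VERSION,
        "paths": {"phospho": phospho, "protein": protein,
                  "output_dir": output_dir},
        "stages": {},
        "parameters": {},
    }
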