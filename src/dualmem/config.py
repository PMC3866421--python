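"""Config-file driven experiment runs with full provenance.

A run is described by a single JSON file with sections ``stimuli``, ``model``,
``training``, ``familiarization`` and ``experiment``; every omitted key takes
its documented default.  ``run_config`` validates the file (unknown keys are
an error, named in the message), executes the named experiment, and writes
to the output directory:

* ``records.csv`` / ``summary.csv`` — per-seed and per-condition results
* ``comparisons.json`` — paired sign tests
* ``projections.csv`` — 2-D PCA coordinates (warping experiment only)
* ``resolved_config.json`` — the exact configuration used, all defaults
  filled in, with a content hash; re-running it reproduces every result
  file bit for bit
* ``run.log`` — a plain-text run log
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from .experiments import (ExperimentResult, FamiliarizationExperimentConfig,
                          WarpingConfig, run_familiarization_experiment,
                          run_warping_experiment)
from .network import ModelConfig
from .stimuli import StimulusDesign
from .training import FamiliarizationConfig


class ConfigError(ValueError):
    """Raised when a run configuration does not validate."""


_STIMULI_KEYS = {"n_basic", "n_exemplars", "n_features", "sigma_global",
                 "sigma_basic", "sigma_basic_overrides", "model_faceless"}
_MODEL_KEYS = {"n_hidden_hippocampal", "n_hidden_cortical", "hippocampal_lr",
               "cortical_lr", "init_scale", "settle_tol", "settle_max_iter",
               "settle_damping"}
_TRAINING_KEYS = {"total_presentations", "label_probability", "exposure_min",
                  "exposure_max"}
_FAM_KEYS = {"criterion", "max_presentations", "per_item", "update_cortical"}
_EXPERIMENT_KEYS = {"n_seeds", "target_category", "n_background_exemplars"}
_TOP_KEYS = {"experiment", "seed", "stimuli", "model", "training",
             "familiarization", "experiment_params", "config_hash"}

EXPERIMENTS = ("warping", "familiarization")


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def validate_config(raw: dict) -> dict:
    """Validate and normalize a raw config dict (defaults not yet filled)."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a JSON object")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "experiment" not in raw:
        raise ConfigError("missing required key 'experiment'")
    if raw["experiment"] not in EXPERIMENTS:
        raise ConfigError(
            f"experiment must be one of {EXPERIMENTS}, got {raw['experiment']!r}")
    _check_keys(raw.get("stimuli", {}), _STIMULI_KEYS, "section 'stimuli'")
    _check_keys(raw.get("model", {}), _MODEL_KEYS, "section 'model'")
    _check_keys(raw.get("training", {}), _TRAINING_KEYS, "section 'training'")
    _check_keys(raw.get("familiarization", {}), _FAM_KEYS,
                "section 'familiarization'")
    _check_keys(raw.get("experiment_params", {}), _EXPERIMENT_KEYS,
                "section 'experiment_params'")
    return raw


def resolve_config(raw: dict) -> dict:
    """Fill every default, producing a fully explicit run description."""
    validate_config(raw)
    design = StimulusDesign(**raw.get("stimuli", {}))
    model = ModelConfig(**raw.get("model", {}))
    fam = FamiliarizationConfig(**raw.get("familiarization", {}))
    resolved = {
        "experiment": raw["experiment"],
        "seed": int(raw.get("seed", 0)),
        "stimuli": {k: getattr(design, k) for k in sorted(_STIMULI_KEYS)},
        "model": {k: getattr(model, k) for k in sorted(_MODEL_KEYS)},
        "training": {**{"total_presentations": 4000, "label_probability": 0.5,
                        "exposure_min": 1, "exposure_max": 1},
                     **raw.get("training", {})},
        "familiarization": {k: getattr(fam, k) for k in sorted(_FAM_KEYS)},
        "experiment_params": {**{"n_seeds": 10, "target_category": "rabbit",
                                 "n_background_exemplars": 2},
                              **raw.get("experiment_params", {})},
    }
    return resolved


def config_hash(resolved: dict) -> str:
    blob = json.dumps(resolved, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_and_run(resolved: dict) -> ExperimentResult:
    design = StimulusDesign(**resolved["stimuli"])
    model = ModelConfig(n_features=design.n_features, **resolved["model"])
    tr = resolved["training"]
    ep = resolved["experiment_params"]
    if resolved["experiment"] == "warping":
        cfg = WarpingConfig(
            n_seeds=ep["n_seeds"], seed=resolved["seed"],
            total_presentations=tr["total_presentations"],
            label_probability=tr["label_probability"],
            exposure_min=tr["exposure_min"], exposure_max=tr["exposure_max"],
            design=design, model=model,
        )
        return run_warping_experiment(cfg)
    fam = FamiliarizationConfig(**resolved["familiarization"])
    cfg = FamiliarizationExperimentConfig(
        n_seeds=ep["n_seeds"], seed=resolved["seed"],
        target_category=ep["target_category"],
        n_background_exemplars=ep["n_background_exemplars"],
        total_presentations=tr["total_presentations"],
        label_probability=tr["label_probability"],
        design=design, model=model, familiarization=fam,
    )
    return run_familiarization_experiment(cfg)


def run_config(path, out_dir) -> ExperimentResult:
    """Execute the experiment described by the config file at ``path``."""
    with open(path) as fh:
        raw = json.load(fh)
    resolved = resolve_config(raw)
    chash = config_hash(resolved)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    result = _build_and_run(resolved)

    records = result.records.copy()
    records["config_hash"] = chash
    records.to_csv(out / "records.csv", index=False)
    summary = result.summary.copy()
    summary["config_hash"] = chash
    summary.to_csv(out / "summary.csv", index=False)
    with open(out / "comparisons.json", "w") as fh:
        json.dump({"config_hash": chash, "comparisons": result.comparisons},
                  fh, indent=2)
    if "projections" in result.extras:
        proj = result.extras["projections"].copy()
        proj["config_hash"] = chash
        proj.to_csv(out / "projections.csv", index=False)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump({**resolved, "config_hash": chash}, fh, indent=2)
    with open(out / "run.log", "w") as fh:
        fh.write(f"experiment: {resolved['experiment']}\n"
                 f"config_hash: {chash}\n"
                 f"elapsed_seconds: {time.time() - t0:.1f}\n")
    return result
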