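"""Multi-seed reproductions of the two headline simulations.

*Warping*: train paired models (identical initial weights, identical object
streams) with and without global-level labels, then compare how well the 26
category-prototype representations in the cortical hidden layer separate by
global category.  Labels warp the representational space: separation is
higher in the labelled model.

*Familiarization*: three background environments — none; all objects but
only two of the eight rabbits, unlabelled; the same with basic-level labels
at 50% probability — followed by familiarization-to-criterion on the six
held-out rabbits.  Background experience shortens familiarization, and
labelled background experience shortens it further.

Across-seed statistics use an exact sign test on the paired per-seed
differences (distribution-free and honest at n = 10), plus paired means.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .analysis import cluster_separation, pca_project, prototype_representations
from .network import ModelConfig, init_model
from .stimuli import StimulusDesign, generate_stimulus_set
from .training import (BackgroundConfig, FamiliarizationConfig,
                       background_train, familiarize)


def _spawn_seeds(base_seed: int, n: int, stream: str) -> list[int]:
    """Deterministic per-seed sub-seeds (< 2**31) for one named stream."""
    tag = zlib.crc32(stream.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([base_seed, tag])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def sign_test(differences: np.ndarray, alternative: str = "greater") -> dict:
    """Exact sign test on paired differences (ties dropped)."""
    d = np.asarray(differences, dtype=float)
    nz = d[d != 0]
    k = int(np.sum(nz > 0))
    n = int(nz.size)
    p = binomtest(k, n, 0.5, alternative=alternative).pvalue if n else 1.0
    return {"n_pairs": int(d.size), "n_nonzero": n, "n_positive": k,
            "p_value": float(p), "mean_difference": float(np.mean(d))}


@dataclass
class ExperimentResult:
    records: pd.DataFrame   # one row per (condition, seed)
    summary: pd.DataFrame   # per-condition mean, sd, n
    comparisons: list[dict]
    extras: dict = field(default_factory=dict)


def _summarize(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    g = records.groupby("condition")[value_col]
    return (pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})
            .reset_index())


@dataclass
class WarpingConfig:
    """Configuration of the label-warping experiment."""

    n_seeds: int = 10
    seed: int = 0
    total_presentations: int = 4000
    label_probability: float = 0.5
    exposure_min: int = 1
    exposure_max: int = 1
    design: StimulusDesign = field(default_factory=StimulusDesign)
    model: ModelConfig = field(default_factory=ModelConfig)


def run_warping_experiment(cfg: WarpingConfig) -> ExperimentResult:
    """Paired labelled/unlabelled comparison of representational separation."""
    stim_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "stimuli")
    model_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "model")
    train_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "train")

    rows = []
    projections = []
    for i in range(cfg.n_seeds):
        sset = generate_stimulus_set(cfg.design.replace(seed=stim_seeds[i]))
        n_global = len(sset.label_vocab_global)
        base = {f.name: getattr(cfg.model, f.name)
                for f in cfg.model.__dataclass_fields__.values()}
        for condition, scheme, n_task in (("unlabelled", "none", 0),
                                          ("global_labels", "global", n_global)):
            model = init_model(ModelConfig(**{**base, "n_task": n_task}),
                               model_seeds[i])
            bg = BackgroundConfig(
                total_presentations=cfg.total_presentations,
                exposure_min=cfg.exposure_min, exposure_max=cfg.exposure_max,
                label_scheme=scheme, label_probability=cfg.label_probability,
                seed=train_seeds[i],
            )
            background_train(model, sset, bg)
            cats, globals_, H = prototype_representations(model, sset)
            metrics = cluster_separation(H, globals_)
            rows.append({"condition": condition, "seed": i,
                         "silhouette": metrics.silhouette,
                         "between_within_ratio": metrics.between_within_ratio})
            coords, evr = pca_project(H, 2)
            for cat, g, (pc1, pc2) in zip(cats, globals_, coords):
                projections.append({"condition": condition, "seed": i,
                                    "basic_category": cat, "global_category": g,
                                    "pc1": pc1, "pc2": pc2})

    records = pd.DataFrame(rows)
    wide = records.pivot(index="seed", columns="condition", values="silhouette")
    diff = (wide["global_labels"] - wide["unlabelled"]).to_numpy()
    comparisons = [{"comparison": "global_labels_vs_unlabelled_silhouette",
                    **sign_test(diff, "greater")}]
    return ExperimentResult(records, _summarize(records, "silhouette"),
                            comparisons,
                            extras={"projections": pd.DataFrame(projections)})


@dataclass
class FamiliarizationExperimentConfig:
    """Configuration of the three-environment familiarization experiment."""

    n_seeds: int = 10
    seed: int = 0
    target_category: str = "rabbit"
    n_background_exemplars: int = 2
    total_presentations: int = 4000
    label_probability: float = 0.5
    design: StimulusDesign = field(default_factory=StimulusDesign)
    model: ModelConfig = field(default_factory=ModelConfig)
    familiarization: FamiliarizationConfig = field(
        default_factory=FamiliarizationConfig)


FAM_CONDITIONS = ("no_background", "unlabelled_background", "labelled_background")


def run_familiarization_experiment(
    cfg: FamiliarizationExperimentConfig) -> ExperimentResult:
    """Three-environment familiarization-to-criterion comparison."""
    stim_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "stimuli")
    model_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "model")
    train_seeds = _spawn_seeds(cfg.seed, cfg.n_seeds, "train")

    rows = []
    for i in range(cfg.n_seeds):
        sset = generate_stimulus_set(cfg.design.replace(seed=stim_seeds[i]))
        target_items = [s for s in sset.exemplars
                        if s.basic_category == cfg.target_category]
        if len(target_items) <= cfg.n_background_exemplars:
            raise ValueError(
                f"category {cfg.target_category!r} has {len(target_items)} "
                f"exemplars, too few to hold out any beyond "
                f"{cfg.n_background_exemplars} background ones")
        held_out = target_items[cfg.n_background_exemplars:]
        excluded = [s.id for s in held_out]
        n_basic = len(sset.label_vocab_basic)
        base = {f.name: getattr(cfg.model, f.name)
                for f in cfg.model.__dataclass_fields__.values()}

        for condition in FAM_CONDITIONS:
            n_task = n_basic if condition == "labelled_background" else 0
            model = init_model(ModelConfig(**{**base, "n_task": n_task}),
                               model_seeds[i])
            if condition != "no_background":
                scheme = "basic" if condition == "labelled_background" else "none"
                bg = BackgroundConfig(
                    total_presentations=cfg.total_presentations,
                    exposure_min=1, exposure_max=1,
                    label_scheme=scheme,
                    label_probability=cfg.label_probability,
                    excluded_items=excluded, seed=train_seeds[i],
                )
                background_train(model, sset, bg)
            res = familiarize(model, held_out, cfg.familiarization)
            rows.append({"condition": condition, "seed": i,
                         "presentations": res.presentations,
                         "converged": res.converged,
                         "initial_error": res.initial_error})

    records = pd.DataFrame(rows)
    wide = records.pivot(index="seed", columns="condition",
                         values="presentations")
    comparisons = [
        {"comparison": "no_background_vs_unlabelled_background",
         **sign_test((wide["no_background"]
                      - wide["unlabelled_background"]).to_numpy(), "greater")},
        {"comparison": "unlabelled_background_vs_labelled_background",
         **sign_test((wide["unlabelled_background"]
                      - wide["labelled_background"]).to_numpy(), "greater")},
    ]
    return ExperimentResult(records, _summarize(records, "presentations"),
                            comparisons)
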