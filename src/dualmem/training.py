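"""Training regimes: background experience and familiarization-to-criterion.

*Background training* emulates an infant's everyday encounters with objects:
objects drawn in random order, each attended for a random exposure length
(a number of consecutive online weight updates), and labelled with some
probability per encounter.  *Familiarization training* emulates the
laboratory looking-time paradigm: a small set of items presented cyclically,
without labels, until the hippocampal reconstruction error falls below a
criterion; the number of presentations needed models familiarization time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DualMemoryModel, train_step, reconstruction_errors
from .stimuli import ObjectStimulus, StimulusSet

LABEL_SCHEMES = ("none", "basic", "global")


@dataclass
class BackgroundConfig:
    """Parameters of the background (world-experience) regime.

    ``exposure_min``/``exposure_max`` bound the random episode length in
    online weight-update steps; an encounter with an object lasts a uniform
    number of steps in that range.  Labelling is decided once per encounter
    with probability ``label_probability``.
    """

    total_presentations: int = 4000
    exposure_min: int = 1
    exposure_max: int = 1000
    label_scheme: str = "none"
    label_probability: float = 0.5
    excluded_items: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.exposure_min <= self.exposure_max):
            raise ValueError("need 1 <= exposure_min <= exposure_max")
        if not 0.0 <= self.label_probability <= 1.0:
            raise ValueError("label_probability must lie in [0, 1]")
        if self.label_scheme not in LABEL_SCHEMES:
            raise ValueError(f"label_scheme must be one of {LABEL_SCHEMES}")
        if self.total_presentations < 0:
            raise ValueError("total_presentations must be >= 0")


@dataclass
class FamiliarizationConfig:
    """Parameters of the familiarization-to-criterion regime.

    ``criterion`` is the hippocampal summed-squared-error threshold per item,
    averaged over the familiarization set (``per_item=True`` requires every
    item to be below it instead).
    """

    criterion: float = 0.05
    max_presentations: int = 10000
    per_item: bool = False
    update_cortical: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion <= 0:
            raise ValueError("criterion must be > 0")


@dataclass
class FamiliarizationResult:
    presentations: int
    converged: bool
    error_trace: list[float]  # mean hippocampal error after each full cycle

    @property
    def initial_error(self) -> float:
        return self.error_trace[0]


def background_train(
    model: DualMemoryModel, sset: StimulusSet, cfg: BackgroundConfig
) -> tuple[DualMemoryModel, pd.DataFrame]:
    """Run background training in place; returns the model and a log.

    The log has one row per weight update: step, stimulus id, label shown
    (empty string when none), and both components' pre-update reconstruction
    errors.  The labelling coin is drawn for every encounter even under
    ``label_scheme='none'`` so that paired labelled/unlabelled runs with the
    same seed see an identical object stream.
    """
    excluded = set(cfg.excluded_items)
    unknown = excluded - {s.id for s in sset.exemplars}
    if unknown:
        raise ValueError(f"excluded_items not in stimulus set: {sorted(unknown)}")
    pool = [s for s in sset.exemplars if s.id not in excluded]
    if not pool:
        raise ValueError("all stimuli excluded from background training")

    rng = np.random.default_rng(cfg.seed)
    rows: list[tuple] = []
    step = 0
    while step < cfg.total_presentations:
        obj = pool[rng.integers(len(pool))]
        length = int(rng.integers(cfg.exposure_min, cfg.exposure_max + 1))
        labelled = rng.random() < cfg.label_probability
        label_idx: int | None = None
        label_name = ""
        if labelled and cfg.label_scheme == "basic":
            label_idx = sset.basic_label_index(obj.basic_category)
            label_name = obj.basic_category
        elif labelled and cfg.label_scheme == "global":
            label_idx = sset.global_label_index(obj.global_category)
            label_name = obj.global_category
        for _ in range(min(length, cfg.total_presentations - step)):
            rec = train_step(model, obj.features, label_idx)
            rows.append((step, obj.id, label_name, rec.hip_error, rec.cor_error))
            step += 1
    log = pd.DataFrame(
        rows, columns=["step", "stimulus_id", "label", "hip_error", "cor_error"]
    )
    return model, log


def _below(model: DualMemoryModel, items: list[ObjectStimulus],
           cfg: FamiliarizationConfig) -> tuple[float, bool]:
    errs = [reconstruction_errors(model, it.features)[0] for it in items]
    mean = float(np.mean(errs))
    if cfg.per_item:
        return mean, all(e < cfg.criterion for e in errs)
    return mean, mean < cfg.criterion


def familiarize(
    model: DualMemoryModel,
    items: list[ObjectStimulus],
    cfg: FamiliarizationConfig,
) -> FamiliarizationResult:
    """Present ``items`` cyclically, without labels, until criterion.

    Returns the number of weight updates executed when the mean hippocampal
    error first falls below criterion (0 if already below), with the
    per-cycle error trace.  Capped at ``max_presentations``; hitting the cap
    flags the result as not converged.  Task weights are never touched: no
    labels occur in the test situation.
    """
    if not items:
        raise ValueError("familiarization item list is empty")
    saved_cor_lr = model.config.cortical_lr
    if not cfg.update_cortical:
        # Freeze the slow system (and the cross/task blocks it owns) for the
        # duration of the laboratory episode; only the fast system learns.
        model.config.cortical_lr = 0.0
    try:
        mean, ok = _below(model, items, cfg)
        trace = [mean]
        if ok:
            return FamiliarizationResult(0, True, trace)
        count = 0
        while count < cfg.max_presentations:
            for it in items:
                train_step(model, it.features, None)
                count += 1
                if count >= cfg.max_presentations:
                    break
            mean, ok = _below(model, items, cfg)
            trace.append(mean)
            if ok:
                return FamiliarizationResult(count, True, trace)
        return FamiliarizationResult(count, False, trace)
    finally:
        model.config.cortical_lr = saved_cor_lr
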