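"""The dual-memory network: two interacting auto-encoders plus label units.

Two three-layer auto-encoders share an input (the object's feature vector):
a fast-learning *hippocampal* component and a slow-learning *cortical*
component.  Their hidden layers exchange activation through trainable
cross-connections until they settle in a stable joint state.  Label ("task")
units read out from the cortical hidden layer and are trained only when a
label accompanies the object.  Looking time in the familiarization paradigm
is modelled as the hippocampal reconstruction error (summed squared
output-input difference): the worse the reconstruction, the more novel the
object, the longer the look.

All units are logistic-sigmoid.  Learning is online backpropagation on the
summed squared error, one weight update per object presentation; gradients
are taken exactly at the settled fixed point (recurrent backpropagation via
the implicit function theorem), with no unrolling of the settling
iterations.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit


class ConfigurationError(ValueError):
    """Raised for inconsistent model configurations."""


@dataclass
class ModelConfig:
    """Hyperparameters of the dual-memory model.

    The hippocampal learning rate must exceed the cortical one: fast episodic
    acquisition versus slow regularity extraction is the point of the
    architecture.  The hidden layers are smaller than the input so that each
    component is a true bottleneck auto-encoder.
    """

    n_features: int = 18
    n_hidden_hippocampal: int = 15
    n_hidden_cortical: int = 15
    n_task: int = 0
    hippocampal_lr: float = 0.1
    cortical_lr: float = 0.05
    init_scale: float = 0.5
    settle_tol: float = 1e-4
    settle_max_iter: int = 50
    settle_damping: float = 0.0

    def __post_init__(self) -> None:
        if self.n_hidden_hippocampal >= self.n_features:
            raise ConfigurationError(
                "hippocampal hidden layer must be smaller than the input "
                f"({self.n_hidden_hippocampal} >= {self.n_features})"
            )
        if self.n_hidden_cortical >= self.n_features:
            raise ConfigurationError(
                "cortical hidden layer must be smaller than the input "
                f"({self.n_hidden_cortical} >= {self.n_features})"
            )
        if self.hippocampal_lr < 0 or self.cortical_lr < 0:
            raise ConfigurationError("learning rates must be >= 0")
        if (self.hippocampal_lr and self.cortical_lr
                and self.hippocampal_lr <= self.cortical_lr):
            raise ConfigurationError(
                "hippocampal learning rate must exceed the cortical rate"
            )
        if self.n_task < 0:
            raise ConfigurationError("n_task must be >= 0")
        if not 0.0 <= self.settle_damping < 1.0:
            raise ConfigurationError("settle_damping must be in [0, 1)")


@dataclass
class AutoEncoderComponent:
    """One memory component: input->hidden and hidden->output weights."""

    W_in: np.ndarray   # (n_hidden, n_features)
    b_h: np.ndarray    # (n_hidden,)
    W_out: np.ndarray  # (n_features, n_hidden)
    b_o: np.ndarray    # (n_features,)
    learning_rate: float

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]


@dataclass
class DualMemoryModel:
    config: ModelConfig
    hippocampal: AutoEncoderComponent
    cortical: AutoEncoderComponent
    W_hip_to_cor: np.ndarray  # (n_hidden_cortical, n_hidden_hippocampal)
    W_cor_to_hip: np.ndarray  # (n_hidden_hippocampal, n_hidden_cortical)
    W_task: np.ndarray | None  # (n_task, n_hidden_cortical) or None
    b_task: np.ndarray | None

    def copy(self) -> "DualMemoryModel":
        return copy.deepcopy(self)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "weights": {
                "hip_W_in": self.hippocampal.W_in.tolist(),
                "hip_b_h": self.hippocampal.b_h.tolist(),
                "hip_W_out": self.hippocampal.W_out.tolist(),
                "hip_b_o": self.hippocampal.b_o.tolist(),
                "cor_W_in": self.cortical.W_in.tolist(),
                "cor_b_h": self.cortical.b_h.tolist(),
                "cor_W_out": self.cortical.W_out.tolist(),
                "cor_b_o": self.cortical.b_o.tolist(),
                "W_hip_to_cor": self.W_hip_to_cor.tolist(),
                "W_cor_to_hip": self.W_cor_to_hip.tolist(),
            },
            "shapes": {
                "hip_W_in": list(self.hippocampal.W_in.shape),
                "cor_W_in": list(self.cortical.W_in.shape),
            },
        }
        if self.W_task is not None:
            d["weights"]["W_task"] = self.W_task.tolist()
            d["weights"]["b_task"] = self.b_task.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DualMemoryModel":
        cfg = ModelConfig(**d["config"])
        w = {k: np.asarray(v, dtype=float) for k, v in d["weights"].items()}
        hip = AutoEncoderComponent(w["hip_W_in"], w["hip_b_h"], w["hip_W_out"],
                                   w["hip_b_o"], cfg.hippocampal_lr)
        cor = AutoEncoderComponent(w["cor_W_in"], w["cor_b_h"], w["cor_W_out"],
                                   w["cor_b_o"], cfg.cortical_lr)
        return cls(cfg, hip, cor, w["W_hip_to_cor"], w["W_cor_to_hip"],
                   w.get("W_task"), w.get("b_task"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DualMemoryModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Activations:
    """Settled network state for one input."""

    h_hip: np.ndarray
    h_cor: np.ndarray
    o_hip: np.ndarray
    o_cor: np.ndarray
    o_task: np.ndarray | None
    settle_iters: int
    converged: bool


@dataclass
class StepRecord:
    """Per-presentation readout: errors before the weight update."""

    hip_error: float
    cor_error: float
    task_error: float | None
    settle_iters: int
    converged: bool


def init_model(config: ModelConfig, seed: int) -> DualMemoryModel:
    """Initialize all weights uniformly in [-init_scale, +init_scale].

    The task-layer weights are drawn *last*, so models that differ only in
    ``n_task`` share bit-identical auto-encoder and cross-connection weights
    for the same seed (needed for paired labelled/unlabelled comparisons).
    """
    rng = np.random.default_rng(seed)
    w0 = config.init_scale
    nf, nh, nc = (config.n_features, config.n_hidden_hippocampal,
                  config.n_hidden_cortical)

    def draw(*shape):
        return rng.uniform(-w0, w0, size=shape)

    hip = AutoEncoderComponent(draw(nh, nf), draw(nh), draw(nf, nh), draw(nf),
                               config.hippocampal_lr)
    cor = AutoEncoderComponent(draw(nc, nf), draw(nc), draw(nf, nc), draw(nf),
                               config.cortical_lr)
    W_hc = draw(nc, nh)
    W_ch = draw(nh, nc)
    if config.n_task > 0:
        W_task, b_task = draw(config.n_task, nc), draw(config.n_task)
    else:
        W_task = b_task = None
    return DualMemoryModel(config, hip, cor, W_hc, W_ch, W_task, b_task)


def forward_settle(model: DualMemoryModel, features: np.ndarray) -> Activations:
    """Propagate input to both hidden layers and settle their interaction.

    Each hidden layer's net input is its component's (fixed) input drive plus
    the cross-connection input from the other layer's current state; both
    layers update synchronously until the largest absolute activation change
    falls below ``settle_tol`` or ``settle_max_iter`` is reached.  Outputs and
    task activations are then computed once from the settled hidden states.
    """
    x = np.asarray(features, dtype=float)
    cfg = model.config
    if x.shape != (cfg.n_features,):
        raise ValueError(f"expected feature vector of length {cfg.n_features}, "
                         f"got shape {x.shape}")
    hip, cor = model.hippocampal, model.cortical
    drive_h = hip.W_in @ x + hip.b_h
    drive_c = cor.W_in @ x + cor.b_h
    h = expit(drive_h)
    c = expit(drive_c)
    damp = cfg.settle_damping
    converged = False
    iters = 0
    for iters in range(1, cfg.settle_max_iter + 1):
        h_new = expit(drive_h + model.W_cor_to_hip @ c)
        c_new = expit(drive_c + model.W_hip_to_cor @ h)
        if damp:
            h_new = (1 - damp) * h_new + damp * h
            c_new = (1 - damp) * c_new + damp * c
        delta = max(np.max(np.abs(h_new - h)), np.max(np.abs(c_new - c)))
        h, c = h_new, c_new
        if delta < cfg.settle_tol:
            converged = True
            break
    o_hip = expit(hip.W_out @ h + hip.b_o)
    o_cor = expit(cor.W_out @ c + cor.b_o)
    o_task = None
    if model.W_task is not None:
        o_task = expit(model.W_task @ c + model.b_task)
    return Activations(h, c, o_hip, o_cor, o_task, iters, converged)


def reconstruction_errors(model: DualMemoryModel,
                          features: np.ndarray) -> tuple[float, float]:
    """Summed squared reconstruction error of both components (no update)."""
    x = np.asarray(features, dtype=float)
    act = forward_settle(model, x)
    return float(np.sum((act.o_hip - x) ** 2)), float(np.sum((act.o_cor - x) ** 2))


def looking_time(model: DualMemoryModel, features: np.ndarray) -> float:
    """Modelled looking time: the hippocampal summed squared error.

    The linking hypothesis is that the worse the hippocampal system
    reconstructs an object, the more novel it is and the longer the infant
    looks at it.
    """
    return reconstruction_errors(model, features)[0]


def train_step(model: DualMemoryModel, features: np.ndarray,
               label_index: int | None = None) -> StepRecord:
    """One online backpropagation update on a single object (in place).

    Targets are the input features for both auto-encoder outputs and, when
    ``label_index`` is given, a one-hot vector on the task layer.  The
    objective is the summed squared error over all target units.  Each weight
    block is updated with its owning component's learning rate; the
    cross-connections and the task weights use the cortical rate.  When no
    label is presented the task weights are untouched.
    """
    x = np.asarray(features, dtype=float)
    cfg = model.config
    if label_index is not None:
        if model.W_task is None:
            raise ValueError("label presented but the model has no task units")
        if not 0 <= label_index < cfg.n_task:
            raise ValueError(f"label_index {label_index} out of range [0, {cfg.n_task})")

    act = forward_settle(model, x)
    h, c = act.h_hip, act.h_cor
    hip, cor = model.hippocampal, model.cortical
    lr_h, lr_c = cfg.hippocampal_lr, cfg.cortical_lr

    e_hip = act.o_hip - x
    e_cor = act.o_cor - x
    hip_err = float(np.sum(e_hip ** 2))
    cor_err = float(np.sum(e_cor ** 2))

    d_o_hip = 2.0 * e_hip * act.o_hip * (1.0 - act.o_hip)
    d_o_cor = 2.0 * e_cor * act.o_cor * (1.0 - act.o_cor)

    g_c = cor.W_out.T @ d_o_cor
    task_err = None
    d_t = None
    if label_index is not None:
        target = np.zeros(cfg.n_task)
        target[label_index] = 1.0
        e_t = act.o_task - target
        task_err = float(np.sum(e_t ** 2))
        d_t = 2.0 * e_t * act.o_task * (1.0 - act.o_task)
        g_c = g_c + model.W_task.T @ d_t

    # Hidden deltas at the settled fixed point (recurrent backpropagation):
    # the pre-activation errors satisfy the self-consistent pair
    #   d_h = s'(h) * (g_h + W_hip_to_cor^T d_c)
    #   d_c = s'(c) * (g_c + W_cor_to_hip^T d_h)
    # because each hidden layer feeds the other through the cross-
    # connections.  Solving this linear system differentiates the loss
    # exactly through the settled state (implicit function theorem), with
    # no unrolling of the settling iterations.
    g_h = hip.W_out.T @ d_o_hip
    Dh = h * (1.0 - h)
    Dc = c * (1.0 - c)
    A = model.W_hip_to_cor.T  # error path cortical-hidden -> hip-hidden
    B = model.W_cor_to_hip.T  # error path hip-hidden -> cortical-hidden
    M = np.eye(h.size) - (Dh[:, None] * A) @ (Dc[:, None] * B)
    d_h = np.linalg.solve(M, Dh * (g_h + A @ (Dc * g_c)))
    d_c = Dc * (g_c + B @ d_h)

    hip.W_out -= lr_h * np.outer(d_o_hip, h)
    hip.b_o -= lr_h * d_o_hip
    hip.W_in -= lr_h * np.outer(d_h, x)
    hip.b_h -= lr_h * d_h

    cor.W_out -= lr_c * np.outer(d_o_cor, c)
    cor.b_o -= lr_c * d_o_cor
    cor.W_in -= lr_c * np.outer(d_c, x)
    cor.b_h -= lr_c * d_c

    model.W_cor_to_hip -= lr_c * np.outer(d_h, c)
    model.W_hip_to_cor -= lr_c * np.outer(d_c, h)

    if d_t is not None:
        model.W_task -= lr_c * np.outer(d_t, c)
        model.b_task -= lr_c * d_t

    return StepRecord(hip_err, cor_err, task_err, act.settle_iters, act.converged)


def total_loss(model: DualMemoryModel, features: np.ndarray,
               label_index: int | None = None) -> float:
    """The training objective at the settled state (used by gradient checks)."""
    x = np.asarray(features, dtype=float)
    act = forward_settle(model, x)
    loss = float(np.sum((act.o_hip - x) ** 2) + np.sum((act.o_cor - x) ** 2))
    if label_index is not None:
        target = np.zeros(model.config.n_task)
        target[label_index] = 1.0
        loss += float(np.sum((act.o_task - target) ** 2))
    return loss
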