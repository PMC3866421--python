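"""scikit-learn estimator surface for the dual-memory network.

``DualMemoryNetwork`` wraps background training of the dual auto-encoder as
``fit`` and exposes the settled cortical hidden representations as
``transform``, so the model composes with sklearn pipelines and model
selection.  ``looking_times`` gives the hippocampal reconstruction errors
that model looking time, and ``familiarize`` runs the laboratory
familiarization-to-criterion procedure on the fitted model.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .network import (DualMemoryModel, ModelConfig, init_model, train_step,
                      forward_settle, reconstruction_errors)
from .training import FamiliarizationConfig, FamiliarizationResult


class DualMemoryNetwork(TransformerMixin, BaseEstimator):
    """Dual-memory auto-encoder with optional label supervision.

    Parameters
    ----------
    n_hidden_hippocampal, n_hidden_cortical : int
        Hidden-layer sizes; each must be smaller than the number of input
        features (bottleneck).
    hippocampal_lr, cortical_lr : float
        Online learning rates; the hippocampal rate must be larger (fast
        episodic memory vs. slow cortical regularity extraction).
    init_scale : float
        Weights start uniform in ``[-init_scale, init_scale]``.
    settle_tol, settle_max_iter : float, int
        Stopping rule of the hidden-layer settling iteration.
    total_presentations : int
        Online updates performed by ``fit``.
    exposure_min, exposure_max : int
        Uniform bounds of the per-encounter exposure length (update steps).
    label_probability : float
        Chance that an encounter is labelled, when ``y`` is given to ``fit``.
    random_state : int, RandomState instance or None
        Controls weight initialization and the training stream.

    Attributes
    ----------
    model_ : DualMemoryModel
        The trained network.
    n_features_in_ : int
    classes_ : ndarray or None
        Label vocabulary seen during ``fit`` (None when unsupervised).
    """

    def __init__(self, n_hidden_hippocampal=15, n_hidden_cortical=15,
                 hippocampal_lr=0.1, cortical_lr=0.05, init_scale=0.5,
                 settle_tol=1e-4, settle_max_iter=50,
                 total_presentations=4000, exposure_min=1, exposure_max=1,
                 label_probability=0.5, random_state=None):
        self.n_hidden_hippocampal = n_hidden_hippocampal
        self.n_hidden_cortical = n_hidden_cortical
        self.hippocampal_lr = hippocampal_lr
        self.cortical_lr = cortical_lr
        self.init_scale = init_scale
        self.settle_tol = settle_tol
        self.settle_max_iter = settle_max_iter
        self.total_presentations = total_presentations
        self.exposure_min = exposure_min
        self.exposure_max = exposure_max
        self.label_probability = label_probability
        self.random_state = random_state

    def fit(self, X, y=None):
        """Background-train the network on objects ``X`` (labels ``y`` optional)."""
        X = check_array(X, dtype=float)
        n, nf = X.shape
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError("feature values must lie in [0, 1]")
        label_idx = None
        self.classes_ = None
        n_task = 0
        if y is not None:
            y = np.asarray(y)
            if y.shape[0] != n:
                raise ValueError("X and y length mismatch")
            self.classes_, label_idx = np.unique(y, return_inverse=True)
            n_task = len(self.classes_)
        cfg = ModelConfig(
            n_features=nf,
            n_hidden_hippocampal=self.n_hidden_hippocampal,
            n_hidden_cortical=self.n_hidden_cortical,
            n_task=n_task,
            hippocampal_lr=self.hippocampal_lr,
            cortical_lr=self.cortical_lr,
            init_scale=self.init_scale,
            settle_tol=self.settle_tol,
            settle_max_iter=self.settle_max_iter,
        )
        if isinstance(self.random_state, numbers.Integral) or self.random_state is None:
            seed = 0 if self.random_state is None else int(self.random_state)
        else:
            seed = int(check_random_state(self.random_state).randint(2 ** 31))
        self.model_ = init_model(cfg, seed)
        rng = np.random.default_rng(seed + 1)
        step = 0
        while step < self.total_presentations:
            i = int(rng.integers(n))
            length = int(rng.integers(self.exposure_min, self.exposure_max + 1))
            labelled = rng.random() < self.label_probability
            lab = int(label_idx[i]) if (labelled and label_idx is not None) else None
            for _ in range(min(length, self.total_presentations - step)):
                train_step(self.model_, X[i], lab)
                step += 1
        self.n_features_in_ = nf
        return self

    def transform(self, X):
        """Settled cortical hidden representation of each row of ``X``."""
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return np.stack([forward_settle(self.model_, x).h_cor for x in X])

    def looking_times(self, X):
        """Modelled looking time (hippocampal reconstruction error) per row."""
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return np.array([reconstruction_errors(self.model_, x)[0] for x in X])

    def score(self, X, y=None):
        """Negative mean hippocampal reconstruction error (higher is better)."""
        return -float(np.mean(self.looking_times(X)))

    def familiarize(self, X, criterion=0.05, max_presentations=10000
                    ) -> FamiliarizationResult:
        """Familiarize the fitted model to the rows of ``X`` until criterion.

        Mutates ``model_`` (familiarization is learning); returns the
        presentations-to-criterion result.
        """
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        from .stimuli import ObjectStimulus
        from .training import familiarize as _familiarize
        items = [ObjectStimulus(id=f"item_{i}", basic_category="item",
                                global_category="item", features=x)
                 for i, x in enumerate(X)]
        cfg = FamiliarizationConfig(criterion=criterion,
                                    max_presentations=max_presentations)
        return _familiarize(self.model_, items, cfg)
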