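"""Synthetic stimulus corpora for the categorization model.

The model consumes objects described by 18 perceptual features (geometric
extents, protrusion measurements, texture, and facial dimensions), scaled to
[0, 1].  Real photograph-derived measurements of this kind are not available,
so this module generates feature vectors with the same *similarity structure*:
26 basic-level categories of 8 exemplars each, nested in 4 global-level
categories (humans, animals, vehicles, furniture), with tight within-basic
similarity and looser within-global similarity.

Generation is hierarchical-Gaussian: one latent anchor per global category,
a generating prototype per basic category drawn around its anchor
(``sigma_global``), and exemplars jittered around the generating prototype
(``sigma_basic``), all clipped to [0, 1].  The *empirical* prototype of a
category — the element-wise mean of its exemplars, which is what the model's
analyses use — is recomputed from the exemplars and is not itself an exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_FEATURES = 18

#: Basic-level -> global-level category taxonomy.
DEFAULT_TAXONOMY: dict[str, str] = {
    "male": "humans",
    "female": "humans",
    "dog": "animals",
    "cat": "animals",
    "rabbit": "animals",
    "horse": "animals",
    "elephant": "animals",
    "giraffe": "animals",
    "cow": "animals",
    "squirrel": "animals",
    "fish": "animals",
    "eagle": "animals",
    "songbird": "animals",
    "duck": "animals",
    "bicycle": "vehicles",
    "forklift": "vehicles",
    "bus": "vehicles",
    "car": "vehicles",
    "plane": "vehicles",
    "ship": "vehicles",
    "desk": "furniture",
    "table": "furniture",
    "bed": "furniture",
    "sofa": "furniture",
    "chest_of_drawers": "furniture",
    "chair": "furniture",
}

GLOBAL_CATEGORIES = ("humans", "animals", "vehicles", "furniture")

#: Global categories whose members have no face; their facial feature
#: dimensions (the last three) are generated near zero.
DEFAULT_FACELESS = ("vehicles", "furniture")

#: Index of the first facial feature dimension (eye separation, face
#: length, face width occupy the last three of the 18 dimensions).
FACE_FEATURE_START = 15


class StimulusError(ValueError):
    """Raised for invalid stimulus configurations or malformed tables."""


@dataclass(frozen=True)
class ObjectStimulus:
    """A single object: an 18-dim feature vector with its category labels."""

    id: str
    basic_category: str
    global_category: str
    features: np.ndarray

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", feats)
        if feats.ndim != 1:
            raise StimulusError(f"features must be a vector, got shape {feats.shape}")
        if np.any(feats < 0) or np.any(feats > 1):
            raise StimulusError(
                f"stimulus {self.id!r}: feature values must lie in [0, 1]"
            )


@dataclass
class StimulusSet:
    """A full corpus: exemplars, empirical prototypes, and label vocabularies."""

    exemplars: list[ObjectStimulus]
    prototypes: dict[str, np.ndarray]
    taxonomy: dict[str, str]
    label_vocab_basic: list[str]
    label_vocab_global: list[str]

    @property
    def n_features(self) -> int:
        return len(self.exemplars[0].features)

    def features_matrix(self) -> np.ndarray:
        """All exemplar feature vectors stacked, shape (n_exemplars, n_features)."""
        return np.stack([s.features for s in self.exemplars])

    def by_id(self, stimulus_id: str) -> ObjectStimulus:
        for s in self.exemplars:
            if s.id == stimulus_id:
                return s
        raise KeyError(stimulus_id)

    def basic_label_index(self, basic_category: str) -> int:
        return self.label_vocab_basic.index(basic_category)

    def global_label_index(self, global_category: str) -> int:
        return self.label_vocab_global.index(global_category)


@dataclass
class StimulusDesign:
    """Parameters of the hierarchical generator.

    ``sigma_global`` is the spread of basic-category generating prototypes
    around their global anchor; ``sigma_basic`` the exemplar jitter around
    the generating prototype.  ``sigma_basic_overrides`` allows per-category
    spreads (within-category similarity varies across real categories).
    """

    n_basic: int = 26
    n_exemplars: int = 8
    n_features: int = N_FEATURES
    taxonomy: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAXONOMY))
    sigma_global: float = 0.15
    sigma_basic: float = 0.05
    sigma_basic_overrides: dict[str, float] = field(default_factory=dict)
    faceless_globals: tuple[str, ...] = DEFAULT_FACELESS
    model_faceless: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_global < 0 or self.sigma_basic < 0:
            raise StimulusError("sigma values must be >= 0")
        if min(self.n_basic, self.n_exemplars, self.n_features) < 1:
            raise StimulusError("counts must be >= 1")
        for c, g in self.taxonomy.items():
            if not isinstance(g, str) or not g:
                raise StimulusError(f"basic category {c!r} mapped to invalid global {g!r}")

    def replace(self, **kw) -> "StimulusDesign":
        return replace(self, **kw)


def _basic_categories(design: StimulusDesign) -> list[str]:
    cats = list(design.taxonomy)
    if design.n_basic <= len(cats):
        return cats[: design.n_basic]
    # synthetic extra categories cycle through the global categories
    globals_ = sorted(set(design.taxonomy.values()))
    extra = [f"category{i:02d}" for i in range(design.n_basic - len(cats))]
    for i, name in enumerate(extra):
        design.taxonomy[name] = globals_[i % len(globals_)]
    return cats + extra


def generate_stimulus_set(design: StimulusDesign) -> StimulusSet:
    """Draw a corpus from the hierarchical generator; deterministic per seed."""
    rng = np.random.default_rng(design.seed)
    basics = _basic_categories(design)
    globals_ = sorted(set(design.taxonomy[c] for c in basics))
    unknown = [g for g in globals_ if g not in design.taxonomy.values()]
    if unknown:
        raise StimulusError(f"unknown global categories: {unknown}")

    # One latent anchor per global category, kept away from the [0,1] walls so
    # that jitter is not mostly clipped.
    anchors = {
        g: rng.uniform(0.25, 0.75, size=design.n_features) for g in sorted(globals_)
    }
    if design.model_faceless and design.n_features >= FACE_FEATURE_START + 3:
        for g in design.faceless_globals:
            if g in anchors:
                anchors[g][FACE_FEATURE_START:] = 0.05

    exemplars: list[ObjectStimulus] = []
    for cat in basics:
        g = design.taxonomy[cat]
        gen_proto = anchors[g] + rng.normal(0.0, design.sigma_global, design.n_features)
        gen_proto = np.clip(gen_proto, 0.0, 1.0)
        sigma = design.sigma_basic_overrides.get(cat, design.sigma_basic)
        for k in range(design.n_exemplars):
            feats = gen_proto + rng.normal(0.0, sigma, design.n_features)
            feats = np.clip(feats, 0.0, 1.0)
            exemplars.append(
                ObjectStimulus(
                    id=f"{cat}_{k}",
                    basic_category=cat,
                    global_category=g,
                    features=feats,
                )
            )

    taxonomy = {c: design.taxonomy[c] for c in basics}
    sset = StimulusSet(
        exemplars=exemplars,
        prototypes={},
        taxonomy=taxonomy,
        label_vocab_basic=list(basics),
        label_vocab_global=sorted(set(taxonomy.values())),
    )
    sset.prototypes = compute_prototypes(sset)
    return sset


def compute_prototypes(sset: StimulusSet) -> dict[str, np.ndarray]:
    """Empirical prototype of each basic category: element-wise exemplar mean."""
    protos: dict[str, np.ndarray] = {}
    for cat in sset.taxonomy:
        members = [s.features for s in sset.exemplars if s.basic_category == cat]
        if not members:
            raise StimulusError(f"category {cat!r} has no exemplars")
        protos[cat] = np.mean(members, axis=0)
    return protos


def write_stimulus_table(sset: StimulusSet, path) -> None:
    """Write the corpus as CSV: id,basic_category,global_category,f1..f18."""
    nf = sset.n_features
    rows = []
    for s in sset.exemplars:
        row = {"id": s.id, "basic_category": s.basic_category,
               "global_category": s.global_category}
        row.update({f"f{j + 1}": s.features[j] for j in range(nf)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_stimulus_table(path) -> StimulusSet:
    """Read a corpus CSV written by :func:`write_stimulus_table`.

    Raises :class:`StimulusError` (citing the offending row) on out-of-range
    features, missing columns, or an empty table.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise StimulusError("no stimuli in table")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    required = ["id", "basic_category", "global_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StimulusError(f"missing columns: {missing}")
    if not feat_cols:
        raise StimulusError("no feature columns f1..fN found")
    exemplars = []
    taxonomy: dict[str, str] = {}
    for i, row in df.iterrows():
        feats = row[feat_cols].to_numpy(dtype=float)
        if np.any(feats < 0) or np.any(feats > 1):
            raise StimulusError(f"row {i + 1}: feature value out of [0, 1]")
        cat, g = str(row["basic_category"]), str(row["global_category"])
        if cat in taxonomy and taxonomy[cat] != g:
            raise StimulusError(
                f"row {i + 1}: basic category {cat!r} mapped to conflicting globals"
            )
        taxonomy[cat] = g
        exemplars.append(
            ObjectStimulus(id=str(row["id"]), basic_category=cat,
                           global_category=g, features=feats)
        )
    sset = StimulusSet(
        exemplars=exemplars,
        prototypes={},
        taxonomy=taxonomy,
        label_vocab_basic=list(taxonomy),
        label_vocab_global=sorted(set(taxonomy.values())),
    )
    sset.prototypes = compute_prototypes(sset)
    return sset
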