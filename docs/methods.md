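# Methods

## The model

`dualmem` simulates infant object categorization with two interacting
memory systems, each a three-layer logistic auto-encoder over the same
18-dimensional object input:

* **hippocampal component** — high learning rate; its reconstruction error on
  a stimulus models looking time in familiarization/novelty-preference
  experiments (badly reconstructed = novel = looked at longer);
* **cortical component** — low learning rate; its hidden-layer activation
  pattern models the child's long-term object representation.

The hidden layers are connected by two independent trainable matrices
(hippocampal→cortical and cortical→hippocampal). On each presentation the
input drives both hidden layers feed-forward, then the hidden states exchange
activation synchronously until the largest absolute change falls below
`settle_tol`; outputs are read once from the settled states. A bank of
**task/label units** reads out from the cortical hidden layer only. Labels
are never inputs: they are supervisory targets, so the only way the network
can produce the right label is to shape its perceptual representations
accordingly. This is the mechanism behind label-induced warping: objects
sharing a label develop more similar cortical representations although the
label was never an object feature.

### Learning rule

Online backpropagation, one weight update per object presentation, on the
summed squared error over the two reconstruction targets plus (when a label
is shown) the one-hot task target. Gradients are computed **exactly at the
settled fixed point** by recurrent backpropagation: the hidden deltas solve
the self-consistent linear system that the cross-connections induce
(implicit-function-theorem differentiation; one 15×15 solve per step).
We chose the exact fixed-point gradient over truncated schemes because it is
no harder to implement, is verifiable against finite differences for every
weight block including the cross-connections (the test suite checks all
blocks to 1e-5 relative on random small networks), and removes an arbitrary
truncation-depth choice. No gradient flows through the settling *iterations*
themselves — only through the settled state.

Task weights are updated only when a label is presented; an unlabelled
presentation leaves them bit-identical (asserted in the suite). Cross-
connection and task weights update at the cortical (slow) rate; each
auto-encoder's own weights at its component's rate.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `n_features` | 18 | object feature dimensionality |
| `n_hidden_cortical` | 15 | cortical bottleneck (the analysed representation) |
| `n_hidden_hippocampal` | 15 | hippocampal bottleneck |
| `hippocampal_lr` | 0.1 | fast episodic learning |
| `cortical_lr` | 0.05 | slow regularity extraction; must stay below the hippocampal rate |
| `init_scale` | 0.5 | weights start uniform in ±0.5 |
| `settle_tol` / `settle_max_iter` | 1e-4 / 50 | settling stopping rule; at the default initialization every default stimulus settles in < 10 iterations |

The learning rates are *documented package defaults*, chosen so that the
fast/slow asymmetry, the warping effect, and the training-stability property
suites all hold robustly across seeds; smaller cortical rates weaken the
label-warping effect roughly in proportion. All are exposed in
`ModelConfig` and the run-config schema.

## Stimuli

The model's experiments need a corpus with the similarity structure of real
object photographs measured on 18 geometric/facial features: 26 basic-level
categories × 8 exemplars nested in 4 global-level categories (humans 2,
animals 12, vehicles 6, furniture 6 basic categories). Such measurements are
not available as data, so `stimuli` generates them hierarchically: one
latent anchor per global category (uniform in [0.25, 0.75] per dimension to
leave jitter room), a generating prototype per basic category (Gaussian
around the anchor, `sigma_global = 0.15`), exemplars around the generating
prototype (`sigma_basic = 0.05`), all clipped to [0, 1]. Vehicles and
furniture get near-zero facial dimensions (last 3 features), giving them the
systematic difference from animates that photographs would show; this is
toggleable. Category prototypes used by the analyses are *empirical*
element-wise exemplar means, never the generating prototypes, and are not
training items.

What the generator does **not** emulate: named, interpretable features;
heavy-tailed or correlated feature noise; the idiosyncratic cross-category
resemblances of real photographs (a plane and an eagle sharing thin
protrusions). Passing tests therefore establish the model's behaviour on a
clean hierarchical similarity structure, not on photograph-derived data.
Per-category spread overrides (`sigma_basic_overrides`) exist because real
categories differ in within-category similarity; defaults are uniform.

## Training regimes

**Background training** emulates everyday experience: draw an object
uniformly, draw an exposure length uniformly in `[exposure_min,
exposure_max]` update steps (defaults 1–1000), decide labelling once per
encounter with probability 0.5, and run that many online updates; stop at the
total step budget (default 4000). "One epoch" of exposure = one online
weight update on that object; with per-presentation online learning there is
no other natural unit. The labelling coin is drawn even when labels are
disabled so that paired labelled/unlabelled runs see identical object
streams.

**Familiarization** emulates the laboratory paradigm: the familiarization
items are presented cyclically without labels; after each full cycle the mean
hippocampal error over the set is evaluated (weights untouched); the result
is the number of updates executed when that mean first falls below
`criterion` (default 0.05 summed squared error per item; a per-item variant
requires every item below criterion). Both components learn during
familiarization by default (`update_cortical=False` freezes the slow system
and the cross/task blocks it owns). The criterion applies to the set mean
because the paradigm defines one familiarization phase for the whole item
set.

## Experiments

Both experiments are paired multi-seed designs: for every seed the compared
conditions start from bit-identical weights (task units are drawn last so
their presence does not perturb the shared blocks) and consume identical
stimulus streams. Statistics across seeds are an exact sign test on paired
differences plus paired means — distribution-free and honest at n = 10.

* **Warping** (default 10 seeds, 4000 single-step presentations): silent vs
  global-label conditions; outcome is the silhouette of the 26 prototype
  representations grouped by global category, computed in the full 15-D
  cortical hidden space (the 2-D PCA projection is written for plotting
  only, to avoid projection artifacts in the quantitative claim). Single-step
  episodes are used here because a 4000-step budget with 1–1000-step episodes
  would expose the model to only a handful of distinct objects.
* **Familiarization** (default 10 seeds): three background environments —
  none; all objects with only 2 of the 8 rabbits, unlabelled; the same with
  basic-level labels at p = 0.5 — each followed by familiarization on the 6
  held-out rabbits. The no-background condition starts from freshly
  initialized weights.

## Numerical choices and degenerate inputs

* Logistic sigmoid everywhere; outputs live in [0, 1] like the features.
* Settling non-convergence is flagged, not raised; optional damping is
  available for adversarial weight scales.
* PCA components carry a fixed sign convention (largest-magnitude loading
  positive) for bit-reproducibility.
* Silhouette: singleton groups contribute 0; all-coincident point sets are
  returned as flagged degenerate (silhouette 0, ratio NaN) rather than
  raising; coincident-within/distinct-between geometry gives ratio ∞.
* Out-of-range values after Gaussian jitter are clipped, not resampled; the
  bias is negligible at default spreads.
* CSV round-trips: features are printed at 17 significant digits and parsed
  with round-trip float precision, so write→read is exact.
* Experiment sub-seeds derive from the base seed via named, CRC-tagged
  `SeedSequence` streams; every result table is reproducible bit-for-bit
  from its emitted resolved config.

## Known limitations

* The background-experience effect is large and stable: models with prior
  experience of related objects familiarize to new category members several
  times faster than naive models, in essentially every seed.
* The *additional* label benefit on familiarization time is not robust at
  the default conditions: labelled and unlabelled background conditions
  typically reach criterion in the same presentation cycle. Diagnostics show
  the underlying mechanism is present — basic-level labels compress the
  rabbit-category cortical representations in 9/10 seeds — but its
  transmission to hippocampal reconstruction error is about an order of
  magnitude smaller than the per-cycle error decrement, so it vanishes under
  the cycle-granular criterion readout; with looser within-category spread
  the compression can even cost item-level reconstruction accuracy and
  reverse the sign. Treat label-facilitated familiarization as a fragile
  prediction of this implementation, sensitive to coupling strength between
  the two memory systems.
* The model is deliberately minimal: no replay or consolidation, no batch
  training, no attention/habituation dynamics, no GPU path.
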