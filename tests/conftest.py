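import numpy as np
import pytest

from dualmem.network import DualMemoryModel, ModelConfig, init_model, total_loss, train_step
from dualmem.stimuli import StimulusDesign, generate_stimulus_set


@pytest.fixture(scope="session")
def default_set():
    """The default corpus: 26 basic categories x 8 exemplars, 18 features."""
    return generate_stimulus_set(StimulusDesign(seed=0))


def small_random_model(seed: int) -> tuple[DualMemoryModel, np.ndarray, int]:
    """A random small network (input<=5, hidden<=3, task<=3) with a probe
    input and label, settled to tight tolerance so gradients are well defined."""
    rng = np.random.default_rng(seed)
    nf = int(rng.integers(3, 6))
    nh = int(rng.integers(2, min(4, nf)))
    nc = int(rng.integers(2, min(4, nf)))
    nt = int(rng.integers(1, 4))
    cfg = ModelConfig(n_features=nf, n_hidden_hippocampal=nh,
                      n_hidden_cortical=nc, n_task=nt,
                      hippocampal_lr=0.1, cortical_lr=0.05,
                      settle_tol=1e-13, settle_max_iter=2000)
    model = init_model(cfg, seed)
    x = rng.uniform(0.1, 0.9, nf)
    label = int(rng.integers(nt))
    return model, x, label


def _weight_blocks(model: DualMemoryModel):
    lr_h = model.config.hippocampal_lr
    lr_c = model.config.cortical_lr
    blocks = [
        ("hip_W_in", lambda m: m.hippocampal.W_in, lr_h),
        ("hip_b_h", lambda m: m.hippocampal.b_h, lr_h),
        ("hip_W_out", lambda m: m.hippocampal.W_out, lr_h),
        ("hip_b_o", lambda m: m.hippocampal.b_o, lr_h),
        ("cor_W_in", lambda m: m.cortical.W_in, lr_c),
        ("cor_b_h", lambda m: m.cortical.b_h, lr_c),
        ("cor_W_out", lambda m: m.cortical.W_out, lr_c),
        ("cor_b_o", lambda m: m.cortical.b_o, lr_c),
        ("W_hip_to_cor", lambda m: m.W_hip_to_cor, lr_c),
        ("W_cor_to_hip", lambda m: m.W_cor_to_hip, lr_c),
    ]
    if model.W_task is not None:
        blocks += [("W_task", lambda m: m.W_task, lr_c),
                   ("b_task", lambda m: m.b_task, lr_c)]
    return blocks


def max_gradient_rel_error(model: DualMemoryModel, x: np.ndarray,
                           label: int | None, h: float = 1e-6) -> float:
    """Compare analytic gradients (recovered from one train_step) against
    central finite differences of the settled-state loss, over every entry
    of every weight block.  Returns the worst relative discrepancy."""
    updated = model.copy()
    train_step(updated, x, label)
    worst = 0.0
    for name, get, lr in _weight_blocks(model):
        analytic = (get(model) - get(updated)) / lr
        fd = np.zeros_like(analytic)
        it = np.nditer(analytic, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            mp = model.copy()
            get(mp)[idx] += h
            mm = model.copy()
            get(mm)[idx] -= h
            fd[idx] = (total_loss(mp, x, label) - total_loss(mm, x, label)) / (2 * h)
        rel = np.max(np.abs(analytic - fd) / (np.abs(fd) + 1e-8))
        worst = max(worst, float(rel))
    return worst
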