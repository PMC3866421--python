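import numpy as np
import pytest
from scipy.special import expit

from dualmem.network import (ConfigurationError, DualMemoryModel, ModelConfig,
                             forward_settle, init_model, looking_time,
                             reconstruction_errors, train_step)

from conftest import max_gradient_rel_error, small_random_model


def test_init_determinism_and_shapes():
    cfg = ModelConfig(n_task=4)
    a = init_model(cfg, 5)
    b = init_model(cfg, 5)
    np.testing.assert_array_equal(a.hippocampal.W_in, b.hippocampal.W_in)
    np.testing.assert_array_equal(a.W_task, b.W_task)
    assert a.cortical.W_in.shape == (15, 18)
    assert a.W_task.shape == (4, 15)
    assert not np.array_equal(a.hippocampal.W_in, init_model(cfg, 6).hippocampal.W_in)


def test_task_units_drawn_last_for_paired_designs():
    """Models differing only in n_task share all other initial weights —
    the basis of the paired labelled/unlabelled experimental design."""
    plain = init_model(ModelConfig(n_task=0), 11)
    labelled = init_model(ModelConfig(n_task=26), 11)
    np.testing.assert_array_equal(plain.hippocampal.W_in, labelled.hippocampal.W_in)
    np.testing.assert_array_equal(plain.cortical.W_out, labelled.cortical.W_out)
    np.testing.assert_array_equal(plain.W_cor_to_hip, labelled.W_cor_to_hip)


def test_configuration_errors():
    with pytest.raises(ConfigurationError):  # bottleneck violated
        ModelConfig(n_hidden_cortical=18)
    with pytest.raises(ConfigurationError):  # fast/slow order violated
        ModelConfig(hippocampal_lr=0.01, cortical_lr=0.1)


def test_zero_cross_weights_equal_feedforward():
    """With no inter-system connections the settled state is the plain
    feed-forward pass of each auto-encoder, reached in one iteration."""
    model = init_model(ModelConfig(), 0)
    model.W_hip_to_cor[:] = 0.0
    model.W_cor_to_hip[:] = 0.0
    x = np.linspace(0.05, 0.95, 18)
    act = forward_settle(model, x)
    h_ff = expit(model.hippocampal.W_in @ x + model.hippocampal.b_h)
    c_ff = expit(model.cortical.W_in @ x + model.cortical.b_h)
    np.testing.assert_array_equal(act.h_hip, h_ff)
    np.testing.assert_array_equal(act.h_cor, c_ff)
    assert act.converged and act.settle_iters == 1


def test_settling_matches_damped_iteration_oracle():
    """The fixed point agrees with an independent heavily-damped iteration."""
    rng = np.random.default_rng(2)
    cfg = ModelConfig(n_features=4, n_hidden_hippocampal=2, n_hidden_cortical=2,
                      settle_tol=1e-12, settle_max_iter=5000)
    model = init_model(cfg, 2)
    x = rng.uniform(0, 1, 4)
    act = forward_settle(model, x)

    drive_h = model.hippocampal.W_in @ x + model.hippocampal.b_h
    drive_c = model.cortical.W_in @ x + model.cortical.b_h
    h, c = expit(drive_h), expit(drive_c)
    for _ in range(200_000):
        h_new = 0.9 * h + 0.1 * expit(drive_h + model.W_cor_to_hip @ c)
        c_new = 0.9 * c + 0.1 * expit(drive_c + model.W_hip_to_cor @ h)
        if max(np.max(np.abs(h_new - h)), np.max(np.abs(c_new - c))) < 1e-14:
            h, c = h_new, c_new
            break
        h, c = h_new, c_new
    np.testing.assert_allclose(act.h_hip, h, atol=1e-10)
    np.testing.assert_allclose(act.h_cor, c, atol=1e-10)


def test_settling_converges_on_default_corpus(default_set):
    model = init_model(ModelConfig(), 0)
    acts = [forward_settle(model, e.features) for e in default_set.exemplars]
    assert all(a.converged for a in acts)
    assert max(a.settle_iters for a in acts) <= 50


def test_looking_time_is_hippocampal_squared_error():
    model = init_model(ModelConfig(), 1)
    x = np.linspace(0.1, 0.9, 18)
    act = forward_settle(model, x)
    expected = float(np.sum((act.o_hip - x) ** 2))
    assert looking_time(model, x) == pytest.approx(expected, abs=0)
    assert looking_time(model, x) >= 0


def test_zero_learning_rates_leave_model_bit_identical():
    cfg = ModelConfig(hippocampal_lr=0.0, cortical_lr=0.0, n_task=3)
    model = init_model(cfg, 4)
    ref = model.copy()
    x = np.linspace(0, 1, 18)
    train_step(model, x, 1)
    np.testing.assert_array_equal(model.hippocampal.W_in, ref.hippocampal.W_in)
    np.testing.assert_array_equal(model.cortical.W_out, ref.cortical.W_out)
    np.testing.assert_array_equal(model.W_task, ref.W_task)
    np.testing.assert_array_equal(model.W_hip_to_cor, ref.W_hip_to_cor)


@pytest.mark.parametrize("seed", range(10))
def test_gradients_match_finite_differences(seed):
    """Analytic backprop through the settled state equals central-difference
    gradients for every weight block, cross-connections and task weights
    included (random small networks, nonzero cross-weights)."""
    model, x, label = small_random_model(seed)
    assert max_gradient_rel_error(model, x, label) < 1e-5


def test_label_gating_no_labels_ever():
    """Unlabelled presentations never move the task weights."""
    model = init_model(ModelConfig(n_task=4), 9)
    W0, b0 = model.W_task.copy(), model.b_task.copy()
    rng = np.random.default_rng(0)
    for _ in range(50):
        train_step(model, rng.uniform(0, 1, 18), None)
    np.testing.assert_array_equal(model.W_task, W0)
    np.testing.assert_array_equal(model.b_task, b0)
    assert not np.array_equal(model.hippocampal.W_in,
                              init_model(ModelConfig(n_task=4), 9).hippocampal.W_in)


def test_label_errors():
    model = init_model(ModelConfig(n_task=0), 0)
    with pytest.raises(ValueError, match="no task units"):
        train_step(model, np.linspace(0, 1, 18), 0)
    model = init_model(ModelConfig(n_task=3), 0)
    with pytest.raises(ValueError, match="out of range"):
        train_step(model, np.linspace(0, 1, 18), 3)


def test_dimension_mismatch():
    model = init_model(ModelConfig(), 0)
    with pytest.raises(ValueError, match="length 18"):
        forward_settle(model, np.zeros(5))


def test_repeated_training_reduces_error():
    """100 updates on one stimulus (no labels, decoupled systems, small
    rates) reduce both components' reconstruction errors."""
    cfg = ModelConfig(hippocampal_lr=0.02, cortical_lr=0.01)
    model = init_model(cfg, 3)
    model.W_hip_to_cor[:] = 0.0
    model.W_cor_to_hip[:] = 0.0
    x = np.linspace(0.1, 0.9, 18)
    hip0, cor0 = reconstruction_errors(model, x)
    for _ in range(100):
        train_step(model, x, None)
    hip1, cor1 = reconstruction_errors(model, x)
    assert hip1 < hip0
    assert cor1 < cor0


def test_component_asymmetry_fast_system_fits_faster():
    """After identical exposure the fast (hippocampal) system reconstructs
    the just-trained item better than the slow (cortical) one."""
    wins = 0
    for seed in range(20):
        model = init_model(ModelConfig(), seed)
        x = np.random.default_rng(seed).uniform(0, 1, 18)
        for _ in range(30):
            train_step(model, x, None)
        hip, cor = reconstruction_errors(model, x)
        wins += hip < cor
    assert wins >= 19


def test_serialization_roundtrip(tmp_path):
    model = init_model(ModelConfig(n_task=4), 13)
    train_step(model, np.linspace(0, 1, 18), 2)
    path = tmp_path / "model.json"
    model.save(path)
    back = DualMemoryModel.load(path)
    np.testing.assert_array_equal(model.hippocampal.W_in, back.hippocampal.W_in)
    np.testing.assert_array_equal(model.W_task, back.W_task)
    np.testing.assert_array_equal(model.W_cor_to_hip, back.W_cor_to_hip)
    assert back.config == model.config
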