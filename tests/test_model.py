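"""Dual-task network: architecture contract, loss, splitting, training."""

import numpy as np
import pytest

from fessemg.labels import FATIGUE_LEVELS, MOTIONS
from fessemg.model import (LabeledExample, ModelConfig, TrainConfig,
                           build_model, dual_loss, load_checkpoint, predict,
                           save_checkpoint, split_dataset, train)

TINY = ModelConfig(input_size=16, conv_channels=4, motion_fc_dim=16,
                   lstm_hidden=8, fatigue_fc_dims=(8, 3), seed=0)


def _toy_examples(n_per_class=4, size=16, seed=0):
    """Trivially separable dataset: one constant color per (motion, fatigue).

    The red channel encodes the motion class, the green channel the fatigue
    class, so each of the 18 label pairs gets a distinct flat color.
    """
    rng = np.random.default_rng(seed)
    examples = []
    for mi, m in enumerate(MOTIONS):
        for fi, f in enumerate(FATIGUE_LEVELS):
            for _ in range(n_per_class):
                img = np.empty((4, 3, size, size), dtype=np.float32)
                img[:, 0] = (mi + 1) / (len(MOTIONS) + 1)
                img[:, 1] = (fi + 1) / (len(FATIGUE_LEVELS) + 1)
                img[:, 2] = 0.5
                img += 0.01 * rng.standard_normal(img.shape).astype(np.float32)
                examples.append(LabeledExample(img, m, f))
    return examples


# -- architecture ------------------------------------------------------------------

def test_full_scale_shape_probe():
    """At full scale the layer plumbing matches the published dimension table."""
    model = build_model(ModelConfig(seed=0))
    assert model.config.feature_size == 16
    assert model.config.concat_dim == 16 * 16 * 20 * 4 == 20480
    assert model.motion_fc1.W.value.shape == (20480, 2048)
    assert model.motion_fc2.W.value.shape == (2048, 6)
    # documented corrections: per-branch LSTMs read 16 rows x 320 features,
    # and the fatigue FC pair composes as 4096 -> 512 -> 3
    assert model.lstm1[0].Wx.value.shape == (320, 4096)
    assert model.fatigue_fc1.W.value.shape == (4096, 512)
    assert model.fatigue_fc2.W.value.shape == (512, 3)
    x = np.random.default_rng(0).random((2, 4, 3, 256, 256), dtype=np.float32)
    pm, pf = model.forward(x, train=False)
    assert pm.shape == (2, 6) and pf.shape == (2, 3)
    assert np.allclose(pm.sum(axis=1), 1.0, atol=1e-6)
    assert np.allclose(pf.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(pm >= 0) and np.all(pf >= 0)


def test_construction_errors_name_offending_layer():
    with pytest.raises(ValueError, match="Pool"):
        ModelConfig(input_size=100).validate()
    with pytest.raises(ValueError, match="fatigue FC2"):
        ModelConfig(fatigue_fc_dims=(512, 4)).validate()


def test_flat_single_step_layout():
    cfg = ModelConfig(input_size=16, conv_channels=4, motion_fc_dim=16,
                      lstm_hidden=8, fatigue_fc_dims=(8, 3),
                      lstm_sequence_layout="flat_single_step", seed=0)
    model = build_model(cfg)
    assert model.lstm1[0].Wx.value.shape[0] == cfg.feature_size**2 * 4
    pm, pf = model.forward(np.zeros((3, 4, 3, 16, 16), np.float32))
    assert pm.shape == (3, 6) and pf.shape == (3, 3)


# -- loss ---------------------------------------------------------------------------

def test_dual_loss_zero_iff_one_hot_correct():
    pm = np.eye(6)[[2]]
    pf = np.eye(3)[[1]]
    assert dual_loss(pm, [2], pf, [1]) == pytest.approx(0.0, abs=1e-9)
    assert dual_loss(pm, [3], pf, [1]) > 1.0


def test_dual_loss_uniform_is_ln6_plus_ln3():
    pm = np.full((4, 6), 1 / 6)
    pf = np.full((4, 3), 1 / 3)
    assert dual_loss(pm, [0, 1, 2, 3], pf, [0, 1, 2, 0]) == \
        pytest.approx(np.log(6) + np.log(3))


def test_dual_loss_additivity_on_random_cases():
    rng = np.random.default_rng(0)
    for _ in range(50):
        pm = rng.dirichlet(np.ones(6), size=5)
        pf = rng.dirichlet(np.ones(3), size=5)
        ym = rng.integers(0, 6, 5)
        yf = rng.integers(0, 3, 5)
        motion_only = -np.log(pm[np.arange(5), ym]).mean()
        fatigue_only = -np.log(pf[np.arange(5), yf]).mean()
        assert dual_loss(pm, ym, pf, yf) == pytest.approx(
            motion_only + fatigue_only, rel=1e-9)


def test_dual_loss_rejects_out_of_range_labels():
    pm, pf = np.full((1, 6), 1 / 6), np.full((1, 3), 1 / 3)
    with pytest.raises(ValueError, match="motion"):
        dual_loss(pm, [6], pf, [0])
    with pytest.raises(ValueError, match="fatigue"):
        dual_loss(pm, [0], pf, [3])


# -- splitting ----------------------------------------------------------------------

def test_split_sizes_exact_disjoint_exhaustive():
    examples = _toy_examples(n_per_class=6)  # 108 examples, 18 strata
    tr, va, te = split_dataset(examples, (0.8, 0.1, 0.1), seed=0)
    n = len(examples)
    assert (len(tr), len(va), len(te)) == (round(0.8 * n), round(0.1 * n),
                                           n - round(0.8 * n) - round(0.1 * n))
    ids = sorted(id(e) for e in tr + va + te)
    assert ids == sorted(id(e) for e in examples)


def test_split_is_stratified():
    examples = _toy_examples(n_per_class=10)
    _, _, te = split_dataset(examples, (0.8, 0.1, 0.1), seed=3)
    per_stratum = {}
    for e in te:
        per_stratum[(e.motion_label, e.fatigue_label)] = \
            per_stratum.get((e.motion_label, e.fatigue_label), 0) + 1
    assert max(per_stratum.values()) - min(per_stratum.values()) <= 1


def test_split_seed_behaviour():
    examples = _toy_examples(n_per_class=4)
    a = split_dataset(examples, seed=1)
    b = split_dataset(examples, seed=1)
    c = split_dataset(examples, seed=2)
    assert [id(e) for e in a[0]] == [id(e) for e in b[0]]
    assert [id(e) for e in a[0]] != [id(e) for e in c[0]]


def test_split_warns_and_falls_back_on_tiny_strata():
    examples = _toy_examples(n_per_class=1)
    with pytest.warns(UserWarning, match="strata"):
        tr, va, te = split_dataset(examples, (0.8, 0.1, 0.1), seed=0)
    assert len(tr) + len(va) + len(te) == len(examples)


# -- training -----------------------------------------------------------------------

def test_training_memorizes_trivially_separable_images():
    examples = _toy_examples(n_per_class=4, size=32)
    model = build_model(ModelConfig.reduced(seed=0))
    model, history = train(model, examples, examples,
                           TrainConfig(epochs=20, batch_size=18, seed=0))
    assert history[0]["train_loss"] <= np.log(6) + np.log(3) + 0.2
    preds = predict(model, examples)
    motion_acc = np.mean([p.motion_label == e.motion_label
                          for p, e in zip(preds, examples)])
    fatigue_acc = np.mean([p.fatigue_label == e.fatigue_label
                           for p, e in zip(preds, examples)])
    assert motion_acc == 1.0 and fatigue_acc == 1.0


def test_training_is_seed_deterministic():
    examples = _toy_examples(n_per_class=2)
    runs = []
    for _ in range(2):
        model = build_model(TINY)
        _, history = train(model, examples, examples,
                           TrainConfig(epochs=2, batch_size=12, seed=5))
        runs.append([h["train_loss"] for h in history])
    assert runs[0] == runs[1]


def test_training_aborts_on_divergence():
    examples = _toy_examples(n_per_class=2)
    for e in examples:
        e.images[:] = np.inf  # poisoned inputs make the loss non-finite
    model = build_model(TINY)
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, examples, examples,
              TrainConfig(epochs=1, batch_size=12, seed=0))


def test_predict_eval_mode_repeatable_and_counts():
    examples = _toy_examples(n_per_class=2)
    model = build_model(TINY)
    a = predict(model, examples)
    b = predict(model, examples)
    assert len(a) == len(examples)
    assert all(np.array_equal(x.motion_probs, y.motion_probs) for x, y in zip(a, b))


def test_checkpoint_round_trip(tmp_path):
    model = build_model(TINY)
    examples = _toy_examples(n_per_class=2)
    before = predict(model, examples)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    after = predict(restored, examples)
    assert all(np.array_equal(x.motion_probs, y.motion_probs)
               for x, y in zip(before, after))
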