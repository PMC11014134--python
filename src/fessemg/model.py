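"""Dual-task recognition network: parallel CNN branches + LSTM fatigue head.

The network consumes the four per-channel time-frequency images of one
window through four parallel CNN branches (four conv->batchnorm->ReLU->pool
blocks each, dropout after the last pool). The flattened branch features are
concatenated into a motion head (two fully-connected layers, 6-way softmax);
per branch, the feature map is also read as a row sequence by two stacked
LSTM layers whose last hidden states are concatenated into the fatigue head
(two fully-connected layers, 3-way softmax). Training minimizes the sum of
the two task cross-entropies.

At full scale the layer dimensions follow the published parameter table
(256x256x3 inputs, 20 conv channels, 20,480-dim concatenation, 2048-dim
motion FC, LSTM hidden 1024). Two printed dimensions there cannot compose
and are corrected here: the fatigue head's fully-connected pair is taken as
4096 -> 512 -> 3 (the printed 1024 output of FC1 does not match FC2's 512
input), and the per-branch LSTMs read the branch's own 16x16x20 map as 16
row-steps of 320 features (the printed 20,480 single-step reading is
available via ``lstm_sequence_layout='flat_single_step'``).

A :meth:`ModelConfig.reduced` profile shrinks the image size and widths for
CPU-scale experiments with the same topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import FATIGUE_LEVELS, MOTIONS
from .nn import (
    F32,
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Layer,
    Linear,
    LSTM,
    MaxPool2x2,
    ReLU,
    cross_entropy,
    softmax,
    softmax_ce_grad,
)


@dataclass(frozen=True)
class ModelConfig:
    n_branches: int = 4
    input_size: int = 256
    input_channels: int = 3
    conv_channels: int = 20
    conv_kernel: int = 3
    n_conv_blocks: int = 4
    dropout_rate: float = 0.3
    motion_classes: int = 6
    fatigue_classes: int = 3
    motion_fc_dim: int = 2048
    lstm_hidden: int = 1024
    lstm_sequence_layout: str = "rows_as_steps"
    fatigue_fc_dims: tuple[int, int] = (512, 3)
    seed: int = 0

    @property
    def feature_size(self) -> int:
        return self.input_size // (2 ** self.n_conv_blocks)

    @property
    def concat_dim(self) -> int:
        return self.feature_size**2 * self.conv_channels * self.n_branches

    def validate(self) -> "ModelConfig":
        if self.input_size % (2 ** self.n_conv_blocks) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"{2 ** self.n_conv_blocks} (layer: Pool{self.n_conv_blocks})"
            )
        if self.fatigue_fc_dims[1] != self.fatigue_classes:
            raise ValueError(
                f"fatigue FC2 output {self.fatigue_fc_dims[1]} != "
                f"fatigue_classes {self.fatigue_classes} (layer: fatigue FC2)"
            )
        if self.lstm_sequence_layout not in ("rows_as_steps", "flat_single_step"):
            raise ValueError(
                f"unknown lstm_sequence_layout {self.lstm_sequence_layout!r}"
            )
        return self

    @classmethod
    def reduced(cls, seed: int = 0) -> "ModelConfig":
        """CPU-scale profile: same topology, smaller images and widths."""
        return cls(input_size=32, conv_channels=8, motion_fc_dim=64,
                   lstm_hidden=64, fatigue_fc_dims=(32, 3), seed=seed)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def validate(self) -> "TrainConfig":
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.split} must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        return self


@dataclass
class LabeledExample:
    """The per-channel images of one window plus its two labels."""

    images: np.ndarray  # (n_branches, 3, S, S) float32
    motion_label: str
    fatigue_label: str
    recording_id: str = ""

    @property
    def motion_index(self) -> int:
        return MOTIONS.index(self.motion_label)

    @property
    def fatigue_index(self) -> int:
        return FATIGUE_LEVELS.index(self.fatigue_label)


@dataclass
class DualPrediction:
    motion_probs: np.ndarray  # 6-simplex
    fatigue_probs: np.ndarray  # 3-simplex

    @property
    def motion_label(self) -> str:
        return MOTIONS[int(np.argmax(self.motion_probs))]

    @property
    def fatigue_label(self) -> str:
        return FATIGUE_LEVELS[int(np.argmax(self.fatigue_probs))]


class FESsEMGNet:
    """Parallel-branch CNN + LSTM dual-task classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config.validate()
        rng = np.random.default_rng(config.seed)
        c = config
        self.branches: list[list[Layer]] = []
        for _ in range(c.n_branches):
            layers: list[Layer] = []
            ch = c.input_channels
            for _ in range(c.n_conv_blocks):
                layers += [Conv2d(ch, c.conv_channels, c.conv_kernel, rng),
                           BatchNorm2d(c.conv_channels), ReLU(), MaxPool2x2()]
                ch = c.conv_channels
            layers.append(Dropout(c.dropout_rate, rng))
            self.branches.append(layers)
        s = c.feature_size
        self.motion_fc1 = Linear(c.concat_dim, c.motion_fc_dim, rng)
        self.motion_relu = ReLU()
        self.motion_fc2 = Linear(c.motion_fc_dim, c.motion_classes, rng)
        if c.lstm_sequence_layout == "rows_as_steps":
            lstm_in = s * c.conv_channels
        else:
            lstm_in = s * s * c.conv_channels
        self.lstm1 = [LSTM(lstm_in, c.lstm_hidden, rng) for _ in range(c.n_branches)]
        self.lstm2 = [LSTM(c.lstm_hidden, c.lstm_hidden, rng) for _ in range(c.n_branches)]
        self.fatigue_fc1 = Linear(c.n_branches * c.lstm_hidden, c.fatigue_fc_dims[0], rng)
        self.fatigue_relu = ReLU()
        self.fatigue_fc2 = Linear(c.fatigue_fc_dims[0], c.fatigue_fc_dims[1], rng)

    # -- parameter plumbing ------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for branch in self.branches:
            out += branch
        out += [self.motion_fc1, self.motion_relu, self.motion_fc2,
                *self.lstm1, *self.lstm2,
                self.fatigue_fc1, self.fatigue_relu, self.fatigue_fc2]
        return out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def state(self) -> dict:
        values = [p.value.copy() for p in self.params]
        bn = [(l.running_mean.copy(), l.running_var.copy())
              for l in self.layers if isinstance(l, BatchNorm2d)]
        return {"params": values, "bn": bn}

    def load_state(self, state: dict) -> None:
        for p, v in zip(self.params, state["params"]):
            p.value[...] = v
        bns = [l for l in self.layers if isinstance(l, BatchNorm2d)]
        for l, (m, v) in zip(bns, state["bn"]):
            l.running_mean[...] = m
            l.running_var[...] = v

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """x: (N, n_branches, 3, S, S) -> (motion_probs, fatigue_probs)."""
        c = self.config
        x = np.asarray(x, dtype=F32)
        if x.ndim != 5 or x.shape[1] != c.n_branches or x.shape[2] != c.input_channels \
                or x.shape[3] != c.input_size or x.shape[4] != c.input_size:
            raise ValueError(
                f"expected input (N, {c.n_branches}, {c.input_channels}, "
                f"{c.input_size}, {c.input_size}), got {x.shape}"
            )
        n = x.shape[0]
        feats = []
        for b, branch in enumerate(self.branches):
            h = x[:, b]
            for layer in branch:
                h = layer.forward(h, train)
            feats.append(h)
        self._feat_shape = feats[0].shape
        flat = np.concatenate([f.reshape(n, -1) for f in feats], axis=1)
        m = self.motion_fc2.forward(
            self.motion_relu.forward(
                self.motion_fc1.forward(flat, train), train), train)
        s = c.feature_size
        last_states = []
        self._seq_shapes = []
        for b in range(c.n_branches):
            if c.lstm_sequence_layout == "rows_as_steps":
                seq = feats[b].transpose(0, 2, 3, 1).reshape(n, s, s * c.conv_channels)
            else:
                seq = feats[b].reshape(n, 1, -1)
            self._seq_shapes.append(seq.shape)
            hs = self.lstm2[b].forward(self.lstm1[b].forward(seq, train), train)
            last_states.append(hs[:, -1])
        fcat = np.concatenate(last_states, axis=1)
        f = self.fatigue_fc2.forward(
            self.fatigue_relu.forward(
                self.fatigue_fc1.forward(fcat, train), train), train)
        return softmax(m), softmax(f)

    def backward(self, d_motion_logits: np.ndarray, d_fatigue_logits: np.ndarray):
        c = self.config
        n = d_motion_logits.shape[0]
        dflat = self.motion_fc1.backward(
            self.motion_relu.backward(
                self.motion_fc2.backward(d_motion_logits)))
        dfcat = self.fatigue_fc1.backward(
            self.fatigue_relu.backward(
                self.fatigue_fc2.backward(d_fatigue_logits)))
        s = c.feature_size
        per_branch = s * s * c.conv_channels
        for b, branch in enumerate(self.branches):
            d_feat = dflat[:, b * per_branch:(b + 1) * per_branch].reshape(self._feat_shape)
            d_last = dfcat[:, b * c.lstm_hidden:(b + 1) * c.lstm_hidden]
            t = self._seq_shapes[b][1]
            dhs = np.zeros((n, t, c.lstm_hidden), dtype=F32)
            dhs[:, -1] = d_last
            dseq = self.lstm1[b].backward(self.lstm2[b].backward(dhs))
            if c.lstm_sequence_layout == "rows_as_steps":
                d_feat = d_feat + dseq.reshape(n, s, s, c.conv_channels).transpose(0, 3, 1, 2)
            else:
                d_feat = d_feat + dseq.reshape(self._feat_shape)
            g = d_feat
            for layer in reversed(branch):
                g = layer.backward(g)


def build_model(config: ModelConfig) -> FESsEMGNet:
    """Construct the network with seeded initialization."""
    return FESsEMGNet(config)


def dual_loss(motion_probs: np.ndarray, motion_labels,
              fatigue_probs: np.ndarray, fatigue_labels) -> float:
    """Summed dual-task cross-entropy; zero iff both heads are one-hot correct."""
    motion_probs = np.atleast_2d(motion_probs)
    fatigue_probs = np.atleast_2d(fatigue_probs)
    ym = np.atleast_1d(np.asarray(motion_labels, dtype=int))
    yf = np.atleast_1d(np.asarray(fatigue_labels, dtype=int))
    if ym.min() < 0 or ym.max() >= motion_probs.shape[1]:
        raise ValueError("motion label out of range")
    if yf.min() < 0 or yf.max() >= fatigue_probs.shape[1]:
        raise ValueError("fatigue label out of range")
    return cross_entropy(motion_probs, ym) + cross_entropy(fatigue_probs, yf)


def split_dataset(examples: list, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                  stratify: bool = True) -> tuple[list, list, list]:
    """Seeded, stratified, disjoint and exhaustive train/val/test split.

    Stratification is by (motion, fatigue) pair; strata with fewer than 3
    examples trigger a fallback to an unstratified split (with a warning).
    Global split sizes are exact: ``round(f * N)`` for val and test, the
    remainder for train.
    """
    import warnings

    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(examples)
    rng = np.random.default_rng(seed)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test

    def _key(e):
        return (e.motion_label, e.fatigue_label)

    strata: dict = {}
    can_stratify = stratify and all(hasattr(e, "motion_label") for e in examples)
    if can_stratify:
        for i, e in enumerate(examples):
            strata.setdefault(_key(e), []).append(i)
        if any(len(v) < 3 for v in strata.values()):
            warnings.warn("some (motion, fatigue) strata have < 3 examples; "
                          "falling back to an unstratified split")
            can_stratify = False
    if not can_stratify:
        strata = {None: list(range(n))}

    # per-stratum quotas by largest remainder, then nudge to exact global sizes
    keys = sorted(strata, key=str)
    pools: dict = {}
    alloc: dict = {}
    fr = np.array([fractions[0], fractions[1], fractions[2]])
    for key in keys:
        idx = np.array(strata[key])
        rng.shuffle(idx)
        pools[key] = list(map(int, idx))
        ideal = fr * len(idx)
        base = np.floor(ideal).astype(int)
        rem = ideal - base
        for _ in range(len(idx) - int(base.sum())):
            j = int(np.argmax(rem))
            base[j] += 1
            rem[j] = -1
        alloc[key] = base
    targets = np.array([n_train, n_val, n_test])
    totals = np.sum([alloc[k] for k in keys], axis=0)
    while not np.array_equal(totals, targets):
        over = int(np.argmax(totals - targets))
        under = int(np.argmin(totals - targets))
        donor = max(keys, key=lambda k: alloc[k][over])
        alloc[donor][over] -= 1
        alloc[donor][under] += 1
        totals[over] -= 1
        totals[under] += 1
    splits: list[list] = [[], [], []]
    for key in keys:
        pool = pools[key]
        a, b = alloc[key][0], alloc[key][0] + alloc[key][1]
        splits[0] += pool[:a]
        splits[1] += pool[a:b]
        splits[2] += pool[b:]
    return tuple([examples[i] for i in part] for part in splits)


def examples_to_arrays(examples: list[LabeledExample]):
    X = np.stack([e.images for e in examples]).astype(F32)
    ym = np.array([e.motion_index for e in examples], dtype=int)
    yf = np.array([e.fatigue_index for e in examples], dtype=int)
    return X, ym, yf


def _accuracy(model: FESsEMGNet, X, ym, yf, batch: int = 100):
    correct_m = correct_f = 0
    losses = []
    for i in range(0, len(X), batch):
        pm, pf = model.forward(X[i:i + batch], train=False)
        correct_m += int((pm.argmax(1) == ym[i:i + batch]).sum())
        correct_f += int((pf.argmax(1) == yf[i:i + batch]).sum())
        losses.append(dual_loss(pm, ym[i:i + batch], pf, yf[i:i + batch]) * len(pm))
    return (correct_m / len(X), correct_f / len(X), float(np.sum(losses)) / len(X))


def train(model: FESsEMGNet, train_examples, val_examples,
          config: TrainConfig) -> tuple[FESsEMGNet, list[dict]]:
    """Mini-batch Adam on the summed dual loss; returns the best-val model.

    History records per-epoch mean train loss, validation loss and both-task
    validation accuracies. The parameters achieving the lowest validation
    loss are restored into the returned model. Deterministic given the seed.
    """
    config.validate()
    if not len(train_examples) or not len(val_examples):
        raise ValueError("train and validation sets must be nonempty")
    if isinstance(train_examples, (list, tuple)):
        Xtr, ym_tr, yf_tr = examples_to_arrays(train_examples)
        Xva, ym_va, yf_va = examples_to_arrays(val_examples)
    else:
        Xtr, ym_tr, yf_tr = train_examples
        Xva, ym_va, yf_va = val_examples
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history: list[dict] = []
    best = {"val_acc": -1.0, "val_loss": np.inf, "state": model.state()}
    n = len(Xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            pm, pf = model.forward(Xtr[idx], train=True)
            loss = dual_loss(pm, ym_tr[idx], pf, yf_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}, "
                    f"batch {i // config.batch_size}; reduce the learning rate"
                )
            opt.zero_grad()
            model.backward(softmax_ce_grad(pm, ym_tr[idx]),
                           softmax_ce_grad(pf, yf_tr[idx]))
            opt.step()
            batch_losses.append(loss)
        acc_m, acc_f, val_loss = _accuracy(model, Xva, ym_va, yf_va)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(batch_losses)),
            "val_loss": val_loss,
            "val_motion_acc": acc_m,
            "val_fatigue_acc": acc_f,
        })
        mean_acc = 0.5 * (acc_m + acc_f)
        # checkpoint on both-task validation accuracy; loss breaks ties (late
        # epochs often grow overconfident, raising loss while accuracy holds)
        if mean_acc > best["val_acc"] or (
                mean_acc == best["val_acc"] and val_loss < best["val_loss"]):
            best = {"val_acc": mean_acc, "val_loss": val_loss,
                    "state": model.state()}
    model.load_state(best["state"])
    return model, history


def predict(model: FESsEMGNet, examples, batch: int = 100) -> list[DualPrediction]:
    """Eval-mode predictions (dropout off, batch-norm running stats)."""
    if isinstance(examples, (list, tuple)) and len(examples) \
            and isinstance(examples[0], LabeledExample):
        X = np.stack([e.images for e in examples]).astype(F32)
    else:
        X = np.asarray(examples, dtype=F32)
    out: list[DualPrediction] = []
    for i in range(0, len(X), batch):
        pm, pf = model.forward(X[i:i + batch], train=False)
        out.extend(DualPrediction(m, f) for m, f in zip(pm, pf))
    return out


def save_checkpoint(model: FESsEMGNet, path) -> None:
    import json

    from dataclasses import asdict

    state = model.state()
    arrays = {f"p{i}": v for i, v in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn"]):
        arrays[f"bn{i}_mean"] = m
        arrays[f"bn{i}_var"] = v
    cfg = asdict(model.config)
    cfg["fatigue_fc_dims"] = list(cfg["fatigue_fc_dims"])
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> FESsEMGNet:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    cfg["fatigue_fc_dims"] = tuple(cfg["fatigue_fc_dims"])
    model = FESsEMGNet(ModelConfig(**cfg))
    n_params = len(model.params)
    state = {
        "params": [data[f"p{i}"] for i in range(n_params)],
        "bn": [(data[f"bn{i}_mean"], data[f"bn{i}_var"])
               for i in range(sum(isinstance(l, BatchNorm2d) for l in model.layers))],
    }
    model.load_state(state)
    return model
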