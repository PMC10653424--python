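"""The FUN-PROSE predictor: promoter CNN branch + TF dense branch + head.

The model maps (one-hot 5xL promoter, vector of TF expression z-scores in
one condition) to a single scalar — the gene's expression z-score in that
condition. Architecture, block order and the shipped default
hyperparameters follow the published configuration:

* promoter branch: conv(256 kernels, len 9, valid) -> maxpool 19 -> ReLU
  -> dropout -> batchnorm -> conv(64 kernels, len 13) -> maxpool 8 -> ReLU
  -> dropout -> batchnorm -> flatten,
* TF branch: dense(n_tfs -> 1024) -> ELU -> dropout,
* head: concat -> 3 x [dense -> ELU -> dropout -> batchnorm] -> dense -> 1.

Max pooling and ReLU commute, so pooling-before-activation equals the
conventional conv->ReLU->pool order. Variants: a 3'UTR second CNN branch,
a mean-TF ablation (the TF vector collapsed to its scalar mean), and
frozen-convolution transfer (see :func:`freeze_conv`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import DTYPE


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the best configuration found in the published
    hyperparameter search; :meth:`small` returns a CPU-scale reduction
    used for the synthetic end-to-end runs.
    """

    promoter_length: int = 1000
    conv1_kernels: int = 256
    conv1_len: int = 9
    pool1: int = 19
    conv2_kernels: int = 64
    conv2_len: int = 13
    pool2: int = 8
    conv_activation: str = "relu"
    conv_dropout: float = 0.398
    tf_hidden: int = 1024
    tf_dropout: float = 0.189
    tf_activation: str = "elu"
    head_activation: str = "elu"
    head_dropout: float = 0.0166
    head_sizes: tuple[int, ...] = (512, 256, 64)
    lr: float = 1.02e-4
    weight_decay: float = 1.64e-3
    batch_size: int = 256
    max_epochs: int = 60
    patience: int = 5
    use_utr: bool = False
    mean_tf_ablation: bool = False

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Reduced configuration for single-CPU synthetic-data runs:
        32 first-layer kernels, TF hidden size 128, proportionally smaller
        second conv and head, lighter regularization and a larger constant
        learning rate suited to the smaller parameter count."""
        cfg = cls(conv1_kernels=32, conv2_kernels=32, tf_hidden=128,
                  head_sizes=(128, 64, 32), conv_dropout=0.05, tf_dropout=0.1,
                  head_dropout=0.02, lr=4e-3, weight_decay=1e-4,
                  max_epochs=12, patience=5)
        return dataclasses.replace(cfg, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_sizes"] = list(self.head_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["head_sizes"] = tuple(d["head_sizes"])
        return cls(**d)


def _activation(name: str) -> nn.Layer:
    name = name.lower()
    if name == "relu":
        return nn.ReLU()
    if name == "elu":
        return nn.ELU()
    raise ValueError(f"unsupported activation {name!r}")


def shape_chain(config: ModelConfig) -> dict[str, int]:
    """Validated sequence-length chain of the conv branch.

    Raises ``ValueError`` with the computed chain if any stage collapses
    below one position.
    """
    L = config.promoter_length
    l1 = L - config.conv1_len + 1
    p1 = l1 // config.pool1
    l2 = p1 - config.conv2_len + 1
    p2 = l2 // config.pool2
    chain = {"input": L, "conv1": l1, "pool1": p1, "conv2": l2, "pool2": p2,
             "flatten": config.conv2_kernels * max(p2, 0)}
    if min(l1, p1, l2, p2) < 1:
        raise ValueError(f"architecture collapses the sequence: {chain}")
    return chain


class FunProse:
    """The predictor. Exposes parameter groups (conv branch, TF branch,
    head), a pure evaluation-mode forward pass, and gradients of the
    scalar output with respect to the TF input (needed for attribution).
    """

    def __init__(self, config: ModelConfig, n_tfs: int, seed: int = 0):
        if n_tfs < 1:
            raise ValueError("n_tfs must be >= 1")
        self.config = config
        self.n_tfs = n_tfs
        self.seed = seed
        self.chain = shape_chain(config)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])

        self.conv_branch = self._build_conv_branch(config, rng)
        self.utr_branch = (self._build_conv_branch(config, rng)
                           if config.use_utr else None)

        concat = self.chain["flatten"] * (2 if config.use_utr else 1)
        if config.mean_tf_ablation:
            self.tf_branch = None
            concat += 1
        else:
            self.tf_branch = nn.Sequential([
                ("lin", nn.Linear(n_tfs, config.tf_hidden, rng)),
                ("act", _activation(config.tf_activation)),
                ("drop", nn.Dropout(config.tf_dropout, self._dropout_rng)),
            ])
            concat += config.tf_hidden
        self.concat_width = concat

        head_layers = []
        width = concat
        for i, h in enumerate(config.head_sizes):
            head_layers += [
                (f"lin{i}", nn.Linear(width, h, rng)),
                (f"act{i}", _activation(config.head_activation)),
                (f"drop{i}", nn.Dropout(config.head_dropout, self._dropout_rng)),
                (f"bn{i}", nn.BatchNorm(h)),
            ]
            width = h
        head_layers.append(("out", nn.Linear(width, 1, rng)))
        self.head = nn.Sequential(head_layers)

    def _build_conv_branch(self, cfg: ModelConfig, rng) -> nn.Sequential:
        return nn.Sequential([
            ("conv1", nn.Conv1d(5, cfg.conv1_kernels, cfg.conv1_len, rng)),
            ("pool1", nn.MaxPool1d(cfg.pool1)),
            ("act1", _activation(cfg.conv_activation)),
            ("drop1", nn.Dropout(cfg.conv_dropout, self._dropout_rng)),
            ("bn1", nn.BatchNorm(cfg.conv1_kernels)),
            ("conv2", nn.Conv1d(cfg.conv1_kernels, cfg.conv2_kernels,
                                cfg.conv2_len, rng)),
            ("pool2", nn.MaxPool1d(cfg.pool2)),
            ("act2", _activation(cfg.conv_activation)),
            ("drop2", nn.Dropout(cfg.conv_dropout, self._dropout_rng)),
            ("bn2", nn.BatchNorm(cfg.conv2_kernels)),
            ("flat", nn.Flatten()),
        ])

    # -- module bookkeeping ------------------------------------------------

    def modules(self) -> list[tuple[str, nn.Layer]]:
        mods = list(self.conv_branch.named_layers("conv"))
        if self.utr_branch is not None:
            mods += list(self.utr_branch.named_layers("utr"))
        if self.tf_branch is not None:
            mods += list(self.tf_branch.named_layers("tf"))
        mods += list(self.head.named_layers("head"))
        return mods

    def state_dict(self):
        return nn.state_dict(self.modules())

    def load_state_dict(self, state):
        nn.load_state_dict(self.modules(), state)

    def conv1_kernels(self) -> tuple[np.ndarray, np.ndarray]:
        """First-layer kernels as ``(K, 5, klen)`` and their biases."""
        conv1 = dict(self.conv_branch.layers)["conv1"]
        return conv1.kernels(), conv1.params["b"].copy()

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def promoter_to_col(onehot: np.ndarray, klen: int) -> np.ndarray:
        """Pre-compute the im2col window matrix of one one-hot promoter
        (``(5, L)`` -> ``(L-klen+1, 5*klen)``, channel-major)."""
        from numpy.lib.stride_tricks import sliding_window_view
        x = np.ascontiguousarray(onehot.T, dtype=DTYPE)  # (L, 5)
        w = sliding_window_view(x, klen, axis=0)  # (Lout, 5, klen)
        return np.ascontiguousarray(w).reshape(w.shape[0], 5 * klen)

    def conv_forward(self, xcol: np.ndarray, train: bool,
                     branch: nn.Sequential | None = None) -> np.ndarray:
        branch = branch or self.conv_branch
        layers = branch.layers
        x = layers[0][1].forward_col(xcol, train)
        for _, layer in layers[1:]:
            x = layer.forward(x, train)
        return x

    def _tf_features(self, tf: np.ndarray, train: bool) -> np.ndarray:
        if self.tf_branch is None:
            return tf.mean(axis=1, keepdims=True)
        return self.tf_branch.forward(tf, train)

    def forward(self, xcol: np.ndarray, tf: np.ndarray,
                utr_xcol: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        """Predict one z-score per (promoter, TF-vector) row of the batch."""
        if tf.shape[1] != self.n_tfs:
            raise ValueError(
                f"TF input has {tf.shape[1]} features, model expects {self.n_tfs}")
        parts = [self.conv_forward(xcol.astype(DTYPE, copy=False), train)]
        if self.utr_branch is not None:
            if utr_xcol is None:
                raise ValueError("model was built with a 3'UTR branch but no "
                                 "UTR input was given")
            parts.append(self.conv_forward(
                utr_xcol.astype(DTYPE, copy=False), train, self.utr_branch))
        parts.append(self._tf_features(tf.astype(DTYPE, copy=False), train))
        self._split = np.cumsum([p.shape[1] for p in parts])[:-1]
        self._n_seq_parts = len(parts) - 1
        h = np.concatenate(parts, axis=1)
        return self.head.forward(h, train)[:, 0]

    def backward(self, dpred: np.ndarray, train: bool = True) -> np.ndarray:
        """Backprop from d(loss)/d(pred); accumulates parameter gradients
        and returns the gradient with respect to the TF input vector."""
        dh = self.head.backward(dpred[:, None].astype(DTYPE))
        parts = np.split(dh, self._split, axis=1)
        self.conv_branch.backward(parts[0], stop_before_first_dx=True)
        if self.utr_branch is not None:
            self.utr_branch.backward(parts[1], stop_before_first_dx=True)
        dtf_feat = parts[-1]
        if self.tf_branch is None:
            return np.repeat(dtf_feat, self.n_tfs, axis=1) / self.n_tfs
        return self.tf_branch.backward(dtf_feat)

    # -- attribution path (promoter representation held fixed) -------------

    def forward_from_flat(self, conv_flat: np.ndarray, tf: np.ndarray,
                          train: bool = False) -> np.ndarray:
        """Forward pass with pre-computed conv-branch output(s); used when
        only the TF input varies (e.g. attribution interpolation)."""
        parts = [conv_flat.astype(DTYPE, copy=False),
                 self._tf_features(tf.astype(DTYPE, copy=False), train)]
        self._split = np.cumsum([p.shape[1] for p in parts])[:-1]
        h = np.concatenate(parts, axis=1)
        return self.head.forward(h, train)[:, 0]

    def tf_input_gradient(self, conv_flat: np.ndarray,
                          tf: np.ndarray) -> np.ndarray:
        """d(output)/d(tf input) row-wise, in evaluation mode."""
        if self.tf_branch is None:
            raise ValueError("per-TF gradients are undefined for the "
                             "mean-TF ablation variant")
        self.forward_from_flat(conv_flat, tf, train=False)
        dh = self.head.backward(np.ones((tf.shape[0], 1), dtype=DTYPE))
        dtf_feat = np.split(dh, self._split, axis=1)[-1]
        return self.tf_branch.backward(dtf_feat)


def build_model(config: ModelConfig, n_tfs: int, seed: int = 0) -> FunProse:
    """Construct the predictor; validates the conv shape chain at build."""
    return FunProse(config, n_tfs, seed=seed)


def build_utr_variant(config: ModelConfig, n_tfs: int, seed: int = 0) -> FunProse:
    return FunProse(dataclasses.replace(config, use_utr=True), n_tfs, seed=seed)


def build_mean_tf_variant(config: ModelConfig, n_tfs: int, seed: int = 0) -> FunProse:
    return FunProse(dataclasses.replace(config, mean_tf_ablation=True),
                    n_tfs, seed=seed)


def predict(model: FunProse, onehots: np.ndarray, tf_vector: np.ndarray,
            utr_onehots: np.ndarray | None = None) -> np.ndarray:
    """Evaluation-mode prediction for a batch of one-hot promoters
    (``(B, 5, L)``) paired row-wise with TF vectors (``(B, n_tfs)``)."""
    onehots = np.asarray(onehots)
    if onehots.ndim == 2:
        onehots = onehots[None]
    if onehots.shape[2] != model.config.promoter_length:
        raise ValueError(
            f"promoter length {onehots.shape[2]} != configured "
            f"{model.config.promoter_length}")
    k = model.config.conv1_len
    xcol = np.stack([FunProse.promoter_to_col(p, k) for p in onehots])
    utr_xcol = None
    if utr_onehots is not None:
        utr_xcol = np.stack([FunProse.promoter_to_col(p, k) for p in utr_onehots])
    return model.forward(xcol, np.atleast_2d(tf_vector), utr_xcol, train=False)


def freeze_conv(model: FunProse) -> None:
    """Mark all convolutional-branch parameters as non-trainable."""
    for _, layer in model.conv_branch.layers:
        layer.frozen = True
    if model.utr_branch is not None:
        for _, layer in model.utr_branch.layers:
            layer.frozen = True


def save_checkpoint(model: FunProse, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "model.npz", **model.state_dict())
    meta = {"config": model.config.to_dict(), "n_tfs": model.n_tfs,
            "seed": model.seed}
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> FunProse:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    model = FunProse(ModelConfig.from_dict(meta["config"]), meta["n_tfs"],
                     seed=meta["seed"])
    with np.load(path / "model.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
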