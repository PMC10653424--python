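"""Split construction and the training loop.

Four split regimes over the gene x condition grid:

* ``elements`` — 10% of the cells withheld for validation, 20% for test,
  uniformly at random;
* ``conditions`` — whole conditions withheld (the model never sees the
  condition's TF profile during training);
* ``genes`` — whole genes withheld (the model never sees the promoter);
* ``clustered_conditions`` — conditions are first clustered by expression
  (agglomerative, average linkage on Euclidean distance) and the test
  conditions are cluster-disjoint from train/validation, so test
  conditions do not resemble any training condition.

Training minimizes mean squared error with AdamW, selects the checkpoint
with the best validation Pearson r, and stops after ``patience`` epochs
without improvement or at ``max_epochs``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .containers import ModelDataset
from .model import FunProse, ModelConfig

MODES = ("elements", "conditions", "genes", "clustered_conditions")


@dataclass
class SplitSpec:
    mode: str = "elements"
    val_frac: float = 0.10
    test_frac: float = 0.20
    seed: int = 0
    n_clusters: int | None = None
    strict_val: bool = True  # clustered mode: val also cluster-disjoint

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0 < self.val_frac < 1 and 0 < self.test_frac < 1
                and self.val_frac + self.test_frac < 1):
            raise ValueError("fractions must lie in (0,1) with val+test < 1")


@dataclass
class Split:
    """Disjoint train/val/test sets of (gene_index, condition_index) pairs."""
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def validate(self, n_genes: int, n_conditions: int) -> None:
        seen = set()
        for part in (self.train, self.val, self.test):
            pairs = set(map(tuple, part.tolist()))
            if pairs & seen:
                raise ValueError("split parts are not disjoint")
            seen |= pairs

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: getattr(self, k).tolist() for k in ("train", "val", "test")}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Split":
        d = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(d[k], dtype=np.int64).reshape(-1, 2)
                      for k in ("train", "val", "test")})


def _all_pairs(n_genes: int, n_conditions: int) -> np.ndarray:
    g, c = np.meshgrid(np.arange(n_genes), np.arange(n_conditions),
                       indexing="ij")
    return np.stack([g.ravel(), c.ravel()], axis=1)


def cluster_conditions(z, n_clusters: int, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of condition columns of the z-score
    matrix (Euclidean distance); returns one integer label per condition."""
    import pandas as pd
    x = z.to_numpy().T if isinstance(z, pd.DataFrame) else np.asarray(z).T
    if n_clusters > x.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds the "
                         f"{x.shape[0]} conditions")
    from sklearn.cluster import AgglomerativeClustering
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage,
                                    metric="euclidean")
    return model.fit_predict(x)


def make_split(dataset: ModelDataset, spec: SplitSpec,
               cluster_labels: np.ndarray | None = None) -> Split:
    """Build a split per the spec; reproducible for a fixed seed."""
    n_genes = len(dataset.gene_ids)
    n_cond = len(dataset.condition_ids)
    if n_genes == 0 or n_cond == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)
    pairs = _all_pairs(n_genes, n_cond)

    if spec.mode == "elements":
        perm = rng.permutation(len(pairs))
        n_test = int(round(spec.test_frac * len(pairs)))
        n_val = int(round(spec.val_frac * len(pairs)))
        test = pairs[perm[:n_test]]
        val = pairs[perm[n_test:n_test + n_val]]
        train = pairs[perm[n_test + n_val:]]
        return Split(train=train, val=val, test=test)

    if spec.mode in ("conditions", "genes"):
        n_axis = n_cond if spec.mode == "conditions" else n_genes
        axis = 1 if spec.mode == "conditions" else 0
        perm = rng.permutation(n_axis)
        n_test = max(1, int(round(spec.test_frac * n_axis)))
        n_val = max(1, int(round(spec.val_frac * n_axis)))
        test_ids = set(perm[:n_test].tolist())
        val_ids = set(perm[n_test:n_test + n_val].tolist())
        part = pairs[:, axis]
        in_test = np.isin(part, list(test_ids))
        in_val = np.isin(part, list(val_ids))
        return Split(train=pairs[~in_test & ~in_val], val=pairs[in_val],
                     test=pairs[in_test])

    # clustered_conditions
    if cluster_labels is None:
        n_clusters = spec.n_clusters or max(3, n_cond // 5)
        cluster_labels = cluster_conditions(dataset.zscores, n_clusters)
    cluster_labels = np.asarray(cluster_labels)
    clusters = np.unique(cluster_labels)
    if len(clusters) < 3:
        raise ValueError("clustered split needs at least 3 clusters")
    order = rng.permutation(clusters)
    sizes = {int(cl): int((cluster_labels == cl).sum()) for cl in clusters}

    def pick_clusters(candidates, target):
        """Whole clusters approximating the target condition count:
        clusters are visited in random order and taken only when doing so
        moves the running total closer to the target, so one oversized
        cluster cannot swallow the whole axis."""
        taken, total = [], 0
        for cl in candidates:
            if total >= target:
                break
            if abs(total + sizes[cl] - target) <= abs(total - target):
                taken.append(cl)
                total += sizes[cl]
        if not taken:  # every cluster overshoots; take the smallest
            taken = [min(candidates, key=lambda c: sizes[c])]
        return taken

    test_taken = pick_clusters(list(order), spec.test_frac * n_cond)
    if len(test_taken) == len(clusters):
        raise ValueError("test clusters would cover every condition")
    test_conds = {c for cl in test_taken
                  for c in np.flatnonzero(cluster_labels == cl).tolist()}
    remaining = np.array(sorted(set(range(n_cond)) - test_conds))
    rest = [cl for cl in order if cl not in test_taken]
    if spec.strict_val:
        val_taken = pick_clusters(rest, spec.val_frac * n_cond)
        if len(val_taken) == len(rest):
            val_taken = val_taken[:-1]
        val_conds = {c for cl in val_taken
                     for c in np.flatnonzero(cluster_labels == cl).tolist()}
    else:
        n_val = max(1, int(round(spec.val_frac * n_cond)))
        val_conds = set(rng.permutation(remaining)[:n_val].tolist())
    if not val_conds:
        val_conds = {int(remaining[0])}
    part = pairs[:, 1]
    in_test = np.isin(part, list(test_conds))
    in_val = np.isin(part, list(val_conds))
    return Split(train=pairs[~in_test & ~in_val], val=pairs[in_val],
                 test=pairs[in_test])


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_r: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_r: float = float("-inf")
    stopping_reason: str = ""
    seconds: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


class _Tensors:
    """Dataset views pre-packed for the training loop: per-gene im2col
    promoter windows, condition TF vectors and the target grid."""

    def __init__(self, dataset: ModelDataset, config: ModelConfig):
        self.xcol = np.stack([
            FunProse.promoter_to_col(p, config.conv1_len)
            for p in dataset.onehot_promoters()])
        self.utr_xcol = None
        if config.use_utr:
            self.utr_xcol = np.stack([
                FunProse.promoter_to_col(p, config.conv1_len)
                for p in dataset.onehot_promoters("utr")])
        self.tf = dataset.tf_expression.to_numpy(dtype=nn.DTYPE).T  # (C, n_tfs)
        self.z = dataset.zscores.to_numpy(dtype=nn.DTYPE)           # (G, C)

    def batch(self, pairs: np.ndarray):
        g, c = pairs[:, 0], pairs[:, 1]
        utr = None if self.utr_xcol is None else self.utr_xcol[g]
        return self.xcol[g], self.tf[c], utr, self.z[g, c]


def predict_pairs(model: FunProse, tensors: _Tensors, pairs: np.ndarray,
                  batch_size: int = 1024) -> np.ndarray:
    out = np.empty(len(pairs), dtype=nn.DTYPE)
    for i in range(0, len(pairs), batch_size):
        xc, tf, utr, _ = tensors.batch(pairs[i:i + batch_size])
        out[i:i + len(xc)] = model.forward(xc, tf, utr, train=False)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def train(model: FunProse, dataset: ModelDataset, split: Split,
          config: ModelConfig | None = None, seed: int = 0,
          verbose: bool = False, restore_best: bool = True,
          ) -> tuple[FunProse, TrainReport]:
    """Fit the model on the train pairs; early-stop on validation
    Pearson r; restore and return the best-validation checkpoint
    (``restore_best=False`` keeps the final-epoch parameters instead)."""
    config = config or model.config
    split.validate(len(dataset.gene_ids), len(dataset.condition_ids))
    tensors = _Tensors(dataset, config)
    rng = np.random.default_rng(seed)
    optimizer = nn.AdamW(model.modules(), lr=config.lr,
                         weight_decay=config.weight_decay)
    report = TrainReport()
    best_state = model.state_dict()
    stall = 0
    t0 = time.time()
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(split.train))
        losses = []
        for i in range(0, len(perm), config.batch_size):
            xc, tf, utr, y = tensors.batch(split.train[perm[i:i + config.batch_size]])
            pred = model.forward(xc, tf, utr, train=True)
            resid = pred - y
            loss = float((resid * resid).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}; "
                    f"lr={config.lr} may be too large for this data")
            losses.append(loss)
            optimizer.zero_grad()
            model.backward((2.0 / len(resid)) * resid)
            optimizer.step()
        val_pred = predict_pairs(model, tensors, split.val)
        _, _, _, val_y = tensors.batch(split.val)
        val_r = _pearson(val_pred, val_y)
        report.train_loss.append(float(np.mean(losses)))
        report.val_r.append(val_r)
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                  f"val r {val_r:.4f}", flush=True)
        if val_r > report.best_val_r:
            report.best_val_r = val_r
            report.best_epoch = epoch
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                report.stopping_reason = (
                    f"no val-r improvement for {config.patience} epochs")
                break
    else:
        report.stopping_reason = f"reached max_epochs={config.max_epochs}"
    if restore_best:
        model.load_state_dict(best_state)
    report.seconds = time.time() - t0
    return model, report


def freeze_conv_and_retrain(source: FunProse, dataset: ModelDataset,
                            split: Split, config: ModelConfig | None = None,
                            seed: int = 0) -> tuple[FunProse, TrainReport]:
    """Transfer learning: copy the source model's convolutional branch,
    freeze it, and retrain the TF branch and head on the target dataset
    (the TF branch is re-initialized for the target's TF count)."""
    from .model import build_model, freeze_conv
    config = config or source.config
    if config.promoter_length != source.config.promoter_length:
        raise ValueError("source and target promoter lengths differ")
    target = build_model(config, n_tfs=len(dataset.tf_ids), seed=seed)
    src_state = source.state_dict()
    conv_state = {k: v for k, v in src_state.items() if k.startswith("conv.")}
    state = target.state_dict()
    state.update(conv_state)
    target.load_state_dict(state)
    freeze_conv(target)
    return train(target, dataset, split, config, seed=seed)
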