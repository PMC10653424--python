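"""Scoring predictions: Pearson r, Low/Mean/High confusion matrices,
residual-bias diagnostics, and the nearest-neighbour condition baseline.

Predicted and observed values are on the per-gene z-score scale, so
trinarization uses mean 0 / sd 1 by default: Low below -1, High above
+1, Mean in between (boundaries inclusive to Mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

CATEGORIES = ("Low", "Mean", "High")


def pearson_correlation(pred: np.ndarray, obs: np.ndarray) -> float:
    """Standard Pearson r; errors on degenerate input."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("zero variance input; Pearson r undefined")
    return float(pearsonr(pred, obs).statistic)


def trinarize(values: np.ndarray, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Discretize into Low (< mean-sd), High (> mean+sd), Mean otherwise;
    values exactly one sd from the mean are Mean."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    values = np.asarray(values, dtype=float)
    cats = np.ones(values.shape, dtype=np.int8)  # Mean
    cats[values < mean - sd] = 0
    cats[values > mean + sd] = 2
    return cats


def confusion_matrix(pred_cat: np.ndarray, obs_cat: np.ndarray) -> np.ndarray:
    """3x3 counts, rows = observed category, cols = predicted."""
    pred_cat = np.asarray(pred_cat)
    obs_cat = np.asarray(obs_cat)
    if pred_cat.shape != obs_cat.shape:
        raise ValueError("category vectors differ in length")
    out = np.zeros((3, 3), dtype=np.int64)
    np.add.at(out, (obs_cat, pred_cat), 1)
    return out


def residual_bias(pred: np.ndarray, obs: np.ndarray,
                  group_labels: np.ndarray) -> pd.Series:
    """Per-group mean(residual)/sd(residual) with residual = pred - obs;
    groups with < 2 members or zero residual sd are excluded."""
    resid = np.asarray(pred, dtype=float) - np.asarray(obs, dtype=float)
    s = pd.Series(resid).groupby(pd.Series(np.asarray(group_labels)))
    out = {}
    for label, grp in s:
        if len(grp) < 2 or grp.std(ddof=0) == 0:
            warnings.warn(f"residual_bias: group {label!r} degenerate, excluded")
            continue
        out[label] = grp.mean() / grp.std(ddof=0)
    return pd.Series(out, dtype=float)


def nearest_neighbor_baseline(train_tf: np.ndarray, train_z: np.ndarray,
                              test_tf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict each test condition as the gene-expression column of the
    Euclidean-nearest training condition in TF-expression space.

    ``train_tf``/``test_tf`` are (n_tfs, n_conditions); ``train_z`` is
    (n_genes, n_train_conditions). Returns (predictions, neighbour
    indices); distance ties resolve to the lowest train index.
    """
    train_tf = np.asarray(train_tf, dtype=float)
    test_tf = np.asarray(test_tf, dtype=float)
    train_z = np.asarray(train_z, dtype=float)
    if train_tf.shape[0] != test_tf.shape[0]:
        raise ValueError("train and test TF dimensions differ")
    if train_tf.shape[1] != train_z.shape[1]:
        raise ValueError("train_tf and train_z condition counts differ")
    if train_tf.shape[1] < 1:
        raise ValueError("need at least one training condition")
    d = cdist(test_tf.T, train_tf.T)  # (n_test, n_train)
    nn_idx = d.argmin(axis=1)         # argmin takes the lowest index on ties
    return train_z[:, nn_idx], nn_idx


@dataclass
class EvalResult:
    pearson_r: float
    confusion: np.ndarray
    per_gene_bias: pd.Series
    per_condition_bias: pd.Series

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "confusion": self.confusion.tolist(),
            "confusion_categories": list(CATEGORIES),
            "per_gene_bias": self.per_gene_bias.to_dict(),
            "per_condition_bias": self.per_condition_bias.to_dict(),
        }


def evaluate(pred: np.ndarray, obs: np.ndarray, gene_labels: np.ndarray,
             condition_labels: np.ndarray) -> EvalResult:
    """Bundle the scores for one set of scored (gene, condition) pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gene_bias = residual_bias(pred, obs, gene_labels)
        cond_bias = residual_bias(pred, obs, condition_labels)
    return EvalResult(
        pearson_r=pearson_correlation(pred, obs),
        confusion=confusion_matrix(trinarize(pred), trinarize(obs)),
        per_gene_bias=gene_bias,
        per_condition_bias=cond_bias,
    )
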