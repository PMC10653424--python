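"""TF -> gene regulatory-network inference from model attributions.

Integrated Gradients (IG) assigns each TF input a share of the change in
the model's prediction between a zero baseline and the actual TF vector:

    IG_t = (x_t - x'_t) * (1/S) * sum_{s=1..S} df/dx_t |_{x' + (s/S)(x - x')}

with a zero baseline and S = 20 interpolation steps by default, the
promoter input held fixed at the gene's true promoter. Per-sample IG
vectors over the withheld-elements test set are averaged per target gene
(signed mean) into a TF x gene score table; thresholding absolute scores
at mean + 3 sd yields a directed network whose hubs, communities
(modularity maximization) and motif-filter associations (hypergeometric
tests with Benjamini-Hochberg control) are then analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ModelDataset
from .model import FunProse


def integrated_gradients(model: FunProse, promoter_onehot: np.ndarray,
                         tf_vector: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 20) -> np.ndarray:
    """IG attributions over the TF inputs for one (gene, condition) pair.

    Right-endpoint Riemann approximation of the path integral; exact for
    models linear in the TF input at any step count, and satisfies the
    completeness identity sum(IG) = f(x) - f(baseline) as steps grows.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    tf_vector = np.asarray(tf_vector, dtype=np.float32).ravel()
    x0 = (np.zeros_like(tf_vector) if baseline is None
          else np.asarray(baseline, dtype=np.float32).ravel())
    xcol = FunProse.promoter_to_col(np.asarray(promoter_onehot),
                                    model.config.conv1_len)[None]
    conv_flat = model.conv_forward(xcol, train=False)
    alphas = (np.arange(1, steps + 1, dtype=np.float32) / steps)[:, None]
    interp = x0[None, :] + alphas * (tf_vector - x0)[None, :]
    flat = np.repeat(conv_flat, steps, axis=0)
    grads = model.tf_input_gradient(flat, interp)
    if not np.isfinite(grads).all():
        raise FloatingPointError("non-finite gradient during IG")
    return (tf_vector - x0) * grads.mean(axis=0)


@dataclass
class TFGeneScoreTable:
    """Signed mean IG per (TF, gene), plus how many test samples each
    gene column was averaged over."""
    scores: pd.DataFrame          # TF x gene
    n_samples: pd.Series          # per gene

    def tf_importance(self) -> pd.Series:
        """Overall TF importance: mean score across target genes."""
        return self.scores.mean(axis=1)


def compute_tf_gene_scores(model: FunProse, dataset: ModelDataset,
                           test_pairs: np.ndarray, steps: int = 20,
                           aggregate: str = "abs") -> TFGeneScoreTable:
    """IG per test sample, averaged per target gene.

    ``aggregate="abs"`` (default) averages |IG| over a gene's test
    samples; ``"signed"`` averages the signed values. The absolute mean
    is the default because TF inputs are mean-zero across conditions, so
    for an effect that is even approximately linear in the TF level the
    signed per-condition attributions cancel in expectation and the
    aggregate underrates genuine regulators; |IG| measures how much a TF
    moves the prediction regardless of direction.

    The convolutional representation of each gene is computed once and
    reused across that gene's test conditions and interpolation steps.
    Genes without test samples are absent from the table.
    """
    if aggregate not in ("abs", "signed"):
        raise ValueError("aggregate must be 'abs' or 'signed'")
    genes = dataset.gene_ids
    tfs = dataset.tf_ids
    tf_mat = dataset.tf_expression.to_numpy(dtype=np.float32).T  # (C, n_tfs)
    onehots = dataset.onehot_promoters()
    alphas = (np.arange(1, steps + 1, dtype=np.float32) / steps)

    cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    test_pairs = np.asarray(test_pairs)
    by_gene: dict[int, list[int]] = {}
    for g, c in test_pairs:
        by_gene.setdefault(int(g), []).append(int(c))
    for g, conds in sorted(by_gene.items()):
        xcol = FunProse.promoter_to_col(onehots[g], model.config.conv1_len)[None]
        conv_flat = model.conv_forward(xcol, train=False)
        x = tf_mat[conds]                                    # (nc, n_tfs)
        interp = alphas[None, :, None] * x[:, None, :]       # zero baseline
        nc = len(conds)
        flat = np.repeat(conv_flat, nc * steps, axis=0)
        grads = model.tf_input_gradient(
            flat, interp.reshape(nc * steps, -1)).reshape(nc, steps, -1)
        if not np.isfinite(grads).all():
            raise FloatingPointError(f"non-finite IG gradient for gene {genes[g]}")
        ig = x * grads.mean(axis=1)                          # (nc, n_tfs)
        if aggregate == "abs":
            ig = np.abs(ig)
        cols[genes[g]] = ig.mean(axis=0)
        counts[genes[g]] = nc
    scores = pd.DataFrame(cols, index=tfs)
    return TFGeneScoreTable(scores=scores, n_samples=pd.Series(counts))


def threshold_network(table: TFGeneScoreTable, k_sd: float = 3.0) -> nx.DiGraph:
    """Directed TF -> gene network keeping pairs whose |score| exceeds
    mean(|scores|) + k_sd * sd(|scores|); isolated nodes are dropped."""
    a = np.abs(table.scores.to_numpy())
    if not np.isfinite(a).all():
        raise ValueError("score table contains non-finite values")
    sd = a.std()
    g = nx.DiGraph()
    if sd == 0:
        warnings.warn("all attribution scores equal; empty network")
        return g
    thr = a.mean() + k_sd * sd
    keep = np.argwhere(a > thr)
    for t, j in keep:
        g.add_edge(table.scores.index[t], table.scores.columns[j],
                   score=float(table.scores.iat[t, j]))
    return g


def degree_statistics(grn: nx.DiGraph, top_n: int = 10) -> dict:
    """Cumulative degree histograms (count of nodes with degree >= x) and
    the fraction of edges covered by the ``top_n`` TFs by out-degree."""
    tf_nodes = [n for n in grn.nodes if grn.out_degree(n) > 0]
    gene_nodes = [n for n in grn.nodes if grn.in_degree(n) > 0]
    out_deg = sorted((grn.out_degree(n) for n in tf_nodes), reverse=True)
    in_deg = sorted((grn.in_degree(n) for n in gene_nodes), reverse=True)

    def cumhist(degs):
        if not degs:
            return []
        return [(x, sum(1 for d in degs if d >= x))
                for x in range(1, max(degs) + 1)]

    hubs = sorted(tf_nodes, key=lambda n: (-grn.out_degree(n), str(n)))[:top_n]
    n_edges = grn.number_of_edges()
    covered = sum(grn.out_degree(h) for h in hubs)
    return {
        "out_degree_cumulative": cumhist(out_deg),
        "in_degree_cumulative": cumhist(in_deg),
        "n_tfs": len(tf_nodes),
        "n_genes": len(gene_nodes),
        "n_edges": n_edges,
        "hubs": [str(h) for h in hubs],
        "hub_coverage": covered / n_edges if n_edges else 0.0,
    }


def modularity_clusters(grn: nx.Graph, seed: int = 0,
                        resolution: float = 1.0) -> tuple[dict, float]:
    """Louvain community detection on the undirected, unweighted view of
    the network; returns (node -> community id, achieved modularity)."""
    und = nx.Graph(grn)
    if und.number_of_edges() == 0:
        return {}, 0.0
    comms = nx.community.louvain_communities(und, seed=seed,
                                             resolution=resolution, weight=None)
    membership = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(und, comms, weight=None)
    return membership, q


def _bh(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def tf_filter_match(grn: nx.DiGraph, feature_maps: np.ndarray,
                    gene_ids: list[str], min_targets: int = 20,
                    act_sd: float = 1.0, q_cutoff: float = 0.2) -> pd.DataFrame:
    """Hypergeometric over-representation of kernel-activated genes among
    each TF's network targets.

    A gene is "activated" by a kernel when its maximum first-layer
    activation over the promoter exceeds mean + ``act_sd`` * sd of that
    statistic across all genes. Only TFs with >= ``min_targets`` targets
    are tested; Benjamini-Hochberg q-values are computed over all tests
    and matches are pairs with q <= ``q_cutoff``.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    population = len(gene_ids)
    maxact = np.asarray(feature_maps).max(axis=2)  # (K, N)
    thr = maxact.mean(axis=1, keepdims=True) + act_sd * maxact.std(axis=1, keepdims=True)
    activated = maxact > thr                       # (K, N) boolean

    rows = []
    for tf in [n for n in grn.nodes if grn.out_degree(n) >= min_targets]:
        targets = [gene_index[g] for g in grn.successors(tf) if g in gene_index]
        n_t = len(targets)
        if n_t < min_targets:
            continue
        for k in range(activated.shape[0]):
            n_act = int(activated[k].sum())
            overlap = int(activated[k, targets].sum())
            p = float(hypergeom.sf(overlap - 1, population, n_act, n_t))
            rows.append((str(tf), k, overlap, n_t, n_act, population, p))
    df = pd.DataFrame(rows, columns=["tf", "kernel", "overlap", "n_targets",
                                     "n_activated", "population", "p"])
    if df.empty:
        df["q"] = []
        df["match"] = []
        return df
    df["q"] = _bh(df["p"].to_numpy())
    df["match"] = df["q"] <= q_cutoff
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT term file: term, description, then member gene ids per line."""
    terms = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip().split("\t")
        if len(parts) >= 3:
            terms[parts[0]] = set(parts[2:])
    return terms


def term_enrichment(communities: dict, terms: dict[str, set[str]],
                    universe: set[str] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in each community
    against the network-universe background, BH-corrected at ``alpha``."""
    if universe is None:
        universe = set(communities)
    terms = {t: gs & universe for t, gs in terms.items()}
    if not any(terms.values()):
        raise ValueError("term file does not intersect the network universe")
    by_comm: dict[int, set[str]] = {}
    for node, comm in communities.items():
        if node in universe:
            by_comm.setdefault(comm, set()).add(node)
    M = len(universe)
    rows = []
    for comm, members in sorted(by_comm.items()):
        for term, gset in terms.items():
            if not gset:
                continue
            overlap = len(members & gset)
            p = float(hypergeom.sf(overlap - 1, M, len(gset), len(members)))
            rows.append((comm, term, overlap, len(members), len(gset), M, p))
    df = pd.DataFrame(rows, columns=["community", "term", "overlap",
                                     "community_size", "term_size",
                                     "population", "p"])
    df["q"] = _bh(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df


def edge_ranking_auroc(table: TFGeneScoreTable, true_edges: set[tuple[str, str]],
                       ) -> float:
    """AUROC of ranking all (TF, gene) pairs by |score| against a set of
    true (tf_id, gene_id) edges."""
    from sklearn.metrics import roc_auc_score
    scores = np.abs(table.scores.to_numpy()).ravel()
    labels = np.array([(t, g) in true_edges
                       for t in table.scores.index
                       for g in table.scores.columns], dtype=int)
    if labels.sum() in (0, len(labels)):
        raise ValueError("true-edge set is degenerate for AUROC")
    return float(roc_auc_score(labels, scores))
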