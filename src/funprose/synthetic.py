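"""Synthetic datasets with known motifs and a known TF->gene effect matrix.

The generator emulates the statistical shape of the real inputs — 1 kb
promoters over A/C/G/T, per-row z-scored TF expression across conditions,
and per-gene z-scored expression targets — while keeping the regulatory
ground truth fully specified, so motif recovery and network recovery can
be scored exactly.

Generative model: each of ``n_motifs`` 9-bp position weight matrices
(PWMs) belongs to one synthetic TF. For every (gene, motif) pair, with
probability ``plant_prob`` one motif instance sampled from the PWM is
written at a random non-overlapping promoter position, and the pair
becomes a regulatory edge with effect size beta (|beta| ~ Uniform[1, 2],
random sign). Expression is the linear read-out

    y[g, c] = sum_t beta[t, g] * tf[t, c] + eps,   eps ~ N(0, noise_sd^2),

z-scored per gene — so a TF moves a gene exactly when its motif is
present in the promoter, which is the interaction structure the predictor
has to discover from sequence alone.

Default sizes (600 genes, 20 TFs, 40 conditions, 8 motifs, plant
probability 0.15, noise sd 0.5) define the standard recovery benchmark.
Generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ModelDataset

BASES = "ACGT"


@dataclass
class PlantedMotif:
    """A 4 x length column-stochastic PWM owned by one synthetic TF."""
    pwm: np.ndarray
    tf_index: int

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))


@dataclass
class GroundTruth:
    """Oracle for recovery scoring: planted edges with effect sizes,
    motif instance positions per gene, and the generating parameters."""
    edges: dict[tuple[int, int], float]          # (tf_index, gene_index) -> beta
    motif_positions: dict[int, list[tuple[int, int]]]  # gene -> [(tf_index, start)]
    noise_sd: float
    seed: int
    motifs: list[PlantedMotif] = field(default_factory=list)

    def edge_matrix(self, n_tfs: int, n_genes: int) -> np.ndarray:
        beta = np.zeros((n_tfs, n_genes))
        for (t, g), b in self.edges.items():
            beta[t, g] = b
        return beta


def generate_pwms(n_motifs: int, length: int = 9, concentration: float = 0.2,
                  seed: int = 0) -> list[PlantedMotif]:
    """Sample column-stochastic PWMs, one Dirichlet draw per column.

    Low ``concentration`` gives near-deterministic consensus columns
    (information-rich, TF-binding-site-like motifs); motif ``i`` is
    assigned to TF ``i``.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    motifs = []
    for m in range(n_motifs):
        pwm = rng.dirichlet(np.full(4, concentration), size=length).T
        motifs.append(PlantedMotif(pwm=pwm, tf_index=m))
    return motifs


def _sample_instance(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=pwm[:, k]) for k in range(pwm.shape[1])]
    return "".join(BASES[i] for i in idx)


def generate_promoters(n_genes: int, motifs: list[PlantedMotif],
                       length: int = 1000, plant_prob: float = 0.15,
                       gc: float = 0.40, seed: int = 0,
                       ) -> tuple[dict[str, str], dict[int, list[tuple[int, int]]]]:
    """I.i.d. background at the given GC content with motif instances
    planted at uniform-random non-overlapping positions.

    Returns the promoter dict (gene ids ``G0000``...) and the position
    map ``gene_index -> [(tf_index, start)]`` (0-based starts).
    """
    mlen = max(m.pwm.shape[1] for m in motifs) if motifs else 0
    if mlen > length:
        raise ValueError("motif longer than the promoter")
    rng = np.random.default_rng(seed)
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    promoters: dict[str, str] = {}
    positions: dict[int, list[tuple[int, int]]] = {}
    for g in range(n_genes):
        seq = list("".join(BASES[i] for i in rng.choice(4, size=length, p=p_bg)))
        occupied: list[tuple[int, int]] = []
        placed: list[tuple[int, int]] = []
        for motif in motifs:
            if rng.random() >= plant_prob:
                continue
            w = motif.pwm.shape[1]
            for _ in range(1000):
                start = int(rng.integers(0, length - w + 1))
                if all(start + w <= a or start >= b for a, b in occupied):
                    break
            else:
                raise RuntimeError(
                    f"could not place motif {motif.tf_index} in gene {g} "
                    "without overlap; promoter too crowded")
            seq[start:start + w] = _sample_instance(motif.pwm, rng)
            occupied.append((start, start + w))
            placed.append((motif.tf_index, start))
        promoters[f"G{g:04d}"] = "".join(seq)
        if placed:
            positions[g] = placed
    return promoters, positions


def generate_tf_expression(n_tfs: int, n_conditions: int, seed: int = 0,
                           n_factors: int = 4) -> pd.DataFrame:
    """TF x condition matrix: a low-rank latent-factor process plus
    independent noise, z-scored per TF row (population sd).

    The latent factors give conditions a correlated, clusterable
    structure, as real condition panels have, without making TF rows
    collinear.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions for a meaningful "
                         "per-row standard deviation")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n_factors, n_conditions))
    loadings = rng.normal(size=(n_tfs, n_factors))
    x = loadings @ latent + 0.7 * rng.normal(size=(n_tfs, n_conditions))
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(x, index=[f"TF{t:02d}" for t in range(n_tfs)],
                        columns=[f"C{c:03d}" for c in range(n_conditions)])


def generate_expression(truth: GroundTruth, tf_expr: pd.DataFrame,
                        gene_ids: list[str]) -> pd.DataFrame:
    """Linear read-out of the planted edges plus Gaussian noise, z-scored
    per gene. Genes with neither an edge nor noise are degenerate and
    raise an error."""
    n_tfs, n_genes = tf_expr.shape[0], len(gene_ids)
    for (t, g) in truth.edges:
        if not (0 <= t < n_tfs and 0 <= g < n_genes):
            raise ValueError(f"edge ({t},{g}) references an unknown TF or gene")
    beta = truth.edge_matrix(n_tfs, n_genes)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(3)[2])
    y = beta.T @ tf_expr.to_numpy()
    y = y + truth.noise_sd * rng.normal(size=y.shape)
    sd = y.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        dead = [gene_ids[i] for i in np.flatnonzero(sd[:, 0] == 0)[:5]]
        raise ValueError(
            f"genes with zero expression variance (e.g. {dead}); they have "
            "no planted edges and noise_sd is 0 — increase noise_sd or "
            "plant_prob")
    z = (y - y.mean(axis=1, keepdims=True)) / sd
    return pd.DataFrame(z, index=gene_ids, columns=tf_expr.columns)


def simulate(n_genes: int = 600, n_tfs: int = 20, n_conditions: int = 40,
             n_motifs: int = 8, plant_prob: float = 0.15,
             noise_sd: float = 0.5, length: int = 1000, gc: float = 0.40,
             concentration: float = 0.2, seed: int = 7,
             ) -> tuple[ModelDataset, GroundTruth]:
    """Generate a complete synthetic dataset plus its ground truth.

    Effect sizes: |beta| ~ Uniform[1, 2] with a random sign per planted
    (TF, gene) pair, so every planted motif has a consequential edge.
    """
    if n_motifs > n_tfs:
        raise ValueError("each motif needs its own TF: n_motifs <= n_tfs")
    ss = np.random.SeedSequence(seed).spawn(3)
    motifs = generate_pwms(n_motifs, concentration=concentration, seed=ss[0])
    promoters, positions = generate_promoters(
        n_genes, motifs, length=length, plant_prob=plant_prob, gc=gc, seed=ss[1])
    tf_expr = generate_tf_expression(n_tfs, n_conditions, seed=ss[2])

    beta_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    edges: dict[tuple[int, int], float] = {}
    for g, placed in positions.items():
        for (t, _start) in placed:
            mag = beta_rng.uniform(1.0, 2.0)
            sign = 1.0 if beta_rng.random() < 0.5 else -1.0
            edges[(t, g)] = sign * mag
    truth = GroundTruth(edges=edges, motif_positions=positions,
                        noise_sd=noise_sd, seed=seed, motifs=motifs)
    z = generate_expression(truth, tf_expr, list(promoters))
    dataset = ModelDataset(zscores=z, promoters=promoters, tf_expression=tf_expr)
    return dataset, truth


def save_truth(truth: GroundTruth, dataset: ModelDataset,
               outdir: str | Path) -> None:
    """Write ground-truth sidecar files next to a saved dataset:
    ``truth_edges.tsv``, ``truth_positions.tsv`` and ``truth_pwms.meme``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = dataset.gene_ids
    tfs = dataset.tf_ids
    rows = [(tfs[t], genes[g], b) for (t, g), b in sorted(truth.edges.items())]
    pd.DataFrame(rows, columns=["tf", "gene", "beta"]).to_csv(
        outdir / "truth_edges.tsv", sep="\t", index=False)
    prows = [(genes[g], tfs[t], start)
             for g, placed in sorted(truth.motif_positions.items())
             for (t, start) in placed]
    pd.DataFrame(prows, columns=["gene", "tf", "start"]).to_csv(
        outdir / "truth_positions.tsv", sep="\t", index=False)
    from .motifs import export_meme
    export_meme([(f"planted_{tfs[m.tf_index]}", m.pwm, 1)
                 for m in truth.motifs], outdir / "truth_pwms.meme")
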