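"""Distilling first-layer convolutional kernels into sequence motifs.

Each first-layer kernel is a 5 x 9 filter scanned across every promoter;
its post-ReLU feature map records how strongly each 9-bp window excites
the kernel. The motif a kernel has learned is summarized by aggregating
the one-hot windows under the top 0.5% of activations, each window
weighted by its own activation value:

    T[j, k] = sum over selected (promoter i, position p) of
              F[i, p] * onehot_i[j, p + k],     k = 0..8,
    M[j, k] = T[j, k] / sum_j T[j, k],

giving a column-stochastic position-specific weight matrix (PSWM).
Positional activation profiles (where along the promoter the top
activations fall, smoothed with a 15-bp moving average) reveal
TSS-proximity preferences; motifs are exported in MEME minimal format
for external comparison tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FunProse


@dataclass
class MotifPSWM:
    """Weighted-count matrix T (5 x w), its column-normalized PSWM M,
    the kernel index and the number of windows aggregated."""
    T: np.ndarray
    M: np.ndarray
    kernel: int
    n_windows: int


def compute_feature_maps(model: FunProse, onehots: np.ndarray,
                         batch_size: int = 64) -> np.ndarray:
    """Post-ReLU first-layer activations for every promoter.

    ``onehots``: (N, 5, L) deduplicated one-hot promoters. Returns
    (n_kernels, N, L - klen + 1).
    """
    onehots = np.asarray(onehots)
    if onehots.shape[2] != model.config.promoter_length:
        raise ValueError(
            f"promoter length {onehots.shape[2]} != configured "
            f"{model.config.promoter_length}")
    kernels, bias = model.conv1_kernels()
    K, _, klen = kernels.shape
    wflat = kernels.reshape(K, 5 * klen).T  # channel-major, matches im2col
    N, _, L = onehots.shape
    lout = L - klen + 1
    maps = np.empty((K, N, lout), dtype=np.float32)
    for i in range(0, N, batch_size):
        xcol = np.stack([FunProse.promoter_to_col(p, klen)
                         for p in onehots[i:i + batch_size]])
        act = xcol @ wflat + bias  # (b, lout, K)
        np.maximum(act, 0.0, out=act)
        maps[:, i:i + act.shape[0], :] = act.transpose(2, 0, 1)
    return maps


def _top_activations(F_x: np.ndarray, top_frac: float):
    """Indices (promoter, position) and values of the top fraction of
    activations, strictly positive only; ties at the threshold break by
    (promoter, position) lexicographic order."""
    n_sel = math.ceil(top_frac * F_x.size)
    i_idx, k_idx = np.nonzero(F_x > 0)
    if i_idx.size == 0:
        return None
    vals = F_x[i_idx, k_idx]
    order = np.lexsort((k_idx, i_idx, -vals))
    take = order[:min(n_sel, len(order))]
    return i_idx[take], k_idx[take], vals[take]


def extract_motif_pswm(F_x: np.ndarray, onehots: np.ndarray, kernel: int = 0,
                       top_frac: float = 0.005, width: int = 9,
                       ) -> MotifPSWM | None:
    """PSWM from one kernel's feature map; ``None`` flags an inactive
    kernel (no positive activation anywhere)."""
    sel = _top_activations(np.asarray(F_x), top_frac)
    if sel is None:
        return None
    i_sel, k_sel, w = sel
    # windows: (n_sel, 5, width) gathered at each selected activation
    offs = k_sel[:, None] + np.arange(width)[None, :]
    windows = np.asarray(onehots, dtype=np.float64)[
        i_sel[:, None, None], np.arange(5)[None, :, None], offs[:, None, :]]
    T = np.einsum("n,njk->jk", w.astype(np.float64), windows)
    colsum = T.sum(axis=0, keepdims=True)
    M = np.divide(T, colsum, out=np.full_like(T, 1.0 / 5), where=colsum > 0)
    return MotifPSWM(T=T, M=M, kernel=kernel, n_windows=len(w))


def extract_all_pswms(model: FunProse, onehots: np.ndarray,
                      top_frac: float = 0.005) -> list[MotifPSWM | None]:
    maps = compute_feature_maps(model, onehots)
    return [extract_motif_pswm(maps[x], onehots, kernel=x, top_frac=top_frac,
                               width=model.config.conv1_len)
            for x in range(maps.shape[0])]


def positional_profile(F_x: np.ndarray, top_frac: float = 0.005,
                       window: int = 15) -> np.ndarray:
    """Per-position count of top activations across promoters, smoothed
    by a centered moving average that shrinks at the edges. Inactive
    kernels yield an all-zero profile."""
    F_x = np.asarray(F_x)
    counts = np.zeros(F_x.shape[1], dtype=float)
    sel = _top_activations(F_x, top_frac)
    if sel is not None:
        np.add.at(counts, sel[1], 1.0)
    return (pd.Series(counts)
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


def sort_by_tss_activation(profiles: np.ndarray,
                           tss_window: int = 300) -> np.ndarray:
    """Kernel order by descending mean profile value over the
    ``tss_window`` positions nearest the start codon (the 3' end of the
    promoter, i.e. the last profile entries)."""
    profiles = np.atleast_2d(np.asarray(profiles))
    scores = profiles[:, -tss_window:].mean(axis=1)
    return np.argsort(-scores, kind="stable")


# -- MEME minimal format --------------------------------------------------

def _acgt_matrix(M: np.ndarray) -> np.ndarray:
    """Drop the N row (if present) and renormalize columns over ACGT."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] == 5:
        M = M[:4]
    colsum = M.sum(axis=0, keepdims=True)
    return np.divide(M, colsum, out=np.full_like(M, 0.25), where=colsum > 0)


def export_meme(pswms, path: str | Path) -> None:
    """Write motifs in MEME minimal format (alphabet ACGT).

    ``pswms`` is a list of :class:`MotifPSWM` or ``(name, matrix,
    nsites)`` tuples with column-stochastic 4- or 5-row matrices.
    """
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "Background letter frequencies",
             "A 0.25000 C 0.25000 G 0.25000 T 0.25000", ""]
    for item in pswms:
        if item is None:
            continue
        if isinstance(item, MotifPSWM):
            name, mat, nsites = f"kernel_{item.kernel}", item.M, item.n_windows
        else:
            name, mat, nsites = item
        mat = np.asarray(mat, dtype=float)
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"motif {name}: columns are not stochastic")
        mat = _acgt_matrix(mat)
        w = mat.shape[1]
        lines.append(f"MOTIF {name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {w} "
                     f"nsites= {nsites} E= 0")
        for k in range(w):
            lines.append(" " + " ".join(f"{mat[j, k]:.6f}" for j in range(4)))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[tuple[str, np.ndarray, int]]:
    """Read a MEME minimal file back into (name, 4 x w matrix, nsites)."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    nsites = 0

    def _flush():
        if name is not None and rows:
            motifs.append((name, np.array(rows).T, nsites))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            _flush()
            name = line.split()[1]
            rows, nsites = [], 0
        elif line.startswith("letter-probability"):
            toks = line.split()
            if "nsites=" in toks:
                nsites = int(float(toks[toks.index("nsites=") + 1]))
        elif name is not None and line and line.lstrip("-")[0].isdigit():
            rows.append([float(v) for v in line.split()])
    _flush()
    return motifs


# -- matching extracted motifs against known PWMs -------------------------

def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def pwm_match_score(extracted: np.ndarray, reference: np.ndarray,
                    max_offset: int = 2) -> float:
    """Mean per-column Pearson correlation between two column-stochastic
    PWMs, maximized over relative offsets in [-max_offset, max_offset]
    and the reference's reverse complement."""
    a = _acgt_matrix(extracted)
    best = -1.0
    for ref in (np.asarray(reference, float), _revcomp_pwm(np.asarray(reference, float))):
        for off in range(-max_offset, max_offset + 1):
            lo_a, lo_b = max(0, off), max(0, -off)
            n = min(a.shape[1] - lo_a, ref.shape[1] - lo_b)
            if n < 3:
                continue
            cols_a = a[:, lo_a:lo_a + n]
            cols_b = ref[:, lo_b:lo_b + n]
            rs = []
            for k in range(n):
                x, y = cols_a[:, k], cols_b[:, k]
                sx, sy = x.std(), y.std()
                rs.append(0.0 if sx == 0 or sy == 0
                          else float(np.corrcoef(x, y)[0, 1]))
            best = max(best, float(np.mean(rs)))
    return best


def best_matches(pswms: list[MotifPSWM | None],
                 references: list[np.ndarray]) -> list[tuple[int, float]]:
    """For each reference PWM, the best-matching extracted kernel and its
    match score; (-1, -1.0) when no kernel is active."""
    out = []
    for ref in references:
        best_k, best_s = -1, -1.0
        for p in pswms:
            if p is None:
                continue
            s = pwm_match_score(p.M, ref)
            if s > best_s:
                best_k, best_s = p.kernel, s
        out.append((best_k, best_s))
    return out
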