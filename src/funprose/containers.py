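"""In-memory containers and the on-disk dataset-directory format.

A model-ready dataset couples three aligned pieces: a genes x conditions
matrix of per-gene expression z-scores (the prediction target), a promoter
sequence per gene (exactly ``promoter_length`` bases over A/C/G/T/N), and
a TFs x conditions matrix of TF expression z-scores (the condition
representation). The on-disk layout is plain text: ``zscores.tsv``,
``tf_expression.tsv``, ``promoters.fasta`` (plus ``utr.fasta`` when
present) and a ``dataset.json`` manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROMOTER_ALPHABET = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(PROMOTER_ALPHABET)}


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a 5 x len(seq) binary matrix
    (channel order A, C, G, T, N; lowercase accepted)."""
    seq = seq.upper()
    bad = [i for i, b in enumerate(seq) if b not in _BASE_INDEX]
    if bad:
        shown = ", ".join(f"{i}:{seq[i]!r}" for i in bad[:10])
        raise ValueError(f"sequence contains non-ACGTN characters at {shown}"
                         + (" ..." if len(bad) > 10 else ""))
    mat = np.zeros((5, len(seq)), dtype=np.uint8)
    idx = np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    mat[idx, np.arange(len(seq))] = 1
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != 5 or not np.all(mat.sum(axis=0) == 1):
        raise ValueError("not a valid one-hot matrix (5 x L, column sums 1)")
    return "".join(PROMOTER_ALPHABET[i] for i in mat.argmax(axis=0))


def write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


@dataclass
class ModelDataset:
    """Aligned z-score targets, promoter sequences and TF inputs.

    ``zscores``: genes x conditions DataFrame; ``promoters``: gene id ->
    promoter string; ``tf_expression``: TFs x conditions DataFrame on the
    same condition axis; ``utr``: optional gene id -> 3'UTR string.
    """

    zscores: pd.DataFrame
    promoters: dict[str, str]
    tf_expression: pd.DataFrame
    utr: dict[str, str] | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        genes = list(self.zscores.index)
        if set(genes) != set(self.promoters):
            raise ValueError("gene sets of zscores and promoters differ")
        if list(self.tf_expression.columns) != list(self.zscores.columns):
            raise ValueError("condition axes of zscores and tf_expression differ")
        lengths = {len(s) for s in self.promoters.values()}
        if len(lengths) > 1:
            raise ValueError(f"promoters have mixed lengths {sorted(lengths)}")
        if self.utr is not None and set(self.utr) != set(genes):
            raise ValueError("gene sets of zscores and utr differ")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.zscores.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.zscores.columns)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.tf_expression.index)

    @property
    def promoter_length(self) -> int:
        return len(next(iter(self.promoters.values())))

    def onehot_promoters(self, which: str = "promoter") -> np.ndarray:
        """One-hot stack ``(n_genes, 5, L)`` in zscores gene order."""
        source = self.promoters if which == "promoter" else self.utr
        if source is None:
            raise ValueError("dataset has no 3'UTR sequences")
        return np.stack([one_hot_encode(source[g]) for g in self.gene_ids])

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.zscores.to_csv(outdir / "zscores.tsv", sep="\t",
                            index_label="gene_id", float_format="%.10g")
        self.tf_expression.to_csv(outdir / "tf_expression.tsv", sep="\t",
                                  index_label="tf_id", float_format="%.10g")
        write_fasta({g: self.promoters[g] for g in self.gene_ids},
                    outdir / "promoters.fasta")
        if self.utr is not None:
            write_fasta({g: self.utr[g] for g in self.gene_ids},
                        outdir / "utr.fasta")
        manifest = {
            "n_genes": len(self.gene_ids),
            "n_conditions": len(self.condition_ids),
            "n_tfs": len(self.tf_ids),
            "promoter_length": self.promoter_length,
            "has_utr": self.utr is not None,
        }
        (outdir / "dataset.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "ModelDataset":
        indir = Path(indir)
        z = pd.read_csv(indir / "zscores.tsv", sep="\t", index_col="gene_id")
        tf = pd.read_csv(indir / "tf_expression.tsv", sep="\t", index_col="tf_id")
        promoters = read_fasta(indir / "promoters.fasta")
        utr = None
        if (indir / "utr.fasta").exists():
            utr = read_fasta(indir / "utr.fasta")
        return cls(zscores=z, promoters=promoters, tf_expression=tf, utr=utr)


def assemble_dataset(zscores: pd.DataFrame, promoters: dict[str, str],
                     tf_expression: pd.DataFrame,
                     utr: dict[str, str] | None = None) -> ModelDataset:
    """Intersect the gene sets of targets and promoters and build the
    aligned dataset; genes present in only one source are dropped with a
    warning, an empty intersection is an error."""
    genes = [g for g in zscores.index if g in promoters]
    if not genes:
        raise ValueError("no genes shared between z-score matrix and promoters")
    n_dropped = (len(zscores.index) - len(genes)) + (len(promoters) - len(genes))
    if n_dropped:
        warnings.warn(f"assemble_dataset: dropped {n_dropped} gene entries "
                      "absent from the other source")
    utr_sub = None
    if utr is not None:
        genes = [g for g in genes if g in utr]
        utr_sub = {g: utr[g] for g in genes}
    return ModelDataset(zscores=zscores.loc[genes],
                        promoters={g: promoters[g] for g in genes},
                        tf_expression=tf_expression, utr=utr_sub)
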