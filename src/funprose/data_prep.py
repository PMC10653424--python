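"""Raw data to model-ready dataset: replicate averaging, expression
filters, log + per-gene z-scoring, promoter extraction and TF selection.

The preprocessing pipeline mirrors the published order: FPKM tables are
replicate-averaged per condition, genes with mean expression < 0.05 or
coefficient of variation < 0.3 are removed, the remainder is
log-transformed (natural log, pseudocount 1 by default) and z-scored per
gene across conditions. Promoters are the 1000 bases immediately upstream
of the annotated start codon (5'UTR included), reverse-complemented for
minus-strand genes; genes with less than 1000 bp of upstream sequence are
dropped and reported.

All statistics here use the population formula (ddof = 0); the z-score
invariant (per-gene mean 0, sd 1) is stated against that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (ModelDataset, assemble_dataset, one_hot_encode,
                         one_hot_decode)

__all__ = [
    "average_replicates", "filter_genes", "log_zscore", "extract_promoters",
    "one_hot_encode", "one_hot_decode", "select_tf_expression",
    "assemble_dataset", "read_annotation", "read_expression",
    "read_replicate_map", "read_tf_list", "prep",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes are downgraded to N (the model has an explicit
# unknown channel) rather than rejected.
_IUPAC = set("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def average_replicates(expr: pd.DataFrame,
                       replicate_map: dict[str, str]) -> pd.DataFrame:
    """Collapse replicate columns to one column per condition by the
    arithmetic mean; condition order follows first appearance among the
    samples, gene order is preserved."""
    missing = [s for s in expr.columns if s not in replicate_map]
    if missing:
        raise KeyError(f"samples with no condition mapping: {missing}")
    order: list[str] = []
    for s in expr.columns:
        c = replicate_map[s]
        if c not in order:
            order.append(c)
    cols = {c: expr.loc[:, [s for s in expr.columns
                            if replicate_map[s] == c]].mean(axis=1)
            for c in order}
    return pd.DataFrame(cols, index=expr.index)[order]


def filter_genes(expr: pd.DataFrame, mean_min: float = 0.05,
                 cv_min: float = 0.3) -> pd.DataFrame:
    """Keep genes with row mean >= ``mean_min`` and coefficient of
    variation (sd/mean, ddof=0) >= ``cv_min``; order preserved."""
    if expr.shape[1] < 1:
        raise ValueError("expression matrix has no condition columns")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = (mean >= mean_min) & (cv >= cv_min)
    out = expr.loc[keep]
    if out.empty:
        warnings.warn("filter_genes removed every gene")
    return out


def log_zscore(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene z-score of log(x + pseudocount) across conditions.

    The log base is immaterial (z-scoring is affine-invariant); natural
    log is used. Genes with zero variance raise an error pointing at the
    CV filter.
    """
    logged = np.log(expr.to_numpy(dtype=float) + pseudocount)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        ids = list(expr.index[zero[:5]])
        raise ValueError(
            f"genes with zero log-expression variance (e.g. {ids}); apply "
            "the CV filter (filter_genes) before z-scoring")
    return pd.DataFrame((logged - mean) / sd, index=expr.index,
                        columns=expr.columns)


@dataclass
class GeneRecord:
    """Minimal annotation record: 1-based start-codon position on the
    contig's forward strand (for minus-strand genes this is the position
    of the codon's last base, i.e. the gene's rightmost coordinate)."""
    gene_id: str
    contig: str
    strand: str
    start_codon_pos: int


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read gene records from GFF3 (seqid, strand, CDS/gene span) or a
    4-column TSV fallback (gene_id, contig, strand, start_codon_pos_1based).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, "
                                 f"got {len(parts)}")
            gid, contig, strand, pos = parts
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: bad strand {strand!r} "
                                 f"for record {gid}")
            recs.append(GeneRecord(gid, contig, strand, int(pos)))
    return recs


def _read_gff3(path: Path) -> list[GeneRecord]:
    """Start codons from GFF3 (via gffutils): the 5'-most CDS bound per
    gene when CDS features exist, else the gene feature's 5' bound."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", merge_strategy="merge",
                            keep_order=True)

    def _gid(feat):
        attrs = feat.attributes
        for key in ("gene_id", "Parent", "ID", "Name"):
            if key in attrs:
                return attrs[key][0]
        raise ValueError(f"{path}: {feat.featuretype} record at "
                         f"{feat.seqid}:{feat.start} without an identifier")

    cds: dict[str, GeneRecord] = {}
    genes: dict[str, GeneRecord] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        if feat.strand not in "+-":
            raise ValueError(f"{path}: record {_gid(feat)} has no strand")
        gid = _gid(feat)
        pos = feat.start if feat.strand == "+" else feat.end
        rec = GeneRecord(gid, feat.seqid, feat.strand, pos)
        book = cds if feat.featuretype == "CDS" else genes
        prev = book.get(gid)
        if prev is None:
            book[gid] = rec
        elif (feat.strand == "+" and pos < prev.start_codon_pos) or \
             (feat.strand == "-" and pos > prev.start_codon_pos):
            book[gid] = rec  # keep the 5'-most bound of split CDS segments
    merged = dict(genes)
    merged.update(cds)  # CDS-derived positions win over gene spans
    return list(merged.values())


def extract_promoters(genome: str | Path | dict[str, str],
                      annotation: list[GeneRecord] | str | Path,
                      length: int = 1000) -> tuple[dict[str, str], list[str]]:
    """Extract the ``length`` bases immediately upstream of each start
    codon, 5'->3' relative to the gene.

    Returns ``(promoters, dropped)`` where ``dropped`` lists genes with
    fewer than ``length`` bases of upstream sequence. ``genome`` may be a
    FASTA path (read via pyfaidx) or an in-memory contig dict.
    """
    if isinstance(annotation, (str, Path)):
        annotation = read_annotation(annotation)
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta
        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = {k: v.upper() for k, v in genome.items()}

    promoters: dict[str, str] = {}
    dropped: list[str] = []
    n_iupac = 0
    for rec in annotation:
        if rec.contig not in contigs:
            raise KeyError(f"contig {rec.contig!r} (gene {rec.gene_id}) "
                           "not found in genome")
        seq = contigs[rec.contig]
        s = rec.start_codon_pos
        if not 1 <= s <= len(seq):
            raise ValueError(f"gene {rec.gene_id}: start-codon position {s} "
                             f"outside contig {rec.contig} (1..{len(seq)})")
        if rec.strand == "+":
            if s - 1 < length:
                dropped.append(rec.gene_id)
                continue
            prom = seq[s - 1 - length:s - 1]
        else:
            if len(seq) - s < length:
                dropped.append(rec.gene_id)
                continue
            prom = reverse_complement(seq[s:s + length])
        cleaned = []
        for b in prom:
            if b in "ACGTN":
                cleaned.append(b)
            elif b in _IUPAC:
                cleaned.append("N")
                n_iupac += 1
            else:
                raise ValueError(f"gene {rec.gene_id}: invalid base {b!r} "
                                 "in genome sequence")
        promoters[rec.gene_id] = "".join(cleaned)
    if n_iupac:
        warnings.warn(f"mapped {n_iupac} IUPAC ambiguity bases to N")
    return promoters, dropped


def select_tf_expression(z: pd.DataFrame, tf_ids: list[str]) -> pd.DataFrame:
    """Row-subset of the z-score matrix restricted to the TF identifiers,
    in the given order; absent TFs are dropped with a warning."""
    present = [t for t in tf_ids if t in z.index]
    missing = [t for t in tf_ids if t not in z.index]
    if not present:
        raise ValueError("none of the TF ids are present in the z-score matrix")
    if missing:
        warnings.warn(f"{len(missing)} TF ids absent from the expression "
                      f"matrix and dropped (e.g. {missing[:5]})")
    return z.loc[present]


# -- file readers ---------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dup}")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression table contains negative values")
    return expr


def read_replicate_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["condition"]))


def read_tf_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def prep(genome, annotation, expression, replicates, tfs,
         promoter_length: int = 1000, mean_min: float = 0.05,
         cv_min: float = 0.3, pseudocount: float = 1.0,
         ) -> tuple[ModelDataset, list[str]]:
    """Full preprocessing pipeline from file paths to a ModelDataset.

    Order: replicate-average FPKM -> expression filters -> log + z-score
    -> promoter extraction -> TF selection -> gene-set intersection.
    Returns the dataset and the list of genes dropped for short promoters.
    """
    expr = read_expression(expression)
    expr = average_replicates(expr, read_replicate_map(replicates))
    expr = filter_genes(expr, mean_min=mean_min, cv_min=cv_min)
    z = log_zscore(expr, pseudocount=pseudocount)
    promoters, dropped = extract_promoters(genome, annotation,
                                           length=promoter_length)
    tf_expr = select_tf_expression(z, read_tf_list(tfs))
    dataset = assemble_dataset(z, promoters, tf_expr)
    return dataset, dropped
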