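"""FPKM computation, housekeeping-coefficient normalisation, fold change.

Normalised FPKM follows a two-step scheme: standard FPKM
(counts / (gene length in kb x mapped reads in millions)) followed by a
per-sample correction coefficient derived from a designated housekeeping-gene
set. The coefficient is the reciprocal of the median, over housekeeping
genes, of each gene's FPKM ratio to its cross-sample geometric mean — a
median-of-ratios construction restricted to the stable gene set, which makes
the normalised values invariant to any per-sample scalar distortion left
after depth normalisation.

Fold changes between sample groups use size factors computed by the
median-of-ratios over all genes (the DESeq-style size factor), with a small
pseudocount for zero-safe ratios. Differential-expression testing is out of
scope; only point fold changes are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ExpressionTable",
    "fpkm",
    "housekeeping_coefficients",
    "fold_change",
    "size_factors",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionTable:
    """Gene-by-sample counts with gene annotation and derived matrices.

    ``counts``: DataFrame (genes x samples); ``gene_lengths`` in bp;
    ``is_housekeeping`` flags the stable normalisation set; ``groups`` maps
    sample id -> group label. ``fpkm_values``, ``coefficients`` and
    ``normalized_fpkm`` are filled by the pipeline functions.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    is_housekeeping: pd.Series
    groups: pd.Series | None = None
    fpkm_values: pd.DataFrame | None = None
    coefficients: pd.Series | None = None
    normalized_fpkm: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.gene_lengths.index.equals(self.counts.index):
            raise ConfigurationError("gene_lengths index mismatch")
        if not self.is_housekeeping.index.equals(self.counts.index):
            raise ConfigurationError("is_housekeeping index mismatch")
        if (self.gene_lengths <= 0).any():
            raise ConfigurationError("gene lengths must be > 0")
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts must be >= 0")


def fpkm(table: ExpressionTable,
         library_sizes: pd.Series | None = None) -> ExpressionTable:
    """Compute FPKM: counts / (length_kb * mapped_millions).

    ``library_sizes`` defaults to per-sample total counts; zero or negative
    sizes are an error.
    """
    if library_sizes is None:
        library_sizes = table.counts.sum(axis=0)
    library_sizes = library_sizes.reindex(table.counts.columns)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ConfigurationError(f"zero library size for samples {bad}")
    len_kb = table.gene_lengths / 1_000.0
    mapped_m = library_sizes / 1e6
    table.fpkm_values = table.counts.div(len_kb, axis=0).div(mapped_m, axis=1)
    return table


def housekeeping_coefficients(table: ExpressionTable) -> ExpressionTable:
    """Per-sample correction coefficients from the housekeeping set.

    coefficient[s] = 1 / median over housekeeping genes g of
    (FPKM[g, s] / geometric mean over samples of FPKM[g, .]).
    Housekeeping genes with a zero FPKM in any sample are dropped from the
    median (their geometric mean is zero or undefined); a sample in which
    every housekeeping gene is zero is an error naming the sample.
    Normalised FPKM = FPKM x coefficient.
    """
    if table.fpkm_values is None:
        fpkm(table)
    if not table.is_housekeeping.any():
        raise ConfigurationError("housekeeping set is empty")
    hk = table.fpkm_values.loc[table.is_housekeeping]
    zero_samples = hk.columns[(hk <= 0).all(axis=0)]
    if len(zero_samples):
        raise ConfigurationError(
            "all housekeeping genes are zero in sample(s) "
            f"{list(zero_samples)}")
    usable = hk[(hk > 0).all(axis=1)]
    if usable.empty:
        raise ConfigurationError(
            "no housekeeping gene is expressed in every sample")
    geomean = np.exp(np.log(usable).mean(axis=1))
    ratios = usable.div(geomean, axis=0)
    table.coefficients = 1.0 / ratios.median(axis=0)
    table.normalized_fpkm = table.fpkm_values.mul(table.coefficients, axis=1)
    return table


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over all genes (DESeq convention).

    Genes with any zero count are excluded from the reference geometric mean.
    """
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ConfigurationError(
            "no gene has nonzero counts in every sample; cannot compute "
            "size factors")
    log_geomean = np.log(pos).mean(axis=1)
    sf = np.exp(np.log(pos).sub(log_geomean, axis=0).median(axis=0))
    return sf


def fold_change(table: ExpressionTable, gene: str, group_a, group_b,
                pseudocount: float = 1.0) -> float:
    """Size-factor-normalised fold change of one gene between two groups.

    Groups are given as sample-id lists or as group labels resolved through
    ``table.groups``. The pseudocount is added to raw counts before
    normalisation so zero counts yield finite ratios.
    """
    if gene not in table.counts.index:
        raise ConfigurationError(f"gene {gene!r} absent from the table")

    def resolve(g):
        if isinstance(g, (list, tuple, pd.Index, np.ndarray)):
            return list(g)
        if table.groups is None:
            raise ConfigurationError(
                "group labels requested but the table has no groups")
        samples = table.groups.index[table.groups == g].tolist()
        return samples

    a = resolve(group_a)
    b = resolve(group_b)
    if not a or not b:
        raise ConfigurationError("both groups must be non-empty")
    sf = size_factors(table.counts)
    norm = (table.counts + pseudocount).div(sf, axis=1)
    return float(norm.loc[gene, a].mean() / norm.loc[gene, b].mean())


# ---------------------------------------------------------------------------
# TSV interchange: genes x samples with length and #housekeeping columns

def write_expression_tsv(table: ExpressionTable, path,
                         matrix: str = "counts") -> None:
    df = getattr(table, matrix if matrix != "counts" else "counts")
    if matrix == "normalized":
        df = table.normalized_fpkm
    if df is None:
        raise ConfigurationError(f"matrix {matrix!r} has not been computed")
    out = pd.DataFrame({
        "gene_id": df.index,
        "length": table.gene_lengths.values,
        "#housekeeping": table.is_housekeeping.astype(int).values,
    }).set_index("gene_id")
    out = pd.concat([out, df], axis=1)
    out.to_csv(path, sep="\t")


def read_expression_tsv(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("length", "#housekeeping"):
        if col not in df.columns:
            raise ConfigurationError(f"expression TSV lacks the {col!r} column")
    lengths = df.pop("length")
    hk = df.pop("#housekeeping").astype(bool)
    return ExpressionTable(counts=df, gene_lengths=lengths, is_housekeeping=hk)
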