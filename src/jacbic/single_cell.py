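"""Single-cell adaptation of the percentile-set biclustering pipeline.

UMI counts are first stripped of near-universally-zero genes, then
transformed to analytic Pearson residuals

    Z_cg = (X_cg - mu_cg) / sqrt(mu_cg + mu_cg^2 / theta)

where mu_cg = (gene g total / grand total) * cell c total is the
expected count of gene *g* in cell *c* under a null in which every cell
has the same composition and differs only in depth, and ``theta`` is the
negative-binomial dispersion of that null (default 100).  Residuals are
not clipped.  The residual matrix is then fed to the bulk biclustering
engine (genes x cells, direction "high"); biclusters pick out programs
of genes co-elevated in a common subset of cells.

A rank-based per-cell signature score summarizes the expression of a
bicluster's gene set in every cell; it is the set-mean of per-gene sample
ranks, centred so the population mean is zero, and is invariant to any
monotone per-gene transform of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .biclustering_core import Bicluster, bicluster_expression
from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "ResidualMatrix",
    "filter_sparse_genes",
    "pearson_residuals",
    "variance_shortlist",
    "sc_bicluster",
    "signature_score",
]


@dataclass
class ResidualMatrix:
    """Pearson residuals of a UMI matrix against the depth x abundance null.

    ``Z`` and ``mu`` are cells x genes; ``source`` is the UMI matrix the
    residuals were computed from (genes x cells orientation, as loaded).
    Row sums of ``mu`` reproduce observed cell totals exactly.
    """

    Z: np.ndarray
    theta: float
    mu: np.ndarray
    source: ExpressionMatrix

    @property
    def cell_ids(self) -> list[str]:
        return self.source.sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.source.gene_ids

    def to_expression(self) -> ExpressionMatrix:
        """Residuals as a genes x cells ExpressionMatrix (scale='residual')."""
        return ExpressionMatrix(
            list(self.gene_ids), list(self.cell_ids), self.Z.T.copy(), "residual"
        )


def filter_sparse_genes(
    umi: ExpressionMatrix, max_zero_frac: float = 0.975
) -> ExpressionMatrix:
    """Drop genes whose zero-fraction across cells exceeds ``max_zero_frac``.

    The default keeps every gene with nonzero counts in at least 2.5% of
    cells, matching a 2.5% percentile-set size: a gene has to be
    detectable in at least one full percentile set to ever form an edge.
    Removal is *strict* — a gene zero in exactly ``max_zero_frac`` of the
    cells is retained.
    """
    if umi.scale != "umi_count":
        raise ValueError(f"expected umi_count scale, got {umi.scale!r}")
    zero_frac = (umi.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        raise ValueError("all genes removed by the zero-fraction filter")
    kept = [g for g, k in zip(umi.gene_ids, keep) if k]
    return umi.subset_genes(kept)


def pearson_residuals(umi: ExpressionMatrix, theta: float = 100.0) -> ResidualMatrix:
    """Analytic Pearson residuals of UMI counts under an NB(theta) null.

    The expectation factorizes as relative gene abundance times cell
    depth, so mu conserves both margins: row sums equal cell totals and
    column sums equal gene totals, exactly.  Genes with zero total count
    get Z = 0 by convention.  ``theta=inf`` gives the classical Poisson
    Pearson residual (X - mu) / sqrt(mu).
    """
    if umi.scale != "umi_count":
        raise ValueError(f"expected umi_count scale, got {umi.scale!r}")
    if theta <= 0:
        raise ValueError("theta must be positive")
    X = umi.values.T  # cells x genes
    if np.any(X < 0):
        raise ValueError("negative counts")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("grand total of counts must be > 0")
    gene_tot = X.sum(axis=0)
    cell_tot = X.sum(axis=1)
    mu = np.outer(cell_tot, gene_tot) / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(mu + mu * mu / theta)
        Z = np.where(denom > 0, (X - mu) / np.where(denom > 0, denom, 1.0), 0.0)
    return ResidualMatrix(Z=Z, theta=theta, mu=mu, source=umi)


def variance_shortlist(res: ResidualMatrix, ddof: int = 1) -> frozenset[str]:
    """Genes whose residual variance exceeds mean + 1 SD of all variances.

    Per-gene variance of Z across cells (denominator n-1); the threshold
    is strict, so a flat variance profile yields an empty shortlist.
    """
    if res.Z.shape[1] < 2:
        raise ValueError("variance shortlist needs at least 2 genes")
    var = res.Z.var(axis=0, ddof=ddof)
    thr = var.mean() + var.std(ddof=ddof)
    return frozenset(g for g, v in zip(res.gene_ids, var) if v > thr)


def sc_bicluster(
    res: ResidualMatrix,
    p: float = 0.025,
    j_min: float = 0.2,
    min_genes: int = 30,
    min_cells: int = 30,
    sample_frequency_threshold: float = 0.5,
    restrict_to_shortlist: bool = False,
    max_edges: int = 500_000,
) -> list[Bicluster]:
    """Bicluster a residual matrix: top-percentile cell sets, Jaccard graph.

    Delegates to the bulk engine on the residuals transposed to
    genes x cells with ``direction="high"``.  By default the graph is
    built over every gene that survived the zero filter; set
    ``restrict_to_shortlist`` to confine it to the high-variance
    shortlist instead.
    """
    expr = res.to_expression()
    if restrict_to_shortlist:
        shortlist = variance_shortlist(res)
        if not shortlist:
            return []
        expr = expr.subset_genes(sorted(shortlist))
    return bicluster_expression(
        expr,
        p=p,
        direction="high",
        j_min=j_min,
        min_genes=min_genes,
        min_samples=min_cells,
        sample_frequency_threshold=sample_frequency_threshold,
        max_edges=max_edges,
    )


def signature_score(
    expr: ExpressionMatrix | ResidualMatrix, gene_set: GeneSet
) -> dict[str, float]:
    """Rank-based per-sample (per-cell) score for a gene set.

    For each set gene, samples are ranked by expression (average ranks on
    ties); the score is the mean rank over set genes, centred to
    population mean zero.  Higher expression of the set means a higher
    score, and any monotone per-gene transform of the input leaves the
    score unchanged.
    """
    if isinstance(expr, ResidualMatrix):
        expr = expr.to_expression()
    present = [g for g in expr.gene_ids if g in gene_set.genes]
    if not present:
        raise ValueError("no overlap between the gene set and matrix genes")
    sub = expr.subset_genes(present)
    ranks = scipy.stats.rankdata(sub.values, axis=1)  # per-gene ranks across samples
    score = ranks.mean(axis=0)
    score = score - score.mean()
    return {s: float(v) for s, v in zip(expr.sample_ids, score)}
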