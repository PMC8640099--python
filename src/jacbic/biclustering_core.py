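"""Percentile-set / Jaccard-proximity biclustering engine.

The method connects gene pairs whose *percentile sets* — the samples in
which each gene is most highly (or most lowly) expressed — overlap
strongly, measured by the Jaccard index |A∩B|/|A∪B|.  Gene pairs whose
overlap meets a threshold ``j_min`` become edges of an undirected gene
graph; biclusters are read off the graph together with the samples that
recur across the member genes' percentile sets.

Conventions (fixed and deterministic):

* percentile-set size is ``ceil(p * n_samples)``, so sets are never empty;
* ties at the percentile boundary are broken by input sample order;
* an edge exists iff Jaccard >= ``j_min`` (one convention adopted for both
  bulk and single-cell thresholds);
* candidate biclusters are the connected components of the gene graph;
  a component's samples are those present in at least a
  ``sample_frequency_threshold`` fraction of its member genes' sets;
* output is ordered by descending gene count, ties by the
  lexicographically smallest gene id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import CONTINUOUS_SCALES, ExpressionMatrix

__all__ = [
    "PercentileSetIndex",
    "GeneGraph",
    "BiclusterParams",
    "Bicluster",
    "compute_percentile_sets",
    "jaccard_index",
    "build_graph",
    "extract_biclusters",
    "bicluster_expression",
]

DEFAULT_MAX_EDGES = 500_000


@dataclass
class PercentileSetIndex:
    """Per-gene top (or bottom) percentile sample sets.

    Every set has exactly ``ceil(p * n_samples)`` members.
    """

    p: float
    direction: str
    sets: dict[str, frozenset[str]]
    n_samples: int

    @property
    def set_size(self) -> int:
        return math.ceil(self.p * self.n_samples)


@dataclass
class GeneGraph:
    """Undirected gene graph with Jaccard-weighted edges.

    ``edges`` are canonical ``(gene_a, gene_b, jaccard)`` triples with
    ``gene_a < gene_b``; every jaccard lies in ``[j_min, 1]`` and the
    total edge count is strictly below ``max_edges``.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    j_min: float
    max_edges: int = DEFAULT_MAX_EDGES

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="jaccard")
        return g


@dataclass(frozen=True)
class BiclusterParams:
    p: float
    j_min: float
    min_genes: int
    min_samples: int
    sample_frequency_threshold: float = 0.5


@dataclass(frozen=True)
class Bicluster:
    """A gene set co-expressed within a sample set, plus provenance parameters."""

    genes: frozenset[str]
    samples: frozenset[str]
    direction: str
    params: BiclusterParams

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def compute_percentile_sets(
    expr: ExpressionMatrix, p: float, direction: str
) -> PercentileSetIndex:
    """Build the top / bottom percentile sample set for every gene.

    For ``direction="high"`` a gene's set holds the ``ceil(p * N)`` samples
    with the largest expression of that gene; ``"low"`` is symmetric with
    the smallest.  Ties at the boundary are resolved by input sample order
    (earlier columns win), so the result is deterministic.
    """
    if not (0 < p <= 1):
        raise ValueError(f"percentile cutoff p must lie in (0, 1], got {p}")
    if direction not in ("high", "low"):
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    if expr.scale not in CONTINUOUS_SCALES:
        raise ValueError(
            f"percentile sets require a continuous scale, got {expr.scale!r} "
            "(transform UMI counts to residuals first)"
        )
    n = expr.n_samples
    k = math.ceil(p * n)
    values = expr.values if direction == "low" else -expr.values
    # stable mergesort: among equal values the smaller column index comes first
    order = np.argsort(values, axis=1, kind="stable")[:, :k]
    samples = np.asarray(expr.sample_ids, dtype=object)
    sets = {
        gene: frozenset(samples[order[i]])
        for i, gene in enumerate(expr.gene_ids)
    }
    return PercentileSetIndex(p=p, direction=direction, sets=sets, n_samples=n)


def jaccard_index(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """|A∩B| / |A∪B| for two sample sets from the same universe."""
    if not set_a and not set_b:
        raise ValueError("Jaccard index undefined for two empty sets")
    inter = len(set_a & set_b)
    union = len(set_a) + len(set_b) - inter
    return inter / union


def build_graph(
    psi: PercentileSetIndex,
    j_min: float,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> GeneGraph:
    """All-pairs Jaccard graph over the genes of a percentile-set index.

    An edge ``(a, b)`` is present iff ``jaccard_index(sets[a], sets[b]) >=
    j_min`` and carries its Jaccard value.  Computed with a boolean
    membership-matrix product, which is exact integer arithmetic and equals
    the brute-force pairwise computation.  If the edge count reaches
    ``max_edges`` the parameters are too permissive and an error instructs
    raising ``j_min`` (or lowering ``p``).
    """
    if not (0 < j_min <= 1):
        raise ValueError(f"j_min must lie in (0, 1], got {j_min}")
    genes = sorted(psi.sets)
    sample_index = {}
    for s in sorted(set().union(*psi.sets.values())) if psi.sets else []:
        sample_index[s] = len(sample_index)
    membership = np.zeros((len(genes), len(sample_index)), dtype=np.int64)
    for i, g in enumerate(genes):
        for s in psi.sets[g]:
            membership[i, sample_index[s]] = 1
    sizes = membership.sum(axis=1)
    inter = membership @ membership.T
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = jac[iu, ju] >= j_min
    edges = [
        (genes[a], genes[b], float(jac[a, b]))
        for a, b in zip(iu[keep], ju[keep])
    ]
    if len(edges) >= max_edges:
        raise ValueError(
            f"graph has {len(edges)} edges, >= max_edges={max_edges}; "
            "raise j_min or lower the percentile cutoff"
        )
    return GeneGraph(nodes=genes, edges=edges, j_min=j_min, max_edges=max_edges)


def extract_biclusters(
    graph: GeneGraph,
    psi: PercentileSetIndex,
    min_genes: int,
    min_samples: int,
    sample_frequency_threshold: float = 0.5,
) -> list[Bicluster]:
    """Read biclusters off the gene graph.

    Each connected component of the graph is a candidate.  Its sample set
    is every sample occurring in at least ``sample_frequency_threshold``
    of the member genes' percentile sets.  Candidates failing ``min_genes``
    or ``min_samples`` are discarded.  Output order: descending gene
    count, ties by lexicographically smallest gene id.
    """
    if not (0 < sample_frequency_threshold <= 1):
        raise ValueError("sample_frequency_threshold must lie in (0, 1]")
    g = graph.to_networkx()
    params = BiclusterParams(
        p=psi.p,
        j_min=graph.j_min,
        min_genes=min_genes,
        min_samples=min_samples,
        sample_frequency_threshold=sample_frequency_threshold,
    )
    out: list[Bicluster] = []
    for comp in nx.connected_components(g):
        genes = frozenset(comp)
        if len(genes) < min_genes:
            continue
        counts: dict[str, int] = {}
        for gene in genes:
            for s in psi.sets[gene]:
                counts[s] = counts.get(s, 0) + 1
        need = sample_frequency_threshold * len(genes)
        samples = frozenset(s for s, c in counts.items() if c >= need)
        if len(samples) < min_samples:
            continue
        out.append(Bicluster(genes=genes, samples=samples, direction=psi.direction, params=params))
    out.sort(key=lambda b: (-len(b.genes), min(b.genes)))
    return out


def bicluster_expression(
    expr: ExpressionMatrix,
    p: float,
    direction: str,
    j_min: float,
    min_genes: int,
    min_samples: int,
    sample_frequency_threshold: float = 0.5,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> list[Bicluster]:
    """Convenience: percentile sets -> Jaccard graph -> biclusters in one call."""
    psi = compute_percentile_sets(expr, p, direction)
    graph = build_graph(psi, j_min, max_edges)
    return extract_biclusters(graph, psi, min_genes, min_samples, sample_frequency_threshold)
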