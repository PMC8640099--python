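"""Phenotype enrichment of biclusters and the associated exact tests.

Over-representation of a phenotype category within a bicluster's samples
is tested with the one-sided upper-tail hypergeometric probability
P(K >= k_obs) — equivalently a one-sided Fisher's exact test — on the
2x2 table (in bicluster x in category).  One test is run per
(bicluster, category level) pair; Benjamini–Hochberg step-up correction
is applied across the full family and pairs with q below the FDR
threshold are reported.

A two-sided Mann–Whitney U test (exact enumeration at small n, normal
approximation with tie correction otherwise) is provided for comparing
continuous sample-level quantities such as tumor-purity estimates
between bicluster members and non-members.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .biclustering_core import Bicluster
from .io_formats import SampleAnnotation

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "bh_fdr",
    "annotate_biclusters",
    "mann_whitney_u",
]


@dataclass
class EnrichmentResult:
    """One bicluster x category over-representation test.

    ``table`` is the 2x2 count matrix
    [[in-bicluster & in-category, in-bicluster & out],
     [out-bicluster & in-category, out & out]].
    ``q`` is filled in by family-wise BH correction, not per test.
    """

    bicluster_id: str
    category: str
    table: np.ndarray
    odds_ratio: float
    p: float
    q: float | None = None


def hypergeom_enrichment(
    bicluster_samples: set | frozenset,
    category_samples: set | frozenset,
    population: set | frozenset,
    *,
    bicluster_id: str = "",
    category: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test.

    With population size N, category size K and draw size n = |bicluster|,
    p = P(K >= k_obs) for the observed overlap k_obs.  The odds ratio
    comes from the 2x2 table; a Haldane 0.5 continuity correction is used
    only when a cell is zero and only for the reported OR, never for p.
    """
    population = frozenset(population)
    if not population:
        raise ValueError("empty population")
    bicluster_samples = frozenset(bicluster_samples)
    category_samples = frozenset(category_samples)
    if not bicluster_samples <= population or not category_samples <= population:
        raise ValueError("bicluster and category samples must be subsets of the population")
    N = len(population)
    K = len(category_samples)
    n = len(bicluster_samples)
    k = len(bicluster_samples & category_samples)
    a = k
    b = n - k
    c = K - k
    d = N - n - c
    table = np.array([[a, b], [c, d]], dtype=int)
    if K == 0:
        p = 1.0
        odds = 0.0
    else:
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
    return EnrichmentResult(
        bicluster_id=bicluster_id,
        category=category,
        table=table,
        odds_ratio=float(odds),
        p=min(p, 1.0),
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def annotate_biclusters(
    biclusters: list[Bicluster],
    annotations: list[SampleAnnotation],
    fdr_threshold: float = 0.01,
    categories: tuple[str, ...] = ("cohort", "region", "subtype", "idh_codel"),
    population: set | None = None,
) -> pd.DataFrame:
    """Test every bicluster against every phenotype category level.

    The population is every annotated sample (or an explicit override).
    BH correction spans the full (bicluster x category level) family in
    one run.  Returns a tidy frame of all tests with counts, odds ratio,
    p and q, sorted by q, with ``significant = q < fdr_threshold``.
    """
    if population is None:
        population = {a.sample_id for a in annotations}
    population = frozenset(population)
    levels: dict[str, set[str]] = {}
    for a in annotations:
        if a.sample_id not in population:
            continue
        for cat in categories:
            val = getattr(a, cat)
            if val is None:
                continue
            levels.setdefault(f"{cat}={val}", set()).add(a.sample_id)
    results: list[EnrichmentResult] = []
    for i, b in enumerate(biclusters):
        bic_samples = frozenset(b.samples) & population
        bid = f"bicluster_{i}"
        for label, members in sorted(levels.items()):
            results.append(
                hypergeom_enrichment(
                    bic_samples, frozenset(members), population,
                    bicluster_id=bid, category=label,
                )
            )
    if not results:
        return pd.DataFrame(
            columns=["bicluster_id", "category", "k", "n", "K", "N", "odds_ratio", "p", "q", "significant"]
        )
    q = bh_fdr([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    rows = [
        {
            "bicluster_id": r.bicluster_id,
            "category": r.category,
            "k": int(r.table[0, 0]),
            "n": int(r.table[0].sum()),
            "K": int(r.table[:, 0].sum()),
            "N": int(r.table.sum()),
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "q": r.q,
            "significant": r.q < fdr_threshold,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(["q", "p", "bicluster_id", "category"]).reset_index(drop=True)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    For n1 + n2 <= 12 the p-value is computed by exhaustive enumeration of
    all C(n1+n2, n1) group labelings of the pooled values (exact even with
    ties); larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= 12:
        # enumerate every assignment of n1 labels to the pooled values
        mean_u = n1 * n2 / 2.0
        obs_dev = abs(u_x - mean_u)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mean_u) >= obs_dev - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_x), float(min(p, 1.0))
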