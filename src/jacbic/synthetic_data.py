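"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three data modalities:

* :func:`gen_bulk` — log-scale bulk expression with gene-specific
  baselines, Gaussian noise, and planted co-up/down-regulated
  gene x sample blocks, plus phenotype labels aligned with the blocks so
  that enrichment tests have planted truth to find;
* :func:`gen_umi` — negative-binomial UMI counts with log-uniform
  library-size variation and one planted co-expression program confined
  to cells of a single donor spread over a few tumor sites (mirroring a
  donor-private tumor program in multi-region single-cell sampling);
* :func:`gen_survival` — proportional-hazards event times whose
  log-hazard is linear in chosen gene expressions and clinical
  covariates, with independent exponential censoring.  The exponential
  baseline gives closed-form checks (e.g. doubling the baseline rate
  halves the median event time).

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, SampleAnnotation, SurvivalRecord

__all__ = [
    "PlantedBiclusterSpec",
    "SurvivalSimSpec",
    "gen_bulk",
    "gen_umi",
    "gen_survival",
]


@dataclass
class PlantedBiclusterSpec:
    """A block of genes shifted by ±``shift`` within a set of samples."""

    gene_indices: frozenset[int]
    sample_indices: frozenset[int]
    shift: float
    direction: str = "up"

    def __post_init__(self) -> None:
        self.gene_indices = frozenset(int(i) for i in self.gene_indices)
        self.sample_indices = frozenset(int(i) for i in self.sample_indices)
        if not self.gene_indices or not self.sample_indices:
            raise ValueError("planted block must have non-empty gene and sample sets")
        if self.shift <= 0:
            raise ValueError("shift must be positive (use direction='down' for down-shifts)")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class SurvivalSimSpec:
    """Exponential proportional-hazards simulation parameters.

    ``beta_gene`` maps gene id -> log-hazard per unit expression;
    ``beta_covariates`` maps annotation field (``age``, ``grade``,
    ``idh_codel``) -> log-hazard per unit of its numeric encoding
    (grade II/III/IV -> 2/3/4; idh_codel wildtype -> 1, else 0).
    """

    beta_gene: dict[str, float]
    beta_covariates: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 1e-3
    censor_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def _covariate_value(ann: SampleAnnotation, name: str) -> float:
    if name == "age":
        return float(ann.age) if ann.age is not None else 0.0
    if name == "grade":
        return {"II": 2.0, "III": 3.0, "IV": 4.0}.get(ann.grade or "", 0.0)
    if name == "idh_codel":
        return 1.0 if ann.idh_codel == "wildtype" else 0.0
    if name == "cohort":
        return 1.0 if ann.cohort == "tumor" else 0.0
    raise KeyError(f"unknown covariate {name!r}")


def gen_bulk(
    n_genes: int,
    n_samples: int,
    specs: list[PlantedBiclusterSpec],
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_range: tuple[float, float] = (2.0, 8.0),
    tumor_fraction: float = 0.35,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Simulate a log-scale bulk compendium with planted expression blocks.

    Background entries are ``Normal(mu_g, noise_sd)`` around gene-specific
    baselines drawn uniformly from ``baseline_range`` (log2 RSEM-like
    units).  Each planted block adds ``+shift`` (or ``-shift``) to its
    gene x sample rectangle.  The returned annotations emulate a mixed
    normal/tumor compendium: the last ``tumor_fraction`` of samples are
    tumors (alternating LGG grade II–III / GBM grade IV, with IDH status),
    the rest are normals.  Samples of planted block *k* get the region
    label ``region_k`` if normal, so phenotype enrichment of a recovered
    block has a planted truth; unplanted normals are labelled
    ``region_other``.
    """
    rng = np.random.default_rng(seed)
    for k, spec in enumerate(specs):
        if max(spec.gene_indices) >= n_genes or max(spec.sample_indices) >= n_samples:
            raise ValueError(f"planted spec {k} has indices out of range")
    baselines = rng.uniform(*baseline_range, size=n_genes)
    values = rng.normal(baselines[:, None], noise_sd, size=(n_genes, n_samples))
    for spec in specs:
        gi = np.fromiter(spec.gene_indices, dtype=int)
        si = np.fromiter(spec.sample_indices, dtype=int)
        delta = spec.shift if spec.direction == "up" else -spec.shift
        values[np.ix_(gi, si)] += delta

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:05d}" for j in range(n_samples)]
    expr = ExpressionMatrix(gene_ids, sample_ids, values, "log_rsem")

    n_tumor = int(round(tumor_fraction * n_samples))
    first_tumor = n_samples - n_tumor
    block_of: dict[int, int] = {}
    for k, spec in enumerate(specs):
        for j in spec.sample_indices:
            block_of.setdefault(j, k)
    annotations: list[SampleAnnotation] = []
    for j in range(n_samples):
        sid = sample_ids[j]
        if j >= first_tumor:
            gbm = (j - first_tumor) % 2 == 1
            annotations.append(
                SampleAnnotation(
                    sample_id=sid,
                    cohort="tumor",
                    subtype="GBM" if gbm else "LGG",
                    grade="IV" if gbm else ("II" if j % 4 < 2 else "III"),
                    idh_codel="wildtype" if gbm or j % 3 == 0 else "mutant_and_or_codel",
                    age=float(rng.integers(25, 80)),
                )
            )
        else:
            region = f"region_{block_of[j]}" if j in block_of else "region_other"
            annotations.append(SampleAnnotation(sample_id=sid, cohort="normal", region=region))
    return expr, annotations


def gen_umi(
    n_cells: int,
    n_genes: int,
    program: GeneSet | None = None,
    program_cells: frozenset[int] | set[int] | None = None,
    depth_range: tuple[float, float] = (1_000.0, 10_000.0),
    nb_dispersion: float = 100.0,
    rate_multiplier: float = 8.0,
    n_donors: int = 13,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a multi-donor UMI count matrix with one planted program.

    Counts are negative-binomial with dispersion ``nb_dispersion`` (the
    Poisson limit as dispersion -> inf), cell library sizes log-uniform
    over ``depth_range``, and gene abundances log-normal.  Genes of
    ``program`` have their rates multiplied by ``rate_multiplier`` in
    ``program_cells`` only.  Program cells all carry a single donor label
    and are split over three tumor-core sites of that donor; every other
    cell gets a donor drawn from the remaining donors and one of that
    donor's sites.

    Returns the (cells x genes stored as genes x samples) UMI
    ExpressionMatrix with cell barcodes as sample ids, plus a metadata
    frame indexed by barcode with ``donor`` and ``site`` columns.
    """
    rng = np.random.default_rng(seed)
    if program is not None:
        if program_cells is None or len(program_cells) == 0:
            raise ValueError("a planted program requires non-empty program_cells")
        program_cells = frozenset(int(c) for c in program_cells)
        if max(program_cells) >= n_cells:
            raise ValueError("program_cells out of range")
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if program is not None:
        missing = set(program.genes) - set(gene_ids)
        if missing:
            raise ValueError(f"program genes outside gene universe: {sorted(missing)[:5]}")
    barcodes = [f"C{j:05d}" for j in range(n_cells)]

    # lognormal relative abundances, heavy right tail like real transcriptomes
    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    abundance /= abundance.sum()
    lo, hi = depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))

    rates = depths[:, None] * abundance[None, :]  # cells x genes
    prog_idx = None
    if program is not None:
        prog_idx = np.array([gene_ids.index(g) for g in sorted(program.genes)])
        cells_idx = np.fromiter(program_cells, dtype=int)
        rates[np.ix_(cells_idx, prog_idx)] *= rate_multiplier

    if np.isinf(nb_dispersion):
        counts = rng.poisson(rates)
    else:
        if nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        p = nb_dispersion / (nb_dispersion + rates)
        counts = rng.negative_binomial(nb_dispersion, p)

    donors = [f"GS{d + 1:02d}" for d in range(n_donors)]
    program_donor = donors[-1]
    core_sites = ["P4", "P5", "P6"]
    donor_col = np.empty(n_cells, dtype=object)
    site_col = np.empty(n_cells, dtype=object)
    prog_set = program_cells if program is not None else frozenset()
    other_donors = donors[:-1] if program is not None else donors
    for j in range(n_cells):
        if j in prog_set:
            donor_col[j] = program_donor
            site_col[j] = core_sites[j % 3]
        else:
            d = other_donors[j % len(other_donors)]
            donor_col[j] = d
            site_col[j] = f"P{j % 4}"
    meta = pd.DataFrame({"donor": donor_col, "site": site_col}, index=barcodes)

    expr = ExpressionMatrix(gene_ids, barcodes, counts.T.astype(float), "umi_count")
    return expr, meta


def gen_survival(
    expr: ExpressionMatrix,
    annotations: list[SampleAnnotation] | None,
    spec: SurvivalSimSpec,
) -> list[SurvivalRecord]:
    """Draw exponential PH survival times from expression and covariates.

    Event time ~ Exponential(baseline_rate * exp(sum beta * x)); censoring
    time independent Exponential(censor_rate); the record keeps the
    minimum and an event indicator.  ``censor_rate == 0`` means no
    censoring.
    """
    missing = [g for g in spec.beta_gene if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"beta_gene names unknown to the matrix: {missing[:5]}")
    rng = np.random.default_rng(spec.seed)
    gene_rows = {g: expr.gene_ids.index(g) for g in spec.beta_gene}
    lin = np.zeros(expr.n_samples)
    for g, beta in spec.beta_gene.items():
        lin += beta * expr.values[gene_rows[g], :]
    if spec.beta_covariates:
        if annotations is None:
            raise ValueError("beta_covariates requires annotations")
        ann_by_id = {a.sample_id: a for a in annotations}
        for name, beta in spec.beta_covariates.items():
            vals = np.array(
                [_covariate_value(ann_by_id[s], name) for s in expr.sample_ids]
            )
            lin += beta * vals
    rate = spec.baseline_rate * np.exp(lin)
    event_time = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, size=expr.n_samples)
    else:
        censor_time = np.full(expr.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return [
        SurvivalRecord(sid, float(t), bool(e))
        for sid, t, e in zip(expr.sample_ids, time, event)
    ]
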