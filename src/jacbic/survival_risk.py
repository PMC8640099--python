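"""Cilium risk-score construction and survival stratification.

The risk score is built in two stages, mirroring common practice for
expression-based prognostic signatures in glioma:

1. *Feature selection*: an L1-penalized (LASSO, elastic-net mixing
   alpha = 1) Cox proportional-hazards model over candidate gene
   expressions plus clinical covariates (IDH1/2 mutation and/or 1p/19q
   co-deletion status, tumor grade, age).  The penalty weight is chosen
   by cross-validated partial likelihood; the selected features are the
   nonzero coefficients at that penalty.
2. *Coefficient estimation*: each selected gene is refit in a
   *univariate* Cox model, and the univariate coefficients beta_g define
   the linear risk score  score_s = sum_g beta_g * x_gs  (gene terms
   only; clinical covariates are adjustment factors, not score
   components).

Partial likelihoods use Breslow tie handling throughout.  A reference
coefficient set for the 12-gene cilium signature (LRGUK, NSUN7, LRRC27,
SPAG17, EFHB, IFT27, DZIP1L, FOLR1, RGS22, TEX9, GALNT3, GLB1L),
estimated on TCGA glioma overall survival, ships with the package.

Stratification splits scored samples at the median (ties to the lower
group) or contrasts top vs bottom quartile, and compares groups with
Kaplan–Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_formats import ExpressionMatrix, SampleAnnotation, SurvivalRecord

__all__ = [
    "RiskModel",
    "StratificationResult",
    "LassoCoxResult",
    "CoxConvergenceError",
    "fit_univariate_cox",
    "fit_lasso_cox",
    "build_risk_model",
    "compute_risk_score",
    "stratify_and_logrank",
    "load_cilium_risk_model",
    "covariate_frame",
]


class CoxConvergenceError(RuntimeError):
    """Raised when the partial likelihood has no finite maximizer."""


@dataclass
class RiskModel:
    """Selected genes with univariate Cox coefficients, plus covariate terms.

    ``gene_coefficients`` defines the risk score; ``covariate_terms`` are
    the clinical adjustment coefficients and are *excluded* from the
    score.  ``alpha`` is the elastic-net mixing used in selection (1 for
    pure LASSO); ``lambda_`` the penalty at which features were selected.
    """

    gene_coefficients: dict[str, float]
    covariate_terms: dict[str, float] = field(default_factory=dict)
    alpha: float = 1.0
    lambda_: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_coefficients:
            raise ValueError("gene_coefficients must be non-empty")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_coefficients": self.gene_coefficients,
                    "covariate_terms": self.covariate_terms,
                    "alpha": self.alpha,
                    "lambda": self.lambda_,
                },
                indent=1,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_coefficients={str(k): float(v) for k, v in d["gene_coefficients"].items()},
            covariate_terms={str(k): float(v) for k, v in d.get("covariate_terms", {}).items()},
            alpha=float(d.get("alpha", 1.0)),
            lambda_=d.get("lambda"),
        )


def load_cilium_risk_model() -> RiskModel:
    """The bundled 12-gene cilium risk-score coefficient set."""
    ref = resources.files("jacbic").joinpath("data/cilium_risk_model.json")
    d = json.loads(ref.read_text())
    return RiskModel(
        gene_coefficients={str(k): float(v) for k, v in d["gene_coefficients"].items()},
        covariate_terms={str(k): float(v) for k, v in d.get("covariate_terms", {}).items()},
        alpha=float(d.get("alpha", 1.0)),
        lambda_=d.get("lambda"),
    )


@dataclass
class StratificationResult:
    """Kaplan–Meier curves and a two-group log-rank comparison."""

    group_labels: dict[str, str]
    curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float


# ---------------------------------------------------------------------------
# Breslow partial likelihood (univariate Newton fit + multivariate evaluation)
# ---------------------------------------------------------------------------

def _sort_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    return time[order], event[order], order


def breslow_loglik(X: np.ndarray, beta: np.ndarray, time, event) -> float:
    """Breslow-tie Cox log partial likelihood at ``beta`` (no fitting)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time, event, order = _sort_survival(time, event)
    X = X[order]
    eta = X @ np.asarray(beta, dtype=float)
    # risk set of t = all with time >= t: accumulate from the largest time down
    ll = 0.0
    i = len(time) - 1
    s0 = 0.0
    exp_eta = np.exp(eta)
    while i >= 0:
        j = i
        while j >= 0 and time[j] == time[i]:
            j -= 1
        s0 += exp_eta[j + 1 : i + 1].sum()
        deaths = [k for k in range(j + 1, i + 1) if event[k]]
        if deaths:
            ll += eta[deaths].sum() - len(deaths) * np.log(s0)
        i = j
    return float(ll)


def _univariate_derivatives(beta: float, x, time, event):
    """(loglik, gradient, hessian) of the univariate Breslow likelihood."""
    x = np.asarray(x, dtype=float)
    time, event, order = _sort_survival(time, event)
    x = x[order]
    w = np.exp(beta * x)
    ll = grad = hess = 0.0
    s0 = s1 = s2 = 0.0
    i = len(time) - 1
    while i >= 0:
        j = i
        while j >= 0 and time[j] == time[i]:
            j -= 1
        sl = slice(j + 1, i + 1)
        s0 += w[sl].sum()
        s1 += (w[sl] * x[sl]).sum()
        s2 += (w[sl] * x[sl] ** 2).sum()
        d = int(event[sl].sum())
        if d:
            xs = x[sl][event[sl]].sum()
            ll += beta * xs - d * np.log(s0)
            m1 = s1 / s0
            grad += xs - d * m1
            hess -= d * (s2 / s0 - m1 * m1)
        i = j
    return ll, grad, hess


def fit_univariate_cox(
    feature,
    survival: list[SurvivalRecord] | tuple,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Maximum-partial-likelihood estimate for a single covariate.

    Newton–Raphson on the Breslow partial likelihood, iterated to
    ``|delta beta| < tol``.  Returns ``(beta, se)``.  A monotone
    likelihood (perfect separation of event order by the feature) is
    reported as :class:`CoxConvergenceError`, never silently clipped.

    ``survival`` may be a list of :class:`SurvivalRecord` aligned with the
    feature vector, or a ``(time, event)`` pair of arrays.
    """
    x = np.asarray(list(feature), dtype=float)
    if isinstance(survival, tuple):
        time, event = survival
    else:
        time = [r.time for r in survival]
        event = [r.event for r in survival]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(x) != len(time):
        raise ValueError("feature and survival lengths differ")
    if event.sum() == 0:
        raise ValueError("no events observed")
    if np.ptp(x) == 0:
        raise ValueError("constant feature")
    beta = 0.0
    for _ in range(max_iter):
        _, grad, hess = _univariate_derivatives(beta, x, time, event)
        if hess >= -1e-12:
            raise CoxConvergenceError("degenerate Hessian; likelihood is flat")
        step = grad / hess
        beta_new = beta - step
        if abs(beta_new) > 50:
            raise CoxConvergenceError(
                "monotone partial likelihood: estimate diverges (perfect separation)"
            )
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise CoxConvergenceError("Newton iterations did not converge")
    _, _, hess = _univariate_derivatives(beta, x, time, event)
    se = float(np.sqrt(-1.0 / hess))
    return float(beta), se


# ---------------------------------------------------------------------------
# LASSO Cox selection
# ---------------------------------------------------------------------------

@dataclass
class LassoCoxResult:
    selected: list[str]
    coefficients: dict[str, float]
    lambda_: float
    alpha: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray


def covariate_frame(
    annotations: list[SampleAnnotation], sample_ids: list[str]
) -> pd.DataFrame:
    """Numeric clinical covariates aligned to ``sample_ids``.

    Encodings: grade II/III/IV -> 2/3/4 (0 if unknown); idh_wildtype ->
    1/0; age in years (0 if unknown).
    """
    by_id = {a.sample_id: a for a in annotations}
    rows = []
    for s in sample_ids:
        a = by_id.get(s)
        rows.append(
            {
                "grade": {"II": 2.0, "III": 3.0, "IV": 4.0}.get(a.grade if a else None, 0.0),
                "idh_wildtype": 1.0 if (a and a.idh_codel == "wildtype") else 0.0,
                "age": float(a.age) if a and a.age is not None else 0.0,
            }
        )
    return pd.DataFrame(rows, index=sample_ids)


def fit_lasso_cox(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame | None,
    survival: list[SurvivalRecord],
    alpha: float = 1.0,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> LassoCoxResult:
    """L1-penalized Cox feature selection with cross-validated penalty.

    Features are the expression of every gene of ``expr`` (samples with
    survival records only) plus optional covariate columns.  Features are
    standardized internally; reported coefficients are on the original
    scale.  The penalty is chosen by K-fold cross-validated
    partial-likelihood deviance: ``lambda_rule="1se"`` (default) takes
    the sparsest penalty within one standard error of the minimum —
    glmnet's parsimony rule, which keeps false selections low —
    ``"min"`` takes the deviance minimum itself.  Selected features are
    the nonzero coefficients at the chosen penalty.
    """
    if lambda_rule not in ("1se", "min"):
        raise ValueError("lambda_rule must be '1se' or 'min'")
    surv_by_id = {r.sample_id: r for r in survival}
    samples = [s for s in expr.sample_ids if s in surv_by_id]
    if len(samples) < cv_folds:
        raise ValueError("fewer scored samples than CV folds")
    sub = expr.subset_samples(samples)
    feat = pd.DataFrame(sub.values.T, index=samples, columns=sub.gene_ids)
    if covariates is not None:
        feat = feat.join(covariates.loc[samples])
    time = np.array([surv_by_id[s].time for s in samples])
    event = np.array([surv_by_id[s].event for s in samples], dtype=bool)
    if event.sum() == 0:
        raise ValueError("no events observed")
    if len(np.unique(time[event])) < 2:
        raise ValueError("need >= 2 distinct event times")

    const = feat.columns[feat.std(axis=0) == 0]
    if len(const):
        warnings.warn(f"dropping constant feature(s): {list(const)}", stacklevel=2)
        feat = feat.drop(columns=const)
    names = list(feat.columns)
    X = feat.to_numpy(dtype=float)
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - mean) / sd
    y = Surv.from_arrays(event=event, time=time)

    if lambda_grid is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6), n_alphas=50,
                                      alpha_min_ratio=0.01, normalize=False)
        path.fit(Xs, y)
        lambda_grid = np.asarray(path.alphas_)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    n = len(samples)
    fold = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(fold)
    cv_dev = np.zeros((cv_folds, len(lambda_grid)))
    for k in range(cv_folds):
        tr, te = fold != k, fold == k
        if event[te].sum() == 0 or event[tr].sum() == 0:
            cv_dev[k] = np.nan
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6), alphas=lambda_grid,
                                   normalize=False, fit_baseline_model=False)
        m.fit(Xs[tr], Surv.from_arrays(event=event[tr], time=time[tr]))
        for a_i, lam in enumerate(lambda_grid):
            coef = m.coef_[:, np.argmin(np.abs(np.asarray(m.alphas_) - lam))]
            cv_dev[k, a_i] = -2.0 * breslow_loglik(Xs[te], coef, time[te], event[te])
    mean_dev = np.nanmean(cv_dev, axis=0)
    best = int(np.nanargmin(mean_dev))
    if lambda_rule == "1se":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se_dev = np.nanstd(cv_dev, axis=0, ddof=1) / np.sqrt(
                np.sum(~np.isnan(cv_dev), axis=0)
            )
        thresh = mean_dev[best] + se_dev[best]
        # grid is descending, so the first index within 1 SE is the sparsest
        best = next(i for i in range(len(lambda_grid)) if mean_dev[i] <= thresh)
    lam_best = float(lambda_grid[best])

    final = CoxnetSurvivalAnalysis(l1_ratio=max(alpha, 1e-6), alphas=lambda_grid,
                                   normalize=False, fit_baseline_model=False)
    final.fit(Xs, y)
    coef_std = final.coef_[:, np.argmin(np.abs(np.asarray(final.alphas_) - lam_best))]
    coef_orig = coef_std / sd
    coefficients = {nm: float(c) for nm, c in zip(names, coef_orig) if c != 0.0}
    return LassoCoxResult(
        selected=sorted(coefficients),
        coefficients=coefficients,
        lambda_=lam_best,
        alpha=alpha,
        lambda_grid=lambda_grid,
        cv_deviance=mean_dev,
    )


def build_risk_model(
    expr: ExpressionMatrix,
    candidate_genes,
    annotations: list[SampleAnnotation] | None,
    survival: list[SurvivalRecord],
    alpha: float = 1.0,
    cv_folds: int = 10,
    seed: int = 0,
) -> RiskModel:
    """Select genes by LASSO Cox, then refit each univariately.

    The univariate Breslow coefficients of the selected *genes* become
    the score weights; selected clinical covariates are kept as
    adjustment terms only.
    """
    candidate_genes = [g for g in candidate_genes if g in expr.gene_ids]
    if not candidate_genes:
        raise ValueError("no candidate genes present in the matrix")
    sub = expr.subset_genes(candidate_genes)
    cov = covariate_frame(annotations, sub.sample_ids) if annotations else None
    sel = fit_lasso_cox(sub, cov, survival, alpha=alpha, cv_folds=cv_folds, seed=seed)
    surv_by_id = {r.sample_id: r for r in survival}
    samples = [s for s in expr.sample_ids if s in surv_by_id]
    time = np.array([surv_by_id[s].time for s in samples])
    event = np.array([surv_by_id[s].event for s in samples], dtype=bool)
    gene_coefficients: dict[str, float] = {}
    covariate_terms: dict[str, float] = {}
    for name in sel.selected:
        if name in expr.gene_ids:
            x = expr.subset_genes([name]).subset_samples(samples).values[0]
            beta, _ = fit_univariate_cox(x, (time, event))
            gene_coefficients[name] = beta
        else:
            x = cov.loc[samples, name].to_numpy()
            beta, _ = fit_univariate_cox(x, (time, event))
            covariate_terms[name] = beta
    if not gene_coefficients:
        raise ValueError("LASSO selected no genes; cannot build a gene risk score")
    return RiskModel(
        gene_coefficients=gene_coefficients,
        covariate_terms=covariate_terms,
        alpha=alpha,
        lambda_=sel.lambda_,
    )


def compute_risk_score(expr: ExpressionMatrix, model: RiskModel) -> dict[str, float]:
    """score_s = sum_g beta_g * x_gs over the model's genes; no intercept.

    Covariate terms are adjustment factors and never enter the score.
    Missing model genes are an error — no imputation.
    """
    missing = [g for g in model.gene_coefficients if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"model genes absent from matrix: {missing}")
    genes = sorted(model.gene_coefficients)
    sub = expr.subset_genes(genes)
    beta = np.array([model.gene_coefficients[g] for g in genes])
    scores = beta @ sub.values
    return {s: float(v) for s, v in zip(expr.sample_ids, scores)}


def stratify_and_logrank(
    scores: dict[str, float],
    survival: list[SurvivalRecord],
    scheme: str = "median",
    subset=None,
) -> StratificationResult:
    """Split scored samples into risk groups and compare survival.

    ``scheme="median"``: low = score <= median, high = score > median
    (boundary ties to the lower-risk group).  ``scheme="quartiles"``:
    low = bottom quartile (score <= Q1), high = top quartile (score >
    Q3), middle half excluded.  Quantiles are linear-interpolation
    empirical quantiles.  Kaplan–Meier curves and the two-group log-rank
    chi-square are computed on the resulting groups.
    """
    surv_by_id = {r.sample_id: r for r in survival}
    ids = [s for s in scores if s in surv_by_id]
    if subset is not None:
        subset = set(subset)
        ids = [s for s in ids if s in subset]
    if not ids:
        raise ValueError("no scored samples with survival records")
    vals = np.array([scores[s] for s in ids])
    labels: dict[str, str] = {}
    if scheme == "median":
        med = float(np.quantile(vals, 0.5))
        for s, v in zip(ids, vals):
            labels[s] = "low" if v <= med else "high"
    elif scheme == "quartiles":
        q1 = float(np.quantile(vals, 0.25))
        q3 = float(np.quantile(vals, 0.75))
        for s, v in zip(ids, vals):
            if v <= q1:
                labels[s] = "low"
            elif v > q3:
                labels[s] = "high"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    groups = {g: [s for s, lab in labels.items() if lab == g] for g in ("low", "high")}
    for g, members in groups.items():
        if not members:
            raise ValueError(f"risk group {g!r} is empty")
    curves: dict[str, pd.DataFrame] = {}
    for g, members in groups.items():
        t = [surv_by_id[s].time for s in members]
        e = [surv_by_id[s].event for s in members]
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=g)
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        at_risk = [int((np.asarray(t) >= tt).sum()) for tt in df["time"]]
        df["at_risk"] = at_risk
        curves[g] = df
    t_low = [surv_by_id[s].time for s in groups["low"]]
    e_low = [surv_by_id[s].event for s in groups["low"]]
    t_high = [surv_by_id[s].time for s in groups["high"]]
    e_high = [surv_by_id[s].event for s in groups["high"]]
    res = logrank_test(t_low, t_high, event_observed_A=e_low, event_observed_B=e_high)
    return StratificationResult(
        group_labels=labels,
        curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )
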