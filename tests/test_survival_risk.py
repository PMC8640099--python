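import numpy as np
import pytest

from jacbic.io_formats import ExpressionMatrix, SurvivalRecord
from jacbic.survival_risk import (
    CoxConvergenceError,
    RiskModel,
    breslow_loglik,
    build_risk_model,
    compute_risk_score,
    fit_lasso_cox,
    fit_univariate_cox,
    load_cilium_risk_model,
    stratify_and_logrank,
)
from jacbic.synthetic_data import SurvivalSimSpec, gen_survival
from conftest import make_expr


def breslow_loglik_oracle(beta, x, time, event):
    """Independent direct-loop Breslow partial log-likelihood (1 covariate)."""
    ll = 0.0
    for t in sorted({ti for ti, ei in zip(time, event) if ei}):
        deaths = [i for i in range(len(time)) if event[i] and time[i] == t]
        risk = [i for i in range(len(time)) if time[i] >= t]
        ll += beta * sum(x[i] for i in deaths)
        ll -= len(deaths) * np.log(sum(np.exp(beta * x[i]) for i in risk))
    return ll


def grid_maximize(x, time, event, lo=-5.0, hi=5.0):
    """Brute-force maximizer of the oracle likelihood, refined to ~1e-6."""
    for _ in range(4):
        grid = np.linspace(lo, hi, 201)
        lls = [breslow_loglik_oracle(b, x, time, event) for b in grid]
        best = grid[int(np.argmax(lls))]
        span = (hi - lo) / 200
        lo, hi = best - 2 * span, best + 2 * span
    return best


def simulate_cox(n, beta, seed, censor_rate=2e-4):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    expr = make_expr(x[None, :], sample_prefix="s")
    spec = SurvivalSimSpec(beta_gene={"g0": beta}, baseline_rate=1e-3,
                           censor_rate=censor_rate, seed=seed)
    recs = gen_survival(expr, None, spec)
    t = np.array([r.time for r in recs])
    e = np.array([r.event for r in recs])
    return x, t, e, expr, recs


class TestUnivariateCox:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        x = rng.normal(size=n)
        time = np.round(rng.exponential(100, size=n), 0) + 1  # ties likely
        event = rng.uniform(size=n) < 0.7
        if event.sum() < 2:
            event[:2] = True
        beta, _ = fit_univariate_cox(x, (time, event))
        beta_grid = grid_maximize(x, time, event)
        assert beta == pytest.approx(beta_grid, abs=1e-4)

    def test_loglik_matches_oracle(self, rng):
        n = 25
        x = rng.normal(size=n)
        time = np.round(rng.exponential(50, size=n)) + 1
        event = rng.uniform(size=n) < 0.6
        event[:2] = True
        for beta in (-1.0, 0.0, 0.7):
            assert breslow_loglik(x[:, None], np.array([beta]), time, event) == pytest.approx(
                breslow_loglik_oracle(beta, x, time, event), rel=1e-10
            )

    def test_rescaling_identity(self):
        x, t, e, *_ = simulate_cox(200, 0.8, seed=5)
        b1, se1 = fit_univariate_cox(x, (t, e))
        b2, se2 = fit_univariate_cox(3.0 * x, (t, e))
        assert b2 == pytest.approx(b1 / 3.0, rel=1e-6)
        assert se2 == pytest.approx(se1 / 3.0, rel=1e-6)

    def test_planted_beta_recovered(self):
        x, t, e, *_ = simulate_cox(500, 1.0, seed=13)
        beta, se = fit_univariate_cox(x, (t, e))
        assert abs(beta - 1.0) < 0.2

    def test_null_coverage(self):
        hits = 0
        for seed in range(100):
            x, t, e, *_ = simulate_cox(500, 0.0, seed=seed)
            beta, se = fit_univariate_cox(x, (t, e))
            if abs(beta) < 2 * se:
                hits += 1
        assert hits >= 90

    def test_monotone_likelihood_reported(self):
        # event order perfectly sorted by the covariate: beta diverges
        x = np.arange(10.0)
        time = 100.0 - 10 * x
        event = np.ones(10, dtype=bool)
        with pytest.raises(CoxConvergenceError):
            fit_univariate_cox(x, (time, event))

    def test_constant_feature_and_no_events_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_univariate_cox(np.ones(10), (np.arange(10.0) + 1, np.ones(10, bool)))
        with pytest.raises(ValueError, match="events"):
            fit_univariate_cox(np.arange(10.0), (np.arange(10.0) + 1, np.zeros(10, bool)))


class TestLassoCox:
    def _dataset(self, seed, n=500, G=50):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(G, n))
        expr = ExpressionMatrix([f"G{i:03d}" for i in range(G)],
                                [f"S{j}" for j in range(n)], X, "log_rsem")
        spec = SurvivalSimSpec(
            beta_gene={"G000": 1.0, "G001": -1.0, "G002": 1.0},
            baseline_rate=1e-3, censor_rate=2e-4, seed=seed,
        )
        return expr, gen_survival(expr, None, spec)

    def test_signal_selected_few_false_positives(self):
        # 10-seed majority: all signal genes in, false selections <= 5
        good = 0
        for seed in range(11, 21):
            expr, surv = self._dataset(seed)
            r = fit_lasso_cox(expr, None, surv, cv_folds=10, seed=seed)
            sel = set(r.selected)
            if {"G000", "G001", "G002"} <= sel and len(sel - {"G000", "G001", "G002"}) <= 5:
                good += 1
        assert good >= 6

    def test_huge_lambda_selects_nothing(self):
        expr, surv = self._dataset(seed=1, n=200, G=20)
        r = fit_lasso_cox(expr, None, surv, lambda_grid=[1e6], cv_folds=5, seed=1)
        assert r.selected == []

    def test_path_sparsity_monotone_in_lambda(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        expr, surv = self._dataset(seed=2, n=300, G=30)
        X = (expr.values.T - expr.values.T.mean(0)) / expr.values.T.std(0)
        y = Surv.from_arrays(event=[r.event for r in surv], time=[r.time for r in surv])
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30, normalize=False)
        m.fit(X, y)
        nnz = (m.coef_ != 0).sum(axis=0)  # alphas_ descending in lambda? ascending
        order = np.argsort(m.alphas_)[::-1]  # descending lambda
        assert all(np.diff(nnz[order]) >= 0)

    def test_duplicated_feature_splits_weight_consistently(self):
        # with an exactly duplicated column the L1 solution is non-unique:
        # coordinate descent may share weight between the twins, but their
        # coefficients never take opposite signs and their sum reproduces
        # the single-column coefficient
        expr, surv = self._dataset(seed=3, n=300, G=10)
        r_single = fit_lasso_cox(expr, None, surv, cv_folds=5, seed=3)
        dup_vals = np.vstack([expr.values, expr.values[0:1, :]])
        dup = ExpressionMatrix(expr.gene_ids + ["G_dup"], expr.sample_ids,
                               dup_vals, "log_rsem")
        r = fit_lasso_cox(dup, None, surv, lambda_grid=r_single.lambda_grid,
                          cv_folds=5, seed=3)
        c0 = r.coefficients.get("G000", 0.0)
        c1 = r.coefficients.get("G_dup", 0.0)
        assert c0 * c1 >= 0
        if "G000" in r_single.coefficients:
            assert c0 + c1 == pytest.approx(r_single.coefficients["G000"], rel=0.2)

    def test_constant_feature_dropped_with_warning(self):
        expr, surv = self._dataset(seed=4, n=100, G=5)
        vals = expr.values.copy()
        vals[4, :] = 7.0
        const = ExpressionMatrix(expr.gene_ids, expr.sample_ids, vals, "log_rsem")
        with pytest.warns(UserWarning, match="constant"):
            r = fit_lasso_cox(const, None, surv, cv_folds=5, seed=4)
        assert "G004" not in r.selected


class TestRiskScore:
    def test_bundled_model_arithmetic(self):
        model = load_cilium_risk_model()
        genes = sorted(model.gene_coefficients)
        assert len(genes) == 12
        ones = ExpressionMatrix(genes, ["s1"], np.ones((12, 1)), "log_rsem")
        assert compute_risk_score(ones, model)["s1"] == pytest.approx(1.02, abs=1e-12)
        zeros = ExpressionMatrix(genes, ["s1"], np.zeros((12, 1)), "log_rsem")
        assert compute_risk_score(zeros, model)["s1"] == 0.0
        lrguk_only = np.zeros((12, 1))
        lrguk_only[genes.index("LRGUK"), 0] = 2.0
        m = ExpressionMatrix(genes, ["s1"], lrguk_only, "log_rsem")
        assert compute_risk_score(m, model)["s1"] == pytest.approx(0.98, abs=1e-12)

    def test_linearity(self, rng):
        model = load_cilium_risk_model()
        genes = sorted(model.gene_coefficients)
        X = rng.normal(size=(12, 4))
        Y = rng.normal(size=(12, 4))
        sx = compute_risk_score(ExpressionMatrix(genes, list("abcd"), X, "log_rsem"), model)
        sy = compute_risk_score(ExpressionMatrix(genes, list("abcd"), Y, "log_rsem"), model)
        sz = compute_risk_score(
            ExpressionMatrix(genes, list("abcd"), 2 * X + 3 * Y, "log_rsem"), model
        )
        for s in "abcd":
            assert sz[s] == pytest.approx(2 * sx[s] + 3 * sy[s], rel=1e-12)

    def test_missing_gene_is_error(self):
        model = load_cilium_risk_model()
        expr = make_expr(np.ones((1, 2)))
        with pytest.raises(KeyError):
            compute_risk_score(expr, model)

    def test_model_json_round_trip(self, tmp_path):
        model = RiskModel({"A": 0.5, "B": -0.25}, {"grade": 0.7}, 1.0, 0.03)
        model.to_json(tmp_path / "m.json")
        back = RiskModel.from_json(tmp_path / "m.json")
        assert back == model


class TestStratification:
    def _records(self, times, events):
        return [SurvivalRecord(f"s{i}", float(t), bool(e))
                for i, (t, e) in enumerate(zip(times, events))]

    def test_identical_survival_gives_null_logrank(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(100, size=100)
        recs = self._records(np.concatenate([times, times]),
                             np.ones(200))
        scores = {f"s{i}": float(i % 2) for i in range(200)}
        res = stratify_and_logrank(scores, recs, scheme="median")
        assert res.logrank_p > 0.5

    def test_km_without_censoring_is_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0]
        recs = self._records(times + [10.0, 20.0, 30.0, 40.0], np.ones(8))
        scores = {f"s{i}": float(i >= 4) for i in range(8)}
        res = stratify_and_logrank(scores, recs, scheme="median")
        low = res.curves["low"].set_index("time")["survival"]
        # S(t) drops by 1/4 at each of the four event times
        np.testing.assert_allclose(low.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])

    def test_median_ties_go_to_lower_group(self):
        recs = self._records(np.arange(1, 7, dtype=float), np.ones(6))
        scores = {f"s{i}": v for i, v in enumerate([1.0, 1.0, 2.0, 2.0, 2.0, 3.0])}
        res = stratify_and_logrank(scores, recs, scheme="median")
        # median = 2.0; scores == 2.0 all land in "low"
        assert sum(1 for v in res.group_labels.values() if v == "low") == 5

    def test_quartile_scheme_excludes_middle(self):
        recs = self._records(np.arange(1, 101, dtype=float), np.ones(100))
        scores = {f"s{i}": float(i) for i in range(100)}
        res = stratify_and_logrank(scores, recs, scheme="quartiles")
        labelled = set(res.group_labels)
        assert len(labelled) < 100
        lows = {s for s, g in res.group_labels.items() if g == "low"}
        highs = {s for s, g in res.group_labels.items() if g == "high"}
        assert max(float(s[1:]) for s in lows) < min(float(s[1:]) for s in highs)

    def test_score_linked_hazard_separates_groups(self):
        x, t, e, expr, recs = simulate_cox(400, np.log(2.0), seed=17)
        scores = {f"s{j}": float(x[j]) for j in range(400)}
        res = stratify_and_logrank(scores, recs, scheme="median")
        assert res.logrank_p < 0.01

    def test_empty_group_is_error(self):
        recs = self._records([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            stratify_and_logrank({"s0": 1.0, "s1": 1.0}, recs, scheme="quartiles")


class TestEndToEndRiskPipeline:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_select_refit_score_split_recovers_risk_groups(self, seed):
        rng = np.random.default_rng(seed)
        n, G = 400, 50
        X = rng.normal(size=(G, n))
        expr = ExpressionMatrix([f"G{i:03d}" for i in range(G)],
                                [f"S{j}" for j in range(n)], X, "log_rsem")
        b = np.log(2.0) / np.sqrt(3)  # HR = 2 per SD of the 3-gene signature
        spec = SurvivalSimSpec(
            beta_gene={"G000": b, "G001": b, "G002": b},
            baseline_rate=1e-3, censor_rate=2e-4, seed=seed,
        )
        surv = gen_survival(expr, None, spec)
        model = build_risk_model(expr, expr.gene_ids, None, surv, seed=seed)
        scores = compute_risk_score(expr, model)
        res = stratify_and_logrank(scores, surv, scheme="median")
        assert res.logrank_p < 0.01
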