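"""REVS: OLS fits, AIC, support ranking, nested sequences, triple selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson

from murmuration.errors import DegenerateFitError, SingularDesignError
from murmuration.revs import (
    FittedModel,
    PredictorMatrix,
    aic,
    build_design,
    build_nested_sequence,
    durbin_watson,
    fit_ols,
    rank_empirical_support,
    run_revs,
    select_revs_models,
    validate_predictors,
)
from oracles import gaussian_aic_oracle, ols_rss_oracle


def _pm(X: dict, y) -> PredictorMatrix:
    return PredictorMatrix(X=pd.DataFrame(X), y=pd.Series(y, name="y", dtype=float))


@pytest.fixture
def random_pm():
    rng = np.random.default_rng(5)
    n = 60
    X = {f"x{i}": rng.normal(size=n) for i in range(4)}
    y = 2.0 + 1.5 * X["x0"] - 0.8 * X["x2"] + rng.normal(0, 0.7, size=n)
    return _pm(X, y)


class TestFitOls:
    def test_exact_linear_one_predictor(self):
        x = np.arange(8.0)
        m = fit_ols(_pm({"x": x}, 3.0 + 2.0 * x))
        assert m.rss == pytest.approx(0.0, abs=1e-18)
        assert m.adj_r2 == pytest.approx(1.0)
        assert m.coefficients == pytest.approx((3.0, 2.0))

    def test_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = fit_ols(_pm({"x": [0.0, 1.0, 0.0, 1.0]}, y), subset=[])
        assert m.coefficients == pytest.approx((3.0,))
        assert m.rss == pytest.approx(float(np.sum((y - 3.0) ** 2)))
        assert m.k_params == 2

    def test_hand_solved_normal_equations(self):
        # x = 0..4, y = (1,3,2,5,4): slope 0.8, intercept 1.4, RSS 3.6
        m = fit_ols(_pm({"x": [0, 1, 2, 3, 4]}, [1.0, 3.0, 2.0, 5.0, 4.0]))
        assert m.coefficients == pytest.approx((1.4, 0.8), abs=1e-6)
        assert m.rss == pytest.approx(3.6, abs=1e-6)
        assert m.r2 == pytest.approx(0.64, abs=1e-6)
        assert sum(m.residuals) == pytest.approx(0.0, abs=1e-9)

    def test_singular_design_names_columns(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(SingularDesignError, match="dup"):
            fit_ols(_pm({"x": x, "dup": x, "z": np.arange(6.0) ** 2}, np.arange(6.0)))


class TestAic:
    def test_formula_values(self):
        assert aic(rss=7.0, n=7, k_params=3) == pytest.approx(6.0)
        # +2 per extra parameter at fixed RSS
        assert aic(5.0, 10, 6) - aic(5.0, 10, 3) == pytest.approx(6.0)

    def test_saturated_fit_flagged(self):
        with pytest.raises(DegenerateFitError):
            aic(0.0, 10, 3)

    def test_delta_matches_full_likelihood_oracle(self, random_pm):
        m1 = fit_ols(random_pm, ["x0"])
        m2 = fit_ols(random_pm, ["x0", "x2"])
        delta = m2.aic - m1.aic
        oracle_delta = gaussian_aic_oracle(m2.rss, m2.n, m2.k_params) - gaussian_aic_oracle(
            m1.rss, m1.n, m1.k_params
        )
        assert delta == pytest.approx(oracle_delta, abs=1e-9)


class TestRanking:
    def test_single_predictor_any_method(self):
        x = np.arange(10.0)
        for method in ("best_subsets_frequency", "univariate"):
            ranking = rank_empirical_support(_pm({"only": x}, 2 * x + 1), method=method)
            assert ranking.order == ("only",)

    def test_true_signal_ranked_first(self):
        rng = np.random.default_rng(3)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        ranking = rank_empirical_support(_pm({"x1": x1, "x2": x2}, x1))
        assert ranking.order[0] == "x1"
        assert ranking.support_score["x1"] >= ranking.support_score["x2"]

    def test_effect_ordering_recovered_across_replicates(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            X = {f"x{i}": rng.normal(size=n) for i in (1, 2, 3)}
            y = 5.0 * X["x1"] + 2.0 * X["x2"] + rng.normal(0, 3.0, size=n)
            ranking = rank_empirical_support(_pm(X, y))
            hits += ranking.order == ("x1", "x2", "x3")
        assert hits >= 27  # >= 90% of replicates

    def test_constant_column_flagged_and_last(self):
        x = np.arange(12.0)
        with pytest.warns(UserWarning, match="constant"):
            ranking = rank_empirical_support(_pm({"x": x, "const": [1.0] * 12}, x))
        assert ranking.order[-1] == "const"
        assert ranking.flagged_constant == ("const",)


class TestNestedSequence:
    def test_prefix_structure_and_r2_monotone(self, random_pm):
        ranking = rank_empirical_support(random_pm)
        seq = build_nested_sequence(random_pm, ranking)
        assert [m.n_predictors for m in seq] == [1, 2, 3, 4]
        for prev, nxt in zip(seq, seq[1:]):
            assert set(prev.predictor_names) < set(nxt.predictor_names)
            assert nxt.r2 >= prev.r2 - 1e-12

    def test_sequence_aics_match_independent_refits(self, random_pm):
        ranking = rank_empirical_support(random_pm)
        seq = build_nested_sequence(random_pm, ranking)
        y = random_pm.y.to_numpy()
        for m in seq:
            rss = ols_rss_oracle(random_pm.X[list(m.predictor_names)].to_numpy(), y)
            assert m.aic == pytest.approx(aic(rss, m.n, m.k_params), abs=1e-9)


class TestTripleSelection:
    @staticmethod
    def _fake(nprec: int, aic_val: float, adj: float) -> FittedModel:
        return FittedModel(
            predictor_names=tuple(f"v{i}" for i in range(nprec)),
            coefficients=(0.0,) * (nprec + 1), rss=1.0, n=50, k_params=nprec + 2,
            aic=aic_val, r2=adj, adj_r2=adj, f_stat=1.0, p_value=0.5,
            residuals=(0.1, -0.1),
        )

    def test_single_model_sequence(self):
        res = select_revs_models([self._fake(1, 10.0, 0.2)])
        assert res.mam == res.optimal == res.maximum == 0

    def test_hand_evaluated_rules(self):
        seq = [
            self._fake(1, 10.0, 0.20),
            self._fake(2, 9.0, 0.30),
            self._fake(3, 9.5, 0.32),
            self._fake(4, 12.0, 0.33),
        ]
        res = select_revs_models(seq)
        assert res.delta_aic == pytest.approx([1.0, 0.0, 0.5, 3.0])
        assert (res.mam, res.optimal, res.maximum) == (0, 1, 2)

    def test_threshold_is_closed_at_two(self):
        seq = [self._fake(1, 2.0, 0.1), self._fake(2, 0.0, 0.3)]
        res = select_revs_models(seq)
        assert res.mam == 0  # delta exactly 2.0 still qualifies

    def test_all_outside_threshold_collapse_to_optimal(self):
        seq = [self._fake(1, 13.0, 0.1), self._fake(2, 0.0, 0.3), self._fake(3, 11.0, 0.4)]
        res = select_revs_models(seq)
        assert res.mam == res.optimal == res.maximum == 1


class TestDurbinWatson:
    def test_constant_residuals(self):
        assert durbin_watson([1.0, 1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_alternating_residuals(self):
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_iid_gaussian_near_two(self):
        rng = np.random.default_rng(11)
        e = rng.normal(size=10_000)
        assert 1.9 < durbin_watson(e) < 2.1

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=200)
        assert durbin_watson(e) == pytest.approx(float(sm_durbin_watson(e)), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])


class TestValidatePredictors:
    def test_presence_equals_sum_of_activities_flagged(self):
        rng = np.random.default_rng(8)
        n = 40
        acts = {f"harrier_{a}": (rng.random(n) < 0.2).astype(float)
                for a in ("perch_silent", "perch_calling", "flying", "engaging")}
        presence = np.clip(sum(acts.values()), 0, 1)
        # force disjoint activities so presence is exactly their sum
        order = list(acts)
        for i, key in enumerate(order):
            for other in order[:i]:
                acts[key] = np.where(acts[other] > 0, 0.0, acts[key])
        presence = sum(acts.values())
        X = {**acts, "harrier_presence": presence}
        y = rng.normal(size=n)
        report = validate_predictors(_pm(X, y))
        assert "harrier_presence" in report.exact_dependencies

    def test_duplicated_column_flagged(self):
        x = np.arange(20.0)
        rng = np.random.default_rng(1)
        report = validate_predictors(_pm({"a": x, "b": x.copy()}, rng.normal(size=20)))
        assert report.exact_dependencies == ("b",)

    def test_full_rank_random_design_clean(self):
        rng = np.random.default_rng(9)
        X = {f"x{i}": (rng.random(200) < 0.4).astype(float) for i in range(5)}
        report = validate_predictors(_pm(X, rng.normal(size=200)))
        assert report.ok


class TestEndToEnd:
    def test_run_revs_triples_satisfy_definitions(self, random_pm):
        res = run_revs(random_pm)
        cand = [i for i, d in enumerate(res.delta_aic) if d <= 2.0]
        assert res.delta_aic[res.optimal] == 0.0
        assert res.sequence[res.mam].n_predictors == min(
            res.sequence[i].n_predictors for i in cand
        )
        assert res.sequence[res.maximum].adj_r2 == max(
            res.sequence[i].adj_r2 for i in cand
        )
        assert set(res.durbin_watson) == {"MAM", "Optimal", "Maximum"}

    def test_build_design_mixes_never(self, make_record):
        records = [make_record(predator_obs={"harrier": "flying"}) for _ in range(60)]
        pm = build_design(records, design="activity", response="duration")
        assert not any(c.endswith("_presence") for c in pm.predictor_names)
        assert pm.X["harrier_flying"].sum() == 60
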