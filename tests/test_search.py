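import itertools
import math

import numpy as np
import pandas as pd
import pytest

from prognosig import (
    CompositeModel,
    DegenerateDesignError,
    SearchConfig,
    SignatureSearch,
    SimConfig,
    composite_score,
    cox_fit,
    enumerate_combinations,
    evaluate_fitness,
    fit_composite,
    search_global,
    search_gradient,
    simulate_cohort,
)
from prognosig.search import SearchError

#: the six-marker composite signature weight vector (per score unit)
SIGNATURE_WEIGHTS = {
    "FOXP3": -0.148,
    "ICOS": -0.158,
    "LIMK2": -0.091,
    "p-cofilin": 0.137,
    "STAT1": -0.038,
    "UCP1": -0.164,
}


@pytest.fixture(scope="module")
def small_planted():
    cohort, truth = simulate_cohort(SimConfig(n_patients=250, n_noise_markers=3, seed=21))
    return cohort, truth


class TestEnumerate:
    @pytest.mark.parametrize("n,r,count", [(6, 3, 20), (6, 6, 1), (10, 1, 10)])
    def test_counts_match_binomial(self, n, r, count):
        names = [f"m{i}" for i in range(n)]
        seq, reported = enumerate_combinations(names, r)
        combos = list(seq)
        assert reported == count == len(combos)
        assert combos == sorted(combos)           # lexicographic in input order
        assert len(set(combos)) == len(combos)

    def test_power_set_identity_n19(self):
        names = [f"m{i}" for i in range(19)]
        total = sum(enumerate_combinations(names, r)[1] for r in range(1, 20))
        assert total == 2**19 - 1 == 524_287

    def test_out_of_range_rejected(self):
        with pytest.raises(SearchError):
            enumerate_combinations(["a", "b"], 3)
        with pytest.raises(SearchError):
            enumerate_combinations(["a", "b"], 0)


class TestCompositeScore:
    def test_published_weight_vector_unit_inputs(self):
        model = CompositeModel(
            markers=tuple(SIGNATURE_WEIGHTS),
            weights=np.array(list(SIGNATURE_WEIGHTS.values())),
        )
        unit = pd.DataFrame(0.0, index=[0], columns=list(SIGNATURE_WEIGHTS))
        foxp3 = unit.copy()
        foxp3.loc[0, "FOXP3"] = 1.0
        assert composite_score(model, foxp3)[0] == pytest.approx(-0.148)
        pcof = unit.copy()
        pcof.loc[0, "p-cofilin"] = 1.0
        assert composite_score(model, pcof)[0] == pytest.approx(0.137)
        assert composite_score(model, unit)[0] == 0.0

    def test_linearity_in_scores(self):
        rng = np.random.default_rng(3)
        model = CompositeModel(markers=("a", "b", "c"), weights=rng.normal(size=3))
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        np.testing.assert_allclose(
            composite_score(model, 2 * X + 3 * Y),
            2 * composite_score(model, X) + 3 * composite_score(model, Y),
        )

    def test_zero_weight_marker_is_inert(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        m2 = CompositeModel(markers=("a", "b"), weights=np.array([0.5, -0.2]))
        m3 = CompositeModel(markers=("a", "b", "c"), weights=np.array([0.5, -0.2, 0.0]))
        np.testing.assert_allclose(composite_score(m2, X), composite_score(m3, X))

    def test_missing_score_gives_nan(self):
        model = CompositeModel(markers=("a", "b"), weights=np.array([1.0, 1.0]))
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 2.0]})
        out = composite_score(model, X)
        assert out[0] == 3.0 and np.isnan(out[1])


class TestFitComposite:
    def test_single_marker_weight_is_univariate_coefficient(self, small_planted):
        cohort, _ = small_planted
        model = fit_composite(["PM1"], cohort.markers, cohort.time, cohort.event)
        uni = cox_fit(cohort.time, cohort.event,
                      cohort.markers[["PM1"]].to_numpy(), names=["PM1"])
        assert model.weights[0] == pytest.approx(uni.coef[0], abs=1e-12)

    def test_duplicate_marker_rejected(self, small_planted):
        cohort, _ = small_planted
        with pytest.raises(DegenerateDesignError):
            fit_composite(["PM1", "PM1"], cohort.markers, cohort.time, cohort.event)

    def test_weights_equal_multivariate_cox_coefficients(self, small_planted):
        cohort, truth = small_planted
        combo = truth.planted_markers
        model = fit_composite(combo, cohort.markers, cohort.time, cohort.event)
        direct = cox_fit(cohort.time, cohort.event,
                         cohort.markers[combo].to_numpy(), names=combo)
        np.testing.assert_allclose(model.weights, direct.coef, atol=1e-12)

    def test_weight_recovery_ci_coverage(self):
        # the Cox weight estimator covers the planted weights at the
        # nominal 95% rate (small replicate count; looser band than the
        # dedicated calibration check in the acceptance suite)
        reps, covered, total = 40, 0, 0
        for seed in range(reps):
            cohort, truth = simulate_cohort(
                SimConfig(n_patients=1000, n_noise_markers=0, seed=1000 + seed))
            model = fit_composite(truth.planted_markers, cohort.markers,
                                  cohort.time, cohort.event)
            fit = model.source_fit
            for i, m in enumerate(truth.planted_markers):
                lo, hi = np.log(fit.hr_ci[i])
                covered += lo <= truth.weights[m] <= hi
                total += 1
        assert 0.88 <= covered / total <= 1.0


class TestEvaluateFitness:
    def test_zero_variance_composite_rejected(self, small_planted):
        cohort, _ = small_planted
        model = CompositeModel(markers=("PM1",), weights=np.array([0.0]))
        with pytest.raises(DegenerateDesignError):
            evaluate_fitness(model, cohort.markers, cohort.time, cohort.event)

    def test_hr_metric_equals_exp_beta_of_same_fit(self, small_planted):
        cohort, truth = small_planted
        model = fit_composite(truth.planted_markers, cohort.markers,
                              cohort.time, cohort.event)
        fs = evaluate_fitness(model, cohort.markers, cohort.time, cohort.event,
                              metric="hr")
        beta = fs.model_detail["covariates"][0]["coef"]
        assert fs.value == pytest.approx(np.exp(beta), rel=1e-10)
        assert fs.key == pytest.approx(abs(beta), rel=1e-10)

    def test_perfect_composite_concordance_is_one(self):
        rng = np.random.default_rng(6)
        n = 60
        X = pd.DataFrame({"m": np.arange(n, dtype=float)})
        # survival strictly decreasing in the marker, no censoring, no ties
        time = (n - np.arange(n)) * 1.0 + rng.random(n) * 1e-6
        event = np.ones(n, dtype=int)
        model = CompositeModel(markers=("m",), weights=np.array([1.0]))
        fs = evaluate_fitness(model, X, time, event, metric="concordance")
        assert fs.value == 1.0

    def test_clinical_covariates_enter_the_model(self, small_planted):
        cohort, truth = small_planted
        model = fit_composite(truth.planted_markers, cohort.markers,
                              cohort.time, cohort.event)
        clin = pd.DataFrame({"stage": (cohort.covariates["t_stage"] == "T4").astype(float)})
        fs = evaluate_fitness(model, cohort.markers, cohort.time, cohort.event,
                              clinical=clin, metric="hr")
        names = [c["name"] for c in fs.model_detail["covariates"]]
        assert names == ["composite", "stage"]


def brute_force_best(markers, cohort, metric, r_values):
    """Independent exhaustive loop: itertools + cox_fit, no search module."""
    best = None
    for r in r_values:
        for combo in itertools.combinations(markers, r):
            X = cohort.markers[list(combo)].dropna()
            t, e = cohort.time, cohort.event
            try:
                wfit = cox_fit(t, e, X.to_numpy(), compute_concordance=False)
            except Exception:
                continue
            comp = X.to_numpy() @ wfit.coef
            z = (comp - comp.mean()) / comp.std(ddof=1)
            ffit = cox_fit(t, e, z[:, None])
            if metric == "hr":
                key = abs(ffit.coef[0])
            elif metric == "coefficient":
                key = abs(ffit.coef[0])
            elif metric == "p_value":
                key = -ffit.p[0]
            else:
                key = ffit.concordance
            if best is None or key > best[0] + 1e-12:
                best = (key, combo)
    return best


class TestSearch:
    def test_single_marker_subset_returned(self, small_planted):
        cohort, _ = small_planted
        res = search_global(["PM1"], cohort.markers, cohort.time, cohort.event)
        assert res.combination == ("PM1",)

    def test_global_matches_independent_brute_force(self, small_planted):
        cohort, _ = small_planted
        markers = cohort.marker_names  # 6 markers -> 63 combinations
        for metric in ("hr", "p_value", "concordance"):
            res = search_global(markers, cohort.markers, cohort.time, cohort.event,
                                config=SearchConfig(fitness_metric=metric))
            key, combo = brute_force_best(markers, cohort, metric, range(1, 7))
            assert res.combination == combo
            assert res.fitness.key == pytest.approx(key, abs=1e-9)

    def test_cap_exceeded_directs_to_gradient(self, small_planted):
        cohort, _ = small_planted
        with pytest.raises(SearchError, match="gradient"):
            search_global(cohort.marker_names, cohort.markers, cohort.time,
                          cohort.event, config=SearchConfig(exhaustive_cap=3))

    def test_trace_counts_match_binomials(self, small_planted):
        cohort, _ = small_planted
        res = search_global(cohort.marker_names, cohort.markers, cohort.time,
                            cohort.event)
        n = len(cohort.marker_names)
        assert [rec["candidates"] for rec in res.trace.records] == [
            math.comb(n, r) for r in range(1, n + 1)
        ]

    def test_global_at_least_as_fit_as_any_single_marker(self, small_planted):
        cohort, _ = small_planted
        res = search_global(cohort.marker_names, cohort.markers, cohort.time,
                            cohort.event)
        for m in cohort.marker_names:
            single = search_global([m], cohort.markers, cohort.time, cohort.event)
            assert res.fitness.key >= single.fitness.key - 1e-12

    def test_gradient_never_beats_global(self, small_planted):
        cohort, _ = small_planted
        markers = cohort.marker_names
        g = search_global(markers, cohort.markers, cohort.time, cohort.event)
        gr = search_gradient(markers, cohort.markers, cohort.time, cohort.event)
        assert gr.fitness.key <= g.fitness.key + 1e-12

    def test_gradient_n2_exhaustive_by_construction(self, small_planted):
        cohort, _ = small_planted
        pair = ["PM1", "PM2"]
        gr = search_gradient(pair, cohort.markers, cohort.time, cohort.event,
                             config=SearchConfig(mode="gradient"))
        g = search_global(pair, cohort.markers, cohort.time, cohort.event)
        assert gr.fitness.key == pytest.approx(g.fitness.key, abs=1e-12)
        assert gr.combination == g.combination

    def test_deterministic_given_inputs(self, small_planted):
        cohort, _ = small_planted
        a = search_global(cohort.marker_names, cohort.markers, cohort.time, cohort.event)
        b = search_global(cohort.marker_names, cohort.markers, cohort.time, cohort.event)
        assert a.combination == b.combination
        assert a.fitness.value == b.fitness.value

    def test_step_size_skips_sizes(self, small_planted):
        cohort, _ = small_planted
        res = search_global(cohort.marker_names, cohort.markers, cohort.time,
                            cohort.event, config=SearchConfig(step=2))
        assert [rec["r"] for rec in res.trace.records] == [1, 3, 5]


class TestSignatureSearchEstimator:
    def test_fit_predict_score(self, small_planted):
        from prognosig import concordance

        cohort, truth = small_planted
        est = SignatureSearch(metric="hr").fit(cohort.markers, cohort.survival())
        assert set(truth.planted_markers) <= set(cohort.marker_names)
        assert est.best_combination_ == est.result_.combination
        scores = est.predict(cohort.markers)
        assert scores.shape == (cohort.n_patients,)
        assert est.score(cohort.markers, cohort.survival()) == pytest.approx(
            concordance(scores, cohort.time, cohort.event))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = SignatureSearch(metric="p_value", r_min=2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
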