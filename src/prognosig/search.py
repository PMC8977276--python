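"""Combinatorial search for the fittest composite marker signature.

For a subset of n retained markers the search enumerates candidate
combinations of size r (r = r_min, r_min + s, ..., r_max).  Each
candidate is turned into a composite variable

    score_i = W1*X1_i + W2*X2_i + ... + Wr*Xr_i

whose weights W are the coefficients of a multivariate Cox model on
exactly those marker scores.  The candidate's fitness is then read off a
second Cox model containing the (optionally standardized) composite plus
a named clinical covariate model: the composite's hazard ratio
(default), coefficient magnitude, Wald p value, or the full model's
concordance index.  Global mode evaluates every combination; gradient
mode starts from the full subset and eliminates one marker per
iteration while fitness strictly improves.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .stats import (
    CoxFit,
    DegenerateDesignError,
    SurvivalDataError,
    cox_fit,
    unpack_survival,
)

log = logging.getLogger(__name__)

FITNESS_METRICS = ("hr", "coefficient", "p_value", "concordance")


class SearchError(ValueError):
    pass


@dataclass
class SearchConfig:
    """Knobs of one combinatorial run over a marker subset."""

    mode: str = "global"                 # global | gradient
    fitness_metric: str = "hr"
    r_min: int = 1
    r_max: int | None = None             # None = subset size
    step: int = 1
    missing_policy: str = "complete_case"   # or impute_mode
    standardize: bool = True
    ties: str = "breslow"
    exhaustive_cap: int = 20
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("global", "gradient"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fitness_metric not in FITNESS_METRICS:
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")
        if self.missing_policy not in ("complete_case", "impute_mode"):
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")
        if self.r_min < 1 or self.step < 1:
            raise ValueError("r_min and step must be >= 1")


@dataclass
class CompositeModel:
    """A marker combination with its Cox-derived weight vector."""

    markers: tuple[str, ...]
    weights: np.ndarray
    source_fit: CoxFit | None = None

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "weights": {m: float(w) for m, w in zip(self.markers, self.weights)},
        }


@dataclass
class FitnessScore:
    """Scalar objective for one candidate combination.

    ``key`` is the orientation-corrected value used for comparison:
    larger key = fitter, regardless of the metric's natural direction
    (p values are lower-better; hazard ratios compare by |log HR|).
    """

    metric: str
    value: float
    higher_is_better: bool
    key: float
    model_detail: dict = field(default_factory=dict)


@dataclass
class SearchTrace:
    mode: str
    records: list[dict] = field(default_factory=list)
    total_evaluated: int = 0
    total_failed: int = 0
    convergence_reason: str = ""


@dataclass
class SearchResult:
    combination: tuple[str, ...]
    model: CompositeModel
    fitness: FitnessScore
    trace: SearchTrace
    leaderboard: list[dict] = field(default_factory=list)


def enumerate_combinations(markers: list[str], r: int) -> tuple[Iterator[tuple], int]:
    """All size-r marker combinations, lazily, with their exact count.

    The count is n! / (r! (n-r)!); the sequence is deterministic
    lexicographic order in the given marker order.
    """
    n = len(markers)
    if not 1 <= r <= n:
        raise SearchError(f"combination size r={r} out of range 1..{n}")
    return itertools.combinations(markers, r), math.comb(n, r)


def _analyzable(X: pd.DataFrame, markers, missing_policy: str) -> pd.DataFrame:
    sub = X[list(markers)].astype(float)
    if missing_policy == "impute_mode":
        for col in sub.columns:
            if sub[col].isna().any():
                mode = sub[col].mode(dropna=True)
                if mode.empty:
                    raise DegenerateDesignError(f"marker {col} entirely missing")
                sub[col] = sub[col].fillna(mode.iloc[0])
        return sub
    return sub.dropna()


def fit_composite(
    markers,
    X: pd.DataFrame,
    time,
    event,
    missing_policy: str = "complete_case",
    ties: str = "breslow",
) -> CompositeModel:
    """Weight a combination by multivariate Cox regression on its markers.

    The fit uses only the combination's marker scores (no clinical
    covariates at this step); weights are the fitted log hazard ratios
    per score unit.
    """
    markers = tuple(markers)
    if len(set(markers)) != len(markers):
        raise DegenerateDesignError(f"duplicate marker in combination {markers}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    sub = _analyzable(X, markers, missing_policy)
    pos = X.index.get_indexer(sub.index)
    fit = cox_fit(time[pos], event[pos], sub.to_numpy(), names=list(markers), ties=ties,
                  compute_concordance=False)
    if not fit.converged:
        raise SurvivalDataError(f"Cox fit for combination {markers} did not converge")
    return CompositeModel(markers=markers, weights=fit.coef.copy(), source_fit=fit)


def composite_score(model: CompositeModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-patient composite score: the weighted sum of marker scores.

    Patients missing any of the model's marker scores get NaN
    (unscorable under complete-case use).
    """
    if isinstance(X, pd.DataFrame):
        mat = X[list(model.markers)].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[None, :]
    if mat.shape[1] != len(model.markers):
        raise ValueError("score matrix width differs from the model's marker count")
    return mat @ model.weights


def evaluate_fitness(
    model: CompositeModel,
    X: pd.DataFrame,
    time,
    event,
    clinical: pd.DataFrame | None = None,
    metric: str = "hr",
    standardize: bool = True,
    ties: str = "breslow",
) -> FitnessScore:
    """Score a composite model under a clinical covariate model.

    Fits Cox on [composite + clinical covariates] (clinical may be
    empty for univariate evaluation).  The composite is standardized to
    unit variance by default so the hazard-ratio metric is per SD and
    scale-free.

    Metrics: ``hr`` — composite hazard ratio, compared by |log HR|;
    ``coefficient`` — |beta|; ``p_value`` — composite Wald p (lower
    better); ``concordance`` — full-model Harrell c (higher better).
    """
    if metric not in FITNESS_METRICS:
        raise ValueError(f"unknown fitness metric {metric!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    comp = composite_score(model, X)
    ok = np.isfinite(comp)
    cols = {"composite": comp}
    names = ["composite"]
    if clinical is not None and clinical.shape[1] > 0:
        clin = clinical.astype(float)
        ok &= clin.notna().all(axis=1).to_numpy()
        for c in clin.columns:
            cols[c] = clin[c].to_numpy(dtype=float)
            names.append(str(c))
    comp_ok = cols["composite"][ok]
    sd = comp_ok.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDesignError("zero-variance composite score")
    if standardize:
        cols["composite"] = (cols["composite"] - comp_ok.mean()) / sd
    design = np.column_stack([cols[c] for c in names])[ok]
    fit = cox_fit(time[ok], event[ok], design, names=names, ties=ties)

    beta = float(fit.coef[0])
    if metric == "hr":
        value, hib, key = float(fit.hr[0]), True, abs(beta)
    elif metric == "coefficient":
        value, hib, key = abs(beta), True, abs(beta)
    elif metric == "p_value":
        value, hib, key = float(fit.p[0]), False, -float(fit.p[0])
    else:
        value, hib, key = float(fit.concordance), True, float(fit.concordance)
    return FitnessScore(
        metric=metric,
        value=value,
        higher_is_better=hib,
        key=key,
        model_detail=fit.summary_dict(),
    )


def _evaluate_candidate(combo, X, time, event, clinical, config: SearchConfig):
    model = fit_composite(
        combo, X, time, event,
        missing_policy=config.missing_policy, ties=config.ties,
    )
    fitness = evaluate_fitness(
        model, X, time, event,
        clinical=clinical,
        metric=config.fitness_metric,
        standardize=config.standardize,
        ties=config.ties,
    )
    return model, fitness


def search_global(
    markers: list[str],
    X: pd.DataFrame,
    time,
    event,
    config: SearchConfig | None = None,
    clinical: pd.DataFrame | None = None,
    top_k: int = 50,
) -> SearchResult:
    """Exhaustive search over all combinations of the subset.

    Evaluates every combination of size r for r = r_min, r_min + step,
    ..., r_max and returns the fitness argmax.  Candidates are visited
    in increasing size and lexicographic order and a strictly larger
    fitness key is required to displace the incumbent, so ties resolve
    to fewer markers, then lexicographically — the result is
    deterministic.
    """
    config = config or SearchConfig()
    markers = list(markers)
    n = len(markers)
    if n == 0:
        raise SearchError("empty marker subset")
    if n > config.exhaustive_cap:
        raise SearchError(
            f"subset of {n} markers exceeds the exhaustive cap "
            f"({config.exhaustive_cap}); use gradient mode"
        )
    r_max = min(config.r_max or n, n)
    trace = SearchTrace(mode="global")
    best: tuple | None = None
    board: list[dict] = []
    for r in range(config.r_min, r_max + 1, config.step):
        combos, count = enumerate_combinations(markers, r)
        r_best = None
        for combo in combos:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    model, fitness = _evaluate_candidate(combo, X, time, event, clinical, config)
            except (DegenerateDesignError, SurvivalDataError) as exc:
                trace.total_failed += 1
                log.debug("combination %s unfit: %s", combo, exc)
                continue
            trace.total_evaluated += 1
            board.append({"markers": list(combo), "metric": fitness.metric, "value": fitness.value, "key": fitness.key})
            if best is None or fitness.key > best[0] + 1e-12:
                best = (fitness.key, combo, model, fitness)
            if r_best is None or fitness.key > r_best[0] + 1e-12:
                r_best = (fitness.key, combo)
        trace.records.append(
            {
                "r": r,
                "candidates": count,
                "best_fitness": None if r_best is None else r_best[0],
                "best_combination": None if r_best is None else list(r_best[1]),
            }
        )
    trace.convergence_reason = "exhausted enumeration"
    if best is None:
        raise SearchError("no combination could be fitted")
    board.sort(key=lambda rec: -rec["key"])
    return SearchResult(
        combination=best[1],
        model=best[2],
        fitness=best[3],
        trace=trace,
        leaderboard=board[:top_k],
    )


def search_gradient(
    markers: list[str],
    X: pd.DataFrame,
    time,
    event,
    config: SearchConfig | None = None,
    clinical: pd.DataFrame | None = None,
) -> SearchResult:
    """Backward-elimination search: drop one marker per iteration.

    Starts from the full subset; each iteration evaluates every
    size-(m-1) sub-combination of the current set and moves to the best
    of them if it strictly improves the incumbent fitness; otherwise the
    walk stops.  Returns the best combination seen overall.  Terminates
    in at most n - r_min iterations.
    """
    config = config or SearchConfig(mode="gradient")
    markers = list(markers)
    if len(markers) < 2:
        raise SearchError("gradient search needs a subset of >= 2 markers")
    trace = SearchTrace(mode="gradient")

    def evaluate(combo):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out = _evaluate_candidate(tuple(combo), X, time, event, clinical, config)
        except (DegenerateDesignError, SurvivalDataError) as exc:
            trace.total_failed += 1
            log.debug("combination %s unfit: %s", combo, exc)
            return None
        trace.total_evaluated += 1
        return out

    current = tuple(markers)
    incumbent = evaluate(current)
    if incumbent is None:
        raise SearchError("full subset could not be fitted")
    best = (incumbent[1].key, current, incumbent[0], incumbent[1])
    trace.records.append(
        {"size": len(current), "candidates": 1, "best_fitness": best[0],
         "best_combination": list(current)}
    )
    while len(current) > config.r_min:
        cand_best = None
        n_cand = 0
        for combo in itertools.combinations(current, len(current) - 1):
            n_cand += 1
            out = evaluate(combo)
            if out is None:
                continue
            if cand_best is None or out[1].key > cand_best[0] + 1e-12:
                cand_best = (out[1].key, combo, out[0], out[1])
        if cand_best is None:
            trace.convergence_reason = "all elimination candidates failed"
            break
        trace.records.append(
            {"size": len(current) - 1, "candidates": n_cand,
             "best_fitness": cand_best[0], "best_combination": list(cand_best[1])}
        )
        if cand_best[0] > best[0] + 1e-12:
            best = cand_best
            current = cand_best[1]
        else:
            trace.convergence_reason = "no strict improvement"
            break
    else:
        trace.convergence_reason = "reached minimum combination size"
    return SearchResult(combination=best[1], model=best[2], fitness=best[3], trace=trace)


class SignatureSearch(BaseEstimator):
    """Combinatorial Cox signature search as a sklearn estimator.

    ``fit(X, y)`` runs the configured search over the columns of the
    marker frame ``X`` against the structured survival outcome ``y`` and
    stores the winning combination; ``predict(X)`` returns the fitted
    composite (linear risk) score per patient; ``score(X, y)`` is
    Harrell's concordance of those predictions.

    Parameters mirror :class:`SearchConfig`; ``clinical`` covariates for
    the fitness models are passed to ``fit`` (numeric, pre-encoded,
    row-aligned with ``X``).

    Attributes
    ----------
    best_combination_ : tuple of marker names
    weights_ : pandas Series, Cox weight per marker
    fitness_ : FitnessScore of the winner
    trace_ : SearchTrace
    model_ : CompositeModel
    """

    def __init__(
        self,
        mode: str = "global",
        metric: str = "hr",
        r_min: int = 1,
        r_max: int | None = None,
        step: int = 1,
        missing_policy: str = "complete_case",
        standardize: bool = True,
        ties: str = "breslow",
        exhaustive_cap: int = 20,
    ):
        self.mode = mode
        self.metric = metric
        self.r_min = r_min
        self.r_max = r_max
        self.step = step
        self.missing_policy = missing_policy
        self.standardize = standardize
        self.ties = ties
        self.exhaustive_cap = exhaustive_cap

    def _config(self) -> SearchConfig:
        return SearchConfig(
            mode=self.mode,
            fitness_metric=self.metric,
            r_min=self.r_min,
            r_max=self.r_max,
            step=self.step,
            missing_policy=self.missing_policy,
            standardize=self.standardize,
            ties=self.ties,
            exhaustive_cap=self.exhaustive_cap,
        )

    def fit(self, X: pd.DataFrame, y, clinical: pd.DataFrame | None = None):
        time, event = unpack_survival(y)
        X = pd.DataFrame(X)
        config = self._config()
        search = search_global if config.mode == "global" else search_gradient
        result = search(list(X.columns), X, time, event, config=config, clinical=clinical)
        self.result_ = result
        self.best_combination_ = result.combination
        self.model_ = result.model
        self.weights_ = pd.Series(result.model.weights, index=list(result.combination))
        self.fitness_ = result.fitness
        self.trace_ = result.trace
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return composite_score(self.model_, pd.DataFrame(X))

    def score(self, X, y) -> float:
        from .stats import concordance

        time, event = unpack_survival(y)
        return concordance(self.predict(X), time, event)
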