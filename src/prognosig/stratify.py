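"""Risk-group stratification and prognostic-independence testing.

A fitted composite signature is turned into k patient groups either by
equal-percentile cut-offs on the composite score (k = 5 gives the four
cut-off points of equal percentiles) or by hierarchical clustering of
the signature markers' standardized scores.  Groups are compared by
log-rank and pairwise hazard ratios against a reference group, and
independence from established clinicopathological prognostic factors is
tested in multivariate Cox models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import classify_path_risk
from .stats import (
    CoxFit,
    DegenerateDesignError,
    KMCurve,
    LogrankResult,
    cox_fit,
    km_estimate,
    logrank,
    unpack_survival,
)


class StratificationError(ValueError):
    pass


@dataclass
class GroupAssignment:
    """Per-patient risk-group labels 1..k ordered by increasing risk."""

    method: str                      # linear_percentile | cluster
    k: int
    labels: np.ndarray               # NaN for unscorable patients
    cutpoints: np.ndarray | None = None   # percentile method only, k-1 values

    def counts(self) -> dict[int, int]:
        lab = self.labels[np.isfinite(self.labels)].astype(int)
        return {int(g): int((lab == g).sum()) for g in range(1, self.k + 1)}


#: the four named multivariate clinical models; ``age`` is an age-group
#: covariate, ``path_risk`` the binary pathological risk classification.
CLINICAL_MODELS: dict[str, list[str]] = {
    "M1": ["age", "t_stage", "n_stage", "emvi"],
    "M2": ["age", "uicc_stage", "emvi"],
    "M3": ["age", "path_risk"],
    "M4_preresection": ["age", "site", "differentiation"],
}


@dataclass
class ClinicalModelSpec:
    name: str
    covariates: list[str] = field(default_factory=list)
    encoding: str = "dummy"          # dummy | ordinal

    @classmethod
    def named(cls, name: str, encoding: str = "dummy") -> "ClinicalModelSpec":
        if name not in CLINICAL_MODELS:
            raise ValueError(f"unknown clinical model {name!r}; pick {list(CLINICAL_MODELS)}")
        return cls(name=name, covariates=list(CLINICAL_MODELS[name]), encoding=encoding)


def percentile_groups(scores, k: int = 5) -> GroupAssignment:
    """Divide composite scores into k groups at equal-percentile cut-offs.

    Cut-offs sit at the 1/k .. (k-1)/k quantiles (linear interpolation);
    intervals are right-closed, so a score equal to a cut-off falls in
    the lower group.  Because the composite is a Cox linear predictor,
    higher score means higher hazard, so labels 1..k are ordered by
    increasing risk.  Unscorable (NaN) patients get NaN labels.
    """
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    finite = scores[ok]
    if k < 2:
        raise StratificationError("k must be >= 2")
    if np.unique(finite).size < k:
        raise StratificationError(f"need >= {k} distinct scores for {k} groups")
    cuts = np.quantile(finite, np.arange(1, k) / k)
    labels = np.full(scores.shape, np.nan)
    labels[ok] = 1 + np.sum(finite[:, None] > cuts[None, :], axis=1)
    return GroupAssignment(method="linear_percentile", k=k, labels=labels, cutpoints=cuts)


def cluster_groups(
    marker_scores: pd.DataFrame,
    k: int = 5,
    risk_scores=None,
) -> GroupAssignment:
    """Group patients by hierarchical clustering of signature markers.

    Agglomerative Ward linkage on Euclidean distances between per-marker
    standardized scores; the tree is cut at k clusters and clusters are
    relabeled 1..k by increasing mean composite risk (``risk_scores``;
    falls back to the mean standardized score when absent).  Requires
    complete (or pre-imputed) scores on the signature markers.
    """
    M = pd.DataFrame(marker_scores).astype(float)
    if M.isna().any().any():
        raise StratificationError("cluster grouping needs complete marker scores (impute first)")
    n = M.shape[0]
    if not 2 <= k <= n:
        raise StratificationError(f"k={k} out of range 2..{n}")
    Z = (M - M.mean()) / M.std(ddof=0).replace(0.0, 1.0)
    tree = linkage(Z.to_numpy(), method="ward", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    if risk_scores is None:
        risk = Z.mean(axis=1).to_numpy()
    else:
        risk = np.asarray(risk_scores, dtype=float)
    order = np.argsort([risk[raw == c].mean() for c in np.unique(raw)], kind="stable")
    relabel = {int(c): rank + 1 for rank, c in enumerate(np.unique(raw)[order])}
    labels = np.array([relabel[int(c)] for c in raw], dtype=float)
    return GroupAssignment(method="cluster", k=int(len(np.unique(raw))), labels=labels)


@dataclass
class PairwiseComparison:
    group: int
    logrank: LogrankResult
    hr: float
    hr_ci: tuple[float, float]
    p: float


@dataclass
class GroupSurvivalReport:
    overall: LogrankResult
    curves: dict[int, KMCurve]
    medians: dict[int, float | None]
    pairwise: list[PairwiseComparison]
    reference_group: int

    def to_dict(self) -> dict:
        return {
            "overall": {"chi_square": self.overall.chi_square, "df": self.overall.df,
                        "p": self.overall.p},
            "reference_group": self.reference_group,
            "medians": {g: m for g, m in self.medians.items()},
            "pairwise": [
                {"group": c.group, "chi_square": c.logrank.chi_square, "p_logrank": c.logrank.p,
                 "hr": c.hr, "hr_ci": list(c.hr_ci), "p": c.p}
                for c in self.pairwise
            ],
        }


def compare_groups_survival(
    labels,
    time,
    event,
    reference_group: int = 1,
) -> GroupSurvivalReport:
    """Overall and pairwise survival comparison of risk groups.

    Computes the k-group log-rank, per-group Kaplan–Meier curves and
    medians, and — for every non-reference group — the two-group
    log-rank plus the univariate Cox hazard ratio against the reference
    group.  The reference group never appears compared with itself.
    """
    labels = np.asarray(labels, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ok = np.isfinite(labels)
    labels, time, event = labels[ok].astype(int), time[ok], event[ok]
    groups = np.unique(labels)
    if groups.size < 2:
        raise StratificationError("need >= 2 non-empty groups")
    if reference_group not in groups:
        raise StratificationError(f"reference group {reference_group} is empty")

    overall = logrank(time, event, labels)
    curves, medians = {}, {}
    for g in groups:
        curve = km_estimate(time[labels == g], event[labels == g])
        curves[int(g)] = curve
        medians[int(g)] = curve.median

    pairwise = []
    ref = labels == reference_group
    for g in groups:
        if g == reference_group:
            continue
        sel = ref | (labels == g)
        lr = logrank(time[sel], event[sel], labels[sel])
        fit = cox_fit(time[sel], event[sel], (labels[sel] == g).astype(float)[:, None],
                      names=[f"group{g}"])
        pairwise.append(
            PairwiseComparison(
                group=int(g),
                logrank=lr,
                hr=float(fit.hr[0]),
                hr_ci=(float(fit.hr_ci[0, 0]), float(fit.hr_ci[0, 1])),
                p=float(fit.p[0]),
            )
        )
    return GroupSurvivalReport(
        overall=overall,
        curves=curves,
        medians=medians,
        pairwise=pairwise,
        reference_group=reference_group,
    )


def encode_covariates(
    covariates: pd.DataFrame,
    spec: ClinicalModelSpec,
) -> pd.DataFrame:
    """Numeric design columns for a clinical model.

    ``dummy`` encoding expands each categorical covariate into
    first-level-reference indicator columns; ``ordinal`` maps sorted
    levels to 0, 1, 2, ...  A requested ``path_risk`` column that is not
    present is derived from T stage, grade, EMVI and N stage.
    """
    cov = covariates.copy()
    if "path_risk" in spec.covariates and "path_risk" not in cov.columns:
        cov["path_risk"] = classify_path_risk(cov)
    missing = [c for c in spec.covariates if c not in cov.columns]
    if missing:
        raise StratificationError(f"clinical model {spec.name} needs covariates {missing}")
    out = {}
    for c in spec.covariates:
        col = cov[c]
        if pd.api.types.is_numeric_dtype(col):
            out[c] = col.astype(float)
            continue
        levels = sorted(col.dropna().astype(str).unique())
        if spec.encoding == "ordinal":
            mapping = {lev: i for i, lev in enumerate(levels)}
            out[c] = col.astype(str).map(mapping).astype(float)
        else:
            for lev in levels[1:]:
                out[f"{c}[{lev}]"] = (col.astype("string") == lev).astype(float).where(
                    col.notna(), np.nan
                )
    return pd.DataFrame(out, index=covariates.index)


@dataclass
class IndependenceReport:
    """Multivariate Cox model of risk groups plus clinical covariates.

    The reference group's hazard ratio is 1 by construction and is never
    estimated; ``group_wald``/``group_p`` test all group indicators
    jointly (df = k - 1).
    """

    model: str
    fit: CoxFit
    group_hr: dict[int, tuple[float, float, float]]   # group -> (hr, lo, hi)
    group_p: dict[int, float]
    group_wald: float
    group_wald_df: int
    group_wald_p: float
    reference_group: int
    n: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "reference_group": self.reference_group,
            "group_hr": {g: {"hr": h, "ci": [lo, hi], "p": self.group_p[g]}
                         for g, (h, lo, hi) in self.group_hr.items()},
            "group_wald": self.group_wald,
            "group_wald_df": self.group_wald_df,
            "group_wald_p": self.group_wald_p,
            "n": self.n,
            "n_events": self.n_events,
            "fit": self.fit.summary_dict(),
        }


def multivariate_independence(
    labels,
    time,
    event,
    covariates: pd.DataFrame,
    spec: ClinicalModelSpec,
    reference_group: int = 1,
) -> IndependenceReport:
    """Test whether group membership is prognostic beyond a clinical model.

    Fits Cox on dummy-coded groups (reference = group 1) plus the
    model's encoded covariates, complete-case.  Reports per-group hazard
    ratios against the reference and the joint Wald statistic for the
    group indicators.  Exact confounding between groups and a covariate
    surfaces as a non-identifiability error.
    """
    labels = np.asarray(labels, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    design_clin = encode_covariates(covariates, spec)

    ok = np.isfinite(labels) & design_clin.notna().all(axis=1).to_numpy()
    lab = labels[ok].astype(int)
    groups = [g for g in np.unique(lab) if g != reference_group]
    if not groups:
        raise StratificationError("only the reference group is present")
    cols, names = [], []
    for g in groups:
        cols.append((lab == g).astype(float))
        names.append(f"group{g}")
    clin = design_clin.loc[ok]
    for c in clin.columns:
        cols.append(clin[c].to_numpy(dtype=float))
        names.append(str(c))
    design = np.column_stack(cols)
    try:
        fit = cox_fit(time[ok], event[ok], design, names=names)
    except DegenerateDesignError as exc:
        raise StratificationError(
            f"non-identifiable model: group labels and covariates are confounded ({exc})"
        ) from exc

    g_idx = np.arange(len(groups))
    beta_g = fit.coef[g_idx]
    cov_g = fit.covariance[np.ix_(g_idx, g_idx)]
    wald = float(beta_g @ np.linalg.solve(cov_g, beta_g))
    df = len(groups)
    group_hr = {int(g): (float(fit.hr[i]), float(fit.hr_ci[i, 0]), float(fit.hr_ci[i, 1]))
                for i, g in enumerate(groups)}
    group_p = {int(g): float(fit.p[i]) for i, g in enumerate(groups)}
    group_hr[reference_group] = (1.0, 1.0, 1.0)
    group_p[reference_group] = float("nan")
    return IndependenceReport(
        model=spec.name,
        fit=fit,
        group_hr=group_hr,
        group_p=group_p,
        group_wald=wald,
        group_wald_df=df,
        group_wald_p=float(sps.chi2.sf(wald, df)),
        reference_group=reference_group,
        n=fit.n,
        n_events=fit.n_events,
    )


class RiskStratifier(BaseEstimator):
    """Composite-score risk grouping as a sklearn estimator.

    ``method='percentile'`` fits k-quantile cut-offs on a 1-D composite
    score and can label new scores via ``predict``; ``method='cluster'``
    Ward-clusters a marker-score matrix (``fit_predict`` only, like
    sklearn's agglomerative clustering).

    Attributes
    ----------
    assignment_ : GroupAssignment for the training data
    cutpoints_ : quantile cut-offs (percentile method)
    labels_ : training labels
    """

    def __init__(self, method: str = "percentile", k: int = 5):
        self.method = method
        self.k = k

    def fit(self, X, y=None, risk_scores=None):
        if self.method == "percentile":
            scores = np.asarray(X, dtype=float).squeeze()
            self.assignment_ = percentile_groups(scores, k=self.k)
            self.cutpoints_ = self.assignment_.cutpoints
        elif self.method == "cluster":
            self.assignment_ = cluster_groups(pd.DataFrame(X), k=self.k,
                                              risk_scores=risk_scores)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.labels_ = self.assignment_.labels
        return self

    def fit_predict(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, y, **kw).labels_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "assignment_")
        if self.method != "percentile":
            raise NotImplementedError("cluster grouping cannot label new patients; refit")
        scores = np.asarray(X, dtype=float).squeeze()
        labels = np.full(scores.shape, np.nan)
        ok = np.isfinite(scores)
        labels[ok] = 1 + np.sum(scores[ok, None] > self.cutpoints_[None, :], axis=1)
        return labels
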