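"""Marker screening and subset assembly.

Stage 1 dichotomizes each marker at its optimal cut-off (the observed
score value whose split minimises the log-rank p value, subject to a
minimum group-size fraction) and keeps markers whose best split is
significant.  Stage 2 assembles the retained markers into overlapping
subsets — by annotated biology, by direction of survival association,
and by correlation structure — that the combinatorial search is run on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import MarkerAnnotation
from .stats import (
    DegenerateDesignError,
    SurvivalDataError,
    cox_fit,
    logrank,
    unpack_survival,
)

log = logging.getLogger(__name__)


class CutpointError(ValueError):
    pass


@dataclass
class CutpointResult:
    """Best dichotomizing threshold for one marker.

    Patients with ``score >= cutpoint`` form the high group; ``hr`` is
    the hazard of the high group relative to the low group, so hr < 1
    means higher expression associates with better survival.
    """

    marker: str
    cutpoint: float
    chi_square: float
    p: float
    hr: float
    direction: str          # higher_better | higher_worse | flat
    n_used: int = 0


@dataclass
class ScreenReport:
    results: dict[str, CutpointResult]
    retained: list[str]
    excluded: list[str]
    alpha: float
    exclusion_reasons: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "retained": self.retained,
            "excluded": self.excluded,
            "exclusion_reasons": self.exclusion_reasons,
            "results": {
                m: {
                    "cutpoint": r.cutpoint,
                    "chi_square": r.chi_square,
                    "p": r.p,
                    "hr": r.hr,
                    "direction": r.direction,
                    "n_used": r.n_used,
                }
                for m, r in self.results.items()
            },
        }


@dataclass
class SubsetSpec:
    name: str
    provenance: str         # biological | direction | correlation | manual
    markers: list[str]

    def to_dict(self) -> dict:
        return {"name": self.name, "provenance": self.provenance, "markers": self.markers}


def find_optimal_cutpoint(
    scores,
    time,
    event,
    marker: str = "marker",
    min_group_fraction: float = 0.1,
) -> CutpointResult:
    """Exhaustive optimal-cutpoint scan for a single marker.

    Every distinct observed score value (except the minimum, which would
    leave the low group empty) is tried as a threshold ``high = score >=
    value``; thresholds whose smaller group holds fewer than
    ``min_group_fraction`` of the analyzable patients are inadmissible.
    Returns the admissible threshold with the smallest log-rank p; ties
    broken toward the smaller threshold.
    """
    if not 0 < min_group_fraction < 0.5:
        raise ValueError("min_group_fraction must lie in (0, 0.5)")
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ok = np.isfinite(scores)
    scores, time, event = scores[ok], time[ok], event[ok]
    n = scores.size
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise CutpointError(f"{marker}: fewer than two distinct scores")

    best: CutpointResult | None = None
    min_n = min_group_fraction * n
    for cut in distinct[1:]:
        high = scores >= cut
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        lr = logrank(time, event, high.astype(int))
        if best is None or lr.p < best.p - 1e-15:
            fit = cox_fit(time, event, high.astype(float)[:, None], names=[marker])
            hr = float(fit.hr[0])
            direction = "higher_better" if hr < 1 else ("higher_worse" if hr > 1 else "flat")
            best = CutpointResult(
                marker=marker,
                cutpoint=float(cut),
                chi_square=lr.chi_square,
                p=lr.p,
                hr=hr,
                direction=direction,
                n_used=n,
            )
    if best is None:
        raise CutpointError(
            f"{marker}: no admissible threshold at min_group_fraction={min_group_fraction}"
        )
    return best


def screen_markers(
    markers: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    min_group_fraction: float = 0.1,
    fdr: bool = False,
) -> ScreenReport:
    """Screen every marker for univariate prognostic power.

    Each marker is analysed complete-case (its own non-missing patients)
    via :func:`find_optimal_cutpoint`; markers are retained iff the best
    split's p value is <= ``alpha``.  No multiplicity correction is
    applied by default (set ``fdr=True`` for Benjamini–Hochberg on the
    best-split p values).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    results: dict[str, CutpointResult] = {}
    reasons: dict[str, str] = {}
    for marker in markers.columns:
        try:
            results[marker] = find_optimal_cutpoint(
                markers[marker].to_numpy(dtype=float),
                time,
                event,
                marker=marker,
                min_group_fraction=min_group_fraction,
            )
        except (CutpointError, DegenerateDesignError, SurvivalDataError) as exc:
            reasons[marker] = str(exc)
            log.info("screening excluded %s: %s", marker, exc)
    pvals = {m: r.p for m, r in results.items()}
    if fdr and pvals:
        from statsmodels.stats.multitest import multipletests

        rej, adj, *_ = multipletests(list(pvals.values()), alpha=alpha, method="fdr_bh")
        keep = {m for m, r in zip(pvals, rej) if r}
    else:
        keep = {m for m, p in pvals.items() if p <= alpha}
    retained = [m for m in markers.columns if m in keep]
    excluded = [m for m in markers.columns if m not in keep]
    for m in results:
        if m not in keep:
            reasons.setdefault(m, f"best p={results[m].p:.4g} > alpha={alpha}")
    return ScreenReport(
        results=results,
        retained=retained,
        excluded=excluded,
        alpha=alpha,
        exclusion_reasons=reasons,
    )


def correlation_groups(
    markers: pd.DataFrame,
    threshold: float = 0.5,
    min_size: int = 2,
) -> list[SubsetSpec]:
    """Group markers by correlation structure.

    Spearman correlation on pairwise-complete scores, average-linkage
    hierarchical clustering of the dissimilarity 1 - |rho|, tree cut at
    ``threshold``; singleton clusters are dropped.
    """
    usable = [c for c in markers.columns if markers[c].dropna().nunique() > 1]
    skipped = [c for c in markers.columns if c not in usable]
    for c in skipped:
        log.info("correlation grouping skipped constant marker %s", c)
    if len(usable) < 2:
        return []
    rho = markers[usable].corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")
    groups = []
    for lab in np.unique(labels):
        members = [usable[i] for i in np.flatnonzero(labels == lab)]
        if len(members) >= min_size:
            groups.append(
                SubsetSpec(
                    name=f"corr_{len(groups) + 1}",
                    provenance="correlation",
                    markers=members,
                )
            )
    return groups


def direction_groups(report: ScreenReport, annotations=None) -> list[SubsetSpec]:
    """Partition retained markers by direction of survival association.

    Direction comes from the hazard ratio of the high-score group at the
    optimal cut-off; a marker with HR exactly 1 falls back on its
    annotation when available and is otherwise flagged (left out, with a
    log entry).
    """
    if not report.results:
        raise ValueError("empty screening report")
    annotations = annotations or {}
    better, worse = [], []
    for m in report.retained:
        direction = report.results[m].direction
        if direction == "flat":
            ann = annotations.get(m)
            direction = ann.direction if ann is not None else "flat"
        if direction == "higher_better":
            better.append(m)
        elif direction == "higher_worse":
            worse.append(m)
        else:
            log.warning("marker %s has HR = 1 and no annotated direction; unassigned", m)
    out = []
    if better:
        out.append(SubsetSpec("higher_better", "direction", better))
    if worse:
        out.append(SubsetSpec("higher_worse", "direction", worse))
    return out


def assemble_subsets(
    report: ScreenReport,
    annotations: dict[str, MarkerAnnotation] | None = None,
    corr_groups: list[SubsetSpec] | None = None,
) -> list[SubsetSpec]:
    """Assemble the search subsets: biology tags, direction, correlation.

    Every subset is restricted to retained markers; a marker carrying
    several pathway tags appears in each of those subsets; subsets with
    identical member sets are deduplicated (first name wins).  Retained
    markers with no annotation are logged and simply carry no biological
    tag.
    """
    annotations = annotations or {}
    retained = set(report.retained)
    candidates: list[SubsetSpec] = []

    tags: dict[str, list[str]] = {}
    for m in report.retained:
        ann = annotations.get(m)
        if ann is None:
            if annotations:
                log.info("retained marker %s has no annotation; no biological tag", m)
            continue
        for tag in ann.subsets:
            tags.setdefault(tag, []).append(m)
    for tag, members in tags.items():
        candidates.append(SubsetSpec(tag, "biological", members))

    candidates.extend(direction_groups(report, annotations))
    for grp in corr_groups or []:
        members = [m for m in grp.markers if m in retained]
        if len(members) >= 2:
            candidates.append(SubsetSpec(grp.name, grp.provenance, members))

    seen: set[frozenset] = set()
    out = []
    for spec in candidates:
        members = [m for m in spec.markers if m in retained]
        if not members:
            continue
        key = frozenset(members)
        if key in seen:
            continue
        seen.add(key)
        out.append(SubsetSpec(spec.name, spec.provenance, members))
    return out


class MarkerScreener(BaseEstimator, TransformerMixin):
    """Optimal-cutpoint univariate screen as a sklearn transformer.

    ``fit(X, y)`` screens every column of the marker frame ``X`` against
    the structured survival outcome ``y``; ``transform(X)`` keeps the
    retained columns.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for retention (best-split log-rank p).
    min_group_fraction : float, default 0.1
        Smallest admissible fraction of patients on either side of a
        candidate cut-off.
    fdr : bool, default False
        Apply Benjamini–Hochberg across markers instead of raw p <= alpha.

    Attributes
    ----------
    report_ : ScreenReport
    retained_ : list of retained marker names
    """

    def __init__(self, alpha: float = 0.05, min_group_fraction: float = 0.1, fdr: bool = False):
        self.alpha = alpha
        self.min_group_fraction = min_group_fraction
        self.fdr = fdr

    def fit(self, X: pd.DataFrame, y):
        time, event = unpack_survival(y)
        X = pd.DataFrame(X)
        self.report_ = screen_markers(
            X, time, event,
            alpha=self.alpha,
            min_group_fraction=self.min_group_fraction,
            fdr=self.fdr,
        )
        self.retained_ = list(self.report_.retained)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]
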