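"""End-to-end discovery pipeline: screen -> group -> search -> evaluate.

Driven by a single run config; emits a JSON run manifest (seed, config
hash, per-stage summaries), a screening report, per-subset leaderboards
and the evaluation of each subset's winning combination.  Results are
deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_annotations, read_cohort, read_schema
from .screening import assemble_subsets, correlation_groups, screen_markers
from .search import SearchConfig, SearchResult, search_global, search_gradient
from .stratify import (
    ClinicalModelSpec,
    compare_groups_survival,
    multivariate_independence,
    percentile_groups,
)
from .search import composite_score

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    cohort_path: str
    schema: dict | str
    out_dir: str
    annotations_path: str | None = None
    alpha: float = 0.05
    min_group_fraction: float = 0.1
    correlation_threshold: float = 0.5
    search: dict = field(default_factory=dict)       # SearchConfig fields
    k_groups: int = 5
    clinical_models: list[str] = field(default_factory=list)
    top_k: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if seed is not None:
            raw["seed"] = seed
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(f"bad run config: {exc}") from exc

    def validate(self) -> None:
        if not Path(self.cohort_path).exists():
            raise PipelineConfigError(f"cohort file not found: {self.cohort_path}")
        if isinstance(self.schema, str) and not Path(self.schema).exists():
            raise PipelineConfigError(f"schema file not found: {self.schema}")
        if self.annotations_path and not Path(self.annotations_path).exists():
            raise PipelineConfigError(f"annotation file not found: {self.annotations_path}")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _search_subset(spec, cohort: Cohort, config: RunConfig) -> SearchResult:
    fields_ = dict(config.search)
    fields_.setdefault("seed", config.seed)
    sc = SearchConfig(**fields_)
    X = cohort.markers
    if sc.mode == "gradient" or len(spec.markers) > sc.exhaustive_cap:
        if len(spec.markers) < 2:
            sc = SearchConfig(**{**fields_, "mode": "global"})
            return search_global(spec.markers, X, cohort.time, cohort.event, config=sc)
        return search_gradient(spec.markers, X, cohort.time, cohort.event, config=sc)
    return search_global(spec.markers, X, cohort.time, cohort.event, config=sc,
                         top_k=config.top_k)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full discovery pipeline and write result files.

    Returns the run manifest (also written to ``manifest.json``).  Any
    stage failure aborts with a stage-tagged error; outputs of completed
    stages are preserved on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                t0 = _time.perf_counter()
                summary = fn()
                summary["elapsed_s"] = round(_time.perf_counter() - t0, 3)
                manifest["stages"][name] = summary
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                return summary
            except Exception as exc:
                raise RuntimeError(f"[stage:{name}] {exc}") from exc
        return deco

    schema = config.schema if isinstance(config.schema, dict) else read_schema(config.schema)
    cohort = read_cohort(config.cohort_path, schema)
    annotations = (
        read_annotations(config.annotations_path) if config.annotations_path else {}
    )
    manifest["cohort"] = {
        "n_patients": cohort.n_patients,
        "n_markers": len(cohort.marker_names),
        "n_events": int(cohort.event.sum()),
    }

    state: dict = {}

    @stage("screen")
    def _screen():
        report = screen_markers(
            cohort.markers, cohort.time, cohort.event,
            alpha=config.alpha, min_group_fraction=config.min_group_fraction,
        )
        state["report"] = report
        (out / "screen.json").write_text(json.dumps(report.to_dict(), indent=2))
        return {"retained": len(report.retained), "excluded": len(report.excluded)}

    @stage("group")
    def _group():
        report = state["report"]
        corr = correlation_groups(
            cohort.markers[report.retained], threshold=config.correlation_threshold
        )
        subsets = assemble_subsets(report, annotations, corr)
        state["subsets"] = subsets
        (out / "subsets.json").write_text(
            json.dumps([s.to_dict() for s in subsets], indent=2)
        )
        return {"n_subsets": len(subsets),
                "names": [s.name for s in subsets]}

    @stage("search")
    def _search():
        results: dict[str, SearchResult] = {}
        for spec in state["subsets"]:
            res = _search_subset(spec, cohort, config)
            results[spec.name] = res
            if res.leaderboard:
                pd.DataFrame(res.leaderboard).to_csv(
                    out / f"leaderboard_{spec.name}.csv", index=False
                )
        state["results"] = results
        (out / "search.json").write_text(json.dumps(
            {
                name: {
                    "combination": list(res.combination),
                    "weights": res.model.to_dict()["weights"],
                    "fitness": {"metric": res.fitness.metric, "value": res.fitness.value},
                    "evaluated": res.trace.total_evaluated,
                    "failed": res.trace.total_failed,
                    "convergence": res.trace.convergence_reason,
                }
                for name, res in results.items()
            },
            indent=2,
        ))
        return {name: {"combination": list(res.combination),
                       "fitness": res.fitness.value}
                for name, res in results.items()}

    @stage("evaluate")
    def _evaluate():
        evaluations = {}
        for name, res in state["results"].items():
            scores = composite_score(res.model, cohort.markers)
            try:
                groups = percentile_groups(scores, k=config.k_groups)
            except ValueError as exc:
                evaluations[name] = {"error": str(exc)}
                continue
            report = compare_groups_survival(groups.labels, cohort.time, cohort.event)
            entry = {"groups": groups.counts(), "survival": report.to_dict()}
            for model_name in config.clinical_models:
                spec = ClinicalModelSpec.named(model_name)
                try:
                    ind = multivariate_independence(
                        groups.labels, cohort.time, cohort.event,
                        cohort.covariates, spec,
                    )
                    entry[model_name] = ind.to_dict()
                except ValueError as exc:
                    entry[model_name] = {"error": str(exc)}
            evaluations[name] = entry
        (out / "evaluation.json").write_text(json.dumps(evaluations, indent=2, default=str))
        return {"evaluated_subsets": list(evaluations)}

    manifest["finished"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
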