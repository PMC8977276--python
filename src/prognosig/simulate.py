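"""Synthetic cohorts with known ground truth.

Generates ordinal marker scores (Gaussian copula for correlated blocks,
latent values discretized at fixed quantile thresholds so marginal score
distributions are controlled exactly), proportional-hazards survival
driven by a planted linear signature plus optional clinical-covariate
effects, and two composable censoring mechanisms (administrative cutoff
and independent exponential dropout).

Defaults emulate a colorectal-cancer discovery cohort: 0–15
semi-quantitative scores, exponential baseline hazard giving a median
overall survival near 100 months, and censoring that leaves roughly
half the patients with an observed death.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, write_cohort


class SimulationError(ValueError):
    pass


@dataclass
class PlantedMarker:
    """One marker with a planted log-hazard weight per score unit."""

    name: str
    weight: float
    level_probs: np.ndarray | None = None   # marginal over score levels; None = uniform


@dataclass
class SimConfig:
    """Full description of a simulated cohort; seed determines everything."""

    n_patients: int = 400
    n_noise_markers: int = 5
    planted: list[PlantedMarker] = field(
        default_factory=lambda: [
            PlantedMarker("PM1", -0.15),
            PlantedMarker("PM2", -0.16),
            PlantedMarker("PM3", +0.14),
        ]
    )
    correlation_blocks: list[tuple[int, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.007          # per month; median ~ ln2/rate ~ 99 months
    admin_censor_time: float | None = 120.0  # months
    dropout_rate: float | None = 0.002       # per month, independent exponential
    score_levels: int = 16                   # ordinal scores 0 .. score_levels-1
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise SimulationError("n_patients must be positive")
        if self.score_levels < 2:
            raise SimulationError("need at least two score levels")
        for pm in self.planted:
            if not np.isfinite(pm.weight):
                raise SimulationError(f"non-finite weight for planted marker {pm.name}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, reproducible from config+seed."""

    planted_markers: list[str]
    weights: dict[str, float]
    linear_predictor: np.ndarray     # centered planted lp + covariate effects
    covariate_effects: dict[str, float]
    config: SimConfig

    def to_dict(self) -> dict:
        return {
            "planted_markers": self.planted_markers,
            "weights": self.weights,
            "covariate_effects": self.covariate_effects,
            "seed": self.config.seed,
            "n_patients": self.config.n_patients,
        }


def _latent_correlation(n_markers: int, blocks: list[tuple[int, float]]) -> np.ndarray:
    """Block-diagonal equicorrelation over the first sum(sizes) markers."""
    C = np.eye(n_markers)
    pos = 0
    for size, rho in blocks:
        if pos + size > n_markers:
            raise SimulationError("correlation blocks exceed marker count")
        C[pos:pos + size, pos:pos + size] = rho
        np.fill_diagonal(C[pos:pos + size, pos:pos + size], 1.0)
        pos += size
    return C


def _discretize(z: np.ndarray, levels: int, probs: np.ndarray | None) -> np.ndarray:
    """Map standard-normal latents to ordinal levels with exact marginals."""
    from scipy.stats import norm

    if probs is None:
        probs = np.full(levels, 1.0 / levels)
    probs = np.asarray(probs, dtype=float)
    if probs.size != levels or not np.isclose(probs.sum(), 1.0):
        raise SimulationError("level probabilities must sum to 1 over the score levels")
    thresholds = norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(thresholds, z, side="left").astype(float)


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw one cohort; returns ``(Cohort, SimTruth)``.

    Marker scores: latent multivariate normal (planted markers first,
    then noise markers; equicorrelated blocks per config) discretized to
    ordinal levels.  Survival: exponential with hazard
    ``baseline * exp(lp - mean(lp))`` where lp is the planted weighted
    score sum plus covariate effects (centering keeps the baseline rate
    interpretable for the average patient).  Censoring: the earlier of
    the administrative cutoff and an independent exponential dropout.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_patients
    planted_names = [pm.name for pm in config.planted]
    n_markers = len(planted_names) + config.n_noise_markers
    names = planted_names + [f"NOISE{i + 1}" for i in range(config.n_noise_markers)]

    C = _latent_correlation(n_markers, config.correlation_blocks)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_markers))
    Z = rng.standard_normal((n, n_markers)) @ L.T
    scores = np.empty_like(Z)
    for j in range(n_markers):
        probs = config.planted[j].level_probs if j < len(config.planted) else None
        scores[:, j] = _discretize(Z[:, j], config.score_levels, probs)
    markers = pd.DataFrame(scores, columns=names)

    # clinical covariates: binary age group, T stage, N stage, EMVI
    covariates = pd.DataFrame(
        {
            "age": np.where(rng.random(n) < 0.5, "<70", ">=70"),
            "t_stage": rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.1, 0.2, 0.5, 0.2]),
            "n_stage": rng.choice(["N0", "N1", "N2"], size=n, p=[0.55, 0.3, 0.15]),
            "emvi": rng.choice(["V0", "V1"], size=n, p=[0.7, 0.3]),
            "differentiation": rng.choice(["G1", "G2", "G3"], size=n, p=[0.15, 0.65, 0.2]),
        }
    )

    lp = np.zeros(n)
    weights = {}
    for pm in config.planted:
        lp += pm.weight * markers[pm.name].to_numpy()
        weights[pm.name] = pm.weight
    for cov, eff in config.covariate_effects.items():
        if cov not in covariates.columns:
            raise SimulationError(f"covariate effect for unknown covariate {cov!r}")
        levels = sorted(covariates[cov].unique())
        ranks = covariates[cov].map({lev: i for i, lev in enumerate(levels)}).to_numpy()
        lp += eff * ranks
    lp_centered = lp - lp.mean()

    hazard = config.baseline_hazard * np.exp(lp_centered)
    t_death = rng.exponential(1.0 / hazard)
    t_cens = np.full(n, np.inf)
    if config.admin_censor_time is not None:
        t_cens = np.minimum(t_cens, config.admin_censor_time)
    if config.dropout_rate:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / config.dropout_rate, size=n))
    time = np.minimum(t_death, t_cens)
    event = (t_death <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)   # strictly positive survival times
    if event.sum() == 0:
        raise SimulationError(
            "simulation produced zero events; raise baseline_hazard or relax censoring"
        )

    ids = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="patient_id")
    markers.index = ids
    covariates.index = ids
    cohort = Cohort(patient_id=ids, time=time, event=event,
                    covariates=covariates, markers=markers)
    truth = SimTruth(
        planted_markers=planted_names,
        weights=weights,
        linear_predictor=lp_centered,
        covariate_effects=dict(config.covariate_effects),
        config=config,
    )
    return cohort, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small deterministic fixture set with a truth manifest.

    Produces a 5-patient hand-checkable cohort, a 400-patient cohort
    with a planted 3-marker signature, and a 400-patient null cohort,
    plus ``manifest.json`` recording the ground truth of each file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    manifest: dict[str, dict] = {}

    tiny = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "D", "E"],
            "time": [12.0, 30.0, 45.0, 60.5, 88.0],
            "event": [1, 0, 1, 0, 0],
            "t_stage": ["T2", "T3", "T4", "T1", "T3"],
            "n_stage": ["N0", "N1", "N0", "N0", "N2"],
            "MK1": [0, 1, 2, np.nan, 3],
            "MK2": [5, 5, np.nan, 2, 1],
            "MK3": [1, 0, 1, 1, 0],
        }
    )
    tiny_path = out_dir / "tiny_cohort.csv"
    tiny.to_csv(tiny_path, index=False, na_rep="NA")
    files["tiny"] = tiny_path
    manifest["tiny"] = {"n_patients": 5, "n_markers": 3, "n_missing_cells": 2}

    planted_cfg = SimConfig(n_patients=400, n_noise_markers=5, seed=seed)
    cohort, truth = simulate_cohort(planted_cfg)
    planted_path = out_dir / "planted_cohort.csv"
    schema = write_cohort(cohort, planted_path)
    files["planted"] = planted_path
    manifest["planted"] = {**truth.to_dict(), "schema": schema}

    null_cfg = SimConfig(
        n_patients=400,
        n_noise_markers=8,
        planted=[],
        seed=seed + 1,
    )
    null_cohort, null_truth = simulate_cohort(null_cfg)
    null_path = out_dir / "null_cohort.csv"
    null_schema = write_cohort(null_cohort, null_path)
    files["null"] = null_path
    manifest["null"] = {**null_truth.to_dict(), "schema": null_schema}

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = manifest_path
    return files
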