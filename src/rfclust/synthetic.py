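"""Synthetic cohorts with the statistical structure of the study data.

The real discovery and validation cohorts are access-restricted, so the
pipeline is exercised on simulated cohorts whose per-cluster composition
matches the published table: cluster sizes, sex mix, age/BMI moments,
fixed hypertension / family-history flags, and cluster-specific diabetes
prevalence.  Follow-up (incident diabetes) and fasting-glucose / lipid
biomarkers are layered on with simple generative models:

* age and BMI are normals truncated to the cohort age window /
  physiologic BMI bounds;
* time to incident diabetes is exponential with a cluster-specific
  hazard, independently exponentially censored and truncated at the
  follow-up horizon, with times rounded to whole months (matching the
  monthly recoding of visit dates);
* biomarkers are normal per (cluster, diabetes-status) cell, with cell
  means free to be non-additive so a planted cluster-by-status
  interaction is recoverable by two-way ANOVA.

Default cluster hazards scale the overall incident rate (about 18% over
ten years of follow-up) by each cluster's relative prevalence, which
reproduces the published ordering of cumulative incidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import tables
from .cohort import CohortTable

BIOMARKERS = ("fg", "tchol", "tg", "hdl")

#: default overall incident-diabetes hazard, events per person-month,
#: chosen so ~18% of the at-risk population converts over a 120-month
#: horizon (1384 of 7574 in the published follow-up).
BASE_HAZARD = 0.0021

#: baseline biomarker means/sds (mmol/L) by diabetes status; FG separates
#: the groups strongly, lipids weakly.
_BIOMARKER_BASE = {
    "ndm": {"fg": 5.2, "tchol": 5.1, "tg": 1.6, "hdl": 1.25},
    "dm": {"fg": 7.6, "tchol": 5.3, "tg": 2.1, "hdl": 1.15},
}
_BIOMARKER_SD = {
    "ndm": {"fg": 0.5, "tchol": 0.9, "tg": 0.9, "hdl": 0.28},
    "dm": {"fg": 2.2, "tchol": 1.0, "tg": 1.4, "hdl": 0.26},
}


@dataclass
class ClusterSpec:
    """Generative description of one synthetic cluster."""

    name: str
    n: int
    male_fraction: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    htn: int
    fhdm: int
    prevalence: float
    hazard: float | None = None  # incident events per person-month
    biomarker_means: Mapping[str, Mapping[str, float]] | None = None
    biomarker_sds: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cluster size must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValueError("sds must be positive")


@dataclass
class SimulationConfig:
    """Reproducible simulation settings; the seed is mandatory."""

    specs: Sequence[ClusterSpec]
    seed: int
    age_window: tuple[float, float] = (40.0, 70.0)
    bmi_bounds: tuple[float, float] = (15.0, 50.0)
    followup_months_max: int = 120
    censoring_rate: float = 0.003  # per person-month
    flag_noise_rate: float = 0.0  # probability of flipping HTN/FHDM flags

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "age_window": list(self.age_window),
            "bmi_bounds": list(self.bmi_bounds),
            "followup_months_max": self.followup_months_max,
            "censoring_rate": self.censoring_rate,
            "flag_noise_rate": self.flag_noise_rate,
            "specs": [
                {k: v for k, v in vars(s).items() if v is not None}
                for s in self.specs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        specs = [ClusterSpec(**s) for s in payload.pop("specs")]
        payload["age_window"] = tuple(payload["age_window"])
        payload["bmi_bounds"] = tuple(payload["bmi_bounds"])
        return cls(specs=specs, **payload)


def _specs_from_table(rows, base_hazard: float) -> list[ClusterSpec]:
    mean_prev = sum(r[11] for r in rows) / sum(r[1] for r in rows)
    specs = []
    for (name, n, m, f, age_m, age_sd, bmi_m, bmi_sd, htn, fhdm, ndm, dm) in rows:
        prev = dm / n
        interaction = 0.4 if name in ("CL1", "CL3") else 0.0
        means = {
            grp: {b: _BIOMARKER_BASE[grp][b] for b in BIOMARKERS} for grp in ("ndm", "dm")
        }
        # mild cluster-level shift of FG plus a non-additive bump for the
        # diabetic cell of selected clusters (the planted interaction)
        shift = 0.2 * (prev - mean_prev) / mean_prev
        means["ndm"]["fg"] += shift * 0.3
        means["dm"]["fg"] += shift * 0.3 + interaction
        sds = {
            grp: {b: _BIOMARKER_SD[grp][b] for b in BIOMARKERS} for grp in ("ndm", "dm")
        }
        specs.append(
            ClusterSpec(
                name=name,
                n=n,
                male_fraction=m / n,
                age_mean=age_m,
                age_sd=age_sd,
                bmi_mean=bmi_m,
                bmi_sd=bmi_sd,
                htn=htn,
                fhdm=fhdm,
                prevalence=prev,
                hazard=base_hazard * prev / mean_prev,
                biomarker_means=means,
                biomarker_sds=sds,
            )
        )
    return specs


def default_discovery_spec() -> list[ClusterSpec]:
    """The six discovery clusters transcribed from the published table.

    Sizes (1985, 3241, 862, 1013, 2645, 277) sum to 10,023; CL1/CL4 are
    all-male, CL2 all-female, the rest mixed with the printed male/female
    counts; prevalences are the printed diabetic fractions (0.09..0.44).
    """
    return _specs_from_table(tables.DISCOVERY_CLUSTERS, BASE_HAZARD)


def default_validation_spec() -> list[ClusterSpec]:
    """The six validation clusters (pooled cross-sectional cohorts)."""
    return _specs_from_table(tables.VALIDATION_CLUSTERS, BASE_HAZARD)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draws whose *post-truncation* mean equals ``mean``.

    The published per-cluster means describe the truncated (observed)
    data, so the latent location is solved such that the truncated
    distribution reproduces the printed mean rather than drifting from it.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    span = (hi - lo) + 6 * sd
    a0, b0 = lo - span, hi + span
    if (trunc_mean(a0) - mean) * (trunc_mean(b0) - mean) < 0:
        loc = brentq(lambda m: trunc_mean(m) - mean, a0, b0, xtol=1e-10)
    else:  # target outside the attainable truncated-mean range
        loc = mean
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a baseline cohort; one block of rows per ClusterSpec.

    Each row carries the five risk factors, the Bernoulli(prevalence)
    diabetes outcome and a hidden ``true_cluster`` column for recovery
    testing.  Identical configs (same seed) give identical tables.
    """
    if not config.specs:
        raise ValueError("empty spec list")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_window
    blo, bhi = config.bmi_bounds
    frames = []
    offset = 0
    for ci, spec in enumerate(config.specs, start=1):
        n = spec.n
        # exact sex counts (male=0): composition is part of the cluster spec
        n_male = int(round(spec.male_fraction * n))
        sex = rng.permutation(np.r_[np.zeros(n_male, int), np.ones(n - n_male, int)])
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, lo, hi, n)
        bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, blo, bhi, n)
        htn = np.full(n, spec.htn, dtype=int)
        fhdm = np.full(n, spec.fhdm, dtype=int)
        if config.flag_noise_rate > 0:
            htn = np.where(rng.random(n) < config.flag_noise_rate, 1 - htn, htn)
            fhdm = np.where(rng.random(n) < config.flag_noise_rate, 1 - fhdm, fhdm)
        dm = (rng.random(n) < spec.prevalence).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"S{offset + i:06d}" for i in range(n)],
                    "sex": sex,
                    "age": age,
                    "bmi": bmi,
                    "htn": htn,
                    "fhdm": fhdm,
                    "dm": dm,
                    "true_cluster": ci,
                }
            )
        )
        offset += n
    df = pd.concat(frames, ignore_index=True)
    return CohortTable(df)


def generate_followup(cohort: CohortTable, config: SimulationConfig) -> CohortTable:
    """Attach incident-diabetes follow-up to baseline non-diabetic rows.

    Onset times are exponential with the cluster hazard, censoring is an
    independent exponential at ``censoring_rate``, both truncated at
    ``followup_months_max``; times are rounded up to whole months.
    Baseline-diabetic rows get missing follow-up fields.
    """
    df = cohort.df.copy()
    if "true_cluster" not in df.columns:
        raise ValueError("cohort lacks the true_cluster column")
    for spec in config.specs:
        if spec.hazard is None:
            raise ValueError(f"spec {spec.name!r} has no hazard")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(df)
    hazard = np.array(
        [config.specs[c - 1].hazard for c in df["true_cluster"]], dtype=float
    )
    with np.errstate(divide="ignore"):
        onset = np.where(
            hazard > 0, rng.exponential(1.0, n) / np.where(hazard > 0, hazard, 1.0), np.inf
        )
    censor = (
        rng.exponential(1.0 / config.censoring_rate, n)
        if config.censoring_rate > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(censor, config.followup_months_max)
    event = (onset <= censor).astype(int)
    time = np.minimum(onset, censor)
    # monthly visit recoding: observed times land on whole months
    time = np.ceil(np.maximum(time, 1e-9))
    at_risk = df["dm"].to_numpy() == 0
    df["followup_months"] = np.where(at_risk, time, np.nan)
    df["event"] = np.where(at_risk, event, np.nan)
    return CohortTable(df)


def generate_biomarkers(cohort: CohortTable, config: SimulationConfig) -> CohortTable:
    """Draw per-(cluster, diabetes-status) normal biomarkers.

    Cell means come from each spec's ``biomarker_means``; non-additive
    cells plant a cluster-by-status interaction that two-way ANOVA should
    recover.
    """
    df = cohort.df.copy()
    if "true_cluster" not in df.columns:
        raise ValueError("cohort lacks the true_cluster column")
    for spec in config.specs:
        if spec.biomarker_means is None or spec.biomarker_sds is None:
            raise ValueError(f"spec {spec.name!r} has no biomarker parameters")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cl = df["true_cluster"].to_numpy()
    grp = np.where(df["dm"].to_numpy() == 1, "dm", "ndm")
    n = len(df)
    for marker in BIOMARKERS:
        mean = np.array(
            [config.specs[c - 1].biomarker_means[g][marker] for c, g in zip(cl, grp)]
        )
        sd = np.array(
            [config.specs[c - 1].biomarker_sds[g][marker] for c, g in zip(cl, grp)]
        )
        df[marker] = mean + sd * rng.standard_normal(n)
    return CohortTable(df)


def stratified_subsample(
    cohort: CohortTable, n: int, seed: int, by: str = "true_cluster"
) -> CohortTable:
    """Subsample ~n rows preserving the relative sizes of the strata.

    Each stratum contributes proportionally (at least one row); used to
    keep the O(n^2) distance computation tractable on large cohorts.
    """
    df = cohort.df
    if n >= len(df):
        return CohortTable(df.copy())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    parts = []
    for _, sub in df.groupby(by, sort=True):
        take = max(1, round(n * len(sub) / len(df)))
        idx = rng.choice(len(sub), size=min(take, len(sub)), replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    return CohortTable(pd.concat(parts, ignore_index=True))
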