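"""Follow-up validation of clusters: Kaplan-Meier curves, log-rank test,
cumulative incidence, and two-way ANOVA of biomarker profiles.

Survival analysis uses the disease-free interval from baseline to
incident diabetes or end of follow-up, with visit dates recoded to whole
months; baseline-diabetic participants are excluded upstream.  Biomarker
structure is tested with a two-factor (cluster x diabetes status) linear
model with interaction; unbalanced designs use Type II sums of squares
by default (the interaction term is identical across types).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .rfc import ClusterAssignment


@dataclass
class ClusterCurve:
    """One product-limit curve: event-time grid and survival steps."""

    cluster: int
    times: np.ndarray  # months, increasing
    survival: np.ndarray  # S(t) at each time, non-increasing from 1
    at_risk: np.ndarray
    n: int
    n_events: int


@dataclass
class SurvivalCurves:
    curves: dict[int, ClusterCurve]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for c, curve in sorted(self.curves.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "cluster": c,
                        "time_months": curve.times,
                        "survival": curve.survival,
                        "at_risk": curve.at_risk,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _followup_frame(cohort, assignment: ClusterAssignment) -> pd.DataFrame:
    df = getattr(cohort, "df", cohort)
    if "followup_months" not in df.columns or "event" not in df.columns:
        raise ValueError("cohort lacks follow-up columns (followup_months, event)")
    out = pd.DataFrame(
        {
            "cluster": assignment.labels,
            "time": df["followup_months"].to_numpy(dtype=float),
            "event": df["event"].to_numpy(dtype=float),
        }
    )
    if "dm" in df.columns:
        out = out[df["dm"].to_numpy() == 0]  # baseline-diabetic rows excluded
    out = out.dropna()
    if out.empty:
        raise ValueError("no follow-up rows after exclusions")
    return out


def km_curves(cohort, assignment: ClusterAssignment) -> SurvivalCurves:
    """Per-cluster Kaplan-Meier (product-limit) disease-free curves."""
    data = _followup_frame(cohort, assignment)
    curves = {}
    for c, sub in data.groupby("cluster"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        table = kmf.event_table
        times = table.index.to_numpy(dtype=float)
        surv = kmf.survival_function_["KM_estimate"].to_numpy()
        curves[int(c)] = ClusterCurve(
            cluster=int(c),
            times=times,
            survival=surv,
            at_risk=table["at_risk"].to_numpy(dtype=int),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return SurvivalCurves(curves=curves)


def logrank_test(cohort, assignment: ClusterAssignment) -> tuple[float, int, float]:
    """k-sample log-rank test across clusters; returns (stat, df, p)."""
    data = _followup_frame(cohort, assignment)
    if data["event"].sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    groups = data["cluster"].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters with follow-up")
    res = multivariate_logrank_test(data["time"], data["cluster"], data["event"])
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def cumulative_incidence(cohort, assignment: ClusterAssignment) -> pd.Series:
    """New cases / initial at-risk per cluster (simple proportion)."""
    data = _followup_frame(cohort, assignment)
    grouped = data.groupby("cluster")["event"]
    return grouped.sum() / grouped.count()


# ---------------------------------------------------------------------------
# biomarker structure


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition for one biomarker.

    ``table`` has rows cluster, dm, interaction, residual with columns
    sum_sq, df, F, p.
    """

    biomarker: str
    table: pd.DataFrame
    ss_type: int

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def interaction_p(self) -> float:
        return float(self.table.loc["interaction", "p"])


def two_way_anova(
    values: Sequence[float] | np.ndarray,
    cluster: Sequence[int] | np.ndarray,
    dm: Sequence[int] | np.ndarray,
    biomarker: str = "biomarker",
    ss_type: int = 2,
) -> AnovaResult:
    """Cluster x diabetes-status ANOVA with interaction.

    Effect degrees of freedom are (k-1), 1 and (k-1); unbalanced data use
    the sums-of-squares convention given by ``ss_type`` (2 by default;
    1 and 3 available).  Any participant filtering (e.g. restricting to
    never-diagnosed individuals via ``prior_dx``) happens upstream.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "cluster": np.asarray(cluster),
            "dm": np.asarray(dm),
        }
    ).dropna()
    if df["cluster"].nunique() < 2:
        raise ValueError("need >= 2 clusters")
    if df["dm"].nunique() < 2:
        raise ValueError("both diabetes-status groups must be present")
    cells = df.groupby(["cluster", "dm"]).size().unstack()
    if cells.isna().any().any() or (cells == 0).any().any():
        raise ValueError(
            "empty (cluster, dm) cell; the interaction is inestimable"
        )
    model = smf.ols("y ~ C(cluster) * C(dm)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    rename = {
        "C(cluster)": "cluster",
        "C(dm)": "dm",
        "C(cluster):C(dm)": "interaction",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename)
    cols = {"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    aov = aov[[c for c in cols if c in aov.columns]].rename(columns=cols)
    return AnovaResult(biomarker=biomarker, table=aov, ss_type=ss_type)


def biomarker_anova(
    cohort,
    assignment: ClusterAssignment,
    biomarkers: Sequence[str] = ("fg", "tchol", "tg", "hdl"),
    never_diagnosed_only: bool = True,
    ss_type: int = 2,
) -> dict[str, AnovaResult]:
    """Run the two-way ANOVA for each biomarker column of a cohort.

    When ``never_diagnosed_only`` and a ``prior_dx`` column exists,
    previously diagnosed participants are excluded first, isolating the
    natural biochemical differences between clusters.
    """
    df = getattr(cohort, "df", cohort)
    mask = np.ones(len(df), dtype=bool)
    if never_diagnosed_only and "prior_dx" in df.columns:
        mask &= df["prior_dx"].to_numpy() != 1
    results = {}
    for marker in biomarkers:
        if marker not in df.columns:
            continue
        results[marker] = two_way_anova(
            df.loc[mask, marker],
            assignment.labels[mask],
            df.loc[mask, "dm"],
            biomarker=marker,
            ss_type=ss_type,
        )
    return results
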