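"""Cluster-specific prediction performance for type 2 diabetes.

Fits per-cluster (or pooled) logistic risk scores on the five risk
factors, evaluates ROC curves and AUCs with DeLong confidence intervals,
compares AUCs between clusters, and sweeps fasting-glucose decision
thresholds to contrast per-cluster sensitivity and specificity.

The AUC is the Mann-Whitney statistic (ties counted 1/2): the
probability that a random case scores above a random control.  Its
variance, and the covariance of paired AUCs, follow DeLong's structural
components, so confidence intervals and difference tests are mutually
coherent.  Clusters are disjoint participant sets, so between-cluster
comparisons use the unpaired variant (independent variances summed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .gower import RISK_FACTORS
from .rfc import ClusterAssignment


# ---------------------------------------------------------------------------
# risk scores


@dataclass
class RiskScore:
    """Fitted logistic score over the risk factors; callable on a cohort."""

    params: pd.Series  # includes intercept; dropped predictors absent
    features: tuple[str, ...]
    dropped: tuple[str, ...]
    converged: bool
    cov: pd.DataFrame | None = None

    def standard_errors(self) -> pd.Series:
        if self.cov is None:
            raise ValueError("no covariance available (penalised fallback fit)")
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def __call__(self, cohort) -> np.ndarray:
        df = getattr(cohort, "df", cohort)
        X = df[list(self.features)].to_numpy(dtype=float)
        eta = self.params.iloc[0] + X @ self.params.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_risk_score(
    cohort, features: Sequence[str] = RISK_FACTORS, outcome: str = "dm"
) -> RiskScore:
    """Multivariable logistic model P(dm | risk factors) on a cohort subset.

    Constant columns (e.g. hypertension inside an all-hypertensive
    cluster) are dropped automatically.  Complete separation or
    non-convergence triggers a warning and a penalised refit.
    """
    import statsmodels.api as sm

    df = getattr(cohort, "df", cohort)
    y = df[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("subset must contain both outcome classes")
    kept = [f for f in features if df[f].nunique() > 1]
    dropped = tuple(f for f in features if f not in kept)
    X = sm.add_constant(df[kept].to_numpy(dtype=float))
    names = ["intercept"] + kept
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0)
        return RiskScore(
            params=pd.Series(fit.params, index=names),
            features=tuple(kept),
            dropped=dropped,
            converged=True,
            cov=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        )
    except Exception:
        warnings.warn(
            "logistic fit failed to converge (possible separation); "
            "using an L2-penalised fallback"
        )
        fit = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=np.r_[0.0, np.full(len(kept), 1e-4)], disp=0
        )
        return RiskScore(
            params=pd.Series(np.asarray(fit.params), index=names),
            features=tuple(kept),
            dropped=dropped,
            converged=False,
        )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Mann-Whitney AUC and DeLong structural components (V10, V01)."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = rankdata(all_scores)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # per-case placement values
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per-control placement values
    return auc, v10, v01


@dataclass
class RocResult:
    """ROC curve, AUC and DeLong 95% CI for one score on one subset."""

    cluster: str
    auc: float
    ci: tuple[float, float]
    var: float
    n_pos: int
    n_neg: int
    sensitivity: np.ndarray
    specificity: np.ndarray
    thresholds: np.ndarray
    v10: np.ndarray | None = None
    v01: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_auc(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    cluster: str = "all",
    ci_level: float = 0.95,
) -> RocResult:
    """ROC curve and AUC with a DeLong confidence interval.

    The AUC uses the rank (Mann-Whitney) construction with ties counted
    1/2; the CI is the asymptotic normal interval with DeLong's variance,
    clipped to [0, 1].  Degenerate variance (perfect separation) yields a
    point interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _delong_components(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    z = norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # ROC staircase over all distinct thresholds (predict positive if
    # score >= t), from most permissive to strictest
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = labels[order] == 1
    distinct = np.r_[True, np.diff(sorted_scores) != 0]
    idx = np.flatnonzero(distinct)
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    last = np.r_[idx[1:] - 1, len(scores) - 1]
    sens = np.r_[0.0, tp[last] / len(pos)]
    spec = np.r_[1.0, 1.0 - fp[last] / len(neg)]
    thresholds = np.r_[np.inf, sorted_scores[idx]]
    return RocResult(
        cluster=cluster,
        auc=float(auc),
        ci=ci,
        var=float(var),
        n_pos=len(pos),
        n_neg=len(neg),
        sensitivity=sens,
        specificity=spec,
        thresholds=thresholds,
        v10=v10,
        v01=v01,
    )


@dataclass
class AucComparison:
    pair: tuple[str, str]
    diff: float
    z: float
    p: float
    paired: bool


def compare_auc(a: RocResult, b: RocResult, paired: bool = False) -> AucComparison:
    """DeLong-style z test of the difference between two AUCs.

    Unpaired (the default; clusters are disjoint subject sets) sums the
    two independent variances.  Paired requires results computed on the
    same subjects in the same order and subtracts twice the covariance of
    the placement values.
    """
    diff = a.auc - b.auc
    if paired:
        if a.n_pos != b.n_pos or a.n_neg != b.n_neg:
            raise ValueError("paired comparison requires identical subject sets")
        cov = 0.0
        if a.n_pos > 1:
            cov += np.cov(a.v10, b.v10, ddof=1)[0, 1] / a.n_pos
        if a.n_neg > 1:
            cov += np.cov(a.v01, b.v01, ddof=1)[0, 1] / a.n_neg
        var = a.var + b.var - 2 * cov
    else:
        var = a.var + b.var
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if var <= 0 and diff == 0 else 2 * norm.sf(abs(z))
    return AucComparison(
        pair=(a.cluster, b.cluster), diff=float(diff), z=float(z), p=float(min(p, 1.0)),
        paired=paired,
    )


# ---------------------------------------------------------------------------
# cluster-level drivers


def cluster_risk_aucs(
    cohort, assignment: ClusterAssignment, features: Sequence[str] = RISK_FACTORS
) -> dict[str, RocResult]:
    """Per-cluster logistic risk scores and their in-sample (apparent) AUCs."""
    df = getattr(cohort, "df", cohort)
    out = {}
    for c in range(1, assignment.k + 1):
        sub = df[assignment.labels == c]
        if sub["dm"].nunique() < 2:
            warnings.warn(f"cluster {c} lacks one outcome class; skipped")
            continue
        score = fit_risk_score(sub, features=features)
        out[f"CL{c}"] = roc_auc(score(sub), sub["dm"], cluster=f"CL{c}")
    return out


def single_model_cluster_aucs(
    cohort, assignment: ClusterAssignment, features: Sequence[str] = RISK_FACTORS
) -> dict[str, RocResult]:
    """One pooled risk model; AUC evaluated within each cluster subset."""
    df = getattr(cohort, "df", cohort)
    score = fit_risk_score(df, features=features)
    scores = score(df)
    out = {"all": roc_auc(scores, df["dm"], cluster="all")}
    for c in range(1, assignment.k + 1):
        mask = assignment.labels == c
        if df.loc[mask, "dm"].nunique() < 2:
            warnings.warn(f"cluster {c} lacks one outcome class; skipped")
            continue
        out[f"CL{c}"] = roc_auc(scores[mask], df.loc[mask, "dm"], cluster=f"CL{c}")
    return out


DEFAULT_FG_GRID = np.round(np.arange(4.95, 5.5001, 0.05), 2)


@dataclass
class ThresholdSweep:
    """Sensitivity/specificity of a marker threshold, per cluster."""

    thresholds: np.ndarray
    sensitivity: pd.DataFrame  # rows thresholds, columns clusters
    specificity: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        sens = self.sensitivity.copy()
        sens.columns = [f"sens_{c}" for c in sens.columns]
        spec = self.specificity.copy()
        spec.columns = [f"spec_{c}" for c in spec.columns]
        out = pd.concat([sens, spec], axis=1)
        out.insert(0, "threshold", self.thresholds)
        return out.reset_index(drop=True)


def threshold_sweep(
    fg: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    assignment: ClusterAssignment,
    grid: Sequence[float] | np.ndarray = DEFAULT_FG_GRID,
) -> ThresholdSweep:
    """Per-cluster sensitivity/specificity of fasting glucose thresholds.

    At threshold t: sensitivity = P(fg >= t | dm=1), specificity =
    P(fg < t | dm=0), within each cluster.  A cluster lacking one
    outcome class gets NaN entries (flagged with a warning).
    """
    fg = np.asarray(fg, dtype=float)
    labels = np.asarray(labels, dtype=int)
    grid = np.asarray(grid, dtype=float)
    clusters = [f"CL{c}" for c in range(1, assignment.k + 1)]
    sens = np.full((len(grid), assignment.k), np.nan)
    spec = np.full_like(sens, np.nan)
    for j, c in enumerate(range(1, assignment.k + 1)):
        mask = assignment.labels == c
        pos = fg[mask & (labels == 1)]
        neg = fg[mask & (labels == 0)]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(f"cluster {c} lacks one outcome class; entries undefined")
        for i, t in enumerate(grid):
            if len(pos):
                sens[i, j] = np.mean(pos >= t)
            if len(neg):
                spec[i, j] = np.mean(neg < t)
    return ThresholdSweep(
        thresholds=grid,
        sensitivity=pd.DataFrame(sens, columns=clusters),
        specificity=pd.DataFrame(spec, columns=clusters),
    )
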