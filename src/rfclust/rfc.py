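"""Risk-factor-based clustering (RFC): agglomerative clustering with an
outcome-heterogeneity stopping rule.

The procedure clusters participants on their Gower dissimilarities with
complete linkage, then chooses the number of clusters k by scanning
k = 2, 3, ...: at each k the tree is cut, a 2 x k nondiabetic/diabetic
contingency table is formed, and its Pearson chi-square heterogeneity is
computed.  The scan stops at the first k whose test is *more* significant
than at k + 1 — splitting further no longer sharpens the prevalence
contrast between clusters.  Clusters are finally relabelled 1..k in
ascending order of diabetes prevalence.

:class:`RiskFactorClustering` wraps the whole procedure as a model object
whose :meth:`~RiskFactorClustering.fit` returns a
:class:`RFCResults` carrying the distance matrix, merge tree, selection
trace, labelled assignment and per-cluster prevalences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.special import gammaln
from scipy.stats import chi2

from .gower import DistanceMatrix, VariableSpec, default_variable_specs, gower_matrix


# ---------------------------------------------------------------------------
# tree construction and cutting


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``merges`` has one row per merge: (left node, right node, height,
    size); original observations are nodes 0..n-1, the i-th merge creates
    node n+i.  Heights are non-decreasing under complete linkage.
    """

    merges: np.ndarray
    n: int

    def to_newick(self) -> str:
        """Newick serialisation with branch lengths from merge heights."""
        tree = sch.to_tree(self.merges)

        def rec(node, parent_height):
            bl = parent_height - node.dist
            if node.is_leaf():
                return f"L{node.id}:{bl:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{bl:g}"

        return rec(tree, tree.dist) + ";"


@dataclass
class ClusterAssignment:
    """Cluster membership labels in 1..k, aligned with the cohort rows."""

    labels: np.ndarray
    k: int
    participant_id: np.ndarray | None = None
    allow_missing: bool = False  # a transferred labelling may miss a class

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if self.allow_missing:
            if present.min() < 1 or present.max() > self.k:
                raise ValueError(f"labels must lie in 1..{self.k}; got {present}")
        elif not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty cluster; got {present}"
            )

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        pid = (
            self.participant_id
            if self.participant_id is not None
            else np.arange(len(self.labels))
        )
        return pd.DataFrame({"participant_id": pid, "cluster": self.labels})


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    Inter-cluster distance is the maximum pairwise member distance.  The
    nearest-neighbour-chain algorithm used here resolves equal-height
    ties deterministically, so repeated runs give identical trees.
    """
    if dist.n < 2:
        raise ValueError("need at least 2 observations")
    merges = sch.linkage(dist.condensed, method="complete")
    return Dendrogram(merges=merges, n=dist.n)


def cut_tree(tree: Dendrogram, k: int) -> ClusterAssignment:
    """The k groups obtained by undoing the last k-1 merges.

    Labels are renumbered 1..k in order of first appearance so the
    mapping is deterministic.
    """
    if not 1 <= k <= tree.n:
        raise ValueError(f"k must be in [1, {tree.n}], got {k}")
    raw = sch.cut_tree(tree.merges, n_clusters=k).ravel()
    _, labels = np.unique(raw, return_inverse=True)
    # renumber in order of first appearance
    order = np.full(k, -1, dtype=int)
    nxt = 1
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if order[lab] == -1:
            order[lab] = nxt
            nxt += 1
        out[i] = order[lab]
    return ClusterAssignment(labels=out, k=k)


# ---------------------------------------------------------------------------
# outcome heterogeneity


@dataclass
class ContingencyTable:
    """2 x k table of nondiabetic / diabetic counts per cluster."""

    ndm: np.ndarray
    dm: np.ndarray

    def __post_init__(self) -> None:
        self.ndm = np.asarray(self.ndm, dtype=np.int64)
        self.dm = np.asarray(self.dm, dtype=np.int64)
        if self.ndm.shape != self.dm.shape or self.ndm.ndim != 1:
            raise ValueError("ndm and dm must be 1-d arrays of equal length")
        if (self.ndm < 0).any() or (self.dm < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.ndm)

    def counts(self) -> np.ndarray:
        return np.vstack([self.ndm, self.dm])

    def sizes(self) -> np.ndarray:
        return self.ndm + self.dm

    def prevalence(self) -> np.ndarray:
        return self.dm / self.sizes()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts(),
            index=["ndm", "dm"],
            columns=[f"CL{i}" for i in range(1, self.k + 1)],
        )


def prevalence_table(
    assignment: ClusterAssignment, dm: Sequence[int] | np.ndarray
) -> ContingencyTable:
    """Per-cluster nondiabetic/diabetic counts from labels and outcomes."""
    dm = np.asarray(dm, dtype=int)
    if len(dm) != len(assignment.labels):
        raise ValueError("assignment and outcome vector lengths differ")
    k = assignment.k
    dm_counts = np.bincount(assignment.labels[dm == 1], minlength=k + 1)[1:]
    sizes = assignment.sizes()
    if (sizes == 0).any():
        empty = np.flatnonzero(sizes == 0) + 1
        raise ValueError(f"cluster(s) {list(empty)} have no members")
    return ContingencyTable(ndm=sizes - dm_counts, dm=dm_counts)


def _chi2_logsf(stat: float, df: int) -> float:
    """log of the chi-square survival function, stable for extreme stats.

    scipy's ``chi2.logsf`` underflows to -inf for statistics of a few
    thousand; beyond that the asymptotic expansion of the upper
    incomplete gamma function Q(a, x) ~ x^(a-1) e^(-x) / Gamma(a) *
    (1 + (a-1)/x + (a-1)(a-2)/x^2 + ...) with a = df/2, x = stat/2 is
    used instead.
    """
    lp = chi2.logsf(stat, df)
    if np.isfinite(lp):
        return float(lp)
    a, x = df / 2.0, stat / 2.0
    series = 1.0
    term = 1.0
    for i in range(1, 12):
        term *= (a - i) / x
        series += term
        if abs(term) < 1e-17 * series:
            break
    return float(-x + (a - 1.0) * math.log(x) - gammaln(a) + math.log(series))


def chi_square_heterogeneity(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of prevalence heterogeneity on a 2 x k table.

    Returns ``(statistic, df, log_p)`` with df = k - 1 and the p-value in
    natural-log space (chi-square statistics in the hundreds drive p far
    below float underflow).  No continuity correction is applied.
    """
    if table.k < 2:
        raise ValueError("heterogeneity test needs k >= 2 clusters")
    obs = table.counts().astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row * col / total
    if (expected == 0).any():
        r, c = np.argwhere(expected == 0)[0]
        raise ValueError(
            f"zero expected count in cell ({['ndm', 'dm'][r]}, cluster {c + 1})"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = table.k - 1
    return stat, df, _chi2_logsf(stat, df)


@dataclass
class KSelectionResult:
    """Trace and outcome of the chi-square heterogeneity scan over k."""

    selected_k: int
    trace: dict[int, tuple[float, int, float]]  # k -> (stat, df, log_p)
    stopping_reason: str

    def to_json(self) -> str:
        payload = {
            "selected_k": self.selected_k,
            "stopping_reason": self.stopping_reason,
            "trace": {
                str(k): {"statistic": s, "df": d, "log_p": lp}
                for k, (s, d, lp) in self.trace.items()
            },
        }
        return json.dumps(payload, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "statistic": s, "df": d, "log10_p": lp / math.log(10)}
            for k, (s, d, lp) in sorted(self.trace.items())
        ]
        return pd.DataFrame(rows)


def select_k(
    tree: Dendrogram,
    dm: Sequence[int] | np.ndarray,
    k_min: int = 2,
    k_max: int = 12,
    min_cluster_size: int = 1,
    policy: str = "global",
) -> KSelectionResult:
    """Choose the cluster count by chi-square prevalence heterogeneity.

    Scans k = k_min..k_max; at each k cuts the tree, builds the 2 x k
    prevalence table and computes its chi-square log p-value.

    ``policy="global"`` (default) splits until the heterogeneity is
    maximised: it returns the k with the smallest log p-value over the
    whole scan (ties go to the smaller k).  ``policy="local"`` is the
    first-improvement variant: the first k with log p(k) strictly smaller
    (more significant) than log p(k+1); a tie continues the scan.  The
    two agree whenever significance increases monotonically up to the
    optimum, but the local rule stops early when an intermediate cut
    happens to be prevalence-neutral.  If the local scan never stops
    before k_max, k_max is returned with reason "scan exhausted".

    Cuts where a cluster falls below ``min_cluster_size``, or where the
    test is inestimable (a zero expected count), are recorded in the
    trace with ``log_p = +inf`` (never more significant than any valid k).
    """
    dm = np.asarray(dm, dtype=int)
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max >= tree.n:
        raise ValueError("k_max must be smaller than the number of observations")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if policy not in ("global", "local"):
        raise ValueError("policy must be 'global' or 'local'")

    trace: dict[int, tuple[float, int, float]] = {}

    def log_p(k: int) -> float:
        if k not in trace:
            assignment = cut_tree(tree, k)
            if assignment.sizes().min() < min_cluster_size:
                trace[k] = (math.nan, k - 1, math.inf)
            else:
                try:
                    trace[k] = chi_square_heterogeneity(
                        prevalence_table(assignment, dm)
                    )
                except ValueError:
                    trace[k] = (math.nan, k - 1, math.inf)
        return trace[k][2]

    if policy == "local":
        for k in range(k_min, k_max):
            if log_p(k) < log_p(k + 1):
                return KSelectionResult(
                    selected_k=k,
                    trace=dict(trace),
                    stopping_reason=f"p({k}) more significant than p({k + 1})",
                )
        log_p(k_max)
        return KSelectionResult(
            selected_k=k_max, trace=dict(trace), stopping_reason="scan exhausted"
        )

    for k in range(k_min, k_max + 1):
        log_p(k)
    best = min(sorted(trace), key=lambda k: (trace[k][2], k))
    if not np.isfinite(trace[best][2]):
        raise ValueError("no k in the scan range yields a valid heterogeneity test")
    return KSelectionResult(
        selected_k=best,
        trace=dict(trace),
        stopping_reason=f"heterogeneity maximal at k={best} over scan "
        f"[{k_min}, {k_max}]",
    )


def label_by_prevalence(
    assignment: ClusterAssignment, dm: Sequence[int] | np.ndarray
) -> ClusterAssignment:
    """Renumber clusters 1..k by ascending diabetes prevalence.

    Ties on (unrounded) prevalence are broken by descending cluster size,
    then by the original label.
    """
    table = prevalence_table(assignment, dm)
    prev = table.prevalence()
    sizes = table.sizes()
    order = sorted(range(assignment.k), key=lambda c: (prev[c], -sizes[c], c))
    mapping = np.empty(assignment.k + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        mapping[old + 1] = new
    return ClusterAssignment(
        labels=mapping[assignment.labels],
        k=assignment.k,
        participant_id=assignment.participant_id,
    )


# ---------------------------------------------------------------------------
# model / results interface


class RiskFactorClustering:
    """Risk-factor-based clustering of a cohort.

    Parameters
    ----------
    cohort : CohortTable or DataFrame
        Must contain the five risk factors (sex, age, bmi, htn, fhdm)
        and the diabetes outcome ``dm``.
    variable_specs : list of VariableSpec, optional
        Gower variable typing; defaults to the standard study specs.
    k_min, k_max : int
        Scan range for the heterogeneity stopping rule.

    Examples
    --------
    >>> model = RiskFactorClustering(cohort)
    >>> res = model.fit()
    >>> res.selected_k, res.prevalences
    """

    def __init__(
        self,
        cohort,
        variable_specs: Sequence[VariableSpec] | None = None,
        k_min: int = 2,
        k_max: int = 12,
        min_cluster_size: int = 1,
        policy: str = "global",
    ):
        self.df = getattr(cohort, "df", cohort)
        if "dm" not in self.df.columns:
            raise ValueError("cohort must carry the diabetes outcome column 'dm'")
        self.variable_specs = (
            list(variable_specs) if variable_specs is not None else default_variable_specs()
        )
        self.k_min = k_min
        self.k_max = k_max
        self.min_cluster_size = min_cluster_size
        self.policy = policy

    def fit(self) -> "RFCResults":
        dist = gower_matrix(self.df, self.variable_specs)
        tree = complete_linkage(dist)
        dm = self.df["dm"].to_numpy(dtype=int)
        selection = select_k(
            tree, dm, self.k_min, self.k_max, self.min_cluster_size, self.policy
        )
        assignment = label_by_prevalence(cut_tree(tree, selection.selected_k), dm)
        if "participant_id" in self.df.columns:
            assignment.participant_id = self.df["participant_id"].to_numpy()
        table = prevalence_table(assignment, dm)
        return RFCResults(
            model=self,
            distance=dist,
            dendrogram=tree,
            selection=selection,
            assignment=assignment,
            contingency=table,
        )


@dataclass
class RFCResults:
    """Fitted clustering: tree, k-selection trace, labels and prevalences."""

    model: RiskFactorClustering
    distance: DistanceMatrix
    dendrogram: Dendrogram
    selection: KSelectionResult
    assignment: ClusterAssignment
    contingency: ContingencyTable

    @property
    def selected_k(self) -> int:
        return self.selection.selected_k

    @property
    def prevalences(self) -> np.ndarray:
        return self.contingency.prevalence()

    def heterogeneity(self) -> tuple[float, int, float]:
        return chi_square_heterogeneity(self.contingency)

    def summary(self) -> pd.DataFrame:
        """Per-cluster composition table of the fitted clustering."""
        df = self.model.df
        labels = self.assignment.labels
        rows = []
        for c in range(1, self.selected_k + 1):
            sub = df[labels == c]
            rows.append(
                {
                    "cluster": f"CL{c}",
                    "n": len(sub),
                    "n_male": int((sub["sex"] == 0).sum()),
                    "n_female": int((sub["sex"] == 1).sum()),
                    "age_mean": sub["age"].mean(),
                    "age_sd": sub["age"].std(),
                    "bmi_mean": sub["bmi"].mean(),
                    "bmi_sd": sub["bmi"].std(),
                    "htn_frac": sub["htn"].mean(),
                    "fhdm_frac": sub["fhdm"].mean(),
                    "prevalence": sub["dm"].mean(),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        stat, dfree, log_p = self.heterogeneity()
        lines = [
            "Risk-factor-based clustering",
            f"  n = {len(self.assignment.labels)}, selected k = {self.selected_k} "
            f"({self.selection.stopping_reason})",
            f"  heterogeneity chi-square = {stat:.2f}, df = {dfree}, "
            f"log10 p = {log_p / math.log(10):.2f}",
            self.summary().to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)
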