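"""Gower dissimilarity for mixed numeric / binary risk-factor profiles.

The Gower distance between two participants is the weighted mean of
per-variable contributions

    d(a, b) = sum_v w_v * delta_v * d_v(a, b) / sum_v w_v * delta_v

where numeric variables contribute ``|a_v - b_v| / range_v`` (always
comparable, ``delta_v = 1``) and binary variables contribute 0/1
mismatch.  Risk-factor binaries (sex, hypertension, family history) are
treated as *asymmetric*: a shared absence (0-0) carries no information
and the pair is excluded from the average (``delta_v = 0``), so the
presence of a risk factor weighs more than its absence.

Numeric ranges default to the observed min/max of the clustering data
and are stored on the result so that distances for a second cohort can
reuse the discovery scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

VariableKind = Literal["numeric", "binary_asymmetric", "binary_symmetric"]

#: canonical risk-factor columns used for clustering
RISK_FACTORS = ("sex", "age", "bmi", "htn", "fhdm")


@dataclass(frozen=True)
class VariableSpec:
    """Typing, scaling range and weight of one clustering variable.

    ``value_range`` is ``None`` for binaries and for numerics whose range
    should be computed from the data at matrix time.  A constant numeric
    variable gets a degenerate range and contributes 0 (flagged with a
    warning).
    """

    name: str
    kind: VariableKind = "numeric"
    value_range: tuple[float, float] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"negative weight for variable {self.name!r}")
        if self.value_range is not None and self.kind != "numeric":
            raise ValueError("value_range only applies to numeric variables")


def default_variable_specs(sex_asymmetric: bool = True) -> list[VariableSpec]:
    """The five risk-factor specs used for clustering.

    Age and BMI are numeric (range-scaled from the data); hypertension
    and family history of diabetes are asymmetric binaries.  Sex
    (male=0, female=1) is asymmetric by default — matching a binary
    treatment where male-male pairs contribute no sex term — with a
    symmetric alternative behind ``sex_asymmetric=False``.
    """
    sex_kind = "binary_asymmetric" if sex_asymmetric else "binary_symmetric"
    return [
        VariableSpec("sex", sex_kind),
        VariableSpec("age", "numeric"),
        VariableSpec("bmi", "numeric"),
        VariableSpec("htn", "binary_asymmetric"),
        VariableSpec("fhdm", "binary_asymmetric"),
    ]


@dataclass
class DistanceMatrix:
    """Condensed pairwise Gower distances plus the resolved variable specs."""

    n: int
    condensed: np.ndarray  # length n*(n-1)//2, float64 in [0, 1]
    variable_specs: list[VariableSpec] = field(default_factory=list)

    def square(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)

    def to_csv(self, path) -> None:
        """Write the full square matrix (for inspection; O(n^2) cells)."""
        pd.DataFrame(self.square()).to_csv(path, index=False)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        if i == j:
            return 0.0
        i, j = (i, j) if i < j else (j, i)
        return float(self.condensed[self.n * i - i * (i + 1) // 2 + (j - i - 1)])


def _check_binary(values: np.ndarray, name: str) -> None:
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"binary variable {name!r} contains values outside {{0, 1}}")


def gower_pair(
    a: Mapping[str, float],
    b: Mapping[str, float],
    specs: Sequence[VariableSpec],
) -> float:
    """Gower dissimilarity between two profiles.

    Numeric specs must carry an explicit ``value_range`` here (there is
    no data to infer one from).  Returns 0 with a warning if every
    variable is an excluded asymmetric 0-0 pair.
    """
    num = 0.0
    den = 0.0
    for spec in specs:
        av, bv = float(a[spec.name]), float(b[spec.name])
        if spec.kind == "numeric":
            if spec.value_range is None:
                raise ValueError(
                    f"numeric variable {spec.name!r} needs an explicit range for "
                    "pairwise evaluation"
                )
            lo, hi = spec.value_range
            if not (lo <= av <= hi and lo <= bv <= hi):
                raise ValueError(f"value outside declared range for {spec.name!r}")
            rng = hi - lo
            num += spec.weight * (abs(av - bv) / rng if rng > 0 else 0.0)
            den += spec.weight
        else:
            _check_binary(np.array([av, bv]), spec.name)
            if spec.kind == "binary_asymmetric" and av == 0 and bv == 0:
                continue  # joint absence: excluded
            num += spec.weight * (0.0 if av == bv else 1.0)
            den += spec.weight
    if den == 0:
        warnings.warn("all variable pairs excluded (joint absences); distance set to 0")
        return 0.0
    return num / den


def resolve_ranges(
    data: pd.DataFrame, specs: Iterable[VariableSpec]
) -> list[VariableSpec]:
    """Fill in numeric ranges from observed min/max where not overridden."""
    resolved = []
    for spec in specs:
        if spec.kind == "numeric" and spec.value_range is None:
            col = data[spec.name].to_numpy(dtype=float)
            spec = replace(spec, value_range=(float(col.min()), float(col.max())))
        resolved.append(spec)
    return resolved


def gower_matrix(
    cohort, specs: Sequence[VariableSpec] | None = None
) -> DistanceMatrix:
    """All pairwise Gower distances for a cohort.

    Parameters
    ----------
    cohort : CohortTable or DataFrame with the spec'd columns.
    specs : variable specs; defaults to :func:`default_variable_specs`.
    """
    df = getattr(cohort, "df", cohort)
    if specs is None:
        specs = default_variable_specs()
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    specs = resolve_ranges(df, specs)

    num = np.zeros(n * (n - 1) // 2)
    den = np.zeros_like(num)
    for spec in specs:
        x = df[spec.name].to_numpy(dtype=float)
        if spec.kind == "numeric":
            lo, hi = spec.value_range
            col_min, col_max = float(x.min()), float(x.max())
            if col_min < lo or col_max > hi:
                raise ValueError(f"value outside declared range for {spec.name!r}")
            rng = hi - lo
            if rng == 0:
                warnings.warn(
                    f"numeric variable {spec.name!r} is constant; it contributes 0"
                )
                den += spec.weight
                continue
            num += spec.weight / rng * pdist(x[:, None], "cityblock")
            den += spec.weight
        else:
            _check_binary(x, spec.name)
            diff = pdist(x[:, None], "cityblock")  # 1 iff the pair differs
            num += spec.weight * diff
            if spec.kind == "binary_asymmetric":
                absent = (x == 0).astype(float)
                both_absent = squareform(np.outer(absent, absent), checks=False)
                den += spec.weight * (1.0 - both_absent)
            else:
                den += spec.weight
    zero_den = den == 0
    if zero_den.any():
        warnings.warn(
            f"{int(zero_den.sum())} pairs share only joint absences; distance set to 0"
        )
        den[zero_den] = 1.0
        num[zero_den] = 0.0
    d = num / den
    # guard against float round-off at the boundaries
    np.clip(d, 0.0, 1.0, out=d)
    return DistanceMatrix(n=n, condensed=d, variable_specs=list(specs))
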