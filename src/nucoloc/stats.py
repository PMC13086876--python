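"""Group comparisons for per-cell colocalization scores.

Two-group comparisons use Welch's unequal-variance t-test by default
(Student's pooled variant is available by flag).  Multi-group designs
use one-way ANOVA followed by either Dunnett's many-to-one procedure
(each treatment vs one control, family-wise adjusted via the
multivariate-t distribution) or Tukey's all-pairs HSD (studentized
range).  All tests are two-sided.  Undefined per-cell coefficients are
excluded listwise and the exclusion count is reported, so group n
always refers to analyzed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "two_group_test",
    "anova_dunnett",
    "anova_tukey",
    "p_to_stars",
]


@dataclass
class ComparisonResult:
    """Outcome of one group-comparison procedure."""

    method: str
    groups: list[str]
    n: list[int]
    mean: list[float]
    sd: list[float]
    statistic: float                       # t for two groups, F for ANOVA
    p_raw: float                           # two-group p, or ANOVA p
    comparisons: pd.DataFrame | None = None  # per-contrast adjusted p-values
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Group summary as a table (one row per group)."""
        return pd.DataFrame(
            {"group": self.groups, "n": self.n, "mean": self.mean, "sd": self.sd}
        )


def _clean(values) -> tuple[np.ndarray, int]:
    arr = np.asarray(
        [v for v in values if v is not None], dtype=float
    )
    finite = arr[np.isfinite(arr)]
    return finite, int(len(list(values)) - finite.size)


def _summaries(groups, names):
    cleaned, excluded = [], 0
    for g in groups:
        arr, nex = _clean(g)
        cleaned.append(arr)
        excluded += nex
    n = [int(a.size) for a in cleaned]
    mean = [float(a.mean()) if a.size else float("nan") for a in cleaned]
    sd = [float(a.std(ddof=1)) if a.size > 1 else float("nan") for a in cleaned]
    return cleaned, n, mean, sd, excluded


def two_group_test(
    a, b, names: tuple[str, str] = ("a", "b"), equal_var: bool = False
) -> ComparisonResult:
    """Two-sample t-test (Welch by default) on defined values.

    Undefined (None/NaN) values are dropped and counted in
    ``n_excluded``.  Each group must retain at least two values.
    """
    (ca, cb), n, mean, sd, excluded = _summaries([a, b], names)
    if min(n) < 2:
        raise ValueError("each group needs at least 2 defined values")
    res = sps.ttest_ind(ca, cb, equal_var=equal_var)
    return ComparisonResult(
        method="student_t" if equal_var else "welch_t",
        groups=list(names),
        n=n,
        mean=mean,
        sd=sd,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n_excluded=excluded,
    )


def anova_dunnett(
    groups,
    control_index: int = 0,
    names: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ComparisonResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    Each non-control group is compared against ``groups[control_index]``
    with family-wise error control over the whole set of contrasts; the
    adjusted p-values come from the equicorrelated multivariate-t
    distribution of the contrast statistics.  ``rng`` seeds the
    quasi-Monte-Carlo evaluation of that distribution so adjusted
    p-values are reproducible.
    """
    groups = list(groups)
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use two_group_test for two")
    names = names or [f"g{i}" for i in range(len(groups))]
    cleaned, n, mean, sd, excluded = _summaries(groups, names)
    if min(n) < 2:
        raise ValueError("each group needs at least 2 defined values")

    f_stat, f_p = sps.f_oneway(*cleaned)
    control = cleaned[control_index]
    treats = [c for i, c in enumerate(cleaned) if i != control_index]
    treat_names = [nm for i, nm in enumerate(names) if i != control_index]
    res = sps.dunnett(*treats, control=control, rng=rng)

    raw = [
        float(sps.ttest_ind(t, control, equal_var=True).pvalue) for t in treats
    ]
    comparisons = pd.DataFrame(
        {
            "comparison": [f"{t} vs {names[control_index]}" for t in treat_names],
            "statistic": np.asarray(res.statistic, dtype=float),
            "p_raw": raw,
            "p_adjusted": np.maximum(np.asarray(res.pvalue, dtype=float), raw),
            "stars": [p_to_stars(p) for p in np.asarray(res.pvalue, dtype=float)],
        }
    )
    return ComparisonResult(
        method="anova_dunnett",
        groups=list(names),
        n=n,
        mean=mean,
        sd=sd,
        statistic=float(f_stat),
        p_raw=float(f_p),
        comparisons=comparisons,
        n_excluded=excluded,
    )


def anova_tukey(groups, names: list[str] | None = None) -> ComparisonResult:
    """One-way ANOVA followed by Tukey's HSD over all pairs."""
    groups = list(groups)
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use two_group_test for two")
    names = names or [f"g{i}" for i in range(len(groups))]
    cleaned, n, mean, sd, excluded = _summaries(groups, names)
    if min(n) < 2:
        raise ValueError("each group needs at least 2 defined values")

    f_stat, f_p = sps.f_oneway(*cleaned)
    res = sps.tukey_hsd(*cleaned)
    rows = []
    for i in range(len(cleaned)):
        for j in range(i + 1, len(cleaned)):
            raw = float(sps.ttest_ind(cleaned[i], cleaned[j], equal_var=True).pvalue)
            adj = float(res.pvalue[i, j])
            rows.append(
                {
                    "comparison": f"{names[i]} vs {names[j]}",
                    "statistic": float(res.statistic[i, j]),
                    "p_raw": raw,
                    "p_adjusted": max(adj, raw),
                    "stars": p_to_stars(adj),
                }
            )
    return ComparisonResult(
        method="anova_tukey",
        groups=list(names),
        n=n,
        mean=mean,
        sd=sd,
        statistic=float(f_stat),
        p_raw=float(f_p),
        comparisons=pd.DataFrame(rows),
        n_excluded=excluded,
    )


def p_to_stars(p: float) -> str:
    """Figure-legend star annotation: p <= .05/.01/.001/.0001 -> * .. ****."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
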