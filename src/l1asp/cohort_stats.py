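"""Group comparison and discrimination statistics for cohort tables.

Per-sample methylation / expression values labelled N (normal tissue from a
cancer-free bladder), CN (histologically normal tissue from a tumor-bearing
bladder) and T (tumor) are compared with a two-sided Mann-Whitney U test
(exact by full enumeration for small tie-free samples, normal approximation
with tie and continuity corrections otherwise), summarized with significance
stars, and assessed as a classifier with ROC curves whose AUC satisfies the
identity AUC = U / (n1 * n2).

For methylation variables the *positive* (disease) class is marked by LOW
values — hypomethylation is the signal — so the ROC direction is an explicit
parameter rather than a silent convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import DataError

EXACT_LIMIT = 16  # n1 + n2 at or below which the exact null distribution is enumerated

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value onto the conventional star annotation."""
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return ""


@dataclass(frozen=True)
class TestResult:
    """A two-sided Mann-Whitney U test result."""

    u: float  # U statistic of the first sample, mid-ranks on ties
    p: float
    method: str  # 'exact' | 'normal-approximation'
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise DataError("U out of range [0, n1*n2]")
        if not 0 < self.p <= 1:
            raise DataError("p-value out of (0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a`` via mid-rank assignment on the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[: a.size].sum())
    return r1 - a.size * (a.size + 1) / 2.0


def _exact_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """Exact two-sided p by enumerating every group-a rank assignment.

    Only valid without ties: the pooled ranks are then 1..N and each of the
    C(N, n1) subsets is equally likely under the null.  The two-sided p is
    the probability of a U at least as far from n1*n2/2 as observed.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for subset in combinations(range(1, n + 1), n1):
        u = sum(subset) - offset
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    U uses mid-ranks on ties.  With ``n1 + n2 <= 16`` and no ties the exact
    two-sided p is computed by full enumeration of rank assignments;
    otherwise a normal approximation with tie correction and a continuity
    correction is used.  The method actually taken is recorded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        p = _exact_two_sided_p(u, n1, n2)
        return TestResult(u=u, p=max(p, np.finfo(float).tiny), method="exact", n1=n1, n2=n2)

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # All pooled values identical: no evidence against the null.
        return TestResult(u=u, p=1.0, method="normal-approximation", n1=n1, n2=n2)
    # Continuity correction: shrink the deviation by 1/2 toward the mean.
    dev = max(abs(u - mu) - 0.5, 0.0)
    z = dev / np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return TestResult(
        u=u, p=max(p, np.finfo(float).tiny), method="normal-approximation", n1=n1, n2=n2
    )


@dataclass(frozen=True)
class RocCurve:
    """A ROC curve from a threshold sweep over the pooled unique scores."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # on the oriented scale (higher = more positive)
    auc: float
    direction: str  # 'low' | 'high': which raw scores mark the positive class

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise DataError("ROC points must be monotone non-decreasing")
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise DataError("AUC out of [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    direction: str = "low",
) -> RocCurve:
    """ROC curve and AUC discriminating the positive from the negative group.

    ``direction='low'`` declares that LOW raw scores mark the positive class
    (the default for methylation, where hypomethylation is the disease
    signal); ``'high'`` the opposite.  The curve sweeps the unique scores as
    thresholds; tied scores contribute diagonal segments, so the trapezoidal
    AUC credits ties 0.5 and equals U / (n1 * n2) exactly.
    """
    if direction not in ("low", "high"):
        raise DataError("direction must be 'low' or 'high'")
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both groups must be non-empty")
    if direction == "low":
        pos, neg = -pos, -neg
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
    tpr_arr = np.asarray(tpr)
    fpr_arr = np.asarray(fpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(
        fpr=fpr_arr,
        tpr=tpr_arr,
        thresholds=np.concatenate([[np.inf], thresholds]),
        auc=auc,
        direction=direction,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptives and all pairwise Mann-Whitney contrasts."""

    per_group: pd.DataFrame  # group, n, mean, median
    contrasts: pd.DataFrame  # group_a, group_b, u, p, method, stars, skipped


def group_summary(
    table: pd.DataFrame,
    variable: str = "methylation",
    groups: Sequence[str] | None = None,
    bonferroni: bool = False,
) -> GroupSummary:
    """Summarize a cohort variable per group with pairwise significance stars.

    The group central value reported as ``mean`` is the one a horizontal
    line would mark on a scatter figure.  Stars follow the conventional
    cutpoints (*** p<0.001, ** p<0.01, * p<0.05), from unadjusted two-sided
    Mann-Whitney p-values by default; ``bonferroni=True`` multiplies each p
    by the number of contrasts computed (capped at 1).  Contrasts involving
    a single-sample group are skipped with a warning.
    """
    if variable not in table.columns:
        raise DataError(f"variable {variable!r} not in table")
    if "group" not in table.columns:
        raise DataError("table must have a 'group' column")
    if groups is None:
        groups = list(dict.fromkeys(table["group"]))
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    values = {}
    for g in groups:
        v = table.loc[table["group"] == g, variable].to_numpy(dtype=float)
        if v.size == 0:
            raise DataError(f"group {g!r} is empty")
        values[g] = v

    per_group = pd.DataFrame(
        {
            "group": list(groups),
            "n": [values[g].size for g in groups],
            "mean": [float(values[g].mean()) for g in groups],
            "median": [float(np.median(values[g])) for g in groups],
        }
    )
    rows = []
    for ga, gb in combinations(groups, 2):
        if values[ga].size < 2 or values[gb].size < 2:
            warnings.warn(
                f"contrast {ga} vs {gb} skipped: single-sample group", stacklevel=2
            )
            rows.append(
                {
                    "group_a": ga, "group_b": gb, "u": np.nan, "p": np.nan,
                    "method": "", "stars": "", "skipped": True,
                }
            )
            continue
        res = mann_whitney_u(values[ga], values[gb])
        rows.append(
            {
                "group_a": ga, "group_b": gb, "u": res.u, "p": res.p,
                "method": res.method, "stars": "", "skipped": False,
            }
        )
    n_tested = sum(not r["skipped"] for r in rows)
    for r in rows:
        if r["skipped"]:
            continue
        if bonferroni:
            r["p"] = min(1.0, r["p"] * n_tested)
        r["stars"] = significance_stars(r["p"])
    contrasts = pd.DataFrame(
        rows, columns=["group_a", "group_b", "u", "p", "method", "stars", "skipped"]
    )
    return GroupSummary(per_group=per_group, contrasts=contrasts)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between methylation and expression."""

    rho: float
    p: float
    sign: str  # 'negative' | 'positive' | 'zero'
    n: int


def methylation_expression_correlation(table: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation of per-sample methylation vs expression.

    A negative sign is the expected direction when the assayed promoter
    drives the measured transcript: hypomethylation permits expression.
    """
    for col in ("methylation", "expression"):
        if col not in table.columns:
            raise DataError(f"table lacks column {col!r}")
    meth = table["methylation"].to_numpy(dtype=float)
    expr = table["expression"].to_numpy(dtype=float)
    if meth.size < 3:
        raise DataError("need at least 3 samples")
    if np.unique(meth).size == 1 or np.unique(expr).size == 1:
        raise DataError("correlation undefined: constant variable")
    rho, p = stats.spearmanr(meth, expr)
    sign = "negative" if rho < 0 else ("positive" if rho > 0 else "zero")
    return CorrelationResult(rho=float(rho), p=float(p), sign=sign, n=meth.size)
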