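"""Statistics for internal-dose (biomonitoring) data.

Urinary cadmium (UCd) reflects long-term body burden and blood cadmium (BCd)
recent exposure; both are measured in ug/L with a detection limit below which
values are substituted by LOD/2.  Group contrasts (sex, smoking status) use
the two-sided Mann-Whitney U test because the concentrations are strongly
right-skewed; external-internal dose agreement uses Pearson (default) or
Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tables import ValidationError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "substitute_lod",
    "mann_whitney",
    "correlation",
]


def substitute_lod(
    values: Sequence[float],
    lod: float,
    below_lod: Sequence[bool] | None = None,
) -> list[float]:
    """Replace values below the detection limit by LOD/2.

    A value is substituted when it is strictly below ``lod`` or explicitly
    flagged in ``below_lod``; the boundary value equal to the LOD is "not
    below" and kept.  Idempotent, since LOD/2 is itself below the LOD and
    maps to LOD/2 again.
    """
    if lod <= 0:
        raise ValidationError("lod must be positive")
    flags = [False] * len(values) if below_lod is None else list(below_lod)
    if len(flags) != len(values):
        raise ValidationError("below_lod flags must match values in length")
    out = []
    for v, flagged in zip(values, flags):
        if v < 0 and not flagged:
            raise ValidationError(f"negative unflagged measurement {v}")
        out.append(lod / 2.0 if flagged or v < lod else float(v))
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample Mann-Whitney comparison."""

    labels: tuple[str, str]
    n: tuple[int, int]
    u_statistic: float
    p_value: float
    means: tuple[float, float]
    medians: tuple[float, float]


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test (U of the first group, from rank sums).

    The exact null distribution is used for small samples
    (min(n1, n2) <= 8) without ties; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        labels=labels,
        n=(int(a.size), int(b.size)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(np.median(a)), float(np.median(b))),
    )


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        method=method,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
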