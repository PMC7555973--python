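"""Statistical primitives for accuracy scoring.

Correlation conventions here differ from scipy's in one deliberate way:
a correlation over fewer than three complete pairs, or involving a
zero-variance vector, is *undefined* (not 0, not a warning + nan).
Undefined correlations propagate as missing components into Fisher-z
aggregation, where they count against the availability proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationValue",
    "AggregateScore",
    "TestResult",
    "pearson_r",
    "spearman_rho",
    "fisher_z",
    "aggregate_z",
    "cronbach_alpha",
    "disattenuate",
    "one_sample_t",
    "pooled_two_sample_t",
]

#: default clip for |r| -> 1 before the Fisher transform (artanh(1) is infinite
#: and a single perfect correlation would otherwise dominate any average)
DEFAULT_CLIP = 0.999

#: default minimum proportion of defined components required for an aggregate
DEFAULT_MIN_PROP = 0.8


@dataclass(frozen=True)
class CorrelationValue:
    """A sample correlation together with the number of pairs it used.

    ``r`` is ``nan`` when the correlation is undefined (fewer than three
    complete pairs, or a zero-variance vector).
    """

    r: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class AggregateScore:
    """Fisher-z average of a set of correlations.

    ``mean_z`` is the mean of the defined components' Fisher-z values and
    ``r_back = tanh(mean_z)`` its back-transform to the correlation scale.
    """

    mean_z: float
    r_back: float
    n_components: int
    n_available: int


@dataclass(frozen=True)
class TestResult:
    """t statistic, degrees of freedom and two-sided p value."""

    statistic: float
    df: float
    p_two_sided: float
    defined: bool = True


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_r(x, y) -> CorrelationValue:
    """Pearson correlation over complete pairs.

    Pairs with a missing (nan) element are dropped first.  Undefined when
    fewer than 3 pairs remain or either vector has zero variance.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 3:
        return CorrelationValue(math.nan, n)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx <= 0.0 or sy <= 0.0:
        return CorrelationValue(math.nan, n)
    r = float(xd @ yd) / math.sqrt(sx * sy)
    return CorrelationValue(max(-1.0, min(1.0, r)), n)


def spearman_rho(x, y) -> CorrelationValue:
    """Spearman rank correlation: Pearson on mid-ranks (ties get mean rank)."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        return CorrelationValue(math.nan, x.size)
    return pearson_r(sps.rankdata(x), sps.rankdata(y))


def fisher_z(r: float, inverse: bool = False, clip: float = DEFAULT_CLIP) -> float:
    """Fisher variance-stabilizing transform artanh(r); ``inverse`` gives tanh.

    Forward values with |r| above ``clip`` are clipped to ±``clip`` so that
    perfect correlations stay finite under averaging.
    """
    if not math.isfinite(r):
        raise ValueError(f"non-finite input to fisher_z: {r}")
    if inverse:
        return math.tanh(r)
    if abs(r) > 1.0:
        raise ValueError(f"|r| > 1: {r}")
    return math.atanh(max(-clip, min(clip, r)))


def aggregate_z(
    rs: Iterable[CorrelationValue],
    min_prop: float = DEFAULT_MIN_PROP,
    clip: float = DEFAULT_CLIP,
) -> AggregateScore | None:
    """Average correlations on the Fisher-z scale.

    Undefined components are dropped but count against availability: if the
    proportion of defined components falls below ``min_prop`` the aggregate
    itself is missing (``None``).  Defaults to the 80% availability rule
    (20 of 24 trait cells; 24 of 30 profile correlations).
    """
    if not 0.0 < min_prop <= 1.0:
        raise ValueError(f"min_prop must be in (0, 1]: {min_prop}")
    rs = list(rs)
    if not rs:
        raise ValueError("empty component list")
    total = len(rs)
    zs = [fisher_z(c.r, clip=clip) for c in rs if c.defined]
    if len(zs) / total < min_prop:
        return None
    mean_z = float(np.mean(zs))
    return AggregateScore(mean_z, math.tanh(mean_z), total, len(zs))


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a units x components matrix.

    Rows with any missing entry are dropped (complete-case).  Returns nan
    when fewer than 2 complete rows remain or the row-sum variance is zero.
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 components")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2:
        return math.nan
    k = m.shape[1]
    total_var = float(np.var(m.sum(axis=1), ddof=1))
    if total_var <= 0.0:
        return math.nan
    item_vars = float(np.var(m, axis=0, ddof=1).sum())
    return k / (k - 1.0) * (1.0 - item_vars / total_var)


def disattenuate(r: float, rel_x: float, rel_y: float) -> float:
    """Correct a correlation for attenuation: r / sqrt(rel_x * rel_y).

    The result may exceed 1 in magnitude; it is returned as-is (callers
    flag it).
    """
    if not (0.0 < rel_x <= 1.0) or not (0.0 < rel_y <= 1.0):
        raise ValueError(f"reliabilities must be in (0, 1]: {rel_x}, {rel_y}")
    if abs(r) > 1.0:
        raise ValueError(f"|r| > 1: {r}")
    return r / math.sqrt(rel_x * rel_y)


def _finite(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    return v[~np.isnan(v)]


def one_sample_t(scores, mu0: float = 0.0) -> TestResult:
    """One-sample Student t test of mean(scores) against ``mu0``, two-sided."""
    v = _finite(scores)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 non-missing scores")
    sd = float(v.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return TestResult(math.nan, df, math.nan, defined=False)
    t = (float(v.mean()) - mu0) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, p)


def pooled_two_sample_t(a, b) -> TestResult:
    """Two-sample Student t with pooled variance, df = n_a + n_b - 2."""
    a = _finite(a)
    b = _finite(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 complete values")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if pooled <= 0.0:
        return TestResult(math.nan, df, math.nan, defined=False)
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = float(a.mean() - b.mean()) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, p)
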