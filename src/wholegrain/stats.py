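"""Survey-weighted descriptives and nonparametric group comparisons.

Intake distributions are right-skewed with a point mass at zero, so group
summaries are weighted medians and interquartile ranges rather than means.
The comparison procedures are implemented here directly (not delegated):

* weighted type-1 quantiles (left-continuous: the smallest value whose
  cumulative normalised weight reaches q);
* Mann–Whitney rank-sum test with midrank ties, exact two-sided p by
  enumeration for small samples and a tie-corrected normal approximation
  otherwise;
* Kruskal–Wallis test with tie correction, chi-square reference;
* weighted least-squares linear trend of intake on an ordinal band index.

Only reference distributions (normal, chi-square, Student t survival
functions) come from scipy. Rank tests run unweighted by default; to
incorporate survey weights approximately, expand samples with
:func:`expand_by_weight` first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import t as _t

from .diary import Participant
from .pipeline import CutoffTier, ParticipantIntake

__all__ = [
    "GroupSummary",
    "TestResult",
    "weighted_quantile",
    "expand_by_weight",
    "mann_whitney",
    "kruskal_wallis",
    "linear_trend",
    "summarize",
    "DEFAULT_AGE_BANDS",
]


@dataclass
class GroupSummary:
    """Weighted descriptive summary of intake in one stratum."""

    stratum: str
    n: int  # unweighted participant count
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    percent_nonconsumers: float  # weighted percent with zero intake at the tier


@dataclass
class TestResult:
    """Outcome of one hypothesis test (two-sided unless stated in meta)."""

    method: str
    statistic: float
    p_value: float
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Weighted quantiles


def weighted_quantile(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
    q: float,
) -> float:
    """Type-1 (left-continuous) weighted quantile.

    Returns the smallest data value whose cumulative normalised weight is at
    least ``q``. With integer weights this equals the type-1 quantile of the
    weight-expanded sample; with equal weights and odd n, q=0.5 gives the
    ordinary sample median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_quantile of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    # tolerance absorbs float summation error at exact weight boundaries
    idx = int(np.searchsorted(cum, q * total - 1e-12 * total, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[idx])


def expand_by_weight(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Replicate each value ``round(weight * scale)`` times (at least once).

    Integerised-weight replication lets the unweighted rank tests consume
    survey weights approximately; larger ``scale`` gives finer resolution at
    the cost of larger expanded samples.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    reps = np.maximum(np.rint(w * scale).astype(int), 1)
    return np.repeat(v, reps)


# ---------------------------------------------------------------------------
# Rank tests


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values sharing their average rank."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Mann–Whitney rank-sum test for a difference between two samples.

    The statistic is ``U = #{x_i > y_j} + tie_pairs/2`` (computed via
    midranks). The two-sided p-value is exact — the proportion of the
    ``C(n, n_x)`` equally likely rank assignments whose U is at least as far
    from its null mean ``n_x n_y / 2`` — when ``n_x + n_y <= exact_max_n``,
    and a tie-corrected normal approximation otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    nx, ny = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = _midranks(pooled)
    u = float(np.sum(ranks[:nx])) - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    dev = abs(u - mu)

    if nx + ny <= exact_max_n:
        hits = 0
        total = 0
        for subset in combinations(range(nx + ny), nx):
            u_s = float(sum(ranks[i] for i in subset)) - nx * (nx + 1) / 2.0
            if abs(u_s - mu) >= dev - 1e-9:
                hits += 1
            total += 1
        p = hits / total
        return TestResult(
            "mann_whitney", u, p, {"n_x": nx, "n_y": ny, "exact": True}
        )

    n = nx + ny
    var = nx * ny / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:  # every observation tied
        return TestResult(
            "mann_whitney", u, 1.0, {"n_x": nx, "n_y": ny, "exact": False, "z": 0.0}
        )
    z = (u - mu) / math.sqrt(var)
    p = float(min(1.0, 2.0 * _norm.sf(abs(z))))
    return TestResult(
        "mann_whitney", u, p, {"n_x": nx, "n_y": ny, "exact": False, "z": z}
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test for a difference across k >= 2 groups.

    H is computed from pooled midranks with the usual tie correction and
    referred to a chi-square distribution with k−1 degrees of freedom.
    Rank-based, hence invariant under monotone transformations of the data.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * (float(np.mean(r)) - (n + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # all observations identical
        return TestResult("kruskal_wallis", 0.0, 1.0, {"df": len(arrays) - 1})
    h /= correction
    df = len(arrays) - 1
    p = float(_chi2.sf(h, df))
    return TestResult("kruskal_wallis", h, p, {"df": df, "n": int(n)})


def linear_trend(
    values: Sequence[float],
    band_index: Sequence[float],
    weights: Sequence[float] | None = None,
) -> TestResult:
    """Weighted least-squares linear trend of intake on an ordinal index.

    Fits ``value = a + b * band_index`` by WLS and tests ``b = 0`` with a
    two-sided t-test on n−2 degrees of freedom. With equal weights this is
    ordinary simple regression. A perfectly constant response gives slope 0
    and p = 1.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(band_index, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if y.size != x.size or y.size != w.size:
        raise ValueError("values, band_index and weights must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("linear_trend requires at least two distinct bands")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    xbar = float(np.sum(w * x) / np.sum(w))
    ybar = float(np.sum(w * y) / np.sum(w))
    sxx = float(np.sum(w * (x - xbar) ** 2))
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    df = y.size - 2
    if df <= 0:
        raise ValueError("linear_trend requires more than two observations")
    s2 = float(np.sum(w * resid**2) / df)
    se = math.sqrt(s2 / sxx)
    if se == 0.0:
        p = 1.0 if slope == 0.0 else 0.0
        tstat = 0.0 if slope == 0.0 else math.inf
    else:
        tstat = slope / se
        p = float(min(1.0, 2.0 * _t.sf(abs(tstat), df)))
    return TestResult(
        "linear_trend",
        slope,
        p,
        {"intercept": intercept, "se": se, "t": tstat, "df": df},
    )


# ---------------------------------------------------------------------------
# Stratified summaries

# Configurable default age bands (label, lower_inclusive, upper_exclusive).
DEFAULT_AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("1.5-4", 1.5, 5.0),
    ("5-12", 5.0, 13.0),
    ("13-17", 13.0, 18.0),
    ("18-24", 18.0, 25.0),
    ("25-34", 25.0, 35.0),
    ("35-44", 35.0, 45.0),
    ("45-54", 45.0, 55.0),
    ("55-64", 55.0, 65.0),
    ("65+", 65.0, math.inf),
)


def age_band_label(
    age_years: float,
    bands: Sequence[tuple[str, float, float]] = DEFAULT_AGE_BANDS,
) -> str:
    for label, lo, hi in bands:
        if lo <= age_years < hi:
            return label
    raise ValueError(f"age {age_years} outside configured bands")


def _stratum_of(
    p: Participant, by: str, bands: Sequence[tuple[str, float, float]]
) -> str | None:
    if by == "sex":
        return p.sex
    if by == "age_band":
        return age_band_label(p.age_years, bands)
    if by == "nssec":
        return None if p.nssec is None else str(p.nssec)
    if by == "adult_child":
        return "adult" if p.is_adult else "child_teen"
    raise ValueError(f"unknown stratum variable {by!r}")


def summarize(
    intakes: Sequence[ParticipantIntake],
    participants: Sequence[Participant],
    by: str = "adult_child",
    tier: CutoffTier = CutoffTier.ANY,
    energy_adjusted: bool = False,
    age_bands: Sequence[tuple[str, float, float]] = DEFAULT_AGE_BANDS,
) -> list[GroupSummary]:
    """Weighted median, IQR, range and non-consumer percent per stratum.

    ``by`` is one of ``sex``, ``age_band``, ``nssec`` or ``adult_child``.
    Participants with missing NS-SEC are excluded from NS-SEC strata only.
    Stratum order is fixed (sexes male/female; bands and classes ascending).
    """
    people = {p.participant_id: p for p in participants}
    grouped: dict[str, list[tuple[float, float, bool]]] = {}
    for it in intakes:
        p = people.get(it.participant_id)
        if p is None:
            raise ValueError(f"intake for unknown participant {it.participant_id!r}")
        stratum = _stratum_of(p, by, age_bands)
        if stratum is None:
            continue
        value = (it.wg_g_per_10MJ if energy_adjusted else it.wg_g_per_day)[tier]
        grouped.setdefault(stratum, []).append(
            (value, p.survey_weight, it.is_nonconsumer[tier])
        )

    if by == "sex":
        order = ["male", "female"]
    elif by == "age_band":
        order = [label for label, _, _ in age_bands]
    elif by == "nssec":
        order = [str(k) for k in range(1, 9)]
    else:
        order = ["adult", "child_teen"]

    out: list[GroupSummary] = []
    for stratum in order:
        rows = grouped.get(stratum)
        if not rows:
            continue
        vals = np.array([r[0] for r in rows])
        wts = np.array([r[1] for r in rows])
        nc = np.array([r[2] for r in rows])
        out.append(
            GroupSummary(
                stratum=stratum,
                n=len(rows),
                median=weighted_quantile(vals, wts, 0.5),
                q25=weighted_quantile(vals, wts, 0.25),
                q75=weighted_quantile(vals, wts, 0.75),
                minimum=float(vals.min()),
                maximum=float(vals.max()),
                percent_nonconsumers=float(100.0 * np.sum(wts[nc]) / np.sum(wts)),
            )
        )
    return out
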