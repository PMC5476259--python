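"""Seasonal trend models for murmuration size and duration.

Murmuration size follows a dome-shaped trajectory over the roosting season
(rising from October to a peak around early February, then declining),
while duration is shallow-U-shaped, tracking the seasonal swing in day
length. Both are modelled by low-degree polynomial regression on the day
index (1 = 1 October), with the degree chosen among candidates by adjusted
R² (raw-R² selection available for compatibility, though it can never
prefer the simpler nested model).

Because the day-length covariate is shared across the whole country for a
given date, the duration–day-length regression is run on weekly aggregates
rather than raw daily data, so that single days with atypically clustered
records cannot dominate the fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from murmuration.errors import InsufficientDataError, SingularDesignError
from murmuration.records import MurmurationRecord

__all__ = [
    "SeasonalFit",
    "WeeklySeries",
    "fit_polynomial_trend",
    "evaluate_trend",
    "select_trend_degree",
    "weekly_aggregate",
    "regress_on_daylength",
]


@dataclass(frozen=True)
class SeasonalFit:
    """A fitted polynomial trend (constant coefficient first)."""

    response: str
    degree: int
    coefficients: tuple[float, ...]
    coef_se: tuple[float, ...]
    r2: float
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


@dataclass(frozen=True)
class WeeklySeries:
    """Per-week summary of one response field.

    ``sem`` is the standard error of the weekly mean (sample SD over √n),
    absent when the week holds a single record.
    """

    week_index: int
    mean: float
    sem: float | None
    n: int
    mean_day_length_h: float | None


def fit_polynomial_trend(
    x: Sequence[float],
    y: Sequence[float],
    degree: int,
    response: str = "response",
) -> SeasonalFit:
    """Least-squares polynomial fit of *y* on powers of *x*.

    The overall F statistic tests all non-constant terms jointly, with
    ``(degree, n - degree - 1)`` degrees of freedom. When the fit
    interpolates exactly (zero residual), R² and adjusted R² are 1 and the
    F statistic is reported as infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n = x.size
    if n < degree + 1:
        raise InsufficientDataError(f"need n >= degree + 1 = {degree + 1}, got n = {n}")
    if np.ptp(x) == 0:
        raise SingularDesignError("all x values are equal")

    # Vandermonde in increasing powers: column j is x**j
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise SingularDesignError("polynomial design matrix is rank-deficient")

    fitted = design @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = degree, n - degree - 1
    if tss == 0.0:
        r2 = adj_r2 = 0.0
        f_stat, p_value = 0.0, 1.0
    elif rss <= tss * 1e-12:
        r2 = adj_r2 = 1.0
        f_stat, p_value = math.inf, 0.0
    else:
        r2 = 1.0 - rss / tss
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df2
        f_stat = (tss - rss) / df1 / (rss / df2)
        p_value = float(stats.f.sf(f_stat, df1, df2))
    if df2 >= 1:
        sigma2 = rss / df2
        cov = sigma2 * np.linalg.pinv(design.T @ design)
        coef_se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:  # saturated fit: no residual degrees of freedom
        coef_se = tuple(math.nan for _ in coef)
    return SeasonalFit(
        response=response,
        degree=degree,
        coefficients=tuple(float(c) for c in coef),
        coef_se=coef_se,
        r2=r2,
        adj_r2=adj_r2,
        f_stat=f_stat,
        df=(df1, df2),
        p_value=p_value,
        n=n,
    )


def evaluate_trend(fit: SeasonalFit, x: float) -> float:
    """Evaluate the fitted polynomial at *x* (constant term first)."""
    return float(np.polynomial.polynomial.polyval(x, np.asarray(fit.coefficients)))


def select_trend_degree(
    x: Sequence[float],
    y: Sequence[float],
    candidate_degrees: Iterable[int] = (1, 2),
    criterion: Literal["adj_r2", "r2"] = "adj_r2",
    response: str = "response",
) -> SeasonalFit:
    """Fit every candidate degree and keep the best.

    Selection is by adjusted R² by default (raw R² cannot prefer a simpler
    nested model); exact ties break toward the lower degree. With
    ``criterion="r2"`` raw R² is used instead.
    """
    degrees = sorted(set(candidate_degrees))
    if not degrees:
        raise ValueError("candidate_degrees must be non-empty")
    best: SeasonalFit | None = None
    for d in degrees:
        fit = fit_polynomial_trend(x, y, d, response=response)
        score = fit.adj_r2 if criterion == "adj_r2" else fit.r2
        if best is None or score > (best.adj_r2 if criterion == "adj_r2" else best.r2):
            best = fit
    assert best is not None
    return best


def _field_value(rec: MurmurationRecord, field: str) -> float:
    if field == "size":
        return float(rec.flock_size)
    if field == "duration":
        return float(rec.duration_min)
    if field == "day_length_h":
        if rec.day_length_h is None:
            raise ValueError(f"record {rec.record_id} has no day_length_h attached")
        return rec.day_length_h
    raise ValueError(f"unknown field {field!r}")


def weekly_aggregate(
    records: Iterable[MurmurationRecord],
    field: Literal["size", "duration", "day_length_h"],
) -> list[WeeklySeries]:
    """Aggregate a record field into weekly means.

    Week boundaries follow ``ceil(day_index / 7)`` from the season start
    (days 1–7 are week 1). Weeks with no records are omitted. The weekly
    mean day length is included whenever every record in the week carries
    an attached ``day_length_h``.
    """
    buckets: dict[int, list[MurmurationRecord]] = {}
    for rec in records:
        buckets.setdefault(-(-rec.day_index // 7), []).append(rec)

    out: list[WeeklySeries] = []
    for week in sorted(buckets):
        recs = buckets[week]
        vals = np.array([_field_value(r, field) for r in recs])
        n = vals.size
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else None
        if all(r.day_length_h is not None for r in recs):
            mean_dl = float(np.mean([r.day_length_h for r in recs]))
        else:
            mean_dl = None
        out.append(
            WeeklySeries(
                week_index=week, mean=float(vals.mean()), sem=sem, n=n, mean_day_length_h=mean_dl
            )
        )
    return out


def regress_on_daylength(
    weekly: Sequence[WeeklySeries],
    response: str = "duration",
) -> SeasonalFit:
    """Simple linear regression of weekly mean response on weekly mean day length.

    All retained weeks are weighted equally. Requires at least three weeks
    with an attached day length; a constant day-length predictor raises
    :class:`SingularDesignError`.
    """
    usable = [w for w in weekly if w.mean_day_length_h is not None]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 weeks with day length attached, got {len(usable)}"
        )
    x = [w.mean_day_length_h for w in usable]
    y = [w.mean for w in usable]
    return fit_polynomial_trend(x, y, degree=1, response=response)
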