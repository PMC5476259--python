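"""Regression with Empirical Variable Selection (REVS).

REVS tames all-subsets regression: instead of comparing every subset of
predictors, it ranks predictors by empirical support, builds the nested
sequence of ordinary-least-squares models that adds one predictor at a
time in rank order, and compares only those p models by AIC. Three models
are reported from the sequence:

* **MAM** (minimum adequate model) — fewest predictors with ΔAIC within
  the support threshold;
* **Optimal** — the ΔAIC = 0 model;
* **Maximum** — the model with the highest adjusted R² within the ΔAIC
  threshold.

Empirical support is measured by best-subsets frequency: for each subset
size the AIC-best subset is found (exhaustively for small p, by greedy
forward search otherwise) and a predictor's support is the number of best
subsets containing it. A univariate ranking (single-predictor AIC) is
available as an alternative.

AIC uses the Gaussian OLS form ``n·ln(RSS/n) + 2k`` with ``k`` counting
the intercept, the slope coefficients, and the error variance. The
additive constant of the full Gaussian log-likelihood is dropped; it
cancels in every ΔAIC, which is the only quantity interpreted.

Two predictor designs are supported for the predator analyses, run
separately because per-species presence is the exact sum of the four
per-species activity indicators (mixing them makes the design singular):

* **presence** — temperature plus presence of each of seven raptor
  species and of corvids and gulls (10 predictors);
* **activity** — temperature plus species × activity indicators for the
  seven raptor species (29 predictors).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from murmuration.errors import DegenerateFitError, SingularDesignError
from murmuration.records import MurmurationRecord
from murmuration.taxa import ACTIVITIES, LOOKALIKE_SPECIES, RAPTOR_SPECIES

__all__ = [
    "PredictorMatrix",
    "FittedModel",
    "SupportRanking",
    "RevsResult",
    "ValidationReport",
    "build_design",
    "fit_ols",
    "aic",
    "rank_empirical_support",
    "build_nested_sequence",
    "select_revs_models",
    "run_revs",
    "durbin_watson",
    "validate_predictors",
]

#: Exhaustive best-subsets search is used up to this many predictors
#: (2^15 subsets); beyond it the per-size best subset comes from greedy
#: forward selection.
EXHAUSTIVE_SEARCH_LIMIT = 15


@dataclass
class PredictorMatrix:
    """A complete-case design: named predictor columns plus a response.

    Columns are binary indicators (species presence, or species × activity)
    or continuous (temperature); the response is flock size or duration.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("PredictorMatrix does not admit missing values")
        if len(self.X) != len(self.y):
            raise ValueError("predictor and response lengths differ")
        if self.n <= self.p + 2:
            raise ValueError(f"need n > p + 2, got n = {self.n}, p = {self.p}")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit of the response on a predictor subset.

    ``k_params`` counts estimated parameters: intercept, one per
    predictor, and the error variance. ``f_stat``/``p_value`` are the
    overall model-level test (NaN for the intercept-only model).
    """

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first
    rss: float
    n: int
    k_params: int
    aic: float
    r2: float
    adj_r2: float
    f_stat: float
    p_value: float
    residuals: tuple[float, ...]

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)


@dataclass(frozen=True)
class SupportRanking:
    """Predictors ordered by empirical support, most-supported first."""

    order: tuple[str, ...]
    support_score: dict[str, float]
    method: str
    flagged_constant: tuple[str, ...] = ()


@dataclass
class RevsResult:
    """The nested sequence with ΔAIC and the MAM/Optimal/Maximum triple."""

    ranking: SupportRanking
    sequence: list[FittedModel]
    delta_aic: list[float]
    mam: int
    optimal: int
    maximum: int
    durbin_watson: dict[str, float] = field(default_factory=dict)

    @property
    def mam_model(self) -> FittedModel:
        return self.sequence[self.mam]

    @property
    def optimal_model(self) -> FittedModel:
        return self.sequence[self.optimal]

    @property
    def maximum_model(self) -> FittedModel:
        return self.sequence[self.maximum]

    def to_table(self) -> pd.DataFrame:
        """Summary table with one row per reported model."""
        rows = []
        for role, idx in (("MAM", self.mam), ("Optimal", self.optimal), ("Maximum", self.maximum)):
            m = self.sequence[idx]
            rows.append(
                {
                    "model": role,
                    "variables": "; ".join(m.predictor_names),
                    "n_predictors": m.n_predictors,
                    "delta_aic": self.delta_aic[idx],
                    "adj_r2": m.adj_r2,
                    "p": m.p_value,
                    "durbin_watson": self.durbin_watson.get(role, float("nan")),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        payload = {
            "ranking": {
                "order": list(self.ranking.order),
                "support_score": self.ranking.support_score,
                "method": self.ranking.method,
            },
            "sequence": [
                {
                    "predictors": list(m.predictor_names),
                    "aic": m.aic,
                    "delta_aic": d,
                    "adj_r2": m.adj_r2,
                    "p": m.p_value,
                }
                for m, d in zip(self.sequence, self.delta_aic)
            ],
            "mam": self.mam,
            "optimal": self.optimal,
            "maximum": self.maximum,
            "durbin_watson": self.durbin_watson,
        }
        return json.dumps(payload, **kwargs)


# ---------------------------------------------------------------------------
# Design construction

def build_design(
    records: Sequence[MurmurationRecord],
    design: Literal["presence", "activity"] = "presence",
    response: Literal["size", "duration"] = "size",
) -> PredictorMatrix:
    """Build a predictor matrix from records for one REVS run.

    Presence and activity columns are never mixed for the same species:
    per-species presence equals the sum of that species' four activity
    indicators, so a mixed design is exactly collinear. Records lacking a
    temperature are dropped (complete-case analysis).
    """
    recs = [r for r in records if r.temperature_c is not None]
    data: dict[str, list[float]] = {"temperature": [r.temperature_c for r in recs]}
    if design == "presence":
        for sp in RAPTOR_SPECIES + LOOKALIKE_SPECIES:
            data[f"{sp}_presence"] = [float(r.activity_of(sp) != "absent") for r in recs]
    elif design == "activity":
        for sp in RAPTOR_SPECIES:
            for act in ACTIVITIES:
                data[f"{sp}_{act}"] = [float(r.activity_of(sp) == act) for r in recs]
    else:
        raise ValueError(f"unknown design {design!r}")

    if response == "size":
        y = pd.Series([float(r.flock_size) for r in recs], name="flock_size")
    elif response == "duration":
        y = pd.Series([float(r.duration_min) for r in recs], name="duration_min")
    else:
        raise ValueError(f"unknown response {response!r}")
    return PredictorMatrix(X=pd.DataFrame(data), y=y)


# ---------------------------------------------------------------------------
# Fitting

def aic(rss: float, n: int, k_params: int) -> float:
    """Gaussian-OLS AIC: ``n·ln(RSS/n) + 2·k_params`` (constant dropped)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0.0:
        raise DegenerateFitError("AIC undefined for a saturated fit (RSS = 0)")
    return n * math.log(rss / n) + 2 * k_params


def fit_ols(pm: PredictorMatrix, subset: Sequence[str] | None = None) -> FittedModel:
    """Exact least-squares fit of the response on a predictor subset.

    An intercept is always included. ``subset=None`` uses every predictor;
    ``subset=[]`` fits the intercept-only model.

    Raises
    ------
    SingularDesignError
        When the design matrix (with intercept) is rank-deficient; the
        message names the offending columns.
    """
    names = list(pm.predictor_names if subset is None else subset)
    X = pm.X[names].to_numpy(dtype=float)
    y = pm.y.to_numpy(dtype=float)
    n, q = len(y), len(names)

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < q + 1:
        dependent = _dependent_columns(design, names)
        raise SingularDesignError(f"rank-deficient design; dependent columns: {dependent}")

    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if q == 0:
        adj_r2, f_stat, p_value = r2, float("nan"), float("nan")
    else:
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
        f_stat = float(res.fvalue)
        p_value = float(res.f_pvalue)
    k = q + 2
    model_aic = aic(rss, n, k) if rss > 0 else float("-inf")
    return FittedModel(
        predictor_names=tuple(names),
        coefficients=tuple(float(c) for c in res.params),
        rss=rss,
        n=n,
        k_params=k,
        aic=model_aic,
        r2=r2,
        adj_r2=adj_r2,
        f_stat=f_stat,
        p_value=p_value,
        residuals=tuple(float(e) for e in res.resid),
    )


def _dependent_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns (by name) linearly dependent on the intercept and earlier columns."""
    dependent = []
    kept = design[:, :1]
    for j, name in enumerate(names):
        candidate = np.column_stack([kept, design[:, j + 1]])
        if np.linalg.matrix_rank(candidate) == kept.shape[1]:
            dependent.append(name)
        else:
            kept = candidate
    return dependent


# ---------------------------------------------------------------------------
# Empirical support ranking

class _SubsetRssSolver:
    """Fast RSS for predictor subsets via the Gram matrix of [1, X]."""

    def __init__(self, pm: PredictorMatrix) -> None:
        X = pm.X.to_numpy(dtype=float)
        y = pm.y.to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(y)), X])
        self.G = Z.T @ Z
        self.Zty = Z.T @ y
        self.yty = float(y @ y)
        self.n = len(y)

    def rss(self, cols: Sequence[int]) -> float:
        """RSS of the OLS fit on predictor columns *cols* (0-based, no intercept)."""
        idx = [0] + [c + 1 for c in cols]
        G = self.G[np.ix_(idx, idx)]
        b = self.Zty[idx]
        try:
            coef = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(G, b, rcond=None)
        return max(self.yty - float(b @ coef), 0.0)


def rank_empirical_support(
    pm: PredictorMatrix,
    method: Literal["best_subsets_frequency", "univariate"] = "best_subsets_frequency",
) -> SupportRanking:
    """Rank predictors by empirical support.

    ``best_subsets_frequency`` (default): for each subset size s the
    AIC-best subset of that size is found — exhaustively when p ≤ 15,
    by greedy forward search otherwise — and a predictor's support score
    is the number of best subsets containing it. Because k is fixed at a
    given size, the AIC-best subset is the RSS-best subset.

    ``univariate``: predictors are ranked by their single-predictor model
    AIC (lower first).

    Ties break by univariate AIC, then by input order. Constant columns
    cannot carry information; they are flagged and ranked last.
    """
    names = pm.predictor_names
    constant = [c for c in names if pm.X[c].nunique() <= 1]
    active = [c for c in names if c not in constant]
    col_of = {c: names.index(c) for c in names}
    solver = _SubsetRssSolver(pm)
    n = solver.n

    def subset_aic(cols: list[int]) -> float:
        rss = solver.rss(cols)
        if rss <= 0:
            return float("-inf")
        return aic(rss, n, len(cols) + 2)

    uni_aic = {c: subset_aic([col_of[c]]) for c in active}

    if method == "univariate":
        score = {c: -uni_aic[c] for c in active}
    elif method == "best_subsets_frequency":
        score = {c: 0.0 for c in active}
        p = len(active)
        if p <= EXHAUSTIVE_SEARCH_LIMIT:
            for s in range(1, p + 1):
                best = min(
                    itertools.combinations(active, s),
                    key=lambda combo: solver.rss([col_of[c] for c in combo]),
                )
                for c in best:
                    score[c] += 1.0
        else:
            # greedy forward path: best subset of size s approximated by the
            # first s forward-selected predictors
            chosen: list[str] = []
            remaining = list(active)
            while remaining:
                nxt = min(
                    remaining,
                    key=lambda c: solver.rss([col_of[x] for x in chosen] + [col_of[c]]),
                )
                chosen.append(nxt)
                remaining.remove(nxt)
            for depth, c in enumerate(chosen):
                score[c] = float(len(active) - depth)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    order = sorted(active, key=lambda c: (-score[c], uni_aic[c], names.index(c)))
    for c in constant:
        score[c] = 0.0
        warnings.warn(f"constant predictor column {c!r} ranked last", stacklevel=2)
    order += constant
    return SupportRanking(
        order=tuple(order),
        support_score=score,
        method=method,
        flagged_constant=tuple(constant),
    )


# ---------------------------------------------------------------------------
# Nested sequence and triple selection

def build_nested_sequence(pm: PredictorMatrix, ranking: SupportRanking) -> list[FittedModel]:
    """Fit the nested model sequence: model i uses the first i ranked predictors.

    A predictor whose addition makes the design singular is skipped with a
    warning and the sequence shortens accordingly. Raw R² is non-decreasing
    along the sequence by nesting.
    """
    if set(ranking.order) != set(pm.predictor_names):
        raise ValueError("ranking must be a permutation of the design's predictors")
    sequence: list[FittedModel] = []
    current: list[str] = []
    for name in ranking.order:
        try:
            model = fit_ols(pm, current + [name])
        except SingularDesignError:
            warnings.warn(f"skipping predictor {name!r}: singular design", stacklevel=2)
            continue
        current.append(name)
        sequence.append(model)
    return sequence


def select_revs_models(
    sequence: Sequence[FittedModel],
    delta_threshold: float = 2.0,
) -> RevsResult:
    """Pick the MAM/Optimal/Maximum triple from a nested sequence.

    ΔAIC is computed relative to the sequence minimum. The candidate set
    holds every model with ΔAIC ≤ *delta_threshold* (a closed bound, so a
    model at exactly the threshold still qualifies). MAM is the candidate
    with fewest predictors (ties to lower AIC); Optimal has ΔAIC = 0
    (ties to fewer predictors); Maximum has the highest adjusted R² among
    candidates (ties to fewer predictors).
    """
    if not sequence:
        raise ValueError("empty model sequence")
    aics = [m.aic for m in sequence]
    best = min(aics)
    delta = [a - best for a in aics]
    candidates = [i for i, d in enumerate(delta) if d <= delta_threshold]

    optimal = min((i for i, d in enumerate(delta) if d == 0.0),
                  key=lambda i: sequence[i].n_predictors)
    mam = min(candidates, key=lambda i: (sequence[i].n_predictors, aics[i]))
    maximum = min(candidates, key=lambda i: (-sequence[i].adj_r2, sequence[i].n_predictors))
    return RevsResult(
        ranking=SupportRanking(order=(), support_score={}, method="external"),
        sequence=list(sequence),
        delta_aic=delta,
        mam=mam,
        optimal=optimal,
        maximum=maximum,
    )


def run_revs(
    pm: PredictorMatrix,
    method: Literal["best_subsets_frequency", "univariate"] = "best_subsets_frequency",
    delta_threshold: float = 2.0,
) -> RevsResult:
    """Full REVS pass: rank, fit the nested sequence, select the triple.

    Durbin-Watson statistics are attached for each reported model,
    computed on residuals in row order — callers should supply the design
    with records already ordered by time within location.
    """
    ranking = rank_empirical_support(pm, method=method)
    sequence = build_nested_sequence(pm, ranking)
    result = select_revs_models(sequence, delta_threshold=delta_threshold)
    result.ranking = ranking
    result.durbin_watson = {
        role: durbin_watson(result.sequence[idx].residuals)
        for role, idx in (("MAM", result.mam), ("Optimal", result.optimal),
                          ("Maximum", result.maximum))
    }
    return result


# ---------------------------------------------------------------------------
# Diagnostics

def durbin_watson(residuals: Sequence[float]) -> float:
    """First-order serial-correlation statistic of ordered residuals.

    ``d = Σ(e_t − e_{t−1})² / Σe_t²`` over consecutive pairs; the range is
    [0, 4] and a value near 2 indicates no autocorrelation (1.5–2.5 is the
    conventional acceptance band). Residuals must arrive already ordered
    by time within location.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


@dataclass(frozen=True)
class ValidationReport:
    """Linear-dependency and collinearity screen for a predictor design."""

    exact_dependencies: tuple[str, ...]
    high_correlation_pairs: tuple[tuple[str, str, float], ...]
    constant_columns: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not (self.exact_dependencies or self.high_correlation_pairs
                    or self.constant_columns)


def validate_predictors(pm: PredictorMatrix, corr_bound: float = 0.8) -> ValidationReport:
    """Screen a design for exact and near collinearity.

    Exact linear dependencies (a duplicated column, or a presence column
    equal to the sum of its four activity columns) are detected by a
    sequential rank test against the intercept and all preceding columns.
    Pairs of full-rank columns with |Pearson r| above *corr_bound* are
    reported as near-collinear. The report never raises; the caller
    decides how to act.
    """
    names = pm.predictor_names
    X = pm.X.to_numpy(dtype=float)
    constant = tuple(c for c in names if pm.X[c].nunique() <= 1)

    design = np.column_stack([np.ones(pm.n), X])
    dependent = tuple(
        c for c in _dependent_columns(design, names) if c not in constant
    )

    usable = [c for c in names if c not in constant and c not in dependent]
    corr_pairs = []
    if len(usable) >= 2:
        corr = pm.X[usable].corr().to_numpy()
        for i, j in itertools.combinations(range(len(usable)), 2):
            r = corr[i, j]
            if abs(r) > corr_bound:
                corr_pairs.append((usable[i], usable[j], float(r)))
    return ValidationReport(
        exact_dependencies=dependent,
        high_correlation_pairs=tuple(corr_pairs),
        constant_columns=constant,
    )
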