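"""Temporal PHS phenotypes: sprouting index, slope, and sigmoid parameters.

Three quantitative phenotypes are derived from a genotype's 7-day mean-score
trajectory S_1..S_7:

* **Sprouting index (SI)** — a weighted mean that gives early sprouting more
  weight: ``SI = sum_{i=1..7} (8-i) * S_i / (7 * n_max)`` with ``n_max = 9``
  the maximum scale level.  SI lies in [0, 4]; low values mean tolerance.
* **Slope** — the OLS slope of score on day over the 8 points
  (0,0),(1,S_1),...,(7,S_7): a 0 on day 0 is anchored before fitting, so the
  slope measures the rate of sprouting from the start of misting.
* **Sigmoid parameters (a, b, c)** — nonlinear least-squares fit of the
  logistic ``y(t) = a / (1 + exp(-b (t - c)))``, where ``a`` is the upper
  asymptote (sprouting extent), ``b`` the growth rate per day and ``c`` the
  day of maximum growth.  A Gompertz form ``a * exp(-exp(-b (t - c)))`` is
  available for comparison.

Genotypes are ranked ascending by slope or SI (rank 1 = most tolerant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError

#: SI weights for days 1..7 (day 1 weighted 7, day 7 weighted 1).
SI_WEIGHTS = np.arange(7, 0, -1, dtype=float)

#: Maximum score level, the n in the SI denominator.
N_MAX = 9.0

SIGMOID_FORMS = ("logistic", "gompertz")


def _as_trajectory(scores, allow_interpolation: bool) -> np.ndarray:
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape != (7,):
        raise DataError(f"expected 7 daily means, got shape {s.shape}")
    missing = ~np.isfinite(s)
    if missing.any():
        if missing.all():
            raise DataError("trajectory is entirely missing")
        if not allow_interpolation:
            raise DataError(
                "trajectory has missing days; pass allow_interpolation=True "
                "to fill gaps linearly from adjacent observed days"
            )
        days = np.arange(1.0, 8.0)
        s = np.interp(days, days[~missing], s[~missing])
    return s


def sprouting_index(scores, n_max: float = N_MAX, allow_interpolation: bool = False) -> float:
    """Weighted sprouting index of a 7-day trajectory, in [0, 4].

    ``SI = (7*S_1 + 6*S_2 + ... + 1*S_7) / (7 * n_max)``; early sprouting
    contributes more.  Missing days raise unless interpolation is enabled.
    """
    s = _as_trajectory(scores, allow_interpolation)
    return float(SI_WEIGHTS @ s / (7.0 * n_max))


def sprouting_slope(scores, allow_interpolation: bool = False) -> float:
    """Day-0-anchored OLS slope of score on day (score units per day).

    A (day=0, score=0) point is prepended to the 7 daily means and an
    ordinary least-squares line (with intercept) is fitted through the 8
    points; the slope is returned.
    """
    s = _as_trajectory(scores, allow_interpolation)
    x = np.arange(0.0, 8.0)
    y = np.concatenate([[0.0], s])
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


@dataclass
class SigmoidFit:
    """Fitted sigmoid growth-curve parameters for one trajectory.

    ``a`` is the upper asymptote (score units), ``b`` the growth rate
    (per day), ``c`` the time of maximum growth (days).  When the fit is
    degenerate (zero-variance trajectory) or the optimizer fails,
    ``converged`` is False, ``a`` carries the last-day mean and ``b``/``c``
    are NaN.
    """

    a: float
    b: float
    c: float
    converged: bool
    rss: float
    form: str = "logistic"


def _sigmoid(t, a, b, c, form):
    if form == "logistic":
        return a / (1.0 + np.exp(-b * (t - c)))
    # Gompertz
    return a * np.exp(-np.exp(-b * (t - c)))


def fit_sigmoid(scores, form: str = "logistic", allow_interpolation: bool = False) -> SigmoidFit:
    """Fit the sigmoid growth curve to a 7-day trajectory.

    Bounds: a in [0, 9.5], b in (0, 10], c in [-2, 14].  Initialisation:
    a0 = max(S); c0 = first day S crosses a0/2 (3.5 if never); b0 = 1.
    """
    if form not in SIGMOID_FORMS:
        raise DataError(f"unknown sigmoid form {form!r}; choose from {SIGMOID_FORMS}")
    s = _as_trajectory(scores, allow_interpolation)
    t = np.arange(1.0, 8.0)

    if np.ptp(s) < 1e-12:  # zero total variance: asymptote undetermined
        return SigmoidFit(a=float(s[-1]), b=np.nan, c=np.nan, converged=False,
                          rss=0.0, form=form)

    a0 = float(max(s.max(), 1e-3))
    above = np.nonzero(s >= a0 / 2.0)[0]
    c0 = float(t[above[0]]) if above.size else 3.5
    c0 = min(max(c0, -1.9), 13.9)
    x0 = np.array([min(a0, 9.5), 1.0, c0])
    lo = np.array([0.0, 1e-6, -2.0])
    hi = np.array([9.5, 10.0, 14.0])

    def resid(p):
        return _sigmoid(t, p[0], p[1], p[2], form) - s

    try:
        res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return SigmoidFit(a=float(s[-1]), b=np.nan, c=np.nan, converged=False,
                          rss=np.nan, form=form)
    if not res.success or not np.all(np.isfinite(res.x)):
        return SigmoidFit(a=float(s[-1]), b=np.nan, c=np.nan, converged=False,
                          rss=np.nan, form=form)
    a, b, c = (float(v) for v in res.x)
    return SigmoidFit(a=a, b=b, c=c, converged=True,
                      rss=float(res.fun @ res.fun), form=form)


def derive_phenotypes(
    trajectories: pd.DataFrame,
    n_max: float = N_MAX,
    form: str = "logistic",
    allow_interpolation: bool = False,
) -> pd.DataFrame:
    """Compute SI, slope and sigmoid (a, b, c) for every trajectory row.

    ``trajectories`` is the wide table from
    :func:`quinoaphs.scoring.daily_genotype_means` (``genotype_id``
    [, ``planting_date``], ``day1``..``day7``).  Returns one row per input
    row with the derived phenotypes plus convergence diagnostics.
    """
    day_cols = [f"day{d}" for d in range(1, 8)]
    missing = [c for c in day_cols if c not in trajectories.columns]
    if missing:
        raise DataError(f"trajectory table is missing columns: {missing}")
    keys = [c for c in ("genotype_id", "planting_date") if c in trajectories.columns]

    records = []
    for _, row in trajectories.iterrows():
        s = row[day_cols].to_numpy(dtype=float)
        fit = fit_sigmoid(s, form=form, allow_interpolation=allow_interpolation)
        rec = {k: row[k] for k in keys}
        rec.update(
            SI=sprouting_index(s, n_max=n_max, allow_interpolation=allow_interpolation),
            slope=sprouting_slope(s, allow_interpolation=allow_interpolation),
            a=fit.a, b=fit.b, c=fit.c, converged=fit.converged, rss=fit.rss,
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def rank_genotypes(records: pd.DataFrame, by: str = "slope") -> pd.DataFrame:
    """Rank genotypes ascending by ``slope`` or ``SI`` (1 = most tolerant).

    Ties are broken by the other metric, then by genotype_id
    lexicographically, so ranks are always a permutation of 1..N.  Adds a
    ``rank_by_slope`` or ``rank_by_SI`` column and returns a sorted copy.
    """
    if by not in ("slope", "SI"):
        raise DataError("rank key must be 'slope' or 'SI'")
    other = "SI" if by == "slope" else "slope"
    out = records.copy()
    ids = out["genotype_id"].astype(str).to_numpy()
    order = np.lexsort((ids, out[other].to_numpy(float), out[by].to_numpy(float)))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out[f"rank_by_{by}"] = ranks
    return out.sort_values(f"rank_by_{by}").reset_index(drop=True)


def correlate_metrics(slopes, sis) -> float:
    """Pearson correlation between slope and SI across genotypes.

    Returns NaN (with no exception) when either metric has zero variance,
    in which case the correlation is undefined.
    """
    x = np.asarray(slopes, dtype=float)
    y = np.asarray(sis, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("slope and SI vectors must be 1-D and equal length")
    if x.size < 2 or np.std(x) < 1e-15 or np.std(y) < 1e-15:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
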