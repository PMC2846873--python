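"""Exponential / logarithmic report-aging models and relevance ranking.

The modelled quantity ``y(x)`` is the complementary cumulative fraction of
views whose report age is at least ``x`` whole months, evaluated at
``x = 1..max_months``.  The exponential family ``y = a * exp(-b x)`` is
fitted by ordinary least squares on ``(x, ln y)`` with R^2 on the log scale
(spreadsheet trend-line behaviour); the logarithmic family
``y = -c * ln(x) + d`` by OLS of ``y`` on ``ln x`` with R^2 on the original
scale.  A direct nonlinear least-squares route for the exponential family
is available behind ``method='nls'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, ParameterError
from .synthetic_data import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

MAX_MONTHS = 44


@dataclass(frozen=True)
class AgeBinSeries:
    """Monthly complementary-cumulative view fractions for one window."""

    label: str
    x: np.ndarray          # whole months, 1..max_months
    y: np.ndarray          # fraction of views aged >= x months, in [0, 1]
    n_views: int


@dataclass(frozen=True)
class AgingFit:
    """A fitted aging trend."""

    family: str            # 'exponential' | 'logarithmic'
    params: dict = field(default_factory=dict)
    r2: float = float("nan")
    n_points: int = 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            return self.params["a"] * np.exp(-self.params["b"] * x)
        return -self.params["c"] * np.log(x) + self.params["d"]

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params),
                "r2": self.r2, "n_points": self.n_points}


def bin_view_ages(
    ages_days, label: str = "", max_months: int = MAX_MONTHS
) -> AgeBinSeries:
    """Bin ages (days) into the monthly complementary-cumulative series.

    ``y(x)`` is the fraction of views at least ``x`` months old, one month
    being 30.4375 days.  Ages beyond ``max_months`` simply keep contributing
    to every bin (they accumulate in the tail); their presence is logged.
    """
    ages = np.asarray(list(ages_days), dtype=float)
    if ages.size == 0:
        raise ParameterError("ages_days: window is empty")
    months = ages / DAYS_PER_MONTH
    x = np.arange(1, max_months + 1)
    y = (months[:, None] >= x[None, :]).mean(axis=0) if ages.size else None
    n_over = int((months > max_months).sum())
    if n_over:
        logger.info("bin_view_ages[%s]: %d views older than %d months kept "
                    "in the tail", label, n_over, max_months)
    return AgeBinSeries(label, x, y, int(ages.size))


def fit_exponential(series: AgeBinSeries, method: str = "log-ols") -> AgingFit:
    """Fit ``y = a * exp(-b x)``.

    Points with ``y <= 0`` are dropped (with a warning) before the log
    transform; at least three points must survive.
    """
    mask = series.y > 0
    n_drop = int((~mask).sum())
    if n_drop:
        logger.warning("fit_exponential[%s]: dropped %d non-positive points",
                       series.label, n_drop)
    x = series.x[mask].astype(float)
    y = series.y[mask]
    if x.size < 3:
        raise FitError(
            f"fit_exponential[{series.label}]: only {x.size} usable points")
    ly = np.log(y)
    slope, intercept = np.polyfit(x, ly, 1)
    resid = ly - (slope * x + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    a, b = float(np.exp(intercept)), float(-slope)
    if method == "nls":
        from scipy.optimize import curve_fit
        (a, b), _ = curve_fit(lambda t, a_, b_: a_ * np.exp(-b_ * t),
                              x, y, p0=(a, b))
        pred = a * np.exp(-b * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        a, b = float(a), float(b)
    elif method != "log-ols":
        raise ParameterError(f"method: {method!r} not in {{'log-ols', 'nls'}}")
    return AgingFit("exponential", {"a": a, "b": b}, float(r2), int(x.size))


def fit_logarithmic(series: AgeBinSeries) -> AgingFit:
    """Fit ``y = -c * ln(x) + d`` by OLS; R^2 on the original scale."""
    x = series.x.astype(float)
    y = series.y
    if x.size < 3:
        raise FitError(
            f"fit_logarithmic[{series.label}]: only {x.size} points")
    lx = np.log(x)
    slope, intercept = np.polyfit(lx, y, 1)
    pred = slope * lx + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return AgingFit("logarithmic", {"c": float(-slope), "d": float(intercept)},
                    float(r2), int(x.size))


def compare_models(fits_per_window: dict[str, dict[str, AgingFit]]) -> dict:
    """Aggregate fits across windows: mean R^2 per family, counts of
    R^2 > 0.9, and the winning family (or an explicit tie)."""
    families: dict[str, list[float]] = {}
    for window, fits in fits_per_window.items():
        for fam, fit in fits.items():
            families.setdefault(fam, []).append(fit.r2)
    report = {"n_windows": len(fits_per_window), "families": {}}
    for fam, r2s in families.items():
        report["families"][fam] = {
            "mean_r2": float(np.mean(r2s)),
            "n_r2_above_0.9": int(sum(r > 0.9 for r in r2s)),
            "n_fits": len(r2s),
        }
    if report["families"]:
        best = max(report["families"].items(), key=lambda kv: kv[1]["mean_r2"])
        ties = [f for f, v in report["families"].items()
                if v["mean_r2"] == best[1]["mean_r2"]]
        report["winner"] = "tie" if len(ties) > 1 else best[0]
    return report


@dataclass(frozen=True)
class Relevance:
    score: float
    highlight: bool | None


def relevance_score(
    report_age_days: float,
    fit: AgingFit | None = None,
    median_life_days: float | None = None,
) -> Relevance:
    """Score a report's current relevance in [0, 1].

    Model mode (``fit`` given): score is the fitted survival
    ``a * exp(-b * age_months)`` clipped to [0, 1].  Threshold mode
    (``median_life_days`` given): the report is highlighted while its age
    is at most the stratum's median life and downgraded after; the score
    halves once per median life, ``0.5 ** (age / median)``.  When both are
    given the fit drives the score and the median drives the highlight.
    """
    if report_age_days < 0:
        raise ParameterError("report_age_days: must be >= 0")
    if fit is None and median_life_days is None:
        raise ParameterError("relevance_score: need a fit or a median life")
    highlight: bool | None = None
    if median_life_days is not None:
        if median_life_days <= 0:
            raise ParameterError("median_life_days: must be > 0")
        highlight = bool(report_age_days <= median_life_days)
    if fit is not None:
        months = report_age_days / DAYS_PER_MONTH
        score = float(np.clip(fit.predict(months), 0.0, 1.0))
    else:
        score = float(np.clip(0.5 ** (report_age_days / median_life_days),
                              0.0, 1.0))
    return Relevance(score, highlight)


def rank_reports(
    reports: pd.DataFrame,
    by_department: dict,
    as_of=None,
    age_col: str = "age_days",
) -> pd.DataFrame:
    """Order reports for display: highlighted first, then by score, then by
    recency (newest availability first); the sort is stable.

    ``by_department`` maps department -> AgingFit, median life (days), or a
    ``{"fit": ..., "median_life_days": ...}`` pair.  Ages are taken from
    ``age_col`` or derived from ``available_at`` against ``as_of``.
    """
    df = reports.copy()
    if age_col not in df.columns:
        if as_of is None:
            raise ParameterError("rank_reports: need an age column or as_of")
        avail = pd.to_datetime(df["available_at"])
        df[age_col] = (pd.Timestamp(as_of) - avail).dt.total_seconds() / 86400.0
    scores, highlights = [], []
    for row in df.itertuples(index=False):
        dept = getattr(row, "department")
        if dept not in by_department:
            raise ParameterError(
                f"rank_reports: no fit/median for department {dept!r}")
        spec = by_department[dept]
        fit = median = None
        if isinstance(spec, AgingFit):
            fit = spec
        elif isinstance(spec, dict):
            fit = spec.get("fit")
            median = spec.get("median_life_days")
        else:
            median = float(spec)
        rel = relevance_score(max(float(getattr(row, age_col)), 0.0),
                              fit=fit, median_life_days=median)
        scores.append(rel.score)
        highlights.append(bool(rel.highlight) if rel.highlight is not None
                          else rel.score >= 0.5)
    df["score"] = scores
    df["highlight"] = highlights
    if "available_at" in df.columns:
        df["_avail"] = pd.to_datetime(df["available_at"])
    else:
        df["_avail"] = pd.Timestamp(0)
    df = df.sort_values(["highlight", "score", "_avail"],
                        ascending=[False, False, False], kind="stable")
    df = df.drop(columns=["_avail"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
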