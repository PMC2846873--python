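"""Median-life statistics, stratified summaries and usage-evolution metrics.

All percentiles use linear interpolation between closest order statistics
(:func:`numpy.percentile`, ``method='linear'``).  The dispersion ratio is
reported alongside the quartiles as p75 / p25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import icd9
from .errors import EmptyStratumError, IntegrityError, ParameterError

#: Age-group bins in whole years; upper bound inclusive.  Age 70 falls in
#: 'senior' (the printed bins leave exactly-70 unassigned; we close the gap
#: upward).
AGE_GROUPS = (
    ("child", 0, 12),
    ("teenager", 13, 19),
    ("young adult", 20, 34),
    ("adult", 35, 54),
    ("old adult", 55, 69),
    ("senior", 70, None),
)

STRATIFIERS = ("sex", "age_group", "department", "creation_encounter_type",
               "icd9_chapter", "icd9_section")

#: Sections with at most this many views are suppressed from the
#: icd9_section summary.
SECTION_MIN_VIEWS = 20


@dataclass(frozen=True)
class MedianLifeSummary:
    """Median life (days) with quartiles for one stratum."""

    stratum: str
    n_views: int
    median_life: float
    p25: float
    p75: float
    dispersion_ratio: float


def report_age(view_time, availability_time) -> float:
    """Report age in fractional days between availability and view."""
    delta = pd.Timestamp(view_time) - pd.Timestamp(availability_time)
    return delta.total_seconds() / 86400.0


def median_life(ages, stratum: str = "all") -> MedianLifeSummary:
    """Median and quartiles (days) of a nonempty collection of ages."""
    arr = np.asarray(list(ages), dtype=float)
    if arr.size == 0:
        raise EmptyStratumError(f"median_life: stratum {stratum!r} is empty")
    if np.isnan(arr).any():
        raise ParameterError("median_life: ages contain NaN")
    p25, p50, p75 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    disp = float(p75 / p25) if p25 > 0 else float("inf")
    return MedianLifeSummary(stratum, int(arr.size), float(p50),
                             float(p25), float(p75), disp)


def assign_age_group(age_years) -> str:
    """Map an integer age in years to its age-group label."""
    age = int(age_years)
    if age < 0:
        raise ParameterError(f"age_years: {age_years!r} must be >= 0")
    for label, low, high in AGE_GROUPS:
        if age >= low and (high is None or age <= high):
            return label
    raise AssertionError("age groups do not partition 0..inf")  # pragma: no cover


def _stratum_series(classified: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "sex":
        return classified["sex"]
    if stratifier == "age_group":
        return classified["patient_age_years"].map(assign_age_group)
    if stratifier == "department":
        return classified["department"]
    if stratifier == "creation_encounter_type":
        return classified["producing_encounter_type"]
    if stratifier in ("icd9_chapter", "icd9_section"):
        inpat = classified["producing_encounter_type"] == "inpatient"
        dx = classified["main_dx"].where(inpat)
        fn = icd9.chapter_of if stratifier == "icd9_chapter" else icd9.section_of
        return dx.map(lambda c: fn(c) if isinstance(c, str) and c else None)
    raise ParameterError(
        f"stratifier: {stratifier!r} not one of {list(STRATIFIERS)}")


def stratified_median_life(
    classified: pd.DataFrame, stratifier: str
) -> pd.DataFrame:
    """One median-life summary row per stratum of ``stratifier``.

    Rows whose stratum cannot be resolved (e.g. non-inpatient reports under
    an ICD-9 stratifier) are dropped.  For ``icd9_section``, strata with 20
    or fewer views are suppressed.
    """
    strata = _stratum_series(classified, stratifier)
    df = pd.DataFrame({
        "stratum": strata,
        "age": classified["report_age_days"],
    }).dropna(subset=["stratum"])
    rows = []
    for key, grp in df.groupby("stratum", sort=True):
        if stratifier == "icd9_section" and len(grp) <= SECTION_MIN_VIEWS:
            continue
        s = median_life(grp["age"].to_numpy(), stratum=str(key))
        rows.append((s.stratum, s.n_views, s.median_life, s.p25, s.p75,
                     s.dispersion_ratio))
    out = pd.DataFrame(rows, columns=["stratum", "n_views", "median_life",
                                      "p25", "p75", "dispersion_ratio"])
    return out.sort_values("median_life", ascending=False).reset_index(drop=True)


def _quarter(ts: pd.Series) -> pd.Series:
    return pd.to_datetime(ts).dt.to_period("Q").astype(str)


def usage_evolution(
    sessions: pd.DataFrame,
    views: pd.DataFrame,
    encounters: pd.DataFrame,
    period: str = "Q",
) -> pd.DataFrame:
    """Per-period usage metrics keyed on the quarter of session start.

    Views are counted in the period of their session's start (all versions,
    one row per view).  Distinct users count distinct logins; distinct
    computers count distinct IPs.  Views per user per 10,000 encounters is
    (views / distinct users) / encounters * 10,000; per-user metrics are
    null for a period without users.
    """
    sess = sessions.copy()
    sess["_period"] = pd.to_datetime(sess["start"]).dt.to_period(period).astype(str)
    v = views.merge(sess[["session_id", "_period"]], on="session_id", how="inner")
    enc = encounters.copy()
    enc["_period"] = pd.to_datetime(enc["start"]).dt.to_period(period).astype(str)

    per_sess = sess.groupby("_period").agg(
        sessions=("session_id", "nunique"),
        distinct_users=("login", "nunique"),
        distinct_computers=("ip", "nunique"))
    per_view = v.groupby("_period").agg(views=("view_id", "size"))
    per_enc = enc.groupby("_period").agg(encounters=("encounter_id", "size"))
    out = per_sess.join(per_view, how="outer").join(per_enc, how="outer")
    out = out.fillna({"sessions": 0, "views": 0, "encounters": 0,
                      "distinct_users": 0, "distinct_computers": 0})
    for c in ("sessions", "views", "encounters", "distinct_users",
              "distinct_computers"):
        out[c] = out[c].astype(int)

    out["views_per_session"] = np.where(
        out["sessions"] > 0, out["views"] / out["sessions"], np.nan)
    out["views_per_encounter"] = np.where(
        out["encounters"] > 0, out["views"] / out["encounters"], np.nan)
    out["views_per_user"] = np.where(
        out["distinct_users"] > 0, out["views"] / out["distinct_users"], np.nan)
    out["views_per_user_per_10k_encounters"] = np.where(
        (out["distinct_users"] > 0) & (out["encounters"] > 0),
        out["views"] / out["distinct_users"] / out["encounters"] * 10000.0,
        np.nan)
    out.index.name = "period"
    return out.sort_index().reset_index()


def creation_view_crosstab(
    views: pd.DataFrame,
    creation_col: str = "age_anchor",
    view_col: str = "request_time",
) -> tuple[pd.DataFrame, pd.Series]:
    """Count matrix of views by (creation quarter x view quarter).

    Returns the matrix (creation quarters as rows) and the per-view-quarter
    percentage of views of reports created in previous quarters, computed
    as ``1 - diagonal / column total``.  A view dated before its report's
    creation violates integrity.
    """
    c = pd.to_datetime(views[creation_col])
    v = pd.to_datetime(views[view_col])
    if (v < c).any():
        raise IntegrityError("creation_view_crosstab: view precedes creation")
    df = pd.DataFrame({"creation": c.dt.to_period("Q").astype(str),
                       "view": v.dt.to_period("Q").astype(str)})
    mat = pd.crosstab(df["creation"], df["view"])
    all_q = sorted(set(mat.index) | set(mat.columns))
    mat = mat.reindex(index=all_q, columns=all_q, fill_value=0)
    col_tot = mat.sum(axis=0)
    diag = pd.Series(np.diag(mat.to_numpy()), index=all_q)
    with np.errstate(invalid="ignore"):
        prev_pct = (1.0 - diag / col_tot.replace(0, np.nan)) * 100.0
    prev_pct.name = "pct_views_of_previous_quarters"
    prev_pct.index.name = "view_quarter"
    return mat, prev_pct


def aging_curve(
    classified: pd.DataFrame, by: str = "producing_encounter_type"
) -> dict[str, pd.DataFrame]:
    """Per-stratum empirical age-at-view curve for survival-style plots.

    For each stratum the curve is the age value at each integer percentile
    0..100 (linear interpolation), so the value at percentile 50 equals the
    stratum's median life exactly.
    """
    out: dict[str, pd.DataFrame] = {}
    q = np.arange(0, 101)
    for key, grp in classified.groupby(by, sort=True):
        ages = grp["report_age_days"].to_numpy(dtype=float)
        if ages.size == 0:
            continue
        vals = np.percentile(ages, q, method="linear")
        out[str(key)] = pd.DataFrame({
            "percentile": q,
            "age_days": vals,
            "fraction_older": 1.0 - q / 100.0,
        })
    return out
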