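"""Assign each view its encounter context and its relation to the report's
producing encounter (present / last / previous / unmatched).

Matching rule: a view matches an inpatient encounter when the view's
calendar date falls inside the closed [start, end] date interval; it
matches a single-day encounter when the calendar dates are equal.  If
several encounters match, interval (inpatient) encounters beat single-day
ones and, within the same kind, the latest start wins.  A view with no
matching encounter gets no context.

Relation rule: *present* if the producing encounter is the viewing
encounter; *last* if it is the patient's immediately preceding encounter
(any type) before the viewing encounter's start; *previous* if it precedes
that; *unmatched* otherwise (no viewing context, no producing encounter, or
a producing encounter that fits none of the three).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IntegrityError

RELATIONS = ("present", "last", "previous", "unmatched")

VIEW_SETTINGS = ("emergency", "inpatient", "outpatient")


def _as_day(ts) -> pd.Timestamp:
    return pd.Timestamp(ts).normalize()


def encounter_at(view_time, patient_encounters: pd.DataFrame):
    """Return the encounter_id active at ``view_time``, or None.

    ``patient_encounters`` must belong to a single patient.
    """
    if patient_encounters["patient_id"].nunique() > 1:
        raise IntegrityError("encounter_at: encounters from multiple patients")
    day = _as_day(view_time)
    best = None  # (is_interval, start, encounter_id)
    for row in patient_encounters.itertuples(index=False):
        start_d = _as_day(row.start)
        end_d = _as_day(row.end)
        if row.type == "inpatient":
            hit = start_d <= day <= end_d
            kind = 1
        else:
            hit = start_d == day
            kind = 0
        if hit:
            key = (kind, pd.Timestamp(row.start))
            if best is None or key > best[0]:
                best = (key, row.encounter_id)
    return None if best is None else best[1]


def classify_relation(
    viewing_encounter_id,
    producing_encounter_id,
    history: pd.DataFrame,
    view_time=None,
) -> str:
    """Classify a single view's relation given a patient's encounter history
    (sorted or not; it is ordered internally by start time)."""
    if viewing_encounter_id is None or producing_encounter_id is None:
        return "unmatched"
    hist = history.sort_values(["start", "encounter_id"], kind="stable")
    starts = {r.encounter_id: pd.Timestamp(r.start)
              for r in hist.itertuples(index=False)}
    if producing_encounter_id not in starts:
        raise IntegrityError(
            f"classify_relation: producing encounter "
            f"{producing_encounter_id!r} not in patient history")
    if viewing_encounter_id not in starts:
        raise IntegrityError(
            f"classify_relation: viewing encounter "
            f"{viewing_encounter_id!r} not in patient history")
    if view_time is not None:
        if _as_day(starts[producing_encounter_id]) > _as_day(view_time):
            raise IntegrityError(
                "classify_relation: report produced in an encounter starting "
                "after the view (future report)")
    if producing_encounter_id == viewing_encounter_id:
        return "present"
    v_start = starts[viewing_encounter_id]
    prior = [(s, e) for e, s in starts.items() if s < v_start]
    if not prior:
        return "unmatched"
    last_start, last_id = max(prior)
    if producing_encounter_id == last_id:
        return "last"
    if starts[producing_encounter_id] < last_start:
        return "previous"
    return "unmatched"


def _match_encounters(views: pd.DataFrame, encounters: pd.DataFrame) -> pd.Series:
    """Vectorized encounter_at over a whole view table (joined on patient)."""
    enc = encounters.copy()
    enc["start"] = pd.to_datetime(enc["start"])
    enc["end"] = pd.to_datetime(enc["end"])
    enc["_start_d"] = enc["start"].dt.normalize()
    enc["_end_d"] = enc["end"].dt.normalize()
    enc["_interval"] = (enc["type"] == "inpatient").astype(int)

    v = views[["view_id", "patient_id", "request_time"]].copy()
    v["_day"] = pd.to_datetime(v["request_time"]).dt.normalize()
    j = v.merge(enc[["encounter_id", "patient_id", "type", "start",
                     "_start_d", "_end_d", "_interval"]],
                on="patient_id", how="left")
    hit_interval = (j["_interval"] == 1) & (j["_start_d"] <= j["_day"]) & \
        (j["_day"] <= j["_end_d"])
    hit_point = (j["_interval"] == 0) & (j["_start_d"] == j["_day"])
    j = j.loc[hit_interval | hit_point]
    j = j.sort_values(["view_id", "_interval", "start"], kind="stable")
    j = j.drop_duplicates("view_id", keep="last")
    return j.set_index("view_id")["encounter_id"]


def classify_views(
    views: pd.DataFrame,
    reports: pd.DataFrame,
    encounters: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    mode: str = "grouped",
    groups: pd.DataFrame | None = None,
    report_to_group: pd.Series | None = None,
) -> pd.DataFrame:
    """Produce the classified-view table used by all downstream statistics.

    ``mode='grouped'`` anchors report age at the version group's first
    availability; ``mode='all'`` at the viewed version's own availability.
    Output columns: view identifiers, department, producing encounter (id,
    type, main_dx), the age anchor, ``report_age_days``, the viewing
    encounter (id, type) and the relation label; plus patient sex and age
    (years, at the anchor) when a patient table is supplied.
    """
    if mode not in ("grouped", "all"):
        raise ValueError(f"mode: {mode!r} not in {{'grouped', 'all'}}")
    from .log_preparation import group_versions

    rep = reports.copy()
    rep["available_at"] = pd.to_datetime(rep["available_at"])
    if groups is None or report_to_group is None:
        groups, report_to_group = group_versions(rep)

    out = views.copy()
    out["request_time"] = pd.to_datetime(out["request_time"])
    out["group_id"] = out["report_id"].map(report_to_group)
    if out["group_id"].isna().any():
        missing = out.loc[out["group_id"].isna(), "report_id"].unique()[:5]
        raise IntegrityError(
            f"classify_views: views reference unknown reports {list(missing)}")

    gmeta = groups.set_index("group_id")
    out["patient_id"] = out["group_id"].map(gmeta["patient_id"])
    out["department"] = out["group_id"].map(gmeta["department"])
    out["producing_encounter_id"] = out["group_id"].map(
        gmeta["producing_encounter_id"])
    if mode == "grouped":
        out["age_anchor"] = out["group_id"].map(gmeta["first_available"])
    else:
        anchor = rep.set_index("report_id")["available_at"]
        out["age_anchor"] = out["report_id"].map(anchor)
    out["report_age_days"] = (
        (out["request_time"] - out["age_anchor"]).dt.total_seconds() / 86400.0)

    enc = encounters.copy()
    enc["start"] = pd.to_datetime(enc["start"])
    emeta = enc.set_index("encounter_id")
    out["producing_encounter_type"] = out["producing_encounter_id"].map(
        emeta["type"])
    dx = out["producing_encounter_id"].map(emeta["main_dx"])
    out["main_dx"] = dx.where(dx.astype(str).str.len() > 0)

    matched = _match_encounters(out, enc)
    out["viewing_encounter_id"] = out["view_id"].map(matched)
    out["viewing_encounter_type"] = out["viewing_encounter_id"].map(
        emeta["type"])

    # relation, vectorized: rank encounters per patient by start time
    enc = enc.sort_values(["patient_id", "start", "encounter_id"], kind="stable")
    enc["_rank"] = enc.groupby("patient_id").cumcount()
    rank = enc.set_index("encounter_id")["_rank"]
    start_of = emeta["start"]
    v_rank = out["viewing_encounter_id"].map(rank)
    p_rank = out["producing_encounter_id"].map(rank)
    p_start = out["producing_encounter_id"].map(start_of)
    if p_start.isna().any():
        missing = out.loc[p_start.isna(), "producing_encounter_id"].unique()[:5]
        raise IntegrityError(
            f"classify_views: reports reference unknown encounters "
            f"{list(missing)}")
    future = p_start.dt.normalize() > out["request_time"].dt.normalize()
    if future.any():
        raise IntegrityError(
            f"classify_views: {int(future.sum())} views predate their "
            f"report's producing encounter (future report)")

    relation = np.full(len(out), "unmatched", dtype=object)
    has_ctx = v_rank.notna()
    present = has_ctx & (out["producing_encounter_id"]
                         == out["viewing_encounter_id"])
    last = has_ctx & ~present & (p_rank == v_rank - 1)
    previous = has_ctx & ~present & (p_rank < v_rank - 1)
    relation[present.to_numpy()] = "present"
    relation[last.to_numpy()] = "last"
    relation[previous.to_numpy()] = "previous"
    out["relation"] = relation

    if patients is not None:
        pmeta = patients.set_index("patient_id")
        out["sex"] = out["patient_id"].map(pmeta["sex"])
        birth = pd.to_datetime(out["patient_id"].map(pmeta["birth_date"]))
        out["patient_age_years"] = np.floor(
            (out["age_anchor"] - birth).dt.days / 365.25).astype(int)

    cols = ["view_id", "report_id", "group_id", "patient_id", "department",
            "producing_encounter_id", "producing_encounter_type", "main_dx",
            "age_anchor", "request_time", "report_age_days",
            "viewing_encounter_id", "viewing_encounter_type", "relation"]
    if patients is not None:
        cols += ["sex", "patient_age_years"]
    return out[cols]


def setting_crosstab(classified: pd.DataFrame) -> pd.DataFrame:
    """Row-percentage table: viewing setting x relation/producing-type.

    Rows are the viewing settings (emergency, inpatient, outpatient);
    columns are ``present``, ``last_<producing type>`` and
    ``previous_<producing type>``.  Cells are percentages of the row total
    over context-matched views; each row sums to 100 up to rounding.
    Unmatched views are excluded.  An empty input yields an empty table.
    """
    df = classified.loc[
        (classified["relation"] != "unmatched")
        & classified["viewing_encounter_type"].isin(VIEW_SETTINGS)
    ].copy()
    if df.empty:
        return pd.DataFrame(index=pd.Index([], name="viewed_in"))
    col = np.where(df["relation"] == "present", "present",
                   df["relation"] + "_" + df["producing_encounter_type"])
    df["_col"] = col
    counts = df.pivot_table(index="viewing_encounter_type", columns="_col",
                            values="view_id", aggfunc="count", fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    order = ["present"]
    for rel in ("last", "previous"):
        order += sorted(c for c in pct.columns if c.startswith(rel + "_"))
    pct = pct[[c for c in order if c in pct.columns]]
    pct.index.name = "viewed_in"
    pct.columns.name = None
    pct["n_views"] = counts.sum(axis=1)
    return pct
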