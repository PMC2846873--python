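"""Raw-log preparation: development-session exclusion, viewing-duration
inference, mistaken-view filtering and report version grouping.

The stages never alter timestamps of surviving rows; they only derive
columns and partition rows.  Every raw view ends up in exactly one of
{kept, removed-dev, removed-mistaken, removed-invalid}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError

logger = logging.getLogger(__name__)

#: Inclusive duration bound (seconds) below which a view counts as mistaken.
MISTAKEN_THRESHOLD_S = 3.0


def exclude_dev_sessions(
    sessions: pd.DataFrame, dev_user_list
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sessions into (kept, removed) by login membership in the
    development-team user list.  An empty list is a warned no-op."""
    dev = set(dev_user_list or ())
    if not dev:
        logger.warning("exclude_dev_sessions: empty dev_user_list; no-op")
        return sessions.copy(), sessions.iloc[0:0].copy()
    is_dev = sessions["login"].isin(dev)
    kept = sessions.loc[~is_dev].copy()
    removed = sessions.loc[is_dev].copy()
    logger.info("exclude_dev_sessions: removed %d of %d sessions",
                len(removed), len(sessions))
    return kept, removed


def infer_view_durations(views: pd.DataFrame) -> pd.DataFrame:
    """Add a ``max_duration`` column (seconds) per view.

    Within each session, views are ordered by request time and the maximum
    viewing duration of each view is the gap to the following request in
    the same session; the last view of a session has no following request
    and its duration is left undefined (NaN).  Views whose request time
    cannot be interpreted are flagged ``invalid``.
    """
    out = views.copy()
    t = pd.to_datetime(out["request_time"], errors="coerce")
    out["invalid"] = t.isna()
    if out["invalid"].any():
        logger.warning("infer_view_durations: %d views with unusable "
                       "timestamps flagged invalid", int(out["invalid"].sum()))
    order = np.lexsort((t.to_numpy(dtype="datetime64[ns]"),
                        out["session_id"].to_numpy()))
    out = out.iloc[order]
    tt = pd.to_datetime(out["request_time"]).to_numpy(dtype="datetime64[ns]")
    same = out["session_id"].to_numpy()[1:] == out["session_id"].to_numpy()[:-1]
    gaps = (tt[1:] - tt[:-1]) / np.timedelta64(1, "s")
    dur = np.full(len(out), np.nan)
    dur[:-1][same] = gaps[same]
    # negative gaps cannot arise after the in-session sort; guard anyway
    neg = dur < 0
    if neg.any():
        out.loc[neg, "invalid"] = True
        dur[neg] = np.nan
    out["max_duration"] = dur
    out.loc[out["invalid"], "max_duration"] = np.nan
    return out.reset_index(drop=True)


def filter_mistaken_views(
    views: pd.DataFrame, threshold_s: float = MISTAKEN_THRESHOLD_S
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split views into (kept, removed) by the mistaken-view rule.

    A view with a defined duration of at most ``threshold_s`` seconds is
    removed; views with undefined durations (last of a session) are kept.
    """
    dur = views["max_duration"]
    mistaken = dur.notna() & (dur <= threshold_s)
    kept = views.loc[~mistaken].copy()
    removed = views.loc[mistaken].copy()
    kept["mistaken"] = False
    removed["mistaken"] = True
    return kept, removed


def group_versions(reports: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse report versions into version groups.

    Returns the group table (one row per group with the first availability
    timestamp as age anchor) and a report_id -> group_id mapping.  Group
    members spanning several patients violate integrity.
    """
    rep = reports.copy()
    rep["available_at"] = pd.to_datetime(rep["available_at"])
    n_pat = rep.groupby("group_id")["patient_id"].nunique()
    bad = n_pat[n_pat > 1]
    if len(bad):
        raise IntegrityError(
            f"group_versions: groups spanning multiple patients: "
            f"{sorted(bad.index[:5].tolist())}")
    rep = rep.sort_values(["group_id", "version"], kind="stable")
    groups = rep.groupby("group_id", sort=True).agg(
        first_available=("available_at", "min"),
        department=("department", "first"),
        patient_id=("patient_id", "first"),
        producing_encounter_id=("producing_encounter_id", "first"),
        n_versions=("report_id", "size"),
    ).reset_index()
    mapping = rep.set_index("report_id")["group_id"]
    return groups, mapping


@dataclass
class PreparationResult:
    """Outcome of the full preparation stage."""

    views: pd.DataFrame            # kept, analysis-ready views
    removed_mistaken: pd.DataFrame
    removed_dev: pd.DataFrame
    removed_invalid: pd.DataFrame
    groups: pd.DataFrame
    report_to_group: pd.Series
    summary: dict = field(default_factory=dict)


def prepare_logs(
    sessions: pd.DataFrame,
    views: pd.DataFrame,
    reports: pd.DataFrame,
    dev_user_list=(),
    threshold_s: float = MISTAKEN_THRESHOLD_S,
) -> PreparationResult:
    """Run the whole preparation stage and tally a conservation summary."""
    n_raw = len(views)
    kept_sessions, removed_sessions = exclude_dev_sessions(sessions, dev_user_list)
    dev_sids = set(removed_sessions["session_id"])
    in_dev = views["session_id"].isin(dev_sids)
    removed_dev = views.loc[in_dev].copy()
    views = views.loc[~in_dev]

    with_dur = infer_view_durations(views)
    invalid = with_dur.loc[with_dur["invalid"]].copy()
    with_dur = with_dur.loc[~with_dur["invalid"]]
    kept, removed_mistaken = filter_mistaken_views(with_dur, threshold_s)
    groups, mapping = group_versions(reports)
    kept = kept.drop(columns=["invalid"])
    kept["group_id"] = kept["report_id"].map(mapping)

    n_after_dev = n_raw - len(removed_dev)
    summary = {
        "n_raw_views": n_raw,
        "n_dev_sessions_removed": int(len(removed_sessions)),
        "n_views_removed_dev": int(len(removed_dev)),
        "n_views_removed_invalid": int(len(invalid)),
        "n_views_removed_mistaken": int(len(removed_mistaken)),
        "n_views_kept": int(len(kept)),
        "pct_mistaken": (100.0 * len(removed_mistaken) / n_after_dev
                         if n_after_dev else 0.0),
        "n_report_versions": int(len(reports)),
        "n_version_groups": int(len(groups)),
    }
    assert (summary["n_views_kept"] + summary["n_views_removed_mistaken"]
            + summary["n_views_removed_invalid"]
            + summary["n_views_removed_dev"]) == n_raw
    return PreparationResult(kept.reset_index(drop=True), removed_mistaken,
                             removed_dev, invalid, groups, mapping, summary)
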