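"""Synthetic hospital audit-log generator.

Produces the five flat tables the analysis pipeline consumes (patients,
encounters, reports, sessions, views) with the statistical structure the
downstream estimators assume:

* view ages drawn per stratum either from a point-mass-at-zero plus
  exponential-tail mixture — whose survival is ``a * exp(-b * months)`` for
  positive ages — or from a log-normal law with a configurable true median;
* laboratory departments emitting multi-version report streams sharing one
  group key;
* a configurable fraction of views engineered to have inferred durations of
  at most three seconds ("mistaken" views);
* a configurable fraction of sessions belonging to a development-team user.

Everything is deterministic given the seed: random streams are split per
table and per entity with :class:`numpy.random.SeedSequence` so that the
same configuration always yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError

DAYS_PER_MONTH = 30.4375

ENCOUNTER_TYPES = (
    "inpatient", "outpatient", "emergency", "day-care", "lab-result", "radiology",
)

#: Departments whose source systems push revised versions of the same report.
LAB_DEPARTMENTS = frozenset({
    "immune-haemotherapy", "clinical pathology", "haemostasis",
    "transfusion laboratory", "molecular biology", "viral markers",
})

DEV_USERS = ("dev001", "dev002", "dev003", "dev004", "dev005")

# Small pool of main-diagnosis codes spanning many chapters.
_SAMPLE_DX = (
    "008.45", "162.9", "174.9", "204.00", "250.00", "285.9", "296.20",
    "345.90", "410.91", "434.91", "486", "531.30", "574.20", "584.9",
    "642.41", "682.9", "715.90", "745.4", "765.10", "780.60", "821.01",
    "969.4", "V30.00", "E880.9",
)

_DEFAULT_TYPE_MIX = {
    "inpatient": 0.10, "outpatient": 0.50, "emergency": 0.25,
    "day-care": 0.05, "lab-result": 0.05, "radiology": 0.05,
}

_DEFAULT_DEPT_MIX = {
    "immune-haemotherapy": 0.40, "clinical pathology": 0.30,
    "pathology": 0.15, "gastroenterology": 0.05, "haemostasis": 0.10,
}


def _check_mix(name: str, mix: dict) -> None:
    if not mix:
        raise ParameterError(f"{name}: probability mix must be nonempty")
    total = float(sum(mix.values()))
    if any(v < 0 for v in mix.values()):
        raise ParameterError(f"{name}: probabilities must be nonnegative")
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"{name}: probabilities sum to {total}, not 1")


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    ``age_mixture_by_stratum`` maps a stratum key (a department name, an
    encounter type, or ``"default"``) to ``{"a": tail_mass, "b": rate_per_month,
    "scale": months_per_unit}``.  ``true_median_by_stratum`` optionally
    overrides a stratum with a log-normal age law whose median (in days)
    equals the given value; it takes precedence over the mixture for the
    same key.  Department keys are resolved before encounter-type keys.
    """

    n_patients: int = 100
    date_span: tuple[str, str] = ("2005-01-01", "2007-12-31")
    encounter_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_MIX))
    dept_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEPT_MIX))
    versions_per_report: dict = field(
        default_factory=lambda: {"kind": "one_plus_poisson", "mean": 0.8})
    mean_encounters_per_patient: float = 3.0
    mean_reports_per_encounter: float = 1.2
    mean_views_per_report: float = 2.0
    mean_session_size: float = 2.0
    age_mixture_by_stratum: dict[str, dict] = field(
        default_factory=lambda: {"default": {"a": 0.5826, "b": 0.12, "scale": 1.0}})
    true_median_by_stratum: dict[str, float] | None = None
    lognormal_sigma: float = 0.75
    mistaken_view_rate: float = 0.022
    dev_session_rate: float = 0.01
    n_users: int = 200
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients: must be >= 1")
        _check_mix("encounter_type_mix", self.encounter_type_mix)
        _check_mix("dept_mix", self.dept_mix)
        unknown = set(self.encounter_type_mix) - set(ENCOUNTER_TYPES)
        if unknown:
            raise ParameterError(
                f"encounter_type_mix: unknown encounter types {sorted(unknown)}")
        kind = self.versions_per_report.get("kind")
        if kind not in ("constant", "one_plus_poisson"):
            raise ParameterError(
                f"versions_per_report: unknown distribution kind {kind!r}")
        for key, law in self.age_mixture_by_stratum.items():
            a, b = law.get("a"), law.get("b")
            if a is None or not 0.0 <= a <= 1.0:
                raise ParameterError(f"age_mixture_by_stratum[{key!r}].a: "
                                     f"{a!r} outside [0, 1]")
            if b is None or b <= 0:
                raise ParameterError(f"age_mixture_by_stratum[{key!r}].b: "
                                     f"{b!r} must be > 0")
            if law.get("scale", 1.0) <= 0:
                raise ParameterError(
                    f"age_mixture_by_stratum[{key!r}].scale: must be > 0")
        if self.true_median_by_stratum:
            for key, m in self.true_median_by_stratum.items():
                if m <= 0:
                    raise ParameterError(
                        f"true_median_by_stratum[{key!r}]: median must be > 0")
        if not 0.0 <= self.mistaken_view_rate < 1.0:
            raise ParameterError("mistaken_view_rate: must be in [0, 1)")
        if not 0.0 <= self.dev_session_rate < 1.0:
            raise ParameterError("dev_session_rate: must be in [0, 1)")
        if self.lognormal_sigma <= 0:
            raise ParameterError("lognormal_sigma: must be > 0")
        start, end = (pd.Timestamp(d) for d in self.date_span)
        if (end - start).days < 30:
            raise ConfigurationError(
                "date_span: too short to host the requested encounters "
                "(need at least 30 days)")
        if ("default" not in self.age_mixture_by_stratum
                and not (self.true_median_by_stratum
                         and "default" in self.true_median_by_stratum)):
            raise ConfigurationError(
                "age law: a 'default' stratum is required in "
                "age_mixture_by_stratum or true_median_by_stratum")

    def resolve_age_law(self, department: str, encounter_type: str) -> dict:
        """Pick the age law for a report: department key wins over encounter
        type, which wins over 'default'; a true-median (log-normal) entry
        wins over a mixture entry for the same key."""
        medians = self.true_median_by_stratum or {}
        for key in (department, encounter_type, "default"):
            if key in medians:
                return {"law": "lognormal", "stratum": key,
                        "median_days": float(medians[key]),
                        "sigma": self.lognormal_sigma}
            if key in self.age_mixture_by_stratum:
                law = self.age_mixture_by_stratum[key]
                return {"law": "mixture", "stratum": key,
                        "a": float(law["a"]), "b": float(law["b"]),
                        "scale": float(law.get("scale", 1.0))}
        raise ConfigurationError("age law: no stratum matched and no default")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["date_span"] = list(d["date_span"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "date_span" in d:
            d["date_span"] = tuple(d["date_span"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """The five generated tables plus the generating ground truth."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    reports: pd.DataFrame
    sessions: pd.DataFrame
    views: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "encounters", "reports", "sessions", "views"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def generate_view_ages(n: int, a: float, b: float, seed=None) -> np.ndarray:
    """Draw ``n`` report ages (in months) from the zero/exponential mixture.

    With probability ``1 - a`` the age is exactly 0; otherwise it is
    exponential with rate ``b`` per month, so that the survival fraction of
    ages at least ``x`` months is ``a * exp(-b * x)`` for ``x > 0``.
    """
    if n < 1:
        raise ParameterError("n: must be >= 1")
    if not 0.0 <= a <= 1.0:
        raise ParameterError(f"a: {a!r} outside [0, 1]")
    if not b > 0:
        raise ParameterError(f"b: {b!r} must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = np.zeros(n)
    tail = rng.random(n) < a
    ages[tail] = rng.exponential(scale=1.0 / b, size=int(tail.sum()))
    return ages


def _sample_ages_days(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if law["law"] == "mixture":
        months = generate_view_ages(n, law["a"], law["b"], rng) * law["scale"]
        return months * DAYS_PER_MONTH
    # log-normal with exact median: median of exp(N(mu, s^2)) is exp(mu)
    mu = math.log(law["median_days"])
    return rng.lognormal(mean=mu, sigma=law["sigma"], size=n)


def _draw_versions(spec: dict, rng: np.random.Generator) -> int:
    if spec["kind"] == "constant":
        return max(1, int(spec["value"]))
    return 1 + int(rng.poisson(spec["mean"]))


def _draw_count(mean: float, rng: np.random.Generator) -> int:
    """1 + Poisson(mean - 1) for mean >= 1 (so mean 1.0 is exactly one),
    plain Poisson below 1."""
    if mean >= 1.0:
        return 1 + int(rng.poisson(mean - 1.0))
    return int(rng.poisson(mean))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Encounters of a patient never overlap; inpatient encounters are
    multi-day intervals with a main ICD-9-CM diagnosis, all other types are
    single-day events.  Each report is anchored to a producing encounter and
    becomes available inside it; views are placed at first availability plus
    a sampled age.  Sessions then partition the time-ordered views; a
    ``mistaken_view_rate`` fraction of non-terminal views is nudged to
    within three seconds of the following request in the same session.
    """
    config.validate()
    span_start, span_end = (pd.Timestamp(d) for d in config.date_span)
    span_days = (span_end - span_start).days

    ss = np.random.SeedSequence(config.seed)
    s_pat, s_enc, s_rep, s_view, s_sess = ss.spawn(5)

    # ---- patients -------------------------------------------------------
    rng = np.random.default_rng(s_pat)
    n = config.n_patients
    patient_ids = [f"P{i:06d}" for i in range(n)]
    sexes = rng.choice(np.array(["F", "M"]), size=n)
    age_years = rng.uniform(0.0, 95.0, size=n)
    birth_dates = (span_start - pd.to_timedelta(age_years * 365.25, unit="D")).normalize()
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "sex": sexes,
        "birth_date": birth_dates.strftime("%Y-%m-%d"),
    })

    # ---- encounters (per-patient stream) --------------------------------
    type_names = list(config.encounter_type_mix)
    type_probs = np.array([config.encounter_type_mix[t] for t in type_names])
    enc_rows: list[tuple] = []
    enc_children = s_enc.spawn(n)
    max_enc = max(1, span_days // 4)
    for i, child in enumerate(enc_children):
        r = np.random.default_rng(child)
        n_enc = 1 + int(r.poisson(max(config.mean_encounters_per_patient - 1, 0)))
        n_enc = min(n_enc, max_enc)
        start_days = np.sort(r.choice(span_days, size=n_enc, replace=False))
        for j, d in enumerate(start_days):
            etype = type_names[int(r.choice(len(type_names), p=type_probs))]
            start = span_start + pd.Timedelta(days=int(d), hours=8)
            limit = int(start_days[j + 1]) - 1 if j + 1 < n_enc else span_days
            if etype == "inpatient":
                dur = 1 + int(r.geometric(0.25))
                dur = max(0, min(dur, limit - int(d)))
                end = span_start + pd.Timedelta(days=int(d) + dur, hours=18)
                dx = _SAMPLE_DX[int(r.choice(len(_SAMPLE_DX)))]
            else:
                end = span_start + pd.Timedelta(days=int(d), hours=18)
                dx = ""
            enc_rows.append((f"E{i:06d}x{j:02d}", patient_ids[i], etype,
                             start, end, dx))
    encounters = pd.DataFrame(
        enc_rows, columns=["encounter_id", "patient_id", "type",
                           "start", "end", "main_dx"])

    # ---- reports (per-encounter stream) ---------------------------------
    dept_names = list(config.dept_mix)
    dept_probs = np.array([config.dept_mix[d] for d in dept_names])
    rep_rows: list[tuple] = []
    group_meta: list[dict] = []  # one entry per version group
    rep_children = s_rep.spawn(len(enc_rows))
    gid_counter = 0
    for (enc_id, pid, etype, start, end, _dx), child in zip(enc_rows, rep_children):
        r = np.random.default_rng(child)
        n_rep = _draw_count(config.mean_reports_per_encounter, r)
        for _ in range(n_rep):
            dept = dept_names[int(r.choice(len(dept_names), p=dept_probs))]
            window_h = max((end - start).total_seconds() / 3600.0, 1.0)
            base = start + pd.Timedelta(hours=float(r.uniform(0.0, window_h)))
            n_ver = (_draw_versions(config.versions_per_report, r)
                     if dept in LAB_DEPARTMENTS else 1)
            gid = f"G{gid_counter:07d}"
            gid_counter += 1
            avail = base
            avail_list = []
            for v in range(1, n_ver + 1):
                rep_rows.append((f"{gid}.v{v}", gid, pid, dept,
                                 avail, enc_id, v))
                avail_list.append(avail)
                avail = avail + pd.Timedelta(hours=float(r.uniform(2.0, 48.0)))
            group_meta.append({
                "group_id": gid, "patient_id": pid, "department": dept,
                "encounter_type": etype, "first_available": base,
                "version_avail": avail_list,
            })
    reports = pd.DataFrame(
        rep_rows, columns=["report_id", "group_id", "patient_id", "department",
                           "available_at", "producing_encounter_id", "version"])

    # ---- views (per-group stream) ---------------------------------------
    view_rows: list[tuple] = []
    view_children = s_view.spawn(len(group_meta))
    strata_truth: dict[str, dict] = {}
    for meta, child in zip(group_meta, view_children):
        r = np.random.default_rng(child)
        n_v = _draw_count(config.mean_views_per_report, r)
        if n_v == 0:
            continue
        law = config.resolve_age_law(meta["department"], meta["encounter_type"])
        strata_truth.setdefault(law["stratum"], {k: v for k, v in law.items()
                                                 if k != "stratum"})
        # sort and pad same-group views 60 s apart: the age point-mass at
        # zero would otherwise collide timestamps and create spurious <= 3 s
        # inferred durations that bias the mistaken-view filter
        ages_days = np.sort(_sample_ages_days(law, n_v, r))
        for k, age in enumerate(ages_days):
            t = meta["first_available"] + pd.Timedelta(
                seconds=float(age) * 86400.0 + 60.0 * k)
            # view the newest version already available at view time
            idx = int(np.searchsorted(
                pd.DatetimeIndex(meta["version_avail"]).asi8,
                t.value, side="right")) - 1
            idx = max(idx, 0)
            view_rows.append((f"{meta['group_id']}.v{idx + 1}", t))
    if not view_rows:
        raise ConfigurationError(
            "generated zero views; increase n_patients or the per-entity means")

    views = pd.DataFrame(view_rows, columns=["report_id", "request_time"])
    views = views.sort_values("request_time", kind="stable").reset_index(drop=True)
    views.insert(0, "view_id", [f"V{i:08d}" for i in range(len(views))])

    # ---- sessions + mistaken-view engineering ---------------------------
    r = np.random.default_rng(s_sess)
    n_views = len(views)
    sizes: list[int] = []
    covered = 0
    while covered < n_views:
        k = 1 + int(r.poisson(max(config.mean_session_size - 1, 0)))
        k = min(k, n_views - covered)
        sizes.append(k)
        covered += k
    session_ids = np.empty(n_views, dtype=object)
    is_last = np.zeros(n_views, dtype=bool)
    sess_rows: list[tuple] = []
    pos = 0
    for si, k in enumerate(sizes):
        sid = f"S{si:07d}"
        session_ids[pos:pos + k] = sid
        is_last[pos + k - 1] = True
        is_dev = bool(r.random() < config.dev_session_rate)
        if is_dev:
            login = DEV_USERS[int(r.choice(len(DEV_USERS)))]
            category = "developer"
        else:
            login = f"u{int(r.integers(config.n_users)):04d}"
            category = "physician"
        ip = f"10.{int(r.integers(0, 32))}.{int(r.integers(0, 256))}.{int(r.integers(1, 255))}"
        sess_rows.append((sid, login, ip, None, category, is_dev))
        pos += k
    views["session_id"] = session_ids

    # Designate mistaken views among non-terminal positions so that the
    # overall designated fraction matches mistaken_view_rate; nudge each
    # designated view to < 3 s before the *following* request so the
    # downstream duration inference marks it mistaken.  The nudged views are
    # excluded from analysis anyway, so distorting their ages is harmless.
    non_last = ~is_last
    m = int(non_last.sum())
    p_eff = min(1.0, config.mistaken_view_rate * n_views / m) if m else 0.0
    mistaken = non_last & (r.random(n_views) < p_eff)
    times = views["request_time"].to_numpy().copy()
    gaps = r.uniform(0.5, 3.0, size=n_views)
    for i in range(n_views - 1, -1, -1):
        if mistaken[i]:
            times[i] = times[i + 1] - np.timedelta64(
                int(gaps[i] * 1e9), "ns")
    views["request_time"] = times

    sessions = pd.DataFrame(
        sess_rows, columns=["session_id", "login", "ip", "start",
                            "user_category", "is_dev"])
    sess_start = views.groupby("session_id")["request_time"].min()
    sessions["start"] = sessions["session_id"].map(sess_start)

    views = views[["view_id", "session_id", "report_id", "request_time"]]

    truth = {
        "seed": config.seed,
        "strata": strata_truth,
        "mistaken_view_rate": config.mistaken_view_rate,
        "dev_session_rate": config.dev_session_rate,
        "dev_users": list(DEV_USERS),
        "days_per_month": DAYS_PER_MONTH,
        "config": config.to_dict(),
    }
    return SyntheticCohort(patients, encounters, reports, sessions, views, truth)
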