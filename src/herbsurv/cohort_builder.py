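"""From raw claims tables to the analysis cohort.

Implements the enrollment flow of a claims-based CHM exposure study:
case identification by the one-inpatient-or-three-outpatient-visits-within-
one-year rule, neurological-subtype classification, the exclusion cascade
(neurological disease before HIV, missing demographics, fewer than 14
cumulative CHM days in the first year, any in-study malignancy), exposure
and index-date assignment, covariate derivation (Charlson score, cumulative
ART defined daily doses, opportunistic-infection flags), and cause-of-death
categorisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import codes as codes_mod
from .codes import CodeSet, match_code
from .errors import DataError
from .synthetic_claims import ART_CLASSES, ClaimsBundle, chm_index_date

log = logging.getLogger(__name__)

EXCLUSION_BINS = (
    "neuro_before_hiv",
    "missing_demographics",
    "low_chm",
    "malignancy",
    "died_before_index",
)


@dataclass
class CohortOptions:
    """Tunable enrollment rules.

    ``chm_threshold_days``: cumulative prescription days in the first year
    after neurological diagnosis that define a CHM user (threshold is
    inclusive: exactly 14 days counts as a user, consistent with the
    below-14-days exclusion rule).  ``nonuser_index`` picks the landmark
    granting non-users an index date: ``"median_lag"`` (neurological
    diagnosis plus the cohort median user lag, limiting immortal-time bias)
    or ``"neuro_date"``.  ``oi_reference`` controls when opportunistic
    infections are flagged (any visit before the index date).
    """

    chm_threshold_days: int = 14
    chm_window_days: int = 365
    visit_window_days: int = 365
    min_inpatient: int = 1
    min_outpatient: int = 3
    hiv_onset_years: tuple[int, int] = (2010, 2017)
    study_end: date = date(2019, 12, 31)
    nonuser_index: str = "median_lag"
    oi_reference: str = "index"


# ---------------------------------------------------------------------------
# Elementary operations


def diagnosis_onset(
    events: pd.DataFrame,
    cs: CodeSet,
    window_days: int = 365,
    min_inpatient: int = 1,
    min_outpatient: int = 3,
) -> date | None:
    """Earliest matched-event date whose forward window satisfies the visit
    rule (at least ``min_inpatient`` inpatient or ``min_outpatient``
    outpatient matched visits within ``window_days``); None otherwise."""
    if events is None or len(events) == 0:
        return None
    mask = events["code"].map(lambda c: match_code(str(c), cs))
    sub = events.loc[mask]
    if len(sub) == 0:
        return None
    dates = pd.to_datetime(sub["date"]).dt.date.to_numpy()
    inpat = (sub["setting"].to_numpy() == "inpatient")
    order = np.argsort(dates, kind="stable")
    dates, inpat = dates[order], inpat[order]
    return _onset_from_arrays(dates, inpat, window_days, min_inpatient, min_outpatient)


def _onset_from_arrays(dates, inpat, window_days, min_inpatient, min_outpatient):
    n = len(dates)
    for i in range(n):
        end = dates[i] + timedelta(days=window_days)
        k_in = 0
        k_out = 0
        for j in range(i, n):
            if dates[j] >= end:
                break
            if inpat[j]:
                k_in += 1
            else:
                k_out += 1
        if k_in >= min_inpatient or k_out >= min_outpatient:
            return dates[i]
    return None


def classify_neuro(
    events: pd.DataFrame,
    after: date,
    subtype_sets: dict[str, CodeSet] | None = None,
    **onset_kwargs,
) -> tuple[date | None, set[str]]:
    """Apply the visit rule per neurological subtype to events dated at or
    after ``after``; return the earliest qualifying onset and all qualifying
    subtypes."""
    if subtype_sets is None:
        subtype_sets = codes_mod.load_neuro_codesets()
    if events is None or len(events) == 0:
        return None, set()
    ev = events.loc[pd.to_datetime(events["date"]).dt.date >= after]
    onset: date | None = None
    subtypes: set[str] = set()
    for name, cs in subtype_sets.items():
        d = diagnosis_onset(ev, cs, **onset_kwargs)
        if d is not None:
            subtypes.add(name)
            if onset is None or d < onset:
                onset = d
    return onset, subtypes


def cumulative_chm_days(
    prescriptions: pd.DataFrame, start: date, window_days: int = 365
) -> int:
    """Sum of prescription ``days`` over CHM rows dated within
    [start, start + window); overlapping prescriptions are summed, not
    merged."""
    if prescriptions is None or len(prescriptions) == 0:
        return 0
    chm = prescriptions.loc[prescriptions["class"] == "CHM"]
    if (chm["days"] < 0).any():
        raise DataError("negative prescription days")
    d = pd.to_datetime(chm["date"]).dt.date
    end = start + timedelta(days=window_days)
    sel = (d >= start) & (d < end)
    return int(chm.loc[sel, "days"].sum())


def assign_exposure(
    prescriptions: pd.DataFrame,
    neuro_date: date,
    threshold_days: int = 14,
    window_days: int = 365,
) -> tuple[str, date | None]:
    """Classify exposure and, for users, compute the index date.

    Users accumulate ``threshold_days`` of CHM within the first year after
    neurological diagnosis; their index date is the day after the
    prescription-day on which the running total first reaches the
    threshold.  Patients with no CHM at all are non-users; anyone else is
    excluded as a low-exposure case.
    """
    chm = (
        prescriptions.loc[prescriptions["class"] == "CHM"]
        if prescriptions is not None and len(prescriptions)
        else None
    )
    if chm is None or len(chm) == 0:
        return "non_user", None
    d = pd.to_datetime(chm["date"]).dt.date
    end = neuro_date + timedelta(days=window_days)
    in_win = chm.loc[(d >= neuro_date) & (d < end)]
    if len(in_win):
        dates = pd.to_datetime(in_win["date"]).dt.date.tolist()
        days = in_win["days"].astype(int).tolist()
        idx = chm_index_date(dates, days, threshold_days)
        if idx is not None:
            return "chm_user", idx
    return "exclude_low_chm", None


def compute_cci(
    events: pd.DataFrame,
    before: date,
    charlson: codes_mod.CharlsonMap | None = None,
) -> tuple[float, str]:
    """Charlson score and comorbidity-count group from diagnoses strictly
    before ``before``.

    The group (0 / 1-2 / >=3) counts distinct Charlson categories after
    applying the severity hierarchy.
    """
    if charlson is None:
        charlson = codes_mod.load_charlson_map()
    cats: set[str] = set()
    if events is not None and len(events):
        ev = events.loc[pd.to_datetime(events["date"]).dt.date < before]
        for code in ev["code"].astype(str).unique():
            for label, cs in charlson.categories.items():
                if match_code(code, cs):
                    cats.add(label)
    for mild, severe in charlson.hierarchy:
        if mild in cats and severe in cats:
            cats.discard(mild)
    score = float(sum(charlson.weights[c] for c in cats))
    n = len(cats)
    group = "0" if n == 0 else ("1-2" if n <= 2 else ">=3")
    return score, group


def cumulative_ddd(
    prescriptions: pd.DataFrame, start: date, end: date
) -> dict[str, float]:
    """Per-ART-class cumulative defined daily doses over [start, end]."""
    if start > end:
        raise DataError("cumulative_ddd: start after end")
    out = {cls: 0.0 for cls in ART_CLASSES}
    if prescriptions is not None and len(prescriptions):
        art = prescriptions.loc[prescriptions["class"].isin(ART_CLASSES)]
        d = pd.to_datetime(art["date"]).dt.date
        sel = art.loc[(d >= start) & (d <= end)]
        for cls, g in sel.groupby("class"):
            out[str(cls)] = float(g["ddd_amount"].sum())
    out["total"] = float(sum(out[c] for c in ART_CLASSES))
    return out


_cause_map: codes_mod.CauseMap | None = None


def categorize_cause(cause_code: str, icd_version: int) -> str:
    """Map a cause-of-death code to one of the eight chapter-level
    categories; unparseable codes map to ``other`` with a warning."""
    global _cause_map
    if _cause_map is None:
        _cause_map = codes_mod.CauseMap()
    try:
        cat = _cause_map.categorize(cause_code, int(icd_version))
    except DataError:
        log.warning("unparseable cause-of-death code %r; categorised as other",
                    cause_code)
        return "other"
    return cat


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class _CodeFlags:
    is_hiv: bool
    subtype: str  # first matching subtype or ""
    subtypes: tuple[str, ...]
    is_malignancy: bool
    charlson: tuple[str, ...]
    oi: tuple[str, ...]


def _index_codes(unique_codes, neuro_sets, hiv_cs, malig_cs, charlson, oi_sets):
    flags = {}
    for code in unique_codes:
        code = str(code)
        subs = tuple(s for s, cs in neuro_sets.items() if match_code(code, cs))
        chars = tuple(lbl for lbl, cs in charlson.categories.items()
                      if match_code(code, cs))
        ois = tuple(k for k, cs in oi_sets.items() if match_code(code, cs))
        flags[code] = _CodeFlags(
            is_hiv=match_code(code, hiv_cs),
            subtype=subs[0] if subs else "",
            subtypes=subs,
            is_malignancy=match_code(code, malig_cs),
            charlson=chars,
            oi=ois,
        )
    return flags


def build_cohort(
    bundle: ClaimsBundle, options: CohortOptions | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the enrollment flow to a claims bundle.

    Returns the retained cohort (one analysis-ready row per subject) and the
    exclusion tally.  Bins are disjoint and exhaustive in cascade order:
    neurological disease before HIV, missing age/sex, below-threshold CHM,
    in-study malignancy, and (defensively, for user-supplied data) death on
    or before the assigned index date.  The tally sums to
    identified-minus-retained.
    """
    opt = options or CohortOptions()
    from .synthetic_claims import validate_bundle

    validate_bundle(bundle)

    neuro_sets = codes_mod.load_neuro_codesets()
    hiv_cs = codes_mod.load_codeset("hiv")
    malig_cs = codes_mod.load_codeset("malignancy")
    charlson = codes_mod.load_charlson_map()
    oi_sets = codes_mod.load_oi_codesets()

    dx = bundle.diagnoses.copy()
    dx["date"] = pd.to_datetime(dx["date"]).dt.date
    flags = _index_codes(dx["code"].astype(str).unique(), neuro_sets, hiv_cs,
                         malig_cs, charlson, oi_sets)
    code_flags = dx["code"].astype(str).map(flags)
    dx["_is_hiv"] = [f.is_hiv for f in code_flags]
    dx["_subtypes"] = [f.subtypes for f in code_flags]
    dx["_is_malig"] = [f.is_malignancy for f in code_flags]
    dx["_charlson"] = [f.charlson for f in code_flags]
    dx["_oi"] = [f.oi for f in code_flags]
    dx["_inpat"] = dx["setting"].to_numpy() == "inpatient"
    dx.sort_values(["patient_id", "date"], inplace=True, kind="stable")

    rx = bundle.prescriptions.copy()
    rx["date"] = pd.to_datetime(rx["date"]).dt.date
    chm_all = rx.loc[rx["class"] == "CHM"]
    if (chm_all["days"] < 0).any():
        raise DataError("prescriptions: negative days")
    art_all = rx.loc[rx["class"].isin(ART_CLASSES)]

    deaths = bundle.deaths
    death_date = {
        pid: pd.Timestamp(d).date()
        for pid, d in zip(deaths["patient_id"], deaths["date"])
    }
    death_cause = {
        pid: categorize_cause(code, ver)
        for pid, code, ver in zip(deaths["patient_id"], deaths["cause_code"],
                                  deaths.get("icd_version", pd.Series(dtype=int)))
    } if len(deaths) else {}

    patients = bundle.patients
    sex_map = dict(zip(patients["id"], patients["sex"]))
    birth_map = {
        pid: (pd.Timestamp(b).date() if pd.notna(b) else None)
        for pid, b in zip(patients["id"], patients["birth_date"])
    }

    # Per-patient numpy views (the per-operation public functions work on
    # DataFrames; this loop is the same logic on plain arrays for speed).
    def _group_slices(df):
        pids = df["patient_id"].to_numpy()
        if len(pids) == 0:
            return {}
        starts = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1]])
        bounds = np.r_[starts, len(pids)]
        return {pids[starts[i]]: (bounds[i], bounds[i + 1])
                for i in range(len(starts))}

    dx_dates = dx["date"].to_numpy()
    dx_inpat = dx["_inpat"].to_numpy()
    dx_hiv = np.asarray(dx["_is_hiv"], dtype=bool)
    dx_malig = np.asarray(dx["_is_malig"], dtype=bool)
    dx_subs = list(dx["_subtypes"])
    dx_chars = list(dx["_charlson"])
    dx_oi = list(dx["_oi"])
    dx_slices = _group_slices(dx)

    chm_all = chm_all.sort_values(["patient_id", "date"], kind="stable")
    chm_dates = chm_all["date"].to_numpy()
    chm_days = chm_all["days"].to_numpy(dtype=int)
    chm_slices = _group_slices(chm_all)

    art_all = art_all.sort_values(["patient_id", "date"], kind="stable")
    art_dates = art_all["date"].to_numpy()
    art_cls = art_all["class"].to_numpy()
    art_ddd = art_all["ddd_amount"].to_numpy(dtype=float)
    art_slices = _group_slices(art_all)

    tally = {b: 0 for b in EXCLUSION_BINS}
    pending: list[dict] = []
    y_lo, y_hi = opt.hiv_onset_years
    subtype_names = tuple(neuro_sets)

    for pid, (lo, hi) in dx_slices.items():
        hiv_mask = dx_hiv[lo:hi]
        if not hiv_mask.any():
            continue
        idx = np.arange(lo, hi)
        hiv_onset = _onset_from_arrays(
            dx_dates[idx[hiv_mask]], dx_inpat[idx[hiv_mask]],
            opt.visit_window_days, opt.min_inpatient, opt.min_outpatient)
        if hiv_onset is None or not (y_lo <= hiv_onset.year <= y_hi):
            continue

        sub_masks = {
            s: np.asarray([s in dx_subs[j] for j in idx], dtype=bool)
            for s in subtype_names
        }
        # neuro onset, unrestricted in time
        sub_onsets_all: dict[str, date] = {}
        for s, m in sub_masks.items():
            if not m.any():
                continue
            d = _onset_from_arrays(
                dx_dates[idx[m]], dx_inpat[idx[m]],
                opt.visit_window_days, opt.min_inpatient, opt.min_outpatient)
            if d is not None:
                sub_onsets_all[s] = d
        if not sub_onsets_all:
            continue  # no neurological disease: outside the study frame
        if min(sub_onsets_all.values()) < hiv_onset:
            tally["neuro_before_hiv"] += 1
            continue

        # onset restricted to dates >= HIV diagnosis
        after = dx_dates[idx] >= hiv_onset
        sub_onsets: dict[str, date] = {}
        for s, m in sub_masks.items():
            m2 = m & after
            if not m2.any():
                continue
            d = _onset_from_arrays(
                dx_dates[idx[m2]], dx_inpat[idx[m2]],
                opt.visit_window_days, opt.min_inpatient, opt.min_outpatient)
            if d is not None:
                sub_onsets[s] = d
        if not sub_onsets:
            tally["neuro_before_hiv"] += 1
            continue
        neuro_date = min(sub_onsets.values())

        sex = sex_map.get(pid, "")
        birth = birth_map.get(pid)
        if sex not in ("M", "F") or birth is None:
            tally["missing_demographics"] += 1
            continue

        # exposure status and user index date (running-total crossing rule)
        status, index_date = "non_user", None
        if pid in chm_slices:
            clo, chi_ = chm_slices[pid]
            cd = chm_dates[clo:chi_]
            win_end = neuro_date + timedelta(days=opt.chm_window_days)
            in_win = (cd >= neuro_date) & (cd < win_end)
            if in_win.any():
                idx2 = chm_index_date(
                    list(cd[in_win]), list(chm_days[clo:chi_][in_win]),
                    opt.chm_threshold_days)
                if idx2 is not None:
                    status, index_date = "chm_user", idx2
                else:
                    status = "exclude_low_chm"
            else:
                status = "exclude_low_chm"
        if status == "exclude_low_chm":
            tally["low_chm"] += 1
            continue

        if dx_malig[lo:hi].any():
            tally["malignancy"] += 1
            continue

        age = (neuro_date - birth).days / 365.25
        band = "lt30" if age < 30 else ("30to40" if age < 40 else "ge40")
        cci_cats: set[str] = set()
        for j in idx:
            if dx_chars[j] and dx_dates[j] < hiv_onset:
                cci_cats.update(dx_chars[j])
        for mild, severe in charlson.hierarchy:
            if mild in cci_cats and severe in cci_cats:
                cci_cats.discard(mild)
        cci_score = float(sum(charlson.weights[c] for c in cci_cats))
        ncat = len(cci_cats)
        cci_group = "0" if ncat == 0 else ("1-2" if ncat <= 2 else ">=3")

        ddd = {cls: 0.0 for cls in ART_CLASSES}
        if pid in art_slices:
            alo, ahi = art_slices[pid]
            ad = art_dates[alo:ahi]
            sel = (ad >= hiv_onset) & (ad <= neuro_date)
            for cls, amt in zip(art_cls[alo:ahi][sel], art_ddd[alo:ahi][sel]):
                ddd[cls] += amt
        ddd["total"] = float(sum(ddd[c] for c in ART_CLASSES))

        pending.append(dict(
            patient_id=pid,
            sex=sex,
            female=int(sex == "F"),
            age_band=band,
            hiv_date=hiv_onset,
            neuro_date=neuro_date,
            neuro_subtypes="|".join(sorted(sub_onsets)),
            index_duration_days=(neuro_date - hiv_onset).days,
            chm_user=int(status == "chm_user"),
            index_date=index_date,
            cci_score=cci_score,
            cci_group=cci_group,
            **{f"ddd_{c.lower()}": ddd[c] for c in ART_CLASSES},
            ddd_total=ddd["total"],
            _dx_span=(lo, hi),
        ))

    # Landmark index for non-users: neurological diagnosis plus the lower
    # median of user lags (index minus neuro date).
    user_lags = sorted(
        (row["index_date"] - row["neuro_date"]).days
        for row in pending if row["chm_user"]
    )
    median_lag = user_lags[(len(user_lags) - 1) // 2] if user_lags else 30

    rows: list[dict] = []
    for row in pending:
        if row["chm_user"]:
            index_date = row["index_date"]
        elif opt.nonuser_index == "neuro_date":
            index_date = row["neuro_date"]
        else:
            index_date = row["neuro_date"] + timedelta(days=median_lag)
        dd = death_date.get(row["patient_id"])
        if dd is not None and dd <= index_date:
            tally["died_before_index"] += 1
            continue
        if dd is not None and dd <= opt.study_end:
            event, followup = 1, (dd - index_date).days
            cause = death_cause.get(row["patient_id"], "other")
        else:
            event, followup = 0, (opt.study_end - index_date).days
            cause = "none"
        lo, hi = row.pop("_dx_span")
        oi_flags = {k: 0 for k in oi_sets}
        for j in range(lo, hi):
            if dx_oi[j] and dx_dates[j] < index_date:
                for k in dx_oi[j]:
                    oi_flags[k] = 1
        row.update(
            index_date=index_date,
            interval_days=(index_date - row["neuro_date"]).days,
            followup_days=int(followup),
            event=event,
            cause_category=cause,
            **{f"oi_{k}": v for k, v in oi_flags.items()},
        )
        rows.append(row)

    cohort = pd.DataFrame(rows)
    log.info("cohort: retained %d subjects; exclusions %s", len(cohort), tally)
    return cohort, tally


# ---------------------------------------------------------------------------
# On-disk artifacts


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in ("hiv_date", "neuro_date", "index_date"):
        out[col] = out[col].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("hiv_date", "neuro_date", "index_date"):
        df[col] = pd.to_datetime(df[col]).dt.date
    df["neuro_subtypes"] = df["neuro_subtypes"].fillna("")
    return df


def write_exclusions(tally: dict[str, int], path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2), encoding="utf-8")
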