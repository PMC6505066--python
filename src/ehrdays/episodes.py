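"""Reconstruct the inpatient nesting from specialty-transfer records.

The hierarchy, from atom to aggregate:

* specialty stay      -- one contiguous period under one treating specialty
                         at one facility (the raw input interval);
* bedded stay         -- consecutive specialty stays (any specialty) at one
                         facility whose records abut exactly in time (a
                         specialty handoff in place);
* single-site hospitalization (SSH)
                      -- a maximal run of *acute* specialty stays at one
                         facility, contiguous up to a configurable calendar
                         gap (default 1 day);
* acute hospitalization
                      -- SSHs of one patient chained across facilities under
                         the same gap rule (inter-facility transfer);
* episode of care     -- bedded stays of any specialty chained the same way.

Day-level expansion emits one row per patient per facility per calendar date
spanned by an SSH (admission and discharge dates inclusive), with an ICU flag
when any ICU specialty stay touches that date at that facility.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

STAY_COLUMNS = ["patient_id", "facility_id", "specialty_code", "admit", "discharge"]


# ---------------------------------------------------------------------------
# Specialty classification
# ---------------------------------------------------------------------------

def classify_specialty(specialty_code: str, config: dict) -> tuple[bool, bool]:
    """Return ``(acute, icu)`` for a treating-specialty code.

    Unknown codes fall back to the configured default and are logged, never
    fatal.
    """
    table = config["specialties"]
    entry = table.get(str(specialty_code).strip().upper())
    if entry is None:
        entry = config.get("unknown_default", {"acute": False, "icu": False})
        logger.warning("unknown specialty code %r classified as %s", specialty_code, entry)
    return bool(entry["acute"]), bool(entry["icu"])


def classify_stays(stays: pd.DataFrame, config: dict) -> pd.DataFrame:
    """Attach ``acute`` and ``icu`` columns derived from the specialty code."""
    out = stays.copy()
    codes = out["specialty_code"].astype(str).str.strip().str.upper()
    table = config["specialties"]
    default = config.get("unknown_default", {"acute": False, "icu": False})
    unknown = sorted(set(codes) - set(table))
    for code in unknown:
        logger.warning("unknown specialty code %r classified as %s", code, default)
    out["acute"] = codes.map(lambda c: bool(table.get(c, default)["acute"]))
    out["icu"] = codes.map(lambda c: bool(table.get(c, default)["icu"]))
    return out


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def prepare_stays(stays: pd.DataFrame, specialty_config: dict) -> pd.DataFrame:
    """Parse datetimes, classify specialties, and resolve overlaps.

    Overlapping stays at one facility are resolved by truncating the earlier
    stay at the later stay's admission (logged); this preserves the partition
    property that every instant belongs to at most one stay per facility.
    """
    df = stays.copy()
    for col in ("admit", "discharge"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    if df["admit"].isna().any():
        bad = df.index[df["admit"].isna()].tolist()
        raise ConfigError(f"specialty stays with unparseable admit datetimes at rows {bad[:10]}")
    df = classify_stays(df, specialty_config)
    df = df.sort_values(["patient_id", "facility_id", "admit", "discharge"],
                        kind="mergesort").reset_index(drop=True)

    # truncate a stay that runs past the next admission at the same facility
    nxt = df.groupby(["patient_id", "facility_id"])["admit"].shift(-1)
    runs_over = nxt.notna() & (df["discharge"].isna() | (df["discharge"] > nxt))
    if runs_over.any():
        logger.warning("truncated %d overlapping specialty stays", int(runs_over.sum()))
        df.loc[runs_over, "discharge"] = nxt[runs_over]
    df["truncated"] = runs_over

    bad = df["discharge"].notna() & (df["discharge"] < df["admit"])
    if bad.any():
        raise ConfigError(f"stays with discharge before admit at rows {df.index[bad].tolist()[:10]}")

    df["stay_id"] = np.arange(len(df))
    df = df.sort_values(["patient_id", "admit", "facility_id"], kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Generic interval chaining
# ---------------------------------------------------------------------------

def _chain_labels(df: pd.DataFrame, group_cols: list[str], start_col: str,
                  end_col: str, gap) -> pd.Series:
    """Label each row with a chain index: a new chain starts whenever the
    row's start exceeds the running maximum end of its group by more than
    ``gap``.  Open intervals (NaT end) extend their chain indefinitely.

    Rows must be pre-sorted by ``group_cols + [start_col]``.
    """
    labels = np.zeros(len(df), dtype=np.int64)
    pos = 0
    for _, grp in df.groupby(group_cols, sort=False):
        chain = 0
        running_end = None  # None == no chain yet; pd.NaT sentinel == open
        for start, end in zip(grp[start_col], grp[end_col]):
            if running_end is None:
                chain = 0
            elif running_end is pd.NaT:
                pass  # open predecessor: always contiguous
            elif start > running_end + gap:
                chain += 1
                running_end = None
            labels[pos] = chain
            if running_end is not pd.NaT:
                if pd.isna(end):
                    running_end = pd.NaT
                elif running_end is None or end > running_end:
                    running_end = end
            pos += 1
    return pd.Series(labels, index=df.index)


# ---------------------------------------------------------------------------
# Bedded stays
# ---------------------------------------------------------------------------

def build_bedded_stays(stays: pd.DataFrame,
                       bedded_gap: pd.Timedelta = pd.Timedelta(0)) -> pd.DataFrame:
    """Group specialty stays into bedded stays.

    A successor stay continues the same bedded stay only when its admission
    abuts the predecessor's discharge (within ``bedded_gap``, default exactly
    zero) at the same facility -- an in-place specialty handoff.  A positive
    time gap means the patient moved beds, which starts a new bedded stay.
    """
    df = stays.sort_values(["patient_id", "facility_id", "admit"], kind="mergesort")
    if df.empty:
        return pd.DataFrame(columns=["bedded_id", "patient_id", "facility_id",
                                     "start", "end", "n_stays", "stay_ids", "any_acute"])
    chain = _chain_labels(df, ["patient_id", "facility_id"], "admit", "discharge", bedded_gap)
    df = df.assign(_chain=chain)
    grouped = df.groupby(["patient_id", "facility_id", "_chain"], sort=False)
    out = grouped.agg(
        start=("admit", "min"),
        end=("discharge", lambda s: pd.NaT if s.isna().any() else s.max()),
        n_stays=("stay_id", "size"),
        stay_ids=("stay_id", lambda s: ";".join(map(str, s))),
        any_acute=("acute", "any"),
    ).reset_index().drop(columns="_chain")
    out["bedded_id"] = (out["patient_id"].astype(str) + "-" + out["facility_id"].astype(str)
                        + "-B" + out["start"].dt.strftime("%Y%m%d%H%M"))
    out = out.sort_values(["patient_id", "start", "facility_id"], kind="mergesort").reset_index(drop=True)
    return out[["bedded_id", "patient_id", "facility_id", "start", "end",
                "n_stays", "stay_ids", "any_acute"]]


# ---------------------------------------------------------------------------
# Single-site hospitalizations
# ---------------------------------------------------------------------------

def build_single_site_hospitalizations(stays: pd.DataFrame, gap_days: int = 1,
                                       observation_end=None) -> pd.DataFrame:
    """Merge maximal runs of contiguous acute stays at one facility into SSHs.

    Non-acute stays are dropped before merging, so an acute run interrupted
    by a non-acute stay at the same facility splits into two SSHs only if the
    calendar gap between the acute stays exceeds ``gap_days``.  A stay with a
    missing discharge yields a censored SSH whose end is taken from
    ``observation_end`` when provided (else its last admission date).
    """
    cols = ["ssh_id", "patient_id", "facility_id", "admit", "discharge",
            "admit_date", "discharge_date", "censored", "n_stays", "stay_ids", "any_icu"]
    dtypes = {"ssh_id": str, "patient_id": str, "facility_id": str,
              "admit": "datetime64[ns]", "discharge": "datetime64[ns]",
              "admit_date": "datetime64[ns]", "discharge_date": "datetime64[ns]",
              "censored": bool, "n_stays": int, "stay_ids": str, "any_icu": bool}
    acute = stays.loc[stays["acute"]].copy()
    if acute.empty:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})
    acute["admit_date"] = acute["admit"].dt.normalize()
    acute["discharge_date"] = acute["discharge"].dt.normalize()
    acute = acute.sort_values(["patient_id", "facility_id", "admit"], kind="mergesort")
    gap = pd.Timedelta(days=gap_days)
    chain = _chain_labels(acute, ["patient_id", "facility_id"],
                          "admit_date", "discharge_date", gap)
    acute = acute.assign(_chain=chain)
    grouped = acute.groupby(["patient_id", "facility_id", "_chain"], sort=False)
    out = grouped.agg(
        admit=("admit", "min"),
        discharge=("discharge", lambda s: pd.NaT if s.isna().any() else s.max()),
        n_stays=("stay_id", "size"),
        stay_ids=("stay_id", lambda s: ";".join(map(str, s))),
        any_icu=("icu", "any"),
        _last_admit_date=("admit_date", "max"),
    ).reset_index().drop(columns="_chain")
    out["censored"] = out["discharge"].isna()
    out["admit_date"] = out["admit"].dt.normalize()
    out["discharge_date"] = out["discharge"].dt.normalize()
    if out["censored"].any():
        fallback = (pd.to_datetime(observation_end).normalize()
                    if observation_end is not None else None)
        fill = out.loc[out["censored"], "_last_admit_date"]
        if fallback is not None:
            fill = fill.where(fill >= fallback, fallback)
        out.loc[out["censored"], "discharge_date"] = fill
        logger.warning("%d censored hospitalizations (missing discharge)",
                       int(out["censored"].sum()))
    out = out.drop(columns="_last_admit_date")
    out["ssh_id"] = (out["patient_id"].astype(str) + "-" + out["facility_id"].astype(str)
                     + "-S" + out["admit_date"].dt.strftime("%Y%m%d"))
    out = out.sort_values(["patient_id", "admit", "facility_id"], kind="mergesort").reset_index(drop=True)
    return out[cols]


def link_acute_hospitalizations(sshs: pd.DataFrame, gap_days: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chain a patient's SSHs into acute hospitalizations.

    A successor SSH joins the chain when its admission date is at most
    ``gap_days`` after the running discharge date (an inter-facility
    transfer).  Returns ``(sshs_with_hosp_id, hospitalizations)``.
    """
    if sshs.empty:
        return (sshs.assign(hosp_id=pd.Series(dtype=str)),
                pd.DataFrame(columns=["hosp_id", "patient_id", "admit_date",
                                      "discharge_date", "n_ssh", "ssh_ids"]))
    df = sshs.sort_values(["patient_id", "admit_date", "facility_id"], kind="mergesort").copy()
    gap = pd.Timedelta(days=gap_days)
    chain = _chain_labels(df, ["patient_id"], "admit_date", "discharge_date", gap)
    df = df.assign(_chain=chain)
    firsts = df.groupby(["patient_id", "_chain"], sort=False)["admit_date"].transform("min")
    df["hosp_id"] = df["patient_id"].astype(str) + "-H" + firsts.dt.strftime("%Y%m%d")
    hosp = df.groupby("hosp_id", sort=True).agg(
        patient_id=("patient_id", "first"),
        admit_date=("admit_date", "min"),
        discharge_date=("discharge_date", "max"),
        n_ssh=("ssh_id", "size"),
        ssh_ids=("ssh_id", lambda s: ";".join(s)),
    ).reset_index()
    df = df.drop(columns="_chain").sort_values(
        ["patient_id", "admit", "facility_id"], kind="mergesort").reset_index(drop=True)
    return df, hosp


def build_episodes_of_care(bedded: pd.DataFrame, gap_days: int = 1) -> pd.DataFrame:
    """Chain bedded stays (any specialty) into overall episodes of care."""
    if bedded.empty:
        return pd.DataFrame(columns=["episode_id", "patient_id", "start_date",
                                     "end_date", "n_bedded", "bedded_ids"])
    df = bedded.copy()
    df["start_date"] = df["start"].dt.normalize()
    df["end_date"] = df["end"].dt.normalize()
    df = df.sort_values(["patient_id", "start_date", "facility_id"], kind="mergesort")
    gap = pd.Timedelta(days=gap_days)
    chain = _chain_labels(df, ["patient_id"], "start_date", "end_date", gap)
    df = df.assign(_chain=chain)
    firsts = df.groupby(["patient_id", "_chain"], sort=False)["start_date"].transform("min")
    df["episode_id"] = df["patient_id"].astype(str) + "-E" + firsts.dt.strftime("%Y%m%d")
    out = df.groupby("episode_id", sort=True).agg(
        patient_id=("patient_id", "first"),
        start_date=("start_date", "min"),
        end_date=("end_date", lambda s: pd.NaT if s.isna().any() else s.max()),
        n_bedded=("bedded_id", "size"),
        bedded_ids=("bedded_id", lambda s: ";".join(s)),
    ).reset_index()
    return out.sort_values(["patient_id", "start_date"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Patient-facility-day expansion
# ---------------------------------------------------------------------------

def expand_patient_facility_days(sshs: pd.DataFrame, stays: pd.DataFrame) -> pd.DataFrame:
    """One row per calendar date per facility per SSH, admission and
    discharge dates inclusive.  ``icu_day`` is true when any ICU specialty
    stay at that facility overlaps the date (the patient spent some time in
    the ICU that day).  A same-day inter-facility transfer therefore yields
    one row per facility.
    """
    if sshs.empty:
        return pd.DataFrame({"patient_id": pd.Series(dtype=str),
                             "facility_id": pd.Series(dtype=str),
                             "date": pd.Series(dtype="datetime64[ns]"),
                             "ssh_id": pd.Series(dtype=str),
                             "day_of_ssh": pd.Series(dtype=int),
                             "icu_day": pd.Series(dtype=bool)})
    spans = (sshs["discharge_date"] - sshs["admit_date"]).dt.days + 1
    rep = sshs.loc[sshs.index.repeat(spans)]
    offsets = np.concatenate([np.arange(n) for n in spans])
    days = pd.DataFrame({
        "patient_id": rep["patient_id"].to_numpy(),
        "facility_id": rep["facility_id"].to_numpy(),
        "date": rep["admit_date"].to_numpy() + offsets.astype("timedelta64[D]"),
        "ssh_id": rep["ssh_id"].to_numpy(),
        "day_of_ssh": offsets + 1,
    })

    icu = stays.loc[stays["icu"], ["patient_id", "facility_id", "admit", "discharge"]].copy()
    days["icu_day"] = False
    if not icu.empty:
        icu["lo"] = icu["admit"].dt.normalize()
        icu["hi"] = icu["discharge"].dt.normalize()
        m = days.merge(icu[["patient_id", "facility_id", "lo", "hi"]],
                       on=["patient_id", "facility_id"], how="inner")
        hit = m.loc[(m["date"] >= m["lo"]) & (m["hi"].isna() | (m["date"] <= m["hi"]))]
        keys = set(zip(hit["patient_id"], hit["facility_id"], hit["date"]))
        if keys:
            tup = list(zip(days["patient_id"], days["facility_id"], days["date"]))
            days["icu_day"] = [t in keys for t in tup]

    days = days.sort_values(["patient_id", "date", "facility_id"], kind="mergesort").reset_index(drop=True)
    dup = days.duplicated(["patient_id", "facility_id", "date"])
    if dup.any():  # cannot happen when SSHs partition correctly
        raise AssertionError("duplicate patient-facility-day keys produced")
    return days


# ---------------------------------------------------------------------------
# Hospitalization-level outcomes
# ---------------------------------------------------------------------------

def compute_outcomes(sshs: pd.DataFrame, deaths: pd.DataFrame | None = None,
                     mortality_days: int = 30, readmit_days: int = 30
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SSH outcomes: in-hospital death, 30-day mortality from the
    admission date, and 30-day readmission among live discharges.

    Readmission looks for the patient's next SSH in a *different* acute
    hospitalization (transfers are not readmissions), admitted within
    ``readmit_days`` of discharge.  Death records dated before a recorded
    admission of the same patient are rejected and reported, not applied.
    Censored SSHs get missing outcomes except admission-anchored mortality.
    Returns ``(outcomes, rejected_death_records)``.
    """
    rejected = pd.DataFrame(columns=["patient_id", "death_date", "reason"])
    death_map: dict = {}
    if deaths is not None and len(deaths):
        d = deaths.copy()
        d["death_date"] = pd.to_datetime(d["death_date"]).dt.normalize()
        last_admit = sshs.groupby("patient_id")["admit_date"].max()
        bad_rows = []
        for _, row in d.iterrows():
            la = last_admit.get(row["patient_id"])
            if la is not None and row["death_date"] < la:
                bad_rows.append({"patient_id": row["patient_id"],
                                 "death_date": row["death_date"],
                                 "reason": "death date precedes a recorded admission"})
            else:
                death_map[row["patient_id"]] = row["death_date"]
        if bad_rows:
            rejected = pd.DataFrame(bad_rows)
            logger.error("rejected %d death records dated before an admission", len(bad_rows))

    df = sshs.sort_values(["patient_id", "admit_date", "facility_id"], kind="mergesort").copy()
    has_hosp = "hosp_id" in df.columns
    death = pd.to_datetime(df["patient_id"].map(death_map))

    in_hosp = (death.notna() & (death >= df["admit_date"])
               & (death <= df["discharge_date"]) & ~df["censored"])
    mort30 = death.notna() & (death <= df["admit_date"] + pd.Timedelta(days=mortality_days))

    readmit = pd.array([pd.NA] * len(df), dtype="boolean")
    by_patient: dict = {}
    for i, row in enumerate(df.itertuples(index=False)):
        by_patient.setdefault(row.patient_id, []).append(i)
    rows = list(df.itertuples(index=False))
    for patient, idxs in by_patient.items():
        for i in idxs:
            r = rows[i]
            if r.censored or in_hosp.iloc[i]:
                continue  # not a live discharge -> excluded from denominator
            limit = r.discharge_date + pd.Timedelta(days=readmit_days)
            found = False
            for j in idxs:
                if j == i:
                    continue
                s2 = rows[j]
                if has_hosp and s2.hosp_id == r.hosp_id:
                    continue
                if r.discharge_date < s2.admit_date <= limit:
                    found = True
                    break
            readmit[i] = found

    out = pd.DataFrame({
        "ssh_id": df["ssh_id"].to_numpy(),
        "in_hospital_mortality": pd.array(
            [pd.NA if c else bool(v) for v, c in zip(in_hosp, df["censored"])], dtype="boolean"),
        "mortality_30d": mort30.astype(bool).to_numpy(),
        "readmit_30d": readmit,
        "los_days": [pd.NA if c else int((dd - ad).days)
                     for ad, dd, c in zip(df["admit_date"], df["discharge_date"], df["censored"])],
    })
    return out.sort_values("ssh_id", kind="mergesort").reset_index(drop=True), rejected
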