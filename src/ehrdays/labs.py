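"""Identify, standardize, validate, and daily-aggregate labs and vital signs.

Laboratory records are matched to standard tests through two routes: the
test's identifier code set, or a case-insensitive substring match on the
facility's local test name -- the name route rescues records whose codes are
blank or wrong, and such rescues are counted separately.  Topography (the
anatomic source of the specimen) gates both routes.  Vital signs are matched
only on the structured vital-type field, never on free text.

After matching, units are linearly converted to the canonical unit, values
outside the plausible range are rejected into an audit report, and the
survivors are aggregated to the daily low/high per patient-facility-day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAB_COLUMNS = ["patient_id", "facility_id", "facility_lab_code", "local_name",
               "loinc", "topography", "value", "unit", "drawn_at"]
VITAL_COLUMNS = ["patient_id", "facility_id", "vital_type", "value", "unit", "taken_at"]


def _norm(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip().str.lower()


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_lab_records(labs: pd.DataFrame, test_config: dict
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Label each lab record with the standard test it measures.

    Returns ``(matched, unmatched, conflicts)``; the three partitions always
    sum to the input record count.  ``matched`` carries ``test_id``,
    ``matched_via`` (``code`` or ``name``), and ``name_rescue`` -- true when
    the record was matched by name despite a blank identifier code.
    Records matching two different tests are conflicts and are excluded.
    """
    labs = labs.reset_index(drop=True)
    n = len(labs)
    loinc = _norm(labs.get("loinc", pd.Series([""] * n)))
    name = _norm(labs.get("local_name", pd.Series([""] * n)))
    topo = _norm(labs.get("topography", pd.Series([""] * n)))

    hits: list[tuple[str, np.ndarray, np.ndarray]] = []
    for test_id, spec in sorted(test_config["tests"].items()):
        if spec.get("kind") != "lab":
            continue
        code_set = {c.strip().lower() for c in spec.get("loinc", [])}
        by_code = loinc.isin(code_set).to_numpy() if code_set else np.zeros(n, bool)
        by_name = np.zeros(n, bool)
        for pat in spec.get("names", []):
            by_name |= name.str.contains(pat.strip().lower(), regex=False).to_numpy()
        allowed = spec.get("topographies")
        if allowed is not None:
            topo_ok = (topo.isin({t.strip().lower() for t in allowed}) | (topo == "")).to_numpy()
        else:
            topo_ok = np.ones(n, bool)
        mask = topo_ok & (by_code | by_name)
        if mask.any():
            hits.append((test_id, mask, by_code))

    n_matches = np.zeros(n, dtype=int)
    for _, mask, _ in hits:
        n_matches += mask
    conflict_mask = n_matches > 1
    single_mask = n_matches == 1

    test_id_col = np.array([""] * n, dtype=object)
    via_col = np.array([""] * n, dtype=object)
    for test_id, mask, by_code in hits:
        take = mask & single_mask
        test_id_col[take] = test_id
        via_col[take] = np.where(by_code[take], "code", "name")

    matched = labs.loc[single_mask].copy()
    matched["test_id"] = test_id_col[single_mask]
    matched["matched_via"] = via_col[single_mask]
    matched["name_rescue"] = (matched["matched_via"] == "name") & (loinc[single_mask] == "")

    conflicts = labs.loc[conflict_mask].copy()
    if len(conflicts):
        conflicts["candidate_tests"] = [
            ";".join(t for t, mask, _ in hits if mask[i]) for i in conflicts.index]
        logger.warning("%d lab records matched multiple tests; excluded", len(conflicts))
    unmatched = labs.loc[~single_mask & ~conflict_mask].copy()
    assert len(matched) + len(unmatched) + len(conflicts) == n
    return matched, unmatched, conflicts


def match_vital_records(vitals: pd.DataFrame, test_config: dict
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label vital-sign records by structured vital type only."""
    vitals = vitals.reset_index(drop=True)
    vtype = _norm(vitals["vital_type"])
    type_map: dict[str, str] = {}
    for test_id, spec in sorted(test_config["tests"].items()):
        if spec.get("kind") != "vital":
            continue
        for t in spec.get("vital_types", []):
            type_map[t.strip().lower()] = test_id
    matched = vitals.copy()
    matched["test_id"] = vtype.map(type_map)
    unmatched = matched.loc[matched["test_id"].isna()].drop(columns="test_id")
    matched = matched.loc[matched["test_id"].notna()].copy()
    matched["matched_via"] = "vital_type"
    matched["name_rescue"] = False
    return matched, unmatched


# ---------------------------------------------------------------------------
# Unit conversion and range validation
# ---------------------------------------------------------------------------

def convert_units(records: pd.DataFrame, test_config: dict
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert each matched record's value to the test's canonical unit.

    Conversions are linear (``a*value + b`` per configured unit).  A blank
    unit is taken as already canonical.  Records with an unknown unit or a
    non-numeric value are flagged unconvertible, excluded, and reported.
    """
    df = records.reset_index(drop=True).copy()
    value = pd.to_numeric(df["value"], errors="coerce")
    unit = _norm(df.get("unit", pd.Series([""] * len(df))))
    out_value = value.copy()
    bad = value.isna()
    reason = pd.Series(np.where(bad, "non-numeric value", ""), index=df.index)

    for test_id, grp in df.groupby("test_id", sort=True):
        spec = test_config["tests"][test_id]
        canonical = spec.get("canonical_unit", "").strip().lower()
        conv = {u.strip().lower(): ab for u, ab in spec.get("unit_conversions", {}).items()}
        for idx in grp.index:
            if bad[idx]:
                continue
            u = unit[idx]
            if u in ("", canonical):
                continue
            if u in conv:
                a, b = conv[u]
                out_value[idx] = a * value[idx] + b
            else:
                bad[idx] = True
                reason[idx] = f"unconvertible unit {u!r}"

    df["value"] = out_value
    converted = df.loc[~bad].copy()
    converted["unit"] = [test_config["tests"][t].get("canonical_unit", "")
                         for t in converted["test_id"]]
    unconvertible = df.loc[bad].copy()
    unconvertible["reason"] = reason[bad]
    if len(unconvertible):
        logger.warning("%d records unconvertible", len(unconvertible))
    return converted, unconvertible


def apply_plausibility_filter(records: pd.DataFrame, test_config: dict
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop values outside each test's plausible range.

    Returns the kept records and a per-facility/test rejection report with
    counts, supporting the clinician review loop over value distributions.
    """
    df = records.reset_index(drop=True)
    lo = df["test_id"].map(lambda t: test_config["tests"][t]["plausible_range"][0])
    hi = df["test_id"].map(lambda t: test_config["tests"][t]["plausible_range"][1])
    ok = (df["value"] >= lo) & (df["value"] <= hi)
    kept, rejected = df.loc[ok].copy(), df.loc[~ok].copy()
    if len(rejected):
        report = (rejected.groupby(["facility_id", "test_id"], sort=True)
                  .size().rename("n_rejected").reset_index())
    else:
        report = pd.DataFrame(columns=["facility_id", "test_id", "n_rejected"])
    return kept, report


# ---------------------------------------------------------------------------
# Derived vitals and microbiology events
# ---------------------------------------------------------------------------

def derive_map(matched_vitals: pd.DataFrame) -> pd.DataFrame:
    """Compute mean arterial pressure as (2*diastolic + systolic)/3 from cuff
    pairs sharing a timestamp, for patient-facility-days lacking any directly
    recorded MAP.  Returns the input plus the derived rows."""
    df = matched_vitals
    if df.empty:
        return df
    df = df.copy()
    df["_date"] = pd.to_datetime(df["taken_at"]).dt.normalize()
    direct_days = set(map(tuple, df.loc[df["test_id"] == "map",
                                        ["patient_id", "facility_id", "_date"]].to_numpy()))
    cuff = df[df["test_id"].isin(["sbp", "dbp"])]
    if cuff.empty:
        return df.drop(columns="_date")
    wide = cuff.pivot_table(index=["patient_id", "facility_id", "taken_at", "_date"],
                            columns="test_id", values="value", aggfunc="mean").reset_index()
    if "sbp" not in wide or "dbp" not in wide:
        return df.drop(columns="_date")
    wide = wide.dropna(subset=["sbp", "dbp"])
    wide = wide[[tuple(k) not in direct_days
                 for k in wide[["patient_id", "facility_id", "_date"]].to_numpy()]]
    if wide.empty:
        return df.drop(columns="_date")
    derived = pd.DataFrame({
        "patient_id": wide["patient_id"],
        "facility_id": wide["facility_id"],
        "vital_type": "map",
        "value": (2.0 * wide["dbp"] + wide["sbp"]) / 3.0,
        "unit": "mmHg",
        "taken_at": wide["taken_at"],
        "test_id": "map",
        "matched_via": "derived",
        "name_rescue": False,
    })
    return pd.concat([df.drop(columns="_date"), derived], ignore_index=True)


def extract_blood_cultures(labs: pd.DataFrame, test_config: dict) -> pd.DataFrame:
    """Blood-culture *events* (patient, facility, date) found by name pattern.

    Cultures are not numeric tests; they anchor the surveillance sepsis
    definition's presumed-infection window.
    """
    patterns = [p.strip().lower() for p in test_config.get("blood_culture_patterns", [])]
    name = _norm(labs.get("local_name", pd.Series([""] * len(labs))))
    mask = np.zeros(len(labs), bool)
    for p in patterns:
        mask |= name.str.contains(p, regex=False).to_numpy()
    ev = labs.loc[mask, ["patient_id", "facility_id", "drawn_at"]].copy()
    ev["date"] = pd.to_datetime(ev["drawn_at"]).dt.normalize()
    ev = ev.drop(columns="drawn_at").drop_duplicates().sort_values(
        ["patient_id", "facility_id", "date"], kind="mergesort").reset_index(drop=True)
    return ev


# ---------------------------------------------------------------------------
# Daily aggregation
# ---------------------------------------------------------------------------

def aggregate_daily_extremes(records: pd.DataFrame, days: pd.DataFrame,
                             timestamp_col: str = "drawn_at"
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily low/high/count per standard test per patient-facility-day.

    Output is wide: ``{test}_low``, ``{test}_high``, ``{test}_n`` keyed by
    (patient_id, facility_id, date).  Records falling on a day with no
    corresponding patient-facility-day row are returned as orphans, not
    silently dropped.
    """
    key = ["patient_id", "facility_id", "date"]
    if records.empty:
        return days[key].copy(), records.copy()
    df = records.copy()
    df["date"] = pd.to_datetime(df[timestamp_col]).dt.normalize()
    day_keys = days[key].drop_duplicates()
    df = df.merge(day_keys.assign(_known=True), on=key, how="left")
    orphans = df.loc[df["_known"].isna()].drop(columns="_known")
    if len(orphans):
        logger.info("%d measurements on days outside any hospitalization", len(orphans))
    df = df.loc[df["_known"].notna()]

    agg = (df.groupby(key + ["test_id"], sort=True)["value"]
           .agg(low="min", high="max", n="count").reset_index())
    wide = agg.pivot(index=key, columns="test_id", values=["low", "high", "n"])
    wide.columns = [f"{test}_{stat}" for stat, test in wide.columns]
    wide = wide.reset_index()
    ordered = key + sorted(c for c in wide.columns if c not in key)
    wide = wide[ordered].sort_values(key, kind="mergesort").reset_index(drop=True)
    return wide, orphans


def harmonize(labs: pd.DataFrame, vitals: pd.DataFrame, days: pd.DataFrame,
              test_config: dict) -> dict:
    """Run the full lab/vital path; returns a dict of frames including the
    wide daily physiology table and every audit report."""
    lab_matched, lab_unmatched, lab_conflicts = match_lab_records(labs, test_config)
    vit_matched, vit_unmatched = match_vital_records(vitals, test_config)
    vit_matched = derive_map(vit_matched)

    lab_conv, lab_unconv = convert_units(lab_matched, test_config)
    vit_conv, vit_unconv = convert_units(vit_matched, test_config)
    lab_kept, lab_rej = apply_plausibility_filter(lab_conv, test_config)
    vit_kept, vit_rej = apply_plausibility_filter(vit_conv, test_config)

    lab_kept = lab_kept.rename(columns={"drawn_at": "measured_at"})
    vit_kept = vit_kept.rename(columns={"taken_at": "measured_at"})
    cols = ["patient_id", "facility_id", "test_id", "value", "measured_at"]
    merged = pd.concat([lab_kept[cols], vit_kept[cols]], ignore_index=True)
    physiology, orphans = aggregate_daily_extremes(merged, days, timestamp_col="measured_at")

    cultures = extract_blood_cultures(labs, test_config)
    return {
        "physiology": physiology,
        "blood_cultures": cultures,
        "lab_unmatched": lab_unmatched,
        "lab_conflicts": lab_conflicts,
        "vital_unmatched": vit_unmatched,
        "unconvertible": pd.concat([lab_unconv, vit_unconv], ignore_index=True),
        "range_rejections": pd.concat([lab_rej, vit_rej], ignore_index=True),
        "orphans": orphans,
        "n_name_rescues": int(lab_matched["name_rescue"].sum()) if len(lab_matched) else 0,
    }
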