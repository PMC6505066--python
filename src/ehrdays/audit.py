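"""Spot-check auditing: re-derive sampled patient-facility-days straight
from the raw records and compare field by field with the pipeline output.

The recomputation here is deliberately independent of the vectorized
production path: plain per-record loops using only the configuration, so a
bug in the pipeline cannot hide itself in the audit.  Raw records are
bucketed by patient-facility-day once up front purely so repeated sampling
stays linear; within a bucket everything is recomputed record by record.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .meds import match_drug
from .synth import RawTables


def _match_one_lab(row, test_config: dict) -> str | None:
    loinc = str(row.get("loinc") or "").strip().lower()
    name = str(row.get("local_name") or "").strip().lower()
    topo = str(row.get("topography") or "").strip().lower()
    hits = []
    for test_id, spec in sorted(test_config["tests"].items()):
        if spec.get("kind") != "lab":
            continue
        allowed = spec.get("topographies")
        if allowed is not None and topo and topo not in {t.strip().lower() for t in allowed}:
            continue
        by_code = loinc and loinc in {c.strip().lower() for c in spec.get("loinc", [])}
        by_name = any(p.strip().lower() in name for p in spec.get("names", []))
        if by_code or by_name:
            hits.append(test_id)
    return hits[0] if len(hits) == 1 else None


def _match_one_vital(row, test_config: dict) -> str | None:
    vtype = str(row.get("vital_type") or "").strip().lower()
    for test_id, spec in sorted(test_config["tests"].items()):
        if spec.get("kind") != "vital":
            continue
        if vtype in {t.strip().lower() for t in spec.get("vital_types", [])}:
            return test_id
    return None


def _canonical_value(row, test_id: str, test_config: dict) -> float | None:
    try:
        value = float(row["value"])
    except (TypeError, ValueError):
        return None
    spec = test_config["tests"][test_id]
    unit = str(row.get("unit") or "").strip().lower()
    canonical = spec.get("canonical_unit", "").strip().lower()
    if unit not in ("", canonical):
        conv = {u.strip().lower(): ab for u, ab in spec.get("unit_conversions", {}).items()}
        if unit not in conv:
            return None
        a, bconst = conv[unit]
        value = a * value + bconst
    lo, hi = spec["plausible_range"]
    if not (lo <= value <= hi):
        return None
    return value


class _RawIndex:
    """Raw records bucketed by (patient, facility, calendar date)."""

    def __init__(self, raw: RawTables):
        self.labs = self._bucket(raw.labs, "drawn_at")
        self.vitals = self._bucket(raw.vitals, "taken_at")
        self.meds = self._bucket(raw.med_admins, "given_at")

    @staticmethod
    def _bucket(df: pd.DataFrame, ts_col: str) -> dict:
        buckets: dict = {}
        if df is None or len(df) == 0:
            return buckets
        dates = pd.to_datetime(df[ts_col]).dt.normalize()
        for (row, date) in zip(df.to_dict("records"), dates):
            key = (row["patient_id"], row["facility_id"], date)
            buckets.setdefault(key, []).append(row)
        return buckets


def recompute_day(raw, patient_id, facility_id, date,
                  test_config: dict, lexicon_config: dict) -> dict:
    """Independently recompute daily extremes and drug indicators for one
    patient-facility-day from the raw tables.  ``raw`` may be a RawTables
    bundle or a prebuilt ``_RawIndex``."""
    index = raw if isinstance(raw, _RawIndex) else _RawIndex(raw)
    key = (patient_id, facility_id, pd.Timestamp(date).normalize())
    values: dict[str, list[float]] = {}

    for row in index.labs.get(key, []):
        test_id = _match_one_lab(row, test_config)
        if test_id is None:
            continue
        v = _canonical_value(row, test_id, test_config)
        if v is not None:
            values.setdefault(test_id, []).append(v)

    direct_map = False
    cuff: dict[str, dict[str, float]] = {}
    for row in index.vitals.get(key, []):
        test_id = _match_one_vital(row, test_config)
        if test_id is None:
            continue
        v = _canonical_value(row, test_id, test_config)
        if v is None:
            continue
        if test_id == "map":
            direct_map = True
        if test_id in ("sbp", "dbp"):
            cuff.setdefault(str(row["taken_at"]), {})[test_id] = v
        values.setdefault(test_id, []).append(v)
    if not direct_map:
        spec = test_config["tests"]["map"]
        for pair in cuff.values():
            if "sbp" in pair and "dbp" in pair:
                m = (2.0 * pair["dbp"] + pair["sbp"]) / 3.0
                if spec["plausible_range"][0] <= m <= spec["plausible_range"][1]:
                    values.setdefault("map", []).append(m)

    extremes = {}
    for test_id, vs in values.items():
        extremes[f"{test_id}_low"] = min(vs)
        extremes[f"{test_id}_high"] = max(vs)

    drugs: set[str] = set()
    for row in index.meds.get(key, []):
        drugs |= match_drug(row, lexicon_config)
    indicators = {f"rx_{d}": (d in drugs) for d in sorted(lexicon_config["drugs"])}
    return {**extremes, **indicators}


def spot_check_sample(day_table: pd.DataFrame, raw: RawTables,
                      test_config: dict, lexicon_config: dict,
                      n: int = 50, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` patient-facility-days uniformly and compare every
    physiology extreme and drug indicator against an independent
    recomputation.  Returns one row per compared field."""
    columns = ["patient_id", "facility_id", "date", "field",
               "expected", "observed", "agree"]
    if n == 0 or day_table.empty:
        return pd.DataFrame(columns=columns)
    rng = np.random.default_rng(seed)
    n = min(n, len(day_table))
    picks = rng.choice(len(day_table), size=n, replace=False)
    index = _RawIndex(raw)
    check_fields = sorted(
        c for c in day_table.columns
        if c.endswith(("_low", "_high")) or c.startswith("rx_"))
    rows = []
    for i in sorted(picks):
        out_row = day_table.iloc[i]
        key = (out_row["patient_id"], out_row["facility_id"], out_row["date"])
        expected = recompute_day(index, *key, test_config, lexicon_config)
        for fieldname in check_fields:
            exp = expected.get(fieldname)
            obs = out_row.get(fieldname)
            if fieldname.startswith("rx_"):
                obs_b = bool(obs) if pd.notna(obs) else False
                rows.append((*key, fieldname, exp, obs_b, bool(exp) == obs_b))
            else:
                obs_f = float(obs) if pd.notna(obs) else None
                if exp is None and obs_f is None:
                    agree = True
                elif exp is None or obs_f is None:
                    agree = False
                else:
                    agree = math.isclose(exp, obs_f, rel_tol=1e-9, abs_tol=1e-9)
                rows.append((*key, fieldname, exp, obs_f, agree))
    return pd.DataFrame(rows, columns=columns)
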