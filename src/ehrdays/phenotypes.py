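"""Daily organ-dysfunction scores and hospitalization-level phenotypes.

Four organ components (coagulation, liver, cardiovascular, renal) are scored
0-4 from the worst physiologic value of each calendar day; respiratory and
central-nervous-system components are deliberately out of scope (no reliable
day-level ventilation signal; inconsistent coma-score recording).  A missing
input yields a missing component -- never an imputed zero.  Organ *failure*
is a component score of 3 or 4.

Two sepsis phenotypes are computed per single-site hospitalization:

* claims-based: concurrent diagnosis codes for infection and acute organ
  dysfunction, or an explicit severe-sepsis/septic-shock code;
* EHR-surveillance-based: a blood culture anchored by a sustained run of
  systemic-antibiotic days, plus at least one acute organ-dysfunction
  criterion within the window around the culture day.

Mechanical ventilation is detected from procedure codes at the
hospitalization level only; day-level queries raise, by design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import UnsupportedOperationError

logger = logging.getLogger(__name__)

SOFA_COMPONENTS = ("coagulation", "liver", "cardiovascular", "renal")

CODE_COLUMNS = ["patient_id", "facility_id", "code", "icd_version", "code_type",
                "position", "coded_at"]


def normalize_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def _any_prefix(codes, prefixes) -> bool:
    return any(c.startswith(p) for c in codes for p in prefixes)


def assign_codes_to_ssh(codes: pd.DataFrame, sshs: pd.DataFrame) -> pd.DataFrame:
    """Attach ``ssh_id`` to code records by patient+facility and date
    containment within the hospitalization's span."""
    if codes.empty or sshs.empty:
        return codes.head(0).assign(ssh_id=pd.Series(dtype=str))
    c = codes.copy()
    c["code"] = c["code"].map(normalize_code)
    c["_date"] = pd.to_datetime(c["coded_at"]).dt.normalize()
    m = c.merge(sshs[["ssh_id", "patient_id", "facility_id", "admit_date", "discharge_date"]],
                on=["patient_id", "facility_id"], how="inner")
    m = m.loc[(m["_date"] >= m["admit_date"]) & (m["_date"] <= m["discharge_date"])]
    return m.drop(columns=["_date", "admit_date", "discharge_date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Daily organ-dysfunction scores
# ---------------------------------------------------------------------------

def _count_below(values: np.ndarray, thresholds) -> np.ndarray:
    score = np.zeros(len(values), dtype=float)
    for t in thresholds:
        score += (values < t)
    score[np.isnan(values)] = np.nan
    return score


def _count_at_or_above(values: np.ndarray, thresholds) -> np.ndarray:
    score = np.zeros(len(values), dtype=float)
    for t in thresholds:
        score += (values >= t)
    score[np.isnan(values)] = np.nan
    return score


def sofa_component_scores(physiology: pd.DataFrame, med_indicators: pd.DataFrame,
                          sofa_config: dict, lexicon_config: dict) -> pd.DataFrame:
    """Score the four organ components per patient-facility-day.

    Coagulation uses the daily platelet low; liver the bilirubin high; renal
    the creatinine high.  Cardiovascular combines the daily MAP low with
    vasopressor administration: without dose data each pressor carries a
    configured tier, and the component is the worse of the MAP tier and the
    highest administered-pressor tier.
    """
    key = ["patient_id", "facility_id", "date"]
    df = physiology.merge(med_indicators, on=key, how="left")
    n = len(df)

    def col(name: str) -> np.ndarray:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, np.nan)

    coag = _count_below(col(sofa_config["coagulation"]["input"]),
                        sofa_config["coagulation"]["below"])
    liver = _count_at_or_above(col(sofa_config["liver"]["input"]),
                               sofa_config["liver"]["at_or_above"])
    renal = _count_at_or_above(col(sofa_config["renal"]["input"]),
                               sofa_config["renal"]["at_or_above"])

    cv_cfg = sofa_config["cardiovascular"]
    map_low = col(cv_cfg["map_input"])
    map_score = np.where(np.isnan(map_low), np.nan,
                         (map_low < cv_cfg["map_threshold"]).astype(float))
    pressor = np.zeros(n, dtype=float)
    for drug, spec in lexicon_config["drugs"].items():
        tier = spec.get("sofa_tier")
        if tier is None:
            continue
        rx = f"rx_{drug}"
        if rx in df.columns:
            given = df[rx].fillna(False).to_numpy(dtype=bool)
            pressor = np.where(given, np.maximum(pressor, float(tier)), pressor)
    cardio = np.where(pressor > 0,
                      np.fmax(map_score, pressor),  # fmax: NaN MAP + pressor -> tier
                      map_score)

    out = df[key].copy()
    for name, arr in (("coagulation", coag), ("liver", liver),
                      ("cardiovascular", cardio), ("renal", renal)):
        out[f"sofa_{name}"] = pd.array(
            [pd.NA if np.isnan(v) else int(v) for v in arr], dtype="Int64")
    return out


def organ_failure_days(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Failure flag per component (score 3 or 4) plus cohort-wide totals of
    flagged patient-facility-days."""
    key = ["patient_id", "facility_id", "date"]
    flags = scores[key].copy()
    totals = {}
    for comp in SOFA_COMPONENTS:
        f = scores[f"sofa_{comp}"].isin([3, 4]).fillna(False).astype(bool)
        flags[f"failure_{comp}"] = f.to_numpy()
        totals[comp] = int(f.sum())
    return flags, totals


# ---------------------------------------------------------------------------
# Claims-based sepsis
# ---------------------------------------------------------------------------

def angus_sepsis(ssh_codes: pd.DataFrame, sshs: pd.DataFrame, code_lists: dict
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Claims-based sepsis per SSH.

    True iff the hospitalization carries (>=1 infection code AND >=1 acute
    organ-dysfunction code) OR >=1 explicit severe-sepsis/septic-shock code,
    using the code list matching the record's coding-system version.
    Records with an unknown version tag are returned as errors.
    """
    lists = code_lists["angus"]
    dx = ssh_codes.loc[ssh_codes["code_type"] == "dx"].copy()
    version = dx["icd_version"].astype(str).str.strip()
    bad = dx.loc[~version.isin(["9", "10"])]
    if len(bad):
        logger.error("%d diagnosis records with unknown code-system version", len(bad))
    dx = dx.loc[version.isin(["9", "10"])]

    flags = []
    grouped = dict(tuple(dx.groupby("ssh_id", sort=False)))
    for ssh_id in sshs["ssh_id"]:
        grp = grouped.get(ssh_id)
        result = False
        if grp is not None:
            for ver in ("9", "10"):
                codes = grp.loc[grp["icd_version"].astype(str).str.strip() == ver, "code"].tolist()
                if not codes:
                    continue
                key = f"icd{ver}"
                if _any_prefix(codes, lists["explicit"][key]) or (
                        _any_prefix(codes, lists["infection"][key])
                        and _any_prefix(codes, lists["organ_dysfunction"][key])):
                    result = True
                    break
        flags.append(result)
    out = pd.DataFrame({"ssh_id": sshs["ssh_id"].to_numpy(), "angus_sepsis": flags})
    return out.sort_values("ssh_id", kind="mergesort").reset_index(drop=True), bad


def convert_code_lists(icd9_list, gem_table: pd.DataFrame, exclusions=()
                       ) -> tuple[list[str], list[str]]:
    """Translate a legacy (ICD-9) code list into its successor-system
    equivalent via a general-equivalence mapping table.

    The result is the union of forward images (listed code -> successor) and
    backward pre-images (successor codes that map back onto a listed code),
    de-duplicated, sorted, with a manual-review exclusion list applied last.
    Listed codes contributing nothing in either direction are returned as
    unmapped.  The mapping table needs columns ``source``, ``target``,
    ``direction`` (``forward`` or ``backward``).
    """
    wanted = {normalize_code(c) for c in icd9_list}
    gem = gem_table.copy()
    gem["source"] = gem["source"].map(normalize_code)
    gem["target"] = gem["target"].map(normalize_code)
    direction = gem["direction"].astype(str).str.strip().str.lower()

    fwd = gem.loc[direction == "forward"]
    bwd = gem.loc[direction == "backward"]
    out: set[str] = set()
    mapped: set[str] = set()
    for _, row in fwd.iterrows():
        if row["source"] in wanted:
            out.add(row["target"])
            mapped.add(row["source"])
    for _, row in bwd.iterrows():
        if row["target"] in wanted:
            out.add(row["source"])
            mapped.add(row["target"])
    excl = {normalize_code(c) for c in exclusions}
    unmapped = sorted(wanted - mapped)
    if unmapped:
        logger.warning("%d codes had no mapping in either direction", len(unmapped))
    return sorted(out - excl), unmapped


# ---------------------------------------------------------------------------
# EHR-surveillance sepsis
# ---------------------------------------------------------------------------

def _consecutive_run(days: set, start: pd.Timestamp) -> int:
    length = 0
    d = start
    one = pd.Timedelta(days=1)
    while d in days:
        length += 1
        d = d + one
    return length


def cdc_ase_sepsis(sshs: pd.DataFrame, days: pd.DataFrame,
                   blood_cultures: pd.DataFrame, med_indicators: pd.DataFrame,
                   physiology: pd.DataFrame, vent_flags: pd.DataFrame | None,
                   ase_config: dict, deaths: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """EHR-surveillance sepsis per SSH, with the qualifying culture day.

    Presumed infection: a blood culture drawn during the hospitalization with
    the start of a run of consecutive systemic-antibiotic days within the
    +/- window, the run lasting at least the configured minimum (or reaching
    discharge/death earlier).  Sepsis additionally requires >=1 acute
    organ-dysfunction criterion inside the window: vasopressor day,
    mechanical ventilation (hospitalization-level), or a configured abnormal
    laboratory criterion (creatinine/bilirubin doubling vs the
    hospitalization baseline, platelet drop, lactate elevation).
    """
    key = ["patient_id", "facility_id", "date"]
    window = pd.Timedelta(days=int(ase_config["window_days"]))
    one = pd.Timedelta(days=1)

    day_data = days[key + ["ssh_id"]].merge(med_indicators, on=key, how="left")
    day_data = day_data.merge(physiology, on=key, how="left")
    cultures = blood_cultures.merge(days[key + ["ssh_id"]], on=key, how="inner")
    vent_map = {}
    if vent_flags is not None and len(vent_flags):
        vent_map = dict(zip(vent_flags["ssh_id"], vent_flags["mechanical_ventilation"]))
    death_map = {}
    if deaths is not None and len(deaths):
        death_map = dict(zip(deaths["patient_id"],
                             pd.to_datetime(deaths["death_date"]).dt.normalize()))

    def num(grp, colname):
        if colname in grp.columns:
            return pd.to_numeric(grp[colname], errors="coerce")
        return pd.Series(np.nan, index=grp.index)

    results = []
    by_ssh = dict(tuple(day_data.groupby("ssh_id", sort=False)))
    cultures_by_ssh = dict(tuple(cultures.groupby("ssh_id", sort=False)))
    for ssh in sshs.itertuples(index=False):
        grp = by_ssh.get(ssh.ssh_id)
        cult = cultures_by_ssh.get(ssh.ssh_id)
        flag, qualifying = False, pd.NaT
        if grp is not None and cult is not None:
            grp = grp.sort_values("date")
            dates = grp["date"]
            abx_days = set(dates[grp["abx_systemic"].fillna(False).astype(bool)])
            vaso_days = set(dates[grp["any_vasopressor"].fillna(False).astype(bool)])
            end_anchor = ssh.discharge_date
            dd = death_map.get(ssh.patient_id)
            if dd is not None and dd < end_anchor:
                end_anchor = dd

            creat_low = num(grp, "creatinine_low")
            creat_high = num(grp, "creatinine_high")
            bili_low = num(grp, "bilirubin_low")
            bili_high = num(grp, "bilirubin_high")
            plt_low = num(grp, "platelets_low")
            plt_high = num(grp, "platelets_high")
            lact_high = num(grp, "lactate_high")
            base_creat = creat_low.min()
            base_bili = bili_low.min()
            base_plt = plt_high.max()

            lab_dysf = pd.Series(False, index=grp.index)
            if pd.notna(base_creat) and base_creat > 0:
                lab_dysf |= creat_high >= ase_config["creatinine_doubling"] * base_creat
            if pd.notna(base_bili) and base_bili > 0:
                lab_dysf |= ((bili_high >= ase_config["bilirubin_doubling"] * base_bili)
                             & (bili_high >= ase_config["bilirubin_floor"]))
            if pd.notna(base_plt) and base_plt >= ase_config["platelet_threshold"]:
                lab_dysf |= ((plt_low < ase_config["platelet_threshold"])
                             & (plt_low <= (1.0 - ase_config["platelet_decline"]) * base_plt))
            lab_dysf |= lact_high >= ase_config["lactate_threshold"]
            lab_days = set(dates[lab_dysf.fillna(False)])

            for c in sorted(set(cult["date"])):
                lo, hi = c - window, c + window
                infection = False
                for a in sorted(abx_days):
                    if a < lo or a > hi:
                        continue
                    run = _consecutive_run(abx_days, a)
                    run_end = a + (run - 1) * one
                    if run >= int(ase_config["min_antibiotic_days"]) or run_end >= end_anchor:
                        infection = True
                        break
                if not infection:
                    continue
                dysfunction = (
                    any(lo <= d <= hi for d in vaso_days)
                    or bool(vent_map.get(ssh.ssh_id, False))
                    or any(lo <= d <= hi for d in lab_days)
                )
                if dysfunction:
                    flag, qualifying = True, c
                    break
        results.append((ssh.ssh_id, flag, qualifying))

    out = pd.DataFrame(results, columns=["ssh_id", "cdc_ase", "ase_culture_date"])
    return out.sort_values("ssh_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mechanical ventilation
# ---------------------------------------------------------------------------

def detect_mechanical_ventilation(ssh_codes: pd.DataFrame, sshs: pd.DataFrame,
                                  code_lists: dict, level: str = "hospitalization"
                                  ) -> pd.DataFrame:
    """Hospitalization-level ventilation flag from procedure codes.

    Day-level detection is refused: procedure codes do not reliably localize
    ventilation to a calendar day.
    """
    if level != "hospitalization":
        raise UnsupportedOperationError(
            "ventilation is detected at the hospitalization level only; "
            f"level={level!r} is not supported")
    vent = code_lists["ventilation_procedures"]
    proc = ssh_codes.loc[ssh_codes["code_type"] == "proc"]
    flags = []
    grouped = dict(tuple(proc.groupby("ssh_id", sort=False)))
    for ssh_id in sshs["ssh_id"]:
        grp = grouped.get(ssh_id)
        result = False
        if grp is not None:
            for ver in ("9", "10"):
                codes = grp.loc[grp["icd_version"].astype(str).str.strip() == ver, "code"].tolist()
                if codes and _any_prefix(codes, vent[f"icd{ver}"]):
                    result = True
                    break
        flags.append(result)
    out = pd.DataFrame({"ssh_id": sshs["ssh_id"].to_numpy(),
                        "mechanical_ventilation": flags})
    return out.sort_values("ssh_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Severity-score components
# ---------------------------------------------------------------------------

def assemble_risk_components(sshs: pd.DataFrame, patients: pd.DataFrame,
                             ssh_codes: pd.DataFrame, physiology: pd.DataFrame,
                             risk_config: dict, composite: bool = False) -> pd.DataFrame:
    """Per-SSH severity-score *components*: age, admission diagnosis
    category, comorbidity flags, and admission-day laboratory values.

    Only components are emitted; requesting a composite predicted-mortality
    score raises, by design, so users fit the score appropriate to their
    question.
    """
    if composite:
        raise UnsupportedOperationError(
            "composite severity scores are not computed; only components are provided")

    age_map = dict(zip(patients["patient_id"], patients["age"])) if len(patients) else {}
    dx = ssh_codes.loc[ssh_codes["code_type"] == "dx"]
    by_ssh = dict(tuple(dx.groupby("ssh_id", sort=False)))
    comorbidities = risk_config["comorbidities"]
    categories = risk_config["dx_categories"]

    phys_keyed = physiology.set_index(["patient_id", "facility_id", "date"]) if len(physiology) else None

    rows = []
    for ssh in sshs.itertuples(index=False):
        row: dict = {"ssh_id": ssh.ssh_id, "age": age_map.get(ssh.patient_id, pd.NA)}
        grp = by_ssh.get(ssh.ssh_id)
        codes9, codes10, primary = [], [], None
        if grp is not None:
            version = grp["icd_version"].astype(str).str.strip()
            codes9 = grp.loc[version == "9", "code"].tolist()
            codes10 = grp.loc[version == "10", "code"].tolist()
            prim = grp.loc[pd.to_numeric(grp["position"], errors="coerce") == 1]
            if len(prim):
                primary = (prim.iloc[0]["code"],
                           str(prim.iloc[0]["icd_version"]).strip())
        category = "other"
        if primary is not None:
            code, ver = primary
            for name, p9, p10 in categories:
                prefixes = p9 if ver == "9" else p10
                if any(code.startswith(p) for p in prefixes):
                    category = name
                    break
        row["admission_dx_category"] = category
        for name, spec in sorted(comorbidities.items()):
            row[f"cm_{name}"] = (_any_prefix(codes9, spec.get("icd9", []))
                                 or _any_prefix(codes10, spec.get("icd10", [])))
        adm = None
        if phys_keyed is not None:
            try:
                adm = phys_keyed.loc[(ssh.patient_id, ssh.facility_id, ssh.admit_date)]
            except KeyError:
                adm = None
        for lab in risk_config["admission_labs"]:
            for stat in ("low", "high"):
                colname = f"{lab}_{stat}"
                val = adm.get(colname) if adm is not None else None
                row[f"adm_{colname}"] = val if val is not None and pd.notna(val) else pd.NA
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["ssh_id", "age", "admission_dx_category"])
    return pd.DataFrame(rows).sort_values("ssh_id", kind="mergesort").reset_index(drop=True)
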