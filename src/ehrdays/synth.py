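"""Synthetic multi-hospital EHR extract generator with known ground truth.

Emits the five raw record tables (specialty transfers, laboratory results,
vital signs, medication administrations, diagnosis/procedure codes) plus
patient demographics, death dates, and ground-truth tables holding the true
hospitalization boundaries, true sepsis flags, and true daily organ scores.

Ground truth is decided *before* values are sampled: each patient-day gets
target component scores, and physiologic values are then drawn uniformly
inside the band corresponding to the target.  The truth tables therefore do
not depend on any scoring code in this package, which makes end-to-end
recovery a real test.

``inject_messiness`` layers on the heterogeneity seen across real
facilities -- blanked identifier codes, facility-specific test names,
hand-typed drug-name noise, and decoy research/study records -- without ever
touching the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

# value bands per target component score; sampled values stay strictly
# inside a band so the worst daily value maps back to exactly that score
PLATELET_BANDS = {0: (150, 400), 1: (100, 149), 2: (50, 99), 3: (20, 49), 4: (5, 19)}
BILIRUBIN_BANDS = {0: (0.2, 1.14), 1: (1.2, 1.94), 2: (2.0, 5.94), 3: (6.0, 11.94), 4: (12.0, 19.94)}
CREATININE_BANDS = {0: (0.4, 1.14), 1: (1.2, 1.94), 2: (2.0, 3.44), 3: (3.5, 4.94), 4: (5.0, 8.94)}
MAP_BANDS = {0: (71, 95), 1: (56, 69)}

_BENIGN_DX = {"9": ["4019", "2724", "53081", "3051", "V4582"],
              "10": ["I10", "E785", "K219", "F17210", "Z951"]}
_ICD10_SWITCH = pd.Timestamp("2015-10-01")

_LAB_META = {
    # test -> (local name, loinc, topography, unit, code suffix)
    "platelets": ("Platelet Count", "777-3", "blood", "K/uL", "PLT"),
    "bilirubin": ("Bilirubin, Total", "1975-2", "serum", "mg/dL", "TBIL"),
    "creatinine": ("Creatinine", "2160-0", "serum", "mg/dL", "CREA"),
    "lactate": ("Lactate", "2524-7", "plasma", "mmol/L", "LACT"),
    "wbc": ("White Blood Cell Count", "6690-2", "blood", "K/uL", "WBC"),
    "sodium": ("Sodium", "2951-2", "serum", "mmol/L", "NA"),
}

_NAME_VARIANTS = {
    "Platelet Count": ["PLT", "PLATELETS AUTO", "plt count"],
    "Bilirubin, Total": ["TBILI", "TOTAL BILIRUBIN", "bilirubin total"],
    "Creatinine": ["CREAT", "CREATININE, SERUM", "creat (bld)"],
    "Lactate": ["LACTIC ACID", "Lactate, Plasma"],
    "White Blood Cell Count": ["WBC", "WBC AUTO"],
    "Sodium": ["NA LEVEL", "Sodium, serum"],
}

TABLE_NAMES = ("specialty_transfers", "labs", "vitals", "med_admins", "codes",
               "patients", "deaths", "ground_truth_ssh", "ground_truth_days")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs controlling cohort size, structure, and injected messiness."""

    n_patients: int = 50
    n_facilities: int = 4
    start_date: str = "2014-01-01"
    end_date: str = "2014-12-31"
    transfer_prob: float = 0.1
    icu_prob: float = 0.3
    nonacute_tail_prob: float = 0.1
    sepsis_prevalence: float = 0.05
    lab_name_variant_rate: float = 0.0
    missing_loinc_rate: float = 0.0
    mortality_rate: float = 0.04
    median_los_days: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_facilities <= 0:
            raise ConfigError("n_patients and n_facilities must be positive")
        for name in ("transfer_prob", "icu_prob", "nonacute_tail_prob",
                     "sepsis_prevalence", "lab_name_variant_rate",
                     "missing_loinc_rate", "mortality_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} is not a probability")
        if self.start > self.end:
            raise ConfigError("empty date range")
        if self.median_los_days < 1:
            raise ConfigError("median_los_days must be >= 1")

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.end_date)


@dataclass
class RawTables:
    """The raw extract bundle: five record tables plus demographics, deaths,
    and ground truth."""

    specialty_transfers: pd.DataFrame
    labs: pd.DataFrame
    vitals: pd.DataFrame
    med_admins: pd.DataFrame
    codes: pd.DataFrame
    patients: pd.DataFrame
    deaths: pd.DataFrame
    ground_truth_ssh: pd.DataFrame
    ground_truth_days: pd.DataFrame

    def copy(self) -> "RawTables":
        return RawTables(**{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def to_dir(self, path) -> None:
        """Write every table as a comma-separated UTF-8 file with a header
        row and ISO-8601 datetimes."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in TABLE_NAMES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False,
                                       float_format="%.6g")

    @classmethod
    def from_dir(cls, path) -> "RawTables":
        path = Path(path)
        frames = {}
        for name in TABLE_NAMES:
            fp = path / f"{name}.csv"
            frames[name] = pd.read_csv(fp, dtype=str) if fp.exists() else pd.DataFrame()
        return cls(**frames)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _los(rng: np.random.Generator, median: float, lo: int = 1, hi: int = 20) -> int:
    d = int(round(float(np.exp(rng.normal(np.log(median), 0.5)))))
    return int(min(max(d, lo), hi))


def _round1(x: float) -> float:
    return float(np.floor(x * 10.0) / 10.0)


def _sample_band(rng, bands: dict, score: int, integer: bool = False) -> float:
    lo, hi = bands[score]
    if integer:
        return float(rng.integers(lo, hi + 1))
    return _round1(rng.uniform(lo, hi))


class _Builder:
    def __init__(self):
        self.stays, self.labs, self.vitals = [], [], []
        self.meds, self.codes, self.patients, self.deaths = [], [], [], []
        self.gt_ssh, self.gt_days = [], []

    def lab(self, pid, fac, test, value, when, unit=None, name=None, loinc=None):
        meta = _LAB_META[test]
        self.labs.append({
            "patient_id": pid, "facility_id": fac,
            "facility_lab_code": f"{fac}-{meta[4]}",
            "local_name": name if name is not None else meta[0],
            "loinc": loinc if loinc is not None else meta[1],
            "topography": meta[2], "value": value,
            "unit": unit if unit is not None else meta[3],
            "drawn_at": when,
        })

    def vital(self, pid, fac, vtype, value, when, unit=""):
        self.vitals.append({"patient_id": pid, "facility_id": fac,
                            "vital_type": vtype, "value": value,
                            "unit": unit, "taken_at": when})

    def med(self, pid, fac, local, national, klass, dosage, route, when):
        self.meds.append({"patient_id": pid, "facility_id": fac,
                          "drug_name_local": local, "drug_name_national": national,
                          "drug_class": klass, "dosage": dosage,
                          "route": route, "given_at": when})

    def code(self, pid, fac, code, version, ctype, position, when):
        self.codes.append({"patient_id": pid, "facility_id": fac, "code": code,
                           "icd_version": version, "code_type": ctype,
                           "position": position, "coded_at": when})


def _emit_day(b: _Builder, rng, pid, fac, date, targets: dict, sepsis_day: bool):
    """Emit one facility-day of labs/vitals/meds realizing the target
    component scores, and record the ground-truth row."""
    t06 = date + pd.Timedelta(hours=6)
    t10 = date + pd.Timedelta(hours=10)
    t16 = date + pd.Timedelta(hours=16)

    gt = {"patient_id": pid, "facility_id": fac, "date": date.date().isoformat()}
    # coagulation / liver / renal: each present with probability 0.85
    for test, bands, comp, integer in (
            ("platelets", PLATELET_BANDS, "coagulation", True),
            ("bilirubin", BILIRUBIN_BANDS, "liver", False),
            ("creatinine", CREATININE_BANDS, "renal", False)):
        score = targets[comp]
        if rng.random() < 0.85:
            n_meas = 1 + int(rng.random() < 0.3)
            for k in range(n_meas):
                v = _sample_band(rng, bands, score, integer=integer)
                b.lab(pid, fac, test, v, t06 + pd.Timedelta(hours=6 * k))
            gt[comp] = score
        else:
            gt[comp] = ""
    # cardiovascular: MAP always measured twice; pressor tier overrides
    cv = targets["cardiovascular"]
    map_band = 1 if cv >= 1 else 0
    for k in range(2):
        b.vital(pid, fac, "MAP", _sample_band(rng, MAP_BANDS, map_band, integer=True),
                t06 + pd.Timedelta(hours=5 * k + 1), unit="mmHg")
    if cv == 3:
        b.med(pid, fac, "NOREPINEPHRINE 8MG/250ML", "NOREPINEPHRINE BITARTRATE INJ",
              "AUTONOMIC", "8MG/250ML", "IV", t10)
    gt["cardiovascular"] = cv
    b.gt_days.append(gt)

    # incidental normal measurements (no bearing on the four components)
    if rng.random() < 0.5:
        b.lab(pid, fac, "wbc", _round1(rng.uniform(4.5, 10.5)), t10)
    if rng.random() < 0.4:
        b.lab(pid, fac, "sodium", float(rng.integers(134, 144)), t10)
    if sepsis_day:
        b.lab(pid, fac, "lactate", _round1(rng.uniform(2.5, 6.0)), t06)
    elif rng.random() < 0.1:
        b.lab(pid, fac, "lactate", _round1(rng.uniform(0.6, 1.7)), t06)
    b.vital(pid, fac, "TEMPERATURE", _round1(rng.uniform(36.2, 37.8)), t10, unit="C")
    b.vital(pid, fac, "PULSE", float(rng.integers(58, 105)), t16, unit="bpm")
    if rng.random() < 0.2:
        b.med(pid, fac, "ACETAMINOPHEN 325MG TAB", "ACETAMINOPHEN TAB",
              "ANALGESIC", "325MG", "PO", t16)


def _daily_targets(rng, sepsis_day: bool) -> dict:
    if sepsis_day:
        return {"coagulation": int(rng.choice([0, 2, 3])),
                "liver": int(rng.choice([0, 1, 2])),
                "renal": int(rng.choice([0, 2, 3])),
                "cardiovascular": 3}
    return {"coagulation": int(rng.choice([0, 0, 0, 0, 1])),
            "liver": int(rng.choice([0, 0, 0, 0, 1])),
            "renal": int(rng.choice([0, 0, 0, 0, 1])),
            "cardiovascular": int(rng.choice([0] * 9 + [1]))}


def generate_cohort(config: CohortConfig) -> RawTables:
    """Sample a cohort of patients with hospitalizations, transfers,
    non-acute tails, and controlled sepsis prevalence.

    Identical config (including seed) reproduces byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    b = _Builder()
    start, end = config.start, config.end
    span_days = (end - start).days
    latest_admit = max(0, span_days - 60)

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        b.patients.append({"patient_id": pid, "age": int(rng.integers(40, 95))})
        n_hosp = 1 + int(rng.random() < 0.25)
        cursor_day = int(rng.integers(0, latest_admit + 1))
        dead = False
        for _ in range(n_hosp):
            if dead or cursor_day > latest_admit:
                break
            admit_day = start + pd.Timedelta(days=cursor_day)
            sepsis = rng.random() < config.sepsis_prevalence
            icu_first = rng.random() < config.icu_prob
            transfer = config.n_facilities >= 2 and rng.random() < config.transfer_prob
            tail = rng.random() < config.nonacute_tail_prob
            fac_a = f"F{rng.integers(config.n_facilities):03d}"

            # --- segments at facility A ---------------------------------
            len1 = _los(rng, config.median_los_days)
            if sepsis:
                len1 = max(len1, 5)
            segs_a = [("MICU" if icu_first else "WARD", len1)]
            if icu_first and rng.random() < 0.7:
                segs_a.append(("WARD", _los(rng, config.median_los_days)))

            stays_plan = []  # (facility, specialty, admit_ts, discharge_ts)
            t = admit_day + pd.Timedelta(hours=8, minutes=int(rng.integers(0, 50)))
            for j, (spec, length) in enumerate(segs_a):
                disc = (t.normalize() + pd.Timedelta(days=length - 1)
                        + pd.Timedelta(hours=11))
                if disc <= t:
                    disc = t + pd.Timedelta(hours=2)
                stays_plan.append([fac_a, spec, t, disc])
                if j + 1 < len(segs_a):
                    # in-place handoff (same bedded stay) or ward move
                    t = disc if rng.random() < 0.5 else disc + pd.Timedelta(hours=2)
            facilities = [fac_a]
            if transfer:
                others = [f"F{k:03d}" for k in range(config.n_facilities) if f"F{k:03d}" != fac_a]
                fac_b = others[int(rng.integers(len(others)))]
                t = stays_plan[-1][3] + pd.Timedelta(hours=2)
                spec_b = "MICU" if (icu_first and rng.random() < 0.3) else "WARD"
                len_b = _los(rng, config.median_los_days)
                disc = t.normalize() + pd.Timedelta(days=len_b - 1) + pd.Timedelta(hours=11)
                if disc <= t:
                    disc = t + pd.Timedelta(hours=3)
                stays_plan.append([fac_b, spec_b, t, disc])
                facilities.append(fac_b)
            if tail:
                t = stays_plan[-1][3] + pd.Timedelta(hours=1)
                disc = t.normalize() + pd.Timedelta(days=int(rng.integers(2, 11))) + pd.Timedelta(hours=10)
                stays_plan.append([stays_plan[-1][0], "CLC", t, disc])

            # clip at observation end
            end_ts = end + pd.Timedelta(hours=23)
            stays_plan = [[f, s, a, min(d, end_ts)] for f, s, a, d in stays_plan if a < end_ts]
            for f, s, a, d in stays_plan:
                b.stays.append({"patient_id": pid, "facility_id": f,
                                "specialty_code": s, "admit": a, "discharge": d})

            # --- true SSH boundaries (acute stays only, per facility) ---
            ssh_bounds = {}
            for f, s, a, d in stays_plan:
                if s == "CLC":
                    continue
                lo, hi = ssh_bounds.get(f, (None, None))
                a0, d0 = a.normalize(), d.normalize()
                ssh_bounds[f] = (a0 if lo is None or a0 < lo else lo,
                                 d0 if hi is None or d0 > hi else hi)
            culture_day = admit_day.normalize() + pd.Timedelta(days=1) if sepsis else None
            sepsis_fac = fac_a
            for f in facilities:
                lo, hi = ssh_bounds[f]
                b.gt_ssh.append({"patient_id": pid, "facility_id": f,
                                 "admit_date": lo.date().isoformat(),
                                 "discharge_date": hi.date().isoformat(),
                                 "sepsis": bool(sepsis and f == sepsis_fac)})

            # --- daily physiology per facility-day ----------------------
            pressor_days = set()
            abx_days = []
            if sepsis:
                pressor_days = {culture_day, culture_day + pd.Timedelta(days=1)}
                abx_days = [culture_day + pd.Timedelta(days=k) for k in range(4)]
            for f in facilities:
                lo, hi = ssh_bounds[f]
                for date in pd.date_range(lo, hi):
                    is_sepsis_day = sepsis and f == sepsis_fac and date in pressor_days
                    targets = _daily_targets(rng, is_sepsis_day)
                    _emit_day(b, rng, pid, f, date, targets, is_sepsis_day)

            # --- sepsis events: culture + antibiotic course -------------
            if sepsis:
                b.lab(pid, sepsis_fac, "creatinine", "", culture_day + pd.Timedelta(hours=7),
                      unit="", name="BLOOD CULTURE", loinc="600-7")
                # overwrite the bogus meta fields set by lab()
                b.labs[-1]["facility_lab_code"] = f"{sepsis_fac}-BCX"
                b.labs[-1]["topography"] = "blood"
                for day in abx_days:
                    if day > ssh_bounds[sepsis_fac][1]:
                        break
                    b.med(pid, sepsis_fac, "VANCOMYCIN 1GM INJ", "VANCOMYCIN HCL INJ",
                          "ANTIBIOTIC", "1GM", "IV", day + pd.Timedelta(hours=9))
                    if rng.random() < 0.5:
                        b.med(pid, sepsis_fac, "PIPERACILLIN-TAZOBACTAM 4.5GM",
                              "PIPERACILLIN/TAZOBACTAM INJ", "ANTIBIOTIC",
                              "4.5GM", "IVPB", day + pd.Timedelta(hours=21))
            elif rng.random() < 0.15:
                # short, culture-free antibiotic course: must not flag
                d0 = ssh_bounds[fac_a][0]
                for k in range(int(rng.integers(1, 3))):
                    day = d0 + pd.Timedelta(days=k)
                    if day <= ssh_bounds[fac_a][1]:
                        b.med(pid, fac_a, "CEFTRIAXONE 1GM INJ", "CEFTRIAXONE INJ",
                              "ANTIBIOTIC", "1GM", "IV", day + pd.Timedelta(hours=9))

            # --- diagnosis / procedure codes ----------------------------
            version = "9" if admit_day < _ICD10_SWITCH else "10"
            for f in facilities:
                lo, hi = ssh_bounds[f]
                when = hi + pd.Timedelta(hours=10)
                position = 1
                if sepsis and f == sepsis_fac:
                    if rng.random() < 0.5:
                        explicit = "99592" if version == "9" else "R6520"
                        b.code(pid, f, explicit, version, "dx", position, when)
                        position += 1
                    else:
                        inf = "0389" if version == "9" else "A419"
                        od = "5849" if version == "9" else "N179"
                        b.code(pid, f, inf, version, "dx", position, when)
                        b.code(pid, f, od, version, "dx", position + 1, when)
                        position += 2
                    if icu_first and rng.random() < 0.5:
                        vent = "9670" if version == "9" else "5A1935Z"
                        b.code(pid, f, vent, version, "proc", 1, when)
                else:
                    if rng.random() < 0.10:
                        # infection code alone: never qualifies as sepsis
                        inf = "486" if version == "9" else "J189"
                        b.code(pid, f, inf, version, "dx", position, when)
                        position += 1
                for _k in range(int(rng.integers(1, 4))):
                    benign = _BENIGN_DX[version][int(rng.integers(len(_BENIGN_DX[version])))]
                    b.code(pid, f, benign, version, "dx", position, when)
                    position += 1

            # --- death --------------------------------------------------
            last_acute_end = max(hi for _, hi in ssh_bounds.values())
            overall_end = max(d for _, _, _, d in stays_plan).normalize()
            if rng.random() < config.mortality_rate:
                dead = True
                if rng.random() < 0.5:
                    death_date = last_acute_end
                else:
                    death_date = last_acute_end + pd.Timedelta(days=int(rng.integers(5, 60)))
                b.deaths.append({"patient_id": pid,
                                 "death_date": death_date.date().isoformat()})
            cursor_day = (overall_end - start).days + int(rng.integers(35, 90))

    def frame(rows, columns, sort_cols):
        df = pd.DataFrame(rows, columns=columns)
        return df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    return RawTables(
        specialty_transfers=frame(b.stays, ["patient_id", "facility_id", "specialty_code",
                                            "admit", "discharge"],
                                  ["patient_id", "admit", "facility_id"]),
        labs=frame(b.labs, ["patient_id", "facility_id", "facility_lab_code", "local_name",
                            "loinc", "topography", "value", "unit", "drawn_at"],
                   ["patient_id", "drawn_at", "facility_id", "local_name"]),
        vitals=frame(b.vitals, ["patient_id", "facility_id", "vital_type", "value",
                                "unit", "taken_at"],
                     ["patient_id", "taken_at", "facility_id", "vital_type"]),
        med_admins=frame(b.meds, ["patient_id", "facility_id", "drug_name_local",
                                  "drug_name_national", "drug_class", "dosage",
                                  "route", "given_at"],
                         ["patient_id", "given_at", "facility_id", "drug_name_local"]),
        codes=frame(b.codes, ["patient_id", "facility_id", "code", "icd_version",
                              "code_type", "position", "coded_at"],
                    ["patient_id", "coded_at", "facility_id", "position", "code"]),
        patients=frame(b.patients, ["patient_id", "age"], ["patient_id"]),
        deaths=frame(b.deaths, ["patient_id", "death_date"], ["patient_id"]),
        ground_truth_ssh=frame(b.gt_ssh, ["patient_id", "facility_id", "admit_date",
                                          "discharge_date", "sepsis"],
                               ["patient_id", "admit_date", "facility_id"]),
        ground_truth_days=frame(b.gt_days, ["patient_id", "facility_id", "date",
                                            "coagulation", "liver", "cardiovascular",
                                            "renal"],
                                ["patient_id", "date", "facility_id"]),
    )


# ---------------------------------------------------------------------------
# The worked transfer example
# ---------------------------------------------------------------------------

def generate_demo_patient() -> RawTables:
    """A fixed single-patient trajectory with a same-day inter-facility
    transfer, an in-facility ICU-to-ward move, and a non-acute nursing-home
    tail: four specialty stays across two facilities, yielding two
    single-site hospitalizations, one acute hospitalization, four bedded
    stays, and one overall episode of care."""
    b = _Builder()
    pid, fbc, faa = "P00001", "FBC", "FAA"
    rng = np.random.default_rng(12345)

    plan = [
        (fbc, "MICU", pd.Timestamp("2014-03-01 08:15"), pd.Timestamp("2014-03-03 09:30")),
        (faa, "MICU", pd.Timestamp("2014-03-03 12:00"), pd.Timestamp("2014-03-07 10:00")),
        (faa, "WARD", pd.Timestamp("2014-03-07 13:00"), pd.Timestamp("2014-03-10 09:00")),
        (faa, "CLC", pd.Timestamp("2014-03-10 11:00"), pd.Timestamp("2014-03-20 10:00")),
    ]
    for f, s, a, d in plan:
        b.stays.append({"patient_id": pid, "facility_id": f, "specialty_code": s,
                        "admit": a, "discharge": d})

    spans = {fbc: ("2014-03-01", "2014-03-03"), faa: ("2014-03-03", "2014-03-10")}
    targets = {"coagulation": 0, "liver": 0, "renal": 0, "cardiovascular": 0}
    for f, (lo, hi) in spans.items():
        b.gt_ssh.append({"patient_id": pid, "facility_id": f, "admit_date": lo,
                         "discharge_date": hi, "sepsis": False})
        for date in pd.date_range(lo, hi):
            gt_targets = dict(targets)
            _emit_day(b, rng, pid, f, date, gt_targets, sepsis_day=False)
        b.code(pid, f, "4019", "9", "dx", 1,
               pd.Timestamp(hi) + pd.Timedelta(hours=10))
    b.patients.append({"patient_id": pid, "age": 66})

    def frame(rows, columns, sort_cols):
        df = pd.DataFrame(rows, columns=columns)
        return df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    return RawTables(
        specialty_transfers=frame(b.stays, ["patient_id", "facility_id", "specialty_code",
                                            "admit", "discharge"],
                                  ["patient_id", "admit", "facility_id"]),
        labs=frame(b.labs, ["patient_id", "facility_id", "facility_lab_code", "local_name",
                            "loinc", "topography", "value", "unit", "drawn_at"],
                   ["patient_id", "drawn_at", "facility_id", "local_name"]),
        vitals=frame(b.vitals, ["patient_id", "facility_id", "vital_type", "value",
                                "unit", "taken_at"],
                     ["patient_id", "taken_at", "facility_id", "vital_type"]),
        med_admins=frame(b.meds, ["patient_id", "facility_id", "drug_name_local",
                                  "drug_name_national", "drug_class", "dosage",
                                  "route", "given_at"],
                         ["patient_id", "given_at", "facility_id", "drug_name_local"]),
        codes=frame(b.codes, ["patient_id", "facility_id", "code", "icd_version",
                              "code_type", "position", "coded_at"],
                    ["patient_id", "coded_at", "facility_id", "position", "code"]),
        patients=frame(b.patients, ["patient_id", "age"], ["patient_id"]),
        deaths=pd.DataFrame(columns=["patient_id", "death_date"]),
        ground_truth_ssh=frame(b.gt_ssh, ["patient_id", "facility_id", "admit_date",
                                          "discharge_date", "sepsis"],
                               ["patient_id", "admit_date", "facility_id"]),
        ground_truth_days=frame(b.gt_days, ["patient_id", "facility_id", "date",
                                            "coagulation", "liver", "cardiovascular",
                                            "renal"],
                                ["patient_id", "date", "facility_id"]),
    )


# ---------------------------------------------------------------------------
# Messiness injection
# ---------------------------------------------------------------------------

def inject_messiness(tables: RawTables, config: CohortConfig) -> RawTables:
    """Make the clean extract look like multi-facility reality.

    Blanks identifier codes at ``missing_loinc_rate`` (the local name
    remains, so the name-matching route can rescue the record), rewrites lab
    names with facility-flavored synonyms at ``lab_name_variant_rate``,
    perturbs drug-name strings (case noise), and inserts decoy records
    carrying research/study tokens.  Ground truth is never altered.
    """
    rng = np.random.default_rng(config.seed + 104729)
    out = tables.copy()

    labs = out.labs
    if len(labs):
        blank = rng.random(len(labs)) < config.missing_loinc_rate
        labs.loc[blank, "loinc"] = ""
        variant = rng.random(len(labs)) < config.lab_name_variant_rate
        new_names = []
        for name, flip in zip(labs["local_name"], variant):
            choices = _NAME_VARIANTS.get(name)
            if flip and choices:
                new_names.append(choices[int(rng.integers(len(choices)))])
            else:
                new_names.append(name)
        labs["local_name"] = new_names

    meds = out.med_admins
    if len(meds):
        flip = rng.random(len(meds)) < 0.3
        meds.loc[flip, "drug_name_local"] = meds.loc[flip, "drug_name_local"].str.lower()
        # decoy research/study records anchored to existing patient-days
        n_decoys = max(2, len(meds) // 200)
        picks = rng.integers(0, len(meds), size=n_decoys)
        decoys = meds.iloc[picks].copy()
        texts = ["VANCOMYCIN STUDY DRUG 1GM", "RESEARCH USE ONLY - NOREPINEPHRINE",
                 "CEFTRIAXONE 1GM (STUDY ARM B)"]
        decoys["drug_name_local"] = [texts[int(rng.integers(len(texts)))]
                                     for _ in range(n_decoys)]
        decoys["drug_name_national"] = "INVESTIGATIONAL DRUG"
        out.med_admins = pd.concat([meds, decoys], ignore_index=True).sort_values(
            ["patient_id", "given_at", "facility_id", "drug_name_local"],
            kind="mergesort").reset_index(drop=True)
    return out


def simulate(config: CohortConfig, messy: bool | None = None) -> RawTables:
    """Generate a cohort, applying messiness when any messiness knob is on."""
    tables = generate_cohort(config)
    if messy is None:
        messy = config.missing_loinc_rate > 0 or config.lab_name_variant_rate > 0
    if messy:
        tables = inject_messiness(tables, config)
    return tables
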