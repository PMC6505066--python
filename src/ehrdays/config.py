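"""Editable configuration defaults.

Everything that is site-specific in a real deployment -- specialty
classifications, laboratory test definitions (identifier sets, name synonyms,
units, plausible ranges), the drug lexicon, organ-dysfunction thresholds, and
diagnosis/procedure code lists -- lives here as plain dictionaries.  Each
``default_*`` function returns a fresh copy that callers may edit, and
``load_yaml_config`` merges a user YAML file over the defaults.

The seeded values are clinically standard but intentionally modest: they are
starting points to be reviewed and extended per site, not authoritative
transcriptions of any institution's lists.  Entries marked ``provisional``
are placeholders whose exact composition must be supplied by the user.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

from .errors import ConfigError

# ---------------------------------------------------------------------------
# Treating-specialty classification: code -> {acute, icu}
# ---------------------------------------------------------------------------

_SPECIALTIES = {
    "MICU": {"acute": True, "icu": True},
    "SICU": {"acute": True, "icu": True},
    "CCU": {"acute": True, "icu": True},
    "NICU": {"acute": True, "icu": True},
    "ICU": {"acute": True, "icu": True},
    "WARD": {"acute": True, "icu": False},
    "MED": {"acute": True, "icu": False},
    "SURG": {"acute": True, "icu": False},
    "NEURO": {"acute": True, "icu": False},
    "TELE": {"acute": True, "icu": False},
    "CLC": {"acute": False, "icu": False},
    "NHCU": {"acute": False, "icu": False},
    "DOM": {"acute": False, "icu": False},
    "REHAB": {"acute": False, "icu": False},
    "PSYCH-RES": {"acute": False, "icu": False},
}


def default_specialty_config() -> dict:
    return {
        "specialties": copy.deepcopy(_SPECIALTIES),
        # classification applied to specialty codes absent from the table
        "unknown_default": {"acute": False, "icu": False},
    }


# ---------------------------------------------------------------------------
# Standard laboratory tests (16) and vital signs (6)
# ---------------------------------------------------------------------------
#
# Each entry: canonical unit, plausible range (inclusive bounds, canonical
# unit), identifier code set, case-insensitive name substrings, allowed
# topographies (None = any), and linear unit conversions value' = a*value + b.
# Plausible ranges are implementer defaults pending clinician review.

_BLOODY = ["blood", "serum", "plasma", "arterial blood", "venous blood",
           "whole blood"]

_LAB_TESTS = {
    "creatinine": {
        "kind": "lab", "canonical_unit": "mg/dL", "plausible_range": [0.1, 40.0],
        "loinc": ["2160-0", "38483-4"],
        "names": ["creatinine", "creat"],
        "topographies": _BLOODY,
        "unit_conversions": {"umol/l": [0.0113122, 0.0]},
    },
    "bilirubin": {
        "kind": "lab", "canonical_unit": "mg/dL", "plausible_range": [0.0, 80.0],
        "loinc": ["1975-2", "42719-5"],
        "names": ["bilirubin total", "total bilirubin", "bilirubin, total", "tbili"],
        "topographies": _BLOODY,
        "unit_conversions": {"umol/l": [0.0584795, 0.0]},
    },
    "platelets": {
        "kind": "lab", "canonical_unit": "K/uL", "plausible_range": [1.0, 2000.0],
        "loinc": ["777-3", "778-1"],
        "names": ["platelet", "plt"],
        "topographies": _BLOODY,
        "unit_conversions": {"10*3/ul": [1.0, 0.0], "/nl": [1.0, 0.0]},
    },
    "wbc": {
        "kind": "lab", "canonical_unit": "K/uL", "plausible_range": [0.01, 300.0],
        "loinc": ["6690-2", "26464-8"],
        "names": ["white blood cell", "wbc", "leukocyte"],
        "topographies": _BLOODY,
        "unit_conversions": {"10*3/ul": [1.0, 0.0]},
    },
    "hematocrit": {
        "kind": "lab", "canonical_unit": "%", "plausible_range": [5.0, 75.0],
        "loinc": ["4544-3", "20570-8"],
        "names": ["hematocrit", "hct"],
        "topographies": _BLOODY,
        "unit_conversions": {},
    },
    "hemoglobin": {
        "kind": "lab", "canonical_unit": "g/dL", "plausible_range": [1.0, 25.0],
        "loinc": ["718-7", "20509-6"],
        "names": ["hemoglobin", "hgb"],
        "topographies": _BLOODY,
        "unit_conversions": {"g/l": [0.1, 0.0]},
    },
    "sodium": {
        "kind": "lab", "canonical_unit": "mmol/L", "plausible_range": [100.0, 185.0],
        "loinc": ["2951-2", "2947-0"],
        "names": ["sodium", "na "],
        "topographies": _BLOODY,
        "unit_conversions": {"meq/l": [1.0, 0.0]},
    },
    "potassium": {
        "kind": "lab", "canonical_unit": "mmol/L", "plausible_range": [1.0, 12.0],
        "loinc": ["2823-3", "6298-4"],
        "names": ["potassium"],
        "topographies": _BLOODY,
        "unit_conversions": {"meq/l": [1.0, 0.0]},
    },
    "chloride": {
        "kind": "lab", "canonical_unit": "mmol/L", "plausible_range": [60.0, 150.0],
        "loinc": ["2075-0"],
        "names": ["chloride"],
        "topographies": _BLOODY,
        "unit_conversions": {"meq/l": [1.0, 0.0]},
    },
    "bicarbonate": {
        "kind": "lab", "canonical_unit": "mmol/L", "plausible_range": [2.0, 60.0],
        "loinc": ["1963-8", "2028-9"],
        "names": ["bicarbonate", "co2", "carbon dioxide"],
        "topographies": _BLOODY,
        "unit_conversions": {"meq/l": [1.0, 0.0]},
    },
    "bun": {
        "kind": "lab", "canonical_unit": "mg/dL", "plausible_range": [1.0, 300.0],
        "loinc": ["3094-0"],
        "names": ["urea nitrogen", "bun"],
        "topographies": _BLOODY,
        "unit_conversions": {"mmol/l": [2.8011204, 0.0]},
    },
    "glucose": {
        "kind": "lab", "canonical_unit": "mg/dL", "plausible_range": [5.0, 2000.0],
        "loinc": ["2345-7", "2339-0"],
        "names": ["glucose"],
        "topographies": _BLOODY,
        "unit_conversions": {"mmol/l": [18.0182, 0.0]},
    },
    "albumin": {
        "kind": "lab", "canonical_unit": "g/dL", "plausible_range": [0.5, 8.0],
        "loinc": ["1751-7"],
        "names": ["albumin"],
        "topographies": _BLOODY,
        "unit_conversions": {"g/l": [0.1, 0.0]},
    },
    "lactate": {
        "kind": "lab", "canonical_unit": "mmol/L", "plausible_range": [0.1, 40.0],
        "loinc": ["2524-7", "2518-9", "2519-7"],
        "names": ["lactate", "lactic acid"],
        "topographies": _BLOODY,
        "unit_conversions": {"mg/dl": [0.111, 0.0]},
    },
    "ph": {
        "kind": "lab", "canonical_unit": "", "plausible_range": [6.5, 8.0],
        "loinc": ["2744-1", "2746-6"],
        "names": ["ph arterial", "arterial ph", "ph, art"],
        "topographies": ["arterial blood", "blood"],
        "unit_conversions": {},
    },
    "pao2": {
        "kind": "lab", "canonical_unit": "mmHg", "plausible_range": [10.0, 700.0],
        "loinc": ["2703-7"],
        "names": ["pao2", "po2 arterial", "o2 pressure"],
        "topographies": ["arterial blood", "blood"],
        "unit_conversions": {"kpa": [7.50062, 0.0]},
    },
}

_VITAL_TESTS = {
    "temperature": {
        "kind": "vital", "canonical_unit": "C", "plausible_range": [25.0, 45.0],
        "vital_types": ["temperature", "temp"],
        "unit_conversions": {"f": [5.0 / 9.0, -160.0 / 9.0]},
    },
    "heart_rate": {
        "kind": "vital", "canonical_unit": "bpm", "plausible_range": [10.0, 300.0],
        "vital_types": ["pulse", "heart rate", "hr"],
        "unit_conversions": {},
    },
    "respiratory_rate": {
        "kind": "vital", "canonical_unit": "breaths/min", "plausible_range": [2.0, 80.0],
        "vital_types": ["respiration", "respiratory rate", "rr"],
        "unit_conversions": {},
    },
    "sbp": {
        "kind": "vital", "canonical_unit": "mmHg", "plausible_range": [30.0, 300.0],
        "vital_types": ["sbp", "systolic"],
        "unit_conversions": {},
    },
    "dbp": {
        "kind": "vital", "canonical_unit": "mmHg", "plausible_range": [10.0, 200.0],
        "vital_types": ["dbp", "diastolic"],
        "unit_conversions": {},
    },
    "map": {
        "kind": "vital", "canonical_unit": "mmHg", "plausible_range": [10.0, 250.0],
        "vital_types": ["map", "mean arterial pressure"],
        "unit_conversions": {},
    },
}


def default_test_config() -> dict:
    tests = copy.deepcopy(_LAB_TESTS)
    tests.update(copy.deepcopy(_VITAL_TESTS))
    return {
        "tests": tests,
        # microbiology events are matched by name, kept out of numeric tests
        "blood_culture_patterns": ["blood culture", "blood cx"],
    }


LAB_TEST_IDS = tuple(sorted(_LAB_TESTS))
VITAL_TEST_IDS = tuple(sorted(_VITAL_TESTS))


# ---------------------------------------------------------------------------
# Drug lexicon
# ---------------------------------------------------------------------------

DRUG_CATEGORIES = ("antibiotic", "vasoactive", "sedative", "analgesic",
                   "paralytic", "other")

_LEXICON = {
    # vasoactive -- extended vasopressor list; sofa_tier feeds the
    # cardiovascular score when dose information is unavailable
    "norepinephrine": {"category": "vasoactive", "tokens": ["norepinephrine", "levophed"], "sofa_tier": 3},
    # not_tokens guard against substring capture (norepinephrine contains
    # "epinephrine")
    "epinephrine": {"category": "vasoactive", "tokens": ["epinephrine", "adrenalin"],
                    "not_tokens": ["norepinephrine"], "sofa_tier": 3},
    "dopamine": {"category": "vasoactive", "tokens": ["dopamine"], "sofa_tier": 3},
    "dobutamine": {"category": "vasoactive", "tokens": ["dobutamine"], "sofa_tier": 2},
    "vasopressin": {"category": "vasoactive", "tokens": ["vasopressin"], "sofa_tier": 3},
    "phenylephrine": {"category": "vasoactive", "tokens": ["phenylephrine", "neo-synephrine"], "sofa_tier": 3},
    "milrinone": {"category": "vasoactive", "tokens": ["milrinone"], "sofa_tier": 2},
    # antibiotics
    "vancomycin": {"category": "antibiotic", "tokens": ["vancomycin"], "abx_class": "glycopeptide"},
    "piperacillin-tazobactam": {"category": "antibiotic",
                                "tokens": ["piperacillin", "zosyn"],
                                "abx_class": "penicillin-combination"},
    "ceftriaxone": {"category": "antibiotic", "tokens": ["ceftriaxone"], "abx_class": "cephalosporin"},
    "cefepime": {"category": "antibiotic", "tokens": ["cefepime"], "abx_class": "cephalosporin"},
    "meropenem": {"category": "antibiotic", "tokens": ["meropenem"], "abx_class": "carbapenem"},
    "levofloxacin": {"category": "antibiotic", "tokens": ["levofloxacin"], "abx_class": "fluoroquinolone"},
    "ciprofloxacin": {"category": "antibiotic", "tokens": ["ciprofloxacin"], "abx_class": "fluoroquinolone"},
    "metronidazole": {"category": "antibiotic", "tokens": ["metronidazole", "flagyl"], "abx_class": "nitroimidazole"},
    "azithromycin": {"category": "antibiotic", "tokens": ["azithromycin"], "abx_class": "macrolide"},
    "mupirocin": {"category": "antibiotic", "tokens": ["mupirocin"], "abx_class": "topical-antibacterial"},
    "rifaximin": {"category": "other", "tokens": ["rifaximin"]},
    # sedatives / analgesics / paralytics
    "propofol": {"category": "sedative", "tokens": ["propofol", "diprivan"]},
    "midazolam": {"category": "sedative", "tokens": ["midazolam", "versed"]},
    "dexmedetomidine": {"category": "sedative", "tokens": ["dexmedetomidine", "precedex"]},
    "fentanyl": {"category": "analgesic", "tokens": ["fentanyl"]},
    "morphine": {"category": "analgesic", "tokens": ["morphine"]},
    "hydromorphone": {"category": "analgesic", "tokens": ["hydromorphone", "dilaudid"]},
    "cisatracurium": {"category": "paralytic", "tokens": ["cisatracurium", "nimbex"]},
    "rocuronium": {"category": "paralytic", "tokens": ["rocuronium"]},
}


def default_lexicon_config() -> dict:
    return {
        "drugs": copy.deepcopy(_LEXICON),
        # any of these substrings anywhere in a name field vetoes the record
        "exclusion_tokens": ["research", "study"],
        "routes": {
            "systemic-iv": ["iv", "ivpb", "intravenous", "iv push", "intraven"],
            "systemic-oral": ["po", "oral", "ng", "g-tube", "j-tube", "by mouth"],
            # everything else (topical, ophthalmic, inhaled, unknown...) is
            # classified non-systemic
        },
    }


# ---------------------------------------------------------------------------
# Organ-dysfunction (4-component) scoring thresholds
# ---------------------------------------------------------------------------
#
# Standard published cutoffs.  Coagulation counts how many descending
# platelet thresholds the daily low falls below; liver/renal count ascending
# thresholds the daily high meets or exceeds.  Cardiovascular combines the
# mean-arterial-pressure floor with vasopressor administration tiers
# (dose-free: each pressor carries a fixed tier from the lexicon).

def default_sofa_config() -> dict:
    return {
        "coagulation": {"input": "platelets_low", "below": [150.0, 100.0, 50.0, 20.0]},
        "liver": {"input": "bilirubin_high", "at_or_above": [1.2, 2.0, 6.0, 12.0]},
        "renal": {"input": "creatinine_high", "at_or_above": [1.2, 2.0, 3.5, 5.0]},
        "cardiovascular": {"map_input": "map_low", "map_threshold": 70.0},
    }


# ---------------------------------------------------------------------------
# Diagnosis / procedure code lists (prefix-matched on normalized codes)
# ---------------------------------------------------------------------------

def default_code_lists() -> dict:
    return {
        "angus": {
            "infection": {
                "icd9": ["001", "008", "038", "041", "481", "482", "486",
                         "510", "513", "540", "567", "5695", "590", "5990",
                         "680", "681", "682", "730", "7907"],
                "icd10": ["A02", "A04", "A40", "A41", "A49", "J13", "J14",
                          "J15", "J18", "J85", "J86", "K65", "K81", "L03",
                          "N10", "N390", "M86", "R7881"],
            },
            "organ_dysfunction": {
                "icd9": ["5184", "51881", "570", "5845", "5849", "5856",
                         "2862", "2866", "3481", "7803", "78551", "78559",
                         "7855"],
                "icd10": ["J80", "J960", "J9600", "K720", "N17", "D65",
                          "D688", "G9341", "R4020", "R578", "R579", "R570"],
            },
            "explicit": {
                "icd9": ["99592", "78552"],
                "icd10": ["R6520", "R6521"],
            },
        },
        "ventilation_procedures": {
            "icd9": ["9670", "9671", "9672"],
            "icd10": ["5A1935Z", "5A1945Z", "5A1955Z"],
        },
    }


# ---------------------------------------------------------------------------
# EHR-surveillance sepsis parameters
# ---------------------------------------------------------------------------

def default_ase_config() -> dict:
    return {
        "window_days": 2,            # +/- days around the blood-culture day
        "min_antibiotic_days": 4,    # consecutive systemic-antibiotic days
        "lactate_threshold": 2.0,
        "platelet_threshold": 100.0,
        "platelet_decline": 0.5,     # required fractional decline vs baseline
        "creatinine_doubling": 2.0,
        "bilirubin_doubling": 2.0,
        "bilirubin_floor": 2.0,
    }


# ---------------------------------------------------------------------------
# Risk-score components (components only; no composite is ever computed)
# ---------------------------------------------------------------------------
#
# The 30 comorbidity groups follow the widely used administrative-comorbidity
# taxonomy; the seeded prefixes cover common codes and are provisional -- each
# deployment must review and extend them.

_COMORBIDITIES = {
    "chf": {"icd9": ["428"], "icd10": ["I50"]},
    "arrhythmia": {"icd9": ["4273"], "icd10": ["I48"]},
    "valvular_disease": {"icd9": ["394", "395", "396", "424"], "icd10": ["I34", "I35", "I36"]},
    "pulm_circulation": {"icd9": ["4150", "4151", "416"], "icd10": ["I26", "I27"]},
    "pvd": {"icd9": ["440", "441"], "icd10": ["I70", "I71"]},
    "htn_uncomplicated": {"icd9": ["401"], "icd10": ["I10"]},
    "htn_complicated": {"icd9": ["402", "403", "404", "405"], "icd10": ["I11", "I12", "I13", "I15"]},
    "paralysis": {"icd9": ["342", "343", "344"], "icd10": ["G81", "G82", "G83"]},
    "neuro_other": {"icd9": ["330", "332", "333", "340", "345"], "icd10": ["G20", "G35", "G40"]},
    "chronic_pulmonary": {"icd9": ["490", "491", "492", "493", "494", "496"], "icd10": ["J40", "J41", "J42", "J43", "J44", "J45", "J47"]},
    "diabetes_uncomplicated": {"icd9": ["2500", "2501", "2502", "2503"], "icd10": ["E109", "E119"]},
    "diabetes_complicated": {"icd9": ["2504", "2505", "2506", "2507"], "icd10": ["E102", "E112", "E113", "E114", "E115"]},
    "hypothyroidism": {"icd9": ["243", "244"], "icd10": ["E00", "E01", "E02", "E03"]},
    "renal_failure": {"icd9": ["585", "586"], "icd10": ["N18", "N19"]},
    "liver_disease": {"icd9": ["570", "571", "572"], "icd10": ["K70", "K72", "K73", "K74", "K76"]},
    "peptic_ulcer": {"icd9": ["531", "532", "533", "534"], "icd10": ["K25", "K26", "K27", "K28"]},
    "aids": {"icd9": ["042"], "icd10": ["B20"]},
    "lymphoma": {"icd9": ["200", "201", "202"], "icd10": ["C81", "C82", "C83", "C84", "C85"]},
    "metastatic_cancer": {"icd9": ["196", "197", "198", "199"], "icd10": ["C77", "C78", "C79", "C80"]},
    "solid_tumor": {"icd9": ["14", "15", "16", "17", "18", "190", "191", "193"], "icd10": ["C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7"]},
    "rheumatic_disease": {"icd9": ["701", "710", "714", "720"], "icd10": ["M05", "M06", "M32", "M34"]},
    "coagulopathy": {"icd9": ["286", "2871", "2873"], "icd10": ["D65", "D66", "D67", "D68", "D69"]},
    "obesity": {"icd9": ["2780"], "icd10": ["E66"]},
    "weight_loss": {"icd9": ["260", "261", "262", "263"], "icd10": ["E40", "E41", "E43", "E44", "R64"]},
    "fluid_electrolyte": {"icd9": ["276"], "icd10": ["E86", "E87"]},
    "blood_loss_anemia": {"icd9": ["2800"], "icd10": ["D500"]},
    "deficiency_anemia": {"icd9": ["281", "2859"], "icd10": ["D51", "D52", "D53", "D649"]},
    "alcohol_abuse": {"icd9": ["2911", "303", "3050"], "icd10": ["F10"]},
    "drug_abuse": {"icd9": ["292", "304", "3052"], "icd10": ["F11", "F12", "F13", "F14", "F15", "F16"]},
    "psychoses": {"icd9": ["295", "297", "298"], "icd10": ["F20", "F22", "F23", "F25", "F28", "F29"]},
}

_DX_CATEGORIES = [
    # (category, icd9 prefixes, icd10 prefixes) -- first match wins
    ("infectious", ["00", "01", "02", "03", "04", "05", "06", "07", "1", "481", "482", "486", "599", "680", "681", "682"], ["A", "B", "J13", "J14", "J15", "J18", "N39", "L03"]),
    ("cardiovascular", ["39", "40", "41", "42", "43", "44", "45"], ["I"]),
    ("respiratory", ["46", "47", "48", "49", "50", "51"], ["J"]),
    ("gastrointestinal", ["52", "53", "54", "55", "56", "57"], ["K"]),
    ("renal", ["58", "59"], ["N"]),
    ("neurologic", ["32", "33", "34", "35", "36"], ["G"]),
]

# Admission labs carried as severity-score components (11 of the standard
# tests); provisional selection pending the fitted score's exact inputs.
_RISK_LABS = ["albumin", "bilirubin", "bun", "creatinine", "glucose",
              "hematocrit", "ph", "potassium", "sodium", "wbc", "pao2"]


def default_risk_config() -> dict:
    return {
        "comorbidities": copy.deepcopy(_COMORBIDITIES),
        "dx_categories": copy.deepcopy(_DX_CATEGORIES),
        "admission_labs": list(_RISK_LABS),
        "provisional": True,
    }


# ---------------------------------------------------------------------------
# Loading / merging
# ---------------------------------------------------------------------------

def _merge(base: Any, override: Any) -> Any:
    if isinstance(base, dict) and isinstance(override, dict):
        out = dict(base)
        for k, v in override.items():
            out[k] = _merge(base[k], v) if k in base else v
        return out
    return override


def load_yaml_config(path, defaults: dict | None = None) -> dict:
    """Read a YAML config file and merge it over ``defaults`` (deep merge)."""
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigError(f"config file {path!r} must contain a mapping")
    return _merge(defaults or {}, loaded)


def dump_yaml_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
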