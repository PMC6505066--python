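"""End-to-end orchestration: raw delimited tables in, patient-facility-day
dataset + hospitalization phenotypes + audit reports out.

Stage order: episode construction -> lab/vital harmonization -> medication
indicators -> daily organ scores and hospitalization phenotypes.  Every run
writes a manifest (config hash, per-stage row counts, rejection counts) and
is byte-identical given identical inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import config as cfg
from . import episodes, labs, meds, phenotypes
from .errors import ConfigError, StageError
from .synth import RawTables

logger = logging.getLogger(__name__)

DAY_KEY = ["patient_id", "facility_id", "date"]


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "out"
    gap_days: int = 1
    bedded_gap_hours: float = 0.0
    observation_end: str | None = None
    audit_seed: int = 0
    specialty: dict = field(default_factory=cfg.default_specialty_config)
    tests: dict = field(default_factory=cfg.default_test_config)
    lexicon: dict = field(default_factory=cfg.default_lexicon_config)
    sofa: dict = field(default_factory=cfg.default_sofa_config)
    code_lists: dict = field(default_factory=cfg.default_code_lists)
    ase: dict = field(default_factory=cfg.default_ase_config)
    risk: dict = field(default_factory=cfg.default_risk_config)

    def validate(self) -> None:
        if self.gap_days < 0 or self.bedded_gap_hours < 0:
            raise ConfigError("gap parameters must be non-negative")
        if not Path(self.input_dir).exists():
            raise ConfigError(f"input_dir {self.input_dir!r} does not exist")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("input_dir", None)   # hash the analytic config only,
        payload.pop("output_dir", None)  # not where it ran

        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        base = cls(**overrides)
        loaded = cfg.load_yaml_config(path, defaults={})
        for key, value in loaded.items():
            if not hasattr(base, key):
                raise ConfigError(f"unknown pipeline config key {key!r}")
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                setattr(base, key, cfg._merge(current, value))
            else:
                setattr(base, key, value)
        return base


def _read_csv(path: Path, columns=None) -> pd.DataFrame:
    if path.exists():
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return df
    return pd.DataFrame(columns=columns or [])


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            vals = out[col]
            if vals.notna().any() and (vals.dropna() == vals.dropna().dt.normalize()).all():
                out[col] = vals.dt.strftime("%Y-%m-%d")
            else:
                out[col] = vals.dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(pconfig: PipelineConfig) -> dict:
    """Execute all stages; write outputs and manifest; return every frame."""
    pconfig.validate()
    indir = Path(pconfig.input_dir)
    outdir = Path(pconfig.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": pconfig.config_hash()}

    # ---- episode construction --------------------------------------------
    stays_raw = _read_csv(indir / "specialty_transfers.csv", episodes.STAY_COLUMNS)
    manifest["in_specialty_transfers"] = len(stays_raw)
    try:
        if len(stays_raw):
            stays = episodes.prepare_stays(stays_raw, pconfig.specialty)
            bedded = episodes.build_bedded_stays(
                stays, bedded_gap=pd.Timedelta(hours=pconfig.bedded_gap_hours))
            sshs = episodes.build_single_site_hospitalizations(
                stays, gap_days=pconfig.gap_days, observation_end=pconfig.observation_end)
            sshs, hosps = episodes.link_acute_hospitalizations(sshs, gap_days=pconfig.gap_days)
            eps = episodes.build_episodes_of_care(bedded, gap_days=pconfig.gap_days)
            days = episodes.expand_patient_facility_days(sshs, stays)
        else:
            stays = stays_raw
            bedded = episodes.build_bedded_stays(stays_raw.assign(
                admit=pd.Series(dtype="datetime64[ns]"), discharge=pd.Series(dtype="datetime64[ns]"),
                acute=pd.Series(dtype=bool), icu=pd.Series(dtype=bool), stay_id=pd.Series(dtype=int)))
            sshs = episodes.build_single_site_hospitalizations(
                stays_raw.assign(acute=pd.Series(dtype=bool)))
            sshs, hosps = episodes.link_acute_hospitalizations(sshs)
            eps = episodes.build_episodes_of_care(bedded)
            days = episodes.expand_patient_facility_days(sshs, stays_raw.assign(
                icu=pd.Series(dtype=bool), admit=pd.Series(dtype="datetime64[ns]"),
                discharge=pd.Series(dtype="datetime64[ns]")))
    except ConfigError as err:
        raise StageError("episode_builder", str(err)) from err
    manifest.update(n_bedded_stays=len(bedded), n_ssh=len(sshs),
                    n_acute_hospitalizations=len(hosps), n_episodes=len(eps),
                    n_patient_facility_days=len(days))

    # ---- lab / vital harmonization ---------------------------------------
    labs_raw = _read_csv(indir / "labs.csv", labs.LAB_COLUMNS)
    vitals_raw = _read_csv(indir / "vitals.csv", labs.VITAL_COLUMNS)
    manifest["in_labs"] = len(labs_raw)
    manifest["in_vitals"] = len(vitals_raw)
    harmonized = labs.harmonize(labs_raw, vitals_raw, days, pconfig.tests)
    physiology = harmonized["physiology"]
    manifest.update(
        labs_unmatched=len(harmonized["lab_unmatched"]),
        labs_conflicts=len(harmonized["lab_conflicts"]),
        vitals_unmatched=len(harmonized["vital_unmatched"]),
        measurements_unconvertible=len(harmonized["unconvertible"]),
        measurements_out_of_range=int(harmonized["range_rejections"]["n_rejected"].sum())
        if len(harmonized["range_rejections"]) else 0,
        measurements_orphaned=len(harmonized["orphans"]),
        lab_name_rescues=harmonized["n_name_rescues"],
    )

    # ---- medications ------------------------------------------------------
    meds_raw = _read_csv(indir / "med_admins.csv", meds.MED_COLUMNS)
    manifest["in_med_admins"] = len(meds_raw)
    med_result = meds.daily_medication_indicators(meds_raw, days, pconfig.lexicon)
    indicators = med_result["indicators"]
    manifest.update(meds_vetoed=len(med_result["vetoed"]),
                    meds_orphaned=len(med_result["orphans"]))

    # ---- phenotypes -------------------------------------------------------
    codes_raw = _read_csv(indir / "codes.csv", phenotypes.CODE_COLUMNS)
    deaths_raw = _read_csv(indir / "deaths.csv", ["patient_id", "death_date"])
    patients_raw = _read_csv(indir / "patients.csv", ["patient_id", "age"])
    manifest["in_codes"] = len(codes_raw)

    scores = phenotypes.sofa_component_scores(
        physiology if len(physiology) else days[DAY_KEY].copy(),
        indicators, pconfig.sofa, pconfig.lexicon)
    failure_flags, failure_totals = phenotypes.organ_failure_days(scores)
    for comp, total in failure_totals.items():
        manifest[f"failure_days_{comp}"] = total

    ssh_codes = phenotypes.assign_codes_to_ssh(codes_raw, sshs)
    angus, bad_codes = phenotypes.angus_sepsis(ssh_codes, sshs, pconfig.code_lists)
    vent = phenotypes.detect_mechanical_ventilation(ssh_codes, sshs, pconfig.code_lists)
    ase = phenotypes.cdc_ase_sepsis(
        sshs, days, harmonized["blood_cultures"], indicators, physiology,
        vent, pconfig.ase,
        deaths=deaths_raw if len(deaths_raw) else None)
    outcomes, rejected_deaths = episodes.compute_outcomes(
        sshs, deaths_raw if len(deaths_raw) else None)
    manifest.update(codes_bad_version=len(bad_codes),
                    deaths_rejected=len(rejected_deaths),
                    n_angus_sepsis=int(angus["angus_sepsis"].sum()),
                    n_cdc_ase=int(ase["cdc_ase"].sum()),
                    n_ventilated=int(vent["mechanical_ventilation"].sum()))

    risk = phenotypes.assemble_risk_components(
        sshs, patients_raw, ssh_codes, physiology, pconfig.risk)

    # ---- assemble outputs -------------------------------------------------
    day_table = days.merge(physiology, on=DAY_KEY, how="left")
    day_table = day_table.merge(indicators, on=DAY_KEY, how="left")
    day_table = day_table.merge(scores, on=DAY_KEY, how="left")
    day_table = day_table.merge(failure_flags, on=DAY_KEY, how="left")
    day_table = day_table.sort_values(DAY_KEY, kind="mergesort").reset_index(drop=True)

    ssh_table = (sshs.merge(outcomes, on="ssh_id", how="left")
                 .sort_values("ssh_id", kind="mergesort").reset_index(drop=True))
    pheno_table = (angus.merge(ase, on="ssh_id").merge(vent, on="ssh_id")
                   .sort_values("ssh_id", kind="mergesort").reset_index(drop=True))

    _write_csv(day_table, outdir / "patient_facility_days.csv")
    _write_csv(ssh_table, outdir / "ssh.csv")
    _write_csv(pheno_table, outdir / "phenotypes.csv")
    _write_csv(hosps, outdir / "acute_hospitalizations.csv")
    _write_csv(eps, outdir / "episodes_of_care.csv")
    _write_csv(risk, outdir / "risk_components.csv")
    audit_dir = outdir / "audit"
    audit_dir.mkdir(exist_ok=True)
    _write_csv(harmonized["lab_unmatched"], audit_dir / "labs_unmatched.csv")
    _write_csv(harmonized["lab_conflicts"], audit_dir / "labs_conflicts.csv")
    _write_csv(harmonized["unconvertible"], audit_dir / "measurements_unconvertible.csv")
    _write_csv(harmonized["range_rejections"], audit_dir / "range_rejections.csv")
    _write_csv(harmonized["orphans"], audit_dir / "measurement_orphans.csv")
    _write_csv(med_result["vetoed"], audit_dir / "meds_vetoed.csv")
    _write_csv(med_result["orphans"], audit_dir / "med_orphans.csv")
    _write_csv(rejected_deaths, audit_dir / "deaths_rejected.csv")
    _write_csv(bad_codes, audit_dir / "codes_bad_version.csv")

    with open(outdir / "manifest.txt", "w", encoding="utf-8") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}={manifest[key]}\n")

    return {
        "manifest": manifest, "stays": stays, "bedded": bedded, "sshs": ssh_table,
        "hospitalizations": hosps, "episodes": eps, "days": day_table,
        "physiology": physiology, "indicators": indicators, "scores": scores,
        "failure_flags": failure_flags, "phenotypes": pheno_table,
        "outcomes": outcomes, "risk": risk, "harmonized": harmonized,
        "med_result": med_result,
    }


def run_pipeline_on_tables(tables: RawTables, output_dir, **kwargs) -> dict:
    """Convenience: write a RawTables bundle to disk and run the pipeline."""
    outdir = Path(output_dir)
    raw_dir = outdir / "raw"
    tables.to_dir(raw_dir)
    pconfig = PipelineConfig(input_dir=str(raw_dir), output_dir=str(outdir / "build"), **kwargs)
    return run_pipeline(pconfig)
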