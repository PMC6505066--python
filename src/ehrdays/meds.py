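"""Barcode medication administration records -> per-day drug indicators.

Drug names are hand-typed in the source tables (case noise, appended dosage
strings), so identification is a case-insensitive token search across every
name field, with a global veto: any record whose name fields contain an
exclusion token ("research", "study" by default) contributes to nothing,
regardless of what else it matches.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MED_COLUMNS = ["patient_id", "facility_id", "drug_name_local", "drug_name_national",
               "drug_class", "dosage", "route", "given_at"]

NAME_FIELDS = ["drug_name_local", "drug_name_national"]


def _combined_names(records: pd.DataFrame) -> pd.Series:
    parts = [records.get(f, pd.Series([""] * len(records))).fillna("").astype(str)
             for f in NAME_FIELDS]
    out = parts[0]
    for p in parts[1:]:
        out = out + " | " + p
    return out.str.lower()


def match_drug(record, lexicon_config: dict) -> set[str]:
    """Return the set of canonical drug names matched by one record.

    ``record`` is a mapping with the name fields.  An exclusion token
    anywhere in any name field vetoes the record entirely (empty set).
    """
    text = " | ".join(str(record.get(f) or "") for f in NAME_FIELDS).lower()
    for tok in lexicon_config["exclusion_tokens"]:
        if tok.lower() in text:
            return set()
    hits = set()
    for drug, spec in lexicon_config["drugs"].items():
        if any(tok.lower() in text for tok in spec.get("not_tokens", [])):
            continue
        if any(tok.lower() in text for tok in spec["tokens"]):
            hits.add(drug)
    return hits


def match_drug_records(records: pd.DataFrame, lexicon_config: dict
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized matching over a table.

    Returns ``(matches, vetoed)``: ``matches`` is long-form with one row per
    (record, drug) hit plus the record's route group; ``vetoed`` holds the
    excluded records for audit.
    """
    records = records.reset_index(drop=True)
    text = _combined_names(records)
    veto = np.zeros(len(records), bool)
    for tok in lexicon_config["exclusion_tokens"]:
        veto |= text.str.contains(tok.lower(), regex=False).to_numpy()
    vetoed = records.loc[veto].copy()
    if len(vetoed):
        logger.info("%d medication records vetoed by exclusion tokens", len(vetoed))

    rows = []
    live = text[~veto]
    for drug, spec in sorted(lexicon_config["drugs"].items()):
        mask = np.zeros(len(live), bool)
        for tok in spec["tokens"]:
            mask |= live.str.contains(tok.lower(), regex=False).to_numpy()
        for tok in spec.get("not_tokens", []):
            mask &= ~live.str.contains(tok.lower(), regex=False).to_numpy()
        for idx in live.index[mask]:
            rows.append((idx, drug))
    if rows:
        matches = pd.DataFrame(rows, columns=["_row", "drug"])
        matches = matches.join(records, on="_row").drop(columns="_row")
    else:
        matches = records.head(0).assign(drug=pd.Series(dtype=str))
    matches["category"] = matches["drug"].map(
        lambda d: lexicon_config["drugs"][d]["category"])
    routes = matches["route"] if "route" in matches.columns else pd.Series([""] * len(matches))
    matches["route_group"] = [route_group(r, lexicon_config) for r in routes]
    return matches.reset_index(drop=True), vetoed


def route_group(route, lexicon_config: dict) -> str:
    """Map a free-text route to systemic-iv / systemic-oral / non-systemic.

    Unknown routes are conservatively non-systemic (logged).
    """
    r = str(route or "").strip().lower()
    routes = lexicon_config.get("routes", {})
    for group in ("systemic-iv", "systemic-oral"):
        for tok in routes.get(group, []):
            if r == tok or r.startswith(tok + " "):
                return group
    if r and not any(r == t for toks in routes.values() for t in toks):
        logger.debug("route %r classified non-systemic", route)
    return "non-systemic"


def classify_antibiotic(drug: str, route, lexicon_config: dict) -> tuple[str, str]:
    """(antibiotic class, route group) for an antibiotic-category drug."""
    spec = lexicon_config["drugs"][drug]
    if spec["category"] != "antibiotic":
        raise ValueError(f"{drug!r} is not categorized as an antibiotic")
    return spec.get("abx_class", "unclassified"), route_group(route, lexicon_config)


def daily_medication_indicators(records: pd.DataFrame, days: pd.DataFrame,
                                lexicon_config: dict) -> dict:
    """Per patient-facility-day boolean indicators for every lexicon drug.

    Also emits derived columns used downstream: ``any_vasopressor`` and
    ``abx_systemic`` (an antibiotic given by a systemic route that day).
    Administrations on days without a patient-facility-day row are reported
    as orphans; vetoed records are reported, never counted.
    """
    key = ["patient_id", "facility_id", "date"]
    drug_names = sorted(lexicon_config["drugs"])
    matches, vetoed = match_drug_records(records, lexicon_config)

    base = days[key].drop_duplicates().sort_values(key, kind="mergesort").reset_index(drop=True)
    for d in drug_names:
        base[f"rx_{d}"] = False
    base["any_vasopressor"] = False
    base["abx_systemic"] = False

    if matches.empty:
        return {"indicators": base, "vetoed": vetoed,
                "orphans": records.head(0), "matches": matches}

    matches = matches.copy()
    matches["date"] = pd.to_datetime(matches["given_at"]).dt.normalize()
    known = base[key].assign(_known=True)
    matches = matches.merge(known, on=key, how="left")
    orphan_rows = matches.loc[matches["_known"].isna()]
    orphans = orphan_rows.drop(columns=["_known"]).drop_duplicates(
        subset=[c for c in records.columns] + ["drug"])
    matches = matches.loc[matches["_known"].notna()].drop(columns="_known")

    idx = base.set_index(key).index
    for d in drug_names:
        hit = matches.loc[matches["drug"] == d, key].drop_duplicates()
        if hit.empty:
            continue
        mask = idx.isin(pd.MultiIndex.from_frame(hit))
        base.loc[mask, f"rx_{d}"] = True
    vaso = matches.loc[matches["category"] == "vasoactive", key].drop_duplicates()
    if len(vaso):
        base.loc[idx.isin(pd.MultiIndex.from_frame(vaso)), "any_vasopressor"] = True
    abx = matches.loc[(matches["category"] == "antibiotic")
                      & (matches["route_group"].isin(["systemic-iv", "systemic-oral"])),
                      key].drop_duplicates()
    if len(abx):
        base.loc[idx.isin(pd.MultiIndex.from_frame(abx)), "abx_systemic"] = True

    return {"indicators": base, "vetoed": vetoed, "orphans": orphans, "matches": matches}
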