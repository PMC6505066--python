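"""Independent brute-force oracles used by the tests.

These deliberately avoid the production code paths: grouping is done by
O(n^2) transitive closure over a pairwise contiguity predicate, and scores
by explicit if/else ladders, so agreement with the vectorized/sweep
implementations is a real check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def closure_partition(intervals: list[tuple], gap) -> list[frozenset]:
    """Connected components of the graph where intervals i, j are linked iff
    neither starts more than ``gap`` after the other ends.  Intervals are
    ``(id, start, end)``; ``end`` may be None (open)."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            _, si, ei = intervals[i]
            _, sj, ej = intervals[j]
            i_then_j = ei is None or sj <= ei + gap
            j_then_i = ej is None or si <= ej + gap
            if i_then_j and j_then_i:
                adj[i][j] = True
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(m for m in range(n) if adj[k][m] and m not in comp)
        seen |= comp
        components.append(frozenset(intervals[k][0] for k in comp))
    return components


def partition_from_groups(df: pd.DataFrame, id_list_col: str) -> set[frozenset]:
    """Turn a grouped table with a ';'-joined id column into a partition."""
    return {frozenset(s.split(";")) for s in df[id_list_col]}


def oracle_bedded_partition(stays: pd.DataFrame, gap=pd.Timedelta(0)) -> set[frozenset]:
    parts = set()
    for (_, _), grp in stays.groupby(["patient_id", "facility_id"]):
        intervals = [(str(r.stay_id), r.admit, None if pd.isna(r.discharge) else r.discharge)
                     for r in grp.itertuples(index=False)]
        parts |= set(closure_partition(intervals, gap))
    return parts


def oracle_ssh_partition(stays: pd.DataFrame, gap_days=1) -> set[frozenset]:
    acute = stays.loc[stays["acute"]]
    parts = set()
    for (_, _), grp in acute.groupby(["patient_id", "facility_id"]):
        intervals = [(str(r.stay_id), r.admit.normalize(),
                      None if pd.isna(r.discharge) else r.discharge.normalize())
                     for r in grp.itertuples(index=False)]
        parts |= set(closure_partition(intervals, pd.Timedelta(days=gap_days)))
    return parts


def oracle_chain_partition(units: pd.DataFrame, id_col: str, start_col: str,
                           end_col: str, gap_days=1) -> set[frozenset]:
    parts = set()
    for _, grp in units.groupby("patient_id"):
        intervals = [(getattr(r, id_col),
                      getattr(r, start_col),
                      None if pd.isna(getattr(r, end_col)) else getattr(r, end_col))
                     for r in grp.itertuples(index=False)]
        parts |= set(closure_partition(intervals, pd.Timedelta(days=gap_days)))
    return parts


def random_stay_table(rng: np.random.Generator, max_stays: int = 50) -> pd.DataFrame:
    """A random specialty-stay table over a few patients and facilities."""
    n = int(rng.integers(1, max_stays + 1))
    base = pd.Timestamp("2015-01-01")
    rows = []
    for _ in range(n):
        admit = (base + pd.Timedelta(days=int(rng.integers(0, 40)),
                                     hours=int(rng.integers(0, 24))))
        discharge = admit + pd.Timedelta(days=int(rng.integers(0, 8)),
                                         hours=int(rng.integers(0, 24)))
        rows.append({
            "patient_id": f"P{int(rng.integers(1, 4))}",
            "facility_id": f"F{int(rng.integers(1, 3))}",
            "specialty_code": str(rng.choice(["MICU", "WARD", "SURG", "CLC", "REHAB"])),
            "admit": admit,
            "discharge": discharge,
        })
    return pd.DataFrame(rows)


# explicit if/else ladders for the four component scores (standard cutoffs)

def coag_score(platelet_low):
    if platelet_low is None:
        return None
    if platelet_low < 20:
        return 4
    if platelet_low < 50:
        return 3
    if platelet_low < 100:
        return 2
    if platelet_low < 150:
        return 1
    return 0


def liver_score(bilirubin_high):
    if bilirubin_high is None:
        return None
    if bilirubin_high >= 12.0:
        return 4
    if bilirubin_high >= 6.0:
        return 3
    if bilirubin_high >= 2.0:
        return 2
    if bilirubin_high >= 1.2:
        return 1
    return 0


def renal_score(creatinine_high):
    if creatinine_high is None:
        return None
    if creatinine_high >= 5.0:
        return 4
    if creatinine_high >= 3.5:
        return 3
    if creatinine_high >= 2.0:
        return 2
    if creatinine_high >= 1.2:
        return 1
    return 0


def cardio_score(map_low, pressor_tiers=()):
    pressor = max(pressor_tiers) if pressor_tiers else 0
    if map_low is None:
        return pressor if pressor else None
    base = 0 if map_low >= 70 else 1
    return max(base, pressor)
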