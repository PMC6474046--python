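"""Virtual rostering and cohort eligibility rules.

Patients are attributed each fiscal year to the physician who billed the
largest dollar amount of primary-care services for them over the two-year
window {year - 1, year} ("virtual" attribution).  Physician-years are kept
only when the physician provided comprehensive care (billed at least 8 of
the 18 core service categories), had at least 100 attributed patients, and
had no prolonged absence; physicians need at least 4 eligible pre-transition
years and 2 eligible post-transition years, and follow-up is censored once
they leave the enhanced fee-for-service model.  Patients must hold valid
coverage, be alive at fiscal year end, be attributed to an in-study
physician, and have at least one primary-care visit to that physician within
the two-year window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    COMPREHENSIVE_MIN_CORE,
    CORE_CATEGORIES,
    MIN_PANEL_SIZE,
)
from .simclaims import parse_absences

ROSTER_COLUMNS = [
    "patient_id", "fiscal_year", "physician_id", "attribution_fee_total",
    "tie_broken",
]


def attribute_patients(claims: pd.DataFrame, fiscal_year: int) -> pd.DataFrame:
    """Attribute each patient with primary-care fees in {year-1, year}.

    The physician with the largest summed primary-care fees over the window
    wins; fee ties go to the physician with more primary-care visits in the
    window, and any remaining tie to the smallest physician_id.  Patients
    with no primary-care fees in the window are unassigned (absent from the
    output).
    """
    years = claims["fiscal_year"]
    if not (years == fiscal_year - 1).any():
        raise ValueError(
            f"attribution window incomputable: no claims for fiscal year "
            f"{fiscal_year - 1}"
        )
    window = claims[
        claims["is_primary_care_visit"]
        & years.isin((fiscal_year - 1, fiscal_year))
    ]
    if window.empty:
        return pd.DataFrame(columns=ROSTER_COLUMNS)

    totals = (
        window.groupby(["patient_id", "physician_id"], sort=False)
        .agg(fee=("fee", "sum"), visits=("fee", "size"))
        .reset_index()
    )
    ranked = totals.sort_values(
        ["patient_id", "fee", "visits", "physician_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    top = ranked.drop_duplicates("patient_id", keep="first")
    # a tie was broken iff the runner-up fee equals the winning fee
    max_fee = totals.groupby("patient_id")["fee"].transform("max")
    n_at_max = (
        totals.assign(at_max=totals["fee"] == max_fee)
        .groupby("patient_id")["at_max"].sum()
    )
    tie = top["patient_id"].map(n_at_max > 1)

    return pd.DataFrame({
        "patient_id": top["patient_id"].to_numpy(),
        "fiscal_year": fiscal_year,
        "physician_id": top["physician_id"].to_numpy(),
        "attribution_fee_total": top["fee"].to_numpy(),
        "tie_broken": tie.to_numpy(),
    }).reset_index(drop=True)


def physician_year_status(
    claims: pd.DataFrame,
    assignments: pd.DataFrame,
    physicians: pd.DataFrame,
    fiscal_year: int,
    core_categories: tuple[str, ...] = CORE_CATEGORIES,
) -> pd.DataFrame:
    """Comprehensiveness, panel size, absence and model state per physician.

    ``comprehensive`` requires >= 8 distinct core service categories billed in
    the fiscal year; ``panel_size`` counts patients attributed that year; a
    physician is in study only if comprehensive, panel >= 100 ("fewer than
    100" excludes 99 and keeps 100), not absent, and not censored.
    """
    known = set(physicians["physician_id"])
    year_claims = claims[claims["fiscal_year"] == fiscal_year]
    unknown = set(year_claims["physician_id"]) - known
    if unknown:
        raise ValueError(
            f"claims reference unknown physician ids: {sorted(unknown)[:5]}"
        )

    core = year_claims[year_claims["service_category"].isin(core_categories)]
    n_core = core.groupby("physician_id")["service_category"].nunique()
    panel = assignments[assignments["fiscal_year"] == fiscal_year] \
        .groupby("physician_id").size()

    out = physicians[["physician_id", "transition_year", "exit_year"]].copy()
    out["fiscal_year"] = fiscal_year
    out["n_core_categories"] = (
        out["physician_id"].map(n_core).fillna(0).astype(int)
    )
    out["comprehensive"] = out["n_core_categories"] >= COMPREHENSIVE_MIN_CORE
    out["panel_size"] = out["physician_id"].map(panel).fillna(0).astype(int)
    out["absent"] = [
        fiscal_year in parse_absences(a) for a in physicians["absence_years"]
    ]
    exited = out["exit_year"].notna() & (fiscal_year >= out["exit_year"])
    out["model_state"] = np.where(
        exited, "censored",
        np.where(fiscal_year >= out["transition_year"], "eFFS", "tFFS"),
    )
    out["in_study"] = (
        out["comprehensive"]
        & (out["panel_size"] >= MIN_PANEL_SIZE)
        & ~out["absent"]
        & (out["model_state"] != "censored")
    )
    return out.drop(columns=["transition_year", "exit_year"])


def censor_followup(
    physicians: pd.DataFrame,
    statuses: pd.DataFrame,
    study_window: tuple[int, int],
    min_pre: int = 4,
    min_post: int = 2,
) -> pd.DataFrame:
    """Apply the pre/post follow-up requirements and exit censoring.

    Only in-study years count toward the requirements (a year failing the
    comprehensiveness, panel or absence rules does not).  Years at or after
    the exit year are already censored via ``model_state`` in the statuses.
    Returns one row per physician with ``retained`` plus the counted years.
    """
    start, end = study_window
    st = statuses[
        (statuses["fiscal_year"] >= start) & (statuses["fiscal_year"] <= end)
    ].merge(
        physicians[["physician_id", "transition_year"]], on="physician_id"
    )
    st = st[st["in_study"]]
    pre = st[st["fiscal_year"] < st["transition_year"]] \
        .groupby("physician_id").size()
    post = st[st["fiscal_year"] >= st["transition_year"]] \
        .groupby("physician_id").size()
    first = st.groupby("physician_id")["fiscal_year"].min()
    last = st.groupby("physician_id")["fiscal_year"].max()

    out = physicians[["physician_id", "transition_year", "exit_year"]].copy()
    out["n_pre"] = out["physician_id"].map(pre).fillna(0).astype(int)
    out["n_post"] = out["physician_id"].map(post).fillna(0).astype(int)
    out["first_year"] = out["physician_id"].map(first)
    out["last_year"] = out["physician_id"].map(last)
    out["retained"] = (out["n_pre"] >= min_pre) & (out["n_post"] >= min_post)
    return out


def filter_patients(
    claims: pd.DataFrame,
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    fiscal_year: int,
    in_study_physicians: set | pd.Index,
) -> pd.DataFrame:
    """Patient eligibility for one fiscal year.

    Returns a DataFrame with ``patient_id`` and ``exclusion_reason`` (NaN for
    eligible patients).  Reasons are applied in order: invalid coverage, not
    alive at fiscal year end, not attributed / attributed to a non-study
    physician, and no primary-care visit to the attributed physician during
    the year of interest or the year prior.
    """
    roster = assignments[assignments["fiscal_year"] == fiscal_year]
    merged = patients[["patient_id", "coverage_valid", "death_year"]].merge(
        roster[["patient_id", "physician_id"]], on="patient_id", how="left"
    )

    window = claims[
        claims["is_primary_care_visit"]
        & claims["fiscal_year"].isin((fiscal_year - 1, fiscal_year))
    ]
    visited = set(map(tuple, window[["patient_id", "physician_id"]]
                      .drop_duplicates().itertuples(index=False)))
    has_visit = [
        (pid, doc) in visited
        for pid, doc in zip(merged["patient_id"], merged["physician_id"])
    ]

    in_study = set(in_study_physicians)
    reason = np.full(len(merged), None, dtype=object)
    alive = merged["death_year"].isna() | (merged["death_year"] > fiscal_year)
    attributed = merged["physician_id"].notna()
    study_doc = merged["physician_id"].isin(in_study)

    reason[~np.asarray(has_visit)] = "no_visit_to_attributed_2yr"
    reason[~study_doc.to_numpy()] = "physician_not_in_study"
    reason[~attributed.to_numpy()] = "unattributed"
    reason[~alive.to_numpy()] = "dead"
    reason[~merged["coverage_valid"].to_numpy()] = "invalid_coverage"

    return pd.DataFrame({
        "patient_id": merged["patient_id"].to_numpy(),
        "physician_id": merged["physician_id"].to_numpy(),
        "exclusion_reason": reason,
    })
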