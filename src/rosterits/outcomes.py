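"""Study outcomes: UPC, group-level UPC, referral index, FPSC indicator.

UPC (usual provider of care) is the percentage of a patient's primary-care
visits over {year - 1, year} made to the attributed physician; patients with
fewer than 3 visits in the window are excluded (their UPC is missing).  The
group-level UPC counts visits to any member of the attributed physician's
practice group in the numerator.  The referral index (RI) is the percentage
of all non-radiology specialist referrals for a physician's rostered
patients in a fiscal year that were made by that physician.  FPSC is a per
patient-year binary indicator of at least one family-practice-sensitive
emergency-department visit, defined only within the ED window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    AGE_BAND_BINS,
    AGE_BAND_LABELS,
    PANEL_SIZE_BINS,
    PANEL_SIZE_LABELS,
    RunConfig,
    is_early_adopter,
)

logger = logging.getLogger(__name__)


def _window_visits(claims: pd.DataFrame, fiscal_year: int) -> pd.DataFrame:
    return claims[
        claims["is_primary_care_visit"]
        & claims["fiscal_year"].isin((fiscal_year - 1, fiscal_year))
    ]


def compute_upc(
    claims: pd.DataFrame,
    assignments: pd.DataFrame,
    fiscal_year: int,
    min_visits: int = 3,
) -> pd.DataFrame:
    """Provider-level UPC per attributed patient for one fiscal year.

    Returns patient_id, upc (percent, NaN when the patient has fewer than
    ``min_visits`` window visits), n_visits and upc_eligible.
    """
    roster = assignments[assignments["fiscal_year"] == fiscal_year]
    window = _window_visits(claims, fiscal_year)
    merged = window.merge(
        roster[["patient_id", "physician_id"]].rename(
            columns={"physician_id": "attributed_id"}),
        on="patient_id",
    )
    total = merged.groupby("patient_id", sort=True).size()
    match = merged["physician_id"] == merged["attributed_id"]
    to_main = match.groupby(merged["patient_id"]).sum()

    out = pd.DataFrame({
        "patient_id": total.index,
        "n_visits": total.to_numpy(),
        "upc": 100.0 * to_main.reindex(total.index).to_numpy()
        / total.to_numpy(),
    })
    out["upc_eligible"] = out["n_visits"] >= min_visits
    out.loc[~out["upc_eligible"], "upc"] = np.nan
    return out.reset_index(drop=True)


def compute_group_upc(
    claims: pd.DataFrame,
    assignments: pd.DataFrame,
    physicians: pd.DataFrame,
    fiscal_year: int,
    min_visits: int = 3,
) -> pd.DataFrame:
    """Group-level UPC: numerator counts visits to any group colleague.

    Practice groups exist only from the transition year onward; patients
    whose attributed physician has not yet transitioned get a missing value
    (with a logged reason), as do patients under the window visit minimum.
    """
    roster = assignments[assignments["fiscal_year"] == fiscal_year]
    phys = physicians.set_index("physician_id")
    attributed = roster[["patient_id", "physician_id"]].rename(
        columns={"physician_id": "attributed_id"})
    attributed = attributed.assign(
        group_id=phys["group_id"].reindex(attributed["attributed_id"]).to_numpy(),
        transitioned=(
            fiscal_year
            >= phys["transition_year"].reindex(attributed["attributed_id"]).to_numpy()
        ),
    )

    window = _window_visits(claims, fiscal_year)
    merged = window.merge(attributed, on="patient_id")
    merged["visit_group"] = phys["group_id"].reindex(
        merged["physician_id"]).to_numpy()
    grp_total = merged.groupby("patient_id").size()
    in_group = (merged["visit_group"] == merged["group_id"]) \
        & merged["transitioned"]
    grp_num = in_group.groupby(merged["patient_id"]).sum()

    out = pd.DataFrame({
        "patient_id": grp_total.index,
        "n_visits": grp_total.to_numpy(),
        "group_upc": 100.0 * grp_num.reindex(grp_total.index).to_numpy()
        / grp_total.to_numpy(),
    })
    pre = ~attributed.set_index("patient_id")["transitioned"] \
        .reindex(out["patient_id"]).fillna(False).to_numpy()
    if pre.any():
        logger.info(
            "group UPC undefined for %d patients attributed to "
            "not-yet-transitioned physicians in %d", int(pre.sum()), fiscal_year,
        )
    out.loc[pre | (out["n_visits"] < min_visits), "group_upc"] = np.nan
    return out.reset_index(drop=True)


def compute_ri(
    referrals: pd.DataFrame,
    assignments: pd.DataFrame,
    fiscal_year: int,
) -> pd.DataFrame:
    """Referral index per physician for one fiscal year.

    Referrals are pooled over the physician's rostered patients (the measure
    is referral-weighted, not a mean of per-patient percentages); diagnostic
    radiology referrals are excluded.  Physicians with no qualifying
    referrals get a missing RI.
    """
    roster = assignments[assignments["fiscal_year"] == fiscal_year]
    refs = referrals[
        (referrals["fiscal_year"] == fiscal_year)
        & ~referrals["is_diagnostic_radiology"]
    ]
    merged = refs.merge(
        roster[["patient_id", "physician_id"]].rename(
            columns={"physician_id": "attributed_id"}),
        on="patient_id",
    )
    total = merged.groupby("attributed_id").size()
    by_main = (
        (merged["referring_physician_id"] == merged["attributed_id"])
        .groupby(merged["attributed_id"]).sum()
    )
    out = pd.DataFrame({
        "physician_id": total.index,
        "n_referrals": total.to_numpy(),
        "ri": 100.0 * by_main.reindex(total.index).to_numpy()
        / total.to_numpy(),
    })
    return out.reset_index(drop=True)


def compute_fpsc(
    ed: pd.DataFrame,
    patients: pd.DataFrame,
    fiscal_year: int,
    ed_window: tuple[int, int],
) -> pd.DataFrame:
    """Dichotomous FPSC outcome per patient; missing outside the ED window."""
    out = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy()})
    lo, hi = ed_window
    if not lo <= fiscal_year <= hi:
        out["fpsc"] = np.nan
        return out
    events = ed[(ed["fiscal_year"] == fiscal_year) & ed["is_fpsc"]]
    hit = set(events["patient_id"])
    out["fpsc"] = out["patient_id"].isin(hit).astype(float)
    return out


# ---------------------------------------------------------------------------
# analysis-table assembly


def panel_size_category(panel_size) -> pd.Categorical:
    """Panel-size strata used as an adjustment covariate."""
    edges = list(PANEL_SIZE_BINS) + [np.inf]
    return pd.cut(panel_size, bins=edges, labels=PANEL_SIZE_LABELS,
                  right=False, include_lowest=True)


def age_band(age) -> pd.Categorical:
    edges = list(AGE_BAND_BINS) + [np.inf]
    return pd.cut(age, bins=edges, labels=AGE_BAND_LABELS, right=False,
                  include_lowest=True)


def _segment_columns(df: pd.DataFrame, study_start: int) -> pd.DataFrame:
    """time / post / tst / early_adopter from fiscal and transition years.

    The transition fiscal year itself is coded as the last pre-period
    observation (post = 0, tst = 0): outcomes are measured over two-year
    windows, so the transition-year observation straddles the switch, and
    the post segment should contain only fully post-transition windows.
    ``tst`` counts years since the transition year, so the first post row
    (the year after transition) has post = 1, tst = 1.
    """
    df = df.copy()
    df["time"] = (df["fiscal_year"] - study_start).astype(float)
    df["post"] = (df["fiscal_year"] > df["transition_year"]).astype(float)
    df["tst"] = np.where(
        df["post"] > 0,
        (df["fiscal_year"] - df["transition_year"]).astype(float), 0.0)
    df["early_adopter"] = is_early_adopter(df["transition_year"]).astype(float)
    return df


def assemble_tables(
    data,
    rosters: dict[int, pd.DataFrame],
    statuses: pd.DataFrame,
    retention: pd.DataFrame,
    config: RunConfig,
    eligibility: dict[int, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the patient-year and physician-year analysis tables.

    One row per eligible patient-year (UPC, FPSC, covariates, segment terms)
    and per eligible physician-year (RI, panel size, covariates, segment
    terms).  ``rosters`` maps fiscal year to the attribution table;
    ``eligibility`` optionally maps fiscal year to the ``filter_patients``
    output (it is computed here when absent).
    """
    from .cohort import filter_patients  # local import to avoid a cycle

    phys = data.physicians.set_index("physician_id")
    retained = set(retention.loc[retention["retained"], "physician_id"])

    pat_cov = data.patients.set_index("patient_id")
    patient_rows = []
    physician_rows = []
    for year in range(config.study_start, config.study_end + 1):
        roster = rosters[year]
        status_year = statuses[statuses["fiscal_year"] == year]
        eligible_phys = {
            p for p in status_year.loc[status_year["in_study"], "physician_id"]
            if p in retained
        }
        if eligibility is not None and year in eligibility:
            flt = eligibility[year]
        else:
            flt = filter_patients(data.claims, roster, data.patients, year,
                                  eligible_phys)
        keep = flt[flt["exclusion_reason"].isna()]

        upc = compute_upc(data.claims, roster, year, config.upc_min_visits)
        fpsc = compute_fpsc(data.ed, data.patients, year,
                            (config.ed_start, config.ed_end))
        rows = keep[["patient_id", "physician_id"]].merge(
            upc, on="patient_id", how="left"
        ).merge(fpsc, on="patient_id", how="left")
        rows = rows[rows["physician_id"].isin(eligible_phys)]
        rows["fiscal_year"] = year
        rows["transition_year"] = phys["transition_year"] \
            .reindex(rows["physician_id"]).to_numpy()
        cov = pat_cov.reindex(rows["patient_id"])
        rows["age"] = year - cov["birth_year"].to_numpy()
        rows["sex"] = cov["sex"].to_numpy()
        rows["income_quintile"] = cov["income_quintile"].to_numpy()
        rows["rurality"] = cov["rurality"].to_numpy()
        rows["morbidity_band"] = cov["morbidity_band"].to_numpy()
        rows["phys_sex"] = phys["sex"].reindex(rows["physician_id"]).to_numpy()
        rows["foreign_trained"] = phys["foreign_trained"] \
            .reindex(rows["physician_id"]).to_numpy()
        rows["years_since_grad"] = (
            rows["transition_year"]
            - phys["graduation_year"].reindex(rows["physician_id"]).to_numpy()
        )
        panel_map = status_year.set_index("physician_id")["panel_size"]
        rows["panel_size"] = panel_map.reindex(rows["physician_id"]).to_numpy()
        patient_rows.append(rows)

        # physician-year rows
        ri = compute_ri(data.referrals, roster, year)
        prow = status_year[status_year["physician_id"].isin(eligible_phys)][
            ["physician_id", "panel_size"]
        ].merge(ri, on="physician_id", how="left")
        prow["fiscal_year"] = year
        prow["transition_year"] = phys["transition_year"] \
            .reindex(prow["physician_id"]).to_numpy()
        prow["phys_sex"] = phys["sex"].reindex(prow["physician_id"]).to_numpy()
        prow["foreign_trained"] = phys["foreign_trained"] \
            .reindex(prow["physician_id"]).to_numpy()
        prow["years_since_grad"] = (
            prow["transition_year"]
            - phys["graduation_year"].reindex(prow["physician_id"]).to_numpy()
        )
        physician_rows.append(prow)

    patient_year = pd.concat(patient_rows, ignore_index=True)
    missing = patient_year["transition_year"].isna()
    if missing.any():
        bad = patient_year.loc[missing, "physician_id"].unique()
        raise ValueError(
            f"patient-year rows reference unknown physicians: {bad[:5]}"
        )
    patient_year = _segment_columns(patient_year, config.study_start)
    patient_year["age_band"] = age_band(patient_year["age"])
    patient_year["panel_category"] = panel_size_category(
        patient_year["panel_size"])

    physician_year = pd.concat(physician_rows, ignore_index=True)
    physician_year = _segment_columns(physician_year, config.study_start)
    physician_year["panel_category"] = panel_size_category(
        physician_year["panel_size"])
    physician_year["n_referrals"] = (
        physician_year["n_referrals"].fillna(0).astype(int))
    return patient_year, physician_year
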