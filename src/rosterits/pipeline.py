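"""End-to-end orchestration: simulate → cohort → outcomes → fit → report.

``run_all`` executes the whole study on synthetic data with one master seed,
persists every intermediate table, and closes with a recovery report that
compares the fitted segment coefficients against the planted truth.  All
randomness flows from the master seed through per-stage derived seeds so any
stage can be reproduced from the persisted intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    attribute_patients,
    censor_followup,
    filter_patients,
    physician_year_status,
)
from .config import MIN_PANEL_SIZE, RunConfig
from .outcomes import assemble_tables
from .segfit import (
    SegmentedFit,
    adopter_class_effects,
    build_design,
    derive_effects,
    fit_adopter_interaction,
    fit_segmented_linear,
    fit_segmented_logistic,
    linearity_check,
    predict_trajectory,
)
from .simclaims import Dataset, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

#: parameter-recovery tolerances used by the recovery report (absolute error
#: on the coefficient scale); parameters without an entry are reported
#: without a pass/fail verdict.
RECOVERY_TOLERANCES: dict[tuple[str, str], float] = {
    ("upc", "slope_pre"): 0.10,
    ("upc", "slope_change"): 0.10,
    ("upc", "early_offset"): 0.50,
    ("ri", "slope_pre"): 0.10,
    ("ri", "slope_change"): 0.10,
    ("fpsc", "slope_change"): 0.005,
}


@dataclass
class CohortResult:
    rosters: dict[int, pd.DataFrame]
    statuses: pd.DataFrame
    retention: pd.DataFrame
    eligibility: dict[int, pd.DataFrame]


def build_cohort(data: Dataset) -> CohortResult:
    """Attribution, physician-year statuses, censoring and patient filters."""
    cfg = data.config
    rosters, status_frames = {}, []
    for year in range(cfg.study_start, cfg.study_end + 1):
        rosters[year] = attribute_patients(data.claims, year)
        status_frames.append(
            physician_year_status(data.claims, rosters[year],
                                  data.physicians, year)
        )
    statuses = pd.concat(status_frames, ignore_index=True)
    retention = censor_followup(
        data.physicians, statuses, (cfg.study_start, cfg.study_end),
        cfg.min_pre_years, cfg.min_post_years,
    )
    retained = set(retention.loc[retention["retained"], "physician_id"])
    eligibility = {}
    for year in range(cfg.study_start, cfg.study_end + 1):
        in_study = set(
            statuses.loc[
                (statuses["fiscal_year"] == year) & statuses["in_study"],
                "physician_id",
            ]
        ) & retained
        eligibility[year] = filter_patients(
            data.claims, rosters[year], data.patients, year, in_study
        )
    return CohortResult(rosters, statuses, retention, eligibility)


def attrition_table(data: Dataset, cohort: CohortResult) -> pd.DataFrame:
    """Counts removed by each eligibility rule, in application order."""
    st = cohort.statuses
    rows = []
    n = len(st)
    rows.append(("physician-year", "total", n))
    keep = st["comprehensive"]
    rows.append(("physician-year", "non_comprehensive(<8 of 18 core)",
                 int((~keep).sum())))
    panel_ok = keep & (st["panel_size"] >= MIN_PANEL_SIZE)
    rows.append(("physician-year", "panel<100", int((keep & ~panel_ok).sum())))
    absent_ok = panel_ok & ~st["absent"]
    rows.append(("physician-year", "absent>=8wk",
                 int((panel_ok & ~absent_ok).sum())))
    final = absent_ok & (st["model_state"] != "censored")
    rows.append(("physician-year", "left_eFFS(censored)",
                 int((absent_ok & ~final).sum())))

    ret = cohort.retention
    rows.append(("physician", "total", len(ret)))
    pre_fail = ret["n_pre"] < data.config.min_pre_years
    rows.append(("physician", "<4_pre_transition_years", int(pre_fail.sum())))
    post_fail = ~pre_fail & (ret["n_post"] < data.config.min_post_years)
    rows.append(("physician", "<2_post_transition_years", int(post_fail.sum())))
    rows.append(("physician", "retained", int(ret["retained"].sum())))

    reasons = pd.concat(
        [e["exclusion_reason"] for e in cohort.eligibility.values()],
        ignore_index=True,
    )
    rows.append(("patient-year", "total", len(reasons)))
    order = ["invalid_coverage", "dead", "unattributed",
             "physician_not_in_study", "no_visit_to_attributed_2yr"]
    counts = reasons.value_counts()
    for rule in order:
        rows.append(("patient-year", rule, int(counts.get(rule, 0))))
    rows.append(("patient-year", "eligible", int(reasons.isna().sum())))
    return pd.DataFrame(rows, columns=["stage", "rule", "count"])


# ---------------------------------------------------------------------------
# fitting and reporting


def _fit_summaries(fit: SegmentedFit) -> dict:
    return {
        "params": fit.params.reset_index().to_dict(orient="records"),
        "re_var": fit.re_var,
        "re_terms": list(fit.re_terms),
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "method": fit.method,
        "scale": fit.scale,
        "notes": fit.notes,
    }


def default_profile(fit: SegmentedFit) -> dict[str, float]:
    """Mean/mode covariate profile for predicted trajectories.

    A 41-year-old urban female patient in income quintile 5 and the second
    morbidity band, under a male Canadian-trained physician, 25 years since
    graduation, panel 1000-1999.
    """
    profile = {
        t: 0.0 for t in fit.params.index
        if t not in ("intercept", "time", "post", "tst")
        and not t.startswith("early_") and t != "early_adopter"
    }
    for name, val in (("age", 41.0), ("female", 1.0), ("inc_q5", 1.0),
                      ("morb_1_4", 1.0), ("years_since_grad", 25.0),
                      ("panel_1000_1999", 1.0)):
        if name in profile:
            profile[name] = val
    return profile


def recovery_report(config: RunConfig, fits: dict[str, SegmentedFit],
                    interaction_fits: dict[str, SegmentedFit]) -> pd.DataFrame:
    """Planted-vs-estimated table for every planted segment parameter."""
    term_of = {"slope_pre": "time", "level_change": "post",
               "slope_change": "tst"}
    rows = []
    for outcome, fit in fits.items():
        block = config.truth.block(outcome)
        # with a planted adopter offset the interaction model is the
        # correctly specified one; both classes share the planted segment
        # values, so report the early-adopter class effect (the dominant
        # class, hence the tighter of the two unbiased estimates)
        source, early = fit, 0.0
        if block.early_offset != 0.0 and outcome in interaction_fits:
            source, early = interaction_fits[outcome], 1.0
        for pname, term in term_of.items():
            combo = {term: 1.0}
            if early:
                combo[f"early_{term}"] = 1.0
            est, se = source.combo(combo)
            planted = getattr(block, pname)
            tol = RECOVERY_TOLERANCES.get((outcome, pname), np.nan)
            rows.append({
                "outcome": outcome, "parameter": pname, "planted": planted,
                "estimate": est, "se": se,
                "abs_error": abs(est - planted), "tolerance": tol,
                "ok": abs(est - planted) <= tol if np.isfinite(tol) else None,
            })
        ifit = interaction_fits.get(outcome)
        if ifit is not None and block.early_offset != 0.0:
            est, se = ifit.combo({"early_adopter": 1.0})
            tol = RECOVERY_TOLERANCES.get((outcome, "early_offset"), np.nan)
            rows.append({
                "outcome": outcome, "parameter": "early_offset",
                "planted": block.early_offset, "estimate": est, "se": se,
                "abs_error": abs(est - block.early_offset), "tolerance": tol,
                "ok": abs(est - block.early_offset) <= tol
                if np.isfinite(tol) else None,
            })
    return pd.DataFrame(rows)


def _plot_trajectories(fit, ifit, outcome, transition_time, times, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    prof = default_profile(fit)
    overall = predict_trajectory(fit, prof, times, transition_time)
    ax.plot(overall["time"], overall["prediction"], label="overall")
    if ifit is not None:
        iprof = default_profile(ifit)
        for label, flag in (("early adopters", 1.0), ("late adopters", 0.0)):
            tr = predict_trajectory(ifit, iprof, times, transition_time,
                                    early_adopter=flag)
            ax.plot(tr["time"], tr["prediction"], "--", label=label)
    ax.axvline(transition_time, color="grey", lw=0.8)
    ax.set_xlabel("years since study start")
    ax.set_ylabel(outcome)
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(out_dir) / f"trajectory_{outcome}.png", dpi=120)
    plt.close(fig)


def run_all(config: RunConfig, seed: int, out_dir,
            make_plots: bool = True) -> pd.DataFrame:
    """Execute every stage and return the recovery report.

    Writes, under ``out_dir``: the simulated dataset, roster and status
    tables, the analysis tables, fit summaries (CSV + JSON), derived-effect
    tables, linearity diagnostics, trajectory figures, the attrition table,
    the recovery report and a run manifest.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: seed=%d", seed)
    data = simulate_dataset(config, seed)
    write_dataset(data, out / "data")

    logger.info("stage cohort")
    cohort = build_cohort(data)
    pd.concat(cohort.rosters.values(), ignore_index=True).to_csv(
        out / "roster.csv", index=False)
    cohort.statuses.to_csv(out / "physician_status.csv", index=False)
    cohort.retention.to_csv(out / "physician_retention.csv", index=False)
    attrition = attrition_table(data, cohort)
    attrition.to_csv(out / "attrition.csv", index=False)

    logger.info("stage outcomes")
    patient_year, physician_year = assemble_tables(
        data, cohort.rosters, cohort.statuses, cohort.retention, config,
        cohort.eligibility,
    )
    patient_year.to_csv(out / "patient_year.csv", index=False)
    physician_year.to_csv(out / "physician_year.csv", index=False)

    logger.info("stage fit")
    fits: dict[str, SegmentedFit] = {}
    ifits: dict[str, SegmentedFit] = {}
    specs = [
        ("upc", patient_year, "linear"),
        ("ri", physician_year, "linear"),
        ("fpsc", patient_year, "logit"),
    ]
    summaries = {}
    for outcome, table, scale in specs:
        design = build_design(table, outcome, scale=scale)
        fit = (fit_segmented_linear(design, config.fit) if scale == "linear"
               else fit_segmented_logistic(design, config.fit))
        fits[outcome] = fit
        try:
            idesign = build_design(table, outcome, scale=scale,
                                   adopter_interaction=True)
            ifits[outcome] = fit_adopter_interaction(idesign, config.fit)
        except ValueError as exc:
            logger.warning("skipping adopter-interaction model for %s: %s",
                           outcome, exc)
        fit.params.to_csv(out / f"fit_{outcome}.csv")
        derive_effects(fit).to_csv(out / f"effects_{outcome}.csv", index=False)
        if outcome in ifits:
            ifits[outcome].params.to_csv(
                out / f"fit_{outcome}_interaction.csv")
            adopter_class_effects(ifits[outcome]).to_csv(
                out / f"adopter_effects_{outcome}.csv", index=False)
        means, lin = linearity_check(table, outcome)
        means.to_csv(out / f"linearity_means_{outcome}.csv", index=False)
        lin.to_csv(out / f"linearity_fits_{outcome}.csv", index=False)
        summaries[outcome] = {
            "main": _fit_summaries(fit),
            "interaction": (_fit_summaries(ifits[outcome])
                            if outcome in ifits else None),
        }
        if make_plots:
            median_transition = float(
                physician_year["transition_year"].median() - config.study_start
            )
            times = np.arange(0, config.study_end - config.study_start + 1.0)
            _plot_trajectories(fit, ifits.get(outcome), outcome,
                               median_transition, times, out)

    with open(out / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(summaries, fh, indent=2, default=float)

    logger.info("stage report")
    report = recovery_report(config, fits, ifits)
    report.to_csv(out / "recovery_report.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "n_patient_year_rows": len(patient_year),
        "n_physician_year_rows": len(physician_year),
        "retained_physicians": int(cohort.retention["retained"].sum()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
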