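"""Synthetic administrative-claims simulator with planted segmented effects.

The simulator emulates the data-generating process an interrupted-time-series
analysis of a primary-care payment reform assumes: family physicians switch
from traditional fee-for-service to a rostering-enhanced model in staggered
fiscal years; each patient has a fixed home physician; the probability that a
given primary-care visit goes to the home physician ("loyalty") follows a
segmented linear trajectory on the percentage scale with per-physician random
effects; specialist referrals are spawned from visits; and non-urgent
(family-practice-sensitive) emergency-department events follow a segmented
logistic model.  Every planted coefficient is recorded in a
:class:`~rosterits.config.TruthTable` so downstream estimates can be compared
with ground truth.

All outputs are plain pandas DataFrames with stable column schemas:

``physicians``
    physician_id, sex, graduation_year, foreign_trained, transition_year,
    exit_year, group_id, absence_years, comprehensive, panel_target
``patients``
    patient_id, birth_year, sex, income_quintile, rurality, morbidity_band,
    home_physician_id, death_year, coverage_valid
``claims``
    patient_id, physician_id, fiscal_year, service_category, fee,
    is_primary_care_visit
``referrals``
    patient_id, referring_physician_id, fiscal_year, is_diagnostic_radiology
``ed``
    patient_id, fiscal_year, is_fpsc

Identifiers are opaque integers; fiscal years are labelled by their April-1
start and no within-year timing is simulated.  Claims are generated for one
burn-in year before the study window so that the two-year attribution and UPC
windows are computable in the first study year.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    ADMIN_FEE,
    CORE_CATEGORIES,
    FEE_SCHEDULE,
    MORBIDITY_BANDS,
    NONCORE_CATEGORIES,
    RURALITY_LEVELS,
    RunConfig,
    SegmentTruth,
    TruthTable,
    is_early_adopter,
)

logger = logging.getLogger(__name__)

CLAIM_COLUMNS = [
    "patient_id", "physician_id", "fiscal_year", "service_category", "fee",
    "is_primary_care_visit",
]
REFERRAL_COLUMNS = [
    "patient_id", "referring_physician_id", "fiscal_year",
    "is_diagnostic_radiology",
]
ED_COLUMNS = ["patient_id", "fiscal_year", "is_fpsc"]


# ---------------------------------------------------------------------------
# population


def generate_population(
    config: RunConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the physician and patient populations.

    Physicians are partitioned into practice groups of
    ``group_size_min``..``group_size_max`` members which transition to the
    enhanced model together (one transition year drawn per group), so every
    group meets the configured minimum size.  Each patient is assigned a
    fixed home physician; panel sizes vary across physicians on a lognormal
    scale.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    J = config.n_physicians

    # practice groups form first and transition together: partition the
    # physicians into groups of group_size_min..group_size_max (a trailing
    # remainder below the minimum merges into the previous group), then draw
    # one transition year per group
    order = rng.permutation(J)
    sizes: list[int] = []
    remaining = J
    while remaining > 0:
        size = int(rng.integers(config.group_size_min,
                                config.group_size_max + 1))
        size = min(size, remaining)
        if size < config.group_size_min and sizes:
            sizes[-1] += size
        else:
            sizes.append(size)
        remaining -= size

    years = np.array(sorted(config.transition_mix))
    probs = np.array([config.transition_mix[y] for y in years], dtype=float)
    probs = probs / probs.sum()
    group_year = rng.choice(years, size=len(sizes), p=probs)

    transition_year = np.empty(J, dtype=int)
    group_id = np.empty(J, dtype=object)
    start = 0
    for g, (size, year) in enumerate(zip(sizes, group_year)):
        members = order[start:start + size]
        transition_year[members] = year
        for j in members:
            group_id[j] = f"G{year}_{g:03d}"
        start += size

    sex = np.where(rng.random(J) < config.phys_female_share, "F", "M")
    foreign = rng.random(J) < config.phys_foreign_share
    ysg = np.clip(
        rng.normal(config.years_since_grad_mean, config.years_since_grad_sd, J),
        3.0, 45.0,
    ).round().astype(int)
    graduation_year = transition_year - ysg

    # exits to another model (capitation) or out of province, >= 2 years
    # after the transition so the exit is a censoring event, not an
    # eligibility failure by construction
    exit_year = np.full(J, np.nan)
    exits = rng.random(J) < config.exit_prob
    for j in np.flatnonzero(exits):
        lo = transition_year[j] + 2
        if lo <= config.study_end:
            exit_year[j] = rng.integers(lo, config.study_end + 1)

    absence_years = np.array([""] * J, dtype=object)
    absentees = rng.random(J) < config.absence_prob
    for j in np.flatnonzero(absentees):
        absence_years[j] = str(rng.integers(config.study_start, config.study_end + 1))

    comprehensive = rng.random(J) >= config.frac_noncomprehensive

    panel = np.exp(
        rng.normal(np.log(config.panel_mean) - config.panel_sigma**2 / 2,
                   config.panel_sigma, J)
    )
    panel = np.clip(panel, config.panel_min, config.panel_max).round().astype(int)

    physicians = pd.DataFrame({
        "physician_id": np.arange(1, J + 1),
        "sex": sex,
        "graduation_year": graduation_year,
        "foreign_trained": foreign,
        "transition_year": transition_year,
        "exit_year": exit_year,
        "group_id": group_id,
        "absence_years": absence_years,
        "comprehensive": comprehensive,
        "panel_target": panel,
    })

    N = int(panel.sum())
    home = np.repeat(physicians["physician_id"].to_numpy(), panel)
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, N), 0, 95)
    birth_year = (config.study_start - age0).round().astype(int)
    psex = np.where(rng.random(N) < config.patient_female_share, "F", "M")
    income = rng.choice(np.arange(1, 6), size=N, p=np.asarray(config.income_probs))
    rurality = rng.choice(np.asarray(RURALITY_LEVELS), size=N,
                          p=np.asarray(config.rurality_probs))
    morbidity = rng.choice(np.asarray(MORBIDITY_BANDS), size=N,
                           p=np.asarray(config.morbidity_probs))
    death_year = np.full(N, np.nan)
    dies = rng.random(N) < config.mortality_prob
    death_year[dies] = rng.integers(config.study_start, config.study_end + 1,
                                    dies.sum())
    coverage = rng.random(N) >= config.coverage_invalid_prob

    patients = pd.DataFrame({
        "patient_id": np.arange(100001, 100001 + N),
        "birth_year": birth_year,
        "sex": psex,
        "income_quintile": income,
        "rurality": rurality,
        "morbidity_band": morbidity,
        "home_physician_id": home,
        "death_year": death_year,
        "coverage_valid": coverage,
    })
    return physicians, patients


def parse_absences(absence_years: str) -> set[int]:
    return {int(tok) for tok in str(absence_years).split(";") if tok.strip()}


def _absent_mask(physicians: pd.DataFrame, year: int) -> np.ndarray:
    return np.array(
        [year in parse_absences(a) for a in physicians["absence_years"]]
    )


# ---------------------------------------------------------------------------
# planted linear predictors


def realize_effects(
    physicians: pd.DataFrame, truth: TruthTable, seed: int
) -> pd.DataFrame:
    """Draw one set of per-physician random effects for all outcome blocks.

    Effects are independent normal deviates with the standard deviations
    declared in the truth table.  The same realization must be shared by the
    claims, referral and ED simulators of one dataset.
    """
    rng = np.random.default_rng(seed)
    J = len(physicians)
    out = {"physician_id": physicians["physician_id"].to_numpy()}
    for name in ("upc", "ri", "fpsc"):
        block = truth.block(name)
        for term, sd in (
            ("int", block.sd_intercept), ("time", block.sd_time),
            ("post", block.sd_post), ("tst", block.sd_tst),
        ):
            out[f"{name}_{term}"] = rng.normal(0.0, sd, J) if sd > 0 else np.zeros(J)
    return pd.DataFrame(out).set_index("physician_id")


def _physician_base(block: SegmentTruth, physicians: pd.DataFrame) -> np.ndarray:
    """Time-constant physician part of a linear predictor (no random effects)."""
    cov = block.covariates
    ysg = (physicians["transition_year"] - physicians["graduation_year"]).to_numpy()
    base = (
        block.intercept
        + np.where(physicians["sex"].to_numpy() == "F", cov.get("phys_female", 0.0), 0.0)
        + np.where(physicians["foreign_trained"].to_numpy(),
                   cov.get("foreign_trained", 0.0), 0.0)
        + cov.get("years_since_grad", 0.0) * ysg
        + np.where(is_early_adopter(physicians["transition_year"].to_numpy()),
                   block.early_offset, 0.0)
    )
    return base.astype(float)


def _patient_static(block: SegmentTruth, patients: pd.DataFrame) -> np.ndarray:
    """Time-constant patient covariate part of a linear predictor."""
    cov = block.covariates
    off = np.zeros(len(patients))
    off += np.where(patients["sex"].to_numpy() == "F", cov.get("female", 0.0), 0.0)
    mb = patients["morbidity_band"].to_numpy()
    for band, key in (("1-4", "morb_1_4"), ("5-9", "morb_5_9"), ("10+", "morb_10p")):
        off += np.where(mb == band, cov.get(key, 0.0), 0.0)
    iq = patients["income_quintile"].to_numpy()
    for q in (2, 3, 4, 5):
        off += np.where(iq == q, cov.get(f"inc_q{q}", 0.0), 0.0)
    rur = patients["rurality"].to_numpy()
    off += np.where(rur == "suburban", cov.get("suburban", 0.0), 0.0)
    off += np.where(rur == "rural", cov.get("rural", 0.0), 0.0)
    return off


def _segment_terms(
    year: int, study_start: int, transition_year: np.ndarray,
    switch_in_transition_year: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """(time, post, tst) segmentation of a planted trajectory.

    Visit loyalty switches within the transition year itself
    (``switch_in_transition_year=True``): rostering happens during that
    fiscal year, and the two-year UPC window of the following analysis year
    is then fully post-transition.  Single-year outcome processes (referral
    concentration, ED events) are planted directly on the analysis
    segmentation, whose first post year is the year after transition.
    """
    time = float(year - study_start)
    if switch_in_transition_year:
        post = (year >= transition_year).astype(float)
    else:
        post = (year > transition_year).astype(float)
    tst = np.maximum(0.0, year - transition_year).astype(float) * post
    return time, post, tst


class _LoyaltyModel:
    """Per patient-year visit-loyalty probabilities from the planted truth."""

    def __init__(self, patients, physicians, truth: TruthTable,
                 effects: pd.DataFrame, study_start: int):
        self.study_start = study_start
        block = truth.upc
        self.block = block
        phys = physicians.set_index("physician_id")
        home = patients["home_physician_id"]
        phys_part = pd.Series(
            _physician_base(block, physicians),
            index=physicians["physician_id"],
        )
        self.static = (
            _patient_static(block, patients)
            + phys_part.reindex(home).to_numpy()
            + effects["upc_int"].reindex(home).to_numpy()
        )
        self.re_time = effects["upc_time"].reindex(home).to_numpy()
        self.re_post = effects["upc_post"].reindex(home).to_numpy()
        self.re_tst = effects["upc_tst"].reindex(home).to_numpy()
        self.transition = phys["transition_year"].reindex(home).to_numpy()
        self.birth_year = patients["birth_year"].to_numpy()
        self.age_coef = block.covariates.get("age", 0.0)
        self.n_clipped = 0

    def prob(self, year: int) -> np.ndarray:
        b = self.block
        time, post, tst = _segment_terms(year, self.study_start, self.transition)
        pred = (
            self.static
            + self.age_coef * (year - self.birth_year)
            + (b.slope_pre + self.re_time) * time
            + (b.level_change + self.re_post) * post
            + (b.slope_change + self.re_tst) * tst
        )
        p = pred / 100.0
        clipped = (p < 0.01) | (p > 1.0)
        self.n_clipped += int(clipped.sum())
        return np.clip(p, 0.01, 1.0)


# ---------------------------------------------------------------------------
# claims


def simulate_claims(
    physicians: pd.DataFrame,
    patients: pd.DataFrame,
    truth: TruthTable,
    config: RunConfig,
    seed: int,
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate visit and fee claims for burn-in + study years.

    Annual per-patient visit counts are overdispersed (gamma-Poisson) with a
    mean set by the morbidity band.  Each visit goes to the home physician
    with the planted loyalty probability; otherwise to a same-group colleague
    with probability ``group_share_post`` once the home physician has
    transitioned, and to a random other physician before that.  Physicians
    bill service categories from a fixed repertoire (comprehensive providers
    use ``repertoire_full`` distinct core categories, limited providers fewer
    than the 8-of-18 comprehensiveness threshold); a small share of visits is
    billed under non-core categories, and occasional non-visit fee items are
    added.  A physician with a planted absence year bills nothing that year.
    """
    ss = np.random.SeedSequence(seed)
    s_eff, s_main = ss.spawn(2)
    if effects is None:
        effects = realize_effects(physicians, truth, s_eff.generate_state(1)[0])
    rng = np.random.default_rng(s_main.generate_state(4))

    J = len(physicians)
    phys_ids = physicians["physician_id"].to_numpy()
    id_to_idx = {pid: i for i, pid in enumerate(phys_ids)}
    transition = physicians["transition_year"].to_numpy()

    # billing repertoires
    rep_size = np.where(physicians["comprehensive"].to_numpy(),
                        config.repertoire_full, config.repertoire_limited)
    max_rep = int(rep_size.max())
    core = np.asarray(CORE_CATEGORIES)
    repertoire = np.empty((J, max_rep), dtype=object)
    for j in range(J):
        cats = rng.choice(core, size=rep_size[j], replace=False)
        repertoire[j, :] = np.resize(cats, max_rep)

    # same-group colleagues per physician
    groups = physicians.groupby("group_id")["physician_id"].apply(list).to_dict()
    colleague_lists = [
        [id_to_idx[c] for c in groups[g] if c != pid]
        for pid, g in zip(phys_ids, physicians["group_id"])
    ]
    max_col = max((len(c) for c in colleague_lists), default=0)
    colleagues = np.full((J, max(max_col, 1)), -1, dtype=np.int64)
    for j, cl in enumerate(colleague_lists):
        colleagues[j, :len(cl)] = cl

    loyalty = _LoyaltyModel(patients, physicians, truth, effects, config.study_start)
    home_idx = np.array([id_to_idx[h] for h in patients["home_physician_id"]])
    band_order = {b: i for i, b in enumerate(MORBIDITY_BANDS)}
    visit_mu = np.asarray(config.visit_mean_by_band)[
        [band_order[b] for b in patients["morbidity_band"]]
    ]
    death = patients["death_year"].to_numpy()
    pat_ids = patients["patient_id"].to_numpy()
    theta = config.visit_dispersion

    frames: list[pd.DataFrame] = []
    for year in range(config.study_start - 1, config.study_end + 1):
        absent = _absent_mask(physicians, year)
        alive = np.isnan(death) | (death >= year)

        p = loyalty.prob(year)
        p_eff = np.where(absent[home_idx], 0.0, p)

        lam = rng.gamma(theta, visit_mu / theta)
        n_visits = rng.poisson(lam) * alive
        n_home = rng.binomial(n_visits, p_eff)
        n_other = n_visits - n_home

        # home-physician visit rows
        h_pat = np.repeat(pat_ids, n_home)
        h_phys = np.repeat(home_idx, n_home)

        # non-home rows: group colleague vs random other physician
        o_pat = np.repeat(pat_ids, n_other)
        o_home = np.repeat(home_idx, n_other)
        o_post = np.repeat(
            (year >= transition[home_idx]) & ~absent[home_idx], n_other
        )
        n_cols = np.array([
            sum(1 for c in cl if not absent[c]) for cl in colleague_lists
        ])
        # colleague table with absent colleagues compacted out, per year
        avail = np.full_like(colleagues, -1)
        for j, cl in enumerate(colleague_lists):
            live = [c for c in cl if not absent[c]]
            avail[j, :len(live)] = live
        use_group = (
            o_post
            & (n_cols[o_home] > 0)
            & (rng.random(len(o_pat)) < config.group_share_post)
        )
        o_phys = np.empty(len(o_pat), dtype=np.int64)
        gi = np.flatnonzero(use_group)
        if gi.size:
            pick = (rng.random(gi.size) * n_cols[o_home[gi]]).astype(np.int64)
            o_phys[gi] = avail[o_home[gi], pick]
        ri_ = np.flatnonzero(~use_group)
        if ri_.size:
            pool = np.flatnonzero(~absent)
            draw = pool[rng.integers(0, len(pool), ri_.size)]
            # avoid billing the home physician on the "random other" path
            clash = draw == o_home[ri_]
            while clash.any():
                draw[clash] = pool[rng.integers(0, len(pool), clash.sum())]
                clash = draw == o_home[ri_]
            o_phys[ri_] = draw

        v_pat = np.concatenate([h_pat, o_pat])
        v_phys = np.concatenate([h_phys, o_phys])

        # service categories: repertoire of the billing physician, with a
        # small non-core share
        m = len(v_pat)
        cat = np.empty(m, dtype=object)
        noncore = rng.random(m) < config.noncore_visit_prob
        pick = (rng.random(m) * rep_size[v_phys]).astype(np.int64)
        cat[~noncore] = repertoire[v_phys[~noncore], pick[~noncore]]
        cat[noncore] = rng.choice(np.asarray(NONCORE_CATEGORIES), noncore.sum())

        fee = np.array([FEE_SCHEDULE[c] for c in cat])

        frame = pd.DataFrame({
            "patient_id": v_pat,
            "physician_id": phys_ids[v_phys],
            "fiscal_year": year,
            "service_category": cat,
            "fee": fee,
            "is_primary_care_visit": True,
        })

        # non-visit fee items billed by the home physician
        admin = alive & (rng.random(len(pat_ids)) < config.admin_claim_prob)
        admin &= ~absent[home_idx]
        if admin.any():
            frame = pd.concat([frame, pd.DataFrame({
                "patient_id": pat_ids[admin],
                "physician_id": phys_ids[home_idx[admin]],
                "fiscal_year": year,
                "service_category": rng.choice(
                    np.asarray(NONCORE_CATEGORIES), int(admin.sum())
                ),
                "fee": ADMIN_FEE,
                "is_primary_care_visit": False,
            })], ignore_index=True)
        frames.append(frame)

    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(
        ["fiscal_year", "patient_id", "physician_id", "service_category"],
        kind="mergesort",
    ).reset_index(drop=True)
    if loyalty.n_clipped:
        logger.info(
            "loyalty predictor clipped to [0.01, 1.0] for %d patient-years",
            loyalty.n_clipped,
        )
    return claims


# ---------------------------------------------------------------------------
# referrals


def simulate_referrals(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    physicians: pd.DataFrame,
    truth: TruthTable,
    config: RunConfig,
    seed: int,
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spawn specialist referrals from visits.

    Every referral is generated from an existing visit (the referring
    physician is the visit's physician), but home visits and non-home visits
    refer at different rates: the home rate is scaled per patient-year so
    that the expected share of a panel's referrals made by the home physician
    equals the planted physician-level concentration trajectory exactly,
    independent of the patient's visit loyalty.  A configured share of
    referrals is flagged as diagnostic radiology (excluded downstream from
    the referral index).
    """
    ss = np.random.SeedSequence(seed)
    s_eff, s_main = ss.spawn(2)
    if effects is None:
        effects = realize_effects(physicians, truth, s_eff.generate_state(1)[0])
    rng = np.random.default_rng(s_main.generate_state(4))

    block = truth.ri
    phys = physicians.set_index("physician_id")
    base = pd.Series(_physician_base(block, physicians),
                     index=physicians["physician_id"])

    loyalty = _LoyaltyModel(patients, physicians, truth, effects,
                            config.study_start)
    pat_index = pd.Index(patients["patient_id"])
    home_of = patients.set_index("patient_id")["home_physician_id"]

    visits = claims[claims["is_primary_care_visit"]
                    & (claims["fiscal_year"] >= config.study_start)]
    out = []
    r0 = config.referral_rate
    for year, chunk in visits.groupby("fiscal_year"):
        p_year = loyalty.prob(int(year))  # aligned with patients order
        p_map = pd.Series(p_year, index=pat_index)
        p = p_map.reindex(chunk["patient_id"]).to_numpy()
        home = home_of.reindex(chunk["patient_id"]).to_numpy()
        is_home = chunk["physician_id"].to_numpy() == home

        tr = phys["transition_year"].reindex(pd.Index(home)).to_numpy()
        time, post, tst = _segment_terms(int(year), config.study_start, tr,
                                         switch_in_transition_year=False)
        re = effects.reindex(pd.Index(home))
        q = (
            base.reindex(pd.Index(home)).to_numpy()
            + re["ri_int"].to_numpy()
            + (block.slope_pre + re["ri_time"].to_numpy()) * time
            + (block.level_change + re["ri_post"].to_numpy()) * post
            + (block.slope_change + re["ri_tst"].to_numpy()) * tst
        ) / 100.0
        q = np.clip(q, 0.01, 0.99)

        with np.errstate(divide="ignore", invalid="ignore"):
            odds_ratio = (q / (1.0 - q)) * ((1.0 - p) / np.maximum(p, 1e-12))
        # keep the home/other rate ratio exact even when the home rate would
        # exceed 1: scale both rates down so the expected home share of
        # referrals stays equal to the planted concentration q
        thin = np.minimum(r0, 1.0 / np.maximum(odds_ratio, 1e-12))
        rate = np.where(is_home, thin * odds_ratio, thin)
        refer = rng.random(len(chunk)) < rate
        if refer.any():
            out.append(pd.DataFrame({
                "patient_id": chunk["patient_id"].to_numpy()[refer],
                "referring_physician_id":
                    chunk["physician_id"].to_numpy()[refer],
                "fiscal_year": int(year),
                "is_diagnostic_radiology":
                    rng.random(int(refer.sum())) < config.radiology_share,
            }))
    if not out:
        return pd.DataFrame(columns=REFERRAL_COLUMNS)
    referrals = pd.concat(out, ignore_index=True)
    return referrals.sort_values(
        ["fiscal_year", "patient_id", "referring_physician_id"],
        kind="mergesort",
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# emergency-department events


def simulate_ed(
    patients: pd.DataFrame,
    physicians: pd.DataFrame,
    truth: TruthTable,
    config: RunConfig,
    seed: int,
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw per patient-year FPSC emergency-department indicators.

    The FPSC log-odds follow the planted segmented trajectory (time, post and
    time-since-transition of the patient's home physician) plus patient and
    provider covariate effects and a physician random intercept.  Records are
    emitted only inside the configured ED window; a small background rate of
    non-FPSC ED visits is included.
    """
    ss = np.random.SeedSequence(seed)
    s_eff, s_main = ss.spawn(2)
    if effects is None:
        effects = realize_effects(physicians, truth, s_eff.generate_state(1)[0])
    rng = np.random.default_rng(s_main.generate_state(4))

    block = truth.fpsc
    home = patients["home_physician_id"]
    base = pd.Series(_physician_base(block, physicians),
                     index=physicians["physician_id"])
    static = (
        _patient_static(block, patients)
        + base.reindex(home).to_numpy()
        + effects["fpsc_int"].reindex(home).to_numpy()
    )
    tr = physicians.set_index("physician_id")["transition_year"] \
        .reindex(home).to_numpy()
    birth = patients["birth_year"].to_numpy()
    death = patients["death_year"].to_numpy()
    age_coef = block.covariates.get("age", 0.0)
    pat_ids = patients["patient_id"].to_numpy()

    out = []
    for year in range(config.ed_start, config.ed_end + 1):
        alive = np.isnan(death) | (death >= year)
        time, post, tst = _segment_terms(year, config.study_start, tr,
                                         switch_in_transition_year=False)
        eta = (
            static
            + age_coef * (year - birth)
            + block.slope_pre * time
            + block.level_change * post
            + block.slope_change * tst
        )
        fpsc = alive & (rng.random(len(pat_ids)) < expit(eta))
        background = alive & (rng.random(len(pat_ids)) < config.ed_background_rate)
        for flag, mask in ((True, fpsc), (False, background)):
            if mask.any():
                out.append(pd.DataFrame({
                    "patient_id": pat_ids[mask],
                    "fiscal_year": year,
                    "is_fpsc": flag,
                }))
    if not out:
        return pd.DataFrame(columns=ED_COLUMNS)
    ed = pd.concat(out, ignore_index=True)
    return ed.sort_values(
        ["fiscal_year", "patient_id", "is_fpsc"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dataset container and round-trip


@dataclass
class Dataset:
    """One simulated study: population, events, and the planted truth."""

    physicians: pd.DataFrame
    patients: pd.DataFrame
    claims: pd.DataFrame
    referrals: pd.DataFrame
    ed: pd.DataFrame
    truth: TruthTable
    config: RunConfig
    seed: int


def simulate_dataset(config: RunConfig, seed: int) -> Dataset:
    """Run all four generators with per-stage seeds derived from one master."""
    ss = np.random.SeedSequence(seed)
    s_pop, s_eff, s_claims, s_ref, s_ed = (
        s.generate_state(1)[0] for s in ss.spawn(5)
    )
    physicians, patients = generate_population(config, s_pop)
    effects = realize_effects(physicians, config.truth, s_eff)
    claims = simulate_claims(physicians, patients, config.truth, config,
                             s_claims, effects)
    referrals = simulate_referrals(claims, patients, physicians, config.truth,
                                   config, s_ref, effects)
    ed = simulate_ed(patients, physicians, config.truth, config, s_ed, effects)
    return Dataset(physicians, patients, claims, referrals, ed,
                   config.truth, config, seed)


def write_dataset(data: Dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("physicians", "patients", "claims", "referrals", "ed"):
        getattr(data, name).to_csv(out / f"{name}.csv", index=False)
    data.truth.to_json(out / "truth.json")
    data.config.to_yaml(out / "config.yaml")
    manifest = {
        "seed": int(data.seed),
        "config_hash": data.config.config_hash(),
        "tables": {
            name: len(getattr(data, name))
            for name in ("physicians", "patients", "claims", "referrals", "ed")
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    tables = {}
    for name in ("physicians", "patients", "claims", "referrals", "ed"):
        tables[name] = pd.read_csv(src / f"{name}.csv")
    tables["physicians"]["absence_years"] = (
        tables["physicians"]["absence_years"].fillna("").astype(str)
        .str.replace(r"\.0$", "", regex=True)
    )
    truth = TruthTable.from_json(src / "truth.json")
    config = RunConfig.from_yaml(src / "config.yaml")
    with open(src / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return Dataset(tables["physicians"], tables["patients"], tables["claims"],
                   tables["referrals"], tables["ed"], truth, config,
                   manifest["seed"])
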