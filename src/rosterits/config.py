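"""Run configuration and planted ground truth.

Everything the simulator and the fitting pipeline need is collected in two
serializable structures:

``SegmentTruth``
    One planted segmented (interrupted time series) trajectory: a baseline
    level, a secular pre-transition slope, a change in level at the
    transition, and a change in slope after it, plus physician random-effect
    standard deviations, covariate effects and an early-adopter baseline
    offset.  The UPC and RI blocks live on the percentage scale; the FPSC
    block on the log-odds scale.

``RunConfig``
    Study windows, population sizes, transition-year mix, simulator knobs,
    fit options and the three truth blocks.

Defaults reproduce the study conditions of the Ontario tFFS-to-eFFS
evaluation this package re-implements: fiscal years 2000-2013, staggered
transitions 2004-2011 with ~86% early adopters (2004-2006), ED outcome
restricted to 2003-2013, and the published adjusted segment coefficients
planted for all three outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

# ---------------------------------------------------------------------------
# planted truth


@dataclass
class SegmentTruth:
    """Planted coefficients for one segmented outcome process.

    ``intercept`` is the baseline level at time 0 for reference covariates,
    ``slope_pre`` the secular trend per year, ``level_change`` the immediate
    change at the transition year, ``slope_change`` the additional slope per
    year after the transition.  ``early_offset`` is added for physicians who
    transition in the early-adopter window.  ``sd_*`` are standard deviations
    of independent per-physician random effects on the four segment terms.
    ``covariates`` maps covariate names to additive effects on the linear
    predictor.
    """

    intercept: float
    slope_pre: float
    level_change: float
    slope_change: float
    early_offset: float = 0.0
    sd_intercept: float = 0.0
    sd_time: float = 0.0
    sd_post: float = 0.0
    sd_tst: float = 0.0
    covariates: dict[str, float] = field(default_factory=dict)

    def segment_values(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "slope_pre": self.slope_pre,
            "level_change": self.level_change,
            "slope_change": self.slope_change,
        }


def _default_upc_truth() -> SegmentTruth:
    # Segment coefficients: published adjusted UPC model.  Baseline chosen so
    # the population-mean loyalty sits near the published unadjusted baseline
    # UPC (~76%); covariate effects modest so the percent-scale predictor
    # stays well inside (1, 100).
    return SegmentTruth(
        intercept=73.0,
        slope_pre=-0.27,
        level_change=0.39,
        slope_change=-0.59,
        early_offset=7.02,
        sd_intercept=2.0,
        sd_time=0.05,
        sd_post=0.2,
        sd_tst=0.05,
        covariates={
            "age": 0.10,
            "female": -1.0,
            "morb_1_4": -2.0,
            "morb_5_9": -4.0,
            "morb_10p": -7.0,
            "inc_q2": 0.0,
            "inc_q3": -0.3,
            "inc_q4": -0.4,
            "inc_q5": -0.4,
            "suburban": -0.3,
            "rural": -1.4,
            "phys_female": -1.0,
            "foreign_trained": -2.6,
            "years_since_grad": 0.15,
        },
    )


def _default_ri_truth() -> SegmentTruth:
    return SegmentTruth(
        intercept=76.0,
        slope_pre=-0.0014,
        level_change=0.29,
        slope_change=-0.34,
        early_offset=9.17,
        sd_intercept=2.0,
        sd_time=0.05,
        sd_post=0.2,
        sd_tst=0.05,
        covariates={
            "phys_female": -2.0,
            "foreign_trained": -3.0,
            "years_since_grad": 0.10,
        },
    )


def _default_fpsc_truth() -> SegmentTruth:
    # Log-odds scale.
    return SegmentTruth(
        intercept=-3.28,
        slope_pre=0.018,
        level_change=-0.010,
        slope_change=-0.011,
        early_offset=0.0,
        sd_intercept=0.25,
        covariates={
            "age": -0.008,
            "female": -0.05,
            "morb_1_4": 0.20,
            "morb_5_9": 0.60,
            "morb_10p": 1.20,
            "inc_q2": -0.05,
            "inc_q3": -0.10,
            "inc_q4": -0.15,
            "inc_q5": -0.20,
            "suburban": 0.40,
            "rural": 0.80,
            "phys_female": -0.04,
            "foreign_trained": -0.20,
            "years_since_grad": 0.005,
        },
    )


@dataclass
class TruthTable:
    """The three planted outcome processes (loyalty/UPC, referral/RI, FPSC)."""

    upc: SegmentTruth = field(default_factory=_default_upc_truth)
    ri: SegmentTruth = field(default_factory=_default_ri_truth)
    fpsc: SegmentTruth = field(default_factory=_default_fpsc_truth)

    def block(self, name: str) -> SegmentTruth:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(
                f"truth table has no block {name!r}; expected one of upc, ri, fpsc"
            ) from None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TruthTable":
        return cls(**{k: SegmentTruth(**v) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# simulator / study configuration

#: default share of physicians per transition fiscal year; 2004-2006 carry
#: ~86% of transitions, mirroring the published early/late adopter mix.
DEFAULT_TRANSITION_MIX: dict[int, float] = {
    2004: 0.30,
    2005: 0.30,
    2006: 0.26,
    2007: 0.035,
    2008: 0.030,
    2009: 0.030,
    2010: 0.025,
    2011: 0.020,
}

#: fiscal years whose adopters count as "early" in the interaction analysis.
EARLY_ADOPTER_YEARS: tuple[int, int] = (2004, 2006)

#: the 18 core primary-care service categories of the synthetic billing
#: dialect; a physician must bill >= 8 distinct ones in a year to count as
#: providing comprehensive care.
CORE_CATEGORIES: tuple[str, ...] = tuple(f"C{i:02d}" for i in range(1, 19))
NONCORE_CATEGORIES: tuple[str, ...] = ("N01", "N02", "N03", "N04")
COMPREHENSIVE_MIN_CORE = 8
MIN_PANEL_SIZE = 100

#: fixed price list per service category.  Core visits share one price so
#: that fee-sum attribution reduces to visit-count attribution; attribution
#: only needs summed fees, not fee realism.
FEE_SCHEDULE: dict[str, float] = {
    **{c: 35.0 for c in CORE_CATEGORIES},
    **{c: 20.0 for c in NONCORE_CATEGORIES},
}
ADMIN_FEE = 15.0

PANEL_SIZE_BINS = (0, 500, 1000, 2000, 3000)
PANEL_SIZE_LABELS = ("<500", "500-999", "1000-1999", "2000-2999", ">3000")

AGE_BAND_BINS = (0, 20, 40, 60, 80)
AGE_BAND_LABELS = ("<=19", "20-39", "40-59", "60-79", ">=80")

MORBIDITY_BANDS = ("0", "1-4", "5-9", "10+")
RURALITY_LEVELS = ("urban", "suburban", "rural")


@dataclass
class FitOptions:
    """Estimation options shared by the linear and logistic mixed fits."""

    reml: bool = True
    method: str = "lbfgs"
    maxiter: int = 200
    rtol: float = 1e-8
    #: random-effect ladder; the fit walks down on non-convergence.
    ladder: tuple[tuple[str, ...], ...] = (
        ("intercept", "time", "post", "tst"),
        ("intercept", "time"),
        ("intercept",),
    )
    #: explicit random-effect terms; None means "use the ladder".  An empty
    #: tuple forces the plain (generalized) linear model.
    re_terms: tuple[str, ...] | None = None


@dataclass
class RunConfig:
    # study windows (fiscal years, labelled by their April-1 start)
    study_start: int = 2000
    study_end: int = 2013
    ed_start: int = 2003
    ed_end: int = 2013

    # population
    n_physicians: int = 150
    panel_mean: float = 300.0
    panel_sigma: float = 0.40  # lognormal sigma of panel sizes
    panel_min: int = 60
    panel_max: int = 1500
    transition_mix: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_MIX)
    )
    group_size_min: int = 3
    group_size_max: int = 5
    phys_female_share: float = 0.365
    phys_foreign_share: float = 0.24
    years_since_grad_mean: float = 24.7
    years_since_grad_sd: float = 9.5
    frac_noncomprehensive: float = 0.04
    repertoire_full: int = 12
    repertoire_limited: int = 5
    absence_prob: float = 0.04
    exit_prob: float = 0.08

    # patients
    patient_female_share: float = 0.564
    age_mean: float = 41.4
    age_sd: float = 22.1
    income_probs: tuple[float, ...] = (0.191, 0.198, 0.198, 0.204, 0.209)
    rurality_probs: tuple[float, ...] = (0.93, 0.06, 0.01)
    morbidity_probs: tuple[float, ...] = (0.013, 0.367, 0.501, 0.119)
    mortality_prob: float = 0.03
    coverage_invalid_prob: float = 0.005

    # visit / referral / ED processes
    visit_mean_by_band: tuple[float, ...] = (2.5, 4.0, 6.5, 9.0)
    visit_dispersion: float = 6.0
    group_share_post: float = 0.8
    noncore_visit_prob: float = 0.10
    admin_claim_prob: float = 0.15
    referral_rate: float = 0.25
    radiology_share: float = 0.30
    ed_background_rate: float = 0.05

    # cohort rules
    min_pre_years: int = 4
    min_post_years: int = 2
    upc_min_visits: int = 3

    truth: TruthTable = field(default_factory=TruthTable)
    fit: FitOptions = field(default_factory=FitOptions)

    def validate(self) -> None:
        """Raise ``ValueError`` describing the first violated constraint."""
        if self.n_physicians <= 0:
            raise ValueError("config requires at least one physician")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        if not (self.study_start <= self.ed_start <= self.ed_end <= self.study_end):
            raise ValueError(
                "ED window must lie inside the study window: "
                f"[{self.ed_start}, {self.ed_end}] vs "
                f"[{self.study_start}, {self.study_end}]"
            )
        years = set(self.transition_mix)
        if not years:
            raise ValueError("transition_mix is empty")
        if min(years) <= self.study_start or max(years) > self.study_end:
            raise ValueError(
                "transition years must fall strictly inside the study window"
            )
        total = sum(self.transition_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"transition_mix probabilities sum to {total}, not 1")
        if self.group_size_min < 1 or self.group_size_max < self.group_size_min:
            raise ValueError("invalid group size bounds")
        for name, probs in [
            ("income_probs", self.income_probs),
            ("rurality_probs", self.rurality_probs),
            ("morbidity_probs", self.morbidity_probs),
        ]:
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if len(self.visit_mean_by_band) != len(MORBIDITY_BANDS):
            raise ValueError("visit_mean_by_band needs one mean per morbidity band")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # YAML/JSON keys must be strings
        d["transition_mix"] = {str(k): v for k, v in d["transition_mix"].items()}
        d["fit"]["ladder"] = [list(t) for t in d["fit"]["ladder"]]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "truth" in d and not isinstance(d["truth"], TruthTable):
            d["truth"] = TruthTable.from_dict(d["truth"])
        if "fit" in d and not isinstance(d["fit"], FitOptions):
            fd = dict(d["fit"])
            if "ladder" in fd:
                fd["ladder"] = tuple(tuple(r) for r in fd["ladder"])
            if fd.get("re_terms") is not None:
                fd["re_terms"] = tuple(fd["re_terms"])
            d["fit"] = FitOptions(**fd)
        if "transition_mix" in d:
            d["transition_mix"] = {int(k): v for k, v in d["transition_mix"].items()}
        for key in ("income_probs", "rurality_probs", "morbidity_probs",
                    "visit_mean_by_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def is_early_adopter(transition_year) -> bool | Any:
    """Early adopters transitioned in 2004-2006; late in 2007-2011.

    Works elementwise on pandas/numpy inputs as well as scalars.
    """
    lo, hi = EARLY_ADOPTER_YEARS
    return (transition_year >= lo) & (transition_year <= hi)
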