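"""Mixed-effects segmented (interrupted time series) regression.

The segmented model splits follow-up at each physician's transition year and
estimates four segment coefficients: a baseline level (intercept), the
secular pre-transition slope per year (``time``), the immediate change in
level at the transition (``post``), and the additional change in slope per
year afterwards (``tst``, time since transition).  Because outcomes are
measured over two-year windows, the transition fiscal year itself (whose
window straddles the switch) is coded as the last pre-period observation;
``post`` measures the level change at the first fully post-transition
window.  Clustering of patients within physicians is handled with
per-physician random effects on the four segment terms (independent
variances); on non-convergence the fit walks down a documented ladder of
simpler random-effect structures.

Continuous outcomes (UPC, RI, percent scale) use a linear mixed model
estimated by REML (:class:`statsmodels.regression.mixed_linear_model.MixedLM`).
The binary FPSC outcome uses a logistic model with a physician random
intercept estimated by Laplace-approximate posterior maximization
(:class:`statsmodels.genmod.bayes_mixed_glm.BinomialBayesMixedGLM.fit_map`);
its reported standard errors come from the Laplace posterior and are
approximate.  Reference levels follow the published tables: male sex, income
quintile 1, urban residence, morbidity band 0, panel size < 500.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.special import expit

from .config import FitOptions, PANEL_SIZE_LABELS

logger = logging.getLogger(__name__)

SEGMENT_TERMS = ("intercept", "time", "post", "tst")

#: design-column builders per source column; reference levels are the ones
#: with no column (male, quintile 1, urban, morbidity band 0, panel < 500)
_PANEL_DUMMY = {
    "500-999": "panel_500_999",
    "1000-1999": "panel_1000_1999",
    "2000-2999": "panel_2000_2999",
    ">3000": "panel_3000p",
}


@dataclass
class Design:
    """Model-ready table plus metadata for the segmented fits."""

    frame: pd.DataFrame
    outcome: str
    scale: str                     # "linear" (percent) or "logit"
    fixed_terms: list[str]         # excluding the intercept
    group_col: str = "physician_id"
    adopter_interaction: bool = False

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_groups(self) -> int:
        return self.frame[self.group_col].nunique()


@dataclass
class SegmentedFit:
    """Coefficients, random-effect variances and metadata of one fit."""

    outcome: str
    scale: str
    params: pd.DataFrame           # index: term; estimate, se, ci_low, ci_high, pvalue
    cov_params: pd.DataFrame
    re_var: dict[str, float]
    re_terms: tuple[str, ...]
    converged: bool
    n_obs: int
    n_clusters: int
    method: str
    adopter_interaction: bool = False
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def combo(self, terms: dict[str, float]) -> tuple[float, float]:
        """Estimate and delta-method SE of a linear combination of terms."""
        names = [t for t in terms if t in self.params.index]
        w = np.array([terms[t] for t in names])
        est = float(w @ self.params.loc[names, "estimate"].to_numpy())
        cov = self.cov_params.loc[names, names].to_numpy()
        se = float(np.sqrt(w @ cov @ w))
        return est, se


# ---------------------------------------------------------------------------
# design construction


def _patient_covariate_columns(records: pd.DataFrame) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    cols["age"] = records["age"].to_numpy(float)
    cols["female"] = (records["sex"] == "F").to_numpy(float)
    mb = records["morbidity_band"].astype(str)
    cols["morb_1_4"] = (mb == "1-4").to_numpy(float)
    cols["morb_5_9"] = (mb == "5-9").to_numpy(float)
    cols["morb_10p"] = (mb == "10+").to_numpy(float)
    iq = records["income_quintile"].to_numpy()
    for q in (2, 3, 4, 5):
        cols[f"inc_q{q}"] = (iq == q).astype(float)
    rur = records["rurality"].astype(str)
    cols["suburban"] = (rur == "suburban").to_numpy(float)
    cols["rural"] = (rur == "rural").to_numpy(float)
    return cols


def _physician_covariate_columns(records: pd.DataFrame) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    sex_col = "phys_sex" if "phys_sex" in records else None
    if sex_col:
        cols["phys_female"] = (records[sex_col] == "F").to_numpy(float)
    if "foreign_trained" in records:
        cols["foreign_trained"] = records["foreign_trained"].to_numpy(float)
    if "years_since_grad" in records:
        cols["years_since_grad"] = records["years_since_grad"].to_numpy(float)
    if "panel_category" in records:
        pc = records["panel_category"].astype(str)
        for level in PANEL_SIZE_LABELS[1:]:
            cols[_PANEL_DUMMY[level]] = (pc == level).to_numpy(float)
    return cols


def build_design(
    records: pd.DataFrame,
    outcome: str,
    scale: str = "linear",
    covariates: str = "auto",
    adopter_interaction: bool = False,
) -> Design:
    """Assemble the model-ready table for one outcome.

    ``covariates``: "auto" includes every patient/provider covariate present
    in ``records``; "none" fits the unadjusted (segments-only) model.  Rows
    with a missing outcome are dropped.  Dummy columns for category levels
    absent from the data are dropped with a log message; a constant
    continuous column or an outcome without variation is an error.
    """
    if outcome not in records.columns:
        raise ValueError(f"records carry no column {outcome!r}")
    for needed in ("time", "post", "tst", "physician_id"):
        if needed not in records.columns:
            raise ValueError(f"records carry no column {needed!r}")

    rows = records[records[outcome].notna()].reset_index(drop=True)
    if rows.empty:
        raise ValueError(f"no non-missing observations of {outcome!r}")

    data: dict[str, np.ndarray] = {
        "y": rows[outcome].to_numpy(float),
        "time": rows["time"].to_numpy(float),
        "post": rows["post"].to_numpy(float),
        "tst": rows["tst"].to_numpy(float),
        "physician_id": rows["physician_id"].to_numpy(),
    }
    if np.ptp(data["y"]) == 0:
        raise ValueError(f"outcome {outcome!r} is constant")

    cov_cols: dict[str, np.ndarray] = {}
    if covariates == "auto":
        if "sex" in rows.columns:
            cov_cols.update(_patient_covariate_columns(rows))
        cov_cols.update(_physician_covariate_columns(rows))
    elif covariates != "none":
        raise ValueError("covariates must be 'auto' or 'none'")

    fixed = ["time", "post", "tst"]
    dummy_like = {"age", "years_since_grad"}
    for name, col in cov_cols.items():
        if np.ptp(col) == 0:
            if name in dummy_like:
                raise ValueError(f"covariate column {name!r} is constant")
            logger.info("dropping empty covariate level column %r", name)
            continue
        data[name] = col
        fixed.append(name)

    if adopter_interaction:
        if "early_adopter" not in rows.columns:
            raise ValueError("records carry no early_adopter column")
        early = rows["early_adopter"].to_numpy(float)
        if np.ptp(early) == 0:
            raise ValueError(
                "adopter-interaction model needs both early and late adopters"
            )
        data["early_adopter"] = early
        data["early_time"] = early * data["time"]
        data["early_post"] = early * data["post"]
        data["early_tst"] = early * data["tst"]
        fixed += ["early_adopter", "early_time", "early_post", "early_tst"]

    frame = pd.DataFrame(data)
    counts = frame.groupby("physician_id").size()
    if (counts == 0).any():
        raise ValueError("empty cluster in design")
    return Design(frame=frame, outcome=outcome, scale=scale,
                  fixed_terms=fixed, adopter_interaction=adopter_interaction)


# ---------------------------------------------------------------------------
# linear mixed fit


def _params_table(names, est, se) -> pd.DataFrame:
    z = stats.norm.ppf(0.975)
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = est / se
        pval = 2 * stats.norm.sf(np.abs(zval))
    return pd.DataFrame({
        "estimate": est,
        "se": se,
        "ci_low": est - z * se,
        "ci_high": est + z * se,
        "pvalue": pval,
    }, index=pd.Index(names, name="term"))


def _rename_intercept(names) -> list[str]:
    return ["intercept" if n in ("Intercept", "const") else n for n in names]


def _fit_ols(design: Design) -> SegmentedFit:
    X = sm.add_constant(design.frame[design.fixed_terms], has_constant="add")
    res = sm.OLS(design.frame["y"], X).fit()
    names = _rename_intercept(res.params.index)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return SegmentedFit(
        outcome=design.outcome, scale=design.scale,
        params=_params_table(names, res.params, res.bse),
        cov_params=cov, re_var={}, re_terms=(), converged=True,
        n_obs=design.n_obs, n_clusters=design.n_groups, method="OLS",
        adopter_interaction=design.adopter_interaction,
    )


def _mixedlm_once(design: Design, re_terms: tuple[str, ...],
                  options: FitOptions, method: str):
    formula = "y ~ " + " + ".join(design.fixed_terms)
    vc = {t: f"0 + {t}" for t in re_terms if t != "intercept"}
    re_formula = "1" if "intercept" in re_terms else "0"
    model = smf.mixedlm(
        formula, design.frame, groups=design.frame["physician_id"],
        re_formula=re_formula, vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=options.reml, method=method,
                        maxiter=options.maxiter)
    return res


def fit_segmented_linear(
    design: Design, options: FitOptions | None = None
) -> SegmentedFit:
    """REML linear mixed fit with the documented random-effect ladder.

    Random effects are independent per-physician deviations on the requested
    segment terms.  If the full structure fails to converge the fit retries
    with random {intercept, time} and then a random intercept alone; the rung
    actually used is recorded in ``re_terms`` and ``notes``.  With
    ``options.re_terms = ()`` the model reduces to OLS.
    """
    options = options or FitOptions()
    if design.scale != "linear":
        raise ValueError("linear fit requires a linear-scale design")
    if design.n_groups < 2:
        raise ValueError("need at least 2 physician clusters")

    ladder = ([options.re_terms] if options.re_terms is not None
              else list(options.ladder))
    notes: list[str] = []
    fallback: SegmentedFit | None = None

    def wrap(res, rung, converged) -> SegmentedFit:
        names = _rename_intercept(res.fe_params.index)
        k = len(names)
        cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                           index=names, columns=names)
        re_var = {}
        if "intercept" in rung:
            re_var["intercept"] = float(np.asarray(res.cov_re)[0, 0])
        for term, v in zip([t for t in rung if t != "intercept"], res.vcomp):
            re_var[term] = float(v)
        return SegmentedFit(
            outcome=design.outcome, scale=design.scale,
            params=_params_table(names, res.fe_params, res.bse_fe),
            cov_params=cov, re_var=re_var, re_terms=rung, converged=converged,
            n_obs=design.n_obs, n_clusters=design.n_groups,
            method="MixedLM-" + ("REML" if options.reml else "ML"),
            adopter_interaction=design.adopter_interaction, notes=list(notes),
        )

    for rung in ladder:
        rung = tuple(rung)
        if rung == ():
            fit = _fit_ols(design)
            fit.notes.extend(notes)
            return fit
        for method in (options.method, "bfgs", "powell"):
            try:
                res = _mixedlm_once(design, rung, options, method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                notes.append(f"rung {rung} ({method}) failed: {exc}")
                continue
            # oversized standard errors mark a degenerate optimizer solution
            # that statsmodels can report as converged
            ok = (bool(res.converged) and np.all(np.isfinite(res.bse_fe))
                  and np.nanmax(np.asarray(res.bse_fe)) < 1e3)
            if ok:
                return wrap(res, rung, True)
            notes.append(f"rung {rung} ({method}) did not converge")
            if fallback is None and np.all(np.isfinite(res.fe_params)) \
                    and np.all(np.isfinite(res.bse_fe)):
                fallback = wrap(res, rung, False)
    if fallback is not None:
        # flagged, not silent: estimates from the highest rung that produced
        # finite results, with converged=False
        logger.warning("segmented linear fit did not converge; %s", notes[-1])
        return fallback
    raise RuntimeError(
        "segmented linear fit failed at every random-effect rung: "
        + "; ".join(notes)
    )


# ---------------------------------------------------------------------------
# logistic mixed fit


def fit_segmented_logistic(
    design: Design, options: FitOptions | None = None
) -> SegmentedFit:
    """Laplace (MAP) logistic fit with a physician random intercept.

    The binary outcome keeps its log-odds scale; fixed-effect point estimates
    closely track the marginal-likelihood MLE while the posterior standard
    deviations (used for the Wald CIs) are approximate.  With
    ``options.re_terms = ()`` the model reduces to an ordinary logistic GLM.
    Complete separation is flagged (not silently returned).
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    class _DeterministicStartGLM(BinomialBayesMixedGLM):
        # upstream draws random-effect starting values from the global numpy
        # RNG; a zero start keeps refits bit-reproducible
        def _get_start(self):
            return np.concatenate([
                np.zeros(self.k_fep), np.ones(self.k_vcp),
                np.zeros(self.k_vc),
            ])

    options = options or FitOptions()
    if design.scale != "logit":
        raise ValueError("logistic fit requires a logit-scale design")
    y = design.frame["y"].to_numpy(float)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("logistic outcome must be binary 0/1")
    if uniq.size < 2:
        raise ValueError(
            "no events" if uniq[0] == 0.0 else "no non-events"
        )
    if design.n_groups < 2:
        raise ValueError("need at least 2 physician clusters")

    X = sm.add_constant(design.frame[design.fixed_terms], has_constant="add")
    names = _rename_intercept(X.columns)

    if options.re_terms == ():
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        cov = pd.DataFrame(np.asarray(res.cov_params()),
                           index=names, columns=names)
        fit = SegmentedFit(
            outcome=design.outcome, scale="logit",
            params=_params_table(names, res.params, res.bse),
            cov_params=cov, re_var={}, re_terms=(), converged=res.converged,
            n_obs=design.n_obs, n_clusters=design.n_groups, method="GLM",
            adopter_interaction=design.adopter_interaction,
        )
    else:
        groups, gidx = np.unique(design.frame["physician_id"].to_numpy(),
                                 return_inverse=True)
        n = len(y)
        vc = sp.csr_matrix(
            (np.ones(n), (np.arange(n), gidx)), shape=(n, len(groups))
        )
        model = _DeterministicStartGLM(
            y, np.asarray(X, float), vc, ident=np.zeros(len(groups), dtype=int)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_map()
        params = _params_table(names, res.fe_mean, res.fe_sd)
        cov = pd.DataFrame(np.diag(np.asarray(res.fe_sd) ** 2),
                           index=names, columns=names)
        sd_re = float(np.exp(res.vcp_mean[0]))
        fit = SegmentedFit(
            outcome=design.outcome, scale="logit", params=params,
            cov_params=cov, re_var={"intercept": sd_re**2},
            re_terms=("intercept",), converged=True,
            n_obs=design.n_obs, n_clusters=design.n_groups,
            method="BayesMixedGLM-MAP",
            adopter_interaction=design.adopter_interaction,
            notes=["Laplace posterior SDs; CIs approximate"],
        )

    big = fit.params["estimate"].abs() > 15
    if big.any():
        offending = list(fit.params.index[big])
        fit.converged = False
        fit.notes.append(f"possible separation; extreme terms: {offending}")
        logger.warning("possible separation in %s fit: %s",
                       design.outcome, offending)
    return fit


def fit_adopter_interaction(
    design: Design, options: FitOptions | None = None
) -> SegmentedFit:
    """Fit the early/late-adopter interaction model.

    The design must be built with ``adopter_interaction=True`` (early-adopter
    main effect plus interactions with time, post and tst).  Dispatches on
    the design scale.
    """
    if not design.adopter_interaction:
        raise ValueError("design was not built with adopter_interaction=True")
    if design.scale == "logit":
        return fit_segmented_logistic(design, options)
    return fit_segmented_linear(design, options)


def adopter_class_effects(fit: SegmentedFit) -> pd.DataFrame:
    """Per-class segment effects from an interaction fit (delta-method CIs)."""
    if not fit.adopter_interaction:
        raise ValueError("fit has no adopter-interaction terms")
    z = stats.norm.ppf(0.975)
    rows = []
    for cls, flag in (("late", 0.0), ("early", 1.0)):
        for term, inter in (("time", "early_time"), ("post", "early_post"),
                            ("tst", "early_tst")):
            est, se = fit.combo({term: 1.0, inter: flag})
            rows.append({
                "adopter_class": cls, "term": term, "estimate": est, "se": se,
                "ci_low": est - z * se, "ci_high": est + z * se,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived effects, trajectories, diagnostics


def derive_effects(fit: SegmentedFit, horizon_years: int = 10) -> pd.DataFrame:
    """Post-transition slope, cumulative change, and (logit) per-year ORs.

    The post-transition slope is time + tst; the cumulative k-year change
    after the transition is k times that slope (the immediate level change is
    reported separately).  For log-odds fits the per-year odds ratios
    exp(time) and exp(time + tst) carry delta-method CIs.
    """
    if not fit.converged:
        raise ValueError("cannot derive effects from a non-converged fit")
    z = stats.norm.ppf(0.975)
    rows = []

    def add(name, est, se):
        rows.append({
            "quantity": name, "estimate": est, "se": se,
            "ci_low": est - z * se, "ci_high": est + z * se,
        })

    b1, s1 = fit.combo({"time": 1.0})
    add("pre_slope_per_year", b1, s1)
    b2, s2 = fit.combo({"post": 1.0})
    add("level_change", b2, s2)
    bp, sp_ = fit.combo({"time": 1.0, "tst": 1.0})
    add("post_slope_per_year", bp, sp_)
    add(f"cumulative_{horizon_years}yr_post_change",
        horizon_years * bp, horizon_years * sp_)

    out = pd.DataFrame(rows)
    if fit.scale == "logit":
        or_rows = []
        for name, (est, se) in (
            ("or_pre_per_year", (b1, s1)),
            ("or_post_per_year", (bp, sp_)),
        ):
            orv = float(np.exp(est))
            or_rows.append({
                "quantity": name, "estimate": orv, "se": orv * se,
                "ci_low": float(np.exp(est - z * se)),
                "ci_high": float(np.exp(est + z * se)),
            })
        out = pd.concat([out, pd.DataFrame(or_rows)], ignore_index=True)
    return out


def predict_trajectory(
    fit: SegmentedFit,
    profile: dict[str, float],
    times,
    transition_time: float,
    early_adopter: float | None = None,
) -> pd.DataFrame:
    """Fixed-effect predicted trajectory for one covariate profile.

    ``times`` are on the model's time scale (years since study start);
    ``transition_time`` locates the discontinuity.  The profile must supply
    every covariate in the fit; for interaction fits ``early_adopter``
    selects the class.  Logit-scale fits return predicted probabilities as
    well as the linear predictor.
    """
    covariate_terms = [
        t for t in fit.params.index
        if t not in ("intercept", "time", "post", "tst")
        and not t.startswith("early_") and t != "early_adopter"
    ]
    missing = [t for t in covariate_terms if t not in profile]
    if missing:
        raise ValueError(f"profile is missing covariates: {missing}")
    if fit.adopter_interaction and early_adopter is None:
        raise ValueError("interaction fit requires early_adopter=0 or 1")

    times = np.asarray(times, float)
    post = (times > transition_time).astype(float)
    tst = np.maximum(0.0, times - transition_time) * post
    eta = (
        fit.estimate("intercept")
        + fit.estimate("time") * times
        + fit.estimate("post") * post
        + fit.estimate("tst") * tst
        + sum(fit.estimate(t) * profile[t] for t in covariate_terms)
    )
    if fit.adopter_interaction:
        e = float(early_adopter)
        eta = (
            eta
            + fit.estimate("early_adopter") * e
            + fit.estimate("early_time") * e * times
            + fit.estimate("early_post") * e * post
            + fit.estimate("early_tst") * e * tst
        )
    out = pd.DataFrame({"time": times, "linear_predictor": eta})
    out["prediction"] = expit(eta) if fit.scale == "logit" else eta
    return out


def linearity_check(
    records: pd.DataFrame,
    outcome: str,
    time_col: str = "fiscal_year",
    cohort_col: str = "transition_year",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unadjusted yearly means with straight-line diagnostics.

    Returns (means, fits): per-year outcome means for the overall population
    and for each transition-year cohort, and per-cohort least-squares slope,
    intercept and R².  Cohorts observed in fewer than 3 years are skipped
    with a log message.  Purely descriptive — nothing is gated on R².
    """
    rows = records[records[outcome].notna()]
    if rows[time_col].nunique() < 3:
        raise ValueError("linearity check needs at least 3 distinct years")

    def summarize(sub: pd.DataFrame, label) -> tuple[pd.DataFrame, dict] | None:
        means = sub.groupby(time_col)[outcome].mean().reset_index()
        means.insert(0, "cohort", label)
        if len(means) < 3:
            logger.info("linearity check: cohort %s has <3 years, skipped",
                        label)
            return None
        x = means[time_col].to_numpy(float)
        y = means[outcome].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
        return means, {
            "cohort": label, "slope": slope, "intercept": intercept,
            "r_squared": r2, "n_years": len(means),
        }

    means_frames, fit_rows = [], []
    res = summarize(rows, "overall")
    if res:
        means_frames.append(res[0])
        fit_rows.append(res[1])
    for cohort, sub in rows.groupby(cohort_col):
        res = summarize(sub, int(cohort))
        if res:
            means_frames.append(res[0])
            fit_rows.append(res[1])
    return (pd.concat(means_frames, ignore_index=True),
            pd.DataFrame(fit_rows))
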