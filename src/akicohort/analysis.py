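"""Statistical layer: group comparisons, spline logistic regression with
bootstrap odds-ratio curves, Cox/Kaplan-Meier survival, and the post-hoc
minimal-detectable-odds-ratio power analysis.

The logistic model for AKI uses age as a restricted (natural) cubic spline
with three knots at the 10th/50th/90th age percentiles, so age acts as a
smooth continuous term rather than banded categories. Age odds ratios are
reported relative to a reference age (default 40) through the fitted
probabilities at a fixed covariate profile, with percentile-bootstrap
confidence intervals (participants resampled with replacement, 1000
replicates by default).

Survival uses Cox proportional hazards (Efron ties, via lifelines) adjusted
for age and qSOFA, alongside per-group Kaplan-Meier curves.

The power analysis answers the post-hoc question "given the achieved group
sizes and the control-group event probability, what is the smallest odds
ratio a two-group comparison could detect?". Three test machineries are
available: exact Fisher power (default; the rejection region is enumerated
and the power is an exact binomial sum) and pooled/unpooled-variance normal
approximations of the two-proportion z-test.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from scipy.optimize import brentq

from . import kdigo
from .records import DomainError, ParticipantRecord
from .scores import qsofa_from_values

# ---------------------------------------------------------------------------
# cohort frame assembly

def cohort_frame(cohort: Sequence[ParticipantRecord],
                 method: str = kdigo.MDRD_G100) -> pd.DataFrame:
    """Analysis-ready DataFrame: covariates, qSOFA, and the AKI outcome under
    the given baseline-creatinine method."""
    rows = []
    for rec in cohort:
        cls = kdigo.classify_participant(rec, method) if rec.cr0 is not None else None
        rows.append({
            "pid": rec.pid,
            "age": rec.age,
            "male": None if rec.sex is None else int(rec.sex == "male"),
            "hiv": None if rec.hiv is None else int(rec.hiv),
            "sbp": rec.sbp, "dbp": rec.dbp, "rr": rec.rr, "gcs": rec.gcs,
            "qsofa": qsofa_from_values(rec.sbp, rec.rr, rec.gcs),
            "haematuria": None if rec.haematuria is None else int(rec.haematuria),
            "proteinuria": None if rec.proteinuria is None else int(rec.proteinuria),
            "ri": rec.ri,
            "aki": None if cls is None else int(cls.aki_stage >= 1),
            "aki_stage": None if cls is None else cls.aki_stage,
            "died": None if rec.died is None else int(rec.died),
            "followup_days": rec.followup_days,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons

SHAPIRO_ALPHA = 0.05


def compare_groups(cohort: Sequence[ParticipantRecord], by: str = "aki",
                   variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-variable comparison between the two levels of ``by`` (default AKI
    status): t-test when both groups pass a Shapiro-Wilk normality check,
    rank-sum otherwise; Fisher's exact test for binary variables.
    Complete-case per variable."""
    df = cohort_frame(cohort)
    if by not in df.columns:
        raise DomainError(f"unknown grouping variable {by!r}")
    df = df.dropna(subset=[by])
    groups = [g for _, g in df.groupby(by)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        present = sorted(df[by].dropna().unique().tolist())
        raise DomainError(f"need two non-empty strata of {by!r}; found levels {present}")
    g0, g1 = groups

    continuous = ["age", "sbp", "dbp", "rr", "gcs", "ri"]
    binary = ["male", "hiv", "haematuria", "proteinuria"]
    if variables is not None:
        continuous = [v for v in continuous if v in variables]
        binary = [v for v in binary if v in variables]

    rows = []
    for var in continuous:
        x0, x1 = g0[var].dropna(), g1[var].dropna()
        if len(x0) < 3 or len(x1) < 3:
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "too few observations"})
            continue
        if x0.nunique() <= 1 and x1.nunique() <= 1:
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "constant in both groups"})
            continue
        normal = all(x.nunique() > 1 and stats.shapiro(x).pvalue > SHAPIRO_ALPHA
                     for x in (x0, x1))
        if normal:
            res = stats.ttest_ind(x0, x1)
            rows.append({"variable": var, "test": "t", "statistic": res.statistic,
                         "p": res.pvalue, "note": ""})
        else:
            res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
            rows.append({"variable": var, "test": "rank-sum", "statistic": res.statistic,
                         "p": res.pvalue, "note": ""})
    for var in binary:
        x0, x1 = g0[var].dropna(), g1[var].dropna()
        if len(x0) == 0 or len(x1) == 0:
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "missing in a stratum"})
            continue
        table = [[int((x0 == 1).sum()), int((x0 == 0).sum())],
                 [int((x1 == 1).sum()), int((x1 == 0).sum())]]
        if (np.array(table).sum(axis=0) == 0).any():
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan,
                         "p": np.nan, "note": "constant in both groups"})
            continue
        odds, p = stats.fisher_exact(table)
        rows.append({"variable": var, "test": "fisher", "statistic": odds,
                     "p": p, "note": ""})
    return pd.DataFrame(rows)


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    return float(stats.fisher_exact(table)[1])


# ---------------------------------------------------------------------------
# logistic regression with a spline age term

def natural_spline_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis with 3 knots: columns [x, nonlinear]."""
    t1, t2, t3 = knots
    if not t1 < t2 < t3:
        raise DomainError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    nl = (pos3(x - t1)
          - pos3(x - t2) * (t3 - t1) / (t3 - t2)
          + pos3(x - t3) * (t2 - t1) / (t3 - t2)) / (t3 - t1) ** 2
    return np.column_stack([x, nl])


#: covariates of the fuller, profile-consistent adjusted model
PROFILE_COVARIATES = ("hiv", "qsofa", "dbp")
#: covariates of the leaner adjusted model (age spline + HIV only)
AGE_HIV_COVARIATES = ("hiv",)

DEFAULT_PROFILE = {"hiv": 1, "qsofa": 2, "dbp": 75.0}


@dataclass
class LogisticFit:
    """A fitted AKI logistic model with its design bookkeeping."""

    result: object                  # statsmodels BinaryResults
    knots: tuple[float, float, float]
    covariates: tuple[str, ...]     # covariates besides the age spline
    data: pd.DataFrame              # complete-case rows the fit used

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def odds_ratios(self) -> pd.DataFrame:
        ci = self.result.conf_int()
        out = pd.DataFrame({
            "OR": np.exp(self.result.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        })
        return out

    def design_row(self, age: float, **profile) -> np.ndarray:
        cols = [1.0, *natural_spline_basis([age], self.knots)[0]]
        for cov in self.covariates:
            if cov not in profile:
                raise DomainError(f"profile must fix covariate {cov!r}")
            cols.append(float(profile[cov]))
        return np.asarray(cols)

    def predict_prob(self, age: float, **profile) -> float:
        eta = float(self.design_row(age, **profile) @ self.result.params.values)
        return 1.0 / (1.0 + math.exp(-eta))


def _design(df: pd.DataFrame, knots, covariates) -> tuple[np.ndarray, np.ndarray]:
    spline = natural_spline_basis(df["age"].values, knots)
    X = np.column_stack([np.ones(len(df)), spline] +
                        [df[c].values.astype(float) for c in covariates])
    return df["aki"].values.astype(float), X


def _fit_logit(df: pd.DataFrame, knots, covariates):
    y, X = _design(df, knots, covariates)
    names = ["const", "age_spline1", "age_spline2", *covariates]
    model = sm.Logit(y, pd.DataFrame(X, columns=names))
    return model.fit(disp=0, maxiter=200)


def age_knots(df: pd.DataFrame) -> tuple[float, float, float]:
    """Spline knots at the 10th/50th/90th age percentiles (order-statistic
    quantiles, so replicated rows leave the knots unchanged)."""
    q = np.percentile(df["age"].dropna().values, [10, 50, 90], method="inverted_cdf")
    return tuple(float(v) for v in q)


def fit_aki_logistic(cohort: Sequence[ParticipantRecord], adjusted: bool = True,
                     covariate_set: str = "profile",
                     baseline_method: str = kdigo.MDRD_G100):
    """Logistic regression of AKI (under ``baseline_method``).

    ``adjusted=True`` fits the age spline plus the covariate set: "profile"
    (HIV + qSOFA + diastolic BP, consistent with the fixed prediction
    profile) or "age_hiv" (HIV only). ``adjusted=False`` fits one covariate
    at a time and returns a dict of per-covariate fits.
    """
    df = cohort_frame(cohort, baseline_method)
    df = df.dropna(subset=["aki", "age"])
    if adjusted:
        covs = {"profile": PROFILE_COVARIATES, "age_hiv": AGE_HIV_COVARIATES}[covariate_set]
        sub = df.dropna(subset=list(covs)).reset_index(drop=True)
        knots = age_knots(sub)
        res = _fit_logit(sub, knots, covs)
        _check_separation(res)
        return LogisticFit(result=res, knots=knots, covariates=tuple(covs), data=sub)
    fits = {}
    for cov in ("hiv", "qsofa", "dbp", "haematuria", "proteinuria", "ri", "male"):
        sub = df.dropna(subset=[cov]).reset_index(drop=True)
        if sub.empty or sub[cov].nunique() <= 1:
            continue
        X = sm.add_constant(sub[[cov]].astype(float))
        res = sm.Logit(sub["aki"].astype(float), X).fit(disp=0, maxiter=200)
        _check_separation(res)
        fits[cov] = res
    return fits


def _check_separation(res) -> None:
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 30:
        raise DomainError(
            "logistic fit did not converge (possible separation); consider a "
            "penalised fit"
        )


@dataclass
class ORCurve:
    """Age odds-ratio curve relative to a reference age, with percentile
    bootstrap confidence bands."""

    reference_age: float
    ages: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    replicates: int
    dropped: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "OR": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def _or_vs_reference(fit: LogisticFit, ages, reference_age, profile) -> np.ndarray:
    p_ref = fit.predict_prob(reference_age, **profile)
    odds_ref = p_ref / (1.0 - p_ref)
    out = []
    for a in ages:
        p = fit.predict_prob(a, **profile)
        out.append((p / (1.0 - p)) / odds_ref)
    return np.asarray(out)


def age_or_curve(fit: LogisticFit, profile: Optional[dict] = None,
                 ages: Sequence[float] = (20, 30, 40, 50, 60, 70, 80),
                 reference_age: float = 40.0, replicates: int = 1000,
                 seed: int = 0, max_dropped_fraction: float = 0.05) -> ORCurve:
    """Odds of AKI at each age relative to ``reference_age``, at a fixed
    covariate profile, with percentile-bootstrap 95% CIs.

    Participants are resampled with replacement; the model is refitted with
    the original knots; replicates that fail to converge are dropped (the
    run fails if more than ``max_dropped_fraction`` are)."""
    profile = dict(DEFAULT_PROFILE if profile is None else profile)
    profile = {k: v for k, v in profile.items() if k in fit.covariates}
    ages = np.asarray(ages, dtype=float)
    point = _or_vs_reference(fit, ages, reference_age, profile)

    rng = np.random.default_rng(seed)
    n = len(fit.data)
    boot = []
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        sample = fit.data.iloc[idx].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # non-converged replicates are dropped below
                res = _fit_logit(sample, fit.knots, fit.covariates)
            if not res.mle_retvals.get("converged", True):
                raise DomainError("bootstrap replicate did not converge")
            bfit = LogisticFit(result=res, knots=fit.knots,
                               covariates=fit.covariates, data=sample)
            boot.append(_or_vs_reference(bfit, ages, reference_age, profile))
        except (DomainError, np.linalg.LinAlgError, ValueError):
            dropped += 1
    if dropped > max_dropped_fraction * replicates:
        raise DomainError(
            f"{dropped}/{replicates} bootstrap replicates failed to converge "
            f"(more than {max_dropped_fraction:.0%} allowed)"
        )
    arr = np.asarray(boot)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    at_ref = np.isclose(ages, reference_age)
    point[at_ref], lo[at_ref], hi[at_ref] = 1.0, 1.0, 1.0
    return ORCurve(reference_age=reference_age, ages=ages, odds_ratio=point,
                   ci_low=lo, ci_high=hi, replicates=replicates - dropped,
                   dropped=dropped, seed=seed)


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalFit:
    """Cox PH fit (exposure + age + qSOFA) with per-group KM curves."""

    exposure: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    cox: CoxPHFitter
    km: dict  # group level -> DataFrame(time, survival)


def fit_survival(cohort: Sequence[ParticipantRecord],
                 exposure: str = "hiv") -> SurvivalFit:
    """Cox proportional hazards for death (exposure + age + qSOFA; Efron
    ties) with Kaplan-Meier curves per exposure group.

    Participants lost to follow-up are censored at last contact.
    """
    if exposure not in ("hiv", "aki"):
        raise DomainError(f"exposure must be 'hiv' or 'aki', got {exposure!r}")
    df = cohort_frame(cohort)
    df["event"] = df["died"].fillna(0).astype(int)  # lost -> censored at last contact
    df = df.dropna(subset=[exposure, "age", "qsofa", "followup_days"])
    if df.empty:
        raise DomainError("no complete-case participants for survival analysis")
    if df["event"].sum() == 0:
        raise DomainError("no deaths observed; Cox model refused (KM would be identically 1)")
    for level, g in df.groupby(exposure):
        if g["event"].sum() == 0:
            raise DomainError(f"no events in stratum {exposure}={level}; hazard ratio undefined")

    cox = CoxPHFitter()
    cox.fit(df[["followup_days", "event", exposure, "age", "qsofa"]],
            duration_col="followup_days", event_col="event")
    hr = float(np.exp(cox.params_[exposure]))
    ci = cox.confidence_intervals_
    lo = float(np.exp(ci.loc[exposure].iloc[0]))
    hi = float(np.exp(ci.loc[exposure].iloc[1]))

    km = {}
    for level, g in df.groupby(exposure):
        fitter = KaplanMeierFitter()
        fitter.fit(g["followup_days"], g["event"], label=f"{exposure}={level}")
        sf = fitter.survival_function_
        km[level] = pd.DataFrame({"time": sf.index.values,
                                  "survival": sf.iloc[:, 0].values})
    return SurvivalFit(exposure=exposure, hazard_ratio=hr, ci_low=lo, ci_high=hi,
                       cox=cox, km=km)


# ---------------------------------------------------------------------------
# post-hoc power: minimal detectable odds ratio

@dataclass(frozen=True)
class PowerSpec:
    """Two-group design for the post-hoc power question."""

    n1: int              # control group size
    n2: int              # exposed group size
    p1: float            # control-group event probability
    alpha: float = 0.05
    power: float = 0.80
    sided: int = 2

    def __post_init__(self):
        if not 0 < self.p1 < 1:
            raise DomainError(f"p1 must lie in (0, 1), got {self.p1}")
        if not 0 < self.alpha < self.power < 1:
            raise DomainError(
                f"need 0 < alpha < power < 1, got alpha={self.alpha}, power={self.power}")
        if self.n1 < 1 or self.n2 < 1:
            raise DomainError("group sizes must be >= 1")
        if self.sided not in (1, 2):
            raise DomainError(f"sided must be 1 or 2, got {self.sided}")


POWER_METHODS = ("fisher_exact", "z_pooled", "z_unpooled")


@lru_cache(maxsize=8)
def _fisher_rejection_region(n1: int, n2: int, alpha: float) -> np.ndarray:
    """Boolean matrix over (x1, x2): two-sided Fisher p <= alpha."""
    rej = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    for x1 in range(n1 + 1):
        for x2 in range(n2 + 1):
            p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])[1]
            rej[x1, x2] = p <= alpha
    return rej


def attained_power(spec: PowerSpec, p2: float, method: str = "fisher_exact") -> float:
    """Probability of rejecting H0 at the given exposed-group probability."""
    n1, n2, p1, alpha = spec.n1, spec.n2, spec.p1, spec.alpha
    a = alpha if spec.sided == 2 else 2 * alpha  # internal two-sided quantile
    if method == "fisher_exact":
        rej = _fisher_rejection_region(n1, n2, alpha)
        b1 = stats.binom.pmf(np.arange(n1 + 1), n1, p1)
        b2 = stats.binom.pmf(np.arange(n2 + 1), n2, p2)
        return float(b1 @ rej @ b2)
    za = stats.norm.ppf(1 - a / 2)
    d = abs(p2 - p1)
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if method == "z_unpooled":
        return float(stats.norm.cdf(d / se1 - za) + stats.norm.cdf(-d / se1 - za))
    if method == "z_pooled":
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        return float(stats.norm.cdf((d - za * se0) / se1)
                     + stats.norm.cdf((-d - za * se0) / se1))
    raise DomainError(f"unknown power method {method!r}; expected one of {POWER_METHODS}")


def minimal_detectable_or(spec: PowerSpec, method: str = "fisher_exact") -> float:
    """Smallest odds ratio detectable with the requested power.

    Solves for the exposed-group probability p2 > p1 at which the chosen
    two-group test attains ``spec.power``, then converts (p1, p2) to an odds
    ratio. The root is located to |power error| < 1e-9.
    """
    def gap(p2):
        return attained_power(spec, p2, method) - spec.power

    hi = 1.0 - 1e-9
    if gap(hi) < 0:
        raise DomainError(
            f"no exposed-group probability below 1 attains power {spec.power}")
    p2 = brentq(gap, spec.p1 + 1e-9, hi, xtol=1e-12)
    return (p2 / (1 - p2)) / (spec.p1 / (1 - spec.p1))


def simulated_power(spec: PowerSpec, p2: float, n_sim: int = 50_000,
                    seed: int = 0, method: str = "fisher_exact") -> float:
    """Monte-Carlo attained power: simulate 2x2 tables at (p1, p2) and apply
    the chosen test."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(spec.n1, spec.p1, size=n_sim)
    x2 = rng.binomial(spec.n2, p2, size=n_sim)
    if method == "fisher_exact":
        rej = _fisher_rejection_region(spec.n1, spec.n2, spec.alpha)
        return float(rej[x1, x2].mean())
    a = spec.alpha if spec.sided == 2 else 2 * spec.alpha
    za = stats.norm.ppf(1 - a / 2)
    ph1, ph2 = x1 / spec.n1, x2 / spec.n2
    d = np.abs(ph2 - ph1)
    if method == "z_unpooled":
        se = np.sqrt(ph1 * (1 - ph1) / spec.n1 + ph2 * (1 - ph2) / spec.n2)
    elif method == "z_pooled":
        pbar = (x1 + x2) / (spec.n1 + spec.n2)
        se = np.sqrt(pbar * (1 - pbar) * (1 / spec.n1 + 1 / spec.n2))
    else:
        raise DomainError(f"unknown power method {method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / se, 0.0)
    return float((z > za).mean())


# ---------------------------------------------------------------------------
# outcome summary table

def outcome_table(cohort: Sequence[ParticipantRecord],
                  classifications: Optional[dict] = None) -> pd.DataFrame:
    """Outcome rows with per-endpoint denominators: AKI under each baseline
    strategy, AKD, stage split, incident AKI, recovery, vital status, and
    3-month AKD/CKD among survivors with a 3-month creatinine."""
    if not cohort:
        raise DomainError("outcome_table requires a non-empty cohort")
    if classifications is None:
        classifications = {
            m: [kdigo.classify_participant(r, m) for r in cohort]
            for m in kdigo.BASELINE_METHODS
        }
    rows = []

    def add(label, num, den):
        rows.append({"label": label, "numerator": int(num), "denominator": int(den),
                     "proportion": num / den if den else float("nan")})

    n = len(cohort)
    for m in kdigo.BASELINE_METHODS:
        cls = classifications[m]
        add(f"AKI ({m})", sum(c.aki_stage >= 1 for c in cls), n)

    primary = classifications[kdigo.MDRD_G100]
    n_aki = sum(c.aki_stage >= 1 for c in primary)
    for s in (3, 2, 1):
        add(f"Stage {s} AKI", sum(c.aki_stage == s for c in primary), n_aki)
    add("AKD at admission", sum(c.akd_admission for c in primary), n)

    inc_den = sum(1 for c in primary
                  if c.aki_stage == 0 and c.incident_aki_48h is not None)
    add("Incident AKI (48 h)", sum(c.incident_aki_48h is True for c in primary
                                   if c.aki_stage == 0), inc_den)
    add("Recovered AKI", sum(c.recovered is True for c in primary
                             if c.aki_stage >= 1), n_aki)

    contactable = [r for r in cohort if r.died is not None]
    add("Alive at 48 h",
        sum(not (r.died and (r.followup_days or 0) <= 2.0) for r in contactable),
        len(contactable))
    add("Alive at 3 months", sum(not r.died for r in contactable), len(contactable))

    surv3m = [(r, c) for r, c in zip(cohort, primary)
              if r.died is False and r.cr3m is not None]
    add("AKD at 3 months", sum(c.akd_3m is True for _, c in surv3m), len(surv3m))
    add("CKD", sum(c.ckd == kdigo.CKD_YES for _, c in surv3m), len(surv3m))

    out = pd.DataFrame(rows)
    assert (out["denominator"] <= n).all()
    return out
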