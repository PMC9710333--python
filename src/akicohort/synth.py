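"""Synthetic infection-cohort generator with stored ground truth.

Emulates the statistical structure of a prospective adult cohort admitted
with infection in a setting where baseline creatinine is undocumented:
right-skewed ages, ~47% male, ~60% HIV prevalence among those with known
status, ~33% AKI at admission (majority stage 3), ~30% three-month
mortality with a designed HIV hazard ratio, partial recovery by 48 h, a
latent chronic-kidney-disease subgroup presenting acute-on-chronic, and
realistic missingness (48-h and 3-month creatinine, HIV status, loss to
follow-up).

Design notes:

* The AKI indicator is drawn from a logistic model in HIV, age, qSOFA and
  diastolic BP whose intercept is calibrated per cohort so the mean designed
  risk equals ``aki_prevalence_target``; the designed HIV odds ratio is
  therefore a conditional effect the analysis layer can try to recover.
* Healthy participants' true baseline GFR equals the assumed 100
  mL/min/1.73 m², so the back-calculated baseline the classifier uses is
  exactly their true baseline and, with measurement noise off, every
  classification reproduces the stored truth. Between-subject baseline
  variation in real cohorts is deliberately not simulated.
* The latent chronic subgroup is realised inside the designed-AKI group
  (acute-on-chronic): a true baseline GFR below 60 forces a >=1.56-fold
  ratio over the GFR-100 baseline, so such subjects cannot present
  AKI-negative under the operative definition.
* Death times are exponential with log-hazard ln(hr_hiv_death) for HIV plus
  age and qSOFA effects, the baseline hazard calibrated so the designed
  probability of death by follow-up equals ``p_death_3m``; administrative
  censoring is uniform around the 92-day median follow-up.
* Measurement noise is multiplicative log-normal at ``noise_cv`` (default
  5%, typical enzymatic creatinine imprecision), applied after ground-truth
  labels are computed.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import equations, kdigo
from .equations import EquationSpec, backcalc_creatinine, combined_egfr
from .records import FEMALE, MALE, ParticipantRecord


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters of the cohort simulator.

    Defaults reproduce the emulation targets of the motivating cohort:
    n=101, median age 38 (IQR 29-48), 47% male, 60% HIV among known status,
    33% AKI with a 21/24/55% stage 1/2/3 split, 30% three-month mortality,
    HIV->death hazard ratio 3.97, ~92-day follow-up.
    """

    n: int = 101
    seed: int = 0
    age_med: float = 38.0
    age_iqr: tuple[float, float] = (29.0, 48.0)
    p_male: float = 0.47
    p_hiv: float = 0.60
    p_hiv_missing: float = 16 / 101
    p_art: float = 0.79
    p_ckd_latent: float = 0.10
    aki_prevalence_target: float = 0.33
    stage_probs: tuple[float, float, float] = (0.21, 0.24, 0.55)
    or_hiv_aki: float = 4.0
    or_age_aki_per_decade: float = 2.0
    or_qsofa_aki: float = 1.8
    or_dbp_aki_per_mmhg: float = 1.01
    hr_hiv_death: float = 3.97
    hr_age_death_per_decade: float = 1.5
    hr_qsofa_death: float = 1.7
    p_death_3m: float = 0.30
    recovery_prob: float = 0.55
    p_incident_aki: float = 0.04
    p_haematuria_aki: float = 0.30
    p_haematuria_noaki: float = 0.12
    p_proteinuria_aki: float = 0.55
    p_proteinuria_noaki: float = 0.30
    noise_cv: float = 0.05
    missing_cr48: float = 0.18
    missing_cr3m: float = 5 / 66
    lost_to_followup: float = 7 / 101
    censor_window_days: tuple[float, float] = (80.0, 100.0)
    healthy_gfr: float = 100.0
    chronic_gfr_range: tuple[float, float] = (25.0, 45.0)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        probs = {
            "p_male": self.p_male, "p_hiv": self.p_hiv,
            "p_hiv_missing": self.p_hiv_missing, "p_art": self.p_art,
            "p_ckd_latent": self.p_ckd_latent,
            "aki_prevalence_target": self.aki_prevalence_target,
            "p_death_3m": self.p_death_3m, "recovery_prob": self.recovery_prob,
            "p_incident_aki": self.p_incident_aki,
            "p_haematuria_aki": self.p_haematuria_aki,
            "p_haematuria_noaki": self.p_haematuria_noaki,
            "p_proteinuria_aki": self.p_proteinuria_aki,
            "p_proteinuria_noaki": self.p_proteinuria_noaki,
            "missing_cr48": self.missing_cr48, "missing_cr3m": self.missing_cr3m,
            "lost_to_followup": self.lost_to_followup,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if len(self.stage_probs) != 3 or not math.isclose(sum(self.stage_probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"stage_probs must be 3 probabilities summing to 1, got {self.stage_probs}")
        if any(p < 0 for p in self.stage_probs):
            raise ValueError(f"stage_probs must be non-negative, got {self.stage_probs}")
        if self.aki_prevalence_target > 0 and self.p_ckd_latent > self.aki_prevalence_target:
            raise ValueError(
                "p_ckd_latent cannot exceed aki_prevalence_target: the chronic "
                "subgroup presents acute-on-chronic inside the AKI group"
            )
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent state behind one emitted participant record."""

    pid: str
    true_baseline_cr: float     # mg/dL, back-calculated from the true GFR
    true_gfr: float             # mL/min/1.73 m² before the acute insult
    chronic: bool               # latent chronic kidney disease
    designed_aki: bool          # drawn from the logistic risk model
    designed_stage: int         # 0 when not AKI
    true_death_time: float      # latent days to death (may exceed follow-up)
    # labels a noise-free classifier must reproduce (computed on the
    # noiseless record with the final missingness pattern, MDRD_G100):
    true_aki_stage: int = 0
    true_incident_aki: Optional[bool] = None
    true_recovered: Optional[bool] = None
    true_akd_admission: bool = False
    true_akd_3m: Optional[bool] = None
    true_ckd: str = kdigo.CKD_INDETERMINATE


def paper_default_config(**overrides) -> SyntheticConfig:
    """The configuration whose targets match the printed cohort summaries."""
    return SyntheticConfig(**overrides)


def _lognormal_age(rng, n, med, iqr, lo=18.0, hi=88.0):
    q1, q3 = iqr
    z75 = 0.6744897501960817  # standard normal 75th percentile
    sigma = math.log(q3 / q1) / (2 * z75)
    ages = np.exp(rng.normal(math.log(med), sigma, size=n))
    return np.clip(ages, lo, hi)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept at which mean(expit(b0 + eta)) equals target."""
    if target <= 0.0:
        return -np.inf

    def f(b0):
        return float(np.mean(expit(b0 + eta))) - target

    return brentq(f, -40.0, 40.0, xtol=1e-12)


def _calibrate_log_hazard(eta: np.ndarray, censor: np.ndarray, target: float) -> float:
    """Baseline log-hazard at which mean P(T <= C) equals target."""
    def f(g0):
        lam = np.exp(g0 + eta)
        return float(np.mean(1.0 - np.exp(-lam * censor))) - target

    return brentq(f, -25.0, 10.0, xtol=1e-12)


def _nudge_combined_egfr(person, cr: float, below: bool, threshold: float = 60.0) -> float:
    """Scale a creatinine minimally so the combined eGFR sits on the intended
    side of the CKD threshold (margin 0.5 mL/min/1.73 m²)."""
    for _ in range(200):
        v = combined_egfr(cr, person).value
        if below and v < threshold - 0.5:
            return cr
        if not below and v >= threshold + 0.5:
            return cr
        cr *= 1.02 if below else 1 / 1.02
    return cr


def generate_cohort(config: SyntheticConfig) -> tuple[list[ParticipantRecord], list[GroundTruth]]:
    """Draw a cohort and its ground truth; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = _lognormal_age(rng, n, config.age_med, config.age_iqr)
    male = rng.random(n) < config.p_male
    sex = np.where(male, MALE, FEMALE)
    hiv = rng.random(n) < config.p_hiv
    hiv_missing = rng.random(n) < config.p_hiv_missing
    art = rng.random(n) < config.p_art

    height = np.clip(rng.normal(np.where(male, 170.0, 162.0), 7.0), 140.0, 200.0)
    weight = np.clip(rng.normal(np.where(male, 62.0, 58.0), 10.0), 35.0, 115.0)
    sbp = np.clip(np.round(rng.normal(115.0, 22.0, n)), 60, 230)
    dbp = np.clip(np.round(rng.normal(75.0, 12.0, n)), 35, 140)
    rr = np.clip(np.round(rng.normal(24.0, 6.0, n)), 10, 60)
    gcs = np.where(rng.random(n) < 0.75, 15, rng.integers(10, 15, size=n))
    qsofa = ((sbp <= 100).astype(int) + (rr >= 22).astype(int) + (gcs < 15).astype(int))

    # designed AKI risk: logistic in HIV, age, qSOFA, diastolic BP
    eta = (math.log(config.or_hiv_aki) * hiv
           + math.log(config.or_age_aki_per_decade) * (age - 40.0) / 10.0
           + math.log(config.or_qsofa_aki) * qsofa
           + math.log(config.or_dbp_aki_per_mmhg) * (dbp - 75.0))
    b0 = _calibrate_intercept(eta, config.aki_prevalence_target)
    p_aki = expit(b0 + eta) if np.isfinite(b0) else np.zeros(n)
    aki = rng.random(n) < p_aki

    # chronic subgroup inside the designed AKI group (acute-on-chronic)
    p_chronic_given_aki = (config.p_ckd_latent / config.aki_prevalence_target
                           if config.aki_prevalence_target > 0 else 0.0)
    chronic = aki & (rng.random(n) < p_chronic_given_aki)

    gfr_true = np.full(n, config.healthy_gfr)
    gfr_true[chronic] = rng.uniform(*config.chronic_gfr_range, size=int(chronic.sum()))

    persons = [ParticipantRecord(pid="", age=a, sex=s).person() for a, s in zip(age, sex)]
    mdrd_spec = EquationSpec(equations.MDRD4)
    est_base = np.array([backcalc_creatinine(config.healthy_gfr, p, mdrd_spec) for p in persons])
    true_base = np.array([backcalc_creatinine(g, p, mdrd_spec) for g, p in zip(gfr_true, persons)])

    # admission creatinine: fold multipliers per designed group
    stage = np.zeros(n, dtype=int)
    acute = aki & ~chronic
    stage[acute] = rng.choice([1, 2, 3], size=int(acute.sum()), p=list(config.stage_probs))
    fold = rng.uniform(0.85, 1.30, size=n)  # acute-illness wobble in non-AKI
    fold[stage == 1] = rng.uniform(1.50, 1.95, size=int((stage == 1).sum()))
    fold[stage == 2] = rng.uniform(2.00, 2.95, size=int((stage == 2).sum()))
    fold[stage == 3] = rng.uniform(3.00, 4.50, size=int((stage == 3).sum()))
    cr0 = est_base * fold
    cr0[chronic] = true_base[chronic] * rng.uniform(1.05, 1.30, size=int(chronic.sum()))
    for i in np.flatnonzero(chronic):
        cr0[i] = _nudge_combined_egfr(persons[i], cr0[i], below=True)
    stage_all = np.array([kdigo.stage_aki(c, b) for c, b in zip(cr0, est_base)])
    stage[chronic] = stage_all[chronic]

    # 48-hour creatinine: recovery among acute AKI; incident AKI among non-AKI
    denom = max(1.0 - p_chronic_given_aki, 1e-12)
    p_recover_acute = min(config.recovery_prob / denom, 1.0)
    recover = acute & (rng.random(n) < p_recover_acute)
    cr48 = cr0 * rng.uniform(0.90, 1.08, size=n)
    cr48[recover] = true_base[recover] * rng.uniform(0.95, 1.10, size=int(recover.sum()))
    nonrec = (aki & ~recover)
    cr48[nonrec] = cr0[nonrec] * rng.uniform(0.98, 1.08, size=int(nonrec.sum()))
    incident = ~aki & (rng.random(n) < config.p_incident_aki)
    cr48[incident] = cr0[incident] + rng.uniform(0.35, 0.80, size=int(incident.sum()))

    # 3-month creatinine
    cr3m = true_base * rng.uniform(0.95, 1.05, size=n)  # healthy / recovered track
    cr3m[nonrec & ~chronic] = (est_base * rng.uniform(1.25, 1.45, size=n))[nonrec & ~chronic]
    cr3m[chronic] = (true_base * rng.uniform(1.00, 1.15, size=n))[chronic]
    for i in np.flatnonzero(chronic):
        cr3m[i] = _nudge_combined_egfr(persons[i], cr3m[i], below=True)
    for i in np.flatnonzero(~chronic):
        if combined_egfr(cr3m[i], persons[i]).value < 61.0:
            cr3m[i] = _nudge_combined_egfr(persons[i], cr3m[i], below=False)

    # urine dipstick and resistive index
    haem = rng.random(n) < np.where(aki, config.p_haematuria_aki, config.p_haematuria_noaki)
    prot = rng.random(n) < np.where(aki, config.p_proteinuria_aki, config.p_proteinuria_noaki)
    ri = np.clip(rng.normal(0.66 + 0.03 * aki, 0.07), 0.40, 0.95)

    # survival: exponential with HIV, age and qSOFA log-hazards
    eta_d = (math.log(config.hr_hiv_death) * hiv
             + math.log(config.hr_age_death_per_decade) * (age - 40.0) / 10.0
             + math.log(config.hr_qsofa_death) * qsofa)
    censor = rng.uniform(*config.censor_window_days, size=n)
    g0 = _calibrate_log_hazard(eta_d, censor, config.p_death_3m)
    death_time = rng.exponential(1.0 / np.exp(g0 + eta_d))
    died = death_time <= censor
    followup = np.minimum(death_time, censor)

    lost = rng.random(n) < config.lost_to_followup
    followup[lost] = rng.uniform(1.0, 45.0, size=int(lost.sum()))

    # missingness (deaths force it; MCAR on top)
    miss48 = (rng.random(n) < config.missing_cr48) | (died & (death_time < 2.0))
    miss3m = (rng.random(n) < config.missing_cr3m) | died | lost

    noiseless = {"cr0": cr0.copy(), "cr48": cr48.copy(), "cr3m": cr3m.copy()}
    for key in ("cr0", "cr48", "cr3m"):
        if config.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
            mult = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=n))
            noiseless[key + "_obs"] = noiseless[key] * mult
        else:
            noiseless[key + "_obs"] = noiseless[key].copy()

    records: list[ParticipantRecord] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        pid = f"P{i + 1:04d}"

        def _rec(cr_source_suffix: str) -> ParticipantRecord:
            return ParticipantRecord(
                pid=pid, age=float(age[i]), sex=str(sex[i]),
                hiv=None if hiv_missing[i] else bool(hiv[i]),
                art=bool(art[i]) if (hiv[i] and not hiv_missing[i]) else None,
                sbp=float(sbp[i]), dbp=float(dbp[i]), rr=float(rr[i]), gcs=int(gcs[i]),
                cr0=float(noiseless["cr0" + cr_source_suffix][i]),
                cr48=None if miss48[i] else float(noiseless["cr48" + cr_source_suffix][i]),
                cr3m=None if miss3m[i] else float(noiseless["cr3m" + cr_source_suffix][i]),
                haematuria=bool(haem[i]), proteinuria=bool(prot[i]),
                ri=float(ri[i]), weight=float(weight[i]), height=float(height[i]),
                died=None if lost[i] else bool(died[i]),
                followup_days=float(followup[i]),
            )

        clean = _rec("")
        cls = kdigo.classify_participant(clean, kdigo.MDRD_G100)
        truths.append(GroundTruth(
            pid=pid,
            true_baseline_cr=float(true_base[i]),
            true_gfr=float(gfr_true[i]),
            chronic=bool(chronic[i]),
            designed_aki=bool(aki[i]),
            designed_stage=int(stage[i]),
            true_death_time=float(death_time[i]),
            true_aki_stage=cls.aki_stage,
            true_incident_aki=cls.incident_aki_48h,
            true_recovered=cls.recovered,
            true_akd_admission=cls.akd_admission,
            true_akd_3m=cls.akd_3m,
            true_ckd=cls.ckd,
        ))
        records.append(_rec("_obs"))

    return records, truths
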