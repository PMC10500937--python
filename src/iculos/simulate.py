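"""Synthetic ICU registry generator.

Emulates a full-year adult ICU registry: 125 ICUs in four hospital classes
(metropolitan, private, rural/regional, tertiary), annual volumes spanning
roughly 150–2900 admissions, realistic severity covariates, a between-ICU
random intercept on the log-mean scale, and a right-skewed length of stay
(marginal mean 3.2 d, median 1.8 d, geometric mean ~1.9 d, SD ~4.9 d)
truncated at 180 days.

The generator draws LOS from ``exp(eta)``-mean noise where
``eta = x'beta - center + u_site``; ground truth (``beta``, ``tau2``,
``sigma2`` and each site's latent intercept) is retained so that estimator
recovery can be tested. All randomness flows through one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .registry import HOSP_CLASSES, ModelSpec, Registry, linear_predictor

# ---------------------------------------------------------------------------
# cohort calibration surface (marginal targets the generator reproduces)
# ---------------------------------------------------------------------------

COHORT_TARGETS = {
    "n_patients": 94_361,
    "n_icus": 125,
    "los_mean": 3.2,
    "los_median": 1.8,
    "age_mean": 61.7,
    "age_sd": 17.5,
    "apache3_mean": 54.6,
    "apache3_sd": 25.7,
    "male": 0.583,
    "died_icu": 0.065,
    "vent_d1": 0.435,
    "arf": 0.050,
    "limitation": 0.052,
    "arrest": 0.034,
    "volume_weighted_mean": 1192.0,
    # patient-share and class-median annual volumes
    "class_share": {"MET": 0.169, "PRI": 0.328, "RUR": 0.064, "TER": 0.438},
    "class_volume_median": {"MET": 520.0, "PRI": 983.0, "RUR": 326.0, "TER": 1500.0},
    "class_volume_sigma": {"MET": 0.708, "PRI": 0.600, "RUR": 0.510, "TER": 0.505},
}

VOLUME_MIN, VOLUME_MAX = 150, 2900


def calibrate_los_marginal(target_mean: float, target_median: float) -> tuple[float, float]:
    """Lognormal parameters reproducing a marginal (mean, median) LOS.

    For a lognormal, median = exp(mu) and mean = exp(mu + var/2), so
    ``mu = ln(median)`` and ``var = 2 ln(mean/median)``. The total variance
    is subsequently split between the site intercept (tau2), the covariate
    signal and the residual (sigma2).
    """
    if not (target_mean > target_median > 0):
        raise ValueError(
            "need mean > median > 0: a lognormal marginal cannot produce "
            f"mean={target_mean}, median={target_median}")
    mu = math.log(target_median)
    total_var = 2.0 * math.log(target_mean / target_median)
    return mu, total_var


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

def _default_covariate_params() -> dict:
    return {
        "age": {"loc": 61.7, "scale": 17.5, "lower": 16.0, "upper": 110.0},
        # positively skewed severity score; skew-normal truncated to [0, 299]
        "apache3": {"a": 3.0, "loc": 24.8, "scale": 39.3, "lower": 0.0, "upper": 299.0},
        # risk of death: logit-normal tied linearly to standardized APACHE III
        # so that risk adjustment has signal (target correlation ~0.7)
        "anzrod": {"alpha": -4.06, "slope": 1.43, "resid_sd": 1.457},
        "preicu_days": {"mu": math.log(0.4), "sigma": 1.626, "cap": 60.0},
        "male": 0.583,
        "arf": 0.050,
        "limitation": 0.052,
        "arrest": 0.034,
        # ventilation tilted by severity; intercept calibrated to 43.5%
        "vent_d1": {"alpha": -0.30, "apache_slope": 0.02},
        # ICU death: Bernoulli with probability proportional to ANZROD
        "died_icu": {"scale": 1.0},
        "dx_group": {"decay": 0.08, "n_levels": 30},
    }


def _default_beta() -> dict[str, float]:
    """Fixed effects on the log-mean scale, expressed on raw covariate units.

    Magnitudes are chosen from standardized effect sizes (e.g. +0.25 log-days
    per SD of APACHE III) so that the covariate signal explains roughly a
    quarter of log-LOS variance, in the range observed for ICU LOS models.
    """
    m_ap, s_ap = 54.6, 25.7
    m_age, s_age = 61.7, 17.5
    z_ap, z2_ap = 0.25, 0.04
    z_age, z2_age = -0.08, 0.03
    beta = {
        "apache3": z_ap / s_ap - 2 * z2_ap * m_ap / s_ap ** 2,
        "apache3_2": z2_ap / s_ap ** 2,
        "age": z_age / s_age - 2 * z2_age * m_age / s_age ** 2,
        "age2": z2_age / s_age ** 2,
        "log_anzrod": 0.10,
        "preicu_days": 0.02,
        "vent_d1": 0.45,
        "died_icu": -0.45,
        "arf": 0.25,
        "limitation": -0.10,
        "arrest": 0.10,
        "class_PRI": -0.05,
        "class_RUR": 0.0,
        "class_TER": 0.05,
    }
    dx_fx = np.random.default_rng(777).normal(0.0, 0.06, 29)
    for k, fx in enumerate(dx_fx, start=2):
        beta[f"dx_{k}"] = float(fx)
    return beta


DEFAULT_GEN_TERMS = [
    "age", "age2", "apache3", "apache3_2", "log_anzrod", "preicu_days",
    "died_icu", "arf", "limitation", "arrest", "vent_d1",
    "hosp_class", "dx_group",
]


@dataclass
class SimConfig:
    """Full description of the synthetic data-generating process."""

    n_icus: int = 125
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            c: v / sum(COHORT_TARGETS["class_share"].values())
            for c, v in COHORT_TARGETS["class_share"].items()})
    #: per-class {n_icus, log_median, sigma, quota}; None means a flat
    #: ``uniform_volume`` per site
    volume_model: Mapping[str, dict] | None = None
    uniform_volume: int | None = None
    covariate_params: dict = field(default_factory=_default_covariate_params)
    beta: dict = field(default_factory=_default_beta)
    gen_terms: list = field(default_factory=lambda: list(DEFAULT_GEN_TERMS))
    #: subtracted from x'beta so the marginal log-LOS mean lands on target
    linear_center: float = 0.0
    tau2: float = 0.05
    sigma2: float = 0.85
    noise_family: str = "lognormal"  # {lognormal | gamma}
    gamma_shape: float = 1.7
    #: weight-centre site intercepts (sum of volume*u = 0) so cohort-level
    #: LOS moments do not drift with the finite draw of 125 site effects;
    #: left off in recovery configs where u must be iid N(0, tau2)
    center_site_effects: bool = False
    los_truncation_days: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_icus < 2:
            raise ValueError("n_icus must be >= 2")
        if not math.isclose(sum(self.class_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix proportions must sum to 1")
        if self.tau2 < 0 or self.sigma2 <= 0:
            raise ValueError("need tau2 >= 0 and sigma2 > 0")
        if self.los_truncation_days <= 0:
            raise ValueError("los_truncation_days must be positive")
        if self.noise_family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")

    def to_provenance(self) -> dict:
        return {
            "n_icus": self.n_icus, "tau2": self.tau2, "sigma2": self.sigma2,
            "noise_family": self.noise_family, "seed": self.seed,
            "linear_center": round(self.linear_center, 6),
            "los_truncation_days": self.los_truncation_days,
        }


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------

def _draw_covariates(n: int, params: dict, hosp_class: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    p_age = params["age"]
    a_lo = (p_age["lower"] - p_age["loc"]) / p_age["scale"]
    a_hi = (p_age["upper"] - p_age["loc"]) / p_age["scale"]
    age = stats.truncnorm.ppf(rng.uniform(size=n), a_lo, a_hi,
                              loc=p_age["loc"], scale=p_age["scale"])

    p_ap = params["apache3"]
    ap_raw = stats.skewnorm.ppf(rng.uniform(size=n), p_ap["a"],
                                loc=p_ap["loc"], scale=p_ap["scale"])
    # re-draw the (rare) out-of-range scores from the clipped body
    ap_raw = np.clip(ap_raw, p_ap["lower"], p_ap["upper"])
    apache3 = np.rint(ap_raw).astype(int)

    p_an = params["anzrod"]
    z_ap = (apache3 - COHORT_TARGETS["apache3_mean"]) / COHORT_TARGETS["apache3_sd"]
    logit = (p_an["alpha"] + p_an["slope"] * z_ap
             + rng.normal(0.0, p_an["resid_sd"], n))
    anzrod = np.clip(1.0 / (1.0 + np.exp(-logit)), 1e-6, 1 - 1e-6)

    p_pre = params["preicu_days"]
    preicu = np.minimum(rng.lognormal(p_pre["mu"], p_pre["sigma"], n), p_pre["cap"])

    male = (rng.uniform(size=n) < params["male"]).astype(int)
    arf = (rng.uniform(size=n) < params["arf"]).astype(int)
    limitation = (rng.uniform(size=n) < params["limitation"]).astype(int)
    arrest = (rng.uniform(size=n) < params["arrest"]).astype(int)

    p_v = params["vent_d1"]
    lv = p_v["alpha"] + p_v["apache_slope"] * (apache3 - COHORT_TARGETS["apache3_mean"])
    vent = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lv))).astype(int)

    p_die = np.minimum(anzrod * params["died_icu"]["scale"], 1.0)
    died = (rng.uniform(size=n) < p_die).astype(int)

    p_dx = params["dx_group"]
    w = np.exp(-p_dx["decay"] * np.arange(1, p_dx["n_levels"] + 1))
    dx = rng.choice(np.arange(1, p_dx["n_levels"] + 1), size=n, p=w / w.sum())

    return pd.DataFrame({
        "age": age, "apache3": apache3, "anzrod": anzrod,
        "preicu_days": preicu, "died_icu": died, "arf": arf,
        "limitation": limitation, "arrest": arrest, "vent_d1": vent,
        "dx_group": dx, "male": male, "hosp_class": hosp_class,
    })


# ---------------------------------------------------------------------------
# site structure (deterministic quantile-stratified volumes)
# ---------------------------------------------------------------------------

def _class_volumes(model: Mapping[str, dict]) -> tuple[list[str], np.ndarray]:
    """Materialize per-site volumes from the per-class volume model.

    Within a class, volumes sit at evenly spaced quantiles of a truncated
    lognormal and are then scaled so the class's total admissions hit its
    patient-share quota; this keeps the class patient shares and the
    volume-weighted mean essentially free of sampling noise.
    """
    classes, volumes = [], []
    for cls in HOSP_CLASSES:
        m = model[cls]
        n_c = int(m["n_icus"])
        q = (np.arange(n_c) + 0.5) / n_c
        v = np.exp(m["log_median"] + m["sigma"] * stats.norm.ppf(q))
        v = np.clip(v, VOLUME_MIN, VOLUME_MAX)
        v = v * (m["quota"] / v.sum())
        v = np.maximum(np.rint(v), VOLUME_MIN).astype(int)
        classes.extend([cls] * n_c)
        volumes.append(v)
    return classes, np.concatenate(volumes)


def _solve_volume_model(n_icus: int, n_patients: int,
                        class_mix: Mapping[str, float]) -> dict:
    """Calibrate the per-class volume model.

    One free dispersion-shrink factor is solved so that the patient-weighted
    mean annual volume matches the cohort target, subject to the class
    patient shares, the class median volumes, and the total ICU count.
    """
    med = COHORT_TARGETS["class_volume_median"]
    sig0 = COHORT_TARGETS["class_volume_sigma"]

    def build(shrink: float) -> dict:
        a = {c: med[c] * math.exp(0.5 * (shrink * sig0[c]) ** 2)
             for c in HOSP_CLASSES}
        raw = {c: class_mix[c] / a[c] for c in HOSP_CLASSES}
        tot = sum(raw.values())
        n_c = {c: max(2, int(round(n_icus * raw[c] / tot))) for c in HOSP_CLASSES}
        # largest-remainder style fixup so counts sum exactly to n_icus
        while sum(n_c.values()) != n_icus:
            step = 1 if sum(n_c.values()) < n_icus else -1
            key = max(HOSP_CLASSES,
                      key=lambda c: step * (n_icus * raw[c] / tot - n_c[c]))
            n_c[key] = max(2, n_c[key] + step)
        return {c: {"n_icus": n_c[c], "log_median": math.log(med[c]),
                    "sigma": shrink * sig0[c],
                    "quota": class_mix[c] * n_patients}
                for c in HOSP_CLASSES}

    def weighted_mean_err(shrink: float) -> float:
        _, v = _class_volumes(build(shrink))
        wm = float((v.astype(float) ** 2).sum() / v.sum())
        return wm - COHORT_TARGETS["volume_weighted_mean"]

    shrink = optimize.brentq(weighted_mean_err, 0.3, 1.3, xtol=1e-4)
    return build(shrink)


# ---------------------------------------------------------------------------
# default-config calibration
# ---------------------------------------------------------------------------

_CAL_SEED = 20_160_101  # internal constant: part of the config definition
_CAL_N = 200_000
_default_cache: dict = {}


def default_sim_config(seed: int = 0, noise_family: str = "lognormal") -> SimConfig:
    """The calibrated default generating process.

    Location parameters of age, severity, ventilation and ICU-death are
    centred on the cohort targets with one large internal covariate draw;
    the residual variance is then set so the marginal LOS reproduces the
    target mean/median via the lognormal moment equations.
    """
    key = noise_family
    if key not in _default_cache:
        _default_cache[key] = _calibrate_default(noise_family)
    return replace(_default_cache[key], seed=seed)


def _calibrate_default(noise_family: str) -> SimConfig:
    mu, total_var = calibrate_los_marginal(
        COHORT_TARGETS["los_mean"], COHORT_TARGETS["los_median"])
    tau2 = 0.05
    params = _default_covariate_params()
    beta = _default_beta()
    rng = np.random.default_rng(_CAL_SEED)
    raw_mix = COHORT_TARGETS["class_share"]  # printed shares sum to 0.999
    tot = sum(raw_mix.values())
    mix = {c: v / tot for c, v in raw_mix.items()}
    cls = rng.choice(HOSP_CLASSES, size=_CAL_N,
                     p=[mix[c] for c in HOSP_CLASSES])

    # pass 1: measure and recentre covariate locations on cohort targets
    cov = _draw_covariates(_CAL_N, params, cls, rng)
    params["age"]["loc"] += COHORT_TARGETS["age_mean"] - cov["age"].mean()
    params["apache3"]["loc"] += COHORT_TARGETS["apache3_mean"] - cov["apache3"].mean()
    pv = cov["vent_d1"].mean()
    params["vent_d1"]["alpha"] += (math.log(COHORT_TARGETS["vent_d1"] / (1 - COHORT_TARGETS["vent_d1"]))
                                   - math.log(pv / (1 - pv)))
    params["died_icu"]["scale"] = COHORT_TARGETS["died_icu"] / cov["anzrod"].mean()

    # pass 2: centre the covariate signal and size the residual variance so
    # exp(E log LOS) and E[LOS] land on the target median and mean
    cov = _draw_covariates(_CAL_N, params, cls, rng)
    spec = ModelSpec(response="los_days", family_link="gaussian_log",
                     fixed_terms=DEFAULT_GEN_TERMS, interactions=[])
    g = linear_predictor(cov, spec, beta)
    center = float(np.mean(g))
    log_m_exp = float(np.log(np.mean(np.exp(g - center))))  # lognormal-equivalent var/2
    sigma2 = total_var - tau2 - 2.0 * log_m_exp
    if sigma2 <= 0.1:
        raise RuntimeError("covariate signal too strong for the marginal target")
    # intercept such that E[LOS | x, u] = exp(eta) and E[log LOS] = mu
    beta = dict(beta)
    beta["intercept"] = mu + sigma2 / 2.0

    volume_model = _solve_volume_model(
        COHORT_TARGETS["n_icus"], COHORT_TARGETS["n_patients"], mix)

    return SimConfig(
        n_icus=COHORT_TARGETS["n_icus"], class_mix=dict(mix),
        volume_model=volume_model, covariate_params=params, beta=beta,
        gen_terms=list(DEFAULT_GEN_TERMS), linear_center=center,
        tau2=tau2, sigma2=sigma2, noise_family=noise_family,
        center_site_effects=True, seed=0)


def simple_sim_config(n_icus: int, patients_per_site: int, *,
                      beta: dict | None = None, gen_terms: list | None = None,
                      tau2: float = 0.05, sigma2: float = 0.85,
                      noise_family: str = "lognormal", gamma_shape: float = 1.7,
                      seed: int = 0) -> SimConfig:
    """Small-scale config with flat volumes, for estimator-recovery studies.

    ``beta`` names design columns (including ``intercept``); generation then
    satisfies eta = x'beta + u exactly, so the generating coefficients are
    the recovery oracle.
    """
    if gen_terms is None:
        gen_terms = ["apache3", "log_anzrod", "vent_d1", "died_icu"]
    if beta is None:
        beta = {"intercept": 0.6, "apache3": 0.008, "log_anzrod": 0.08,
                "vent_d1": 0.4, "died_icu": -0.4}
    mix = {"MET": 0.25, "PRI": 0.25, "RUR": 0.25, "TER": 0.25}
    return SimConfig(n_icus=n_icus, class_mix=mix, volume_model=None,
                     uniform_volume=patients_per_site, beta=dict(beta),
                     gen_terms=list(gen_terms), linear_center=0.0,
                     tau2=tau2, sigma2=sigma2, noise_family=noise_family,
                     gamma_shape=gamma_shape, seed=seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_registry(config: SimConfig) -> Registry:
    """Draw one registry from ``config``; deterministic given its seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    if config.volume_model is not None:
        classes, volumes = _class_volumes(config.volume_model)
    elif config.uniform_volume is not None:
        order = sorted(config.class_mix, key=lambda c: HOSP_CLASSES.index(c))
        classes = [order[i % len(order)] for i in range(config.n_icus)]
        volumes = np.full(config.n_icus, int(config.uniform_volume))
    else:
        raise ValueError("config needs volume_model or uniform_volume")

    n_sites = len(classes)
    icu_ids = np.arange(1, n_sites + 1)
    true_re = (rng.normal(0.0, math.sqrt(config.tau2), n_sites)
               if config.tau2 > 0 else np.zeros(n_sites))
    if config.center_site_effects and config.tau2 > 0:
        w = volumes / volumes.sum()
        true_re = true_re - float(w @ true_re)
    sites = pd.DataFrame({"icu_id": icu_ids, "hosp_class": classes,
                          "annual_volume": volumes, "true_re": true_re})

    site_index = np.repeat(np.arange(n_sites), volumes)
    n = len(site_index)
    cov = _draw_covariates(n, config.covariate_params,
                           np.asarray(classes, dtype=object)[site_index], rng)

    spec = ModelSpec(response="los_days", family_link="gaussian_log",
                     fixed_terms=config.gen_terms, interactions=[])
    eta = (linear_predictor(cov, spec, config.beta) - config.linear_center
           + true_re[site_index])
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; rejecting config")

    if config.noise_family == "lognormal":
        # E[LOS | eta] = exp(eta) requires the -sigma2/2 offset on the log scale
        log_los = (eta - config.sigma2 / 2.0
                   + math.sqrt(config.sigma2) * rng.standard_normal(n))
        los = np.exp(log_los)
    else:  # gamma: mean exp(eta), fixed shape => constant coefficient of variation
        k = config.gamma_shape
        los = rng.gamma(k, np.exp(eta) / k, n)
    los = np.clip(los, 1e-3, config.los_truncation_days)

    patients = cov.assign(icu_id=icu_ids[site_index], los_days=los)
    patients = patients[["icu_id", "age", "apache3", "anzrod", "preicu_days",
                         "died_icu", "arf", "limitation", "arrest", "vent_d1",
                         "dx_group", "los_days", "male", "hosp_class"]]
    return Registry(patients=patients, sites=sites,
                    provenance={"sim_config": config.to_provenance()})


def true_fe_prediction(registry: Registry, config: SimConfig,
                       scale: str = "days") -> np.ndarray:
    """Oracle fixed-effect prediction from the generating process.

    ``days``: E[LOS | x] without the site effect, i.e. exp(x'beta - center);
    ``log_days``: E[log LOS | x] under lognormal noise.
    """
    spec = ModelSpec(fixed_terms=config.gen_terms, interactions=[])
    eta = linear_predictor(registry.patients, spec, config.beta) - config.linear_center
    if scale == "days":
        return np.exp(eta)
    if scale == "log_days":
        return eta - config.sigma2 / 2.0
    raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# demographic summary
# ---------------------------------------------------------------------------

def summarize_registry(registry: Registry) -> pd.DataFrame:
    """Cohort demographics in the registry's reporting style.

    One row per variable with mean/SD, median/IQR, geometric mean where the
    variable is positive, and proportions for binary flags. The geometric
    mean is exp(mean(log x)).
    """
    p = registry.patients
    if len(p) == 0:
        raise ValueError("empty registry")
    rows = []

    def cont(name, x, geometric=False):
        x = np.asarray(x, dtype=float)
        row = {"variable": name, "mean": x.mean(), "sd": x.std(ddof=1),
               "median": np.median(x), "q25": np.percentile(x, 25),
               "q75": np.percentile(x, 75), "geo_mean": np.nan,
               "proportion": np.nan}
        if geometric:
            row["geo_mean"] = float(np.exp(np.mean(np.log(x))))
        rows.append(row)

    def binary(name, x):
        rows.append({"variable": name, "mean": np.nan, "sd": np.nan,
                     "median": np.nan, "q25": np.nan, "q75": np.nan,
                     "geo_mean": np.nan, "proportion": float(np.mean(x))})

    cont("age", p["age"])
    cont("preicu_days", p["preicu_days"])
    vol = registry.sites.set_index("icu_id")["annual_volume"]
    cont("icu_annual_volume", p["icu_id"].map(vol))
    cont("apache3", p["apache3"])
    cont("los_days", p["los_days"], geometric=True)
    if "male" in p.columns:
        binary("male", p["male"])
    for flag in ["died_icu", "vent_d1", "arf", "arrest", "limitation"]:
        binary(flag, p[flag])
    for cls in HOSP_CLASSES:
        binary(f"class_{cls}", (p["hosp_class"] == cls).astype(float))
    return pd.DataFrame(rows)
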