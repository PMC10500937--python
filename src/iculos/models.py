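"""Mixed-effects estimators of ICU length of stay.

Two estimators of the same covariate structure, each with an ICU random
intercept:

* **LMM** — linear mixed model on log(LOS), identity link (via
  :class:`statsmodels` ``MixedLM``, maximum likelihood).
* **GLMM** — gaussian family with a log link on raw LOS in days, i.e. a
  nonlinear mixed model with conditional mean ``exp(x'b + u)``. No installed
  package fits this family/link with a random intercept, so the marginal
  likelihood is maximized here under a Laplace approximation: an inner
  Newton solve for each site's intercept mode and a Gauss-Newton profile of
  the fixed effects, wrapped in a quasi-Newton search over the two variance
  components. Starting values come from the LMM fit.

Both report ML variance components, per-ICU predicted random intercepts
(posterior modes) with conditional SEs, and information criteria computed
from the (Laplace) log-likelihood, so AIC/BIC are comparable across
fixed-effect sets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .registry import ModelSpec, Registry, build_design

log = logging.getLogger("iculos")

MAX_OUTER_ITER = 500


@dataclass
class FittedMixedModel:
    kind: str                      # {lmm | glmm}
    spec: ModelSpec
    beta_hat: pd.Series            # fixed coefficients, named by design column
    tau2_hat: float                # between-ICU intercept variance
    sigma2_hat: float              # residual variance (log scale for LMM, days^2 for GLMM)
    re: pd.DataFrame               # columns: icu_id, re, se (posterior modes, conditional SE)
    loglik: float
    n_used: int
    converged: bool
    n_iter: int

    @property
    def n_params(self) -> int:
        return len(self.beta_hat) + 2  # fixed effects + (tau2, sigma2)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_used)


@dataclass
class PredictionSet:
    values: pd.Series              # indexed like the complete-case patient rows
    mode: str                      # {FE | RE}
    scale: str                     # {days | log_days}
    model_kind: str


@dataclass
class ValidationReport:
    r2_development: float
    r2_validation: float
    development_sites: list
    validation_sites: list
    n_development: int
    n_validation: int


# ---------------------------------------------------------------------------
# shared data preparation
# ---------------------------------------------------------------------------

def _prepare(registry: Registry, spec: ModelSpec):
    df = registry.patients
    if not (df["los_days"] > 0).all():
        raise ValueError("all los_days must be positive")
    X, names, mask = build_design(df, spec)
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("complete-case analysis: dropped %d/%d rows with missing "
                 "covariates", n_dropped, len(df))
    sub = df.loc[mask]
    y = sub["los_days"].to_numpy(dtype=float)
    groups = sub["icu_id"].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = [names[i] for i in np.where(np.abs(vt[s < s.max() * 1e-10]).max(axis=0) > 0.1)[0]] \
            if (s < s.max() * 1e-10).any() else names
        raise ValueError(f"singular design matrix; involved columns: {bad}")
    return X, names, y, groups, sub.index


def _conditional_se_lmm(tau2: float, sigma2: float, n_i: np.ndarray) -> np.ndarray:
    # posterior variance of a random intercept given its site's data
    return np.sqrt(tau2 * sigma2 / (sigma2 + n_i * tau2)) if tau2 > 0 \
        else np.zeros(len(n_i))


# ---------------------------------------------------------------------------
# LMM on log(LOS)
# ---------------------------------------------------------------------------

def fit_lmm(registry: Registry, spec: ModelSpec | None = None) -> FittedMixedModel:
    """ML linear mixed model of log(LOS) with an ICU random intercept."""
    spec = spec or ModelSpec.lmm_default()
    X, names, y, groups, _ = _prepare(registry, spec)
    logy = np.log(y)
    site_ids, site_codes = np.unique(groups, return_inverse=True)
    n_i = np.bincount(site_codes)

    if len(site_ids) < 2:
        # one group: the intercept absorbs the site; model degenerates to OLS
        beta, _, _, _ = np.linalg.lstsq(X, logy, rcond=None)
        resid = logy - X @ beta
        sigma2 = float(resid @ resid / len(logy))  # ML
        ll = float(-0.5 * len(logy) * (math.log(2 * math.pi * sigma2) + 1))
        re = pd.DataFrame({"icu_id": site_ids, "re": [0.0], "se": [0.0],
                           "n": [len(logy)]})
        return FittedMixedModel("lmm", spec, pd.Series(beta, index=names),
                                0.0, sigma2, re, ll, len(logy), True, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(logy, X, groups=site_codes)
        res = model.fit(reml=False, maxiter=MAX_OUTER_ITER)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    # posterior-mode (BLUP) intercepts in closed form; robust at tau2 -> 0
    resid = logy - X @ res.fe_params
    site_mean = np.bincount(site_codes, weights=resid) / n_i
    re_vals = (tau2 * n_i / (sigma2 + n_i * tau2)) * site_mean
    re = pd.DataFrame({"icu_id": site_ids, "re": re_vals,
                       "se": _conditional_se_lmm(tau2, sigma2, n_i), "n": n_i})
    return FittedMixedModel("lmm", spec, pd.Series(np.asarray(res.fe_params), index=names),
                            tau2, sigma2, re, float(res.llf), len(logy),
                            bool(res.converged), MAX_OUTER_ITER)


# ---------------------------------------------------------------------------
# GLMM: gaussian family, log link (Laplace-approximated ML)
# ---------------------------------------------------------------------------

def _segment_sums(v: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(v, starts)


def _glmm_modes(eta0, y, u, starts, codes, sigma2, tau2, max_iter=50, tol=1e-10):
    """Newton solve for each site's intercept mode (vectorized over sites)."""
    for _ in range(max_iter):
        mu = np.exp(eta0 + u[codes])
        r = y - mu
        grad = _segment_sums(r * mu, starts) / sigma2 - u / tau2
        curv = _segment_sums(mu * mu - r * mu, starts) / sigma2 + 1.0 / tau2
        curv = np.maximum(curv, 1e-10)
        step = np.clip(grad / curv, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    return u


def _glmm_profile(X, y, starts, codes, n_i, beta, u, sigma2, tau2,
                  max_iter=100, tol=1e-11):
    """Joint penalized Gauss-Newton for (beta, u) at fixed variance ratio.

    Minimizes ||y - exp(X b + Z u)||^2 + (sigma2/tau2)||u||^2 via the
    augmented normal equations, assembling the u-block with segment sums so
    the n x m indicator matrix is never formed.
    """
    lam_pen = sigma2 / tau2
    m, p = len(n_i), X.shape[1]

    def pen_ss(b, v):
        r = y - np.exp(np.clip(X @ b + v[codes], -700, 700))
        return r @ r + lam_pen * (v @ v)

    current = pen_ss(beta, u)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + u[codes], -700, 700)
        mu = np.exp(eta)
        r = y - mu
        muX = mu[:, None] * X
        H = np.empty((p + m, p + m))
        H[:p, :p] = muX.T @ muX
        Hbu = np.stack([_segment_sums(mu * mu * X[:, k], starts)
                        for k in range(p)])        # p x m
        H[:p, p:] = Hbu
        H[p:, :p] = Hbu.T
        H[p:, p:] = np.diag(_segment_sums(mu * mu, starts) + lam_pen)
        g = np.concatenate([muX.T @ r, _segment_sums(mu * r, starts) - lam_pen * u])
        H[np.diag_indices_from(H)] += 1e-12 * max(np.trace(H) / (p + m), 1.0)
        step = np.linalg.solve(H, g)
        scale = 1.0
        for _ in range(40):
            b_new = beta + scale * step[:p]
            u_new = u + scale * step[p:]
            new = pen_ss(b_new, u_new)
            if new <= current + 1e-12:
                break
            scale *= 0.5
        else:
            break
        moved = scale * np.max(np.abs(step))
        beta, u, current = b_new, u_new, new
        if moved < tol * (1.0 + np.max(np.abs(beta))):
            break
    u = _glmm_modes(X @ beta, y, u, starts, codes, sigma2, tau2)
    return beta, u


def _glmm_laplace_ll(X, y, starts, codes, n_i, beta, u, sigma2, tau2):
    eta = X @ beta + u[codes]
    mu = np.exp(eta)
    r = y - mu
    ss_i = _segment_sums(r * r, starts)
    curv = _segment_sums(mu * mu - r * mu, starts) / sigma2 + 1.0 / tau2
    curv = np.maximum(curv, 1e-12)
    ll = float(np.sum(
        -ss_i / (2 * sigma2) - u ** 2 / (2 * tau2)
        - 0.5 * n_i * math.log(2 * math.pi * sigma2)
        - 0.5 * math.log(tau2) - 0.5 * np.log(curv)))
    return ll


def _fit_exp_nls(X, y, names, spec, site_ids, logy_start):
    """Degenerate GLMM (tau2 pinned at 0): gaussian nonlinear LS with exp link."""
    beta = logy_start
    for _ in range(200):
        mu = np.exp(np.clip(X @ beta, -700, 700))
        r = y - mu
        J = mu[:, None] * X
        JtJ = J.T @ J
        JtJ[np.diag_indices_from(JtJ)] += 1e-12 * max(np.trace(JtJ), 1.0)
        step = np.linalg.solve(JtJ, J.T @ r)
        ss0 = r @ r
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            r_c = y - np.exp(np.clip(X @ cand, -700, 700))
            if r_c @ r_c <= ss0:
                break
            lam *= 0.5
        beta = beta + lam * step
        if np.max(np.abs(lam * step)) < 1e-12 * (1 + np.max(np.abs(beta))):
            break
    resid = y - np.exp(X @ beta)
    sigma2 = float(resid @ resid / len(y))
    ll = float(-0.5 * len(y) * (math.log(2 * math.pi * sigma2) + 1))
    re = pd.DataFrame({"icu_id": site_ids, "re": np.zeros(len(site_ids)),
                       "se": np.zeros(len(site_ids))})
    re["n"] = len(y) if len(site_ids) == 1 else np.nan
    return FittedMixedModel("glmm", spec, pd.Series(beta, index=names),
                            0.0, sigma2, re, ll, len(y), True, 1)


def fit_glmm_log_gaussian(registry: Registry, spec: ModelSpec | None = None,
                          start_from: FittedMixedModel | None = None,
                          fix_tau2_zero: bool = False) -> FittedMixedModel:
    """Gaussian-family, log-link mixed model of raw LOS (days).

    Laplace-approximated maximum likelihood; see the module docstring for
    the optimization scheme. Non-convergence within the iteration budget is
    flagged on the result (never silent).
    """
    spec = spec or ModelSpec.glmm_default()
    X, names, y, groups, _ = _prepare(registry, spec)

    order = np.argsort(groups, kind="stable")
    X, y, groups = X[order], y[order], groups[order]
    site_ids, codes = np.unique(groups, return_inverse=True)
    n_i = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(n_i)[:-1]])

    # starting values from the log-scale linear model
    if start_from is not None and list(start_from.beta_hat.index) == names:
        lmm = start_from
    else:
        lmm = fit_lmm(registry, ModelSpec(response="log_los",
                                          family_link="gaussian_identity_on_log",
                                          fixed_terms=spec.fixed_terms,
                                          interactions=spec.interactions,
                                          grouping=spec.grouping))
    beta0 = lmm.beta_hat.to_numpy().copy()
    beta0[0] += lmm.sigma2_hat / 2.0  # lognormal mean offset

    if fix_tau2_zero or len(site_ids) < 2:
        return _fit_exp_nls(X, y, names, spec, site_ids, beta0)

    sigma2_0 = max(float(np.mean((y - np.exp(np.clip(X @ beta0, -700, 700))) ** 2)),
                   1e-6)
    tau2_0 = max(lmm.tau2_hat, 1e-4)

    state = {"beta": beta0, "u": np.zeros(len(site_ids)), "nfev": 0}

    def negll(theta):
        sigma2, tau2 = np.exp(theta)
        beta, u = _glmm_profile(X, y, starts, codes, n_i,
                                state["beta"].copy(), state["u"].copy(),
                                sigma2, tau2)
        state["beta"], state["u"] = beta, u
        state["nfev"] += 1
        return -_glmm_laplace_ll(X, y, starts, codes, n_i, beta, u, sigma2, tau2)

    # derivative-free outer search: the profiled Laplace objective is cheap
    # in 2-d and finite-difference gradients of a profiled objective are
    # unreliable near the optimum
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            negll, np.log([sigma2_0, tau2_0]), method="Nelder-Mead",
            bounds=[(-10.0, 12.0), (-16.0, 4.0)],
            options={"maxiter": MAX_OUTER_ITER, "xatol": 1e-4, "fatol": 1e-7})

    sigma2, tau2 = np.exp(res.x)
    beta, u = _glmm_profile(X, y, starts, codes, n_i, state["beta"], state["u"],
                            sigma2, tau2, max_iter=200, tol=1e-12)
    ll = _glmm_laplace_ll(X, y, starts, codes, n_i, beta, u, sigma2, tau2)
    mu = np.exp(X @ beta + u[codes])
    curv = _segment_sums(mu * mu - (y - mu) * mu, starts) / sigma2 + 1.0 / tau2
    se = 1.0 / np.sqrt(np.maximum(curv, 1e-12))
    converged = bool(res.success)
    if not converged:
        log.warning("GLMM outer optimizer did not converge: %s", res.message)
    re = pd.DataFrame({"icu_id": site_ids, "re": u, "se": se, "n": n_i})
    return FittedMixedModel("glmm", spec, pd.Series(beta, index=names),
                            float(tau2), float(sigma2), re, ll, len(y),
                            converged, int(state["nfev"]))


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def predict_los(model: FittedMixedModel, registry: Registry, mode: str = "FE",
                scale: str | None = None) -> PredictionSet:
    """Predicted LOS per patient.

    FE uses the fixed effects only — the form used for quality metrics, so
    that site performance is not adjusted away; RE adds the site's predicted
    intercept. GLMM predictions on the days scale are exp(eta), hence
    strictly positive. LMM predictions are reported on the log scale only;
    no retransformation correction is applied back to days.
    """
    if mode not in ("FE", "RE"):
        raise ValueError("mode must be FE or RE")
    if scale is None:
        scale = "days" if model.kind == "glmm" else "log_days"
    if model.kind == "lmm" and scale == "days":
        raise ValueError("LMM predictions are reported on the log scale; no "
                         "retransformation to days is applied")

    X, names, mask = build_design(registry.patients, model.spec)
    if names != list(model.beta_hat.index):
        raise ValueError("registry design does not match the fitted model")
    idx = registry.patients.index[mask]
    eta = X @ model.beta_hat.to_numpy()
    if mode == "RE":
        re_map = model.re.set_index("icu_id")["re"]
        sites = registry.patients.loc[idx, "icu_id"]
        unseen = set(sites) - set(re_map.index)
        if unseen:
            raise KeyError(f"no estimated random effect for site(s) "
                           f"{sorted(unseen)[:5]}")
        eta = eta + sites.map(re_map).to_numpy()
    values = np.exp(eta) if (model.kind == "glmm" and scale == "days") else eta
    if model.kind == "lmm" and scale != "log_days":
        raise ValueError(f"unsupported scale {scale!r} for LMM")
    return PredictionSet(pd.Series(values, index=idx), mode, scale, model.kind)


def r_squared(observed, predicted, level: str = "patient",
              icu_ids=None) -> float:
    """Square of the product-moment correlation of LOS vs predictions.

    At the ICU level both vectors are first averaged within ICU. Returns
    NaN (undefined) when either vector is constant. Note the known quirk of
    this definition: a perfectly anti-correlated prediction also scores 1.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if level == "icu":
        if icu_ids is None:
            raise ValueError("icu level requires icu_ids")
        df = pd.DataFrame({"o": observed, "p": predicted, "g": np.asarray(icu_ids)})
        agg = df.groupby("g").mean()
        observed, predicted = agg["o"].to_numpy(), agg["p"].to_numpy()
    elif level != "patient":
        raise ValueError("level must be patient or icu")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r)


def split_sample_validation(registry: Registry, spec: ModelSpec,
                            estimator: str = "lmm", fraction: float = 0.6,
                            seed: int = 0) -> ValidationReport:
    """Split-sample check: whole ICUs randomly allocated to development
    (default 60% of sites) vs validation; the model is fitted on development
    sites only. Development R² uses RE (fitted) predictions in-sample;
    validation R² uses FE predictions, since validation sites have no
    estimated random effect.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    sites = registry.sites["icu_id"].to_numpy()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sites)
    n_dev = int(round(fraction * len(sites)))
    dev_sites, val_sites = sorted(perm[:n_dev]), sorted(perm[n_dev:])
    if len(dev_sites) < 2 or len(val_sites) < 2:
        raise ValueError("split leaves fewer than 2 sites in one arm")

    def subset(ids):
        mask = registry.patients["icu_id"].isin(ids)
        return Registry(registry.patients.loc[mask].copy(),
                        registry.sites[registry.sites["icu_id"].isin(ids)].copy(),
                        provenance=dict(registry.provenance))

    dev, val = subset(dev_sites), subset(val_sites)
    fit = fit_lmm if estimator == "lmm" else fit_glmm_log_gaussian
    model = fit(dev, spec)

    def r2(arm: Registry, mode: str) -> float:
        pred = predict_los(model, arm, mode=mode)
        obs = arm.patients.loc[pred.values.index, "los_days"].to_numpy()
        if pred.scale == "log_days":
            obs = np.log(obs)
        return r_squared(obs, pred.values.to_numpy())

    return ValidationReport(r2(dev, "RE"), r2(val, "FE"),
                            list(dev_sites), list(val_sites),
                            dev.n_patients, val.n_patients)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(model: FittedMixedModel, registry: Registry,
                         kind: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Residual table and summary for a fitted model.

    LMM: conventional (raw) residuals on the log scale and residuals
    standardized by the estimated conditional SD. GLMM (gaussian family):
    the deviance residual is y - mu, and the Anscombe residual reduces to
    the same quantity because the gaussian variance function is constant.
    """
    pred = predict_los(model, registry, mode="RE")
    obs = registry.patients.loc[pred.values.index, "los_days"].to_numpy(dtype=float)
    if model.kind == "lmm":
        raw = np.log(obs) - pred.values.to_numpy()
        table = pd.DataFrame({
            "residual": raw,
            "standardized": raw / math.sqrt(model.sigma2_hat),
        }, index=pred.values.index)
    else:
        dev = obs - pred.values.to_numpy()
        table = pd.DataFrame({"deviance": dev, "anscombe": dev},
                             index=pred.values.index)
    col = table.columns[-1]
    z = table[col].to_numpy() / (table[col].std() or 1.0)
    summary = {"mean": float(table[col].mean()), "sd": float(table[col].std()),
               "frac_abs_gt2": float(np.mean(np.abs(z) > 2))}
    return table, summary


@dataclass
class NormalityResult:
    statistic: float
    pvalue: float
    rejected: bool
    n: int


def normality_check(values, alpha: float = 0.05, max_n: int = 5000,
                    seed: int = 0) -> NormalityResult:
    """Skewness/kurtosis omnibus normality test on (a subsample of) values."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValueError("need at least 20 observations")
    if np.std(x) == 0:
        raise ValueError("constant input has no defined normality test")
    if len(x) > max_n:
        x = np.random.default_rng(seed).choice(x, size=max_n, replace=False)
    stat, p = stats.normaltest(x)
    return NormalityResult(float(stat), float(p), bool(p < alpha), len(x))
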