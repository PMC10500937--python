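"""Per-ICU quality metrics with BCa bootstrap confidence intervals.

Three indices, all built from fixed-effect (FE) model predictions so that
site performance is not adjusted away:

* **OMELOS** — observed minus expected LOS, in days (GLMM predictions);
* **RALOSR (arithmetic)** — ratio of the mean observed to mean predicted
  LOS in days (GLMM);
* **RALOSR (geometric)** — ratio of geometric means, from log-scale LMM
  predictions;

plus the Wald intervals for each site's predicted random intercept.

Bootstrap policy: patients are resampled within each ICU, (observed,
predicted) pairs jointly; the model is fitted once, not per replicate. One
master seed spawns a per-ICU child stream keyed on the ICU id, so results
do not depend on iteration order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import Registry

log = logging.getLogger("iculos")

NULL_VALUES = {"omelos": 0.0, "ralosr_arith": 1.0, "ralosr_geo": 1.0,
               "site_re": 0.0}


@dataclass
class MetricTable:
    """One (metric_kind, source_model) estimate per ICU.

    ``table`` columns: icu_id, metric_kind, source_model, point, ci_low,
    ci_high, ci_method, n_patients, rank_point, rank_se — the last two being
    the point estimate and SE on the scale used for rank inference (log
    scale for ratio metrics, identity otherwise).
    """

    table: pd.DataFrame
    metric_kind: str
    source_model: str
    alpha: float = 0.05
    bootstrap_reps: int = 1000

    @property
    def null_value(self) -> float:
        return NULL_VALUES[self.metric_kind]


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def _bca_core(values: np.ndarray, statistic, B: int, alpha: float,
              rng: np.random.Generator) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("BCa needs at least 2 observations")
    point = float(statistic(values))

    idx = rng.integers(0, n, size=(B, n))
    theta_star = np.array([statistic(values[i]) for i in idx], dtype=float)

    if np.ptp(theta_star) == 0.0:
        v = float(theta_star[0]) if np.isclose(theta_star[0], point) else point
        return {"point": point, "lo": v, "hi": v, "method": "bca",
                "theta_star": theta_star}

    frac = np.mean(theta_star < point)
    if frac == 0.0 or frac == 1.0:
        log.warning("BCa bias term is infinite (all bootstrap replicates on "
                    "one side of the estimate); falling back to percentile CI")
        lo, hi = np.quantile(theta_star, [alpha / 2, 1 - alpha / 2])
        return {"point": point, "lo": float(lo), "hi": float(hi),
                "method": "percentile", "theta_star": theta_star}
    z0 = stats.norm.ppf(frac)

    # acceleration from the jackknife third-moment formula
    jack = np.array([statistic(np.delete(values, i, axis=0)) for i in range(n)])
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = float((d ** 3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(theta_star, adj)
    return {"point": point, "lo": float(lo), "hi": float(hi), "method": "bca",
            "theta_star": theta_star}


def bca_interval(values, statistic, B: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float, float]:
    """Bias-corrected and accelerated bootstrap CI of a scalar statistic.

    ``values`` is a sample (rows are resampled jointly, so paired statistics
    take an (n, 2) array); the bias term is ``z0 = Phi^-1(#{theta* < theta}/B)``
    and the acceleration comes from the jackknife third-moment formula.
    Deterministic given ``seed``. Degenerate bootstrap distributions give a
    zero-width interval; an infinite bias term falls back to the percentile
    interval with a warning.
    """
    out = _bca_core(np.asarray(values, dtype=float), statistic, B, alpha,
                    np.random.default_rng(seed))
    return out["point"], out["lo"], out["hi"]


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

def _child_rng(master_seed: int, icu_id) -> np.random.Generator:
    # stable per-ICU stream, independent of iteration order
    key = zlib.crc32(str(icu_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), key)))


def _metric_table(registry: Registry, predictions: pd.Series, *,
                  metric_kind: str, source_model: str, statistic, pair: bool,
                  log_rank_scale: bool, B: int, alpha: float,
                  seed: int) -> MetricTable:
    obs_col = "los_days"
    pat = registry.patients.loc[predictions.index]
    rows = []
    for icu_id, grp in pat.groupby("icu_id", sort=True):
        obs = grp[obs_col].to_numpy(dtype=float)
        pred = predictions.loc[grp.index].to_numpy(dtype=float)
        sample = np.column_stack([obs, pred])
        n = len(obs)
        if n < 2:
            point = float(statistic(sample))
            log.warning("ICU %s has < 2 patients; Wald fallback (zero-width CI)",
                        icu_id)
            rows.append({"icu_id": icu_id, "point": point, "ci_low": point,
                         "ci_high": point, "ci_method": "wald", "n_patients": n,
                         "rank_point": np.log(point) if log_rank_scale else point,
                         "rank_se": np.nan})
            continue
        out = _bca_core(sample, statistic, B, alpha, _child_rng(seed, icu_id))
        ts = out["theta_star"]
        if log_rank_scale:
            rank_point = float(np.log(out["point"]))
            rank_se = float(np.std(np.log(np.maximum(ts, 1e-12)), ddof=1))
        else:
            rank_point = out["point"]
            rank_se = float(np.std(ts, ddof=1))
        rows.append({"icu_id": icu_id, "point": out["point"],
                     "ci_low": out["lo"], "ci_high": out["hi"],
                     "ci_method": out["method"], "n_patients": n,
                     "rank_point": rank_point, "rank_se": rank_se})
    table = pd.DataFrame(rows)
    table.insert(1, "metric_kind", metric_kind)
    table.insert(2, "source_model", source_model)
    return MetricTable(table, metric_kind, source_model, alpha, B)


def omelos_table(registry: Registry, fe_predictions_days: pd.Series,
                 B: int = 1000, alpha: float = 0.05, seed: int = 0,
                 source_model: str = "glmm") -> MetricTable:
    """Observed minus expected LOS per ICU (days), BCa by paired resampling."""
    stat = lambda s: float(np.mean(s[:, 0]) - np.mean(s[:, 1]))
    return _metric_table(registry, fe_predictions_days, metric_kind="omelos",
                         source_model=source_model, statistic=stat, pair=True,
                         log_rank_scale=False, B=B, alpha=alpha, seed=seed)


def ralosr_arith_table(registry: Registry, fe_predictions_days: pd.Series,
                       B: int = 1000, alpha: float = 0.05, seed: int = 0,
                       source_model: str = "glmm") -> MetricTable:
    """Ratio of mean observed to mean predicted LOS per ICU (dimensionless)."""
    stat = lambda s: float(np.mean(s[:, 0]) / np.mean(s[:, 1]))
    return _metric_table(registry, fe_predictions_days,
                         metric_kind="ralosr_arith", source_model=source_model,
                         statistic=stat, pair=True, log_rank_scale=True,
                         B=B, alpha=alpha, seed=seed)


def ralosr_geo_table(registry: Registry, fe_predictions_log: pd.Series,
                     B: int = 1000, alpha: float = 0.05, seed: int = 0,
                     source_model: str = "lmm") -> MetricTable:
    """Ratio of the geometric mean LOS to the geometric mean of log-scale
    predictions, exp(mean(log obs)) / exp(mean(pred_log)), per ICU."""
    stat = lambda s: float(np.exp(np.mean(np.log(s[:, 0])) - np.mean(s[:, 1])))
    return _metric_table(registry, fe_predictions_log,
                         metric_kind="ralosr_geo", source_model=source_model,
                         statistic=stat, pair=True, log_rank_scale=True,
                         B=B, alpha=alpha, seed=seed)


def site_re_table(model, alpha: float = 0.05) -> MetricTable:
    """Predicted site random intercepts with Wald intervals (point ± z·SE)."""
    re = model.re
    if re["se"].isna().any():
        raise ValueError("model lacks standard errors for some random effects")
    z = stats.norm.ppf(1 - alpha / 2)
    table = pd.DataFrame({
        "icu_id": re["icu_id"],
        "metric_kind": "site_re",
        "source_model": model.kind,
        "point": re["re"],
        "ci_low": re["re"] - z * re["se"],
        "ci_high": re["re"] + z * re["se"],
        "ci_method": "wald",
        "n_patients": re["n"] if "n" in re.columns else np.nan,
        "rank_point": re["re"],
        "rank_se": re["se"],
    })
    return MetricTable(table, "site_re", model.kind, alpha, 0)
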