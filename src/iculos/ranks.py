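"""Confidence sets for ICU ranks.

Point estimates and SEs (one per ICU) are treated as independent Gaussians
— the same construction as feeding a rank-inference package a column of
estimates and standard errors. For each unit the procedure bounds, with
Monte-Carlo critical values, which competitors are *confidently better* and
*confidently worse*, yielding an interval of ranks:

* **marginal** sets use a per-unit critical value covering that unit's
  |N|-1 studentized differences jointly — the set covers a single ICU's
  true rank with probability 1-alpha;
* **simultaneous** sets use one critical value for all pairwise
  studentized differences — the sets cover every ICU's true rank jointly.

Single-step critical values only (no stepdown refinement), hence the sets
are conservative; both kinds share the Monte-Carlo draws, so the marginal
set is nested inside the simultaneous set for every unit on every seed.
Ratio-valued metrics should be rank-analyzed on the log scale, where the
Gaussian approximation is defensible (the metric tables expose
``rank_point``/``rank_se`` for exactly this).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RankConfig:
    alpha: float = 0.05
    n_draws: int = 10_000
    orientation: str = "ascending_best"  # lower estimate => rank 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_draws < 1000:
            raise ValueError("n_draws must be at least 1000")
        if self.orientation not in ("ascending_best", "descending_best"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class RankTable:
    """Per-unit point rank plus [rank_low, rank_high] confidence set."""

    table: pd.DataFrame  # columns: icu_id, point_rank, rank_low, rank_high
    kind: str            # {marginal | simultaneous}
    alpha: float
    seed: int
    source: str = ""


def point_ranks(estimates, orientation: str = "ascending_best") -> np.ndarray:
    """Competition ranks: 1 + number of strictly better units; ties share
    the minimal rank."""
    est = np.asarray(estimates, dtype=float)
    if np.isnan(est).any():
        raise ValueError("estimates contain NaN")
    sgn = 1.0 if orientation == "ascending_best" else -1.0
    e = sgn * est
    return 1 + (e[None, :] < e[:, None]).sum(axis=1)


def _rank_bounds(est: np.ndarray, ses: np.ndarray, c: np.ndarray | float
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = len(est)
    denom = np.sqrt(ses[None, :] ** 2 + ses[:, None] ** 2)  # [i, j]
    better = (est[None, :] + c * denom) < est[:, None]
    worse = (est[None, :] - c * denom) > est[:, None]
    np.fill_diagonal(better, False)
    np.fill_diagonal(worse, False)
    return 1 + better.sum(axis=1), n - worse.sum(axis=1)


def _critical_values(est, ses, config: RankConfig):
    n = len(est)
    ties = (est[None, :] == est[:, None]) & ~np.eye(n, dtype=bool)
    both_zero = (ses[None, :] == 0) & (ses[:, None] == 0)
    if (ties & both_zero).any():
        raise ValueError("tied estimates with zero SE: jitter the estimates "
                         "or supply an exact-tie policy")
    rng = np.random.default_rng(config.seed)
    scaled = rng.standard_normal((config.n_draws, n)) * ses  # draws of theta*-theta
    c_marg = np.empty(n)
    global_max = np.zeros(config.n_draws)
    for i in range(n):
        denom = np.sqrt(ses ** 2 + ses[i] ** 2)
        denom[i] = np.inf
        denom[denom == 0] = np.inf  # zero-SE pairs: infinitely separated
        m_i = np.max(np.abs(scaled - scaled[:, i:i + 1]) / denom, axis=1)
        c_marg[i] = np.quantile(m_i, 1 - config.alpha, method="higher")
        np.maximum(global_max, m_i, out=global_max)
    c_sim = float(np.quantile(global_max, 1 - config.alpha, method="higher"))
    return c_marg, c_sim


def _rank_sets(estimates, ses, config: RankConfig, ids=None):
    est = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.isnan(est).any() or np.isnan(s).any() or (s < 0).any():
        raise ValueError("estimates/SEs must be finite with non-negative SEs")
    if ids is None:
        ids = np.arange(1, len(est) + 1)
    sgn = 1.0 if config.orientation == "ascending_best" else -1.0
    e = sgn * est
    c_marg, c_sim = _critical_values(e, s, config)
    pr = point_ranks(e)
    out = {}
    for kind, c in (("marginal", c_marg), ("simultaneous", c_sim)):
        lo, hi = _rank_bounds(e, s, c)
        out[kind] = RankTable(
            pd.DataFrame({"icu_id": ids, "point_rank": pr,
                          "rank_low": lo, "rank_high": hi}),
            kind, config.alpha, config.seed)
    return out


def marginal_rank_sets(estimates, ses, config: RankConfig | None = None,
                       ids=None) -> RankTable:
    """Per-unit rank confidence sets at joint 1-alpha coverage of that
    unit's studentized differences; deterministic given the config seed."""
    return _rank_sets(estimates, ses, config or RankConfig(), ids)["marginal"]


def simultaneous_rank_sets(estimates, ses, config: RankConfig | None = None,
                           ids=None) -> RankTable:
    """Rank sets covering all units' true ranks jointly with probability
    1-alpha (one critical value for every pairwise difference)."""
    return _rank_sets(estimates, ses, config or RankConfig(), ids)["simultaneous"]


def rank_sets_from_metric(metric_table, config: RankConfig | None = None
                          ) -> dict[str, RankTable]:
    """Both kinds of rank set from a metric table's rank-scale columns."""
    t = metric_table.table
    out = _rank_sets(t["rank_point"].to_numpy(), t["rank_se"].to_numpy(),
                     config or RankConfig(), ids=t["icu_id"].to_numpy())
    for kind in out:
        out[kind].source = f"{metric_table.metric_kind}-{metric_table.source_model}"
    return out


def rank_coverage_sim(scenario: dict, n_reps: int = 200, seed: int = 0,
                      config: RankConfig | None = None) -> dict:
    """Empirical coverage of the two rank-set constructions.

    ``scenario`` supplies ``true_effects`` and ``ses``; each replicate draws
    estimates around the truth, builds both set kinds, and checks whether
    every unit's true rank is covered. Reports per-unit marginal coverage
    and joint simultaneous coverage with Monte-Carlo SEs.
    """
    config = config or RankConfig()
    truth = np.asarray(scenario["true_effects"], dtype=float)
    ses = np.asarray(scenario["ses"], dtype=float)
    true_rank = point_ranks(truth, config.orientation)
    rng = np.random.default_rng(seed)
    marg_cover = np.zeros(len(truth))
    sim_joint = 0
    nesting_violations = 0
    for rep in range(n_reps):
        est = truth + ses * rng.standard_normal(len(truth))
        rep_cfg = RankConfig(config.alpha, config.n_draws, config.orientation,
                             seed=int(rng.integers(2 ** 31)))
        sets = _rank_sets(est, ses, rep_cfg)
        m, s = sets["marginal"].table, sets["simultaneous"].table
        marg_cover += ((m["rank_low"] <= true_rank) &
                       (true_rank <= m["rank_high"])).to_numpy()
        sim_joint += int(((s["rank_low"] <= true_rank) &
                          (true_rank <= s["rank_high"])).all())
        nesting_violations += int(not ((s["rank_low"] <= m["rank_low"]) &
                                       (m["rank_high"] <= s["rank_high"])).all())
    marg = marg_cover / n_reps
    return {
        "marginal_coverage": marg,
        "marginal_coverage_mean": float(marg.mean()),
        "simultaneous_joint_coverage": sim_joint / n_reps,
        "nesting_violations": nesting_violations,
        "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
        "n_reps": n_reps,
    }
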