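"""(Dis)agreement of ICU rankings across models and metrics, plus displays.

The headline question is whether different estimators (LMM vs GLMM) and
different quality indices (RALOSR, OMELOS, site RE) rank the same ICUs the
same way. Agreement is quantified with the tie-corrected Kendall tau-b
(primary) and Spearman's rho (secondary). Display functions always return
the exact plotted data table alongside the figure so tests never parse
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConcordanceResult:
    pair: tuple[str, str]
    kendall_tau_b: float
    spearman_rho: float
    n_units: int


@dataclass
class FlagCounts:
    table_id: str
    null_value: float
    n_below: int   # ICUs whose whole CI sits below the null
    n_above: int   # ICUs whose whole CI sits above the null
    n_units: int


def concordance(ranking_a, ranking_b, labels: tuple[str, str] = ("a", "b")
                ) -> ConcordanceResult:
    """Kendall tau-b and Spearman rho between two rankings of one unit set.

    Accepts pandas Series (aligned on their index) or equal-length arrays.
    """
    if isinstance(ranking_a, pd.Series) and isinstance(ranking_b, pd.Series):
        if set(ranking_a.index) != set(ranking_b.index):
            raise ValueError("rankings cover different unit sets")
        ranking_b = ranking_b.reindex(ranking_a.index)
    a = np.asarray(ranking_a, dtype=float)
    b = np.asarray(ranking_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rankings cover different unit sets")
    import warnings
    with warnings.catch_warnings():
        # a constant ranking has undefined correlation; report NaN quietly
        warnings.simplefilter("ignore")
        tau = stats.kendalltau(a, b).statistic  # tau-b (tie-corrected)
        rho = stats.spearmanr(a, b).statistic
    return ConcordanceResult(labels, float(tau), float(rho), len(a))


def flag_counts(metric_table, null_value: float | None = None) -> FlagCounts:
    """How many ICUs' 95% CIs exclude the metric's null value.

    A CI endpoint exactly equal to the null counts as *not* excluded.
    """
    t = metric_table.table
    null = metric_table.null_value if null_value is None else null_value
    return FlagCounts(
        table_id=f"{metric_table.metric_kind}-{metric_table.source_model}",
        null_value=null,
        n_below=int((t["ci_high"] < null).sum()),
        n_above=int((t["ci_low"] > null).sum()),
        n_units=len(t),
    )


# ---------------------------------------------------------------------------
# displays
# ---------------------------------------------------------------------------

def _save(fig, out_path):
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    import matplotlib.pyplot as plt
    plt.close(fig)


def render_caterpillar(metric_table, out_path=None) -> pd.DataFrame:
    """Ranked caterpillar/forest display: ICUs ordered by point estimate
    with horizontal 95% CI bars and the null reference line. Returns the
    plotted table (ordered as drawn)."""
    import matplotlib.pyplot as plt

    t = metric_table.table
    if len(t) == 0:
        raise ValueError("empty metric table")
    plotted = t.sort_values(["point", "icu_id"], kind="stable").reset_index(drop=True)
    plotted["display_order"] = np.arange(1, len(plotted) + 1)

    fig, ax = plt.subplots(figsize=(7, max(3, 0.09 * len(plotted) + 1.5)))
    y = plotted["display_order"]
    ax.hlines(y, plotted["ci_low"], plotted["ci_high"], color="0.4", lw=1)
    ax.plot(plotted["point"], y, "o", ms=3, color="C0")
    ax.axvline(metric_table.null_value, color="C3", ls="--", lw=1)
    ax.set_xlabel(f"{metric_table.metric_kind} ({metric_table.source_model})")
    ax.set_ylabel("ICU (ranked by point estimate)")
    _save(fig, out_path)
    return plotted


def render_rank_sets(rank_table, out_path=None) -> pd.DataFrame:
    """Rank confidence-set display: bars span [rank_low, rank_high] with a
    point-rank marker, units ordered by point rank."""
    import matplotlib.pyplot as plt

    t = rank_table.table
    if len(t) == 0:
        raise ValueError("empty rank table")
    plotted = t.sort_values(["point_rank", "icu_id"], kind="stable").reset_index(drop=True)
    plotted["display_order"] = np.arange(1, len(plotted) + 1)

    fig, ax = plt.subplots(figsize=(7, max(3, 0.09 * len(plotted) + 1.5)))
    y = plotted["display_order"]
    ax.hlines(y, plotted["rank_low"], plotted["rank_high"], color="0.4", lw=1)
    ax.plot(plotted["point_rank"], y, "o", ms=3, color="C0")
    ax.set_xlabel(f"rank ({rank_table.kind}, {rank_table.source})")
    ax.set_ylabel("ICU (by point rank)")
    _save(fig, out_path)
    return plotted


def render_density(values_by_label: dict, out_path=None,
                   truncate: float | None = None, grid_size: int = 512
                   ) -> pd.DataFrame:
    """Gaussian kernel density (Silverman bandwidth) per labelled series,
    optionally truncating the display range; returns the evaluated grid."""
    import matplotlib.pyplot as plt

    frames = []
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, values in values_by_label.items():
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if len(x) < 2:
            raise ValueError(f"series {label!r} needs at least 2 values")
        kde = stats.gaussian_kde(x, bw_method="silverman")
        lo, hi = x.min(), x.max()
        if truncate is not None:
            hi = min(hi, truncate)
        pad = 0.05 * (hi - lo or 1.0)
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        dens = kde(grid)
        ax.plot(grid, dens, label=str(label))
        frames.append(pd.DataFrame({"label": str(label), "x": grid,
                                    "density": dens}))
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    ax.legend()
    _save(fig, out_path)
    return pd.concat(frames, ignore_index=True)
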