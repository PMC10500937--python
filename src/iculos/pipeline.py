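"""End-to-end driver: registry -> models -> metrics -> ranks -> report.

Every artifact is written under one run directory with the configuration
hash and master seed embedded, and the whole run is deterministic given the
config + seed. Stage failures abort with a stage-named error; a
non-converged GLMM produces a clearly flagged partial run rather than a
silent result.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as qm
from .concordance import concordance as _concordance, flag_counts, \
    render_caterpillar, render_density, render_rank_sets
from .models import fit_glmm_log_gaussian, fit_lmm, predict_los, r_squared
from .ranks import RankConfig, rank_sets_from_metric
from .registry import ModelSpec, Registry, config_hash, read_registry_csv, \
    write_registry_csv
from .simulate import SimConfig, default_sim_config, generate_registry, \
    simple_sim_config, summarize_registry

log = logging.getLogger("iculos")

STAGES = ["simulate", "fit", "metrics", "ranks", "report"]


@dataclass
class PipelineConfig:
    """Everything a run needs: input source, model terms, bootstrap and
    rank settings, output directory and the master seed."""

    out_dir: str = "iculos_run"
    seed: int = 0
    simulate: SimConfig | None = None          # exclusive with csv paths
    patients_csv: str | None = None
    sites_csv: str | None = None
    fixed_terms: list | None = None            # None = full default term set
    interactions: list | None = None
    bootstrap_reps: int = 1000
    alpha: float = 0.05
    rank: RankConfig = field(default_factory=RankConfig)
    log_level: str = "INFO"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.patients_csv and self.sites_csv):
            raise ValueError("config needs either a simulate block or both "
                             "patients_csv and sites_csv")
        if self.simulate is not None:
            self.simulate = (self.simulate if isinstance(self.simulate, SimConfig)
                             else _sim_from_dict(self.simulate))

    def model_spec(self, kind: str) -> ModelSpec:
        base = ModelSpec.lmm_default() if kind == "lmm" else ModelSpec.glmm_default()
        if self.fixed_terms is not None:
            base.fixed_terms = list(self.fixed_terms)
        if self.interactions is not None:
            base.interactions = [tuple(x) for x in self.interactions]
        return base

    def provenance(self) -> dict:
        d = {"seed": self.seed, "bootstrap_reps": self.bootstrap_reps,
             "alpha": self.alpha, "fixed_terms": self.fixed_terms,
             "interactions": self.interactions,
             "rank": asdict(self.rank)}
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_provenance()
        else:
            d["patients_csv"] = self.patients_csv
            d["sites_csv"] = self.sites_csv
        return d


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    preset = d.pop("preset", "default")
    if preset == "default":
        return default_sim_config(seed=int(d.pop("seed", 0)),
                                  noise_family=d.pop("noise_family", "lognormal"))
    if preset == "simple":
        return simple_sim_config(
            int(d.pop("n_icus")), int(d.pop("patients_per_site")), **d)
    raise ValueError(f"unknown simulate preset {preset!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "rank" in raw:
        raw["rank"] = RankConfig(**raw["rank"])
    return PipelineConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path, tag: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {tag}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig, until: str = "report") -> Path:
    """Execute the pipeline up to (and including) stage ``until``.

    Returns the run directory. Artifacts: registry CSVs and demographic
    summary; model coefficient/RE CSVs; one metric CSV per
    (metric, source model); marginal + simultaneous rank CSVs per metric;
    concordance/flag-count report (markdown) and display files.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config_hash(config.provenance())
    t0 = time.time()

    def stage_done(name):
        log.info("stage %-8s done at %6.1fs", name, time.time() - t0)

    # -- simulate / ingest --------------------------------------------------
    try:
        if config.simulate is not None:
            sim = config.simulate
            if sim.seed != config.seed:
                from dataclasses import replace
                sim = replace(sim, seed=config.seed)
            registry = generate_registry(sim)
        else:
            registry = read_registry_csv(config.patients_csv, config.sites_csv)
        write_registry_csv(registry, out / "patients.csv", out / "sites.csv")
        _write_csv(summarize_registry(registry), out / "summary.csv", tag)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    stage_done("simulate")
    if until == "simulate":
        return _finish(out, config, tag, t0)

    # -- model fitting ------------------------------------------------------
    try:
        lmm = fit_lmm(registry, config.model_spec("lmm"))
        glmm = fit_glmm_log_gaussian(registry, config.model_spec("glmm"),
                                     start_from=lmm)
        partial = not (lmm.converged and glmm.converged)
        for m in (lmm, glmm):
            coefs = m.beta_hat.rename("estimate").rename_axis("term").reset_index()
            coefs.loc[len(coefs)] = ["tau2", m.tau2_hat]
            coefs.loc[len(coefs)] = ["sigma2", m.sigma2_hat]
            coefs.loc[len(coefs)] = ["loglik", m.loglik]
            coefs.loc[len(coefs)] = ["aic", m.aic]
            coefs.loc[len(coefs)] = ["bic", m.bic]
            _write_csv(coefs, out / f"model_{m.kind}.csv", tag)
            _write_csv(m.re, out / f"re_{m.kind}.csv", tag)
        if partial:
            (out / "PARTIAL_RUN").write_text(
                "model fitting did not fully converge; downstream artifacts "
                "are flagged\n")
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e
    stage_done("fit")
    if until == "fit":
        return _finish(out, config, tag, t0)

    # -- quality metrics ----------------------------------------------------
    try:
        fe_days = predict_los(glmm, registry, mode="FE", scale="days")
        fe_log = predict_los(lmm, registry, mode="FE", scale="log_days")
        B, a, s = config.bootstrap_reps, config.alpha, config.seed
        tables = {
            "omelos-glmm": qm.omelos_table(registry, fe_days.values, B, a, s),
            "ralosr_arith-glmm": qm.ralosr_arith_table(registry, fe_days.values, B, a, s),
            "ralosr_geo-lmm": qm.ralosr_geo_table(registry, fe_log.values, B, a, s),
            "re-glmm": qm.site_re_table(glmm, a),
            "re-lmm": qm.site_re_table(lmm, a),
        }
        for name, mt in tables.items():
            _write_csv(mt.table, out / f"metric_{name}.csv", tag)
    except Exception as e:
        raise RuntimeError(f"stage 'metrics' failed: {e}") from e
    stage_done("metrics")
    if until == "metrics":
        return _finish(out, config, tag, t0)

    # -- rank confidence sets -----------------------------------------------
    try:
        rank_cfg = RankConfig(config.rank.alpha, config.rank.n_draws,
                              config.rank.orientation, seed=config.seed)
        rank_tables = {}
        for name, mt in tables.items():
            try:
                sets = rank_sets_from_metric(mt, rank_cfg)
            except ValueError as err:
                # e.g. a collapsed random-effect table (tau2_hat = 0): every
                # estimate 0 with zero SE carries no ranking information
                log.warning("skipping rank sets for %s: %s", name, err)
                continue
            for kind, rt in sets.items():
                rank_tables[f"{name}-{kind}"] = rt
                df = rt.table.assign(alpha=rt.alpha, seed=rt.seed, kind=kind)
                _write_csv(df, out / f"ranks_{name}_{kind}.csv", tag)
    except Exception as e:
        raise RuntimeError(f"stage 'ranks' failed: {e}") from e
    stage_done("ranks")
    if until == "ranks":
        return _finish(out, config, tag, t0)

    # -- concordance report + displays --------------------------------------
    try:
        names = list(tables)
        lines = [f"# ICU LOS quality-metric run `{tag}`", "",
                 f"- patients: {registry.n_patients}, ICUs: {registry.n_sites}",
                 f"- master seed: {config.seed}; bootstrap reps: {config.bootstrap_reps}",
                 "", "## Model fit", ""]
        obs = registry.patients.loc[fe_days.values.index, "los_days"]
        r2p = r_squared(obs, fe_days.values)
        r2i = r_squared(obs, fe_days.values, level="icu",
                        icu_ids=registry.patients.loc[fe_days.values.index, "icu_id"])
        lines += [f"- GLMM: loglik {glmm.loglik:.1f}, AIC {glmm.aic:.1f}, "
                  f"BIC {glmm.bic:.1f}, tau2 {glmm.tau2_hat:.4f}, "
                  f"converged: {glmm.converged}",
                  f"- LMM: loglik {lmm.loglik:.1f}, AIC {lmm.aic:.1f}, "
                  f"BIC {lmm.bic:.1f}, tau2 {lmm.tau2_hat:.4f}",
                  f"- GLMM FE R2 (patient / ICU): {r2p:.3f} / {r2i:.3f}",
                  "", "## Ranking concordance (Kendall tau-b / Spearman rho)", ""]
        lines.append("| pair | tau_b | rho |")
        lines.append("|---|---|---|")
        conc_rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ra = tables[names[i]].table.set_index("icu_id")["rank_point"]
                rb = tables[names[j]].table.set_index("icu_id")["rank_point"]
                res = _concordance(ra, rb, (names[i], names[j]))
                conc_rows.append({"a": names[i], "b": names[j],
                                  "kendall_tau_b": res.kendall_tau_b,
                                  "spearman_rho": res.spearman_rho})
                lines.append(f"| {names[i]} vs {names[j]} | "
                             f"{res.kendall_tau_b:.3f} | {res.spearman_rho:.3f} |")
        _write_csv(pd.DataFrame(conc_rows), out / "concordance.csv", tag)
        lines += ["", "## ICUs whose 95% CI excludes the null", "",
                  "| metric | below | above | of |", "|---|---|---|---|"]
        for name, mt in tables.items():
            fc = flag_counts(mt)
            lines.append(f"| {name} | {fc.n_below} | {fc.n_above} | {fc.n_units} |")
        (out / "report.md").write_text("\n".join(lines) + "\n")

        if config.make_plots:
            for name, mt in tables.items():
                plotted = render_caterpillar(mt, out / f"caterpillar_{name}.png")
                _write_csv(plotted, out / f"caterpillar_{name}.csv", tag)
            for name, rt in rank_tables.items():
                render_rank_sets(rt, out / f"rankplot_{name}.png")
            dens = render_density(
                {"observed": obs, "GLMM FE": fe_days.values},
                out / "density_los.png", truncate=20.0)
            _write_csv(dens, out / "density_los.csv", tag)
    except Exception as e:
        raise RuntimeError(f"stage 'report' failed: {e}") from e
    stage_done("report")
    return _finish(out, config, tag, t0)


def _finish(out: Path, config: PipelineConfig, tag: str, t0: float) -> Path:
    manifest = {"config_hash": tag, "seed": config.seed,
                "elapsed_s": round(time.time() - t0, 2),
                "config": config.provenance()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return out
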