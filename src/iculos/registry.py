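"""Registry containers, model term definitions, and CSV serialization.

A registry is the universe every pipeline stage consumes: one row per ICU
admission (``patients``) plus one row per ICU site (``sites``). Patients are
kept as a plain :class:`pandas.DataFrame` in a fixed column dialect so that
round-trips through CSV are bit-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("iculos")

#: exact, ordered patient column dialect; ``male`` is an optional trailing flag
PATIENT_COLUMNS = [
    "icu_id", "age", "apache3", "anzrod", "preicu_days", "died_icu", "arf",
    "limitation", "arrest", "vent_d1", "dx_group", "los_days",
]
OPTIONAL_PATIENT_COLUMNS = ["male"]
SITE_COLUMNS = ["icu_id", "hosp_class", "annual_volume"]
OPTIONAL_SITE_COLUMNS = ["true_re"]

HOSP_CLASSES = ["MET", "PRI", "RUR", "TER"]

#: ANZROD probabilities are floored here before taking logs; avoids -inf
#: without introducing a shift parameter on LOS itself.
ANZROD_FLOOR = 1e-4


@dataclass
class Registry:
    """Patient-level admissions joined to an ICU site table."""

    patients: pd.DataFrame
    sites: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PATIENT_COLUMNS) - set(self.patients.columns)
        if missing:
            raise ValueError(f"patients table missing columns: {sorted(missing)}")
        unknown_sites = set(self.patients["icu_id"]) - set(self.sites["icu_id"])
        if unknown_sites:
            raise ValueError(
                f"patients reference icu_id values absent from sites: "
                f"{sorted(unknown_sites)[:5]}"
            )
        # hospital class travels with each admission for model design matrices
        if "hosp_class" not in self.patients.columns:
            cls = self.sites.set_index("icu_id")["hosp_class"]
            self.patients = self.patients.assign(
                hosp_class=self.patients["icu_id"].map(cls)
            )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def equals(self, other: "Registry", rtol: float = 1e-9) -> bool:
        """Content equality; float columns compared to ``rtol`` so that a
        CSV round-trip (which may perturb the last ulp) still compares equal."""
        def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            if len(a) != len(b):
                return False
            a, b = a.reset_index(drop=True), b.reset_index(drop=True)
            for col in a.columns:
                if col not in b.columns:
                    return False
                if pd.api.types.is_float_dtype(a[col]):
                    if not np.allclose(a[col], b[col], rtol=rtol, atol=1e-12,
                                       equal_nan=True):
                        return False
                elif not a[col].equals(b[col].astype(a[col].dtype)):
                    return False
            return True

        pcols = PATIENT_COLUMNS + [c for c in OPTIONAL_PATIENT_COLUMNS
                                   if c in self.patients.columns]
        scols = SITE_COLUMNS + [c for c in OPTIONAL_SITE_COLUMNS
                                if c in self.sites.columns]
        return frames_equal(self.patients[pcols], other.patients) and \
            frames_equal(self.sites[scols], other.sites)


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

#: default interaction list; the exact interaction set used by the reference
#: analysis is not published, so this explicit list is the swappable default
DEFAULT_INTERACTIONS: list[tuple[str, str]] = [
    ("vent_d1", "log_anzrod"),
    ("died_icu", "log_anzrod"),
    ("hosp_class", "apache3"),
]

DEFAULT_FIXED_TERMS = [
    "age", "age2", "apache3", "apache3_2", "log_anzrod", "preicu_days",
    "died_icu", "arf", "limitation", "arrest", "vent_d1",
    "hosp_class", "dx_group",
]


@dataclass
class ModelSpec:
    """Which response, link and fixed-effect terms a mixed model uses.

    ``response``/``family_link`` pairings are fixed per estimator: the linear
    mixed model analyses ``log_los`` on the identity link, the generalized
    linear mixed model analyses raw ``los_days`` with a gaussian family and
    log link. The grouping factor is always the ICU random intercept.
    """

    response: str = "log_los"  # {log_los | los_days}
    family_link: str = "gaussian_identity_on_log"  # {.. | gaussian_log}
    fixed_terms: Sequence[str] = field(default_factory=lambda: list(DEFAULT_FIXED_TERMS))
    interactions: Sequence[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_INTERACTIONS))
    grouping: str = "icu_id"

    @classmethod
    def lmm_default(cls) -> "ModelSpec":
        return cls(response="log_los", family_link="gaussian_identity_on_log")

    @classmethod
    def glmm_default(cls) -> "ModelSpec":
        return cls(response="los_days", family_link="gaussian_log")


def _term_columns(df: pd.DataFrame, term: str) -> pd.DataFrame:
    """Expand one named term into its design column(s)."""
    if term == "age":
        return pd.DataFrame({"age": df["age"].astype(float)})
    if term == "age2":
        return pd.DataFrame({"age2": df["age"].astype(float) ** 2})
    if term == "apache3":
        return pd.DataFrame({"apache3": df["apache3"].astype(float)})
    if term == "apache3_2":
        return pd.DataFrame({"apache3_2": df["apache3"].astype(float) ** 2})
    if term == "log_anzrod":
        p = df["anzrod"].astype(float).clip(lower=ANZROD_FLOOR)
        return pd.DataFrame({"log_anzrod": np.log(p)})
    if term in ("preicu_days", "died_icu", "arf", "limitation", "arrest",
                "vent_d1", "male"):
        return pd.DataFrame({term: df[term].astype(float)})
    if term == "hosp_class":
        d = pd.get_dummies(pd.Categorical(df["hosp_class"], categories=HOSP_CLASSES),
                           prefix="class", dtype=float)
        return d.iloc[:, 1:]  # MET is the reference class
    if term == "dx_group":
        levels = list(range(1, 31))
        d = pd.get_dummies(pd.Categorical(df["dx_group"], categories=levels),
                           prefix="dx", dtype=float)
        return d.iloc[:, 1:]  # group 1 is the reference
    raise KeyError(f"unknown model term: {term!r}")


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the fixed-effects design matrix for ``spec``.

    Returns ``(X, column_names, complete_case_mask)`` where the mask marks
    rows free of missing values in every covariate the spec touches. ``X``
    contains only complete-case rows and always includes an intercept.
    """
    blocks: list[pd.DataFrame] = [pd.DataFrame({"intercept": np.ones(len(df))},
                                               index=df.index)]
    for term in spec.fixed_terms:
        blocks.append(_term_columns(df, term).set_index(df.index))
    for a, b in spec.interactions:
        left = _term_columns(df, a).set_index(df.index)
        right = _term_columns(df, b).set_index(df.index)
        inter = {}
        for ca in left.columns:
            for cb in right.columns:
                inter[f"{ca}:{cb}"] = left[ca].to_numpy() * right[cb].to_numpy()
        blocks.append(pd.DataFrame(inter, index=df.index))
    full = pd.concat(blocks, axis=1)
    mask = full.notna().all(axis=1).to_numpy()
    X = full.loc[mask].to_numpy(dtype=float)
    return X, full.columns.tolist(), mask


def linear_predictor(df: pd.DataFrame, spec: ModelSpec, beta: dict[str, float]) -> np.ndarray:
    """x'beta for named coefficients; unnamed design columns get zero weight.

    Used by the synthetic generator so that generation and estimation share
    one definition of every covariate transform.
    """
    X, names, mask = build_design(df, spec)
    if not mask.all():
        raise ValueError("linear_predictor requires complete cases")
    b = np.array([beta.get(name, 0.0) for name in names])
    extra = set(beta) - set(names)
    if extra:
        raise KeyError(f"beta names not in design: {sorted(extra)}")
    return X @ b


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable provenance object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_registry_csv(registry: Registry, patients_path, sites_path) -> None:
    pcols = PATIENT_COLUMNS + [c for c in OPTIONAL_PATIENT_COLUMNS
                               if c in registry.patients.columns]
    scols = SITE_COLUMNS + [c for c in OPTIONAL_SITE_COLUMNS
                            if c in registry.sites.columns]
    tag = config_hash(registry.provenance)
    for path, frame in ((patients_path, registry.patients[pcols]),
                        (sites_path, registry.sites[scols])):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {tag}\n")
            frame.to_csv(fh, index=False, lineterminator="\n")


def read_registry_csv(patients_path, sites_path) -> Registry:
    """Read a registry from the two-CSV dialect.

    Rows with non-positive LOS are rejected (logged); rows with missing
    covariates are retained and flagged — the models drop them complete-case
    and log the count, mirroring registry practice of reporting the missing
    fraction rather than imputing.
    """
    patients = pd.read_csv(patients_path, comment="#")
    sites = pd.read_csv(sites_path, comment="#")

    unknown = set(patients.columns) - set(PATIENT_COLUMNS) - set(OPTIONAL_PATIENT_COLUMNS)
    if unknown:
        log.warning("ignoring unknown patient columns: %s", sorted(unknown))
        patients = patients.drop(columns=sorted(unknown))
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patients file missing required columns: {sorted(missing)}")
    missing_s = set(SITE_COLUMNS) - set(sites.columns)
    if missing_s:
        raise ValueError(f"sites file missing required columns: {sorted(missing_s)}")

    bad_los = ~(patients["los_days"] > 0)
    if bad_los.any():
        log.warning("rejecting %d rows with non-positive los_days", int(bad_los.sum()))
        patients = patients.loc[~bad_los].reset_index(drop=True)

    orphan = set(patients["icu_id"]) - set(sites["icu_id"])
    if orphan:
        raise ValueError(f"patients reference unknown icu_id: {sorted(orphan)[:5]}")

    n_incomplete = int(patients[PATIENT_COLUMNS].isna().any(axis=1).sum())
    if n_incomplete:
        log.info("%d/%d rows have missing covariates (retained; models drop "
                 "them complete-case)", n_incomplete, len(patients))
    return Registry(patients=patients, sites=sites,
                    provenance={"source": str(patients_path)})
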