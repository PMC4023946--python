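"""Synthetic hierarchical surgical cohorts (hospitals > wards > patients).

The national surveillance data that motivate this package are not publicly
deposited, so the package ships a generator that emulates their statistical
structure: a three-level hierarchy with a rare binary outcome (surgical site
infection, SSI), patient-level binary/categorical covariates drawn at
configurable marginal prevalences, ward-level random intercepts and an
optional ward-level random coefficient on the follow-up indicator, and an
optional hospital-level random intercept.

The outcome of patient i in ward j of hospital k is

    y_ijk ~ Bernoulli(pi_ijk),
    logit(pi_ijk) = b0 + beta . x_ijk + v_k + u0_j + u1_j * f_ijk,

with v_k ~ N(0, sigma2_v), (u0_j, u1_j) ~ N2(0, ward_covariance) and f the
binary follow-up >= 15 days indicator.  Covariates are generated mutually
independently — real surveillance covariates are correlated (e.g. wound
class with procedure type), which this generator deliberately does not
reproduce.

Default parameter values emulate a large French SSI surveillance extract:
overall infection risk near 1%, eleven patient covariates at their observed
marginal prevalences, published adjusted odds ratios as generating effects,
and ward-effect (co)variances chosen so the stratum median odds ratios match
the published ones (6.92 for follow-up < 15 days, 3.32 for >= 15 days).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "BINARY_COVARIATES",
    "PROCEDURE_TYPES",
    "PROCEDURE_DUMMIES",
    "COLUMNS",
    "SyntheticConfig",
    "CohortTable",
    "default_config",
    "calibrate_intercept",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Binary patient covariates, in canonical column order.
BINARY_COVARIATES = (
    "gender_female",
    "age_ge65",
    "asa_gt2",
    "preop_ge48h",
    "altemeier_gt2",
    "endoscopic",
    "emergency",
    "ambulatory",
    "followup_ge15",
    "duration_gt_p75",
)

#: Surgical procedure categories; "gastrointestinal" is the reference.
PROCEDURE_TYPES = (
    "gastrointestinal",
    "gynecologic",
    "cardiovascular",
    "orthopedic",
    "ophthalmic",
    "other",
)

#: Design-matrix dummy names for the non-reference procedure categories.
PROCEDURE_DUMMIES = tuple(f"procedure_{t}" for t in PROCEDURE_TYPES[1:])

#: Fixed CSV column order of the cohort dialect.
COLUMNS = (
    "hospital_id",
    "ward_id",
    "ssi",
    *BINARY_COVARIATES,
    "procedure_type",
    "duration_minutes",
    "followup_days",
)

_OPTIONAL_COLUMNS = ("duration_minutes", "followup_days")

IntOrRange = Union[int, tuple[int, int]]


def _chol2_psd(s00: float, s01: float, s11: float) -> np.ndarray:
    """Lower Cholesky-like factor of a 2x2 PSD matrix, tolerating singularity."""
    if s00 <= 0.0:
        return np.array([[0.0, 0.0], [0.0, np.sqrt(max(s11, 0.0))]])
    l00 = np.sqrt(s00)
    l10 = s01 / l00
    rem = s11 - l10 * l10
    return np.array([[l00, 0.0], [l10, np.sqrt(max(rem, 0.0))]])


def _as_range(value: IntOrRange, name: str) -> tuple[int, int]:
    if isinstance(value, (int, np.integer)):
        lo = hi = int(value)
    else:
        lo, hi = (int(v) for v in value)
    if lo < 1 or hi < lo:
        raise ValueError(f"{name} must be a positive count or (lo, hi) range, got {value!r}")
    return lo, hi


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a synthetic cohort.

    ``ward_covariance`` is the triplet (sigma2_00, sigma_01, sigma2_11):
    variance of the ward random intercept, its covariance with the random
    follow-up coefficient, and the variance of that coefficient.  Setting
    the last two to zero yields a pure random-intercept generator.
    """

    n_hospitals: int = 20
    wards_per_hospital: IntOrRange = (2, 5)
    patients_per_ward: IntOrRange = (10, 250)
    covariate_prevalences: Mapping[str, float] = field(default_factory=dict)
    procedure_mix: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    ward_covariance: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hospital_variance: float = 0.0
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        _as_range(self.wards_per_hospital, "wards_per_hospital")
        _as_range(self.patients_per_ward, "patients_per_ward")
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        for name, p in self.covariate_prevalences.items():
            if name not in BINARY_COVARIATES:
                raise ValueError(f"unknown covariate {name!r} in covariate_prevalences")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0, 1], got {p}")
        mix = np.asarray(self.procedure_mix, dtype=float)
        if mix.shape != (len(PROCEDURE_TYPES),) or np.any(mix < 0):
            raise ValueError("procedure_mix must be 6 non-negative probabilities")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"procedure_mix must sum to 1, sums to {mix.sum()!r}")
        for name in self.beta:
            if name not in BINARY_COVARIATES and name not in PROCEDURE_DUMMIES:
                raise ValueError(f"unknown coefficient name {name!r} in beta")
        s00, s01, s11 = self.ward_covariance
        if s00 < 0 or s11 < 0 or s01 * s01 > s00 * s11 + 1e-12:
            raise ValueError(
                f"ward_covariance {self.ward_covariance!r} is not positive semidefinite"
            )
        if self.hospital_variance < 0:
            raise ValueError("hospital_variance must be >= 0")
        for name, r in self.missing_rates.items():
            if name not in BINARY_COVARIATES:
                raise ValueError(f"unknown covariate {name!r} in missing_rates")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate of {name!r} must be in [0, 1), got {r}")

    def digest(self) -> str:
        payload = {
            "n_hospitals": self.n_hospitals,
            "wards_per_hospital": list(_as_range(self.wards_per_hospital, "w")),
            "patients_per_ward": list(_as_range(self.patients_per_ward, "p")),
            "covariate_prevalences": dict(sorted(self.covariate_prevalences.items())),
            "procedure_mix": list(self.procedure_mix),
            "beta": dict(sorted(self.beta.items())),
            "intercept": self.intercept,
            "ward_covariance": list(self.ward_covariance),
            "hospital_variance": self.hospital_variance,
            "missing_rates": dict(sorted(self.missing_rates.items())),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CohortTable:
    """An ordered patient-level table plus free-text provenance.

    ``df`` holds one row per surgical procedure with the columns of
    :data:`COLUMNS`; binary columns use pandas' nullable ``Int64`` dtype so
    that missing values survive CSV round-trips.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("a cohort must contain at least one record")

    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def n_wards(self) -> int:
        return self.df["ward_id"].nunique()

    @property
    def n_hospitals(self) -> int:
        return self.df["hospital_id"].nunique()


#: Marginal covariate prevalences of the emulated surveillance population.
_DEFAULT_PREVALENCES = {
    "gender_female": 0.563,
    "age_ge65": 0.413,
    "asa_gt2": 0.174,
    "preop_ge48h": 0.076,
    "altemeier_gt2": 0.043,
    "endoscopic": 0.161,
    "emergency": 0.113,
    "ambulatory": 0.277,
    "followup_ge15": 0.650,
    "duration_gt_p75": 0.168,
}

#: Procedure-type shares (gastro, gyneco, cardio, ortho, ophthalmic, other),
#: renormalized over the specified categories.
_RAW_PROCEDURE_MIX = np.array([0.202, 0.166, 0.061, 0.253, 0.119, 0.196])
_DEFAULT_PROCEDURE_MIX = tuple(_RAW_PROCEDURE_MIX / _RAW_PROCEDURE_MIX.sum())

#: Generating log-odds ratios: natural logs of the adjusted ORs of the
#: random-coefficient model the defaults emulate.
_DEFAULT_OR = {
    "gender_female": 0.83,
    "age_ge65": 1.15,
    "asa_gt2": 1.99,
    "preop_ge48h": 1.63,
    "altemeier_gt2": 2.09,
    "endoscopic": 0.70,
    "procedure_gynecologic": 0.94,
    "procedure_cardiovascular": 0.59,
    "procedure_orthopedic": 0.31,
    "procedure_ophthalmic": 0.06,
    "procedure_other": 0.52,
    "duration_gt_p75": 2.11,
    "emergency": 0.95,
    "ambulatory": 0.35,
    "followup_ge15": 0.19,
}

# Ward-effect covariance implying stratum variances 4.112 (follow-up < 15d)
# and 1.582 (>= 15d), i.e. stratum MORs 6.92 and 3.32.  The split of the
# combined variance into slope variance and covariance is underdetermined;
# a slope variance of 1.0 is adopted, giving covariance
# (1.582 - 4.112 - 1.0)/2 = -1.765 (intercept-slope correlation -0.87).
_DEFAULT_WARD_COV = (4.112, -1.765, 1.0)

# Intercept calibrated by Monte-Carlo root-finding (calibrate_intercept,
# 2_000_000 patients) so the default configuration yields an overall SSI
# prevalence of ~1%.
_DEFAULT_INTERCEPT = -4.8504


def default_config(seed: int = 0) -> SyntheticConfig:
    """The reference configuration emulating the surveillance population.

    Covariate prevalences match the observed marginals, generating effects
    are the logs of the published adjusted odds ratios, the ward-effect
    covariance reproduces the published stratum MORs, the hospital level is
    absent (its contribution was negligible in the source analysis), and
    the intercept is calibrated for ~1% overall SSI prevalence.
    """
    return SyntheticConfig(
        n_hospitals=30,
        wards_per_hospital=(2, 5),
        patients_per_ward=(10, 250),
        covariate_prevalences=dict(_DEFAULT_PREVALENCES),
        procedure_mix=_DEFAULT_PROCEDURE_MIX,
        beta={k: float(np.log(v)) for k, v in _DEFAULT_OR.items()},
        intercept=_DEFAULT_INTERCEPT,
        ward_covariance=_DEFAULT_WARD_COV,
        hospital_variance=0.0,
        seed=seed,
    )


def _linear_predictor(config: SyntheticConfig, rng: np.random.Generator, n: int):
    """Draw covariates for n patients and return (covariates, eta_fixed)."""
    cols: dict[str, np.ndarray] = {}
    eta = np.full(n, float(config.intercept))
    for name in BINARY_COVARIATES:
        p = config.covariate_prevalences.get(name, 0.0)
        x = (rng.random(n) < p).astype(np.int64)
        cols[name] = x
        b = config.beta.get(name, 0.0)
        if b:
            eta += b * x
    proc_idx = rng.choice(len(PROCEDURE_TYPES), size=n, p=np.asarray(config.procedure_mix))
    cols["procedure_type"] = np.asarray(PROCEDURE_TYPES)[proc_idx]
    for i, dummy in enumerate(PROCEDURE_DUMMIES, start=1):
        b = config.beta.get(dummy, 0.0)
        if b:
            eta += b * (proc_idx == i)
    return cols, eta


def calibrate_intercept(
    config: SyntheticConfig,
    target_prevalence: float = 0.01,
    n_mc: int = 500_000,
    seed: int = 12345,
) -> float:
    """Solve for the intercept giving a target marginal outcome prevalence.

    Uses 1-D root-finding (Brent) on a Monte-Carlo estimate of the marginal
    prevalence with common random numbers: covariates, ward and hospital
    effects are drawn once and the intercept shifted.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    base = replace(config, intercept=0.0)
    cols, eta_fixed = _linear_predictor(base, rng, n_mc)
    L = _chol2_psd(*config.ward_covariance)
    u = rng.standard_normal((n_mc, 2)) @ L.T
    v = rng.normal(0.0, np.sqrt(config.hospital_variance), size=n_mc)
    f = cols["followup_ge15"]
    eta = eta_fixed + u[:, 0] + u[:, 1] * f + v

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean()) - target_prevalence

    return float(brentq(gap, -20.0, 10.0, xtol=1e-4))


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Generate a cohort from a validated configuration, reproducibly.

    Hospital effects, ward effects (bivariate: intercept and follow-up
    coefficient), covariates and outcomes are all drawn from a single
    `numpy` Generator seeded with ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    w_lo, w_hi = _as_range(config.wards_per_hospital, "wards_per_hospital")
    p_lo, p_hi = _as_range(config.patients_per_ward, "patients_per_ward")

    n_wards_per_hosp = rng.integers(w_lo, w_hi + 1, size=config.n_hospitals)
    n_wards = int(n_wards_per_hosp.sum())
    ward_hosp = np.repeat(np.arange(config.n_hospitals), n_wards_per_hosp)
    ward_sizes = rng.integers(p_lo, p_hi + 1, size=n_wards)
    n = int(ward_sizes.sum())

    hosp_eff = rng.normal(0.0, np.sqrt(config.hospital_variance), size=config.n_hospitals)
    L = _chol2_psd(*config.ward_covariance)
    ward_eff = rng.standard_normal((n_wards, 2)) @ L.T

    ward_idx = np.repeat(np.arange(n_wards), ward_sizes)
    hosp_idx = ward_hosp[ward_idx]

    cols, eta = _linear_predictor(config, rng, n)
    f = cols["followup_ge15"]
    eta = eta + hosp_eff[hosp_idx] + ward_eff[ward_idx, 0] + ward_eff[ward_idx, 1] * f
    y = (rng.random(n) < expit(eta)).astype(np.int64)

    hosp_width = max(3, len(str(config.n_hospitals)))
    hosp_names = np.array([f"H{k + 1:0{hosp_width}d}" for k in range(config.n_hospitals)])
    ward_width = max(2, len(str(int(n_wards_per_hosp.max()))))
    ward_local = np.concatenate([np.arange(m) + 1 for m in n_wards_per_hosp])
    ward_names = np.array(
        [f"{hosp_names[h]}-W{w:0{ward_width}d}" for h, w in zip(ward_hosp, ward_local)]
    )

    data: dict[str, object] = {
        "hospital_id": hosp_names[hosp_idx],
        "ward_id": ward_names[ward_idx],
        "ssi": y,
    }
    for name in BINARY_COVARIATES:
        data[name] = cols[name]
    data["procedure_type"] = cols["procedure_type"]
    data["duration_minutes"] = np.full(n, np.nan)
    data["followup_days"] = np.full(n, np.nan)

    df = pd.DataFrame(data, columns=list(COLUMNS))
    for name in ("ssi",) + BINARY_COVARIATES:
        df[name] = df[name].astype("Int64")

    for name, rate in config.missing_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, name] = pd.NA

    return CohortTable(df, provenance=f"synthetic:{config.digest()}")


# ---------------------------------------------------------------------------
# CSV dialect


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as UTF-8 CSV with the documented fixed column order.

    Missing values are written as empty fields; a leading ``# provenance:``
    comment line records the generator digest or source filename.
    """
    df = cohort.df.loc[:, list(COLUMNS)]
    buf = io.StringIO()
    buf.write(f"# provenance: {cohort.provenance}\n")
    df.to_csv(buf, index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV, validating the header and binary-column domains.

    Raises ``ValueError`` naming the offending row and column when a binary
    column holds anything other than 0, 1 or an empty (missing) field.
    """
    path = Path(path)
    provenance = str(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, skiprows=skip, dtype={"hospital_id": str, "ward_id": str})

    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s) in cohort file: {unknown}")
    missing = [c for c in COLUMNS if c not in df.columns and c not in _OPTIONAL_COLUMNS]
    if missing:
        raise ValueError(f"cohort file lacks required column(s): {missing}")
    for c in _OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    for name in ("ssi",) + BINARY_COVARIATES:
        col = pd.to_numeric(df[name], errors="coerce")
        raw_missing = df[name].isna()
        bad = (~raw_missing & col.isna()) | (~col.isna() & ~col.isin([0, 1]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid value {df[name].iloc[row]!r} in binary column {name!r}, "
                f"row {row} (values must be 0, 1 or empty)"
            )
        df[name] = col.astype("Int64")

    bad_proc = df["procedure_type"].notna() & ~df["procedure_type"].isin(PROCEDURE_TYPES)
    if bad_proc.any():
        row = int(np.flatnonzero(bad_proc.to_numpy())[0])
        raise ValueError(
            f"invalid value {df['procedure_type'].iloc[row]!r} in column "
            f"'procedure_type', row {row}"
        )

    nested = df.groupby("ward_id", observed=True)["hospital_id"].nunique()
    if (nested > 1).any():
        bad_ward = nested.index[nested > 1][0]
        raise ValueError(f"ward {bad_ward!r} appears under more than one hospital")

    return CohortTable(df.loc[:, list(COLUMNS)], provenance=provenance)
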