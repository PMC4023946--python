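"""Cohort preparation: ward-size filter, hospital subsampling, sparse-variable
discard and covariate dichotomization.

These are the steps a surveillance analyst applies between the raw extract
and model fitting.  Small wards carry almost no information about their own
random effect and destabilize variance estimation, hence the minimum-size
filter; hospital-level subsampling draws whole hospitals (with all their
wards and patients) to preserve the hierarchy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ssiml.synthetic_cohort import BINARY_COVARIATES, CohortTable

__all__ = [
    "filter_small_wards",
    "sample_hospitals",
    "drop_sparse_variables",
    "dichotomize_duration",
    "dichotomize_followup",
]


def filter_small_wards(cohort: CohortTable, min_n: int = 10) -> CohortTable:
    """Keep only wards with at least ``min_n`` patients.

    Record order is preserved; the operation is idempotent.  Raises
    ``ValueError`` if no ward survives.
    """
    sizes = cohort.df.groupby("ward_id", observed=True)["ward_id"].transform("size")
    kept = cohort.df.loc[sizes >= min_n]
    if len(kept) == 0:
        raise ValueError(f"no ward has at least {min_n} patients; empty result")
    return CohortTable(kept.reset_index(drop=True), provenance=cohort.provenance)


def sample_hospitals(
    cohort: CohortTable, fraction: float, seed: int
) -> tuple[CohortTable | None, CohortTable | None]:
    """Randomly partition the cohort by whole hospitals.

    ``round(fraction * n_hospitals)`` hospitals (half-up rounding) are drawn
    without replacement into the sample; all of a hospital's wards and
    patients travel together.  Returns ``(sample, remainder)``; either part
    may be ``None`` when it would be empty.  Deterministic per seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    hospitals = np.asarray(sorted(cohort.df["hospital_id"].unique()))
    n_take = int(np.floor(fraction * len(hospitals) + 0.5))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(hospitals, size=n_take, replace=False))
    in_sample = cohort.df["hospital_id"].isin(chosen)

    def _part(mask) -> CohortTable | None:
        part = cohort.df.loc[mask]
        if len(part) == 0:
            return None
        return CohortTable(part.reset_index(drop=True), provenance=cohort.provenance)

    return _part(in_sample), _part(~in_sample)


def drop_sparse_variables(
    cohort: CohortTable, max_missing: float = 0.10
) -> tuple[CohortTable, list[str]]:
    """Discard covariates whose missingness exceeds ``max_missing``.

    The threshold is strict ("greater than"): a covariate missing in exactly
    10% of records is retained at the default.  Dropped columns are removed
    from the table and their names returned.
    """
    n = len(cohort.df)
    dropped = [
        name
        for name in BINARY_COVARIATES
        if name in cohort.df.columns and cohort.df[name].isna().sum() / n > max_missing
    ]
    if not dropped:
        return cohort, []
    return (
        CohortTable(cohort.df.drop(columns=dropped), provenance=cohort.provenance),
        dropped,
    )


def dichotomize_duration(cohort: CohortTable, quantile: float = 0.75) -> CohortTable:
    """Flag surgeries longer than the within-procedure-type duration quantile.

    The quantile (default the 75th percentile, linear interpolation between
    order statistics) is computed per procedure type over the non-missing
    durations of the input cohort itself; ``duration_gt_p75`` is 1 iff the
    duration strictly exceeds it.  Missing durations propagate as missing
    flags.
    """
    df = cohort.df
    if df["duration_minutes"].isna().all():
        raise ValueError("dichotomize_duration requires duration_minutes values")
    out = df.copy()
    cutoffs = df.groupby("procedure_type", observed=True)["duration_minutes"].quantile(
        quantile, interpolation="linear"
    )
    cut = df["procedure_type"].map(cutoffs)
    flag = pd.array(
        (df["duration_minutes"] > cut).astype("int64"), dtype="Int64"
    )
    flag[df["duration_minutes"].isna().to_numpy()] = pd.NA
    out["duration_gt_p75"] = flag
    return CohortTable(out, provenance=cohort.provenance)


def dichotomize_followup(followup_days, cutoff: int = 15):
    """1 iff post-surgery follow-up lasted at least ``cutoff`` days.

    Accepts a scalar or array; negative day counts are rejected.
    """
    days = np.asarray(followup_days, dtype=float)
    if np.any(days[~np.isnan(days)] < 0):
        raise ValueError("follow-up duration cannot be negative")
    flag = (days >= cutoff).astype(np.int64)
    if days.ndim == 0:
        return int(flag)
    return flag
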