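"""End-to-end analysis pipeline.

Reproduces the full surveillance workflow on one cohort: generate or load
-> ward-size filter -> train/validation split by whole hospitals -> empty
model and level selection -> univariate screening -> random-intercept model
-> random-coefficient model -> MOR table -> out-of-sample ROC and SIR.

The hospital level is dropped when its variance-component test yields
p >= 0.05.  A single master seed fans out to fixed per-stage substreams so
reruns are bit-reproducible; stage runtimes go to the log only, keeping the
report body deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from ssiml import heterogeneity
from ssiml.hierarchical_model import (
    DEFAULT_COVARIATES,
    McmcSettings,
    ModelSpec,
    fit_mcmc,
    fit_model1_empty,
    fit_model2_intercept,
    fit_model3_slope,
    test_level_variance,
    univariate_screen,
)
from ssiml.prediction_validation import compare_aucs, predict_prob, sir_by_ward
from ssiml.preprocess import filter_small_wards, sample_hospitals
from ssiml.synthetic_cohort import (
    BINARY_COVARIATES,
    CohortTable,
    SyntheticConfig,
    default_config,
    generate_cohort,
    read_cohort,
)

__all__ = ["run_pipeline", "synthetic_config_from_dict"]

log = logging.getLogger("ssiml.pipeline")


def synthetic_config_from_dict(d: dict, seed: int) -> SyntheticConfig:
    """Build a SyntheticConfig from a YAML-style mapping.

    ``preset: default`` starts from the reference configuration; any other
    key overrides the corresponding field.  Sequence fields accept lists.
    """
    d = dict(d)
    preset = d.pop("preset", "default")
    cfg = default_config(seed) if preset == "default" else SyntheticConfig(seed=seed)
    fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    overrides = {}
    for key, val in d.items():
        if key not in fields:
            raise ValueError(f"unknown synthetic-config key {key!r}")
        if key in ("wards_per_hospital", "patients_per_ward") and isinstance(val, list):
            val = tuple(val)
        if key in ("ward_covariance", "procedure_mix") and isinstance(val, list):
            val = tuple(val)
        overrides[key] = val
    overrides["seed"] = seed
    return replace(cfg, **overrides)


def _descriptive_table(cohort: CohortTable) -> dict:
    """Prevalence of each covariate by SSI status plus overall counts."""
    df = cohort.df
    out: dict = {
        "n_patients": int(len(df)),
        "n_wards": int(cohort.n_wards),
        "n_hospitals": int(cohort.n_hospitals),
        "n_ssi": int(df["ssi"].sum()),
        "ssi_rate_percent": round(float(df["ssi"].mean()) * 100, 2),
        "covariates": {},
    }
    ssi1 = df["ssi"] == 1
    for name in BINARY_COVARIATES:
        if name not in df.columns:
            continue
        col = df[name]
        out["covariates"][name] = {
            "prevalence": round(float(col.mean()), 4),
            "prevalence_ssi": round(float(col[ssi1].mean()), 4)
            if int(ssi1.sum()) else None,
            "missing": int(col.isna().sum()),
        }
    return out


def _coefficient_table(summary) -> list[dict]:
    rows = []
    for _, row in summary.coefficients.iterrows():
        rows.append(
            {
                "coefficient": row["coefficient"],
                "or": round(float(row["or"]), 2),
                "or_lower": round(float(row["or_lower"]), 2),
                "or_upper": round(float(row["or_upper"]), 2),
                "p": float(f"{row['p']:.3g}"),
            }
        )
    return rows


def _mor_table(draws) -> list[dict]:
    return [
        {
            "stratum": m.stratum,
            "mor": round(m.mor, 2),
            "lower": round(m.lower, 2),
            "upper": round(m.upper, 2),
        }
        for m in heterogeneity.stratified_mor(draws)
    ]


def _stage(name: str, seed: Optional[int], n: Optional[int]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start (seed=%s, n=%s)", name, seed, n)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.1fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.1fs (%s)", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config_path) -> dict:
    """Execute the full workflow described by a YAML configuration file.

    Returns the report dictionary; also writes ``report.json`` and
    ``report.md`` (plus posterior archives) to the configured output
    directory, if any.  Stage failures propagate with the stage name in the
    log; intermediate artifacts written so far are left on disk.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg["out_dir"]) if "out_dir" in cfg else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    mcmc_cfg = cfg.get("mcmc", {})
    mcmc = McmcSettings(
        burn_in=int(mcmc_cfg.get("burn_in", 2000)),
        iterations=int(mcmc_cfg.get("iterations", 12000)),
        thin=int(mcmc_cfg.get("thin", 10)),
        seed=seed + 2,
    )
    report: dict = {"config": cfg, "seed": seed}

    with _stage("cohort", seed, None):
        if "cohort" in cfg:
            cohort = read_cohort(cfg["cohort"])
        else:
            syn = synthetic_config_from_dict(cfg.get("synthetic", {}), seed)
            cohort = generate_cohort(syn)
        report["cohort_provenance"] = cohort.provenance

    min_ward = int(cfg.get("min_ward_size", 10))
    with _stage("filter_small_wards", None, cohort.n_patients):
        cohort = filter_small_wards(cohort, min_ward)

    frac = float(cfg.get("validation_fraction", 0.2))
    with _stage("train_validation_split", seed + 1, cohort.n_patients):
        validation, train = sample_hospitals(cohort, frac, seed + 1)
        if train is None:
            raise ValueError("validation_fraction leaves no training hospitals")
    report["descriptive"] = _descriptive_table(train)

    with _stage("model1_empty", mcmc.seed, train.n_patients):
        level_p = test_level_variance(train, ("ward", "hospital"), ("ward",))
        hosp_policy = cfg.get("hospital_level", "auto")
        keep_hospital = {"auto": level_p < 0.05, "keep": True, "drop": False}[hosp_policy]
        levels1 = ("ward", "hospital")
        draws1, summ1 = fit_model1_empty(train, levels=levels1, mcmc=mcmc)
        report["model1"] = {
            "levels": list(levels1),
            "hospital_level_p": float(f"{level_p:.3g}"),
            "hospital_level_retained": bool(keep_hospital),
            "coefficients": _coefficient_table(summ1),
            "mor": _mor_table(draws1),
            "warnings": summ1.warnings,
        }
        if out_dir:
            from ssiml.hierarchical_model import save_draws

            save_draws(draws1, out_dir / "model1_posterior.npz")

    candidates = tuple(cfg.get("candidates", DEFAULT_COVARIATES))
    if cfg.get("screening", {}).get("enabled", True):
        alpha = float(cfg.get("screening", {}).get("alpha", 0.20))
        with _stage("univariate_screen", mcmc.seed, train.n_patients):
            screen_mcmc = McmcSettings(
                burn_in=max(500, mcmc.burn_in // 4),
                iterations=max(3000, mcmc.iterations // 4),
                thin=max(1, mcmc.thin // 2),
                seed=seed + 3,
            )
            covariates = tuple(
                univariate_screen(train, candidates, alpha, mcmc=screen_mcmc)
            )
        report["screening"] = {
            "alpha": alpha,
            "candidates": list(candidates),
            "retained": list(covariates),
        }
    else:
        covariates = candidates
        report["screening"] = {"enabled": False, "retained": list(covariates)}
    if not covariates:
        raise ValueError("univariate screening retained no covariates")

    levels23 = ("ward", "hospital") if keep_hospital else ("ward",)
    with _stage("model2_intercept", mcmc.seed, train.n_patients):
        spec2 = ModelSpec(
            covariates=covariates, levels=levels23, mcmc=replace(mcmc, seed=seed + 4)
        )
        draws2, summ2 = fit_mcmc(spec2, train)
        report["model2"] = {
            "levels": list(levels23),
            "coefficients": _coefficient_table(summ2),
            "mor": _mor_table(draws2),
            "warnings": summ2.warnings,
        }
        if out_dir:
            from ssiml.hierarchical_model import save_draws

            save_draws(draws2, out_dir / "model2_posterior.npz")

    slope_cov = cfg.get("random_slope", "followup_ge15")
    if slope_cov not in covariates:
        slope_cov = None
    if slope_cov:
        with _stage("model3_slope", mcmc.seed, train.n_patients):
            spec3 = ModelSpec(
                covariates=covariates,
                levels=levels23,
                random_slope=slope_cov,
                mcmc=replace(mcmc, seed=seed + 5),
            )
            draws3, summ3 = fit_mcmc(spec3, train)
            report["model3"] = {
                "random_slope": slope_cov,
                "coefficients": _coefficient_table(summ3),
                "mor": _mor_table(draws3),
                "warnings": summ3.warnings,
            }
            if out_dir:
                from ssiml.hierarchical_model import save_draws

                save_draws(draws3, out_dir / "model3_posterior.npz")
        final_draws = draws3
    else:
        final_draws = draws2

    if validation is not None:
        with _stage("validation", seed + 6, validation.n_patients):
            ref_spec = ModelSpec(
                covariates=covariates, levels=(), mcmc=replace(mcmc, seed=seed + 6)
            )
            ref_draws, _ = fit_mcmc(ref_spec, train)
            policy = cfg.get("ward_effect_policy", "empirical_bayes")
            p_multi = predict_prob(final_draws, validation, policy)
            p_ref = predict_prob(ref_draws, validation, "zero")
            ok = (
                ~np.isnan(p_multi)
                & ~np.isnan(p_ref)
                & validation.df["ssi"].notna().to_numpy()
            )
            y = validation.df["ssi"].to_numpy(dtype=float)[ok]
            roc = compare_aucs(p_multi[ok], p_ref[ok], y)
            report["validation"] = {
                "n": int(ok.sum()),
                "ward_effect_policy": policy,
                "auc_multilevel": round(roc.auc_a, 3),
                "auc_single_level": round(roc.auc_b, 3),
                "z": round(roc.z, 2),
                "p": float(f"{roc.p:.3g}"),
                "engine": roc.engine,
            }
            sirs = sir_by_ward(validation, p_multi)
            report["sir"] = [
                {
                    "scope": s.scope,
                    "observed": s.observed,
                    "expected": round(s.expected, 2),
                    "sir": round(s.sir, 2),
                }
                for s in sirs
            ]

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        (out_dir / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# SSI multilevel analysis report", ""]
    d = report["descriptive"]
    lines += [
        "## Training cohort",
        "",
        f"- patients: {d['n_patients']} in {d['n_wards']} wards / "
        f"{d['n_hospitals']} hospitals",
        f"- SSI: {d['n_ssi']} ({d['ssi_rate_percent']}%)",
        "",
        "| covariate | prevalence | prevalence (SSI) | missing |",
        "|---|---|---|---|",
    ]
    for name, row in d["covariates"].items():
        lines.append(
            f"| {name} | {row['prevalence']} | {row['prevalence_ssi']} "
            f"| {row['missing']} |"
        )
    for key, title in (
        ("model1", "Model 1 (empty)"),
        ("model2", "Model 2 (random intercept)"),
        ("model3", "Model 3 (random coefficient)"),
    ):
        if key not in report:
            continue
        m = report[key]
        lines += ["", f"## {title}", ""]
        if key == "model1":
            lines.append(
                f"- hospital-level variance test p = {m['hospital_level_p']}; "
                f"retained: {m['hospital_level_retained']}"
            )
        lines += ["", "| coefficient | OR | 95% CI | p |", "|---|---|---|---|"]
        for c in m["coefficients"]:
            lines.append(
                f"| {c['coefficient']} | {c['or']} | "
                f"({c['or_lower']} to {c['or_upper']}) | {c['p']} |"
            )
        for mor in m["mor"]:
            lines.append(
                f"\nMOR [{mor['stratum']}]: {mor['mor']} "
                f"({mor['lower']} to {mor['upper']})"
            )
    if "validation" in report:
        v = report["validation"]
        lines += [
            "",
            "## Validation",
            "",
            f"- multilevel AUC: {v['auc_multilevel']}",
            f"- single-level AUC: {v['auc_single_level']}",
            f"- paired comparison ({v['engine']}): z = {v['z']}, p = {v['p']}",
        ]
    return "\n".join(lines) + "\n"
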