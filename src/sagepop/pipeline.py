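"""Pipeline orchestration: simulate -> estimate -> matrices -> lambda -> LTRE.

One declarative config drives a deterministic run.  Stages communicate
only through the CSV contracts (vital-rate table, encounter histories,
model-selection tables), so each stage can also be run alone on files
produced elsewhere.  Every run directory contains a ``report.md``
embedding the seed, the config hash, and every design flag in effect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import brood_survival as bs
from . import known_fate_survival as kf
from .core_types_io import (
    AnnualVitalRates,
    BroodHistory,
    FemaleHistory,
    NestHistory,
    RateEstimate,
    RateKey,
    load_packaged_vital_rates,
    read_vital_rate_table,
    season_of_month,
    write_vital_rate_table,
)
from .ltre import ltre_contributions
from .matrix_demography import (
    BootstrapConfig,
    LambdaResult,
    bootstrap_lambda,
    multi_year_summary,
)
from .rate_estimators import derive_juvenile_survival, pooled_proportion
from .synthetic_data import (
    SimulationTruth,
    simulate_broods,
    simulate_females,
    simulate_nests,
    stage_rng,
)

logger = logging.getLogger("sagepop")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "estimate_vital_rates"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "replicates": 10_000,
    "sjuv_mode": "derived",     # lambda pipeline: S_juv recomputed per replicate
    "cs2_mode": "table",
    "resample_h": False,
    "vital_rates": "packaged",  # or a path to a vital_rates.csv
    "ltre": {
        "eval_rule": "reference",
        "sjuv_mode": "table",   # LTRE treats tabled S_juv as its own rate
        "reference_year": None,  # default: first year
    },
    "simulate": {
        "enabled": False,
        # model sets used when estimating from simulated histories
        "nest_models": ["intercept", "year", "year + T"],
        "female_models": ["year + age + winter", "year + age", "intercept"],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Defaults, optionally overlaid with a YAML file and kwargs."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg = _merge(cfg, user)
    return _merge(cfg, overrides)


# ---------------------------------------------------------------------------
# Estimation from encounter histories
# ---------------------------------------------------------------------------

def estimate_vital_rates(
    females: Sequence[FemaleHistory],
    nests: Sequence[NestHistory],
    broods: Sequence[BroodHistory],
    base_rates: Sequence[AnnualVitalRates],
    nest_models: Sequence[str] = ("intercept", "year", "year + T"),
    female_models: Sequence[str] = ("year + age + winter", "year + age", "intercept"),
    brood_rho_models: Sequence[str] = bs.RHO_MODEL_SET,
    brood_phi_models: Sequence[str] = bs.PHI_MODEL_SET,
    gps_adjust: bool = False,
) -> tuple[list[AnnualVitalRates], dict[str, pd.DataFrame]]:
    """Estimate every estimable vital rate from encounter histories.

    Closed-form rates (NI1, NI2) come from counts; NS, monthly female
    survival and chick survival from the likelihood engines with AICc
    model averaging; S_juv is derived from the estimated adult survival.
    Clutch sizes and hatchability are copied from ``base_rates`` (they
    come from egg counts, which encounter histories do not carry).
    Returns the per-year tables plus the model-selection tables.
    """
    years = sorted({h.year for h in females})
    out = {a.year: AnnualVitalRates(year=a.year) for a in base_rates}
    for avr in base_rates:
        for key, est in avr.rates.items():
            if key.rate_name in ("CS1", "CS2", "H"):
                out[avr.year].add(est)
    selection: dict[str, pd.DataFrame] = {}

    # --- nest initiation (closed-form proportions)
    females_by = {
        (y, a): [h for h in females if h.year == y and h.age_class == a]
        for y in years for a in ("SY", "ASY")
    }
    first_nests = [h for h in nests if h.attempt == "first"]
    renests = [h for h in nests if h.attempt == "renest"]
    for y in years:
        for age in ("SY", "ASY"):
            trials = len(females_by[(y, age)])
            if trials == 0:
                continue
            succ = sum(1 for h in first_nests if h.year == y and h.age_class == age)
            est = pooled_proportion([(min(succ, trials), trials)])
            out[y].add(RateEstimate(RateKey("NI1", age), y, est.p, est.se, trials))
        failed_first = [h for h in first_nests if h.year == y and h.fate == "failed"]
        if failed_first:
            succ2 = sum(1 for h in renests if h.year == y)
            est2 = pooled_proportion([(min(succ2, len(failed_first)), len(failed_first))])
            out[y].add(
                RateEstimate(RateKey("NI2"), y, est2.p, est2.se, len(failed_first))
            )

    # --- nest survival: separate runs per the study design
    nest_runs = {
        ("NS1", "SY"): [h for h in first_nests if h.age_class == "SY"],
        ("NS1", "ASY"): [h for h in first_nests if h.age_class == "ASY"],
        ("NS2", "pooled"): renests,
    }
    for (rate_name, age), subset in nest_runs.items():
        if not subset:
            continue
        records = kf.expand_nest_histories(subset)
        fits = [kf.fit_known_fate(records, m) for m in nest_models]
        ranked = kf.rank_models(fits)
        selection[f"nest_{rate_name}_{age}"] = model_selection_table(ranked)
        for y in sorted({h.year for h in subset}):
            n_y = sum(1 for h in subset if h.year == y)
            iv = kf.model_average(ranked, year=y)
            ns, se = kf.derive_window_products(iv, "nest27")
            key_age = age if rate_name == "NS1" else "pooled"
            out[y].add(RateEstimate(RateKey(rate_name, key_age), y, ns, se, n_y))

    # --- monthly female survival: one run, year+age base structure
    records = kf.expand_female_histories(females)
    fits = [kf.fit_known_fate(records, m) for m in female_models]
    ranked = kf.rank_models(fits)
    selection["female_survival"] = model_selection_table(ranked)
    for y in years:
        for age in ("SY", "ASY"):
            n_y = len(females_by[(y, age)])
            if n_y == 0:
                continue
            iv = kf.model_average(ranked, year=y, age=age)
            s_ann, se = kf.derive_window_products(iv, "annual12")
            if gps_adjust:
                from .rate_estimators import adjust_gps_bias

                s_ann = adjust_gps_bias(s_ann)
            out[y].add(RateEstimate(RateKey("S_annual", age), y, s_ann, se, n_y))
            for season in ("breed", "fall", "winter"):
                months = [m for m in range(1, 13) if _season_tag(m) == season]
                s_seas, se_s = kf.derive_window_products(iv, "season4", months=months)
                out[y].add(
                    RateEstimate(RateKey(f"S_{season}", age), y, s_seas, se_s, n_y)
                )

    # --- chick survival: two-stage brood model selection
    if broods:
        stage1, stage2 = bs.two_stage_selection(
            broods, rho_formulas=brood_rho_models, phi_formulas=brood_phi_models
        )
        selection["brood_rho"] = brood_selection_table(stage1)
        selection["brood_phi"] = brood_selection_table(stage2)
        w = np.array([f.akaike_weight for f in stage2])
        by_year = {y: sum(1 for h in broods if h.year == y) for y in years}
        for y in years:
            n_y = by_year.get(y, 0)
            if n_y == 0:
                continue
            vals = np.array(
                [f.chick_survival_54d().get(y, np.nan) for f in stage2]
            )
            ok = np.isfinite(vals)
            s54 = float(np.sum(w[ok] * vals[ok]) / np.sum(w[ok]))
            # binomial-scale approximation on the brood sample for the SE
            se = float(np.sqrt(max(s54 * (1 - s54), 1e-12) / max(n_y, 1)))
            out[y].add(RateEstimate(RateKey("S_chick"), y, min(s54, 1.0), se, n_y))

    # --- derived juvenile survival from estimated adult survival
    for y in years:
        s_asy = out[y].get("S_annual", "ASY")
        if s_asy is not None and s_asy.mean > 0:
            sj, se = derive_juvenile_survival(s_asy.mean)
            out[y].add(RateEstimate(RateKey("S_juv"), y, sj, se, s_asy.n))

    return [out[y] for y in sorted(out)], selection


def _season_tag(month: int) -> str:
    s = season_of_month(month)
    return "breed" if s == "breeding" else s


def model_selection_table(ranked: Sequence[kf.SurvivalModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.design.formula for f in ranked],
            "K": [f.K for f in ranked],
            "delta_aicc": [f.delta_aicc for f in ranked],
            "weight": [f.akaike_weight for f in ranked],
            "log_likelihood": [f.log_likelihood for f in ranked],
        }
    )


def brood_selection_table(ranked: Sequence[bs.BroodFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.spec.name for f in ranked],
            "K": [f.K for f in ranked],
            "delta_aicc": [f.delta_aicc for f in ranked],
            "weight": [f.akaike_weight for f in ranked],
            "log_likelihood": [f.log_likelihood for f in ranked],
        }
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    outdir: Path
    config: dict
    vital_rates: list[AnnualVitalRates]
    lambda_results: list[LambdaResult]
    summary: Any
    ltre: Any
    paths: dict[str, Path]


def run_pipeline(config: dict | str | Path | None, outdir: str | Path) -> RunResult:
    """Execute the configured stages into ``outdir``.

    Deterministic for a given config: all randomness flows from
    ``config['seed']`` through named substreams.  Outputs:
    ``vital_rates.csv``, optional ``model_selection_*.csv``,
    ``lambda_results.csv``, ``ltre_contributions.csv``,
    ``ltre_totals.csv`` and ``report.md``.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    paths: dict[str, Path] = {}
    selection: dict[str, pd.DataFrame] = {}

    # stage: vital rates (simulated+estimated, or loaded)
    if cfg["simulate"]["enabled"]:
        truth = SimulationTruth.from_table(seed=seed)
        females = simulate_females(truth, stage_rng(seed, "females"))
        nests = simulate_nests(truth, stage_rng(seed, "nests"))
        broods = simulate_broods(truth, stage_rng(seed, "broods"))
        base = load_packaged_vital_rates()
        rates, selection = estimate_vital_rates(
            females, nests, broods, base,
            nest_models=cfg["simulate"]["nest_models"],
            female_models=cfg["simulate"]["female_models"],
        )
    elif cfg["vital_rates"] == "packaged":
        rates = load_packaged_vital_rates()
    else:
        rates = read_vital_rate_table(cfg["vital_rates"])
    paths["vital_rates"] = outdir / "vital_rates.csv"
    write_vital_rate_table(rates, paths["vital_rates"])
    for name, table in selection.items():
        p = outdir / f"model_selection_{name}.csv"
        table.to_csv(p, index=False)
        paths[f"model_selection_{name}"] = p

    # stage: annual lambda bootstrap
    usable = [a for a in rates if not a.missing_matrix_rates()]
    boot_cfg = BootstrapConfig(
        n_replicates=int(cfg["replicates"]),
        sjuv_mode=cfg["sjuv_mode"],
        cs2_mode=cfg["cs2_mode"],
        resample_h=bool(cfg["resample_h"]),
    )
    rng = stage_rng(seed, "bootstrap")
    results = [bootstrap_lambda(a, boot_cfg, rng) for a in usable]
    summary = multi_year_summary(results) if results else None
    lam_rows = []
    for r in results:
        lo, hi = r.ci
        lam_rows.append(
            {
                "year": r.year,
                "lambda_point": r.lambda_point,
                "lambda_boot_mean": r.boot_mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "classification": r.classification,
            }
        )
    paths["lambda_results"] = outdir / "lambda_results.csv"
    pd.DataFrame(lam_rows).to_csv(
        paths["lambda_results"], index=False, float_format="%.6f"
    )

    # stage: LTRE against the reference year
    ltre_cfg = cfg["ltre"]
    ref_year = ltre_cfg["reference_year"] or usable[0].year
    reference = next(a for a in usable if a.year == ref_year)
    treatments = [a for a in usable if a.year != ref_year]
    ltre_res = None
    if treatments:
        ltre_res = ltre_contributions(
            reference,
            treatments,
            eval_rule=ltre_cfg["eval_rule"],
            sjuv_mode=ltre_cfg["sjuv_mode"],
            cs2_mode=cfg["cs2_mode"],
        )
        paths["ltre_contributions"] = outdir / "ltre_contributions.csv"
        ltre_res.contributions.to_csv(paths["ltre_contributions"], index=False)
        paths["ltre_totals"] = outdir / "ltre_totals.csv"
        ltre_res.totals.rename("total").to_csv(paths["ltre_totals"])

    paths["report"] = outdir / "report.md"
    paths["report"].write_text(_report(cfg, rates, results, summary, ltre_res))
    return RunResult(
        outdir=outdir,
        config=cfg,
        vital_rates=rates,
        lambda_results=results,
        summary=summary,
        ltre=ltre_res,
        paths=paths,
    )


def _report(cfg, rates, results, summary, ltre_res) -> str:
    cfg_hash = hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [
        "# sagepop run report",
        "",
        f"- seed: {cfg['seed']}",
        f"- config hash: {cfg_hash}",
        f"- replicates: {cfg['replicates']}",
        f"- sjuv_mode: {cfg['sjuv_mode']} | cs2_mode: {cfg['cs2_mode']} | "
        f"resample_h: {cfg['resample_h']}",
        f"- ltre: eval_rule={cfg['ltre']['eval_rule']} "
        f"sjuv_mode={cfg['ltre']['sjuv_mode']}",
        f"- years: {[a.year for a in rates]}",
        "",
        "## Annual finite rate of population change",
        "",
        "| year | lambda | boot mean | 95% CI | classification |",
        "|------|--------|-----------|--------|----------------|",
    ]
    for r in results:
        lo, hi = r.ci
        lines.append(
            f"| {r.year} | {r.lambda_point:.3f} | {r.boot_mean:.3f} | "
            f"({lo:.2f}, {hi:.2f}) | {r.classification} |"
        )
    if summary is not None:
        lines += [
            "",
            f"Geometric mean lambda {summary.years[0]}-{summary.years[-1]}: "
            f"{summary.geo_mean_point:.3f} (replicate mean "
            f"{summary.geo_mean_boot_mean:.3f}, 95% CI {summary.ci[0]:.2f}-"
            f"{summary.ci[1]:.2f})",
        ]
    if ltre_res is not None:
        lines += [
            "",
            "## LTRE totals (treatment minus reference)",
            "",
            ltre_res.totals.round(4).to_string(),
            "",
            f"Reference year: {ltre_res.reference_year}; rule: {ltre_res.eval_rule}",
        ]
    return "\n".join(lines) + "\n"
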