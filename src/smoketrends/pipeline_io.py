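"""Readers, writers, configuration and the end-to-end pipeline.

The pipeline ties the stages together the way the source analysis runs
them: simulate (or load) survey micro-data, harmonize the smoking
questions, compute age-and-education standardized prevalence per study
(Table-1-style), pool education effects per sex (forest tables), fit
trend meta-regressions to education-stratified prevalence, and run the
mortality-attribution and survivor-selection models.

All tabular exchange is CSV; summaries are JSON.  Every output carries
the configuration hash (CSV: a leading ``# config_hash=...`` comment
line; JSON: a ``config_hash`` key) and nothing is written unless every
requested stage succeeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import HazardProfile, avoided_deaths
from .attrition import CohortParams, GompertzHazard, prevalence_reduction, selected_prevalence
from .errors import ConfigurationError, DataError, PipelineError
from .harmonize import SmokingDefinition, harmonize_records
from .meta import StudyEffect, dl_pool, fit_all_studies, forest_table, meta_regress
from .standardize import (direct_standardize, double_standardize,
                          education_standard, european_standard_1976,
                          stratum_prevalence, age_group)
from .survey_synth import (PrevalenceSurface, RECORD_COLUMNS, SurveyDesign,
                           cross_sectional_designs, generate_mortality,
                           generate_scenario, path_from_surface, rlms_designs)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def read_survey_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read survey records, validating the documented schema.

    Returns (records, report); malformed rows (unparseable age/flags,
    unknown categories, inconsistent daily/occasional flags) are dropped
    and counted in the report rather than silently kept.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"survey CSV missing mandatory columns: {missing}")
    n_read = len(df)
    bad = pd.Series(False, index=df.index)
    reasons: dict[str, int] = {}

    def flag(mask, reason):
        nonlocal bad
        mask = mask & ~bad
        if mask.any():
            reasons[reason] = int(mask.sum())
        bad |= mask

    age = pd.to_numeric(df["age"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    flag(age.isna() | (age < 0) | (age % 1 != 0), "bad age")
    flag(year.isna(), "bad year")
    flag(~df["sex"].isin(["male", "female"]), "bad sex")
    flag(~df["education"].isin(["low", "secondary", "high"]), "bad education")
    bools = {}
    for col in ("smokes_daily", "smokes_occasionally",
                "lifetime_cigarettes_ge_100", "former_smoker"):
        b = df[col].str.lower().map(_BOOL_MAP)
        flag(b.isna(), f"bad {col}")
        bools[col] = b
    flag((bools["smokes_daily"] == True) & (bools["smokes_occasionally"] == True),  # noqa: E712
         "daily and occasional both set")
    ysq = pd.to_numeric(df["years_since_quit"].mask(df["years_since_quit"] == ""),
                        errors="coerce")
    ysq_bad = (bools["former_smoker"] == True) & (ysq.isna() | (ysq < 0))  # noqa: E712
    flag(ysq_bad, "former smoker without valid years_since_quit")

    keep = ~bad
    out = pd.DataFrame({
        "survey": df.loc[keep, "survey"],
        "year": year[keep].astype(int),
        "sex": df.loc[keep, "sex"],
        "age": age[keep].astype(int),
        "education": df.loc[keep, "education"],
        "smokes_daily": bools["smokes_daily"][keep].astype(bool),
        "smokes_occasionally": bools["smokes_occasionally"][keep].astype(bool),
        "lifetime_cigarettes_ge_100": bools["lifetime_cigarettes_ge_100"][keep].astype(bool),
        "former_smoker": bools["former_smoker"][keep].astype(bool),
        "years_since_quit": ysq[keep],
    }).reset_index(drop=True)
    report = {"n_read": n_read, "n_kept": len(out),
              "n_malformed": int(bad.sum()), "reasons": reasons}
    return out, report


def write_survey_csv(records: pd.DataFrame, path, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        records.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Pipeline configuration with the synthetic default scenario."""

    seed: int = 0
    output_dir: str = "results"
    input_csv: str | None = None          # load instead of simulating
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "prevalence": True, "meta": True,
        "metareg": True, "attribution": True, "attrition": True})
    include_cross_sections: bool = True
    exclude_surveys: tuple = ()           # e.g. distorted panel rounds
    definitions: dict = field(default_factory=dict)  # survey -> variant override
    capture_prob: float = 0.5
    education_standard: tuple = (0.30, 0.50, 0.20)
    min_age_coverage: float = 0.9         # standardized-table inclusion rule
    hazard_ratios: dict = field(default_factory=lambda: {"15-49": 2.0, "50-64": 1.7, "65+": 1.3})
    baseline_cvd_rates: dict = field(default_factory=lambda: {"15-49": 0.0008, "50-64": 0.006, "65+": 0.03})
    populations: dict = field(default_factory=lambda: {"15-49": 3.0e7, "50-64": 1.2e7, "65+": 6.0e6})
    attribution_years: tuple = (2007, 2016)
    attrition: dict = field(default_factory=lambda: {
        "p0": 0.6, "hazard_ratio": 2.0, "entry_age": 25.0,
        "gompertz_a": 8e-4, "gompertz_b": 0.075})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.input_csv and not Path(cfg.input_csv).exists():
            raise ConfigurationError(f"input_csv not found: {cfg.input_csv}")
        return cfg

    def hash(self) -> str:
        """Hash of the analysis configuration (where outputs go is not
        part of the analysis, so ``output_dir`` is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


def _designs(config: RunConfig) -> list[SurveyDesign]:
    designs = rlms_designs()
    if config.include_cross_sections:
        designs += cross_sectional_designs()
    designs = [d for d in designs if d.survey not in set(config.exclude_surveys)]
    for i, d in enumerate(designs):
        variant = config.definitions.get(d.survey)
        if variant:
            designs[i] = dataclasses.replace(d, variant=variant)
    return designs


def _harmonize_by_survey(records: pd.DataFrame, variants: dict, capture_prob: float,
                         seed: int) -> pd.DataFrame:
    parts = []
    for i, (survey, sub) in enumerate(records.groupby("survey", observed=True, sort=True)):
        d = SmokingDefinition(variant=variants.get(str(survey), "who_current"),
                              capture_prob=capture_prob)
        parts.append(harmonize_records(sub, d, seed=seed + i))
    return pd.concat(parts, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the run log.  All outputs are accumulated in memory and only
    written once every stage has succeeded; a stage failure raises
    :class:`PipelineError` naming the stage, and nothing is written.
    """
    chash = config.hash()
    outputs: list[tuple[str, object]] = []   # (relpath, DataFrame | dict)
    surface = PrevalenceSurface.default()

    def stage(name, enabled, fn):
        if not enabled:
            return None
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    # --- data ------------------------------------------------------------
    variants: dict[str, str] = {}

    def _data():
        if config.input_csv:
            recs, report = read_survey_csv(config.input_csv)
            variants.update({s: "who_current" for s in recs["survey"].unique()})
            variants.update(config.definitions)
            recs = recs[~recs["survey"].isin(set(config.exclude_surveys))]
            return recs, report
        designs = _designs(config)
        variants.update({d.survey: d.variant for d in designs})
        recs = generate_scenario(designs, surface, config.seed)
        return recs, {"n_read": len(recs), "n_kept": len(recs),
                      "n_malformed": 0, "reasons": {}}

    records, data_report = stage("data", True, _data)
    records = stage("harmonize", True, lambda: _harmonize_by_survey(
        records, variants, config.capture_prob, config.seed))
    if config.stages.get("simulate") and not config.input_csv:
        outputs.append(("records.csv", records))

    edu_w = education_standard(*config.education_standard)

    # --- standardized prevalence (Table-1-style) --------------------------
    def _prevalence():
        rows = []
        for (survey, year, sex), sub in records.groupby(
                ["survey", "year", "sex"], observed=True, sort=True):
            amin, amax = int(sub["age"].min()), int(sub["age"].max())
            age_w = european_standard_1976(18, 79)
            est = double_standardize(sub, age_w, edu_w)
            rows.append({"survey": survey, "year": int(year), "sex": sex,
                         "value": est.value, "se": est.se, "n": est.n,
                         "age_coverage": est.coverage,
                         "included": est.coverage >= config.min_age_coverage})
        return pd.DataFrame(rows)

    prev_table = stage("prevalence", config.stages.get("prevalence", True), _prevalence)
    if prev_table is not None:
        outputs.append(("standardized_prevalence.csv", prev_table))

    # --- education meta-analysis (forest tables) --------------------------
    meta_log = {}

    def _meta():
        out = {}
        for sex in ("male", "female"):
            sub = records[records["sex"] == sex]
            effects, excluded = fit_all_studies(sub, contrast="low")
            meta_log[sex] = {"excluded": excluded, "k": len(effects)}
            pooled = dl_pool(effects)
            out[sex] = forest_table(effects, pooled)
        return out

    forests = stage("meta", config.stages.get("meta", True), _meta)
    if forests is not None:
        for sex, tbl in forests.items():
            outputs.append((f"forest_low_vs_high_{sex}.csv", tbl))

    # --- trend meta-regression (Fig-2-style) -------------------------------
    def _metareg():
        age_w = european_standard_1976(18, 79)
        trend_rows, slope_rows = [], []
        for sex in ("male", "female"):
            for edu in ("low", "secondary", "high"):
                effs = []
                for (survey, year), sub in records[
                        (records["sex"] == sex) & (records["education"] == edu)
                        ].groupby(["survey", "year"], observed=True, sort=True):
                    sub = sub.copy()
                    sub["_ag"] = age_group(sub["age"].to_numpy())
                    est_df = stratum_prevalence(sub, "_ag")
                    est = direct_standardize(est_df, age_w, stratum_col="_ag")
                    trend_rows.append({"survey": survey, "year": int(year),
                                       "sex": sex, "education": edu,
                                       "value": est.value, "se": est.se,
                                       "age_coverage": est.coverage})
                    if est.se > 0 and est.coverage >= config.min_age_coverage:
                        effs.append(StudyEffect(study=str(survey), effect=est.value,
                                                variance=est.se ** 2,
                                                covariate=float(year)))
                if len(effs) >= 3:
                    fit = meta_regress(effs)
                    slope_rows.append({"sex": sex, "education": edu,
                                       "slope_per_year": fit.slope,
                                       "slope_se": fit.slope_se,
                                       "p_value": fit.p_value,
                                       "residual_tau2": fit.tau2, "k": fit.k})
        return pd.DataFrame(trend_rows), pd.DataFrame(slope_rows)

    metareg_out = stage("metareg", config.stages.get("metareg", True), _metareg)
    if metareg_out is not None:
        outputs.append(("education_trends.csv", metareg_out[0]))
        outputs.append(("trend_slopes.csv", metareg_out[1]))

    # --- mortality attribution --------------------------------------------
    def _attribution():
        y0, y1 = config.attribution_years
        profile = HazardProfile(hr=dict(config.hazard_ratios))
        path = path_from_surface(surface, range(y0, y1 + 1), sex="male")
        sched = generate_mortality(config.baseline_cvd_rates, path, profile,
                                   config.populations)
        cf = path.frozen(y0)
        res = avoided_deaths(sched, path, cf, profile, base_year=y0,
                             years=[y for y in path.years if y > y0])
        summary = res.summary()
        summary["years"] = f"{y0 + 1}-{y1}"
        return res.cells, summary

    attr_out = stage("attribution", config.stages.get("attribution", True), _attribution)
    if attr_out is not None:
        outputs.append(("avoided_deaths_cells.csv", attr_out[0]))
        outputs.append(("attribution_summary.json", attr_out[1]))

    # --- survivor selection -------------------------------------------------
    def _attrition():
        a = config.attrition
        params = CohortParams(p0=a["p0"], hazard_ratio=a["hazard_ratio"],
                              entry_age=a["entry_age"],
                              hazard=GompertzHazard(a["gompertz_a"], a["gompertz_b"]))
        return {
            "reduction_25_75_average": prevalence_reduction(params),
            "reduction_25_75_endpoint": prevalence_reduction(params, mode="endpoint"),
            "prevalence_at_75": selected_prevalence(params, 75.0),
        }

    attrition_out = stage("attrition", config.stages.get("attrition", True), _attrition)
    if attrition_out is not None:
        outputs.append(("attrition_summary.json", attrition_out))

    # --- write bundle -------------------------------------------------------
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for relpath, payload in outputs:
        dest = outdir / relpath
        if isinstance(payload, pd.DataFrame):
            with open(dest, "w") as fh:
                fh.write(f"# config_hash={chash}\n")
                payload.to_csv(fh, index=False)
        else:
            payload = {"config_hash": chash, **payload}
            dest.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(str(relpath))

    log = {
        "config_hash": chash,
        "seed": config.seed,
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "data": data_report,
        "meta_exclusions": meta_log,
        "outputs": written,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
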