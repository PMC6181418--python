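"""End-to-end orchestration: simulate → densities → cutpoints → score →
survival tables → differential expression.

:func:`run_pipeline` reproduces the full analysis workflow on a cohort
table (simulated or loaded from CSV): per-compartment high/low calls at
fixed or optimized cutoffs, Immunoscore assignment, Kaplan-Meier exports
and log-rank tests per marker and per Immunoscore grade for both
endpoints, univariable and multivariable Cox tables, the responder
density comparison, and (optionally) the luminal/basal differential
expression stage. Every output is written under one directory together
with a manifest (config hash, seed, file checksums) so a run is fully
reproducible from its manifest.

All randomness is routed through the single ``PipelineConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import survival as surv
from .cutpoint import optimize_cutpoint
from .density import COMPARTMENTS, HIGH, LOW
from .errors import ConfigurationError, ConvergenceError, DataError
from .expression import de_two_group, geneset_summary
from .score import score_cohort
from .simulate import (COVARIATES, ExpressionSimConfig, SimulationConfig,
                       generate_cohort, generate_expression)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort",
           "load_pipeline_config"]

#: published density thresholds (cells/mm²), usable as fixed cutoffs
DEFAULT_CUTOFFS = {"cd3_ct": 490.0, "cd3_im": 290.0,
                   "cd8_ct": 116.0, "cd8_im": 70.0}

DEFAULT_ADJUSTMENT = ["organ_confined", "margin", "lvi", "intravesical",
                      "chemo"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    output_dir: str | Path = "tilscore_run"
    cohort_csv: str | Path | None = None       # mutually exclusive with
    simulation: SimulationConfig | None = None  # simulation config
    compartments: Sequence[str] = tuple(COMPARTMENTS)
    #: either a mapping compartment → cells/mm², or the string "optimize"
    cutoffs: Mapping[str, float] | str = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS))
    min_group_frac: float = 0.10
    correction: str = "miller_siegmund"
    cutpoint_endpoint: str = "OS"
    endpoints: Sequence[str] = ("OS", "DFS")
    adjustment: Sequence[str] = tuple(DEFAULT_ADJUSTMENT)
    alpha: float = 0.05
    expression: ExpressionSimConfig | None = None

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of cohort_csv or simulation must be given")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        if isinstance(self.cutoffs, str):
            if self.cutoffs != "optimize":
                raise ConfigurationError(
                    f"cutoffs must be a mapping or 'optimize', "
                    f"got {self.cutoffs!r}")
        else:
            missing = [c for c in self.compartments if c not in self.cutoffs]
            if missing:
                raise ConfigurationError(f"no cutoff for {missing}")
        for ep in self.endpoints:
            if ep not in ("OS", "DFS"):
                raise ConfigurationError(f"unknown endpoint {ep!r}")


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    return ("os_months", "os_event") if endpoint == "OS" else (
        "dfs_months", "dfs_event")


def _hr_row(model: surv.CoxModel, name: str) -> dict[str, float]:
    i = model.names.index(name)
    return {
        "hr": float(model.hr[i]),
        "ci_lower": float(model.ci_lower[i]),
        "ci_upper": float(model.ci_upper[i]),
        "p": float(model.p[i]),
    }


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: counts/percent per binary level, median (IQR)
    for continuous columns, missing counts footnoted per variable.

    Percentages use the non-missing denominator.
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    rows = []
    binary_cols = [c for c in [*COVARIATES, "nac_response", "os_event",
                               "dfs_event"] if c in cohort.columns]
    for col in binary_cols:
        vals = pd.to_numeric(cohort[col], errors="coerce")
        n_missing = int(vals.isna().sum())
        nonmiss = vals.dropna()
        for level in (0, 1):
            n = int((nonmiss == level).sum())
            pct = 100.0 * n / len(nonmiss) if len(nonmiss) else float("nan")
            rows.append({"variable": col, "level": "yes" if level else "no",
                         "n": n, "percent": round(pct, 1),
                         "n_missing": n_missing})
    continuous = [c for c in [*COMPARTMENTS, "os_months", "dfs_months"]
                  if c in cohort.columns]
    for col in continuous:
        vals = pd.to_numeric(cohort[col], errors="coerce")
        nonmiss = vals.dropna()
        q1, med, q3 = (nonmiss.quantile([0.25, 0.5, 0.75])
                       if len(nonmiss) else (np.nan,) * 3)
        rows.append({"variable": col, "level": "median (IQR)",
                     "n": int(len(nonmiss)),
                     "median": round(float(med), 2) if len(nonmiss) else np.nan,
                     "iqr": round(float(q3 - q1), 2) if len(nonmiss) else np.nan,
                     "n_missing": int(vals.isna().sum())})
    return pd.DataFrame(rows)


def _km_exports(scored: pd.DataFrame, out: Path, alpha: float) -> dict:
    """Per-marker and per-Immunoscore KM curves + log-rank results."""
    km_dir = out / "km"
    km_dir.mkdir(exist_ok=True)
    results: dict[str, Any] = {}
    for endpoint in ("OS", "DFS"):
        tcol, ecol = _endpoint_cols(endpoint)
        for comp in COMPARTMENTS:
            call_col = f"{comp}_call"
            sub = scored.dropna(subset=[call_col, tcol, ecol])
            key = f"{comp}_{endpoint}"
            for level in (LOW, HIGH):
                grp = sub[sub[call_col] == level]
                if len(grp) == 0:
                    continue
                curve = surv.km_estimate(grp[tcol], grp[ecol])
                curve.to_frame().to_csv(
                    km_dir / f"{key}_{level}.tsv", sep="\t", index=False)
            if sub[call_col].nunique() == 2 and sub[ecol].sum() > 0:
                lr = surv.logrank_test(sub[tcol], sub[ecol], sub[call_col])
                results[key] = {"chi_square": lr.chi_square, "df": lr.df,
                                "p": lr.p,
                                "significant": bool(lr.p < alpha)}
        # Immunoscore grades
        sub = scored.dropna(subset=["immunoscore", tcol, ecol])
        grades = sorted(sub["immunoscore"].dropna().unique())
        for g in grades:
            grp = sub[sub["immunoscore"] == g]
            curve = surv.km_estimate(grp[tcol], grp[ecol])
            curve.to_frame().to_csv(
                km_dir / f"immunoscore_{endpoint}_I{int(g)}.tsv",
                sep="\t", index=False)
        if len(grades) >= 2 and sub[ecol].sum() > 0:
            hetero = surv.logrank_test(
                sub[tcol], sub[ecol], sub["immunoscore"].astype(int))
            entry = {"heterogeneity": {"chi_square": hetero.chi_square,
                                       "df": hetero.df, "p": hetero.p}}
            if len(grades) >= 3:
                trend = surv.logrank_trend(
                    sub[tcol], sub[ecol], sub["immunoscore"].astype(int))
                entry["trend"] = {"chi_square": trend.chi_square,
                                  "df": trend.df, "p": trend.p}
            results[f"immunoscore_{endpoint}"] = entry
    (out / "km" / "logrank.json").write_text(
        json.dumps(results, indent=2, sort_keys=True))
    return results


def _cox_tables(scored: pd.DataFrame, out: Path,
                adjustment: Sequence[str]) -> dict:
    """One adjusted model per immune marker plus an Immunoscore-level model,
    per endpoint; written as a Tables-2/3-shaped TSV and a full JSON."""
    cox_dir = out / "cox"
    cox_dir.mkdir(exist_ok=True)
    all_models: dict[str, Any] = {}
    for endpoint in ("OS", "DFS"):
        tcol, ecol = _endpoint_cols(endpoint)
        rows = []
        for comp in COMPARTMENTS:
            call_col = f"{comp}_call"
            sub = scored.dropna(subset=[call_col, tcol, ecol]
                                + list(adjustment)).copy()
            sub["marker_high"] = (sub[call_col] == HIGH).astype(int)
            row: dict[str, Any] = {"covariate": comp, "level": "high vs low"}
            try:
                uni = surv.cox_fit(sub[["marker_high"]], sub[tcol], sub[ecol])
                multi = surv.cox_fit(
                    sub[["marker_high", *adjustment]], sub[tcol], sub[ecol])
                row.update({f"uni_{k}": v for k, v in
                            _hr_row(uni, "marker_high").items()})
                row.update({f"multi_{k}": v for k, v in
                            _hr_row(multi, "marker_high").items()})
                all_models[f"{comp}_{endpoint}"] = {
                    "univariable": uni.summary().to_dict("records"),
                    "multivariable": multi.summary().to_dict("records"),
                    "n": multi.n, "n_events": multi.n_events,
                    "converged": bool(uni.converged and multi.converged),
                }
            except (ConvergenceError, DataError) as exc:
                row["error"] = str(exc)
                all_models[f"{comp}_{endpoint}"] = {"error": str(exc)}
            rows.append(row)
        # covariates: univariable each, multivariable from the CD8_IM model
        sub = scored.dropna(subset=[tcol, ecol] + list(adjustment)).copy()
        sub["marker_high"] = (scored["cd8_im_call"] == HIGH).astype(int)
        for cov in adjustment:
            row = {"covariate": cov, "level": "yes vs no"}
            try:
                uni = surv.cox_fit(sub[[cov]], sub[tcol], sub[ecol])
                multi = surv.cox_fit(
                    sub[["marker_high", *adjustment]], sub[tcol], sub[ecol])
                row.update({f"uni_{k}": v for k, v in
                            _hr_row(uni, cov).items()})
                row.update({f"multi_{k}": v for k, v in
                            _hr_row(multi, cov).items()})
            except (ConvergenceError, DataError) as exc:
                row["error"] = str(exc)
            rows.append(row)
        # Immunoscore entered as indicator levels against the lowest grade
        sub = scored.dropna(subset=["immunoscore", tcol, ecol]
                            + list(adjustment)).copy()
        grades = sorted(sub["immunoscore"].dropna().astype(int).unique())
        if len(grades) >= 2:
            ref = grades[0]
            levels = grades[1:]
            design = pd.DataFrame({
                f"I{g}": (sub["immunoscore"].astype(int) == g).astype(int)
                for g in levels}, index=sub.index)
            try:
                multi = surv.cox_fit(
                    pd.concat([design,
                               sub[list(adjustment)]], axis=1),
                    sub[tcol], sub[ecol])
                for g in levels:
                    row = {"covariate": "immunoscore",
                           "level": f"I{g} vs I{ref}"}
                    row.update({f"multi_{k}": v for k, v in
                                _hr_row(multi, f"I{g}").items()})
                    rows.append(row)
                all_models[f"immunoscore_{endpoint}"] = {
                    "reference": f"I{ref}",
                    "multivariable": multi.summary().to_dict("records"),
                    "converged": multi.converged,
                }
            except (ConvergenceError, DataError) as exc:
                rows.append({"covariate": "immunoscore", "error": str(exc)})
                all_models[f"immunoscore_{endpoint}"] = {"error": str(exc)}
        pd.DataFrame(rows).to_csv(
            cox_dir / f"{endpoint.lower()}_table.tsv", sep="\t", index=False)
    (cox_dir / "models.json").write_text(
        json.dumps(all_models, indent=2, sort_keys=True, default=float))
    return all_models


def _responder_comparison(scored: pd.DataFrame, alpha: float) -> dict:
    """CD8_IM density by NAC response (responders vs non-responders) and
    the prior-intravesical-therapy null comparisons."""
    out: dict[str, Any] = {}
    sub = scored.dropna(subset=["nac_response", "cd8_im"])
    if sub["nac_response"].nunique() == 2:
        stat, p = surv.compare_density_groups(
            sub["cd8_im"], sub["nac_response"].astype(int))
        out["cd8_im_by_nac_response"] = {
            "statistic": stat, "p": p, "significant": bool(p < alpha),
            "n_responder": int((sub["nac_response"] == 1).sum()),
            "n_nonresponder": int((sub["nac_response"] == 0).sum()),
            "median_responder": float(
                sub.loc[sub["nac_response"] == 1, "cd8_im"].median()),
            "median_nonresponder": float(
                sub.loc[sub["nac_response"] == 0, "cd8_im"].median()),
        }
    for comp in COMPARTMENTS:
        sub = scored.dropna(subset=["intravesical", comp])
        if sub["intravesical"].nunique() == 2:
            stat, p = surv.compare_density_groups(
                sub[comp], sub["intravesical"].astype(int))
            out[f"{comp}_by_intravesical"] = {"statistic": stat, "p": p}
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the manifest dict.

    Outputs under ``config.output_dir``: the scored cohort CSV, cutpoint
    JSONs and scan TSVs (when optimizing), KM TSVs and log-rank JSON, Cox
    tables, the responder comparison, DE outputs when an expression stage
    is configured, a cohort characteristics table, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = generate_cohort(sim)
        else:
            cohort = pd.read_csv(config.cohort_csv)

        stage = "cutpoint"
        cutpoint_results = {}
        if config.cutoffs == "optimize":
            tcol, ecol = _endpoint_cols(config.cutpoint_endpoint)
            cutoffs = {}
            cp_dir = out / "cutpoints"
            cp_dir.mkdir(exist_ok=True)
            for i, comp in enumerate(config.compartments):
                sub = cohort.dropna(subset=[comp, tcol, ecol])
                res = optimize_cutpoint(
                    sub[comp], sub[tcol], sub[ecol],
                    min_group_frac=config.min_group_frac,
                    correction=config.correction,
                    compartment=comp, endpoint=config.cutpoint_endpoint,
                    seed=config.seed + 1 + i)
                cutoffs[comp] = res.cutoff
                cutpoint_results[comp] = res.to_dict()
                (cp_dir / f"{comp}.json").write_text(
                    json.dumps(res.to_dict(), indent=2))
        else:
            cutoffs = {c: float(v) for c, v in dict(config.cutoffs).items()}

        stage = "score"
        scored = score_cohort(cohort, cutoffs)
        scored.to_csv(out / "cohort_scored.csv", index=False)
        summarize_cohort(scored).to_csv(
            out / "cohort_summary.tsv", sep="\t", index=False)

        stage = "survival"
        logrank = _km_exports(scored, out, config.alpha)
        cox = _cox_tables(scored, out, config.adjustment)
        responders = _responder_comparison(scored, config.alpha)
        (out / "responders.json").write_text(
            json.dumps(responders, indent=2, sort_keys=True))

        stage = "expression"
        de_summary = None
        if config.expression is not None:
            de_dir = out / "de"
            de_dir.mkdir(exist_ok=True)
            expr_cfg = dataclasses.replace(
                config.expression, seed=config.seed + 101)
            matrix, labels, gene_set = generate_expression(expr_cfg)
            results = de_two_group(matrix, labels, gene_set)
            results.to_csv(de_dir / "results.tsv", sep="\t")
            summary, slice_idx = geneset_summary(
                results, gene_set, threshold=config.alpha)
            de_summary = dataclasses.asdict(summary)
            (de_dir / "summary.json").write_text(
                json.dumps(de_summary, indent=2))
            matrix.loc[slice_idx].to_csv(
                de_dir / "heatmap_slice.tsv", sep="\t")
            (de_dir / "gene_set.txt").write_text("\n".join(gene_set) + "\n")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "seed": config.seed,
        "cutoffs": cutoffs,
        "cutpoint_results": cutpoint_results,
        "n_patients": int(len(scored)),
        "logrank": logrank,
        "responders": responders,
        "de_summary": de_summary,
        "config_hash": _config_hash(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a JSON or YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    sim = raw.pop("simulation", None)
    expr = raw.pop("expression", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "density_correlation" in sim:
            sim["density_correlation"] = np.asarray(
                sim["density_correlation"], dtype=float)
        cfg.simulation = SimulationConfig(**sim)
    if expr is not None:
        cfg.expression = ExpressionSimConfig(**expr)
    return cfg
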