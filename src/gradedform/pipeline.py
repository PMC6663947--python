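"""End-to-end scale-development pipeline.

Runs the full flow the library implements piecewise: response-time
cleaning, GRM calibration, item fit, local dependence, DIF (when group
labels are supplied), flag-based exclusion, short-form construction and
comparison.  Every stage's decisions (flag thresholds, exclusions with
reasons) land in a machine-readable JSON report plus a Markdown summary;
outputs are byte-identical given identical inputs, configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .calibrate import CalibrationConfig, fit_grm, standard_errors
from .data import ResponseMatrix
from .diagnostics import (DEFAULT_ALPHA_LEVEL, LD_FLAG_THRESHOLD, cronbach_alpha,
                          item_fit_sx2, local_dependence, model_fit)
from .dif import DifConfig, dif_scan, group_icc_overlay
from .grm import ThetaGrid
from .plots import plot_group_overlay, plot_icc, plot_tif
from .shortform import ShortForm, build_form, compare_forms, exclude_flagged

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Single configuration object for a full run (YAML/JSON loadable)."""

    responses_path: str = ""
    response_times_path: str | None = None
    covariates_path: str | None = None        # respondent_id + e.g. group column
    content_map_path: str | None = None
    output_dir: str = "out"
    origin: int = 0
    # calibration
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    # diagnostics
    alpha_level: float = DEFAULT_ALPHA_LEVEL
    min_expected: float = 1.0
    ld_threshold: float = LD_FLAG_THRESHOLD
    compute_m2: bool = True
    # dif
    group_column: str | None = None
    dif_level: float = 0.01
    max_purification_iterations: int = 10
    # shortform
    strategy: str = "content_first"
    form_size: int = 10
    # misc
    seed: int = 0
    make_plots: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        cal = raw.pop("calibration", None)
        cfg = cls(**raw)
        if cal:
            cfg.calibration = CalibrationConfig(**cal)
        return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute clean -> calibrate -> item fit -> LD -> DIF -> exclusions ->
    short forms -> comparison, writing a report bundle to the output dir.

    Returns the report dict.  Any stage failure raises
    :class:`PipelineError` carrying the stage name and an error code.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "alpha_level": config.alpha_level, "ld_threshold": config.ld_threshold,
        "dif_level": config.dif_level, "strategy": config.strategy,
        "form_size": config.form_size, "seed": config.seed,
        "calibration": asdict(config.calibration),
    }}

    # ---- load & clean -----------------------------------------------------
    try:
        responses = gio.read_responses(config.responses_path, origin=config.origin)
    except Exception as exc:
        raise PipelineError("read", "validation", str(exc)) from exc
    report["input"] = {"n_respondents": responses.n_respondents,
                       "n_items": responses.n_items,
                       "n_categories": responses.n_categories,
                       "missing_rate": round(responses.missing_rate, 4)}
    if config.response_times_path:
        rt = gio.read_response_times(config.response_times_path)
        responses, removal = gio.rt_filter(responses, rt)
        report["rt_filter"] = {"n_removed": len(removal),
                               "removals": removal.to_dict(orient="records")}

    groups = None
    if config.covariates_path and config.group_column:
        cov = pd.read_csv(config.covariates_path, index_col=0)
        if config.group_column not in cov.columns:
            raise PipelineError("read", "validation",
                                f"group column {config.group_column!r} not in covariates")
        groups = cov.reindex(responses.respondent_ids)[config.group_column].to_numpy(object)

    # ---- calibrate --------------------------------------------------------
    try:
        result = fit_grm(responses, config.calibration)
        standard_errors(result, responses)
    except Exception as exc:
        raise PipelineError("calibrate", "convergence", str(exc)) from exc
    if not result.converged:
        raise PipelineError("calibrate", "convergence",
                            f"EM not converged after {result.n_cycles} cycles")
    gio.write_parameter_table(result, out / "parameters.csv")
    report["calibration"] = {"converged": result.converged, "n_cycles": result.n_cycles,
                             "minus2ll": result.minus2ll, "n_effective": result.n_effective}

    # ---- diagnostics ------------------------------------------------------
    fit_records = item_fit_sx2(result, responses, alpha_level=config.alpha_level,
                               min_expected=config.min_expected)
    misfit = {r.item_id for r in fit_records if r.flagged}
    ld = local_dependence(result, responses, min_expected=config.min_expected)
    ld_pairs = ld.flagged_pairs()
    ld_sets = _pair_components(ld_pairs)
    stats = model_fit(result, responses, compute_m2=config.compute_m2)
    report["item_fit"] = [r.__dict__ for r in fit_records]
    report["local_dependence"] = {"flagged_pairs": [list(p) for p in ld_pairs],
                                  "borderline_pairs": [list(p) for p in ld.borderline_pairs()]}
    report["model_fit"] = stats.__dict__

    # ---- DIF --------------------------------------------------------------
    dif_items: set = set()
    if groups is not None:
        dif_cfg = DifConfig(level=config.dif_level,
                            max_iterations=config.max_purification_iterations,
                            calibration=config.calibration)
        dres = dif_scan(responses, groups, dif_cfg)
        dif_items = set(dres.flagged_items)
        report["dif"] = {"tests": dres.to_frame().to_dict(orient="records"),
                        "anchors": dres.anchors, "excluded": dres.excluded,
                        "group_summary": {k: list(v) for k, v in dres.group_summary.items()},
                        "iterations": dres.iteration_log}
        if config.make_plots:
            for item_id in dres.flagged_items:
                ov = group_icc_overlay(dres.reference_bank[item_id],
                                       dres.focal_bank[item_id], result.grid)
                plot_group_overlay(ov, item_id,
                                   out / f"dif_{_slug(item_id)}.png")
    else:
        report["dif"] = {"skipped": "no group column configured"}

    # ---- exclusions & short forms ----------------------------------------
    eligible, ledger = exclude_flagged(result.bank, misfit=misfit,
                                       ld_sets=ld_sets, dif=dif_items)
    report["exclusions"] = ledger.records.assign(
        reasons=ledger.records.reasons.map(list)).to_dict(orient="records")

    forms_report = None
    if config.content_map_path:
        cmap = gio.read_content_map(config.content_map_path).restrict_to(result.bank)
        form = build_form(eligible, cmap, result.bank, strategy=config.strategy,
                          size=config.form_size)
        table = compare_forms([ShortForm(name="full_bank",
                                         item_ids=list(result.bank.item_ids)), form],
                              responses, config=config.calibration)
        table.to_csv(out / "form_comparison.csv", index=False, float_format="%.6g")
        forms_report = {"form": {"name": form.name, "items": form.item_ids,
                                 "coverage": form.coverage_count,
                                 "rationale": form.rationale},
                        "comparison": table.to_dict(orient="records")}
        if config.make_plots:
            plot_tif({"full bank": result.bank,
                      form.name: result.bank.subset(form.item_ids)},
                     path=out / "tif.png")
    report["short_forms"] = forms_report or {"skipped": "no content map configured"}

    # ---- write bundle -----------------------------------------------------
    if config.make_plots:
        best = max(result.bank, key=lambda it: it.slope)
        plot_icc(best, path=out / f"icc_{_slug(best.item_id)}.png")
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable) + "\n")
    (out / "summary.md").write_text(_markdown_summary(result, fit_records, ld, stats, report))
    return report


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text)[:40]


def _pair_components(pairs) -> list:
    comp: dict = {}
    for a, b in pairs:
        group = comp.get(a, {a}) | comp.get(b, {b})
        for x in group:
            comp[x] = group
    seen, out = set(), []
    for a, _ in pairs:
        if a not in seen:
            out.append(comp[a])
            seen |= comp[a]
    return out


def _markdown_summary(result, fit_records, ld, stats, report) -> str:
    lines = ["# Calibration summary", "",
             "| item | a | " + " | ".join(f"b{j}" for j in range(1, 5)) +
             " | S-X2 | df | p(BH) | LD partners |",
             "|---|---|---|---|---|---|---|---|---|"]
    ld_partner = {}
    for a, b in ld.flagged_pairs():
        ld_partner.setdefault(a, []).append(b)
        ld_partner.setdefault(b, []).append(a)
    recs = {r.item_id: r for r in fit_records}
    for it in result.bank:
        r = recs[it.item_id]
        bs = list(it.thresholds) + [np.nan] * (4 - it.thresholds.size)
        lines.append(
            f"| {it.item_id} | {it.slope:.2f} | "
            + " | ".join("" if np.isnan(b) else f"{b:.2f}" for b in bs)
            + f" | {r.sx2:.1f} | {r.df} | {r.p_adjusted:.3f}"
            + ("*" if r.flagged else "")
            + f" | {', '.join(ld_partner.get(it.item_id, []))} |")
    lines += ["", "## Model fit", "",
              f"- -2LL = {stats.minus2ll:.2f}; AIC = {stats.aic:.2f}; BIC = {stats.bic:.2f}",
              f"- M2 = {stats.m2:.2f} (df {stats.m2_df}, p {stats.m2_p:.4g}); "
              f"RMSEA = {stats.rmsea:.4f}",
              f"- Cronbach alpha = {stats.cronbach_alpha:.3f}; "
              f"marginal reliability = {stats.marginal_reliability:.3f}", ""]
    return "\n".join(lines) + "\n"
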