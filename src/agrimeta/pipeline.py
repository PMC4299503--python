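"""End-to-end analysis pipeline: table in, report tables out.

Stages: read -> effect sizes -> adequacy summary -> landscape imputation ->
grand-mean hierarchical fit -> per-covariate subgroup metaregressions ->
landscape slope models (with the outlier-sensitivity refit) ->
heterogeneity -> bias diagnostics.  Every stage logs its record counts;
a failure in any stage aborts with a stage-named error before any output
file is written.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import bias as bias_mod
from .effects import (
    EffectSize,
    adequacy_summary,
    effects_from_records,
    percent_change,
    write_effect_table,
)
from .hblm import (
    DesignMatrix,
    build_design,
    credible_interval,
    fit_hblm,
    heterogeneity,
    residuals_and_precision,
)
from .io import read_study_table, write_rejection_report
from .landscape import impute_country_means

logger = logging.getLogger("agrimeta")

__all__ = ["AnalysisReport", "run_full_analysis", "outlier_refit", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "subgroup_covariates": ["functional_group", "taxon_group", "crop_type", "scale"],
    "references": {"scale": "farm", "functional_group": "producers",
                   "taxon_group": "arthropods", "crop_type": "cereals"},
    "landscape_terms": [
        {"var": "pct_arable", "kind": "continuous", "scale": 0.01},
        {"var": "n_habitats", "kind": "continuous"},
        {"var": "avg_field_size", "kind": "continuous"},
    ],
    "outlier_threshold": 2.0,
    "fit": {"tau_grid_size": 201},
    "seed": 0,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisReport:
    grand_mean: dict
    adequacy: dict
    subgroups: dict
    landscape: dict
    heterogeneity: dict
    bias: dict
    provenance: dict
    effects: list[EffectSize] = field(repr=False, default_factory=list)
    traces: dict = field(repr=False, default_factory=dict)
    funnel: list = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "grand_mean": self.grand_mean,
            "adequacy": self.adequacy,
            "subgroups": self.subgroups,
            "landscape": self.landscape,
            "heterogeneity": self.heterogeneity,
            "bias": self.bias,
            "provenance": self.provenance,
        }


def _fit_summary(fit, level: float = 0.95) -> dict:
    ci = credible_interval(fit, level)
    return {
        "labels": list(fit.labels),
        "beta": [float(b) for b in fit.beta],
        "post_se": [float(s) for s in fit.post_se],
        "ci_low": [float(x) for x in ci[:, 0]],
        "ci_high": [float(x) for x in ci[:, 1]],
        "tau": fit.tau,
        "tau2": fit.tau2,
        "phi": fit.phi,
        "I2": fit.I2,
        "N": fit.N,
        "p": fit.p,
    }


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


def outlier_refit(
    effects: Sequence[EffectSize],
    threshold: float = 2.0,
    *,
    term: dict | None = None,
    fit_kwargs: dict | None = None,
) -> dict:
    """Refit the pct_arable slope model excluding effects with y > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    term = term or {"var": "pct_arable", "kind": "continuous", "scale": 0.01}
    fit_kwargs = dict(fit_kwargs or {})

    def slope_fit(effs):
        records = [e.record for e in effs]
        if any(r is None for r in records):
            raise ValueError("effects must carry their source records")
        design = build_design(records, [term])
        return fit_hblm(effs, design, **fit_kwargs)

    fit_before = slope_fit(effects)
    kept = [e for e in effects if e.y <= threshold]
    removed = len(effects) - len(kept)
    if len(kept) <= fit_before.p:
        raise ValueError("outlier threshold removed too many effects to refit")
    fit_after = slope_fit(kept) if removed else fit_before
    return {
        "threshold": threshold,
        "n_removed": removed,
        "slope_before": float(fit_before.beta[1]),
        "slope_after": float(fit_after.beta[1]),
        "fit_before": _fit_summary(fit_before),
        "fit_after": _fit_summary(fit_after),
    }


def run_full_analysis(
    table_path: str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run every analysis stage on a study table and assemble the report.

    When ``out_dir`` is given, the report JSON plus plot-ready CSV tables
    (coefficients, funnel data, cumulative traces, rejections) are written
    there; nothing is written if any stage fails.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if seed is not None:
        cfg["seed"] = seed
    fit_kwargs = dict(cfg.get("fit", {}))
    table_path = Path(table_path)

    parse = _stage("read", read_study_table, table_path)
    logger.info("read: %d records, %d rejected", len(parse.records),
                len(parse.rejections))
    if not parse.records:
        raise StageError("read", "no valid records in input table")

    effects = _stage("effect_sizes", effects_from_records, parse.records)
    adequacy = _stage("adequacy", adequacy_summary, effects)
    logger.info("effect_sizes: %d computed", len(effects))

    records = _stage("imputation", impute_country_means, parse.records)
    effects = _stage("effect_sizes", effects_from_records, records)
    n_imputed = sum(r.landscape_imputed for r in records)
    logger.info("imputation: %d records imputed", n_imputed)

    grand_fit = _stage("grand_mean", fit_hblm, effects, **fit_kwargs)
    grand_ci = credible_interval(grand_fit)
    grand = {
        **_fit_summary(grand_fit),
        "estimate": float(grand_fit.beta[0]),
        "percent_change": percent_change(float(grand_fit.beta[0])),
        "percent_ci": [percent_change(float(grand_ci[0, 0])),
                       percent_change(float(grand_ci[0, 1]))],
        "var_tau": grand_fit.var_tau,
        "var_tau2": grand_fit.var_tau2,
    }
    logger.info("grand_mean: estimate %.4f", grand["estimate"])

    subgroups: dict = {}
    for cov in cfg["subgroup_covariates"]:
        def _one(cov=cov):
            cell = build_design(records, [{"var": cov, "kind": "categorical",
                                           "cell_means": True}], intercept=False)
            cell_fit = fit_hblm(effects, cell, **fit_kwargs)
            ref = cfg["references"].get(cov)
            observed = {getattr(r, cov) for r in records}
            if ref not in observed:  # fall back when the data lack the level
                ref = sorted(observed)[0]
            contrast = build_design(records, [{"var": cov, "kind": "categorical",
                                               "reference": ref}])
            contrast_fit = fit_hblm(effects, contrast, **fit_kwargs)
            return {
                "cell_means": _fit_summary(cell_fit),
                "contrasts": _fit_summary(contrast_fit),
                "reference": ref,
            }
        subgroups[cov] = _stage(f"subgroup:{cov}", _one)
        logger.info("subgroup:%s fitted (%d levels)", cov,
                    len(subgroups[cov]["cell_means"]["labels"]))

    def _landscape_models():
        out = {"slopes": {}}
        for term in cfg["landscape_terms"]:
            design = build_design(records, [term])
            fit = fit_hblm(effects, design, **fit_kwargs)
            ci = credible_interval(fit)
            out["slopes"][term["var"]] = {
                "slope": float(fit.beta[1]),
                "ci_low": float(ci[1, 0]),
                "ci_high": float(ci[1, 1]),
            }
        out["outlier_refit"] = outlier_refit(
            effects, cfg["outlier_threshold"],
            term=cfg["landscape_terms"][0], fit_kwargs=fit_kwargs,
        )
        # separate-slopes interaction of arable cover with functional group;
        # sparse groups can alias their slope with the cell mean, in which
        # case the interaction is reported as unavailable rather than
        # aborting the whole analysis
        try:
            inter = build_design(
                records,
                [{"var": "functional_group", "kind": "categorical",
                  "cell_means": True},
                 {"var": "pct_arable", "kind": "continuous", "scale": 0.01,
                  "by": "functional_group"}],
                intercept=False,
            )
            ifit = fit_hblm(effects, inter, **fit_kwargs)
            out["arable_by_functional_group"] = _fit_summary(ifit)
        except ValueError as exc:
            out["arable_by_functional_group"] = {"error": str(exc)}
        return out

    landscape = _stage("landscape_models", _landscape_models)
    logger.info("landscape_models: %d slopes", len(landscape["slopes"]))

    het = _stage("heterogeneity", heterogeneity, grand_fit,
                 [e.v for e in effects])
    het["var_tau"] = grand_fit.var_tau
    het["var_tau2"] = grand_fit.var_tau2

    def _bias_block():
        funnel = residuals_and_precision(grand_fit, effects)
        tf = bias_mod.trim_and_fill(effects, side="right", fit_kwargs=fit_kwargs)
        cum_v = bias_mod.cumulative_meta(effects, "sampling_variance",
                                         fit_kwargs=fit_kwargs)
        cum_y = bias_mod.cumulative_meta(effects, "publication_year",
                                         fit_kwargs=fit_kwargs)
        slope_v = bias_mod.slope_test(effects, "sampling_variance",
                                      fit_kwargs=fit_kwargs)
        slope_y = bias_mod.slope_test(effects, "publication_year",
                                      fit_kwargs=fit_kwargs)
        min_v = cum_v.minimum()
        block = {
            "trim_and_fill": {
                "k0": tf.k0, "estimate": tf.estimate,
                "ci": [tf.ci_low, tf.ci_high],
                "adjustment": tf.adjustment, "iterations": tf.iterations,
            },
            "cumulative_by_variance": {
                "minimum": min_v.estimate,
                "minimum_step": min_v.step,
                "minimum_ci": [min_v.ci_low, min_v.ci_high],
                "final": cum_v.final.estimate,
            },
            "cumulative_by_year": {"final": cum_y.final.estimate},
            "slope_sampling_variance": {k: slope_v[k] for k in
                                        ("slope", "ci_low", "ci_high")},
            "slope_publication_year": {k: slope_y[k] for k in
                                       ("slope", "ci_low", "ci_high")},
        }
        return funnel, tf, cum_v, cum_y, block

    funnel, tf, cum_v, cum_y, bias_block = _stage("bias_diagnostics", _bias_block)
    logger.info("bias_diagnostics: k0=%d", tf.k0)

    provenance = {
        "input_sha256": hashlib.sha256(table_path.read_bytes()).hexdigest(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.get("seed"),
        "n_records": len(records),
        "n_rejections": len(parse.rejections),
        "n_imputed": n_imputed,
        "fit_config": grand_fit.config,
    }

    report = AnalysisReport(
        grand_mean=grand,
        adequacy=adequacy,
        subgroups=subgroups,
        landscape=landscape,
        heterogeneity=het,
        bias=bias_block,
        provenance=provenance,
        effects=effects,
        traces={"sampling_variance": cum_v, "publication_year": cum_y},
        funnel=funnel,
    )

    if out_dir is not None:
        _stage("write_outputs", _write_outputs, report, parse.rejections,
               Path(out_dir))
    return report


def _write_outputs(report: AnalysisReport, rejections, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=_json_default)
    )
    write_rejection_report(rejections, out_dir / "rejections.csv")
    write_effect_table(report.effects, out_dir / "effects.csv")
    with (out_dir / "funnel.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residual", "precision"])
        writer.writerows(report.funnel)
    for key, trace in report.traces.items():
        with (out_dir / f"cumulative_{key}.csv").open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "key", "estimate", "ci_low", "ci_high", "n"])
            for s in trace.steps:
                writer.writerow([s.step, s.key, s.estimate, s.ci_low, s.ci_high, s.n])
    with (out_dir / "coefficients.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "term", "estimate", "se", "ci_low", "ci_high"])
        gm = report.grand_mean
        writer.writerow(["grand_mean", "intercept", gm["estimate"],
                         gm["post_se"][0], gm["ci_low"][0], gm["ci_high"][0]])
        for cov, sub in report.subgroups.items():
            cm = sub["cell_means"]
            for i, label in enumerate(cm["labels"]):
                writer.writerow([f"subgroup:{cov}", label, cm["beta"][i],
                                 cm["post_se"][i], cm["ci_low"][i], cm["ci_high"][i]])


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"cannot serialise {type(obj)}")
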