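"""End-to-end analysis pipeline and report writing.

One call runs the whole study analysis on a cohort (loaded from CSV or
simulated): Table-1-style summary, the continuous-outcome logistic
regression overall and stratified by delivery mode (vaginal, pooled
cesarean), the conventional 500 mL binary model, the cut-off sweep, the
hemorrhage-prevalence curve over prepartum platelets, the 50 G/L shift
effect, and the pre/postpartum platelet-FXIII rank correlations.

Outputs are plain files in the output directory — ``report.json`` plus
CSVs for the summary table, the sweep and the prevalence curve, and one
serialized fit per model — so every reported estimate is traceable to a
fit object on disk.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import spearman
from .cohort import (
    MODEL_COVARIATES,
    CohortTable,
    read_cohort_csv,
    stratify,
    summarize,
)
from .model import ColrSpec, fit_colr, odds_ratios, pph_prevalence_curve, shift_effect
from .sweep import BinaryLogisticRegression, sweep_cutoffs
from .synthetic import SimConfig, simulate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis"]

log = logging.getLogger("colrpph")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` (a cohort CSV) or ``sim`` (a synthetic
    data-generating configuration) must be set.
    """

    input_path: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    sim: SimConfig | None = None
    covariates: tuple[str, ...] = MODEL_COVARIATES
    order: int = 6
    log_scale: bool = False
    ci_level: float = 0.95
    sweep_grid: str | list[float] = "auto"
    threshold: float = 500.0
    shift_delta: float = 50.0
    separate_cesarean: bool = False
    outdir: str = "colrpph_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError(
                "exactly one of input_path or sim must be configured"
            )
        if self.threshold <= 0:
            raise ValueError("threshold must be positive (mL)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("sim"), dict):
            sim_raw = dict(raw["sim"])
            if "rank_corr" in sim_raw:
                sim_raw["rank_corr"] = {
                    tuple(k.split("~")): v for k, v in sim_raw["rank_corr"].items()
                }
            raw["sim"] = SimConfig(**sim_raw)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    report: dict
    outdir: Path
    partial: bool = False

    def to_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)


def _or_block(table: pd.DataFrame) -> dict:
    return {
        cov: {
            "or": round(float(row["or"]), 6),
            "ci_low": round(float(row["ci_low"]), 6),
            "ci_high": round(float(row["ci_high"]), 6),
            "p_value": float(row["p_value"]),
        }
        for cov, row in table.iterrows()
    }


def _load_cohort(config: AnalysisConfig) -> CohortTable:
    if config.sim is not None:
        log.info("simulating synthetic cohort (seed=%d)", config.seed)
        return simulate_cohort(config.sim, seed=config.seed)
    log.info("reading cohort from %s", config.input_path)
    return read_cohort_csv(config.input_path, column_map=config.column_map)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full analysis and write the report to ``config.outdir``.

    Deterministic given config and seed.  A stage failure marks the report
    partial (with the failing stage named) instead of discarding completed
    stages; callers exit nonzero on a partial report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {
            "package": f"colrpph {__version__}",
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "seed": config.seed,
        "config": {
            "covariates": list(config.covariates),
            "order": config.order,
            "log_scale": config.log_scale,
            "threshold_ml": config.threshold,
            "shift_delta": config.shift_delta,
            "input": config.input_path or "synthetic",
        },
    }
    partial = False
    failed: list[str] = []

    cohort = _load_cohort(config)
    report["n_subjects"] = len(cohort)
    report["validation"] = cohort.validation.__dict__

    def stage(name):
        def deco(fn):
            nonlocal partial
            try:
                log.info("stage: %s", name)
                fn()
            except Exception as exc:  # noqa: BLE001 - report, don't crash the run
                log.error("stage %s failed: %s", name, exc)
                failed.append(name)
                partial = True
            return fn
        return deco

    @stage("summary_table")
    def _summary():
        summary = summarize(cohort)
        summary.to_csv(outdir / "summary_table.csv", index=False)
        med = summary[(summary["stratum"] == "all")].set_index("variable")["median"]
        report["overall_medians"] = {
            c: float(med[c]) for c in config.covariates if c in med.index
        }

    spec = ColrSpec(
        covariates=config.covariates,
        order=config.order,
        log_scale=config.log_scale,
        ci_level=config.ci_level,
    )
    fits: dict[str, object] = {}

    strata = ["all", "vaginal"]
    strata += ["elective_cs", "unplanned_cs"] if config.separate_cesarean else ["cesarean"]
    for label in strata:
        @stage(f"colr_fit_{label}")
        def _fit(label=label):
            sub = stratify(cohort, label)
            fit = fit_colr(spec, sub)
            fits[label] = fit
            key = "overall" if label == "all" else label
            fname = outdir / f"fit_{key}.json"
            fname.write_text(json.dumps(fit.to_dict(), indent=2))
            report.setdefault("continuous_model", {})[key] = {
                "n": fit.n_obs,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "odds_ratios": _or_block(odds_ratios(fit)),
            }

    @stage("binary_500")
    def _binary():
        y01 = (cohort.mbl <= config.threshold).astype(float)
        est = BinaryLogisticRegression().fit(
            cohort.covariate_matrix(config.covariates), y01
        )
        report["binary_500"] = {
            "threshold_ml": config.threshold,
            "n_below": int(y01.sum()),
            "converged": bool(est.converged_),
            "odds_ratios": _or_block(est.summary(config.ci_level)),
        }

    @stage("cutoff_sweep")
    def _sweep():
        sweep = sweep_cutoffs(
            cohort, covariates=config.covariates, grid=config.sweep_grid,
            level=config.ci_level,
        )
        sweep.to_csv(outdir / "sweep.csv")
        for item in sweep.skipped:
            log.warning("sweep: cut-off %.0f mL skipped (n_below=%d)",
                        item["cutoff_ml"], item["n_below"])
        report["sweep"] = {
            "n_cutoffs": int(sweep.grid.size),
            "n_skipped": len(sweep.skipped),
            "file": "sweep.csv",
        }
        if "binary_500" in report and config.threshold in sweep.grid:
            sub = sweep.table[sweep.table["cutoff_ml"] == config.threshold]
            report["sweep"]["at_threshold"] = {
                r["covariate"]: round(float(np.exp(r["coef"])), 6)
                for _, r in sub.iterrows()
            }

    @stage("prevalence_curve")
    def _curve():
        fit = fits["all"]
        focal = "platelets_pre"
        lo, hi = np.percentile(
            cohort.df[focal].to_numpy(dtype=float), [1, 99]
        )
        curve = pph_prevalence_curve(
            fit, focal, np.linspace(lo, hi, 101),
            threshold=config.threshold, level=config.ci_level,
        )
        curve.to_csv(outdir / "prevalence_curve.csv", index=False)
        report["prevalence_curve"] = {
            "focal": focal, "threshold_ml": config.threshold,
            "x_ref": dict(zip(config.covariates, fit.x_ref.tolist())),
            "file": "prevalence_curve.csv",
        }

    @stage("shift_effect")
    def _shift():
        fit = fits["all"]
        eff = shift_effect(
            fit, "platelets_pre", config.shift_delta,
            threshold=config.threshold,
        )
        report["shift_effect"] = {
            "covariate": eff.covariate,
            "delta": eff.delta,
            "odds_factor": eff.odds_factor,
            "pct_rise_below": eff.pct_rise_below,
            "pct_drop_pph": eff.pct_drop_pph,
        }

    @stage("associations")
    def _assoc():
        pre = spearman(cohort.df["platelets_pre"], cohort.df["fxiii_pre"])
        report["association"] = {
            "prepartum": {"rho": pre.rho, "n": pre.n, "p_value": pre.p_value},
        }
        post_x = cohort.df.get("platelets_post")
        post_y = cohort.df.get("fxiii_post")
        if post_x is not None and post_y is not None and post_x.notna().sum() >= 3:
            post = spearman(post_x, post_y)
            report["association"]["postpartum"] = {
                "rho": post.rho, "n": post.n, "p_value": post.p_value,
            }

    if partial:
        report["partial"] = True
        report["failed_stages"] = failed
    result = AnalysisReport(report=report, outdir=outdir, partial=partial)
    (outdir / "report.json").write_text(result.to_json())
    _write_human_summary(report, outdir / "summary.txt")
    return result


def _write_human_summary(report: dict, path: Path) -> None:
    lines = [f"colrpph analysis report (seed {report['seed']})",
             f"subjects: {report.get('n_subjects')}"]
    cm = report.get("continuous_model", {})
    for key, block in cm.items():
        ors = block["odds_ratios"].get("platelets_pre")
        if ors:
            lines.append(
                f"continuous model [{key}]: platelet OR {ors['or']:.3f} "
                f"(95% CI {ors['ci_low']:.3f}-{ors['ci_high']:.3f}), "
                f"p = {ors['p_value']:.3g}"
            )
    b5 = report.get("binary_500", {}).get("odds_ratios", {}).get("platelets_pre")
    if b5:
        lines.append(
            f"binary 500 mL model: platelet OR {b5['or']:.3f} "
            f"(95% CI {b5['ci_low']:.3f}-{b5['ci_high']:.3f})"
        )
    se = report.get("shift_effect")
    if se:
        lines.append(
            f"+{se['delta']:.0f} G/L platelets: odds to stay below any "
            f"cut-off x{se['odds_factor']:.3f} (+{se['pct_rise_below']:.1f}%), "
            f"P(PPH) drop {se['pct_drop_pph']:.1f}%"
        )
    assoc = report.get("association", {})
    for when, a in assoc.items():
        lines.append(
            f"Spearman platelets~FXIII ({when}): rho = {a['rho']:.3f}, "
            f"p = {a['p_value']:.3g} (n = {a['n']})"
        )
    if report.get("partial"):
        lines.append(f"PARTIAL RUN - failed stages: {report['failed_stages']}")
    path.write_text("\n".join(lines) + "\n")
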