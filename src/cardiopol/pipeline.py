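"""End-to-end orchestration: samples → summaries → fits → cut-off → metrics.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes the
stages in order, logs each one, and returns a JSON-serializable report.
Given identical inputs and seed the serialized report is byte-identical.
Floats are reported at full precision; display rounding (3 decimals for DOLP
statistics, percentages to 2 decimals) is applied only in the plain-text
summary table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from .cohort import (
    GroupFit,
    TissueSample,
    classify,
    fit_group,
    group_summary,
    select_cutoff,
)
from .datasets import load_study_dolp
from .io import read_samples

__all__ = ["RunConfig", "run_pipeline", "render_summary_table"]

logger = logging.getLogger("cardiopol")

CONTRASTS = {"control-vs-RHD": "RHD", "control-vs-MV": "MV"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    ``samples_path=None`` analyses the packaged study DOLP records (which
    carry no thicknesses, hence imply ``summaries_only``).  ``fixed_slope``
    is required iff ``cutoff_strategy="fixed"``.
    """

    samples_path: str | None = None
    contrast: str = "control-vs-RHD"
    cutoff_strategy: str = "max-accuracy"
    fixed_slope: float | None = None
    anchor: str = "intersection"
    summaries_only: bool = False
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(
                f"unknown contrast {self.contrast!r}; expected one of "
                f"{sorted(CONTRASTS)}"
            )
        if self.cutoff_strategy == "fixed" and self.fixed_slope is None:
            raise ValueError("cutoff_strategy='fixed' requires fixed_slope")
        if self.cutoff_strategy != "fixed" and self.fixed_slope is not None:
            raise ValueError("fixed_slope given but cutoff_strategy is not 'fixed'")
        if self.samples_path is not None and not Path(self.samples_path).exists():
            raise FileNotFoundError(self.samples_path)


def _fit_to_dict(fit: GroupFit) -> dict:
    return {
        "group": fit.group,
        "slope_per_mm": fit.slope,
        "intercept": fit.intercept,
        "n": fit.n,
        "r2": fit.r2,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis and return the report dictionary.

    Stages: load samples → per-(group, ventricle) summaries → pooled OLS fit
    per group → cut-off selection → per-sample classification and confusion
    metrics.  The fit/classify stages are skipped in summaries-only mode or
    when the input records carry no thicknesses.
    """
    if config.samples_path is None:
        logger.info("stage=load source=packaged-study-dolp")
        samples = load_study_dolp()
    else:
        logger.info("stage=load source=%s", config.samples_path)
        samples = read_samples(config.samples_path)
    diseased_group = CONTRASTS[config.contrast]
    subset = [s for s in samples if s.group in ("control", diseased_group)]
    if not subset:
        raise ValueError(f"no samples for contrast {config.contrast}")

    report: dict = {
        "config": {
            "samples_path": config.samples_path,
            "contrast": config.contrast,
            "cutoff_strategy": config.cutoff_strategy,
            "fixed_slope": config.fixed_slope,
            "anchor": config.anchor,
            "summaries_only": config.summaries_only,
            "seed": config.seed,
        },
        "n_samples": len(subset),
    }

    summaries = []
    for grp in ("control", diseased_group):
        for vent in ("LV", "RV"):
            if any(s.group == grp and s.ventricle == vent for s in subset):
                summaries.append(asdict(group_summary(subset, grp, vent)))
    report["group_summaries"] = summaries
    logger.info("stage=summaries n=%d", len(summaries))

    have_thickness = all(s.thickness_mm is not None for s in subset)
    if config.summaries_only or not have_thickness:
        logger.info(
            "stage=classification skipped=%s",
            "summaries_only" if config.summaries_only else "missing thickness",
        )
        _maybe_write(report, subset, config)
        return report

    control = [s for s in subset if s.group == "control"]
    diseased = [s for s in subset if s.group == diseased_group]
    control_fit = fit_group(control)
    diseased_fit = fit_group(diseased)
    report["fits"] = {
        "control": _fit_to_dict(control_fit),
        diseased_group: _fit_to_dict(diseased_fit),
    }
    logger.info(
        "stage=fits control_slope=%.6g diseased_slope=%.6g",
        control_fit.slope,
        diseased_fit.slope,
    )

    cutoff = select_cutoff(
        control_fit,
        diseased_fit,
        subset,
        strategy=config.cutoff_strategy,
        fixed_slope=config.fixed_slope,
        anchor=config.anchor,
        diseased_groups=(diseased_group,),
    )
    report["cutoff"] = {
        "slope_per_mm": cutoff.slope,
        "anchor_thickness_mm": cutoff.anchor_thickness_mm,
        "anchor_dolp": cutoff.anchor_dolp,
        "strategy": cutoff.strategy,
    }
    logger.info("stage=cutoff slope=%.6g strategy=%s", cutoff.slope, cutoff.strategy)

    labels, metrics = classify(subset, cutoff, diseased_groups=(diseased_group,))
    report["labels"] = {
        f"{s.subject_id}-{s.ventricle}": lab for s, lab in zip(subset, labels)
    }
    report["metrics"] = asdict(metrics)
    logger.info(
        "stage=classify sensitivity=%.4f specificity=%.4f accuracy=%.4f",
        metrics.sensitivity,
        metrics.specificity,
        metrics.accuracy,
    )
    _maybe_write(report, subset, config)
    return report


def serialize_report(report: dict) -> str:
    """Canonical JSON form of a report (sorted keys, 2-space indent)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def _maybe_write(report: dict, samples: list[TissueSample], config: RunConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(serialize_report(report))
    (out / "summary.txt").write_text(render_summary_table(samples, report))
    logger.info("stage=write out=%s", out)


def _pct(x: float) -> str:
    # round half-up to 2 decimals in percent, display only
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_summary_table(samples: list[TissueSample], report: dict) -> str:
    """Plain-text per-subject DOLP table with group mean ± SEM footers."""
    lines = []
    groups = sorted({s.group for s in samples}, key=("control", "RHD", "MV").index)
    for grp in groups:
        lines.append(f"Group: {grp}")
        lines.append(f"{'subject':<10}{'DOLP LV':>10}{'DOLP RV':>10}")
        by_subject: dict[str, dict[str, float]] = {}
        for s in samples:
            if s.group == grp:
                by_subject.setdefault(s.subject_id, {})[s.ventricle] = s.dolp
        for subject, vals in by_subject.items():
            lv = f"{vals['LV']:.3f}" if "LV" in vals else "-"
            rv = f"{vals['RV']:.3f}" if "RV" in vals else "-"
            lines.append(f"{subject:<10}{lv:>10}{rv:>10}")
        cells = {
            (d["ventricle"]): d
            for d in report["group_summaries"]
            if d["group"] == grp
        }
        foot = {
            v: (
                f"{cells[v]['mean_dolp']:.3f}±{cells[v]['sem_dolp']:.3f}"
                if v in cells
                else "-"
            )
            for v in ("LV", "RV")
        }
        lines.append(f"{'mean±SEM':<10}{foot['LV']:>12}{foot['RV']:>12}")
        lines.append("")
    if "metrics" in report:
        m = report["metrics"]
        lines.append(
            "sensitivity/specificity/accuracy: "
            f"{_pct(m['sensitivity'])}% / {_pct(m['specificity'])}% / "
            f"{_pct(m['accuracy'])}%"
        )
        lines.append("")
    return "\n".join(lines)
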