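"""End-to-end orchestration.

Replicates the study design on synthetic (or loaded) cohorts: a hospital
pool is split into construction/internal cohorts, an independent cohort
is generated separately with older ages; metrics are derived, the
HGI-lifespan inflection located, SHORT/MID correction models fitted on
the construction cohort, applied to all three cohorts, and each cohort
validated.  Every artifact is plain text and byte-identical across
re-runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io as gio
from .core import (
    CorrectionModel,
    LifespanGroup,
    PatientRecord,
    boundary_discontinuities,
    compute_metrics,
    write_models,
)
from .errors import ConfigurationError, DataValidationError
from .stats import detect_inflection, fit_correction_model, proportion_report
from .synth import SyntheticCohortConfig, simulate_cohort
from .validation import POOR_CONTROL_THRESHOLD, ValidationReport, evaluate_scores

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "split_cohort", "run_pipeline"]

#: cohort sizes printed for the hospital pool split
FIXED_SPLIT_SIZES = (416, 100)


def split_cohort(
    records: Sequence[PatientRecord],
    ratio: Tuple[int, int] = (4, 1),
    seed: int = 0,
    sizes: Optional[Tuple[int, int]] = None,
) -> Tuple[List[PatientRecord], List[PatientRecord]]:
    """Simple random construction/internal allocation, no stratification.

    With ``sizes`` given the split is exact (e.g. the study's 416/100,
    which is not an exact 4:1 of 516); otherwise the construction size is
    round(n * a / (a + b)), so sizes differ from the exact ratio by < 1.
    """
    n = len(records)
    if n < 5:
        raise DataValidationError("need at least 5 records to split")
    if sizes is not None:
        n_con, n_int = sizes
        if n_con <= 0 or n_int <= 0 or n_con + n_int != n:
            raise ConfigurationError(
                f"fixed sizes {sizes} incompatible with cohort of {n}"
            )
    else:
        a, b = ratio
        if a <= 0 or b <= 0:
            raise ConfigurationError("both ratio parts must be positive")
        n_con = round(n * a / (a + b))
        n_con = min(max(n_con, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    construction = [
        dataclasses.replace(records[i], cohort_label="construction")
        for i in sorted(perm[:n_con])
    ]
    internal = [
        dataclasses.replace(records[i], cohort_label="internal")
        for i in sorted(perm[n_con:])
    ]
    return construction, internal


@dataclass
class PipelineConfig:
    """Configuration for a full replica run."""

    mode: str = "simulate"  # 'simulate' | 'load'
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    n_independent: int = 165
    independent_seed_offset: int = 10_000
    independent_age_range: Tuple[float, float] = (60.0, 75.0)
    split_mode: str = "fixed"  # 'fixed' (416/100) | 'ratio'
    split_ratio: Tuple[int, int] = (4, 1)
    split_seed: int = 0
    load_paths: Optional[Mapping[str, str]] = None  # cohort_label -> csv path
    breakpoint_grid: Optional[Sequence[float]] = None
    threshold_pct: float = POOR_CONTROL_THRESHOLD
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError("mode must be 'simulate' or 'load'")
        if self.split_mode not in ("fixed", "ratio"):
            raise ConfigurationError("split_mode must be 'fixed' or 'ratio'")
        if any(p <= 0 for p in self.split_ratio):
            raise ConfigurationError("split_ratio parts must be positive")
        if self.mode == "load":
            if not self.load_paths or "construction" not in self.load_paths:
                raise ConfigurationError("load mode requires at least a construction path")
            for label, path in self.load_paths.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"{label} cohort file not found: {path}")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return {k: default(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, LifespanGroup):
                return o.value
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, (set, tuple)):
                return list(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # where artifacts land is not part of identity
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohorts: Dict[str, List[PatientRecord]]
    models: Dict[LifespanGroup, CorrectionModel]
    inflection: object  # ChangepointResult
    proportions: Dict[str, dict]
    reports: Dict[str, ValidationReport]
    audit: dict


def _assemble_cohorts(config: PipelineConfig) -> Dict[str, List[PatientRecord]]:
    if config.mode == "load":
        cohorts = {}
        for label, path in config.load_paths.items():
            records = [
                dataclasses.replace(r, cohort_label=label) for r in gio.read_cohort(path)
            ]
            cohorts[label] = records
        if "internal" not in cohorts:
            construction, internal = split_cohort(
                cohorts["construction"],
                ratio=config.split_ratio,
                seed=config.split_seed,
            )
            cohorts["construction"], cohorts["internal"] = construction, internal
        return cohorts

    pool = simulate_cohort(config.cohort, cohort_label="construction")
    sizes = FIXED_SPLIT_SIZES if (
        config.split_mode == "fixed" and config.cohort.n_patients == sum(FIXED_SPLIT_SIZES)
    ) else None
    construction, internal = split_cohort(
        pool, ratio=config.split_ratio, seed=config.split_seed, sizes=sizes
    )
    indep_cfg = dataclasses.replace(
        config.cohort,
        n_patients=config.n_independent,
        seed=config.cohort.seed + config.independent_seed_offset,
        covariate_ranges={
            **dict(config.cohort.covariate_ranges),
            "age_years": config.independent_age_range,
        },
    )
    independent = simulate_cohort(indep_cfg, cohort_label="independent")
    return {
        "construction": construction,
        "internal": internal,
        "independent": independent,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; optionally write the artifact tree."""
    audit: dict = {"config_hash": config.config_hash(), "stages": [], "flags": {}}

    def stage(name: str, **info) -> None:
        audit["stages"].append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    try:
        cohorts = _assemble_cohorts(config)
    except (ConfigurationError, DataValidationError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'assemble' failed: {exc}") from exc
    stage("assemble", sizes={k: len(v) for k, v in cohorts.items()})

    construction = cohorts["construction"]
    groups = [r.group for r in construction]
    proportions = proportion_report(groups)
    stage("proportions", report={k: v for k, v in proportions.items() if k != "total"})

    # inflection on the construction cohort's raw HGI-lifespan relation
    from .core import estimated_hba1c, hgi as hgi_fn

    lifespans = [r.rbc_lifespan_days for r in construction]
    hgis = [hgi_fn(r.hba1c_pct, estimated_hba1c(r.ag_mmol_L)) for r in construction]
    inflection = detect_inflection(lifespans, hgis, grid=config.breakpoint_grid)
    stage(
        "inflection",
        inflection_days=inflection.inflection_days,
        material=inflection.material,
        sse_improvement=inflection.sse_improvement,
    )

    models = {
        grp: fit_correction_model(construction, grp)
        for grp in (LifespanGroup.SHORT, LifespanGroup.MID)
    }
    jumps = boundary_discontinuities(models)
    audit["flags"]["boundary_discontinuities"] = jumps
    logger.info("piecewise correction discontinuities: %s", jumps)
    stage("fit", coefficients={
        grp.value: [m.beta_lifespan, m.beta_hba1c, m.intercept] for grp, m in models.items()
    })

    metrics = {}
    n_warn = 0
    import warnings as _warnings

    for label, records in cohorts.items():
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            metrics[label] = [compute_metrics(r, models) for r in records]
            n_warn += len(caught)
    audit["flags"]["out_of_range_corrections"] = n_warn
    stage("metrics", records=sum(len(m) for m in metrics.values()), flagged=n_warn)

    reports = {}
    for label, ms in metrics.items():
        reports[label] = evaluate_scores(
            cohort_label=label,
            corrected_hba1c=[m.hba1c_corrected_pct for m in ms],
            ehba1c=[m.ehba1c_pct for m in ms],
            threshold_pct=config.threshold_pct,
        )
    stage("validate", auc={k: r.auc for k, r in reports.items()})

    result = PipelineResult(
        cohorts=cohorts,
        models=models,
        inflection=inflection,
        proportions=proportions,
        reports=reports,
        audit=audit,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, metrics)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult, metrics) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, records in result.cohorts.items():
        gio.write_cohort(records, out / f"cohort_{label}.csv")
        gio.write_metrics(metrics[label], out / f"metrics_{label}.csv")
    write_models(result.models, out / "models.txt")

    infl = result.inflection
    (out / "inflection.json").write_text(
        json.dumps(
            {
                "inflection_days": infl.inflection_days,
                "slope_pre": infl.slope_pre,
                "slope_post": infl.slope_post,
                "sse": infl.sse,
                "single_line_sse": infl.single_line_sse,
                "material": infl.material,
                "candidate_profile": {str(k): v for k, v in infl.candidate_profile.items()},
            },
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
    (out / "proportions.json").write_text(
        json.dumps(result.proportions, sort_keys=True, indent=2) + "\n"
    )
    for label, report in result.reports.items():
        (out / f"validation_{label}.json").write_text(report.to_json() + "\n")
    header = "\t".join(ValidationReport.SUMMARY_FIELDS)
    rows = [result.reports[k].summary_row() for k in sorted(result.reports)]
    (out / "validation_summary.tsv").write_text(header + "\n" + "\n".join(rows) + "\n")
    (out / "audit.json").write_text(
        json.dumps(
            {"seed": config.cohort.seed, **result.audit}, sort_keys=True, indent=2
        )
        + "\n"
    )
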