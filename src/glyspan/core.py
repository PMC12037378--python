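"""Pure-formula layer.

Everything in this module is a deterministic function of its inputs:
RBC-lifespan estimation from an alveolar CO breath sample, the ADAG
average-glucose-to-HbA1c conversion, the hemoglobin glycation index
(HGI), lifespan-group classification, and the piecewise linear HbA1c
correction.

Units
-----
HbA1c and eHbA1c are NGSP percent, average glucose (AG) is mmol/L by
default (``ag_units='mg/dL'`` converts by /18.016), RBC lifespan is days,
hemoglobin is g/L, CO concentrations are ppm.

Lifespan groups partition the positive axis as [0, 66] (SHORT),
(66, 90) (MID) and [90, inf) (NORMAL).  On integer days this coincides
with the <=66 / 67--89 / >=90 labelling; fractional days fall in the
interval that contains them (66.5 is MID).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

from .errors import ConfigurationError, DataValidationError, DegenerateDataError

__all__ = [
    "ADAG_SLOPE",
    "ADAG_OFFSET",
    "MGDL_PER_MMOL",
    "LifespanGroup",
    "COBreathSample",
    "PatientRecord",
    "CorrectionModel",
    "GlycemiaMetrics",
    "estimate_rbc_lifespan",
    "estimated_hba1c",
    "hgi",
    "classify_lifespan",
    "correct_hba1c",
    "compute_metrics",
    "published_models",
    "read_models",
    "write_models",
    "boundary_discontinuities",
]

#: ADAG linear relation: eHbA1c [%] = (AG [mmol/L] + ADAG_OFFSET) / ADAG_SLOPE
ADAG_SLOPE = 1.5944
ADAG_OFFSET = 2.5944

#: glucose unit conversion, mg/dL per mmol/L
MGDL_PER_MMOL = 18.016

SHORT_MAX_DAYS = 66.0
NORMAL_MIN_DAYS = 90.0

COHORT_LABELS = ("construction", "internal", "independent")


class LifespanGroup(str, Enum):
    """RBC lifespan stratum: [0,66] / (66,90) / [90,inf) days."""

    SHORT = "SHORT"
    MID = "MID"
    NORMAL = "NORMAL"

    def __str__(self) -> str:  # keeps CSV/JSON output plain
        return self.value


@dataclass(frozen=True)
class COBreathSample:
    """One end-expiratory CO measurement used to estimate RBC lifespan.

    ``k_cal`` folds the physical constants and blood/alveolar volume
    ratio of the Levitt relation into a single calibration constant
    (days*ppm*L/g); the default of 1.0 maps (Hb=140 g/L, net CO=1.4 ppm)
    to 100 days.
    """

    alveolar_co_ppm: float
    ambient_co_ppm: float
    hb_g_per_L: float
    k_cal: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alveolar_co_ppm) and math.isfinite(self.ambient_co_ppm)):
            raise DataValidationError("CO concentrations must be finite")
        if self.ambient_co_ppm < 0:
            raise DataValidationError("ambient CO must be >= 0")
        if self.alveolar_co_ppm <= self.ambient_co_ppm:
            raise DataValidationError(
                "degenerate breath sample: alveolar CO must exceed ambient CO"
            )
        if not self.hb_g_per_L > 0:
            raise DataValidationError("hemoglobin concentration must be positive")
        if not self.k_cal > 0:
            raise DataValidationError("calibration constant k_cal must be positive")

    @property
    def net_co_ppm(self) -> float:
        return self.alveolar_co_ppm - self.ambient_co_ppm


def estimate_rbc_lifespan(sample: COBreathSample) -> float:
    """RBC lifespan (days) from a CO breath sample.

    lifespan = k_cal * [Hb] / (alveolar CO - ambient CO): CO released per
    unit hemoglobin catabolised divided by the CO excretion rate.  The
    result is homogeneous of degree +1 in Hb and -1 in net CO.
    """
    return sample.k_cal * sample.hb_g_per_L / sample.net_co_ppm


def estimated_hba1c(ag: float, ag_units: str = "mmol/L") -> float:
    """Estimated HbA1c (%) from average glucose via the ADAG relation.

    eHbA1c = (AG + 2.5944) / 1.5944 with AG in mmol/L.
    """
    if ag_units == "mg/dL":
        ag = ag / MGDL_PER_MMOL
    elif ag_units != "mmol/L":
        raise ConfigurationError(f"unknown AG units {ag_units!r}")
    if not math.isfinite(ag):
        raise DataValidationError("average glucose must be finite")
    return (ag + ADAG_OFFSET) / ADAG_SLOPE


def ag_from_ehba1c(ehba1c_pct: float) -> float:
    """Inverse ADAG relation: AG (mmol/L) = 1.5944 * eHbA1c - 2.5944."""
    return ADAG_SLOPE * ehba1c_pct - ADAG_OFFSET


def hgi(hba1c_pct: float, ehba1c_pct: float) -> float:
    """Hemoglobin glycation index: measured HbA1c minus estimated HbA1c."""
    if not (math.isfinite(hba1c_pct) and math.isfinite(ehba1c_pct)):
        raise DataValidationError("HGI inputs must be finite")
    return hba1c_pct - ehba1c_pct


def classify_lifespan(lifespan_days: float) -> LifespanGroup:
    """Assign a lifespan (days) to its stratum; rejects non-positive input."""
    if not (math.isfinite(lifespan_days) and lifespan_days > 0):
        raise DataValidationError(f"lifespan must be positive, got {lifespan_days!r}")
    if lifespan_days <= SHORT_MAX_DAYS:
        return LifespanGroup.SHORT
    if lifespan_days < NORMAL_MIN_DAYS:
        return LifespanGroup.MID
    return LifespanGroup.NORMAL


@dataclass
class CorrectionModel:
    """Linear correction HbA1c(c) = beta_lifespan*days + beta_hba1c*HbA1c + intercept.

    Applies within one lifespan stratum (SHORT or MID).  ``multiple_r``
    is the multiple correlation coefficient sqrt(R^2) of the fit;
    ``f_stat``/``f_pvalue`` the overall regression F test.
    """

    beta_lifespan: float
    beta_hba1c: float
    intercept: float
    group: LifespanGroup
    multiple_r: Optional[float] = None
    f_stat: Optional[float] = None
    f_pvalue: Optional[float] = None
    n_obs: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.group, str):
            self.group = LifespanGroup(self.group)
        if self.group not in (LifespanGroup.SHORT, LifespanGroup.MID):
            raise ConfigurationError("correction models apply only to SHORT or MID groups")
        if self.multiple_r is not None and not (0.0 <= self.multiple_r <= 1.0 + 1e-12):
            raise ConfigurationError("multiple_R must lie in [0, 1]")

    def predict(self, lifespan_days: float, hba1c_pct: float) -> float:
        return (
            self.beta_lifespan * lifespan_days
            + self.beta_hba1c * hba1c_pct
            + self.intercept
        )


def _validate_optional_flag(name: str, value: Optional[int]) -> Optional[int]:
    if value is None:
        return None
    if value in (0, 1):
        return int(value)
    raise DataValidationError(f"{name} must be 0, 1 or absent, got {value!r}")


@dataclass
class PatientRecord:
    """One subject's glycemic measurements, lifespan, covariates and flags."""

    patient_id: str
    hba1c_pct: float
    ag_mmol_L: float
    rbc_lifespan_days: float
    age_years: Optional[float] = None
    duration_years: Optional[float] = None
    hb_g_per_L: Optional[float] = None
    scr_umol_L: Optional[float] = None
    bun_mmol_L: Optional[float] = None
    tg_mmol_L: Optional[float] = None
    tc_mmol_L: Optional[float] = None
    ldl_mmol_L: Optional[float] = None
    hdl_mmol_L: Optional[float] = None
    cvd_flag: Optional[int] = None
    neuropathy_flag: Optional[int] = None
    fundus_flag: Optional[int] = None
    cohort_label: str = "construction"

    def __post_init__(self) -> None:
        if not 3.0 < self.hba1c_pct < 20.0:
            raise DataValidationError(
                f"hba1c_pct must lie in (3, 20), got {self.hba1c_pct}"
            )
        if not 2.0 < self.ag_mmol_L < 35.0:
            raise DataValidationError(
                f"ag_mmol_L must lie in (2, 35), got {self.ag_mmol_L}"
            )
        if not 20.0 < self.rbc_lifespan_days < 200.0:
            raise DataValidationError(
                f"rbc_lifespan_days must lie in (20, 200), got {self.rbc_lifespan_days}"
            )
        for name in ("cvd_flag", "neuropathy_flag", "fundus_flag"):
            setattr(self, name, _validate_optional_flag(name, getattr(self, name)))
        if self.cohort_label not in COHORT_LABELS:
            raise DataValidationError(
                f"cohort_label must be one of {COHORT_LABELS}, got {self.cohort_label!r}"
            )

    @property
    def group(self) -> LifespanGroup:
        return classify_lifespan(self.rbc_lifespan_days)


@dataclass(frozen=True)
class GlycemiaMetrics:
    """Derived per-patient quantities."""

    patient_id: str
    ehba1c_pct: float
    hgi: float
    group: LifespanGroup
    hba1c_corrected_pct: float


def correct_hba1c(
    hba1c_pct: float,
    lifespan_days: float,
    models: Mapping[LifespanGroup, CorrectionModel],
) -> float:
    """Corrected HbA1c (%): piecewise linear for SHORT/MID, identity for NORMAL.

    The published SHORT/MID equations are applied verbatim with no
    blending across the 66- and 90-day boundaries.  The result is not
    clamped; values outside the plausible (3, 20)% range raise a warning
    only.
    """
    group = classify_lifespan(lifespan_days)
    if group is LifespanGroup.NORMAL:
        return hba1c_pct
    model = models.get(group)
    if model is None:
        raise ConfigurationError(f"no correction model configured for group {group}")
    if model.group is not group:
        raise ConfigurationError(
            f"model registered under {group} was fitted for {model.group}"
        )
    corrected = model.predict(lifespan_days, hba1c_pct)
    if not 3.0 < corrected < 20.0:
        warnings.warn(
            f"corrected HbA1c {corrected:.3f}% outside plausible (3, 20)% range",
            stacklevel=2,
        )
    return corrected


def compute_metrics(
    record: PatientRecord,
    models: Mapping[LifespanGroup, CorrectionModel],
    ag_units: str = "mmol/L",
) -> GlycemiaMetrics:
    """eHbA1c, HGI, group and corrected HbA1c for one record."""
    e = estimated_hba1c(record.ag_mmol_L, ag_units=ag_units)
    return GlycemiaMetrics(
        patient_id=record.patient_id,
        ehba1c_pct=e,
        hgi=hgi(record.hba1c_pct, e),
        group=record.group,
        hba1c_corrected_pct=correct_hba1c(
            record.hba1c_pct, record.rbc_lifespan_days, models
        ),
    )


def boundary_discontinuities(
    models: Mapping[LifespanGroup, CorrectionModel], hba1c_pct: float = 7.0
) -> dict:
    """Jump sizes of the piecewise correction at the 66/67 and 89/90 boundaries.

    Evaluated at a reference measured HbA1c; reported in audit logs since
    the published equations are applied without smoothing.
    """
    short = models[LifespanGroup.SHORT]
    mid = models[LifespanGroup.MID]
    return {
        "at_66_67": mid.predict(67.0, hba1c_pct) - short.predict(66.0, hba1c_pct),
        "at_89_90": hba1c_pct - mid.predict(89.0, hba1c_pct),
        "reference_hba1c_pct": hba1c_pct,
    }


# ---------------------------------------------------------------------------
# model coefficient serialization (plain-text key = value, one key per line)
# ---------------------------------------------------------------------------

_MODEL_FIELDS = (
    "beta_lifespan",
    "beta_hba1c",
    "intercept",
    "multiple_r",
    "f_stat",
    "f_pvalue",
    "n_obs",
)


def write_models(models: Mapping[LifespanGroup, CorrectionModel], path) -> None:
    """Write a model set to the versioned key-value text format."""
    lines = ["format = glyspan-models-1"]
    for group in (LifespanGroup.SHORT, LifespanGroup.MID):
        model = models.get(group)
        if model is None:
            continue
        prefix = group.value.lower()
        for name in _MODEL_FIELDS:
            value = getattr(model, name)
            if value is None:
                continue
            lines.append(f"{prefix}.{name} = {value!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_model_text(text: str, source: str) -> dict:
    groups: dict = {}
    fmt_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{source}:{lineno}: expected 'key = value'")
        key, _, value = (part.strip() for part in line.partition("="))
        if key == "format":
            if value != "glyspan-models-1":
                raise ConfigurationError(f"{source}: unsupported format {value!r}")
            fmt_seen = True
            continue
        if "." not in key:
            raise ConfigurationError(f"{source}:{lineno}: key {key!r} lacks group prefix")
        prefix, _, name = key.partition(".")
        try:
            group = LifespanGroup(prefix.upper())
        except ValueError:
            raise ConfigurationError(f"{source}:{lineno}: unknown group {prefix!r}") from None
        if name not in _MODEL_FIELDS:
            raise ConfigurationError(f"{source}:{lineno}: unknown field {name!r}")
        groups.setdefault(group, {})[name] = (
            int(value) if name == "n_obs" else float(value)
        )
    if not fmt_seen:
        raise ConfigurationError(f"{source}: missing 'format = glyspan-models-1' line")
    return groups


def read_models(path) -> dict:
    """Read a model set written by :func:`write_models`."""
    with open(path) as fh:
        text = fh.read()
    parsed = _parse_model_text(text, str(path))
    models = {}
    for group, fields in parsed.items():
        for required in ("beta_lifespan", "beta_hba1c", "intercept"):
            if required not in fields:
                raise ConfigurationError(
                    f"{path}: group {group.value} missing field {required!r}"
                )
        models[group] = CorrectionModel(group=group, **fields)
    return models


def published_models() -> dict:
    """The published SHORT/MID correction coefficient set shipped as data."""
    text = resources.files("glyspan").joinpath("data/published_models.txt").read_text()
    parsed = _parse_model_text(text, "published_models.txt")
    return {g: CorrectionModel(group=g, **fields) for g, fields in parsed.items()}
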