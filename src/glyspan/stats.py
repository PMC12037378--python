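"""Inferential stages.

Correlation and group-comparison statistics (Spearman, Kruskal-Wallis,
chi-square), HGI-lifespan inflection detection via an exhaustive hinge
(two-segment continuous linear) breakpoint search, subgroup correction
model fitting by OLS, stratum proportion reporting, and 2x2 odds ratios
with Woolf confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .core import (
    CorrectionModel,
    LifespanGroup,
    PatientRecord,
    classify_lifespan,
    estimated_hba1c,
)
from .errors import ConfigurationError, DataValidationError, DegenerateDataError

__all__ = [
    "spearman_correlation",
    "kruskal_wallis",
    "chi_square_association",
    "detect_inflection",
    "fit_correction_model",
    "proportion_report",
    "odds_ratio",
    "ChangepointResult",
    "ContingencyTable2x2",
    "OddsRatioResult",
    "RCSFit",
]


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho with average-rank tie handling; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise DataValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman rho undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df.

    A completely constant pooled sample is not an error: it carries no
    evidence, so (H, p) = (0, 1) is returned.
    """
    if len(groups) < 2:
        raise DataValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DataValidationError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def chi_square_association(table, yates: bool = False) -> Tuple[float, float]:
    """Pearson chi-square of independence on an r x c count table.

    No continuity correction by default; ``yates=True`` enables it for
    2x2 tables.  A zero row or column margin is rejected explicitly.
    """
    if isinstance(table, ContingencyTable2x2):
        counts = table.as_array()
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DataValidationError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise DataValidationError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    for axis_name, sums in (("row", row_sums), ("column", col_sums)):
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise DegenerateDataError(
                f"degenerate margin: {axis_name}(s) {zero.tolist()} have zero total"
            )
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=yates)
    return float(chi2), float(p)


@dataclass(frozen=True)
class RCSFit:
    """Restricted cubic spline fit (Harrell truncated-power basis)."""

    knots: np.ndarray
    coefficients: np.ndarray  # intercept, linear, then one per interior basis fn

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        scale = (t[-1] - t[0]) ** 2
        cols = [np.ones_like(x), x]
        for j in range(k - 2):
            term = (
                np.maximum(x - t[j], 0) ** 3
                - np.maximum(x - t[-2], 0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + np.maximum(x - t[-1], 0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            cols.append(term / scale)
        return np.column_stack(cols)

    def predict(self, x) -> np.ndarray:
        return self.basis(np.asarray(x, dtype=float)) @ self.coefficients


def fit_rcs(
    x: np.ndarray,
    y: np.ndarray,
    quantiles: Sequence[float] = (0.05, 0.35, 0.65, 0.95),
) -> RCSFit:
    """Least-squares restricted cubic spline with knots at data quantiles."""
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x, quantiles)
    if np.unique(knots).size != len(knots):
        raise DegenerateDataError("duplicate spline knots; data too concentrated")
    fit = RCSFit(knots=knots, coefficients=np.zeros(len(knots)))
    design = fit.basis(x)
    coef, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float), rcond=None)
    return RCSFit(knots=knots, coefficients=coef)


@dataclass
class ChangepointResult:
    """Outcome of the exhaustive hinge-breakpoint search."""

    inflection_days: float
    slope_pre: float
    slope_post: float
    sse: float
    single_line_sse: float
    candidate_profile: Dict[float, float]
    material: bool  #: False when the hinge improves SSE by < 1% over one line
    spline: Optional[RCSFit] = None

    @property
    def sse_improvement(self) -> float:
        if self.single_line_sse == 0:
            return 0.0
        return 1.0 - self.sse / self.single_line_sse


def detect_inflection(
    lifespan: Sequence[float],
    hgi: Sequence[float],
    grid: Optional[Sequence[float]] = None,
    min_side: int = 3,
    fit_spline: bool = True,
) -> ChangepointResult:
    """Locate the HGI-lifespan inflection by exhaustive hinge search.

    For each candidate breakpoint c on the grid (default: integer days
    45-110) a continuous two-segment model with design
    (1, lifespan, max(0, lifespan - c)) is fitted by least squares; the
    SSE-minimising candidate wins, smallest c on ties.  Candidates with
    fewer than ``min_side`` points strictly on either side are skipped.
    A 4-knot restricted cubic spline is fitted alongside for plotting.
    """
    x = np.asarray(lifespan, dtype=float)
    y = np.asarray(hgi, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("lifespan and hgi must be 1-D and equal length")
    if x.size < 20:
        raise DataValidationError("need at least 20 points for inflection detection")
    grid = np.arange(45.0, 111.0) if grid is None else np.sort(np.asarray(grid, dtype=float))

    feasible = [c for c in grid if (x < c).sum() >= min_side and (x > c).sum() >= min_side]
    if not feasible:
        raise DataValidationError(
            f"breakpoint grid [{grid[0]:g}, {grid[-1]:g}] lies outside the data range "
            f"[{x.min():g}, {x.max():g}]"
        )

    line_design = np.column_stack([np.ones_like(x), x])
    _, line_res, *_ = np.linalg.lstsq(line_design, y, rcond=None)
    single_sse = float(line_res[0]) if line_res.size else float(
        np.sum((y - line_design @ np.linalg.lstsq(line_design, y, rcond=None)[0]) ** 2)
    )

    profile: Dict[float, float] = {}
    best_c, best_sse, best_coef = None, np.inf, None
    for c in feasible:
        design = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ coef) ** 2))
        profile[float(c)] = sse
        if sse < best_sse:  # strict: ties keep the earlier (smaller) candidate
            best_c, best_sse, best_coef = float(c), sse, coef

    improvement = 1.0 - best_sse / single_sse if single_sse > 0 else 0.0
    return ChangepointResult(
        inflection_days=best_c,
        slope_pre=float(best_coef[1]),
        slope_post=float(best_coef[1] + best_coef[2]),
        sse=best_sse,
        single_line_sse=single_sse,
        candidate_profile=profile,
        material=improvement >= 0.01,
        spline=fit_rcs(x, y) if fit_spline else None,
    )


def fit_correction_model(
    records: Iterable[PatientRecord], group: LifespanGroup
) -> CorrectionModel:
    """OLS of eHbA1c on (lifespan, measured HbA1c) within one stratum.

    The dependent variable is recomputed from AG through the ADAG
    relation.  Returns the fitted coefficients together with the multiple
    correlation R = sqrt(R^2) and the overall regression F test.
    """
    if group not in (LifespanGroup.SHORT, LifespanGroup.MID):
        raise ConfigurationError("correction models are fitted for SHORT or MID only")
    subset = [r for r in records if classify_lifespan(r.rbc_lifespan_days) is group]
    if len(subset) < 10:
        raise DataValidationError(
            f"need >= 10 records in group {group.value}, got {len(subset)}"
        )
    lifespan = np.array([r.rbc_lifespan_days for r in subset])
    hba1c = np.array([r.hba1c_pct for r in subset])
    e = np.array([estimated_hba1c(r.ag_mmol_L) for r in subset])

    design = sm.add_constant(np.column_stack([lifespan, hba1c]), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDataError(
            f"singular design in group {group.value}: lifespan or HbA1c is constant"
        )
    fit = sm.OLS(e, design).fit()
    r2 = min(max(float(fit.rsquared), 0.0), 1.0)
    return CorrectionModel(
        beta_lifespan=float(fit.params[1]),
        beta_hba1c=float(fit.params[2]),
        intercept=float(fit.params[0]),
        group=group,
        multiple_r=math.sqrt(r2),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        n_obs=len(subset),
    )


def proportion_report(groups: Iterable[LifespanGroup]) -> Dict[str, dict]:
    """Stratum counts and percentages (2 dp), plus the pooled <90-day row."""
    groups = list(groups)
    total = len(groups)
    if total == 0:
        raise DataValidationError("cannot report proportions of an empty cohort")
    report = {}
    for grp in (LifespanGroup.SHORT, LifespanGroup.MID, LifespanGroup.NORMAL):
        count = sum(g is grp for g in groups)
        report[grp.value] = {"count": count, "percent": round(100.0 * count / total, 2)}
    below = report["SHORT"]["count"] + report["MID"]["count"]
    report["BELOW_90"] = {"count": below, "percent": round(100.0 * below / total, 2)}
    report["total"] = total
    return report


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: (exposed, unexposed) x (case, non-case)."""

    exposed_cases: int
    exposed_noncases: int
    unexposed_cases: int
    unexposed_noncases: int

    def __post_init__(self) -> None:
        cells = self.as_tuple()
        if any(c < 0 for c in cells):
            raise DataValidationError("counts must be non-negative")
        if sum(cells) == 0:
            raise DataValidationError("table total must be positive")

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (
            self.exposed_cases,
            self.exposed_noncases,
            self.unexposed_cases,
            self.unexposed_noncases,
        )

    def as_array(self) -> np.ndarray:
        a, b, c, d = self.as_tuple()
        return np.array([[a, b], [c, d]], dtype=float)

    @classmethod
    def from_flags(cls, exposed: Sequence[int], case: Sequence[int]) -> "ContingencyTable2x2":
        exposed = np.asarray(exposed, dtype=bool)
        case = np.asarray(case, dtype=bool)
        if exposed.shape != case.shape:
            raise DataValidationError("exposure and outcome vectors differ in length")
        return cls(
            exposed_cases=int(np.sum(exposed & case)),
            exposed_noncases=int(np.sum(exposed & ~case)),
            unexposed_cases=int(np.sum(~exposed & case)),
            unexposed_noncases=int(np.sum(~exposed & ~case)),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


def odds_ratio(table: ContingencyTable2x2, z: float = 1.96) -> OddsRatioResult:
    """Unadjusted OR with the 95% Woolf (log) interval.

    When any cell is zero the Haldane-Anscombe +0.5 correction is applied
    to every cell and flagged in the result; a zero diagonal (both cells
    of either diagonal zero) leaves the OR undefined and is rejected.
    """
    a, b, c, d = (float(v) for v in table.as_tuple())
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise DegenerateDataError("odds ratio undefined: a whole diagonal is zero")
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=est,
        ci_low=math.exp(math.log(est) - z * se),
        ci_high=math.exp(math.log(est) + z * se),
        continuity_corrected=corrected,
    )
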