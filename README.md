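# glyspan

Lifespan-aware HbA1c correction for type-2 diabetes cohorts.

A shortened red-blood-cell (RBC) lifespan reduces hemoglobin's glycation
exposure time and makes the measured HbA1c underestimate true glycemia.
`glyspan` quantifies that underestimation via the hemoglobin glycation
index (HGI = measured HbA1c − estimated HbA1c from average glucose),
locates the inflection of the HGI–lifespan relation, fits piecewise
linear correction models within the short-lifespan strata, applies them,
and validates the corrected values (ROC/AUC with DeLong or bootstrap
confidence intervals, threshold metrics, calibration). A seeded
synthetic cohort generator reproduces the statistical structure of the
motivating study so the entire pipeline is testable without patient
data.

## Layout

| module | contents |
|---|---|
| `glyspan.core` | formulas: Levitt CO-breath lifespan estimate, ADAG conversion, HGI, lifespan-group classification `[0,66] / (66,90) / [90,∞)` days, piecewise correction, model-coefficient text format |
| `glyspan.synth` | `SyntheticCohortConfig` + `simulate_cohort` (three strata ≈ 19/33/48%, HGI medians near −0.855/−0.415/−0.020, complication odds ratios 1.865/1.599 for lifespan < 90 d) |
| `glyspan.stats` | Spearman, Kruskal–Wallis, chi-square, exhaustive hinge-breakpoint inflection search + restricted cubic spline, subgroup OLS correction fit, stratum proportions, 2×2 odds ratios (Woolf CI) |
| `glyspan.validation` | AUC (Mann–Whitney ties half-credit, DeLong/bootstrap CI), accuracy/sensitivity/specificity, quantile-bin calibration with logistic link |
| `glyspan.pipeline` | 4:1 (or fixed 416/100) construction/internal split, full replica run, deterministic artifact tree |
| `glyspan.io` | delimited-text cohort contract with row-level diagnostics |

The published correction coefficients ship as plain text in
`src/glyspan/data/published_models.txt` and can be swapped for any file
in the same format.

## CLI

```sh
glyspan simulate --n 516 --seed 1 --out cohort.csv
glyspan metrics  --cohort cohort.csv --out metrics.csv      # published coefficients
glyspan fit      --cohort cohort.csv --out models.txt
glyspan correct  --cohort cohort.csv --models models.txt --out corrected.csv
glyspan validate --cohort cohort.csv --out report.json
glyspan run-all  --seed 1 --out-dir out/                    # full replica
```

Exit codes: 0 success, 2 configuration error, 3 data error, 1 internal
error. `--config` accepts a YAML file mirroring the
`SyntheticCohortConfig` / `PipelineConfig` fields.

Python API:

```python
from glyspan import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(out_dir="out"))
print(result.inflection.inflection_days)          # ~66
print({k: r.auc for k, r in result.reports.items()})
```

Re-running with an identical configuration produces a byte-identical
output tree.

## Conventions and caveats

- AG is mmol/L by default; `ag_units="mg/dL"` divides by 18.016.
- Fractional lifespans use the intervals `[0,66] / (66,90) / [90,∞)`,
  which coincide with the integer-day labels ≤66 / 67–89 / ≥90.
- The piecewise correction is applied verbatim and is therefore
  discontinuous at the 66/67 and 89/90 boundaries; the jump sizes are
  recorded in the audit log. Corrected values outside (3, 20)% warn but
  are not clamped.
- The Levitt lifespan formula is implemented structurally as
  `k_cal · [Hb] / net CO` with the constant bundle exposed as the single
  calibration constant `k_cal` (default 1.0 days·ppm·L/g, i.e.
  Hb = 140 g/L at 1.4 ppm net CO → 100 days).
- The generator's noise scale and the SHORT-stratum lifespan bounds are
  tuned so default cohorts reproduce the target group HGI medians; they
  are stand-ins, not derived quantities.
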