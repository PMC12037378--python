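import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from glyspan import (
    ContingencyTable2x2,
    CorrectionModel,
    DataValidationError,
    DegenerateDataError,
    LifespanGroup,
    SyntheticCohortConfig,
    chi_square_association,
    detect_inflection,
    fit_correction_model,
    kruskal_wallis,
    odds_ratio,
    proportion_report,
    simulate_cohort,
    spearman_correlation,
)
from glyspan.core import ag_from_ehba1c, estimated_hba1c, published_models
from glyspan.synth import simulate_hinge_hgi

from conftest import make_exact_cohort, make_record


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of any glyspan internals)
# ---------------------------------------------------------------------------

def _average_ranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _spearman_oracle(x, y):
    rx, ry = _average_ranks(x), _average_ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    rho = num / den
    t = rho * math.sqrt((n - 2) / max(1 - rho**2, 1e-300))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return rho, p


def _kruskal_oracle(groups):
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    ranks = _average_ranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos : pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in counts.values())
    correction = 1 - tie_sum / (n_total**3 - n_total)
    return h / correction


def _chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def _woolf_ci_oracle(a, b, c, d):
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 5, 8]
        assert spearman_correlation(x, [v**3 for v in x])[0] == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_oracle_random_8_points(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = spearman_correlation(x, y)
        rho_o, p_o = _spearman_oracle(list(x), list(y))
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, rel=1e-8)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_sweep_small_instances_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.integers(0, 4, size=n).astype(float)  # forces ties
        y = rng.integers(0, 4, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(_spearman_oracle(list(x), list(y))[0], abs=1e-12)

    def test_constant_input_signalled(self):
        with pytest.raises(DegenerateDataError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch(self):
        with pytest.raises(DataValidationError):
            spearman_correlation([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_matches_formula_oracle_9_values(self):
        groups = [[3.1, 4.5, 2.2], [5.0, 4.5, 6.1], [1.0, 2.2, 7.7]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(_kruskal_oracle(groups), abs=1e-10)

    def test_separated_ranks_maximal_at_n6(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        best = max(
            _kruskal_oracle([[values[i] for i in comb],
                             [v for j, v in enumerate(values) if j not in comb]])
            for comb in itertools.combinations(range(6), 3)
        )
        h, _ = kruskal_wallis([values[:3], values[3:]])
        assert h == pytest.approx(best, abs=1e-10)

    def test_constant_everywhere(self):
        assert kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]]) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_sweep(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [list(rng.integers(0, 5, size=rng.integers(2, 5)).astype(float))
                  for _ in range(int(rng.integers(2, 4)))]
        if np.ptp([v for g in groups for v in g]) == 0:
            pytest.skip("degenerate draw")
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(_kruskal_oracle(groups), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(DataValidationError):
            kruskal_wallis([[1.0], []])


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_proportional_table_is_zero(self):
        chi2, p = chi_square_association([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        table = [[20, 10], [10, 20]]
        chi2, _ = chi_square_association(table)
        assert chi2 == pytest.approx(_chi2_oracle(table), abs=1e-10)

    def test_column_permutation_invariance_2x3(self):
        table = np.array([[5, 9, 2], [7, 3, 8]])
        base = chi_square_association(table)[0]
        for perm in itertools.permutations(range(3)):
            assert chi_square_association(table[:, perm])[0] == pytest.approx(base, abs=1e-10)

    def test_zero_margin_named(self):
        with pytest.raises(DegenerateDataError, match="column"):
            chi_square_association([[5, 0], [7, 0]])

    def test_yates_differs_on_2x2(self):
        table = [[20, 10], [10, 20]]
        assert chi_square_association(table, yates=True)[0] < chi_square_association(table)[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_sweep(self, seed):
        rng = np.random.default_rng(200 + seed)
        table = rng.integers(1, 10, size=(2, 2))
        chi2, _ = chi_square_association(table)
        assert chi2 == pytest.approx(_chi2_oracle(table), abs=1e-10)


# ---------------------------------------------------------------------------
# inflection detection
# ---------------------------------------------------------------------------

class TestDetectInflection:
    def test_noiseless_break_at_66_exact(self):
        L, H = simulate_hinge_hgi(300, seed=1, noise_sd=0.0)
        result = detect_inflection(L, H)
        assert result.inflection_days == 66.0
        assert result.slope_pre == pytest.approx(0.0563, abs=1e-9)
        assert result.slope_post == pytest.approx(0.0, abs=1e-9)
        assert result.sse <= min(result.candidate_profile.values()) + 1e-15

    def test_globally_linear_flagged_immaterial(self, rng):
        L = rng.uniform(45, 110, size=200)
        H = 0.01 * L - 1.0
        result = detect_inflection(L, H)
        assert not result.material
        assert result.sse_improvement < 0.01

    def test_constant_data_ties_pick_smallest_candidate(self, rng):
        L = rng.uniform(40, 120, size=100)
        H = np.zeros(100)
        result = detect_inflection(L, H, grid=[50, 60, 70])
        assert result.inflection_days == 50.0
        assert not result.material

    def test_shift_equivariance_noiseless(self):
        L, H = simulate_hinge_hgi(250, seed=5, noise_sd=0.0)
        base = detect_inflection(L, H, grid=np.arange(50, 100))
        shifted = detect_inflection(L + 7, H, grid=np.arange(50, 100) + 7)
        assert shifted.inflection_days == base.inflection_days + 7

    def test_default_cohort_recovery_within_3_days(self):
        cfg = SyntheticCohortConfig(n_patients=5000, seed=42)
        records = simulate_cohort(cfg)
        L = [r.rbc_lifespan_days for r in records]
        H = [r.hba1c_pct - estimated_hba1c(r.ag_mmol_L) for r in records]
        result = detect_inflection(L, H)
        assert abs(result.inflection_days - 66.0) <= 3.0

    def test_grid_outside_data_range(self, rng):
        L = rng.uniform(45, 110, size=50)
        with pytest.raises(DataValidationError, match="grid"):
            detect_inflection(L, np.zeros(50), grid=[150, 160])

    def test_too_few_points(self):
        with pytest.raises(DataValidationError, match="20 points"):
            detect_inflection([50.0] * 10, [0.0] * 10)

    def test_spline_fit_present_with_4_knots(self):
        L, H = simulate_hinge_hgi(500, seed=2)
        result = detect_inflection(L, H)
        assert result.spline is not None
        assert len(result.spline.knots) == 4
        # spline prediction should track the hinge structure loosely
        pred = result.spline.predict([50.0, 100.0])
        assert pred[0] < pred[1]


# ---------------------------------------------------------------------------
# correction model fitting
# ---------------------------------------------------------------------------

class TestFitCorrectionModel:
    def test_zero_noise_short_recovery(self, models):
        short = models[LifespanGroup.SHORT]
        records = make_exact_cohort(short, 200, seed=11, lifespan_range=(40, 66))
        fit = fit_correction_model(records, LifespanGroup.SHORT)
        assert fit.beta_lifespan == pytest.approx(-0.05629, abs=1e-6)
        assert fit.beta_hba1c == pytest.approx(1.127, abs=1e-6)
        assert fit.intercept == pytest.approx(3.178, abs=1e-6)
        assert fit.multiple_r == pytest.approx(1.0, abs=1e-9)
        assert fit.f_pvalue < 0.05

    def test_zero_noise_mid_recovery(self, models):
        mid = models[LifespanGroup.MID]
        records = make_exact_cohort(mid, 200, seed=12, lifespan_range=(67, 89))
        fit = fit_correction_model(records, LifespanGroup.MID)
        assert fit.beta_lifespan == pytest.approx(-0.004772, abs=1e-6)
        assert fit.beta_hba1c == pytest.approx(0.7569, abs=1e-6)
        assert fit.intercept == pytest.approx(2.394, abs=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        # 12 noisy points; oracle solves (X'X) beta = X'y directly
        lifespan = rng.uniform(40, 66, size=12)
        hba1c = rng.uniform(5, 11, size=12)
        e = 0.3 - 0.02 * lifespan + 0.9 * hba1c + rng.normal(0, 0.2, size=12)
        records = [
            make_record(i, hba1c=float(hba1c[i]), ag=float(ag_from_ehba1c(e[i])),
                        lifespan=float(lifespan[i]))
            for i in range(12)
        ]
        fit = fit_correction_model(records, LifespanGroup.SHORT)
        X = np.column_stack([np.ones(12), lifespan, hba1c])
        e_back = np.array([estimated_hba1c(r.ag_mmol_L) for r in records])
        beta = np.linalg.solve(X.T @ X, X.T @ e_back)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.beta_lifespan == pytest.approx(beta[1], abs=1e-8)
        assert fit.beta_hba1c == pytest.approx(beta[2], abs=1e-8)

    def test_residual_orthogonality(self, rng):
        lifespan = rng.uniform(40, 66, size=200)
        hba1c = rng.uniform(5, 11, size=200)
        e = 1.0 - 0.03 * lifespan + 0.8 * hba1c + rng.normal(0, 0.3, size=200)
        records = [
            make_record(i, hba1c=float(hba1c[i]), ag=float(ag_from_ehba1c(e[i])),
                        lifespan=float(lifespan[i]))
            for i in range(200)
        ]
        fit = fit_correction_model(records, LifespanGroup.SHORT)
        resid = e - (fit.intercept + fit.beta_lifespan * lifespan + fit.beta_hba1c * hba1c)
        for col in (np.ones(200), lifespan, hba1c):
            assert abs(resid @ col) < 1e-8 * 200

    def test_singular_design(self):
        records = [
            make_record(i, hba1c=6 + 0.1 * i, ag=8.0, lifespan=60.0) for i in range(12)
        ]
        with pytest.raises(DegenerateDataError, match="singular"):
            fit_correction_model(records, LifespanGroup.SHORT)

    def test_too_few_records(self):
        records = [make_record(i, lifespan=60.0) for i in range(5)]
        with pytest.raises(DataValidationError, match=">= 10"):
            fit_correction_model(records, LifespanGroup.SHORT)

    def test_normal_group_not_fittable(self):
        with pytest.raises(Exception):
            fit_correction_model([], LifespanGroup.NORMAL)

    @pytest.mark.parametrize("target", ["beta_lifespan", "beta_hba1c", "intercept"])
    def test_recovery_rmse_shrinks_with_n(self, target, models):
        truth = {
            "beta_lifespan": -0.05629, "beta_hba1c": 1.127, "intercept": 3.178,
        }[target]
        rmses = []
        for n in (200, 2000, 20000):
            errs = []
            for seed in range(20):
                cfg = SyntheticCohortConfig(
                    n_patients=n, seed=seed, group_proportions=(1.0, 0.0, 0.0)
                )
                fit = fit_correction_model(simulate_cohort(cfg), LifespanGroup.SHORT)
                errs.append(getattr(fit, target) - truth)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]


# ---------------------------------------------------------------------------
# proportions and odds ratios
# ---------------------------------------------------------------------------

class TestProportionReport:
    def test_printed_construction_counts(self):
        groups = (
            [LifespanGroup.SHORT] * 80
            + [LifespanGroup.MID] * 138
            + [LifespanGroup.NORMAL] * 198
        )
        report = proportion_report(groups)
        assert report["SHORT"]["percent"] == 19.23
        assert report["MID"]["percent"] == 33.17
        assert report["NORMAL"]["percent"] == 47.60
        assert report["BELOW_90"]["percent"] == 52.40
        assert report["total"] == 416

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            proportion_report([])


class TestOddsRatio:
    def test_balanced(self):
        r = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_arithmetic(self):
        assert odds_ratio(ContingencyTable2x2(50, 50, 25, 50)).odds_ratio == pytest.approx(2.0)

    def test_ci_matches_log_variance_oracle(self):
        r = odds_ratio(ContingencyTable2x2(40, 40, 20, 40))
        lo, hi = _woolf_ci_oracle(40, 40, 20, 40)
        assert r.ci_low == pytest.approx(lo, abs=1e-10)
        assert r.ci_high == pytest.approx(hi, abs=1e-10)

    def test_ordering_invariant(self):
        r = odds_ratio(ContingencyTable2x2(7, 13, 3, 21))
        assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert r.ci_low > 0

    def test_haldane_correction_flagged(self):
        r = odds_ratio(ContingencyTable2x2(0, 10, 5, 10))
        assert r.continuity_corrected
        assert r.odds_ratio > 0

    def test_zero_diagonal_undefined(self):
        with pytest.raises(DegenerateDataError, match="diagonal"):
            odds_ratio(ContingencyTable2x2(0, 10, 5, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(DataValidationError):
            ContingencyTable2x2(-1, 10, 5, 5)
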