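"""Slope t-test: closed forms, brute-force oracles, and calibration.

The regression is checked against a dense grid-search least-squares
oracle, the t tail probability against numerical integration of the t
density, and the test's calibration against the exact binomial interval
for its rejection rate under the null.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from liberality.errors import (
    InsufficientDataError,
    PerfectFitWarning,
    ValidationError,
    ZeroVarianceError,
)
from liberality.io import SampleSheet
from liberality.stats import (
    fit_slope,
    run_paper_contrasts,
    slope_tests_to_frame,
    student_t_two_sided_p,
)


def t_density(x: float, df: float) -> float:
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    return np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))


def two_sided_p_by_quadrature(t: float, df: float) -> float:
    tail, _ = quad(t_density, abs(t), np.inf, args=(df,))
    return 2.0 * tail


def grid_search_ols(x, y, beta_hat, intercept_hat, halfwidth=0.5, steps=201):
    """Dense (slope, intercept) grid around the fit; returns the SSE
    minimizer. Independent of the centered-sums algebra under test."""
    betas = np.linspace(beta_hat - halfwidth, beta_hat + halfwidth, steps)
    intercepts = np.linspace(intercept_hat - halfwidth, intercept_hat + halfwidth, steps)
    B, A = np.meshgrid(betas, intercepts, indexing="ij")
    sse = ((y[None, None, :] - A[..., None] - B[..., None] * x[None, None, :]) ** 2).sum(
        axis=-1
    )
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return betas[i], intercepts[j]


class TestStudentT:
    def test_cauchy_closed_form(self):
        assert student_t_two_sided_p(1.0, 1) == pytest.approx(0.5, abs=1e-12)

    def test_t_zero_gives_one(self):
        for df in (1, 2, 5, 30):
            assert student_t_two_sided_p(0.0, df) == 1.0

    def test_symmetry(self):
        assert student_t_two_sided_p(2.5, 7) == pytest.approx(
            student_t_two_sided_p(-2.5, 7), abs=1e-15
        )

    def test_df2_closed_form(self):
        t = 1.51186
        expected = 2 * (1 - (0.5 + t / (2 * np.sqrt(2) * np.sqrt(1 + t * t / 2))))
        assert student_t_two_sided_p(t, 2) == pytest.approx(expected, abs=1e-6)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValidationError):
            student_t_two_sided_p(1.0, 0)

    @pytest.mark.parametrize("df", list(range(1, 31)))
    def test_agrees_with_numerical_integration(self, df):
        for t in (0.1, 0.7, 1.5, 3.0, 6.0, 10.0):
            assert student_t_two_sided_p(t, df) == pytest.approx(
                two_sided_p_by_quadrature(t, df), abs=1e-8
            )


class TestFitSlope:
    def test_hand_computed_case(self):
        fit = fit_slope([0, 1, 2, 3], [1, 2, 1, 4])
        assert fit.beta_hat == pytest.approx(0.8, abs=1e-12)
        assert fit.intercept_hat == pytest.approx(0.8, abs=1e-12)
        assert fit.se_beta == pytest.approx(np.sqrt(0.28), abs=1e-9)
        assert fit.t_stat == pytest.approx(0.8 / np.sqrt(0.28), abs=1e-9)
        assert fit.df == 2
        assert fit.p_two_sided == pytest.approx(0.2696, abs=2e-4)

    def test_constant_y_no_signal(self):
        fit = fit_slope([0, 1, 2], [3.0, 3.0, 3.0])
        assert fit.beta_hat == 0.0
        assert fit.t_stat == 0.0
        assert fit.p_two_sided == 1.0
        assert not fit.perfect_fit

    def test_perfect_fit_flag_and_warning(self):
        with pytest.warns(PerfectFitWarning):
            fit = fit_slope([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert fit.perfect_fit
        assert fit.p_two_sided == 0.0
        assert fit.beta_hat == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ZeroVarianceError):
            fit_slope([2, 2, 2], [1, 2, 3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_slope([0, 1], [1, 2])

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(3, 9)
            x = rng.normal(0, 1, n)
            while np.ptp(x) == 0:
                x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            fit = fit_slope(x, y)
            beta_grid, _ = grid_search_ols(x, y, fit.beta_hat, fit.intercept_hat)
            # the grid contains beta_hat exactly at its center; the oracle
            # must not find a strictly better SSE elsewhere
            assert abs(beta_grid - fit.beta_hat) <= 1e-8

    def test_affine_equivariance(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        base = fit_slope(x, y)
        shifted = fit_slope(x, y + 7.5)
        assert shifted.beta_hat == pytest.approx(base.beta_hat, abs=1e-12)
        assert shifted.t_stat == pytest.approx(base.t_stat, abs=1e-9)
        assert shifted.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)
        scaled = fit_slope(x, 3.0 * y)
        assert scaled.beta_hat == pytest.approx(3.0 * base.beta_hat, abs=1e-9)
        assert scaled.se_beta == pytest.approx(3.0 * base.se_beta, abs=1e-9)
        assert scaled.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)

    def test_power_monotone_in_effect_size(self, rng):
        """Rejection rate at alpha=0.05 is non-decreasing in |beta|."""
        x = np.tile([0.0, 0.5, 1.0], 3)
        reps = 2000
        rates = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            noise = rng.normal(0, 1, (reps, x.size))
            hits = sum(
                fit_slope(x, beta * x + noise[r]).p_two_sided < 0.05
                for r in range(reps)
            )
            rates.append(hits / reps)
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestRunPaperContrasts:
    @staticmethod
    def _sheet_and_results(entropies, doses, strain="p50"):
        rows, res = [], []
        for i, (h, d) in enumerate(zip(entropies, doses), start=1):
            sid = f"S{i:02d}"
            rows.append(
                {
                    "sample_id": sid,
                    "strain": strain,
                    "treatment": "control" if d == 0 else "mulberry",
                    "dose": d,
                    "time_h": 90.0,
                }
            )
            res.append({"sample_id": sid, "H_bits": h})
        return pd.DataFrame(res), SampleSheet(pd.DataFrame(rows))

    def test_negative_dose_effect_recovered(self, rng):
        doses = [0.0] * 3 + [0.001] * 3 + [0.01] * 3
        entropies = [10.5 - 40.0 * d + rng.normal(0, 0.01) for d in doses]
        results, sheet = self._sheet_and_results(entropies, doses)
        fit = run_paper_contrasts(results, sheet, covariate="dose",
                                  treatments=("control", "mulberry"))
        assert fit.beta_hat < 0
        assert fit.n == 9 and fit.df == 7

    def test_single_dose_level_rejected(self, rng):
        doses = [0.01] * 4
        results, sheet = self._sheet_and_results([10, 10.1, 10.2, 9.9], doses)
        with pytest.raises(ZeroVarianceError):
            run_paper_contrasts(results, sheet, covariate="dose")

    def test_join_mismatch_lists_ids(self, rng):
        results, sheet = self._sheet_and_results([10.0, 10.1, 9.9], [0, 0.001, 0.01])
        results.loc[0, "sample_id"] = "GHOST"
        with pytest.raises(ValidationError, match="GHOST"):
            run_paper_contrasts(results, sheet)

    def test_treatment_filter_excludes_other_arms(self, rng):
        doses = [0.0] * 3 + [0.001] * 3 + [0.01] * 3
        entropies = [10.0 - 30 * d + rng.normal(0, 0.02) for d in doses]
        results, sheet = self._sheet_and_results(entropies, doses)
        sheet_df = sheet.data.copy()
        # add a midgut arm that must not enter the dose regression
        extra = pd.DataFrame(
            [{"sample_id": "S99", "strain": "p50", "treatment": "midgut",
              "dose": 0.1, "time_h": 90.0}]
        )
        sheet2 = SampleSheet(pd.concat([sheet_df, extra], ignore_index=True))
        res2 = pd.concat(
            [results, pd.DataFrame([{"sample_id": "S99", "H_bits": 5.0}])],
            ignore_index=True,
        )
        fit = run_paper_contrasts(res2, sheet2, covariate="dose",
                                  treatments=("control", "mulberry"))
        assert fit.n == 9

    def test_log_dose_encoding(self, rng):
        doses = [0.0] * 3 + [0.001] * 3 + [0.01] * 3
        entropies = [10.0 - 30 * d + rng.normal(0, 0.02) for d in doses]
        results, sheet = self._sheet_and_results(entropies, doses)
        fit = run_paper_contrasts(results, sheet, encoding="log10", log_offset=1e-4)
        assert fit.covariate_encoding == "log10"
        assert np.isfinite(fit.p_two_sided)

    def test_null_time_course_p_roughly_uniform(self, rng):
        """With no true time effect, p-values over repeated simulated time
        courses (0/12/24/48 h) are approximately uniform."""
        times = np.repeat([0.0, 12.0, 24.0, 48.0], 3)
        reps = 400
        pvals = []
        for _ in range(reps):
            y = 10.0 + rng.normal(0, 0.05, times.size)
            pvals.append(fit_slope(times, y).p_two_sided)
        pvals = np.array(pvals)
        # KS-free coarse check on quartile occupancy
        for lo in (0.0, 0.25, 0.5, 0.75):
            frac = ((pvals >= lo) & (pvals < lo + 0.25)).mean()
            assert abs(frac - 0.25) < 0.08

    def test_output_frame_schema(self, rng):
        doses = [0.0] * 3 + [0.001] * 3 + [0.01] * 3
        entropies = [10.0 - 30 * d + rng.normal(0, 0.02) for d in doses]
        results, sheet = self._sheet_and_results(entropies, doses)
        fit = run_paper_contrasts(results, sheet, name="p50-dose")
        frame = slope_tests_to_frame([fit])
        assert list(frame["contrast_name"]) == ["p50-dose"]
        for col in ("n", "beta_hat", "se_beta", "t_stat", "df", "p_two_sided"):
            assert col in frame.columns
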