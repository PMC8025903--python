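"""Two-way ANOVA decomposition, absolute-agreement ICC, interpretation
bands, and rank consistency — checked against independent brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ments import (DegenerateDataError, RatingMatrix, anova_decompose,
                   icc_absolute_agreement, interpret_icc, per_site_icc,
                   rank_agreement)

# fixed 6 cases x 2 raters fixture (totals on the instrument scale)
FIXTURE_6X2 = np.array([
    [30.0, 32.0],
    [34.0, 33.0],
    [40.0, 44.0],
    [25.0, 26.0],
    [38.0, 35.0],
    [29.0, 31.0],
])


def anova_oracle(x):
    """Sum-of-squares decomposition by explicit double loops."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((row[i] - grand) ** 2 for i in range(n))
    ss_cols = n * sum((col[j] - grand) ** 2 for j in range(k))
    ss_err = sum((x[i][j] - row[i] - col[j] + grand) ** 2
                 for i in range(n) for j in range(k))
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_oracle(x):
    n, k = x.shape
    msr, msc, mse = anova_oracle(x)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestAnova:
    def test_identical_columns_leave_no_rater_or_residual_variance(self):
        x = np.tile([[30.0], [40.0], [35.0]], (1, 2))
        d = anova_decompose(RatingMatrix.from_values(x))
        assert d.ms_cols == pytest.approx(0.0)
        assert d.ms_error == pytest.approx(0.0)
        assert d.ms_rows > 0

    def test_constant_matrix_all_zero(self):
        d = anova_decompose(RatingMatrix.from_values(np.full((4, 2), 33.0)))
        assert (d.ms_rows, d.ms_cols, d.ms_error) == (0.0, 0.0, 0.0)

    def test_degrees_of_freedom(self):
        d = anova_decompose(RatingMatrix.from_values(FIXTURE_6X2))
        assert (d.df_rows, d.df_cols, d.df_error) == (5, 1, 5)

    def test_fixture_matches_double_loop_oracle(self):
        d = anova_decompose(RatingMatrix.from_values(FIXTURE_6X2))
        msr, msc, mse = anova_oracle(FIXTURE_6X2)
        assert d.ms_rows == pytest.approx(msr, abs=1e-12)
        assert d.ms_cols == pytest.approx(msc, abs=1e-12)
        assert d.ms_error == pytest.approx(mse, abs=1e-12)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            RatingMatrix.from_values([[1.0, 2.0]])
        with pytest.raises(ValueError):
            RatingMatrix.from_values([[1.0], [2.0]])


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.tile([[30.0], [40.0], [35.0], [22.0]], (1, 2))
        res = icc_absolute_agreement(RatingMatrix.from_values(x))
        assert res.estimate == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_systematic_offset_is_penalized(self):
        base = FIXTURE_6X2.copy()
        prev = icc_absolute_agreement(RatingMatrix.from_values(base)).estimate
        for c in (2.0, 5.0, 10.0):
            shifted = base.copy()
            shifted[:, 1] += c
            est = icc_absolute_agreement(RatingMatrix.from_values(shifted)).estimate
            assert est < prev
            prev = est

    def test_fixture_matches_oracle(self):
        res = icc_absolute_agreement(RatingMatrix.from_values(FIXTURE_6X2))
        assert res.estimate == pytest.approx(icc_oracle(FIXTURE_6X2), abs=1e-10)

    def test_200_random_matrices_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            k = int(rng.integers(2, 5))
            x = rng.normal(30, 6, (n, k)) + rng.normal(0, 2, (n, 1))
            est = icc_absolute_agreement(RatingMatrix.from_values(x)).estimate
            assert est == pytest.approx(icc_oracle(x), abs=1e-10)
            assert est <= 1.0 + 1e-12

    def test_matches_pingouin_reference(self):
        """Cross-check the ICC(2,1) estimate against an independent
        implementation on the fixture matrix."""
        import pandas as pd
        import pingouin as pg

        n, k = FIXTURE_6X2.shape
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": FIXTURE_6X2.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_est = float(ref.loc[mask, "ICC"].iloc[0])
        est = icc_absolute_agreement(RatingMatrix.from_values(FIXTURE_6X2)).estimate
        assert est == pytest.approx(ref_est, abs=1e-9)

    def test_invariance_under_shift_and_positive_scaling(self):
        base = icc_absolute_agreement(RatingMatrix.from_values(FIXTURE_6X2)).estimate
        shifted = icc_absolute_agreement(
            RatingMatrix.from_values(FIXTURE_6X2 + 17.0)).estimate
        scaled = icc_absolute_agreement(
            RatingMatrix.from_values(FIXTURE_6X2 * 2.5)).estimate
        assert shifted == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_constant_matrix_is_undefined_not_zero(self):
        with pytest.raises(DegenerateDataError):
            icc_absolute_agreement(RatingMatrix.from_values(np.full((5, 2), 33.0)))

    def test_average_measure_exceeds_single(self):
        m = RatingMatrix.from_values(FIXTURE_6X2)
        single = icc_absolute_agreement(m, measure="single").estimate
        average = icc_absolute_agreement(m, measure="average").estimate
        assert average > single


class TestBands:
    @pytest.mark.parametrize("estimate,band", [
        (0.72, "good"),
        (0.73, "good"),
        (0.65, "good"),
        (0.77, "excellent"),
        (0.75, "excellent"),
        (0.10, "poor"),
        (0.399, "poor"),
        (0.40, "fair"),
        (0.59, "fair"),
        (0.60, "good"),
        (1.0, "excellent"),
        (-0.2, "poor"),
    ])
    def test_cicchetti_bands(self, estimate, band):
        assert interpret_icc(estimate) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            interpret_icc(float("nan"))


class TestPerSite:
    @staticmethod
    def _sheets_for(rubric, site, n, noise_p, seed):
        from ments import CohortConfig, RaterNoiseModel, generate_cohort, \
            simulate_rater_pair
        cfg = CohortConfig.default(n=n, seed=seed)
        cases = [c.replace(site_id=site) for c in generate_cohort(cfg)]
        att, tr = simulate_rater_pair(
            rubric, cases, RaterNoiseModel(noise_p, seed=seed))
        # re-key case ids per site to keep them unique when pooled
        att = [type(s)(**{**s.__dict__, "case_id": f"{site}-{s.case_id}"})
               for s in att]
        tr = [type(s)(**{**s.__dict__, "case_id": f"{site}-{s.case_id}"})
              for s in tr]
        sites = {s.case_id: site for s in att}
        return att + tr, sites

    def test_noisier_site_scores_lower(self, rubric):
        quiet, sites_q = self._sheets_for(rubric, "Q", 60, 0.05, 11)
        noisy, sites_n = self._sheets_for(rubric, "N", 60, 0.60, 12)
        res = per_site_icc(quiet + noisy, {**sites_q, **sites_n})
        assert res.by_site["Q"].estimate > res.by_site["N"].estimate

    def test_pooled_equals_stacked_matrix(self, rubric):
        sheets_a, sites_a = self._sheets_for(rubric, "A", 30, 0.2, 3)
        sheets_b, sites_b = self._sheets_for(rubric, "B", 30, 0.2, 4)
        all_sheets = sheets_a + sheets_b
        res = per_site_icc(all_sheets, {**sites_a, **sites_b})
        stacked = icc_absolute_agreement(RatingMatrix.from_sheets(all_sheets))
        assert res.pooled.estimate == pytest.approx(stacked.estimate, abs=1e-12)

    def test_site_with_single_pair_reported_insufficient(self, rubric):
        sheets, sites = self._sheets_for(rubric, "A", 20, 0.2, 5)
        lone, lone_sites = self._sheets_for(rubric, "B", 2, 0.2, 6)
        # keep only one complete pair at site B
        lone = [s for s in lone if s.case_id.endswith("C0001")]
        lone_sites = {s.case_id: "B" for s in lone}
        res = per_site_icc(sheets + lone, {**sites, **lone_sites})
        assert res.by_site["B"] is None
        assert res.n_pairs["B"] == 0
        assert res.by_site["A"] is not None


class TestRankAgreement:
    def test_identity_is_one(self):
        r = list(range(1, 11))
        assert rank_agreement(r, r) == 1.0

    def test_reversal_of_ten_is_point_two(self):
        # |i - (11 - i)| <= 2 only for ranks 5 and 6 -> 2/10
        a = list(range(1, 11))
        b = list(range(10, 0, -1))
        assert rank_agreement(a, b) == pytest.approx(0.2)

    def test_difference_of_exactly_two_counts_as_consistent(self):
        a = [1, 2, 3, 4, 5]
        b = [3, 4, 5, 1, 2]  # non-wrapping items differ by exactly 2
        frac = rank_agreement(a, b, tolerance=2)
        assert frac == pytest.approx(3 / 5)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            rank_agreement([1, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            rank_agreement([1, 2, 3], [1, 2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_symmetric_and_saturates_at_full_tolerance(self, data):
        n = data.draw(st.integers(2, 12))
        a = data.draw(st.permutations(range(1, n + 1)))
        b = data.draw(st.permutations(range(1, n + 1)))
        tol = data.draw(st.integers(0, n))
        assert rank_agreement(a, b, tol) == rank_agreement(b, a, tol)
        assert rank_agreement(a, b, tolerance=n - 1) == 1.0
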