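"""Per-protein regression, BH adjustment and the selection filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rppaflow import (
    ScreenThresholds,
    ValidationError,
    adjust_fdr,
    fit_protein_regression,
    generate_rppa_timeseries,
    normalize_to_baseline,
    run_screen,
    select_candidates,
)

from .conftest import bh_oracle, ols_oracle


class TestFitProteinRegression:
    def test_exact_colinearity(self):
        rec = fit_protein_regression("p", [1, 2, 3], [2, 4, 6])
        assert rec.slope == pytest.approx(2.0)
        assert rec.intercept == pytest.approx(0.0)
        assert rec.r == pytest.approx(1.0)
        assert rec.p_slope < 1e-8

    def test_anticorrelation(self):
        rec = fit_protein_regression("p", [1, 2, 3], [3, 2, 1])
        assert rec.r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closed_form_oracle(self, seed):
        """Slope, intercept, r and p agree with textbook OLS formulas to 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        x = rng.normal(1.0, 0.5, n)
        y = 0.5 + 1.3 * x + rng.normal(0, 0.3, n)
        rec = fit_protein_regression("p", x, y)
        b, a, r, p = ols_oracle(x, y)
        assert rec.slope == pytest.approx(b, abs=1e-9)
        assert rec.intercept == pytest.approx(a, abs=1e-9)
        assert rec.r == pytest.approx(r, abs=1e-9)
        assert rec.p_slope == pytest.approx(p, abs=1e-9)

    def test_r_squared_equals_coefficient_of_determination(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = 2 * x + rng.normal(size=8)
        rec = fit_protein_regression("p", x, y)
        yhat = rec.intercept + rec.slope * x
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert rec.r**2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)

    def test_sign_of_r_matches_slope(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rec = fit_protein_regression("p", x, y)
            if rec.slope != 0:
                assert np.sign(rec.r) == np.sign(rec.slope)

    def test_zero_variance_is_flagged_not_fatal(self):
        rec = fit_protein_regression("p", [1, 1, 1], [1, 2, 3])
        assert rec.degenerate
        assert rec.p_slope == 1.0
        assert np.isnan(rec.r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fit_protein_regression("p", [1, 2, 3], [1, 2])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_protein_regression("p", [1, 2], [1, 2])


class TestAdjustFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_cases(self, p, expected):
        np.testing.assert_allclose(adjust_fdr(p), expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 60)))
        np.testing.assert_allclose(adjust_fdr(p), bh_oracle(p), atol=1e-9)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_q_at_least_p_and_monotone(self, p):
        q = adjust_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_fdr([0.5, 1.5])

    def test_fdr_controlled_on_uniform_nulls(self):
        """BH at level 0.3 keeps P(any false call) near 0.3 under the global null."""
        rng = np.random.default_rng(0)
        any_call = [
            (adjust_fdr(rng.uniform(size=100)) < 0.3).any() for _ in range(400)
        ]
        rate = np.mean(any_call)
        assert rate <= 0.3 + 1.96 * np.sqrt(0.3 * 0.7 / 400)


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "q, r, selected",
        [
            (0.2, 0.8, True),
            (0.2, 0.69, False),  # fails the correlation filter
            (0.31, 0.95, False),  # fails the FDR filter
            (0.2, 1.0, True),  # upper bound inclusive
            (0.2, 0.7, False),  # lower bound strict
            (0.3, 0.8, False),  # FDR bound strict
        ],
    )
    def test_threshold_boundaries(self, q, r, selected):
        from rppaflow import ScreenRecord

        rec = ScreenRecord("p", slope=1.0, intercept=0.0, p_slope=0.01, r=r, q=q)
        select_candidates([rec])
        assert rec.selected is selected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ScreenThresholds(fdr_max=1.5)
        with pytest.raises(ValidationError):
            ScreenThresholds(r_min=0.9, r_max=0.7)


class TestRunScreen:
    def test_noiseless_planted_all_perfect(self):
        """With zero noise every planted protein attains |r| = 1 and a floor p-value."""
        a, b, truth = generate_rppa_timeseries(
            seed=11, n_proteins=10, n_planted=10, noise_sd=0.0
        )
        res = run_screen(normalize_to_baseline(a), normalize_to_baseline(b))
        for rec in res.records:
            assert abs(rec.r) == pytest.approx(1.0, abs=1e-9)
            assert rec.p_slope < 1e-8

    def test_order_invariance(self):
        """Permuting protein order permutes screen outputs identically."""
        a, b, _ = generate_rppa_timeseries(seed=2, n_proteins=30, n_planted=5)
        na, nb = normalize_to_baseline(a), normalize_to_baseline(b)
        base = {r.protein_id: (r.q, r.selected) for r in run_screen(na, nb).records}
        perm = np.random.default_rng(0).permutation(na.protein_ids)
        na2 = na.with_values(na.values.loc[perm])
        nb2 = nb.with_values(nb.values.loc[perm])
        shuffled = {r.protein_id: (r.q, r.selected) for r in run_screen(na2, nb2).records}
        assert base == shuffled

    def test_mismatched_panels_rejected(self):
        a, b, _ = generate_rppa_timeseries(seed=2, n_proteins=10, n_planted=2)
        na, nb = normalize_to_baseline(a), normalize_to_baseline(b)
        nb_short = nb.with_values(nb.values.iloc[:-1])
        with pytest.raises(ValidationError):
            run_screen(na, nb_short)

    def test_summary_counts(self):
        a, b, _ = generate_rppa_timeseries(seed=4, n_proteins=40, n_planted=10)
        res = run_screen(normalize_to_baseline(a), normalize_to_baseline(b))
        s = res.summary()
        assert s["n_tested"] == 40
        assert s["n_selected"] == sum(r.selected for r in res.records)
        assert s["fdr_method"] == "benjamini-hochberg"
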