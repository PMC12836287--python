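"""Statistical harness: exact tests, corrections, LOO validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dosemimic.validation_stats import (
    Contrast,
    build_comparison_table,
    fisher_exact,
    friedman,
    holm_bonferroni,
    leave_one_out,
    mann_whitney_u,
    wilcoxon_signed_rank,
)


def holm_oracle(pvalues, alpha=0.05):
    """Literal step-down enumeration of the Holm procedure."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    reject = [False] * m
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    adjusted = [0.0] * m
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adjusted[idx] = running
    return adjusted, reject


class TestFisherExact:
    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            # oracle: enumerate every table with the observed margins
            a, b = int(t[0, 0]), int(t[0, 1])
            c, d = int(t[1, 0]), int(t[1, 1])
            n, r1, c1 = t.sum(), a + b, a + c
            p_obs = sps.hypergeom.pmf(a, n, r1, c1)
            total = 0.0
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                pk = sps.hypergeom.pmf(k, n, r1, c1)
                if pk <= p_obs * (1 + 1e-7):
                    total += pk
            assert fisher_exact(t) == pytest.approx(min(total, 1.0), abs=1e-12)

    def test_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact(t) == pytest.approx(
                float(sps.fisher_exact(t)[1]), abs=1e-10
            )

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact([[0, 0], [3, 5]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        _, p, method = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        assert method == "degenerate"

    def test_separated_samples_exact_enumeration(self):
        u, p, method = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert method == "exact"
        # C(6,3) = 20 equally likely rank splits; 2 are this extreme
        assert p == pytest.approx(2 / 20)

    def test_symmetry_in_sample_order(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 6)
        _, p_xy, _ = mann_whitney_u(x, y)
        _, p_yx, _ = mann_whitney_u(y, x)
        assert p_xy == pytest.approx(p_yx)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        # W = 0; exact two-sided p = 2 / 2^6 = 0.03125
        w, p, method = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert w == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.03125)

    def test_zero_differences_dropped(self):
        _, p, method = wilcoxon_signed_rank([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        assert method == "degenerate"


class TestFriedman:
    def test_identical_conditions_give_zero_statistic(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        stat, p = friedman(m)
        assert stat == 0.0
        assert p == 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(8, 4))
        stat, _ = friedman(m)
        for perm in itertools.permutations(range(4)):
            stat_p, _ = friedman(m[:, perm])
            assert stat_p == pytest.approx(stat)

    def test_shape_preconditions(self):
        with pytest.raises(ValueError):
            friedman(np.zeros((1, 3)))


class TestHolmBonferroni:
    def test_step_down_example(self):
        adjusted, reject = holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        # 0.01 <= 0.05/3 rejected; 0.03 > 0.05/2 stops the cascade
        np.testing.assert_array_equal(reject, [True, False, False])
        assert adjusted[0] == pytest.approx(0.03)

    def test_all_ones_nothing_rejected(self):
        adjusted, reject = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(adjusted, 1.0)

    def test_single_small_p_rejected(self):
        _, reject = holm_bonferroni([0.04])
        assert reject[0]

    def test_empty_input(self):
        adjusted, reject = holm_bonferroni([])
        assert adjusted.size == 0 and reject.size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_enumeration_oracle(self, pvals):
        adjusted, reject = holm_bonferroni(pvals)
        oracle_adj, oracle_rej = holm_oracle(pvals)
        np.testing.assert_allclose(adjusted, oracle_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, oracle_rej)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_rejections_monotone_in_p(self, pvals):
        _, reject = holm_bonferroni(pvals)
        for i, j in itertools.permutations(range(len(pvals)), 2):
            if pvals[i] < pvals[j] and reject[j]:
                assert reject[i]


class TestComparisonTable:
    def _arm(self, rng, shift=0.0, n=10):
        return pd.DataFrame(
            {
                "metric_a": rng.normal(5 + shift, 1, n),
                "metric_b": rng.normal(20, 2, n),
            }
        )

    def test_identical_cohorts_nothing_significant(self):
        rng = np.random.default_rng(4)
        base = self._arm(rng)
        cohorts = {"x": base, "y": base.copy()}
        table = build_comparison_table(
            cohorts, [Contrast("x_vs_y", "x", "y", paired=True)]
        )
        assert not table["significant_x_vs_y"].any()

    def test_large_shift_detected_after_correction(self):
        rng = np.random.default_rng(5)
        cohorts = {
            "x": self._arm(rng),
            "y": self._arm(rng, shift=10.0),
        }
        table = build_comparison_table(
            cohorts, [Contrast("x_vs_y", "x", "y", paired=True)]
        )
        assert bool(table.loc["metric_a", "significant_x_vs_y"])

    def test_unpaired_contrast_uses_mann_whitney(self):
        rng = np.random.default_rng(6)
        cohorts = {"x": self._arm(rng, n=8), "y": self._arm(rng, shift=2, n=11)}
        table = build_comparison_table(
            cohorts, [Contrast("x_vs_y", "x", "y", paired=False)]
        )
        assert table["test_x_vs_y"].str.startswith("mann-whitney").all()
        assert set(table.index) == {"metric_a", "metric_b"}

    def test_row_and_column_structure(self):
        rng = np.random.default_rng(7)
        cohorts = {"a": self._arm(rng), "b": self._arm(rng)}
        table = build_comparison_table(
            cohorts, [Contrast("c", "a", "b", paired=False)]
        )
        for col in ("a_mean", "a_sd", "b_mean", "b_sd", "p_c"):
            assert col in table.columns

    def test_mismatched_pairing_rejected(self):
        rng = np.random.default_rng(8)
        cohorts = {"a": self._arm(rng, n=10), "b": self._arm(rng, n=7)}
        with pytest.raises(ValueError, match="paired"):
            build_comparison_table(
                cohorts, [Contrast("c", "a", "b", paired=True)]
            )


class TestLeaveOneOut:
    def test_too_few_cases_rejected(self, coarse_cohort):
        with pytest.raises(ValueError, match="at least 3"):
            leave_one_out(coarse_cohort.cases[:2])

    def test_identical_cohort_recovers_every_case(self, coarse_template, coarse_spec):
        from dosemimic.phantom_synth import synth_dose
        from dosemimic.volumes_io import PatientCase

        dose = synth_dose(coarse_template, coarse_spec)
        cases = [
            PatientCase(
                id=f"c{i}",
                ct=coarse_template.ct,
                dose=dose,
                structures=coarse_template.structures,
            )
            for i in range(3)
        ]
        loo = leave_one_out(cases)
        assert len(loo.cases) == 3
        for r in loo.cases:
            assert r.dsc_2gy >= 0.99
            assert r.mean_abs_error_gy <= 0.5
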