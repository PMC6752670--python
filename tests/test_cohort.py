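"""Exact 2x2 inference: Fisher point-probability p, CMLE odds ratio, bounds."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from mosaicmap import (
    CohortAssociation,
    ContingencyTable,
    fisher_two_sided,
    or_cmle,
    or_exact_bound,
    rate_summary,
)

COHORT_TABLE = ContingencyTable(3, 15, 2, 451)


def brute_force_p(t: ContingencyTable) -> Fraction:
    """Independent oracle: enumerate every 2x2 table with the observed
    margins; weight each by the multinomial coefficient n!/(a!b!c!d!)
    (proportional to its conditional probability) and sum, exactly."""
    r1, r2, c1, c2 = t.margins
    n = r1 + r2
    fact = [math.factorial(i) for i in range(n + 1)]

    def weight(a):
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        if min(b, c, d) < 0:
            return None
        return fact[n] // (fact[a] * fact[b] * fact[c] * fact[d])

    weights = [(a, weight(a)) for a in range(min(r1, c1) + 1)]
    weights = [(a, w) for a, w in weights if w is not None]
    w_obs = dict(weights)[t.a]
    return Fraction(sum(w for _, w in weights if w <= w_obs),
                    sum(w for _, w in weights))


class TestFisher:
    def test_cohort_table_p_value(self):
        """Sex comparison of mosaicism rates: p to 4 significant figures."""
        assert fisher_two_sided(COHORT_TABLE) == pytest.approx(
            0.0004492, rel=5e-4)

    def test_symmetric_table(self):
        assert fisher_two_sided(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_matches_enumeration_oracle(self):
        t = ContingencyTable(2, 3, 4, 5)
        assert fisher_two_sided(t) == pytest.approx(
            float(brute_force_p(t)), abs=1e-14)

    def test_matches_scipy(self):
        for cells in [(3, 15, 2, 451), (5, 5, 5, 5), (0, 10, 3, 7),
                      (8, 2, 1, 9), (1, 0, 0, 1)]:
            t = ContingencyTable(*cells)
            assert fisher_two_sided(t) == pytest.approx(
                fisher_exact([[t.a, t.b], [t.c, t.d]])[1], rel=1e-10)

    def test_degenerate_margin(self, caplog):
        assert fisher_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    def test_transpose_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(t.transpose()), abs=1e-12)


class TestOddsRatio:
    def test_cohort_table_cmle(self):
        """Exact CMLE for the sex comparison (43.50; published software
        prints 43.47 under its looser root tolerance)."""
        psi, flag = or_cmle(COHORT_TABLE)
        assert flag == ""
        assert psi == pytest.approx(43.5028, abs=5e-4)

    def test_matches_scipy_conditional(self):
        for cells in [(3, 15, 2, 451), (5, 5, 2, 8), (7, 3, 4, 6)]:
            psi, _ = or_cmle(ContingencyTable(*cells))
            ref = scipy_odds_ratio([[cells[0], cells[1]], [cells[2], cells[3]]],
                                   kind="conditional").statistic
            assert psi == pytest.approx(ref, rel=1e-6)

    def test_no_association(self):
        psi, _ = or_cmle(ContingencyTable(1, 1, 1, 1))
        assert psi == pytest.approx(1.0, abs=1e-8)

    def test_boundary_unbounded(self):
        psi, flag = or_cmle(ContingencyTable(5, 0, 0, 5))
        assert math.isinf(psi) and flag == "boundary_high"
        psi, flag = or_cmle(ContingencyTable(0, 5, 5, 0))
        assert psi == 0.0 and flag == "boundary_low"

    def test_score_equation_residual(self):
        """E[X | psi_hat] equals the observed cell to < 1e-6."""
        from mosaicmap.cohort import _conditional_mean, _support_weights

        for cells in [(3, 15, 2, 451), (4, 6, 3, 7), (9, 1, 2, 8)]:
            t = ContingencyTable(*cells)
            psi, _ = or_cmle(t)
            xs, w = _support_weights(t)
            logw = np.array([math.log(v) for v in w])
            assert abs(_conditional_mean(math.log(psi), xs, logw) - t.a) < 1e-6

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(1, 10), st.integers(1, 10),
           st.integers(1, 10), st.integers(1, 10))
    def test_transpose_inverts_psi(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        psi, flag = or_cmle(t)
        swapped, flag2 = or_cmle(ContingencyTable(b, a, d, c))
        if flag or flag2:
            return
        assert psi * swapped == pytest.approx(1.0, rel=1e-6)


class TestExactBounds:
    def test_cohort_one_sided_lower(self):
        """One-sided exact 95% lower bound on the odds ratio is 6.33."""
        lo = or_exact_bound(COHORT_TABLE, level=0.95, side="lower")
        assert lo == pytest.approx(6.33, abs=0.005)

    def test_matches_scipy_two_sided(self):
        t = ContingencyTable(7, 3, 4, 6)
        ref = scipy_odds_ratio([[7, 3], [4, 6]],
                               kind="conditional").confidence_interval(0.95)
        assert or_exact_bound(t, 0.975, "lower") == pytest.approx(ref.low, rel=1e-6)
        assert or_exact_bound(t, 0.975, "upper") == pytest.approx(ref.high, rel=1e-6)

    def test_null_table_bound_below_one(self):
        """Test-inversion oracle on a dense psi grid brackets the bound."""
        t = ContingencyTable(1, 1, 1, 1)
        lo = or_exact_bound(t, 0.95, "lower")
        assert lo < 1.0
        # dense-grid inversion: tail probability crosses 0.05 at the bound
        from mosaicmap.cohort import _support_weights, _tail_prob

        xs, w = _support_weights(t)
        logw = np.array([math.log(v) for v in w])
        grid = np.linspace(math.log(lo) - 0.05, math.log(lo) + 0.05, 401)
        tails = np.array([_tail_prob(g, xs, logw, t.a, upper=True) for g in grid])
        assert tails[0] < 0.05 < tails[-1]

    def test_zero_cell_lower_bound(self):
        assert or_exact_bound(ContingencyTable(0, 10, 5, 5), 0.95, "lower") == 0.0

    def test_bad_level(self):
        with pytest.raises(ValueError):
            or_exact_bound(COHORT_TABLE, 1.5, "lower")


class TestRates:
    @pytest.mark.parametrize("x,n,display", [
        (5, 471, "5/471 (1.1%)"),
        (3, 18, "3/18 (16.7%)"),
        (5, 21, "5/21 (23.8%)"),
        (0, 100, "0/100 (0.0%)"),
    ])
    def test_display_rounding(self, x, n, display):
        assert rate_summary(x, n).display == display

    def test_ci_is_exact_binomial(self):
        from scipy.stats import binomtest

        rs = rate_summary(5, 471)
        ref = binomtest(5, 471).proportion_ci(0.95, method="exact")
        assert rs.ci_low == pytest.approx(ref.low, rel=1e-9)
        assert rs.ci_high == pytest.approx(ref.high, rel=1e-9)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            rate_summary(0, 0)


class TestCohortAssociation:
    def test_fit_summary_and_dict(self):
        res = CohortAssociation(COHORT_TABLE).fit()
        d = res.to_dict()
        assert d["p_two_sided"] == pytest.approx(0.0004492, rel=5e-4)
        assert d["ci_one_sided_lower"] == pytest.approx(6.33, abs=0.005)
        assert d["ci_two_sided"][1] < math.inf  # two-sided interval is finite
        text = res.summary()
        assert "6.33" in text and "0.0004492" in text

    def test_from_cohort_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "sex": ["M"] * 18 + ["F"] * 453,
            "is_mosaic": [True] * 3 + [False] * 15 + [True] * 2 + [False] * 451,
        })
        model = CohortAssociation.from_cohort(df)
        assert model.table == COHORT_TABLE
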