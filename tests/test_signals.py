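"""Disproportionality estimators against independent formula oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitewatch.contingency import ContingencyTable
from bitewatch.signals import (
    BcpnnPriors,
    bcpnn_estimate,
    classify_signal,
    estimate_signals,
    ic_grade,
    mgps_estimate,
    prr_estimate,
    ror_estimate,
)

# ---------------------------------------------------------------------------
# Independent one-line oracles (deliberately separate code paths).

def oracle_ror(a, b, c, d):
    return (a / c) / (b / d)


def oracle_ror_ci(a, b, c, d):
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lr = math.log((a * d) / (b * c))
    return math.exp(lr - 1.96 * se), math.exp(lr + 1.96 * se)


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_prr_ci(a, b, c, d):
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lp = math.log(oracle_prr(a, b, c, d))
    return math.exp(lp - 1.96 * se), math.exp(lp + 1.96 * se)


def oracle_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    return math.log2(a * n / ((a + b) * (a + c)))


def oracle_ic025(a, b, c, d, a1=1.0, b1=1.0, al=2.0, be=2.0, g11=1.0):
    n = a + b + c + d
    g = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (a + b + a1) * (a + c + b1))
    )
    v = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    ) / math.log(2) ** 2
    return e_ic - 2 * math.sqrt(v)


def oracle_ebgm(a, b, c, d):
    n = a + b + c + d
    return a * n / ((a + c) * (a + b))


def oracle_ebgm05(a, b, c, d):
    return math.exp(
        math.log(oracle_ebgm(a, b, c, d))
        - 1.64 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    )


GRID = [
    (a, b, c, d)
    for a in (1, 2, 3, 7)
    for b in (1, 2, 5, 40)
    for c in (1, 3, 9, 97)
    for d in (1, 10, 100, 893, 10_000)
]


def test_oracle_equivalence_over_grid():
    """All estimators and bounds match independent formula evaluations
    to 1e-10 relative over a grid of small tables."""
    assert len(GRID) >= 300
    rel = 1e-10
    for a, b, c, d in GRID:
        t = ContingencyTable(a, b, c, d)
        ror, lo, hi = ror_estimate(t)
        assert ror == pytest.approx(oracle_ror(a, b, c, d), rel=rel)
        assert (lo, hi) == pytest.approx(oracle_ror_ci(a, b, c, d), rel=rel)
        prr, plo, phi, chi2 = prr_estimate(t)
        assert prr == pytest.approx(oracle_prr(a, b, c, d), rel=rel)
        assert (plo, phi) == pytest.approx(oracle_prr_ci(a, b, c, d), rel=rel)
        assert chi2 == pytest.approx(oracle_chi2(a, b, c, d), rel=rel, abs=1e-12)
        ic, ic025 = bcpnn_estimate(t)
        assert ic == pytest.approx(oracle_ic(a, b, c, d), rel=rel)
        assert ic025 == pytest.approx(oracle_ic025(a, b, c, d), rel=rel)
        ebgm, ebgm05 = mgps_estimate(t)
        assert ebgm == pytest.approx(oracle_ebgm(a, b, c, d), rel=rel)
        assert ebgm05 == pytest.approx(oracle_ebgm05(a, b, c, d), rel=rel)


class TestFrozenExamples:
    """Hand-evaluated values for the (3, 7, 97, 893) and symmetric tables."""

    T = ContingencyTable(3, 7, 97, 893)
    SYM = ContingencyTable(10, 10, 10, 10)

    def test_ror(self):
        ror, lo, _ = ror_estimate(self.T)
        assert ror == pytest.approx(2679 / 679, rel=1e-12)
        assert ror_estimate(self.SYM)[0] == pytest.approx(1.0)
        assert ror_estimate(self.SYM)[1] == pytest.approx(
            math.exp(-1.96 * math.sqrt(0.4)), rel=1e-12
        )

    def test_prr_and_chi2(self):
        prr, _, _, chi2 = prr_estimate(self.T)
        assert prr == pytest.approx(297 / 97, rel=1e-12)
        assert chi2 == pytest.approx(
            1000 * (2679 - 679) ** 2 / (10 * 990 * 100 * 900), rel=1e-12
        )
        sym_prr, _, _, sym_chi2 = prr_estimate(self.SYM)
        assert sym_prr == pytest.approx(1.0)
        assert sym_chi2 == pytest.approx(0.0, abs=1e-12)

    def test_ic(self):
        ic, _ = bcpnn_estimate(self.T)
        assert ic == pytest.approx(math.log2(3), rel=1e-12)
        sym_ic, sym_ic025 = bcpnn_estimate(self.SYM)
        assert sym_ic == pytest.approx(0.0, abs=1e-12)
        # prior-based lower bound on a tiny symmetric table is negative
        assert sym_ic025 == pytest.approx(-0.9707024, abs=1e-6)

    def test_ebgm(self):
        ebgm, ebgm05 = mgps_estimate(self.T)
        assert ebgm == pytest.approx(3.0, rel=1e-12)
        assert ebgm05 == pytest.approx(0.95447, abs=1e-4)
        assert mgps_estimate(self.SYM)[0] == pytest.approx(1.0)


@given(
    st.integers(1, 500),
    st.integers(1, 500),
    st.integers(1, 500),
    st.integers(1, 5000),
)
@settings(deadline=None, derandomize=True, max_examples=150)
def test_ic_equals_log2_ebgm(a, b, c, d):
    """Point IC and EBGM are log/plain forms of the same ratio."""
    t = ContingencyTable(a, b, c, d)
    ic, _ = bcpnn_estimate(t)
    ebgm, _ = mgps_estimate(t)
    assert ic == pytest.approx(math.log2(ebgm), rel=1e-12)


@given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 2000))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_independence_tables_are_null(c, d, scale):
    """Exact independence (a/(a+b) = c/(c+d)) gives ROR=PRR=EBGM=1, IC=0."""
    # top row is the bottom row scaled: a/b = c/d exactly
    a, b = c * scale, d * scale
    t = ContingencyTable(a, b, c, d)
    assert ror_estimate(t)[0] == pytest.approx(1.0, rel=1e-12)
    assert prr_estimate(t)[0] == pytest.approx(1.0, rel=1e-12)
    assert mgps_estimate(t)[0] == pytest.approx(1.0, rel=1e-12)
    assert bcpnn_estimate(t)[0] == pytest.approx(0.0, abs=1e-12)


@given(st.integers(1, 50), st.integers(1, 100), st.integers(1, 100), st.integers(1, 2000))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_point_estimates_increase_in_a(a, b, c, d):
    """Holding b, c, d fixed, ROR and PRR strictly increase in a.

    The observed/expected estimators (EBGM, hence IC) also grow both
    margins and N with a, so they are strictly increasing only when
    bc > a(a+1); on tiny tables they can plateau or even fall (e.g.
    (1,1,1,5) -> (3,1,1,5) takes EBGM from 2 to 1.875).
    """
    t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    assert ror_estimate(t2)[0] > ror_estimate(t1)[0]
    assert prr_estimate(t2)[0] > prr_estimate(t1)[0]
    if b * c > a * (a + 1):
        assert mgps_estimate(t2)[0] > mgps_estimate(t1)[0]
        assert bcpnn_estimate(t2)[0] > bcpnn_estimate(t1)[0]


class TestEvaluability:
    def test_zero_cell_ror_non_evaluable(self):
        assert all(math.isnan(x) for x in ror_estimate(ContingencyTable(0, 5, 5, 5)))

    def test_zero_a_keeps_ic025(self):
        ic, ic025 = bcpnn_estimate(ContingencyTable(0, 5, 5, 5))
        assert math.isnan(ic) and math.isfinite(ic025)

    def test_zero_cell_keeps_ebgm_point(self):
        ebgm, ebgm05 = mgps_estimate(ContingencyTable(3, 0, 5, 5))
        assert math.isfinite(ebgm) and math.isnan(ebgm05)

    def test_estimate_signals_marks_non_evaluable(self):
        est = estimate_signals(ContingencyTable(0, 5, 5, 5))
        assert not est.evaluable and not est.combined_pos


class TestCriteria:
    def test_a_below_three_blocks_ror_prr(self):
        # enormous disproportionality but only two cases
        t = ContingencyTable(2, 1, 1, 10_000)
        est = estimate_signals(t)
        assert est.ror > 100 and not est.ror_pos and not est.prr_pos

    def test_a_of_three_with_strong_signal_flags(self):
        est = estimate_signals(ContingencyTable(3, 1, 1, 10_000))
        assert est.ror_pos and est.prr_pos

    def test_negative_ic025_blocks_bcpnn(self):
        est = estimate_signals(ContingencyTable(10, 10, 10, 10))
        assert est.ic025 < 0 and not est.bcpnn_pos

    def test_combined_requires_all_four(self):
        strong = estimate_signals(ContingencyTable(60, 40, 100, 99_800))
        assert (
            strong.ror_pos
            and strong.prr_pos
            and strong.bcpnn_pos
            and strong.mgps_pos
            and strong.combined_pos
        )
        weak = estimate_signals(ContingencyTable(10, 10, 10, 10))
        assert not weak.combined_pos

    def test_yates_reduces_chi2(self):
        t = ContingencyTable(30, 70, 100, 800)
        assert prr_estimate(t, yates=True)[3] < prr_estimate(t)[3]

    @pytest.mark.parametrize(
        "ic025,grade",
        [
            (-0.1, "none"),
            (0.0, "none"),
            (0.01, "low"),
            (1.5, "low"),
            (1.51, "medium"),
            (3.0, "medium"),
            (3.2, "high"),
        ],
    )
    def test_ic_grade_boundaries(self, ic025, grade):
        assert ic_grade(ic025) == grade

    def test_ebgm05_boundary_strict(self):
        """EBGM05 exactly 2 is not a signal; the criterion is strictly >2."""
        from dataclasses import replace
        t = ContingencyTable(10, 10, 10, 10)
        est = estimate_signals(t)
        est2 = replace(est, ebgm05=2.0)
        assert not classify_signal(t, est2).mgps_pos
        est3 = replace(est, ebgm05=2.0001)
        assert classify_signal(t, est3).mgps_pos

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha1=0)
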