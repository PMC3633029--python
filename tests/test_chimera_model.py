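import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcdiv import chimera_model as cm
from gcdiv.types import ChimeraMix, ScoringThresholds, SectionGeometry

from oracles import enumerate_section_probs


class TestBasicExpectedFractions:
    def test_table1_reference_B_column(self, paper_mix):
        # n fixed by inverting the observed pure-B fraction 0.06
        n = cm.invert_founders(0.06, 0.21)
        t = cm.basic_expected_fractions(n, paper_mix)
        assert round(100 * t.f_A, 1) == 65.4
        assert round(100 * t.f_Mix, 1) == 28.6

    def test_single_founder_is_pure(self):
        mix = ChimeraMix(p=0.3)
        t = cm.basic_expected_fractions(1, mix)
        assert t.f_Mix == pytest.approx(0.0, abs=1e-15)
        assert t.f_A == mix.q
        assert t.f_B == mix.p

    def test_symmetric_two_founders(self):
        t = cm.basic_expected_fractions(2, ChimeraMix(p=0.5))
        assert t.as_tuple() == pytest.approx((0.25, 0.25, 0.5))

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            cm.basic_expected_fractions(0, ChimeraMix(p=0.2))

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            ChimeraMix(p=1.2)

    @given(
        n=st.floats(min_value=0.1, max_value=20),
        p=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_components_sum_to_one(self, n, p):
        t = cm.basic_expected_fractions(n, ChimeraMix(p=p))
        assert t.total == pytest.approx(1.0, abs=1e-12)
        assert -1e-12 <= t.f_A <= 1 + 1e-12
        assert -1e-12 <= t.f_B <= 1 + 1e-12


class TestInvertFounders:
    def test_paper_n_A(self):
        assert cm.invert_founders(0.14, 0.79) == pytest.approx(8.34, abs=0.01)
        assert round(cm.invert_founders(0.14, 0.79)) == 8

    def test_paper_n_B(self):
        assert cm.invert_founders(0.06, 0.21) == pytest.approx(1.80, abs=0.01)
        assert round(cm.invert_founders(0.06, 0.21)) == 2

    def test_identity(self):
        assert cm.invert_founders(0.37, 0.37) == pytest.approx(1.0)

    @pytest.mark.parametrize("f,base", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0), (-0.1, 0.5), (0.5, 1.5)])
    def test_domain_errors(self, f, base):
        with pytest.raises(ValueError):
            cm.invert_founders(f, base)

    def test_round_trip_with_basic_model(self):
        mix = ChimeraMix(p=0.3)
        t = cm.basic_expected_fractions(5, mix)
        assert cm.invert_founders(t.f_A, mix.q) == pytest.approx(5.0, abs=1e-10)


class TestPureSectionProbs:
    # frozen from the exhaustive enumeration oracle:
    # C(2,1)*0.21*0.79 * 55/210 with r = s = 5 in a 10-cell GC, 4-cell sections
    ENUM_VALUE = 0.0869

    def test_k_zero_is_q_to_n(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        got = cm.pure_A_section_prob(3, 0, paper_mix, small_geom, thr)
        assert got == pytest.approx(paper_mix.q**3, abs=1e-14)

    def test_k_n_is_p_to_n(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        got = cm.pure_B_section_prob(3, 3, paper_mix, small_geom, thr)
        assert got == pytest.approx(paper_mix.p**3, abs=1e-14)

    def test_enumeration_example_A(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        got = cm.pure_A_section_prob(2, 1, paper_mix, small_geom, thr)
        assert got == pytest.approx(self.ENUM_VALUE, abs=1e-12)

    def test_enumeration_example_B_symmetric(self, small_geom, paper_mix):
        # r = s = 5 makes the two directions symmetric
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        got = cm.pure_B_section_prob(2, 1, paper_mix, small_geom, thr)
        assert got == pytest.approx(self.ENUM_VALUE, abs=1e-12)

    def test_whole_gc_section_cannot_hide_cells(self, paper_mix):
        geom = SectionGeometry(M=8, m=8)
        thr = ScoringThresholds(l_TA=2, l_TB=0)
        assert cm.pure_A_section_prob(2, 1, paper_mix, geom, thr) == 0.0

    def test_whole_gc_section_pure_B_zero(self, paper_mix):
        geom = SectionGeometry(M=8, m=8)
        thr = ScoringThresholds(l_TA=0, l_TB=2)
        assert cm.pure_B_section_prob(2, 1, paper_mix, geom, thr) == 0.0

    def test_k_out_of_range(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        with pytest.raises(ValueError):
            cm.pure_A_section_prob(2, 3, paper_mix, small_geom, thr)

    def test_degenerate_thresholds_rejected(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=2, l_TB=2)  # sum >= m = 4
        with pytest.raises(ValueError):
            cm.pure_A_section_prob(2, 1, paper_mix, small_geom, thr)

    def test_unknown_rounding_mode(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        with pytest.raises(ValueError):
            cm.pure_A_section_prob(2, 1, paper_mix, small_geom, thr, r_mode="up")


class TestFixedNFractions:
    def test_enumeration_example(self, small_geom, paper_mix):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        t = cm.fixed_n_fractions(2, paper_mix, small_geom, thr)
        assert t.f_A == pytest.approx(0.7110, abs=1e-12)
        assert t.f_B == pytest.approx(0.1310, abs=1e-12)
        assert t.f_Mix == pytest.approx(0.1580, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 10])
    @pytest.mark.parametrize("p", [0.1, 0.21, 0.5])
    def test_reduces_to_basic_model(self, n, p):
        """m = M with zero thresholds removes sampling and scoring error."""
        mix = ChimeraMix(p=p)
        geom = SectionGeometry(M=40, m=40)
        thr = ScoringThresholds(l_TA=0, l_TB=0)
        ext = cm.fixed_n_fractions(n, mix, geom, thr)
        basic = cm.basic_expected_fractions(n, mix)
        assert ext.f_A == pytest.approx(basic.f_A, abs=1e-12)
        assert ext.f_B == pytest.approx(basic.f_B, abs=1e-12)
        assert ext.f_Mix == pytest.approx(basic.f_Mix, abs=1e-12)

    @pytest.mark.parametrize("n,p,l_TA,l_TB", [
        (2, 0.21, 1, 1),
        (3, 0.5, 0, 1),
        (4, 0.3, 1, 0),
    ])
    def test_sums_to_one(self, small_geom, n, p, l_TA, l_TB):
        t = cm.fixed_n_fractions(n, ChimeraMix(p=p), small_geom,
                                 ScoringThresholds(l_TA=l_TA, l_TB=l_TB))
        assert t.total == pytest.approx(1.0, abs=1e-12)

    def test_rejects_real_n(self, small_geom, paper_mix):
        with pytest.raises(ValueError):
            cm.fixed_n_fractions(2.5, paper_mix, small_geom,
                                 ScoringThresholds(l_TA=1, l_TB=1))

    def test_monotone_in_l_TB(self, paper_mix):
        """Allowing more overlooked type-B cells can only grow f_A."""
        geom = SectionGeometry(M=60, m=12)
        prev = -1.0
        for l_TB in range(0, 6):
            t = cm.fixed_n_fractions(4, paper_mix, geom,
                                     ScoringThresholds(l_TA=2, l_TB=l_TB))
            assert t.f_A >= prev - 1e-14
            prev = t.f_A


ORACLE_CONFIGS = [
    # (M, m, n, p, l_TA, l_TB)
    (6, 3, 1, 0.21, 1, 1),
    (6, 3, 2, 0.5, 0, 0),
    (8, 4, 2, 0.21, 1, 2),
    (10, 4, 2, 0.21, 1, 1),
    (10, 5, 3, 0.3, 2, 2),
    (10, 3, 4, 0.7, 1, 0),
    (12, 6, 2, 0.21, 2, 2),
    (12, 4, 3, 0.5, 0, 2),
    (12, 2, 4, 0.1, 1, 0),
    (7, 7, 2, 0.4, 2, 2),
]


@pytest.mark.parametrize("M,m,n,p,l_TA,l_TB", ORACLE_CONFIGS)
def test_oracle_equivalence(M, m, n, p, l_TA, l_TB):
    """Analytic per-k probabilities and triples match exhaustive enumeration."""
    mix = ChimeraMix(p=p)
    geom = SectionGeometry(M=M, m=m)
    thr = ScoringThresholds(l_TA=l_TA, l_TB=l_TB)
    P_A, P_B, triple = enumerate_section_probs(M, m, n, p, l_TA, l_TB)
    for k in range(n + 1):
        assert cm.pure_A_section_prob(n, k, mix, geom, thr) == pytest.approx(
            P_A[k], abs=1e-12
        )
        assert cm.pure_B_section_prob(n, k, mix, geom, thr) == pytest.approx(
            P_B[k], abs=1e-12
        )
    t = cm.fixed_n_fractions(n, mix, geom, thr)
    assert t.as_tuple() == pytest.approx(triple, abs=1e-12)


class TestPoissonFractions:
    def test_normalization(self, paper_mix):
        geom = SectionGeometry(M=50, m=10)
        thr = ScoringThresholds(l_TA=3, l_TB=1)
        for lam in (0.5, 2.0, 8.0, 25.0):
            t = cm.poisson_fractions(lam, paper_mix, geom, thr)
            assert t.total == pytest.approx(1.0 - math.exp(-lam), abs=1e-11)

    def test_small_lambda_dominated_by_single_founder(self, paper_mix):
        geom = SectionGeometry(M=30, m=30)
        thr = ScoringThresholds(l_TA=0, l_TB=0)
        lam = 1e-4
        t = cm.poisson_fractions(lam, paper_mix, geom, thr)
        scale = 1.0 - math.exp(-lam)
        assert t.f_A / scale == pytest.approx(paper_mix.q, rel=1e-3)
        assert t.f_B / scale == pytest.approx(paper_mix.p, rel=1e-3)
        assert t.f_Mix / scale == pytest.approx(0.0, abs=1e-3)

    def test_rejects_nonpositive_lambda(self, paper_mix, small_geom):
        with pytest.raises(ValueError):
            cm.poisson_fractions(0.0, paper_mix, small_geom,
                                 ScoringThresholds(l_TA=1, l_TB=1))

    def test_matches_direct_mixture(self, paper_mix):
        """Independent re-summation of Poisson-weighted fixed-n triples."""
        from scipy import stats

        geom = SectionGeometry(M=20, m=6)
        thr = ScoringThresholds(l_TA=2, l_TB=1)
        lam = 4.0
        direct = np.zeros(3)
        for n in range(1, 80):
            t = cm.fixed_n_fractions(n, paper_mix, geom, thr)
            direct += stats.poisson.pmf(n, lam) * np.array(t.as_tuple())
        got = cm.poisson_fractions(lam, paper_mix, geom, thr)
        assert got.as_tuple() == pytest.approx(tuple(direct), abs=1e-10)

    def test_F_A_decreasing_in_lambda_paper_config(self, paper_mix, paper_geom):
        # between lambda = 1 and 2 the n >= 1 Poisson mass is still growing,
        # so the unnormalized F_A rises briefly; it is strictly decreasing
        # from lambda = 2 on, which covers the whole fitting range
        thr = ScoringThresholds.from_percent(62, 10, paper_geom.m)
        lams = np.arange(2, 61)
        f_A = [cm.poisson_fractions(lam, paper_mix, paper_geom, thr).f_A
               for lam in lams]
        assert np.all(np.diff(f_A) < 0)


class TestFindLambdaCrossing:
    def test_round_trip(self, paper_mix):
        geom = SectionGeometry(M=200, m=20)
        thr = ScoringThresholds(l_TA=0, l_TB=2)
        target = cm.poisson_fractions(5.0, paper_mix, geom, thr).f_A
        # start the bracket past the small-lambda rise of the unnormalized F_A
        lam = cm.find_lambda_crossing(target, paper_mix, geom, thr,
                                      bracket=(3.0, 100.0))
        assert lam == pytest.approx(5.0, abs=1e-4)

    def test_matches_grid_evaluation(self, paper_mix):
        """The crossing agrees with a direct bracketing on a lambda grid."""
        geom = SectionGeometry(M=200, m=20)
        thr = ScoringThresholds(l_TA=0, l_TB=0)
        target = 0.3
        lam = cm.find_lambda_crossing(target, paper_mix, geom, thr,
                                      bracket=(3.0, 100.0))
        grid = np.linspace(lam - 0.5, lam + 0.5, 11)
        f = np.array([cm.poisson_fractions(g, paper_mix, geom, thr).f_A
                      for g in grid])
        assert f[0] > target > f[-1]

    def test_unbracketed_target(self, paper_mix, small_geom):
        thr = ScoringThresholds(l_TA=1, l_TB=1)
        with pytest.raises(ValueError):
            cm.find_lambda_crossing(0.9999, paper_mix, small_geom, thr)


class TestNumericalStability:
    def test_hypergeometric_tables_within_unit_interval(self):
        for threshold in (0, 20, 124):
            table = cm._hyp_cdf_table(5000, 200, threshold)
            assert np.all(table >= 0.0)
            assert np.all(table <= 1.0 + 1e-9)

    def test_r_rounding_convention_is_minor_at_fit_scale(self, paper_mix, paper_geom):
        """floor/nearest/ceil for r = kM/n barely move the model at M = 5000."""
        thr = ScoringThresholds.from_percent(62, 10, paper_geom.m)
        triples = {
            mode: cm.poisson_fractions(19.0, paper_mix, paper_geom, thr, r_mode=mode)
            for mode in ("floor", "nearest", "ceil")
        }
        for mode in ("floor", "ceil"):
            assert triples[mode].f_A == pytest.approx(
                triples["nearest"].f_A, rel=0.02
            )
            assert triples[mode].f_B == pytest.approx(
                triples["nearest"].f_B, rel=0.05
            )
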