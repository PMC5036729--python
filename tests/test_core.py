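import math

import pytest
from hypothesis import given

from ifcr.core import (
    SUM_TOL,
    CrossRatioIFV,
    IFVConstraintError,
    IFVDomainError,
    INDIFFERENT,
    OddsPair,
    complement,
    from_odds,
    make_ifv,
    oplus,
    otimes,
    power,
    scalar_mul,
    to_odds,
)

from .conftest import (
    assert_pair_close,
    fuzzy_ifvs,
    ifvs,
    lams,
    law_lams,
    oracle_oplus,
    oracle_otimes,
    oracle_power,
    oracle_scalar_mul,
)


class TestMakeIFV:
    def test_indifference_value(self):
        a = make_ifv(0.5, 0.5)
        assert a == INDIFFERENT

    def test_fraction_strings_parsed_exactly(self):
        a = make_ifv("5/8", "1/5")
        assert a.membership == 0.625
        assert a.nonmembership == 0.2

    def test_sum_above_one_rejected(self):
        with pytest.raises(IFVConstraintError):
            make_ifv(0.9, 0.2)

    def test_boundary_component_rejected(self):
        with pytest.raises(IFVDomainError):
            make_ifv(0.0, 0.5)
        with pytest.raises(IFVDomainError):
            make_ifv(0.5, 1.0)

    def test_nan_rejected(self):
        with pytest.raises(IFVDomainError):
            make_ifv(float("nan"), 0.5)

    def test_sum_tolerance(self):
        # just inside the tolerance is accepted
        a = make_ifv(0.5, 0.5 + 0.5 * SUM_TOL)
        assert a.membership == 0.5

    def test_clamp_mode_accepts_boundary(self):
        a = make_ifv(0.0, 0.5, clamp=True)
        assert 0.0 < a.membership < 1e-8
        with pytest.raises(IFVDomainError):
            make_ifv(-0.1, 0.5, clamp=True)

    def test_hesitancy_derived(self):
        assert make_ifv(0.3, 0.3).hesitancy == pytest.approx(0.4)
        assert make_ifv(0.6, 0.4).hesitancy == 0.0


class TestComplement:
    def test_swaps_components(self):
        assert complement(make_ifv("5/8", "1/5")) == make_ifv("1/5", "5/8")

    def test_fixed_point(self):
        assert complement(INDIFFERENT) == INDIFFERENT

    @given(ifvs())
    def test_involution(self, a):
        assert complement(complement(a)) == a


class TestOdds:
    def test_known_values(self):
        o = to_odds(make_ifv(0.9, 0.1))
        assert o.odds_membership == pytest.approx(9.0, rel=1e-12)
        assert o.odds_nonmembership == pytest.approx(1 / 9, rel=1e-12)
        assert to_odds(INDIFFERENT) == OddsPair(1.0, 1.0)

    def test_from_odds(self):
        a = from_odds(OddsPair(3.0, 1 / 3))
        assert a.membership == pytest.approx(0.75, rel=1e-12)
        assert a.nonmembership == pytest.approx(0.25, rel=1e-12)

    def test_nonpositive_odds_rejected(self):
        with pytest.raises(IFVDomainError):
            OddsPair(0.0, 1.0)
        with pytest.raises(IFVDomainError):
            OddsPair(1.0, -2.0)

    def test_odds_product_constraint(self):
        with pytest.raises(IFVConstraintError):
            OddsPair(9.0, 1.0)  # would mean sum > 1

    @given(ifvs())
    def test_round_trip(self, a):
        b = from_odds(to_odds(a))
        assert math.isclose(b.membership, a.membership, rel_tol=1e-12)
        assert math.isclose(b.nonmembership, a.nonmembership, rel_tol=1e-12)


class TestOplus:
    def test_indifferent_pair(self):
        # odds add: 1 + 1 = 2 -> 2/3; harmonic(1, 1) = 1/2 -> 1/3
        assert_pair_close(oplus(INDIFFERENT, INDIFFERENT), (2 / 3, 1 / 3))

    def test_frozen_example(self):
        # odds 1.5 + 7/3 = 23/6 -> value 23/29;
        # harmonic(3/7, 1/4) = odds 3/19 -> value 3/22
        got = oplus(make_ifv(0.6, 0.3), make_ifv(0.7, 0.2))
        assert_pair_close(got, (23 / 29, 3 / 22))
        assert round(got.membership, 5) == 0.79310
        assert round(got.nonmembership, 5) == 0.13636

    @given(ifvs(), ifvs())
    def test_commutative(self, a, b):
        assert_pair_close(
            oplus(a, b),
            (oplus(b, a).membership, oplus(b, a).nonmembership),
        )

    @given(ifvs(), ifvs())
    def test_matches_oracle(self, a, b):
        assert_pair_close(oplus(a, b), oracle_oplus(a, b))


class TestOtimes:
    @given(ifvs())
    def test_neutral_element(self, a):
        assert_pair_close(otimes(INDIFFERENT, a), (a.membership, a.nonmembership))

    def test_frozen_example(self):
        # odds multiply: 1.5 * 7/3 = 3.5 -> 7/9; (3/7)(1/4) = 3/28 -> 3/31
        got = otimes(make_ifv(0.6, 0.3), make_ifv(0.7, 0.2))
        assert_pair_close(got, (7 / 9, 3 / 31))
        assert round(got.membership, 5) == 0.77778
        assert round(got.nonmembership, 5) == 0.09677

    def test_inverse_pair(self):
        got = otimes(make_ifv(0.9, 0.1), make_ifv(0.1, 0.9))
        assert_pair_close(got, (0.5, 0.5))

    @given(ifvs(), ifvs())
    def test_commutative_and_oracle(self, a, b):
        assert_pair_close(otimes(a, b), oracle_otimes(a, b))
        assert_pair_close(otimes(b, a), oracle_otimes(a, b))


class TestScalarMul:
    @given(ifvs())
    def test_identity(self, a):
        assert_pair_close(scalar_mul(1.0, a), (a.membership, a.nonmembership))

    def test_doubling_indifference(self):
        assert_pair_close(scalar_mul(2.0, INDIFFERENT), (2 / 3, 1 / 3))

    def test_nonpositive_rejected(self):
        with pytest.raises(IFVDomainError):
            scalar_mul(0.0, INDIFFERENT)
        with pytest.raises(IFVDomainError):
            scalar_mul(-1.0, INDIFFERENT)

    @given(ifvs())
    def test_two_a_equals_a_plus_a(self, a):
        d = oplus(a, a)
        assert_pair_close(scalar_mul(2.0, a), (d.membership, d.nonmembership))

    @given(lams, ifvs())
    def test_matches_oracle(self, lam, a):
        assert_pair_close(scalar_mul(lam, a), oracle_scalar_mul(lam, a))

    @given(lams, ifvs())
    def test_accuracy_conserved(self, lam, a):
        # odds product is invariant under (lam*u, v/lam)
        oa, ob = to_odds(a), to_odds(scalar_mul(lam, a))
        assert math.isclose(
            oa.odds_membership * oa.odds_nonmembership,
            ob.odds_membership * ob.odds_nonmembership,
            rel_tol=1e-9,
        )


class TestPower:
    @given(ifvs())
    def test_identity(self, a):
        assert_pair_close(power(a, 1.0), (a.membership, a.nonmembership))

    def test_square_root_example(self):
        # odds 9^0.5 = 3 -> 3/4; (1/9)^0.5 = 1/3 -> 1/4
        assert_pair_close(power(make_ifv(0.9, 0.1), 0.5), (0.75, 0.25))

    def test_zero_exponent_is_neutral(self):
        assert power(make_ifv(0.7, 0.2), 0.0) == INDIFFERENT

    def test_negative_rejected(self):
        with pytest.raises(IFVDomainError):
            power(INDIFFERENT, -0.5)

    @given(ifvs())
    def test_square_equals_self_product(self, a):
        p = otimes(a, a)
        assert_pair_close(power(a, 2.0), (p.membership, p.nonmembership))

    @given(ifvs(), lams)
    def test_matches_oracle(self, a, lam):
        assert_pair_close(power(a, lam), oracle_power(a, lam))


class TestAlgebraicLaws:
    """Distributivity / exponent laws of the four operations.

    Composed expressions materialise intermediates as probabilities, which
    quantises the underlying log-odds, so the laws cannot hold to machine
    precision when an intermediate approaches the interval boundary; with
    components in [0.01, 0.99] and exponents up to 4 the error stays below
    1e-7 relative.
    """

    @given(law_lams, ifvs(0.01, 0.99), ifvs(0.01, 0.99))
    def test_scalar_distributes_over_oplus(self, lam, a, b):
        left = scalar_mul(lam, oplus(a, b))
        right = oplus(scalar_mul(lam, a), scalar_mul(lam, b))
        assert_pair_close(left, (right.membership, right.nonmembership),
                          rel=1e-7, abs_tol=1e-9)

    @given(law_lams, ifvs(0.01, 0.99), ifvs(0.01, 0.99))
    def test_power_distributes_over_otimes(self, lam, a, b):
        left = power(otimes(a, b), lam)
        right = otimes(power(a, lam), power(b, lam))
        assert_pair_close(left, (right.membership, right.nonmembership),
                          rel=1e-7, abs_tol=1e-9)

    @given(law_lams, law_lams, ifvs(0.01, 0.99))
    def test_scalar_sums(self, l1, l2, a):
        left = oplus(scalar_mul(l1, a), scalar_mul(l2, a))
        right = scalar_mul(l1 + l2, a)
        assert_pair_close(left, (right.membership, right.nonmembership),
                          rel=1e-7, abs_tol=1e-9)

    @given(law_lams, law_lams, ifvs(0.01, 0.99))
    def test_exponent_sums(self, l1, l2, a):
        left = otimes(power(a, l1), power(a, l2))
        right = power(a, l1 + l2)
        assert_pair_close(left, (right.membership, right.nonmembership),
                          rel=1e-7, abs_tol=1e-9)


class TestClosure:
    """Every operation returns a valid value (the constructor re-validates)."""

    @given(ifvs(), ifvs(), lams)
    def test_all_operations_closed(self, a, b, lam):
        for out in (oplus(a, b), otimes(a, b), scalar_mul(lam, a), power(a, lam)):
            assert 0.0 < out.membership < 1.0
            assert 0.0 < out.nonmembership < 1.0
            assert out.membership + out.nonmembership <= 1.0 + SUM_TOL

    @given(fuzzy_ifvs(), fuzzy_ifvs(), lams)
    def test_fuzzy_values_stay_fuzzy(self, a, b, lam):
        for out in (oplus(a, b), otimes(a, b), scalar_mul(lam, a), power(a, lam)):
            assert out.membership + out.nonmembership == pytest.approx(1.0, abs=1e-9)
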