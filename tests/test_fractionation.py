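"""Recovery identity, purity ratio, lookup and grid interpolation."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wheyfrac import (ExtrapolationError, NoMatchingConditionError,
                      ValidationError, interpolate_outcome, lookup_outcome,
                      purity_ratio, purity_report, recovery_from_composition,
                      round_half_away)
from wheyfrac.types import PROTEINS


class TestRecoveryFromComposition:
    @pytest.mark.parametrize("x_agg, Y, x_wpi, expected", [
        (0.610, 0.236, 0.1802, 0.79893),   # ~ the reported 80.1%
        (0.435, 0.404, 0.1802, 0.97527),   # ~ the reported 97.7%
    ])
    def test_reference_rows(self, x_agg, Y, x_wpi, expected):
        assert recovery_from_composition(x_agg, Y, x_wpi) == pytest.approx(
            expected, abs=1e-4)

    def test_full_recovery_identity(self):
        x, Y = 0.3, 0.5
        assert recovery_from_composition(x, Y, x * Y) == pytest.approx(1.0)

    def test_small_excess_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert recovery_from_composition(0.3, 0.5, 0.1480) == 1.0

    def test_large_excess_rejected(self):
        with pytest.raises(ValidationError):
            recovery_from_composition(0.3, 0.5, 0.10)

    def test_species_absent_from_feed(self):
        with pytest.raises(ValidationError):
            recovery_from_composition(0.3, 0.5, 0.0)


class TestPurityRatio:
    @pytest.mark.parametrize("rec_a, rec_b_liq, expected_1dp", [
        (0.801, 0.886, 7.0),
        (0.977, 0.632, 2.7),
    ])
    def test_reference_rows(self, rec_a, rec_b_liq, expected_1dp):
        assert round_half_away(purity_ratio(rec_a, 1 - rec_b_liq), 1) \
            == expected_1dp

    def test_equal_rates_give_unity(self):
        assert purity_ratio(0.4, 0.4) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            purity_ratio(0.8, 0.0)


def test_recomputed_purity_ratio_matches_reported_column(table):
    """For every row, rec_alpha/(1 - liquid beta recovery) is within 0.06
    (1-dp rounding of both inputs) of the reported purity-ratio column."""
    reported = [5.3, 5.1, 4.9, 7.0, 5.3, 6.3, 4.2, 3.2, 2.7, 4.1, 2.2]
    for o, printed in zip(table, reported):
        ratio = purity_ratio(o.recovery_solid["alpha_la"],
                             o.recovery_solid["beta_lg"])
        assert ratio == pytest.approx(printed, abs=0.06)


class TestLookup:
    def test_node_lookup(self, table):
        o = lookup_outcome(62, 10, 5.5, table)
        assert o.solid_yield == pytest.approx(0.224)
        assert o.solid_composition["alpha_la"] == pytest.approx(0.570)
        o5 = lookup_outcome(60, 5, 31.0, table)
        assert o5.solid_yield == pytest.approx(0.283)

    def test_outside_tolerance(self, table):
        with pytest.raises(NoMatchingConditionError, match="interpolate"):
            lookup_outcome(61, 10, 5.5, table)

    def test_backfilled_recoveries_are_flagged(self, table):
        o = lookup_outcome(60, 5, 8.3, table)
        assert "recovery_solid.minor" in o.derived_fields
        assert 0 < o.recovery_solid["minor"] <= 1


class TestInterpolation:
    @pytest.mark.parametrize("idx", range(11))
    def test_exact_at_every_node(self, table, idx):
        node = table[idx]
        o = interpolate_outcome(node.T, node.C_wpi, node.P, table)
        assert o.interpolated
        assert o.solid_yield == pytest.approx(node.solid_yield, abs=1e-9)
        assert o.ph == pytest.approx(node.ph, abs=1e-9)
        for k, v in node.solid_composition.items():
            assert o.solid_composition[k] == pytest.approx(v, abs=1e-9)

    def test_midpoint_bounded_by_endpoints(self, table):
        o = interpolate_outcome(60, 10, (8.3 + 31.0) / 2, table)
        assert 0.209 <= o.solid_yield <= 0.289

    def test_extrapolation_refused(self, table):
        with pytest.raises(ExtrapolationError):
            interpolate_outcome(59, 10, 8.3, table)
        with pytest.raises(ExtrapolationError):
            interpolate_outcome(60, 4, 8.3, table)

    @given(T=st.floats(60, 65), lp=st.floats(0, 1), w=st.floats(0, 1))
    def test_interpolant_within_node_range(self, table, T, lp, w):
        """Barycentric interpolation never leaves the span of node values."""
        P = float(np.exp(np.log(5.5) + lp * (np.log(31.0) - np.log(5.5))))
        # stay inside the 10 wt% plane hull: T free on [60, 65] only at
        # P >= 8.3 for the 5% plane, so query the 10% plane.
        try:
            o = interpolate_outcome(T, 10, P, table)
        except ExtrapolationError:
            return
        ys = [n.solid_yield for n in table if n.C_wpi == 10]
        assert min(ys) - 1e-9 <= o.solid_yield <= max(ys) + 1e-9
        for k in PROTEINS:
            rs = [n.recovery_solid.get(k) for n in table]
            rs = [r for r in rs if r is not None]
            if k in o.recovery_solid and rs:
                assert 0.0 <= o.recovery_solid[k] <= 1.0


def test_liquid_recovery_is_exact_complement(table):
    for o in table:
        for k in o.recovery_solid:
            assert o.recovery_solid[k] + o.recovery_liquid(k) == 1.0


def test_purity_report_fields(table):
    rep = purity_report(lookup_outcome(60, 5, 8.3, table))
    assert rep.alpha_purity == pytest.approx(0.610)
    assert rep.alpha_recovery == pytest.approx(0.801)
    assert rep.beta_recovery_liquid == pytest.approx(0.886)
    assert rep.purity_ratio == pytest.approx(0.801 / 0.114, rel=1e-9)
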