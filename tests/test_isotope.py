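"""Delta <-> atom percent conversions, excess, derivatization, pooling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulsetrace.isotope import (
    ExcessValue,
    FameRecord,
    IsotopeValue,
    atom_percent_excess,
    atom_percent_to_delta,
    correct_derivatization,
    delta_to_atom_percent,
    forward_derivatization,
    pool_group_enrichment,
)


class TestDeltaConversion:
    @pytest.mark.parametrize(
        "delta, element, expected",
        [
            # closed-form evaluation at the reference point delta = 0:
            # 100 * R_std / (1 + R_std)
            (0.0, "C", 100 * 0.0111802 / 1.0111802),
            (0.0, "N", 100 * 0.0036765 / 1.0036765),
        ],
    )
    def test_reference_point(self, delta, element, expected):
        assert delta_to_atom_percent(delta, element) == pytest.approx(expected, rel=1e-12)

    def test_reference_values_printed_precision(self):
        assert delta_to_atom_percent(0.0, "C") == pytest.approx(1.10566, abs=5e-6)
        assert delta_to_atom_percent(0.0, "N") == pytest.approx(0.36630, abs=5e-6)

    @given(st.floats(min_value=-950, max_value=50000), st.sampled_from(["C", "N"]))
    def test_round_trip_identity(self, delta, element):
        ap = delta_to_atom_percent(delta, element)
        assert atom_percent_to_delta(ap, element) == pytest.approx(delta, rel=1e-10, abs=1e-10)

    @given(
        st.floats(min_value=-900, max_value=10000),
        st.floats(min_value=1e-6, max_value=1000),
        st.sampled_from(["C", "N"]),
    )
    def test_strictly_increasing(self, delta, step, element):
        assert delta_to_atom_percent(delta + step, element) > delta_to_atom_percent(delta, element)

    def test_rejects_physically_impossible_delta(self):
        with pytest.raises(ValueError):
            delta_to_atom_percent(-1000.0, "C")

    def test_rejects_unknown_element(self):
        with pytest.raises(ValueError):
            delta_to_atom_percent(0.0, "O")

    def test_vectorised(self):
        out = delta_to_atom_percent(np.array([0.0, 100.0]), "C")
        assert out.shape == (2,) and out[1] > out[0]


class TestExcess:
    def test_sample_equals_baseline_gives_zero(self):
        v = IsotopeValue("C", -27.0)
        assert atom_percent_excess(v, v).atom_percent_excess == 0.0

    def test_subtraction_by_definition(self):
        s = IsotopeValue.from_atom_percent(1.30, "C")
        b = IsotopeValue.from_atom_percent(1.10, "C")
        assert atom_percent_excess(s, b).atom_percent_excess == pytest.approx(0.20, abs=1e-12)

    def test_element_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            atom_percent_excess(IsotopeValue("C", 0.0), IsotopeValue("N", 0.0))

    def test_negative_excess_retained_and_flagged(self):
        s = IsotopeValue("C", -30.0)
        b = IsotopeValue("C", -25.0)
        ev = atom_percent_excess(s, b)
        assert ev.atom_percent_excess < 0 and ev.is_negative


class TestDerivatization:
    def test_equal_delta_fixed_point(self):
        for c in (14, 16, 19):
            rec = FameRecord("x", c, delta_fame=-29.3, delta_meoh=-29.3)
            assert correct_derivatization(rec) == pytest.approx(-29.3, abs=1e-12)

    def test_hand_evaluated_example(self):
        rec = FameRecord("16:0", 16, delta_fame=100.0, delta_meoh=-29.3)
        assert correct_derivatization(rec) == pytest.approx(
            (17 * 100 - 1 * (-29.3)) / 16, abs=1e-12
        )
        assert correct_derivatization(rec) == pytest.approx(108.08125, abs=1e-10)

    @given(
        st.floats(min_value=-100, max_value=2000),
        st.integers(min_value=10, max_value=24),
        st.floats(min_value=-60, max_value=0),
    )
    def test_exact_inverse_of_forward_dilution(self, d_plfa, c_plfa, d_meoh):
        d_fame = forward_derivatization(d_plfa, c_plfa, d_meoh)
        rec = FameRecord("x", c_plfa, d_fame, d_meoh)
        assert correct_derivatization(rec) == pytest.approx(d_plfa, rel=1e-10, abs=1e-10)

    def test_nonpositive_carbon_count_rejected(self):
        with pytest.raises(ValueError):
            FameRecord("x", 0, 0.0)


class TestGroupPooling:
    def test_constant_excess_passes_through(self):
        assert pool_group_enrichment([(2.0, 1.5), (5.0, 1.5)]) == pytest.approx(1.5)

    def test_hand_arithmetic(self):
        assert pool_group_enrichment([(2.0, 1.0), (6.0, 3.0)]) == pytest.approx(2.5)

    def test_singleton(self):
        assert pool_group_enrichment([(3.0, 0.7)]) == pytest.approx(0.7)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=100),
                st.floats(min_value=-1, max_value=10),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_bounded_by_member_range(self, members):
        pooled = pool_group_enrichment(members)
        excesses = [e for _, e in members]
        assert min(excesses) - 1e-9 <= pooled <= max(excesses) + 1e-9

    def test_rejects_zero_total_carbon(self):
        with pytest.raises(ValueError):
            pool_group_enrichment([(0.0, 1.0)])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            pool_group_enrichment([])
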