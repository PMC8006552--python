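"""Per-tracheid hydraulics: lumen + wall resistance, pit count, Mork class."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ringflow import (InputDomainError, ModelParams, default_wt_law,
                      hydraulic_diameter, lumen_resistance, make_record,
                      pit_count, tracheid_resistance)


def brute_force_lumen_resistance(L_um, T_um, mu, beta, length):
    """Independent transcription of the rectangular Hagen-Poiseuille term."""
    L, T = L_um * 1e-3, T_um * 1e-3
    return 8.0 * mu * beta * length * (L + T) ** 4 / (math.pi * L ** 4 * T ** 4)


def brute_force_pit_count(L_um, alpha_m2, length_mm):
    """Independent transcription of the density x wall-area product."""
    return alpha_m2 * (L_um * 1e-6) * (length_mm * 1e-3) * 1.0


class TestHydraulicDiameter:
    def test_square_lumen_reduces_to_side_length(self):
        assert hydraulic_diameter(12.0, 12.0) == pytest.approx(12.0)

    def test_rectangular_example(self):
        # 2*10*12.286 / (10 + 12.286) = 11.0258
        assert hydraulic_diameter(10.0, 12.286) == pytest.approx(11.0258,
                                                                 abs=1e-3)

    def test_slit_limit_approaches_twice_the_narrow_side(self):
        assert hydraulic_diameter(1e9, 14.0) == pytest.approx(28.0, rel=1e-6)


class TestLumenResistance:
    def test_matches_hand_evaluation_at_10um(self, params22):
        # L=10 µm with WT from the declining law -> T = 30 - 2*8.857
        assert lumen_resistance(10.0, 12.286, params22) == pytest.approx(
            3.04, rel=0.01)

    def test_matches_printed_wide_cell_value(self, params25):
        # widest cell of the bundled 1994 ring; printed as 73 on the
        # 10^-3 MPa s mm^-3 table scale
        assert lumen_resistance(36.09, 30 - 2 * 3.58, params25) == pytest.approx(
            0.0733, rel=0.01)

    def test_square_lumen_equals_circular_hagen_poiseuille(self, params22):
        """With L = T = d the rectangular formula is algebraically the
        circular one evaluated at the hydraulic diameter Dh = d."""
        for d in (5.0, 12.0, 27.5):
            dh = hydraulic_diameter(d, d) * 1e-3
            circular = (128.0 * params22.mu * params22.beta * params22.l
                        / (math.pi * dh ** 4))
            assert lumen_resistance(d, d, params22) == pytest.approx(
                circular, rel=1e-12)

    @settings(derandomize=True, max_examples=150)
    @given(L=st.floats(min_value=2.0, max_value=60.0),
           T=st.floats(min_value=2.0, max_value=28.0))
    def test_agrees_with_independent_oracle(self, L, T):
        params = ModelParams()
        assert lumen_resistance(L, T, params) == pytest.approx(
            brute_force_lumen_resistance(L, T, params.mu, params.beta, params.l),
            rel=1e-12)


class TestPitCount:
    @pytest.mark.parametrize("L, expected_rounded", [(36.09, 52), (20.94, 30)])
    def test_matches_printed_integers(self, L, expected_rounded, params25):
        n = pit_count(L, params25)
        assert n != round(n)  # real-valued internally
        assert round(n) == expected_rounded

    def test_linear_in_lumen_diameter(self, params25):
        assert pit_count(10.0, params25) == pytest.approx(
            pit_count(20.0, params25) / 2.0, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(L=st.floats(min_value=1.0, max_value=80.0))
    def test_agrees_with_unit_reconciled_oracle(self, L):
        params = ModelParams()
        assert pit_count(L, params) == pytest.approx(
            brute_force_pit_count(L, params.alpha, params.l), rel=1e-12)


class TestMorkClassification:
    def test_earlywood_iff_lumen_exceeds_twice_wall(self, params25):
        assert make_record(1, 20.0, 9.0, params25).wood_class == "earlywood"
        assert make_record(1, 10.0, 6.0, params25).wood_class == "latewood"

    def test_tie_classifies_as_latewood(self, params25):
        assert make_record(1, 12.0, 6.0, params25).wood_class == "latewood"

    def test_wall_too_thick_for_tangential_lumen_is_hard_error(self, params25):
        with pytest.raises(InputDomainError) as err:
            make_record(3, 10.0, 15.0, params25)
        assert err.value.position == 3


class TestTracheidResistance:
    def test_widest_1994_cell_matches_printed_row(self, params25):
        h = tracheid_resistance(make_record(1, 36.09, 3.58, params25), params25)
        # printed on the 10^-3 MPa s mm^-3 scale: Rwall 16, Rlum 73, R 89
        assert h.Rwall * 1e3 == pytest.approx(16.0, rel=0.10)
        assert h.Rlum * 1e3 == pytest.approx(73.0, rel=0.05)
        assert h.R * 1e3 == pytest.approx(89.0, rel=0.05)
        assert h.K == pytest.approx(11.20, rel=0.05)

    def test_widest_2009_cell_conductance(self, params25):
        h = tracheid_resistance(make_record(2, 52.40, 3.57, params25), params25)
        assert h.K == pytest.approx(18.27, rel=0.05)

    def test_series_sum_and_reciprocal_identities_are_exact(self, params25):
        h = tracheid_resistance(make_record(1, 23.46, 3.91, params25), params25)
        assert h.R == h.Rlum + h.Rwall
        assert h.K * h.R == pytest.approx(1.0, rel=1e-15)
        assert h.Rwall == pytest.approx(2.0 * h.pit.R_pit / h.Npit, rel=1e-15)

    def test_infinite_pit_density_leaves_only_the_lumen(self, params25):
        base = tracheid_resistance(make_record(1, 20.0, 4.0, params25), params25)
        dense = params25.replace(alpha=params25.alpha * 1e9)
        h = tracheid_resistance(make_record(1, 20.0, 4.0, dense), dense)
        assert h.Rwall < 1e-6 * base.Rwall
        assert h.R == pytest.approx(h.Rlum, rel=1e-6)

    def test_cell_wall_area_reproduces_printed_values(self, params25,
                                                      larix_reference):
        """Recomputed CWA stays within 0.5% of every printed value."""
        for _, row in larix_reference.iterrows():
            rec = make_record(int(row["pos"]), row["L_um"], row["WT_um"],
                              params25)
            h = tracheid_resistance(rec, params25)
            assert h.CWA == pytest.approx(row["CWA_um2"], rel=5e-3), (
                row["ring"], row["pos"])

    def test_resistances_fall_with_lumen_size_wall_faster_than_lumen(
            self, params22):
        """Under the declining wall-thickness law both components drop
        monotonically with L, and the pit side falls faster."""
        Ls = [6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0]
        hs = [tracheid_resistance(
            make_record(1, L, default_wt_law(L), params22), params22)
            for L in Ls]
        for a, b in zip(hs, hs[1:]):
            assert b.R < a.R
            assert b.Rlum < a.Rlum
            assert b.Rwall < a.Rwall
            assert b.Rwall / b.Rlum < a.Rwall / a.Rlum

    def test_wall_share_crosses_half_between_latewood_and_earlywood(
            self, params22):
        narrow = tracheid_resistance(
            make_record(1, 10.0, default_wt_law(10.0), params22), params22)
        wide = tracheid_resistance(
            make_record(1, 30.0, default_wt_law(30.0), params22), params22)
        assert narrow.Rwall / narrow.R > 0.5
        assert wide.Rwall / wide.R < 0.5
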