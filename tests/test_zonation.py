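"""Zonation gradients: endpoint rules, mean preservation, field assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zonetox as zt
from zonetox.errors import (InfeasibleProfileError, InvalidLevelError,
                            InvalidParameterError)
from zonetox.zonation import (CENTRAL_HIGH, CYP_ENDPOINTS, PORTAL_HIGH,
                              ZonationSpec, cyp_table, round_sig)

# Published endpoint table, (central, portal) per level, 3 significant
# figures.  The glucuronidation 0% cells both carry the portal-row
# baseline 3.46e-5: the printed central 0% entry (3.64e-5) is inconsistent
# with every nonzero-level cell of its row and is treated as a typo.
TABLE2 = {
    ("APAP uptake", 0.0): (8.33e-05, 8.33e-05),
    ("APAP uptake", 0.2): (1.00e-04, 6.67e-05),
    ("APAP uptake", 0.5): (1.25e-04, 4.17e-05),
    ("APAP uptake", 0.8): (1.50e-04, 1.67e-05),
    ("Sulfation", 0.0): (2.62e+09, 2.62e+09),
    ("Sulfation", 0.2): (2.09e+09, 3.14e+09),
    ("Sulfation", 0.5): (1.31e+09, 3.92e+09),
    ("Sulfation", 0.8): (5.23e+08, 4.71e+09),
    ("Glucuronidation", 0.0): (3.46e-05, 3.46e-05),
    ("Glucuronidation", 0.2): (4.15e-05, 2.77e-05),
    ("Glucuronidation", 0.5): (5.19e-05, 1.73e-05),
    ("Glucuronidation", 0.8): (6.23e-05, 6.92e-06),
    ("GSH initial concentration", 0.0): (6.87e-15, 6.87e-15),
    ("GSH initial concentration", 0.2): (5.50e-15, 8.24e-15),
    ("GSH initial concentration", 0.5): (3.44e-15, 1.03e-14),
    ("GSH initial concentration", 0.8): (1.37e-15, 1.24e-14),
    ("GSH production", 0.0): (1.59e-19, 1.59e-19),
    ("GSH production", 0.2): (1.27e-19, 1.91e-19),
    ("GSH production", 0.5): (7.95e-20, 2.39e-19),
    ("GSH production", 0.8): (3.18e-20, 2.86e-19),
    ("GSH binding", 0.0): (1.85e+13, 1.85e+13),
    ("GSH binding", 0.2): (1.48e+13, 2.22e+13),
    ("GSH binding", 0.5): (9.26e+12, 2.78e+13),
    ("GSH binding", 0.8): (3.70e+12, 3.33e+13),
    ("NAPQI-Cys formation", 0.0): (1.27e-03, 1.27e-03),
    ("NAPQI-Cys formation", 0.2): (1.53e-03, 1.02e-03),
    ("NAPQI-Cys formation", 0.5): (1.91e-03, 6.37e-04),
    ("NAPQI-Cys formation", 0.8): (2.29e-03, 2.55e-04),
}

# Published CYP isoenzyme endpoint table, (central, portal) per level.
TABLE3 = {
    ("kCYP1A2", 0.0): (2.60e-06, 2.60e-06),
    ("kCYP1A2", 0.2): (2.87e-06, 2.34e-06),
    ("kCYP1A2", 0.5): (3.20e-06, 1.88e-06),
    ("kCYP1A2", 0.8): (3.54e-06, 1.43e-06),
    ("kCYP2E1", 0.0): (2.80e-06, 2.80e-06),
    ("kCYP2E1", 0.2): (2.86e-06, 2.28e-06),
    ("kCYP2E1", 0.5): (2.99e-06, 1.53e-06),
    ("kCYP2E1", 0.8): (3.12e-06, 7.80e-07),
    ("kCYP3A4", 0.0): (5.60e-06, 5.60e-06),
    ("kCYP3A4", 0.2): (6.30e-06, 4.55e-06),
    ("kCYP3A4", 0.5): (7.43e-06, 3.06e-06),
    ("kCYP3A4", 0.8): (8.55e-06, 1.56e-06),
}


class TestRoundSig:
    @pytest.mark.parametrize("value,expected", [
        (3.435e-15, 3.44e-15),      # half rounds away from zero
        (2.385e-19, 2.39e-19),
        (1.4994e-04, 1.50e-04),
        (9.26e+12, 9.26e+12),
        (0.0, 0.0),
    ])
    def test_three_significant_figures(self, value, expected):
        assert round_sig(value) == pytest.approx(expected, rel=1e-12)


class TestLinearGradient:
    def test_endpoint_identity(self):
        x = np.array([0.0, 1.0])
        for level in (0.2, 0.5, 0.8):
            v = zt.linear_gradient(10.0, level, CENTRAL_HIGH, x)
            assert v[1] / 10.0 == pytest.approx(1 + level, rel=1e-15)
            assert v[0] / 10.0 == pytest.approx(1 - level, rel=1e-15)
            w = zt.linear_gradient(10.0, level, PORTAL_HIGH, x)
            assert w[0] / 10.0 == pytest.approx(1 + level, rel=1e-15)

    def test_level_zero_is_uniform(self):
        x = np.linspace(0, 1, 101)
        assert np.all(zt.linear_gradient(5.0, 0.0, CENTRAL_HIGH, x) == 5.0)

    def test_level_one_rejected(self):
        with pytest.raises(InvalidLevelError):
            zt.linear_gradient(1.0, 1.0, CENTRAL_HIGH, np.array([0.5]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(level=st.floats(0.0, 0.99), n=st.integers(3, 500),
           central=st.booleans())
    def test_mean_preservation_and_direction(self, level, n, central):
        x = zt.build_lattice(n).x
        direction = CENTRAL_HIGH if central else PORTAL_HIGH
        v = zt.linear_gradient(2.5, level, direction, x)
        assert abs(v.mean() - 2.5) <= 1e-9 * 2.5
        diffs = np.diff(v)
        assert np.all(diffs >= 0) if central else np.all(diffs <= 0)


class TestCypGradient:
    def test_equal_endpoints_uniform(self):
        x = np.linspace(0, 1, 50)
        v = zt.cyp_gradient(3.0, 3.0, 3.0, x)
        assert np.all(v == 3.0)

    def test_baseline_outside_endpoints_rejected(self):
        with pytest.raises(InfeasibleProfileError):
            zt.cyp_gradient(5.0, 4.0, 2.0, np.linspace(0, 1, 10))

    @pytest.mark.parametrize("name", sorted(CYP_ENDPOINTS))
    @pytest.mark.parametrize("level", [0.2, 0.5, 0.8])
    def test_pins_and_mean_on_default_lattice(self, default_lattice, name,
                                              level):
        base = getattr(zt.MetabolicParameters(), name)
        portal, central = CYP_ENDPOINTS[name][level]
        v = zt.cyp_gradient(base, central, portal, default_lattice.x)
        assert v[0] == pytest.approx(portal, rel=1e-12)
        assert v[-1] == pytest.approx(central, rel=1e-12)
        assert abs(v.mean() - base) <= 1e-6 * base
        assert np.all(np.diff(v) >= 0)


class TestParameterField:
    def test_h1_endpoints_match_table(self, small_lattice):
        field = zt.build_parameter_field(ZonationSpec("H1", 0.8),
                                         small_lattice)
        assert round_sig(field["ku"].iloc[-1]) == pytest.approx(1.50e-04)
        assert round_sig(field["ku"].iloc[0]) == pytest.approx(1.67e-05)

    def test_h7_pericentral_endpoint(self, small_lattice):
        field = zt.build_parameter_field(ZonationSpec("H7", 0.5),
                                         small_lattice)
        assert round_sig(field["kPSH"].iloc[-1]) == pytest.approx(1.91e-03)

    def test_level_zero_field_uniform_baseline(self, small_lattice):
        base = zt.MetabolicParameters()
        field = zt.build_parameter_field(ZonationSpec("H4", 0.0),
                                         small_lattice, base)
        for name in field.columns:
            assert np.all(field[name].to_numpy() == getattr(base, name))

    def test_only_impacted_parameters_vary(self, small_lattice):
        field = zt.build_parameter_field(ZonationSpec("H6", 0.5),
                                         small_lattice)
        varying = [c for c in field.columns if field[c].nunique() > 1]
        assert varying == ["kGSH"]

    def test_h5_couples_pool_and_production(self, small_lattice):
        base = zt.MetabolicParameters()
        field = zt.build_parameter_field(ZonationSpec("H5", 0.5),
                                         small_lattice, base)
        # pool tracks production through the fixed degradation rate
        assert np.allclose(field["G0"], field["bG"] / base.dG, rtol=1e-15)
        assert round_sig(field["G0"].iloc[-1]) == pytest.approx(3.44e-15)
        assert round_sig(field["bG"].iloc[0]) == pytest.approx(2.39e-19)

    def test_unknown_hypothesis_rejected(self):
        with pytest.raises(InvalidParameterError):
            ZonationSpec("H9", 0.5)

    def test_steady_start_consistency_flag(self):
        assert zt.MetabolicParameters().steady_start_consistent()


class TestTables:
    def test_full_endpoint_table_reproduced(self):
        table = zt.zonation_table()
        assert len(table) == len(TABLE2)
        for _, row in table.iterrows():
            central, portal = TABLE2[(row["parameter"], row["level"])]
            assert row["central"] == pytest.approx(central, rel=1e-12), row
            assert row["portal"] == pytest.approx(portal, rel=1e-12), row

    def test_cyp_endpoint_table_reproduced(self):
        table = cyp_table()
        assert len(table) == len(TABLE3)
        for _, row in table.iterrows():
            central, portal = TABLE3[(row["parameter"], row["level"])]
            assert row["central"] == pytest.approx(central, rel=1e-12), row
            assert row["portal"] == pytest.approx(portal, rel=1e-12), row
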