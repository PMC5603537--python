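"""Electron bookkeeping and reaction balance for methanogenic donors."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanocosm.stoichiometry import (
    CELL_BIOMASS,
    SUBSTRATES,
    PartitionFactors,
    Substrate,
    biomass_yield,
    build_reaction,
    conversion_efficiency,
    electron_equivalents,
    get_substrate,
    substrate_cod,
    theoretical_ch4_yield,
    theoretical_yield_per_g_carbon,
)


class TestSubstrate:
    def test_molar_mass_and_carbon_fraction(self, glucose):
        assert glucose.molar_mass == pytest.approx(180.156, rel=1e-3)
        assert glucose.carbon_mass_fraction == pytest.approx(6 * 12.011 / 180.156, rel=1e-6)

    def test_cell_biomass_mass_close_to_conventional_113(self):
        assert CELL_BIOMASS.molar_mass == pytest.approx(113.0, rel=2e-3)

    def test_rejects_carbon_free_formula(self):
        with pytest.raises(ValueError, match="carbon"):
            Substrate("water-ish", n=0, a=2, b=1)

    def test_registry_lookup(self):
        assert get_substrate("Xylose").n == 5
        with pytest.raises(KeyError, match="unknown substrate"):
            get_substrate("sucrose")


class TestElectronEquivalents:
    @pytest.mark.parametrize(
        ("substrate", "expected"),
        [
            (SUBSTRATES["glucose"], 24),
            (SUBSTRATES["acetic acid"], 8),
            (CELL_BIOMASS, 20),
            (SUBSTRATES["xylose"], 20),
            (SUBSTRATES["cellobiose"], 48),
        ],
    )
    def test_known_donors(self, substrate, expected):
        assert electron_equivalents(substrate) == expected

    def test_non_oxidizable_formula_is_an_error(self):
        co2_like = Substrate("carbon dioxide", n=1, a=0, b=2)
        with pytest.raises(ValueError, match="CO2"):
            electron_equivalents(co2_like)


class TestBuildReaction:
    def test_glucose_standard_partition(self, glucose, factors):
        rxn = build_reaction(glucose, factors)
        assert rxn.d == 24
        assert rxn.coeff_ch4 == pytest.approx(2.4)
        assert rxn.coeff_co2 == pytest.approx(2.64)
        assert rxn.coeff_cells == pytest.approx(0.24)
        assert rxn.coeff_nh4 == pytest.approx(-0.24)
        assert rxn.coeff_hco3 == pytest.approx(-0.24)
        # net water production = -(2n + c - b - 9dfs/20 - dfe/4)
        assert rxn.coeff_water == pytest.approx(0.96)
        assert rxn.is_balanced()

    def test_zero_synthesis_routes_all_electrons_to_methane(self, glucose):
        rxn = build_reaction(glucose, PartitionFactors(fs=0.0))
        assert rxn.coeff_cells == 0.0
        assert rxn.coeff_ch4 == pytest.approx(rxn.d / 8)

    def test_invalid_fs_rejected(self, glucose):
        with pytest.raises(ValueError, match="fs"):
            build_reaction(glucose, PartitionFactors(fs=1.5, fe=-0.5))

    def test_pretty_equation_moves_consumed_species_left(self, glucose, factors):
        eq = build_reaction(glucose, factors).equation()
        lhs, rhs = eq.split(" -> ")
        assert "NH4+" in lhs and "HCO3-" in lhs
        assert "CH4" in rhs and "C5H7O2N" in rhs

    def test_coefficient_table_contains_donor(self, glucose, factors):
        table = build_reaction(glucose, factors).coefficient_table()
        assert table[0] == ("C6H12O6", -1.0)
        assert len(table) == 7


@st.composite
def oxidizable_formulas(draw):
    n = draw(st.integers(1, 12))
    a = draw(st.integers(0, 24))
    b = draw(st.integers(0, 12))
    c = draw(st.integers(0, 2))
    sub = Substrate("random", n, a, b, c)
    if 4 * n + a - 2 * b - 3 * c <= 0:
        return None
    return sub


class TestReactionInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(sub=oxidizable_formulas(), fs=st.floats(0.0, 1.0))
    def test_element_and_charge_balance(self, sub, fs):
        if sub is None:
            return
        rxn = build_reaction(sub, PartitionFactors(fs=fs))
        for element, residual in rxn.element_balance().items():
            assert abs(residual) < 1e-9, element

    @settings(max_examples=100, derandomize=True)
    @given(sub=oxidizable_formulas(), fs=st.floats(0.0, 1.0))
    def test_electron_conservation(self, sub, fs):
        """All donor electrons end up in methane (8 e-/mol) or cells (20 e-/mol)."""
        if sub is None:
            return
        rxn = build_reaction(sub, PartitionFactors(fs=fs))
        assert 8 * rxn.coeff_ch4 + 20 * rxn.coeff_cells == pytest.approx(rxn.d, abs=1e-9)

    def test_methane_decreases_and_cells_increase_with_fs(self, glucose):
        fs_grid = np.linspace(0.0, 1.0, 11)
        ch4 = [build_reaction(glucose, PartitionFactors(fs=f)).coeff_ch4 for f in fs_grid]
        cells = [build_reaction(glucose, PartitionFactors(fs=f)).coeff_cells for f in fs_grid]
        assert np.all(np.diff(ch4) < 0)
        assert np.all(np.diff(cells) > 0)


class TestYields:
    @pytest.mark.parametrize(
        ("name", "fs", "expected"),
        [
            ("glucose", 0.2, 2.4),
            ("galactose", 0.2, 2.4),
            ("mannose", 0.2, 2.4),
            ("xylose", 0.2, 2.0),
            ("arabinose", 0.2, 2.0),
            ("acetic acid", 0.2, 0.8),
            ("glucose", 0.0, 3.0),  # complete-conversion (Buswell) limit
        ],
    )
    def test_theoretical_methane_yield(self, name, fs, expected):
        sub = SUBSTRATES[name]
        assert theoretical_ch4_yield(sub, PartitionFactors(fs=fs)) == pytest.approx(expected)

    def test_biomass_yield_linear_in_fs(self):
        assert biomass_yield(PartitionFactors(fs=0.2)) == pytest.approx(0.14125)
        assert biomass_yield(PartitionFactors(fs=0.0)) == 0.0
        slope = biomass_yield(PartitionFactors(fs=1.0))
        assert float(f"{slope:.3g}") == 0.706

    @pytest.mark.parametrize(
        ("substrate", "expected"),
        [(SUBSTRATES["glucose"], 192.0), (SUBSTRATES["acetate"], 64.0), (CELL_BIOMASS, 160.0)],
    )
    def test_cod_is_8_grams_per_electron_equivalent(self, substrate, expected):
        assert substrate_cod(substrate) == expected

    def test_yield_per_gram_carbon_bridge(self, glucose):
        # 3 mol CH4 / (6 * 12.011 g C) at complete conversion
        val = theoretical_yield_per_g_carbon(glucose, PartitionFactors(fs=0.0))
        assert val == pytest.approx(3.0 / 72.066 * 1e6, rel=1e-6)
        assert val == pytest.approx(41628.5, abs=1.0)


class TestConversionEfficiency:
    def test_partitioned_basis(self, glucose, factors):
        assert conversion_efficiency(2.13, glucose, factors) == pytest.approx(88.75)
        acetate = SUBSTRATES["acetate"]
        assert conversion_efficiency(0.4, acetate, factors) == pytest.approx(50.0)

    def test_complete_basis_uses_buswell_limit(self, glucose, factors):
        assert conversion_efficiency(3.0, glucose, factors, basis="complete") == pytest.approx(100.0)

    def test_zero_observed_is_zero_percent(self, glucose, factors):
        assert conversion_efficiency(0.0, glucose, factors) == 0.0

    def test_negative_observed_rejected(self, glucose, factors):
        with pytest.raises(ValueError, match="nonnegative"):
            conversion_efficiency(-0.1, glucose, factors)

    def test_unknown_basis_rejected(self, glucose, factors):
        with pytest.raises(ValueError, match="basis"):
            conversion_efficiency(1.0, glucose, factors, basis="owen")
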