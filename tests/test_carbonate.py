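"""Carbonate speciation and carbon-ledger accounting."""

import numpy as np
import pytest

from methanocosm.carbonate import (
    BottleConfig,
    CarbonateSystem,
    DayRecord,
    carbon_ledger,
    dissolved_co2,
    gas_to_moles,
    speciate_dic,
)
from methanocosm.stoichiometry import MASS_C, PartitionFactors, build_reaction
from methanocosm.synthetic import _partition_inorganic


class TestCarbonateSystem:
    def test_default_constants(self):
        sys_ = CarbonateSystem()
        assert sys_.pk1 == 6.35 and sys_.pk2 == 10.33 and sys_.henry_kh == 0.0339

    def test_pk_order_enforced(self):
        with pytest.raises(ValueError, match="pK1"):
            CarbonateSystem(pk1=11.0, pk2=10.0)

    def test_vant_hoff_warming_shifts_constants_correct_way(self):
        warm = CarbonateSystem.at_temperature(30.0)
        ref = CarbonateSystem()
        assert warm.pk1 < ref.pk1          # acid slightly stronger when warm
        assert warm.henry_kh < ref.henry_kh  # CO2 less soluble when warm


class TestSpeciation:
    def test_equal_fractions_at_pk1(self):
        a0, a1, _ = speciate_dic(6.35)
        assert a0 == pytest.approx(a1, rel=1e-12)

    def test_bicarbonate_fraction_at_neutral_ph(self):
        _, a1, _ = speciate_dic(7.0)
        assert a1 == pytest.approx(0.8168, abs=5e-4)

    def test_acidic_limit_fully_protonated(self):
        a0, _, _ = speciate_dic(3.0)
        assert a0 > 0.999

    def test_fractions_sum_to_one_everywhere(self):
        for ph in np.linspace(0.5, 13.5, 20):
            fracs = speciate_dic(float(ph))
            assert all(0.0 <= f <= 1.0 for f in fracs)
            assert sum(fracs) == pytest.approx(1.0, abs=1e-12)

    def test_ph_domain_enforced(self):
        with pytest.raises(ValueError, match="pH"):
            speciate_dic(0.0)


class TestGasToMoles:
    def test_zero_fraction(self, glucose_bottle):
        assert gas_to_moles(0.0, glucose_bottle) == 0.0

    def test_pure_gas_at_reference_conditions(self, glucose):
        bottle = BottleConfig(glucose, 1e-3, headspace_volume_l=0.1, buffer_mg_per_l=1.0)
        # 0.1 L ideal gas at 1 atm, 25 C: 0.1 / 24.4655 L/mol
        assert gas_to_moles(1.0, bottle) == pytest.approx(4087.4, abs=0.5)

    def test_linear_in_headspace_volume(self, glucose):
        small = BottleConfig(glucose, 1e-3, headspace_volume_l=0.05, buffer_mg_per_l=1.0)
        large = BottleConfig(glucose, 1e-3, headspace_volume_l=0.10, buffer_mg_per_l=1.0)
        assert gas_to_moles(0.5, large) == pytest.approx(2 * gas_to_moles(0.5, small))

    def test_fraction_domain_enforced(self, glucose_bottle):
        with pytest.raises(ValueError, match="fraction"):
            gas_to_moles(1.2, glucose_bottle)


class TestDissolvedCo2:
    def test_zero_partial_pressure(self, glucose_bottle):
        assert dissolved_co2(0.0, glucose_bottle, ph=6.5) == 0.0

    def test_henry_alpha_composition_at_pk1(self, glucose_bottle):
        # alpha0 = 0.5 at pH = pK1, so DIC/L = KH * pCO2 / 0.5
        dic = dissolved_co2(0.1, glucose_bottle, ph=6.35)
        assert dic / glucose_bottle.liquid_volume_l == pytest.approx(0.00678, rel=1e-3)

    def test_monotone_increasing_in_ph(self, glucose_bottle):
        vals = [dissolved_co2(0.1, glucose_bottle, ph=p) for p in (5.0, 6.0, 7.0, 8.0)]
        assert np.all(np.diff(vals) > 0)


class TestCarbonLedger:
    def test_missing_ph_is_an_error(self, glucose_bottle):
        record = DayRecord(day=2, ch4_frac=0.01, co2_frac=0.05, ph=None)
        with pytest.raises(ValueError, match="pH"):
            carbon_ledger(record, glucose_bottle)

    def test_all_zero_measurements_leave_carbon_in_substrate_and_buffer(self, glucose_bottle):
        record = DayRecord(day=0, ch4_frac=0.0, co2_frac=0.0, ph=7.0, substrate_mm=10.0)
        ledger = carbon_ledger(record, glucose_bottle)
        assert ledger.ch4_c == 0.0 and ledger.co2_gas_c == 0.0 and ledger.dic_c == 0.0
        assert ledger.substrate_c == pytest.approx(glucose_bottle.substrate_carbon_g)
        assert ledger.buffer_c == pytest.approx(glucose_bottle.buffer_carbon_mol * MASS_C)
        assert ledger.biomass_c == pytest.approx(0.0, abs=1e-12)

    def test_ledger_sums_to_added_carbon_for_arbitrary_inputs(self, glucose_bottle, rng):
        for _ in range(50):
            record = DayRecord(
                day=float(rng.uniform(0, 128)),
                ch4_frac=float(rng.uniform(0, 0.5)),
                co2_frac=float(rng.uniform(0, 0.5)),
                acetic_mm=float(rng.uniform(0, 20)),
                formic_mm=float(rng.uniform(0, 5)),
                lactic_mm=float(rng.uniform(0, 8)),
                ph=float(rng.uniform(5.5, 7.5)),
                substrate_mm=float(rng.uniform(0, 10)),
            )
            ledger = carbon_ledger(record, glucose_bottle)
            assert ledger.total == pytest.approx(glucose_bottle.added_carbon_g, abs=1e-12)

    def test_overfull_bottle_flags_negative_biomass(self, glucose_bottle):
        record = DayRecord(day=128, ch4_frac=0.9, co2_frac=0.9, acetic_mm=50.0,
                           ph=6.5, substrate_mm=10.0)
        ledger = carbon_ledger(record, glucose_bottle)
        assert not ledger.closure_ok
        assert ledger.biomass_c < 0
        assert ledger.total == pytest.approx(glucose_bottle.added_carbon_g, abs=1e-12)

    def test_stoichiometric_glucose_bottle_recovers_fs_implied_biomass(self, glucose_bottle):
        """A bottle whose gases follow the fs=0.2 reaction books ~20% of
        substrate carbon as biomass (cells carry 5 C each; part of it is
        drawn from bicarbonate)."""
        system = CarbonateSystem()
        ph = 6.35
        rxn = build_reaction(glucose_bottle.substrate, PartitionFactors(fs=0.2))
        dose = glucose_bottle.substrate_dose_mol
        ch4_mol = rxn.coeff_ch4 * dose
        # net inorganic C: produced CO2 minus bicarbonate drawn into cells
        inorganic_mol = (rxn.coeff_co2 + rxn.coeff_hco3) * dose + glucose_bottle.buffer_carbon_mol
        gas_mol, _ = _partition_inorganic(inorganic_mol, ph, glucose_bottle, system)
        headspace_mol = gas_to_moles(1.0, glucose_bottle) * 1e-6
        record = DayRecord(
            day=128,
            ch4_frac=ch4_mol / headspace_mol,
            co2_frac=gas_mol / headspace_mol,
            ph=ph,
        )
        ledger = carbon_ledger(record, glucose_bottle, system)
        fraction = ledger.biomass_c / glucose_bottle.substrate_carbon_g
        assert fraction == pytest.approx(0.20, abs=0.004)
        assert ledger.closure_ok


class TestBottleConfig:
    def test_default_buffer_warns(self, glucose):
        with pytest.warns(UserWarning, match="1 mg/L"):
            bottle = BottleConfig(glucose, 1e-3)
        assert bottle.buffer_mg_per_l == 1.0

    def test_added_carbon_combines_substrate_and_buffer(self, glucose_bottle):
        # 0.1 g NaHCO3 dosed (1 g/L in 100 mL) -> 0.1/84.007 mol C
        expected = 6 * MASS_C * 1e-3 + 0.1 / 84.007 * MASS_C
        assert glucose_bottle.added_carbon_g == pytest.approx(expected, rel=1e-12)

    def test_positive_volumes_required(self, glucose):
        with pytest.raises(ValueError, match="volume"):
            BottleConfig(glucose, 1e-3, liquid_volume_l=0.0, buffer_mg_per_l=1.0)
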