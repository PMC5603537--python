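"""Carbonate speciation and the per-sampling-day carbon mass balance.

A sealed anaerobic bottle receives a known dose of carbon: the substrate
plus the sodium-bicarbonate buffer.  At each sampling day that carbon is
partitioned among headspace CH4 and CO2, dissolved inorganic carbon (DIC,
speciated by pH among H2CO3*, HCO3- and CO3^2-), dissolved organic acids
(acetic, formic, lactic), unconsumed substrate, and — as the closing
residual — microbial biomass.  Because biomass closes the balance by
construction, the ledger reproduces the conventional batch-assay
accounting, which can overestimate biomass whenever carbon leaves through
an unmeasured route; a negative residual is flagged rather than clipped.

Equilibrium assumptions: the headspace and liquid are at steady state, CO2
obeys Henry's law, and the carbonate system is at equilibrium at the
measured pH.  Sorption of CO2 onto the solid phase is neglected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stoichiometry import MASS_C, Substrate

__all__ = [
    "CarbonateSystem",
    "BottleConfig",
    "DayRecord",
    "CarbonLedger",
    "speciate_dic",
    "gas_to_moles",
    "dissolved_co2",
    "carbon_ledger",
]

R_GAS = 0.0820573  # L atm / (mol K)
STP_TEMPERATURE_C = 25.0  # gas amounts reported at 1 atm, 25 C
NAHCO3_MOLAR_MASS = 84.007  # g/mol

# carbon atoms per molecule of each measured acid
ACID_CARBONS = {"acetic": 2, "formic": 1, "lactic": 3}


@dataclass(frozen=True)
class CarbonateSystem:
    """Carbonic-acid equilibrium constants and CO2 Henry constant.

    Defaults are the standard fresh-water values at 25 C: pK1 = 6.35,
    pK2 = 10.33, KH = 0.0339 mol/(L atm).  ``at_temperature`` applies a
    van't Hoff correction for incubations run warmer or cooler.
    """

    temperature_c: float = 25.0
    pk1: float = 6.35
    pk2: float = 10.33
    henry_kh: float = 0.0339

    def __post_init__(self) -> None:
        if not (self.pk1 < self.pk2):
            raise ValueError(f"pK1 ({self.pk1}) must be below pK2 ({self.pk2})")
        if self.henry_kh <= 0:
            raise ValueError("Henry constant must be positive")

    @classmethod
    def at_temperature(cls, temperature_c: float) -> "CarbonateSystem":
        """Van't Hoff-corrected constants at the given temperature.

        Standard reaction enthalpies: 7.7 kJ/mol (K1), 14.9 kJ/mol (K2),
        -19.4 kJ/mol (CO2 dissolution).
        """
        Rj = 8.314e-3  # kJ/(mol K)
        t0, t1 = 298.15, temperature_c + 273.15
        fac = (1.0 / t0 - 1.0 / t1) / (Rj * np.log(10.0))
        return cls(
            temperature_c=temperature_c,
            pk1=6.35 - 7.7 * fac,
            pk2=10.33 - 14.9 * fac,
            henry_kh=0.0339 * 10 ** (-19.4 * fac),
        )


def speciate_dic(ph: float, system: CarbonateSystem | None = None) -> tuple[float, float, float]:
    """Ionization fractions (alpha0, alpha1, alpha2) of H2CO3*, HCO3-, CO3^2-.

    Closed-form diprotic-acid fractions at the given pH; they are
    nonnegative and sum to one.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {ph}")
    system = system or CarbonateSystem()
    r1 = 10.0 ** (system.pk1 - ph)   # [H2CO3*]/[HCO3-]
    r2 = 10.0 ** (ph - system.pk2)   # [CO3--]/[HCO3-]
    denom = 1.0 + r1 + r2
    return r1 / denom, 1.0 / denom, r2 / denom


def gas_to_moles(mole_fraction: float, bottle: "BottleConfig") -> float:
    """Headspace amount of a gas species, umol, from its mole fraction.

    Ideal gas at the bottle's headspace pressure and the 25 C / 1 atm
    reporting convention.
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError(f"mole fraction must lie in [0, 1], got {mole_fraction}")
    t_k = STP_TEMPERATURE_C + 273.15
    mol = mole_fraction * bottle.headspace_pressure_atm * bottle.headspace_volume_l / (R_GAS * t_k)
    return mol * 1e6


def dissolved_co2(
    headspace_co2_atm: float, bottle: "BottleConfig", system: CarbonateSystem | None = None,
    ph: float | None = None,
) -> float:
    """Total dissolved inorganic carbon, mol, in the liquid phase.

    Henry's law fixes [H2CO3*] = KH * pCO2; dividing by alpha0 at the
    measured pH gives total DIC concentration, scaled by liquid volume.
    """
    if headspace_co2_atm < 0:
        raise ValueError("CO2 partial pressure must be nonnegative")
    system = system or CarbonateSystem()
    ph = bottle.ph_for_speciation if ph is None else ph
    if ph is None:
        raise ValueError("pH required to speciate DIC")
    h2co3 = system.henry_kh * headspace_co2_atm  # mol/L
    alpha0, _, _ = speciate_dic(ph, system)
    return h2co3 / alpha0 * bottle.liquid_volume_l


@dataclass(frozen=True)
class BottleConfig:
    """Physical configuration of one microcosm bottle.

    The default buffer dose follows the nominal medium recipe of
    1 mg/L NaHCO3 — implausibly low for an actual buffer, so a warning is
    emitted when the default is used; pass ``buffer_mg_per_l`` explicitly
    to silence it.
    """

    substrate: Substrate
    substrate_dose_mol: float
    liquid_volume_l: float = 0.1
    headspace_volume_l: float = 0.06
    headspace_pressure_atm: float = 1.0
    temperature_c: float = 30.0
    buffer_mg_per_l: float | None = None
    ph_for_speciation: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.liquid_volume_l <= 0 or self.headspace_volume_l <= 0:
            raise ValueError("bottle volumes must be positive")
        if self.substrate_dose_mol < 0:
            raise ValueError("substrate dose must be nonnegative")
        if self.buffer_mg_per_l is None:
            warnings.warn(
                "buffer dose not given; defaulting to the nominal 1 mg/L NaHCO3, "
                "which provides almost no buffering capacity",
                stacklevel=2,
            )
            object.__setattr__(self, "buffer_mg_per_l", 1.0)

    @property
    def buffer_carbon_mol(self) -> float:
        """Mol of inorganic carbon contributed by the NaHCO3 buffer."""
        return self.buffer_mg_per_l / 1000.0 / NAHCO3_MOLAR_MASS * self.liquid_volume_l

    @property
    def substrate_carbon_g(self) -> float:
        return self.substrate_dose_mol * self.substrate.n * MASS_C

    @property
    def added_carbon_g(self) -> float:
        """Total carbon dosed: substrate plus buffer, g per bottle."""
        return self.substrate_carbon_g + self.buffer_carbon_mol * MASS_C


@dataclass(frozen=True)
class DayRecord:
    """Measurements for one bottle on one sampling day."""

    day: float
    ch4_frac: float          # headspace mole fraction
    co2_frac: float          # headspace mole fraction
    acetic_mm: float = 0.0   # mM in liquid
    formic_mm: float = 0.0
    lactic_mm: float = 0.0
    ph: float | None = None
    substrate_mm: float = 0.0  # residual substrate, mM


@dataclass(frozen=True)
class CarbonLedger:
    """Partition of the added carbon on one sampling day, g C per bottle."""

    day: float
    ch4_c: float
    co2_gas_c: float       # biogenic CO2 in the headspace
    dic_c: float           # biogenic dissolved inorganic carbon
    buffer_c: float        # inorganic carbon attributed to the added buffer
    acetic_c: float
    formic_c: float
    lactic_c: float
    substrate_c: float     # residual (unconsumed) substrate
    biomass_c: float       # closing residual
    closure_ok: bool       # False when biomass_c < 0

    @property
    def total(self) -> float:
        return (
            self.ch4_c + self.co2_gas_c + self.dic_c + self.buffer_c
            + self.acetic_c + self.formic_c + self.lactic_c
            + self.substrate_c + self.biomass_c
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "day": self.day, "ch4_c": self.ch4_c, "co2_gas_c": self.co2_gas_c,
            "dic_c": self.dic_c, "buffer_c": self.buffer_c, "acetic_c": self.acetic_c,
            "formic_c": self.formic_c, "lactic_c": self.lactic_c,
            "substrate_c": self.substrate_c, "biomass_c": self.biomass_c,
        }


def carbon_ledger(
    record: DayRecord, bottle: BottleConfig, system: CarbonateSystem | None = None
) -> CarbonLedger:
    """Build the carbon ledger for one bottle-day.

    Gas pools come from headspace mole fractions via the ideal-gas law;
    DIC from Henry's law and pH speciation.  The buffer's inorganic carbon
    is subtracted from the measured inorganic pool (liquid first, then gas)
    before the remainder is booked as biogenic, and is carried as its own
    pool so the ledger always sums to the carbon added.  Biomass carbon is
    the closing residual; a negative value marks a closure failure.
    """
    system = system or CarbonateSystem()
    if record.ph is None and (record.co2_frac > 0 or bottle.buffer_carbon_mol > 0):
        raise ValueError(f"day {record.day}: pH missing, cannot speciate the carbonate system")

    ch4_c = gas_to_moles(record.ch4_frac, bottle) * 1e-6 * MASS_C
    co2_gas_mol = gas_to_moles(record.co2_frac, bottle) * 1e-6
    p_co2 = record.co2_frac * bottle.headspace_pressure_atm
    dic_mol = (
        dissolved_co2(p_co2, bottle, system, ph=record.ph) if record.ph is not None else 0.0
    )

    # attribute the buffer's carbon to the liquid inorganic pool first
    buffer_mol = bottle.buffer_carbon_mol
    dic_biogenic = dic_mol - buffer_mol
    leftover = max(0.0, -dic_biogenic)
    dic_biogenic = max(0.0, dic_biogenic)
    co2_gas_biogenic = max(0.0, co2_gas_mol - leftover)

    acid_c = {
        name: getattr(record, f"{name}_mm") / 1000.0 * bottle.liquid_volume_l
        * ACID_CARBONS[name] * MASS_C
        for name in ACID_CARBONS
    }
    substrate_c = (
        record.substrate_mm / 1000.0 * bottle.liquid_volume_l * bottle.substrate.n * MASS_C
    )

    accounted = (
        ch4_c
        + co2_gas_biogenic * MASS_C
        + dic_biogenic * MASS_C
        + buffer_mol * MASS_C
        + sum(acid_c.values())
        + substrate_c
    )
    biomass_c = bottle.added_carbon_g - accounted
    return CarbonLedger(
        day=record.day,
        ch4_c=ch4_c,
        co2_gas_c=co2_gas_biogenic * MASS_C,
        dic_c=dic_biogenic * MASS_C,
        buffer_c=buffer_mol * MASS_C,
        acetic_c=acid_c["acetic"],
        formic_c=acid_c["formic"],
        lactic_c=acid_c["lactic"],
        substrate_c=substrate_c,
        biomass_c=biomass_c,
        closure_ok=biomass_c >= 0.0,
    )
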