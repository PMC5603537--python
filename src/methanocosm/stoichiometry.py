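"""Methanogenic half-reaction stoichiometry with electron partitioning.

An organic electron donor C_nH_aO_bN_c carries ``d = 4n + a - 2b - 3c``
electron equivalents per mole.  In the Rittmann–McCarty framework a fraction
``fs`` of those electrons is routed to cell synthesis (cells as C5H7O2N) and
the complementary fraction ``fe = 1 - fs`` to energy, which under
methanogenic conditions (CO2 as the terminal electron acceptor) appears as
methane at d*fe/8 mol per mol donor.  This module builds the full balanced
reaction, the theoretical methane and biomass yields that follow from it,
and Owen-style conversion efficiencies of observed methane against those
theoretical yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Substrate",
    "PartitionFactors",
    "MethanogenesisReaction",
    "SUBSTRATES",
    "CELL_BIOMASS",
    "electron_equivalents",
    "build_reaction",
    "theoretical_ch4_yield",
    "biomass_yield",
    "substrate_cod",
    "conversion_efficiency",
    "theoretical_yield_per_g_carbon",
]

# IUPAC 2021 conventional atomic masses, 3 d.p.
MASS_C = 12.011
MASS_H = 1.008
MASS_O = 15.999
MASS_N = 14.007

#: g cells per mol cells for the conventional biomass formula C5H7O2N.
CELL_MOLAR_MASS = 113.0
#: electron equivalents per mol of C5H7O2N cells.
CELL_ELECTRON_EQUIV = 20
#: g COD per electron equivalent of donor.
COD_PER_EEQ = 8.0


@dataclass(frozen=True)
class Substrate:
    """An organic electron donor with empirical formula C_nH_aO_bN_c."""

    name: str
    n: int
    a: int
    b: int
    c: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.name}: need at least one carbon, got n={self.n}")
        for sym, v in (("a", self.a), ("b", self.b), ("c", self.c)):
            if v < 0:
                raise ValueError(f"{self.name}: negative atom count {sym}={v}")

    @property
    def molar_mass(self) -> float:
        """g per mol of formula unit."""
        return MASS_C * self.n + MASS_H * self.a + MASS_O * self.b + MASS_N * self.c

    @property
    def carbon_mass_fraction(self) -> float:
        return MASS_C * self.n / self.molar_mass

    @property
    def formula(self) -> str:
        parts = []
        for sym, v in (("C", self.n), ("H", self.a), ("O", self.b), ("N", self.c)):
            if v == 1:
                parts.append(sym)
            elif v > 1:
                parts.append(f"{sym}{v}")
        return "".join(parts)


@dataclass(frozen=True)
class PartitionFactors:
    """Electron split between synthesis (fs) and energy (fe); fs + fe = 1."""

    fs: float
    fe: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fe is None:
            object.__setattr__(self, "fe", 1.0 - self.fs)
        if not 0.0 <= self.fs <= 1.0:
            raise ValueError(f"fs must lie in [0, 1], got {self.fs}")
        if not math.isclose(self.fs + self.fe, 1.0, abs_tol=1e-12):
            raise ValueError(f"fs + fe must equal 1, got {self.fs + self.fe}")


#: Default partitioning for anaerobic methanogenic biomass.
DEFAULT_FACTORS = PartitionFactors(fs=0.2)

#: Cell biomass C5H7O2N, usable anywhere a Substrate is accepted.
CELL_BIOMASS = Substrate("cell biomass", n=5, a=7, b=2, c=1)

#: Built-in donors covering the standard microcosm treatments.
SUBSTRATES: dict[str, Substrate] = {
    "glucose": Substrate("glucose", 6, 12, 6),
    "galactose": Substrate("galactose", 6, 12, 6),
    "mannose": Substrate("mannose", 6, 12, 6),
    "xylose": Substrate("xylose", 5, 10, 5),
    "arabinose": Substrate("arabinose", 5, 10, 5),
    "cellobiose": Substrate("cellobiose", 12, 22, 11),
    "acetic acid": Substrate("acetic acid", 2, 4, 2),
}
SUBSTRATES["acetate"] = SUBSTRATES["acetic acid"]


def electron_equivalents(substrate: Substrate) -> int:
    """Electron equivalents d per mole of donor: d = 4n + a - 2b - 3c."""
    d = 4 * substrate.n + substrate.a - 2 * substrate.b - 3 * substrate.c
    if d <= 0:
        raise ValueError(
            f"{substrate.name} ({substrate.formula}) is not an oxidizable donor: "
            f"d = 4n + a - 2b - 3c = {d} <= 0"
        )
    return d


@dataclass(frozen=True)
class MethanogenesisReaction:
    """Balanced methanogenic donor-oxidation/cell-synthesis reaction.

    All coefficients are mol per mol donor, signed on a product-side
    convention: positive means produced, negative means consumed.  The donor
    itself always carries an implicit coefficient of -1.  Water is stored
    product-side (it is consumed for carbohydrate donors, so its coefficient
    is typically negative), and for nitrogen-free donors NH4+ and HCO3- have
    negative coefficients: the cells' nitrogen must be drawn from ammonium
    and the corresponding charge from bicarbonate.
    """

    substrate: Substrate
    factors: PartitionFactors
    d: int
    coeff_water: float
    coeff_ch4: float
    coeff_co2: float
    coeff_cells: float
    coeff_nh4: float
    coeff_hco3: float

    def element_balance(self) -> dict[str, float]:
        """Net production minus consumption per element and for charge.

        Zero everywhere iff the reaction is balanced (the donor counts as one
        mole consumed).
        """
        species = {
            # (C, H, O, N, charge) per formula unit
            "donor": (self.substrate.n, self.substrate.a, self.substrate.b, self.substrate.c, 0),
            "water": (0, 2, 1, 0, 0),
            "ch4": (1, 4, 0, 0, 0),
            "co2": (1, 0, 2, 0, 0),
            "cells": (5, 7, 2, 1, 0),
            "nh4": (0, 4, 0, 1, +1),
            "hco3": (1, 1, 3, 0, -1),
        }
        coeffs = {
            "donor": -1.0,
            "water": self.coeff_water,
            "ch4": self.coeff_ch4,
            "co2": self.coeff_co2,
            "cells": self.coeff_cells,
            "nh4": self.coeff_nh4,
            "hco3": self.coeff_hco3,
        }
        totals = dict.fromkeys(("C", "H", "O", "N", "charge"), 0.0)
        for sp, (nc, nh, no, nn, q) in species.items():
            k = coeffs[sp]
            totals["C"] += k * nc
            totals["H"] += k * nh
            totals["O"] += k * no
            totals["N"] += k * nn
            totals["charge"] += k * q
        return totals

    def is_balanced(self, tol: float = 1e-9) -> bool:
        return all(abs(v) < tol for v in self.element_balance().values())

    def equation(self) -> str:
        """Plain-text balanced equation with negatives moved to reactants."""
        names = {
            "water": "H2O",
            "ch4": "CH4",
            "co2": "CO2",
            "cells": "C5H7O2N",
            "nh4": "NH4+",
            "hco3": "HCO3-",
        }
        lhs = [self.substrate.formula]
        rhs = []
        for key, label in names.items():
            k = getattr(self, f"coeff_{key}")
            if abs(k) < 1e-12:
                continue
            term = f"{abs(k):g} {label}"
            (rhs if k > 0 else lhs).append(term)
        return " + ".join(lhs) + " -> " + " + ".join(rhs)

    def coefficient_table(self) -> "list[tuple[str, float]]":
        """(species, signed coefficient) rows, donor included as -1."""
        rows = [(self.substrate.formula, -1.0)]
        for key, label in (("water", "H2O"), ("ch4", "CH4"), ("co2", "CO2"),
                           ("cells", "C5H7O2N"), ("nh4", "NH4+"), ("hco3", "HCO3-")):
            rows.append((label, getattr(self, f"coeff_{key}")))
        return rows


def build_reaction(
    substrate: Substrate, factors: PartitionFactors = DEFAULT_FACTORS
) -> MethanogenesisReaction:
    """Construct the balanced reaction for a donor at the given fs/fe split.

    With d electron equivalents per mole of donor, d*fe/8 mol go to CH4
    (8 e-eq per mol CH4) and d*fs/20 mol to cells (20 e-eq per mol C5H7O2N);
    CO2, water, ammonium and bicarbonate close the element and charge
    balances.
    """
    d = electron_equivalents(substrate)
    n, b, c = substrate.n, substrate.b, substrate.c
    fs, fe = factors.fs, factors.fe
    water_consumed = 2 * n + c - b - 9 * d * fs / 20 - d * fe / 4
    rxn = MethanogenesisReaction(
        substrate=substrate,
        factors=factors,
        d=d,
        coeff_water=-water_consumed,
        coeff_ch4=d * fe / 8,
        coeff_co2=n - c - d * fs / 5 - d * fe / 8,
        coeff_cells=d * fs / 20,
        coeff_nh4=c - d * fs / 20,
        coeff_hco3=c - d * fs / 20,
    )
    assert rxn.is_balanced(), f"internal error: unbalanced reaction for {substrate.formula}"
    return rxn


def theoretical_ch4_yield(
    substrate: Substrate, factors: PartitionFactors = DEFAULT_FACTORS
) -> float:
    """Theoretical methane yield, mol CH4 per mol substrate."""
    return build_reaction(substrate, factors).coeff_ch4


def substrate_cod(substrate: Substrate) -> float:
    """Chemical oxygen demand of the donor, g COD per mol (8 g COD per e-eq)."""
    return COD_PER_EEQ * electron_equivalents(substrate)


def biomass_yield(factors: PartitionFactors) -> float:
    """Net biomass yield Y, g cells per g COD of donor.

    Y = fs * Mc / (ne * 8 g COD per e-eq) with Mc = 113 g/mol and ne = 20,
    i.e. Y = 0.70625 * fs (reported to 3 s.f. as 0.706 fs).
    """
    return factors.fs * CELL_MOLAR_MASS / (CELL_ELECTRON_EQUIV * COD_PER_EEQ)


def theoretical_yield_per_g_carbon(
    substrate: Substrate, factors: PartitionFactors = DEFAULT_FACTORS
) -> float:
    """Theoretical CH4 in umol per g of substrate carbon.

    Bridges the molar stoichiometry to the per-gram-carbon unit in which
    cumulative microcosm methane is usually reported.
    """
    return theoretical_ch4_yield(substrate, factors) / (MASS_C * substrate.n) * 1e6


def conversion_efficiency(
    observed_peak_ch4: float,
    substrate: Substrate,
    factors: PartitionFactors = DEFAULT_FACTORS,
    basis: str = "partitioned",
) -> float:
    """Observed peak methane as a percentage of the theoretical yield.

    Parameters
    ----------
    observed_peak_ch4
        Peak cumulative methane, mol per mol substrate dosed.
    basis
        ``"partitioned"`` uses the fs/fe split as given (Rittmann–McCarty
        theoretical yield); ``"complete"`` sets fs = 0, the Owen/Buswell
        complete-conversion limit d/8.
    """
    if observed_peak_ch4 < 0:
        raise ValueError("observed peak methane must be nonnegative")
    if basis == "partitioned":
        theo = theoretical_ch4_yield(substrate, factors)
    elif basis == "complete":
        theo = theoretical_ch4_yield(substrate, PartitionFactors(fs=0.0))
    else:
        raise ValueError(f"unknown basis {basis!r}; use 'partitioned' or 'complete'")
    if theo == 0:
        raise ValueError(f"theoretical yield is zero for {substrate.name}")
    return 100.0 * observed_peak_ch4 / theo


def get_substrate(name: str) -> Substrate:
    """Look up a built-in donor by name (case-insensitive)."""
    try:
        return SUBSTRATES[name.lower()]
    except KeyError:
        known = ", ".join(sorted(set(SUBSTRATES)))
        raise KeyError(f"unknown substrate {name!r}; built-ins: {known}") from None
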