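"""Dataset container plus CSV/YAML readers and writers.

A microcosm dataset is a directory with three text files:

``config.yaml``
    experiment configuration: the random seed (if synthetic) and one bottle
    configuration per treatment (substrate formula, dose, volumes, buffer).
``gas.csv``
    long format, one row per bottle per gas-sampling day:
    ``treatment, replicate, day, ch4_umol_per_gC, co2_umol_per_gC,
    ch4_frac, co2_frac``.
``liquids.csv``
    one row per bottle per liquid-sampling day:
    ``treatment, replicate, day, acetic_mM, formic_mM, lactic_mM, pH,
    substrate_mM``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .carbonate import BottleConfig
from .kinetics import MethaneSeries
from .stoichiometry import SUBSTRATES, Substrate

__all__ = ["MicrocosmDataset", "read_dataset", "write_dataset", "SchemaError"]

GAS_COLUMNS = [
    "treatment", "replicate", "day",
    "ch4_umol_per_gC", "co2_umol_per_gC", "ch4_frac", "co2_frac",
]
LIQUID_COLUMNS = [
    "treatment", "replicate", "day",
    "acetic_mM", "formic_mM", "lactic_mM", "pH", "substrate_mM",
]


class SchemaError(ValueError):
    """A dataset file violates the documented schema."""


@dataclass
class MicrocosmDataset:
    """In-memory microcosm experiment: per-treatment config + time series."""

    treatments: dict[str, BottleConfig]
    gas: pd.DataFrame
    liquids: pd.DataFrame
    seed: int | None = None

    def methane_series(self, treatment: str) -> list[MethaneSeries]:
        """Per-replicate cumulative methane series for one treatment."""
        sub = self.gas[self.gas["treatment"] == treatment]
        if sub.empty:
            raise KeyError(f"treatment {treatment!r} not present in gas table")
        out = []
        for rep, grp in sub.groupby("replicate", sort=True):
            grp = grp.sort_values("day")
            out.append(
                MethaneSeries(
                    treatment, str(rep),
                    grp["day"].to_numpy(float),
                    grp["ch4_umol_per_gC"].to_numpy(float),
                )
            )
        return out

    def validate(self) -> None:
        _check_columns(self.gas, GAS_COLUMNS, "gas")
        _check_columns(self.liquids, LIQUID_COLUMNS, "liquids")
        for name, df in (("gas", self.gas), ("liquids", self.liquids)):
            bad = df.index[~np.isfinite(pd.to_numeric(df["day"], errors="coerce"))]
            if len(bad):
                raise SchemaError(f"{name}.csv row {bad[0] + 2}: day is not numeric")
            if (df["day"] < 0).any():
                row = int(df.index[df["day"] < 0][0]) + 2
                raise SchemaError(f"{name}.csv row {row}: negative day")
            unknown = set(df["treatment"]) - set(self.treatments)
            if unknown:
                raise SchemaError(f"{name}.csv references unknown treatment(s): {sorted(unknown)}")
        for (trt, rep), grp in self.gas.groupby(["treatment", "replicate"]):
            days = grp.sort_index()["day"].to_numpy(float)
            if len(days) > 1 and not np.all(np.diff(days) > 0):
                raise SchemaError(f"gas.csv: non-monotone days for bottle {trt}/{rep}")


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}.csv is missing column(s): {missing}")


def _substrate_from_config(entry: dict) -> Substrate:
    sub = entry["substrate"]
    if isinstance(sub, str):
        if sub.lower() not in SUBSTRATES:
            raise SchemaError(f"unknown substrate name {sub!r}; give a formula dict instead")
        return SUBSTRATES[sub.lower()]
    return Substrate(sub.get("name", "custom"), int(sub["n"]), int(sub["a"]),
                     int(sub["b"]), int(sub.get("c", 0)))


def _bottle_to_config(bottle: BottleConfig) -> dict:
    sub = bottle.substrate
    return {
        "substrate": {"name": sub.name, "n": sub.n, "a": sub.a, "b": sub.b, "c": sub.c},
        "substrate_dose_mol": bottle.substrate_dose_mol,
        "liquid_volume_l": bottle.liquid_volume_l,
        "headspace_volume_l": bottle.headspace_volume_l,
        "headspace_pressure_atm": bottle.headspace_pressure_atm,
        "temperature_c": bottle.temperature_c,
        "buffer_mg_per_l": bottle.buffer_mg_per_l,
    }


def write_dataset(dataset: MicrocosmDataset, path: str | Path) -> Path:
    """Write the dataset directory (config.yaml, gas.csv, liquids.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = {
        "seed": dataset.seed,
        "treatments": {name: _bottle_to_config(b) for name, b in dataset.treatments.items()},
    }
    (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    dataset.gas.to_csv(path / "gas.csv", index=False)
    dataset.liquids.to_csv(path / "liquids.csv", index=False)
    return path


def read_dataset(path: str | Path) -> MicrocosmDataset:
    """Load and validate a dataset directory."""
    path = Path(path)
    cfg_file = path / "config.yaml"
    if not cfg_file.exists():
        raise FileNotFoundError(f"no config.yaml under {path}")
    cfg = yaml.safe_load(cfg_file.read_text())
    treatments: dict[str, BottleConfig] = {}
    for name, entry in cfg.get("treatments", {}).items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # buffer default warning handled at build time
            treatments[name] = BottleConfig(
                substrate=_substrate_from_config(entry),
                substrate_dose_mol=float(entry["substrate_dose_mol"]),
                liquid_volume_l=float(entry.get("liquid_volume_l", 0.1)),
                headspace_volume_l=float(entry.get("headspace_volume_l", 0.06)),
                headspace_pressure_atm=float(entry.get("headspace_pressure_atm", 1.0)),
                temperature_c=float(entry.get("temperature_c", 30.0)),
                buffer_mg_per_l=entry.get("buffer_mg_per_l"),
            )
    gas = pd.read_csv(path / "gas.csv")
    liquids = pd.read_csv(path / "liquids.csv")
    ds = MicrocosmDataset(
        treatments=treatments, gas=gas, liquids=liquids, seed=cfg.get("seed")
    )
    ds.validate()
    return ds
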