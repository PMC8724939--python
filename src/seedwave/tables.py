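"""Access to the packaged coefficient tables (per-treatment model fits)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .props import DiffusivityModel, LossFactorModel, MicrowaveSource

TREATMENTS = (
    "0.70kW-20",
    "0.70kW-35",
    "0.70kW-50",
    "0.35kW-20",
    "0.35kW-35",
    "0.35kW-50",
)


@lru_cache(maxsize=1)
def load_tables() -> dict:
    """Raw coefficient tables as a nested dict (verbatim published rows)."""
    with resources.files("seedwave.data").joinpath("coefficients.json").open() as fh:
        return json.load(fh)


def _table_frame(section: str) -> pd.DataFrame:
    tab = load_tables()[section]
    df = pd.DataFrame.from_dict(tab["treatments"], orient="index")
    return df[["power_kW", "imc_db"] + tab["columns"]]


def loss_factor_table() -> pd.DataFrame:
    """Per-treatment loss-factor coefficients g0..g7."""
    return _table_frame("loss_factor")


def diffusivity_table() -> pd.DataFrame:
    """Per-treatment diffusivity coefficients D0, Ea, a0, a1."""
    return _table_frame("diffusivity")


def loss_factor_model(treatment: str = "average", ash_db: float = 2.6) -> LossFactorModel:
    """LossFactorModel from a named treatment row (or the Average row)."""
    tab = load_tables()["loss_factor"]
    row = tab["average"] if treatment == "average" else tab["treatments"][treatment]
    return LossFactorModel(g=tuple(row[c] for c in tab["columns"]), ash_db=ash_db)


def diffusivity_model(treatment: str = "average") -> DiffusivityModel:
    """DiffusivityModel from a named treatment row (or the Average row)."""
    tab = load_tables()["diffusivity"]
    row = tab["average"] if treatment == "average" else tab["treatments"][treatment]
    return DiffusivityModel(**{c: row[c] for c in tab["columns"]})


def biot_numbers(treatment: str) -> tuple[float, float]:
    """(Bi_heat, Bi_mass) reported for a treatment."""
    tab = load_tables()["biot"]
    return tab["heat"][treatment], tab["mass"][treatment]


def microwave_source(treatment: str) -> MicrowaveSource:
    """MicrowaveSource with the calibrated power/reflection of a treatment."""
    power = treatment.split("kW")[0]
    cfg = load_tables()["source_power"][power]
    return MicrowaveSource(Pav=cfg["pav_watts"], S11=cfg["s11"])
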