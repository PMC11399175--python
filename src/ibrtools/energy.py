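"""Cellular energy allocation (CEA).

Energy available, Ea, is the sum of the glucose, lipid and protein energy
reserves measured in muscle tissue; energy consumed, Ec, is the
electron-transport-system activity.  CEA = Ea - Ec.  Components are summed
in the normalised assay units produced by :mod:`ibrtools.assay`; users with
calibrations to joules can supply per-component conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnergyBudget", "energy_available", "cellular_energy_allocation", "add_energy_columns"]

RESERVE_COLUMNS = ("protein_energy", "glucose_energy", "lipid_energy")


@dataclass(frozen=True)
class EnergyBudget:
    """Per-animal energy budget: reserves, Ea, Ec and CEA."""

    animal_id: str
    protein_energy: float
    glucose_energy: float
    lipid_energy: float
    Ec: float

    @property
    def Ea(self) -> float:
        return energy_available(self.protein_energy, self.glucose_energy, self.lipid_energy)

    @property
    def CEA(self) -> float:
        return cellular_energy_allocation(self.Ea, self.Ec)


def energy_available(protein: float, glucose: float, lipid: float) -> float:
    """Ea = protein + glucose + lipid reserves.

    A missing (NaN) component makes Ea missing; missingness propagates,
    it is never imputed.
    """
    return float(protein) + float(glucose) + float(lipid)


def cellular_energy_allocation(ea: float, ec: float) -> float:
    """CEA = Ea - Ec.  Negative values (consumption exceeding reserves) are kept."""
    return float(ea) - float(ec)


def add_energy_columns(
    table: pd.DataFrame,
    conversion: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Append Ea and CEA columns to a biomarker table holding reserves and Ec.

    ``conversion`` optionally scales (protein, glucose, lipid) reserves to a
    common energy unit before summing; the default leaves assay units as-is.
    """
    missing = [c for c in (*RESERVE_COLUMNS, "Ec") if c not in table.columns]
    if missing:
        raise KeyError(f"biomarker table lacks energy columns: {missing}")
    out = table.copy()
    scaled = [out[c].astype(float) * k for c, k in zip(RESERVE_COLUMNS, conversion)]
    out["Ea"] = scaled[0] + scaled[1] + scaled[2]
    out["CEA"] = out["Ea"] - out["Ec"].astype(float)
    units = dict(out.attrs.get("units", {}))
    units.setdefault("Ea", units.get("protein_energy", "assay units"))
    units.setdefault("CEA", units.get("Ea", "assay units"))
    out.attrs["units"] = units
    # keep NaN where any component was missing (pandas addition already does)
    assert np.isnan(out.loc[out[list(RESERVE_COLUMNS)].isna().any(axis=1), "Ea"]).all()
    return out
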