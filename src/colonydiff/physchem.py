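"""Derived physico-chemical quantities.

Free-water diffusivities from the Stokes-Einstein relation
D_w = k_B T / (6 pi eta r_h), ratio tables (D_in/D_out, D_w/D_in) and the
tortuosity index sqrt(D_w/D_in) for solute/strain combinations, and the
microbial-adhesion-to-solvents (MATS) percentage used to classify cell
surface hydrophobicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .fitdiff import DiffusionFit

__all__ = [
    "SoluteRecord",
    "PhysicalConstants",
    "TortuosityRow",
    "MatsMeasurement",
    "stokes_einstein",
    "tortuosity_index",
    "build_table3",
    "mats_adhesion",
    "classify_hydrophobicity",
    "load_solute_table",
    "load_mats_table",
    "solute_records",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants for the Stokes-Einstein relation.

    Defaults are water at 20 degC (293.15 K, 1.002 mPa s), the reference
    condition for tabulated free-water diffusivities.
    """

    boltzmann: float = BOLTZMANN_J_PER_K  # J/K
    temperature: float = 293.15  # K
    viscosity: float = 1.002e-3  # Pa s

    def __post_init__(self) -> None:
        if min(self.boltzmann, self.temperature, self.viscosity) <= 0:
            raise ValueError("all physical constants must be strictly positive")


@dataclass(frozen=True)
class SoluteRecord:
    """One fluorescently labeled solute and its transport-relevant properties."""

    name: str
    molecular_weight: float  # kDa
    hydrodynamic_radius: float  # nm
    flexibility: str = "flexible"
    charge_note: str = ""
    isoelectric_point: float | None = None

    def __post_init__(self) -> None:
        if self.hydrodynamic_radius <= 0:
            raise ValueError("hydrodynamic_radius must be positive")


@dataclass
class TortuosityRow:
    """Per-(solute, strain) derived quantities, ready for reporting."""

    solute: str
    strain: str
    d_in: float  # um^2/s
    d_out: float  # um^2/s
    d_w: float  # um^2/s
    ratio_in_out: float
    ratio_w_in: float
    tortuosity: float


@dataclass(frozen=True)
class MatsMeasurement:
    """One MATS assay reading: optical density at 400 nm of the aqueous
    phase before and after mixing with the solvent."""

    solvent: str
    od_initial: float
    od_after: float

    def __post_init__(self) -> None:
        if self.od_initial <= 0:
            raise ValueError("od_initial must be positive")
        if self.od_after < 0:
            raise ValueError("od_after must be non-negative")


def stokes_einstein(
    r_h_nm: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Free-water diffusivity (um^2/s) of a sphere of hydrodynamic radius
    ``r_h_nm`` nanometers: D = k_B T / (6 pi eta r)."""
    if r_h_nm <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    d_m2_per_s = constants.boltzmann * constants.temperature / (
        6.0 * np.pi * constants.viscosity * r_h_nm * 1e-9
    )
    return d_m2_per_s * 1e12


def tortuosity_index(ratio_w_in: float) -> float:
    """Tortuosity index sqrt(D_w / D_in).

    Quantifies how convoluted the interstitial diffusion path between cells
    is relative to free water; 1 means unhindered diffusion.  Report output
    rounds to one decimal.
    """
    if ratio_w_in < 0:
        raise ValueError("D_w/D_in ratio must be non-negative")
    return float(np.sqrt(ratio_w_in))


def build_table3(
    fits: Iterable[tuple[SoluteRecord, str, DiffusionFit]],
    constants: PhysicalConstants = PhysicalConstants(),
) -> pd.DataFrame:
    """Ratio/tortuosity report, one row per (solute, strain) fit.

    Flagged fits (undefined D) yield rows with NaN ratios rather than being
    dropped.  Columns carry full precision; ``round_report`` applies the
    printed precision (2 decimals for ratios, 1 for the index).
    """
    rows = []
    for solute, strain, fit in fits:
        d_w = stokes_einstein(solute.hydrodynamic_radius, constants)
        d_in, d_out = fit.fit_in.d_eff, fit.fit_out.d_eff
        ratio_w_in = d_w / d_in if d_in and np.isfinite(d_in) else float("nan")
        rows.append(
            TortuosityRow(
                solute=solute.name,
                strain=strain,
                d_in=d_in,
                d_out=d_out,
                d_w=d_w,
                ratio_in_out=fit.ratio_in_out,
                ratio_w_in=ratio_w_in,
                tortuosity=(
                    tortuosity_index(ratio_w_in)
                    if np.isfinite(ratio_w_in)
                    else float("nan")
                ),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def round_report(table: pd.DataFrame) -> pd.DataFrame:
    """Apply report precision: ratios to 2 decimals, tortuosity to 1."""
    out = table.copy()
    for col in ("ratio_in_out", "ratio_w_in"):
        out[col] = out[col].round(2)
    out["tortuosity"] = out["tortuosity"].round(1)
    return out


def mats_adhesion(m: MatsMeasurement) -> float:
    """Percent adhesion to a solvent: 100 (OD_initial - OD_after)/OD_initial.

    May be negative when the aqueous-phase density increases after mixing;
    such values are reported as-is for the caller to flag.
    """
    return 100.0 * (m.od_initial - m.od_after) / m.od_initial


def classify_hydrophobicity(adhesion_percent: float, threshold: float = 40.0) -> str:
    """Surface class from hexadecane affinity: below 40% is hydrophilic."""
    return "hydrophilic" if adhesion_percent < threshold else "hydrophobic"


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("colonydiff").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_solute_table() -> pd.DataFrame:
    """Reference properties of the six studied solutes (three dextrans,
    BSA, lactoferrin, alpha-s1-casein)."""
    return _read_packaged("solutes_table1.csv")


def load_mats_table() -> pd.DataFrame:
    """Reference MATS adhesion means for the two L. lactis strains."""
    return _read_packaged("mats_table2.csv")


def solute_records() -> dict[str, SoluteRecord]:
    """Packaged solute table as SoluteRecord objects keyed by name."""
    out = {}
    for _, row in load_solute_table().iterrows():
        pi = row["isoelectric_point"]
        out[row["name"]] = SoluteRecord(
            name=row["name"],
            molecular_weight=row["molecular_weight_kda"],
            hydrodynamic_radius=row["hydrodynamic_radius_nm"],
            flexibility=row["flexibility"],
            charge_note=row["hydrophobicity"],
            isoelectric_point=None if pd.isna(pi) else float(pi),
        )
    return out
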