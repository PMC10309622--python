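"""Odorant physicochemical properties and the dimensionless wall-uptake parameter.

Odorant transport from nasal air into the mucus film is controlled by three
material properties: the diffusivity in air ``Da``, the diffusivity in mucus
``Dm``, and the air/mucus partition coefficient ``beta`` (air-phase over
mucus-phase concentration at the interface; a *small* beta means a highly
mucosa-soluble odorant).  Together with the mucus film thickness ``d`` and a
reference hydraulic diameter ``d_in`` these combine into a single
dimensionless wall-uptake parameter

    K = d_in * Dm / (Da * beta * d)

which sets the Robin boundary condition dC'/dy' + K C' = 0 obeyed by the
normalized air-phase concentration at the air/mucus interface.  K -> 0 is the
insoluble (no-uptake) limit; large K approaches a perfectly absorbing wall.

Air diffusivities that are not measured can be estimated from the
Wilke-Chang correlation, applied here with the carrier gas (air) playing the
role of the solvent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EpitheliumClass",
    "Odorant",
    "MucosaSpec",
    "UptakeParameter",
    "estimate_air_diffusivity",
    "wall_uptake_parameter",
    "read_odorant_table",
    "write_odorant_table",
    "builtin_odorant_table",
    "DEFAULT_MUCUS_THICKNESS",
    "DEFAULT_MUCUS_DIFFUSIVITY",
]

logger = logging.getLogger(__name__)

#: Default mucus film thickness [m]; a 30 um aqueous layer coats the airway wall.
DEFAULT_MUCUS_THICKNESS = 30e-6

#: Fallback mucus diffusivity [m^2/s] — typical small-molecule aqueous value,
#: used only when a table row supplies no Dm (the substitution is logged).
DEFAULT_MUCUS_DIFFUSIVITY = 1e-9


class EpitheliumClass(str, Enum):
    """Histological class of the epithelium lining a channel wall."""

    SQUAMOUS = "squamous"
    RESPIRATORY = "respiratory"
    OLFACTORY = "olfactory"


@dataclass(frozen=True)
class Odorant:
    """Physicochemical description of one odorant.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"2-acetylthiazole"``.
    molecular_weight : float
        Molar mass [g/mol].
    molar_volume : float
        Solute molar volume at the normal boiling point [cm^3/mol]; used by
        the Wilke-Chang diffusivity estimate.
    beta : float
        Air/mucus partition coefficient (air concentration over mucus
        concentration at the interface), dimensionless.  Smaller beta means
        more mucosa-soluble.
    Da : float
        Diffusivity in air [m^2/s].
    Dm : float
        Diffusivity in mucus [m^2/s].
    """

    name: str
    molecular_weight: float
    molar_volume: float
    beta: float
    Da: float
    Dm: float

    def __post_init__(self) -> None:
        for field in ("molecular_weight", "molar_volume", "beta", "Da", "Dm"):
            value = getattr(self, field)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"Odorant.{field} must be finite and > 0, got {value!r}")

    def with_beta(self, beta: float) -> "Odorant":
        """Copy of this odorant with a different partition coefficient (for sweeps)."""
        return replace(self, beta=beta)


@dataclass(frozen=True)
class MucosaSpec:
    """Mucosal lining of a channel wall: epithelium class plus mucus film thickness [m]."""

    epithelium_class: EpitheliumClass
    mucus_thickness: float = DEFAULT_MUCUS_THICKNESS

    def __post_init__(self) -> None:
        if not self.mucus_thickness > 0:
            raise ValueError(f"mucus_thickness must be > 0, got {self.mucus_thickness!r}")


@dataclass(frozen=True)
class UptakeParameter:
    """Dimensionless wall-uptake parameter K and the reference length it was scaled by."""

    K: float
    d_in: float

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not self.d_in > 0:
            raise ValueError("d_in must be > 0")


def estimate_air_diffusivity(
    odorant: Odorant,
    temperature: float = 298.15,
    carrier_molar_mass: float = 28.96,
    carrier_viscosity: float = 0.0185,
    association_factor: float = 1.0,
) -> float:
    """Estimate the odorant diffusivity in the carrier gas via Wilke-Chang.

    The correlation, in its customary mixed units, reads

        D [cm^2/s] = 7.4e-8 * (phi * M_B)**0.5 * T / (mu_B * V_A**0.6)

    with ``phi`` the solvent association factor, ``M_B`` the solvent molar
    mass [g/mol], ``T`` the absolute temperature [K], ``mu_B`` the solvent
    viscosity [cP] and ``V_A`` the solute molar volume at its boiling point
    [cm^3/mol].  The result is converted to SI [m^2/s].

    The correlation was developed for liquid solvents; it is applied here to
    the gas phase as a stated modelling choice (see the methods note).
    Measured ``Da`` values in an odorant table always take precedence.
    """
    for name, value in (
        ("temperature", temperature),
        ("carrier_molar_mass", carrier_molar_mass),
        ("carrier_viscosity", carrier_viscosity),
        ("association_factor", association_factor),
    ):
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    d_cm2_s = (
        7.4e-8
        * math.sqrt(association_factor * carrier_molar_mass)
        * temperature
        / (carrier_viscosity * odorant.molar_volume**0.6)
    )
    return d_cm2_s * 1e-4  # cm^2/s -> m^2/s


def wall_uptake_parameter(d_in: float, odorant: Odorant, mucosa: MucosaSpec) -> UptakeParameter:
    """Dimensionless wall-uptake parameter K = d_in * Dm / (Da * beta * d).

    ``d_in`` is the reference hydraulic diameter used to normalize the wall
    coordinate (the hydraulic diameter of the naris in whole-nose work).
    K is monotone increasing in ``d_in`` and ``Dm`` and decreasing in
    ``beta`` and the mucus thickness ``d``; the insoluble limit
    ``beta -> inf`` gives K -> 0.
    """
    if not d_in > 0:
        raise ValueError(f"d_in must be > 0, got {d_in!r}")
    K = d_in * odorant.Dm / (odorant.Da * odorant.beta * mucosa.mucus_thickness)
    return UptakeParameter(K=K, d_in=d_in)


# ---------------------------------------------------------------------------
# Odorant table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["name", "molecular_weight", "molar_volume", "beta", "Da", "Dm"]


def read_odorant_table(
    path: str | Path,
    *,
    temperature: float = 298.15,
    default_Dm: float = DEFAULT_MUCUS_DIFFUSIVITY,
) -> list[Odorant]:
    """Read an odorant property table from CSV.

    The expected header is ``name,molecular_weight,molar_volume,beta,Da,Dm``
    with SI units (Da, Dm in m^2/s) except the molar quantities
    (g/mol, cm^3/mol).  An empty ``Da`` cell triggers a Wilke-Chang estimate
    from the molar volume; an empty ``Dm`` cell falls back to ``default_Dm``
    (both substitutions are logged).
    """
    frame = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"odorant table {path} missing columns: {missing}")
    odorants: list[Odorant] = []
    for row in frame.itertuples(index=False):
        Dm = getattr(row, "Dm")
        if pd.isna(Dm):
            logger.info(
                "odorant %s: no Dm in table, using default %.3g m^2/s", row.name, default_Dm
            )
            Dm = default_Dm
        Da = getattr(row, "Da")
        if pd.isna(Da):
            stub = Odorant(
                name=str(row.name),
                molecular_weight=float(row.molecular_weight),
                molar_volume=float(row.molar_volume),
                beta=float(row.beta),
                Da=1.0,  # placeholder, replaced below
                Dm=float(Dm),
            )
            Da = estimate_air_diffusivity(stub, temperature=temperature)
            logger.info(
                "odorant %s: no Da in table, Wilke-Chang estimate %.3g m^2/s", row.name, Da
            )
        odorants.append(
            Odorant(
                name=str(row.name),
                molecular_weight=float(row.molecular_weight),
                molar_volume=float(row.molar_volume),
                beta=float(row.beta),
                Da=float(Da),
                Dm=float(Dm),
            )
        )
    return odorants


def write_odorant_table(odorants: Iterable[Odorant], path: str | Path) -> None:
    """Write odorants to CSV with full float precision (round-trip safe)."""
    rows = [
        {
            "name": o.name,
            "molecular_weight": repr(o.molecular_weight),
            "molar_volume": repr(o.molar_volume),
            "beta": repr(o.beta),
            "Da": repr(o.Da),
            "Dm": repr(o.Dm),
        }
        for o in odorants
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def builtin_odorant_table() -> list[Odorant]:
    """The odorant fixture table shipped with the package.

    Properties are placeholders chosen to span the air/mucus partition
    coefficient over more than six log-decades; they are synthetic values,
    not measurements.
    """
    from importlib.resources import files

    with (files("nosegc") / "data" / "odorants.csv").open("rb") as fh:
        return read_odorant_table(fh)  # type: ignore[arg-type]
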