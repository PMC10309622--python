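"""Chromatographic efficiency of olfactory channels: Golay plate theory.

Each olfactory airway path is treated as an open-tubular gas-chromatography
column whose mobile phase is the channel air and whose stationary phase is
the 30 um mucus film on the wall.  Band broadening per unit length is the
Golay plate height

    H(u) = 2*Da/u
         + 2*k'*d^2*u / (3*(1+k')^2*Dm)
         + (11*k'^2 + 6*k' + 1)*dc^2*u / (96*(1+k')^2*Da)

(longitudinal diffusion + stationary-phase + mobile-phase resistance to mass
transfer), with ``u`` the mean linear velocity, ``dc`` the channel width,
``d`` the film thickness and ``k'`` the capacity (retention) factor.  The
efficiency index is the plate number N = Lc/H with ``Lc`` the column
(averaged path) length; H is of the form A/u + B*u so the optimum is at
u_opt = sqrt(A/B) with H_min = 2*sqrt(A*B).

The capacity factor follows from the inlet/outlet concentrations at two
sampling planes: k' = (Cin - Cout)/Cout * Vm/Va, where — in the convention
adopted here, matching the source analysis and documented prominently
because the subscripts are unconventional — Vm is the *stationary* (mucus)
volume and Va the *mobile* (air) volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .odorants import Odorant, DEFAULT_MUCUS_THICKNESS

__all__ = [
    "GCColumnSpec",
    "RetentionEstimate",
    "PlateCurve",
    "SpeciesCalibration",
    "capacity_factor",
    "retention_from_absorption",
    "golay_plate_height",
    "golay_coefficients",
    "plate_number_curve",
    "species_comparison",
    "load_calibration",
    "builtin_calibration",
    "builtin_calibration_names",
    "default_velocity_grid",
]

#: Relative clamp applied to Cout when total absorption would make k' diverge.
CAPACITY_FACTOR_EPS = 1e-9


@dataclass(frozen=True)
class GCColumnSpec:
    """Geometric description of an olfactory 'column'.

    column_length : m — averaged odor path length Lc
    channel_width : m — averaged channel width dc
    mucus_thickness : m — stationary-phase film thickness d
    volume_ratio : dimensionless — stationary/mobile phase volume ratio Vm/Va
    """

    column_length: float
    channel_width: float
    mucus_thickness: float = DEFAULT_MUCUS_THICKNESS
    volume_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("column_length", "channel_width", "mucus_thickness", "volume_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"GCColumnSpec.{name} must be > 0")


@dataclass(frozen=True)
class RetentionEstimate:
    """Capacity factor derived from two concentration sampling planes."""

    Cin: float
    Cout: float
    Cm: float  # stationary-phase share: Cin - Cout
    Ca: float  # mobile-phase share: Cout
    k_prime: float


def capacity_factor(Cin: float, Cout: float, volume_ratio: float) -> RetentionEstimate:
    """k' = ((Cin - Cout)/Cout) * Vm/Va from inlet/outlet sampling planes.

    ``volume_ratio`` is Vm/Va with Vm the stationary (mucus) and Va the
    mobile (air) volume.  Cout = 0 (total absorption) makes k' diverge;
    callers should clamp Cout >= 1e-9*Cin and are told so.
    """
    if not volume_ratio > 0:
        raise ValueError("volume_ratio must be > 0")
    if not Cin > 0 or Cout > Cin:
        raise ValueError("require Cin >= Cout > 0")
    if Cout <= 0:
        raise ValueError(
            "Cout = 0 (total absorption): k' undefined. "
            f"Clamp Cout to >= {CAPACITY_FACTOR_EPS}*Cin before calling."
        )
    Cm = Cin - Cout
    k_prime = (Cm / Cout) * volume_ratio
    return RetentionEstimate(Cin=Cin, Cout=Cout, Cm=Cm, Ca=Cout, k_prime=k_prime)


def golay_coefficients(
    odorant: Odorant, column: GCColumnSpec, k_prime: float
) -> tuple[float, float]:
    """(A, B) of H(u) = A/u + B*u: longitudinal term and the combined u-linear slope."""
    if k_prime < 0:
        raise ValueError("k_prime must be >= 0")
    A = 2.0 * odorant.Da
    one_plus = (1.0 + k_prime) ** 2
    stationary = 2.0 * k_prime * column.mucus_thickness**2 / (3.0 * one_plus * odorant.Dm)
    mobile = (
        (11.0 * k_prime**2 + 6.0 * k_prime + 1.0)
        * column.channel_width**2
        / (96.0 * one_plus * odorant.Da)
    )
    return A, stationary + mobile


def golay_plate_height(u: float, odorant: Odorant, column: GCColumnSpec, k_prime: float) -> float:
    """Golay plate height H(u) [m] for an open-tubular column."""
    if not u > 0:
        raise ValueError(f"velocity must be > 0, got {u!r}")
    A, B = golay_coefficients(odorant, column, k_prime)
    return A / u + B * u


def default_velocity_grid(n: int = 2000, lo: float = 1e-4, hi: float = 1.0) -> np.ndarray:
    """Log-spaced velocity grid [m/s] covering the physiological range."""
    return np.geomspace(lo, hi, n)


@dataclass
class PlateCurve:
    """Plate height/number as a function of linear velocity for one column."""

    u: np.ndarray
    H: np.ndarray
    N: np.ndarray
    u_peak: float  # grid argmax of N
    N_peak: float
    u_opt: float  # closed-form optimum sqrt(A/B)
    H_min: float  # closed-form 2*sqrt(A*B)
    operating_velocities: tuple[float, float] | None = None
    N_at_operating: tuple[float, float] | None = None  # (min, max) over the range

    @property
    def N_peak_rounded(self) -> int:
        """Nearest-integer peak plate number (the reporting convention)."""
        return round(self.N_peak)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u": self.u, "H": self.H, "N": self.N})

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def plate_number_curve(
    column: GCColumnSpec,
    odorant: Odorant,
    k_prime: float,
    u_grid: Sequence[float] | None = None,
    operating_velocities: tuple[float, float] | float | None = None,
) -> PlateCurve:
    """N(u) = Lc/H(u) over a velocity grid, plus peak and operating-point values."""
    u = np.asarray(u_grid, dtype=float) if u_grid is not None else default_velocity_grid()
    if not np.all(u > 0):
        raise ValueError("velocity grid must be positive")
    u = np.sort(u)
    A, B = golay_coefficients(odorant, column, k_prime)
    H = A / u + B * u
    N = column.column_length / H
    i_peak = int(np.argmax(N))
    op_range: tuple[float, float] | None = None
    n_at_op: tuple[float, float] | None = None
    if operating_velocities is not None:
        if np.isscalar(operating_velocities):
            op_range = (float(operating_velocities), float(operating_velocities))
        else:
            lo, hi = operating_velocities
            op_range = (float(lo), float(hi))
        n_lo, n_hi = (column.column_length / (A / v + B * v) for v in op_range)
        n_at_op = (min(n_lo, n_hi), max(n_lo, n_hi))
    return PlateCurve(
        u=u,
        H=H,
        N=N,
        u_peak=float(u[i_peak]),
        N_peak=float(N[i_peak]),
        u_opt=math.sqrt(A / B),
        H_min=2.0 * math.sqrt(A * B),
        operating_velocities=op_range,
        N_at_operating=n_at_op,
    )


def retention_from_absorption(result, volume_ratio: float, clamp: bool = True) -> RetentionEstimate:
    """Wire the capacity factor from an absorption solve's sampling planes.

    ``Cin`` is the concentration entering the dorsal-medial channel (the
    olfactory inlet plane) and ``Cout`` the flow-weighted mean outlet
    concentration of the coil segments (the olfactory outlet plane).  Highly
    soluble odorants can absorb completely in the coils; with ``clamp`` the
    outlet is floored at ``1e-9 * Cin`` so k' stays finite, as recommended.
    """
    table = result.segment_table
    dm = table[table["region"] == "dorsal_medial"]
    coils = table[table["region"] == "olfactory_coil"]
    if dm.empty or coils.empty:
        raise ValueError("absorption result lacks dorsal-medial or coil segments")
    Cin = float(dm["inlet_concentration"].max())
    Cout = float((coils["outlet_concentration"] * coils["q"]).sum() / coils["q"].sum())
    if clamp:
        Cout = max(Cout, CAPACITY_FACTOR_EPS * Cin)
    return capacity_factor(Cin, Cout, volume_ratio)


# ---------------------------------------------------------------------------
# Species calibrations and comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesCalibration:
    """A named column calibration: geometry, odorant transport properties,
    retention factor, and the physiological operating velocity (range)."""

    name: str
    column: GCColumnSpec
    odorant: Odorant
    k_prime: float
    operating_velocities: tuple[float, float]
    reference: bool = False
    notes: str = ""

    def plate_curve(self, u_grid: Sequence[float] | None = None) -> PlateCurve:
        return plate_number_curve(
            self.column,
            self.odorant,
            self.k_prime,
            u_grid=u_grid,
            operating_velocities=self.operating_velocities,
        )


def _calibration_from_mapping(payload: Mapping) -> SpeciesCalibration:
    col = dict(payload["column"])
    if "channel_width" not in col:
        # straight-tube rule: diameter from the feeding stream's flow and velocity
        area = float(col.pop("dm_flow")) / float(col.pop("dm_velocity"))
        col["channel_width"] = math.sqrt(4.0 * area / math.pi)
    column = GCColumnSpec(
        column_length=float(col["length"]),
        channel_width=float(col["channel_width"]),
        mucus_thickness=float(col.get("mucus_thickness", DEFAULT_MUCUS_THICKNESS)),
        volume_ratio=float(col.get("volume_ratio", 1.0)),
    )
    od = payload["odorant"]
    odorant = Odorant(
        name=od.get("name", "calibration-odorant"),
        molecular_weight=float(od.get("molecular_weight", 100.0)),
        molar_volume=float(od.get("molar_volume", 100.0)),
        beta=float(od.get("beta", 1.0)),
        Da=float(od["Da"]),
        Dm=float(od["Dm"]),
    )
    op = payload["operating_velocity"]
    if np.isscalar(op):
        op_range = (float(op), float(op))
    else:
        op_range = (float(op[0]), float(op[1]))
    return SpeciesCalibration(
        name=str(payload["name"]),
        column=column,
        odorant=odorant,
        k_prime=float(payload.get("k_prime", 1.0)),
        operating_velocities=op_range,
        reference=bool(payload.get("reference", False)),
        notes=str(payload.get("notes", "")),
    )


def load_calibration(path: str | Path) -> SpeciesCalibration:
    """Load a species calibration from a YAML file."""
    with open(path) as fh:
        return _calibration_from_mapping(yaml.safe_load(fh))


def builtin_calibration_names() -> list[str]:
    from importlib.resources import files

    folder = files("nosegc") / "data" / "species"
    return sorted(p.name.removesuffix(".yaml") for p in folder.iterdir() if p.name.endswith(".yaml"))


def builtin_calibration(name: str) -> SpeciesCalibration:
    """Load one of the calibrations shipped with the package (cat, rat, human, straight_tube)."""
    from importlib.resources import files

    resource = files("nosegc") / "data" / "species" / f"{name}.yaml"
    with resource.open() as fh:
        return _calibration_from_mapping(yaml.safe_load(fh))


def species_comparison(
    calibrations: Sequence[SpeciesCalibration], u_grid: Sequence[float] | None = None
) -> pd.DataFrame:
    """Compare plate-number curves across calibrations.

    The "actual" plate number of a calibration is the best (maximum) N within
    its physiological operating-velocity range; ``ratio_to_reference`` is
    that value divided by the reference calibration's.
    """
    if len(calibrations) < 2:
        raise ValueError("need at least 2 calibrations to compare")
    references = [c for c in calibrations if c.reference]
    if len(references) != 1:
        raise ValueError("exactly one calibration must be flagged as reference")
    curves = {c.name: c.plate_curve(u_grid) for c in calibrations}
    ref_actual = curves[references[0].name].N_at_operating[1]
    rows = []
    for cal in calibrations:
        curve = curves[cal.name]
        n_lo, n_hi = curve.N_at_operating
        rows.append(
            {
                "name": cal.name,
                "u_opt": curve.u_opt,
                "N_peak": curve.N_peak,
                "N_peak_rounded": curve.N_peak_rounded,
                "operating_u_min": cal.operating_velocities[0],
                "operating_u_max": cal.operating_velocities[1],
                "N_at_operating_min": n_lo,
                "N_at_operating_max": n_hi,
                "ratio_to_reference": n_hi / ref_actual,
                "reference": cal.reference,
            }
        )
    return pd.DataFrame(rows)
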