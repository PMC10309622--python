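"""Pressure-driven laminar flow on a nasal channel network.

A reduced-order stand-in for 3D CFD: each segment is a laminar
(Hagen-Poiseuille) resistor ``R = s * 128 * mu * L / (pi * d_h**4) / m``
with hydraulic diameter ``d_h``, shape factor ``s`` (1 = pure
hydraulic-diameter approximation) and bundle multiplicity ``m``.  Flows and
node pressures follow from Kirchhoff's laws with the total breathing flow
imposed at the naris.  The solve is steady and direction-symmetric
(reversing inlet and outlet negates every flow), so inhale/exhale asymmetry
is out of reach by construction; the breathing frequency enters only the
dimensionless regime report (Womersley, Strouhal, Reynolds numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ChannelSegment, NasalNetwork, NetworkStructureError, Region

__all__ = [
    "BreathingCondition",
    "FlowSolution",
    "RegimeReport",
    "segment_resistance",
    "solve_network_flow",
    "dm_fraction",
    "regime_report",
    "RESTFUL",
    "SNIFFING",
]


@dataclass(frozen=True)
class BreathingCondition:
    """Breathing operating point.

    total_flow : m^3/s — volumetric flow through the nose
    frequency : Hz — breathing cycle frequency (regime report only)
    kinematic_viscosity : m^2/s — of air
    air_density : kg/m^3 — used to form the dynamic viscosity for resistances
    """

    total_flow: float = 22e-6
    frequency: float = 1.0
    kinematic_viscosity: float = 1.5e-5
    air_density: float = 1.2

    def __post_init__(self) -> None:
        if not self.total_flow > 0:
            raise ValueError("total_flow must be > 0")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if not (self.kinematic_viscosity > 0 and self.air_density > 0):
            raise ValueError("kinematic_viscosity and air_density must be > 0")

    @property
    def dynamic_viscosity(self) -> float:
        return self.kinematic_viscosity * self.air_density


#: Restful breathing of a ~5 kg cat: 22 ml/s at 1 Hz.
RESTFUL = BreathingCondition(total_flow=22e-6, frequency=1.0)
#: Sniffing: 140 ml/s at 5 Hz.
SNIFFING = BreathingCondition(total_flow=140e-6, frequency=5.0)


def segment_resistance(seg: ChannelSegment, dynamic_viscosity: float) -> float:
    """Laminar hydraulic resistance [Pa s/m^3] of a segment (bundle-aware)."""
    single = (
        seg.shape_factor
        * 128.0
        * dynamic_viscosity
        * seg.length
        / (math.pi * seg.hydraulic_diameter**4)
    )
    return single / seg.multiplicity


@dataclass
class FlowSolution:
    """Per-segment flows and node pressures for one breathing condition."""

    q: dict[str, float]  # segment id -> volumetric flow through the bundle [m^3/s]
    u: dict[str, float]  # segment id -> mean velocity in a single channel [m/s]
    pressure: dict[str, float]  # node -> pressure relative to the outlet [Pa]
    condition: BreathingCondition

    def to_frame(self, net: NasalNetwork) -> pd.DataFrame:
        rows = []
        for _, _, seg in net.segment_edges():
            u_val = self.u[seg.id]
            rows.append(
                {
                    "segment": seg.id,
                    "region": seg.region.value,
                    "q": self.q[seg.id],
                    "u": u_val,
                    "Re": abs(u_val) * seg.hydraulic_diameter / self.condition.kinematic_viscosity,
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, net: NasalNetwork, path: str | Path) -> None:
        self.to_frame(net).to_csv(path, index=False)


def solve_network_flow(net: NasalNetwork, condition: BreathingCondition) -> FlowSolution:
    """Solve the linear resistance network for flows and pressures.

    Imposes ``total_flow`` injected at the inlet and withdrawn at the outlet,
    grounds the outlet pressure at 0, and solves the weighted graph Laplacian.
    Kirchhoff balance at every junction holds to solver precision
    (``<= 1e-12`` relative) and the solution is unique.
    """
    g = net.graph
    if not nx.is_weakly_connected(g):
        raise NetworkStructureError("cannot solve flow on a disconnected network")
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mu = condition.dynamic_viscosity
    rows, cols, vals = [], [], []
    conductances = []
    for u_node, v_node, seg in net.segment_edges():
        G = 1.0 / segment_resistance(seg, mu)
        conductances.append((u_node, v_node, seg, G))
        i, j = index[u_node], index[v_node]
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [G, G, -G, -G]
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b = np.zeros(n)
    b[index[net.inlet]] = condition.total_flow
    b[index[net.outlet]] = -condition.total_flow
    # ground the outlet: replace its equation by p_outlet = 0
    lap = lap.tolil()
    lap[index[net.outlet], :] = 0.0
    lap[index[net.outlet], index[net.outlet]] = 1.0
    b[index[net.outlet]] = 0.0
    try:
        p = spla.spsolve(lap.tocsr(), b)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular flow system: {exc}") from exc
    if not np.all(np.isfinite(p)):
        raise RuntimeError("flow solve produced non-finite pressures (singular system?)")
    q = {}
    u = {}
    for u_node, v_node, seg, G in conductances:
        flow = G * (p[index[u_node]] - p[index[v_node]])
        q[seg.id] = flow
        u[seg.id] = flow / (seg.multiplicity * seg.area)
    pressure = {node: float(p[index[node]]) for node in nodes}
    return FlowSolution(q=q, u=u, pressure=pressure, condition=condition)


def dm_fraction(flow: FlowSolution, net: NasalNetwork) -> float:
    """Fraction of the total flow entering the dorsal-medial channel.

    Measured at the upstream junction of the DM region: the summed flow of
    dorsal-medial segments whose tail node receives no dorsal-medial inflow.
    """
    dm_edges = [(u, v, s) for u, v, s in net.segment_edges() if s.region is Region.DORSAL_MEDIAL]
    if not dm_edges:
        raise NetworkStructureError("network has no dorsal-medial segments")
    dm_heads = {v for _, v, _ in dm_edges}
    entry_flow = sum(flow.q[s.id] for u, _, s in dm_edges if u not in dm_heads)
    return float(entry_flow / flow.condition.total_flow)


@dataclass
class RegimeReport:
    """Dimensionless regime numbers per segment plus naris-based globals.

    quasi-steady when W0 < 4 and S < 1; laminar when Re < 2300.
    """

    table: pd.DataFrame  # per-segment W0, S, Re, flags, axial position, Peclet
    naris_womersley: float
    naris_reynolds: float
    quasi_steady: bool
    laminar: bool


def regime_report(
    net: NasalNetwork,
    flow: FlowSolution,
    condition: BreathingCondition,
    axial_positions: list[float] | None = None,
) -> RegimeReport:
    """Evaluate Womersley, Strouhal and Reynolds numbers along the network.

    Per segment (at its midpoint, or at the supplied axial positions mapped
    to the segment spanning them): W0 = R*sqrt(2*pi*f/nu) with R the local
    hydraulic diameter, S = 2*pi*f*L/U with L the axial distance from the
    inlet, Re = U*R/nu.  The report also carries the naris-based W0 and Re
    (R = hydraulic diameter of the inlet segment, U = inlet velocity), the
    whole-nose analog of the classical criteria.  Zero local velocity gives
    S = +inf and a false quasi-steady flag.  The axial Peclet number
    ``u*L/Da`` (Da ~ 6e-6 m^2/s) is included as a plug-flow validity check.
    """
    f = condition.frequency
    nu = condition.kinematic_viscosity
    omega = 2.0 * math.pi * f
    spans = []
    for u_node, _, seg in net.segment_edges():
        start = net.inlet_distance(u_node)
        spans.append((start, start + seg.length, seg))

    def locate(position: float) -> tuple[float, ChannelSegment]:
        for start, end, seg in spans:
            if start - 1e-12 <= position <= end + 1e-12:
                return position, seg
        raise ValueError(f"axial position {position} outside network extent")

    if axial_positions is None:
        samples = [(0.5 * (start + end), seg) for start, end, seg in spans]
    else:
        samples = [locate(p) for p in axial_positions]

    rows = []
    for position, seg in samples:
        R = seg.hydraulic_diameter
        U = abs(flow.u[seg.id])
        W0 = R * math.sqrt(omega / nu)
        S = (omega * position / U) if U > 0 else math.inf
        Re = U * R / nu
        peclet = U * seg.length / 6e-6
        rows.append(
            {
                "segment": seg.id,
                "axial_position": position,
                "W0": W0,
                "S": S,
                "Re": Re,
                "Peclet": peclet,
                "quasi_steady": (W0 < 4.0) and (S < 1.0),
                "laminar": Re < 2300.0,
            }
        )
    table = pd.DataFrame(rows)
    inlet_seg = next(seg for u, _, seg in net.segment_edges() if u == net.inlet)
    naris_R = inlet_seg.hydraulic_diameter
    naris_U = abs(flow.u[inlet_seg.id])
    return RegimeReport(
        table=table,
        naris_womersley=naris_R * math.sqrt(omega / nu),
        naris_reynolds=naris_U * naris_R / nu,
        quasi_steady=bool(table["quasi_steady"].all()),
        laminar=bool(table["laminar"].all()),
    )
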