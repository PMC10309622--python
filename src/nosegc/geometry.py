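"""Synthetic nasal channel networks.

The nasal cavity is reduced to a directed graph of laminar channel segments
running from the naris (single inlet) to the nasopharynx (single outlet).
Four regions are distinguished:

* ``anterior_respiratory`` — vestibule trunk, the anterior (non-olfactory)
  portion of the dorsal-medial airway, and the maxillary turbinate bundle;
* ``dorsal_medial`` — the posterior dorsal-medial (DM) channel that feeds the
  olfactory region at high speed;
* ``olfactory_coil`` — parallel coiled ethmoid-turbinate channels, each a
  candidate chromatographic column;
* ``posterior_respiratory`` — the respiratory pathway running parallel
  (ventral) to the olfactory region.

The generator is a stand-in for CT-derived anatomy: it reproduces the
*structural* features the downstream analysis relies on (a fast DM stream
bypassing the absorbing maxillary labyrinth, many slow parallel olfactory
coils, a three-region partition) without any claim of anatomical fidelity.
Dense bundles of identical parallel channels (maxillary and posterior
turbinates) are lumped into one segment with a ``multiplicity`` count, the
usual device of reduced airway-tree models; olfactory coils are kept as
explicit parallel branches because the analysis samples individual paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .odorants import EpitheliumClass, MucosaSpec, DEFAULT_MUCUS_THICKNESS

__all__ = [
    "Region",
    "ChannelSegment",
    "NasalNetwork",
    "AreaProfile",
    "AnteriorSpec",
    "PosteriorSpec",
    "slit_geometry",
    "circular_geometry",
    "build_parallel_coil_network",
    "build_straight_tube_network",
    "cat_default_network",
    "surface_area_profile",
    "mean_path_length",
    "validate_network",
]


class Region(str, Enum):
    ANTERIOR_RESPIRATORY = "anterior_respiratory"
    DORSAL_MEDIAL = "dorsal_medial"
    OLFACTORY_COIL = "olfactory_coil"
    POSTERIOR_RESPIRATORY = "posterior_respiratory"


#: Regions whose segments make up the "olfactory region" in aggregate results.
OLFACTORY_REGIONS = frozenset({Region.DORSAL_MEDIAL, Region.OLFACTORY_COIL})


def slit_geometry(width: float, aspect: float = 3.0) -> tuple[float, float]:
    """(area, perimeter) of a rectangular slit of given width and depth = aspect*width.

    Turbinate airways are slit-like; a 3:1 depth:width rectangle is the
    default cross-section for generated channels.
    """
    if not (width > 0 and aspect > 0):
        raise ValueError("width and aspect must be > 0")
    depth = aspect * width
    return width * depth, 2.0 * (width + depth)


def circular_geometry(diameter: float) -> tuple[float, float]:
    """(area, perimeter) of a circular duct."""
    if not diameter > 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter**2 / 4.0, math.pi * diameter


@dataclass(frozen=True)
class ChannelSegment:
    """One laminar channel (or a bundle of ``multiplicity`` identical channels).

    ``area`` and ``perimeter`` describe a *single* channel cross-section; a
    bundle of m identical channels in parallel has total cross-section
    ``m*area``, total lateral surface ``m*perimeter*length`` and 1/m the
    single-channel hydraulic resistance.
    """

    id: str
    length: float
    area: float
    perimeter: float
    mucosa: MucosaSpec
    region: Region
    multiplicity: int = 1
    shape_factor: float = 1.0  # laminar resistance correction; 1 = pure d_h approximation

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.area > 0 and self.perimeter > 0):
            raise ValueError(f"segment {self.id}: length, area, perimeter must be > 0")
        if self.multiplicity < 1:
            raise ValueError(f"segment {self.id}: multiplicity must be >= 1")
        if not self.shape_factor > 0:
            raise ValueError(f"segment {self.id}: shape_factor must be > 0")

    @property
    def hydraulic_diameter(self) -> float:
        """4 * area / perimeter of a single channel [m]."""
        return 4.0 * self.area / self.perimeter

    @property
    def lateral_area(self) -> float:
        """Total wetted wall area of the bundle: multiplicity * perimeter * length [m^2]."""
        return self.multiplicity * self.perimeter * self.length

    @property
    def is_circular(self) -> bool:
        return math.isclose(self.perimeter**2, 4.0 * math.pi * self.area, rel_tol=1e-9)


@dataclass
class NasalNetwork:
    """Directed channel network with a single inlet (naris) and outlet (nasopharynx)."""

    graph: nx.MultiDiGraph
    inlet: str
    outlet: str
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_segments(
        cls,
        edges: Sequence[tuple[str, str, ChannelSegment]],
        inlet: str,
        outlet: str,
        provenance: Mapping | None = None,
    ) -> "NasalNetwork":
        g = nx.MultiDiGraph()
        for tail, head, seg in edges:
            g.add_edge(tail, head, key=seg.id, segment=seg)
        net = cls(graph=g, inlet=inlet, outlet=outlet, provenance=dict(provenance or {}))
        validate_network(net)
        return net

    # -- access ------------------------------------------------------------

    def segments(self) -> list[ChannelSegment]:
        return [d["segment"] for _, _, d in self.graph.edges(data=True)]

    def segment_edges(self) -> list[tuple[str, str, ChannelSegment]]:
        """(tail, head, segment) triples sorted by segment id for determinism."""
        triples = [(u, v, d["segment"]) for u, v, d in self.graph.edges(data=True)]
        return sorted(triples, key=lambda t: t[2].id)

    def segment(self, seg_id: str) -> ChannelSegment:
        for _, _, seg in self.segment_edges():
            if seg.id == seg_id:
                return seg
        raise KeyError(seg_id)

    def inlet_distance(self, node: str) -> float:
        """Shortest path length [m] from the inlet to ``node`` along segment lengths."""
        # multigraph: the weight callable receives the dict of parallel edges
        return nx.shortest_path_length(
            self.graph,
            self.inlet,
            node,
            weight=lambda u, v, d: min(dd["segment"].length for dd in d.values()),
        )

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "inlet": self.inlet,
            "outlet": self.outlet,
            "provenance": self.provenance,
            "nodes": sorted(self.graph.nodes),
            "segments": [
                {
                    "id": seg.id,
                    "tail": u,
                    "head": v,
                    "length": seg.length,
                    "area": seg.area,
                    "perimeter": seg.perimeter,
                    "multiplicity": seg.multiplicity,
                    "shape_factor": seg.shape_factor,
                    "region": seg.region.value,
                    "epithelium": seg.mucosa.epithelium_class.value,
                    "mucus_thickness": seg.mucosa.mucus_thickness,
                }
                for u, v, seg in self.segment_edges()
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "NasalNetwork":
        payload = json.loads(text)
        edges = []
        for s in payload["segments"]:
            seg = ChannelSegment(
                id=s["id"],
                length=s["length"],
                area=s["area"],
                perimeter=s["perimeter"],
                multiplicity=s["multiplicity"],
                shape_factor=s["shape_factor"],
                region=Region(s["region"]),
                mucosa=MucosaSpec(
                    epithelium_class=EpitheliumClass(s["epithelium"]),
                    mucus_thickness=s["mucus_thickness"],
                ),
            )
            edges.append((s["tail"], s["head"], seg))
        return cls.from_segments(
            edges, inlet=payload["inlet"], outlet=payload["outlet"], provenance=payload["provenance"]
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "NasalNetwork":
        return cls.from_json(Path(path).read_text())


class NetworkStructureError(ValueError):
    """Raised when a network violates the structural invariants."""


def validate_network(net: NasalNetwork) -> None:
    """Check the structural invariants; raise :class:`NetworkStructureError` on failure.

    Invariants: weak connectivity; exactly one inlet (no in-edges) and one
    outlet (no out-edges); every segment on at least one inlet->outlet path;
    hydraulic-diameter consistency; olfactory coils fed from dorsal-medial
    segments.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise NetworkStructureError("network has no segments")
    if not nx.is_weakly_connected(g):
        raise NetworkStructureError("network is not weakly connected")
    sources = [n for n in g.nodes if g.in_degree(n) == 0]
    sinks = [n for n in g.nodes if g.out_degree(n) == 0]
    if set(sources) != {net.inlet} or set(sinks) != {net.outlet}:
        raise NetworkStructureError(
            f"expected single inlet {net.inlet!r} and outlet {net.outlet!r}, "
            f"found sources={sources}, sinks={sinks}"
        )
    reachable = nx.descendants(g, net.inlet) | {net.inlet}
    reaching = nx.ancestors(g, net.outlet) | {net.outlet}
    for u, v, seg in net.segment_edges():
        if u not in reachable or v not in reaching:
            raise NetworkStructureError(f"segment {seg.id} lies on no inlet->outlet path")
    # coil feeding: each node where coil segments start must receive flow
    # from a dorsal-medial (or upstream coil) segment only
    coil_heads = {u for u, v, seg in net.segment_edges() if seg.region is Region.OLFACTORY_COIL}
    for node in coil_heads:
        feeders = [d["segment"].region for _, _, d in g.in_edges(node, data=True)]
        if feeders and not any(
            r in (Region.DORSAL_MEDIAL, Region.OLFACTORY_COIL) for r in feeders
        ):
            raise NetworkStructureError(
                f"olfactory coils at node {node!r} are not fed by dorsal-medial segments"
            )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnteriorSpec:
    """Anterior respiratory region: vestibule trunk, the anterior portion of
    the DM airway, and the maxillary turbinate bundle feeding the posterior
    respiratory pathway."""

    trunk_length: float
    trunk_area: float
    trunk_perimeter: float
    feed_length: float  # anterior (non-olfactory) DM portion; shares the DM cross-section
    maxillary_channels: int
    maxillary_width: float
    maxillary_length: float
    maxillary_aspect: float = 3.0


@dataclass(frozen=True)
class PosteriorSpec:
    """Posterior respiratory bundle running parallel to the olfactory region."""

    n_channels: int
    width: float
    length: float
    aspect: float = 3.0


_DEFAULT_MUCOSA = {
    "trunk": MucosaSpec(EpitheliumClass.SQUAMOUS),
    "anterior": MucosaSpec(EpitheliumClass.RESPIRATORY),
    "dorsal_medial": MucosaSpec(EpitheliumClass.OLFACTORY),
    "olfactory_coil": MucosaSpec(EpitheliumClass.OLFACTORY),
    "posterior": MucosaSpec(EpitheliumClass.RESPIRATORY),
}


def build_parallel_coil_network(
    n_coils: int,
    coil_path_length: float,
    coil_width: float,
    dm_length: float,
    dm_width: float,
    anterior_spec: AnteriorSpec,
    posterior_spec: PosteriorSpec,
    mucosa_map: Mapping[str, MucosaSpec] | None = None,
    seed: int = 0,
    coil_aspect: float = 3.0,
) -> NasalNetwork:
    """Generate a parallel-coil nasal network.

    Topology::

        naris --trunk--> n0 --antDM--> n1 --DM--> n2 ==coils==> nasopharynx
                          \\--maxillary--> n3 --posterior--> nasopharynx

    The DM pathway (anterior DM feed, posterior DM channel, ``n_coils``
    identical parallel coils) carries the olfactory stream; the maxillary /
    posterior bundles carry the respiratory stream.  Deterministic given the
    parameters; ``seed`` is recorded in provenance and consumed only by the
    (currently jitter-free) generator, so identical calls are byte-identical.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    for name, value in (
        ("coil_path_length", coil_path_length),
        ("coil_width", coil_width),
        ("dm_length", dm_length),
        ("dm_width", dm_width),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    mucosa = dict(_DEFAULT_MUCOSA)
    mucosa.update(mucosa_map or {})

    dm_area, dm_perimeter = slit_geometry(dm_width, coil_aspect)
    coil_area, coil_perimeter = slit_geometry(coil_width, coil_aspect)
    max_area, max_perimeter = slit_geometry(
        anterior_spec.maxillary_width, anterior_spec.maxillary_aspect
    )
    post_area, post_perimeter = slit_geometry(posterior_spec.width, posterior_spec.aspect)

    edges: list[tuple[str, str, ChannelSegment]] = [
        (
            "naris",
            "n0",
            ChannelSegment(
                id="trunk",
                length=anterior_spec.trunk_length,
                area=anterior_spec.trunk_area,
                perimeter=anterior_spec.trunk_perimeter,
                mucosa=mucosa["trunk"],
                region=Region.ANTERIOR_RESPIRATORY,
            ),
        ),
        (
            "n0",
            "n1",
            ChannelSegment(
                id="anterior_dm_feed",
                length=anterior_spec.feed_length,
                area=dm_area,
                perimeter=dm_perimeter,
                mucosa=mucosa["anterior"],
                region=Region.ANTERIOR_RESPIRATORY,
            ),
        ),
        (
            "n1",
            "n2",
            ChannelSegment(
                id="dorsal_medial",
                length=dm_length,
                area=dm_area,
                perimeter=dm_perimeter,
                mucosa=mucosa["dorsal_medial"],
                region=Region.DORSAL_MEDIAL,
            ),
        ),
        (
            "n0",
            "n3",
            ChannelSegment(
                id="maxillary_bundle",
                length=anterior_spec.maxillary_length,
                area=max_area,
                perimeter=max_perimeter,
                multiplicity=anterior_spec.maxillary_channels,
                mucosa=mucosa["anterior"],
                region=Region.ANTERIOR_RESPIRATORY,
            ),
        ),
        (
            "n3",
            "nasopharynx",
            ChannelSegment(
                id="posterior_bundle",
                length=posterior_spec.length,
                area=post_area,
                perimeter=post_perimeter,
                multiplicity=posterior_spec.n_channels,
                mucosa=mucosa["posterior"],
                region=Region.POSTERIOR_RESPIRATORY,
            ),
        ),
    ]
    width = len(str(n_coils - 1))
    for i in range(n_coils):
        edges.append(
            (
                "n2",
                "nasopharynx",
                ChannelSegment(
                    id=f"coil_{i:0{width}d}",
                    length=coil_path_length,
                    area=coil_area,
                    perimeter=coil_perimeter,
                    mucosa=mucosa["olfactory_coil"],
                    region=Region.OLFACTORY_COIL,
                ),
            )
        )
    provenance = {
        "generator": "build_parallel_coil_network",
        "seed": seed,
        "parameters": {
            "n_coils": n_coils,
            "coil_path_length": coil_path_length,
            "coil_width": coil_width,
            "coil_aspect": coil_aspect,
            "dm_length": dm_length,
            "dm_width": dm_width,
            "anterior_spec": vars(anterior_spec) | {},
            "posterior_spec": vars(posterior_spec) | {},
        },
    }
    return NasalNetwork.from_segments(edges, inlet="naris", outlet="nasopharynx", provenance=provenance)


def build_straight_tube_network(
    dm_flow: float,
    dm_velocity: float,
    tube_length: float,
    mucosa: MucosaSpec | None = None,
) -> NasalNetwork:
    """Amphibian-like straight-tube olfactory channel.

    A single circular tube sized so the dorsal-medial stream would pass at
    its native velocity: cross-section A = dm_flow / dm_velocity, diameter
    D = sqrt(4A/pi); the tube length is the straight-line distance between
    olfactory inlet and outlet (a configuration value, not a coiled path
    length).
    """
    for name, value in (("dm_flow", dm_flow), ("dm_velocity", dm_velocity), ("tube_length", tube_length)):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    area = dm_flow / dm_velocity
    diameter = math.sqrt(4.0 * area / math.pi)
    seg_area, seg_perimeter = circular_geometry(diameter)
    seg = ChannelSegment(
        id="straight_tube",
        length=tube_length,
        area=seg_area,
        perimeter=seg_perimeter,
        mucosa=mucosa or MucosaSpec(EpitheliumClass.OLFACTORY),
        region=Region.OLFACTORY_COIL,
    )
    provenance = {
        "generator": "build_straight_tube_network",
        "parameters": {
            "dm_flow": dm_flow,
            "dm_velocity": dm_velocity,
            "tube_length": tube_length,
            "diameter": diameter,
        },
    }
    return NasalNetwork.from_segments(
        [("naris", "nasopharynx", seg)], inlet="naris", outlet="nasopharynx", provenance=provenance
    )


#: Documented cat-like calibration (see docs/methods.md for the derivation).
#: Chosen so that at restful breathing (22 ml/s) the DM pathway carries
#: ~15-20% of the flow at ~0.3 m/s, coil velocities fall in 0.01-0.11 m/s,
#: the olfactory-epithelium share of the wall area is ~12%, and the mean
#: olfactory path length is 0.181 m.
CAT_DEFAULTS = dict(
    n_coils=100,
    coil_path_length=0.151,
    coil_width=5.0e-4,
    dm_length=0.03,
    dm_width=2.04e-3,
    anterior_spec=AnteriorSpec(
        trunk_length=0.01,
        trunk_area=8.0e-5,
        trunk_perimeter=0.08,  # flat naris cross-section, d_h = 4 mm
        feed_length=0.02,
        maxillary_channels=2100,
        maxillary_width=3.0e-4,
        maxillary_length=0.035,
    ),
    posterior_spec=PosteriorSpec(n_channels=2100, width=3.0e-4, length=0.06),
)


def cat_default_network(seed: int = 0) -> NasalNetwork:
    """Cat-like parallel-coil network under the documented default calibration."""
    return build_parallel_coil_network(seed=seed, **CAT_DEFAULTS)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------


@dataclass
class AreaProfile:
    """Wall surface area vs. distance from the naris, split by epithelium class."""

    bin_edges: np.ndarray  # [m], len n+1
    total_area: np.ndarray  # [m^2] per bin, len n
    fractions: pd.DataFrame  # one column per epithelium class, rows = bins

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def surface_area_profile(net: NasalNetwork, bin_width: float) -> AreaProfile:
    """Distribute each segment's lateral area along its inlet-distance span.

    Distance is measured along the shortest inlet->segment path (the network
    analog of the axial "distance to the nostril" coordinate); each segment's
    wall area ``multiplicity * P * L`` is spread uniformly over
    [dist(tail), dist(tail) + L] and accumulated into bins of ``bin_width``.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    spans = []
    for u, _, seg in net.segment_edges():
        start = net.inlet_distance(u)
        spans.append((start, start + seg.length, seg))
    max_dist = max(end for _, end, _ in spans)
    n_bins = max(1, int(math.ceil(max_dist / bin_width - 1e-12)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    classes = [c.value for c in EpitheliumClass]
    per_class = {c: np.zeros(n_bins) for c in classes}
    for start, end, seg in spans:
        density = seg.lateral_area / (end - start)  # m^2 per m of path
        lo = np.clip(edges[:-1], start, end)
        hi = np.clip(edges[1:], start, end)
        overlap = np.maximum(hi - lo, 0.0)
        per_class[seg.mucosa.epithelium_class.value] += density * overlap
    total = sum(per_class.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {c: np.where(total > 0, per_class[c] / total, 0.0) for c in classes}
    return AreaProfile(
        bin_edges=edges,
        total_area=np.asarray(total),
        fractions=pd.DataFrame(frac),
    )


def mean_path_length(net: NasalNetwork, n_paths: int = 10, seed: int = 0) -> float:
    """Mean length of sampled inlet->outlet paths through the olfactory region.

    Paths are uniform random walks (sampled with replacement) over the
    subgraph of olfactory-region segments (dorsal-medial + coils), started at
    the subgraph's entry nodes; at each junction an outgoing olfactory
    segment is chosen uniformly, ties broken by segment id order.  The
    default of 10 sampled paths mirrors the path-averaging procedure used to
    define a chromatographic column length for the coiled olfactory region.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    sub_edges = [
        (u, v, seg) for u, v, seg in net.segment_edges() if seg.region in OLFACTORY_REGIONS
    ]
    if not sub_edges:
        raise NetworkStructureError("network has no olfactory-region segments")
    out_by_node: dict[str, list[tuple[str, ChannelSegment]]] = {}
    heads = set()
    tails = set()
    for u, v, seg in sub_edges:
        out_by_node.setdefault(u, []).append((v, seg))
        tails.add(u)
        heads.add(v)
    for cands in out_by_node.values():
        cands.sort(key=lambda t: t[1].id)
    entry_nodes = sorted(tails - heads)
    if not entry_nodes:
        raise NetworkStructureError("olfactory subgraph has no entry node (cycle?)")
    rng = np.random.default_rng(seed)
    lengths = []
    for _ in range(n_paths):
        node = entry_nodes[int(rng.integers(len(entry_nodes)))]
        total = 0.0
        while node in out_by_node:
            nxt, seg = out_by_node[node][int(rng.integers(len(out_by_node[node])))]
            total += seg.length
            node = nxt
        lengths.append(total)
    return float(np.mean(lengths))
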