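import numpy as np
import pytest

from nosegc.airflow import RESTFUL, solve_network_flow
from nosegc.geometry import (
    ChannelSegment,
    NasalNetwork,
    Region,
    cat_default_network,
    circular_geometry,
    slit_geometry,
)
from nosegc.odorants import EpitheliumClass, MucosaSpec, Odorant


@pytest.fixture(scope="session")
def cat_network():
    return cat_default_network(seed=0)


@pytest.fixture(scope="session")
def cat_flow(cat_network):
    return solve_network_flow(cat_network, RESTFUL)


@pytest.fixture
def reference_odorant():
    """Generic odorant with the transport coefficients used throughout the docs."""
    return Odorant(
        name="reference",
        molecular_weight=100.0,
        molar_volume=100.0,
        beta=1.0,
        Da=6e-6,
        Dm=1e-9,
    )


def make_segment(
    seg_id="s",
    length=0.05,
    diameter=None,
    width=None,
    region=Region.ANTERIOR_RESPIRATORY,
    epithelium=EpitheliumClass.RESPIRATORY,
    mucus_thickness=30e-6,
    multiplicity=1,
):
    """Convenience constructor for toy segments (circular unless a slit width is given)."""
    if width is not None:
        area, perimeter = slit_geometry(width)
    else:
        area, perimeter = circular_geometry(diameter or 1e-3)
    return ChannelSegment(
        id=seg_id,
        length=length,
        area=area,
        perimeter=perimeter,
        mucosa=MucosaSpec(epithelium, mucus_thickness),
        region=region,
        multiplicity=multiplicity,
    )


def make_chain(*segments, inlet="in", outlet="out"):
    """Serial chain network from segments, in order."""
    nodes = [inlet] + [f"j{i}" for i in range(len(segments) - 1)] + [outlet]
    edges = [(nodes[i], nodes[i + 1], seg) for i, seg in enumerate(segments)]
    return NasalNetwork.from_segments(edges, inlet=inlet, outlet=outlet)


@pytest.fixture
def three_region_toy():
    """Anterior trunk feeding an olfactory and a posterior branch in parallel."""
    anterior = make_segment("anterior", diameter=4e-3, length=0.03, region=Region.ANTERIOR_RESPIRATORY)
    dm = make_segment(
        "dm", diameter=2e-3, length=0.02, region=Region.DORSAL_MEDIAL,
        epithelium=EpitheliumClass.OLFACTORY,
    )
    coil = make_segment(
        "coil", width=5e-4, length=0.1, region=Region.OLFACTORY_COIL,
        epithelium=EpitheliumClass.OLFACTORY,
    )
    posterior = make_segment("posterior", diameter=2e-3, length=0.05, region=Region.POSTERIOR_RESPIRATORY)
    return NasalNetwork.from_segments(
        [
            ("in", "n0", anterior),
            ("n0", "n1", dm),
            ("n1", "out", coil),
            ("n0", "out", posterior),
        ],
        inlet="in",
        outlet="out",
    )
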