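import math

import numpy as np
import pytest

from nosegc.airflow import RESTFUL, solve_network_flow
from nosegc.absorption import solve_network_absorption
from nosegc.geometry import (
    CAT_DEFAULTS,
    AnteriorSpec,
    NasalNetwork,
    NetworkStructureError,
    PosteriorSpec,
    Region,
    build_parallel_coil_network,
    build_straight_tube_network,
    cat_default_network,
    mean_path_length,
    surface_area_profile,
    validate_network,
)
from nosegc.odorants import EpitheliumClass

from conftest import make_chain, make_segment


def small_coil_network(n_coils):
    params = dict(CAT_DEFAULTS)
    params["n_coils"] = n_coils
    return build_parallel_coil_network(seed=0, **params)


class TestParallelCoilGenerator:
    def test_single_coil_is_a_serial_olfactory_chain(self):
        net = small_coil_network(1)
        coils = [s for s in net.segments() if s.region is Region.OLFACTORY_COIL]
        assert len(coils) == 1
        # the DM pathway anterior->DM->coil is a serial chain to the outlet
        path = ["trunk", "anterior_dm_feed", "dorsal_medial", coils[0].id]
        node = net.inlet
        for seg_id in path:
            edges = [(u, v) for u, v, s in net.segment_edges() if s.id == seg_id]
            (u, v), = edges
            assert u == node
            node = v
        assert node == net.outlet

    def test_ten_identical_parallel_coils(self):
        net = small_coil_network(10)
        coils = [s for s in net.segments() if s.region is Region.OLFACTORY_COIL]
        assert len(coils) == 10
        assert len({(s.length, s.area, s.perimeter) for s in coils}) == 1
        assert all(s.mucosa.epithelium_class is EpitheliumClass.OLFACTORY for s in coils)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            small_coil_network(0)
        params = dict(CAT_DEFAULTS)
        params["coil_width"] = -1.0
        with pytest.raises(ValueError):
            build_parallel_coil_network(seed=0, **params)

    def test_cat_default_olfactory_area_share(self, cat_network):
        """Olfactory epithelium covers ~12% of the total wall surface."""
        olfactory = sum(
            s.lateral_area
            for s in cat_network.segments()
            if s.mucosa.epithelium_class is EpitheliumClass.OLFACTORY
        )
        total = sum(s.lateral_area for s in cat_network.segments())
        assert 0.11 <= olfactory / total <= 0.13

    def test_hydraulic_diameter_consistency(self, cat_network):
        for seg in cat_network.segments():
            assert seg.hydraulic_diameter == pytest.approx(4 * seg.area / seg.perimeter, rel=1e-12)

    def test_generator_determinism(self):
        a = cat_default_network(seed=3).to_json()
        b = cat_default_network(seed=3).to_json()
        assert a == b

    def test_json_round_trip(self, cat_network):
        back = NasalNetwork.from_json(cat_network.to_json())
        assert back.to_json() == cat_network.to_json()

    def test_coil_exchangeability(self, reference_odorant):
        """Permuting coil identities leaves downstream pipeline outputs unchanged."""
        net = small_coil_network(5)
        edges = []
        coil_idx = [4, 2, 0, 3, 1]
        k = 0
        for u, v, seg in net.segment_edges():
            if seg.region is Region.OLFACTORY_COIL:
                seg = type(seg)(
                    id=f"coil_{coil_idx[k]}", length=seg.length, area=seg.area,
                    perimeter=seg.perimeter, mucosa=seg.mucosa, region=seg.region,
                )
                k += 1
            edges.append((u, v, seg))
        permuted = NasalNetwork.from_segments(edges, net.inlet, net.outlet)
        for network in (net, permuted):
            flow = solve_network_flow(network, RESTFUL)
            result = solve_network_absorption(network, flow, reference_odorant)
            assert result.region_fractions == pytest.approx(
                solve_network_absorption(
                    net, solve_network_flow(net, RESTFUL), reference_odorant
                ).region_fractions
            )


class TestStraightTube:
    def test_diameter_from_dm_inlet_area_rule(self):
        net = build_straight_tube_network(dm_flow=4.4e-6, dm_velocity=0.3, tube_length=0.0264)
        (seg,) = net.segments()
        assert seg.area == pytest.approx(1.4667e-5, rel=1e-3)
        diameter = math.sqrt(4 * seg.area / math.pi)
        assert diameter == pytest.approx(4.3213e-3, rel=1e-3)
        assert seg.hydraulic_diameter == pytest.approx(diameter, rel=1e-12)
        assert seg.is_circular

    def test_area_inverse_in_velocity(self):
        a1 = build_straight_tube_network(4.4e-6, 0.3, 0.0264).segments()[0].area
        a2 = build_straight_tube_network(4.4e-6, 0.6, 0.0264).segments()[0].area
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            build_straight_tube_network(0.0, 0.3, 0.0264)


class TestSurfaceAreaProfile:
    def test_single_segment_profile(self):
        net = make_chain(make_segment("only", length=0.03))
        profile = surface_area_profile(net, bin_width=0.01)
        nonempty = profile.total_area > 0
        assert nonempty.sum() == 3
        assert np.allclose(profile.fractions["respiratory"][nonempty], 1.0)

    def test_total_area_conserved(self, cat_network):
        profile = surface_area_profile(cat_network, bin_width=0.005)
        total = sum(s.lateral_area for s in cat_network.segments())
        assert profile.total_area.sum() == pytest.approx(total, rel=1e-9)

    def test_cat_profile_has_interior_olfactory_peak(self, cat_network):
        """The olfactory fraction peaks at depth, away from the naris."""
        profile = surface_area_profile(cat_network, bin_width=0.005)
        interior = profile.fractions["olfactory"].iloc[1:-1]
        assert interior.max() >= 0.45
        assert profile.fractions["olfactory"].iloc[0] < 0.45

    def test_rejects_bad_bin_width(self, cat_network):
        with pytest.raises(ValueError):
            surface_area_profile(cat_network, bin_width=0.0)


class TestMeanPathLength:
    def test_identical_paths(self, cat_network):
        # all cat coils are identical: DM (0.030 m) + coil (0.151 m)
        for n_paths in (1, 10, 25):
            assert mean_path_length(cat_network, n_paths, seed=1) == pytest.approx(0.181)

    def test_two_path_sampling_converges_to_enumerated_mean(self):
        """Two equally likely olfactory paths of 0.1 and 0.2 m average to 0.15 m."""
        dm = make_segment("dm", diameter=2e-3, length=0.04, region=Region.DORSAL_MEDIAL)
        short = make_segment("coil_a", width=5e-4, length=0.06, region=Region.OLFACTORY_COIL)
        long = make_segment("coil_b", width=5e-4, length=0.16, region=Region.OLFACTORY_COIL)
        net = NasalNetwork.from_segments(
            [("in", "n", dm), ("n", "out", short), ("n", "out", long)], inlet="in", outlet="out"
        )
        mean = mean_path_length(net, n_paths=4000, seed=7)
        # enumerated distribution: 0.5*(0.04+0.06) + 0.5*(0.04+0.16) = 0.15
        assert mean == pytest.approx(0.15, abs=0.005)

    def test_deterministic_given_seed(self, cat_network):
        assert mean_path_length(cat_network, 10, seed=5) == mean_path_length(cat_network, 10, seed=5)

    def test_no_olfactory_path_is_an_error(self):
        net = make_chain(make_segment("resp", length=0.05))
        with pytest.raises(NetworkStructureError):
            mean_path_length(net)


class TestValidator:
    def test_cat_network_passes(self, cat_network):
        validate_network(cat_network)

    def test_dangling_branch_rejected(self):
        seg1 = make_segment("a", length=0.05)
        seg2 = make_segment("b", length=0.05)
        with pytest.raises(NetworkStructureError):
            NasalNetwork.from_segments(
                [("in", "out", seg1), ("in", "dead", seg2)], inlet="in", outlet="out"
            )

    def test_coils_must_be_fed_by_dorsal_medial(self):
        resp = make_segment("resp", length=0.05, region=Region.ANTERIOR_RESPIRATORY)
        coil = make_segment("coil", width=5e-4, length=0.05, region=Region.OLFACTORY_COIL)
        with pytest.raises(NetworkStructureError):
            NasalNetwork.from_segments(
                [("in", "n", resp), ("n", "out", coil)], inlet="in", outlet="out"
            )
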