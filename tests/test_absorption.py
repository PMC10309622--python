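import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from nosegc.airflow import RESTFUL, solve_network_flow
from nosegc.absorption import (
    SHERWOOD_LAMINAR,
    anterior_depletion_experiment,
    closure_outlet_ratio,
    graetz_reference_solution,
    segment_conductances,
    segment_uptake,
    solubility_sweep,
    solve_network_absorption,
)
from nosegc.geometry import (
    CAT_DEFAULTS,
    AnteriorSpec,
    NasalNetwork,
    PosteriorSpec,
    Region,
    build_parallel_coil_network,
)
from nosegc.odorants import EpitheliumClass, MucosaSpec, Odorant

from conftest import make_chain, make_segment


def odorant(beta=1.0, Da=6e-6, Dm=1e-9):
    return Odorant(name="o", molecular_weight=100.0, molar_volume=100.0, beta=beta, Da=Da, Dm=Dm)


class TestSegmentUptake:
    def test_insoluble_limit_passes_through(self, reference_odorant):
        seg = make_segment(diameter=1e-3, length=0.05)
        assert segment_uptake(seg, 0.05, reference_odorant.with_beta(1e12)) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_long_column_absorbs_everything(self, reference_odorant):
        seg = make_segment(diameter=1e-3, length=50.0)
        assert segment_uptake(seg, 0.05, reference_odorant) == pytest.approx(0.0, abs=1e-12)

    def test_reference_closure_value_against_ode_oracle(self, reference_odorant):
        """Circular d_h = 1 mm, L = 5 cm, u = 5 cm/s: ratio = exp(-0.1331) = 0.8754,
        cross-checked by stiff integration of the plug-flow balance."""
        seg = make_segment(diameter=1e-3, length=0.05)
        ratio = segment_uptake(seg, 0.05, reference_odorant)
        assert ratio == pytest.approx(0.8754, rel=2e-4)
        k_conv, k_wall, k_tot = segment_conductances(seg, reference_odorant)
        assert k_conv == pytest.approx(0.02196, rel=1e-3)
        assert k_wall == pytest.approx(3.333e-5, rel=1e-3)
        # oracle: dC/dx = -(P k_tot / (u A)) C integrated over the segment
        rate = seg.perimeter * k_tot / (0.05 * seg.area)
        sol = solve_ivp(lambda x, c: -rate * c, (0.0, seg.length), [1.0], method="BDF", rtol=1e-10)
        assert ratio == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_disabled_uptake(self, reference_odorant):
        seg = make_segment(diameter=1e-3, length=0.05)
        assert segment_uptake(seg, 0.05, reference_odorant, enabled=False) == 1.0

    def test_rejects_nonpositive_velocity(self, reference_odorant):
        with pytest.raises(ValueError):
            segment_uptake(make_segment(), 0.0, reference_odorant)


class TestNetworkAbsorption:
    def test_all_regions_disabled(self, cat_network, cat_flow, reference_odorant):
        result = solve_network_absorption(
            cat_network, cat_flow, reference_odorant, disabled_regions=set(Region)
        )
        assert result.outlet_concentration == pytest.approx(1.0, rel=1e-12)
        assert all(v == 0.0 for v in result.region_fractions.values())

    def test_serial_segments_compose_multiplicatively(self, reference_odorant):
        a = make_segment("a", diameter=1e-3, length=0.05)
        b = make_segment("b", diameter=8e-4, length=0.03)
        net = make_chain(a, b)
        flow = solve_network_flow(net, RESTFUL)
        result = solve_network_absorption(net, flow, reference_odorant)
        r1 = segment_uptake(a, flow.u["a"], reference_odorant)
        r2 = segment_uptake(b, flow.u["b"], reference_odorant)
        assert result.outlet_concentration == pytest.approx(r1 * r2, rel=1e-12)

    def test_three_segment_toy_matches_hand_enumeration(self, three_region_toy):
        """Region fractions against an explicit mass balance on the branched toy."""
        od = odorant(beta=0.01)
        flow = solve_network_flow(three_region_toy, RESTFUL)
        result = solve_network_absorption(three_region_toy, flow, od)
        Q = RESTFUL.total_flow
        r_ant = segment_uptake(three_region_toy.segment("anterior"), flow.u["anterior"], od)
        r_dm = segment_uptake(three_region_toy.segment("dm"), flow.u["dm"], od)
        r_coil = segment_uptake(three_region_toy.segment("coil"), flow.u["coil"], od)
        r_post = segment_uptake(three_region_toy.segment("posterior"), flow.u["posterior"], od)
        q_olf = flow.q["dm"]
        q_post = flow.q["posterior"]
        expected_ant = 1.0 - r_ant
        expected_olf = (q_olf / Q) * r_ant * (1.0 - r_dm * r_coil)
        expected_post = (q_post / Q) * r_ant * (1.0 - r_post)
        assert result.region_fractions["anterior_respiratory"] == pytest.approx(expected_ant, rel=1e-9)
        assert result.region_fractions["olfactory"] == pytest.approx(expected_olf, rel=1e-9)
        assert result.region_fractions["posterior_respiratory"] == pytest.approx(expected_post, rel=1e-9)

    def test_mass_balance_on_cat_network(self, cat_network, cat_flow, reference_odorant):
        result = solve_network_absorption(cat_network, cat_flow, reference_odorant)
        assert result.mass_balance_error() <= 1e-9
        total = sum(result.region_fractions.values())
        assert 0.0 <= total <= 1.0

    @given(
        beta=st.floats(min_value=1e-5, max_value=1e2),
        n_coils=st.integers(min_value=1, max_value=12),
        coil_width=st.floats(min_value=2e-4, max_value=1.2e-3),
        post_length=st.floats(min_value=0.02, max_value=0.12),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mass_conservation_property(self, beta, n_coils, coil_width, post_length):
        """Inlet mass flux = outlet flux + absorbed on randomized networks."""
        params = dict(CAT_DEFAULTS)
        params.update(n_coils=n_coils, coil_width=coil_width)
        spec = params["posterior_spec"]
        params["posterior_spec"] = PosteriorSpec(
            n_channels=spec.n_channels, width=spec.width, length=post_length
        )
        net = build_parallel_coil_network(seed=0, **params)
        flow = solve_network_flow(net, RESTFUL)
        result = solve_network_absorption(net, flow, odorant(beta=beta))
        assert result.mass_balance_error() <= 1e-9
        assert all(0.0 <= v <= 1.0 for v in result.region_fractions.values())


class TestAnteriorDepletion:
    def test_insoluble_odorant_makes_scenarios_coincide(self, cat_network, cat_flow):
        exp = anterior_depletion_experiment(cat_network, cat_flow, odorant(beta=1e12))
        table = exp.region_table()
        assert np.allclose(table["with_anterior"], table["without_anterior"], atol=1e-9)

    def test_serial_chain_composition_identity(self):
        """With-anterior olfactory uptake = (1 - a_ant) * without-anterior value."""
        ant = make_segment("ant", diameter=2e-3, length=0.04, region=Region.ANTERIOR_RESPIRATORY)
        dm = make_segment("dm", diameter=2e-3, length=0.03, region=Region.DORSAL_MEDIAL)
        coil = make_segment("coil", width=5e-4, length=0.08, region=Region.OLFACTORY_COIL)
        post = make_segment("post", diameter=2e-3, length=0.03, region=Region.POSTERIOR_RESPIRATORY)
        net = make_chain(ant, dm, coil, post)
        flow = solve_network_flow(net, RESTFUL)
        od = odorant(beta=0.05)
        exp = anterior_depletion_experiment(net, flow, od)
        a_ant = exp.with_anterior.region_fractions["anterior_respiratory"]
        with_val = exp.with_anterior.region_fractions["olfactory"]
        without_val = exp.without_anterior.region_fractions["olfactory"]
        assert with_val == pytest.approx((1.0 - a_ant) * without_val, rel=1e-9)

    def test_cat_dm_stream_shields_the_olfactory_region(self, cat_network, cat_flow):
        """Anterior uptake reduces posterior absorption more than olfactory absorption."""
        exp = anterior_depletion_experiment(cat_network, cat_flow, odorant(beta=1e-4))
        table = exp.region_table().set_index("region")
        olf = table.loc["olfactory", "relative_reduction"]
        post = table.loc["posterior_respiratory", "relative_reduction"]
        assert olf < post


class TestSolubilitySweep:
    def test_monotone_without_anterior_uptake(self, cat_network, cat_flow, reference_odorant):
        sweep = solubility_sweep(
            cat_network, cat_flow, reference_odorant, np.logspace(-5, 2, 15)
        )
        olf = sweep.table[
            (sweep.table["region"] == "olfactory")
            & (sweep.table["scenario"] == "without_anterior")
        ].sort_values("beta")
        assert (np.diff(olf["fraction"].to_numpy()) <= 1e-12).all()

    def test_interior_peak_with_anterior_uptake(self, cat_network, cat_flow, reference_odorant):
        """Intermediate-solubility odorants maximize olfactory absorption."""
        sweep = solubility_sweep(
            cat_network, cat_flow, reference_odorant, np.logspace(-5, 2, 15)
        )
        assert sweep.peak_beta is not None
        olf = sweep.olfactory_curve()
        assert olf["fraction"].idxmax() not in (0, len(olf) - 1)

    def test_peak_shifts_to_more_soluble_when_anterior_is_shortened(self, reference_odorant):
        def peak(feed_length):
            params = dict(CAT_DEFAULTS)
            spec = params["anterior_spec"]
            params["anterior_spec"] = AnteriorSpec(
                trunk_length=spec.trunk_length, trunk_area=spec.trunk_area,
                trunk_perimeter=spec.trunk_perimeter, feed_length=feed_length,
                maxillary_channels=spec.maxillary_channels, maxillary_width=spec.maxillary_width,
                maxillary_length=spec.maxillary_length,
            )
            net = build_parallel_coil_network(seed=0, **params)
            flow = solve_network_flow(net, RESTFUL)
            sweep = solubility_sweep(net, flow, reference_odorant, np.logspace(-6, 2, 33))
            return sweep.peak_beta

        assert peak(0.004) <= peak(0.08)

    def test_rejects_narrow_beta_grid(self, cat_network, cat_flow, reference_odorant):
        with pytest.raises(ValueError):
            solubility_sweep(cat_network, cat_flow, reference_odorant, np.logspace(-1, 1, 5))


class TestGraetzOracle:
    def test_zero_uptake_is_identity(self):
        sol = graetz_reference_solution(peclet=0, K_hat=0.0, z_star_end=0.5, n_radial=32)
        assert sol.outlet_ratio == pytest.approx(1.0, abs=1e-6)

    def test_dirichlet_limit_recovers_classical_sherwood(self):
        sol = graetz_reference_solution(peclet=0, K_hat=1e6, z_star_end=1.2, n_radial=96)
        assert sol.sherwood_fully_developed() == pytest.approx(3.6568, rel=0.01)

    def test_grid_convergence(self):
        """Outlet ratio changes <= 0.5% between successive radial grid doublings."""
        ratios = [
            graetz_reference_solution(peclet=0, K_hat=1.0, z_star_end=0.5, n_radial=n).outlet_ratio
            for n in (32, 64, 128)
        ]
        assert abs(ratios[2] - ratios[1]) / ratios[2] <= 0.005
        assert abs(ratios[1] - ratios[0]) / ratios[1] <= 0.01

    def test_closure_tracks_oracle_at_moderate_wall_conductance(self):
        sol = graetz_reference_solution(peclet=0, K_hat=1.0, z_star_end=0.4, n_radial=96)
        assert closure_outlet_ratio(1.0, 0.4) == pytest.approx(sol.outlet_ratio, rel=0.15)
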