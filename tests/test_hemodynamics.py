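"""Flow-solver oracles: closed forms, symmetry, conservation, adaptation."""

import numpy as np
import pytest

from retsim import SimConfig, occlude, solve_flow
from retsim.hemodynamics import adapt_diameters, kirchhoff_residual, wall_shear_stress
from .conftest import make_line_network, make_y_network


def test_single_segment_poiseuille_closed_form(config):
    net = make_line_network(1, diameter=5.0, seg_len=100.0, p_in=40.0, p_out=20.0)
    flow = solve_flow(net, config)
    g = np.pi * 5.0**4 / (128.0 * config.mu_blood_mmHg_s * 100.0)
    assert flow.seg_flow[0] == pytest.approx(g * 20.0, rel=1e-12)
    assert flow.seg_velocity[0] > 0  # towards the low-pressure end
    assert float(flow.total_inflow) == pytest.approx(g * 20.0, rel=1e-12)


def test_series_midpoint_pressure(config):
    net = make_line_network(2, p_in=40.0, p_out=20.0)
    flow = solve_flow(net, config)
    assert flow.node_pressure[1] == pytest.approx(30.0, rel=1e-9)


def test_symmetric_y_branch_equal_split(config):
    net = make_y_network()
    flow = solve_flow(net, config)
    q1, q2 = flow.seg_flow[1], flow.seg_flow[2]
    assert q1 == pytest.approx(q2, rel=1e-9)
    assert q1 + q2 == pytest.approx(flow.seg_flow[0], rel=1e-9)


def test_kirchhoff_residual_small_on_generated_network(hex_net, config):
    flow = solve_flow(hex_net, config)
    assert kirchhoff_residual(hex_net, flow) < 1e-9 * float(flow.total_inflow)


def test_inflow_equals_outflow(hex_net, config):
    flow = solve_flow(hex_net, config)
    bf = flow.boundary_flux
    assert bf[bf > 0].sum() == pytest.approx(-bf[bf < 0].sum(), rel=1e-9)


def test_occlusion_zeroes_flow_and_is_irreversible(config):
    net = make_line_network(2)
    occlude(net, 0, eps_d=config.eps_d_um)
    flow = solve_flow(net, config)
    assert flow.seg_flow[0] == 0.0
    assert flow.seg_velocity[0] == 0.0
    assert float(flow.total_inflow) == 0.0  # sole path severed
    with pytest.warns(UserWarning):
        occlude(net, 0)
    assert net.seg_state[0] == 2


def test_reocclusion_conservation_after_redistribution(hex_net, config):
    net = hex_net.copy()
    flow0 = solve_flow(net, config)
    interior = np.flatnonzero(~net.node_is_boundary[net.seg_nodes].any(axis=1))
    occlude(net, int(interior[0]), eps_d=config.eps_d_um)
    flow = solve_flow(net, config)
    bf = flow.boundary_flux
    assert bf[bf > 0].sum() == pytest.approx(-bf[bf < 0].sum(), rel=1e-9)
    assert kirchhoff_residual(net, flow) < 1e-9 * float(flow.total_inflow)


def test_zero_flow_segment_removal_leaves_solution_unchanged(config):
    # a dangling zero-flow spur must not affect pressures elsewhere
    net = make_y_network()
    flow_y = solve_flow(net, config)
    net2 = make_y_network()
    net2.node_btype[3] = 0
    net2.node_is_boundary[3] = False
    net2.node_pressure[3] = np.nan
    flow_dead = solve_flow(net2, config)
    assert abs(flow_dead.seg_flow[2]) < 1e-9 * float(flow_dead.total_inflow)
    # remaining path behaves as a pure 2-segment series (actual lengths)
    k = np.pi * 5.0**4 / (128.0 * config.mu_blood_mmHg_s)
    L1, L2 = net2.seg_length[0], net2.seg_length[1]
    q_expected = 20.0 / (L1 / k + L2 / k)
    assert flow_dead.seg_flow[0] == pytest.approx(q_expected, rel=1e-9)


def test_adaptation_fixed_point_and_bounds(config):
    net = make_line_network(2)
    flow = solve_flow(net, config)
    tau_ref = wall_shear_stress(net, flow, config)
    d0 = net.seg_diameter.copy()
    adapt_diameters(net, flow, config, tau_ref)
    assert np.allclose(net.seg_diameter, d0)  # τ == τ_ref is a fixed point

    # repeated adaptation under elevated shear stays within hard bounds
    lo, hi = config.adapt_bounds
    for _ in range(100):
        flow = solve_flow(net, config)
        adapt_diameters(net, flow, config, 0.01 * tau_ref)
    assert np.all(net.seg_diameter <= hi * net.seg_ref_diameter + 1e-12)
    assert np.all(net.seg_diameter >= lo * net.seg_ref_diameter - 1e-12)


def test_occlusion_dilates_parallel_path(config):
    net = make_y_network()
    flow0 = solve_flow(net, config)
    tau_ref = wall_shear_stress(net, flow0, config)
    occlude(net, 1, eps_d=config.eps_d_um)
    flow1 = solve_flow(net, config)
    d_before = net.seg_diameter[2]
    adapt_diameters(net, flow1, config, tau_ref)
    assert net.seg_diameter[2] > d_before
    assert net.seg_diameter[2] <= d_before * (1 + config.adapt_step_cap) + 1e-12
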