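"""Poiseuille network flow, occlusion application and diameter adaptation.

The pressure field solves mass conservation on the patent subgraph with
segment conductance g = π d⁴ / (128 μ L); boundary nodes are Dirichlet.
Patent components that contain no pressure boundary (islands created by
occlusions) carry exactly zero flow; in strict mode they raise instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import SimConfig
from .network import STATE_OCCLUDED, VascularNetwork

__all__ = ["FlowSolution", "OrphanComponentError", "solve_flow", "occlude", "adapt_diameters", "wall_shear_stress"]


class OrphanComponentError(RuntimeError):
    """A patent component has no pressure boundary; lists its nodes."""

    def __init__(self, orphan_nodes: List[int]):
        self.orphan_nodes = orphan_nodes
        super().__init__(
            f"patent component disconnected from every pressure boundary; "
            f"orphan nodes: {orphan_nodes[:20]}{'...' if len(orphan_nodes) > 20 else ''}"
        )


@dataclass
class FlowSolution:
    """Node pressures and signed per-segment flows/velocities."""

    node_pressure: np.ndarray   # (N,) mmHg
    seg_flow: np.ndarray        # (M,) μm³/s, signed node_a -> node_b
    seg_velocity: np.ndarray    # (M,) μm/s, signed likewise
    total_inflow: np.ndarray    # scalar, μm³/s (sum of boundary inflows)
    boundary_flux: np.ndarray   # (N,) μm³/s, >0 where flow enters the network

    @property
    def seg_speed(self) -> np.ndarray:
        return np.abs(self.seg_velocity)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"segment_id": np.arange(len(self.seg_flow)),
             "flow_um3_s": self.seg_flow,
             "velocity_um_s": self.seg_velocity}
        )


def _conductance(net: VascularNetwork, config: SimConfig) -> np.ndarray:
    L = net.seg_length
    return np.pi * net.seg_diameter**4 / (128.0 * config.mu_blood_mmHg_s * L)


def solve_flow(net: VascularNetwork, config: SimConfig, strict: bool = False) -> FlowSolution:
    """Solve the linear pressure system and return flows and velocities.

    Requires boundary pressures assigned (``assign_boundary_conditions``).
    With ``strict=True``, boundary-less patent components raise
    :class:`OrphanComponentError`; otherwise they get zero flow and the
    mean boundary pressure.
    """
    n, m = net.n_nodes, net.n_segments
    patent = net.patent
    fixed = net.node_is_boundary & np.isfinite(net.node_pressure)
    if not fixed.any():
        raise ValueError("no boundary pressures assigned; call assign_boundary_conditions first")

    pressures = np.where(fixed, net.node_pressure, 0.0)
    g = _conductance(net, config)
    g_eff = np.where(patent, g, 0.0)

    if patent.sum() == 0:
        P = np.where(fixed, pressures, np.nanmean(net.node_pressure[fixed]))
        z = np.zeros(m)
        return FlowSolution(P, z, z.copy(), np.asarray(0.0), np.zeros(n))

    a, b = net.seg_nodes[:, 0], net.seg_nodes[:, 1]
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([b, a, a, b])
    vals = np.concatenate([-g_eff, -g_eff, g_eff, g_eff])
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    free = ~fixed
    # orphan detection: free nodes untouched by any patent segment path to a boundary
    adj = sp.csr_matrix(
        (np.ones(patent.sum() * 2), (np.concatenate([a[patent], b[patent]]), np.concatenate([b[patent], a[patent]]))),
        shape=(n, n),
    )
    n_comp, labels = sp.csgraph.connected_components(adj, directed=False)
    has_bc = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(has_bc, labels[fixed], True)
    touched = np.zeros(n, dtype=bool)
    touched[net.seg_nodes[patent].ravel()] = True
    orphan = touched & free & ~has_bc[labels]
    if orphan.any():
        if strict:
            raise OrphanComponentError(sorted(map(int, np.flatnonzero(orphan))))
        free = free & ~orphan
    # nodes whose every segment is occluded have an all-zero row; fix them too
    isolated = free & ~touched
    if isolated.any():
        free = free & ~isolated
        orphan = orphan | isolated

    P = pressures.astype(float).copy()
    idx_free = np.flatnonzero(free)
    if len(idx_free):
        A = lap[idx_free][:, idx_free].tocsc()
        rhs = -(lap[idx_free][:, ~free] @ P[~free])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", spla.MatrixRankWarning)
            sol = spla.spsolve(A, rhs)
        if not np.all(np.isfinite(sol)):
            raise OrphanComponentError(sorted(map(int, idx_free)))
        P[idx_free] = sol
    if orphan.any():
        P[orphan] = float(np.mean(pressures[fixed]))

    Q = g_eff * (P[a] - P[b])
    area = np.pi * net.seg_diameter**2 / 4.0
    v = np.where(patent, Q / np.where(area > 0, area, 1.0), 0.0)
    Q = np.where(patent, Q, 0.0)

    flux = np.zeros(n)
    np.add.at(flux, a, -Q)
    np.add.at(flux, b, Q)
    boundary_flux = np.where(net.node_is_boundary, -flux, 0.0)
    total_inflow = np.asarray(boundary_flux[boundary_flux > 0].sum())
    return FlowSolution(P, Q, v, total_inflow, boundary_flux)


def kirchhoff_residual(net: VascularNetwork, flow: FlowSolution) -> float:
    """Max absolute net flow at interior nodes (μm³/s)."""
    n = net.n_nodes
    a, b = net.seg_nodes[:, 0], net.seg_nodes[:, 1]
    acc = np.zeros(n)
    np.add.at(acc, a, -flow.seg_flow)
    np.add.at(acc, b, flow.seg_flow)
    interior = ~net.node_is_boundary
    return float(np.abs(acc[interior]).max(initial=0.0))


def occlude(net: VascularNetwork, segment_id: int, eps_d: float = 1e-6) -> VascularNetwork:
    """Mark a segment occluded in place (irreversible); caller re-solves flow."""
    if net.seg_state[segment_id] == STATE_OCCLUDED:
        warnings.warn(f"segment {segment_id} is already occluded; no-op", stacklevel=2)
        return net
    net.seg_state[segment_id] = STATE_OCCLUDED
    net.seg_diameter[segment_id] = eps_d
    return net


def wall_shear_stress(net: VascularNetwork, flow: FlowSolution, config: SimConfig) -> np.ndarray:
    """Magnitude of Poiseuille wall shear stress τ = 32 μ |Q| / (π d³)."""
    d = net.seg_diameter
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = 32.0 * config.mu_blood_mmHg_s * np.abs(flow.seg_flow) / (np.pi * d**3)
    return np.where(net.patent, tau, 0.0)


def adapt_diameters(
    net: VascularNetwork,
    flow: FlowSolution,
    config: SimConfig,
    tau_ref: np.ndarray,
) -> VascularNetwork:
    """One shear-stress adaptation event, in place.

    Each patent non-trunk capillary moves its diameter by a factor
    ``1 + clip(k_adapt·ln(τ/τ_ref))`` with the dilation step capped at
    ``adapt_step_cap`` and the constriction step at
    ``adapt_step_cap·adapt_constrict_frac`` (the acute shear response is
    dilation-dominant), then clipped to ``adapt_bounds × reference
    diameter``.  τ_ref is the segment's wall shear stress at construction,
    so the undamaged state is a fixed point.
    """
    tau = wall_shear_stress(net, flow, config)
    lo, hi = config.adapt_bounds
    mask = net.patent & ~net.seg_is_trunk & (tau_ref > 0)
    with np.errstate(divide="ignore"):
        ratio = np.where(tau > 0, tau / np.where(tau_ref > 0, tau_ref, 1.0), 1e-12)
        step = config.k_adapt * np.log(ratio)
    step = np.clip(step, -config.adapt_step_cap * config.adapt_constrict_frac,
                   config.adapt_step_cap)
    d_new = net.seg_diameter * (1.0 + step)
    d_new = np.clip(d_new, lo * net.seg_ref_diameter, hi * net.seg_ref_diameter)
    net.seg_diameter[mask] = d_new[mask]
    return net
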