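"""Oxygen transport: conveyor-belt advection, diffusion, consumption.

Each perfused segment is discretized into a chain of equally sized
conveyor belts; belt size equals flow speed × the flux time step, so one
belt-shift per step conveys oxygen at exactly the blood velocity.  At
junctions the discharged last-belt volumes are split among downstream
chains in proportion to their volumetric flows.  Belts are mapped to the
capillary block (CAP) enclosing their centre; before diffusion every CAP
sums its belts, and after diffusion the belts are rescaled by the CAP's
post/pre-diffusion volume ratio so that advection and diffusion compose
without double counting.

Diffusion is pairwise contact-area exchange on the tissue contact graph,
consumption is Michaelis–Menten in Mueller cells and other tissue, and the
avascular-zone cell is pinned as an oxygen source.  The steady-state
driver iterates advect → belts-to-CAP → diffuse+consume → CAP-to-belts
until the per-iteration relative tension change stays below tolerance
over a settling window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .config import SimConfig
from .hemodynamics import FlowSolution
from .network import VascularNetwork
from .tissue import KIND_CAP, Tissue

__all__ = [
    "ConveyorChains",
    "OxygenState",
    "ConvergenceError",
    "JunctionConservationError",
    "discretize_belts",
    "build_chains",
    "advect_step",
    "belts_to_caps",
    "caps_to_belts",
    "diffuse_step",
    "consume_step",
    "run_oxygen_to_steady_state",
    "two_block_pipe_trace",
]


SS_BLOCK = 200  # iterations per convergence-check block (ripple averaging)


class ConvergenceError(RuntimeError):
    """Steady-state iteration hit the iteration cap; carries the residual."""

    def __init__(self, residual: float, iters: int):
        self.residual = residual
        self.iters = iters
        super().__init__(f"no steady state after {iters} iterations (residual {residual:.3e})")


class JunctionConservationError(RuntimeError):
    """A junction received advected oxygen but has no outflow to carry it."""


@dataclass
class ConveyorChains:
    """Belt discretization of all perfused segments, concatenated.

    ``start[c]:start[c]+count[c]`` slices the belt arrays for chain *c*;
    belts are ordered upstream → downstream.
    """

    seg_of_chain: np.ndarray      # (nc,) segment id
    start: np.ndarray             # (nc,)
    count: np.ndarray             # (nc,)
    belt_vol: np.ndarray          # (B,) oxygen volume
    belt_geom: np.ndarray         # (B,) blood volume of the belt, μm³
    belt_cap: np.ndarray          # (B,) global cell id of the host CAP
    shift_frac: np.ndarray        # (nc,) Courant number v·Δt / belt_size  (≤ 1)
    inlet_refill: np.ndarray      # (nc,) oxygen volume of one arterial belt (0 if interior)
    split: sp.csr_matrix          # (nc, nc) junction routing: inbox += split @ discharge
    sink_frac: np.ndarray         # (nc,) fraction of discharge leaving the system
    first_idx: np.ndarray = field(default=None)  # (nc,) global index of first belts
    last_idx: np.ndarray = field(default=None)   # (nc,) global index of last belts
    is_first: np.ndarray = field(default=None)   # (B,) bool
    chain_of_belt: np.ndarray = field(default=None)  # (B,) chain index

    def __post_init__(self):
        self.first_idx = self.start.copy()
        self.last_idx = self.start + self.count - 1
        self.is_first = np.zeros(len(self.belt_vol), dtype=bool)
        if len(self.start):
            self.is_first[self.start] = True
        self.chain_of_belt = np.repeat(np.arange(self.n_chains), self.count)

    @property
    def n_chains(self) -> int:
        return len(self.seg_of_chain)

    def chain_of_segment(self, sid: int) -> Optional[int]:
        hits = np.flatnonzero(self.seg_of_chain == sid)
        return int(hits[0]) if len(hits) else None


@dataclass
class OxygenState:
    """Per-cell oxygen tension plus belt chains and balance accounting."""

    tension: np.ndarray           # (C,) mmHg
    chains: ConveyorChains
    alpha: float
    advected_in: float = 0.0      # cumulative oxygen volume entering at inlets
    discharged_out: float = 0.0   # cumulative volume leaving at outlets / stagnant routes
    consumed: float = 0.0         # cumulative metabolized volume
    iters: int = 0


def discretize_belts(
    length: float,
    velocity: float,
    dt_flux: float,
    belt_min: float = 0.5,
) -> Tuple[int, float, float]:
    """Belt geometry of one segment: (belt_count, belt_size, shift_frac).

    The ideal belt size is ``velocity × dt`` (never below ``belt_min``);
    the count is the largest number of *uniform* belts of at least that
    size that tile the segment, and the actual size is ``length/count``.
    A chain shifts once per step when its size equals v·Δt and every
    ``1/shift_frac``-th step otherwise, so the mean conveying speed is
    exactly the blood velocity.
    """
    if velocity <= 0:
        return 0, 0.0, 0.0
    ideal = max(velocity * dt_flux, belt_min)
    n = max(1, int(length / ideal))
    size = length / n
    shift_frac = min(1.0, velocity * dt_flux / size)
    return n, size, shift_frac


def build_chains(
    net: VascularNetwork,
    flow: FlowSolution,
    tissue: Tissue,
    config: SimConfig,
    cap_tension: Optional[np.ndarray] = None,
) -> ConveyorChains:
    """Discretize every perfused segment and precompute junction routing.

    When ``cap_tension`` (per-cell mmHg) is given, existing CAP oxygen is
    redistributed onto the new belts in proportion to belt blood volume
    (uniform tension within each CAP), conserving each CAP's total.
    """
    dt = config.dt_flux_s
    speeds = flow.seg_speed
    perfused = np.flatnonzero(net.patent & (speeds > config.v_stagnant_um_s))
    seg_len = net.seg_length

    starts, counts, segs = [], [], []
    geom_list, cap_list, shift_list = [], [], []
    pos = 0
    area = np.pi * net.seg_diameter**2 / 4.0
    for sid in perfused:
        k, size, frac = discretize_belts(seg_len[sid], speeds[sid], dt, config.belt_min_um)
        segs.append(sid)
        starts.append(pos)
        counts.append(k)
        shift_list.append(frac)
        geom_list.append(np.full(k, size * area[sid]))
        # belt centres upstream->downstream; host CAP by centre rule
        centers = (np.arange(k) + 0.5) * size
        up_first = flow.seg_flow[sid] >= 0  # belts run a->b
        s_arc = centers if up_first else seg_len[sid] - centers
        blk = np.minimum((s_arc / tissue.block_len[sid]).astype(int), tissue.seg_block_count[sid] - 1)
        cap_list.append(tissue.seg_block_start[sid] + blk)
        pos += k

    nc = len(segs)
    seg_of_chain = np.asarray(segs, dtype=np.int64)
    start = np.asarray(starts, dtype=np.int64)
    count = np.asarray(counts, dtype=np.int64)
    belt_geom = np.concatenate(geom_list) if nc else np.empty(0)
    belt_cap = np.concatenate(cap_list).astype(np.int64) if nc else np.empty(0, dtype=np.int64)
    shift_frac = np.asarray(shift_list)

    # junction routing -------------------------------------------------------
    chain_of = -np.ones(net.n_segments, dtype=np.int64)
    chain_of[seg_of_chain] = np.arange(nc)
    a, bnode = net.seg_nodes[:, 0], net.seg_nodes[:, 1]
    down_node = np.where(flow.seg_flow[seg_of_chain] >= 0, bnode[seg_of_chain], a[seg_of_chain])
    up_node = np.where(flow.seg_flow[seg_of_chain] >= 0, a[seg_of_chain], bnode[seg_of_chain])

    # outflowing chains at each node
    from collections import defaultdict

    node_out = defaultdict(list)  # node -> [(chain, |Q|)]
    for c in range(nc):
        node_out[int(up_node[c])].append((c, abs(flow.seg_flow[seg_of_chain[c]])))

    rows, cols, vals = [], [], []
    sink_frac = np.zeros(nc)
    for c in range(nc):
        n = int(down_node[c])
        if net.node_is_boundary[n]:
            sink_frac[c] = 1.0
            continue
        outs = node_out.get(n, [])
        qtot = sum(q for _, q in outs)
        if qtot <= 0:
            # downstream mass has nowhere to go; treat as a stagnation sink
            sink_frac[c] = 1.0
            continue
        for cc, q in outs:
            rows.append(cc)
            cols.append(c)
            vals.append(q / qtot)
    split = sp.csr_matrix((vals, (rows, cols)), shape=(nc, nc))

    # inlet refill: upstream boundary node with inflow (arterial-tension blood)
    refill = np.zeros(nc)
    alpha_blood = config.alpha_o2 * config.hb_capacity_factor
    for c in range(nc):
        n = int(up_node[c])
        if net.node_is_boundary[n] and flow.boundary_flux[n] > 0:
            o2 = net.node_oxygen[n]
            if not np.isfinite(o2):
                o2 = config.po2_art_mmHg * config.inlet_o2_scale
            first_geom = belt_geom[start[c]] if count[c] else 0.0
            refill[c] = alpha_blood * o2 * first_geom

    belt_vol = np.zeros(len(belt_geom))
    chains = ConveyorChains(
        seg_of_chain=seg_of_chain,
        start=start,
        count=count,
        belt_vol=belt_vol,
        belt_geom=belt_geom,
        belt_cap=belt_cap,
        shift_frac=shift_frac,
        inlet_refill=refill,
        split=split,
        sink_frac=sink_frac,
    )
    if cap_tension is not None and nc:
        # existing CAP oxygen goes onto the new belts at uniform tension
        chains.belt_vol[:] = alpha_blood * cap_tension[belt_cap] * belt_geom
    return chains


def cell_capacities(tissue: Tissue, chains: ConveyorChains, config: SimConfig) -> np.ndarray:
    """Oxygen capacity per cell: tension → oxygen volume conversion.

    Tissue cells hold dissolved oxygen (α·V); capillary blocks hold blood
    (α·hb_capacity_factor × the blood volume of their assigned belts, or
    of the whole lumen when the segment is not perfused).
    """
    alpha_blood = config.alpha_o2 * config.hb_capacity_factor
    cap = tissue.kind == KIND_CAP
    capacity = config.alpha_o2 * tissue.volume.copy()
    capacity[cap] = alpha_blood * tissue.volume[cap]
    if len(chains.belt_cap):
        geom_per_cap = np.bincount(chains.belt_cap, weights=chains.belt_geom,
                                   minlength=tissue.n_cells)
        belted = geom_per_cap > 0
        capacity[belted] = alpha_blood * geom_per_cap[belted]
    return capacity


def advect_step(chains: ConveyorChains, state: Optional[OxygenState] = None) -> ConveyorChains:
    """One conveying action: move belt volumes one position downstream.

    A chain whose belt size equals v·Δt (Courant number 1) hands each
    belt's whole volume to the next belt — the literal conveyor action.
    Chains whose belts are larger than v·Δt (slow segments, kept at the
    minimum belt size) move the Courant fraction of each belt's volume
    per step, which conveys at exactly the blood velocity on average.
    Discharged last-belt volumes are split among downstream chains in
    proportion to their volumetric flows (or leave at boundary outlets);
    inlet chains ingest arterial-tension blood at their volumetric rate.
    """
    nc = chains.n_chains
    if nc == 0:
        return chains
    bv = chains.belt_vol
    f_belt = chains.shift_frac[chains.chain_of_belt]
    moved = f_belt * bv                      # volume leaving each belt downstream

    discharge = chains.shift_frac * bv[chains.last_idx]
    routed = chains.split @ discharge        # arrives at downstream first belts
    sunk = float((chains.sink_frac * discharge).sum())
    supplied = chains.shift_frac * chains.inlet_refill

    bv -= moved
    shifted = np.empty_like(moved)
    shifted[1:] = moved[:-1]
    shifted[chains.is_first] = 0.0
    bv += shifted
    bv[chains.first_idx] += routed + supplied

    if state is not None:
        state.advected_in += float(supplied.sum())
        state.discharged_out += sunk
    return chains


def belts_to_caps(chains: ConveyorChains, n_cells: int) -> np.ndarray:
    """Pre-diffusion CAP oxygen volume: sum of each CAP's belts."""
    if len(chains.belt_vol) == 0:
        return np.zeros(n_cells)
    return np.bincount(chains.belt_cap, weights=chains.belt_vol, minlength=n_cells)


def caps_to_belts(chains: ConveyorChains, pre_vol: np.ndarray, post_vol: np.ndarray) -> ConveyorChains:
    """Rescale belts by their CAP's post/pre-diffusion volume ratio.

    A CAP with zero pre-diffusion volume that gained oxygen distributes
    the gain over its belts by blood volume (relative scaling is undefined
    at zero and discarding the gain would break conservation).
    """
    if len(chains.belt_vol) == 0:
        return chains
    pre_b = pre_vol[chains.belt_cap]
    post_b = post_vol[chains.belt_cap]
    ratio = np.where(pre_b > 0, post_b / np.where(pre_b > 0, pre_b, 1.0), 0.0)
    chains.belt_vol *= ratio
    zero_pre = (pre_b <= 0) & (post_b > 0)
    if zero_pre.any():
        geom_per_cap = np.bincount(chains.belt_cap, weights=chains.belt_geom,
                                   minlength=len(pre_vol))
        share = chains.belt_geom / geom_per_cap[chains.belt_cap]
        chains.belt_vol[zero_pre] = (post_b * share)[zero_pre]
    return chains


def diffuse_step(
    tension: np.ndarray,
    exchange_op: sp.csr_matrix,
    d_coeff: float,
    alpha: float,
    dt: float,
    pinned: Optional[np.ndarray] = None,
    pinned_value: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Explicit pairwise-exchange diffusion step on the contact graph.

    ``exchange_op`` is :meth:`Tissue.exchange_operator`; flux between i, j
    is ``d_coeff·A_ij·(C_i − C_j)`` oxygen volume per second, i.e.
    dC = dt·(d_coeff/alpha)·(M @ C).  Pinned cells are reset afterwards.
    """
    out = tension + (dt * d_coeff / alpha) * (exchange_op @ tension)
    if pinned is not None:
        out[pinned] = pinned_value if pinned_value is not None else tension[pinned]
    return out


def consume_step(
    tension: np.ndarray,
    consuming: np.ndarray,
    vmax: float,
    km: float,
    dt: float,
) -> np.ndarray:
    """Michaelis–Menten consumption in consuming cells; tension floored at 0."""
    c = tension[consuming]
    tension[consuming] = np.maximum(c - dt * vmax * c / (km + c), 0.0)
    return tension


def check_stability(tissue: Tissue, config: SimConfig) -> float:
    """Explicit-Euler stability factor max(Δt·D·ΣA/capacity); must be < 1.

    Uses the lumen capacity (without belts) for capillary blocks, the most
    restrictive case.
    """
    A = tissue.contact_matrix()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    cap_o2 = config.alpha_o2 * tissue.volume.copy()
    cap_o2[tissue.kind == KIND_CAP] *= config.hb_capacity_factor
    f_o2 = config.dt_flux_s * config.d_o2 * rowsum / cap_o2
    f_v = config.dt_flux_s * config.d_vegf * rowsum / tissue.volume
    factor = float(max(f_o2.max(), f_v.max()))
    if factor >= 1.0:
        raise ValueError(
            f"explicit diffusion unstable (factor {factor:.2f} >= 1): "
            "reduce dt_flux_s or use a coarser tiling"
        )
    return factor


def run_oxygen_to_steady_state(
    net: VascularNetwork,
    flow: FlowSolution,
    tissue: Tissue,
    config: SimConfig,
    init_tension: Optional[np.ndarray] = None,
) -> OxygenState:
    """Iterate advection/diffusion/consumption to the oxygen steady state.

    Convergence: discrete belt shifts make the instantaneous state ripple
    even at equilibrium (chains shift on different sub-cadences), so the
    criterion is applied to block means: every ``SS_BLOCK`` iterations the
    time-averaged tension of the block is compared to the previous
    block's, and the run stops when the per-iteration-equivalent relative
    change stays below ``tol_ss`` for two consecutive blocks.  Raises
    :class:`ConvergenceError` at the iteration cap.
    """
    n_cells = tissue.n_cells
    if init_tension is not None:
        C = init_tension.copy()
    else:
        C = np.full(n_cells, 0.5 * config.po2_art_mmHg)
    if tissue.faz_cell >= 0:
        C[tissue.faz_cell] = config.po2_faz_mmHg

    chains = build_chains(net, flow, tissue, config, cap_tension=C)
    state = OxygenState(tension=C, chains=chains, alpha=config.alpha_o2)
    capacity = cell_capacities(tissue, chains, config)
    A = tissue.contact_matrix()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    M = (sp.diags(1.0 / capacity) @ (A - sp.diags(rowsum))).tocsr()
    cons = tissue.consuming_mask
    cons_capacity = capacity[cons]
    dt = config.dt_flux_s
    dcoef = dt * config.d_o2
    vmax, km = config.vmax_o2, config.km_o2
    faz = tissue.faz_cell
    belted = np.zeros(n_cells, dtype=bool)
    if len(chains.belt_cap):
        belted[chains.belt_cap] = True
    inv_cap = 1.0 / capacity

    good = 0
    floor = 1.0  # mmHg scale floor for the relative-change criterion
    block = SS_BLOCK
    block_sum = np.zeros(n_cells)
    prev_mean: Optional[np.ndarray] = None
    delta_it = np.inf

    from ._kernels import HAVE_NUMBA, oxygen_iterate

    split_csr = chains.split.tocsr()
    geom_per_cap = np.bincount(chains.belt_cap, weights=chains.belt_geom,
                               minlength=n_cells) if len(chains.belt_cap) else np.zeros(n_cells)
    geom_per_cap = np.where(geom_per_cap > 0, geom_per_cap, 1.0)

    def run_block_kernel(nsteps):
        a, o, cns = oxygen_iterate(
            nsteps,
            chains.belt_vol, chains.belt_geom, chains.belt_cap, chains.is_first,
            chains.first_idx, chains.last_idx, chains.shift_frac,
            chains.sink_frac, chains.inlet_refill,
            split_csr.indptr, split_csr.indices, split_csr.data,
            C, capacity, geom_per_cap,
            M.indptr, M.indices, M.data,
            cons, belted,
            dt, dcoef, vmax, km, faz, config.po2_faz_mmHg,
            block_sum,
        )
        state.advected_in += a
        state.discharged_out += o
        state.consumed += cns

    def run_block_numpy(nsteps):
        for _ in range(nsteps):
            advect_step(chains, state)
            pre = belts_to_caps(chains, n_cells)
            C[belted] = (pre * inv_cap)[belted]
            C[:] = C + dcoef * (M @ C)
            c = C[cons]
            dcons = np.minimum(dt * vmax * c / (km + c), c)
            C[cons] = c - dcons
            state.consumed += float((dcons * cons_capacity).sum())
            np.maximum(C, 0.0, out=C)
            if faz >= 0:
                C[faz] = config.po2_faz_mmHg
            post = C * capacity
            caps_to_belts(chains, pre, post)
            block_sum[:] = block_sum + C

    run_block = run_block_kernel if HAVE_NUMBA and len(chains.belt_vol) else run_block_numpy

    for start_it in range(0, config.max_ss_iters, block):
        nsteps = min(block, config.max_ss_iters - start_it)
        run_block(nsteps)
        state.iters = start_it + nsteps
        mean = block_sum / nsteps
        block_sum[:] = 0.0
        if prev_mean is not None:
            delta_it = float(
                (np.abs(mean - prev_mean) / np.maximum(prev_mean, floor)).max()
            ) / nsteps
            if delta_it < config.tol_ss:
                good += 1
                if good >= 2:
                    state.tension = mean  # report the ripple-averaged state
                    return state
            else:
                good = 0
        prev_mean = mean
    raise ConvergenceError(delta_it, state.iters)


# ---------------------------------------------------------------------------
# worked two-block pipe
# ---------------------------------------------------------------------------

def two_block_pipe_trace(
    n_steps: int = 3,
    inflow_per_step: float = 1.0,
    prescribed_losses: dict | None = None,
    belts_per_block: int = 2,
):
    """Belt/CAP bookkeeping on a two-block pipe with prescribed diffusion.

    A linear pipe of two capillary blocks, each holding ``belts_per_block``
    belts; every step one unit of oxygen is advected into the first belt,
    the blocks sum their belts to a pre-diffusion volume, a prescribed
    diffusion loss is removed per block, and the belts are rescaled by the
    post/pre ratio.  ``prescribed_losses[(step, block)]`` gives the volume
    removed by diffusion (default 0).  Returns a list of per-step records
    with belt volumes after advection, pre/post-diffusion block volumes,
    diffused fractions, and belt volumes after rescaling, plus the volume
    advected across the block boundary each step.

    This mirrors exactly the composition used by the full solver
    (:func:`belts_to_caps` / :func:`caps_to_belts` with the same relative
    rescaling rule) on a pipeline small enough to follow by hand.
    """
    losses = prescribed_losses or {}
    nb = 2 * belts_per_block
    belts = np.zeros(nb)
    trace = []
    for step in range(1, n_steps + 1):
        transferred = float(belts[belts_per_block - 1])  # crosses into block 2
        belts[1:] = belts[:-1]
        belts[0] = inflow_per_step
        after_advect = belts.copy()
        pre = np.array([belts[:belts_per_block].sum(), belts[belts_per_block:].sum()])
        loss = np.array([float(losses.get((step, blk), 0.0)) for blk in (1, 2)])
        post = pre - loss
        if np.any(post < -1e-12):
            raise ValueError(f"prescribed loss exceeds block volume at step {step}")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(pre > 0, post / np.where(pre > 0, pre, 1.0), 0.0)
        frac = np.where(pre > 0, loss / np.where(pre > 0, pre, 1.0), 0.0)
        belts[:belts_per_block] *= ratio[0]
        belts[belts_per_block:] *= ratio[1]
        trace.append(
            {
                "step": step,
                "transferred_to_second_block": transferred,
                "belts_after_advection": after_advect,
                "pre_diffusion": pre.copy(),
                "post_diffusion": post.copy(),
                "diffused_fraction": frac.copy(),
                "belts_after_rescale": belts.copy(),
            }
        )
    return trace
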