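"""VEGF field: hypoxic Mueller-cell synthesis, diffusion, first-order decay.

Hypoxic Mueller cells (tension below the hypoxia threshold) are the only
VEGF source; synthesis ramps linearly with oxygen deficit and shuts off
linearly as the local level approaches saturation.  All Mueller cells also
carry the small basal synthesis that balances decay at the basal level
``v_b``, which keeps the undamaged diabetic retina at a low but nonzero
VEGF tone.  VEGF diffuses by pairwise contact-area exchange, decays with
first-order kinetics everywhere, is not advected, and the avascular-zone
cell is a pinned sink at level 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .config import SimConfig
from .oxygen import ConvergenceError
from .tissue import Tissue

__all__ = ["VEGFState", "update_mc_states", "synthesis_rate", "synthesize_step",
           "diffuse_decay_step", "run_vegf_to_steady_state"]


@dataclass
class VEGFState:
    """Per-cell VEGF level in arbitrary units."""

    level: np.ndarray
    iters: int = 0


def update_mc_states(tension: np.ndarray, tissue: Tissue, o2_hyp: float) -> np.ndarray:
    """Hypoxic-Mueller-cell mask: MC and tension strictly below threshold.

    The transition is reversible; the mask is recomputed from scratch at
    every call.
    """
    return tissue.mc_mask & (tension < o2_hyp)


def _basal_rate(tissue: Tissue, config: SimConfig) -> float:
    """Basal MC synthesis rate that balances whole-tissue decay at v_b.

    Mueller cells are the only producers but decay acts in every cell, so
    the basal term is volume-weighted: k_dec·v_b·(total volume)/(MC volume).
    """
    v_mc = float(tissue.volume[tissue.mc_mask].sum())
    v_all = float(tissue.volume.sum())
    if tissue.faz_cell >= 0:
        v_all -= float(tissue.volume[tissue.faz_cell])
    return config.k_dec * config.v_b * (v_all / max(v_mc, 1e-12))


def synthesis_rate(
    tension: np.ndarray,
    level: np.ndarray,
    tissue: Tissue,
    config: SimConfig,
    hypoxic: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-cell VEGF production rate [A.U./s].

    Hypoxic MCs produce ``k_syn·(1 − C/O2_hyp)₊·(1 − V/V_sat)₊``; every MC
    additionally produces the basal term ``k_dec·v_b`` that balances decay
    at the basal level.  Non-MC cells produce nothing.
    """
    if hypoxic is None:
        hypoxic = update_mc_states(tension, tissue, config.o2_hypoxia_mmHg)
    rate = np.zeros(len(level))
    mc = tissue.mc_mask
    rate[mc] = _basal_rate(tissue, config)
    deficit = np.clip(1.0 - tension[hypoxic] / config.o2_hypoxia_mmHg, 0.0, None) ** config.syn_o2_exp
    headroom = np.clip(1.0 - level[hypoxic] / config.v_sat, 0.0, None) ** config.syn_v_exp
    rate[hypoxic] += config.k_syn * deficit * headroom
    return rate


def synthesize_step(state: VEGFState, tension: np.ndarray, tissue: Tissue, config: SimConfig) -> VEGFState:
    """Add one flux step of synthesis."""
    state.level += config.dt_flux_s * synthesis_rate(tension, state.level, tissue, config)
    return state


def diffuse_decay_step(
    state: VEGFState,
    exchange_op: sp.csr_matrix,
    tissue: Tissue,
    config: SimConfig,
) -> VEGFState:
    """One explicit step of contact-graph diffusion plus first-order decay."""
    V = state.level
    V += config.dt_flux_s * (config.d_vegf * (exchange_op @ V) - config.k_dec * V)
    np.maximum(V, 0.0, out=V)
    if tissue.faz_cell >= 0:
        V[tissue.faz_cell] = 0.0
    return state


def run_vegf_to_steady_state(
    tension: np.ndarray,
    tissue: Tissue,
    config: SimConfig,
    init_level: Optional[np.ndarray] = None,
) -> VEGFState:
    """Iterate synthesis + diffusion + decay to the VEGF steady state.

    The stationarity condition ``D_V·(M₀V) − k_dec·V + prod(V) = 0`` is
    linear except for the saturation ramp in the production term, so the
    driver solves the sparse linear system directly and iterates
    (Picard) on the saturation factor until the fixed point is reached —
    the same state the explicit synthesis/diffusion/decay stepping
    converges to, without its O(1/(k_dec·Δt)) iteration count.
    """
    import scipy.sparse as sps
    import scipy.sparse.linalg as spla

    n = tissue.n_cells
    V = init_level.copy() if init_level is not None else np.full(n, config.v_b)
    if tissue.faz_cell >= 0:
        V[tissue.faz_cell] = 0.0
    state = VEGFState(level=V)
    M0 = tissue.exchange_operator()
    hypoxic = update_mc_states(tension, tissue, config.o2_hypoxia_mmHg)
    mc = tissue.mc_mask
    basal = np.zeros(n)
    basal[mc] = _basal_rate(tissue, config)
    deficit = np.zeros(n)
    deficit[hypoxic] = np.clip(1.0 - tension[hypoxic] / config.o2_hypoxia_mmHg, 0.0, None) ** config.syn_o2_exp

    A0 = (config.k_dec * sps.identity(n, format="csr") - config.d_vegf * M0).tolil()
    if tissue.faz_cell >= 0:
        f = tissue.faz_cell
        A0.rows[f] = [f]
        A0.data[f] = [1.0]
    A0 = A0.tocsr()
    gain = config.k_syn * deficit  # a_i: maximal production per cell

    if config.syn_v_exp == 1.0:
        # linear saturation: production = a_i·(1 − V/v_sat) while V < v_sat,
        # 0 beyond.  Fold the linear part into the matrix and iterate on the
        # active set (cells still below saturation) — converges in a few
        # refactorizations even at high synthesis gain.
        active = np.ones(n, dtype=bool)
        for it in range(1, 60):
            a_act = np.where(active, gain, 0.0)
            A = A0 + sps.diags(a_act / config.v_sat)
            rhs = basal + a_act
            if tissue.faz_cell >= 0:
                rhs[tissue.faz_cell] = 0.0
            V_new = spla.spsolve(A.tocsc(), rhs)
            np.maximum(V_new, 0.0, out=V_new)
            new_active = V_new < config.v_sat
            state.iters = it
            if np.array_equal(new_active, active):
                delta = float(np.abs(V_new - V).max())
                state.level = V_new
                return state
            active = new_active
            V = V_new
        raise ConvergenceError(float(np.abs(V_new - V).max()), state.iters)

    # general exponents: strongly damped Picard
    solver = spla.factorized(A0.tocsc())
    relax = 0.2
    for it in range(1, 2000):
        headroom = np.clip(1.0 - V / config.v_sat, 0.0, None) ** config.syn_v_exp
        rhs = basal + gain * headroom
        if tissue.faz_cell >= 0:
            rhs[tissue.faz_cell] = 0.0
        V_new = solver(rhs)
        np.maximum(V_new, 0.0, out=V_new)
        V_next = V + relax * (V_new - V)
        delta = float(np.abs(V_next - V).max() / max(config.v_b, 1e-9))
        V = V_next
        state.level = V
        state.iters = it
        if delta < 1e-8:
            return state
    raise ConvergenceError(delta, state.iters)
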