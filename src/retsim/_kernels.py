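"""Compiled inner loop for the oxygen steady-state driver.

The kernel performs ``nsteps`` flux iterations of the advect →
belts-to-blocks → diffuse+consume → blocks-to-belts cycle on flat arrays,
mirroring the reference numpy implementation in :mod:`retsim.oxygen`
operation for operation.  It exists purely for speed; when numba is
unavailable the solver falls back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def oxygen_iterate(
    nsteps,
    # belts
    belt_vol, belt_geom, belt_cap, is_first,
    # chains
    first_idx, last_idx, shift_frac, sink_frac, inlet_refill,
    split_indptr, split_indices, split_data,
    # cells
    C, capacity, geom_per_cap,
    M_indptr, M_indices, M_data,
    cons_mask, belted_mask,
    dt, dcoef, vmax, km, faz, po2faz,
    block_sum,
):
    """Run nsteps oxygen flux iterations in place; returns flux totals."""
    n_cells = C.shape[0]
    nc = first_idx.shape[0]
    B = belt_vol.shape[0]
    adv_in = 0.0
    out = 0.0
    consumed = 0.0
    pre = np.zeros(n_cells)
    Cn = np.zeros(n_cells)
    discharge = np.zeros(nc)
    routed = np.zeros(nc)

    for _ in range(nsteps):
        # ---- advection ----------------------------------------------------
        for c in range(nc):
            discharge[c] = shift_frac[c] * belt_vol[last_idx[c]]
            routed[c] = 0.0
        for c in range(nc):
            for k in range(split_indptr[c], split_indptr[c + 1]):
                routed[c] += split_data[k] * discharge[split_indices[k]]
            out += sink_frac[c] * discharge[c]
        # shift the Courant fraction downstream (descending keeps old values)
        for c in range(nc):
            f = shift_frac[c]
            s = first_idx[c]
            e = last_idx[c]
            for i in range(e, s, -1):
                belt_vol[i] += f * (belt_vol[i - 1] - belt_vol[i])
            supplied = f * inlet_refill[c]
            belt_vol[s] += routed[c] + supplied - f * belt_vol[s]
            adv_in += supplied

        # ---- belts -> blocks ----------------------------------------------
        for i in range(n_cells):
            pre[i] = 0.0
        for i in range(B):
            pre[belt_cap[i]] += belt_vol[i]
        for i in range(n_cells):
            if belted_mask[i]:
                C[i] = pre[i] / capacity[i]

        # ---- diffusion (one explicit matvec) + consumption -----------------
        for i in range(n_cells):
            acc = 0.0
            for k in range(M_indptr[i], M_indptr[i + 1]):
                acc += M_data[k] * C[M_indices[k]]
            Cn[i] = C[i] + dcoef * acc
        for i in range(n_cells):
            ci = Cn[i]
            if cons_mask[i]:
                d = dt * vmax * ci / (km + ci)
                if d > ci:
                    d = ci
                ci -= d
                consumed += d * capacity[i]
            if ci < 0.0:
                ci = 0.0
            C[i] = ci
        if faz >= 0:
            C[faz] = po2faz

        # ---- blocks -> belts (relative rescale) ----------------------------
        for i in range(B):
            cap = belt_cap[i]
            p = pre[cap]
            post = C[cap] * capacity[cap]
            if p > 0.0:
                belt_vol[i] *= post / p
            elif post > 0.0:
                belt_vol[i] = post * belt_geom[i] / geom_per_cap[cap]

        for i in range(n_cells):
            block_sum[i] += C[i]

    return adv_in, out, consumed
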