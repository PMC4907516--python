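"""Generalized-cell tiling and the contact-area adjacency used by diffusion.

The tissue is a 2.5-D scaffold: square tiles of pitch ``a_mc`` in the XY
plane carry a thickness (Z extent), alternately labelled Mueller cell (MC)
and other retinal tissue (OT) on a checkerboard to a configured MC
fraction.  Capillary blocks (CAP) are laid along each segment centreline
at a fixed per-block length and exchange with the tile containing their
midpoint.  The avascular zone, when present, is a single pinned source
cell contacting the tiles along its rim.

Diffusive exchange between two cells is proportional to their shared
contact area, so the tissue exposes a sparse symmetric contact graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .config import SimConfig
from .network import VascularNetwork

__all__ = ["KIND_CAP", "KIND_MC", "KIND_OT", "KIND_FAZ", "Tissue", "build_tissue", "min_cell_vessel_distance"]

KIND_CAP, KIND_MC, KIND_OT, KIND_FAZ = 0, 1, 2, 3


@dataclass
class Tissue:
    """Cells, contact graph and CAP↔segment bookkeeping."""

    kind: np.ndarray              # (C,) int8
    centroid: np.ndarray          # (C, 2) μm
    area: np.ndarray              # (C,) μm² (XY footprint)
    volume: np.ndarray            # (C,) μm³
    cell_segment: np.ndarray      # (C,) int, segment id for CAP cells else -1
    seg_block_start: np.ndarray   # (M,) first CAP cell id of each segment
    seg_block_count: np.ndarray   # (M,) number of CAP blocks per segment
    block_len: np.ndarray         # (M,) CAP block length per segment, μm
    contact_i: np.ndarray         # (E,) cell ids
    contact_j: np.ndarray         # (E,)
    contact_area: np.ndarray      # (E,) μm²
    tile_index: np.ndarray        # (C,) flattened grid index for tiles, -1 otherwise
    grid_shape: Tuple[int, int] = (0, 0)
    faz_cell: int = -1

    @property
    def n_cells(self) -> int:
        return len(self.kind)

    @property
    def mc_mask(self) -> np.ndarray:
        return self.kind == KIND_MC

    @property
    def consuming_mask(self) -> np.ndarray:
        return (self.kind == KIND_MC) | (self.kind == KIND_OT)

    def cap_cells_of(self, sid: int) -> np.ndarray:
        s = self.seg_block_start[sid]
        return np.arange(s, s + self.seg_block_count[sid])

    def contact_matrix(self) -> sp.csr_matrix:
        """Symmetric sparse matrix of contact areas (μm²)."""
        n = self.n_cells
        m = sp.coo_matrix(
            (np.concatenate([self.contact_area, self.contact_area]),
             (np.concatenate([self.contact_i, self.contact_j]),
              np.concatenate([self.contact_j, self.contact_i]))),
            shape=(n, n),
        )
        return m.tocsr()

    def exchange_operator(self) -> sp.csr_matrix:
        """M such that dC/dt = D · (M @ C) for a unit exchange coefficient.

        Row i of M is (A_ij (C_j - C_i)) / V_i summed over contacts; pinned
        cells are handled by the solvers, not here.
        """
        A = self.contact_matrix()
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        M = A - sp.diags(rowsum)
        Vinv = sp.diags(1.0 / self.volume)
        return (Vinv @ M).tocsr()


def _tile_grid(net: VascularNetwork, config: SimConfig):
    dom = net.domain
    x0, x1 = dom[0]
    y0, y1 = dom[1]
    pitch = config.a_mc_um
    # rounding (not ceil) keeps the clipped last row/column within
    # [0.5, 1.5]×pitch, avoiding sliver tiles that would destabilize
    # the explicit diffusion step
    nx = max(1, int(round((x1 - x0) / pitch)))
    ny = max(1, int(round((y1 - y0) / pitch)))
    xs = x0 + pitch * (np.arange(nx) + 0.5)
    ys = y0 + pitch * (np.arange(ny) + 0.5)
    # clip the last row/column so the tiling exactly partitions the footprint
    wx = np.full(nx, pitch)
    wy = np.full(ny, pitch)
    wx[-1] = (x1 - x0) - pitch * (nx - 1)
    wy[-1] = (y1 - y0) - pitch * (ny - 1)
    xs[-1] = x0 + pitch * (nx - 1) + wx[-1] / 2
    ys[-1] = y0 + pitch * (ny - 1) + wy[-1] / 2
    return xs, ys, wx, wy


def _in_faz(net: VascularNetwork, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if net.faz_ellipse is None:
        return np.zeros(np.shape(x), dtype=bool)
    cx, cy, rx, ry = net.faz_ellipse
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 < 1.0


def build_tissue(net: VascularNetwork, config: SimConfig) -> Tissue:
    """Tile the domain and lay CAP blocks; returns the contact-graph scaffold.

    MC/OT labels interleave on a checkerboard; when ``mc_fraction`` differs
    from 0.5 the checkerboard is rebalanced deterministically by striding.
    The avascular zone is not cellularized: tiles inside it collapse into
    one pinned source cell.
    """
    dom = net.domain
    if dom is None:
        raise ValueError("network has no domain box")
    pos = net.node_pos
    if (pos[:, 0].min() < dom[0, 0] - 1e-6 or pos[:, 0].max() > dom[0, 1] + 1e-6
            or pos[:, 1].min() < dom[1, 0] - 1e-6 or pos[:, 1].max() > dom[1, 1] + 1e-6):
        raise ValueError("vessel outside domain box")
    th = config.thickness_um

    # ---- CAP blocks along each segment ------------------------------------
    kinds: List[np.ndarray] = []
    cents: List[np.ndarray] = []
    areas: List[np.ndarray] = []
    vols: List[np.ndarray] = []
    cseg: List[np.ndarray] = []

    M = net.n_segments
    seg_len = net.seg_length
    n_blocks = np.maximum(1, np.ceil(seg_len / config.cap_block_len_um).astype(int))
    block_len = seg_len / n_blocks
    seg_block_start = np.zeros(M, dtype=np.int64)
    nid = 0
    a, b = net.seg_nodes[:, 0], net.seg_nodes[:, 1]
    for sid in range(M):
        k = n_blocks[sid]
        seg_block_start[sid] = nid
        t = (np.arange(k) + 0.5) / k
        p = pos[a[sid], :2][None, :] * (1 - t[:, None]) + pos[b[sid], :2][None, :] * t[:, None]
        d_ref = net.seg_ref_diameter[sid]
        cents.append(p)
        kinds.append(np.full(k, KIND_CAP, dtype=np.int8))
        areas.append(np.full(k, d_ref * block_len[sid]))
        vols.append(np.full(k, np.pi * d_ref**2 / 4.0 * block_len[sid]))
        cseg.append(np.full(k, sid, dtype=np.int64))
        nid += k

    # ---- tissue tiles ------------------------------------------------------
    xs, ys, wx, wy = _tile_grid(net, config)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gwx, gwy = np.meshgrid(wx, wy, indexing="ij")
    faz_mask = _in_faz(net, gx, gy)
    tis_mask = ~faz_mask
    ix, iy = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), indexing="ij")
    checker = (ix + iy) % 2 == 0
    # rebalance towards mc_fraction by demoting/promoting every k-th tile
    frac = config.mc_fraction
    mc_lab = checker.copy()
    if abs(frac - 0.5) > 1e-9:
        flat_order = np.flatnonzero(tis_mask.ravel())
        want = int(round(frac * len(flat_order)))
        have = int(mc_lab.ravel()[flat_order].sum())
        lab = mc_lab.ravel()
        if want > have:
            cand = flat_order[~lab[flat_order]]
            lab[cand[: want - have]] = True
        elif want < have:
            cand = flat_order[lab[flat_order]]
            lab[cand[: have - want]] = False
        mc_lab = lab.reshape(mc_lab.shape)

    tile_ids = -np.ones(gx.shape, dtype=np.int64)
    sel = np.flatnonzero(tis_mask.ravel())
    tile_ids.ravel()[sel] = nid + np.arange(len(sel))
    t_area = (gwx * gwy).ravel()[sel]
    cents.append(np.column_stack([gx.ravel()[sel], gy.ravel()[sel]]))
    kinds.append(np.where(mc_lab.ravel()[sel], KIND_MC, KIND_OT).astype(np.int8))
    areas.append(t_area)
    vols.append(t_area * th)
    cseg.append(np.full(len(sel), -1, dtype=np.int64))
    nid += len(sel)

    faz_cell = -1
    if faz_mask.any():
        faz_cell = nid
        cx, cy, rx, ry = net.faz_ellipse
        f_area = (gwx * gwy)[faz_mask].sum()
        cents.append(np.array([[cx, cy]]))
        kinds.append(np.array([KIND_FAZ], dtype=np.int8))
        areas.append(np.array([f_area]))
        vols.append(np.array([f_area * th]))
        cseg.append(np.array([-1], dtype=np.int64))
        nid += 1

    kind = np.concatenate(kinds)
    centroid = np.vstack(cents)
    area = np.concatenate(areas)
    volume = np.concatenate(vols)
    cell_segment = np.concatenate(cseg)
    tile_index = -np.ones(nid, dtype=np.int64)
    tile_index[tile_ids.ravel()[sel]] = sel

    # ---- contacts ----------------------------------------------------------
    ci: List[np.ndarray] = []
    cj: List[np.ndarray] = []
    ca: List[np.ndarray] = []

    # tile-tile: 4-neighbourhood, area = shared edge length × thickness
    nxg, nyg = tile_ids.shape
    for axis, wlist in ((0, wy), (1, wx)):
        if axis == 0:
            p, q = tile_ids[:-1, :], tile_ids[1:, :]
            edge_w = np.minimum(gwy[:-1, :], gwy[1:, :])
        else:
            p, q = tile_ids[:, :-1], tile_ids[:, 1:]
            edge_w = np.minimum(gwx[:, :-1], gwx[:, 1:])
        both = (p >= 0) & (q >= 0)
        ci.append(p[both])
        cj.append(q[both])
        ca.append(edge_w[both] * th)
        # tile against the avascular-zone cell
        if faz_cell >= 0:
            fm = faz_mask if axis == 0 else faz_mask
            pf = (p >= 0) & (fm[1:, :] if axis == 0 else fm[:, 1:])
            qf = (q >= 0) & (fm[:-1, :] if axis == 0 else fm[:, :-1])
            for m_, tids in ((pf, p), (qf, q)):
                if m_.any():
                    ci.append(tids[m_])
                    cj.append(np.full(m_.sum(), faz_cell, dtype=np.int64))
                    ca.append(edge_w[m_] * th * config.faz_contact_factor)

    # CAP-tile: block's midpoint tile, area = lateral surface of the block
    x0, y0 = dom[0, 0], dom[1, 0]
    pitch = config.a_mc_um
    cap_cells = np.flatnonzero(kind == KIND_CAP)
    cx_idx = np.clip(((centroid[cap_cells, 0] - x0) / pitch).astype(int), 0, nxg - 1)
    cy_idx = np.clip(((centroid[cap_cells, 1] - y0) / pitch).astype(int), 0, nyg - 1)
    host = tile_ids[cx_idx, cy_idx]
    sid_of = cell_segment[cap_cells]
    # thick-walled trunk arterioles/venules exchange through an unenhanced
    # interface; the perivascular enhancement applies to capillaries only
    interface = np.where(net.seg_is_trunk[sid_of], 2.0, config.cap_contact_factor)
    lateral = np.pi * net.seg_ref_diameter[sid_of] * block_len[sid_of] * interface
    ok = host >= 0
    ci.append(cap_cells[ok])
    cj.append(host[ok])
    ca.append(lateral[ok])
    if faz_cell >= 0 and (~ok).any():
        # capillary blocks whose midpoint falls inside the avascular rim
        ci.append(cap_cells[~ok])
        cj.append(np.full((~ok).sum(), faz_cell, dtype=np.int64))
        ca.append(lateral[~ok])

    # CAP-CAP: consecutive blocks share the lumen cross-section
    cross = np.pi * net.seg_ref_diameter**2 / 4.0
    for sid in range(M):
        k = n_blocks[sid]
        if k > 1:
            s = seg_block_start[sid]
            idx = np.arange(s, s + k - 1)
            ci.append(idx)
            cj.append(idx + 1)
            ca.append(np.full(k - 1, cross[sid]))
    # CAP-CAP across junctions: end blocks of segments sharing a node
    from collections import defaultdict

    node_end_blocks = defaultdict(list)
    for sid in range(M):
        s, k = seg_block_start[sid], n_blocks[sid]
        node_end_blocks[int(a[sid])].append((s, cross[sid]))
        node_end_blocks[int(b[sid])].append((s + k - 1, cross[sid]))
    ji, jj, jarea = [], [], []
    for _, blocks in node_end_blocks.items():
        for u in range(len(blocks)):
            for v in range(u + 1, len(blocks)):
                ji.append(blocks[u][0])
                jj.append(blocks[v][0])
                jarea.append(min(blocks[u][1], blocks[v][1]))
    if ji:
        ci.append(np.asarray(ji))
        cj.append(np.asarray(jj))
        ca.append(np.asarray(jarea))

    contact_i = np.concatenate(ci)
    contact_j = np.concatenate(cj)
    contact_area = np.concatenate(ca)
    keep = contact_area > 0
    return Tissue(
        kind=kind,
        centroid=centroid,
        area=area,
        volume=volume,
        cell_segment=cell_segment,
        seg_block_start=seg_block_start,
        seg_block_count=n_blocks,
        block_len=block_len,
        contact_i=contact_i[keep],
        contact_j=contact_j[keep],
        contact_area=contact_area[keep],
        tile_index=tile_index,
        grid_shape=(nxg, nyg),
        faz_cell=faz_cell,
    )


def min_cell_vessel_distance(tissue: Tissue, net: VascularNetwork) -> np.ndarray:
    """Per-MC Euclidean distance (μm) to the nearest patent segment centreline.

    Infinite sentinel when no patent segment remains.
    """
    mc = np.flatnonzero(tissue.mc_mask)
    patent = np.flatnonzero(net.patent)
    if len(patent) == 0:
        return np.full(len(mc), np.inf)
    p = tissue.centroid[mc]                       # (nmc, 2)
    a = net.node_pos[net.seg_nodes[patent, 0], :2]  # (np, 2)
    b = net.node_pos[net.seg_nodes[patent, 1], :2]
    ab = b - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-12)
    # broadcast point-to-segment distance
    ap = p[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(p[:, None, :] - proj, axis=2)
    return d.min(axis=1)
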