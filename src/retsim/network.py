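"""Vascular network data model, synthetic generators and file I/O.

A :class:`VascularNetwork` is a geometric graph: nodes carry 3-D positions
(μm) and, when they terminate the modelled region, boundary pressures and
oxygen tensions; segments are straight cylinders with a diameter, a state
(normal / leaky / occluded) and a construction-time reference diameter.

Three generators emulate the capillary architectures used throughout the
package:

* :func:`generate_hexagonal` — a honeycomb lattice (default 65 μm edges)
  with an optional fraction of edges deleted at random, the reference
  geometry for calibrating oxygen kinetics;
* :func:`generate_peripheral_ladder` — alternating arteriolar/venular
  rails joined by an apical 18-μm shunt and 10-μm "ladder" rung
  capillaries, as in the far peripheral retina;
* :func:`generate_macular_sector` — a synthetic juxtafoveal
  arteriole-venule sector (510×600 μm footprint) with a Gaussian(5, 0.5) μm
  capillary mesh and an avascular zone along one edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import networkx as nx

from .config import SimConfig

__all__ = [
    "STATE_NORMAL",
    "STATE_LEAKY",
    "STATE_OCCLUDED",
    "BTYPE_NONE",
    "BTYPE_ARTERIAL",
    "BTYPE_VENOUS",
    "BTYPE_INTERMEDIATE",
    "VascularNetwork",
    "NetworkSchemaError",
    "ConnectivityError",
    "generate_hexagonal",
    "generate_peripheral_ladder",
    "generate_macular_sector",
    "ladder_rung_sector",
    "assign_boundary_conditions",
    "read_network",
    "write_network",
]

STATE_NORMAL, STATE_LEAKY, STATE_OCCLUDED = 0, 1, 2
_STATE_NAMES = {STATE_NORMAL: "normal", STATE_LEAKY: "leaky", STATE_OCCLUDED: "occluded"}
_STATE_CODES = {v: k for k, v in _STATE_NAMES.items()}

BTYPE_NONE, BTYPE_ARTERIAL, BTYPE_VENOUS, BTYPE_INTERMEDIATE = 0, 1, 2, 3
_BTYPE_NAMES = {0: "none", 1: "arterial", 2: "venous", 3: "intermediate"}
_BTYPE_CODES = {v: k for k, v in _BTYPE_NAMES.items()}

SCHEMA_VERSION = 1


class NetworkSchemaError(ValueError):
    """Raised when a network file violates the documented schema."""


class ConnectivityError(RuntimeError):
    """Raised when a construction or deletion request breaks A→V connectivity."""


@dataclass
class VascularNetwork:
    """Geometric capillary graph with boundary conditions.

    Array-of-struct layout: ``node_*`` arrays are indexed by node id,
    ``seg_*`` arrays by segment id (both dense 0..n-1).
    """

    node_pos: np.ndarray                 # (N, 3) float, μm
    node_is_boundary: np.ndarray         # (N,) bool
    node_btype: np.ndarray               # (N,) int8, BTYPE_*
    node_pressure: np.ndarray            # (N,) float, mmHg (NaN if unset)
    node_oxygen: np.ndarray              # (N,) float, mmHg (NaN if unset)
    seg_nodes: np.ndarray                # (M, 2) int
    seg_diameter: np.ndarray             # (M,) float, μm
    seg_ref_diameter: np.ndarray         # (M,) float, μm
    seg_state: np.ndarray                # (M,) int8, STATE_*
    seg_is_trunk: np.ndarray             # (M,) bool
    faz_ellipse: Optional[Tuple[float, float, float, float]] = None  # (cx, cy, rx, ry) in XY
    domain: Optional[np.ndarray] = None  # (3, 2) extents, μm
    meta: Dict = field(default_factory=dict)

    # -- derived ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_pos)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def seg_length(self) -> np.ndarray:
        a, b = self.seg_nodes[:, 0], self.seg_nodes[:, 1]
        return np.linalg.norm(self.node_pos[a] - self.node_pos[b], axis=1)

    @property
    def patent(self) -> np.ndarray:
        """Mask of unoccluded segments."""
        return self.seg_state != STATE_OCCLUDED

    @property
    def arterial_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_btype == BTYPE_ARTERIAL)

    @property
    def venous_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_btype == BTYPE_VENOUS)

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            node_pos=self.node_pos.copy(),
            node_is_boundary=self.node_is_boundary.copy(),
            node_btype=self.node_btype.copy(),
            node_pressure=self.node_pressure.copy(),
            node_oxygen=self.node_oxygen.copy(),
            seg_nodes=self.seg_nodes.copy(),
            seg_diameter=self.seg_diameter.copy(),
            seg_ref_diameter=self.seg_ref_diameter.copy(),
            seg_state=self.seg_state.copy(),
            seg_is_trunk=self.seg_is_trunk.copy(),
            faz_ellipse=self.faz_ellipse,
            domain=None if self.domain is None else self.domain.copy(),
            meta=dict(self.meta),
        )

    def graph(self, patent_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        length = self.seg_length
        for sid, (a, b) in enumerate(self.seg_nodes):
            if patent_only and self.seg_state[sid] == STATE_OCCLUDED:
                continue
            g.add_edge(int(a), int(b), sid=sid, length=float(length[sid]))
        return g

    def has_av_path(self) -> bool:
        """True if at least one patent path joins an arterial to a venous boundary."""
        g = self.graph(patent_only=True)
        art, ven = self.arterial_nodes, self.venous_nodes
        if len(art) == 0 or len(ven) == 0:
            return False
        comp = {n: i for i, c in enumerate(nx.connected_components(g)) for n in c}
        art_c = {comp[int(n)] for n in art}
        return any(comp[int(n)] in art_c for n in ven)

    def validate(self) -> None:
        """Structural invariant check; raises on violation."""
        if self.n_nodes == 0 or self.n_segments == 0:
            raise ValueError("empty network")
        if self.seg_nodes.max() >= self.n_nodes:
            raise ValueError("segment references unknown node")
        patent = self.patent
        if np.any(self.seg_diameter[patent] <= 0):
            raise ValueError("patent segment with non-positive diameter")
        if len(self.arterial_nodes) == 0 or len(self.venous_nodes) == 0:
            raise ValueError("network lacks arterial or venous boundary designation")
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.seg_nodes.ravel(), 1)
        bd = self.node_is_boundary
        if np.any(deg[bd] != 1):
            raise ValueError("boundary nodes must have degree 1 within the modelled region")
        if not self.has_av_path():
            raise ConnectivityError("no patent arterial-to-venous path")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> Dict:
        nodes = []
        for i in range(self.n_nodes):
            rec = {
                "id": i,
                "x": float(self.node_pos[i, 0]),
                "y": float(self.node_pos[i, 1]),
                "z": float(self.node_pos[i, 2]),
                "is_boundary": bool(self.node_is_boundary[i]),
                "btype": _BTYPE_NAMES[int(self.node_btype[i])],
            }
            if np.isfinite(self.node_pressure[i]):
                rec["pressure"] = float(self.node_pressure[i])
            if np.isfinite(self.node_oxygen[i]):
                rec["oxygen"] = float(self.node_oxygen[i])
            nodes.append(rec)
        edges = []
        for j in range(self.n_segments):
            edges.append(
                {
                    "id": j,
                    "node_a": int(self.seg_nodes[j, 0]),
                    "node_b": int(self.seg_nodes[j, 1]),
                    "diameter_um": float(self.seg_diameter[j]),
                    "reference_diameter_um": float(self.seg_ref_diameter[j]),
                    "state": _STATE_NAMES[int(self.seg_state[j])],
                    "is_trunk": bool(self.seg_is_trunk[j]),
                }
            )
        out = {
            "schema_version": SCHEMA_VERSION,
            "nodes": nodes,
            "edges": edges,
            "metadata": dict(self.meta),
        }
        if self.faz_ellipse is not None:
            out["faz_ellipse"] = list(self.faz_ellipse)
        if self.domain is not None:
            out["domain"] = self.domain.tolist()
        return out

    @classmethod
    def from_dict(cls, d: Dict) -> "VascularNetwork":
        for key in ("nodes", "edges"):
            if key not in d:
                raise NetworkSchemaError(f"missing top-level key: {key}")
        nodes, edges = d["nodes"], d["edges"]
        n, m = len(nodes), len(edges)
        net = cls(
            node_pos=np.zeros((n, 3)),
            node_is_boundary=np.zeros(n, dtype=bool),
            node_btype=np.zeros(n, dtype=np.int8),
            node_pressure=np.full(n, np.nan),
            node_oxygen=np.full(n, np.nan),
            seg_nodes=np.zeros((m, 2), dtype=np.int64),
            seg_diameter=np.zeros(m),
            seg_ref_diameter=np.zeros(m),
            seg_state=np.zeros(m, dtype=np.int8),
            seg_is_trunk=np.zeros(m, dtype=bool),
        )
        for rec in nodes:
            try:
                i = int(rec["id"])
                net.node_pos[i] = (rec["x"], rec["y"], rec["z"])
                net.node_is_boundary[i] = bool(rec["is_boundary"])
            except KeyError as e:
                raise NetworkSchemaError(f"nodes[{rec.get('id', '?')}]: missing field {e}") from None
            net.node_btype[i] = _BTYPE_CODES.get(rec.get("btype", "none"), BTYPE_NONE)
            net.node_pressure[i] = rec.get("pressure", np.nan)
            net.node_oxygen[i] = rec.get("oxygen", np.nan)
        for rec in edges:
            try:
                j = int(rec["id"])
                net.seg_nodes[j] = (int(rec["node_a"]), int(rec["node_b"]))
                net.seg_diameter[j] = float(rec["diameter_um"])
            except KeyError as e:
                raise NetworkSchemaError(f"edges[{rec.get('id', '?')}]: missing field {e}") from None
            net.seg_ref_diameter[j] = float(rec.get("reference_diameter_um", rec["diameter_um"]))
            state = rec.get("state", "normal")
            if state not in _STATE_CODES:
                raise NetworkSchemaError(f"edges[{j}].state: unknown state {state!r}")
            net.seg_state[j] = _STATE_CODES[state]
            net.seg_is_trunk[j] = bool(rec.get("is_trunk", False))
        net.meta = dict(d.get("metadata", {}))
        extra = {k: v for k, v in d.items()
                 if k not in ("schema_version", "nodes", "edges", "metadata", "faz_ellipse", "domain")}
        if extra:
            net.meta.setdefault("_extra", {}).update(extra)
        if "faz_ellipse" in d and d["faz_ellipse"] is not None:
            net.faz_ellipse = tuple(d["faz_ellipse"])
        if "domain" in d and d["domain"] is not None:
            net.domain = np.asarray(d["domain"], dtype=float)
        return net


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _finalize(net: VascularNetwork, pad: float = 6.0) -> VascularNetwork:
    """Attach a bounding-box domain (padded in XY) if absent."""
    if net.domain is None:
        lo = net.node_pos.min(axis=0) - (pad, pad, 0)
        hi = net.node_pos.max(axis=0) + (pad, pad, 0)
        lo[2], hi[2] = 0.0, 50.0
        net.domain = np.column_stack([lo, hi])
    return net


class _Builder:
    """Incremental node/edge accumulator used by the generators."""

    def __init__(self) -> None:
        self.pos: List[Tuple[float, float, float]] = []
        self.btype: List[int] = []
        self.edges: List[Tuple[int, int]] = []
        self.diam: List[float] = []
        self.trunk: List[bool] = []

    def add_node(self, x: float, y: float, z: float = 25.0, btype: int = BTYPE_NONE) -> int:
        self.pos.append((x, y, z))
        self.btype.append(btype)
        return len(self.pos) - 1

    def add_edge(self, a: int, b: int, diameter: float, trunk: bool = False) -> int:
        self.edges.append((a, b))
        self.diam.append(diameter)
        self.trunk.append(trunk)
        return len(self.edges) - 1

    def build(self, meta: Dict, faz=None) -> VascularNetwork:
        pos = np.asarray(self.pos, dtype=float)
        btype = np.asarray(self.btype, dtype=np.int8)
        diam = np.asarray(self.diam, dtype=float)
        net = VascularNetwork(
            node_pos=pos,
            node_is_boundary=btype != BTYPE_NONE,
            node_btype=btype,
            node_pressure=np.full(len(pos), np.nan),
            node_oxygen=np.full(len(pos), np.nan),
            seg_nodes=np.asarray(self.edges, dtype=np.int64),
            seg_diameter=diam,
            seg_ref_diameter=diam.copy(),
            seg_state=np.zeros(len(diam), dtype=np.int8),
            seg_is_trunk=np.asarray(self.trunk, dtype=bool),
            faz_ellipse=faz,
            meta=meta,
        )
        return _finalize(net)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_hexagonal(
    edge_length_um: float = 65.0,
    n_rows: int = 4,
    n_cols: int = 4,
    deleted_edge_fraction: float = 0.0,
    seed: int | None = 0,
    capillary_diameter_um: float = 5.0,
) -> VascularNetwork:
    """Honeycomb capillary lattice with optional random edge deletion.

    Opposite lattice sides are designated arterial (left) and venous
    (right); every boundary attachment gets a degree-1 stub node so that
    boundary nodes terminate exactly one segment.  Edge deletion removes
    the requested fraction of interior edges uniformly at random, skipping
    any removal that would disconnect all arterial from all venous
    boundaries.
    """
    if edge_length_um <= 0:
        raise ValueError("edge_length_um must be positive")
    if not 0 <= deleted_edge_fraction < 1:
        raise ValueError("deleted_edge_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    hexg = nx.hexagonal_lattice_graph(n_rows, n_cols)
    pos = {n: np.asarray(hexg.nodes[n]["pos"], dtype=float) * edge_length_um for n in hexg}
    order = sorted(hexg.nodes())
    index = {n: i for i, n in enumerate(order)}

    b = _Builder()
    for n in order:
        x, y = pos[n]
        b.add_node(x, y)
    for u, v in hexg.edges():
        b.add_edge(index[u], index[v], capillary_diameter_um)

    xs = np.array([pos[n][0] for n in order])
    xmin, xmax = xs.min(), xs.max()
    stub = edge_length_um * 0.25
    left = [i for i, n in enumerate(order) if abs(pos[n][0] - xmin) < 1e-9]
    right = [i for i, n in enumerate(order) if abs(pos[n][0] - xmax) < 1e-9]
    ys_left = [b.pos[i][1] for i in left]
    ys_right = [b.pos[i][1] for i in right]
    a_attach = left[int(np.argsort(ys_left)[len(left) // 2])]
    v_attach = right[int(np.argsort(ys_right)[len(right) // 2])]
    for i in left:
        btype = BTYPE_ARTERIAL if i == a_attach else BTYPE_INTERMEDIATE
        s = b.add_node(b.pos[i][0] - stub, b.pos[i][1], btype=btype)
        b.add_edge(i, s, capillary_diameter_um)
    for i in right:
        btype = BTYPE_VENOUS if i == v_attach else BTYPE_INTERMEDIATE
        s = b.add_node(b.pos[i][0] + stub, b.pos[i][1], btype=btype)
        b.add_edge(i, s, capillary_diameter_um)

    net = b.build(
        meta={
            "generator": "hexagonal",
            "edge_length_um": edge_length_um,
            "n_rows": n_rows,
            "n_cols": n_cols,
            "deleted_edge_fraction": deleted_edge_fraction,
            "seed": None if seed is None else int(seed),
        }
    )

    if deleted_edge_fraction > 0:
        interior = [
            sid for sid in range(net.n_segments)
            if not net.node_is_boundary[net.seg_nodes[sid]].any()
        ]
        target = int(round(deleted_edge_fraction * len(interior)))
        candidates = list(rng.permutation(interior))
        removed: List[int] = []
        for sid in candidates:
            if len(removed) == target:
                break
            net.seg_state[sid] = STATE_OCCLUDED  # provisional removal
            if net.has_av_path():
                removed.append(sid)
            else:
                net.seg_state[sid] = STATE_NORMAL
        if len(removed) < target:
            raise ConnectivityError(
                f"cannot delete {target} edges while preserving arterial-venous "
                f"connectivity (managed {len(removed)})"
            )
        keep = np.ones(net.n_segments, dtype=bool)
        keep[removed] = False
        net = _subset_segments(net, keep)
    return net


def _subset_segments(net: VascularNetwork, keep: np.ndarray) -> VascularNetwork:
    """Drop segments (and orphaned nodes), re-indexing densely."""
    seg_nodes = net.seg_nodes[keep]
    used = np.zeros(net.n_nodes, dtype=bool)
    used[seg_nodes.ravel()] = True
    remap = -np.ones(net.n_nodes, dtype=np.int64)
    remap[used] = np.arange(used.sum())
    return VascularNetwork(
        node_pos=net.node_pos[used],
        node_is_boundary=net.node_is_boundary[used],
        node_btype=net.node_btype[used],
        node_pressure=net.node_pressure[used],
        node_oxygen=net.node_oxygen[used],
        seg_nodes=remap[seg_nodes],
        seg_diameter=net.seg_diameter[keep],
        seg_ref_diameter=net.seg_ref_diameter[keep],
        seg_state=net.seg_state[keep],
        seg_is_trunk=net.seg_is_trunk[keep],
        faz_ellipse=net.faz_ellipse,
        domain=net.domain,
        meta=dict(net.meta),
    )


def generate_peripheral_ladder(
    n_sectors: int = 3,
    rung_count: int = 4,
    rung_spacing_um: float = 140.0,
    seed: int | None = 0,
    shunt_diameter_um: float = 18.0,
    rung_diameter_um: float = 10.0,
    rail_base_diameter_um: float = 20.0,
    rail_tip_diameter_um: float = 12.0,
    sector_width_um: float = 360.0,
) -> VascularNetwork:
    """Peripheral 'ladder' capillary sectors.

    Alternating arteriolar and venular rails (A V A V …) run from their
    boundary bases towards the ora serrata, tapering towards the tip so
    that most of the arteriovenous pressure head dissipates along the
    rails rather than across individual rungs; adjacent rails are joined
    by an apical arterio-venous shunt (18 μm lumen) and by equally spaced
    rung capillaries (10 μm lumen).  Rails and shunts are trunk vessels.
    """
    if n_sectors < 1 or rung_count < 2:
        raise ValueError("need n_sectors >= 1 and rung_count >= 2")
    if rung_spacing_um <= 0 or sector_width_um <= 0:
        raise ValueError("geometry lengths must be positive")

    n_rails = n_sectors + 1
    top_y = rung_spacing_um * (rung_count + 1)
    b = _Builder()
    rail_nodes: List[List[int]] = []
    taper = np.linspace(rail_base_diameter_um, rail_tip_diameter_um, rung_count + 1)
    for r in range(n_rails):
        x = r * sector_width_um
        is_art = r % 2 == 0
        base = b.add_node(x, rung_spacing_um * 0.5, btype=BTYPE_ARTERIAL if is_art else BTYPE_VENOUS)
        col = [base]
        prev = base
        for j in range(rung_count):
            nid = b.add_node(x, rung_spacing_um * (j + 1))
            b.add_edge(prev, nid, float(taper[j]), trunk=True)
            prev = nid
            col.append(nid)
        apex = b.add_node(x, top_y)
        b.add_edge(prev, apex, float(taper[rung_count]), trunk=True)
        col.append(apex)
        rail_nodes.append(col)
    for r in range(n_sectors):
        # apical shunt between neighbouring rails
        b.add_edge(rail_nodes[r][-1], rail_nodes[r + 1][-1], shunt_diameter_um, trunk=True)
        for j in range(1, rung_count + 1):
            b.add_edge(rail_nodes[r][j], rail_nodes[r + 1][j], rung_diameter_um)

    net = b.build(
        meta={
            "generator": "peripheral_ladder",
            "n_sectors": n_sectors,
            "rung_count": rung_count,
            "rung_spacing_um": rung_spacing_um,
            "sector_width_um": sector_width_um,
            "seed": None if seed is None else int(seed),
        }
    )
    return net


def ladder_rung_sector(net: VascularNetwork) -> np.ndarray:
    """Sector index of each rung segment (-1 for trunk vessels)."""
    if net.meta.get("generator") != "peripheral_ladder":
        raise ValueError("not a ladder network")
    width = net.meta.get("sector_width_um", 360.0)
    sec = -np.ones(net.n_segments, dtype=int)
    mid_x = 0.5 * (net.node_pos[net.seg_nodes[:, 0], 0] + net.node_pos[net.seg_nodes[:, 1], 0])
    rungs = ~net.seg_is_trunk
    sec[rungs] = np.floor(mid_x[rungs] / width).astype(int)
    return sec


def generate_macular_sector(
    seed: int | None = 0,
    domain_xy: Tuple[float, float] = (510.0, 600.0),
    n_mesh_nodes: int = 85,
    mean_capillary_um: float = 5.0,
    sd_capillary_um: float = 0.5,
    trunk_diameter_um: float = 10.0,
    max_link_um: float = 135.0,
) -> VascularNetwork:
    """Synthetic juxtafoveal arteriole-venule sector with an avascular zone.

    Template: an arteriolar trunk enters at the lower right and a venular
    trunk exits at the upper right; both hug the sector rim and curl
    towards the foveal side.  Between the two trunk tips a perifoveal
    arcade — the ring capillary bordering the avascular zone — runs along
    the rim, fed from the interior mesh only at its midpoint, so each
    arcade span is individually load-bearing: losing one span link leaves
    a stagnant dead-end stretch and an ischemic juxtafoveal patch, the
    clinically typical first lesion.  The interior is a Delaunay-linked,
    relative-neighbourhood-pruned capillary mesh.  Capillary diameters are
    drawn Gaussian(5, 0.5) μm truncated positive; trunk diameters taper
    from 10 μm at the entrance to capillary calibre at the tip.
    """
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    W, H = domain_xy
    # half-ellipse on the left edge; ry slightly over H/2 so the foveal-side
    # corners are avascular zone rather than unsupplied dead tissue
    faz = (0.0, H / 2.0, 150.0, 380.0)
    fcx, fcy, frx, fry = faz

    def in_faz(x, y, margin=1.0):
        return ((x - fcx) / (frx * margin)) ** 2 + ((y - fcy) / (fry * margin)) ** 2 < 1.0

    b = _Builder()

    # trunks: polylines from the right edge arcing towards the fovea
    # trunks hug the sector rim, then curl around the avascular zone
    n_t = 10
    t = np.linspace(0.0, 1.0, n_t)
    tx = W - 14.0 - t * (W - 14.0 - 160.0)
    turn = np.clip((260.0 - tx) / (260.0 - 160.0), 0.0, 1.0)
    art_pts = np.column_stack([tx, 38.0 + 150.0 * turn**2])
    ven_pts = np.column_stack([tx, H - 38.0 - 150.0 * turn**2])
    trunk_d = trunk_diameter_um - 5.5 * t  # taper 10 -> 4.5 μm at the foveal tip

    def add_trunk(pts, entrance_btype):
        ids = []
        ent = b.add_node(pts[0, 0] + 12.0, pts[0, 1], btype=entrance_btype)
        first = b.add_node(*pts[0])
        b.add_edge(ent, first, trunk_diameter_um, trunk=True)
        ids.append(first)
        for k in range(1, len(pts)):
            nid = b.add_node(*pts[k])
            b.add_edge(ids[-1], nid, float(0.5 * (trunk_d[k - 1] + trunk_d[k])), trunk=True)
            ids.append(nid)
        return ids

    art_ids = add_trunk(art_pts, BTYPE_ARTERIAL)
    ven_ids = add_trunk(ven_pts, BTYPE_VENOUS)

    def cap_d() -> float:
        return max(0.5, float(rng.normal(mean_capillary_um, sd_capillary_um)))

    # perifoveal arcade between the trunk tips, offset from the rim
    arc_y = np.linspace(art_pts[-1, 1], ven_pts[-1, 1], 7)[1:-1]
    arc_x = frx * np.sqrt(np.clip(1.0 - ((arc_y - fcy) / fry) ** 2, 0.0, None)) + 16.0
    arcade = [b.add_node(float(x), float(y)) for x, y in zip(arc_x, arc_y)]
    ring_chain = [art_ids[-1]] + arcade + [ven_ids[-1]]
    for u, v in zip(ring_chain[:-1], ring_chain[1:]):
        b.add_edge(u, v, cap_d())

    # interior capillary mesh nodes (clear of the rim strip)
    mesh: List[int] = []
    mesh_xy: List[Tuple[float, float]] = []
    attempts = 0
    while len(mesh_xy) < n_mesh_nodes and attempts < n_mesh_nodes * 60:
        attempts += 1
        x = rng.uniform(235.0, W - 15.0)
        y = rng.uniform(42.0, H - 42.0)
        df = np.hypot((x - fcx) / frx, (y - fcy) / fry) - 1.0
        d_excl = 64.0 if df < 0.8 else 52.0
        if mesh_xy:
            d2 = np.min(np.sum((np.asarray(mesh_xy) - (x, y)) ** 2, axis=1))
            if d2 < d_excl**2:
                continue
        mesh_xy.append((x, y))
    for x, y in mesh_xy:
        mesh.append(b.add_node(x, y))

    # Delaunay linking over mesh + trunk nodes
    trunk_all = art_ids + ven_ids
    cloud_ids = mesh + trunk_all
    cloud = np.asarray([b.pos[i][:2] for i in cloud_ids])
    tri = Delaunay(cloud)
    links = set()
    for simplex in tri.simplices:
        for u, v in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[u], simplex[v]))
            links.add((i, j))
    trunk_set = set(range(len(mesh), len(cloud_ids)))
    art_set = set(range(len(mesh), len(mesh) + len(art_ids)))
    ven_set = set(range(len(mesh) + len(art_ids), len(cloud_ids)))
    faz_cross = lambda p, q: in_faz(*(0.5 * (p + q)), margin=1.02)

    def rng_edge(i, j):
        # relative-neighbourhood criterion: thins the Delaunay web to the
        # loopy, roughly degree-3 topology of real capillary meshes
        p, q = cloud[i], cloud[j]
        d_pq = np.linalg.norm(p - q)
        for r in range(len(cloud)):
            if r == i or r == j:
                continue
            if max(np.linalg.norm(cloud[r] - p), np.linalg.norm(cloud[r] - q)) < d_pq:
                return False
        return True

    for i, j in sorted(links):
        if i in trunk_set and j in trunk_set:
            continue  # trunk topology is the polyline
        if (i in art_set and j in ven_set) or (i in ven_set and j in art_set):
            continue  # no direct A-V shunts
        p, q = cloud[i], cloud[j]
        if np.linalg.norm(p - q) > max_link_um or faz_cross(p, q):
            continue
        if not rng_edge(i, j):
            continue
        b.add_edge(cloud_ids[i], cloud_ids[j], cap_d())


    net = b.build(
        meta={
            "generator": "macular_sector",
            "seed": None if seed is None else int(seed),
            "n_mesh_nodes": n_mesh_nodes,
        },
        faz=faz,
    )
    # the modelled sector is bounded by the two trunks; trim the thin
    # strips beyond them so no unvascularized dead corners remain
    net.domain = np.array([[0.0, W], [26.0, H - 26.0], [0.0, 50.0]])

    # keep the component containing the trunks, prune interior dead ends
    g = net.graph(patent_only=True)
    art_n = int(net.arterial_nodes[0])
    comp = nx.node_connected_component(g, art_n)
    keep = np.array([(a in comp and bb in comp) for a, bb in net.seg_nodes])
    net = _subset_segments(net, keep)
    while True:
        deg = np.zeros(net.n_nodes, dtype=int)
        np.add.at(deg, net.seg_nodes.ravel(), 1)
        dangling = (deg == 1) & ~net.node_is_boundary
        if not dangling.any():
            break
        keep = ~dangling[net.seg_nodes].any(axis=1)
        if keep.all():
            break
        net = _subset_segments(net, keep)

    # side branches that reach the domain edge terminate as boundary stubs:
    # promote near-edge degree-1-able mesh nodes adjacent to the right edge
    if not net.has_av_path():
        raise ConnectivityError("macular template lost A-V connectivity (rerun with another seed)")
    return net


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

def assign_boundary_conditions(net: VascularNetwork, config: SimConfig) -> VascularNetwork:
    """Assign boundary pressures and inlet oxygen tensions in place.

    Arterial-tagged boundary nodes get ``p_art``, venous-tagged ``p_ven``;
    intermediate boundary nodes are interpolated between the two by
    normalized length-weighted graph distance to the nearest arterial vs
    venous boundary.  All boundary nodes get a prospective inflow oxygen
    tension (arterial value, scaled by ``inlet_o2_scale`` for non-arterial
    boundaries); it only matters where flow actually enters.
    """
    art, ven = net.arterial_nodes, net.venous_nodes
    if len(art) == 0 or len(ven) == 0:
        raise ValueError("network lacks designated arterial/venous trunks")
    net.node_pressure[:] = np.nan
    net.node_oxygen[:] = np.nan
    net.node_pressure[art] = config.p_art_mmHg
    net.node_pressure[ven] = config.p_ven_mmHg
    net.node_oxygen[art] = config.po2_art_mmHg

    inter = np.flatnonzero(net.node_btype == BTYPE_INTERMEDIATE)
    if len(inter):
        g = net.graph(patent_only=True)
        d_art = nx.multi_source_dijkstra_path_length(g, set(map(int, art)), weight="length")
        d_ven = nx.multi_source_dijkstra_path_length(g, set(map(int, ven)), weight="length")
        for i in inter:
            da, dv = d_art.get(int(i)), d_ven.get(int(i))
            if da is None or dv is None:
                f = 0.5
            else:
                f = da / (da + dv) if (da + dv) > 0 else 0.5
            net.node_pressure[i] = config.p_art_mmHg + f * (config.p_ven_mmHg - config.p_art_mmHg)
        net.node_oxygen[inter] = config.po2_art_mmHg * config.inlet_o2_scale
    net.node_oxygen[ven] = config.po2_art_mmHg * config.inlet_o2_scale
    return net


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_network(net: VascularNetwork, path) -> None:
    """Write a network as JSON (or a CSV node/edge pair if *path* ends .csv).

    The CSV form writes ``<stem>.nodes.csv`` and ``<stem>.edges.csv``.
    """
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        stem = path[:-4]
        d = net.to_dict()
        pd.DataFrame(d["nodes"]).to_csv(stem + ".nodes.csv", index=False)
        pd.DataFrame(d["edges"]).to_csv(stem + ".edges.csv", index=False)
        return
    with open(path, "w") as fh:
        json.dump(net.to_dict(), fh, indent=1)


def read_network(path) -> VascularNetwork:
    """Read a network written by :func:`write_network`."""
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        stem = path[:-4]
        try:
            nodes = pd.read_csv(stem + ".nodes.csv")
            edges = pd.read_csv(stem + ".edges.csv")
        except FileNotFoundError as e:
            raise NetworkSchemaError(f"missing CSV table: {e.filename}") from None
        for col in ("id", "x", "y", "z", "is_boundary"):
            if col not in nodes.columns:
                raise NetworkSchemaError(f"nodes.csv: missing column {col!r}")
        for col in ("id", "node_a", "node_b", "diameter_um"):
            if col not in edges.columns:
                raise NetworkSchemaError(f"edges.csv: missing column {col!r}")
        d = {
            "schema_version": SCHEMA_VERSION,
            "nodes": nodes.replace({np.nan: None}).to_dict("records"),
            "edges": edges.replace({np.nan: None}).to_dict("records"),
        }
        for rec in d["nodes"]:
            rec["pressure"] = rec.get("pressure") if rec.get("pressure") is not None else np.nan
            rec["oxygen"] = rec.get("oxygen") if rec.get("oxygen") is not None else np.nan
        return VascularNetwork.from_dict(d)
    with open(path) as fh:
        return VascularNetwork.from_dict(json.load(fh))
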