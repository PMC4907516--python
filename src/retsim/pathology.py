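"""Stochastic capillary occlusion, leaky-state transitions and edema.

Occlusion abstracts VEGF-primed leukocyte plugging: the per-check
probability rises with the segment's local VEGF level (Hill form) and is
suppressed exponentially by blood speed, so slow, VEGF-bathed juxtafoveal
capillaries are the most vulnerable.  Occlusion is irreversible and acts
on whole segments; trunk vessels are never drawn.

A segment whose local VEGF exceeds the leak threshold turns "leaky"
(reversible).  Each weekly check a leaky segment deposits one fluid
portion into the tissue column beneath it while every wet column drains a
fixed quota (the pigment-epithelium pump), so net thickening requires
sustained leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .config import SimConfig
from .network import STATE_LEAKY, STATE_NORMAL, STATE_OCCLUDED, VascularNetwork
from .hemodynamics import FlowSolution, occlude
from .tissue import Tissue

__all__ = ["EdemaState", "segment_vegf_levels", "segment_vegf_max", "check_leaky",
           "form_edema", "occlusion_probability", "apply_occlusion_checks"]


def segment_vegf_levels(net: VascularNetwork, tissue: Tissue, vegf_level: np.ndarray) -> np.ndarray:
    """Per-segment VEGF: mean over the segment's capillary blocks."""
    sums = np.zeros(net.n_segments)
    for sid in range(net.n_segments):
        cells = tissue.cap_cells_of(sid)
        sums[sid] = vegf_level[cells].mean()
    return sums


def segment_vegf_max(net: VascularNetwork, tissue: Tissue, vegf_level: np.ndarray) -> np.ndarray:
    """Per-segment VEGF: maximum over the segment's capillary blocks.

    The leaky transition and the occlusion hazard are local block events,
    so the segment-level summaries used for them are maxima, not means.
    """
    out = np.zeros(net.n_segments)
    for sid in range(net.n_segments):
        cells = tissue.cap_cells_of(sid)
        out[sid] = vegf_level[cells].max()
    return out


def check_leaky(net: VascularNetwork, seg_vegf: np.ndarray, threshold: float) -> VascularNetwork:
    """Update normal↔leaky states in place; occluded segments unchanged.

    Trunk arterioles/venules are exempt: their thick muscular walls do not
    leak, so only capillaries respond to supra-threshold VEGF.
    """
    live = (net.seg_state != STATE_OCCLUDED) & ~net.seg_is_trunk
    above = seg_vegf > threshold
    net.seg_state[live & above] = STATE_LEAKY
    net.seg_state[live & ~above] = STATE_NORMAL
    return net


@dataclass
class EdemaState:
    """Per-tissue-column added fluid and the resulting thickness map."""

    fluid_um3: np.ndarray           # (C,) per-cell column fluid volume
    created_units: int = 0
    removed_um3: float = 0.0

    def thickness(self, tissue: Tissue, base_um: float) -> np.ndarray:
        """Thickness per cell column: base + fluid column height."""
        return base_um + self.fluid_um3 / np.maximum(tissue.area, 1e-12)

    @classmethod
    def fresh(cls, tissue: Tissue) -> "EdemaState":
        return cls(fluid_um3=np.zeros(tissue.n_cells))


def form_edema(
    net: VascularNetwork,
    tissue: Tissue,
    edema: EdemaState,
    config: SimConfig,
) -> EdemaState:
    """One weekly edema check: deposit under leaky segments, drain wet columns.

    One fluid portion of ``fp_unit_volume_um3`` appears in the tissue tile
    under the midpoint of every leaky segment; afterwards every column
    holding fluid drains up to ``fp_removal_um3`` (bottom elimination by
    the retinal pigment epithelium).
    """
    leaky = np.flatnonzero(net.seg_state == STATE_LEAKY)
    for sid in leaky:
        cells = tissue.cap_cells_of(sid)
        mid_cell = cells[len(cells) // 2]
        host = _host_tile(tissue, mid_cell)
        edema.fluid_um3[host] += config.fp_unit_volume_um3
        edema.created_units += 1
    wet = edema.fluid_um3 > 0
    drained = np.minimum(edema.fluid_um3[wet], config.fp_removal_um3)
    edema.fluid_um3[wet] -= drained
    edema.removed_um3 += float(drained.sum())
    return edema


def _host_tile(tissue: Tissue, cap_cell: int) -> int:
    """Tissue tile in contact with a CAP cell (the column that thickens)."""
    hits = tissue.contact_j[(tissue.contact_i == cap_cell)]
    hits = hits[np.isin(tissue.kind[hits], (1, 2))]
    if len(hits) == 0:
        hits2 = tissue.contact_i[(tissue.contact_j == cap_cell)]
        hits = hits2[np.isin(tissue.kind[hits2], (1, 2))]
    return int(hits[0]) if len(hits) else int(cap_cell)


def occlusion_probability(
    seg_vegf: np.ndarray,
    seg_speed: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Per-check occlusion probability.

    ``p = p_max · V^h / (V^h + V_half^h) · exp(−v / v_scale)`` — strictly
    increasing in VEGF, strictly decreasing in speed, bounded by p_max.
    """
    v = np.asarray(seg_vegf, dtype=float)
    s = np.abs(np.asarray(seg_speed, dtype=float))
    h = config.hill_occl
    vh = np.power(v, h, where=v > 0, out=np.zeros_like(v))
    hill = vh / (vh + config.v_half_occl**h)
    return config.p_occl_max * hill * np.exp(-s / config.v_scale_occl)


def apply_occlusion_checks(
    net: VascularNetwork,
    tissue: Tissue,
    vegf_level: np.ndarray,
    flow: FlowSolution,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[VascularNetwork, List[int]]:
    """Monthly occlusion draws: one Bernoulli trial per patent capillary.

    The hazard uses the segment-level VEGF (mean over the segment's
    blocks, since plugging takes out the whole segment) and the segment's
    blood speed.  Draws run in ascending segment id from the replicate's
    stream, so the occlusion sequence is reproducible given (network,
    config, seed).  Trunk vessels are exempt — they fail only by losing
    all their connections.
    """
    occluded: List[int] = []
    seg_vegf = segment_vegf_levels(net, tissue, vegf_level)
    p = occlusion_probability(seg_vegf, flow.seg_speed, config)
    for sid in range(net.n_segments):
        if net.seg_state[sid] == STATE_OCCLUDED or net.seg_is_trunk[sid]:
            continue
        if rng.random() < p[sid]:
            occlude(net, sid, eps_d=config.eps_d_um)
            occluded.append(sid)
    return net, occluded
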