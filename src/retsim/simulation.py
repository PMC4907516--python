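"""Event loop, calibration, replicate ensembles and summary metrics.

A run couples the fast physics (flow, oxygen, VEGF steady states,
re-established within seconds of any vascular event) to the slow disease
clocks: capillary leakiness and edema are checked every model week,
occlusion every four weeks, for a default horizon of 156 weeks after the
first occlusion.  After every occlusion event the diameters adapt to the
new shear field and all steady states are recomputed (quasi-static
coupling).  Ensembles replicate a run over independent RNG streams and
summarize per-segment patency, flow–oxygen phase trajectories and the
75 %-rule progressive classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import SimConfig
from .network import VascularNetwork, assign_boundary_conditions
from .hemodynamics import FlowSolution, adapt_diameters, occlude, solve_flow, wall_shear_stress
from .oxygen import run_oxygen_to_steady_state, check_stability
from .tissue import Tissue, build_tissue, min_cell_vessel_distance
from .vegf import run_vegf_to_steady_state, update_mc_states
from . import pathology

__all__ = [
    "CheckpointMetrics",
    "TrajectoryRecord",
    "EnsembleSummary",
    "compute_metrics",
    "run_simulation",
    "run_ensemble",
    "calibrate_defaults",
    "sweep_parameters",
    "phase_orientation",
    "occlusion_locality_test",
]

HIST_BIN_MMHG = 4.0


@dataclass
class CheckpointMetrics:
    model_week: int
    total_inflow: float
    mean_mc_oxygen: float
    hypoxic_mc_fraction: float
    mean_dmin_scaled: float
    oxygen_histogram: np.ndarray      # fractions per 4-mmHg bin, sums to 1
    patent_segments: int
    thickness_change_pct: float
    min_tension: float


@dataclass
class TrajectoryRecord:
    """Metrics time series and event log of one run."""

    config: SimConfig
    baseline: CheckpointMetrics
    checkpoints: List[CheckpointMetrics] = field(default_factory=list)
    events: List[Tuple[int, str, int]] = field(default_factory=list)  # (week, type, segment)
    terminated_early: bool = False
    final_tension: Optional[np.ndarray] = None
    final_vegf: Optional[np.ndarray] = None
    final_network: Optional[VascularNetwork] = None
    final_thickness: Optional[np.ndarray] = None

    @property
    def weeks(self) -> np.ndarray:
        return np.array([c.model_week for c in self.checkpoints])

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(c, name) for c in self.checkpoints])

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in [self.baseline] + self.checkpoints:
            rows.append(
                {
                    "model_week": c.model_week,
                    "total_inflow": c.total_inflow,
                    "mean_mc_oxygen": c.mean_mc_oxygen,
                    "hypoxic_mc_fraction": c.hypoxic_mc_fraction,
                    "mean_dmin_scaled": c.mean_dmin_scaled,
                    "patent_segments": c.patent_segments,
                    "thickness_change_pct": c.thickness_change_pct,
                    "min_tension": c.min_tension,
                }
            )
        return pd.DataFrame(rows)


def compute_metrics(
    net: VascularNetwork,
    tissue: Tissue,
    flow: FlowSolution,
    tension: np.ndarray,
    config: SimConfig,
    week: int,
    thickness: Optional[np.ndarray] = None,
    base_thickness_total: Optional[float] = None,
) -> CheckpointMetrics:
    """Checkpoint summary of one converged state bundle."""
    mc = tissue.mc_mask
    hyp = update_mc_states(tension, tissue, config.o2_hypoxia_mmHg)
    dmin = min_cell_vessel_distance(tissue, net)
    finite = np.isfinite(dmin)
    dmin_scaled = float(np.mean(dmin[finite]) / config.a_mc_um) if finite.any() else math.inf
    nbins = max(1, int(np.ceil((tension.max() + 1e-9) / HIST_BIN_MMHG)))
    hist, _ = np.histogram(tension, bins=np.arange(nbins + 1) * HIST_BIN_MMHG)
    hist = hist / max(1, len(tension))
    if thickness is None:
        thick_pct = 0.0
    else:
        total = float(thickness.sum())
        base = base_thickness_total if base_thickness_total else total
        thick_pct = 100.0 * (total - base) / base
    return CheckpointMetrics(
        model_week=week,
        total_inflow=float(flow.total_inflow),
        mean_mc_oxygen=float(tension[mc].mean()),
        hypoxic_mc_fraction=float(hyp.sum() / max(1, mc.sum())),
        mean_dmin_scaled=dmin_scaled,
        oxygen_histogram=hist,
        patent_segments=int(net.patent.sum()),
        thickness_change_pct=thick_pct,
        min_tension=float(tension.min()),
    )


def _resolve_states(net, tissue, config, tension, vegf_level):
    """Recompute flow and both steady states (warm-started)."""
    flow = solve_flow(net, config)
    ox = run_oxygen_to_steady_state(net, flow, tissue, config, init_tension=tension)
    vg = run_vegf_to_steady_state(ox.tension, tissue, config, init_level=vegf_level)
    return flow, ox, vg


def run_simulation(net: VascularNetwork, config: SimConfig) -> TrajectoryRecord:
    """Run the full event loop on one network.

    The clock starts (week 0) at the first occlusion: a user-designated
    segment in ``forced`` mode, or the first spontaneous success of the
    basal-state monthly draws in ``spontaneous`` mode.  Weekly: leaky/edema
    update.  Every 4th week: occlusion draws.  After any occlusion:
    diameter adaptation and recomputation of all steady states.  Stops at
    the horizon or when no patent arterial-venous path remains.
    """
    net = net.copy()
    rng = np.random.default_rng(config.seed)
    assign_boundary_conditions(net, config)
    tissue = build_tissue(net, config)
    check_stability(tissue, config)

    flow = solve_flow(net, config)
    tau_ref = wall_shear_stress(net, flow, config)
    ox = run_oxygen_to_steady_state(net, flow, tissue, config)
    vg = run_vegf_to_steady_state(ox.tension, tissue, config)
    edema = pathology.EdemaState.fresh(tissue)
    base_thickness = edema.thickness(tissue, config.thickness_um)
    base_total = float(base_thickness.sum())

    baseline = compute_metrics(net, tissue, flow, ox.tension, config, week=-1,
                               thickness=base_thickness, base_thickness_total=base_total)
    record = TrajectoryRecord(config=config, baseline=baseline)

    # ---- first occlusion (defines week 0) ---------------------------------
    if config.run_mode == "forced":
        sid = config.forced_segment
        if sid is None:
            sid = default_forced_segment(net, flow)
        occlude(net, int(sid), eps_d=config.eps_d_um)
        record.events.append((0, "occlusion", int(sid)))
    else:
        waited = 0
        while waited < config.max_wait_checks:
            _, occluded = pathology.apply_occlusion_checks(net, tissue, vg.level, flow, config, rng)
            waited += 1
            if occluded:
                for s in occluded:
                    record.events.append((0, "occlusion", int(s)))
                break
        else:
            record.terminated_early = True
            record.final_tension = ox.tension
            record.final_vegf = vg.level
            record.final_network = net
            record.final_thickness = base_thickness
            return record
    adapt_diameters(net, flow, config, tau_ref)
    flow, ox, vg = _resolve_states(net, tissue, config, ox.tension, vg.level)

    occl_every = config.occlusion_every_weeks
    record.checkpoints.append(
        compute_metrics(net, tissue, flow, ox.tension, config, 0,
                        edema.thickness(tissue, config.thickness_um), base_total)
    )

    for week in range(1, config.horizon_weeks + 1):
        seg_vegf = pathology.segment_vegf_max(net, tissue, vg.level)
        pathology.check_leaky(net, seg_vegf, config.mvegf_thr_leak)
        pathology.form_edema(net, tissue, edema, config)

        new_occl: List[int] = []
        if week % occl_every == 0:
            _, new_occl = pathology.apply_occlusion_checks(net, tissue, vg.level, flow, config, rng)
            for s in new_occl:
                record.events.append((week, "occlusion", int(s)))
        if new_occl:
            adapt_diameters(net, flow, config, tau_ref)
            if not net.has_av_path():
                record.terminated_early = True
                flow = solve_flow(net, config)
                record.checkpoints.append(
                    compute_metrics(net, tissue, flow, ox.tension, config, week,
                                    edema.thickness(tissue, config.thickness_um), base_total)
                )
                break
            flow, ox, vg = _resolve_states(net, tissue, config, ox.tension, vg.level)
        if new_occl or week % 4 == 0:
            record.checkpoints.append(
                compute_metrics(net, tissue, flow, ox.tension, config, week,
                                edema.thickness(tissue, config.thickness_um), base_total)
            )

    record.final_tension = ox.tension
    record.final_vegf = vg.level
    record.final_network = net
    record.final_thickness = edema.thickness(tissue, config.thickness_um)
    return record


def default_forced_segment(net: VascularNetwork, flow: FlowSolution) -> int:
    """Default forced initial site: a slow, supply-critical capillary.

    Among perfused non-trunk capillaries in the slower half of the speed
    distribution, picks the one with the greatest isolation radius (the
    distance from its midpoint to the nearest other patent segment) — the
    capillary whose loss leaves the largest unsupplied pocket.  On the
    macular template this lands on a slow juxtafoveal capillary, the
    clinically typical first lesion location.
    """
    patent = net.patent & ~net.seg_is_trunk & (flow.seg_speed > 0)
    slow = np.flatnonzero(patent)
    if len(slow) == 0:
        raise ValueError("no occludable patent segment")
    mids = 0.5 * (net.node_pos[net.seg_nodes[:, 0], :2] + net.node_pos[net.seg_nodes[:, 1], :2])
    if net.faz_ellipse is not None:
        # juxtafoveal site: the patent capillary nearest the avascular rim
        cx, cy, rx, ry = net.faz_ellipse
        rim_d = np.abs(np.hypot((mids[slow, 0] - cx) / rx, (mids[slow, 1] - cy) / ry) - 1.0)
        return int(slow[np.argmin(rim_d)])
    a = net.node_pos[net.seg_nodes[:, 0], :2]
    b = net.node_pos[net.seg_nodes[:, 1], :2]
    patent_all = np.flatnonzero(net.patent)
    iso = np.empty(len(slow))
    for k, sid in enumerate(slow):
        others = patent_all[patent_all != sid]
        pa, pb = a[others], b[others]
        ab = pb - pa
        denom = np.maximum((ab**2).sum(axis=1), 1e-12)
        t = np.clip(((mids[sid] - pa) * ab).sum(axis=1) / denom, 0.0, 1.0)
        proj = pa + t[:, None] * ab
        iso[k] = np.linalg.norm(mids[sid] - proj, axis=1).min()
    return int(slow[np.argmax(iso)])


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Replicate-level outputs: patency, phase points, progression flags."""

    records: List[TrajectoryRecord]
    patency_frequency: np.ndarray          # (M,) fraction of runs segment ends patent
    progressive: np.ndarray                # (n,) bool, 75 % rule
    phase_points: List[np.ndarray]         # per run, (k, 3): week, inflow, mean MC O2
    failures: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def patency_index(self) -> np.ndarray:
        """Per-run percentage of segments patent at the end."""
        return np.array(
            [100.0 * r.checkpoints[-1].patent_segments / r.final_network.n_segments
             if r.checkpoints else 100.0
             for r in self.records]
        )


def run_ensemble(
    network: VascularNetwork | Callable[[], VascularNetwork],
    config: SimConfig,
    n_replicates: int,
    seeds: Optional[Sequence[int]] = None,
) -> EnsembleSummary:
    """Independent replicate runs differing only in their RNG streams.

    A fixed network instance is reused across replicates (patency-map
    design); a callable generator is invoked once per replicate.
    Individual failures are recorded and the ensemble continues.
    """
    if seeds is None:
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(config.seed).spawn(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")
    records: List[TrajectoryRecord] = []
    failures: List[Tuple[int, str]] = []
    for i, s in enumerate(seeds):
        cfg = config.model_copy(update={"seed": int(s)})
        net_i = network() if callable(network) else network
        try:
            records.append(run_simulation(net_i, cfg))
        except Exception as e:  # noqa: BLE001 - ensemble robustness contract
            failures.append((i, repr(e)))
    if not records:
        raise RuntimeError(f"all {n_replicates} replicates failed: {failures[:3]}")

    m = records[0].final_network.n_segments
    patent_end = np.zeros(m)
    for r in records:
        patent_end += r.final_network.patent
    patency_frequency = patent_end / len(records)

    progressive = np.zeros(len(records), dtype=bool)
    phase_points = []
    for i, r in enumerate(records):
        base_f = r.baseline.total_inflow
        base_o = r.baseline.mean_mc_oxygen
        if r.checkpoints:
            last = r.checkpoints[-1]
            progressive[i] = (last.total_inflow < 0.75 * base_f) or (last.mean_mc_oxygen < 0.75 * base_o)
            pts = np.column_stack([r.weeks, r.series("total_inflow"), r.series("mean_mc_oxygen")])
        else:
            pts = np.empty((0, 3))
        phase_points.append(pts)
    return EnsembleSummary(records, patency_frequency, progressive, phase_points, failures)


def phase_orientation(record: TrajectoryRecord) -> float:
    """Signed area of the (inflow, mean O2) phase trajectory (closed).

    Negative signed area means clockwise passage — baseline → higher flow
    at falling oxygen → collapse of both — the signature of a progressive
    run.  Coordinates are normalized by baseline before the shoelace sum.
    """
    if not record.checkpoints:
        return 0.0
    x = np.concatenate([[1.0], record.series("total_inflow") / max(record.baseline.total_inflow, 1e-12)])
    y = np.concatenate([[1.0], record.series("mean_mc_oxygen") / max(record.baseline.mean_mc_oxygen, 1e-12)])
    x = np.append(x, x[0])
    y = np.append(y, y[0])
    return float(0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def occlusion_locality_test(
    summary: EnsembleSummary,
    net: VascularNetwork,
    initial_segment: int,
    n_permutations: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Permutation test: are secondary occlusions nearer the initial site
    than a uniform-random draw over the same network?

    Distance is graph distance (hops) between segments on the line graph of
    the patent baseline network.  Returns the observed mean distance, the
    null mean, and the permutation p-value (one-sided, smaller is nearer).
    """
    import networkx as nx

    rng = rng or np.random.default_rng(0)
    g = nx.Graph()
    for sid, (a, b) in enumerate(net.seg_nodes):
        g.add_edge(int(a), int(b), sid=sid)
    lg = nx.line_graph(g)
    edge_of = {}
    for u, v, d in g.edges(data=True):
        edge_of[d["sid"]] = (u, v) if (u, v) in lg else (v, u)
    src = edge_of[initial_segment]
    dist = nx.single_source_shortest_path_length(lg, src)
    seg_dist = np.array([dist.get(edge_of[s], np.inf) for s in range(net.n_segments)])

    observed: List[float] = []
    for r in summary.records:
        for wk, kind, sid in r.events:
            if kind == "occlusion" and sid != initial_segment:
                if np.isfinite(seg_dist[sid]):
                    observed.append(seg_dist[sid])
    if not observed:
        return {"observed_mean": math.nan, "null_mean": math.nan, "p_value": 1.0, "n_secondary": 0}
    observed = np.asarray(observed)
    candidates = np.flatnonzero(np.isfinite(seg_dist) & ~net.seg_is_trunk
                                & (np.arange(net.n_segments) != initial_segment))
    null_means = np.empty(n_permutations)
    for k in range(n_permutations):
        null_means[k] = seg_dist[rng.choice(candidates, size=len(observed), replace=True)].mean()
    obs_mean = float(observed.mean())
    p = float((np.sum(null_means <= obs_mean) + 1) / (n_permutations + 1))
    return {
        "observed_mean": obs_mean,
        "null_mean": float(null_means.mean()),
        "p_value": p,
        "n_secondary": int(len(observed)),
    }


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_defaults(
    network_factory: Optional[Callable[[], VascularNetwork]] = None,
    config: Optional[SimConfig] = None,
    verbose: bool = False,
) -> Tuple[SimConfig, Dict[str, float]]:
    """Deterministic search for the oxygen/VEGF/occlusion constants.

    Stage 1 adjusts (V_max, PO2art, D_O2) until the pre-occlusion steady
    state of the 65-μm hexagonal reference lattice satisfies: minimum cell
    tension ≥ 4 mmHg, bulk of cells within 10–25 mmHg, near-vessel cells
    reaching 35–40 mmHg.  Stage 2 checks that a single occlusion raises
    the VEGF peak above V_half over the ischemic patch and that the basal
    spontaneous occlusion rate is of order one per network-year, nudging
    (k_syn, p_occl_max) if not.  Returns the calibrated config and a
    report of the achieved figures.
    """
    from .network import generate_hexagonal

    factory = network_factory or (lambda: generate_hexagonal(65.0, 4, 4, 0.0, seed=0))
    cfg = (config or SimConfig()).model_copy()
    report: Dict[str, float] = {}

    def stage1_metrics(c: SimConfig):
        net = factory()
        assign_boundary_conditions(net, c)
        tissue = build_tissue(net, c)
        flow = solve_flow(net, c)
        ox = run_oxygen_to_steady_state(net, flow, tissue, c)
        t = ox.tension
        tiles = tissue.kind != 0
        bulk = float(np.mean((t[tiles] >= 10) & (t[tiles] <= 25)))
        near = t[tissue.kind == 0]  # vessel blocks carry the near-vessel tension
        return net, tissue, flow, ox, {
            "min_tension": float(t.min()),
            "bulk_10_25": bulk,
            "near_vessel_median": float(np.median(near)),
        }

    # stage 1: bisect po2_art so near-vessel tension lands in 35-40 mmHg,
    # then raise/lower vmax to put the tissue bulk in band with min >= 4
    for _ in range(8):
        net, tissue, flow, ox, m = stage1_metrics(cfg)
        ok_near = 35.0 <= m["near_vessel_median"] <= 40.0
        ok_min = m["min_tension"] >= 4.0
        ok_bulk = m["bulk_10_25"] >= 0.5
        if ok_near and ok_min and ok_bulk:
            break
        if not ok_near:
            cfg = cfg.model_copy(update={
                "po2_art_mmHg": cfg.po2_art_mmHg * np.clip(37.5 / max(m["near_vessel_median"], 1.0), 0.7, 1.4)
            })
            continue
        if not ok_min:
            cfg = cfg.model_copy(update={"vmax_o2": cfg.vmax_o2 * 0.85})
            continue
        if not ok_bulk:
            cfg = cfg.model_copy(update={"vmax_o2": cfg.vmax_o2 * 1.1})
    report.update(m)

    # stage 2: basal occlusion rate (kept low — spontaneous events must not
    # swamp the focal propagation dynamics) and post-occlusion VEGF peak
    vg0 = run_vegf_to_steady_state(ox.tension, tissue, cfg)
    seg_vegf = pathology.segment_vegf_levels(net, tissue, vg0.level)
    p = pathology.occlusion_probability(seg_vegf, flow.seg_speed, cfg)
    p = p[net.patent & ~net.seg_is_trunk]
    checks_per_year = 365.0 / cfg.dt_occlusion_days
    rate = float(p.sum() * checks_per_year)
    for _ in range(6):
        if rate <= 1.0:
            break
        cfg = cfg.model_copy(update={
            "p_occl_max": float(np.clip(cfg.p_occl_max / max(rate, 1e-9), 1e-4, 1.0))
        })
        p = pathology.occlusion_probability(seg_vegf, flow.seg_speed, cfg)
        p = p[net.patent & ~net.seg_is_trunk]
        rate = float(p.sum() * checks_per_year)
    report["basal_occlusions_per_year"] = rate

    # single-occlusion VEGF peak vs V_half, probed on the edge-deleted
    # lattice (the full honeycomb is deliberately robust to one loss; the
    # deleted variant carries the vulnerable patches propagation needs)
    from .network import generate_hexagonal

    net2 = generate_hexagonal(65.0, 4, 4, 0.25, seed=1)
    assign_boundary_conditions(net2, cfg)
    tissue2 = build_tissue(net2, cfg)
    mid = net2.node_pos[:, :2].mean(axis=0)
    mids = 0.5 * (net2.node_pos[net2.seg_nodes[:, 0], :2]
                  + net2.node_pos[net2.seg_nodes[:, 1], :2])
    interior = np.flatnonzero(~net2.node_is_boundary[net2.seg_nodes].any(axis=1))
    sid = int(interior[np.argmin(np.linalg.norm(mids[interior] - mid, axis=1))])
    occlude(net2, sid, eps_d=cfg.eps_d_um)
    flow2 = solve_flow(net2, cfg)
    ox2 = run_oxygen_to_steady_state(net2, flow2, tissue2, cfg)
    vg2 = run_vegf_to_steady_state(ox2.tension, tissue2, cfg)
    peak = float(vg2.level.max())
    if peak <= cfg.v_half_occl:
        cfg = cfg.model_copy(update={"k_syn": cfg.k_syn * 2.0})
        vg2 = run_vegf_to_steady_state(ox2.tension, tissue2, cfg)
        peak = float(vg2.level.max())
    report["single_occlusion_vegf_peak"] = peak
    report["v_half_occl"] = cfg.v_half_occl
    if verbose:
        for k, v in report.items():
            print(f"  {k}: {v:.4g}")
    return cfg, report


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def sweep_parameters(
    network_factory: Callable[[], VascularNetwork],
    config: SimConfig,
    grid: Dict[str, Sequence[float]],
    n_replicates: int = 28,
):
    """One-at-a-time parameter sweep.

    For each named config field and each multiplier/value in its list, run
    ``n_replicates`` replicates and report the mean patency index (% of
    segments patent at the end) and mean % thickness change.  Values are
    absolute; pass ``config_field_value * k`` for fold variations.
    Returns a tidy DataFrame.
    """
    import pandas as pd

    rows = []
    for name, values in grid.items():
        if not hasattr(config, name):
            raise KeyError(f"unknown config field: {name}")
        for val in values:
            cfg = config.model_copy(update={name: val})
            try:
                summ = run_ensemble(network_factory, cfg, n_replicates)
                rows.append({
                    "parameter": name,
                    "value": val,
                    "mean_patency_index": float(summ.patency_index.mean()),
                    "mean_thickness_change_pct": float(np.mean([
                        r.checkpoints[-1].thickness_change_pct if r.checkpoints else 0.0
                        for r in summ.records
                    ])),
                    "n_ok": len(summ.records),
                    "n_failed": len(summ.failures),
                })
            except Exception as e:  # noqa: BLE001 - per-cell failure propagation
                rows.append({"parameter": name, "value": val, "error": repr(e)})
    return pd.DataFrame(rows)
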