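"""Simulation configuration.

All model constants live in one validated container so that a run is fully
specified by (network, config, seed).  Units are micrometres, seconds and
mmHg unless a field name says otherwise.  VEGF is in arbitrary units (A.U.)
with the basal level ``v_b`` defining the unit scale.

Default kinetic and transport constants are the package's calibrated
defaults: they were chosen by the deterministic calibration procedure in
:mod:`retsim.simulation` so that the pre-occlusion steady state on the
65-μm hexagonal reference lattice has no cell below the 4 mmHg hypoxia
threshold, the bulk of cells between 10 and 25 mmHg and near-vessel cells
at 35–40 mmHg, and so that the spontaneous occlusion rate of an undamaged
network is of order one event per network-year.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

__all__ = ["SimConfig"]


class SimConfig(BaseModel):
    """All time steps, thresholds, kinetic/transport constants and seeds."""

    model_config = {"validate_assignment": True}

    # ---- clocks -----------------------------------------------------------
    dt_flux_s: float = Field(0.002, gt=0, description="integration step for oxygen/VEGF fluxes [s]")
    dt_edema_days: float = Field(7.0, gt=0, description="interval between leakiness/edema checks [days]")
    dt_occlusion_days: float = Field(28.0, gt=0, description="interval between occlusion checks [days]")
    horizon_weeks: int = Field(156, gt=0, description="simulated horizon after first occlusion [weeks]")

    # ---- hemodynamics -----------------------------------------------------
    p_art_mmHg: float = Field(38.0, description="arteriolar trunk boundary pressure")
    p_ven_mmHg: float = Field(18.0, description="venular trunk boundary pressure")
    mu_blood_cP: float = Field(2.0, gt=0, description="effective blood viscosity [centipoise]")
    k_adapt: float = Field(0.5, ge=0, description="gain of the shear-stress diameter adaptation law")
    adapt_step_cap: float = Field(0.01, gt=0, description="max relative diameter change per adaptation event")
    adapt_constrict_frac: float = Field(0.15, ge=0, le=1, description="constriction response relative to dilation (shear-dilation dominates acutely)")
    adapt_bounds: Tuple[float, float] = Field((0.8, 1.3), description="hard diameter bounds, × reference diameter")
    eps_d_um: float = Field(1e-6, gt=0, description="diameter assigned to occluded segments")

    # ---- oxygen -----------------------------------------------------------
    po2_art_mmHg: float = Field(42.0, gt=0, description="arterial inlet oxygen tension")
    po2_faz_mmHg: float = Field(18.0, ge=0, description="Dirichlet oxygen tension of the avascular-zone source")
    inlet_o2_scale: float = Field(0.8, gt=0, le=1.0, description="oxygen of secondary inflow boundaries, × arterial")
    alpha_o2: float = Field(1.0, gt=0, description="oxygen content per (mmHg × μm³ of cell volume)")
    hb_capacity_factor: float = Field(30.0, ge=1, description="blood:tissue oxygen capacity ratio (hemoglobin binding)")
    d_o2: float = Field(9.5, gt=0, description="pairwise oxygen exchange coefficient [μm/s per unit α]")
    vmax_o2: float = Field(1.0, ge=0, description="Michaelis–Menten maximal consumption [mmHg/s]")
    km_o2: float = Field(4.0, gt=0, description="Michaelis–Menten half-saturation tension [mmHg]")
    o2_hypoxia_mmHg: float = Field(4.0, gt=0, description="tension below which a Mueller cell turns hypoxic")

    # ---- VEGF -------------------------------------------------------------
    v_b: float = Field(1.0, gt=0, description="basal VEGF level [A.U.]; defines the VEGF unit scale")
    v_sat: float = Field(50.0, gt=0, description="VEGF saturation level for synthesis shut-off [A.U.]")
    k_syn: float = Field(140.0, ge=0, description="maximal hypoxic synthesis rate [A.U./s]")
    syn_o2_exp: float = Field(1.0, gt=0, description="exponent of the oxygen-deficit ramp in VEGF synthesis")
    syn_v_exp: float = Field(1.0, gt=0, description="exponent of the VEGF-saturation ramp in synthesis")
    k_dec: float = Field(0.1, gt=0, description="first-order VEGF decay rate [1/s]")
    d_vegf: float = Field(15.0, gt=0, description="pairwise VEGF exchange coefficient [μm/s]")

    # ---- pathology --------------------------------------------------------
    mvegf_thr_leak: float = Field(4.0, gt=0, description="VEGF threshold for the leaky CAP state [A.U.]")
    p_occl_max: float = Field(0.9, ge=0, le=1, description="ceiling of the per-check occlusion probability")
    v_half_occl: float = Field(2.8, gt=0, description="VEGF level of half-maximal occlusion probability [A.U.]")
    hill_occl: float = Field(10.0, ge=1, description="Hill exponent of the VEGF dependence")
    v_scale_occl: float = Field(6000.0, gt=0, description="velocity scale of flow protection [μm/s]")
    fp_unit_volume_um3: float = Field(3000.0, gt=0, description="fluid volume added per leaky segment per weekly check")
    fp_removal_um3: float = Field(1500.0, ge=0, description="fluid volume drained per wet tissue column per week")

    # ---- tissue geometry --------------------------------------------------
    a_mc_um: float = Field(12.0, gt=0, description="Mueller-cell tile pitch")
    mc_fraction: float = Field(0.5, gt=0, lt=1, description="fraction of tissue tiles labelled Mueller cells")
    cap_block_len_um: float = Field(10.0, gt=0, description="capillary block length along the centreline")
    cap_contact_factor: float = Field(1.5, gt=0, description="perivascular interface enhancement of CAP-tissue contact area")
    thickness_um: float = Field(50.0, gt=0, description="baseline retinal thickness (Z extent)")
    faz_contact_factor: float = Field(0.05, gt=0, description="permeability scaling of the avascular-zone rim interface")

    # ---- numerics ---------------------------------------------------------
    belt_min_um: float = Field(0.5, gt=0, description="minimum conveyor-belt size (slow segments sub-step)")
    v_stagnant_um_s: float = Field(2.0, ge=0, description="speed below which a segment is treated as non-advecting")
    tol_ss: float = Field(1e-6, gt=0, description="relative per-iteration change defining steady state")
    ss_window: int = Field(10, ge=1, description="consecutive sub-tolerance iterations required")
    max_ss_iters: int = Field(1_000_000, ge=1, description="hard iteration cap for steady-state drivers")

    # ---- run control ------------------------------------------------------
    seed: int = Field(0, ge=0)
    run_mode: Literal["spontaneous", "forced"] = "forced"
    forced_segment: Optional[int] = Field(None, description="segment occluded at week 0 in forced mode")
    max_wait_checks: int = Field(2000, ge=1, description="spontaneous mode: max monthly draws before week 0")

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.p_art_mmHg <= self.p_ven_mmHg:
            raise ValueError("arterial pressure must exceed venous pressure")
        if self.adapt_bounds[0] >= self.adapt_bounds[1]:
            raise ValueError("adapt_bounds must be increasing")
        if self.run_mode == "forced" and self.forced_segment is None:
            # forced mode with unspecified site: the driver picks a default site
            pass
        if round(self.horizon_weeks * 7.0 / self.dt_edema_days, 9) % 1 != 0:
            raise ValueError("horizon must be a whole number of edema intervals")
        return self

    # convenience ------------------------------------------------------------
    @property
    def mu_blood_mmHg_s(self) -> float:
        """Blood viscosity in mmHg·s (1 mmHg = 133.322 Pa; 1 cP = 1e-3 Pa·s)."""
        return self.mu_blood_cP * 1e-3 / 133.322

    @property
    def occlusion_every_weeks(self) -> int:
        return int(round(self.dt_occlusion_days / self.dt_edema_days))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, default=list)
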