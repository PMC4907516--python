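# retsim

A mechanistic simulator of progressive retinal capillary occlusion in
diabetic retinopathy, for researchers studying how focal microvascular
damage propagates into contiguous ischemia and macular edema.

Strictly random capillary occlusion cannot produce the large contiguous
ischemic areas seen clinically, so the model implements an adverse
feedback loop on an explicit capillary network:

1. a capillary segment occludes (leukocyte plugging, abstracted as a
   stochastic event);
2. the tissue it supplied drops below the hypoxia threshold
   (4 mmHg O₂) and its Mueller cells synthesize VEGF;
3. VEGF diffuses a few cell widths and raises the occlusion hazard of
   neighbouring capillaries,
   `p = p_max · V^h/(V^h + V_half^h) · e^{−v/v_scale}`,
   promoted by VEGF and protected by blood speed `v`;
4. each new occlusion deepens the hypoxia — ischemia spreads locally
   while oxygenated halos around arterioles and venules act as barriers.

The physics underneath: Poiseuille network flow
(`g = πd⁴/128μL`, Kirchhoff-exact), conveyor-belt oxygen advection along
each perfused segment coupled to contact-area diffusion
(`J = D·A·ΔC`) and Michaelis–Menten consumption
(`vmax·C/(Km+C)`) on a generalized-cell tiling, a
synthesis–diffusion–decay VEGF field, weekly VEGF-threshold capillary
leakiness with fluid bookkeeping (retinal thickness), and shear-driven
diameter adaptation after every occlusion.  Three built-in generators
provide the study geometries: a 65-μm hexagonal lattice (with optional
edge deletion), a peripheral arteriovenous "ladder" network (18-μm
shunts, 10-μm rungs), and a synthetic macular arteriole–venule sector
with a foveal avascular zone (510×600 μm, capillaries ~ N(5, 0.5) μm).

## Worked example

A three-year macular run with a forced juxtafoveal first occlusion:

```python
from retsim import SimConfig, generate_macular_sector, run_simulation

config = SimConfig(seed=3, run_mode="forced")
network = generate_macular_sector(seed=0)
record = run_simulation(network, config)

base, final = record.baseline, record.checkpoints[-1]
print(f"segments: {network.n_segments}, occlusion events: {len(record.events)}")
print(f"baseline: inflow {base.total_inflow:.3g} um^3/s, "
      f"mean MC oxygen {base.mean_mc_oxygen:.1f} mmHg")
print(f"week {final.model_week}: inflow {100*final.total_inflow/base.total_inflow:.0f}% "
      f"of baseline, hypoxic fraction {final.hypoxic_mc_fraction:.2f}")
```

prints

```
segments: 80, occlusion events: 6
baseline: inflow 1.08e+05 um^3/s, mean MC oxygen 26.3 mmHg
week 156: inflow 84% of baseline, hypoxic fraction 0.02
```

— a *bounded* replicate: the forced occlusion killed the perifoveal ring
and a handful of neighbours, then the dense interior mesh arrested the
wave.  Other seeds of the same network produce progressive replicates in
which inflow first rises a few percent (shear-driven dilation of the
surviving paths) and then collapses below 75 % of baseline while the
hypoxic fraction climbs — the two outcomes whose mixture the replicate
ensemble analyses quantify (`run_ensemble`, patency maps, flow–oxygen
phase trajectories, progressive classification).

A command-line interface wraps the same library:

```bash
retsim generate macular --seed 0 --out net.json
retsim run net.json --seed 3 --outdir traj/
retsim report traj/
retsim ensemble net.json -n 20 --seed 1 --outdir ens/
```

## Layout

| module | contents |
| --- | --- |
| `retsim.network` | network data model, the three generators, boundary conditions, JSON/CSV I/O |
| `retsim.hemodynamics` | Poiseuille solver, occlusion, diameter adaptation |
| `retsim.tissue` | generalized-cell tiling, contact graph, cell-to-vessel distances |
| `retsim.oxygen` | conveyor-belt advection, diffusion, consumption, steady-state driver |
| `retsim.vegf` | Mueller-cell VEGF synthesis, diffusion/decay, steady-state driver |
| `retsim.pathology` | occlusion hazard, leaky states, edema/thickness bookkeeping |
| `retsim.simulation` | event loop, calibration, ensembles, metrics, sweeps |
| `retsim.cli` | `retsim` command-line entry point |

`docs/methods.md` documents the model assumptions, the calibration of
every constant, and the known limitations.
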