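# willisflow

Outlet boundary-condition benchmarking for cerebrovascular flow models on a
lumped Circle-of-Willis network.

## The problem

Simulations of blood flow in the cerebral arteries — whether full 3D CFD or
reduced-order models — impose volumetric flows at the four feeding vessels
(left/right internal carotid arteries LICA/RICA and vertebral arteries
LVA/RVA) and need *pressure* boundary conditions at the six outflow vessels
(anterior, middle and posterior cerebral arteries: LACA/RACA, LMCA/RMCA,
LPCA/RPCA). The choice of outlet BC dominates the predicted distribution of
total cerebral blood flow (tCBF), the flow pulsatility index and the
transient arterial pressures. `willisflow` provides, for researchers in
computational hemodynamics, the machinery to define, fit and compare five
outlet BC families against time-resolved reference flow/pressure recordings:

| BC  | form |
|-----|------|
| ZP  | one stationary gauge pressure p̄ for all outlets |
| SP  | stationary side-averaged means, p = p̄ₙ + ½·cₙ·ρ·(Q/A)² |
| DEP | direct playback of measured outlet pressure curves |
| WM  | two-element Windkessel, C·dp/dt = Q − p/R, with uniform τ = R·C |
| PM  | phase modulation, p = p̄ₙ·(1 + PI_p/2·cos(2πft + φ + β·cos(2πft + φ))) |

The Windkessel resistances come from fitting Δp = R·Q to the reference data
(left/right class-averaged); the PM parameters (PI_p, φ, β) are across-outlet
medians of per-outlet nonlinear least-squares fits. Results are scored with
the field's standard descriptors: cycle-averaged flows and tCBF fractions,
pulsatility index PI = (Q̂_sys − Q̂_dia)/Q̄, pulse pressure, and RMSD/NRMSD
(RMSD normalized by the cycle-averaged reference value) over the last cardiac
cycle.

Because licensed 3D CFD solvers are not a reasonable dependency for a
benchmarking library, the transient solver here is a 0D lumped
resistive–inertial network of the Circle of Willis (Poiseuille resistance
128μl/(πd⁴), inertance 4ρl/(πd²) per segment, Kirchhoff nodal equations,
backward-Euler time stepping at 1 ms, explicit Euler for the Windkessel
state). All BC machinery, coupling and metrics are identical in kind to the
3D setting; 3D deviation magnitudes are not reproducible at this scale.

A calibrated synthetic-data generator emulates the benchtop reference
experiment (1 Hz displacement pump, 40:60 systole:diastole, tCBF ≈
660 mL·min⁻¹, physiological per-vessel PI and pressures, sensor noise), so
the whole pipeline is testable without any measurement download.

## Worked example

```python
import willisflow as wf

# calibrated synthetic reference dataset: 10 vessels x {flow, pressure}
ws = wf.generate_waveform_set(wf.default_config(seed=1))

# calibration table of the reference
rep = wf.table1_report(ws)
print(f"tCBF in  = {rep['tcbf_in']:.1f} mL/min")
print(f"tCBF out = {rep['tcbf_out']:.1f} mL/min")
p = rep["pressure"]
print(f"mean pressure decrease  {p['mean_pressure_decrease_pct']:.1f}%")
print(f"pulse pressure decrease {p['pulse_pressure_decrease_pct']:.1f}%")

# run the Windkessel BC set on the lumped Circle of Willis
net = wf.build_network(wf.synthetic_cow_geometry())
res = wf.run_bc_set(net, ws, "wm", params={"C_MCA": 2.5e-10})
print(res.summary())
```

prints

```
tCBF in  = 659.3 mL/min
tCBF out = 660.7 mL/min
mean pressure decrease  15.9%
pulse pressure decrease 9.8%
0D network simulation (wm outlet BC)
  dt = 1 ms, 3 cycles (3000 steps), f = 1.0 Hz
  max |sum Q_in - sum Q_out| = 1.016e-20 m^3/s
  outlet     mean flow [mL/min]   mean pressure [mmHg]
  LACA              95.53             85.73
  RACA              95.46             85.68
  LMCA             170.09             86.42
  RMCA             169.83             86.30
  LPCA              64.13             87.67
  RPCA              64.12             87.66
```

The totals and pressure drops confirm the synthetic reference is calibrated
to physiological conditions; the per-step conservation residual shows the
solver conserves mass to machine precision; and the Windkessel outlet flows
track the reference distribution (94.2 / 93.8 / 170.1 / 171.8 / 68.7 /
62.4 mL·min⁻¹) more closely than any stationary-pressure BC does — the
uniform-pressure ZP BC instead shifts flow from the anterior to the
posterior circulation.

A thin CLI mirrors the library: `willisflow synth | table1 | fit | simulate
| evaluate` (see `--help` on each).

## Layout

- `willisflow.waveform` — waveform containers, CSV dialect, Butterworth
  filtering, cycle segmentation/averaging, resampling
- `willisflow.synthetic` — calibrated waveform generator, Windkessel ground
  truth
- `willisflow.metrics` — PI, pulse pressure, tCBF distribution, RMSD/NRMSD
- `willisflow.boundary_conditions` — the five BC families and their fitting
  (`WindkesselModel`, `PhaseModulationModel` with `.fit()` → results +
  `summary()`)
- `willisflow.network` — geometry lumping, steady and transient solvers
- `willisflow.evaluation` — benchmark orchestration and reports

See `docs/methods.md` for the modeling assumptions and numerical choices.
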