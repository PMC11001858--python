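# Methods

## Scope and model

`willisflow` benchmarks outlet pressure boundary conditions (BCs) for
cerebrovascular flow models. The reference configuration is a complete
Circle of Willis (CoW) perfused through four inlets (LICA, RICA, LVA, RVA)
and drained through six outlets (LACA, RACA, LMCA, RMCA, LPCA, RPCA), with
time-resolved volumetric flow (mL·min⁻¹) and gauge static pressure (mmHg)
available at every boundary at 1 kHz over three 1 Hz cardiac cycles. All
pressures are gauge; external units are clinical, internal arithmetic is SI
(1 mmHg = 133.322 Pa, 1 mL·min⁻¹ = 1/60 × 10⁻⁶ m³·s⁻¹).

The transient solver is a 0D lumped network, not a 3D CFD model. Each vessel
segment of length l and diameter d is lumped into a Poiseuille resistance
R = 128 μ l/(π d⁴) and an inertance L = 4 ρ l/(π d²). The working fluid is a
blood-analogue water–glycerol mixture (ρ = 1137 kg·m⁻³, μ = 4.01 mPa·s);
walls are rigid, flow laminar, fluid incompressible. Volumetric flows are
imposed at the inlets, pressures at the outlets; unknown nodal pressures
follow from Kirchhoff's current law with the segment law
p_a − p_b = R q + L dq/dt discretized by backward Euler (unconditionally
stable), so each step solves one sparse linear system whose matrix is
constant over the run and factorized once (direct sparse LU; the system has
~tens of nodes, so no iterative tolerance exists to tune). Global mass
conservation per step is exact up to linear-solver round-off (measured
≈ 10⁻²⁰ m³·s⁻¹, i.e. ~10⁻¹⁵ relative).

What the 0D surrogate deliberately gives up: spatial velocity fields,
secondary flows, nonlinear momentum (except the quadratic SP outlet term),
and any wall compliance. Deviation magnitudes between a rigid 3D CFD model
and a compliant experiment are therefore *not* reproducible here; the solver
is validated instead by closed-form properties (conservation, dense-oracle
equivalence, gauge invariance, current-divider limits, Windkessel steady
states) and by qualitative BC behavior (e.g. the direction of the
anterior→posterior flow shift under a uniform outlet pressure).

## Outlet boundary conditions

All five families share one interface, `pressure(outlet, t, Q)` in mmHg; the
Windkessel is the only stateful member (`advance(outlet, Q, dt)`).

- **ZP** — one stationary gauge pressure for all outlets, the cycle average
  of all measured outlet pressures (87 mmHg for the calibrated reference).
- **SP** — stationary side-averaged class means (ACA, MCA, PCA; the left and
  right member of a class share p̄ₙ) plus the quadratic term
  ½ cₙ ρ (Q/A)². The loss coefficients cₙ and outlet areas A are
  configuration inputs; shipped defaults (cₙ = 1, A from the synthetic
  geometry) are placeholders and logged as such. Inside the transient solver
  the quadratic term is evaluated with the previous step's outlet flow
  (quasi-stationary; the term is ≲ 1 mmHg at physiological outlet flows).
- **DEP** — playback of the measured per-outlet pressure curves by linear
  interpolation with periodic extension; by construction its outlet-pressure
  deviation is the floor for every other BC.
- **WM** — two-element Windkessel C dp/dt = Q − p/R per outlet, with Δp
  taken as outlet gauge pressure relative to a zero venous datum (no venous
  pressure is available, so R ≈ p̄ₙ/Q̄ₙ at cycle means). R is fitted from
  Δp = R·Q — either instantaneous least squares through the origin on
  transient pairs (default of the fitting API) or the ratio of cycle means
  (`mode="mean"`), which is exact in a steady periodic state; the
  instantaneous fit on data from a compliant element is biased by the RC
  phase lag (observed ≲ 5%, tested at that tolerance). Left/right members
  of a class share the averaged R. Capacitances follow from a uniform
  relaxation time τ = R_MCA·C_MCA across outlets; C_MCA is a required
  configuration value with a documented placeholder default
  (2.5 × 10⁻¹⁰ m³·Pa⁻¹, giving τ ≈ 1 s at the calibrated MCA operating
  point) because no authoritative number ships with the package. The WM
  state is advanced by explicit Euler in the simulation step, initialized at
  the cycle-averaged outlet pressure to shorten the start-up transient;
  dt/τ > 0.5 warns and dt/τ ≥ 2 (the explicit-Euler stability bound) raises.
- **PM** — the phase-modulated closed form
  p = p̄ₙ (1 + PI_p/2 · cos(2πft + φ + β cos(2πft + φ))). Fitting is
  bounded nonlinear least squares per outlet (p̄ₙ > 0, PI_p ∈ [0, 5],
  β ∈ [0, 2]) with a four-point multi-start over φ, since the objective is
  non-convex in phase; the sign conventions PI_p, β ≥ 0 remove the
  (φ+π, −β) ambiguity. (PI_p, φ, β) are pooled as across-outlet medians — φ
  circularly, by taking the median in a frame rotated to the circular mean —
  while p̄ₙ stays per outlet. Non-converged outlets are excluded from the
  medians with a warning.

The two fitting procedures are exposed statsmodels-style
(`WindkesselModel(...).fit()`, `PhaseModulationModel(...).fit()`) returning
results objects with estimates, standard errors from the least-squares
Jacobian, residuals and `summary()`.

## Synthetic reference data

The generator emulates the benchtop experiment phenomenologically — there is
no heart or arterial-tree mechanism. Every signal is drawn from the same
modulated-cosine family as the PM boundary condition,
x̄ (1 + PI/2 cos(θ + β cos θ)); useful identities (verified by brute-force
oracles in the tests) are that its cycle mean is exactly x̄ (Bessel-series
cancellation), its peak-to-trough amplitude exactly x̄·PI for β within the
fitted bounds, and β > 0 compresses the upstroke, emulating the 40:60
systole:diastole asymmetry of the pump (default β = 0.5).

Defaults are the calibrated study conditions: 1 Hz, 3 cycles at 1 kHz;
per-vessel mean flows and flow PI equal to the reference experiment's
cycle-averaged results (tCBF in 659.2, out 661.0 mL·min⁻¹ as the sums of the
per-vessel values); inlet pressures 102–105 mmHg with 76–81 mmHg pulse
pressure; outlet pressures 84–90 mmHg (average 87) with 68–73 mmHg pulse
pressure, reproducing the ≈16% mean-pressure and ≈10% pulse-pressure drop
from inlets to outlets. Only pressure *ranges* are reported per boundary
side, so the per-vessel assignment is a package choice; posterior outlet
means are placed above and anterior below the 87 mmHg average, the ordering
implied by the observed anterior→posterior flow shift under the ZP boundary
condition. Per-vessel phases (inlets lead outlets by 0.25–0.35 rad) are
phenomenological; no reference numbers exist.

Measurement noise is i.i.d. Gaussian per sample with SD equal to half the
stated sensor uncertainty bounds (0.25 mmHg, 2.5 mL·min⁻¹) — uncertainties
are quoted as bounds, not SDs, so a conservative mapping is used. One
integer seed drives all noise and is recorded in the CSV sidecar.

Compliance: the emulated phantom is compliant, so instantaneous mass
conservation between inlets and outlets does not hold (outlet pulsatility is
strongly damped: flow-weighted inlet PI ≈ 1.06 vs outlet ≈ 0.50). The
default (`compliant=True`) therefore skips renormalization and matches the
calibrated PI values; `compliant=False` renormalizes outlet flows per sample
to the inlet sum, producing a rigid, conservative set for solver tests. The
two properties — calibrated outlet PI and per-sample mass consistency — are
mutually exclusive by arithmetic, one per mode.

What passing tests on synthetic data do **not** show: fidelity to real
waveform morphology (dicrotic notch, reflected waves), real phase
relationships, non-Gaussian or correlated sensor noise, or any 3D flow
feature. They do show that the fitting, solving and scoring machinery is
internally correct and that the calibration targets are faithfully encoded.

## Experimental post-processing layer

CSV dialect: one column per (vessel, quantity), `<VESSEL>_q` / `<VESSEL>_p`,
optional leading `t` seconds column (0.1% jitter tolerance), default rate
1 kHz. Reading never filters implicitly — whether a dataset ships raw or
pre-filtered flows is unknowable from the file, so filtering is always an
explicit call. The flow filter is a 6th-order Butterworth low-pass at 7 Hz;
the default is a causal single pass initialized at the DC steady state
(matching an online acquisition filter), with zero-phase
forward–backward filtering available by flag for phase-sensitive analyses
(the calibration table uses it to avoid transient edge bias). Cycle
segmentation defaults to fixed 1/f windows anchored at the first sample —
the pump frequency is fixed and known — with flow-minimum foot detection as
an optional mode. Cycle selectors: Table-style statistics use all complete
cycles (mean ± SD across cycles); BC comparisons use the last cycle only.

## Metrics

PI = (Q̂_sys − Q̂_dia)/Q̄ with per-cycle global extrema (ties to first
occurrence) and means averaged across the selected cycles before forming the
ratio; PI_p = pulse pressure / mean pressure analogously. tCBF fractions are
cycle-mean outlet flows over their sum (sum exactly 1). RMSD is the
root-mean-square pointwise difference over the evaluation window; NRMSD
divides by the cycle-averaged reference value, is stored as a fraction and
formatted as percent. Simulated and reference last cycles are compared on
the reference grid with no phase re-alignment — phase error is part of the
deviation being measured.

## Numerical choices and degenerate inputs

- Backward Euler for segment inertance (A-stable), explicit Euler only for
  the WM state, both at dt = 1 ms for 3 cycles with last-cycle evaluation.
- PI raises for zero mean flow (|Q̄| below 10⁻¹² of the extrema).
- A network with no pressure-imposed node is rejected (singular system);
  missing communicating arteries (incomplete CoW) only warn, supporting
  incomplete-anatomy experiments.
- The shipped CoW geometry is a synthetic stand-in assembled from standard
  literature calibers (ICA 4.4 mm, M1 2.9 mm, A1 2.3 mm, P2 2.1 mm,
  communicating arteries 1.4 mm, …); any geometry table with columns
  `segment, node_a, node_b, length_mm, diameter_mm` can replace it.
- Windkessel ground-truth pressures for recovery tests are integrated with
  an adaptive high-accuracy ODE solver (rtol 10⁻¹⁰, max step equal to the
  sample interval), independent of the explicit-Euler path it validates.

## Known limitations

- 0D: no wave propagation, no spatial fields; network pressure drops
  (≲ 1 mmHg inlet→outlet) are far below the ≈16 mmHg of the reference
  experiment, whose losses are dominated by 3D and tubing effects.
- Rigid network vs compliant reference: simulated outlet flows inherit the
  full inlet pulsatility, so flow-deviation metrics against the compliant
  reference are large by design for every BC — the benchmark ranks BCs, it
  does not certify absolute accuracy.
- The Windkessel venous datum is zero gauge pressure; a nonzero venous
  pressure would lower all fitted resistances proportionally.
- cₙ, outlet areas and C_MCA ship as documented placeholders; conclusions
  that depend on their absolute values require measured inputs.
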