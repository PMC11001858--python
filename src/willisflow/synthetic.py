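"""Physiologically structured synthetic flow/pressure waveform sets.

The generator emulates a benchtop cerebrovascular perfusion experiment: a
displacement pump at 1 Hz (40:60 systole:diastole) feeding a Circle-of-Willis
phantom through four inlets (LICA, RICA, LVA, RVA) and draining through six
outlets (LACA, RACA, LMCA, RMCA, LPCA, RPCA), with ultrasound flow probes
(±5 mL·min⁻¹) and pressure transducers (±0.5 mmHg) at every boundary.

Every waveform is drawn from the phase-modulated cosine family

    x(t) = x̄ · (1 + PI/2 · cos(θ + β·cos θ)),   θ = 2πf·t + φ,

whose cycle mean is exactly x̄, whose peak-to-trough amplitude is exactly
x̄·PI, and whose systolic upstroke is compressed relative to diastole for
β > 0 — the same closed form used as the phase-modulation outlet boundary
condition. The default configuration is calibrated to the reference
experiment: per-vessel mean flows and pulsatility indices from its
cycle-averaged results table (tCBF ≈ 659 mL·min⁻¹ in, ≈ 661 out), inlet
pressures 101–105 mmHg with 76–81 mmHg pulse pressure, outlet pressures
84–91 mmHg with 68–73 mmHg pulse pressure, reproducing the ≈16% mean-pressure
and ≈10% pulse-pressure drop from inlets to outlets.

Because the emulated phantom is compliant, instantaneous mass conservation
does **not** hold between inlets and outlets (outlet pulsatility is damped);
set ``compliant=False`` to renormalize outlet flows per sample to the inlet
sum, producing a rigid, conservative set for solver tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .waveform import INLETS, OUTLETS, VESSELS, Waveform, WaveformSet

__all__ = [
    "SynthConfig",
    "default_config",
    "generate_waveform_set",
    "generate_windkessel_truth",
    "pm_waveform",
]


def pm_waveform(t, mean, pi, f=1.0, phi=0.0, beta=0.0):
    """Evaluate the phase-modulated cosine family x̄·(1 + PI/2·cos(θ + β·cosθ))."""
    theta = 2.0 * np.pi * f * np.asarray(t, dtype=float) + phi
    return mean * (1.0 + 0.5 * pi * np.cos(theta + beta * np.cos(theta)))


# Per-vessel calibration of the default config. Mean flows (mL·min⁻¹) and flow
# PI reproduce the reference experiment's cycle-averaged table; pressure means
# and pulse pressures sit inside its reported ranges, with posterior outlet
# pressures above and anterior below the 87 mmHg outlet average (the ordering
# implied by the observed anterior→posterior shift under a uniform-pressure
# outlet BC).
_FLOW_MEAN = {
    "LICA": 249.5, "RICA": 241.0, "LVA": 87.8, "RVA": 80.9,
    "LACA": 94.2, "RACA": 93.8, "LMCA": 170.1, "RMCA": 171.8,
    "LPCA": 68.7, "RPCA": 62.4,
}
_FLOW_PI = {
    "LICA": 1.21, "RICA": 0.89, "LVA": 1.08, "RVA": 1.07,
    "LACA": 0.45, "RACA": 0.50, "LMCA": 0.53, "RMCA": 0.46,
    "LPCA": 0.60, "RPCA": 0.52,
}
_PRESSURE_MEAN = {
    "LICA": 105.0, "RICA": 104.0, "LVA": 102.0, "RVA": 103.0,
    "LACA": 84.0, "RACA": 85.0, "LMCA": 88.0, "RMCA": 86.0,
    "LPCA": 90.0, "RPCA": 89.0,
}
_PULSE_PRESSURE = {
    "LICA": 81.0, "RICA": 79.0, "LVA": 76.0, "RVA": 77.0,
    "LACA": 70.0, "RACA": 71.0, "LMCA": 72.0, "RMCA": 73.0,
    "LPCA": 69.0, "RPCA": 68.0,
}
# Pressure lags flow slightly and outlets lag inlets (compliant transit);
# magnitudes are phenomenological (the reference prints none).
_PHASE = {
    "LICA": 0.00, "RICA": 0.00, "LVA": -0.20, "RVA": -0.20,
    "LACA": -0.35, "RACA": -0.35, "LMCA": -0.30, "RMCA": -0.30,
    "LPCA": -0.25, "RPCA": -0.25,
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic waveform generator.

    Attributes
    ----------
    f : float
        Pump frequency in Hz.
    n_cycles : int
        Number of cardiac cycles to generate.
    sample_rate : float
        Samples per second.
    flow_mean, flow_pi : dict
        Per-vessel mean flow (mL·min⁻¹) and flow pulsatility index.
    pressure_mean, pulse_pressure : dict
        Per-vessel mean gauge pressure (mmHg) and pulse pressure (mmHg); the
        pressure pulsatility is their ratio.
    phase : dict
        Per-vessel phase offset φ in radians.
    beta : float
        Modulation index shared by all vessels; β > 0 shortens systole.
    noise_sd_flow, noise_sd_pressure : float
        SDs of additive i.i.d. Gaussian measurement noise (mL·min⁻¹, mmHg).
    compliant : bool
        If True (the experimental default), outlet flows are left damped and
        instantaneous mass conservation between inlets and outlets is not
        enforced; if False, outlet flows are renormalized per sample so their
        sum equals the inlet sum.
    seed : int
        Seed for all noise.
    """

    f: float = 1.0
    n_cycles: int = 3
    sample_rate: float = 1000.0
    flow_mean: dict = field(default_factory=dict)
    flow_pi: dict = field(default_factory=dict)
    pressure_mean: dict = field(default_factory=dict)
    pulse_pressure: dict = field(default_factory=dict)
    phase: dict = field(default_factory=dict)
    beta: float = 0.5
    systole_fraction: float = 0.4
    noise_sd_flow: float = 2.5
    noise_sd_pressure: float = 0.25
    compliant: bool = True
    seed: int = 20240408

    def validate(self):
        if self.f <= 0:
            raise ValueError("pump frequency f must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd_flow < 0 or self.noise_sd_pressure < 0:
            raise ValueError("noise SDs must be non-negative")
        for v, q in self.flow_mean.items():
            if q <= 0:
                raise ValueError(f"mean flow for {v} must be positive")
        for v, pi in self.flow_pi.items():
            if pi < 0:
                raise ValueError(f"flow PI for {v} must be non-negative")
        return self

    def pressure_pi(self, vessel: str) -> float:
        """PI_p = pulse pressure over mean pressure for one vessel."""
        return self.pulse_pressure[vessel] / self.pressure_mean[vessel]

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(**overrides) -> SynthConfig:
    """Table-calibrated default configuration of the emulated experiment.

    1 Hz pump, 3 cycles at 1 kHz, per-vessel means/PI from the reference
    cycle-averaged results, measurement-noise SDs at half the stated sensor
    uncertainty bounds (0.25 mmHg, 2.5 mL·min⁻¹), fixed seed.
    """
    cfg = SynthConfig(
        flow_mean=dict(_FLOW_MEAN),
        flow_pi=dict(_FLOW_PI),
        pressure_mean=dict(_PRESSURE_MEAN),
        pulse_pressure=dict(_PULSE_PRESSURE),
        phase=dict(_PHASE),
        **overrides,
    )
    return cfg.validate()


def generate_waveform_set(cfg: SynthConfig) -> WaveformSet:
    """Generate the full 10-vessel flow/pressure set from a configuration."""
    cfg.validate()
    n = int(round(cfg.n_cycles * cfg.sample_rate / cfg.f))
    t = np.arange(n) / cfg.sample_rate
    rng = np.random.default_rng(cfg.seed)

    vessels = sorted(cfg.flow_mean)
    flows = {}
    for v in vessels:
        flows[v] = pm_waveform(
            t, cfg.flow_mean[v], cfg.flow_pi[v], cfg.f,
            cfg.phase.get(v, 0.0), cfg.beta,
        )

    inlets = [v for v in vessels if v in INLETS]
    outlets = [v for v in vessels if v in OUTLETS]
    if not cfg.compliant and inlets and outlets:
        s_in = np.sum([flows[v] for v in inlets], axis=0)
        s_out = np.sum([flows[v] for v in outlets], axis=0)
        scale = s_in / s_out
        for v in outlets:
            flows[v] = flows[v] * scale

    waveforms = {}
    for v in vessels:
        noisy = flows[v]
        if cfg.noise_sd_flow > 0:
            noisy = noisy + rng.normal(0.0, cfg.noise_sd_flow, size=n)
        waveforms[(v, "flow")] = Waveform(v, "flow", noisy, cfg.sample_rate)
    for v in sorted(cfg.pressure_mean):
        p = pm_waveform(
            t, cfg.pressure_mean[v], cfg.pressure_pi(v), cfg.f,
            cfg.phase.get(v, 0.0), cfg.beta,
        )
        if cfg.noise_sd_pressure > 0:
            p = p + rng.normal(0.0, cfg.noise_sd_pressure, size=n)
        waveforms[(v, "pressure")] = Waveform(v, "pressure", p, cfg.sample_rate)
    return WaveformSet(waveforms=waveforms)


def generate_windkessel_truth(R, C, Q: Waveform, p0=0.0, f=1.0) -> Waveform:
    """Reference solution of the two-element Windkessel C·dp/dt = Q − p/R.

    Ground-truth generator for resistance/compliance recovery tests. ``R`` is
    in Pa·s·m⁻³, ``C`` in m³·Pa⁻¹, ``Q`` a flow waveform in mL·min⁻¹ (played
    back periodically with frequency ``f``), ``p0`` the initial gauge pressure
    in mmHg. Integrated with an adaptive high-accuracy solver and sampled on
    Q's grid; returns pressure in mmHg.
    """
    from scipy.integrate import solve_ivp

    from . import units
    from .waveform import sample_periodic

    if R <= 0 or C <= 0:
        raise ValueError("R and C must be positive")

    def q_si(t):
        return units.mlmin_to_m3s(sample_periodic(Q, t, f=f))

    def rhs(t, p):
        return (q_si(t) - p / R) / C

    t_eval = Q.t
    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        [units.mmhg_to_pa(p0)],
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-8,
        max_step=Q.dt,
    )
    if not sol.success:
        raise RuntimeError(f"windkessel reference integration failed: {sol.message}")
    return Waveform(
        vessel=Q.vessel,
        quantity="pressure",
        values=units.pa_to_mmhg(sol.y[0]),
        sample_rate=Q.sample_rate,
        t0=Q.t0,
    )
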