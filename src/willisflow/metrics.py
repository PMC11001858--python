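"""Scalar descriptors of hemodynamic waveforms.

Pulsatility index PI = (Q̂_systolic − Q̂_diastolic)/Q̄, pulse pressure,
pressure pulsatility PI_p = pulse pressure / mean pressure, the percentage
distribution of total cerebral blood flow (tCBF) across the six outlets, and
the RMSD/NRMSD deviation between a simulated and a reference waveform
(normalized by the cycle-averaged reference value).

Per-cycle extrema and means are computed inside each selected cardiac-cycle
window and then averaged across cycles before forming ratios; extremum ties
break to the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import OUTLETS, CycleIndex, Waveform, WaveformSet, cycle_average

__all__ = [
    "PulsatilityResult",
    "DeviationResult",
    "DistributionResult",
    "pulsatility_index",
    "pulse_pressure",
    "pressure_pulsatility",
    "tcbf_distribution",
    "rmsd",
    "nrmsd",
]


@dataclass
class PulsatilityResult:
    vessel: str
    q_systolic: float  # cycle-averaged per-cycle peak
    q_diastolic: float  # cycle-averaged per-cycle minimum
    q_mean: float
    pi: float
    pi_sd: float = 0.0  # SD of single-cycle PI across selected cycles


@dataclass
class DeviationResult:
    boundary: str
    quantity: str
    rmsd: float
    nrmsd: float
    normalizer: float


@dataclass
class DistributionResult:
    mean_flow: dict  # vessel -> cycle-mean flow, mL/min
    tcbf: float
    fractions: dict  # vessel -> mean flow / tcbf


def _per_cycle(w: Waveform, ci: CycleIndex, which):
    idx = ci.select(which)
    if not idx:
        raise ValueError("no cycles selected")
    segs = [w.values[ci.window(i)] for i in idx]
    return segs


def pulsatility_index(Q: Waveform, ci: CycleIndex, which="all") -> PulsatilityResult:
    """Flow pulsatility index over the selected cycles.

    Per-cycle max, min and mean are averaged across cycles first; the PI is
    formed from the averaged components. Undefined (error) for zero mean flow.
    """
    segs = _per_cycle(Q, ci, which)
    maxs = np.array([s.max() for s in segs])
    mins = np.array([s.min() for s in segs])
    means = np.array([s.mean() for s in segs])
    q_sys, q_dia, q_mean = maxs.mean(), mins.mean(), means.mean()
    if abs(q_mean) <= 1e-12 * max(abs(q_sys), abs(q_dia), 1e-300):
        raise ZeroDivisionError("PI undefined for zero mean flow")
    per_cycle_pi = (maxs - mins) / means
    return PulsatilityResult(
        vessel=Q.vessel,
        q_systolic=float(q_sys),
        q_diastolic=float(q_dia),
        q_mean=float(q_mean),
        pi=float((q_sys - q_dia) / q_mean),
        pi_sd=float(per_cycle_pi.std(ddof=1)) if len(segs) > 1 else 0.0,
    )


def pulse_pressure(p: Waveform, ci: CycleIndex, which="all") -> float:
    """Per-cycle (max − min), averaged across the selected cycles."""
    segs = _per_cycle(p, ci, which)
    return float(np.mean([s.max() - s.min() for s in segs]))


def pressure_pulsatility(p: Waveform, ci: CycleIndex, which="all") -> float:
    """PI_p: pulse pressure over cycle-mean pressure."""
    mean = cycle_average(p, ci, which)
    if mean == 0:
        raise ZeroDivisionError("PI_p undefined for zero mean pressure")
    return pulse_pressure(p, ci, which) / mean


def tcbf_distribution(
    ws: WaveformSet, ci: CycleIndex, which="all", vessels=OUTLETS
) -> DistributionResult:
    """Cycle-mean flows, their total (tCBF), and per-outlet fractions."""
    missing = [v for v in vessels if (v, "flow") not in ws]
    if missing:
        raise KeyError(f"missing outlet flow waveforms: {', '.join(missing)}")
    means = {v: cycle_average(ws.get(v, "flow"), ci, which) for v in vessels}
    tcbf = float(sum(means.values()))
    return DistributionResult(
        mean_flow=means,
        tcbf=tcbf,
        fractions={v: m / tcbf for v, m in means.items()},
    )


def rmsd(sim: Waveform, exp: Waveform) -> float:
    """Root-mean-squared deviation between two equally sampled waveforms."""
    if sim.n != exp.n:
        raise ValueError(f"length mismatch: {sim.n} vs {exp.n}")
    if not np.isclose(sim.sample_rate, exp.sample_rate):
        raise ValueError("sample-rate mismatch")
    return float(np.sqrt(np.mean((sim.values - exp.values) ** 2)))


def nrmsd(sim: Waveform, exp: Waveform, normalizer: float) -> DeviationResult:
    """RMSD normalized by the cycle-averaged reference value (a fraction)."""
    if normalizer == 0:
        raise ZeroDivisionError("NRMSD undefined for zero normalizer")
    r = rmsd(sim, exp)
    return DeviationResult(
        boundary=exp.vessel,
        quantity=exp.quantity,
        rmsd=r,
        nrmsd=r / abs(normalizer),
        normalizer=float(normalizer),
    )
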