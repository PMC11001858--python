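"""Time-resolved flow/pressure waveforms and their experimental post-processing.

This module holds the in-memory containers for the measured (or synthesized)
hemodynamic signals — volumetric flow in mL·min⁻¹ and gauge static pressure in
mmHg per vessel — together with the operations applied to the raw recordings:
CSV ingest/export, Butterworth low-pass filtering, segmentation of the signal
into cardiac cycles of the known pump period, cycle averaging, and linear
resampling with periodic extension.

The CSV dialect is one column per (vessel, quantity) pair named ``<VESSEL>_q``
(flow) or ``<VESSEL>_p`` (pressure), with an optional leading ``t`` column in
seconds; without a time column the sample rate defaults to 1 kHz, the
acquisition rate of the reference experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

INLETS = ("LICA", "RICA", "LVA", "RVA")
OUTLETS = ("LACA", "RACA", "LMCA", "RMCA", "LPCA", "RPCA")
VESSELS = INLETS + OUTLETS

#: canonical unit per quantity
UNITS = {"flow": "mL/min", "pressure": "mmHg"}
_SUFFIX = {"q": "flow", "p": "pressure"}


@dataclass
class Waveform:
    """A uniformly sampled scalar time series for one vessel.

    Parameters
    ----------
    vessel : str
        Vessel label (e.g. ``"LICA"``).
    quantity : {"flow", "pressure"}
    values : ndarray
        Samples in clinical units (mL·min⁻¹ for flow, mmHg for pressure).
    sample_rate : float
        Samples per second (Hz).
    t0 : float
        Time of the first sample in seconds.
    """

    vessel: str
    quantity: str
    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    unit: str = field(default="")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity not in UNITS:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not self.unit:
            self.unit = UNITS[self.quantity]
        if self.unit != UNITS[self.quantity]:
            raise ValueError(
                f"unit {self.unit!r} inconsistent with quantity {self.quantity!r}"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) * self.dt

    def with_values(self, values: np.ndarray) -> "Waveform":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class WaveformSet:
    """Collection of waveforms keyed by ``(vessel, quantity)``.

    All members share sample rate and length. ``vessel_roles`` maps each vessel
    to ``"inlet"`` or ``"outlet"`` (assigned automatically for the ten
    canonical labels).
    """

    waveforms: dict
    vessel_roles: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.waveforms:
            raise ValueError("WaveformSet must contain at least one waveform")
        rates = {w.sample_rate for w in self.waveforms.values()}
        lengths = {w.n for w in self.waveforms.values()}
        if len(rates) > 1 or len(lengths) > 1:
            raise ValueError("all member waveforms must share sample_rate and length")
        for v in self.vessels:
            if v not in self.vessel_roles:
                if v in INLETS:
                    self.vessel_roles[v] = "inlet"
                elif v in OUTLETS:
                    self.vessel_roles[v] = "outlet"

    def __getitem__(self, key) -> Waveform:
        return self.waveforms[key]

    def __contains__(self, key) -> bool:
        return key in self.waveforms

    @property
    def vessels(self):
        return sorted({v for v, _ in self.waveforms})

    @property
    def sample_rate(self) -> float:
        return next(iter(self.waveforms.values())).sample_rate

    @property
    def n(self) -> int:
        return next(iter(self.waveforms.values())).n

    def get(self, vessel: str, quantity: str) -> Waveform:
        try:
            return self.waveforms[(vessel, quantity)]
        except KeyError:
            raise KeyError(f"no {quantity} waveform for vessel {vessel!r}") from None

    def inlet_flows(self) -> dict:
        return {
            v: self.get(v, "flow")
            for v in self.vessels
            if self.vessel_roles.get(v) == "inlet" and (v, "flow") in self.waveforms
        }

    def outlet_flows(self) -> dict:
        return {
            v: self.get(v, "flow")
            for v in self.vessels
            if self.vessel_roles.get(v) == "outlet" and (v, "flow") in self.waveforms
        }

    def outlet_pressures(self) -> dict:
        return {
            v: self.get(v, "pressure")
            for v in self.vessels
            if self.vessel_roles.get(v) == "outlet"
            and (v, "pressure") in self.waveforms
        }


@dataclass
class CycleIndex:
    """Fixed-period cardiac-cycle segmentation of a waveform.

    ``cycle_starts`` are sample indices of the start of each complete cycle;
    consecutive starts differ by ``period * sample_rate``.
    """

    period: float
    cycle_starts: np.ndarray
    systole_fraction: float = 0.4
    sample_rate: float = 1000.0

    def __post_init__(self):
        self.cycle_starts = np.asarray(self.cycle_starts, dtype=int)
        if not 0.0 < self.systole_fraction < 1.0:
            raise ValueError("systole_fraction must lie in (0, 1)")

    @property
    def n_cycles(self) -> int:
        return self.cycle_starts.size

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period * self.sample_rate))

    def window(self, i: int):
        """Half-open sample slice of cycle ``i`` (negative indices allowed)."""
        starts = self.cycle_starts
        s = int(starts[i])
        return slice(s, s + self.samples_per_cycle)

    def select(self, which):
        """Resolve a cycle selector (``"all"``, ``"last"``, or int) to indices."""
        if which == "all":
            return list(range(self.n_cycles))
        if which == "last":
            return [self.n_cycles - 1]
        i = int(which)
        if not -self.n_cycles <= i < self.n_cycles:
            raise IndexError(f"cycle selector {which!r} out of range")
        return [i % self.n_cycles]


# ---------------------------------------------------------------------------
# CSV ingest / export


def read_dataset_csv(
    path,
    sample_rate: float = 1000.0,
    require_all_vessels: bool = True,
    time_column: str = "t",
) -> WaveformSet:
    """Read a flow/pressure recording in the ``<VESSEL>_q`` / ``<VESSEL>_p`` dialect.

    A column named ``time_column`` (seconds) overrides ``sample_rate``; its
    spacing must be uniform to within 0.1%. With ``require_all_vessels`` the
    ten canonical vessels must each supply both a flow and a pressure column.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    t0 = 0.0
    if time_column in cols:
        t = df[time_column].to_numpy(dtype=float)
        dts = np.diff(t)
        if dts.size == 0 or np.any(dts <= 0):
            raise ValueError("time column must be strictly increasing")
        jitter = (dts.max() - dts.min()) / dts.mean()
        if jitter > 1e-3:
            raise ValueError(
                f"inconsistent time step: relative jitter {jitter:.2e} exceeds 0.1%"
            )
        sample_rate = 1.0 / dts.mean()
        t0 = float(t[0])
        cols.remove(time_column)

    waveforms = {}
    for col in cols:
        if "_" not in col:
            continue
        vessel, _, suffix = col.rpartition("_")
        if suffix not in _SUFFIX:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(f"non-numeric value in column {col!r} at row {bad[0]}")
        waveforms[(vessel, _SUFFIX[suffix])] = Waveform(
            vessel=vessel,
            quantity=_SUFFIX[suffix],
            values=vals,
            sample_rate=sample_rate,
            t0=t0,
        )

    if require_all_vessels:
        missing = [
            f"{v}_{s}"
            for v in VESSELS
            for s, q in _SUFFIX.items()
            if (v, q) not in waveforms
        ]
        if missing:
            raise ValueError(f"missing canonical vessel columns: {', '.join(missing)}")
    if not waveforms:
        raise ValueError("no <VESSEL>_q / <VESSEL>_p columns found")
    return WaveformSet(waveforms=waveforms)


def write_dataset_csv(ws: WaveformSet, path, time_column: bool = True):
    """Write a WaveformSet in the same dialect ``read_dataset_csv`` accepts.

    Round-trips every sample to better than 1e-9 relative error.
    """
    data = {}
    if time_column:
        first = next(iter(ws.waveforms.values()))
        data["t"] = first.t
    suffix = {"flow": "q", "pressure": "p"}
    for (vessel, quantity), w in sorted(ws.waveforms.items()):
        data[f"{vessel}_{suffix[quantity]}"] = w.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Filtering, segmentation, averaging, resampling


def lowpass_filter(
    w: Waveform, order: int = 6, cutoff: float = 7.0, zero_phase: bool = False
) -> Waveform:
    """Butterworth low-pass filter (DC gain 1).

    Default is a causal single pass; ``zero_phase`` applies the filter forward
    and backward (``filtfilt``), doubling the effective order but removing
    phase delay.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = w.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=w.sample_rate, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, w.values)
    else:
        # start from the DC steady state so a constant input stays constant
        zi = sps.sosfilt_zi(sos) * w.values[0]
        filtered, _ = sps.sosfilt(sos, w.values, zi=zi)
    return w.with_values(filtered)


def segment_cycles(w: Waveform, f: float = 1.0, anchor: str = "t0") -> CycleIndex:
    """Segment a waveform into fixed-period cardiac cycles.

    With ``anchor="t0"`` windows of length 1/f start at the first sample; the
    number of complete cycles is ``floor(duration * f)``. ``anchor="foot"``
    instead anchors the windows at the detected global flow minimum within the
    first period (foot of the waveform).
    """
    if f <= 0:
        raise ValueError("f must be positive")
    period = 1.0 / f
    spc = int(round(period * w.sample_rate))
    n_cycles = math.floor(w.duration * f + 1e-9)
    if n_cycles < 1:
        raise ValueError(
            f"waveform duration {w.duration:.3f} s shorter than one period {period} s"
        )
    start0 = 0
    if anchor == "foot":
        start0 = int(np.argmin(w.values[:spc]))
        n_cycles = (w.n - start0) // spc
        if n_cycles < 1:
            raise ValueError("no complete cycle after the detected foot")
    elif anchor != "t0":
        raise ValueError(f"unknown anchor {anchor!r}")
    starts = start0 + spc * np.arange(n_cycles)
    return CycleIndex(
        period=period,
        cycle_starts=starts,
        sample_rate=w.sample_rate,
    )


def cycle_average(w: Waveform, ci: CycleIndex, which="all") -> float:
    """Arithmetic mean of the samples in the selected cycle window(s)."""
    idx = ci.select(which)
    parts = [w.values[ci.window(i)] for i in idx]
    return float(np.concatenate(parts).mean())


def resample_linear(w: Waveform, dt: float, n: int | None = None, f: float = 1.0):
    """Resample by linear interpolation with periodic extension.

    Queries outside the recorded span wrap with period ``1/f``. Returns a new
    Waveform with ``n`` samples at spacing ``dt`` (default: cover the original
    duration).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n is None:
        n = int(round(w.duration / dt))
    t_query = w.t0 + np.arange(n) * dt
    vals = sample_periodic(w, t_query, f=f)
    return Waveform(
        vessel=w.vessel,
        quantity=w.quantity,
        values=vals,
        sample_rate=1.0 / dt,
        t0=w.t0,
    )


def sample_periodic(w: Waveform, t, f: float = 1.0) -> np.ndarray:
    """Evaluate a waveform at arbitrary times with periodic extension.

    Interpolation is linear on the recorded grid; times outside the recording
    are wrapped with period 1/f onto the first recorded period, treating the
    signal as periodic (sample at t and t + 1/f agree to machine precision).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    period = 1.0 / f
    tau = t - w.t0
    inside = (tau >= 0) & (tau <= (w.n - 1) * w.dt)
    tau_wrapped = np.where(inside, tau, np.mod(tau, period))
    grid = np.arange(w.n) * w.dt
    # periodic closure: append the first sample one period after cycle start
    spc = int(round(period * w.sample_rate))
    if spc < w.n:
        out = np.interp(tau_wrapped, grid, w.values)
    else:
        grid_ext = np.append(grid[:spc], period)
        vals_ext = np.append(w.values[:spc], w.values[0])
        out = np.where(
            inside,
            np.interp(tau_wrapped, grid, w.values),
            np.interp(tau_wrapped, grid_ext, vals_ext),
        )
    return out
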