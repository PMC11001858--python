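"""Benchmark orchestration: fit outlet BCs, simulate, score against reference.

``run_evaluation`` takes a reference dataset (measured CSV or the synthetic
generator), derives each requested outlet boundary condition from it, runs
the 0D network for each, and scores the simulated inlet pressures, outlet
pressures and outlet flows against the reference over the last cardiac cycle
with RMSD/NRMSD, tCBF fractions, pulsatility indices and pulse pressures.
``table1_report`` produces the calibration table of the reference itself
(per-vessel cycle-mean flow ± SD, tCBF fraction, PI ± SD, pressure summary
with the inlet→outlet mean- and pulse-pressure percentage decreases).

Reports are tidy long-format tables (bc, vessel, quantity, metric, value);
solver rows are labelled "0d-surrogate" — NRMSD magnitudes of a 3D CFD solve
of the same network are not comparable to these.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    nrmsd,
    pressure_pulsatility,
    pulsatility_index,
    pulse_pressure,
    tcbf_distribution,
)
from .network import build_network, run_bc_set, synthetic_cow_geometry
from .waveform import (
    INLETS,
    OUTLETS,
    Waveform,
    WaveformSet,
    cycle_average,
    lowpass_filter,
    read_dataset_csv,
    resample_linear,
    segment_cycles,
)

ALL_BCS = ("zp", "sp", "dep", "wm", "pm")


@dataclass
class EvaluationConfig:
    """Configuration of one benchmark run.

    ``dataset`` is a CSV path or None (generate the default synthetic set with
    ``seed``); ``geometry`` a geometry CSV path or None (synthetic complete
    Circle of Willis); ``C_MCA`` the MCA capacitance anchoring the Windkessel
    τ constraint (m³·Pa⁻¹ — a documented placeholder, the in-vivo source value
    is not printed in the reference).
    """

    dataset: str | None = None
    geometry: str | None = None
    bc_list: tuple = ALL_BCS
    f: float = 1.0
    dt: float = 1e-3
    n_cycles: int = 3
    which: str = "last"
    filter_order: int = 6
    filter_cutoff: float = 7.0
    zero_phase: bool = True
    C_MCA: float = 2.5e-10
    seed: int = 20240408
    out_dir: str | None = None

    def __post_init__(self):
        if not self.bc_list:
            raise ValueError("bc_list must be non-empty")
        unknown = set(self.bc_list) - set(ALL_BCS)
        if unknown:
            raise ValueError(f"unknown BC kinds: {sorted(unknown)}")


@dataclass
class MetricsReport:
    """Tidy benchmark report plus run provenance."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir):
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.csv", index=False, float_format="%.10g")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        return out


def _load_dataset(cfg: EvaluationConfig) -> WaveformSet:
    if cfg.dataset is None:
        from .synthetic import default_config, generate_waveform_set

        return generate_waveform_set(default_config(seed=cfg.seed))
    return read_dataset_csv(cfg.dataset)


def _align_to(sim: Waveform, ref: Waveform) -> Waveform:
    """Resample a simulated waveform onto the reference grid if needed."""
    if sim.n == ref.n and np.isclose(sim.sample_rate, ref.sample_rate):
        return sim
    return resample_linear(sim, ref.dt, n=ref.n)


def run_evaluation(cfg: EvaluationConfig) -> MetricsReport:
    """Full benchmark: per BC, fit → simulate → score against the reference."""
    ws = _load_dataset(cfg)
    geometry = (
        synthetic_cow_geometry() if cfg.geometry is None else pd.read_csv(cfg.geometry)
    )
    net = build_network(geometry)

    ref_ci = segment_cycles(ws.get(OUTLETS[0], "pressure"), f=cfg.f)
    rows = []
    params = {"C_MCA": cfg.C_MCA}
    ref_dist = tcbf_distribution(ws, ref_ci, cfg.which)
    for o, frac in ref_dist.fractions.items():
        rows.append(("experiment", o, "flow", "tcbf_fraction", frac))
        rows.append(("experiment", o, "flow", "mean", ref_dist.mean_flow[o]))

    for bc in cfg.bc_list:
        try:
            sim = run_bc_set(
                net, ws, bc, params=params, dt=cfg.dt, n_cycles=cfg.n_cycles, f=cfg.f
            )
        except Exception as err:  # noqa: BLE001 — abort with stage context
            raise RuntimeError(f"BC set {bc!r}: simulation stage failed") from err
        sl = sim.last_cycle_slice()

        sim_ws = WaveformSet(
            waveforms={
                **{(v, "pressure"): w for v, w in sim.inlet_pressure.items()},
                **{(o, "pressure"): w for o, w in sim.outlet_pressure.items()},
                **{(o, "flow"): w for o, w in sim.outlet_flow.items()},
            }
        )
        sim_ci = segment_cycles(sim.outlet_flow[net.outlets[0]], f=cfg.f)
        dist = tcbf_distribution(sim_ws, sim_ci, "last")
        for o, frac in dist.fractions.items():
            rows.append((bc, o, "flow", "tcbf_fraction", frac))
            rows.append((bc, o, "flow", "mean", dist.mean_flow[o]))

        for vessel in list(net.inlets) + list(net.outlets):
            for quantity in ("pressure", "flow"):
                if vessel in net.inlets and quantity == "flow":
                    continue  # inlet flows are imposed, not computed
                try:
                    sim_w = sim_ws.get(vessel, quantity)
                except KeyError as err:
                    raise RuntimeError(
                        f"BC set {bc!r}: missing simulated {quantity} for {vessel}"
                    ) from err
                ref_w = ws.get(vessel, quantity)
                ref_last = ref_w.with_values(ref_w.values[ref_ci.window(-1)])
                sim_last = sim_w.with_values(sim_w.values[sl])
                sim_last = _align_to(sim_last, ref_last)
                normalizer = cycle_average(ref_w, ref_ci, cfg.which)
                dev = nrmsd(sim_last, ref_last, normalizer)
                rows.append((bc, vessel, quantity, "rmsd", dev.rmsd))
                rows.append((bc, vessel, quantity, "nrmsd", dev.nrmsd))
                if quantity == "flow":
                    pi = pulsatility_index(sim_w, sim_ci, "last")
                    rows.append((bc, vessel, "flow", "pi", pi.pi))
                else:
                    rows.append(
                        (bc, vessel, "pressure", "pulse_pressure",
                         pulse_pressure(sim_w, sim_ci, "last")),
                    )

    table = pd.DataFrame(
        rows, columns=["bc", "vessel", "quantity", "metric", "value"]
    )
    if not np.all(np.isfinite(table["value"])):
        bad = table[~np.isfinite(table["value"])]
        raise RuntimeError(f"non-finite metrics produced:\n{bad}")
    report = MetricsReport(
        table=table,
        provenance={
            "config": asdict(cfg),
            "solver": "0d-surrogate",
            "version": __version__,
            "wm_params": {"C_MCA": cfg.C_MCA},
        },
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


def table1_report(
    ws: WaveformSet,
    f: float = 1.0,
    filter_flows: bool = True,
    filter_order: int = 6,
    filter_cutoff: float = 7.0,
    zero_phase: bool = True,
    which: str = "all",
) -> dict:
    """Calibration summary of a reference dataset.

    Returns ``{"vessels": DataFrame, "pressure": dict}`` — per-vessel mean
    flow ± SD across cycles, tCBF fraction and flow PI ± SD (computed on
    low-pass-filtered flows by default, mirroring the experimental
    post-processing), separate tCBF-in/out totals, and the inlet/outlet
    pressure summary with percentage decreases of mean and pulse pressure.
    """
    missing = [
        v for v in INLETS + OUTLETS
        if (v, "flow") not in ws or (v, "pressure") not in ws
    ]
    if missing:
        raise KeyError(f"missing vessels in dataset: {', '.join(missing)}")
    ci = segment_cycles(ws.get("LICA", "flow"), f=f)

    rows = []
    tcbf = {}
    for role, vessels in (("inlet", INLETS), ("outlet", OUTLETS)):
        means = {}
        for v in vessels:
            q = ws.get(v, "flow")
            if filter_flows:
                q = lowpass_filter(
                    q, order=filter_order, cutoff=filter_cutoff, zero_phase=zero_phase
                )
            per_cycle_mean = [q.values[ci.window(i)].mean() for i in ci.select(which)]
            pi = pulsatility_index(q, ci, which)
            means[v] = float(np.mean(per_cycle_mean))
            rows.append(
                {
                    "vessel": v,
                    "role": role,
                    "mean_flow": means[v],
                    "sd_flow": float(np.std(per_cycle_mean, ddof=1))
                    if len(per_cycle_mean) > 1 else 0.0,
                    "pi": pi.pi,
                    "sd_pi": pi.pi_sd,
                }
            )
        tcbf[role] = float(sum(means.values()))
        for r in rows:
            if r["role"] == role and "tcbf_fraction" not in r:
                r["tcbf_fraction"] = r["mean_flow"] / tcbf[role]
    vessels_df = pd.DataFrame(rows)

    p_mean = {
        v: cycle_average(ws.get(v, "pressure"), ci, which) for v in INLETS + OUTLETS
    }
    pp = {
        v: pulse_pressure(ws.get(v, "pressure"), ci, which) for v in INLETS + OUTLETS
    }
    mi = float(np.mean([p_mean[v] for v in INLETS]))
    mo = float(np.mean([p_mean[v] for v in OUTLETS]))
    ppi = float(np.mean([pp[v] for v in INLETS]))
    ppo = float(np.mean([pp[v] for v in OUTLETS]))
    pressure = {
        "inlet_mean": mi,
        "outlet_mean": mo,
        "inlet_pulse_pressure": ppi,
        "outlet_pulse_pressure": ppo,
        "mean_pressure_decrease_pct": 100.0 * (mi - mo) / mi,
        "pulse_pressure_decrease_pct": 100.0 * (ppi - ppo) / ppi,
        "per_vessel_mean": p_mean,
        "per_vessel_pulse_pressure": pp,
        "per_vessel_pi_p": {
            v: pressure_pulsatility(ws.get(v, "pressure"), ci, which)
            for v in INLETS + OUTLETS
        },
    }
    return {
        "vessels": vessels_df,
        "tcbf_in": tcbf["inlet"],
        "tcbf_out": tcbf["outlet"],
        "pressure": pressure,
    }
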