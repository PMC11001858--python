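"""Transient 0D (lumped resistive–inertial) Circle-of-Willis network solver.

Each vessel segment is lumped into a Poiseuille resistance
R = 128·μ·l/(π·d⁴) and an inertance L = 4·ρ·l/(π·d²) between two nodes.
Volumetric flows are imposed at the four inlet nodes, pressures at the six
outlet nodes (by any of the outlet BC families), and the unknown nodal
pressures follow from Kirchhoff's current law with the segment law
p_a − p_b = R·q + L·dq/dt discretized by backward Euler. The system matrix is
constant over the run and factorized once; only the right-hand side (history
terms and BC pressures) changes per step. The stateful Windkessel BC is
advanced by explicit Euler with the outlet flows the solve produced, in the
same time step.

This is a desk-scale surrogate for a 3D CFD solve of the same network: it
shares the boundary-condition machinery, time stepping (1 ms, 3 cycles,
last-cycle evaluation) and metrics, but carries no spatial flow features, so
3D deviation magnitudes are not reproducible here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from . import units
from .boundary_conditions import FluidProps, OutletBC
from .waveform import INLETS, OUTLETS, Waveform, WaveformSet, sample_periodic

__all__ = [
    "VesselSegment",
    "NetworkModel",
    "SimulationResult",
    "synthetic_cow_geometry",
    "build_network",
    "simulate",
    "steady_solve",
    "run_bc_set",
]


@dataclass
class VesselSegment:
    """A lumped vessel: Poiseuille resistance and inertance between two nodes."""

    name: str
    node_a: str
    node_b: str
    length: float  # m
    diameter: float  # m
    R_seg: float = 0.0  # Pa·s·m⁻³
    L_seg: float = 0.0  # Pa·s²·m⁻³

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"segment {self.name}: length and diameter must be > 0")
        mu_rho_set = self.R_seg > 0
        if not mu_rho_set:
            raise ValueError("use VesselSegment.from_geometry to set R/L")

    @classmethod
    def from_geometry(cls, name, node_a, node_b, length, diameter, fluid: FluidProps):
        R = 128.0 * fluid.mu * length / (np.pi * diameter**4)
        L = 4.0 * fluid.rho * length / (np.pi * diameter**2)
        seg = cls.__new__(cls)
        seg.name, seg.node_a, seg.node_b = name, node_a, node_b
        seg.length, seg.diameter = length, diameter
        seg.R_seg, seg.L_seg = R, L
        if length <= 0 or diameter <= 0:
            raise ValueError(f"segment {name}: length and diameter must be > 0")
        return seg

    @property
    def area(self) -> float:
        return np.pi * self.diameter**2 / 4.0


@dataclass
class NetworkModel:
    """Directed multigraph of lumped vessel segments with boundary roles."""

    segments: list
    inlets: list
    outlets: list
    fluid: FluidProps = field(default_factory=FluidProps)

    def __post_init__(self):
        g = self.graph()
        if not nx.is_connected(g):
            raise ValueError("vessel network is disconnected")
        for n in self.inlets + self.outlets:
            if n not in g:
                raise ValueError(f"boundary node {n!r} not in network")
            if g.degree(n) != 1:
                raise ValueError(f"boundary node {n!r} must have degree 1")

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for s in self.segments:
            g.add_edge(s.node_a, s.node_b, key=s.name)
        return g

    @property
    def nodes(self) -> list:
        seen = {}
        for s in self.segments:
            seen.setdefault(s.node_a)
            seen.setdefault(s.node_b)
        return list(seen)

    @property
    def cycle_rank(self) -> int:
        g = self.graph()
        return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)

    def outlet_areas(self) -> dict:
        """Terminal cross-section area per outlet (m²)."""
        term = {}
        for s in self.segments:
            for n in (s.node_a, s.node_b):
                if n in self.outlets:
                    term[n] = s.area
        return term


#: literature-informed calibers/lengths for a complete Circle of Willis.
_COW_ROWS = [
    # name, node_a, node_b, length_mm, diameter_mm
    ("LICA", "LICA", "LICAt", 100.0, 4.4),
    ("RICA", "RICA", "RICAt", 100.0, 4.4),
    ("LVA", "LVA", "VBj", 60.0, 3.2),
    ("RVA", "RVA", "VBj", 60.0, 3.2),
    ("BA", "VBj", "BAtop", 30.0, 3.5),
    ("LP1", "BAtop", "LPCAj", 7.0, 2.2),
    ("RP1", "BAtop", "RPCAj", 7.0, 2.2),
    ("LP2", "LPCAj", "LPCA", 30.0, 2.1),
    ("RP2", "RPCAj", "RPCA", 30.0, 2.1),
    ("LPCoA", "LICAt", "LPCAj", 15.0, 1.4),
    ("RPCoA", "RICAt", "RPCAj", 15.0, 1.4),
    ("LM1", "LICAt", "LMCA", 35.0, 2.9),
    ("RM1", "RICAt", "RMCA", 35.0, 2.9),
    ("LA1", "LICAt", "ACAjL", 13.0, 2.3),
    ("RA1", "RICAt", "ACAjR", 13.0, 2.3),
    ("ACoA", "ACAjL", "ACAjR", 3.0, 1.4),
    ("LA2", "ACAjL", "LACA", 25.0, 2.4),
    ("RA2", "ACAjR", "RACA", 25.0, 2.4),
]


def synthetic_cow_geometry() -> pd.DataFrame:
    """Synthetic complete Circle-of-Willis geometry table.

    A stand-in vessel table assembled from standard literature calibers (not
    a patient- or phantom-specific geometry): internal carotid and vertebral
    feeding vessels, basilar artery, the communicating-artery ring (ACoA,
    both PCoAs) and the six cerebral outflow segments, with columns
    ``segment, node_a, node_b, length_mm, diameter_mm``.
    """
    return pd.DataFrame(
        _COW_ROWS, columns=["segment", "node_a", "node_b", "length_mm", "diameter_mm"]
    )


def build_network(
    geometry: pd.DataFrame,
    fluid: FluidProps | None = None,
    inlets=None,
    outlets=None,
) -> NetworkModel:
    """Lump a geometry table into a NetworkModel.

    ``geometry`` needs columns segment, node_a, node_b, length_mm,
    diameter_mm. Inlet/outlet nodes default to the canonical vessel labels
    present in the table. Warns when the communicating arteries (ACoA, both
    PCoAs) are absent, i.e. the Circle of Willis is incomplete.
    """
    fluid = fluid or FluidProps()
    segments = [
        VesselSegment.from_geometry(
            row.segment,
            row.node_a,
            row.node_b,
            row.length_mm * 1e-3,
            row.diameter_mm * 1e-3,
            fluid,
        )
        for row in geometry.itertuples()
    ]
    nodes = {s.node_a for s in segments} | {s.node_b for s in segments}
    if inlets is None:
        inlets = [v for v in INLETS if v in nodes]
    if outlets is None:
        outlets = [v for v in OUTLETS if v in nodes]
    if not outlets:
        raise ValueError("network needs at least one outlet (pressure datum)")
    names = {s.name for s in segments}
    missing_comm = {"ACoA", "LPCoA", "RPCoA"} - names
    if set(inlets) >= set(INLETS) and missing_comm:
        warnings.warn(
            f"incomplete Circle of Willis: missing {sorted(missing_comm)}",
            RuntimeWarning,
            stacklevel=2,
        )
    return NetworkModel(segments=segments, inlets=list(inlets), outlets=list(outlets), fluid=fluid)


@dataclass
class SimulationResult:
    """Boundary waveforms and diagnostics of one transient network run."""

    inlet_pressure: dict  # vessel -> Waveform (mmHg)
    outlet_pressure: dict  # vessel -> Waveform (mmHg)
    outlet_flow: dict  # vessel -> Waveform (mL/min)
    dt: float
    n_cycles: int
    f: float
    conservation_residual: np.ndarray  # per-step |ΣQ_in − ΣQ_out| (m³/s)
    bc_kind: str = ""

    @property
    def n_steps(self) -> int:
        return self.conservation_residual.size

    def last_cycle_slice(self) -> slice:
        spc = int(round(1.0 / (self.f * self.dt)))
        return slice(self.n_steps - spc, self.n_steps)

    def max_relative_residual(self, total_inflow: float) -> float:
        """Worst per-step conservation residual relative to total inflow (m³/s)."""
        return float(self.conservation_residual.max() / abs(total_inflow))

    def summary(self) -> str:
        lines = [
            f"0D network simulation ({self.bc_kind or 'custom'} outlet BC)",
            f"  dt = {self.dt * 1e3:.3g} ms, {self.n_cycles} cycles "
            f"({self.n_steps} steps), f = {self.f} Hz",
            f"  max |sum Q_in - sum Q_out| = "
            f"{self.conservation_residual.max():.3e} m^3/s",
            "  outlet     mean flow [mL/min]   mean pressure [mmHg]",
        ]
        sl = self.last_cycle_slice()
        for o in self.outlet_flow:
            q = self.outlet_flow[o].values[sl].mean()
            p = self.outlet_pressure[o].values[sl].mean()
            lines.append(f"  {o:<8}   {q:>12.2f}        {p:>10.2f}")
        return "\n".join(lines)


class _Assembly:
    """Constant-matrix backward-Euler assembly of the nodal equations."""

    def __init__(self, net: NetworkModel, dt: float | None):
        self.net = net
        self.dt = dt
        self.unknown = [n for n in net.nodes if n not in net.outlets]
        self.index = {n: i for i, n in enumerate(self.unknown)}
        self.outlet_index = {n: i for i, n in enumerate(net.outlets)}
        # effective conductance per segment: 1/(R + L/dt); steady: 1/R
        self.g = np.array(
            [
                1.0 / (s.R_seg + (s.L_seg / dt if dt else 0.0))
                for s in net.segments
            ]
        )
        self.hist_coeff = np.array(
            [(s.L_seg / dt if dt else 0.0) for s in net.segments]
        )
        n = len(self.unknown)
        rows, cols, vals = [], [], []
        # B maps outlet pressures into the RHS; rows align with unknown nodes
        self.B = np.zeros((n, len(net.outlets)))
        for g, s in zip(self.g, net.segments):
            for node, other, sign in (
                (s.node_a, s.node_b, 1.0),
                (s.node_b, s.node_a, -1.0),
            ):
                if node not in self.index:
                    continue
                i = self.index[node]
                rows.append(i)
                cols.append(i)
                vals.append(g)
                if other in self.index:
                    rows.append(i)
                    cols.append(self.index[other])
                    vals.append(-g)
                else:
                    self.B[i, self.outlet_index[other]] += g
        self.lu = splu(csc_matrix((vals, (rows, cols)), shape=(n, n)))

    def solve(self, inflow: dict, p_out_pa: np.ndarray, q_prev: np.ndarray):
        """One linear solve; returns nodal pressures (Pa) and segment flows (m³/s)."""
        rhs = self.B @ p_out_pa
        for v, q in inflow.items():
            rhs[self.index[v]] += q
        # history sources from the inertance discretization
        for k, s in enumerate(self.net.segments):
            h = self.g[k] * self.hist_coeff[k] * q_prev[k]
            if s.node_a in self.index:
                rhs[self.index[s.node_a]] -= h
            if s.node_b in self.index:
                rhs[self.index[s.node_b]] += h
        p = self.lu.solve(rhs)

        def node_p(n):
            return p[self.index[n]] if n in self.index else p_out_pa[self.outlet_index[n]]

        q = np.array(
            [
                self.g[k]
                * (node_p(s.node_a) - node_p(s.node_b) + self.hist_coeff[k] * q_prev[k])
                for k, s in enumerate(self.net.segments)
            ]
        )
        return p, q


def _outlet_segment_flows(net: NetworkModel, q: np.ndarray) -> dict:
    """Flow into each outlet node (m³/s), signed toward the outlet."""
    out = {}
    for k, s in enumerate(net.segments):
        if s.node_b in net.outlets:
            out[s.node_b] = q[k]
        elif s.node_a in net.outlets:
            out[s.node_a] = -q[k]
    return out


def steady_solve(net: NetworkModel, inlet_flows: dict, outlet_pressures: dict):
    """Purely resistive steady solve (the dt→∞, L→0 limit of ``simulate``).

    ``inlet_flows`` in mL·min⁻¹ per inlet, ``outlet_pressures`` in mmHg per
    outlet. Returns ``(node_pressures_mmHg, outlet_flows_mlmin)``.
    """
    asm = _Assembly(net, dt=None)
    inflow = {v: units.mlmin_to_m3s(q) for v, q in inlet_flows.items()}
    p_out = np.array([units.mmhg_to_pa(outlet_pressures[o]) for o in net.outlets])
    p, q = asm.solve(inflow, p_out, np.zeros(len(net.segments)))
    node_p = {n: units.pa_to_mmhg(p[asm.index[n]]) for n in asm.unknown}
    node_p.update({o: outlet_pressures[o] for o in net.outlets})
    qo = {o: units.m3s_to_mlmin(v) for o, v in _outlet_segment_flows(net, q).items()}
    return node_p, qo


def simulate(
    net: NetworkModel,
    inlet_flows: dict,
    outlet_bc: OutletBC,
    dt: float = 1e-3,
    n_cycles: int = 3,
    f: float = 1.0,
    bc_kind: str = "",
) -> SimulationResult:
    """Transient network run with imposed inlet flows and one outlet BC.

    ``inlet_flows`` maps each inlet to its flow Waveform (mL·min⁻¹), played
    back periodically; ``outlet_bc`` supplies the outlet pressures each step
    (the Windkessel BC additionally advances its state with the computed
    outlet flows). Runs ``n_cycles`` cycles of period 1/f at step ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    missing = [v for v in net.inlets if v not in inlet_flows]
    if missing:
        raise ValueError(f"missing inlet flow waveforms: {', '.join(missing)}")
    outlet_bc.reset()
    asm = _Assembly(net, dt=dt)
    n_steps = int(round(n_cycles / (f * dt)))
    t_grid = np.arange(n_steps) * dt

    # pre-sample inlet flows on the solver grid (SI)
    inflow_si = {
        v: units.mlmin_to_m3s(sample_periodic(inlet_flows[v], t_grid, f=f))
        for v in net.inlets
    }
    q_prev = np.zeros(len(net.segments))
    q_out_prev = {o: 0.0 for o in net.outlets}

    rec_p_in = {v: np.empty(n_steps) for v in net.inlets}
    rec_p_out = {o: np.empty(n_steps) for o in net.outlets}
    rec_q_out = {o: np.empty(n_steps) for o in net.outlets}
    residual = np.empty(n_steps)

    for k in range(n_steps):
        t = t_grid[k]
        # SP's quadratic dynamic term uses the previous step's outlet flow
        p_out_mmhg = np.array(
            [
                outlet_bc.pressure(o, t, Q=units.m3s_to_mlmin(q_out_prev[o]))
                for o in net.outlets
            ]
        )
        inflow_k = {v: inflow_si[v][k] for v in net.inlets}
        p, q = asm.solve(inflow_k, units.mmhg_to_pa(p_out_mmhg), q_prev)
        q_out = _outlet_segment_flows(net, q)

        for i, o in enumerate(net.outlets):
            rec_p_out[o][k] = p_out_mmhg[i]
            rec_q_out[o][k] = units.m3s_to_mlmin(q_out[o])
        for v in net.inlets:
            rec_p_in[v][k] = units.pa_to_mmhg(p[asm.index[v]])
        residual[k] = abs(sum(inflow_k.values()) - sum(q_out.values()))

        for o in net.outlets:
            outlet_bc.advance(o, units.m3s_to_mlmin(q_out[o]), dt)
        q_prev = q
        q_out_prev = q_out

    sr = 1.0 / dt

    def as_wave(vals, vessel, quantity):
        return Waveform(vessel=vessel, quantity=quantity, values=vals, sample_rate=sr)

    return SimulationResult(
        inlet_pressure={v: as_wave(rec_p_in[v], v, "pressure") for v in net.inlets},
        outlet_pressure={o: as_wave(rec_p_out[o], o, "pressure") for o in net.outlets},
        outlet_flow={o: as_wave(rec_q_out[o], o, "flow") for o in net.outlets},
        dt=dt,
        n_cycles=n_cycles,
        f=f,
        conservation_residual=residual,
        bc_kind=bc_kind,
    )


def run_bc_set(
    net: NetworkModel,
    dataset: WaveformSet,
    bc_kind: str,
    params: dict | None = None,
    dt: float = 1e-3,
    n_cycles: int = 3,
    f: float = 1.0,
) -> SimulationResult:
    """Derive the requested outlet BC from a reference dataset and simulate.

    ``bc_kind`` is one of ``zp | sp | dep | wm | pm``; ``params`` supplies
    configuration the dataset cannot provide (``C_MCA`` in m³·Pa⁻¹ for wm,
    optional ``c_loss``/``areas`` for sp, fit ``mode`` for wm).
    """
    from .boundary_conditions import (
        DEPSpec,
        ZPSpec,
        derive_sp_params,
        fit_pm_params,
        fit_wm_spec,
    )
    from .waveform import segment_cycles

    params = dict(params or {})
    ref = dataset.get(net.outlets[0], "pressure")
    ci = segment_cycles(ref, f=f)

    if bc_kind == "zp":
        bc = ZPSpec.from_dataset(dataset, ci)
    elif bc_kind == "sp":
        areas = params.get("areas") or net.outlet_areas()
        bc = derive_sp_params(
            dataset, c_loss=params.get("c_loss"), areas=areas, ci=ci,
            rho=net.fluid.rho,
        )
    elif bc_kind == "dep":
        bc = DEPSpec(
            pressures={o: dataset.get(o, "pressure") for o in net.outlets}, f=f
        )
    elif bc_kind == "wm":
        if "C_MCA" not in params:
            raise KeyError("run_bc_set(bc_kind='wm') requires params['C_MCA']")
        bc = fit_wm_spec(
            dataset, ci, C_MCA=params["C_MCA"], mode=params.get("mode", "mean")
        )
    elif bc_kind == "pm":
        fit = fit_pm_params(
            {o: dataset.get(o, "pressure") for o in net.outlets}, f=f
        )
        bc = fit.spec
    else:
        raise ValueError(f"unknown bc_kind {bc_kind!r}")

    inlet_flows = {v: dataset.get(v, "flow") for v in net.inlets}
    return simulate(
        net, inlet_flows, bc, dt=dt, n_cycles=n_cycles, f=f, bc_kind=bc_kind
    )
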