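"""Outlet pressure boundary conditions for cerebrovascular flow models.

Five families of outlet BCs of increasing complexity, all exposing the same
interface — ``pressure(outlet, t, Q=..)`` in mmHg, plus a no-op ``advance``
hook that only the stateful Windkessel uses:

ZP   zero pressure: one stationary gauge pressure for all outlets, the
     cycle-average of all measured outlet pressures.
SP   symmetrical pressure: stationary per-class mean pressures (left/right
     averaged for ACA, MCA, PCA) plus a quadratic dynamic term
     p = p̄ₙ + ½·cₙ·ρ·(Q/A)².
DEP  direct experimental pressure: transient playback of the measured outlet
     pressure curves (linear interpolation, periodic extension).
WM   two-element Windkessel: parallel resistance R and capacitance C per
     outlet, C·dp/dt = Q − p/R, advanced by explicit Euler in the simulation
     time step; R from fitting Δp = R·Q to the data, C from the constraint
     that τ = R·C is uniform across outlets.
PM   phase modulation: closed-form transient pressure
     p = p̄ₙ·(1 + PI_p/2·cos(2πf·t + φ + β·cos(2πf·t + φ)))
     with per-outlet mean levels p̄ₙ and one shared (PI_p, φ, β) obtained as
     the across-outlet medians of per-outlet nonlinear least-squares fits.

Pressures are gauge; external units are clinical (mmHg, mL·min⁻¹), internal
Windkessel state is SI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import units
from .waveform import (
    OUTLETS,
    CycleIndex,
    Waveform,
    WaveformSet,
    cycle_average,
    sample_periodic,
    segment_cycles,
)

logger = logging.getLogger(__name__)

#: left/right members of each outlet class
VESSEL_CLASSES = {
    "ACA": ("LACA", "RACA"),
    "MCA": ("LMCA", "RMCA"),
    "PCA": ("LPCA", "RPCA"),
}
CLASS_OF = {v: c for c, pair in VESSEL_CLASSES.items() for v in pair}


@dataclass
class FluidProps:
    """Blood-analogue fluid: density in kg·m⁻³, dynamic viscosity in Pa·s."""

    rho: float = 1137.0
    mu: float = 4.01e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")


# ---------------------------------------------------------------------------
# BC specs — common interface: pressure(outlet, t, Q=0.0) -> mmHg


class OutletBC:
    """Interchangeability contract shared by all five BC families."""

    stateful = False

    def pressure(self, outlet: str, t: float, Q: float = 0.0) -> float:
        raise NotImplementedError

    def advance(self, outlet: str, Q: float, dt: float) -> None:
        """Advance internal state with the computed outlet flow (WM only)."""

    def reset(self) -> None:
        """Restore initial state (WM only)."""


@dataclass
class ZPSpec(OutletBC):
    """Single stationary gauge pressure p̄ for every outlet."""

    p_zp: float = 87.0  # mmHg

    def pressure(self, outlet, t, Q=0.0):
        return self.p_zp

    @classmethod
    def from_dataset(cls, ws: WaveformSet, ci: CycleIndex, which="all"):
        """Cycle-average of all experimental outlet pressures."""
        means = [
            cycle_average(w, ci, which) for w in ws.outlet_pressures().values()
        ]
        if not means:
            raise ValueError("dataset has no outlet pressure waveforms")
        return cls(p_zp=float(np.mean(means)))


@dataclass
class SPSpec(OutletBC):
    """Side-averaged stationary means plus a quadratic dynamic term.

    ``p_mean`` maps each outlet to its class-averaged mean pressure (mmHg),
    identical for the left and right members of a class; ``c_loss`` the
    dimensionless hydraulic loss coefficient; ``area`` the outlet
    cross-section in m². Flow Q is taken in mL·min⁻¹.
    """

    p_mean: dict
    c_loss: dict
    area: dict
    rho: float = 1137.0

    def pressure(self, outlet, t, Q=0.0):
        if outlet not in self.p_mean:
            raise KeyError(f"unknown outlet {outlet!r}")
        q_si = units.mlmin_to_m3s(Q)
        dyn_pa = 0.5 * self.c_loss[outlet] * self.rho * (q_si / self.area[outlet]) ** 2
        return self.p_mean[outlet] + units.pa_to_mmhg(dyn_pa)


@dataclass
class DEPSpec(OutletBC):
    """Transient playback of per-outlet experimental pressure waveforms."""

    pressures: dict  # outlet -> Waveform (mmHg)
    f: float = 1.0

    def pressure(self, outlet, t, Q=0.0):
        if outlet not in self.pressures:
            raise KeyError(f"unknown outlet {outlet!r}")
        return float(sample_periodic(self.pressures[outlet], t, f=self.f)[0])


@dataclass
class WMSpec(OutletBC):
    """Two-element Windkessel per outlet: C·dp/dt = Q − p/R.

    ``R`` in Pa·s·m⁻³, ``C`` in m³·Pa⁻¹; the characteristic time τ = R·C is
    uniform for all outlets. ``p_init`` (mmHg) initializes the pressure state
    (cycle-averaged outlet pressure by default, to shorten the start-up
    transient). State is advanced externally via :meth:`advance` with the
    flow the network solver computed, by explicit Euler in the same step.
    """

    R: dict
    C: dict
    p_init: dict
    stateful = True
    _state_pa: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        taus = np.array([self.R[o] * self.C[o] for o in self.R])
        if taus.size and (taus.max() - taus.min()) > 1e-9 * taus.max():
            raise ValueError("characteristic time R*C must be uniform across outlets")
        self.reset()

    @property
    def tau(self) -> float:
        o = next(iter(self.R))
        return self.R[o] * self.C[o]

    def reset(self):
        self._state_pa = {
            o: units.mmhg_to_pa(self.p_init.get(o, 0.0)) for o in self.R
        }

    def pressure(self, outlet, t, Q=0.0):
        if outlet not in self._state_pa:
            raise KeyError(f"unknown outlet {outlet!r}")
        return units.pa_to_mmhg(self._state_pa[outlet])

    def advance(self, outlet, Q, dt):
        self._state_pa[outlet] = wm_step(
            self._state_pa[outlet],
            units.mlmin_to_m3s(Q),
            self.R[outlet],
            self.C[outlet],
            dt,
        )


@dataclass
class PMSpec(OutletBC):
    """Phase-modulated closed-form outlet pressure (Eq. PM).

    Per-outlet mean levels ``p_mean`` (mmHg); one shared pressure pulsatility
    ``pi_p``, phase ``phi`` (rad) and modulation index ``beta`` for all
    outlets.
    """

    p_mean: dict
    pi_p: float
    phi: float
    beta: float
    f: float = 1.0

    def pressure(self, outlet, t, Q=0.0):
        if outlet not in self.p_mean:
            raise KeyError(f"unknown outlet {outlet!r}")
        theta = 2.0 * np.pi * self.f * t + self.phi
        return self.p_mean[outlet] * (
            1.0 + 0.5 * self.pi_p * np.cos(theta + self.beta * np.cos(theta))
        )


# convenience single-call evaluators over the spec objects
def zp_pressure(spec: ZPSpec, t: float) -> float:
    return spec.pressure("", t)


def sp_pressure(spec: SPSpec, Q: float, outlet: str, t: float = 0.0) -> float:
    return spec.pressure(outlet, t, Q)


def dep_pressure(spec: DEPSpec, outlet: str, t: float) -> float:
    return spec.pressure(outlet, t)


def pm_pressure(spec: PMSpec, outlet: str, t: float) -> float:
    return spec.pressure(outlet, t)


def wm_step(p, Q, R, C, dt, stability_warn=0.5):
    """One explicit-Euler step of the two-element Windkessel.

    ``p_{k+1} = p_k + (dt/C)·(Q − p_k/R)`` in any consistent unit system
    (SI inside the solver). Warns when dt/τ exceeds ``stability_warn`` and
    raises when dt/τ ≥ 2, where explicit Euler is unstable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = R * C
    ratio = dt / tau
    if ratio >= 2.0:
        raise ValueError(f"explicit Euler unstable: dt/tau = {ratio:.3g} >= 2")
    if ratio > stability_warn:
        warnings.warn(
            f"dt/tau = {ratio:.3g} exceeds {stability_warn}; "
            "Windkessel update is marginally resolved",
            RuntimeWarning,
            stacklevel=2,
        )
    return p + (dt / C) * (Q - p / R)


# ---------------------------------------------------------------------------
# Parameter estimation


class WindkesselModel:
    """Peripheral-resistance model Δp = R·Q fitted to outlet data.

    Parameters
    ----------
    pressure : Waveform
        Outlet gauge pressure (mmHg). The pressure drop Δp across the
        peripheral element is this pressure relative to a zero venous datum.
    flow : Waveform
        Outlet flow (mL·min⁻¹).

    ``fit(mode="instantaneous")`` regresses the transient Δp(t) on Q(t)
    through the origin (the default, matching a transient curve fit);
    ``mode="mean"`` uses the ratio of cycle means, which is exact in a steady
    periodic state and immune to the phase lag a compliant element introduces.
    """

    def __init__(self, pressure: Waveform, flow: Waveform):
        if pressure.n != flow.n:
            raise ValueError("pressure and flow must have equal length")
        self.pressure = pressure
        self.flow = flow

    def fit(self, mode: str = "instantaneous") -> "WindkesselResults":
        p = units.mmhg_to_pa(self.pressure.values)
        q = units.mlmin_to_m3s(self.flow.values)
        if np.allclose(q, 0):
            raise ValueError("flow is identically zero; resistance unidentifiable")
        if mode == "instantaneous":
            denom = float(q @ q)
            R = float(p @ q) / denom
            resid = p - R * q
            # 1-parameter linear LS standard error
            dof = max(q.size - 1, 1)
            se = float(np.sqrt((resid @ resid) / dof / denom))
        elif mode == "mean":
            qbar = float(q.mean())
            if qbar == 0:
                raise ValueError("zero mean flow; resistance unidentifiable")
            R = float(p.mean()) / qbar
            resid = p - R * q
            se = float("nan")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if R <= 0:
            raise ValueError("fitted resistance is non-positive")
        return WindkesselResults(
            model=self, R=R, bse=se, resid_pa=resid, mode=mode
        )


@dataclass
class WindkesselResults:
    """Fitted peripheral resistance with its uncertainty and residuals."""

    model: WindkesselModel
    R: float  # Pa·s·m⁻³
    bse: float
    resid_pa: np.ndarray
    mode: str

    def summary(self) -> str:
        lines = [
            "Windkessel resistance fit (dp = R*Q, zero venous datum)",
            f"  vessel: {self.model.flow.vessel}   mode: {self.mode}",
            f"  R    = {self.R:.4e} Pa s m^-3  (se {self.bse:.2e})",
            f"  RMS residual = {np.sqrt(np.mean(self.resid_pa ** 2)):.3e} Pa",
            f"  n    = {self.model.flow.n}",
        ]
        return "\n".join(lines)


def fit_resistance(pressure: Waveform, flow: Waveform, mode="instantaneous") -> float:
    """Least-squares resistance of Δp = R·Q in Pa·s·m⁻³."""
    return WindkesselModel(pressure, flow).fit(mode=mode).R


def derive_capacitances(R_by_class: dict, C_MCA: float) -> dict:
    """Per-class capacitances from the uniform-relaxation-time constraint.

    τ = R_MCA·C_MCA; every class n receives Cₙ = τ/Rₙ so that Rₙ·Cₙ = τ.
    Returns ``{"tau": τ, "C": {class: Cₙ}}``.
    """
    if "MCA" not in R_by_class:
        raise KeyError("R_by_class must contain the MCA class")
    if C_MCA <= 0 or any(R <= 0 for R in R_by_class.values()):
        raise ValueError("resistances and C_MCA must be positive")
    tau = R_by_class["MCA"] * C_MCA
    return {"tau": tau, "C": {cls: tau / R for cls, R in R_by_class.items()}}


def fit_wm_spec(
    ws: WaveformSet,
    ci: CycleIndex,
    C_MCA: float,
    mode: str = "mean",
    which="all",
) -> WMSpec:
    """Derive a complete Windkessel spec from a reference dataset.

    Per-outlet resistances are fitted from Δp = R·Q, averaged over the left
    and right members of each class, and capacitances follow from the uniform
    τ constraint anchored at the MCA capacitance ``C_MCA`` (m³·Pa⁻¹).
    """
    R_fit = {}
    for o in OUTLETS:
        R_fit[o] = fit_resistance(ws.get(o, "pressure"), ws.get(o, "flow"), mode=mode)
    R_cls = {
        cls: 0.5 * (R_fit[pair[0]] + R_fit[pair[1]])
        for cls, pair in VESSEL_CLASSES.items()
    }
    caps = derive_capacitances(R_cls, C_MCA)
    R = {o: R_cls[CLASS_OF[o]] for o in OUTLETS}
    C = {o: caps["C"][CLASS_OF[o]] for o in OUTLETS}
    p_init = {
        o: cycle_average(ws.get(o, "pressure"), ci, which) for o in OUTLETS
    }
    return WMSpec(R=R, C=C, p_init=p_init)


def derive_sp_params(
    ws: WaveformSet,
    c_loss: dict | None = None,
    areas: dict | None = None,
    ci: CycleIndex | None = None,
    which="all",
    rho: float = 1137.0,
) -> SPSpec:
    """Side-averaged stationary outlet pressures plus configured cₙ and A.

    Cycle-averaged pressures of the left and right members of each outlet
    class are averaged and assigned to both sides. ``c_loss`` defaults to a
    placeholder of 1.0 per outlet (the reference values live in configuration)
    and ``areas`` to 5×10⁻⁶ m²; both placeholders are logged.
    """
    missing = [o for o in OUTLETS if (o, "pressure") not in ws]
    if missing:
        raise KeyError(f"missing outlet pressures: {', '.join(missing)}")
    if ci is None:
        ci = segment_cycles(ws.get(OUTLETS[0], "pressure"))
    means = {o: cycle_average(ws.get(o, "pressure"), ci, which) for o in OUTLETS}
    p_mean = {}
    for cls, (left, right) in VESSEL_CLASSES.items():
        m = 0.5 * (means[left] + means[right])
        p_mean[left] = p_mean[right] = m
    if c_loss is None:
        logger.warning("SP loss coefficients c_n not supplied; using placeholder 1.0")
        c_loss = {o: 1.0 for o in OUTLETS}
    if areas is None:
        logger.warning("SP outlet areas not supplied; using placeholder 5e-6 m^2")
        areas = {o: 5e-6 for o in OUTLETS}
    return SPSpec(p_mean=p_mean, c_loss=dict(c_loss), area=dict(areas), rho=rho)


# ---------------------------------------------------------------------------
# Phase-modulation fitting


def _pm_model(t, p_mean, pi_p, phi, beta, f):
    theta = 2.0 * np.pi * f * t + phi
    return p_mean * (1.0 + 0.5 * pi_p * np.cos(theta + beta * np.cos(theta)))


def _circular_median(angles):
    """Median of angles, computed in a frame rotated to the circular mean."""
    angles = np.asarray(angles, dtype=float)
    mean = np.angle(np.mean(np.exp(1j * angles)))
    centered = np.angle(np.exp(1j * (angles - mean)))
    return float((mean + np.median(centered)) % (2.0 * np.pi))


class PhaseModulationModel:
    """Pooled phase-modulation pressure model over the six outlets.

    Fits p(t) = p̄ₙ·(1 + PI_p/2·cos(2πf·t + φ + β·cos(2πf·t + φ))) to each
    outlet's pressure waveform by bounded nonlinear least squares with a
    four-point multi-start over φ (the objective is non-convex in phase),
    then pools (PI_p, φ, β) as across-outlet medians while keeping the mean
    level p̄ₙ per outlet.
    """

    N_PHASE_STARTS = 4
    BETA_MAX = 2.0

    def __init__(self, pressures: dict, f: float = 1.0):
        if not pressures:
            raise ValueError("at least one outlet pressure waveform is required")
        for o, w in pressures.items():
            if w.duration < 1.0 / f - 1e-9:
                raise ValueError(f"waveform for {o!r} spans less than one cycle")
        self.pressures = dict(pressures)
        self.f = f

    def _fit_one(self, w: Waveform):
        t, y = w.t, w.values
        p0, a0 = y.mean(), (y.max() - y.min()) / max(abs(y.mean()), 1e-12)
        best = None
        for phi0 in np.arange(self.N_PHASE_STARTS) * 2 * np.pi / self.N_PHASE_STARTS:
            res = least_squares(
                lambda x: _pm_model(t, *x, self.f) - y,
                x0=[p0, max(a0, 1e-3), phi0, 0.5],
                bounds=([1e-9, 0.0, -2 * np.pi, 0.0],
                        [np.inf, 5.0, 4 * np.pi, self.BETA_MAX]),
                method="trf",
            )
            if best is None or res.cost < best.cost:
                best = res
        return best

    def fit(self) -> "PhaseModulationResults":
        per_outlet, failed = {}, []
        for o, w in self.pressures.items():
            res = self._fit_one(w)
            if res is None or not res.success:
                failed.append(o)
                logger.warning("PM fit did not converge for outlet %s; excluded", o)
                continue
            p_mean, pi_p, phi, beta = res.x
            # parameter covariance from the LS Jacobian
            dof = max(w.n - 4, 1)
            s2 = 2 * res.cost / dof
            try:
                cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
                bse = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                bse = np.full(4, np.nan)
            per_outlet[o] = {
                "p_mean": float(p_mean),
                "pi_p": float(pi_p),
                "phi": float(phi % (2 * np.pi)),
                "beta": float(beta),
                "bse": bse,
                "resid": _pm_model(w.t, *res.x, self.f) - w.values,
            }
        if not per_outlet:
            raise RuntimeError("phase-modulation fit failed for every outlet")
        pooled = PMSpec(
            p_mean={o: d["p_mean"] for o, d in per_outlet.items()},
            pi_p=float(np.median([d["pi_p"] for d in per_outlet.values()])),
            phi=_circular_median([d["phi"] for d in per_outlet.values()]),
            beta=float(np.median([d["beta"] for d in per_outlet.values()])),
            f=self.f,
        )
        return PhaseModulationResults(
            model=self, per_outlet=per_outlet, spec=pooled, failed=failed
        )


@dataclass
class PhaseModulationResults:
    """Per-outlet PM fits and the pooled (median) parameter set."""

    model: PhaseModulationModel
    per_outlet: dict
    spec: PMSpec
    failed: list

    @property
    def params(self) -> dict:
        return {
            "pi_p": self.spec.pi_p,
            "phi": self.spec.phi,
            "beta": self.spec.beta,
            "p_mean": dict(self.spec.p_mean),
        }

    def summary(self) -> str:
        lines = [
            "Phase-modulation pressure fit",
            f"  pooled: PI_p = {self.spec.pi_p:.4f}   phi = {self.spec.phi:.4f} rad"
            f"   beta = {self.spec.beta:.4f}   f = {self.spec.f} Hz",
            "  outlet    p_mean[mmHg]   PI_p     phi[rad]   beta     rms resid",
        ]
        for o, d in sorted(self.per_outlet.items()):
            rms = np.sqrt(np.mean(d["resid"] ** 2))
            lines.append(
                f"  {o:<8}  {d['p_mean']:>10.3f}  {d['pi_p']:.4f}  "
                f"{d['phi']:.4f}    {d['beta']:.4f}   {rms:.3e}"
            )
        if self.failed:
            lines.append(f"  excluded (non-converged): {', '.join(self.failed)}")
        return "\n".join(lines)


def fit_pm_params(pressures: dict, f: float = 1.0) -> PhaseModulationResults:
    """Fit the PM pressure family to per-outlet waveforms; median-pooled spec."""
    return PhaseModulationModel(pressures, f=f).fit()
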