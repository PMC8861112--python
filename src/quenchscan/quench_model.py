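"""Forward kinetic model of halide-sensitive YFP quenching in whole cells.

The assay: cells co-expressing mCherry and a YFP(H148Q/I152L)-CFTR fusion are
imaged every 2 s. After a baseline, forskolin (or DMSO) is added to activate
CFTR; 230 s later, when gating has reached steady state, extracellular iodide
is raised to 100 mM. Iodide entering through open anion channels binds YFP and
quenches its fluorescence, so the quench time course reports the whole-cell
anion conductance ``G`` (nS) and the steady-state membrane potential ``V_m``
(mV) that set the electrochemical driving force.

The model integrates intracellular Cl⁻ and I⁻ and (optionally) the membrane
potential from the moment of iodide addition. Before that moment the cell is
treated as being at an exact steady state (symmetrical 140 mM Cl⁻, no iodide,
V_m at its fitted value), so the predicted anion-free YFP fraction is flat at
its baseline value. The anion conductance available for halide flux is

    g(t) = G + G_trans * exp(-(t - t_add) / tau_trans)    for t >= t_add,

where ``t_add`` is the time of the iodide addition: the transient term models
an endogenous anion conductance elicited by the fluid addition itself, which
is why it is measurable in DMSO controls where CFTR stays closed.

Fluxes use the Goldman–Hodgkin–Katz constant-field form by default, with the
permeability scale calibrated so that the slope conductance under the
pre-addition symmetrical-chloride condition equals g(t) exactly; iodide
permeability is ``p_ratio`` times that of chloride. An ohmic/Nernst flux law
is available behind ``flux_law="ohmic"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ProtocolSpec",
    "Addition",
    "QuenchModelParams",
    "IonState",
    "PredictedTrace",
    "InvalidProtocolError",
    "standard_protocol",
    "protocol_concentrations",
    "anion_binding_fraction",
    "steady_state",
    "simulate_trace",
]

#: Faraday constant scaled for pA, pl, mM, s units:
#: d[X]/dt (mM/s) = I (pA) / (F_SCALE * V_cell (pl)).
F_SCALE = 96.485

#: Gas constant (J/mol/K) and Faraday (C/mol) for the thermal voltage.
_R = 8.314462618
_F = 96485.33212


class InvalidProtocolError(ValueError):
    """Raised when an addition schedule is physically inconsistent."""


@dataclass(frozen=True)
class Addition:
    """One fluid addition: at ``time`` s, ``volume`` µl of solution carrying
    the given solute concentrations (mM for anions, µM for forskolin)."""

    time: float
    volume: float
    concentrations: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ProtocolSpec:
    """Imaging and fluid-addition protocol for one well.

    Times in seconds, volumes in µl. ``additions`` must be strictly
    increasing in time and lie within ``[0, total_duration]``.
    """

    well_volume_start: float = 100.0
    additions: tuple[Addition, ...] = ()
    frame_interval: float = 2.0
    baseline_duration: float = 20.0
    total_duration: float = 290.0
    start_concentrations: dict[str, float] = field(
        default_factory=lambda: {"Cl": 140.0, "I": 0.0, "fsk": 0.0}
    )

    def __post_init__(self) -> None:
        if self.well_volume_start <= 0:
            raise InvalidProtocolError("starting well volume must be positive")
        if self.frame_interval <= 0:
            raise InvalidProtocolError("frame interval must be positive")
        last = -math.inf
        for add in self.additions:
            if add.volume <= 0:
                raise InvalidProtocolError("addition volume must be positive")
            if not (0.0 <= add.time <= self.total_duration):
                raise InvalidProtocolError("addition time outside protocol window")
            if add.time <= last:
                raise InvalidProtocolError("addition times must be strictly increasing")
            last = add.time
            if any(c < 0 for c in add.concentrations.values()):
                raise InvalidProtocolError("negative solute concentration")
        if any(c < 0 for c in self.start_concentrations.values()):
            raise InvalidProtocolError("negative starting concentration")

    @property
    def frame_times(self) -> np.ndarray:
        n = int(round(self.total_duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def addition_times(self) -> list[float]:
        return [a.time for a in self.additions]


def standard_protocol(forskolin: bool = True) -> ProtocolSpec:
    """The standard two-addition protocol: 20 s baseline in 100 µl buffer,
    +50 µl activator buffer (forskolin to 10 µM final, or DMSO), then 230 s
    later +50 µl iodide buffer (400 mM NaI, chloride-free) bringing
    extracellular iodide to 100 mM; imaging continues 40 s more."""
    return ProtocolSpec(
        well_volume_start=100.0,
        additions=(
            Addition(20.0, 50.0, {"Cl": 140.0, "I": 0.0, "fsk": 30.0 if forskolin else 0.0}),
            Addition(250.0, 50.0, {"Cl": 0.0, "I": 400.0, "fsk": 10.0 if forskolin else 0.0}),
        ),
        frame_interval=2.0,
        baseline_duration=20.0,
        total_duration=290.0,
    )


@dataclass(frozen=True)
class QuenchModelParams:
    """Free parameters of the quench model plus fixed physical constants.

    ``Vm`` (mV) and ``G`` (nS) describe the steady state reached before the
    iodide addition; ``G_trans`` (nS) and ``tau_trans`` (s) describe the
    transient endogenous anion conductance elicited by the addition.

    The ``constants`` are calibration inputs, not fitted: halide dissociation
    constants of the YFP sensor (``K_I``, ``K_Cl``, mM), intracellular volume
    (``V_cell``, pl), membrane capacitance (``C_m``, pF), iodide/chloride
    permeability ratio (``p_ratio``), initial intracellular chloride
    (``Cl_in0``, mM), temperature (K) and the background leak conductance
    (``g_bg``, nS) that pins the pre-addition steady state.
    """

    Vm: float = -40.0
    G: float = 10.0
    G_trans: float = 9.0
    tau_trans: float = 11.4
    constants: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS)
    )

    def __post_init__(self) -> None:
        if self.G < 0 or self.G_trans < 0:
            raise ValueError("conductances must be non-negative")
        if self.tau_trans <= 0:
            raise ValueError("tau_trans must be positive")
        c = self.constants
        if c["K_I"] <= 0 or c["K_Cl"] <= 0:
            raise ValueError("dissociation constants must be positive")
        if c["V_cell"] <= 0 or c["C_m"] <= 0:
            raise ValueError("cell volume and capacitance must be positive")
        if c["p_ratio"] < 0 or c["Cl_in0"] < 0:
            raise ValueError("p_ratio and Cl_in0 must be non-negative")

    def with_(self, **kw) -> "QuenchModelParams":
        return replace(self, **kw)

    @property
    def thermal_voltage(self) -> float:
        """RT/F in mV."""
        return 1000.0 * _R * self.constants["temperature"] / _F


DEFAULT_CONSTANTS: dict[str, float] = {
    "K_I": 1.9,        # mM, iodide affinity of YFP(H148Q/I152L)
    "K_Cl": 85.0,      # mM, chloride affinity of YFP(H148Q/I152L)
    "V_cell": 2.0,     # pl, HEK293 intracellular volume
    "C_m": 20.0,       # pF, HEK293 membrane capacitance
    "p_ratio": 0.4,    # P_I / P_Cl through the anion conductance
    "Cl_in0": 140.0,   # mM, symmetrical chloride at steady state
    "Cl_out": 140.0,   # mM, starting bath chloride
    "temperature": 301.15,  # K (28 degC)
    "g_bg": 2.0,       # nS, background leak reversing at the fitted Vm
}


@dataclass(frozen=True)
class IonState:
    """Intracellular anion concentrations (mM) and membrane potential (mV)."""

    Cl_in: float
    I_in: float
    Vm_t: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.Cl_in < 0 or self.I_in < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class PredictedTrace:
    times: np.ndarray
    unbound_fraction: np.ndarray
    Cl_in: np.ndarray
    I_in: np.ndarray
    Vm: np.ndarray

    @property
    def baseline_fraction(self) -> float:
        return float(self.unbound_fraction[0])

    def normalized(self) -> np.ndarray:
        """Unbound fraction scaled so the baseline equals 1 (what a
        baseline-normalized fluorescence trace measures)."""
        return self.unbound_fraction / self.baseline_fraction


# ---------------------------------------------------------------------------
# protocol arithmetic


def protocol_concentrations(protocol: ProtocolSpec) -> list[dict]:
    """Piecewise-constant extracellular concentration schedule.

    Each addition instantaneously mixes: for every species, the new
    concentration is (moles present + moles added) / (new total volume).
    Returns one segment per interval, covering [0, total_duration], each a
    dict with ``t_start``, ``t_end``, ``volume`` (µl) and ``concentrations``
    (mM / µM by species).
    """
    species = set(protocol.start_concentrations)
    for add in protocol.additions:
        species |= set(add.concentrations)

    vol = protocol.well_volume_start
    conc = {s: protocol.start_concentrations.get(s, 0.0) for s in species}
    segments: list[dict] = []
    t0 = 0.0
    for add in protocol.additions:
        segments.append(
            {"t_start": t0, "t_end": add.time, "volume": vol, "concentrations": dict(conc)}
        )
        new_vol = vol + add.volume
        conc = {
            s: (conc[s] * vol + add.concentrations.get(s, 0.0) * add.volume) / new_vol
            for s in species
        }
        vol = new_vol
        t0 = add.time
    segments.append(
        {"t_start": t0, "t_end": protocol.total_duration, "volume": vol,
         "concentrations": dict(conc)}
    )
    return segments


def anion_binding_fraction(I_in: float, Cl_in: float, K_I: float, K_Cl: float):
    """Anion-free fraction of the YFP sensor at binding equilibrium.

    Competitive single-site binding of I⁻ and Cl⁻:
    ``f_unbound = 1 / (1 + I/K_I + Cl/K_Cl)``. Accepts scalars or arrays.
    """
    I_in = np.asarray(I_in, dtype=float)
    Cl_in = np.asarray(Cl_in, dtype=float)
    if np.any(I_in < 0) or np.any(Cl_in < 0):
        raise ValueError("anion concentrations must be non-negative")
    if K_I <= 0 or K_Cl <= 0:
        raise ValueError("dissociation constants must be positive")
    out = 1.0 / (1.0 + I_in / K_I + Cl_in / K_Cl)
    return float(out) if out.ndim == 0 else out


def steady_state(params: QuenchModelParams, pre_addition_bath: dict[str, float] | None = None) -> IonState:
    """State of the cell immediately before the iodide addition.

    The membrane potential is the fitted ``Vm`` (a description of this steady
    state, not derived from ``G``); intracellular chloride is ``Cl_in0`` and
    there is no intracellular iodide. The pre-addition bath must be
    iodide-free.
    """
    if pre_addition_bath is not None and pre_addition_bath.get("I", 0.0) > 0:
        raise ValueError("pre-addition bath must not contain iodide")
    return IonState(Cl_in=params.constants["Cl_in0"], I_in=0.0, Vm_t=params.Vm, t=0.0)


# ---------------------------------------------------------------------------
# flux laws


def _ghk_drive(Vm: float, c_in: float, c_out: float, vt: float, c_ref: float) -> float:
    """GHK driving term for a monovalent anion, scaled so that the symmetric
    reference condition (c_in = c_out = c_ref) gives exactly ``Vm``; the
    current is then ``g * drive`` in pA for g in nS.
    """
    u = Vm / vt
    if abs(u) < 1e-6:
        # series limit of Vm*(c_in - c_out*e^u)/(1 - e^u)
        return (vt * (c_out - c_in) + 0.5 * Vm * (c_in + c_out)) / c_ref
    eu = math.exp(u)
    return Vm * (c_in - c_out * eu) / ((1.0 - eu) * c_ref)


def _ohmic_drive(Vm: float, c_in: float, c_out: float, vt: float, c_ref: float) -> float:
    """Ohmic driving term g*(Vm - E) with the anion Nernst potential
    E = -vt*ln(c_out/c_in); concentrations floored to keep E finite."""
    ci = max(c_in, 1e-6)
    co = max(c_out, 1e-6)
    e_rev = -vt * math.log(co / ci)
    return Vm - e_rev


def simulate_trace(
    params: QuenchModelParams,
    protocol: ProtocolSpec,
    *,
    vm_mode: str = "fixed",
    flux_law: str = "ghk",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PredictedTrace:
    """Predicted anion-free YFP fraction over the full imaging protocol.

    Up to the last (iodide) addition the cell sits at the fitted steady state,
    so the trace is flat at the baseline binding equilibrium. From the iodide
    addition onward the intracellular Cl⁻/I⁻ (and, in ``vm_mode="dynamic"``,
    the membrane potential) are integrated with a stiff-safe adaptive solver,
    the bath held at the piecewise-constant mixed concentrations (infinite
    reservoir). ``vm_mode="fixed"`` holds V_m at the fitted value throughout.
    """
    if vm_mode not in ("dynamic", "fixed"):
        raise ValueError("vm_mode must be 'dynamic' or 'fixed'")
    if flux_law not in ("ghk", "ohmic"):
        raise ValueError("flux_law must be 'ghk' or 'ohmic'")
    c = params.constants
    vt = params.thermal_voltage
    c_ref = c["Cl_in0"] if c["Cl_in0"] > 0 else 140.0
    drive = _ghk_drive if flux_law == "ghk" else _ohmic_drive

    segments = protocol_concentrations(protocol)
    times = protocol.frame_times
    n = times.size
    cl = np.full(n, c["Cl_in0"])
    iod = np.zeros(n)
    vm = np.full(n, params.Vm)

    if protocol.additions:
        t_add = protocol.additions[-1].time
    else:
        t_add = math.inf

    post = times >= t_add - 1e-12
    if not np.any(post):
        f = anion_binding_fraction(iod, cl, c["K_I"], c["K_Cl"])
        return PredictedTrace(times, f, cl, iod, vm)

    final = segments[-1]["concentrations"]
    cl_out = final.get("Cl", 0.0)
    i_out = final.get("I", 0.0)
    G, G_trans, tau = params.G, params.G_trans, params.tau_trans
    p_ratio, v_cell, c_m, g_bg = c["p_ratio"], c["V_cell"], c["C_m"], c["g_bg"]
    vm0 = params.Vm
    dynamic = vm_mode == "dynamic"

    def rhs(y, t: float):
        cl_in, i_in, vm_t = y
        cl_in = max(cl_in, 0.0)
        i_in = max(i_in, 0.0)
        g = G + G_trans * math.exp(-(t - t_add) / tau)
        i_cl = g * drive(vm_t, cl_in, cl_out, vt, c_ref)
        i_i = p_ratio * g * drive(vm_t, i_in, i_out, vt, c_ref)
        # outward-positive anion current corresponds to anion influx
        dcl = i_cl / (F_SCALE * v_cell)
        di = i_i / (F_SCALE * v_cell)
        if dynamic:
            i_leak = g_bg * (vm_t - vm0)
            dvm = -1000.0 * (i_cl + i_i + i_leak) / c_m
        else:
            dvm = 0.0
        return (dcl, di, dvm)

    t_eval = times[post]
    # integration starts exactly at the addition (LSODA via odeint)
    t_grid = t_eval if abs(t_eval[0] - t_add) < 1e-12 else np.concatenate([[t_add], t_eval])
    y0 = (c["Cl_in0"], 0.0, vm0)
    y, info = odeint(
        rhs, y0, t_grid, rtol=rtol, atol=(atol, atol, 1e-7),
        hmax=protocol.frame_interval, full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"quench-model integration failed: {info['message']}")
    if t_grid.size != t_eval.size:
        y = y[1:]
    cl[post] = np.maximum(y[:, 0], 0.0)
    iod[post] = np.maximum(y[:, 1], 0.0)
    vm[post] = y[:, 2]

    f = anion_binding_fraction(iod, cl, c["K_I"], c["K_Cl"])
    if np.any(f < -1e-12) or np.any(f > 1.0 + 1e-12):
        raise RuntimeError("unbound fraction left [0, 1]: model inconsistency")
    return PredictedTrace(times, np.clip(f, 0.0, 1.0), cl, iod, vm)
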