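"""Estimate V_m and G from observed quench traces by nonlinear least squares.

The observed per-well YFP fluorescence time course (background-corrected,
baseline-normalized so the pre-addition mean is 1) is fitted to the forward
model's predicted anion-free fraction, itself normalized to its baseline.
Two modes mirror the screen's procedure: ``four_free`` fits
(V_m, G, G_trans, tau_trans); ``constrained`` fixes the transient parameters
to values estimated from negative (DMSO) controls — 9 nS and 11.4 s by
default — and fits only (V_m, G).

Only the informative window (20 s before the iodide addition through the end
of the recording) enters the objective by default; the flat pre-activation
baseline carries no information about the anion fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .quench_model import (
    ProtocolSpec,
    QuenchModelParams,
    anion_binding_fraction,
    simulate_trace,
)

__all__ = [
    "QuenchTrace",
    "FitResult",
    "DegenerateTraceError",
    "normalize_trace",
    "fit_trace",
    "estimate_transient_params",
    "normalize_G",
]

#: Default transient-conductance constraints, the DMSO-control averages.
DEFAULT_G_TRANS = 9.0     # nS
DEFAULT_TAU_TRANS = 11.4  # s

VM_BOUNDS = (-100.0, 10.0)
G_BOUNDS = (0.0, 500.0)
GTRANS_BOUNDS = (0.0, 100.0)
TAU_BOUNDS = (0.5, 100.0)

#: Multi-start grid (Vm mV, G nS), best residual wins.
STARTS = ((-60.0, 1.0), (-30.0, 20.0), (-10.0, 100.0))


class DegenerateTraceError(ValueError):
    """Raised when a trace cannot be baseline-normalized."""


@dataclass
class QuenchTrace:
    """One well's fluorescence time course with its addition timepoints."""

    times: np.ndarray
    fluorescence: np.ndarray
    addition_times: Sequence[float] = ()
    plate: str = ""
    well: str = ""
    genotype: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")

    @property
    def n_baseline(self) -> int:
        if not self.addition_times:
            return self.times.size
        return int(np.sum(self.times < min(self.addition_times)))


@dataclass
class FitResult:
    Vm_hat: float
    G_hat: float
    G_trans_hat: float
    tau_trans_hat: float
    residual_ss: float
    converged: bool
    G_normalized: float | None = None
    n_obs: int = 0
    mode: str = "constrained"

    def as_dict(self) -> dict:
        return {
            "Vm_hat": self.Vm_hat, "G_hat": self.G_hat,
            "G_trans_hat": self.G_trans_hat, "tau_trans_hat": self.tau_trans_hat,
            "residual_ss": self.residual_ss, "converged": self.converged,
            "G_normalized": self.G_normalized, "n_obs": self.n_obs, "mode": self.mode,
        }


def normalize_trace(trace: QuenchTrace, min_baseline_frames: int = 5) -> QuenchTrace:
    """Divide the fluorescence by its mean over the pre-first-addition window.

    The output baseline mean is exactly 1, making the observed trace
    commensurate with the model's (baseline-normalized) anion-free fraction.
    Multiplicatively scaled inputs normalize to identical outputs.
    """
    n_base = trace.n_baseline
    if n_base < min_baseline_frames:
        raise DegenerateTraceError(
            f"need >= {min_baseline_frames} baseline frames, got {n_base}"
        )
    base = float(np.mean(trace.fluorescence[:n_base]))
    if base <= 0:
        raise DegenerateTraceError("baseline mean is zero or negative")
    return QuenchTrace(
        times=trace.times,
        fluorescence=trace.fluorescence / base,
        addition_times=tuple(trace.addition_times),
        plate=trace.plate, well=trace.well,
        genotype=trace.genotype, condition=trace.condition,
    )


def _fit_window_mask(times: np.ndarray, protocol: ProtocolSpec, pre_window: float) -> np.ndarray:
    if not protocol.additions:
        return np.ones_like(times, dtype=bool)
    t_iodide = protocol.additions[-1].time
    return times >= (t_iodide - pre_window)


def _predict_normalized(theta: np.ndarray, base_params: QuenchModelParams,
                        protocol: ProtocolSpec, free: tuple[str, ...],
                        vm_mode: str, flux_law: str) -> np.ndarray:
    kw = dict(zip(free, theta))
    params = base_params.with_(**{k: float(v) for k, v in kw.items()})
    pred = simulate_trace(params, protocol, vm_mode=vm_mode, flux_law=flux_law)
    return pred.normalized()


def fit_trace(
    trace: QuenchTrace,
    protocol: ProtocolSpec,
    mode: str = "constrained",
    constraints: dict | None = None,
    *,
    base_params: QuenchModelParams | None = None,
    vm_mode: str = "fixed",
    flux_law: str = "ghk",
    pre_window: float = 20.0,
    full_window: bool = False,
) -> FitResult:
    """Least-squares fit of the quench model to one normalized trace.

    ``mode="constrained"`` fits (V_m, G) with G_trans and tau_trans fixed
    (defaults 9 nS, 11.4 s, overridable via ``constraints``);
    ``mode="four_free"`` also fits the transient parameters. Three starts
    spanning the plausible (V_m, G) range are run and the best residual kept.
    Non-convergence is reported through the ``converged`` flag, not raised.
    """
    if mode not in ("constrained", "four_free"):
        raise ValueError("mode must be 'constrained' or 'four_free'")
    constraints = constraints or {}
    base = base_params if base_params is not None else QuenchModelParams()
    base = base.with_(
        G_trans=float(constraints.get("G_trans", DEFAULT_G_TRANS)),
        tau_trans=float(constraints.get("tau_trans", DEFAULT_TAU_TRANS)),
    )

    trace = normalize_trace(trace)
    frame_times = protocol.frame_times
    if trace.times.size < frame_times.size:
        raise ValueError("trace shorter than the protocol it claims to follow")
    if not np.allclose(trace.times[: frame_times.size], frame_times):
        raise ValueError("trace timepoints inconsistent with protocol frames")
    obs = trace.fluorescence[: frame_times.size]
    mask = (np.ones_like(frame_times, dtype=bool) if full_window
            else _fit_window_mask(frame_times, protocol, pre_window))

    if mode == "constrained":
        free: tuple[str, ...] = ("Vm", "G")
        lo = np.array([VM_BOUNDS[0], G_BOUNDS[0]])
        hi = np.array([VM_BOUNDS[1], G_BOUNDS[1]])
        starts = [np.array(s) for s in STARTS]
    else:
        free = ("Vm", "G", "G_trans", "tau_trans")
        lo = np.array([VM_BOUNDS[0], G_BOUNDS[0], GTRANS_BOUNDS[0], TAU_BOUNDS[0]])
        hi = np.array([VM_BOUNDS[1], G_BOUNDS[1], GTRANS_BOUNDS[1], TAU_BOUNDS[1]])
        starts = [np.array([vm, g, 9.0, 11.4]) for vm, g in STARTS]

    def residuals(theta: np.ndarray) -> np.ndarray:
        pred = _predict_normalized(theta, base, protocol, free, vm_mode, flux_law)
        return pred[mask] - obs[mask]

    best = None
    any_ok = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                x_scale=np.where(np.abs(x0) > 1, np.abs(x0), 1.0),
            )
        except Exception:
            continue
        any_ok = any_ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(np.nan, np.nan, base.G_trans, base.tau_trans,
                         np.inf, False, n_obs=int(mask.sum()), mode=mode)

    theta = best.x
    est = dict(zip(free, theta))
    return FitResult(
        Vm_hat=float(est["Vm"]),
        G_hat=float(est["G"]),
        G_trans_hat=float(est.get("G_trans", base.G_trans)),
        tau_trans_hat=float(est.get("tau_trans", base.tau_trans)),
        residual_ss=float(2.0 * best.cost),
        converged=bool(any_ok),
        n_obs=int(mask.sum()),
        mode=mode,
    )


def estimate_transient_params(
    dmso_traces: Sequence[QuenchTrace],
    protocol: ProtocolSpec,
    *,
    base_params: QuenchModelParams | None = None,
    vm_mode: str = "fixed",
    flux_law: str = "ghk",
    pre_window: float = 20.0,
    control_vm: float | None = -40.0,
) -> tuple[float, float]:
    """Control-average transient conductance from the DMSO wells.

    The negative controls quench only through the addition-elicited transient
    conductance, so their traces identify its amplitude and decay constant.
    The estimate is a JOINT fit: one shared (G_trans, tau_trans) pair across
    all controls with per-trace basal conductances as nuisance parameters.

    The membrane potential multiplies every conductance through the driving
    force, so from quench traces alone the transient AMPLITUDE is only
    determined up to the assumed control V_m (a Fisher-information analysis
    puts the free-V_m uncertainty of G_trans above 10× its value even when
    pooling 20 controls). ``control_vm`` therefore fixes the control resting
    potential (default −40 mV, a typical HEK293 value and this package's
    standing default); pass ``None`` to fit per-trace V_m freely and accept
    that only tau_trans remains meaningfully constrained. Requires at least
    3 controls.
    """
    n = len(dmso_traces)
    if n < 3:
        raise ValueError("need at least 3 DMSO control traces")
    base = base_params if base_params is not None else QuenchModelParams()
    frame_times = protocol.frame_times
    mask = _fit_window_mask(frame_times, protocol, pre_window)
    obs = []
    for tr in dmso_traces:
        norm = normalize_trace(tr)
        if norm.times.size < frame_times.size:
            raise ValueError("trace shorter than the protocol it claims to follow")
        obs.append(norm.fluorescence[: frame_times.size][mask])
    obs = np.concatenate(obs)

    fixed_vm = control_vm is not None

    def residuals(theta: np.ndarray) -> np.ndarray:
        g_trans, tau = theta[0], theta[1]
        out = []
        for i in range(n):
            if fixed_vm:
                vm, g = control_vm, theta[2 + i]
            else:
                vm, g = theta[2 + 2 * i], theta[3 + 2 * i]
            params = base.with_(Vm=float(vm), G=float(g),
                                G_trans=float(g_trans), tau_trans=float(tau))
            pred = simulate_trace(params, protocol, vm_mode=vm_mode,
                                  flux_law=flux_law)
            out.append(pred.normalized()[mask])
        return np.concatenate(out) - obs

    if fixed_vm:
        lo = np.concatenate([[GTRANS_BOUNDS[0], TAU_BOUNDS[0]],
                             np.full(n, G_BOUNDS[0])])
        hi = np.concatenate([[GTRANS_BOUNDS[1], TAU_BOUNDS[1]],
                             np.full(n, G_BOUNDS[1])])
    else:
        lo = np.concatenate([[GTRANS_BOUNDS[0], TAU_BOUNDS[0]],
                             np.tile([VM_BOUNDS[0], G_BOUNDS[0]], n)])
        hi = np.concatenate([[GTRANS_BOUNDS[1], TAU_BOUNDS[1]],
                             np.tile([VM_BOUNDS[1], G_BOUNDS[1]], n)])
    # starts span the plausible transient range; per-trace nuisances start at
    # a typical control well (basal conductance, resting potential)
    best = None
    for gt0, tau0 in ((1.0, 5.0), (10.0, 15.0), (40.0, 50.0)):
        nuis = np.full(n, 2.0) if fixed_vm else np.tile([-30.0, 2.0], n)
        x0 = np.concatenate([[gt0, tau0], nuis])
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                x_scale=np.where(np.abs(x0) > 1, np.abs(x0), 1.0),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("transient estimation failed to converge")
    return float(best.x[0]), float(best.x[1])


def normalize_G(G_hat: float, mean_mcherry: float) -> float:
    """Scale a fitted conductance by cellular mCherry to correct for
    transfection efficiency: ``G_normalized = G_hat / mean_mcherry``."""
    if mean_mcherry <= 0:
        raise ValueError("mean mCherry intensity must be positive")
    return G_hat / mean_mcherry
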