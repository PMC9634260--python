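"""Analytic bridge between membrane potential and spike timing.

For a presynaptic LIF neuron driven by a constant current ``I > v_th`` the
subthreshold trajectory is ``v(t) = I + c * exp(-t / tau_m)``, so the time
difference to the nearest presynaptic spike can be recovered from a single
voltage sample:

    |dt| = tau_m * min(|ln((v_th - I) / (v - I))|,
                       |ln((v_reset - I) / (v - I))|),

where the first argument is the time *until* the next spike and the second
the time *since* the previous one.  Substituting this into the exponential
STDP window (with v_th = 1, v_reset = -1) gives the closed-form window as a
function of voltage alone:

    dw =  ((v - I) / (-1 - I)) ** (tau_m / tau_plus)     if v < I - sqrt(I^2 - 1)
    dw = -((1 - I) / (v - I)) ** (tau_m / tau_minus)     otherwise,

i.e. Hebbian STDP can be computed exactly from the presynaptic potential at
the postsynaptic spike time.  This module implements both formulas, the
fine-timestep simulations that validate them, and the empirical VDSP
window-scan protocol (a presynaptic neuron firing periodically, a
postsynaptic spike forced at a grid of offsets, the VDSP update recorded at
fixed initial weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .neurons import ConfigurationError, LIFParams
from .plasticity import VDSPParams, vdsp_dw

__all__ = [
    "AnalyticConfig",
    "delta_t_from_voltage",
    "stdp_window_from_voltage",
    "simulate_lif_trace",
    "delta_t_oracle_run",
    "vdsp_window_scan",
    "window_halfwidth",
]


@dataclass(frozen=True)
class AnalyticConfig:
    """Parameters of the two-neuron analytic protocol.

    ``I`` must exceed ``v_th`` so the presynaptic neuron spikes in finite
    time; the closed forms assume no refractory period.
    """

    tau_m: float = 30.0
    v_th: float = 1.0
    v_reset: float = -1.0
    I: float = 2.0
    tau_plus: float = 20.0
    tau_minus: float = 20.0

    def __post_init__(self) -> None:
        if self.I <= self.v_th:
            raise ConfigurationError(
                f"constant drive I={self.I} must exceed v_th={self.v_th}"
            )
        if self.tau_m <= 0 or self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ConfigurationError("time constants must be positive")


def delta_t_from_voltage(v_post_obs: float, cfg: AnalyticConfig) -> float:
    """Absolute time (ms) from a voltage sample to the nearest presynaptic
    spike, assuming steady periodic firing under constant drive."""
    if not (cfg.v_reset <= v_post_obs < cfg.v_th):
        raise ValueError(
            f"v_post_obs={v_post_obs} outside [v_reset={cfg.v_reset}, v_th={cfg.v_th})"
        )
    to_next = abs(math.log((cfg.v_th - cfg.I) / (v_post_obs - cfg.I)))
    since_last = abs(math.log((cfg.v_reset - cfg.I) / (v_post_obs - cfg.I)))
    return cfg.tau_m * min(to_next, since_last)


def stdp_window_from_voltage(v_post_obs: float, cfg: AnalyticConfig) -> float:
    """Normalized STDP weight change computed from the presynaptic potential
    alone (closed form; requires v_th = 1, v_reset = -1).

    The branch point ``v = I - sqrt(I^2 - 1)`` realizes the min of the
    time-distance formula: below it the presynaptic spike lies in the recent
    past (potentiation), above it in the near future (depression).
    """
    if not (cfg.v_th == 1.0 and cfg.v_reset == -1.0):
        raise ConfigurationError(
            "closed-form window requires v_th = 1 and v_reset = -1"
        )
    if not (cfg.v_reset <= v_post_obs < cfg.v_th):
        raise ValueError("v_post_obs outside [v_reset, v_th)")
    I = cfg.I
    if I - math.sqrt(I * I - 1.0) > v_post_obs:
        return ((v_post_obs - I) / (-1.0 - I)) ** (cfg.tau_m / cfg.tau_plus)
    return -(((1.0 - I) / (v_post_obs - I)) ** (cfg.tau_m / cfg.tau_minus))


@njit(cache=True)
def _lif_trace_kernel(
    equilibrium: float,
    tau_m: float,
    v_th: float,
    v_reset: float,
    t_ref: float,
    dt: float,
    n_steps: int,
    v0: float,
):  # pragma: no cover - exercised through simulate_lif_trace
    v = np.empty(n_steps, dtype=np.float64)
    spikes = np.zeros(n_steps, dtype=np.bool_)
    alpha = math.exp(-dt / tau_m)
    vv = v0
    refrac = 0.0
    for k in range(n_steps):
        if refrac > 0.0:
            vv = v_reset
            refrac -= dt
        else:
            vv = equilibrium + (vv - equilibrium) * alpha
            if vv >= v_th:
                spikes[k] = True
                vv = v_reset
                refrac = t_ref
        v[k] = vv
    return v, spikes


def simulate_lif_trace(
    params: LIFParams,
    drive: float,
    dt: float,
    duration: float,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clock-driven trace of a single LIF neuron under constant drive.

    Returns the stored membrane potential at the end of each step (reset
    value at spike steps) and the boolean spike train.  Step semantics match
    :func:`vdspnet.neurons.step_lif`.
    """
    if dt <= 0 or duration <= 0:
        raise ConfigurationError("dt and duration must be positive")
    equilibrium = params.gain * drive + params.bias + params.v_rest
    n_steps = int(round(duration / dt))
    return _lif_trace_kernel(
        equilibrium,
        params.tau_m,
        params.v_th,
        params.v_reset,
        params.t_ref,
        dt,
        n_steps,
        params.v_rest if v0 is None else v0,
    )


def delta_t_oracle_run(
    cfg: AnalyticConfig,
    n_obs: int = 1000,
    dt: float = 0.01,
    duration: float = 2000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical validation of the voltage-to-time-distance formula.

    Simulates a presynaptic LIF (no refractory period) at fine ``dt``, draws
    random observation times between the first and last spike, and compares
    the predicted distance to the nearest presynaptic spike against the
    distance measured from the simulated spike train.  Returns a table with
    columns (t_obs_ms, v_obs, predicted_ms, measured_ms, error_ms).
    """
    params = LIFParams(
        tau_m=cfg.tau_m, v_th=cfg.v_th, v_reset=cfg.v_reset, v_rest=0.0, t_ref=0.0
    )
    v, spikes = simulate_lif_trace(params, cfg.I, dt, duration)
    spike_steps = np.nonzero(spikes)[0]
    if spike_steps.size < 3:
        raise ConfigurationError("simulation too short: fewer than 3 spikes")
    rng = np.random.default_rng(seed)
    obs_steps = rng.integers(spike_steps[0], spike_steps[-1], size=n_obs)
    spike_times = spike_steps * dt
    rows = []
    for k in obs_steps:
        t_obs = k * dt
        measured = np.min(np.abs(spike_times - t_obs))
        predicted = delta_t_from_voltage(float(v[k]), cfg)
        rows.append((t_obs, v[k], predicted, measured, predicted - measured))
    return pd.DataFrame(
        rows, columns=["t_obs_ms", "v_obs", "predicted_ms", "measured_ms", "error_ms"]
    )


def vdsp_window_scan(
    cfg: AnalyticConfig,
    lr: float = 1e-3,
    w0: float = 0.5,
    delta_t_grid: np.ndarray | None = None,
    dt: float = 0.05,
    t_ref: float = 2.0,
) -> pd.DataFrame:
    """Empirical VDSP plasticity window for a two-neuron protocol.

    The presynaptic neuron fires periodically under constant drive ``cfg.I``;
    a postsynaptic spike is forced (by direct injection, bypassing any output
    dynamics) at each offset ``delta_t`` relative to a steady-state
    presynaptic spike, and the VDSP update at fixed initial weight ``w0`` is
    recorded.  Offsets inside the presynaptic refractory period read the
    reset potential, producing the characteristic plateau.  Returns a table
    with columns (delta_t_ms, delta_w).
    """
    if delta_t_grid is None:
        delta_t_grid = np.arange(-40.0, 40.0 + dt / 2, 0.25)
    delta_t_grid = np.asarray(delta_t_grid, dtype=np.float64)
    params = LIFParams(
        tau_m=cfg.tau_m, v_th=cfg.v_th, v_reset=cfg.v_reset, v_rest=0.0, t_ref=t_ref
    )
    isi_guess = t_ref + cfg.tau_m * math.log(
        (cfg.I - cfg.v_reset) / (cfg.I - cfg.v_th)
    )
    span = float(np.max(np.abs(delta_t_grid)))
    duration = 12 * isi_guess + 2 * span
    v, spikes = simulate_lif_trace(params, cfg.I, dt, duration)
    spike_steps = np.nonzero(spikes)[0]
    # anchor on a steady-state spike far from both ends
    anchor = spike_steps[len(spike_steps) // 2]
    vdsp = VDSPParams(lr=lr, w_max=1.0, v_bound=cfg.v_reset)
    rows = []
    for offset in delta_t_grid:
        k = anchor + int(round(offset / dt))
        rows.append((offset, float(vdsp_dw(float(v[k]), w0, vdsp))))
    return pd.DataFrame(rows, columns=["delta_t_ms", "delta_w"])


def window_halfwidth(table: pd.DataFrame) -> float:
    """Half-width (ms) of a plasticity window table.

    The |delta_t| on the potentiation side (delta_t >= 0) at which |delta_w|
    first falls to half its maximum, linearly interpolated between grid
    points.
    """
    side = table[table["delta_t_ms"] >= 0].sort_values("delta_t_ms")
    t = side["delta_t_ms"].to_numpy(dtype=np.float64)
    w = np.abs(side["delta_w"].to_numpy(dtype=np.float64))
    if t.size < 2 or np.ptp(w) == 0:
        raise ValueError("window table is flat; half-width undefined")
    peak = float(np.max(w))
    half = peak / 2.0
    start = int(np.argmax(w))
    for i in range(start, t.size - 1):
        if w[i] >= half >= w[i + 1]:
            if w[i] == w[i + 1]:
                return float(t[i])
            frac = (w[i] - half) / (w[i] - w[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise ValueError("window never falls to half maximum on the grid")
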