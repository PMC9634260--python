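"""Pair-based exponential STDP with the two-trace online formulation.

The comparison rule for the frequency-robustness experiments.  For an
isolated spike pair with time difference ``dt = t_post - t_pre``:

    dw =  a_plus  * (w_max - w) * exp(-dt / tau_plus)    if t_pre < t_post
    dw = -a_minus * w           * exp( dt / tau_minus)   otherwise

The soft-bound multiplicative factors ``(w_max - w)`` and ``w`` keep weights
inside ``[0, w_max]``.  Online, each neuron carries a decaying eligibility
trace: a postsynaptic spike potentiates proportionally to the presynaptic
trace and a presynaptic spike depresses proportionally to the postsynaptic
trace.  Updates pair spikes of *earlier* steps only: when pre and post fire
in the same step, depression is applied before potentiation and the
simultaneous pair itself contributes nothing (traces are incremented after
the updates).  Pairing simultaneous spikes at ``dt = 0`` instead makes
winner columns saturate under winner-take-all at a coarse timestep and
destroys the competition; see the methods notes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neurons import ConfigurationError
from .plasticity import WeightMatrix

__all__ = ["STDPParams", "TraceState", "stdp_dw", "step_traces"]


@dataclass(frozen=True)
class STDPParams:
    """Amplitudes and time constants of the pair-based STDP window."""

    a_plus: float = 5e-2
    a_minus: float = 5e-2
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    trace_increment: float = 1.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ConfigurationError("STDP time constants must be positive")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ConfigurationError("STDP amplitudes must be non-negative")


@dataclass
class TraceState:
    """Per-neuron decaying spike traces (all entries >= 0)."""

    x_pre: np.ndarray
    x_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre, dtype=np.float64), np.zeros(n_post, dtype=np.float64))

    def copy(self) -> "TraceState":
        return TraceState(self.x_pre.copy(), self.x_post.copy())


def stdp_dw(delta_t: float, w: float, params: STDPParams) -> float:
    """Weight change of the pair rule for spike time difference
    ``delta_t = t_post - t_pre`` (ms) at current weight ``w``."""
    if delta_t >= 0:
        return params.a_plus * (params.w_max - w) * math.exp(-delta_t / params.tau_plus)
    return -params.a_minus * w * math.exp(delta_t / params.tau_minus)


def step_traces(
    traces: TraceState,
    W: WeightMatrix,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    params: STDPParams,
) -> tuple[TraceState, WeightMatrix]:
    """Advance the trace model by one step and apply the induced updates.

    Order within a step: decay both traces; depress rows of presynaptic
    spikers against the (decayed) postsynaptic trace; potentiate columns of
    postsynaptic spikers against the (decayed) presynaptic trace; finally
    increment the traces of this step's spikers.  Spikes therefore pair with
    earlier steps only.  Weights are kept in ``[0, w_max]``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    pre_spikes = np.asarray(pre_spikes, dtype=bool)
    post_spikes = np.asarray(post_spikes, dtype=bool)
    out = traces.copy()
    Wout = W.copy()

    out.x_pre *= math.exp(-dt / params.tau_plus)
    out.x_post *= math.exp(-dt / params.tau_minus)

    if pre_spikes.any():
        rows = np.nonzero(pre_spikes)[0]
        Wout.w[rows, :] -= params.a_minus * Wout.w[rows, :] * out.x_post[None, :]
    if post_spikes.any():
        cols = np.nonzero(post_spikes)[0]
        Wout.w[:, cols] += (
            params.a_plus * (params.w_max - Wout.w[:, cols]) * out.x_pre[:, None]
        )
    np.clip(Wout.w, 0.0, params.w_max, out=Wout.w)

    out.x_pre[pre_spikes] += params.trace_increment
    out.x_post[post_spikes] += params.trace_increment
    return out, Wout
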