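"""Clock-driven leaky integrate-and-fire (LIF) and adaptive LIF (ALIF) populations.

The membrane potential of a LIF neuron obeys

    tau_m dv/dt = -(v - v_rest) + gain * I + bias,

so between spikes it relaxes exponentially toward the equilibrium
``E = gain * I + bias + v_rest``.  When ``v`` reaches the threshold ``v_th``
the neuron emits a spike, ``v`` is reset to ``v_reset`` and the neuron is held
there for the refractory period ``t_ref``.  The ALIF neuron adds a spike-
triggered adaptation current ``n`` that is subtracted from the drive and
decays with time constant ``tau_n``, lowering the firing rate under sustained
strong input.

Integration uses the exact exponential (zero-order-hold) update per step,
``v' = E + (v - E) * exp(-dt / tau_m)``, which is accurate even at the coarse
5 ms step used by the classification network.  Threshold detection happens at
the end of each step; the spike time is the step's timestamp.  A neuron can
additionally be *clamped*: its potential is pinned to zero and all drive is
ignored until the clamp timer expires (used for winner-take-all inhibition).
Clamping overrides refractoriness; both timers decrement concurrently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "ALIFParams",
    "NeuronPopulationState",
    "ConfigurationError",
    "step_lif",
    "step_alif",
    "closed_form_isi",
    "apply_clamp",
]


class ConfigurationError(ValueError):
    """Raised for invalid neuron/network configuration or mismatched shapes."""


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    Parameters
    ----------
    tau_m : float
        Membrane leak time constant in ms.
    v_th, v_reset, v_rest : float
        Threshold, post-spike reset and resting potentials (V).  A reset
        below rest lets a downstream plasticity rule distinguish a neuron
        that spiked recently (v < 0) from an inactive one (v >= 0).
    t_ref : float
        Refractory period in ms; the membrane is held at ``v_reset``.
    bias : float
        Constant additive drive (same scale as the input current).
    gain : float
        Multiplicative scale on the external current (default 1).
    """

    tau_m: float = 30.0
    v_th: float = 1.0
    v_reset: float = -1.0
    v_rest: float = 0.0
    t_ref: float = 5.0
    bias: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive")
        if self.t_ref < 0:
            raise ConfigurationError("t_ref must be non-negative")
        if not (self.v_reset < self.v_th and self.v_rest < self.v_th):
            raise ConfigurationError("v_reset and v_rest must lie below v_th")


@dataclass(frozen=True)
class ALIFParams(LIFParams):
    """LIF parameters plus spike-triggered adaptation.

    ``inc_n`` is added to the adaptation variable on each spike and the
    variable decays with time constant ``tau_n`` (ms); its value is
    subtracted from the input current.
    """

    inc_n: float = 0.01
    tau_n: float = 1000.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.inc_n < 0:
            raise ConfigurationError("inc_n must be non-negative")
        if self.tau_n <= 0:
            raise ConfigurationError("tau_n must be positive")


@dataclass
class NeuronPopulationState:
    """Per-neuron state vectors of a population."""

    v: np.ndarray
    refrac_remaining: np.ndarray
    n: np.ndarray
    clamp_remaining: np.ndarray

    @classmethod
    def zeros(cls, size: int, v0: float = 0.0) -> "NeuronPopulationState":
        return cls(
            v=np.full(size, v0, dtype=np.float64),
            refrac_remaining=np.zeros(size, dtype=np.float64),
            n=np.zeros(size, dtype=np.float64),
            clamp_remaining=np.zeros(size, dtype=np.float64),
        )

    def copy(self) -> "NeuronPopulationState":
        return NeuronPopulationState(
            self.v.copy(),
            self.refrac_remaining.copy(),
            self.n.copy(),
            self.clamp_remaining.copy(),
        )

    def __len__(self) -> int:
        return self.v.shape[0]


def _check_step_args(state: NeuronPopulationState, drive: np.ndarray, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    drive = np.asarray(drive, dtype=np.float64)
    if drive.ndim == 0:
        drive = np.full(len(state), float(drive))
    if drive.shape != state.v.shape:
        raise ConfigurationError(
            f"drive has shape {drive.shape}, expected {state.v.shape}"
        )
    return drive


def step_lif(
    state: NeuronPopulationState,
    params: LIFParams,
    drive: np.ndarray,
    dt: float,
) -> tuple[NeuronPopulationState, np.ndarray]:
    """Advance a LIF population by one step of ``dt`` ms.

    Returns the new state and a boolean spike mask.  Neurons whose potential
    reaches ``v_th`` at the end of the step spike and are reset; refractory
    neurons are held at ``v_reset``; clamped neurons are held at 0 and ignore
    all drive.
    """
    drive = _check_step_args(state, drive, dt)
    return _step(state, params, drive, dt, adapt=False)


def step_alif(
    state: NeuronPopulationState,
    params: ALIFParams,
    drive: np.ndarray,
    dt: float,
) -> tuple[NeuronPopulationState, np.ndarray]:
    """Advance an ALIF population by one step: LIF with the adaptation
    variable ``n`` subtracted from the drive, incremented on spikes and
    decaying with ``tau_n`` between them."""
    drive = _check_step_args(state, drive, dt)
    return _step(state, params, drive, dt, adapt=True)


def _step(
    state: NeuronPopulationState,
    params: LIFParams,
    drive: np.ndarray,
    dt: float,
    adapt: bool,
) -> tuple[NeuronPopulationState, np.ndarray]:
    out = state.copy()
    alpha = math.exp(-dt / params.tau_m)

    if adapt:
        # Adaptation decays every step, including refractory/clamped ones.
        out.n *= math.exp(-dt / params.tau_n)  # type: ignore[union-attr]
        effective = params.gain * drive + params.bias - out.n
    else:
        effective = params.gain * drive + params.bias
    equilibrium = effective + params.v_rest

    clamped = out.clamp_remaining > 0
    refractory = (out.refrac_remaining > 0) & ~clamped
    free = ~clamped & ~refractory

    out.v[free] = equilibrium[free] + (out.v[free] - equilibrium[free]) * alpha
    out.v[refractory] = params.v_reset
    out.v[clamped] = 0.0
    out.refrac_remaining = np.maximum(out.refrac_remaining - dt, 0.0)
    out.clamp_remaining = np.maximum(out.clamp_remaining - dt, 0.0)

    spikes = free & (out.v >= params.v_th)
    out.v[spikes] = params.v_reset
    out.refrac_remaining[spikes] = params.t_ref
    if adapt:
        out.n[spikes] += params.inc_n
    return out, spikes


def closed_form_isi(params: LIFParams, drive: float) -> float:
    """Closed-form inter-spike interval (ms) of a LIF neuron under constant
    drive, or ``inf`` when the equilibrium never reaches threshold.

    Solving the membrane equation from ``v_reset`` to ``v_th`` gives

        ISI = t_ref + tau_m * ln((E - v_reset) / (E - v_th)),

    with ``E = gain * drive + bias + v_rest``.  Serves as the independent
    oracle for the simulated dynamics.
    """
    equilibrium = params.gain * drive + params.bias + params.v_rest
    if equilibrium <= params.v_th:
        return math.inf
    return params.t_ref + params.tau_m * math.log(
        (equilibrium - params.v_reset) / (equilibrium - params.v_th)
    )


def apply_clamp(
    state: NeuronPopulationState,
    mask: np.ndarray,
    duration: float,
) -> NeuronPopulationState:
    """Pin the potential of the masked neurons to zero for ``duration`` ms.

    While clamped a neuron ignores all drive; the clamp overrides
    refractoriness (both timers keep decrementing).
    """
    if duration < 0:
        raise ConfigurationError("clamp duration must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != state.v.shape:
        raise ConfigurationError("clamp mask shape mismatch")
    out = state.copy()
    out.v[mask] = 0.0
    out.clamp_remaining[mask] = duration
    return out
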