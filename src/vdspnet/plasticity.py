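"""Voltage-dependent synaptic plasticity (VDSP).

VDSP is a Hebbian rule that updates a synapse only when the *postsynaptic*
neuron spikes, using the *presynaptic membrane potential* at that moment in
place of spike timing.  For a presynaptic LIF neuron with reset below rest,
a negative potential signals "spiked recently" (potentiate) and a positive
potential signals "about to spike" (depress).  The update is multiplicative
in the current weight, which keeps weights inside ``[0, w_max]`` with no
hard clipping:

    dw = (w_max - w) * (exp(-v_pre) - 1) * lr    if v_pre < 0   (potentiation)
    dw = -w * (exp(v_pre) - 1) * lr              if v_pre > 0   (depression)
    dw = 0                                       if v_pre = 0

Both one-sided limits vanish at ``v_pre = 0``, so the rule is continuous
there.  Weight containment without clipping requires the safe-bound
condition ``lr * (exp(|v_bound|) - 1) <= 1`` where ``v_bound`` is the most
negative reachable presynaptic potential (normally ``v_reset``); a violation
raises a warning at configuration time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .neurons import ConfigurationError

__all__ = ["VDSPParams", "WeightMatrix", "vdsp_dw", "apply_on_post_spikes", "init_weights"]


@dataclass(frozen=True)
class VDSPParams:
    """Learning rate and weight bound of the VDSP rule.

    ``v_bound`` is the most negative presynaptic potential the rule can see
    (the presynaptic reset potential); it is only used to check the
    safe-bound condition that guarantees weight containment.
    """

    lr: float = 5e-2
    w_max: float = 1.0
    v_bound: float = -1.0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be positive")
        if self.lr * (math.exp(abs(self.v_bound)) - 1.0) > 1.0 + 1e-12:
            warnings.warn(
                "VDSP safe-bound condition lr*(exp(|v_bound|)-1) <= 1 violated; "
                "iterated updates may overshoot the weight bounds",
                stacklevel=2,
            )


@dataclass
class WeightMatrix:
    """Dense synaptic conductances, presynaptic index x postsynaptic index.

    Entries live in ``[0, w_max]`` at all times; the multiplicative VDSP
    update preserves the bounds without clipping.
    """

    w: np.ndarray
    w_max: float = 1.0

    @property
    def n_pre(self) -> int:
        return self.w.shape[0]

    @property
    def n_post(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy(), self.w_max)

    def validate(self) -> None:
        if np.any(self.w < 0) or np.any(self.w > self.w_max):
            raise ConfigurationError("weights outside [0, w_max]")

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV, one row per presynaptic neuron."""
        np.savetxt(path, self.w, delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path, w_max: float = 1.0) -> "WeightMatrix":
        w = np.loadtxt(path, delimiter=",", dtype=np.float64)
        if w.ndim == 1:
            w = w[:, None]
        return cls(w, w_max)

    def to_npz(self, path: str | Path) -> None:
        np.savez(path, w=self.w, w_max=np.float64(self.w_max))

    @classmethod
    def from_npz(cls, path: str | Path) -> "WeightMatrix":
        with np.load(path) as data:
            return cls(data["w"].astype(np.float64), float(data["w_max"]))


def vdsp_dw(
    v_pre: float | np.ndarray,
    w: float | np.ndarray,
    params: VDSPParams,
) -> float | np.ndarray:
    """Weight change for presynaptic potential(s) ``v_pre`` and weight(s) ``w``.

    Vectorized over broadcast-compatible inputs.  The result has the sign of
    ``-v_pre`` (or is zero) and vanishes at the respective weight bound.
    """
    v = np.asarray(v_pre, dtype=np.float64)
    wa = np.asarray(w, dtype=np.float64)
    if np.any(wa < -1e-12) or np.any(wa > params.w_max + 1e-12):
        raise ConfigurationError("weight outside [0, w_max]")
    # The update factor lr*(exp(|v|)-1) is saturated at 1 so a single update
    # can never overshoot a bound even for potentials beyond the safe-bound
    # range (possible transiently at a coarse timestep).
    pot = (params.w_max - wa) * np.minimum(np.expm1(-v) * params.lr, 1.0)
    dep = -wa * np.minimum(np.expm1(v) * params.lr, 1.0)
    dw = np.where(v < 0, pot, np.where(v > 0, dep, 0.0))
    if np.isscalar(v_pre) and np.isscalar(w):
        return float(dw)
    return dw


def apply_on_post_spikes(
    W: WeightMatrix,
    v_pre: np.ndarray,
    post_spikes: np.ndarray,
    params: VDSPParams,
) -> WeightMatrix:
    """Apply the VDSP update to every column whose postsynaptic neuron spiked.

    ``v_pre`` holds the presynaptic potentials stored at the end of the
    timestep in which the postsynaptic spikes occurred (the reset value for
    presynaptic neurons that spiked in the same step).  Columns of
    non-spiking neurons are untouched.
    """
    v_pre = np.asarray(v_pre, dtype=np.float64)
    post_spikes = np.asarray(post_spikes, dtype=bool)
    if v_pre.shape[0] != W.n_pre:
        raise ConfigurationError("v_pre length does not match presynaptic dimension")
    if post_spikes.shape[0] != W.n_post:
        raise ConfigurationError("post_spikes length does not match postsynaptic dimension")
    if not post_spikes.any():
        return W
    out = W.copy()
    cols = np.nonzero(post_spikes)[0]
    for j in cols:
        out.w[:, j] += vdsp_dw(v_pre, out.w[:, j], params)
    return out


def init_weights(
    n_pre: int,
    n_post: int,
    seed: int | np.random.Generator,
    w_max: float = 1.0,
) -> WeightMatrix:
    """Uniformly random initial weights on ``[0, w_max]``, reproducible by seed."""
    if n_pre <= 0 or n_post <= 0:
        raise ConfigurationError("weight matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    return WeightMatrix(rng.uniform(0.0, w_max, size=(n_pre, n_post)), w_max)
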