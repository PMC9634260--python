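"""Two-layer fully connected spiking network with winner-take-all output.

Input LIF neurons (one per pixel) project through plastic synapses onto an
ALIF output population.  Lateral inhibition is realized as hard
winner-take-all: when one or more output neurons cross threshold in a step,
the one with the largest pre-reset potential (ties to the lowest index)
spikes and every other output neuron is clamped to zero for ``inhibit_ms``.
At most one output spike can therefore occur per step.

Per step the loop is: (1) advance the input neurons (or consume a provided
spike-raster row in Poisson mode); (2) low-pass filter the weighted input
spikes into the synaptic current ``syn``; (3) advance the output ALIF
neurons with drive ``syn``; (4) resolve the winner and clamp the losers;
(5) if learning, apply the configured rule (VDSP reads the presynaptic
potentials stored at the end of the step, so a presynaptic neuron that
spiked in the same step reads its reset value and a same-step causal
pre/post pair potentiates; STDP uses the two-trace model).

The synaptic filter is exponential with time constant ``syn_tau`` and is
normalized so that a single spike through weight ``w`` contributes a
time-integrated current of exactly ``w`` regardless of ``dt``.  Neuron
state is *not* reset between samples; membrane, adaptation and synaptic
variables carry over, matching presentation with no wait time between
images.

The hot loop is compiled with numba; :meth:`Network.step` and
:meth:`Network.run_sample` share the same kernel, so stepping one step at a
time and running a whole presentation are bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .encoding import EncodedSample
from .neurons import ALIFParams, ConfigurationError, LIFParams, NeuronPopulationState
from .plasticity import VDSPParams, WeightMatrix, init_weights
from .stdp import STDPParams, TraceState

__all__ = ["NetworkConfig", "Network", "NumericalError"]


class NumericalError(RuntimeError):
    """Raised when a state vector becomes non-finite during simulation."""


@dataclass(frozen=True)
class NetworkConfig:
    """Topology, timing and learning-rule configuration of the network."""

    n_in: int
    n_out: int
    dt: float = 5.0
    present_ms: float = 350.0
    inhibit_ms: float = 10.0
    syn_tau: float = 5.0
    rule: str = "vdsp"
    seed: int = 0
    input_params: LIFParams = field(default_factory=lambda: LIFParams(bias=0.5))
    output_params: ALIFParams = field(
        default_factory=lambda: ALIFParams(v_reset=0.0, bias=0.0)
    )
    vdsp: VDSPParams = field(default_factory=VDSPParams)
    stdp: STDPParams = field(default_factory=STDPParams)

    def __post_init__(self) -> None:
        if self.n_in <= 0 or self.n_out <= 0:
            raise ConfigurationError("n_in and n_out must be positive")
        if self.dt <= 0 or self.syn_tau <= 0:
            raise ConfigurationError("dt and syn_tau must be positive")
        for name, value in (("present_ms", self.present_ms), ("inhibit_ms", self.inhibit_ms)):
            if abs(round(value / self.dt) * self.dt - value) > 1e-9:
                raise ConfigurationError(f"{name} must be a multiple of dt")
        if self.rule not in ("vdsp", "stdp"):
            raise ConfigurationError(f"unknown plasticity rule {self.rule!r}")


@njit(cache=True)
def _sim_kernel(
    n_steps,
    dt,
    drive,            # (Td, n_in) float64; Td == 1 -> constant; in raster mode 0/1
    raster_mode,
    v_in, refrac_in,
    in_p,             # tau_m, v_th, v_reset, v_rest, t_ref, bias, gain
    v_out, refrac_out, n_adapt, clamp_out,
    out_p,            # tau_m, v_th, v_reset, v_rest, t_ref, bias, gain, inc_n, tau_n
    W, w_max,
    syn, syn_tau, inhibit_ms,
    learn, rule_stdp, lr,
    a_plus, a_minus, tau_plus, tau_minus, trace_inc,
    x_pre, x_post,
    rec_in, rec_out,  # (n_steps, n) bool spike records
):  # pragma: no cover - exercised through Network
    n_in = v_in.shape[0]
    n_out = v_out.shape[0]
    a_in = math.exp(-dt / in_p[0])
    a_out = math.exp(-dt / out_p[0])
    a_syn = math.exp(-dt / syn_tau)
    a_n = math.exp(-dt / out_p[8])
    a_xpre = math.exp(-dt / tau_plus)
    a_xpost = math.exp(-dt / tau_minus)
    syn_inc = (1.0 - a_syn) / dt
    v_learn = np.empty(n_in, dtype=np.float64)

    for t in range(n_steps):
        d = drive[t] if drive.shape[0] > 1 else drive[0]

        # (1) input layer
        for i in range(n_in):
            if raster_mode:
                if refrac_in[i] > 0.0:
                    v_in[i] = in_p[2]
                    refrac_in[i] -= dt
                else:
                    eq = in_p[5] + in_p[3]  # bias + v_rest, no current drive
                    v_in[i] = eq + (v_in[i] - eq) * a_in
                    if d[i] > 0.5:
                        rec_in[t, i] = True
                        v_in[i] = in_p[2]
                        refrac_in[i] = in_p[4]
            else:
                if refrac_in[i] > 0.0:
                    v_in[i] = in_p[2]
                    refrac_in[i] -= dt
                else:
                    eq = in_p[6] * d[i] + in_p[5] + in_p[3]
                    v = eq + (v_in[i] - eq) * a_in
                    if v >= in_p[1]:
                        rec_in[t, i] = True
                        v = in_p[2]
                        refrac_in[i] = in_p[4]
                    v_in[i] = v
            # Plasticity reads the stored end-of-step potential: a neuron that
            # spiked this step reads its reset value, so a same-step causal
            # pre/post pair potentiates (Hebbian at coarse dt).
            v_learn[i] = v_in[i]

        # (2) synaptic low-pass of weighted input spikes
        for j in range(n_out):
            syn[j] *= a_syn
        for i in range(n_in):
            if rec_in[t, i]:
                for j in range(n_out):
                    syn[j] += W[i, j] * syn_inc

        # (3) output ALIF layer
        winner = -1
        v_winner = -1.0e300
        for j in range(n_out):
            n_adapt[j] *= a_n
            if clamp_out[j] > 0.0:
                v_out[j] = 0.0
                clamp_out[j] -= dt
                if refrac_out[j] > 0.0:
                    refrac_out[j] -= dt
            elif refrac_out[j] > 0.0:
                v_out[j] = out_p[2]
                refrac_out[j] -= dt
            else:
                eq = out_p[6] * syn[j] + out_p[5] + out_p[3] - n_adapt[j]
                v = eq + (v_out[j] - eq) * a_out
                v_out[j] = v
                if v >= out_p[1] and v > v_winner:
                    winner = j
                    v_winner = v

        # (4) winner-take-all: single spike, clamp all other outputs
        if winner >= 0:
            rec_out[t, winner] = True
            v_out[winner] = out_p[2]
            refrac_out[winner] = out_p[4]
            n_adapt[winner] += out_p[7]
            for j in range(n_out):
                if j != winner:
                    v_out[j] = 0.0
                    clamp_out[j] = inhibit_ms

        # (5) plasticity
        if learn:
            if rule_stdp:
                for i in range(n_in):
                    x_pre[i] *= a_xpre
                for j in range(n_out):
                    x_post[j] *= a_xpost
                # spikes pair with earlier steps only; depression before
                # potentiation on simultaneous spikes, traces incremented last
                for i in range(n_in):
                    if rec_in[t, i]:
                        for j in range(n_out):
                            w = W[i, j] - a_minus * W[i, j] * x_post[j]
                            W[i, j] = w if w > 0.0 else 0.0
                if winner >= 0:
                    for i in range(n_in):
                        w = W[i, winner] + a_plus * (w_max - W[i, winner]) * x_pre[i]
                        W[i, winner] = w if w < w_max else w_max
                for i in range(n_in):
                    if rec_in[t, i]:
                        x_pre[i] += trace_inc
                if winner >= 0:
                    x_post[winner] += trace_inc
            elif winner >= 0:
                for i in range(n_in):
                    v = v_learn[i]
                    if v < 0.0:
                        f = lr * math.expm1(-v)
                        if f > 1.0:
                            f = 1.0
                        W[i, winner] += (w_max - W[i, winner]) * f
                    elif v > 0.0:
                        f = lr * math.expm1(v)
                        if f > 1.0:
                            f = 1.0
                        W[i, winner] -= W[i, winner] * f


class Network:
    """A configured network instance owning all mutable simulation state."""

    def __init__(self, config: NetworkConfig, weights: WeightMatrix | None = None):
        self.config = config
        self.input_state = NeuronPopulationState.zeros(
            config.n_in, v0=config.input_params.v_rest
        )
        self.output_state = NeuronPopulationState.zeros(
            config.n_out, v0=config.output_params.v_rest
        )
        if weights is None:
            weights = init_weights(
                config.n_in, config.n_out, config.seed, config.vdsp.w_max
            )
        if weights.w.shape != (config.n_in, config.n_out):
            raise ConfigurationError("weight matrix shape does not match topology")
        self.weights = weights
        self.syn_current = np.zeros(config.n_out, dtype=np.float64)
        self.traces = TraceState.zeros(config.n_in, config.n_out)
        self.clock = 0.0

    # -- internals ---------------------------------------------------------
    def _param_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.config.input_params
        q = self.config.output_params
        in_p = np.array(
            [p.tau_m, p.v_th, p.v_reset, p.v_rest, p.t_ref, p.bias, p.gain]
        )
        out_p = np.array(
            [q.tau_m, q.v_th, q.v_reset, q.v_rest, q.t_ref, q.bias, q.gain,
             q.inc_n, q.tau_n]
        )
        return in_p, out_p

    def _run(self, drive: np.ndarray, raster_mode: bool, learn: bool,
             n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        rec_in = np.zeros((n_steps, cfg.n_in), dtype=np.bool_)
        rec_out = np.zeros((n_steps, cfg.n_out), dtype=np.bool_)
        in_p, out_p = self._param_arrays()
        _sim_kernel(
            n_steps, cfg.dt, drive, raster_mode,
            self.input_state.v, self.input_state.refrac_remaining,
            in_p,
            self.output_state.v, self.output_state.refrac_remaining,
            self.output_state.n, self.output_state.clamp_remaining,
            out_p,
            self.weights.w, cfg.vdsp.w_max,
            self.syn_current, cfg.syn_tau, cfg.inhibit_ms,
            learn, cfg.rule == "stdp", cfg.vdsp.lr,
            cfg.stdp.a_plus, cfg.stdp.a_minus,
            cfg.stdp.tau_plus, cfg.stdp.tau_minus, cfg.stdp.trace_increment,
            self.traces.x_pre, self.traces.x_post,
            rec_in, rec_out,
        )
        self.clock += n_steps * cfg.dt
        if not (
            np.isfinite(self.input_state.v).all()
            and np.isfinite(self.output_state.v).all()
            and np.isfinite(self.weights.w).all()
        ):
            raise NumericalError(
                f"non-finite state at t={self.clock} ms; check configuration"
            )
        return rec_in, rec_out

    # -- public API --------------------------------------------------------
    def step(
        self, input_drive: np.ndarray, learn: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance one timestep.  ``input_drive`` is either a per-input
        constant-current vector or a boolean spike row (Poisson mode).
        Returns the (input spikes, output spikes) boolean masks."""
        input_drive = np.asarray(input_drive)
        if input_drive.shape != (self.config.n_in,):
            raise ConfigurationError(
                f"input drive has shape {input_drive.shape}, expected ({self.config.n_in},)"
            )
        raster_mode = input_drive.dtype == np.bool_
        drive = np.ascontiguousarray(input_drive[None, :], dtype=np.float64)
        rec_in, rec_out = self._run(drive, raster_mode, learn, n_steps=1)
        return rec_in[0], rec_out[0]

    def run_sample(
        self, sample: EncodedSample, learn: bool = False
    ) -> np.ndarray:
        """Present one encoded sample for its full duration (no state reset
        afterwards) and return the per-output-neuron spike counts."""
        cfg = self.config
        n_steps = int(round(sample.duration / cfg.dt))
        drive = sample.drive
        if drive.ndim == 1:
            if drive.shape[0] != cfg.n_in:
                raise ConfigurationError("sample dimension does not match n_in")
            dmat = np.ascontiguousarray(drive[None, :], dtype=np.float64)
            raster_mode = False
        else:
            if drive.shape[1] != cfg.n_in:
                raise ConfigurationError("sample dimension does not match n_in")
            if drive.shape[0] != n_steps:
                raise ConfigurationError(
                    "time-resolved drive length does not match duration / dt"
                )
            raster_mode = sample.is_raster
            dmat = np.ascontiguousarray(drive, dtype=np.float64)
        rec_in, rec_out = self._run(dmat, raster_mode, learn, n_steps=n_steps)
        return rec_out.sum(axis=0).astype(np.int64)

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint config + full mutable state to an .npz container."""
        cfg = self.config
        meta = {
            "n_in": cfg.n_in, "n_out": cfg.n_out, "dt": cfg.dt,
            "present_ms": cfg.present_ms, "inhibit_ms": cfg.inhibit_ms,
            "syn_tau": cfg.syn_tau, "rule": cfg.rule, "seed": cfg.seed,
            "input_params": vars(cfg.input_params),
            "output_params": vars(cfg.output_params),
            "vdsp": vars(cfg.vdsp),
            "stdp": vars(cfg.stdp),
        }
        np.savez(
            path,
            config=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            w=self.weights.w,
            v_in=self.input_state.v,
            refrac_in=self.input_state.refrac_remaining,
            v_out=self.output_state.v,
            refrac_out=self.output_state.refrac_remaining,
            n_out=self.output_state.n,
            clamp_out=self.output_state.clamp_remaining,
            syn=self.syn_current,
            x_pre=self.traces.x_pre,
            x_post=self.traces.x_post,
            clock=np.float64(self.clock),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with np.load(path) as data:
            meta = json.loads(bytes(data["config"]).decode())
            cfg = NetworkConfig(
                n_in=meta["n_in"], n_out=meta["n_out"], dt=meta["dt"],
                present_ms=meta["present_ms"], inhibit_ms=meta["inhibit_ms"],
                syn_tau=meta["syn_tau"], rule=meta["rule"], seed=meta["seed"],
                input_params=LIFParams(**meta["input_params"]),
                output_params=ALIFParams(**meta["output_params"]),
                vdsp=VDSPParams(**meta["vdsp"]),
                stdp=STDPParams(**meta["stdp"]),
            )
            net = cls(cfg, weights=WeightMatrix(data["w"].copy(), cfg.vdsp.w_max))
            net.input_state.v[:] = data["v_in"]
            net.input_state.refrac_remaining[:] = data["refrac_in"]
            net.output_state.v[:] = data["v_out"]
            net.output_state.refrac_remaining[:] = data["refrac_out"]
            net.output_state.n[:] = data["n_out"]
            net.output_state.clamp_remaining[:] = data["clamp_out"]
            net.syn_current[:] = data["syn"]
            net.traces.x_pre[:] = data["x_pre"]
            net.traces.x_post[:] = data["x_post"]
            net.clock = float(data["clock"])
        return net
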