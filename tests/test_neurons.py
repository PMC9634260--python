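"""LIF/ALIF dynamics against closed-form oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdspnet.neurons import (
    ALIFParams,
    ConfigurationError,
    LIFParams,
    NeuronPopulationState,
    apply_clamp,
    closed_form_isi,
    step_alif,
    step_lif,
)

TABLE_INPUT = LIFParams(
    tau_m=30.0, v_th=1.0, v_reset=-1.0, v_rest=0.0, t_ref=5.0, bias=0.5
)


def simulate_isi(params: LIFParams, drive: float, dt: float, duration: float) -> float:
    """Mean inter-spike interval measured from a clock-driven run."""
    state = NeuronPopulationState.zeros(1, v0=params.v_rest)
    d = np.array([drive])
    spike_times = []
    n_steps = int(round(duration / dt))
    for k in range(n_steps):
        state, spikes = step_lif(state, params, d, dt)
        if spikes[0]:
            spike_times.append((k + 1) * dt)
    if len(spike_times) < 3:
        return math.inf
    return float(np.mean(np.diff(spike_times)))


class TestClosedFormISI:
    def test_reference_value(self):
        # tau_m = 30, v_reset = -1, v_th = 1, t_ref = 5, equilibrium 1.5:
        # ISI = 5 + 30*ln((1.5+1)/(1.5-1)) = 5 + 30*ln(5)
        params = LIFParams(tau_m=30.0, v_reset=-1.0, t_ref=5.0)
        assert closed_form_isi(params, 1.5) == pytest.approx(
            5.0 + 30.0 * math.log(5.0), abs=1e-12
        )
        assert closed_form_isi(params, 1.5) == pytest.approx(53.28313737302301, abs=1e-9)

    def test_subthreshold_drive_never_spikes(self):
        params = LIFParams()
        assert closed_form_isi(params, 0.99) == math.inf
        assert closed_form_isi(params, 1.0) == math.inf  # equilibrium == threshold

    def test_bias_and_gain_enter_equilibrium(self):
        base = LIFParams(tau_m=30.0, t_ref=0.0)
        biased = LIFParams(tau_m=30.0, t_ref=0.0, bias=0.5)
        gained = LIFParams(tau_m=30.0, t_ref=0.0, gain=2.0)
        assert closed_form_isi(biased, 1.0) == pytest.approx(
            closed_form_isi(base, 1.5), abs=1e-12
        )
        assert closed_form_isi(gained, 0.75) == pytest.approx(
            closed_form_isi(base, 1.5), abs=1e-12
        )

    @pytest.mark.parametrize("drive", [1.2, 1.5, 2.0, 4.0])
    def test_simulation_converges_to_closed_form(self, drive):
        params = LIFParams(tau_m=30.0, v_reset=-1.0, t_ref=5.0)
        oracle = closed_form_isi(params, drive)
        measured = simulate_isi(params, drive, dt=0.01, duration=40 * oracle)
        assert measured == pytest.approx(oracle, abs=0.02)  # within 2 fine steps

    def test_coarse_step_overestimates_by_at_most_dt(self):
        # end-of-step detection can delay each spike by less than one step
        params = TABLE_INPUT
        drive = 1.0  # equilibrium 1.5 with the bias
        oracle = closed_form_isi(params, drive)
        measured = simulate_isi(params, drive, dt=5.0, duration=500 * 5.0)
        assert oracle <= measured <= oracle + 5.0


class TestStepDynamics:
    def test_exact_exponential_update(self):
        params = LIFParams(tau_m=30.0, bias=0.0)
        state = NeuronPopulationState.zeros(1, v0=0.3)
        state, spikes = step_lif(state, params, np.array([0.5]), dt=5.0)
        expected = 0.5 + (0.3 - 0.5) * math.exp(-5.0 / 30.0)
        assert not spikes[0]
        assert state.v[0] == pytest.approx(expected, abs=1e-15)

    def test_spike_resets_and_sets_refractory(self):
        params = LIFParams(tau_m=30.0, v_th=1.0, v_reset=-1.0, t_ref=10.0)
        state = NeuronPopulationState.zeros(1, v0=0.99)
        state, spikes = step_lif(state, params, np.array([5.0]), dt=5.0)
        assert spikes[0]
        assert state.v[0] == -1.0
        assert state.refrac_remaining[0] == 10.0
        # held at reset while refractory, regardless of drive
        state, spikes = step_lif(state, params, np.array([50.0]), dt=5.0)
        assert not spikes[0]
        assert state.v[0] == -1.0
        state, spikes = step_lif(state, params, np.array([50.0]), dt=5.0)
        assert state.refrac_remaining[0] == 0.0

    def test_leak_decays_toward_rest_without_drive(self):
        params = LIFParams(tau_m=30.0, v_rest=0.0)
        state = NeuronPopulationState.zeros(1, v0=0.8)
        for _ in range(200):
            state, _ = step_lif(state, params, np.array([0.0]), dt=5.0)
        assert abs(state.v[0]) < 1e-9

    def test_population_vectorization_matches_scalar(self):
        params = LIFParams(bias=0.2)
        drives = np.array([0.0, 0.5, 1.2, 3.0])
        pop = NeuronPopulationState.zeros(4)
        singles = [NeuronPopulationState.zeros(1) for _ in drives]
        for _ in range(50):
            pop, pop_spikes = step_lif(pop, params, drives, dt=5.0)
            for i, d in enumerate(drives):
                singles[i], s = step_lif(singles[i], params, np.array([d]), dt=5.0)
                assert s[0] == pop_spikes[i]
        for i in range(4):
            assert singles[i].v[0] == pop.v[i]

    def test_shape_mismatch_raises(self):
        state = NeuronPopulationState.zeros(3)
        with pytest.raises(ConfigurationError):
            step_lif(state, LIFParams(), np.zeros(4), dt=5.0)

    def test_nonpositive_dt_raises(self):
        state = NeuronPopulationState.zeros(1)
        with pytest.raises(ConfigurationError):
            step_lif(state, LIFParams(), np.zeros(1), dt=0.0)

    @given(
        v0=st.floats(-1.0, 0.99),
        drive=st.floats(0.0, 5.0),
        dt=st.floats(0.5, 10.0),
    )
    @settings(max_examples=200)
    def test_potential_never_exceeds_threshold_after_step(self, v0, drive, dt):
        # threshold detection resets in the same step, so stored v < v_th always
        params = LIFParams()
        state = NeuronPopulationState.zeros(1, v0=v0)
        for _ in range(5):
            state, _ = step_lif(state, params, np.array([drive]), dt)
            assert state.v[0] < params.v_th


class TestAdaptation:
    def test_adaptation_accumulates_and_decays(self):
        params = ALIFParams(v_reset=0.0, inc_n=0.01, tau_n=1000.0, t_ref=0.0)
        state = NeuronPopulationState.zeros(1)
        state, _ = step_alif(state, params, np.array([50.0]), dt=5.0)
        assert state.n[0] == pytest.approx(0.01)
        # without further spikes n decays with tau_n
        quiet = state.copy()
        quiet, spikes = step_alif(quiet, params, np.array([0.0]), dt=5.0)
        assert not spikes[0]
        assert quiet.n[0] == pytest.approx(0.01 * math.exp(-5.0 / 1000.0))

    def test_adaptation_slows_firing(self):
        dt, duration = 5.0, 60_000.0
        drive = np.array([2.0])
        n_steps = int(duration / dt)
        counts = {}
        for inc in (0.0, 0.05):
            params = ALIFParams(v_reset=0.0, inc_n=inc, tau_n=1000.0)
            state = NeuronPopulationState.zeros(1)
            c = 0
            for _ in range(n_steps):
                state, spikes = step_alif(state, params, drive, dt)
                c += int(spikes[0])
            counts[inc] = c
        assert counts[0.05] < counts[0.0]

    def test_zero_increment_matches_lif(self):
        alif = ALIFParams(v_reset=-1.0, inc_n=0.0)
        lif = LIFParams(v_reset=-1.0)
        sa = NeuronPopulationState.zeros(3)
        sl = NeuronPopulationState.zeros(3)
        drive = np.array([0.3, 1.4, 2.5])
        for _ in range(100):
            sa, spa = step_alif(sa, alif, drive, dt=5.0)
            sl, spl = step_lif(sl, lif, drive, dt=5.0)
            assert np.array_equal(spa, spl)
        assert np.array_equal(sa.v, sl.v)


class TestClamp:
    def test_clamp_pins_to_zero_and_ignores_drive(self):
        params = LIFParams()
        state = NeuronPopulationState.zeros(2, v0=0.7)
        state = apply_clamp(state, np.array([True, False]), duration=10.0)
        assert state.v[0] == 0.0
        state, spikes = step_lif(state, params, np.array([100.0, 0.0]), dt=5.0)
        assert not spikes[0]
        assert state.v[0] == 0.0

    def test_clamp_expires_after_duration(self):
        params = LIFParams()
        state = NeuronPopulationState.zeros(1)
        state = apply_clamp(state, np.array([True]), duration=10.0)
        for _ in range(2):
            state, _ = step_lif(state, params, np.array([0.5]), dt=5.0)
        assert state.clamp_remaining[0] == 0.0
        state, _ = step_lif(state, params, np.array([0.5]), dt=5.0)
        assert state.v[0] > 0.0  # integrating again

    def test_clamp_overrides_refractoriness_and_timers_run_concurrently(self):
        params = LIFParams(t_ref=15.0)
        state = NeuronPopulationState.zeros(1, v0=2.0)
        state, spikes = step_lif(state, params, np.array([0.0]), dt=5.0)
        assert spikes[0] and state.refrac_remaining[0] == 15.0
        state = apply_clamp(state, np.array([True]), duration=10.0)
        state, _ = step_lif(state, params, np.array([0.0]), dt=5.0)
        assert state.v[0] == 0.0  # clamp wins over the refractory hold at v_reset
        assert state.refrac_remaining[0] == 10.0  # still decremented

    def test_negative_duration_raises(self):
        state = NeuronPopulationState.zeros(1)
        with pytest.raises(ConfigurationError):
            apply_clamp(state, np.array([True]), duration=-1.0)


class TestValidation:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ConfigurationError):
            LIFParams(tau_m=0.0)
        with pytest.raises(ConfigurationError):
            LIFParams(t_ref=-1.0)
        with pytest.raises(ConfigurationError):
            LIFParams(v_reset=2.0)  # above threshold
        with pytest.raises(ConfigurationError):
            ALIFParams(inc_n=-0.1)
        with pytest.raises(ConfigurationError):
            ALIFParams(tau_n=0.0)
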