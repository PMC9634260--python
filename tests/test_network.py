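"""Two-layer WTA network: winner semantics, kernel equivalence, checkpoints."""

import numpy as np
import pytest

from vdspnet.encoding import EncodedSample, EncoderConfig, encode_poisson
from vdspnet.network import Network, NetworkConfig, NumericalError
from vdspnet.neurons import ALIFParams, ConfigurationError, LIFParams
from vdspnet.plasticity import VDSPParams, WeightMatrix


def small_config(**overrides) -> NetworkConfig:
    defaults = dict(
        n_in=16,
        n_out=4,
        dt=5.0,
        present_ms=350.0,
        inhibit_ms=10.0,
        rule="vdsp",
        seed=0,
        input_params=LIFParams(bias=0.5),
        # gain sized for this 16-pixel toy network (~8 active inputs, vs ~30
        # in the 100-pixel task where 4.0 is the operating point)
        output_params=ALIFParams(v_reset=0.0, bias=0.0, gain=16.0),
        vdsp=VDSPParams(lr=5e-2),
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


def strong_drive(n_in: int) -> np.ndarray:
    drive = np.zeros(n_in)
    drive[: n_in // 2] = 1.0
    return drive


class TestWinnerTakeAll:
    def test_at_most_one_output_spike_per_step(self):
        net = Network(small_config())
        drive = strong_drive(16)
        for _ in range(400):
            _, out_spikes = net.step(drive, learn=True)
            assert out_spikes.sum() <= 1

    def test_losers_clamped_after_winner_spike(self):
        net = Network(small_config())
        drive = strong_drive(16)
        for _ in range(400):
            _, out_spikes = net.step(drive)
            if out_spikes.any():
                w = int(np.argmax(out_spikes))
                losers = np.arange(4) != w
                assert np.all(net.output_state.v[losers] == 0.0)
                assert np.all(net.output_state.clamp_remaining[losers] == 10.0)
                break
        else:
            pytest.fail("no output spike in 400 steps")

    def test_tie_breaks_to_lowest_index(self):
        # identical weight columns and no adaptation -> potentials stay tied
        # whenever all neurons are eligible, so index 0 wins every round
        cfg = small_config(
            seed=1,
            output_params=ALIFParams(v_reset=0.0, bias=0.0, gain=16.0, inc_n=0.0),
        )
        W = WeightMatrix(np.full((16, 4), 0.8))
        net = Network(cfg, weights=W)
        drive = strong_drive(16)
        winners = []
        for _ in range(200):
            _, out_spikes = net.step(drive)
            if out_spikes.any():
                winners.append(int(np.argmax(out_spikes)))
        assert winners and set(winners) == {0}


class TestKernelEquivalence:
    def test_step_and_run_sample_are_bit_identical(self):
        drive = strong_drive(16) * 0.8
        sample = EncodedSample(drive=drive, label=0, duration=350.0)
        net_a = Network(small_config())
        net_b = Network(small_config())
        counts_a = net_a.run_sample(sample, learn=True)
        counts_b = np.zeros(4, dtype=np.int64)
        for _ in range(int(350.0 / 5.0)):
            _, out_spikes = net_b.step(drive, learn=True)
            counts_b += out_spikes
        assert np.array_equal(counts_a, counts_b)
        assert np.array_equal(net_a.weights.w, net_b.weights.w)
        assert np.array_equal(net_a.input_state.v, net_b.input_state.v)
        assert np.array_equal(net_a.output_state.v, net_b.output_state.v)
        assert np.array_equal(net_a.syn_current, net_b.syn_current)

    def test_state_carries_over_between_samples(self):
        net = Network(small_config())
        sample = EncodedSample(drive=strong_drive(16), label=0, duration=350.0)
        net.run_sample(sample)
        assert net.clock == 350.0
        assert np.any(net.input_state.v != net.config.input_params.v_rest)
        net.run_sample(sample)
        assert net.clock == 700.0


class TestLearning:
    def test_frozen_weights_without_learning(self):
        net = Network(small_config())
        before = net.weights.w.copy()
        net.run_sample(EncodedSample(drive=strong_drive(16), label=0, duration=700.0))
        assert np.array_equal(net.weights.w, before)

    def test_vdsp_separates_active_from_background_synapses(self):
        net = Network(small_config())
        drive = strong_drive(16)
        sample = EncodedSample(drive=drive, label=0, duration=350.0)
        counts = np.zeros(4, dtype=np.int64)
        for _ in range(40):
            counts += net.run_sample(sample, learn=True)
        winner = int(np.argmax(counts))
        active = net.weights.w[:8, winner]
        background = net.weights.w[8:, winner]
        assert active.mean() > 0.9
        assert background.mean() < 0.1

    def test_weights_stay_in_bounds_during_training(self):
        net = Network(small_config())
        rng = np.random.default_rng(0)
        for _ in range(30):
            drive = rng.uniform(0, 1, 16)
            net.run_sample(EncodedSample(drive=drive, label=0, duration=350.0), learn=True)
            assert net.weights.w.min() >= 0.0
            assert net.weights.w.max() <= 1.0

    def test_stdp_rule_updates_weights(self):
        net = Network(small_config(rule="stdp"))
        before = net.weights.w.copy()
        sample = EncodedSample(drive=strong_drive(16), label=0, duration=700.0)
        net.run_sample(sample, learn=True)
        assert not np.array_equal(net.weights.w, before)
        assert net.weights.w.min() >= 0.0 and net.weights.w.max() <= 1.0

    def test_raster_input_drives_and_learns(self):
        cfg = small_config()
        net = Network(cfg)
        px = np.zeros(16)
        px[:8] = 255.0
        enc = EncoderConfig(poisson_max_rate=60.0)
        before = net.weights.w.copy()
        total = 0
        for k in range(30):
            s = encode_poisson(px, 350.0, cfg.dt, enc, rng=k)
            total += int(net.run_sample(s, learn=True).sum())
        assert total > 0
        assert not np.array_equal(net.weights.w, before)


class TestDeterminismAndErrors:
    def test_identical_seeds_identical_runs(self):
        results = []
        for _ in range(2):
            net = Network(small_config(seed=5))
            counts = net.run_sample(
                EncodedSample(drive=strong_drive(16), label=0, duration=700.0),
                learn=True,
            )
            results.append((counts, net.weights.w.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])

    def test_nonfinite_drive_raises_numerical_error(self):
        net = Network(small_config())
        bad = np.zeros(16)
        bad[0] = np.inf
        with pytest.raises(NumericalError):
            net.run_sample(EncodedSample(drive=bad, label=0, duration=350.0))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            small_config(inhibit_ms=7.0)  # not a multiple of dt
        with pytest.raises(ConfigurationError):
            small_config(rule="hebb")
        with pytest.raises(ConfigurationError):
            small_config(n_out=0)
        with pytest.raises(ConfigurationError):
            Network(small_config(), weights=WeightMatrix(np.zeros((3, 3))))

    def test_drive_shape_mismatch_raises(self):
        net = Network(small_config())
        with pytest.raises(ConfigurationError):
            net.step(np.zeros(5))
        with pytest.raises(ConfigurationError):
            net.run_sample(EncodedSample(drive=np.zeros(5), label=0, duration=350.0))


class TestCheckpoint:
    def test_roundtrip_resumes_bit_identically(self, tmp_path):
        sample = EncodedSample(drive=strong_drive(16) * 0.9, label=0, duration=350.0)
        net = Network(small_config(seed=2))
        net.run_sample(sample, learn=True)
        net.save(tmp_path / "ckpt.npz")
        restored = Network.load(tmp_path / "ckpt.npz")
        assert restored.clock == net.clock
        a = net.run_sample(sample, learn=True)
        b = restored.run_sample(sample, learn=True)
        assert np.array_equal(a, b)
        assert np.array_equal(net.weights.w, restored.weights.w)
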