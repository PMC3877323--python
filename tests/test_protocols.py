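"""Training/testing protocols: calibration, pairing, propagation, ablation."""

from dataclasses import replace

import numpy as np
import pytest

import stdpnet as sn
from stdpnet import (
    CalibrationError,
    ConnectivityConfig,
    GeometryConfig,
    NeuronParams,
    StdpParams,
    SynapseParams,
    TrainingProtocol,
    ablate,
    calibrate_pulse_amplitude,
    generate_network,
    resolve_training,
    stdp_kernel,
    train_network,
    train_pair,
)
from stdpnet import TestProtocol as PropagationProbe
from stdpnet import test_propagation as run_propagation_test
from stdpnet.network_model import class_mask

from conftest import pair_network


@pytest.fixture(scope="module")
def scaled_net():
    """Small trained-ready lattice shared by the protocol tests."""
    geometry = GeometryConfig(10, 5)
    connectivity = ConnectivityConfig(k=0.3, lambda_c=geometry.layer_spacing)
    return generate_network(geometry, connectivity, seed=11)


class TestCalibration:
    def test_matches_closed_form_threshold(self, neuron, synapse):
        """Grid calibration agrees with the analytic minimal amplitude.

        An isolated neuron under constant I fires within t_d iff
        I (1 - exp(-t_d/tau)) >= v_th - v_rest; the smallest 1-mV grid value
        satisfying that is the calibrated amplitude.
        """
        t_d = 5.0
        i_min = (neuron.v_th - neuron.v_rest) / (1 - np.exp(-t_d / neuron.tau_m))
        expected = float(np.ceil(i_min))
        assert calibrate_pulse_amplitude(neuron, synapse, t_d) == expected

    def test_resolve_training_fills_amplitude(self, neuron, synapse, scaled_net):
        tr = resolve_training(TrainingProtocol(), scaled_net, neuron, synapse)
        assert tr.i_s is not None and tr.i_s > 0

    def test_unset_amplitude_rejected_by_train_pair(self, neuron, synapse, scaled_net):
        with pytest.raises(ValueError):
            train_pair(scaled_net.copy(), 1, TrainingProtocol(), neuron, synapse, StdpParams())


class TestTrainPair:
    def test_two_neuron_weight_change_equals_kernel_at_realized_lags(self, neuron, synapse):
        """On an isolated reciprocal pair, one pulse pair changes the weights by
        exactly the STDP kernel evaluated at the spike-time differences read
        off the raster."""
        p = StdpParams()
        net = pair_network(0.5, 0.5)
        tr = resolve_training(
            TrainingProtocol(delta_t=10.0, n_trials=1), net, neuron, synapse, verify_layer=1
        )
        raster = train_pair(net, 1, tr, neuron, synapse, p)
        t_pre = raster.times[raster.neurons == 0]
        t_post = raster.times[raster.neurons == 1]
        assert len(t_pre) == 1 and len(t_post) == 1
        lag = float(t_post[0] - t_pre[0])
        w_fwd = net.weights[(net.pre == 0) & (net.post == 1)][0]
        w_bwd = net.weights[(net.pre == 1) & (net.post == 0)][0]
        assert w_fwd == pytest.approx(0.5 + stdp_kernel(lag, p), abs=1e-12)
        assert w_bwd == pytest.approx(0.5 + stdp_kernel(-lag, p), abs=1e-12)

    def test_huge_interval_leaves_interlayer_weights_untouched(self, neuron, synapse):
        """At delta_t >> tau the pairing is negligible but recurrent synapses
        still potentiate through their synchronous volleys."""
        p = StdpParams()
        geometry = GeometryConfig(2, 5)
        connectivity = ConnectivityConfig(k=1.0, lambda_c=10.0)  # fully connected
        net = generate_network(geometry, connectivity, seed=0)
        w0 = net.weights.copy()
        tr = resolve_training(TrainingProtocol(delta_t=500.0, n_trials=1), net, neuron, synapse)
        train_pair(net, 1, tr, neuron, synapse, p)
        inter = class_mask(net, "feedforward") | class_mask(net, "feedback")
        rec = class_mask(net, "recurrent")
        assert np.max(np.abs(net.weights[inter] - w0[inter])) < 0.01 * p.a_plus
        assert np.all(net.weights[rec] >= w0[rec])
        assert np.any(net.weights[rec] > w0[rec])

    def test_training_confined_to_stimulated_layers(self, neuron, synapse, scaled_net):
        """The calibrated pulse drives no spikes outside the stimulated pair."""
        net = scaled_net.copy()
        tr = resolve_training(TrainingProtocol(delta_t=0.0), net, neuron, synapse)
        for l in (1, 5, 9):
            raster = train_pair(net, l, tr, neuron, synapse, StdpParams())
            layers = set(net.layer_of[raster.neurons].tolist())
            assert layers <= {l, l + 1}

    def test_pair_index_bounds(self, neuron, synapse, scaled_net):
        tr = TrainingProtocol(i_s=73.0)
        with pytest.raises(ValueError):
            train_pair(scaled_net.copy(), 10, tr, neuron, synapse, StdpParams())

    def test_silent_layer_raises_calibration_error(self, neuron, synapse, scaled_net):
        tr = TrainingProtocol(i_s=1.0)  # far too weak to fire anything
        with pytest.raises(CalibrationError):
            train_pair(scaled_net.copy(), 1, tr, neuron, synapse, StdpParams())


class TestTrainNetwork:
    def test_zero_trials_is_identity(self, neuron, synapse, scaled_net):
        net = scaled_net.copy()
        w0 = net.weights.copy()
        traj = train_network(net, TrainingProtocol(n_trials=0), neuron, synapse, StdpParams())
        np.testing.assert_array_equal(net.weights, w0)
        assert len(traj) == 1

    def test_training_is_deterministic(self, neuron, synapse, scaled_net):
        results = []
        for _ in range(2):
            net = scaled_net.copy()
            train_network(
                net, TrainingProtocol(delta_t=10.0, n_trials=3), neuron, synapse, StdpParams()
            )
            results.append(net.weights.copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_feedforward_grows_feedback_shrinks_toward_bounds(self, neuron, synapse, scaled_net):
        """Repeated short-interval training drives the class means apart."""
        net = scaled_net.copy()
        traj = train_network(
            net, TrainingProtocol(delta_t=0.0, n_trials=10), neuron, synapse, StdpParams()
        )
        ff = traj["feedforward_mean"].to_numpy()
        fb = traj["feedback_mean"].to_numpy()
        assert ff[-1] > ff[0] and fb[-1] < fb[0]
        assert np.all(np.diff(ff) >= -1e-12) and np.all(np.diff(fb) <= 1e-12)
        # late in training the trained (adjacent) part has saturated
        assert traj["recurrent_mean"].iloc[-1] > 0.9

    def test_symmetric_per_trial_conservation_before_saturation(self, neuron, synapse):
        """With symmetric STDP the feedforward gain per sweep mirrors the
        feedback loss while both classes are off the bounds."""
        geometry = GeometryConfig(10, 5)
        connectivity = ConnectivityConfig(k=0.3, lambda_c=geometry.layer_spacing)
        net = generate_network(geometry, connectivity, seed=4)
        p = StdpParams(a_plus=0.02, a_minus=0.02)
        traj = train_network(
            net, TrainingProtocol(delta_t=10.0, n_trials=5), neuron, synapse, p
        )
        inc = np.diff(traj["feedforward_mean"])
        dec = -np.diff(traj["feedback_mean"])
        np.testing.assert_allclose(inc, dec, rtol=0.25)


class TestPropagation:
    def test_zero_interlayer_weights_give_zero_count(self, neuron, synapse, scaled_net):
        net = scaled_net.copy()
        inter = class_mask(net, "feedforward") | class_mask(net, "feedback")
        net.weights[inter] = 0.0
        res = run_propagation_test(net, PropagationProbe(i_t=200.0, target_layer=3), neuron, synapse)
        assert res.total_spikes == 0
        assert res.per_layer[2] > 0  # the driven layer itself fires

    def test_count_non_decreasing_in_amplitude(self, neuron):
        """S is non-decreasing in the steady test amplitude on a fixed network."""
        preset = sn.propagation_preset(20.0)
        net = sn.generate_network(preset.geometry, preset.connectivity, 2)
        tr = resolve_training(preset.training, net, preset.neuron, preset.synapse)
        train_network(net, tr, preset.neuron, preset.synapse, preset.stdp)
        counts = [
            run_propagation_test(
                net, replace(preset.test, i_t=i_t), preset.neuron, preset.synapse
            ).total_spikes
            for i_t in (730.0, 900.0, 1200.0)
        ]
        assert counts == sorted(counts)
        assert counts[-1] > 0

    def test_target_layer_validated(self, neuron, synapse, scaled_net):
        with pytest.raises(ValueError):
            run_propagation_test(scaled_net, PropagationProbe(i_t=100.0, target_layer=99), neuron, synapse)


class TestAblate:
    def test_drop_feedback_only(self, scaled_net):
        out = ablate(scaled_net, "feedback")
        assert class_mask(out, "feedback").sum() == 0
        for cls in ("feedforward", "recurrent"):
            assert class_mask(out, cls).sum() == class_mask(scaled_net, cls).sum()

    def test_idempotent(self, scaled_net):
        once = ablate(scaled_net, "both")
        twice = ablate(once, "both")
        assert once.n_synapses == twice.n_synapses
        np.testing.assert_array_equal(once.weights, twice.weights)

    def test_unknown_class_rejected(self, scaled_net):
        with pytest.raises(ValueError):
            ablate(scaled_net, "lateral")


class TestRecurrentInvariance:
    def test_recurrent_mean_independent_of_interval(self, neuron, synapse):
        """Recurrent modification is set by the stimulation time alone, not by
        the inter-stimulus interval (coefficient of variation < 5%)."""
        geometry = GeometryConfig(10, 5)
        connectivity = ConnectivityConfig(k=0.3, lambda_c=geometry.layer_spacing)
        base = generate_network(geometry, connectivity, seed=11)
        means = []
        for dT in (0.0, 20.0, 40.0, 60.0):
            net = base.copy()
            train_network(
                net,
                TrainingProtocol(delta_t=dT, n_trials=5),
                neuron,
                synapse,
                StdpParams(a_plus=0.02, a_minus=0.02),
            )
            means.append(net.weights[class_mask(net, "recurrent")].mean())
        means = np.array(means)
        assert means.std() / means.mean() < 0.05
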