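"""Event-driven simulation: closed forms, spike rules, oracle equivalence."""

import math

import numpy as np
import pytest

import burstclique as bc
from burstclique.dynamics import (
    StimulusProgram,
    apply_spike_to_synapse,
    natural_period,
    synapse_free_evolution,
)
from burstclique.reference import reference_simulate
from conftest import make_random_motif, single_neuron_net


class TestNaturalPeriod:
    @pytest.mark.parametrize(
        "i_b, expected",
        [
            (15.32, 30.0 * math.log((15.32 - 13.5) / (15.32 - 15.0))),
            (15.23, 30.0 * math.log((15.23 - 13.5) / (15.23 - 15.0))),
            (18.0, 30.0 * math.log(4.5 / 3.0)),
        ],
    )
    def test_closed_form(self, i_b, expected):
        assert natural_period(i_b) == pytest.approx(expected, rel=1e-12)

    def test_at_or_below_threshold_never_fires(self):
        assert natural_period(15.0) == np.inf
        assert natural_period(14.2) == np.inf

    def test_isolated_neuron_fires_at_its_period(self):
        net = single_neuron_net(15.32)
        spikes = bc.simulate(net, 500.0, seed=0, burn_in_ms=0.0,
                             v_init=np.array([13.5]))
        period = natural_period(15.32)
        assert spikes.n_spikes == int(500.0 // period)
        assert np.allclose(np.diff(spikes.times), period, atol=1e-8)

    def test_first_crossing_from_reset_with_strong_drive(self):
        # V from V_r under constant I=18 crosses at 30 ln(4.5/3) ~ 12.16 ms
        net = single_neuron_net(18.0)
        spikes = bc.simulate(net, 50.0, seed=0, burn_in_ms=0.0,
                             v_init=np.array([13.5]))
        assert spikes.times[0] == pytest.approx(30.0 * math.log(4.5 / 3.0), abs=1e-8)


class TestSynapseRules:
    def test_pure_decay_of_active_fraction(self):
        y, z, _ = synapse_free_evolution(1.0, 0.0, 3.0, t_i=3.0, t_r=800.0)
        assert y == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_conservation_under_free_evolution(self):
        y0, z0 = 0.3, 0.5
        for dt in (0.1, 5.0, 300.0):
            y, z, _ = synapse_free_evolution(y0, z0, dt, t_i=3.0, t_r=800.0)
            x = 1.0 - y - z
            assert 0.0 <= y <= 1.0 and 0.0 <= z <= 1.0 and 0.0 <= x <= 1.0

    def test_two_exponential_inactive_solution(self):
        # check Z against a tiny explicit Euler integration
        y0, z0, ti, tr = 0.8, 0.1, 3.0, 100.0
        y, z = y0, z0
        dt = 1e-5
        for _ in range(int(5.0 / dt)):
            y, z = y + dt * (-y / ti), z + dt * (y / ti - z / tr)
        yc, zc, _ = synapse_free_evolution(y0, z0, 5.0, t_i=ti, t_r=tr)
        assert zc == pytest.approx(z, abs=1e-4)
        assert yc == pytest.approx(y, abs=1e-4)

    def test_depressing_release(self):
        y, z, u = apply_spike_to_synapse(0.0, 0.0, 0.5, 0.5, facilitating=False)
        assert y == pytest.approx(0.5) and u == 0.5

    def test_facilitation_update_then_use(self):
        # first spike at u = U = 0.04: u -> 0.04 + 0.04*0.96 = 0.0784 before release
        y, z, u = apply_spike_to_synapse(0.0, 0.0, 0.04, 0.04, facilitating=True)
        assert u == pytest.approx(0.0784, rel=1e-12)
        assert y == pytest.approx(0.0784, rel=1e-12)

    def test_release_conserves_total(self):
        y, z, u = apply_spike_to_synapse(0.2, 0.3, 0.5, 0.5, facilitating=False)
        assert y + z <= 1.0 and y == pytest.approx(0.2 + 0.5 * 0.5)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 4])
    def test_spike_times_match_fixed_step_integrator(self, seed):
        n = 6 if seed == 0 else 5
        net = make_random_motif(n, seed)
        v0 = 13.5 + 1.4 * np.random.default_rng(seed + 50).random(n)
        ed = bc.simulate(net, 1000.0, seed=0, burn_in_ms=0.0, v_init=v0)
        rt, ri, w = reference_simulate(net, 1000.0, v0, dt_ms=1e-3)
        assert ed.n_spikes == len(rt)
        assert np.array_equal(ed.ids, ri)
        assert np.max(np.abs(ed.times - rt)) < 1e-3
        # synaptic fractions stay physical in the independent integrator
        E = net.n_edges
        y, z = w[n:n + E], w[n + E:n + 2 * E]
        assert np.all(y >= -1e-10) and np.all(z >= -1e-10)
        assert np.all(y + z <= 1.0 + 1e-10)


class TestSimulationContracts:
    def test_deterministic_for_fixed_seed(self):
        net = bc.generate_fixture("gate")
        a = bc.simulate(net, 2000.0, seed=5, burn_in_ms=500.0)
        b = bc.simulate(net, 2000.0, seed=5, burn_in_ms=500.0)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.ids, b.ids)

    def test_reset_noise_perturbs_spike_times(self):
        net = bc.generate_fixture("gate")
        quiet = bc.simulate(net, 2000.0, seed=5, burn_in_ms=500.0)
        noisy = bc.simulate(net, 2000.0,
                            program=StimulusProgram(noise_delta=0.5),
                            seed=5, burn_in_ms=500.0)
        assert not np.array_equal(quiet.times, noisy.times)

    def test_noise_bound_validation(self):
        with pytest.raises(ValueError):
            StimulusProgram(noise_delta=2.0).validate(3)
        with pytest.raises(ValueError):
            StimulusProgram(deletions=(9,)).validate(3)
        with pytest.raises(ValueError):
            StimulusProgram(dc_steps=((0, 1.0, 10.0, 5.0),)).validate(3)

    def test_deleted_neuron_never_fires(self):
        net = bc.generate_fixture("pair_entrain")
        sd = bc.simulate(net, 2000.0, program=StimulusProgram(deletions=(0,)),
                         seed=1, burn_in_ms=500.0)
        assert sd.spikes_of(0).size == 0
        assert sd.spikes_of(1).size == 0  # its follower loses all drive

    def test_dc_step_sets_firing_rate(self):
        net = single_neuron_net(14.0)  # silent in control
        program = StimulusProgram(dc_steps=((0, 4.0, 0.0, 1000.0),))  # I -> 18 mV
        sd = bc.simulate(net, 1000.0, program=program, seed=0, burn_in_ms=200.0)
        expected = 1000.0 / natural_period(18.0)
        assert sd.rate(0) == pytest.approx(expected, abs=1.5)

    def test_entrainment_pair_locks_one_to_one(self):
        net = bc.generate_fixture("pair_entrain")
        sd = bc.simulate(net, 3000.0, seed=2, burn_in_ms=1000.0)
        n_driver = sd.spikes_of(0).size
        n_follower = sd.spikes_of(1).size
        assert n_driver > 40
        assert abs(n_follower - n_driver) <= 1

    def test_empty_window_rejected(self):
        net = single_neuron_net(15.2)
        with pytest.raises(ValueError):
            bc.simulate(net, 0.0, seed=0)
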