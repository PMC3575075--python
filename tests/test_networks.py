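"""Structural checks for the six network builders."""

import numpy as np
import pytest

from spikesim.substrate import SubstrateConfig, enforce_shared_parameters
from spikesim.networks import (build_antennal_lobe, build_attractor, build_brn,
                               build_lsm, build_swta, build_synfire)
from spikesim.networks.swta import ring_distance


class TestSynfire:
    def test_filter_variant_sizes(self):
        net, info = build_synfire("filter", seed=0)
        assert info.n_groups == 3
        assert net.n_neurons == 3 * (45 + 18) == 189

    def test_original_in_degrees_are_exact(self):
        net, info = build_synfire("original", n_groups=3, seed=1)
        W = net.weight_matrix()
        rs1 = info.rs_groups[1]
        d_rs0 = [d for nid in info.rs_groups[0] for d in net.drivers_of_neuron(int(nid))]
        fan = (W[np.ix_(d_rs0, rs1)] > 0).sum(axis=0)
        assert np.all(fan == 60)
        # each RS also draws exactly 25 inputs from its local FS population
        d_fs1 = [d for nid in info.fs_groups[1] for d in net.drivers_of_neuron(int(nid))]
        fan_fs = (W[np.ix_(d_fs1, rs1)] > 0).sum(axis=0)
        assert np.all(fan_fs == 25)

    def test_loop_closes_ring_and_fits_chip(self):
        net, info = build_synfire("loop", seed=0)
        assert net.n_neurons == 192
        W = net.weight_matrix()
        d_last = [d for nid in info.rs_groups[-1][:1]
                  for d in net.drivers_of_neuron(int(nid))]
        # the last group's RS axons reach group 0
        assert (W[np.ix_(d_last, info.rs_groups[0])] > 0).any()
        report = enforce_shared_parameters(net, SubstrateConfig())
        assert report.violations == []

    def test_builders_are_deterministic(self):
        a = build_synfire("original", n_groups=3, seed=5)[0].weight_matrix()
        b = build_synfire("original", n_groups=3, seed=5)[0].weight_matrix()
        assert np.array_equal(a, b)


class TestBRN:
    def test_population_sizes_and_downscale_factor(self):
        net, info = build_brn(seed=0)
        assert info.exc.size == 100 and info.inh.size == 25
        assert 12_500 // (info.exc.size + info.inh.size) == 100

    def test_projection_counts_binomial(self):
        net, info = build_brn(seed=2)
        W = net.weight_matrix()
        d_exc = [net.drivers_of_neuron(int(n))[0] for n in info.exc]
        n_syn = (W[np.ix_(d_exc, info.inh)] > 0).sum()
        expected = 100 * 25 * 0.1
        sd = np.sqrt(expected * 0.9)
        assert abs(n_syn - expected) < 4 * sd

    def test_inhibition_four_times_excitation(self):
        net, info = build_brn(seed=0)
        d_e = net.drivers_of_neuron(int(info.exc[0]))[0]
        d_i = net.drivers_of_neuron(int(info.inh[0]))[0]
        assert net.driver_g_max[d_i] / net.driver_g_max[d_e] == pytest.approx(4.0)

    def test_excitatory_efferents_are_depressing(self):
        net, info = build_brn(seed=0)
        d_e = net.drivers_of_neuron(int(info.exc[0]))[0]
        d_i = net.drivers_of_neuron(int(info.inh[0]))[0]
        assert net.driver_stp[d_e].mode == "depressing"
        assert net.driver_stp[d_i].mode == "off"

    def test_fits_substrate(self):
        net, _ = build_brn(seed=0)
        assert enforce_shared_parameters(net, SubstrateConfig()).violations == []


class TestSWTA:
    def test_ring_distance_is_circular(self):
        assert ring_distance(0, 49, 50) == 1
        assert ring_distance(0, 25, 50) == 25
        assert ring_distance(13, 38, 50) == 25

    def test_stimulus_clipped_beyond_three_sigma(self):
        net, info = build_swta(seed=0)
        # neurons farther than 9 from a cone center receive no cone sources
        stimulated = set(info.cone1_sources) | set(info.cone2_sources)
        for i in range(50):
            near = min(ring_distance(i, 13), ring_distance(i, 38)) <= 9
            assert (i in stimulated) == near

    def test_recurrent_profile_symmetric(self):
        net, info = build_swta(seed=0)
        W = net.weight_matrix()
        d_of = {int(n): net.drivers_of_neuron(int(n))[0] for n in info.exc}
        for i, j in [(0, 5), (10, 14), (40, 48)]:
            wij = W[d_of[int(info.exc[i])], info.exc[j]]
            wji = W[d_of[int(info.exc[j])], info.exc[i]]
            assert wij == pytest.approx(wji)

    def test_fits_substrate(self):
        net, _ = build_swta(seed=0)
        assert enforce_shared_parameters(net, SubstrateConfig()).violations == []


class TestAttractor:
    def test_scaled_configuration_fits_chip(self):
        net, info = build_attractor(seed=0)
        assert net.n_neurons <= 192
        assert enforce_shared_parameters(net, SubstrateConfig()).violations == []

    def test_original_configuration_totals_2673(self):
        # 9 hypercolumns x 9 minicolumns x (30 pyr + 2 RSNP + 1 basket)
        assert 9 * 9 * (30 + 2 + 1) == 2673

    def test_patterns_are_orthogonal(self):
        _, info = build_attractor(seed=0)
        pats = info.patterns
        assert len(pats) == info.n_mc
        for p in range(len(pats)):
            for q in range(p + 1, len(pats)):
                assert not set(pats[p]) & set(pats[q])

    def test_rsnp_inhibits_only_its_own_minicolumn(self):
        net, info = build_attractor(seed=0)
        W = net.weight_matrix()
        d = net.drivers_of_neuron(int(info.rsnp[0][0][0]))[0]
        targets = np.nonzero(W[d])[0]
        assert set(targets) <= set(int(i) for i in info.pyr[0][0])


class TestAntennalLobe:
    def test_neuron_and_source_counts(self):
        net, info = build_antennal_lobe(seed=0)
        assert net.n_neurons == 10 * (7 + 3) == 100
        assert sum(len(s) for s in info.rn_sources) == 60

    def test_q_zero_removes_lateral_weights(self):
        net, info = build_antennal_lobe(seed=0, q=0.0)
        for d, n, _w in info.lateral_synapses:
            assert net.get_weight(d, n) == 0.0

    def test_ln_never_projects_to_own_glomerulus(self):
        net, info = build_antennal_lobe(seed=0, q=1.0)
        W = net.weight_matrix()
        for gi in range(10):
            own_pns = set(int(i) for i in info.pn_ids[gi])
            for ln in info.ln_ids[gi]:
                for d in net.drivers_of_neuron(int(ln)):
                    assert not (set(np.nonzero(W[d])[0]) & own_pns)

    def test_fits_substrate(self):
        net, _ = build_antennal_lobe(seed=0)
        assert enforce_shared_parameters(net, SubstrateConfig()).violations == []


class TestLSM:
    def test_liquid_size_and_split(self):
        net, info = build_lsm(seed=0)
        assert info.liquid.size == 191
        ratio = info.exc.size / 191
        assert abs(info.exc.size - 0.8 * 191) <= 1
        assert info.exc.size + info.inh.size == 191

    def test_every_neuron_has_exactly_four_inputs_per_source_group(self):
        net, info = build_lsm(seed=1)
        W = net.weight_matrix()
        d_se = [net.drivers_of_source(int(s))[0] for s in info.src_exc]
        d_si = [net.drivers_of_source(int(s))[0] for s in info.src_inh]
        for nid in info.liquid:
            assert (W[d_se, nid] > 0).sum() == 4
            assert (W[d_si, nid] > 0).sum() == 4

    def test_fits_substrate(self):
        net, _ = build_lsm(seed=0)
        assert enforce_shared_parameters(net, SubstrateConfig()).violations == []
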