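"""Generator-level tests: topologies, cascades, indicator, puncta, ventral roots."""

import numpy as np
import networkx as nx
import pytest

from neurophen.events import EventRaster
from neurophen.simulate import (
    CascadeParams,
    IndicatorParams,
    PunctaSceneSpec,
    TopologySpec,
    VRSimSpec,
    build_topology,
    generate_cluster_set,
    generate_full_sync_benchmark,
    generate_puncta_scene,
    generate_vr_traces,
    render_puncta_scene,
    simulate_cascades,
    spikes_to_fluorescence,
)
from neurophen.synchrony import synchronous_groups


class TestTopology:
    @pytest.mark.parametrize(
        "spec, n_edges",
        [
            (TopologySpec(4, "complete"), 6),  # n(n-1)/2
            (TopologySpec(10, "random", edge_prob=0.0), 0),
            (TopologySpec(20, "scale_free", attachment_m=1), 19),  # tree: n-1 edges
        ],
    )
    def test_edge_counts(self, spec, n_edges):
        adjacency = build_topology(spec)
        assert adjacency.sum() // 2 == n_edges

    def test_preferential_attachment_tree_is_connected(self):
        adjacency = build_topology(TopologySpec(20, "scale_free", attachment_m=1, seed=5))
        assert nx.is_connected(nx.from_numpy_array(adjacency))

    @pytest.mark.parametrize(
        "kind, kwargs",
        [
            ("scale_free", dict(attachment_m=2)),
            ("random", dict(edge_prob=0.4)),
            ("small_world", dict(ring_degree=4, rewire_beta=0.2)),
            ("complete", {}),
        ],
    )
    def test_adjacency_invariants(self, kind, kwargs):
        adjacency = build_topology(TopologySpec(12, kind, seed=3, **kwargs))
        assert np.array_equal(adjacency, adjacency.T)
        assert set(np.unique(adjacency)) <= {0, 1}
        assert np.all(np.diag(adjacency) == 0)

    def test_same_seed_identical(self):
        spec = TopologySpec(15, "small_world", ring_degree=4, rewire_beta=0.3, seed=9)
        assert np.array_equal(build_topology(spec), build_topology(spec))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_neurons=1, kind="complete"),
            dict(n_neurons=5, kind="scale_free", attachment_m=5),
            dict(n_neurons=8, kind="small_world", ring_degree=3),
            dict(n_neurons=8, kind="random", edge_prob=1.5),
        ],
    )
    def test_invalid_specs_raise(self, bad):
        with pytest.raises(ValueError):
            TopologySpec(**bad)


class TestCascades:
    def test_silenced_network_is_empty(self):
        adjacency = build_topology(TopologySpec(10, "complete"))
        params = CascadeParams(spontaneous_rate=0.0, transmission_prob=0.0)
        assert simulate_cascades(adjacency, params, seed=0).sum() == 0

    def test_forced_spike_propagates_on_complete_graph(self):
        adjacency = build_topology(TopologySpec(6, "complete"))
        params = CascadeParams(
            spontaneous_rate=0.0, transmission_prob=1.0, refractory_frames=10_000
        )
        raster = simulate_cascades(adjacency, params, seed=0, seed_spikes=[(0, 0)])
        assert raster[0, 0] == 1
        assert np.all(raster[1:, 1] == 1)  # full next-frame recruitment
        assert raster.sum() == 6  # refractory forbids any further firing

    def test_spontaneous_rate_matches_renewal_expectation(self):
        # With transmission off, each neuron is a Bernoulli process of
        # per-frame rate p = 1-exp(-rate*dt), thinned by the 1-frame
        # refractory period: expected total over T frames is
        # n * T * p / (1 + p * refractory) = 119.4 for these settings
        # (vs 120 for the pure Poisson count).
        adjacency = np.zeros((20, 20), dtype=np.uint8)
        params = CascadeParams(
            spontaneous_rate=0.05, transmission_prob=0.0, refractory_frames=1
        )
        totals = [simulate_cascades(adjacency, params, seed=s).sum() for s in range(50)]
        poisson_mean = 20 * 0.05 * 120.0
        sigma_of_mean = np.sqrt(poisson_mean / 50)
        assert abs(np.mean(totals) - poisson_mean) < 3 * sigma_of_mean

    def test_every_transmitted_spike_has_a_firing_neighbor(self):
        adjacency = build_topology(TopologySpec(12, "random", edge_prob=0.5, seed=2))
        params = CascadeParams(spontaneous_rate=0.0, transmission_prob=0.5)
        raster = simulate_cascades(
            adjacency, params, seed=4, seed_spikes=[(0, 0), (3, 100), (7, 600)]
        )
        forced = {(0, 0), (3, 100), (7, 600)}
        for i, t in zip(*np.nonzero(raster)):
            if (i, t) in forced:
                continue
            assert t > 0 and adjacency[i] @ raster[:, t - 1] > 0

    def test_refractory_enforced(self):
        adjacency = build_topology(TopologySpec(8, "complete"))
        params = CascadeParams(
            spontaneous_rate=5.0, transmission_prob=1.0, refractory_frames=10
        )
        raster = simulate_cascades(adjacency, params, seed=1)
        for row in raster:
            gaps = np.diff(np.flatnonzero(row))
            assert gaps.size == 0 or gaps.min() > 10

    def test_determinism_and_asymmetry_error(self):
        adjacency = build_topology(TopologySpec(10, "random", edge_prob=0.3, seed=1))
        params = CascadeParams()
        a = simulate_cascades(adjacency, params, seed=11)
        b = simulate_cascades(adjacency, params, seed=11)
        assert np.array_equal(a, b)
        bad = adjacency.copy()
        bad[0, 1], bad[1, 0] = 1, 0
        with pytest.raises(ValueError):
            simulate_cascades(bad, params, seed=0)


class TestIndicator:
    def test_empty_raster_gives_constant_baseline(self):
        raster = np.zeros((3, 100), dtype=np.uint8)
        rec = spikes_to_fluorescence(raster, IndicatorParams(noise_sd=0.0))
        assert np.allclose(rec.values, 100.0)

    def test_single_spike_closed_form(self):
        params = IndicatorParams(noise_sd=0.0)
        raster = np.zeros((2, 200), dtype=np.uint8)
        raster[0, 50] = 1
        rec = spikes_to_fluorescence(raster, params, dt_s=0.1)
        dff = rec.values / params.baseline_f0 - 1.0
        k = np.arange(150)
        expected = params.spike_amplitude * np.exp(-k * 0.1 / params.decay_tau_s)
        assert np.allclose(dff[0, 50:], expected)
        assert np.allclose(dff[0, :50], 0.0)
        assert np.allclose(dff[1], 0.0)

    def test_transients_sum_linearly(self):
        params = IndicatorParams(noise_sd=0.0)
        one = np.zeros((2, 300), dtype=np.uint8)
        two = one.copy()
        one[0, 40] = 1
        other = np.zeros_like(one)
        other[0, 60] = 1
        two[0, 40] = two[0, 60] = 1
        f = lambda r: spikes_to_fluorescence(r, params).values / params.baseline_f0 - 1
        assert np.allclose(f(two), f(one) + f(other))

    def test_noise_seed_determinism(self):
        raster = np.zeros((2, 50), dtype=np.uint8)
        a = spikes_to_fluorescence(raster, IndicatorParams(noise_sd=0.1), seed=3)
        b = spikes_to_fluorescence(raster, IndicatorParams(noise_sd=0.1), seed=3)
        assert np.array_equal(a.values, b.values)


class TestClusterSets:
    @pytest.mark.parametrize("n_clusters, mode", [(6, "control_like"), (5, "mutant_like")])
    def test_set_shapes(self, n_clusters, mode):
        samples = generate_cluster_set(n_clusters, mode, (9, 25), seed=1)
        assert len(samples) == n_clusters
        for s in samples:
            assert 9 <= s.recording.n_neurons <= 25
            assert s.recording.n_frames == 1200
            assert s.truth_raster.onsets.shape == s.recording.values.shape
            assert s.adjacency.shape == (s.recording.n_neurons,) * 2

    def test_boundary_single_cluster(self):
        (sample,) = generate_cluster_set(1, "control_like", (9, 9), seed=0)
        assert sample.recording.n_neurons == 9

    def test_zero_clusters_raises(self):
        with pytest.raises(ValueError):
            generate_cluster_set(0, "control_like")

    def test_set_determinism(self):
        a = generate_cluster_set(3, "mutant_like", seed=5)
        b = generate_cluster_set(3, "mutant_like", seed=5)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.recording.values, sb.recording.values)
            assert np.array_equal(sa.truth_raster.onsets, sb.truth_raster.onsets)

    def test_full_sync_benchmark_ground_truth(self, benchmark_set):
        samples, labels = benchmark_set
        assert labels.sum() == 21 and len(samples) == 35
        for sample, label in zip(samples, labels):
            sizes = synchronous_groups(sample.truth_raster)
            n = sample.truth_raster.n_neurons
            assert (max(sizes) == n) == label


class TestPunctaScenes:
    def test_full_colocalization_by_construction(self):
        spec = PunctaSceneSpec(n_pairs=4, coloc_fraction=1.0, seed=3)
        scene = generate_puncta_scene(spec)
        assert len(scene.true_pairs) == len(scene.spots_a)
        for ia, ib in scene.true_pairs:
            dist = np.hypot(*(scene.spots_a[ia] - scene.spots_b[ib]))
            assert dist <= spec.coloc_jitter_um + 1e-9

    def test_sixteen_ground_truth_pairs(self):
        scene = generate_puncta_scene(PunctaSceneSpec(n_pairs=16, seed=1))
        assert len(scene.polylines_a) == len(scene.polylines_b) == 16

    def test_chance_overlap_matches_1d_formula(self):
        # With no true partners, the expected number of B spots within radius
        # r of an A spot on a parallel line at separation d is the 1-D overlap
        # 2*sqrt(r^2-d^2)*density_B; totals over 50 seeds stay within 4 sigma.
        r, d, lam = 0.5, 0.3, 0.05
        total, n_a = 0, 0
        from neurophen.puncta import count_colocalized

        for seed in range(50):
            spec = PunctaSceneSpec(
                n_pairs=8,
                puncta_per_um=lam,
                coloc_fraction=0.0,
                pair_separation_um=d,
                lateral_jitter_um=0.0,
                seed=seed,
            )
            scene = generate_puncta_scene(spec)
            total += count_colocalized(scene.spots_a, scene.spots_b, r)
            n_a += len(scene.spots_a)
        expected = n_a * 2 * np.sqrt(r**2 - d**2) * lam
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError):
            generate_puncta_scene(
                PunctaSceneSpec(n_pairs=40, field_um=50, pair_length_um=40, seed=0)
            )

    def test_scene_determinism_and_rendering(self):
        spec = PunctaSceneSpec(n_pairs=3, seed=8)
        a, b = generate_puncta_scene(spec), generate_puncta_scene(spec)
        assert np.array_equal(a.spots_a, b.spots_a)
        assert np.array_equal(a.spots_b, b.spots_b)
        stack = render_puncta_scene(a)
        assert stack.shape[0] == 2 and stack.min() >= 0
        # total deposited mass is preserved by the Gaussian blur
        assert np.isclose(stack[0].sum(), len(a.spots_a), rtol=1e-3)


class TestVentralRoot:
    def test_alternating_truth_phases(self):
        _, truth = generate_vr_traces(VRSimSpec(mode="alternating", noise_sd=0.0))
        assert np.allclose(truth.phases, 0.5)

    def test_synchronous_truth_phases(self):
        _, truth = generate_vr_traces(VRSimSpec(mode="synchronous", noise_sd=0.0))
        assert np.allclose(truth.phases, 0.0)

    def test_silent_mode_has_no_bursts(self):
        pair, truth = generate_vr_traces(VRSimSpec(mode="silent", seed=2))
        assert truth.left_bursts == [] and truth.right_bursts == []
        assert np.std(pair.left) < 0.2  # baseline noise only

    def test_arrhythmic_phases_are_circular_uniform(self):
        # Rayleigh test (pingouin) should fail to reject uniformity at the 5%
        # level for the vast majority of seeds.
        import pingouin as pg

        not_rejected = 0
        for seed in range(50):
            _, truth = generate_vr_traces(VRSimSpec(mode="arrhythmic", seed=seed))
            _, p = pg.circ_rayleigh(2 * np.pi * truth.phases)
            not_rejected += p > 0.05
        assert not_rejected >= 45  # >= 90% of 50 seeds

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError):
            VRSimSpec(duration_s=1.0, cycle_period_s=2.0)

    def test_trace_determinism(self):
        spec = VRSimSpec(mode="alternating", seed=6)
        (a, _), (b, _) = generate_vr_traces(spec), generate_vr_traces(spec)
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)
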