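"""Topology tests: Hough synapse maps, reservoir generators, module DAG."""

import numpy as np
import networkx as nx
import pytest
from scipy.stats import chisquare

from modlsm import (
    DEFAULT_C_MAP,
    HoughCircleGrid,
    HoughLineGrid,
    ModuleGraph,
    TopologyConfig,
    assemble_reservoir,
    build_circle_hough,
    build_input_synapses,
    build_line_hough,
    connect_modules,
    generate_dag,
    generate_metric,
    generate_random,
    generate_small_world,
    metric_connection_probability,
)


def hough_counts(syn, active_pixels):
    """Per-accumulator-cell count of connected active pixels."""
    active = np.zeros(syn.n_pre, dtype=bool)
    active[list(active_pixels)] = True
    counts = np.zeros(syn.n_post, dtype=int)
    for p, q in zip(syn.pre, syn.post):
        if active[p]:
            counts[q] += 1
    return counts


class TestLineHough:
    def test_default_grid_has_192_cells(self):
        grid = HoughLineGrid()
        syn = build_line_hough(grid)
        assert grid.n_cells == syn.n_post == 16 * 12

    def test_vertical_line_votes_match_brute_force_at_theta_zero(self):
        # integer rho bins {0..15} with theta = 0: condition rho - x = 0 exact
        grid = HoughLineGrid(rho_values=np.arange(16), theta_values=np.array([0.0]),
                             quantization="strict")
        syn = build_line_hough(grid, (28, 28))
        column = [y * 28 + 5 for y in range(28)]
        counts = hough_counts(syn, column)
        # brute-force accumulator: enumerate pixels and bins
        expected = np.zeros(16, dtype=int)
        for y in range(28):
            for rho in range(16):
                if rho - 5 == 0:
                    expected[rho] += 1
        np.testing.assert_array_equal(counts, expected)
        assert counts[5] == 28 and counts.sum() == 28

    def test_empty_image_gives_empty_accumulator(self):
        syn = build_line_hough(HoughLineGrid())
        assert hough_counts(syn, []).sum() == 0

    def test_nearest_mode_every_pixel_votes_once_per_theta(self):
        grid = HoughLineGrid()
        syn = build_line_hough(grid)
        votes = np.bincount(syn.pre, minlength=784)
        assert (votes == grid.n_theta).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HoughLineGrid(rho_values=np.array([]))


class TestCircleHough:
    def test_default_grid_has_216_cells(self):
        grid = HoughCircleGrid()
        syn = build_circle_hough(grid)
        assert grid.n_cells == syn.n_post == 6 * 6 * 6

    def test_strict_radius_five_connects_twelve_lattice_points(self):
        grid = HoughCircleGrid(a_values=np.array([13.0]), b_values=np.array([13.0]),
                               r_values=np.array([5.0]), quantization="strict")
        syn = build_circle_hough(grid, (28, 28))
        assert syn.n_synapses == 12
        offsets = sorted(
            (int(p % 28) - 13, int(p // 28) - 13) for p in syn.pre
        )
        expected = sorted(
            {(5, 0), (-5, 0), (0, 5), (0, -5), (3, 4), (3, -4), (-3, 4), (-3, -4),
             (4, 3), (4, -3), (-4, 3), (-4, -3)}
        )
        assert offsets == expected

    def test_radius_zero_connects_center_only(self):
        grid = HoughCircleGrid(a_values=np.array([7.0]), b_values=np.array([9.0]),
                               r_values=np.array([0.0]), quantization="strict")
        syn = build_circle_hough(grid, (28, 28))
        assert syn.n_synapses == 1
        assert syn.pre[0] == 9 * 28 + 7

    def test_strict_counts_equal_brute_force_accumulator(self):
        grid = HoughCircleGrid(a_values=np.array([13.0]), b_values=np.array([13.0]),
                               r_values=np.array([3.0, 5.0]), quantization="strict")
        syn = build_circle_hough(grid, (28, 28))
        active = list(range(784))
        counts = hough_counts(syn, active)
        expected = np.zeros(2, dtype=int)
        for y in range(28):
            for x in range(28):
                for k, r in enumerate((3, 5)):
                    if r * r == (x - 13) ** 2 + (y - 13) ** 2:
                        expected[k] += 1
        np.testing.assert_array_equal(counts, expected)


class TestSmallWorld:
    @staticmethod
    def king_edge_count(rows, cols):
        """Independent enumeration of directed king-lattice edges."""
        n = 0
        for r in range(rows):
            for c in range(cols):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) != (0, 0) and 0 <= r + dr < rows and 0 <= c + dc < cols:
                            n += 1
        return n

    def test_unrewired_lattice_is_exact_king_lattice(self):
        syn = generate_small_world(9, 15, 8, p_rewire=0.0, seed=0)
        assert syn.n_synapses == self.king_edge_count(9, 15) == 940

    @pytest.mark.parametrize("p_rewire", [0.2, 0.35, 1.0])
    def test_rewiring_preserves_out_degree(self, p_rewire):
        base = generate_small_world(9, 15, 8, 0.0, seed=3)
        rewired = generate_small_world(9, 15, 8, p_rewire, seed=3)
        np.testing.assert_array_equal(base.out_degrees(), rewired.out_degrees())

    def test_no_self_loops_or_duplicates_after_full_rewiring(self):
        syn = generate_small_world(5, 5, 8, 1.0, seed=11)
        assert (syn.pre != syn.post).all()
        pairs = set(zip(syn.pre.tolist(), syn.post.tolist()))
        assert len(pairs) == syn.n_synapses

    def test_deterministic_under_seed(self):
        a = generate_small_world(9, 15, 8, 1.0, seed=42)
        b = generate_small_world(9, 15, 8, 1.0, seed=42)
        np.testing.assert_array_equal(a.pre, b.pre)
        np.testing.assert_array_equal(a.post, b.post)


class TestRandom:
    def test_p_zero_empty_and_p_one_complete(self):
        assert generate_random(50, 0.0, seed=0).n_synapses == 0
        full = generate_random(50, 1.0, seed=0)
        assert full.n_synapses == 50 * 49
        assert (full.out_degrees() == 49).all()

    def test_mean_out_degree_matches_np(self):
        # N=1,500 at p=0.01 -> 14.99 expected
        degs = [
            generate_random(1500, 0.01, seed=s).out_degrees().mean()
            for s in range(20)
        ]
        assert abs(np.mean(degs) - 15.0) < 0.1

    def test_pair_frequency_consistent_with_p(self):
        counts = np.zeros((12, 12))
        n_rep = 400
        for s in range(n_rep):
            syn = generate_random(12, 0.3, seed=s)
            counts[syn.pre, syn.post] += 1
        off = ~np.eye(12, dtype=bool)
        observed = np.array([counts[off].sum(), n_rep * off.sum() - counts[off].sum()])
        expected = np.array([0.3, 0.7]) * n_rep * off.sum()
        assert chisquare(observed, expected).pvalue > 1e-4


class TestMetric:
    def test_adjacent_excitatory_probability_formula(self):
        # C=0.3, lambda=2, D=1 -> 0.3 * exp(-1/4)
        p = metric_connection_probability(True, True, 1.0, 2.0)
        assert p == pytest.approx(0.3 * np.exp(-0.25), abs=1e-12)
        assert p == pytest.approx(0.2336, abs=5e-4)

    def test_probability_vanishes_for_tiny_lambda(self):
        assert metric_connection_probability(True, True, 1.0, 1e-4) < 1e-300

    def test_unknown_type_pair_rejected(self):
        with pytest.raises(KeyError):
            generate_metric((3, 3, 3), c_map={("ex", "ex"): 0.3}, seed=0)

    def test_empirical_out_degree_matches_analytic_expectation(self):
        # small lattice: compare sampling against the exact expectation
        from scipy.spatial.distance import cdist

        dims, lam = (6, 6, 6), 2.0
        rng = np.random.default_rng(0)
        n = 216
        exc = rng.random(n) < 0.8
        coords = np.indices(dims).reshape(3, -1).T
        d2 = cdist(coords, coords, "sqeuclidean")
        c_pre_ex = np.where(exc, 0.3, 0.4)
        c_pre_in = np.where(exc, 0.2, 0.1)
        c = np.where(exc[:, None], c_pre_ex[None, :], c_pre_in[None, :])
        prob = c * np.exp(-d2 / lam**2)
        np.fill_diagonal(prob, 0.0)
        expected = prob.sum() / n
        degs = [
            generate_metric(dims, lam, excitatory=exc, seed=s).out_degrees().mean()
            for s in range(10)
        ]
        assert np.mean(degs) == pytest.approx(expected, abs=0.15)


class TestModuleDag:
    def test_p_zero_no_edges_p_one_all_candidates(self):
        assert generate_dag(10, 0.0, (1, 2), seed=0).edges == []
        g = generate_dag(10, 1.0, (1, 2), seed=0)
        assert len(g.edges) == 44  # sum_{i=3..10} (i-1)

    def test_mean_edge_count_quarter_of_candidates(self):
        means = [len(generate_dag(10, 0.25, (1, 2), seed=s).edges) for s in range(1000)]
        assert abs(np.mean(means) - 11.0) < 0.4

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_graphs_acyclic_and_inputs_protected(self, seed):
        g = generate_dag(10, 0.5, (1, 2), seed=seed)
        dg = nx.DiGraph(g.edges)
        dg.add_nodes_from(g.module_ids)
        assert nx.is_directed_acyclic_graph(dg)
        assert all(b not in (1, 2) for _, b in g.edges)
        assert g.topological_order() == list(nx.lexicographical_topological_sort(dg))

    def test_cycle_detection_names_edge(self):
        with pytest.raises(ValueError, match=r"cycle.*\(|edge"):
            ModuleGraph([1, 2, 3], {}, [(2, 3), (3, 2)], input_modules=(1,))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_dag(10, 1.5, (1, 2))

    def test_depths_follow_longest_path(self):
        g = ModuleGraph([1, 2, 3, 4], {}, [(1, 3), (2, 3), (3, 4)], input_modules=(1, 2))
        assert g.depths() == {1: 0, 2: 0, 3: 1, 4: 2}


class TestConnectModules:
    def test_exact_fan_out(self):
        syn = connect_modules(135, 135, 10, weight=20.0, seed=0,
                              pre_pop="m3", post_pop="m4")
        assert syn.n_synapses == 1350
        assert (syn.out_degrees() == 10).all()
        assert (syn.weight == 20.0).all()

    def test_fan_out_truncated_to_small_module(self):
        syn = connect_modules(8, 6, 10, seed=0, pre_pop="a", post_pop="b")
        assert (syn.out_degrees() == 6).all()
        for u in range(8):
            targets = syn.post[syn.pre == u]
            assert np.unique(targets).size == targets.size

    def test_deterministic_under_seed(self):
        a = connect_modules(20, 30, 10, seed=5, pre_pop="a", post_pop="b")
        b = connect_modules(20, 30, 10, seed=5, pre_pop="a", post_pop="b")
        np.testing.assert_array_equal(a.post, b.post)

    def test_same_population_rejected(self):
        with pytest.raises(ValueError):
            connect_modules(5, 5, 2, pre_pop="m1", post_pop="m1")


class TestAssemble:
    def test_modular_reservoir_structure(self):
        net = assemble_reservoir(TopologyConfig.full("modular"), seed=0)
        assert net.n_neurons == 1488
        assert net.module_sizes[1] == 192 and net.module_sizes[2] == 216
        assert all(net.module_sizes[m] == 135 for m in range(3, 11))
        # Hough modules all-excitatory, no recurrence; SW modules recurrent
        assert net.module_types(1).all() and net.module_types(2).all()
        intra = {s.pre_pop for s in net.projections if s.pre_pop == s.post_pop}
        assert intra == {f"m{m}" for m in range(3, 11)}
        # inter-module projections realise the DAG at constant weight
        inter = [s for s in net.projections if s.pre_pop != s.post_pop]
        assert {( int(s.pre_pop[1:]), int(s.post_pop[1:])) for s in inter} == set(net.graph.edges)
        for s in inter:
            assert (s.weight == 20.0).all()

    def test_single_module_sizes(self):
        assert assemble_reservoir(TopologyConfig.full("small_world"), seed=0).n_neurons == 1500
        assert assemble_reservoir(TopologyConfig.full("random"), seed=0).n_neurons == 1500
        assert assemble_reservoir(TopologyConfig.full("metric"), seed=0).n_neurons == 1500

    def test_modular_without_dag_edges_has_no_inter_synapses(self):
        cfg = TopologyConfig(kind="modular", dag_p=0.0, n_modules=6,
                             module_rows=3, module_cols=3)
        net = assemble_reservoir(cfg, seed=1)
        assert all(s.pre_pop == s.post_pop for s in net.projections)

    def test_assembly_deterministic(self):
        a = assemble_reservoir(TopologyConfig.small("modular"), seed=9)
        b = assemble_reservoir(TopologyConfig.small("modular"), seed=9)
        assert a.graph.edges == b.graph.edges
        for sa, sb in zip(a.projections, b.projections):
            np.testing.assert_array_equal(sa.pre, sb.pre)
            np.testing.assert_array_equal(sa.post, sb.post)
            np.testing.assert_array_equal(sa.weight, sb.weight)

    def test_hough_input_wiring_targets_input_modules(self):
        cfg = TopologyConfig.small("modular")
        net = assemble_reservoir(cfg, seed=2)
        inputs = build_input_synapses(net, cfg, (28, 28), "hough", seed=2)
        assert [s.post_pop for s in inputs] == ["m1", "m2"]
        assert inputs[0].n_post == 192 and inputs[1].n_post == 216
        assert all((s.weight == 20.0).all() for s in inputs)

    def test_random_input_wiring_for_single_module(self):
        cfg = TopologyConfig.small("small_world")
        net = assemble_reservoir(cfg, seed=2)
        (syn,) = build_input_synapses(net, cfg, (28, 28), "random", seed=2)
        assert syn.n_pre == 784
        assert (syn.out_degrees() == 10).all()

    def test_hough_wiring_rejected_for_non_modular(self):
        cfg = TopologyConfig.small("random")
        net = assemble_reservoir(cfg, seed=0)
        with pytest.raises(ValueError):
            build_input_synapses(net, cfg, (28, 28), "hough")
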