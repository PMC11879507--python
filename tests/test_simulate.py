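import math

import numpy as np
import pytest

from treediscord.indices import time_to_ils_index
from treediscord.quartet_freq import induced_quartet_topology
from treediscord.simulate import (
    SIMPLE_FOCAL_INDEXES,
    SIMPLE_FOCAL_TAXA,
    HybridEdge,
    HybridizationModel,
    PopulationJoin,
    as_tree_list,
    builtin_model,
    coalescent_topology_counts,
    dump_model,
    load_model,
    paper_grid,
    run_sweep,
    sample_topology_counts,
    simple_model,
    simulate_gene_trees,
)


class TestModelValidation:
    def test_simple_model_structure(self):
        m = simple_model(0.368, 0.4)
        assert m.root_population == "root"
        assert len(m.hybrid_edges) == 1
        # internal branch spans -ln(0.368) * Ne generations
        t1 = m.joins[1].time - m.joins[0].time
        assert time_to_ils_index(t1, ne=m.ne) == pytest.approx(0.368)

    def test_join_before_child_exists_rejected(self):
        with pytest.raises(ValueError, match="inconsistent|does not exist"):
            HybridizationModel(
                taxa=("a", "b", "c"),
                joins=(PopulationJoin(1e5, ("a", "x"), "p"),
                       PopulationJoin(2e5, ("p", "c"), "root")),
            )

    def test_hybrid_edge_outside_lifetime_rejected(self):
        with pytest.raises(ValueError, match="inconsistent times"):
            HybridizationModel(
                taxa=("a", "b"),
                joins=(PopulationJoin(1e5, ("a", "b"), "root"),),
                hybrid_edges=(HybridEdge(5e5, "a", "b", 0.3),),
            )

    def test_inheritance_proportion_bounded(self):
        with pytest.raises(ValueError, match="proportion"):
            HybridizationModel(
                taxa=("a", "b"),
                joins=(PopulationJoin(1e5, ("a", "b"), "root"),),
                hybrid_edges=(HybridEdge(5e4, "a", "b", 0.7),),
            )

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            HybridizationModel(taxa=("a", "b", "c"),
                               joins=(PopulationJoin(1e5, ("a", "b"), "p"),))


class TestMultinomialEngine:
    def test_zero_trees(self):
        assert sample_topology_counts(0.5, 0.1, 0, seed=1) == (0, 0, 0)

    def test_degenerate_no_discordance(self):
        assert sample_topology_counts(0.0, 0.0, 1000, seed=1) == (1000, 0, 0)

    def test_counts_near_expectation(self):
        n = 10_000
        counts = sample_topology_counts(0.368, 0.4, n, seed=7)
        for c, p in zip(counts, (0.50187, 0.37547, 0.12267)):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(c - n * p) < 4 * sd

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sample_topology_counts(1.5, 0.0, 10, seed=0)


class TestCoalescentEngine:
    def test_no_discordance_limit(self):
        # H = 0 and an effectively infinite internal branch: every gene tree
        # matches the species tree
        m = simple_model(0.0, 0.0)
        rng = np.random.default_rng(5)
        counts = coalescent_topology_counts(m, 300, SIMPLE_FOCAL_INDEXES, rng)
        assert counts == (300, 0, 0)

    def test_ih_only_limit_two_topologies(self):
        # H = 0.5 with no ILS: gene trees split between exactly two topologies
        m = simple_model(0.0, 0.5)
        rng = np.random.default_rng(6)
        counts = coalescent_topology_counts(m, 2000, SIMPLE_FOCAL_INDEXES, rng)
        # slots: (species {2,3}, minor {2,4}, introgressed {3,4})
        assert counts[1] == 0  # the non-introgressed minor never occurs
        assert counts[0] > 0 and counts[2] > 0
        assert abs(counts[0] - counts[2]) < 4 * math.sqrt(2000 * 0.25)

    def test_maximal_ils_equal_thirds(self):
        m = simple_model(1.0, 0.0)
        rng = np.random.default_rng(7)
        n = 30_000
        counts = coalescent_topology_counts(m, n, SIMPLE_FOCAL_INDEXES, rng)
        sd = math.sqrt(n * (1 / 3) * (2 / 3))
        for c in counts:
            assert abs(c - n / 3) < 3 * sd

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0])
    def test_minor_topology_law(self, t):
        # under pure ILS each minor topology occurs with probability e^(-t)/3
        ne = 1e5
        m = simple_model(math.exp(-t), 0.0, ne=ne)
        rng = np.random.default_rng(int(10 * t))
        n = 30_000
        counts = coalescent_topology_counts(m, n, SIMPLE_FOCAL_INDEXES, rng)
        p_minor = math.exp(-t) / 3
        # both minors at e^(-t)/3: test the level (their total) and the
        # symmetry (their difference), the two orthogonal contrasts
        p_tot = 2 * p_minor
        sd_tot = math.sqrt(n * p_tot * (1 - p_tot))
        assert abs(counts[1] + counts[2] - n * p_tot) < 3 * sd_tot
        sd_diff = math.sqrt(2 * n * p_minor * (1 - p_minor))
        assert abs(counts[1] - counts[2]) < 3 * sd_diff

    def test_fast_classification_matches_newick_route(self):
        m = simple_model(0.5, 0.3)
        trees = simulate_gene_trees(m, 150, seed=9)
        fast = [t.quartet_pairing(*SIMPLE_FOCAL_INDEXES) for t in trees]
        dendro = as_tree_list(trees)
        slow = [induced_quartet_topology(g, *SIMPLE_FOCAL_TAXA) for g in dendro]
        assert fast == slow

    def test_engines_agree_on_expected_frequencies(self):
        n = 20_000
        m = simple_model(0.368, 0.4)
        rng = np.random.default_rng(11)
        counts = coalescent_topology_counts(m, n, SIMPLE_FOCAL_INDEXES, rng)
        # slot order: species topology, non-introgressed minor, introgressed
        for c, p in zip(counts, (0.50187, 0.12267, 0.37547)):
            sd = math.sqrt(n * p * (1 - p))
            assert abs(c - n * p) < 4 * sd

    def test_divergence_time_rescaling_invariance(self):
        # T1 from 1e3 to 1e8 generations with Ne rescaled to keep t constant
        n = 10_000
        expected_minor = math.exp(-1.0) / 3
        sd = math.sqrt(n * expected_minor * (1 - expected_minor))
        for t1 in (1e3, 1e6, 1e8):
            ne = t1  # t = T1/Ne = 1 coalescent unit
            m = simple_model(math.exp(-1.0), 0.0, ne=ne, t0=10 * ne,
                             hybrid_time=10 * ne)
            rng = np.random.default_rng(13)
            counts = coalescent_topology_counts(m, n, SIMPLE_FOCAL_INDEXES, rng)
            assert abs(counts[2] - n * expected_minor) < 3 * sd

    def test_seed_determinism_and_sensitivity(self):
        m = simple_model(0.368, 0.4)
        a = [t.newick() for t in simulate_gene_trees(m, 25, seed=42)]
        b = [t.newick() for t in simulate_gene_trees(m, 25, seed=42)]
        c = [t.newick() for t in simulate_gene_trees(m, 25, seed=43)]
        assert a == b
        assert a != c

    def test_newick_branch_lengths_add_up(self):
        m = simple_model(0.368, 0.4)
        (tree,) = simulate_gene_trees(m, 1, seed=3)
        dendro = as_tree_list([tree])[0]
        # all leaves are at time 0: root-to-tip path lengths are equal
        depths = [lf.distance_from_root() for lf in dendro.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-6 * max(depths)


class TestAgainstMsprime:
    def test_discordance_matches_independent_coalescent_simulator(self):
        msprime = pytest.importorskip("msprime")
        t = 1.0
        ne = 1e5
        n = 4000
        dem = msprime.Demography()
        for pop in ("p1", "p2", "p3", "p4", "a23", "a234", "rootp"):
            dem.add_population(name=pop, initial_size=ne)
        dem.add_population_split(time=1e6, derived=["p2", "p3"], ancestral="a23")
        dem.add_population_split(time=1e6 + t * ne, derived=["a23", "p4"],
                                 ancestral="a234")
        dem.add_population_split(time=2e6 + t * ne, derived=["a234", "p1"],
                                 ancestral="rootp")
        discordant = 0
        reps = msprime.sim_ancestry(
            samples={"p1": 1, "p2": 1, "p3": 1, "p4": 1}, demography=dem,
            ploidy=1, num_replicates=n, random_seed=99)
        for ts in reps:
            tree = ts.first()
            # topology: the pair with the lowest MRCA time
            tmrca = {(i, j): tree.time(tree.mrca(i, j))
                     for i in range(4) for j in range(i + 1, 4)}
            cherry = min(tmrca, key=tmrca.get)
            if cherry != (1, 2):  # species pairing is samples 1 and 2
                discordant += 1
        m = simple_model(math.exp(-t), 0.0, ne=ne)
        rng = np.random.default_rng(17)
        counts = coalescent_topology_counts(m, n, SIMPLE_FOCAL_INDEXES, rng)
        ours = (counts[1] + counts[2]) / n
        theirs = discordant / n
        p = (2 / 3) * math.exp(-t)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(ours - p) < 3 * sd
        assert abs(theirs - p) < 3 * sd


class TestSweep:
    def test_single_point_recovers_truth(self):
        sweep = run_sweep([(0.368, 0.40)], n_trees=10_000, reps=100, seed=21,
                          engine="multinomial")
        row = sweep.table.iloc[0]
        assert 38.0 <= row.ih_mean <= 42.0
        assert 34.0 <= row.ils_mean <= 39.0
        assert row.ils_lo <= row.ils_mean <= row.ils_hi
        assert row.ih_lo <= row.ih_mean <= row.ih_hi
        assert 0.0 <= row.topology_error <= 1.0

    def test_pure_ils_column_unbiased(self):
        grid = [(0.2, 0.0), (0.5, 0.0), (0.8, 0.0)]
        sweep = run_sweep(grid, n_trees=10_000, reps=50, seed=22,
                          engine="multinomial")
        for _, row in sweep.table.iterrows():
            assert abs(row.ils_mean - row.ils_true) < 2.0

    def test_paper_grid_has_121_points(self):
        assert len(paper_grid()) == 121
        assert (1.0, 0.5) in paper_grid() and (0.0, 0.0) in paper_grid()

    def test_sweep_deterministic_under_seed(self):
        a = run_sweep([(0.4, 0.2)], n_trees=2000, reps=10, seed=5,
                      engine="coalescent")
        b = run_sweep([(0.4, 0.2)], n_trees=2000, reps=10, seed=5,
                      engine="coalescent")
        assert a.table.equals(b.table)

    def test_tsv_output(self, tmp_path):
        sweep = run_sweep([(0.4, 0.2)], n_trees=500, reps=5, seed=5)
        out = tmp_path / "sweep.tsv"
        sweep.to_tsv(str(out))
        lines = out.read_text().strip().split("\n")
        assert lines[0].split("\t")[0] == "ils_true"
        assert len(lines) == 2


class TestBuiltinModels:
    @pytest.mark.parametrize("name", ["ret1", "ret2", "ret3", "ret4"])
    def test_reticulation_fixtures_load_and_simulate(self, name):
        m = builtin_model(name)
        assert set(m.taxa) == {"1", "2", "3", "4", "5"}
        assert all(h.proportion == 0.4 for h in m.hybrid_edges)
        trees = simulate_gene_trees(m, 20, seed=1)
        assert len(trees) == 20
        assert all(t.newick().endswith(";") for t in trees)

    def test_ret_models_have_expected_event_counts(self):
        assert len(builtin_model("ret1").hybrid_edges) == 1
        assert len(builtin_model("ret2").hybrid_edges) == 1
        assert len(builtin_model("ret3").hybrid_edges) == 2
        assert len(builtin_model("ret4").hybrid_edges) == 2

    def test_yaml_round_trip(self):
        m = builtin_model("ret3")
        again = load_model(dump_model(m), is_path=False)
        assert again == m

    def test_unknown_builtin_rejected(self):
        with pytest.raises(ValueError, match="unknown builtin"):
            builtin_model("ret9")
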