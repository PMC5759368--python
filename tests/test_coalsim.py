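"""Structured-coalescent gene trees: constraints, timing, Newick I/O."""

import math

import numpy as np
import pytest

from dsense.coalsim import (LEAF_LABELS, GeneTree, read_gene_trees,
                            simulate_gene_tree, write_gene_trees)
from tests.conftest import mid_scenario


@pytest.fixture(scope="module")
def trees():
    scn = mid_scenario()
    rng = np.random.default_rng(99)
    return scn, [simulate_gene_tree(scn, rng) for _ in range(400)]


class TestTreeStructure:
    def test_leaves_and_internal_nodes(self, trees):
        _, ts = trees
        for tr in ts[:50]:
            assert tr.labels == LEAF_LABELS
            assert tr.n_nodes == 2 * tr.n_leaves - 1
            # every non-root node has a parent later in time
            for i in range(tr.n_nodes - 1):
                p = tr.parent[i]
                assert p > i
                assert tr.times[p] >= tr.times[i]

    def test_coalescence_respects_species_tree(self, trees):
        scn, ts = trees
        for tr in ts:
            assert tr.mrca_time("H1", "H2") >= scn.T2
            assert tr.mrca_time("H1", "H3a") >= scn.T3
            assert tr.mrca_time("H2", "H4") >= scn.T4
            assert tr.mrca_time("H3f", "H3a") >= scn.Tgf
            assert tr.mrca_time("H2f", "H2") >= scn.Tgf
            # same-population samples may coalesce any time
            assert tr.mrca_time("H3a", "H3b") > 0

    def test_species_tree_topology_in_low_ils_limit(self):
        scn = mid_scenario(Ne=0.01 * 0.001)  # Ne/T3 -> 0
        rng = np.random.default_rng(5)
        for _ in range(50):
            tr = simulate_gene_tree(scn, rng)
            assert tr.triplet_topology("H1", "H2", "H3a") == ("H1", "H2")


class TestCoalescentTiming:
    def test_pairwise_excess_is_about_ne_generations(self, trees):
        """Two lineages entering a shared population of Ne gene copies
        coalesce on average Ne generations after entry."""
        scn, ts = trees
        excess = np.mean([tr.mrca_time("H3a", "H3b") for tr in ts])
        se = scn.Ne / math.sqrt(len(ts))
        assert abs(excess - scn.Ne) < 4 * se

    def test_h3_pair_coalesced_by_t3_fraction(self, trees):
        scn, ts = trees
        frac = np.mean([tr.mrca_time("H3a", "H3b") < scn.T3 for tr in ts])
        expect = 1.0 - math.exp(-scn.T3 / scn.Ne)
        assert abs(frac - expect) < 4 * math.sqrt(expect * (1 - expect)
                                                  / len(ts))

    def test_triplet_discordance_matches_closed_form(self):
        """Fraction of (H1,H2,H3) gene trees discordant with the species
        tree is (2/3) e^-t, t = (T3-T2)/Ne in coalescent units."""
        rng = np.random.default_rng(11)
        t_units = 1.0
        scn = mid_scenario(Ne=(0.01 - 0.005) / t_units)
        n = 3000
        disc = 0
        for _ in range(n):
            tr = simulate_gene_tree(scn, rng)
            disc += tr.triplet_topology("H1", "H2", "H3a") != ("H1", "H2")
        expect = (2 / 3) * math.exp(-t_units)
        assert abs(disc / n - expect) < 4 * math.sqrt(expect * (1 - expect)
                                                      / n)


class TestAgainstIndependentEngines:
    def test_discordance_agrees_with_brute_force_wright_fisher(self):
        """Topology frequencies from the package's structured coalescent
        match the discrete-generation Wright-Fisher reference sampler."""
        from dsense.synthetic import brute_force_coalescent
        t_units = 1.0
        scn = mid_scenario(Ne=(0.01 - 0.005) / t_units)
        rng = np.random.default_rng(404)
        n = 4000
        disc_pkg = np.mean([
            simulate_gene_tree(scn, rng).triplet_topology("H1", "H2", "H3a")
            != ("H1", "H2") for _ in range(n)])
        ref = brute_force_coalescent(t_units, 40_000, rng)
        disc_ref = ref["AC"] + ref["BC"]
        se = math.sqrt(disc_ref * (1 - disc_ref) * (1 / n + 1 / 40_000))
        assert abs(disc_pkg - disc_ref) < 4 * se

    def test_discordance_agrees_with_msprime(self):
        """Cross-check against an established coalescent engine on the
        three-population reduction (with ploidy=1 msprime's population size
        counts gene copies, matching this package's Ne convention)."""
        import msprime

        scn = mid_scenario()
        demography = msprime.Demography()
        for name in ("H1", "H2", "H3", "A12", "A123"):
            demography.add_population(name=name,
                                      initial_size=scn.Ne * 1e6)
        demography.add_population_split(time=scn.T2 * 1e6,
                                        derived=["H1", "H2"],
                                        ancestral="A12")
        demography.add_population_split(time=scn.T3 * 1e6,
                                        derived=["A12", "H3"],
                                        ancestral="A123")
        reps = msprime.sim_ancestry(
            samples={"H1": 1, "H2": 1, "H3": 1}, ploidy=1,
            demography=demography, num_replicates=4000, random_seed=9)
        disc_ms = np.mean([
            (lambda t: t.mrca(0, 1) == t.root)(ts.first()) for ts in reps])
        rng = np.random.default_rng(77)
        n = 4000
        disc_pkg = np.mean([
            simulate_gene_tree(scn, rng).triplet_topology("H1", "H2", "H3a")
            != ("H1", "H2") for _ in range(n)])
        se = math.sqrt(max(disc_ms, 1e-3) * (1 - disc_ms) * (2 / n))
        assert abs(disc_pkg - disc_ms) < 4 * se


class TestNewickIO:
    def test_round_trip_preserves_topology_and_lengths(self, trees, tmp_path):
        _, ts = trees
        path = tmp_path / "trees.nwk"
        write_gene_trees(ts[:5], path)
        back = read_gene_trees(path)
        assert len(back) == 5
        for tr, dt in zip(ts[:5], back):
            tips = {leaf.taxon.label for leaf in dt.leaf_node_iter()}
            assert tips == set(tr.labels)
            total = sum(e.length for e in dt.preorder_edge_iter()
                        if e.length)
            expect = sum(tr.branch_length(i) for i in range(tr.n_nodes - 1))
            assert total == pytest.approx(expect, rel=1e-9)

    def test_single_cherry_round_trip(self, tmp_path):
        tr = GeneTree(labels=("A", "B"),
                      times=np.array([0.0, 0.0, 0.1]),
                      parent=np.array([2, 2, -1]))
        path = tmp_path / "one.nwk"
        write_gene_trees([tr], path)
        assert path.read_text().strip() == "(A:0.1,B:0.1):0;"
        back = read_gene_trees(path)
        assert len(back) == 1

    def test_empty_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "none.nwk"
        write_gene_trees([], path)
        assert read_gene_trees(path) == []
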