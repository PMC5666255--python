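import numpy as np
import pandas as pd
import pytest

from haplostat import Alignment, build_network, coalsim, collapse_haplotypes, network
from haplostat.errors import DomainError
from haplostat.seq_io import HaplotypeTable


def _table(haps: dict[str, tuple[str, int]]) -> HaplotypeTable:
    """haps: id -> (sequence, frequency), single pooled group."""
    ids = list(haps)
    counts = pd.DataFrame({"all": [haps[h][1] for h in ids]}, index=ids)
    return HaplotypeTable(
        haplotypes=[(h, haps[h][0]) for h in ids], counts=counts
    )


class TestConnectionLimit:
    def test_production_matches_quadrature_oracle(self):
        for L in (100, 554):
            for j in range(1, 16):
                p = network.parsimony_probability(j, L)
                o = network.parsimony_probability_oracle(j, L)
                assert p == pytest.approx(o, rel=1e-6)

    def test_limit_frozen_oracle_value_554(self):
        # regression constant fixed from the quadrature oracle before wiring
        # the closed form into production
        assert network.connection_limit(554, 0.95) == 6
        assert network.connection_limit(
            554, 0.95, _prob=network.parsimony_probability_oracle
        ) == 6

    def test_monotone_in_alpha(self):
        for L in (100, 554, 1000):
            assert network.connection_limit(L, 0.95) <= network.connection_limit(L, 0.90)

    def test_vanishing_alpha_connects_everything(self):
        L = 12
        assert network.connection_limit(L, 1e-12) == L

    def test_probability_decreases_in_j(self):
        probs = [network.parsimony_probability(j, 554) for j in range(1, 20)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_alpha_domain_guard(self):
        with pytest.raises(DomainError):
            network.connection_limit(554, 1.5)


class TestBuildNetwork:
    def test_single_haplotype(self):
        net = build_network(_table({"H1": ("AAAA", 5)}), limit=5)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.ancestral_id == "H1"

    def test_two_haplotypes_one_step(self):
        net = build_network(_table({"H1": ("AAAA", 3), "H2": ("AAAT", 1)}), limit=5)
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1
        assert net.inferred_nodes == []

    def test_three_step_pair_inserts_two_intermediates(self):
        net = build_network(_table({"H1": ("AAAA", 5), "H2": ("ATTT", 1)}), limit=5)
        assert len(net.inferred_nodes) == 2
        assert net.graph.number_of_edges() == 3
        # intermediates mutate sites in ascending order from the H1 side
        seqs = {net.graph.nodes[v]["sequence"] for v in net.inferred_nodes}
        assert seqs == {"ATAA", "ATTA"}
        for u, v in net.graph.edges:
            a = net.graph.nodes[u]["sequence"]
            b = net.graph.nodes[v]["sequence"]
            assert sum(x != y for x, y in zip(a, b)) == 1

    def test_beyond_limit_stays_disconnected(self):
        net = build_network(_table({"H1": ("AAAA", 2), "H2": ("TTTT", 2)}), limit=3)
        assert len(net.components) == 2

    def test_forest_edge_count_identity(self, rng):
        spec = coalsim.SimulationSpec(n_per_deme=(30,), theta=4.0, L=100)
        for _ in range(10):
            ds = coalsim.simulate(spec, rng)
            table = collapse_haplotypes(ds.alignment)
            net = build_network(table, limit=10)
            g = net.graph
            assert g.number_of_edges() == g.number_of_nodes() - len(net.components)

    def test_inferred_nodes_have_degree_two_or_more(self, rng):
        spec = coalsim.SimulationSpec(n_per_deme=(25,), theta=6.0, L=120)
        ds = coalsim.simulate(spec, rng)
        net = build_network(collapse_haplotypes(ds.alignment), limit=12)
        for v in net.inferred_nodes:
            assert net.graph.degree[v] >= 2

    def test_total_observed_frequency_equals_n(self, rng):
        spec = coalsim.SimulationSpec(n_per_deme=(40,), theta=3.0)
        ds = coalsim.simulate(spec, rng)
        net = build_network(collapse_haplotypes(ds.alignment), limit=10)
        assert net.total_frequency() == 40

    def test_graphml_round_trip(self, tmp_path, rng):
        import networkx as nx

        spec = coalsim.SimulationSpec(n_per_deme=(15,), theta=3.0)
        ds = coalsim.simulate(spec, rng)
        table = collapse_haplotypes(ds.alignment, ds.metadata, grouping="population")
        net = build_network(table, limit=8)
        p = tmp_path / "net.graphml"
        net.to_graphml(p)
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == net.graph.number_of_nodes()


class TestAncestralHaplotype:
    def test_star_center_wins(self):
        haps = {"H1": ("AAAA", 10)}
        for i, base in enumerate("CGT"):
            haps[f"H{i+2}"] = ("AAA" + base, 1)
        net = build_network(_table(haps), limit=3)
        assert net.ancestral_id == "H1"

    def test_tie_breaks_to_lower_id_and_flags(self):
        net = build_network(_table({"H1": ("AAAA", 3), "H2": ("AAAT", 3)}), limit=3)
        assert net.ancestral_id == "H1"
        assert net.ancestral_tied

    def test_recovers_true_root_on_star_expansions(self):
        """Designated ancestor matches the simulated root haplotype in a
        strong majority of star-like expansion replicates."""
        hits = 0
        reps = 100
        gen = np.random.default_rng(17)
        spec = coalsim.SimulationSpec(
            n_per_deme=(50,), theta=None, theta0=0.05, theta1=50.0, tau=3.0, L=554
        )
        for _ in range(reps):
            ds = coalsim.simulate(spec, gen)
            table = collapse_haplotypes(ds.alignment)
            net = build_network(table, limit=10)
            anc_seq = net.graph.nodes[net.ancestral_id]["sequence"]
            if anc_seq == ds.root_haplotype:
                hits += 1
        assert hits >= 60
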