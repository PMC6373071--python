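import random
from itertools import combinations

import pytest

from interonet.ipn import build_ipn, coverage
from interonet.ops import OPS
from interonet.ppin import SpeciesNetwork

from oracles import brute_force_ipn_edges


def make_instance(rng, n_ops=6, k=3, edge_p=0.4):
    """Random OPS list + per-species networks over the members."""
    species = [f"s{i}" for i in range(k)]
    ops_list = [
        OPS(f"OPS{i + 1}", {s: f"{s}_m{i}" for s in species})
        for i in range(n_ops)
    ]
    networks = {}
    for s in species:
        net = SpeciesNetwork(s)
        for i, j in combinations(range(n_ops), 2):
            if rng.random() < edge_p:
                net.add_edge(f"{s}_m{i}", f"{s}_m{j}", rng.randint(400, 1000))
        networks[s] = net
    return species, ops_list, networks


def nets_as_sets(networks):
    return {s: set(net.edges) for s, net in networks.items()}


class TestCoverage:
    def _setup(self, supported_in):
        species = ["s1", "s2", "s3"]
        ops_i = OPS("OPS1", {s: f"{s}_a" for s in species})
        ops_j = OPS("OPS2", {s: f"{s}_b" for s in species})
        networks = {}
        for s in species:
            net = SpeciesNetwork(s)
            if s in supported_in:
                net.add_edge(f"{s}_a", f"{s}_b", 900)
            networks[s] = net
        return ops_i, ops_j, networks

    def test_partial_support(self):
        ops_i, ops_j, nets = self._setup({"s1", "s2"})
        assert coverage(ops_i, ops_j, nets) == (2, {"s1", "s2"})

    def test_no_support(self):
        ops_i, ops_j, nets = self._setup(set())
        assert coverage(ops_i, ops_j, nets) == (0, set())

    def test_full_support(self):
        ops_i, ops_j, nets = self._setup({"s1", "s2", "s3"})
        assert coverage(ops_i, ops_j, nets) == (3, {"s1", "s2", "s3"})

    def test_missing_network_is_an_error(self):
        ops_i, ops_j, nets = self._setup({"s1"})
        del nets["s2"]
        with pytest.raises(ValueError, match="s2"):
            coverage(ops_i, ops_j, nets)


class TestBuildIpn:
    def test_threshold_inclusive(self):
        rng = random.Random(0)
        species, ops_list, networks = make_instance(rng, n_ops=2, k=3, edge_p=0.0)
        networks["s0"].add_edge("s0_m0", "s0_m1", 900)
        networks["s1"].add_edge("s1_m0", "s1_m1", 900)
        assert len(build_ipn(ops_list, networks, 2).edges) == 1
        assert len(build_ipn(ops_list, networks, 3).edges) == 0

    @pytest.mark.parametrize("cutoff", [0, 4])
    def test_out_of_range_cutoff(self, cutoff):
        rng = random.Random(1)
        _, ops_list, networks = make_instance(rng, k=3)
        with pytest.raises(ValueError):
            build_ipn(ops_list, networks, cutoff)

    def test_isolated_nodes_are_kept(self):
        rng = random.Random(2)
        _, ops_list, networks = make_instance(rng, n_ops=4, k=2, edge_p=0.0)
        ipn = build_ipn(ops_list, networks, 1)
        assert len(ipn.nodes) == 4 and len(ipn.edges) == 0

    def test_equals_double_loop_oracle(self):
        rng = random.Random(31)
        for _ in range(25):
            k = rng.randint(2, 4)
            species, ops_list, networks = make_instance(
                rng, n_ops=rng.randint(2, 7), k=k, edge_p=rng.choice([0.2, 0.5])
            )
            members = {o.ops_id: dict(o.members) for o in ops_list}
            for cutoff in range(1, k + 1):
                got = {
                    (e.ops_i, e.ops_j) for e in build_ipn(ops_list, networks, cutoff).edges
                }
                assert got == brute_force_ipn_edges(
                    members, nets_as_sets(networks), cutoff
                )

    def test_edge_count_anti_monotone_in_coverage_cutoff(self):
        rng = random.Random(8)
        for _ in range(10):
            k = rng.randint(2, 4)
            _, ops_list, networks = make_instance(rng, n_ops=6, k=k)
            counts = [
                len(build_ipn(ops_list, networks, c).edges)
                for c in range(1, k + 1)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_supporting_species_consistent_with_coverage(self):
        rng = random.Random(12)
        _, ops_list, networks = make_instance(rng, n_ops=5, k=3)
        for e in build_ipn(ops_list, networks, 1).edges:
            assert e.coverage == len(e.supporting_species)
            assert 1 <= e.coverage <= 3

    def test_size_bound_at_full_coverage(self):
        """With conservation required in every species, the conserved
        network cannot exceed the smallest species network."""
        rng = random.Random(55)
        for _ in range(15):
            k = rng.randint(2, 4)
            _, ops_list, networks = make_instance(rng, n_ops=6, k=k)
            ipn = build_ipn(ops_list, networks, k)
            assert len(ipn.edges) <= min(len(n) for n in networks.values())

    def test_identity_limit_two_identical_species(self):
        """Two species with identical members and networks at cutoff 2:
        the conserved network equals the input network."""
        species = ["s0", "s1"]
        ops_list = [
            OPS(f"OPS{i + 1}", {s: f"{s}_m{i}" for s in species})
            for i in range(5)
        ]
        pattern = {(0, 1), (1, 2), (0, 3), (3, 4)}
        networks = {}
        for s in species:
            net = SpeciesNetwork(s)
            for i, j in pattern:
                net.add_edge(f"{s}_m{i}", f"{s}_m{j}", 800)
            networks[s] = net
        ipn = build_ipn(ops_list, networks, 2)
        got = {
            (int(e.ops_i[3:]) - 1, int(e.ops_j[3:]) - 1) for e in ipn.edges
        }
        assert got == pattern


def test_parameter_recovery_ancestral_edges(small_bundle):
    """Species-private decoy edges vanish at full coverage; the planted
    ancestral (conserved) edges survive exactly."""
    from interonet.ppin import filter_by_score, read_edge_list, restrict_to_ops

    spec, truth, out = small_bundle
    species = spec.species_ids
    ops_list = [
        OPS(f"OPS{i + 1}", dict(truth.groups[i])) for i in sorted(truth.groups)
    ]
    networks = {}
    for s in species:
        net = read_edge_list(out / f"{s}_edges.tsv", s)
        networks[s] = restrict_to_ops(filter_by_score(net, 400), ops_list)
    ipn = build_ipn(ops_list, networks, spec.k)
    got = {
        tuple(sorted((int(e.ops_i[3:]) - 1, int(e.ops_j[3:]) - 1)))
        for e in ipn.edges
    }
    assert got == truth.conserved_edges
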