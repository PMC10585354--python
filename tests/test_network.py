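"""Topology expansion, identifiability constraints, transition probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonedyn as cd
from clonedyn.network import (TopologyError, UndefinedProbabilityError,
                              UnidentifiableParameterError)


# -- random tree topologies for property tests ------------------------------

@st.composite
def tree_networks(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    nodes = tuple(f"N{i}" for i in range(n))
    parents = [None] + [f"N{draw(st.integers(0, i - 1))}" for i in range(1, n)]
    edges = tuple((p, c) for c, p in zip(nodes, parents) if p is not None)
    observed = tuple(draw(st.booleans()) for _ in range(n))
    dup = tuple(draw(st.booleans()) for _ in range(n))
    death = tuple(draw(st.booleans()) for _ in range(n))
    branch = tuple(draw(st.sampled_from(["myeloid", "lymphoid", "none"]))
                   for _ in range(n))
    return cd.DifferentiationNetwork(
        nodes=nodes, observed=observed, branch=branch,
        ancestor=tuple(parents), edges=edges, dup=dup, death=death)


class TestReactionSystem:
    def test_two_node_reactions(self, two_node):
        net, rs, _ = two_node
        assert rs.K == 5
        # duplications, then deaths, then differentiations
        assert rs.rate_names == ("alpha:A", "alpha:B", "delta:A", "delta:B",
                                 "lambda:A->B")
        expected = np.array([[1, 0, -1, 0, -1],
                             [0, 1, 0, -1, 2]])
        np.testing.assert_array_equal(rs.net_effect_matrix, expected)

    def test_single_dup_only_node(self):
        net = cd.DifferentiationNetwork(
            nodes=("A",), observed=(True,), branch=("none",),
            ancestor=(None,), edges=(), dup=(True,), death=(False,))
        rs = cd.build_reaction_system(net)
        assert rs.K == 1
        np.testing.assert_array_equal(rs.net_effect_matrix, [[1]])

    def test_six_node_chain_counts(self):
        # HSC -> P1 -> P2 -> {T, B, G}: 6 nodes, 5 edges, dup+death on all
        net = cd.load_network("fig3a")
        rs = cd.build_reaction_system(net)
        assert net.n == 6
        assert rs.K == 6 + 6 + 5
        assert rs.net_effect_matrix.shape == (6, 17)

    def test_edge_to_missing_node_rejected(self):
        with pytest.raises(TopologyError):
            cd.DifferentiationNetwork(
                nodes=("A",), observed=(True,), branch=("none",),
                ancestor=(None,), edges=(("A", "B"),), dup=(True,),
                death=(True,))

    @settings(max_examples=50, derandomize=True)
    @given(net=tree_networks())
    def test_column_sums_by_kind(self, net):
        """Duplication/differentiation columns sum to +1, death to -1."""
        rs = cd.build_reaction_system(net)
        for k, r in enumerate(rs.reactions):
            s = rs.net_effect_matrix[:, k].sum()
            assert s == (-1 if r.kind == "death" else 1)


class TestConstraintMap:
    def test_fully_observed_is_identity(self, two_node):
        net, rs, _ = two_node
        cm = cd.build_constraint_map(net)
        assert cm.p_free == cm.p == rs.K
        np.testing.assert_array_equal(cm.matrix, np.eye(rs.K))

    def test_conservation_chain(self):
        """Hidden HSC -> hidden MPP -> observed {T, B}: incoming rate into
        MPP equals the sum of its outgoing rates."""
        net = cd.DifferentiationNetwork(
            nodes=("HSC", "MPP", "T", "B"), observed=(False, False, True, True),
            branch=("none", "none", "lymphoid", "lymphoid"),
            ancestor=(None, "HSC", "MPP", "MPP"),
            edges=(("HSC", "MPP"), ("MPP", "T"), ("MPP", "B")),
            dup=(True,) * 4, death=(True,) * 4)
        cm = cd.build_constraint_map(net)
        assert set(cm.free_names) >= {"lambda:MPP->T", "lambda:MPP->B"}
        assert "lambda:HSC->MPP" not in cm.free_names
        tf = np.arange(1.0, cm.p_free + 1)
        full = dict(zip(cm.full_names, cm.expand(tf)))
        free = dict(zip(cm.free_names, tf))
        assert full["lambda:HSC->MPP"] == pytest.approx(
            free["lambda:MPP->T"] + free["lambda:MPP->B"], abs=1e-12)

    def test_averaging_single_observed_offspring(self):
        """Hidden-to-hidden rate with one measured sibling edge: equality."""
        net = cd.DifferentiationNetwork(
            nodes=("MPP", "G", "CLP"), observed=(False, True, False),
            branch=("none", "myeloid", "lymphoid"),
            ancestor=(None, "MPP", "MPP"),
            edges=(("MPP", "G"), ("MPP", "CLP")),
            dup=(True, True, False), death=(False, False, False))
        cm = cd.build_constraint_map(net)
        tf = np.arange(1.0, cm.p_free + 1)
        full = dict(zip(cm.full_names, cm.expand(tf)))
        free = dict(zip(cm.free_names, tf))
        assert full["lambda:MPP->CLP"] == pytest.approx(
            free["lambda:MPP->G"], abs=1e-12)

    def test_empty_averaging_set_raises(self):
        # hidden leaf whose parent has no measured offspring
        net = cd.DifferentiationNetwork(
            nodes=("A", "B"), observed=(False, False),
            branch=("none", "none"), ancestor=(None, "A"),
            edges=(("A", "B"),), dup=(True, True), death=(False, False))
        with pytest.raises(UnidentifiableParameterError):
            cd.build_constraint_map(net)

    def test_no_flags_is_identity(self):
        net = cd.load_network("fig3a")
        cm = cd.build_constraint_map(net, use_conservation=False,
                                     use_averaging=False)
        np.testing.assert_array_equal(cm.matrix, np.eye(cm.p))

    @settings(max_examples=40, derandomize=True)
    @given(net=tree_networks(), data=st.data())
    def test_constraint_identities_hold_exactly(self, net, data):
        """Expanded rates satisfy every conservation sum and averaging mean."""
        try:
            cm = cd.build_constraint_map(net)
        except UnidentifiableParameterError:
            return
        tf = np.array([data.draw(st.floats(0.0, 5.0)) for _ in
                       range(cm.p_free)])
        full = dict(zip(cm.full_names, cm.expand(tf)))
        assert all(v >= 0 for v in full.values())
        for src, dst in net.edges:
            if net.is_observed(src) or net.is_observed(dst):
                continue
            offspring = net.offspring(dst)
            if offspring:   # conservation sum
                assert full[f"lambda:{src}->{dst}"] == pytest.approx(
                    sum(full[f"lambda:{dst}->{c}"] for c in offspring),
                    abs=1e-10)
            else:           # averaging mean over measured offspring of src
                obs_off = [c for c in net.offspring(src) if net.is_observed(c)]
                assert full[f"lambda:{src}->{dst}"] == pytest.approx(
                    np.mean([full[f"lambda:{src}->{c}"] for c in obs_off]),
                    abs=1e-10)

    def test_chained_hidden_compartments_resolve_to_observed(self):
        """fig3a with HSC/P1/P2 hidden: both hidden-to-hidden rates equal
        the sum of the measured terminal rates."""
        net = cd.load_network("fig3a")
        cm = cd.build_constraint_map(net)
        tf = np.random.default_rng(0).uniform(0.1, 1.0, cm.p_free)
        full = dict(zip(cm.full_names, cm.expand(tf)))
        total = sum(full[f"lambda:P2->{x}"] for x in ("T", "B", "G"))
        assert full["lambda:P1->P2"] == pytest.approx(total, abs=1e-12)
        assert full["lambda:HSC->P1"] == pytest.approx(total, abs=1e-12)


class TestTransitionProbabilities:
    def test_direct_evaluation(self):
        net = cd.DifferentiationNetwork(
            nodes=("A", "B"), observed=(True, True), branch=("none",) * 2,
            ancestor=(None, "A"), edges=(("A", "B"),),
            dup=(True, False), death=(False, False))
        rs = cd.build_reaction_system(net)
        theta = cd.RateParameters.from_mapping(
            rs, {"alpha:A": 0.2, "lambda:A->B": 0.3})
        probs = cd.transition_probabilities(net, theta)
        assert probs[("A", "B")] == pytest.approx(0.6)
        # no self-renewal: probability 1
        theta0 = cd.RateParameters.from_mapping(
            rs, {"alpha:A": 0.0, "lambda:A->B": 0.7})
        assert cd.transition_probabilities(net, theta0)[("A", "B")] == 1.0

    def test_symmetric_split(self):
        net = cd.DifferentiationNetwork(
            nodes=("I", "A", "B"), observed=(True,) * 3, branch=("none",) * 3,
            ancestor=(None, "I", "I"), edges=(("I", "A"), ("I", "B")),
            dup=(True, False, False), death=(False,) * 3)
        rs = cd.build_reaction_system(net)
        theta = cd.RateParameters.from_mapping(
            rs, {"alpha:I": 2.0, "lambda:I->A": 1.0, "lambda:I->B": 1.0})
        probs = cd.transition_probabilities(net, theta)
        assert probs[("I", "A")] == pytest.approx(0.25)
        assert probs[("I", "B")] == pytest.approx(0.25)

    def test_scale_invariance(self, two_node):
        net, rs, theta = two_node
        p1 = cd.transition_probabilities(net, theta)
        scaled = cd.RateParameters(rs, theta.values * 7.5)
        p2 = cd.transition_probabilities(net, scaled)
        for e in p1:
            assert p1[e] == pytest.approx(p2[e], rel=1e-12)

    def test_zero_denominator_raises(self):
        net = cd.DifferentiationNetwork(
            nodes=("A", "B"), observed=(True, True), branch=("none",) * 2,
            ancestor=(None, "A"), edges=(("A", "B"),),
            dup=(True, False), death=(False, False))
        rs = cd.build_reaction_system(net)
        theta = cd.RateParameters.from_mapping(rs, {})
        with pytest.raises(UndefinedProbabilityError):
            cd.transition_probabilities(net, theta)


class TestFixtures:
    @pytest.mark.parametrize("name,n_nodes,n_edges", [
        ("fig2a", 12, 11), ("fig2b", 13, 12), ("fig2c", 13, 13),
        ("fig2d", 14, 13), ("fig3a", 6, 5), ("fig3b", 8, 7),
        ("fig3c", 9, 9), ("fig3d", 13, 12)])
    def test_shipped_fixture_shapes(self, name, n_nodes, n_edges):
        net = cd.load_network(name)
        assert net.n == n_nodes
        assert len(net.edges) == n_edges
        cd.build_constraint_map(net)     # every fixture is identifiable

    def test_classical_tree_structure(self):
        net = cd.load_network("fig2b")
        assert set(net.offspring("MPP")) == {"CMP", "CLP"}
        assert set(net.offspring("CLP")) == {"T", "B", "NK"}
        assert set(net.offspring("MEP")) == {"P", "ERY"}

    def test_myeloid_based_adds_cmp_to_nk(self):
        b = cd.load_network("fig2b")
        c = cd.load_network("fig2c")
        assert set(c.edges) - set(b.edges) == {("CMP", "NK")}

    def test_nk_progenitor_model(self):
        d = cd.load_network("fig2d")
        assert "NKP" in d.nodes
        assert d.offspring("NKP") == ("NK",)
        assert "NK" not in d.offspring("CLP")

    def test_fig3d_hides_all_progenitors(self):
        net = cd.load_network("fig3d")
        hidden = {x for x in net.nodes if not net.is_observed(x)}
        assert hidden == {"HSC", "MPP", "CMP", "CLP", "MEP", "GMP"}

    def test_yaml_roundtrip(self, tmp_path):
        net = cd.load_network("fig2d")
        p = tmp_path / "net.yaml"
        net.to_yaml(p)
        again = cd.DifferentiationNetwork.from_yaml(p)
        assert again == net

    def test_observability_override(self):
        net = cd.load_network("fig2b")
        geno = net.with_observed({"NK": False, "G": False})
        assert not geno.is_observed("NK")
        assert net.is_observed("NK")        # original untouched

    def test_networkx_export_with_weights(self, two_node, tmp_path):
        import networkx as nx
        net, rs, theta = two_node
        probs = cd.transition_probabilities(net, theta)
        g = net.to_networkx(edge_probabilities=probs)
        assert g.edges[("A", "B")]["transition_probability"] == \
            pytest.approx(0.6)
        nx.write_graphml(g, tmp_path / "net.graphml")
        assert (tmp_path / "net.graphml").exists()
        dot = net.to_dot(edge_probabilities=probs)
        assert "A" in dot and "transition_probability" in dot
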