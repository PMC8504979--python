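"""Network structures (DAGs over variables), constraints and CPDAGs.

A :class:`NetworkStructure` is a DAG whose nodes are :class:`VariableSpec`
objects.  Structural validity for mixed networks means: acyclic, no edge
into a genetic (causal-anchor) variable, and no continuous parent of a
discrete node.  A :class:`ConstraintSet` carries hard white/black lists and
soft directed-edge priors p(e) (the reverse direction implicitly carries
1 - p(e)).

Observational (Markov) equivalence is decided through the CPDAG: two DAGs
are equivalent iff they share skeleton and v-structures, equivalently iff
their CPDAGs coincide.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .dataset import ConfigurationError, VariableSpec

__all__ = [
    "NetworkStructure",
    "ConstraintSet",
    "PDAG",
    "ValidityReport",
    "validate_structure",
    "cpdag",
    "read_edge_list",
    "read_soft_priors",
]


class NetworkStructure:
    """A directed acyclic graph over typed variables.

    Edges are ordered ``(parent, child)`` name pairs.  At most one edge is
    allowed per unordered pair.  Acyclicity and the mixed-type/genetic rules
    are enforced by :func:`validate_structure`; construction only enforces
    the one-edge-per-pair rule and known node names.
    """

    def __init__(self, variables, edges=()):
        self.variables: list[VariableSpec] = list(variables)
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise ConfigurationError("duplicate node names")
        self.edges: set = set()
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction --------------------------------------------------------

    def add_edge(self, u, v):
        if u not in self._by_name or v not in self._by_name:
            raise ConfigurationError(f"edge ({u}, {v}) references unknown node")
        if u == v:
            raise ConfigurationError(f"self-loop on {u!r}")
        if (v, u) in self.edges:
            raise ConfigurationError(
                f"both directions between {u!r} and {v!r}: at most one edge "
                f"per pair"
            )
        self.edges.add((u, v))

    def remove_edge(self, u, v):
        self.edges.remove((u, v))

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.variables, self.edges)

    # -- queries -------------------------------------------------------------

    @property
    def node_names(self) -> list:
        return [v.name for v in self.variables]

    def spec(self, name) -> VariableSpec:
        return self._by_name[name]

    def parents(self, name) -> set:
        return {u for (u, v) in self.edges if v == name}

    def children(self, name) -> set:
        return {v for (u, v) in self.edges if u == name}

    def adjacent(self, name) -> set:
        return self.parents(name) | self.children(name)

    def has_edge(self, u, v) -> bool:
        return (u, v) in self.edges

    def topological_order(self):
        """Kahn's algorithm; returns node names or None if cyclic."""
        indeg = {n: 0 for n in self._by_name}
        for _, v in self.edges:
            indeg[v] += 1
        queue = sorted(n for n, d in indeg.items() if d == 0)
        order = []
        children = {n: [] for n in self._by_name}
        for u, v in self.edges:
            children[u].append(v)
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in sorted(children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
            queue.sort()
        return order if len(order) == len(self._by_name) else None

    def is_acyclic(self) -> bool:
        return self.topological_order() is not None

    def __eq__(self, other):
        return (
            isinstance(other, NetworkStructure)
            and self.node_names == other.node_names
            and self.edges == other.edges
        )

    def __hash__(self):
        return hash((tuple(self.node_names), frozenset(self.edges)))

    def __repr__(self):
        es = ", ".join(f"{u}->{v}" for u, v in sorted(self.edges))
        return f"<NetworkStructure nodes={len(self.variables)} edges=[{es}]>"

    def to_dot(self, name="network", edge_attrs=None) -> str:
        """Graphviz DOT export. ``edge_attrs`` maps edge -> attribute dict."""
        lines = [f"digraph {name} {{"]
        for v in self.variables:
            shape = "box" if v.is_discrete else "ellipse"
            extra = ', style=filled, fillcolor="lightblue"' if v.genetic else ""
            lines.append(f'  "{v.name}" [shape={shape}{extra}];')
        for u, v in sorted(self.edges):
            attrs = (edge_attrs or {}).get((u, v), {})
            a = (
                " [" + ", ".join(f'{k}="{val}"' for k, val in attrs.items()) + "]"
                if attrs
                else ""
            )
            lines.append(f'  "{u}" -> "{v}"{a};')
        lines.append("}")
        return "\n".join(lines)


class ConstraintSet:
    """Hard white/black edge lists plus soft directed-edge priors.

    ``soft_priors`` maps a directed edge ``(u, v)`` to p(e) in [0, 1]; the
    reverse direction automatically carries 1 - p(e).  Supplying both
    directions explicitly is accepted only if the two probabilities sum
    to 1.  Priors are stored canonically under one direction per pair.
    """

    def __init__(self, whitelist=(), blacklist=(), soft_priors=None):
        self.whitelist = {tuple(e) for e in whitelist}
        self.blacklist = {tuple(e) for e in blacklist}
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ConfigurationError(
                f"edges both whitelisted and blacklisted: {sorted(overlap)}"
            )
        self.soft_priors: dict = {}
        for (u, v), p in (soft_priors or {}).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prior p({u}->{v})={p} outside [0, 1]")
            if (v, u) in self.soft_priors:
                q = self.soft_priors[(v, u)]
                if abs(p + q - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"priors for both directions of {u}--{v} sum to "
                        f"{p + q}, not 1"
                    )
                continue  # reverse already stored; consistent
            self.soft_priors[(u, v)] = float(p)

    def is_empty(self) -> bool:
        return not (self.whitelist or self.blacklist or self.soft_priors)

    def prior_log_term(self, edges) -> float:
        """Sum of ln p(e) over prior-carrying edges present in ``edges``.

        A present edge whose prior (in that direction) is 0 yields -inf:
        the network is rejected outright.
        """
        total = 0.0
        for (u, v), p in self.soft_priors.items():
            if (u, v) in edges:
                total += math.log(p) if p > 0 else -math.inf
            if (v, u) in edges:
                q = 1.0 - p
                total += math.log(q) if q > 0 else -math.inf
        return total

    def must_connect_pairs(self) -> set:
        """Unordered pairs whitelisted in both directions (edge required,
        either orientation)."""
        return {
            frozenset((u, v))
            for (u, v) in self.whitelist
            if (v, u) in self.whitelist
        }

    def fixed_whitelist_edges(self) -> set:
        """Whitelist edges whose direction is pinned (only one direction
        listed)."""
        return {(u, v) for (u, v) in self.whitelist if (v, u) not in self.whitelist}

    def check_nodes(self, known):
        known = set(known)
        for u, v in itertools.chain(
            self.whitelist, self.blacklist, self.soft_priors
        ):
            if u not in known or v not in known:
                raise ConfigurationError(
                    f"constraint references unknown node in edge ({u}, {v})"
                )


@dataclass
class ValidityReport:
    """Outcome of structural validation; ``valid`` iff no violations."""

    violations: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, rule, detail):
        self.violations.append((rule, detail))

    def __repr__(self):
        if self.valid:
            return "<ValidityReport: valid>"
        items = "; ".join(f"{r}: {d}" for r, d in self.violations)
        return f"<ValidityReport: {items}>"


def validate_structure(dag: NetworkStructure, constraints: ConstraintSet = None):
    """Check every structural rule; report all violations.

    Rules: ``cycle``, ``genetic-in-edge`` (no arrow into a causal anchor),
    ``mixed-parent`` (no continuous parent of a discrete node),
    ``blacklist`` (forbidden edge present), ``whitelist-missing`` (required
    edge absent).  A whitelist entry pointing into a genetic node is a
    configuration error, not a recorded violation: the anchor semantics are
    absolute.
    """
    constraints = constraints or ConstraintSet()
    constraints.check_nodes(dag.node_names)
    for u, v in constraints.whitelist:
        if dag.spec(v).genetic and not (v, u) in constraints.whitelist:
            raise ConfigurationError(
                f"whitelist edge {u}->{v} points into genetic node {v!r}"
            )
    report = ValidityReport()
    if not dag.is_acyclic():
        report.add("cycle", "graph contains a directed cycle")
    for u, v in sorted(dag.edges):
        if dag.spec(v).genetic:
            report.add("genetic-in-edge", f"{u}->{v} enters genetic node {v}")
        if dag.spec(u).is_continuous and dag.spec(v).is_discrete:
            report.add("mixed-parent", f"discrete {v} has continuous parent {u}")
        if (u, v) in constraints.blacklist:
            report.add("blacklist", f"{u}->{v} is blacklisted")
    for pair in constraints.must_connect_pairs():
        u, v = sorted(pair)
        if (u, v) not in dag.edges and (v, u) not in dag.edges:
            report.add("whitelist-missing", f"required connection {u}--{v} absent")
    for u, v in constraints.fixed_whitelist_edges():
        if (u, v) not in dag.edges:
            report.add("whitelist-missing", f"required edge {u}->{v} absent")
    return report


class PDAG:
    """A partially directed graph: directed plus undirected edges.

    Equality of two CPDAGs decides observational equivalence of the DAGs
    they were computed from.
    """

    def __init__(self, nodes, directed=(), undirected=()):
        self.nodes = tuple(nodes)
        self.directed = frozenset((u, v) for u, v in directed)
        self.undirected = frozenset(frozenset((u, v)) for u, v in undirected)

    def __eq__(self, other):
        return (
            isinstance(other, PDAG)
            and set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __hash__(self):
        return hash((frozenset(self.nodes), self.directed, self.undirected))

    def __repr__(self):
        d = ", ".join(f"{u}->{v}" for u, v in sorted(self.directed))
        u_ = ", ".join("--".join(sorted(e)) for e in sorted(self.undirected, key=sorted))
        return f"<PDAG directed=[{d}] undirected=[{u_}]>"


def cpdag(dag: NetworkStructure) -> PDAG:
    """Completed partially directed graph of ``dag``'s equivalence class.

    Construction: keep the skeleton; orient exactly the v-structure edges
    (colliders x -> z <- y with x, y non-adjacent, which every equivalent
    DAG shares); close under the Meek orientation rules.  Edges left
    undirected vary in direction across the class.
    """
    nodes = dag.node_names
    adj = {n: dag.adjacent(n) for n in nodes}
    directed = set()  # compelled orientations
    skeleton = {frozenset((u, v)) for u, v in dag.edges}

    for z in nodes:
        ps = sorted(dag.parents(z))
        for x, y in itertools.combinations(ps, 2):
            if y not in adj[x]:
                directed.add((x, z))
                directed.add((y, z))

    def is_undirected(u, v):
        return (
            frozenset((u, v)) in skeleton
            and (u, v) not in directed
            and (v, u) not in directed
        )

    changed = True
    while changed:
        changed = False
        for e in skeleton:
            a, b = tuple(e)
            for u, v in ((a, b), (b, a)):
                if not is_undirected(u, v):
                    continue
                # Meek R1: w -> u, u -- v, w and v non-adjacent  =>  u -> v
                if any(
                    (w, u) in directed and v not in adj[w]
                    for w in adj[u]
                ):
                    directed.add((u, v))
                    changed = True
                    continue
                # Meek R2: u -> w -> v with u -- v  =>  u -> v
                if any(
                    (u, w) in directed and (w, v) in directed
                    for w in adj[u] & adj[v]
                ):
                    directed.add((u, v))
                    changed = True
                    continue
                # Meek R3: u -- w1, u -- w2, w1 -> v, w2 -> v,
                # w1, w2 non-adjacent  =>  u -> v
                ws = [
                    w
                    for w in adj[u] & adj[v]
                    if is_undirected(u, w) and (w, v) in directed
                ]
                if any(
                    w2 not in adj[w1]
                    for w1, w2 in itertools.combinations(ws, 2)
                ):
                    directed.add((u, v))
                    changed = True
    undirected = [
        tuple(e)
        for e in skeleton
        if tuple(e) not in directed and tuple(reversed(tuple(e))) not in directed
    ]
    return PDAG(nodes, directed, undirected)


def read_edge_list(path) -> set:
    """One directed edge per line: ``from<TAB>to``."""
    edges = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path} line {lineno}: expected 'from<TAB>to'"
                )
            edges.add((parts[0], parts[1]))
    return edges


def read_soft_priors(path) -> dict:
    """Soft priors file: ``from<TAB>to<TAB>p`` per line."""
    priors = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{path} line {lineno}: expected 'from<TAB>to<TAB>p'"
                )
            priors[(parts[0], parts[1])] = float(parts[2])
    return priors
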