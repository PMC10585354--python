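"""Differentiation-network topologies and their quasi-reaction expansions.

A differentiation network is a directed graph over cell lineages (HSC at the
root, mature blood cells at the leaves).  Each node may duplicate (x -> 2x)
and die (x -> 0); each directed edge i -> j is a differentiation reaction
(x_i -> 2 x_j, one parent cell becoming two committed daughters).  The
network expands into a stochastic quasi-reaction system with mass-action
hazards, and — when some lineages are unmeasured by the assay — into a
linear identifiability-constraint map that ties their rates to observed ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

BRANCHES = ("myeloid", "lymphoid", "none")


class TopologyError(ValueError):
    """Raised when a network definition is internally inconsistent."""


class UnidentifiableParameterError(ValueError):
    """Raised when a constrained rate has an empty resolving set."""


class UndefinedProbabilityError(ValueError):
    """Raised when a transition-probability denominator is zero."""


@dataclass(frozen=True)
class DifferentiationNetwork:
    """A candidate cell-differentiation topology.

    Parameters
    ----------
    nodes
        Ordered lineage names; the order fixes state-vector coordinates.
    observed
        Per-node flag: ``True`` if the assay measures this lineage.
    branch
        Per-node label in ``{"myeloid", "lymphoid", "none"}``; ``"none"``
        (typically the root and shared multipotent compartments) is treated
        as compatible with both branches when averaging sets are formed.
    ancestor
        Per-node parent lineage (``None`` for the root).
    edges
        Ordered directed differentiation pairs ``(i, j)``.
    dup, death
        Per-node flags enabling the duplication / death reactions.
    name
        Optional identifier (used in reports and exports).
    """

    nodes: tuple[str, ...]
    observed: tuple[bool, ...]
    branch: tuple[str, ...]
    ancestor: tuple[str | None, ...]
    edges: tuple[tuple[str, str], ...]
    dup: tuple[bool, ...]
    death: tuple[bool, ...]
    name: str = "network"

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise TopologyError("duplicate node names")
        for seq, what in [(self.observed, "observed"), (self.branch, "branch"),
                          (self.ancestor, "ancestor"), (self.dup, "dup"),
                          (self.death, "death")]:
            if len(seq) != n:
                raise TopologyError(f"{what} has length {len(seq)}, expected {n}")
        for b in self.branch:
            if b not in BRANCHES:
                raise TopologyError(f"unknown branch label {b!r}")
        for a in self.ancestor:
            if a is not None and a not in self.nodes:
                raise TopologyError(f"ancestor {a!r} is not a node")
        seen = set()
        for i, j in self.edges:
            if i not in self.nodes or j not in self.nodes:
                raise TopologyError(f"edge ({i}, {j}) references a missing node")
            if i == j:
                raise TopologyError(f"self-loop edge on {i}")
            if (i, j) in seen:
                raise TopologyError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))

    # -- basic queries ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def is_observed(self, node: str) -> bool:
        return self.observed[self.index(node)]

    def offspring(self, node: str) -> tuple[str, ...]:
        """Offspring set O(i): lineages reachable by one differentiation."""
        return tuple(j for i, j in self.edges if i == node)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(i for i, j in self.edges if j == node)

    def observed_nodes(self) -> tuple[str, ...]:
        return tuple(x for x, o in zip(self.nodes, self.observed) if o)

    def branch_of(self, node: str) -> str:
        return self.branch[self.index(node)]

    def ancestor_of(self, node: str) -> str | None:
        return self.ancestor[self.index(node)]

    def resolved_ancestor(self, node: str) -> str:
        """Nearest observed-or-root ancestor of ``node``.

        Walks up the ancestor chain and returns the first measured lineage
        encountered, or the chain's root if every ancestor is unmeasured.
        For the root itself (no ancestor) returns the node itself.  This is
        the comparison point used when forming averaging sets for rates of
        unmeasured lineages: two lineages are "siblings" for averaging
        purposes when their chains resolve to the same measured-or-root
        compartment.
        """
        a = self.ancestor_of(node)
        if a is None:
            return node
        while True:
            if self.is_observed(a):
                return a
            up = self.ancestor_of(a)
            if up is None:
                return a
            a = up

    def with_observed(self, observed: Mapping[str, bool]) -> "DifferentiationNetwork":
        """Return a copy with per-node observability overridden.

        A lineage measured in one study may be missing in another; datasets
        can therefore override the fixture's default flags.
        """
        new = list(self.observed)
        for node, flag in observed.items():
            new[self.index(node)] = bool(flag)
        return DifferentiationNetwork(
            nodes=self.nodes, observed=tuple(new), branch=self.branch,
            ancestor=self.ancestor, edges=self.edges, dup=self.dup,
            death=self.death, name=self.name)

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "DifferentiationNetwork":
        nodes = [nd["name"] for nd in d["nodes"]]
        return cls(
            nodes=tuple(nodes),
            observed=tuple(bool(nd.get("observed", True)) for nd in d["nodes"]),
            branch=tuple(str(nd.get("branch", "none")) for nd in d["nodes"]),
            ancestor=tuple(nd.get("ancestor") for nd in d["nodes"]),
            edges=tuple((str(e[0]), str(e[1])) for e in d.get("edges", [])),
            dup=tuple(bool(nd.get("dup", True)) for nd in d["nodes"]),
            death=tuple(bool(nd.get("death", True)) for nd in d["nodes"]),
            name=str(d.get("name", "network")),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [
                {"name": x, "observed": o, "branch": b, "ancestor": a,
                 "dup": du, "death": de}
                for x, o, b, a, du, de in zip(
                    self.nodes, self.observed, self.branch, self.ancestor,
                    self.dup, self.death)
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_yaml(cls, path) -> "DifferentiationNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_networkx(self, edge_probabilities: Mapping[tuple[str, str], float] | None = None):
        """Export as a :mod:`networkx` DiGraph (GraphML/DOT-writable)."""
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        for x, o, b in zip(self.nodes, self.observed, self.branch):
            g.add_node(x, observed=bool(o), branch=b)
        for i, j in self.edges:
            attrs = {}
            if edge_probabilities is not None and (i, j) in edge_probabilities:
                attrs["transition_probability"] = float(edge_probabilities[(i, j)])
            g.add_edge(i, j, **attrs)
        return g

    def to_dot(self, edge_probabilities: Mapping[tuple[str, str], float] | None = None
               ) -> str:
        """Graphviz DOT text with optional transition-probability weights."""
        lines = [f'digraph "{self.name}" {{']
        for x, o in zip(self.nodes, self.observed):
            style = "solid" if o else "dashed"
            lines.append(f'  "{x}" [style={style}];')
        for i, j in self.edges:
            attr = ""
            if edge_probabilities is not None and (i, j) in edge_probabilities:
                attr = (f' [transition_probability='
                        f'{edge_probabilities[(i, j)]:.6g}]')
            lines.append(f'  "{i}" -> "{j}"{attr};')
        lines.append("}")
        return "\n".join(lines)


REACTION_KINDS = ("duplication", "death", "differentiation")


@dataclass(frozen=True)
class Reaction:
    kind: str                  # duplication | death | differentiation
    source: int                # state index i(k)
    target: int | None         # state index j(k); differentiation only
    rate_name: str             # e.g. "alpha:HSC", "lambda:HSC->P1"


@dataclass(frozen=True)
class ReactionSystem:
    """The K quasi-reactions of a network, with net-effect matrix V (n x K).

    Reaction (and rate-coordinate) order is fixed: duplications in node
    order, then deaths in node order, then differentiations in edge
    declaration order.  The rate vector theta shares this layout, so
    ``rate_index`` is the identity permutation; it is kept explicit so that
    downstream code never relies on the coincidence.
    """

    network: DifferentiationNetwork
    reactions: tuple[Reaction, ...]
    net_effect_matrix: np.ndarray          # (n, K) int
    rate_index: np.ndarray                 # (K,) int: reaction -> theta coord
    source_index: np.ndarray               # (K,) int

    @property
    def n(self) -> int:
        return self.network.n

    @property
    def K(self) -> int:
        return len(self.reactions)

    @property
    def n_rates(self) -> int:
        return self.K

    @property
    def rate_names(self) -> tuple[str, ...]:
        return tuple(r.rate_name for r in self.reactions)

    @cached_property
    def net_effect_float(self) -> np.ndarray:
        """Float view of V, cached (the integer matrix is authoritative)."""
        return self.net_effect_matrix.astype(float)


def build_reaction_system(net: DifferentiationNetwork) -> ReactionSystem:
    """Expand a network into its quasi-reaction system.

    One duplication and one death reaction per flagged node, one
    differentiation reaction per edge.  Net-effect columns: duplication +1
    on the source; death -1; differentiation -1 on the source and +2 on the
    target (one parent cell leaves compartment i, two daughters enter j).
    """
    n = net.n
    reactions: list[Reaction] = []
    cols: list[np.ndarray] = []

    for i, node in enumerate(net.nodes):
        if net.dup[i]:
            v = np.zeros(n, dtype=int)
            v[i] = 1
            reactions.append(Reaction("duplication", i, None, f"alpha:{node}"))
            cols.append(v)
    for i, node in enumerate(net.nodes):
        if net.death[i]:
            v = np.zeros(n, dtype=int)
            v[i] = -1
            reactions.append(Reaction("death", i, None, f"delta:{node}"))
            cols.append(v)
    for src, dst in net.edges:
        i, j = net.index(src), net.index(dst)
        v = np.zeros(n, dtype=int)
        v[i] = -1
        v[j] = 2
        reactions.append(Reaction("differentiation", i, j, f"lambda:{src}->{dst}"))
        cols.append(v)

    V = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=int)
    K = len(reactions)
    return ReactionSystem(
        network=net,
        reactions=tuple(reactions),
        net_effect_matrix=V,
        rate_index=np.arange(K),
        source_index=np.array([r.source for r in reactions], dtype=int),
    )


@dataclass
class RateParameters:
    """Full dynamic-rate vector theta = (alpha, delta, lambda) for a system.

    The flattened layout matches :class:`ReactionSystem`'s reaction order.
    """

    rs: ReactionSystem
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.rs.n_rates,):
            raise ValueError(
                f"theta has shape {self.values.shape}, expected ({self.rs.n_rates},)")
        if np.any(self.values < 0):
            raise ValueError("rates must be nonnegative")

    @classmethod
    def from_mapping(cls, rs: ReactionSystem, rates: Mapping[str, float],
                     default: float = 0.0) -> "RateParameters":
        return cls(rs, np.array([float(rates.get(nm, default))
                                 for nm in rs.rate_names]))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.rs.rate_names, map(float, self.values)))

    def rate(self, name: str) -> float:
        return float(self.values[self.rs.rate_names.index(name)])

    def alpha(self, node: str) -> float:
        return self.rate(f"alpha:{node}")

    def lam(self, src: str, dst: str) -> float:
        return self.rate(f"lambda:{src}->{dst}")


@dataclass(frozen=True)
class ConstraintMap:
    """Linear map theta_full = C @ theta_free enforcing identifiability.

    Rates whose reactions touch only unmeasured lineages cannot be told
    apart by the likelihood; they are re-expressed as nonnegative linear
    combinations (sums along the tree, or averages over measured siblings)
    of identifiable rates.  C has nonnegative entries, so a nonnegative free
    vector always expands to a nonnegative full vector.
    """

    matrix: np.ndarray                     # (p, p_free)
    full_names: tuple[str, ...]
    free_names: tuple[str, ...]
    descriptions: tuple[str, ...]          # human-readable, one per constrained coord

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def p_free(self) -> int:
        return self.matrix.shape[1]

    def expand(self, theta_free: np.ndarray) -> np.ndarray:
        theta_free = np.asarray(theta_free, dtype=float)
        return self.matrix @ theta_free

    def reduce_initial(self, theta_full: np.ndarray) -> np.ndarray:
        """Project a full vector onto free coordinates (for warm starts)."""
        free_pos = [self.full_names.index(nm) for nm in self.free_names]
        return np.asarray(theta_full, dtype=float)[free_pos]


def _topological_order(net: DifferentiationNetwork) -> list[str]:
    import networkx as nx

    g = net.to_networkx()
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:   # cyclic differentiation graph
        raise TopologyError("differentiation edges contain a cycle; "
                            "constraint resolution needs a DAG") from exc


def _branch_compatible(b1: str, b2: str) -> bool:
    return b1 == "none" or b2 == "none" or b1 == b2


def build_constraint_map(net: DifferentiationNetwork,
                         use_conservation: bool = True,
                         use_averaging: bool = True) -> ConstraintMap:
    """Build the identifiability-constraint map C for a network.

    Constrained coordinates (those whose reaction involves only unmeasured
    lineages) are resolved as follows, walking nodes from the leaves toward
    the root so that chained unmeasured compartments compose:

    * a differentiation rate a->b between unmeasured lineages where b has
      outgoing edges becomes the *sum* of b's outgoing rates (conservation:
      cells flowing into b are the cells flowing out of it);
    * otherwise it becomes the *mean* of a's differentiation rates into its
      measured offspring;
    * duplication/death rates of an unmeasured lineage become the mean of
      the corresponding rates of measured lineages in a compatible branch
      whose nearest measured-or-root ancestor coincides with its own.

    Raises :class:`UnidentifiableParameterError` when a resolving set is
    empty.
    """
    rs = build_reaction_system(net)
    full_names = list(rs.rate_names)
    p = len(full_names)

    def is_constrained(r: Reaction) -> bool:
        src = net.nodes[r.source]
        if r.kind == "differentiation":
            dst = net.nodes[r.target]
            return (use_conservation or use_averaging) and \
                not net.is_observed(src) and not net.is_observed(dst)
        return use_averaging and not net.is_observed(src)

    constrained = {nm for r, nm in zip(rs.reactions, full_names)
                   if is_constrained(r)}
    free_names = [nm for nm in full_names if nm not in constrained]
    free_pos = {nm: k for k, nm in enumerate(free_names)}

    # expression of each full coordinate in the free basis
    expr: dict[str, np.ndarray] = {}
    for nm in free_names:
        e = np.zeros(len(free_names))
        e[free_pos[nm]] = 1.0
        expr[nm] = e

    descriptions: list[str] = []
    order = _topological_order(net)
    # deepest nodes first, so an edge's target-side rates are resolved
    # before the edge itself is
    for node in reversed(order):
        # lambda rates into `node`
        for src in net.parents(node):
            nm = f"lambda:{src}->{node}"
            if nm not in constrained or nm in expr:
                continue
            offspring = net.offspring(node)
            if use_conservation and offspring:
                e = np.zeros(len(free_names))
                for c in offspring:
                    e += expr[f"lambda:{node}->{c}"]
                expr[nm] = e
                descriptions.append(
                    f"{nm} = sum of outgoing differentiation rates of {node}")
            elif use_averaging:
                obs_off = [c for c in net.offspring(src) if net.is_observed(c)]
                if not obs_off:
                    raise UnidentifiableParameterError(
                        f"{nm}: {node} has no outgoing edges and {src} has no "
                        f"measured offspring to average over")
                e = np.zeros(len(free_names))
                for c in obs_off:
                    e += expr[f"lambda:{src}->{c}"] / len(obs_off)
                expr[nm] = e
                descriptions.append(
                    f"{nm} = mean differentiation rate of {src} into its "
                    f"measured offspring {obs_off}")
            else:
                raise UnidentifiableParameterError(
                    f"{nm}: no enabled constraint rule applies "
                    f"(conservation={use_conservation}, averaging={use_averaging})")
        # alpha / delta of `node`
        for prefix, flag in (("alpha", net.dup[net.index(node)]),
                             ("delta", net.death[net.index(node)])):
            nm = f"{prefix}:{node}"
            if not flag or nm not in constrained or nm in expr:
                continue
            anchor = net.resolved_ancestor(node)
            b = net.branch_of(node)
            mates = [
                o for o in net.observed_nodes()
                if _branch_compatible(b, net.branch_of(o))
                and net.resolved_ancestor(o) == anchor
                and f"{prefix}:{o}" in expr
            ]
            if not mates:
                raise UnidentifiableParameterError(
                    f"{nm}: no measured branch-mates share the resolved "
                    f"ancestor {anchor!r}")
            e = np.zeros(len(free_names))
            for o in mates:
                e += expr[f"{prefix}:{o}"] / len(mates)
            expr[nm] = e
            descriptions.append(
                f"{nm} = mean {prefix} of measured branch-mates {mates}")

    C = np.zeros((p, len(free_names)))
    for row, nm in enumerate(full_names):
        if nm not in expr:
            raise UnidentifiableParameterError(
                f"{nm} could not be resolved to free coordinates")
        C[row] = expr[nm]
    return ConstraintMap(matrix=C, full_names=tuple(full_names),
                         free_names=tuple(free_names),
                         descriptions=tuple(descriptions))


def transition_probabilities(net: DifferentiationNetwork,
                             theta: RateParameters) -> dict[tuple[str, str], float]:
    """Multinomial differentiation probabilities p_ij per edge.

    ``p_ij = lambda_ij / (alpha_i + sum_k lambda_ik)``: the probability that
    lineage i's next event is commitment into j rather than self-renewal or
    another commitment.  Per source the probabilities sum to at most 1,
    with equality exactly when the source does not self-renew.
    """
    probs: dict[tuple[str, str], float] = {}
    for node in net.nodes:
        offspring = net.offspring(node)
        if not offspring:
            continue
        i = net.index(node)
        alpha = theta.alpha(node) if net.dup[i] else 0.0
        denom = alpha + sum(theta.lam(node, j) for j in offspring)
        if denom <= 0:
            raise UndefinedProbabilityError(
                f"zero denominator for source {node}: alpha + outgoing "
                f"lambdas must be positive")
        for j in offspring:
            probs[(node, j)] = theta.lam(node, j) / denom
    return probs
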