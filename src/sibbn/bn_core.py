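"""Data model for discrete Bayesian belief networks.

A network is a directed acyclic graph over categorical nodes.  Each node
carries an ordered list of state labels and a conditional probability table
(CPT): one probability vector over the node's states for every combination
of its parents' states.  The ordered state list declared on the node is the
single source of truth for column order everywhere (CPT vectors,
serialization, ROC scoring).

CPT rows are keyed by explicit parent-state tuples rather than positional
index so that hand-built deterministic tables remain auditable.  A CPT may
be ``locked``, marking it as fixed: parameter learning never touches it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NodeDef",
    "CPT",
    "NetworkSpec",
    "NetworkValidationError",
    "build_network",
    "topological_order",
    "joint_probability",
]

#: Roles a node can play in the sanitary-inspection models.
NODE_ROLES = ("outer_SI", "intermediate", "water_quality", "treatment", "external")

_PROB_TOL = 1e-9


class NetworkValidationError(ValueError):
    """Raised when a network, node or CPT violates a structural invariant."""


@dataclass(frozen=True)
class NodeDef:
    """A categorical node: a name, an ordered state list and a role."""

    name: str
    states: tuple[str, ...]
    role: str = "external"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise NetworkValidationError(f"node {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise NetworkValidationError(f"node {self.name!r} has duplicate states")
        if self.role not in NODE_ROLES:
            raise NetworkValidationError(
                f"node {self.name!r}: unknown role {self.role!r}"
            )

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise NetworkValidationError(
                f"unknown state {state!r} for node {self.name!r}"
            ) from None


@dataclass
class CPT:
    """Conditional probability table of one child node.

    ``table`` maps each full parent-state combination (a tuple ordered like
    ``parents``) to a probability vector ordered like the child's state list.
    Roots use the empty tuple ``()`` as their single key.
    """

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[str, ...], np.ndarray]
    locked: bool = False

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = {
            tuple(k): np.asarray(v, dtype=float) for k, v in self.table.items()
        }

    def row(self, parent_states: tuple[str, ...]) -> np.ndarray:
        return self.table[tuple(parent_states)]

    def copy(self) -> "CPT":
        return CPT(
            child=self.child,
            parents=self.parents,
            table={k: v.copy() for k, v in self.table.items()},
            locked=self.locked,
        )


@dataclass
class NetworkSpec:
    """A validated network: nodes plus exactly one CPT per node.

    The edge set is implied by the CPT parent lists.  Instances should be
    built through :func:`build_network`, which enforces every invariant.
    """

    nodes: dict[str, NodeDef]
    cpts: dict[str, CPT]
    _order: list[str] = field(default_factory=list, repr=False)

    # -- structure ---------------------------------------------------------

    def node(self, name: str) -> NodeDef:
        try:
            return self.nodes[name]
        except KeyError:
            raise NetworkValidationError(f"unknown node {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        return self.node(name).states

    def parents(self, name: str) -> tuple[str, ...]:
        return self.cpts[name].parents

    def children(self, name: str) -> list[str]:
        return sorted(c for c, cpt in self.cpts.items() if name in cpt.parents)

    @property
    def node_names(self) -> list[str]:
        return list(self.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, cpt in self.cpts.items() for p in cpt.parents]

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            nodes=dict(self.nodes),
            cpts={n: c.copy() for n, c in self.cpts.items()},
            _order=list(self._order),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Documented JSON layout: nodes (name/states/role), then per-node
        parents and rows keyed by '|'-joined parent states."""
        return {
            "nodes": [
                {"name": n.name, "states": list(n.states), "role": n.role}
                for n in self.nodes.values()
            ],
            "cpts": [
                {
                    "child": c.child,
                    "parents": list(c.parents),
                    "locked": c.locked,
                    "rows": {
                        "|".join(k): [float(x) for x in v]
                        for k, v in sorted(c.table.items())
                    },
                }
                for c in self.cpts.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        nodes = [NodeDef(x["name"], tuple(x["states"]), x["role"]) for x in d["nodes"]]
        cpts = [
            CPT(
                child=x["child"],
                parents=tuple(x["parents"]),
                locked=x["locked"],
                table={
                    tuple(k.split("|")) if k else (): np.array(v, dtype=float)
                    for k, v in x["rows"].items()
                },
            )
            for x in d["cpts"]
        ]
        return build_network(nodes, cpts)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _parent_combinations(net_nodes: dict[str, NodeDef], parents: tuple[str, ...]):
    return itertools.product(*(net_nodes[p].states for p in parents))


def build_network(nodes: list[NodeDef], cpts: list[CPT]) -> NetworkSpec:
    """Validate nodes and CPTs and assemble a :class:`NetworkSpec`.

    Raises :class:`NetworkValidationError` on duplicate nodes, missing or
    extra CPTs, missing or surplus CPT rows, rows that do not sum to one,
    unknown parents, or a cyclic edge set.
    """
    if not nodes or not cpts:
        raise NetworkValidationError("nodes and cpts must be non-empty")
    node_map: dict[str, NodeDef] = {}
    for n in nodes:
        if n.name in node_map:
            raise NetworkValidationError(f"duplicate node {n.name!r}")
        node_map[n.name] = n

    cpt_map: dict[str, CPT] = {}
    for c in cpts:
        if c.child not in node_map:
            raise NetworkValidationError(f"CPT for unknown node {c.child!r}")
        if c.child in cpt_map:
            raise NetworkValidationError(f"duplicate CPT for {c.child!r}")
        cpt_map[c.child] = c
    missing = set(node_map) - set(cpt_map)
    if missing:
        raise NetworkValidationError(f"nodes without CPT: {sorted(missing)}")

    g = nx.DiGraph()
    g.add_nodes_from(node_map)
    for c in cpt_map.values():
        for p in c.parents:
            if p not in node_map:
                raise NetworkValidationError(
                    f"CPT of {c.child!r} names unknown parent {p!r}"
                )
            g.add_edge(p, c.child)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise NetworkValidationError(f"cycle detected: {cycle}")

    for c in cpt_map.values():
        child = node_map[c.child]
        expected = set(_parent_combinations(node_map, c.parents))
        got = set(c.table)
        n_required = int(np.prod([len(node_map[p].states) for p in c.parents]))
        if got != expected:
            raise NetworkValidationError(
                f"CPT of {c.child!r}: {len(got)} rows, {n_required} required "
                f"(missing {len(expected - got)}, extra {len(got - expected)})"
            )
        for key, vec in c.table.items():
            if vec.shape != (len(child.states),):
                raise NetworkValidationError(
                    f"CPT of {c.child!r}, row {key}: length {vec.shape} != "
                    f"{len(child.states)} states"
                )
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > _PROB_TOL:
                raise NetworkValidationError(
                    f"CPT of {c.child!r}, row {key}: not a distribution "
                    f"(sum={vec.sum()!r})"
                )

    # deterministic topological order, name-order tie-break
    order = list(nx.lexicographical_topological_sort(g))
    return NetworkSpec(nodes=node_map, cpts=cpt_map, _order=order)


def topological_order(net: NetworkSpec) -> list[str]:
    """Node names, every node after all its parents; ties broken by name."""
    if net._order:
        return list(net._order)
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges())
    return list(nx.lexicographical_topological_sort(g))


def joint_probability(net: NetworkSpec, assignment: dict[str, str]) -> float:
    """Chain-rule probability of one full assignment.

    ``assignment`` must name a legal state for every node in the network.
    """
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise NetworkValidationError(f"assignment misses nodes: {sorted(missing)}")
    p = 1.0
    for name, cpt in net.cpts.items():
        node = net.nodes[name]
        idx = node.state_index(assignment[name])
        key = tuple(assignment[q] for q in cpt.parents)
        p *= float(cpt.table[key][idx])
        if p == 0.0:
            return 0.0
    return p
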