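"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's inference path: they work
straight off the CPT dictionaries by exhaustive enumeration of full joint
assignments, so they can certify variable elimination, EM likelihoods and
scenario posteriors from the outside.
"""

import itertools

import numpy as np
import pytest

from sibbn.bn_core import CPT, NetworkSpec, NodeDef, build_network

# ---------------------------------------------------------------- oracles


def enum_joint(net: NetworkSpec, assignment: dict) -> float:
    """Chain-rule joint computed directly from the CPT dicts."""
    p = 1.0
    for name, cpt in net.cpts.items():
        states = net.nodes[name].states
        key = tuple(assignment[q] for q in cpt.parents)
        p *= cpt.table[key][states.index(assignment[name])]
    return float(p)


def enum_all_assignments(net: NetworkSpec):
    names = list(net.nodes)
    for combo in itertools.product(*(net.nodes[n].states for n in names)):
        yield dict(zip(names, combo))


def enum_evidence_probability(net: NetworkSpec, ev: dict) -> float:
    total = 0.0
    for a in enum_all_assignments(net):
        if all(a[k] == v for k, v in ev.items()):
            total += enum_joint(net, a)
    return total


def enum_posterior(net: NetworkSpec, query: str, ev: dict) -> np.ndarray:
    states = net.nodes[query].states
    vals = np.zeros(len(states))
    for a in enum_all_assignments(net):
        if all(a[k] == v for k, v in ev.items()):
            vals[states.index(a[query])] += enum_joint(net, a)
    z = vals.sum()
    if z == 0:
        raise ZeroDivisionError("evidence has zero probability")
    return vals / z


def auc_pairwise(scores, labels) -> float:
    """O(n²) Mann–Whitney AUC by explicit pairwise comparison."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ----------------------------------------------------------- net builders


def make_net(spec: dict[str, tuple[tuple[str, ...], dict]],
             states: dict[str, tuple[str, ...]]) -> NetworkSpec:
    """Terse builder: spec maps child -> (parents, {parent_combo: probs})."""
    nodes = [NodeDef(n, states[n]) for n in states]
    cpts = [
        CPT(child=c, parents=parents,
            table={k: np.array(v, float) for k, v in table.items()})
        for c, (parents, table) in spec.items()
    ]
    return build_network(nodes, cpts)


def random_network(rng: np.random.Generator, n_nodes: int,
                   max_states: int = 3, max_parents: int = 3) -> NetworkSpec:
    """Random DAG with Dirichlet CPT rows; parents drawn from earlier nodes."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    nodes, cpts = [], []
    for i, name in enumerate(names):
        k = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(k))
        nodes.append(NodeDef(name, states))
        n_par = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(
            names[j] for j in sorted(rng.choice(i, size=n_par, replace=False))
        ) if n_par else ()
        table = {}
        for combo in itertools.product(*(nodes[names.index(p)].states
                                         for p in parents)):
            table[combo] = rng.dirichlet(np.ones(k))
        cpts.append(CPT(child=name, parents=parents, table=table))
    return build_network(nodes, cpts)


def random_evidence(rng: np.random.Generator, net: NetworkSpec,
                    n_obs: int, exclude: set[str] = frozenset()) -> dict:
    candidates = [n for n in net.nodes if n not in exclude]
    chosen = rng.choice(len(candidates), size=min(n_obs, len(candidates)),
                        replace=False)
    return {
        candidates[i]: net.nodes[candidates[i]].states[
            int(rng.integers(len(net.nodes[candidates[i]].states)))
        ]
        for i in chosen
    }


# --------------------------------------------------------------- fixtures


@pytest.fixture
def chain_net():
    """A → B → C, all binary, asymmetric CPTs."""
    states = {"A": ("a0", "a1"), "B": ("b0", "b1"), "C": ("c0", "c1")}
    return make_net({
        "A": ((), {(): (0.3, 0.7)}),
        "B": (("A",), {("a0",): (0.9, 0.1), ("a1",): (0.2, 0.8)}),
        "C": (("B",), {("b0",): (0.6, 0.4), ("b1",): (0.25, 0.75)}),
    }, states)


@pytest.fixture
def collider_net():
    """A → C ← B with an extra leaf D ← C; used for d-separation checks."""
    states = {"A": ("a0", "a1"), "B": ("b0", "b1"),
              "C": ("c0", "c1"), "D": ("d0", "d1")}
    return make_net({
        "A": ((), {(): (0.4, 0.6)}),
        "B": ((), {(): (0.7, 0.3)}),
        "C": (("A", "B"), {
            ("a0", "b0"): (0.9, 0.1), ("a0", "b1"): (0.5, 0.5),
            ("a1", "b0"): (0.3, 0.7), ("a1", "b1"): (0.1, 0.9),
        }),
        "D": (("C",), {("c0",): (0.8, 0.2), ("c1",): (0.35, 0.65)}),
    }, states)


def monotone_config(rng: np.random.Generator, variant: str):
    """A randomized but always risk-monotone generator configuration."""
    from sibbn.synthetic_data import GeneratorConfig

    def inc(lo, hi, k):
        steps = rng.uniform(lo, hi, size=k - 1)
        return tuple(np.concatenate([[0.0], np.cumsum(steps)]))

    return GeneratorConfig(
        variant=variant,
        outcome_base=float(rng.uniform(-4.0, -2.5)),
        beta_poc_detected=float(rng.uniform(0.8, 2.0)),
        beta_no_hwt=float(rng.uniform(0.3, 1.2)),
        beta_env=inc(0.2, 0.6, 3),
        beta_storage=inc(0.15, 0.5, 3),
        beta_fullness=tuple(reversed(inc(0.1, 0.4, 5))),
        well_logit_base=float(rng.uniform(-2.8, -1.8)),
        well_logit_per_risk=float(rng.uniform(0.4, 0.8)),
    )
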