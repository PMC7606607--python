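"""Exact posterior inference by variable elimination.

Used for prediction, the E-step of EM, ΔP sweeps and scenario simulation.
The networks in this package are tiny (≤ ~20 nodes), so probabilities are
kept in linear space with a per-step renormalization whose scale is tracked,
which keeps the results directly comparable with a brute-force enumeration
oracle.  The elimination order is the min-degree heuristic with a node-name
tie-break: determinism matters here, optimality does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bn_core import NetworkSpec, NetworkValidationError

__all__ = [
    "Evidence",
    "InferenceResult",
    "ImpossibleEvidenceError",
    "posterior",
    "evidence_probability",
    "predict_outcome",
]

Evidence = dict  # mapping node -> observed state; may be empty


class ImpossibleEvidenceError(ValueError):
    """The evidence set has probability exactly zero under the network.

    Distinguished from numerical underflow: it is raised only when the
    summed-out probability of the evidence is exactly 0.0.
    """


@dataclass
class InferenceResult:
    """Posterior distribution over one query node given evidence."""

    query: str
    states: tuple[str, ...]
    posterior: np.ndarray
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, state: str) -> float:
        return float(self.posterior[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.posterior)}


class _Factor:
    """A nonnegative table over a tuple of variables (axes in order)."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = variables
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(out_vars)
        b = other._broadcast(out_vars)
        return _Factor(out_vars, a * b)

    def _broadcast(self, out_vars: tuple[str, ...]) -> np.ndarray:
        # move existing axes into position, add length-1 axes for the rest
        src = [self.vars.index(v) for v in out_vars if v in self.vars]
        arr = np.transpose(self.values, src) if self.vars else self.values
        shape = [arr.shape[[v for v in out_vars if v in self.vars].index(v)]
                 if v in self.vars else 1 for v in out_vars]
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax)
        )


def _check_evidence(net: NetworkSpec, ev: dict[str, str]) -> None:
    for node, state in ev.items():
        net.node(node).state_index(state)


def _cpt_factor(net: NetworkSpec, child: str, ev: dict[str, str]) -> _Factor:
    cpt = net.cpts[child]
    axes = cpt.parents + (child,)
    shape = tuple(len(net.states(v)) for v in axes)
    arr = np.empty(shape)
    for key, vec in cpt.table.items():
        idx = tuple(net.node(p).state_index(s) for p, s in zip(cpt.parents, key))
        arr[idx] = vec
    # reduce observed axes to the observed state
    keep_vars, slicer = [], []
    for v in axes:
        if v in ev:
            slicer.append(net.node(v).state_index(ev[v]))
        else:
            keep_vars.append(v)
            slicer.append(slice(None))
    return _Factor(tuple(keep_vars), arr[tuple(slicer)])


def _eliminate(net: NetworkSpec, keep: set[str], ev: dict[str, str],
               order: list[str] | None = None) -> tuple[_Factor, float]:
    """Sum out every hidden variable not in ``keep``.

    Returns the product factor over ``keep`` (unnormalized) together with a
    scale such that ``scale * factor.sum()`` equals P(evidence ∧ keep-margin).
    """
    factors = [_cpt_factor(net, child, ev) for child in net.cpts]
    hidden = [v for v in net.nodes if v not in keep and v not in ev]
    if order is None:
        order = _min_degree_order(factors, hidden)
    else:
        assert sorted(order) == sorted(hidden)

    log_scale = 0.0
    for var in order:
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        prod = prod.sum_out(var)
        tot = float(prod.values.sum())
        if tot > 0.0:  # renormalize, tracking the scale
            prod = _Factor(prod.vars, prod.values / tot)
            log_scale += np.log(tot)
        factors.append(prod)

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    return result, float(np.exp(log_scale))


def _min_degree_order(factors: list[_Factor], hidden: list[str]) -> list[str]:
    # interaction graph over the hidden variables only
    neighbors: dict[str, set[str]] = {v: set() for v in hidden}
    cliques = [set(f.vars) for f in factors]
    order: list[str] = []
    remaining = set(hidden)
    while remaining:
        for v in remaining:
            nb = set()
            for cl in cliques:
                if v in cl:
                    nb |= cl
            neighbors[v] = (nb & remaining) - {v}
        var = min(remaining, key=lambda v: (len(neighbors[v]), v))
        merged = {var}
        new_cliques = []
        for cl in cliques:
            if var in cl:
                merged |= cl
            else:
                new_cliques.append(cl)
        merged.discard(var)
        new_cliques.append(merged)
        cliques = new_cliques
        remaining.discard(var)
        order.append(var)
    return order


def posterior(net: NetworkSpec, query: str, ev: Evidence | None = None,
              order: list[str] | None = None) -> InferenceResult:
    """Exact marginal P(query | evidence) by variable elimination.

    Raises :class:`ImpossibleEvidenceError` when the evidence set has zero
    probability.  ``order`` optionally fixes the elimination order of the
    hidden variables (used by tests to check order invariance).
    """
    ev = dict(ev or {})
    _check_evidence(net, ev)
    net.node(query)
    if query in ev:
        raise ValueError(f"query node {query!r} is part of the evidence")
    factor, scale = _eliminate(net, {query}, ev, order=order)
    vals = factor._broadcast((query,)) * scale
    z = float(vals.sum())
    if z == 0.0:
        raise ImpossibleEvidenceError(f"evidence {ev!r} has probability 0")
    return InferenceResult(
        query=query, states=net.states(query), posterior=vals / z, evidence=ev
    )


def evidence_probability(net: NetworkSpec, ev: Evidence | None = None) -> float:
    """P(evidence): the joint summed over all unobserved nodes."""
    ev = dict(ev or {})
    _check_evidence(net, ev)
    factor, scale = _eliminate(net, set(), ev)
    return float(factor.values) * scale


def predict_outcome(net: NetworkSpec, record: dict[str, str | None],
                    outcome: str, state: str) -> float:
    """P(outcome = state | the non-missing fields of one survey record).

    Missing fields (``None`` values) are simply absent from the evidence and
    therefore marginalized over; the outcome itself is never conditioned on.
    """
    ev = {
        k: v for k, v in record.items()
        if v is not None and k != outcome and k in net.nodes
    }
    res = posterior(net, outcome, ev)
    return res[state]
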