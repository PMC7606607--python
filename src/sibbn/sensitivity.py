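"""Predictive inference (ΔP sweeps) and best-scenario simulation.

Predictive inference asks, node by node: if every household were in a given
state of that node (hard evidence, posterior mass 1), what would the updated
probability of the outcome's designated state be?  A node's ΔP is the spread
— maximum minus minimum — of that updated probability across its states, in
percentage points; large ΔP marks an influential node.  The best-scenario
simulation asserts the best state of every scored outer variable at once,
plus treatment performed and no contamination at the source, and compares
the updated outcome probability with the no-evidence baseline.

Updated probabilities are kept at full precision internally and reported
in percent; rounding to integers happens only at the presentation layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .bn_core import NetworkSpec
from .inference import ImpossibleEvidenceError, posterior
from .si_model import (
    ECOLI_POC,
    ECOLI_POU,
    ENV_PARENTS,
    FULLNESS,
    HWT,
    STORAGE_PARENTS,
    VARIABLES,
    WELL_SI_PARENTS,
    ModelVariant,
)

__all__ = [
    "DeltaPTable",
    "Scenario",
    "predictive_inference",
    "run_scenario",
    "best_states",
    "delta_p",
]


def delta_p(updated: dict[str, float]) -> float:
    """Spread of updated probabilities across a node's states (max − min)."""
    vals = [v for v in updated.values() if v is not None]
    if not vals:
        return 0.0
    return max(vals) - min(vals)


@dataclass
class DeltaPTable:
    """Machine twin of a predictive-inference table.

    ``updated`` maps node → state → updated probability of the designated
    outcome state, in percent (``None`` marks a state with zero prior
    probability, excluded from ΔP); ``dp`` maps node → ΔP in percentage
    points; ``baseline`` is the no-evidence outcome probability in percent.
    """

    outcome: str
    designated_state: str
    baseline: float
    updated: dict[str, dict[str, float | None]]
    dp: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dp:
            self.dp = {n: delta_p(u) for n, u in self.updated.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: node, state, updated %, ΔP (repeated per node)."""
        rows = []
        for node, states in self.updated.items():
            for state, val in states.items():
                rows.append({
                    "node": node,
                    "state": state,
                    "updated_pct": val,
                    "delta_p": self.dp[node],
                })
        return pd.DataFrame(rows)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.dp.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class Scenario:
    """Joint hard evidence on a set of nodes (never the outcome)."""

    evidence: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Scenario":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.evidence)


def predictive_inference(net: NetworkSpec, outcome: str = ECOLI_POU,
                         designated_state: str = "not_detected") -> DeltaPTable:
    """Sweep every node and state, recording the updated outcome probability.

    For each node ≠ outcome and each of its states, computes
    P(outcome = designated_state | node = state) as a percent.  States with
    zero prior probability have no defined update; they are reported as
    ``None`` with a warning and excluded from the node's ΔP.
    """
    base = posterior(net, outcome, {})[designated_state] * 100.0
    updated: dict[str, dict[str, float | None]] = {}
    for node in net.node_names:
        if node == outcome:
            continue
        prior = posterior(net, node, {})
        per_state: dict[str, float | None] = {}
        for state in net.states(node):
            if prior[state] == 0.0:
                warnings.warn(
                    f"state {node}={state} has zero prior probability; "
                    f"updated probability undefined, excluded from ΔP"
                )
                per_state[state] = None
                continue
            res = posterior(net, outcome, {node: state})
            per_state[state] = res[designated_state] * 100.0
        updated[node] = per_state
    return DeltaPTable(
        outcome=outcome,
        designated_state=designated_state,
        baseline=base,
        updated=updated,
    )


def run_scenario(net: NetworkSpec, sc: Scenario | dict,
                 outcome: str = ECOLI_POU,
                 designated_state: str = "not_detected",
                 ) -> tuple[float, float]:
    """Updated outcome probability (percent) under a scenario, plus baseline.

    Raises :class:`~sibbn.inference.ImpossibleEvidenceError` when the joint
    evidence has probability zero.
    """
    if isinstance(sc, dict):
        sc = Scenario.from_dict(sc)
    ev = sc.as_dict()
    if outcome in ev:
        raise ValueError("scenario must not assert the outcome node")
    baseline = posterior(net, outcome, {})[designated_state] * 100.0
    try:
        updated = posterior(net, outcome, ev)[designated_state] * 100.0
    except ImpossibleEvidenceError:
        raise
    return updated, baseline


def best_states(variant: ModelVariant | str) -> Scenario:
    """The best-case scenario of one variant: every scored outer variable at
    its best state, treatment performed, source water clean, and (for B
    variants) a full storage container.  Intermediates are never asserted —
    their deterministic tables imply them."""
    variant = ModelVariant.parse(variant)
    ev: dict[str, str] = {}
    for name in ENV_PARENTS + STORAGE_PARENTS:
        ev[name] = VARIABLES[name].best_state
    if variant.poc_mode == "well_si":
        for name in WELL_SI_PARENTS:
            ev[name] = VARIABLES[name].best_state
    ev[HWT] = "yes_treat"
    ev[ECOLI_POC] = "not_detected"
    if variant.fullness_included:
        ev[FULLNESS] = "full"
    return Scenario.from_dict(ev)
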