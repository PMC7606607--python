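"""The four sanitary-inspection network variants (1A, 1B, 2A, 2B).

The models link household drinking-water quality at the point of use (POU)
to the water quality at the point of collection (POC), household water
treatment (HWT), and two cluster-summary ("intermediate") nodes built from
scored sanitary-inspection (SI) observations:

* the *water storage* cluster — storage covered, storage cracked, place of
  storage — summarized as the chance of (re)contamination from storage;
* the *surrounding environment / hygiene* cluster — open defecation,
  livestock near the house, floor cleanliness, faeces, garbage and flies
  around — summarized as the chance of (re)contamination from environment.

Each scored SI variable is binary and awards score 1 for its *best* state
(e.g. score 1 when the storage is covered, score 1 when it is not cracked).
A cluster's scores are summed and the total mapped through fixed cut-offs
to a three-level category; the intermediate node's CPT encodes this mapping
deterministically and is locked against learning.

Variants differ on the POC side: model 1 uses the type of source (piped,
well, spring, river, other) as the parent of E. coli detection at POC;
model 2 restricts to wells and uses six well-SI observations as parents.
The "B" variants add the fullness level of the storage container as a fifth
parent of the outcome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bn_core import CPT, NetworkSpec, NodeDef, build_network

__all__ = [
    "SIVariable",
    "IndexRule",
    "ModelVariant",
    "VARIABLES",
    "score_variable",
    "cluster_index",
    "deterministic_cpt",
    "discretize_ecoli",
    "build_model",
    "storage_rule",
    "environment_rule",
    "poc_block_nodes",
    "ECOLI_POU",
    "ECOLI_POC",
    "HWT",
    "TYPE_OF_POC",
    "FULLNESS",
    "ENV_NODE",
    "STORAGE_NODE",
    "ENV_PARENTS",
    "STORAGE_PARENTS",
    "WELL_SI_PARENTS",
    "RISK_LEVELS",
]

# node-name constants
ECOLI_POU = "ecoli_pou"
ECOLI_POC = "ecoli_poc"
HWT = "household_water_treatment"
TYPE_OF_POC = "type_of_poc"
FULLNESS = "fullness_of_water_at_storage"
ENV_NODE = "contamination_from_environment"
STORAGE_NODE = "contamination_from_storage"

RISK_LEVELS = ("low", "moderate", "high")
ECOLI_STATES = ("detected", "not_detected")
FULLNESS_STATES = ("almost_empty", "one_quarter", "half", "three_quarter", "full")
POC_TYPES = ("piped", "well", "spring", "river", "other")

ENV_PARENTS = (
    "open_defecation",
    "livestock_nearby_house",
    "floor_cleanliness",
    "faeces_around",
    "garbage_around",
    "flies_around",
)
STORAGE_PARENTS = ("storage_covered", "storage_cracked", "place_of_storage")
WELL_SI_PARENTS = (
    "cracked_structure",
    "livestock_nearby_poc",
    "proper_fencing",
    "excreta_garbage_nearby",
    "prone_to_erosion",
    "latrine_within_10m",
)


@dataclass(frozen=True)
class SIVariable:
    """One scored survey variable: states, the state awarded score 1, cluster."""

    name: str
    states: tuple[str, ...]
    best_state: str
    cluster: str  # environment_hygiene | water_storage | poc | hwt | external

    def __post_init__(self) -> None:
        if self.best_state not in self.states:
            raise ValueError(
                f"{self.name}: best_state {self.best_state!r} not in states"
            )


def _binary(name, best, cluster, states=("yes", "no")):
    return SIVariable(name, tuple(states), best, cluster)


#: Full variable inventory of the survey instrument.
VARIABLES: dict[str, SIVariable] = {
    v.name: v
    for v in [
        # environment / hygiene cluster — risk absent is best
        _binary("open_defecation", "no", "environment_hygiene"),
        _binary("livestock_nearby_house", "no", "environment_hygiene"),
        SIVariable("floor_cleanliness", ("dirty", "clean"), "clean",
                   "environment_hygiene"),
        _binary("faeces_around", "no", "environment_hygiene"),
        _binary("garbage_around", "no", "environment_hygiene"),
        _binary("flies_around", "no", "environment_hygiene"),
        # water storage cluster
        _binary("storage_covered", "yes", "water_storage"),
        _binary("storage_cracked", "no", "water_storage"),
        SIVariable("place_of_storage",
                   ("easy_to_contaminate", "not_easy_to_contaminate"),
                   "not_easy_to_contaminate", "water_storage"),
        # well SI (model 2 POC cluster)
        _binary("cracked_structure", "no", "poc"),
        _binary("livestock_nearby_poc", "no", "poc"),
        _binary("proper_fencing", "yes", "poc"),
        _binary("excreta_garbage_nearby", "no", "poc"),
        _binary("prone_to_erosion", "no", "poc"),
        _binary("latrine_within_10m", "no", "poc"),
        # treatment and external
        SIVariable(HWT, ("yes_treat", "no"), "yes_treat", "hwt"),
        SIVariable(FULLNESS, FULLNESS_STATES, "full", "external"),
    ]
}


@dataclass(frozen=True)
class IndexRule:
    """A cluster's scored parents and the score→category cut-offs.

    ``cutoffs`` maps inclusive total-score ranges ``(lo, hi)`` to the three
    category labels; the ranges must partition ``0..len(parents)``.
    ``direction`` selects the semantics of the labels: ``"results"`` (the
    default) reads them as chance of contamination, so a *high* hygiene
    total maps to *low* risk; ``"methods"`` applies the cut-off labels to
    the raw total literally.
    """

    parents: tuple[str, ...]
    cutoffs: tuple[tuple[int, int, str], ...]  # (lo, hi, label)
    direction: str = "results"

    def __post_init__(self) -> None:
        covered = sorted(
            s for lo, hi, _ in self.cutoffs for s in range(lo, hi + 1)
        )
        if covered != list(range(len(self.parents) + 1)):
            raise ValueError("cutoff ranges must partition 0..n_parents")
        if {lab for *_, lab in self.cutoffs} != set(RISK_LEVELS):
            raise ValueError("cutoffs must use exactly low/moderate/high")
        if self.direction not in ("results", "methods"):
            raise ValueError(f"unknown direction {self.direction!r}")


_FLIP = {"low": "high", "moderate": "moderate", "high": "low"}


def storage_rule(direction: str = "results") -> IndexRule:
    """Storage cluster: totals 0–1 / 2 / 3 → low / moderate / high score band."""
    return IndexRule(STORAGE_PARENTS,
                     ((0, 1, "low"), (2, 2, "moderate"), (3, 3, "high")),
                     direction)


def environment_rule(direction: str = "results") -> IndexRule:
    """Environment cluster: totals 0–2 / 3–4 / 5–6 → low / moderate / high band."""
    return IndexRule(ENV_PARENTS,
                     ((0, 2, "low"), (3, 4, "moderate"), (5, 6, "high")),
                     direction)


def score_variable(var: SIVariable, observed: str) -> int:
    """Score 1 iff the observed state is the variable's best state."""
    if observed not in var.states:
        raise ValueError(f"{var.name}: unknown state {observed!r}")
    return int(observed == var.best_state)


def cluster_index(rule: IndexRule, scores: list[int]) -> str:
    """Map per-variable 0/1 scores to the cluster's risk category.

    Under the default ``results`` direction the label is the chance of
    contamination, so a total of 3 on the storage cluster (all criteria
    met) yields ``"low"``.
    """
    if len(scores) != len(rule.parents):
        raise ValueError(
            f"expected {len(rule.parents)} scores, got {len(scores)}"
        )
    if any(s not in (0, 1) for s in scores):
        raise ValueError(f"scores must be 0/1, got {scores!r}")
    total = sum(scores)
    for lo, hi, label in rule.cutoffs:
        if lo <= total <= hi:
            return _FLIP[label] if rule.direction == "results" else label
    raise AssertionError("unreachable: cutoffs partition the range")


def deterministic_cpt(rule: IndexRule, child: str) -> CPT:
    """Locked degenerate CPT of an intermediate node: each parent-state
    combination puts probability 1 on its :func:`cluster_index` category."""
    table: dict[tuple[str, ...], np.ndarray] = {}
    parent_vars = [VARIABLES[p] for p in rule.parents]
    for combo in itertools.product(*(v.states for v in parent_vars)):
        scores = [score_variable(v, s) for v, s in zip(parent_vars, combo)]
        label = cluster_index(rule, scores)
        vec = np.zeros(len(RISK_LEVELS))
        vec[RISK_LEVELS.index(label)] = 1.0
        table[combo] = vec
    return CPT(child=child, parents=rule.parents, table=table, locked=True)


def discretize_ecoli(cfu: int) -> str:
    """Dichotomize a CFU/1 ml plate count: detected iff any colony formed."""
    if cfu < 0:
        raise ValueError(f"negative CFU count: {cfu}")
    return "not_detected" if cfu == 0 else "detected"


@dataclass(frozen=True)
class ModelVariant:
    """One of the four network variants; the tag determines everything."""

    tag: str

    _VALID = ("1A", "1B", "2A", "2B")

    def __post_init__(self) -> None:
        if self.tag not in self._VALID:
            raise ValueError(f"unknown variant {self.tag!r}; use one of {self._VALID}")

    @property
    def poc_mode(self) -> str:
        """'type' (type-of-POC parent) for model 1, 'well_si' for model 2."""
        return "type" if self.tag.startswith("1") else "well_si"

    @property
    def fullness_included(self) -> bool:
        return self.tag.endswith("B")

    @classmethod
    def parse(cls, v: "ModelVariant | str") -> "ModelVariant":
        return v if isinstance(v, ModelVariant) else cls(str(v).upper())


def poc_block_nodes(variant: ModelVariant | str) -> tuple[str, ...]:
    """The POC-side fields that go missing together when no source sample
    was taken (the study's block-missingness pattern)."""
    variant = ModelVariant.parse(variant)
    if variant.poc_mode == "type":
        return (TYPE_OF_POC, ECOLI_POC)
    return WELL_SI_PARENTS + (ECOLI_POC,)


def _uniform_cpt(net_nodes: dict[str, NodeDef], child: str,
                 parents: tuple[str, ...] = ()) -> CPT:
    k = len(net_nodes[child].states)
    table = {
        combo: np.full(k, 1.0 / k)
        for combo in itertools.product(*(net_nodes[p].states for p in parents))
    }
    return CPT(child=child, parents=parents, table=table, locked=False)


def build_model(variant: ModelVariant | str, direction: str = "results") -> NetworkSpec:
    """Assemble the network structure of one variant.

    Intermediate-node CPTs are deterministic and locked; every other CPT is
    initialized uniform (use :func:`sibbn.learning.initialize_cpts` for a
    random restart) and is meant to be estimated from data.
    """
    variant = ModelVariant.parse(variant)
    nodes: list[NodeDef] = []

    def add(name, states, role):
        nodes.append(NodeDef(name, tuple(states), role))

    for p in ENV_PARENTS + STORAGE_PARENTS:
        add(p, VARIABLES[p].states, "outer_SI")
    add(ENV_NODE, RISK_LEVELS, "intermediate")
    add(STORAGE_NODE, RISK_LEVELS, "intermediate")
    add(HWT, VARIABLES[HWT].states, "treatment")
    if variant.poc_mode == "type":
        add(TYPE_OF_POC, POC_TYPES, "outer_SI")
    else:
        for p in WELL_SI_PARENTS:
            add(p, VARIABLES[p].states, "outer_SI")
    add(ECOLI_POC, ECOLI_STATES, "water_quality")
    if variant.fullness_included:
        add(FULLNESS, FULLNESS_STATES, "external")
    add(ECOLI_POU, ECOLI_STATES, "water_quality")

    node_map = {n.name: n for n in nodes}
    cpts: list[CPT] = [
        deterministic_cpt(environment_rule(direction), ENV_NODE),
        deterministic_cpt(storage_rule(direction), STORAGE_NODE),
    ]
    for p in ENV_PARENTS + STORAGE_PARENTS:
        cpts.append(_uniform_cpt(node_map, p))
    cpts.append(_uniform_cpt(node_map, HWT))
    if variant.poc_mode == "type":
        cpts.append(_uniform_cpt(node_map, TYPE_OF_POC))
        cpts.append(_uniform_cpt(node_map, ECOLI_POC, (TYPE_OF_POC,)))
    else:
        for p in WELL_SI_PARENTS:
            cpts.append(_uniform_cpt(node_map, p))
        cpts.append(_uniform_cpt(node_map, ECOLI_POC, WELL_SI_PARENTS))
    outcome_parents = (ECOLI_POC, HWT, ENV_NODE, STORAGE_NODE)
    if variant.fullness_included:
        cpts.append(_uniform_cpt(node_map, FULLNESS))
        outcome_parents = outcome_parents + (FULLNESS,)
    cpts.append(_uniform_cpt(node_map, ECOLI_POU, outcome_parents))
    return build_network(nodes, cpts)
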