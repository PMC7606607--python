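"""Maximum-likelihood and EM estimation of CPTs from survey records.

The survey tables here have a characteristic block-missingness pattern:
households whose water source was not sampled are missing every POC-side
field at once.  EM handles this exactly — the E-step distributes each
record's unit weight over the joint configurations of its missing fields in
proportion to their posterior probability given the observed fields, and
the M-step re-normalizes the expected counts (with an optional symmetric
pseudo-count).  CPTs flagged ``locked`` (the deterministic cluster-index
tables) are never updated.

Records are aggregated by distinct observation pattern before iterating, so
complete records contribute their sufficient statistics once, outside the
EM loop; only incomplete patterns are re-scored each iteration.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn_core import CPT, NetworkSpec, joint_probability

__all__ = [
    "SurveyTable",
    "FitResult",
    "ml_estimate",
    "em_fit",
    "initialize_cpts",
]

# Upper bound on enumerated joint configurations of one record's missing
# fields; the study's block pattern needs at most a few hundred.
_MAX_MISSING_CONFIGS = 65536


@dataclass
class SurveyTable:
    """Rectangular collection of household records, possibly with gaps.

    Each record maps node name → state label, with ``None`` marking a
    missing field.  Validation against a network checks every observed
    value is a legal state of its node.
    """

    records: list[dict[str, str | None]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("survey table needs at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, net: NetworkSpec) -> None:
        for i, rec in enumerate(self.records):
            for node, state in rec.items():
                if node not in net.nodes:
                    raise ValueError(f"record {i}: unknown node {node!r}")
                if state is not None:
                    net.node(node).state_index(state)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurveyTable":
        recs = []
        for row in df.itertuples(index=False):
            rec = {}
            for col, val in zip(df.columns, row):
                rec[col] = None if pd.isna(val) or val == "" else str(val)
            recs.append(rec)
        return cls(recs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {k: (v if v is not None else np.nan) for k, v in rec.items()}
            for rec in self.records
        ])


@dataclass
class FitResult:
    """Outcome of an EM run: the fitted network plus its likelihood trace."""

    network: NetworkSpec
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    settings: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _empty_counts(net: NetworkSpec) -> dict[str, dict[tuple, np.ndarray]]:
    counts: dict[str, dict[tuple, np.ndarray]] = {}
    for name, cpt in net.cpts.items():
        if cpt.locked:
            continue
        counts[name] = {k: np.zeros(len(net.states(name))) for k in cpt.table}
    return counts


def _accumulate(net: NetworkSpec, counts, assignment: dict[str, str],
                w: float) -> None:
    for name, cells in counts.items():
        cpt = net.cpts[name]
        key = tuple(assignment[p] for p in cpt.parents)
        cells[key][net.node(name).state_index(assignment[name])] += w


def _normalize_counts(net: NetworkSpec, counts, prior_count: float) -> None:
    """M-step in place: (count + prior) / (total + prior * n_states);
    an all-zero row with zero prior becomes uniform."""
    for name, cells in counts.items():
        k = len(net.states(name))
        cpt = net.cpts[name]
        for key, vec in cells.items():
            tot = vec.sum() + prior_count * k
            if tot == 0.0:
                cpt.table[key] = np.full(k, 1.0 / k)
            else:
                cpt.table[key] = (vec + prior_count) / tot


def ml_estimate(net: NetworkSpec, data: SurveyTable,
                prior_count: float = 0.0) -> NetworkSpec:
    """Closed-form smoothed relative-frequency estimate from complete data.

    Every unlocked CPT row becomes ``(count + prior) / (total + prior·k)``
    where *k* is the child's state count; locked tables pass through
    untouched.  Raises if any record has a missing field.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    data.validate(net)
    fitted = net.copy()
    counts = _empty_counts(fitted)
    for i, rec in enumerate(data.records):
        if any(rec.get(n) is None for n in net.nodes):
            raise ValueError(f"record {i} has missing fields; use em_fit")
        _accumulate(fitted, counts, rec, 1.0)
    _normalize_counts(fitted, counts, prior_count)
    return fitted


def initialize_cpts(net: NetworkSpec, mode: str = "uniform",
                    seed: int | None = None) -> NetworkSpec:
    """Reset unlocked CPT rows to uniform, or to seeded random distributions."""
    if mode not in ("uniform", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = net.copy()
    for cpt in out.cpts.values():
        if cpt.locked:
            continue
        k = len(out.states(cpt.child))
        for key in cpt.table:
            if mode == "uniform":
                cpt.table[key] = np.full(k, 1.0 / k)
            else:
                v = rng.gamma(1.0, 1.0, size=k) + 1e-6
                cpt.table[key] = v / v.sum()
    return out


def _pattern_key(net: NetworkSpec, rec: dict) -> tuple:
    return tuple(rec.get(n) for n in net.node_names)


def em_fit(net: NetworkSpec, data: SurveyTable, prior_count: float = 1.0,
           tol: float = 1e-6, max_iter: int = 200,
           seed: int | None = None, init: str | None = None) -> FitResult:
    """EM estimation of the unlocked CPTs under missing fields.

    Alternates an E-step (expected sufficient statistics per record, the
    posterior over each record's missing fields given its observed ones)
    with the M-step of :func:`ml_estimate` applied to expected counts.
    Stops when the relative log-likelihood gain drops below ``tol`` or
    after ``max_iter`` iterations.  ``init`` optionally re-initializes the
    unlocked CPTs first ('uniform' or 'random' with ``seed``); by default
    the network's current CPTs are the starting point.

    The log-likelihood is the observed-data likelihood,
    ``Σ_records log P(observed fields)``, and is non-decreasing across
    iterations (a property the test-suite asserts).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    data.validate(net)
    current = initialize_cpts(net, init, seed) if init else net.copy()

    # aggregate records by identical observation pattern; canonical (sorted)
    # pattern order makes the fit invariant to record order
    patterns = Counter(_pattern_key(current, r) for r in data.records)
    patterns = dict(sorted(
        patterns.items(),
        key=lambda kv: tuple(x if x is not None else "" for x in kv[0]),
    ))
    names = current.node_names
    complete_pats: list[tuple[dict, int]] = []
    missing_pats: list[tuple[dict, list[str], int, int]] = []
    first_index: dict[tuple, int] = {}
    for idx, rec in enumerate(data.records):
        key = _pattern_key(current, rec)
        first_index.setdefault(key, idx)
    for key, mult in patterns.items():
        rec = dict(zip(names, key))
        missing = [n for n in names if rec[n] is None]
        if missing:
            n_cfg = int(np.prod([len(current.states(n)) for n in missing]))
            if n_cfg > _MAX_MISSING_CONFIGS:
                raise ValueError(
                    f"record pattern with {len(missing)} missing fields has "
                    f"{n_cfg} configurations; too many to enumerate"
                )
            missing_pats.append((rec, missing, mult, first_index[key]))
        else:
            complete_pats.append((rec, mult))

    # complete-pattern counts never change across iterations
    base_counts = _empty_counts(current)
    for rec, mult in complete_pats:
        _accumulate(current, base_counts, rec, float(mult))

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = {
            name: {k: v.copy() for k, v in cells.items()}
            for name, cells in base_counts.items()
        }
        ll = 0.0
        for rec, mult in complete_pats:
            p = joint_probability(current, rec)
            if p == 0.0:
                i = first_index[_pattern_key(current, rec)]
                raise ValueError(
                    f"record {i}: observed combination impossible under "
                    f"current parameters"
                )
            ll += mult * math.log(p)
        for rec, missing, mult, idx in missing_pats:
            configs = list(itertools.product(
                *(current.states(n) for n in missing)))
            weights = np.empty(len(configs))
            full = dict(rec)
            for j, cfg in enumerate(configs):
                full.update(zip(missing, cfg))
                weights[j] = joint_probability(current, full)
            z = weights.sum()
            if z == 0.0:
                raise ValueError(
                    f"record {idx}: observed combination impossible under "
                    f"current parameters"
                )
            ll += mult * math.log(z)
            weights *= mult / z
            for j, cfg in enumerate(configs):
                if weights[j] == 0.0:
                    continue
                full.update(zip(missing, cfg))
                _accumulate(current, counts, full, float(weights[j]))
        _normalize_counts(current, counts, prior_count)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if (ll - prev) < tol * abs(prev):
                converged = True
                break

    # record the likelihood under the final parameters
    final_ll = 0.0
    for rec, mult in complete_pats:
        final_ll += mult * math.log(joint_probability(current, rec))
    for rec, missing, mult, _ in missing_pats:
        full = dict(rec)
        z = 0.0
        for cfg in itertools.product(*(current.states(n) for n in missing)):
            full.update(zip(missing, cfg))
            z += joint_probability(current, full)
        final_ll += mult * math.log(z)
    trace.append(final_ll)

    return FitResult(
        network=current,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        settings={"prior_count": prior_count, "tol": tol,
                  "max_iter": max_iter, "seed": seed, "init": init},
    )
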