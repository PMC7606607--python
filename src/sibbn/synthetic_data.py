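"""Synthetic household-survey generator.

The field study this package analyses surveyed 328 households in East
Sumba, Indonesia, pairing sanitary-inspection observations with E. coli
testing of stored drinking water (point of use, POU) and of the water
source (point of collection, POC); 49 households had no POC sample.  The
raw records are not public, so every stage of the pipeline is exercised on
synthetic tables drawn from a fully specified ground-truth network that
reproduces the study's published marginal structure:

* root marginals at the printed survey frequencies (56% practising
  household water treatment, 23% uncovered storage, 66.7% livestock near
  the house, 89% garbage, 70% flies, POC-type mix led by piped 31.8%,
  well 27.2%, spring 17.4%, ...);
* E. coli detection at the POC conditional on source type (piped/spring
  ≈ 10%, well 42%, river 83% detected);
* monotone risk-increasing CPTs for the outcome (each risk factor can only
  raise the detection probability);
* deterministic cluster-index intermediates, exactly as in the fitted
  models;
* a block-missingness pattern removing the whole POC side of a record
  (default 49 of 328 records), missing completely at random by default,
  optionally weighted by POC type to emulate informative missingness.

Quantities the study never prints (the river share of the source mix, the
well-SI prevalences, the logistic effect sizes of the outcome CPT) are
free parameters of :class:`GeneratorConfig` with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bn_core import CPT, NetworkSpec, NodeDef, build_network, topological_order
from .learning import SurveyTable
from .si_model import (
    ECOLI_POC,
    ECOLI_POU,
    ENV_NODE,
    ENV_PARENTS,
    FULLNESS,
    HWT,
    STORAGE_NODE,
    STORAGE_PARENTS,
    TYPE_OF_POC,
    WELL_SI_PARENTS,
    ModelVariant,
    build_model,
    poc_block_nodes,
)

__all__ = [
    "GeneratorConfig",
    "TruthBundle",
    "default_truth",
    "sample_table",
    "apply_missingness",
    "generate",
    "recovery_error",
]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generator.

    Marginals carry the published survey frequencies; effect sizes are the
    package's documented defaults (the study prints none).  All
    probabilities are P(first listed state) unless noted.
    """

    variant: str = "1B"
    n: int = 328
    poc_missing: int = 49
    seed: int | None = None

    # root marginals, P("yes"/risk-present state) unless stated
    p_open_defecation: float = 0.327
    p_livestock_house: float = 0.667
    p_floor_dirty: float = 0.714          # natural (soil) floor share
    p_faeces_around: float = 0.60
    p_garbage_around: float = 0.89
    p_flies_around: float = 0.70
    p_storage_covered: float = 0.77       # P(yes)
    p_storage_cracked: float = 0.04
    p_place_easy: float = 0.51
    p_hwt_yes: float = 0.56
    poc_type_mix: tuple[float, ...] = (0.318, 0.272, 0.174, 0.015, 0.221)
    fullness_mix: tuple[float, ...] = (0.10, 0.15, 0.25, 0.25, 0.25)
    # model-2 well-SI prevalences, P(risk present)
    well_si_prevalence: tuple[float, ...] = (0.35, 0.50, 0.40, 0.45, 0.40, 0.30)

    # P(E. coli detected at POC | type), order piped/well/spring/river/other
    p_poc_detect_by_type: tuple[float, ...] = (0.10, 0.42, 0.10, 0.83, 0.30)
    # model 2: logistic in the count of well risk factors
    well_logit_base: float = -2.2
    well_logit_per_risk: float = 0.6

    # outcome CPT: logistic risk score for P(detected at POU)
    outcome_base: float = -3.65  # calibrated so P(detected at POU) ≈ 0.18
    beta_poc_detected: float = 1.6
    beta_no_hwt: float = 0.9
    beta_env: tuple[float, float, float] = (0.0, 0.4, 0.8)       # low/mod/high
    beta_storage: tuple[float, float, float] = (0.0, 0.3, 0.6)
    beta_fullness: tuple[float, ...] = (0.7, 0.45, 0.25, 0.1, 0.0)

    # missingness: "mcar" or "by_poc_type" (relative weights per type)
    missing_mechanism: str = "mcar"
    missing_type_weights: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 1.0)

    def __post_init__(self) -> None:
        ModelVariant.parse(self.variant)
        if not 0 <= self.poc_missing <= self.n:
            raise ValueError("poc_missing must be between 0 and n")
        if abs(sum(self.poc_type_mix) - 1.0) > 1e-9:
            raise ValueError("poc_type_mix must sum to 1")
        if abs(sum(self.fullness_mix) - 1.0) > 1e-9:
            raise ValueError("fullness_mix must sum to 1")


@dataclass
class TruthBundle:
    """A generating network, the table sampled from it, and the mask of
    records whose POC block was removed."""

    truth: NetworkSpec
    table: SurveyTable
    missing_mask: np.ndarray
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def _set_root(net: NetworkSpec, name: str, probs: list[float]) -> None:
    net.cpts[name].table[()] = np.asarray(probs, dtype=float)


def default_truth(variant: ModelVariant | str,
                  config: GeneratorConfig | None = None) -> NetworkSpec:
    """A fully specified generating network for one model variant."""
    variant = ModelVariant.parse(variant)
    cfg = config or GeneratorConfig(variant=variant.tag)
    net = build_model(variant)

    _set_root(net, "open_defecation", [cfg.p_open_defecation,
                                       1 - cfg.p_open_defecation])
    _set_root(net, "livestock_nearby_house", [cfg.p_livestock_house,
                                              1 - cfg.p_livestock_house])
    _set_root(net, "floor_cleanliness", [cfg.p_floor_dirty, 1 - cfg.p_floor_dirty])
    _set_root(net, "faeces_around", [cfg.p_faeces_around, 1 - cfg.p_faeces_around])
    _set_root(net, "garbage_around", [cfg.p_garbage_around,
                                      1 - cfg.p_garbage_around])
    _set_root(net, "flies_around", [cfg.p_flies_around, 1 - cfg.p_flies_around])
    _set_root(net, "storage_covered", [cfg.p_storage_covered,
                                       1 - cfg.p_storage_covered])
    _set_root(net, "storage_cracked", [cfg.p_storage_cracked,
                                       1 - cfg.p_storage_cracked])
    _set_root(net, "place_of_storage", [cfg.p_place_easy, 1 - cfg.p_place_easy])
    _set_root(net, HWT, [cfg.p_hwt_yes, 1 - cfg.p_hwt_yes])

    if variant.poc_mode == "type":
        _set_root(net, TYPE_OF_POC, list(cfg.poc_type_mix))
        cpt = net.cpts[ECOLI_POC]
        for ptype, p in zip(net.states(TYPE_OF_POC), cfg.p_poc_detect_by_type):
            cpt.table[(ptype,)] = np.array([p, 1 - p])
    else:
        for name, prev in zip(WELL_SI_PARENTS, cfg.well_si_prevalence):
            best = "yes" if name == "proper_fencing" else "no"
            p_yes = (1 - prev) if best == "yes" else prev
            _set_root(net, name, [p_yes, 1 - p_yes])
        cpt = net.cpts[ECOLI_POC]
        from .si_model import VARIABLES, score_variable
        for key in cpt.table:
            n_risk = sum(
                1 - score_variable(VARIABLES[p], s)
                for p, s in zip(WELL_SI_PARENTS, key)
            )
            p = _sigmoid(cfg.well_logit_base + cfg.well_logit_per_risk * n_risk)
            cpt.table[key] = np.array([p, 1 - p])

    if variant.fullness_included:
        _set_root(net, FULLNESS, list(cfg.fullness_mix))

    out = net.cpts[ECOLI_POU]
    env_states = net.states(ENV_NODE)
    sto_states = net.states(STORAGE_NODE)
    full_states = net.states(FULLNESS) if variant.fullness_included else None
    for key in out.table:
        kv = dict(zip(out.parents, key))
        x = cfg.outcome_base
        if kv[ECOLI_POC] == "detected":
            x += cfg.beta_poc_detected
        if kv[HWT] == "no":
            x += cfg.beta_no_hwt
        x += cfg.beta_env[env_states.index(kv[ENV_NODE])]
        x += cfg.beta_storage[sto_states.index(kv[STORAGE_NODE])]
        if full_states is not None:
            x += cfg.beta_fullness[full_states.index(kv[FULLNESS])]
        p = _sigmoid(x)
        out.table[key] = np.array([p, 1 - p])
    return net


def sample_table(truth: NetworkSpec, n: int, seed: int | None = None) -> SurveyTable:
    """Ancestral (forward) sampling of ``n`` complete records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = topological_order(truth)
    records: list[dict[str, str | None]] = []
    # pre-draw uniforms column-wise for speed and reproducibility
    u = {name: rng.random(n) for name in order}
    cum = {
        name: {k: np.cumsum(v) for k, v in truth.cpts[name].table.items()}
        for name in order
    }
    for i in range(n):
        rec: dict[str, str | None] = {}
        for name in order:
            cpt = truth.cpts[name]
            key = tuple(rec[p] for p in cpt.parents)
            idx = int(np.searchsorted(cum[name][key], u[name][i], side="right"))
            idx = min(idx, len(truth.states(name)) - 1)
            rec[name] = truth.states(name)[idx]
        records.append(rec)
    return SurveyTable(records)


def apply_missingness(table: SurveyTable, poc_missing: int,
                      seed: int | None = None,
                      variant: ModelVariant | str | None = None,
                      mechanism: str = "mcar",
                      type_weights: tuple[float, ...] | None = None,
                      ) -> tuple[SurveyTable, np.ndarray]:
    """Blank the entire POC block in a seeded subset of records.

    Returns the masked table and a boolean mask of affected records.  The
    block is all-or-nothing: a record either keeps every POC-side field or
    loses them all, matching the study's 49 households without a source
    sample.  ``mechanism='by_poc_type'`` draws the subset with per-type
    relative weights instead of uniformly (informative missingness).
    """
    n = len(table)
    if not 0 <= poc_missing <= n:
        raise ValueError("poc_missing must be between 0 and record count")
    if variant is None:
        variant = "1" if TYPE_OF_POC in table.records[0] else "2"
        variant += "B" if FULLNESS in table.records[0] else "A"
    block = poc_block_nodes(variant)
    rng = np.random.default_rng(seed)
    if mechanism == "mcar":
        chosen = rng.choice(n, size=poc_missing, replace=False)
    elif mechanism == "by_poc_type":
        weights = np.ones(n)
        tw = type_weights or (0.5, 1.0, 1.5, 2.0, 1.0)
        types = ("piped", "well", "spring", "river", "other")
        for i, rec in enumerate(table.records):
            t = rec.get(TYPE_OF_POC)
            if t in types:
                weights[i] = tw[types.index(t)]
        weights /= weights.sum()
        chosen = rng.choice(n, size=poc_missing, replace=False, p=weights)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    records = []
    for i, rec in enumerate(table.records):
        rec = dict(rec)
        if mask[i]:
            for node in block:
                if node in rec:
                    rec[node] = None
        records.append(rec)
    return SurveyTable(records), mask


def recovery_error(truth: NetworkSpec, fitted: NetworkSpec,
                   weighted: bool = True) -> float:
    """Mean absolute error of the fitted unlocked CPT entries vs the truth.

    With ``weighted=True`` (the default) each CPT row's error is weighted by
    the probability of its parent configuration under the truth network.
    This is the identifiable-recovery view: a row whose parent combination
    essentially never occurs contributes essentially nothing to the
    likelihood, so its parameter cannot be recovered from data of any
    realistic size and an unweighted average is dominated by such rows.
    ``weighted=False`` gives the plain mean over all entries.
    """
    from .inference import evidence_probability

    num = 0.0
    den = 0.0
    for name, cpt in truth.cpts.items():
        if cpt.locked:
            continue
        fit_cpt = fitted.cpts[name]
        for key, true_vec in cpt.table.items():
            err = float(np.abs(fit_cpt.table[key] - true_vec).mean())
            if weighted:
                w = evidence_probability(truth, dict(zip(cpt.parents, key)))
            else:
                w = 1.0
            num += w * err
            den += w
    return num / den


def generate(variant: ModelVariant | str = "1B", n: int | None = None,
             poc_missing: int | None = None, seed: int | None = None,
             config: GeneratorConfig | None = None) -> TruthBundle:
    """Truth network → sampled table → block missingness, in one call."""
    variant = ModelVariant.parse(variant)
    cfg = config or GeneratorConfig(variant=variant.tag)
    if n is not None or poc_missing is not None or seed is not None:
        cfg = replace(
            cfg,
            variant=variant.tag,
            n=cfg.n if n is None else n,
            poc_missing=cfg.poc_missing if poc_missing is None else poc_missing,
            seed=cfg.seed if seed is None else seed,
        )
    ss = np.random.SeedSequence(cfg.seed)
    s_sample, s_miss = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    truth = default_truth(variant, cfg)
    table = sample_table(truth, cfg.n, seed=s_sample)
    masked, mask = apply_missingness(
        table, cfg.poc_missing, seed=s_miss, variant=variant,
        mechanism=cfg.missing_mechanism,
        type_weights=cfg.missing_type_weights,
    )
    return TruthBundle(truth=truth, table=masked, missing_mask=mask, config=cfg)
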