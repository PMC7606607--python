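"""Model/Results front-end over the library modules.

`WaterQualityBBN` is built from a survey table (or pandas DataFrame) and a
variant tag; `fit()` runs EM and returns a `WaterQualityBBNResults` that
carries the fitted network, the likelihood trace, diagnostics, and the
downstream analyses — prediction, cross-validation, ΔP sweeps and scenario
simulation — as methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bn_core import NetworkSpec
from .evaluation import ValidationReport, cross_validate
from .inference import posterior, predict_outcome
from .learning import FitResult, SurveyTable, em_fit
from .sensitivity import (
    DeltaPTable,
    Scenario,
    best_states,
    predictive_inference,
    run_scenario,
)
from .si_model import ECOLI_POU, ModelVariant, build_model

__all__ = ["WaterQualityBBN", "WaterQualityBBNResults"]


class WaterQualityBBN:
    """A sanitary-inspection belief network over household survey data.

    Parameters
    ----------
    data : SurveyTable or pandas.DataFrame
        One row per household; missing cells are marginalized by EM.
    variant : str or ModelVariant
        '1A', '1B', '2A' or '2B'.
    direction : str
        Cluster-index label semantics; 'results' (default) reads the
        low/moderate/high categories as chance of contamination.
    """

    def __init__(self, data, variant="1B", direction: str = "results",
                 outcome: str = ECOLI_POU):
        if isinstance(data, pd.DataFrame):
            data = SurveyTable.from_dataframe(data)
        if not isinstance(data, SurveyTable):
            raise TypeError("data must be a SurveyTable or DataFrame")
        self.variant = ModelVariant.parse(variant)
        self.structure = build_model(self.variant, direction=direction)
        data.validate(self.structure)
        self.data = data
        self.outcome = outcome

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant="1B", **kw):
        return cls(df, variant=variant, **kw)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(self, prior_count: float = 1.0, tol: float = 1e-6,
            max_iter: int = 200, seed: int | None = None,
            init: str = "uniform") -> "WaterQualityBBNResults":
        res = em_fit(self.structure, self.data, prior_count=prior_count,
                     tol=tol, max_iter=max_iter, seed=seed, init=init)
        return WaterQualityBBNResults(self, res)

    def cross_validate(self, k: int = 10, seed: int | None = None,
                       **em_settings) -> ValidationReport:
        """k-fold cross-validated AUC with per-fold EM refitting."""
        return cross_validate(self.variant, self.data, k=k, seed=seed,
                              outcome=self.outcome, **em_settings)


class WaterQualityBBNResults:
    """Fitted network plus diagnostics and the downstream analyses."""

    def __init__(self, model: WaterQualityBBN, fit_result: FitResult):
        self.model = model
        self._fit = fit_result
        self.network: NetworkSpec = fit_result.network
        self.loglik_trace = fit_result.loglik_trace
        self.converged = fit_result.converged
        self.n_iter = fit_result.n_iter

    @property
    def loglik(self) -> float:
        return self._fit.loglik

    # -- prediction --------------------------------------------------------

    def predict(self, data=None, state: str = "detected") -> np.ndarray:
        """P(outcome = state | each record's non-missing fields)."""
        data = data if data is not None else self.model.data
        if isinstance(data, pd.DataFrame):
            data = SurveyTable.from_dataframe(data)
        return np.array([
            predict_outcome(self.network, rec, self.model.outcome, state)
            for rec in data.records
        ])

    def marginal(self, node: str) -> dict[str, float]:
        """Fitted no-evidence marginal of one node."""
        return posterior(self.network, node, {}).as_dict()

    # -- sensitivity -------------------------------------------------------

    def delta_p(self, designated_state: str = "not_detected") -> DeltaPTable:
        return predictive_inference(self.network, self.model.outcome,
                                    designated_state)

    def scenario(self, sc: Scenario | dict | None = None,
                 designated_state: str = "not_detected"):
        """Updated outcome probability (%) under a scenario (the variant's
        best-case scenario by default), plus the baseline."""
        if sc is None:
            sc = best_states(self.model.variant)
        return run_scenario(self.network, sc, self.model.outcome,
                            designated_state)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Sanitary-inspection belief network".center(64),
            "=" * 64,
            f"Variant:        {self.model.variant.tag}"
            f"          Households:  {self.model.nobs}",
            f"Outcome:        {self.model.outcome}",
            f"EM iterations:  {self.n_iter}"
            f"           Converged:   {self.converged}",
            f"Log-likelihood: {self.loglik:.3f}",
            "-" * 64,
            "Fitted marginals (%)",
        ]
        for name in self.network.node_names:
            marg = self.marginal(name)
            states = "  ".join(f"{s}={100 * p:.1f}" for s, p in marg.items())
            lines.append(f"  {name:<34}{states}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<WaterQualityBBNResults variant={self.model.variant.tag} "
                f"n={self.model.nobs} loglik={self.loglik:.2f}>")
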