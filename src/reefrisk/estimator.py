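"""Scikit-learn-style front end: fit on elicitation records, predict reefs.

:class:`ReefDeclineNetwork` wraps the full elicitation → CPT → inference
pipeline behind the familiar estimator contract: ``fit`` consumes a table of
4-point expert responses and builds the network; ``predict_proba`` consumes
a reef table and returns per-reef decline probabilities under a chosen
scenario.  The class is clone-compatible and composes with sklearn model
selection, though the "X" of ``fit`` (expert responses) and of ``predict``
(reefs) are deliberately different tables — this is an elicited model, not a
supervised one.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import elicitation as _elic
from . import layers as _layers
from . import network as _net
from . import scenarios as _scen

__all__ = ["ReefDeclineNetwork"]


class ReefDeclineNetwork(BaseEstimator):
    """Expert-elicited Bayesian network predicting 10-year coral decline.

    Parameters
    ----------
    parameterization : {"mean", "pessimistic", "optimistic"}, default="mean"
        Which pooled parameterization of the elicited probabilities to use.
    target_level : float, default=90.0
        Credible level (percent) to which stated expert confidence is
        standardized.
    orientation_mode : {"adverse", "literal"}, default="adverse"
        How pessimistic/optimistic labels map to percentiles; ``adverse``
        makes "pessimistic" the higher adverse-event probability.
    structure : (nodes, composite_weights) tuple or None
        Custom network structure; ``None`` uses the default wiring.

    Attributes
    ----------
    parameterization_ : Parameterization
        The pooled values fitted from the responses.
    model_ : NetworkModel
        The assembled network with all CPTs.
    quantities_ : list of str
        Quantity ids the structure requires.
    classes_ : ndarray of shape (2,)
        ``[0, 1]`` — no-decline vs. decline.
    """

    def __init__(self, parameterization: str = "mean",
                 target_level: float = 90.0,
                 orientation_mode: str = "adverse",
                 structure=None):
        self.parameterization = parameterization
        self.target_level = target_level
        self.orientation_mode = orientation_mode
        self.structure = structure

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Pool expert responses and assemble the network.

        ``X`` is either a DataFrame with the elicitation-record columns
        (expert_id, quantity_id, lowest, best, highest, confidence) or an
        iterable of :class:`~reefrisk.elicitation.FourPointResponse`.
        ``y`` is ignored (elicited, not supervised).
        """
        if self.parameterization not in _elic.PARAMETERIZATION_LABELS:
            raise ValueError(
                f"parameterization must be one of "
                f"{_elic.PARAMETERIZATION_LABELS}, got {self.parameterization!r}")
        responses = self._coerce_responses(X)
        if self.structure is None:
            nodes, weights = _net.default_structure()
        else:
            nodes, weights = self.structure
        self.quantities_ = _net.required_quantities(nodes)
        orientation = _net.default_orientation_map(nodes)
        self.parameterization_ = _elic.build_parameterization(
            responses, self.parameterization, orientation,
            required=self.quantities_, mode=self.orientation_mode,
            target_level=self.target_level)
        self.model_ = _net.build_model(self.parameterization_, nodes, weights)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame, scenario=None,
                      stats: Mapping[str, _layers.LayerStats] | None = None
                      ) -> np.ndarray:
        """Per-reef [P(no decline), P(decline)] under a scenario.

        ``X`` is a reef table; ``scenario`` a :class:`Scenario`, a shipped
        scenario name, or ``None`` for baseline.  Layer statistics default
        to the supplied table's own mid-shelf mean/SD.
        """
        self._check_fitted()
        scenario = self._coerce_scenario(scenario)
        if stats is None:
            stats = _layers.compute_layer_stats(X)
        pred = _scen.predict_all(self.model_, X, scenario, stats,
                                 parameterization=self.parameterization)
        p = np.array([pred.probabilities[str(r)] for r in X["reef_id"]])
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame, scenario=None, stats=None) -> np.ndarray:
        """1 where decline is more likely than not, else 0."""
        return (self.predict_proba(X, scenario, stats)[:, 1] >= 0.5).astype(int)

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError(
                "this ReefDeclineNetwork instance is not fitted yet; "
                "call fit(responses) first")

    @staticmethod
    def _coerce_responses(X) -> list[_elic.FourPointResponse]:
        if isinstance(X, pd.DataFrame):
            return [
                _elic.FourPointResponse(
                    expert_id=str(r.expert_id), quantity_id=str(r.quantity_id),
                    lowest=float(r.lowest), best=float(r.best),
                    highest=float(r.highest), confidence=float(r.confidence))
                for r in X.itertuples(index=False)
            ]
        return list(X)

    @staticmethod
    def _coerce_scenario(scenario) -> _scen.Scenario:
        if scenario is None:
            return _scen.default_scenarios()["baseline"]
        if isinstance(scenario, str):
            shipped = _scen.default_scenarios()
            if scenario not in shipped:
                raise ValueError(
                    f"unknown scenario {scenario!r}; shipped: {sorted(shipped)}")
            return shipped[scenario]
        return scenario
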