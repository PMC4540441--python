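"""Scenario definitions, per-reef prediction, summaries and change maps.

A scenario is a fixed what-if over a ten-year horizon, not a forecast: a
categorical shift (±1 state or no change) per stressor, a temperature delta
added to anomalies before discretization, and a multiplicative increase in
cyclone exposure.  The four shipped scenarios are:

1. ``baseline``            — current conditions, everything unchanged;
2. ``climate``             — +0.2 °C anomalies, cyclone chance ×1.3, disease
                             and bleaching frequency up one state; no local
                             management;
3. ``climate_management``  — as 2, plus nutrients, sediment, pollution and
                             fishing down one state (≈30 % ≙ 1 SD reduction);
4. ``management``          — the local reductions of 3 without further
                             climate change (best case).

Shifts on input layers act on the discretized evidence; shifts on latent
event nodes (disease, bleaching) act on the event's CPT by moving
probability mass along the state order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import layers as _layers
from .layers import LayerStats, discretize_layer, discretize_temperature
from .network import NetworkModel, infer_decline, validate_network

__all__ = [
    "Scenario",
    "PredictionSet",
    "ZoneSummary",
    "shift_state",
    "apply_scenario",
    "predict_all",
    "summarize_by_zone",
    "change_map",
    "relative_change",
    "default_scenarios",
    "scenarios_from_yaml",
    "scenarios_to_yaml",
    "read_predictions",
    "write_predictions",
]

#: variables a scenario may shift (the scenario-table columns)
SCENARIO_VARIABLES = (
    "temperature", "cyclones", "disease", "bleaching", "irradiance",
    "cots", "nutrients", "sediment", "pollution", "fishing",
)
#: of those, the latent event nodes (shifted through the CPT, not evidence)
EVENT_VARIABLES = ("disease", "bleaching", "cots")

_STATES = ("below", "average", "above")


@dataclass(frozen=True)
class Scenario:
    """One what-if: categorical shifts plus continuous climate knobs."""

    name: str
    shifts: Mapping[str, int] = field(default_factory=dict)
    temp_delta: float = 0.0
    cyclone_multiplier: float = 1.0

    def __post_init__(self) -> None:
        unknown = sorted(set(self.shifts) - set(SCENARIO_VARIABLES))
        if unknown:
            raise ValueError(f"scenario {self.name!r}: unknown variables {unknown}")
        bad = {v: s for v, s in self.shifts.items() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"scenario {self.name!r}: shifts must be -1/0/+1, got {bad}")
        if not math.isfinite(self.temp_delta):
            raise ValueError(f"scenario {self.name!r}: temp_delta must be finite")
        if not self.cyclone_multiplier > 0:
            raise ValueError(f"scenario {self.name!r}: cyclone_multiplier must be > 0")
        object.__setattr__(self, "shifts", dict(self.shifts))

    @property
    def event_shifts(self) -> dict[str, int]:
        return {v: s for v, s in self.shifts.items()
                if v in EVENT_VARIABLES and s != 0}

    @property
    def input_shifts(self) -> dict[str, int]:
        return {v: s for v, s in self.shifts.items()
                if v not in EVENT_VARIABLES and s != 0}


@dataclass
class PredictionSet:
    """Per-reef decline probabilities for one scenario × parameterization."""

    scenario: str
    parameterization: str
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        bad = {r: p for r, p in self.probabilities.items() if not 0.0 <= p <= 1.0}
        if bad:
            raise ValueError(f"probabilities outside [0,1]: {bad}")

    def mean(self) -> float:
        import numpy as np
        return float(np.mean(list(self.probabilities.values())))


@dataclass
class ZoneSummary:
    """Reef-weighted mean decline probabilities by zoning status.

    Means are arithmetic over reefs.  An empty zone leaves its mean (and the
    difference) as ``None`` and is named in ``flags``.
    """

    mean_overall: float | None
    mean_no_take: float | None
    mean_open: float | None
    difference: float | None  # mean_open − mean_no_take
    flags: list[str] = field(default_factory=list)


def shift_state(state: str, shift: int,
                states: Sequence[str] = _STATES) -> str:
    """Move a categorical state by ±1 along its order, clamped at the ends."""
    if shift not in (-1, 0, 1):
        raise ValueError(f"shift must be -1, 0 or +1, got {shift}")
    i = states.index(state)
    return states[min(len(states) - 1, max(0, i + shift))]


def apply_scenario(
    reef: Mapping[str, float] | pd.Series,
    scenario: Scenario,
    stats: Mapping[str, LayerStats],
) -> dict[str, str]:
    """Evidence for one reef under a scenario.

    Temperature: the delta is added to the anomaly before the ±1 °C rule.
    Cyclones: the exposure is multiplied before SD discretization (applied to
    the continuous value, then any categorical shift on top).  Other shifted
    inputs move one category from their baseline state.  Event-node shifts do
    not appear in the evidence; they transform the model (see
    :func:`predict_all`).
    """
    evidence: dict[str, str] = {}
    input_shifts = scenario.input_shifts
    for layer in _layers.INPUT_LAYERS:
        value = float(reef[layer])
        if layer == "temperature":
            state = discretize_temperature(value + scenario.temp_delta)
        elif layer == "cyclones":
            state = discretize_layer(value * scenario.cyclone_multiplier,
                                     stats[layer])
        else:
            state = discretize_layer(value, stats[layer])
        if layer in input_shifts:
            state = shift_state(state, input_shifts[layer])
        evidence[layer] = state
    return evidence


def predict_all(
    model: NetworkModel,
    reefs: pd.DataFrame,
    scenario: Scenario,
    stats: Mapping[str, LayerStats],
    parameterization: str = "mean",
) -> PredictionSet:
    """Exact decline probability for every reef under one scenario."""
    if reefs.empty:
        raise ValueError("reef table is empty")
    report = validate_network(model)
    if not report:
        raise ValueError("invalid model:\n" + "\n".join(report.problems))
    run_model = model.with_event_shifts(scenario.event_shifts) \
        if scenario.event_shifts else model
    probs: dict[str, float] = {}
    for _, row in reefs.iterrows():
        try:
            evidence = apply_scenario(row, scenario, stats)
            probs[str(row["reef_id"])] = infer_decline(
                run_model, evidence, validate=False)
        except Exception as exc:
            raise RuntimeError(
                f"prediction failed for reef {row['reef_id']!r} "
                f"under scenario {scenario.name!r}: {exc}"
            ) from exc
    return PredictionSet(scenario=scenario.name,
                         parameterization=parameterization,
                         probabilities=probs)


def summarize_by_zone(pred: PredictionSet, reefs: pd.DataFrame) -> ZoneSummary:
    """Arithmetic mean decline probability overall and by no-take status."""
    missing = sorted(set(reefs["reef_id"].astype(str)) - set(pred.probabilities))
    if missing:
        raise ValueError(f"predictions missing for reefs: {missing}")
    flags: list[str] = []
    p = reefs["reef_id"].astype(str).map(pred.probabilities)
    no_take = reefs["no_take"].astype(bool)

    def _mean(series) -> float | None:
        return float(series.mean()) if len(series) else None

    mean_overall = _mean(p)
    mean_no_take = _mean(p[no_take])
    mean_open = _mean(p[~no_take])
    if mean_no_take is None:
        flags.append("no_take zone empty: mean undefined")
    if mean_open is None:
        flags.append("open zone empty: mean undefined")
    difference = (mean_open - mean_no_take
                  if mean_open is not None and mean_no_take is not None else None)
    return ZoneSummary(mean_overall, mean_no_take, mean_open, difference, flags)


def change_map(pred_a: PredictionSet,
               pred_b: PredictionSet) -> dict[str, float | None]:
    """Per-reef relative change (b − a) / a between two prediction sets.

    A reef where the first scenario predicts exactly zero gets ``None`` (the
    relative change is undefined there) rather than a number.
    """
    a_ids, b_ids = set(pred_a.probabilities), set(pred_b.probabilities)
    if a_ids != b_ids:
        raise ValueError(
            f"prediction sets cover different reefs; symmetric difference: "
            f"{sorted(a_ids ^ b_ids)}"
        )
    out: dict[str, float | None] = {}
    for reef_id in pred_a.probabilities:
        a = pred_a.probabilities[reef_id]
        b = pred_b.probabilities[reef_id]
        out[reef_id] = None if a == 0.0 else (b - a) / a
    return out


def relative_change(a: float, b: float) -> float:
    """Scalar form of the change-map formula: (b − a) / a."""
    if a == 0.0:
        raise ZeroDivisionError("relative change undefined when the first value is 0")
    return (b - a) / a


def default_scenarios() -> dict[str, Scenario]:
    """The four shipped scenarios (see module docstring)."""
    reductions = {"nutrients": -1, "sediment": -1, "pollution": -1, "fishing": -1}
    return {
        "baseline": Scenario("baseline"),
        "climate": Scenario(
            "climate", shifts={"disease": 1, "bleaching": 1},
            temp_delta=0.2, cyclone_multiplier=1.3),
        "climate_management": Scenario(
            "climate_management",
            shifts={"disease": 1, "bleaching": 1, **reductions},
            temp_delta=0.2, cyclone_multiplier=1.3),
        "management": Scenario("management", shifts=dict(reductions)),
    }


# ---------------------------------------------------------------------------
# Files

def scenarios_to_yaml(scenarios: Mapping[str, Scenario], path: str | Path) -> None:
    doc = {
        name: {
            "shifts": dict(s.shifts),
            "temp_delta": s.temp_delta,
            "cyclone_multiplier": s.cyclone_multiplier,
        }
        for name, s in scenarios.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenarios_from_yaml(path: str | Path) -> dict[str, Scenario]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: dict[str, Scenario] = {}
    for name, spec in doc.items():
        shifts = {v: int(s) for v, s in (spec.get("shifts") or {}).items()}
        out[name] = Scenario(
            name=name, shifts=shifts,
            temp_delta=float(spec.get("temp_delta", 0.0)),
            cyclone_multiplier=float(spec.get("cyclone_multiplier", 1.0)),
        )
    return out


def write_predictions(pred: PredictionSet, path: str | Path) -> None:
    rows = [
        {"reef_id": reef_id, "scenario": pred.scenario,
         "parameterization": pred.parameterization,
         "p_decline": repr(p)}
        for reef_id, p in sorted(pred.probabilities.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions(path: str | Path) -> PredictionSet:
    df = pd.read_csv(path, dtype={"reef_id": str})
    scenarios_ = df["scenario"].unique()
    params = df["parameterization"].unique()
    if len(scenarios_) != 1 or len(params) != 1:
        raise ValueError(f"{path}: expected one scenario and one parameterization")
    return PredictionSet(
        scenario=scenarios_[0], parameterization=params[0],
        probabilities=dict(zip(df["reef_id"], df["p_decline"].astype(float))),
    )
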