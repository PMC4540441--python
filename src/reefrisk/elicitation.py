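"""Expert elicitation: 4-point responses, pooling, and model parameterizations.

Experts are asked, for each conditional probability the network needs, for the
lowest possible value, their best estimate, the highest possible value, and
their confidence (a credible level in percent) that the true value lies inside
the stated interval.  Responses are standardized to a common credible level by
linearly rescaling the interval half-widths, pooled across experts with equal
weights, and turned into three complete parameterizations of the network:

``mean``
    the group mean of best estimates per elicited quantity;
``pessimistic``
    per quantity, the percentile of best estimates that yields the *more
    adverse* probability (by default the 75th percentile for quantities whose
    state is adverse, the 25th for beneficial ones);
``optimistic``
    the mirror image of ``pessimistic``.

Only best estimates feed the parameterizations; standardized intervals are
retained for diagnostics.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FourPointResponse",
    "StandardizedInterval",
    "Parameterization",
    "standardize_response",
    "pool_experts",
    "build_parameterization",
    "read_responses",
    "write_responses",
    "read_parameterization",
    "write_parameterization",
    "PARAMETERIZATION_LABELS",
]

PARAMETERIZATION_LABELS = ("mean", "pessimistic", "optimistic")

#: pooling statistics understood by :func:`pool_experts`
_POOL_STATS = ("mean", "p25", "p75")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class FourPointResponse:
    """One expert's 4-point estimate of one elicited probability.

    ``confidence`` is the credible level, in percent, the expert attaches to
    the interval ``[lowest, highest]``.
    """

    expert_id: str
    quantity_id: str
    lowest: float
    best: float
    highest: float
    confidence: float

    def __post_init__(self) -> None:
        ctx = f"(expert {self.expert_id!r}, quantity {self.quantity_id!r})"
        if not (0.0 <= self.lowest <= self.best <= self.highest <= 1.0):
            raise ValueError(
                f"require 0 <= lowest <= best <= highest <= 1, got "
                f"({self.lowest}, {self.best}, {self.highest}) {ctx}"
            )
        if not (0.0 < self.confidence <= 100.0):
            raise ValueError(
                f"confidence must lie in (0, 100], got {self.confidence} {ctx}"
            )


@dataclass(frozen=True)
class StandardizedInterval:
    """A 4-point response rescaled to a common credible level."""

    quantity_id: str
    expert_id: str
    best: float
    low_s: float
    high_s: float
    target_level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_s <= self.best <= self.high_s <= 1.0):
            raise ValueError(
                f"standardized interval violates low <= best <= high in [0,1]: "
                f"({self.low_s}, {self.best}, {self.high_s})"
            )


@dataclass
class Parameterization:
    """A complete assignment of pooled probabilities to elicited quantities."""

    label: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {q: v for q, v in self.values.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"parameterization values outside [0,1]: {bad}")

    def require(self, quantity_ids: Iterable[str]) -> None:
        """Raise if any required quantity lacks a value, listing all absences."""
        missing = sorted(set(quantity_ids) - set(self.values))
        if missing:
            raise KeyError(
                f"parameterization {self.label!r} missing quantities: {missing}"
            )

    def __getitem__(self, quantity_id: str) -> float:
        return self.values[quantity_id]


def standardize_response(
    resp: FourPointResponse, target_level: float = 90.0
) -> StandardizedInterval:
    """Rescale a response's interval to ``target_level`` percent credibility.

    Half-widths ``best - lowest`` and ``highest - best`` are multiplied by
    ``target_level / confidence`` and the endpoints clamped to [0, 1]; the
    best estimate is untouched.  When stated confidence equals the target
    level this is the identity.
    """
    if not (0.0 < target_level <= 100.0):
        raise ValueError(f"target_level must lie in (0, 100], got {target_level}")
    if resp.confidence <= 0.0:  # unreachable through the dataclass, kept for raw dicts
        raise ValueError(
            f"confidence must be positive to standardize "
            f"(expert {resp.expert_id!r}, quantity {resp.quantity_id!r})"
        )
    factor = target_level / resp.confidence
    low = _clamp01(resp.best - (resp.best - resp.lowest) * factor)
    high = _clamp01(resp.best + (resp.highest - resp.best) * factor)
    return StandardizedInterval(
        quantity_id=resp.quantity_id,
        expert_id=resp.expert_id,
        best=resp.best,
        low_s=low,
        high_s=high,
        target_level=target_level,
    )


def pool_experts(
    responses: Sequence[StandardizedInterval | FourPointResponse],
    stat: str,
) -> float:
    """Pool one quantity's best estimates across experts.

    ``stat`` is one of ``mean``, ``p25``, ``p75``.  Percentiles use linear
    interpolation between order statistics.
    """
    if stat not in _POOL_STATS:
        raise ValueError(f"stat must be one of {_POOL_STATS}, got {stat!r}")
    if not responses:
        raise ValueError("cannot pool an empty collection of responses")
    qids = {r.quantity_id for r in responses}
    if len(qids) > 1:
        raise ValueError(f"responses mix quantities: {sorted(qids)}")
    bests = np.asarray([r.best for r in responses], dtype=float)
    if stat == "mean":
        return float(bests.mean())
    q = 25.0 if stat == "p25" else 75.0
    return float(np.percentile(bests, q, method="linear"))


def _stat_for_label(label: str, orientation: str, mode: str) -> str:
    """Resolve the pooling statistic for one quantity under one label.

    In the default ``adverse`` mode, pessimistic means the higher adverse
    probability: adverse quantities take p75, beneficial ones p25, neutral
    ones the mean (and the mirror for optimistic).  The ``literal`` mode
    applies the 25th percentile to every quantity under the pessimistic label
    and the 75th under the optimistic one, regardless of orientation.
    """
    if label == "mean":
        return "mean"
    if label not in PARAMETERIZATION_LABELS:
        raise ValueError(f"unknown parameterization label {label!r}")
    if mode == "literal":
        return "p25" if label == "pessimistic" else "p75"
    if mode != "adverse":
        raise ValueError(f"orientation mode must be 'adverse' or 'literal', got {mode!r}")
    if orientation == "neutral":
        return "mean"
    hi = orientation == "adverse"
    if label == "pessimistic":
        return "p75" if hi else "p25"
    return "p25" if hi else "p75"


def build_parameterization(
    all_responses: Iterable[FourPointResponse],
    label: str,
    adverse_orientation_map: Mapping[str, str] | None = None,
    *,
    required: Iterable[str] | None = None,
    mode: str = "adverse",
    target_level: float = 90.0,
) -> Parameterization:
    """Pool every elicited quantity into one parameterization.

    Parameters
    ----------
    all_responses:
        Raw 4-point responses covering every required quantity.
    label:
        ``mean``, ``pessimistic`` or ``optimistic``.
    adverse_orientation_map:
        Maps quantity id to ``adverse``, ``beneficial`` or ``neutral``.
        Quantities absent from the map are treated as neutral.
    required:
        Quantity ids the network needs; missing ones raise with the full list.
    mode:
        ``adverse`` (default; pessimistic = higher adverse probability) or
        ``literal`` (pessimistic = 25th percentile of every quantity).
    """
    orient = dict(adverse_orientation_map or {})
    by_quantity: dict[str, list[StandardizedInterval]] = defaultdict(list)
    for resp in all_responses:
        by_quantity[resp.quantity_id].append(
            standardize_response(resp, target_level=target_level)
        )
    if required is not None:
        missing = sorted(set(required) - set(by_quantity))
        if missing:
            raise KeyError(f"no responses for required quantities: {missing}")
    values = {
        qid: pool_experts(
            resps, _stat_for_label(label, orient.get(qid, "neutral"), mode)
        )
        for qid, resps in by_quantity.items()
    }
    return Parameterization(label=label, values=values)


# ---------------------------------------------------------------------------
# CSV interfaces

_RESPONSE_FIELDS = ["expert_id", "quantity_id", "lowest", "best", "highest", "confidence"]


def read_responses(path: str | Path) -> list[FourPointResponse]:
    """Read elicitation records from a CSV with the documented header."""
    out: list[FourPointResponse] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_RESPONSE_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                FourPointResponse(
                    expert_id=row["expert_id"],
                    quantity_id=row["quantity_id"],
                    lowest=float(row["lowest"]),
                    best=float(row["best"]),
                    highest=float(row["highest"]),
                    confidence=float(row["confidence"]),
                )
            )
    return out


def write_responses(responses: Iterable[FourPointResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESPONSE_FIELDS)
        for r in responses:
            writer.writerow(
                [r.expert_id, r.quantity_id, repr(float(r.lowest)),
                 repr(float(r.best)), repr(float(r.highest)),
                 repr(float(r.confidence))]
            )


def write_parameterization(param: Parameterization, path: str | Path) -> None:
    """Write ``quantity_id,label,value`` rows; floats round-trip bit-exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["quantity_id", "label", "value"])
        for qid in sorted(param.values):
            writer.writerow([qid, param.label, repr(float(param.values[qid]))])


def read_parameterization(path: str | Path) -> Parameterization:
    values: dict[str, float] = {}
    labels: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            values[row["quantity_id"]] = float(row["value"])
            labels.add(row["label"])
    if len(labels) != 1:
        raise ValueError(f"{path}: expected exactly one label, found {sorted(labels)}")
    return Parameterization(label=labels.pop(), values=values)
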