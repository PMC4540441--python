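"""Discrete Bayesian network: structure, CPT construction, exact inference.

The network links per-reef stressor evidence (input nodes) to the probability
of hard-coral-cover decline over a ten-year horizon (outcome node) through
latent stress events (mass bleaching, disease outbreak, crown-of-thorns
outbreak) and two weighted composite indices (water quality, anthropogenic
stress).  Every node is discrete with a total order over its states running
from least to most adverse.

CPTs for elicited nodes are built from the two extreme-endpoint distributions
experts provide (all parents least adverse vs. all most adverse) by linear
interpolation along the mean normalized parent ordinal.  Composite-index CPTs
are deterministic threshold functions of the weighted mean parent ordinal.
Inference is exact variable elimination; the network is small enough that no
approximation is ever warranted.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "NodeSpec",
    "CPT",
    "EndpointElicitation",
    "NetworkModel",
    "ValidationReport",
    "ordinal_score",
    "interpolate_cpt",
    "composite_cpt",
    "validate_network",
    "infer",
    "infer_decline",
    "default_structure",
    "build_model",
    "required_quantities",
    "default_orientation_map",
    "structure_from_yaml",
    "structure_to_yaml",
    "read_cpts",
    "write_cpts",
]

NODE_KINDS = ("input", "composite", "event", "outcome")

#: default state labels, ordered least → most adverse
INPUT_STATES = ("below", "average", "above")
EVENT_STATES = ("decreased", "unchanged", "increased")
COMPOSITE_STATES = ("low", "medium", "high")
OUTCOME_STATES = ("no_decline", "decline")


@dataclass(frozen=True)
class NodeSpec:
    """One node: its kind, ordered states (increasing adversity) and parents."""

    name: str
    kind: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"node {self.name!r}: unknown kind {self.kind!r}")
        if not self.states:
            raise ValueError(f"node {self.name!r}: states must be non-empty")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"node {self.name!r}: duplicate states")
        if self.kind == "input" and self.parents:
            raise ValueError(f"input node {self.name!r} must have no parents")
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"{state!r} is not a state of node {self.name!r} "
                f"(states: {self.states})"
            ) from None


@dataclass
class CPT:
    """Distribution over a node's states per combination of parent states.

    ``table`` maps a tuple of parent states (in declared parent order; the
    empty tuple for parentless nodes) to a probability vector over
    ``states``.
    """

    node: str
    states: tuple[str, ...]
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    table: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict)

    def validate(self, atol: float = 1e-9) -> list[str]:
        """Return a list of problems (empty when the CPT is well-formed)."""
        problems: list[str] = []
        expected = set(product(*self.parent_states)) if self.parents else {()}
        present = set(self.table)
        for combo in sorted(expected - present):
            problems.append(f"CPT {self.node!r}: missing row for combo {combo}")
        for combo in sorted(present - expected):
            problems.append(f"CPT {self.node!r}: unexpected combo {combo}")
        for combo, row in self.table.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (len(self.states),):
                problems.append(
                    f"CPT {self.node!r}: row {combo} has length {row.size}, "
                    f"expected {len(self.states)}"
                )
                continue
            if np.any(row < -atol) or np.any(row > 1 + atol):
                problems.append(f"CPT {self.node!r}: row {combo} outside [0,1]")
            if abs(row.sum() - 1.0) > atol:
                problems.append(
                    f"CPT {self.node!r}: row {combo} sums to {row.sum():.12f}"
                )
        return problems

    def as_array(self) -> np.ndarray:
        """Dense array of shape (*parent cardinalities, n_states)."""
        cards = [len(ps) for ps in self.parent_states]
        arr = np.empty(cards + [len(self.states)], dtype=float)
        for combo, row in self.table.items():
            idx = tuple(
                self.parent_states[i].index(s) for i, s in enumerate(combo)
            )
            arr[idx] = np.asarray(row, dtype=float)
        return arr


@dataclass
class EndpointElicitation:
    """Elicited distributions at the two parent-configuration extremes."""

    node: str
    low_endpoint: np.ndarray   # all parents least adverse
    high_endpoint: np.ndarray  # all parents most adverse

    def __post_init__(self) -> None:
        for name, dist in (("low", self.low_endpoint), ("high", self.high_endpoint)):
            dist = np.asarray(dist, dtype=float)
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.node!r} {name} endpoint sums to {dist.sum():.12f}, not 1"
                )
            if np.any(dist < 0):
                raise ValueError(f"{self.node!r} {name} endpoint has negative mass")
        self.low_endpoint = np.asarray(self.low_endpoint, dtype=float)
        self.high_endpoint = np.asarray(self.high_endpoint, dtype=float)


@dataclass
class NetworkModel:
    """Nodes, CPTs for all non-input nodes, and composite weights."""

    nodes: dict[str, NodeSpec]
    cpts: dict[str, CPT]
    composite_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    _arrays: dict[str, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[name]

    def cpt_array(self, name: str) -> np.ndarray:
        """Dense CPT array, cached — inference touches these repeatedly."""
        if self._arrays is None:
            self._arrays = {}
        if name not in self._arrays:
            self._arrays[name] = self.cpts[name].as_array()
        return self._arrays[name]

    @property
    def input_nodes(self) -> list[str]:
        return [n for n, s in self.nodes.items() if s.kind == "input"]

    @property
    def outcome_node(self) -> str:
        outs = [n for n, s in self.nodes.items() if s.kind == "outcome"]
        if len(outs) != 1:
            raise ValueError(f"model must have exactly one outcome node, found {outs}")
        return outs[0]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for spec in self.nodes.values():
            for p in spec.parents:
                g.add_edge(p, spec.name)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))

    def with_event_shifts(self, shifts: Mapping[str, int]) -> "NetworkModel":
        """A copy whose event-node CPT rows are shifted along the state order.

        A shift of +1 moves each state's mass one step toward the most
        adverse state (clamped); −1 the reverse.  Used by scenarios that
        posit an increase or decrease in event frequency.
        """
        new_cpts = dict(self.cpts)
        for name, shift in shifts.items():
            if name not in self.nodes or self.nodes[name].kind != "event":
                raise ValueError(f"{name!r} is not an event node of this model")
            if shift == 0:
                continue
            old = self.cpts[name]
            k = len(old.states)
            new_table = {}
            for combo, row in old.table.items():
                shifted = np.zeros(k)
                for i, p in enumerate(np.asarray(row, dtype=float)):
                    shifted[min(k - 1, max(0, i + shift))] += p
                new_table[combo] = shifted
            new_cpts[name] = CPT(
                node=old.node, states=old.states, parents=old.parents,
                parent_states=old.parent_states, table=new_table,
            )
        return NetworkModel(
            nodes=dict(self.nodes), cpts=new_cpts,
            composite_weights={k: dict(v) for k, v in self.composite_weights.items()},
        )


@dataclass
class ValidationReport:
    passed: bool
    problems: list[str]

    def __bool__(self) -> bool:
        return self.passed


# ---------------------------------------------------------------------------
# CPT construction

def ordinal_score(combo: Sequence[str], parents: Sequence[NodeSpec]) -> float:
    """Mean normalized state ordinal of a parent assignment, in [0, 1].

    0 iff every parent is in its least adverse state, 1 iff every parent is
    most adverse.  A single-state parent carries no ordering information and
    contributes 0 (with a warning).
    """
    if len(combo) != len(parents):
        raise ValueError(
            f"combo has {len(combo)} states for {len(parents)} parents"
        )
    if not parents:
        return 0.0
    total = 0.0
    for state, spec in zip(combo, parents):
        if spec.n_states == 1:
            warnings.warn(
                f"parent {spec.name!r} has a single state; it contributes 0 "
                f"to the ordinal score", stacklevel=2,
            )
            continue
        total += spec.state_index(state) / (spec.n_states - 1)
    return total / len(parents)


def interpolate_cpt(ep: EndpointElicitation, parents: Sequence[NodeSpec],
                    states: Sequence[str]) -> CPT:
    """Fill a full CPT by linear interpolation between elicited endpoints.

    A parent combination with ordinal score ``s`` receives the row
    ``(1 - s) * low + s * high`` (renormalized against accumulated rounding);
    the rows at s = 0 and s = 1 are the elicited endpoints verbatim.
    """
    states = tuple(states)
    low = np.asarray(ep.low_endpoint, dtype=float)
    high = np.asarray(ep.high_endpoint, dtype=float)
    if low.shape != (len(states),) or high.shape != (len(states),):
        raise ValueError(
            f"{ep.node!r}: endpoint length does not match {len(states)} states"
        )
    parent_states = tuple(p.states for p in parents)
    table: dict[tuple[str, ...], np.ndarray] = {}
    for combo in product(*parent_states) if parents else [()]:
        s = ordinal_score(combo, parents)
        if s == 0.0:
            row = low.copy()
        elif s == 1.0:
            row = high.copy()
        else:
            row = (1.0 - s) * low + s * high
            row = row / row.sum()
        table[combo] = row
    return CPT(node=ep.node, states=states,
               parents=tuple(p.name for p in parents),
               parent_states=parent_states, table=table)


def composite_cpt(node: NodeSpec, parents: Sequence[NodeSpec],
                  weights: Mapping[str, float],
                  thresholds: tuple[float, float] = (1 / 3, 2 / 3)) -> CPT:
    """Deterministic CPT for a weighted composite index node.

    The weighted mean of normalized parent ordinals is cut at ``thresholds``
    into the composite node's ordered states: index >= upper threshold maps
    to the most adverse state, index >= lower threshold to the middle one.
    Each row puts probability 1 on exactly one state.
    """
    w = np.asarray([float(weights.get(p.name, 0.0)) for p in parents])
    if np.any(w < 0):
        raise ValueError(f"composite {node.name!r}: weights must be non-negative")
    if w.sum() == 0:
        raise ValueError(f"composite {node.name!r}: weights must not all be zero")
    if node.n_states != 3:
        raise ValueError(f"composite {node.name!r} must have 3 ordered states")
    lo, hi = thresholds
    w = w / w.sum()
    parent_states = tuple(p.states for p in parents)
    table: dict[tuple[str, ...], np.ndarray] = {}
    for combo in product(*parent_states):
        ordinals = np.asarray([
            p.state_index(s) / (p.n_states - 1) if p.n_states > 1 else 0.0
            for p, s in zip(parents, combo)
        ])
        index = float(w @ ordinals)
        state = 2 if index >= hi else 1 if index >= lo else 0
        row = np.zeros(3)
        row[state] = 1.0
        table[combo] = row
    return CPT(node=node.name, states=node.states,
               parents=tuple(p.name for p in parents),
               parent_states=parent_states, table=table)


# ---------------------------------------------------------------------------
# Validation

def validate_network(model: NetworkModel) -> ValidationReport:
    """Check acyclicity, CPT presence/completeness and row normalization."""
    problems: list[str] = []
    g = model.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append(f"graph contains a cycle: {cycle}")
    for name, spec in model.nodes.items():
        for p in spec.parents:
            if p not in model.nodes:
                problems.append(f"node {name!r}: unknown parent {p!r}")
        if spec.kind != "input":
            if name not in model.cpts:
                problems.append(f"non-input node {name!r} has no CPT")
            else:
                cpt = model.cpts[name]
                if cpt.states != spec.states:
                    problems.append(
                        f"CPT {name!r}: states {cpt.states} != node states "
                        f"{spec.states}"
                    )
                if cpt.parents != spec.parents:
                    problems.append(
                        f"CPT {name!r}: parents {cpt.parents} != node parents "
                        f"{spec.parents}"
                    )
                problems.extend(cpt.validate())
    for name in model.cpts:
        if name not in model.nodes:
            problems.append(f"CPT for unknown node {name!r}")
    return ValidationReport(passed=not problems, problems=problems)


# ---------------------------------------------------------------------------
# Exact inference (variable elimination)

class _Factor:
    """A non-negative table over a tuple of variables."""

    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    def reduce(self, var: str, index: int) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:],
            np.take(self.values, index, axis=ax),
        )

    def multiply(self, other: "_Factor") -> "_Factor":
        new_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(new_vars)
        b = other._broadcast(new_vars)
        return _Factor(new_vars, a * b)

    def _broadcast(self, new_vars: tuple[str, ...]) -> np.ndarray:
        # move existing axes into position, add length-1 axes for new vars
        perm = [self.vars.index(v) for v in new_vars if v in self.vars]
        arr = np.transpose(self.values, perm)
        shape = []
        k = 0
        for v in new_vars:
            if v in self.vars:
                shape.append(arr.shape[k])
                k += 1
            else:
                shape.append(1)
        return arr.reshape(shape)

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:],
            self.values.sum(axis=ax),
        )


def infer(model: NetworkModel, evidence: Mapping[str, str],
          query: str, *, validate: bool = True) -> np.ndarray:
    """Exact posterior over ``query``'s states given the evidence.

    Performs variable elimination over the factors defined by the model's
    CPTs after reducing them on the evidence.  Nodes without a CPT (input
    nodes) must be observed, or be ancestors only through observed nodes.
    ``validate=False`` skips the structural re-check for repeated calls on a
    model already known valid.
    """
    if validate:
        report = validate_network(model)
        if not report:
            raise ValueError("invalid model:\n" + "\n".join(report.problems))
    for node, state in evidence.items():
        model.node(node).state_index(state)  # raises on illegal state

    factors: list[_Factor] = []
    for name, cpt in model.cpts.items():
        f = _Factor(cpt.parents + (name,), model.cpt_array(name))
        for var in f.vars:
            if var in evidence:
                f = f.reduce(var, model.node(var).state_index(evidence[var]))
        factors.append(f)
    # unobserved input nodes appearing in some factor have no distribution
    dangling = {
        v for f in factors for v in f.vars
        if model.node(v).kind == "input" and v not in evidence
    }
    if dangling:
        raise ValueError(
            f"evidence missing for input nodes: {sorted(dangling)}"
        )
    if query in evidence:
        out = np.zeros(model.node(query).n_states)
        out[model.node(query).state_index(evidence[query])] = 1.0
        return out

    hidden = [
        n for n in model.topological_order()
        if n != query and n not in evidence
        and any(n in f.vars for f in factors)
    ]
    for var in hidden:
        related = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    if query not in result.vars:
        raise ValueError(f"query node {query!r} does not appear in the model factors")
    # collapse any stray scalar axes, normalize (evidence likelihood divides out)
    values = np.transpose(result.values, [result.vars.index(query)] +
                          [i for i, v in enumerate(result.vars) if v != query])
    values = values.reshape(model.node(query).n_states, -1).sum(axis=1)
    total = values.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    return values / total


def infer_decline(model: NetworkModel, evidence: Mapping[str, str],
                  *, validate: bool = True) -> float:
    """Exact probability of the outcome node's most adverse (decline) state."""
    missing = sorted(set(model.input_nodes) - set(evidence))
    if missing:
        raise ValueError(f"evidence missing for input nodes: {missing}")
    outcome = model.outcome_node
    posterior = infer(model, evidence, outcome, validate=validate)
    return float(posterior[-1])


# ---------------------------------------------------------------------------
# Default structure and model assembly

def default_structure() -> tuple[dict[str, NodeSpec], dict[str, dict[str, float]]]:
    """The default network wiring and composite weights.

    The published figure this follows is schematic, so the exact parent sets
    are an assumption and the structure is fully editable via the YAML
    interface.  Inputs feed two composites (water quality from terrestrial
    runoff layers; anthropogenic stress from fishing and water quality),
    three latent stress events, and a binary decline outcome; cyclones act on
    the outcome directly.
    """
    nodes = {}
    for name in ("temperature", "cyclones", "plume", "nutrients", "sediment",
                 "pollution", "irradiance", "fishing"):
        nodes[name] = NodeSpec(name, "input", INPUT_STATES)
    nodes["water_quality"] = NodeSpec(
        "water_quality", "composite", COMPOSITE_STATES,
        ("plume", "nutrients", "sediment", "pollution"))
    nodes["anthro_stress"] = NodeSpec(
        "anthro_stress", "composite", COMPOSITE_STATES,
        ("fishing", "water_quality"))
    nodes["bleaching"] = NodeSpec(
        "bleaching", "event", EVENT_STATES,
        ("temperature", "irradiance", "water_quality"))
    nodes["disease"] = NodeSpec(
        "disease", "event", EVENT_STATES, ("temperature", "water_quality"))
    nodes["cots"] = NodeSpec("cots", "event", EVENT_STATES, ("water_quality",))
    nodes["coral_decline"] = NodeSpec(
        "coral_decline", "outcome", OUTCOME_STATES,
        ("bleaching", "disease", "cots", "cyclones", "anthro_stress"))
    weights = {
        "water_quality": {"plume": 1.0, "nutrients": 1.0, "sediment": 1.0,
                          "pollution": 1.0},
        "anthro_stress": {"fishing": 1.0, "water_quality": 1.0},
    }
    return nodes, weights


def required_quantities(nodes: Mapping[str, NodeSpec]) -> list[str]:
    """Quantity ids the elicitation must cover: per elicited node, the state
    probabilities at the all-low and all-high parent endpoints."""
    out = []
    for spec in nodes.values():
        if spec.kind in ("event", "outcome"):
            for endpoint in ("low", "high"):
                for state in spec.states:
                    out.append(f"{spec.name}:{endpoint}:{state}")
    return out


def default_orientation_map(nodes: Mapping[str, NodeSpec]) -> dict[str, str]:
    """Adverse/beneficial orientation per elicited quantity.

    A quantity is the probability of one node state; states above the middle
    of the adversity order are adverse, below it beneficial, the middle
    neutral.
    """
    orient: dict[str, str] = {}
    for spec in nodes.values():
        if spec.kind not in ("event", "outcome"):
            continue
        mid = (spec.n_states - 1) / 2
        for endpoint in ("low", "high"):
            for i, state in enumerate(spec.states):
                qid = f"{spec.name}:{endpoint}:{state}"
                orient[qid] = ("adverse" if i > mid
                               else "beneficial" if i < mid else "neutral")
    return orient


def build_model(
    parameterization,
    nodes: Mapping[str, NodeSpec] | None = None,
    composite_weights: Mapping[str, Mapping[str, float]] | None = None,
    thresholds: tuple[float, float] = (1 / 3, 2 / 3),
) -> NetworkModel:
    """Assemble a full model from a parameterization of elicited quantities.

    Composite nodes get deterministic threshold CPTs; event and outcome
    nodes get endpoint-interpolated CPTs whose endpoint distributions are the
    (renormalized) pooled probabilities ``<node>:low:<state>`` and
    ``<node>:high:<state>`` from the parameterization.
    """
    if nodes is None:
        nodes, default_w = default_structure()
        if composite_weights is None:
            composite_weights = default_w
    composite_weights = {k: dict(v) for k, v in (composite_weights or {}).items()}
    parameterization.require(required_quantities(nodes))

    cpts: dict[str, CPT] = {}
    for spec in nodes.values():
        parents = [nodes[p] for p in spec.parents]
        if spec.kind == "composite":
            if spec.name not in composite_weights:
                raise ValueError(f"composite node {spec.name!r} has no weights")
            cpts[spec.name] = composite_cpt(
                spec, parents, composite_weights[spec.name], thresholds)
        elif spec.kind in ("event", "outcome"):
            low = np.array([parameterization[f"{spec.name}:low:{s}"]
                            for s in spec.states])
            high = np.array([parameterization[f"{spec.name}:high:{s}"]
                             for s in spec.states])
            if low.sum() <= 0 or high.sum() <= 0:
                raise ValueError(f"{spec.name!r}: endpoint has zero total mass")
            ep = EndpointElicitation(spec.name, low / low.sum(), high / high.sum())
            cpts[spec.name] = interpolate_cpt(ep, parents, spec.states)
    model = NetworkModel(nodes=dict(nodes), cpts=cpts,
                         composite_weights=composite_weights)
    report = validate_network(model)
    if not report:
        raise ValueError("built model is invalid:\n" + "\n".join(report.problems))
    return model


# ---------------------------------------------------------------------------
# Structure and CPT files

def structure_to_yaml(nodes: Mapping[str, NodeSpec],
                      composite_weights: Mapping[str, Mapping[str, float]],
                      path: str | Path) -> None:
    doc = {
        "nodes": [
            {"name": s.name, "kind": s.kind, "states": list(s.states),
             "parents": list(s.parents)}
            for s in nodes.values()
        ],
        "composite_weights": {k: dict(v) for k, v in composite_weights.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def structure_from_yaml(path: str | Path) -> tuple[dict[str, NodeSpec],
                                                   dict[str, dict[str, float]]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    nodes = {
        d["name"]: NodeSpec(d["name"], d["kind"], tuple(d["states"]),
                            tuple(d.get("parents", [])))
        for d in doc["nodes"]
    }
    weights = {k: {p: float(w) for p, w in v.items()}
               for k, v in doc.get("composite_weights", {}).items()}
    return nodes, weights


def write_cpts(cpts: Mapping[str, CPT], path: str | Path) -> None:
    """Long-format CSV: node, pipe-joined parent combo, state, probability.

    Probabilities are written with ``repr`` so the file round-trips
    bit-exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "parents", "parent_states", "state", "probability"])
        for name in sorted(cpts):
            cpt = cpts[name]
            for combo in sorted(cpt.table):
                row = cpt.table[combo]
                for state, p in zip(cpt.states, row):
                    writer.writerow([name, "|".join(cpt.parents),
                                     "|".join(combo), state, repr(float(p))])


def read_cpts(path: str | Path,
              nodes: Mapping[str, NodeSpec]) -> dict[str, CPT]:
    rows: dict[str, dict[tuple[str, ...], dict[str, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            combo = tuple(rec["parent_states"].split("|")) if rec["parent_states"] else ()
            rows.setdefault(rec["node"], {}).setdefault(combo, {})[rec["state"]] = (
                float(rec["probability"])
            )
    cpts: dict[str, CPT] = {}
    for name, table in rows.items():
        spec = nodes[name]
        parent_states = tuple(nodes[p].states for p in spec.parents)
        cpts[name] = CPT(
            node=name, states=spec.states, parents=spec.parents,
            parent_states=parent_states,
            table={combo: np.array([d[s] for s in spec.states])
                   for combo, d in table.items()},
        )
    return cpts
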