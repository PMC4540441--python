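"""Shared fixtures: synthetic inputs, fitted models, and the enumeration oracle."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

import reefrisk as rr
from reefrisk.network import CPT, NetworkModel, NodeSpec


def enumerate_outcome_posterior(model: NetworkModel, evidence: dict[str, str],
                                query: str) -> np.ndarray:
    """Brute-force posterior by full-joint enumeration.

    Independent of the package's variable-elimination path: iterates every
    joint assignment of all nodes, multiplies raw CPT rows looked up by
    state label, and conditions by summation.  Exponential; only for tiny
    networks.
    """
    names = list(model.nodes)
    state_lists = [model.nodes[n].states for n in names]
    q_spec = model.nodes[query]
    post = np.zeros(q_spec.n_states)
    for assignment in product(*state_lists):
        world = dict(zip(names, assignment))
        if any(world[n] != s for n, s in evidence.items()):
            continue
        p = 1.0
        for n in names:
            if n in model.cpts:
                cpt = model.cpts[n]
                combo = tuple(world[par] for par in cpt.parents)
                p *= float(np.asarray(cpt.table[combo])[cpt.states.index(world[n])])
        post[q_spec.states.index(world[query])] += p
    total = post.sum()
    if total == 0:
        raise ValueError("evidence has zero probability")
    return post / total


def random_small_network(rng: np.random.Generator, max_nodes: int = 6,
                         n_states: int = 3) -> tuple[NetworkModel, dict[str, str]]:
    """A random DAG with Dirichlet CPT rows plus complete input evidence.

    Parentless nodes are split between observed inputs and latent events
    with elicited priors; the topologically last node is the binary-free
    outcome (kept at ``n_states`` states, its last state read as decline).
    """
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    parents: dict[str, list[str]] = {m: [] for m in names}
    for j in range(1, n):
        for i in range(j):
            if rng.random() < 0.5:
                parents[names[j]].append(names[i])
    states = tuple(f"s{k}" for k in range(n_states))
    nodes: dict[str, NodeSpec] = {}
    evidence: dict[str, str] = {}
    for j, name in enumerate(names):
        if j == n - 1:
            kind = "outcome"
        elif not parents[name] and rng.random() < 0.5:
            kind = "input"
        else:
            kind = "event"
        nodes[name] = NodeSpec(name, kind, states, tuple(parents[name]))
        if kind == "input":
            evidence[name] = states[int(rng.integers(n_states))]
    cpts: dict[str, CPT] = {}
    for name, spec in nodes.items():
        if spec.kind == "input":
            continue
        parent_states = tuple(nodes[p].states for p in spec.parents)
        table = {
            combo: rng.dirichlet(np.ones(n_states))
            for combo in (product(*parent_states) if spec.parents else [()])
        }
        cpts[name] = CPT(name, states, spec.parents, parent_states, table)
    return NetworkModel(nodes=nodes, cpts=cpts), evidence


@pytest.fixture(scope="session")
def expert_responses() -> list[rr.FourPointResponse]:
    return rr.generate_expert_pool(rr.ExpertGenConfig(seed=7))


@pytest.fixture(scope="session")
def responses_frame(expert_responses) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in expert_responses])


@pytest.fixture(scope="session")
def small_fleet() -> pd.DataFrame:
    return rr.generate_reefs(rr.ReefGenConfig(n_reefs=60, seed=11))


@pytest.fixture(scope="session")
def fleet_stats(small_fleet):
    return rr.compute_layer_stats(small_fleet)


@pytest.fixture(scope="session")
def fitted(responses_frame) -> rr.ReefDeclineNetwork:
    return rr.ReefDeclineNetwork().fit(responses_frame)


@pytest.fixture(scope="session")
def default_model(fitted):
    return fitted.model_
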