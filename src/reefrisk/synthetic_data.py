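"""Synthetic reef fleets, expert pools and effort grids.

Everything the pipeline consumes can be generated here, reproducibly from a
seed, with the statistical structure the analysis assumes: a fleet of ~775
mid-shelf reefs spanning 15.77–22.31 °S with about one third inside no-take
zones, and a pool of 21 simulated experts whose 4-point responses scatter
around a configurable "true" set of CPT endpoint probabilities.

These are synthetic stand-ins for qualitative realism and testability; the
layer distributions are not estimates of actual Great Barrier Reef
conditions, and the generated fields carry no spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .elicitation import FourPointResponse
from .network import NodeSpec, default_structure

__all__ = [
    "ReefGenConfig",
    "ExpertGenConfig",
    "generate_reefs",
    "generate_expert_pool",
    "generate_effort_grids",
    "default_truth",
]

#: per-layer sampling families and parameters: (family, loc, scale)
DEFAULT_LAYER_PARAMS: dict[str, tuple[str, float, float]] = {
    "temperature": ("normal", 0.0, 0.5),     # anomaly, °C
    "irradiance": ("normal", 450.0, 40.0),   # mean surface irradiance index
    "cyclones": ("poisson", 1.5, 0.0),       # Cat-II+ exposures per decade
    "cots": ("poisson", 0.8, 0.0),           # outbreaks on record
    "fishing": ("lognormal", 2.0, 0.6),      # line-fishing effort (days)
    "plume": ("gamma", 2.0, 1.0),            # flood-plume exposure index
    "nutrients": ("gamma", 3.0, 1.5),        # DIN load index
    "sediment": ("gamma", 3.0, 1.2),         # sediment load index
    "pollution": ("gamma", 2.0, 0.8),        # pollutant load index
}


@dataclass(frozen=True)
class ReefGenConfig:
    """Configuration for the synthetic mid-shelf reef fleet."""

    n_reefs: int = 775
    lat_range: tuple[float, float] = (-22.31, -15.77)
    lon_range: tuple[float, float] = (145.0, 152.0)
    no_take_fraction: float = 0.33
    layer_params: Mapping[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reefs < 1:
            raise ValueError(f"n_reefs must be >= 1, got {self.n_reefs}")
        if not 0.0 <= self.no_take_fraction <= 1.0:
            raise ValueError(
                f"no_take_fraction must lie in [0,1], got {self.no_take_fraction}")
        for layer, (family, loc, scale) in self.layer_params.items():
            if family in ("normal", "lognormal", "gamma") and scale <= 0:
                raise ValueError(f"layer {layer!r}: scale must be > 0")
            if family == "poisson" and loc <= 0:
                raise ValueError(f"layer {layer!r}: poisson rate must be > 0")
            if family not in ("normal", "lognormal", "gamma", "poisson"):
                raise ValueError(f"layer {layer!r}: unknown family {family!r}")


@dataclass(frozen=True)
class ExpertGenConfig:
    """Configuration for the simulated expert pool.

    ``truth`` maps elicited quantity ids to the true probabilities the
    experts' best estimates scatter around; ``noise`` is ``additive``
    (symmetric on the probability scale, clamped) or ``logit`` (symmetric on
    the log-odds scale, boundary-safe).
    """

    n_experts: int = 21
    truth: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    interval_width: float = 0.15
    confidence: float = 80.0
    noise: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError(f"n_experts must be >= 1, got {self.n_experts}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.confidence <= 100.0:
            raise ValueError(f"confidence must lie in (0,100], got {self.confidence}")
        if self.noise not in ("additive", "logit"):
            raise ValueError(f"noise must be 'additive' or 'logit', got {self.noise!r}")
        bad = {q: v for q, v in self.truth.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"truth probabilities outside [0,1]: {bad}")
        object.__setattr__(self, "truth", dict(self.truth))


def default_truth(nodes: Mapping[str, NodeSpec] | None = None) -> dict[str, float]:
    """A plausible true endpoint parameterization for the default structure.

    High endpoints stochastically dominate low endpoints on the adversity
    order (more stress never makes adverse event states less likely), and
    every entry stays within [0.1, 0.9] so boundary clamping of additive
    expert noise cannot bias pooled means appreciably.
    """
    if nodes is None:
        nodes, _ = default_structure()
    endpoint_dists = {
        "bleaching": {"low": (0.60, 0.30, 0.10), "high": (0.10, 0.30, 0.60)},
        "disease": {"low": (0.60, 0.30, 0.10), "high": (0.15, 0.35, 0.50)},
        "cots": {"low": (0.55, 0.35, 0.10), "high": (0.20, 0.40, 0.40)},
        "coral_decline": {"low": (0.65, 0.35), "high": (0.10, 0.90)},
    }
    truth: dict[str, float] = {}
    for spec in nodes.values():
        if spec.kind not in ("event", "outcome"):
            continue
        dists = endpoint_dists.get(spec.name)
        if dists is None:
            # uniform fallback for custom structures
            dists = {ep: tuple([1.0 / spec.n_states] * spec.n_states)
                     for ep in ("low", "high")}
        for endpoint in ("low", "high"):
            for state, p in zip(spec.states, dists[endpoint]):
                truth[f"{spec.name}:{endpoint}:{state}"] = float(p)
    return truth


def generate_reefs(cfg: ReefGenConfig = ReefGenConfig()) -> pd.DataFrame:
    """Simulate a reef table; a pure function of the config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reefs
    lat = rng.uniform(*sorted(cfg.lat_range), size=n)
    lon = rng.uniform(*sorted(cfg.lon_range), size=n)
    df = pd.DataFrame({
        "reef_id": [f"reef_{i:04d}" for i in range(n)],
        "lon": np.round(lon, 5),
        "lat": np.round(lat, 5),
        "shelf": "mid",
    })
    n_no_take = int(round(cfg.no_take_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_no_take, replace=False)] = True
    df["no_take"] = flags
    for layer, (family, loc, scale) in cfg.layer_params.items():
        if family == "normal":
            vals = rng.normal(loc, scale, size=n)
        elif family == "lognormal":
            vals = rng.lognormal(loc, scale, size=n)
        elif family == "gamma":
            vals = rng.gamma(loc, scale, size=n)
        else:  # poisson
            vals = rng.poisson(loc, size=n).astype(float)
        df[layer] = vals
    return df


def generate_expert_pool(
    cfg: ExpertGenConfig = ExpertGenConfig(),
) -> list[FourPointResponse]:
    """Simulate 4-point responses around the configured truth.

    Best estimates are the truth plus symmetric noise (clamped to [0, 1] in
    ``additive`` mode); the interval endpoints sit ``interval_width`` either
    side of the best estimate (clamped), at the configured stated confidence.
    """
    cfg = replace(cfg, truth=cfg.truth or default_truth())
    rng = np.random.default_rng(cfg.seed)
    responses: list[FourPointResponse] = []
    quantities = sorted(cfg.truth)
    for e in range(cfg.n_experts):
        expert_id = f"expert_{e:02d}"
        noise = rng.normal(0.0, cfg.noise_sd, size=len(quantities))
        for qid, eps in zip(quantities, noise):
            p = cfg.truth[qid]
            if cfg.noise == "additive" or cfg.noise_sd == 0.0:
                best = min(1.0, max(0.0, p + eps))
            else:  # logit-scale noise; truths at the boundary stay put
                if p in (0.0, 1.0):
                    best = p
                else:
                    z = np.log(p / (1 - p)) + eps
                    best = float(1.0 / (1.0 + np.exp(-z)))
            responses.append(FourPointResponse(
                expert_id=expert_id,
                quantity_id=qid,
                lowest=max(0.0, best - cfg.interval_width),
                best=best,
                highest=min(1.0, best + cfg.interval_width),
                confidence=cfg.confidence,
            ))
    return responses


def generate_effort_grids(
    n_blocks: int = 4,
    cells_per_block: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Seeded coarse-block totals and fine-cell weights for downscaling."""
    if n_blocks < 1 or cells_per_block < 1:
        raise ValueError("n_blocks and cells_per_block must be >= 1")
    rng = np.random.default_rng(seed)
    totals: dict[str, float] = {}
    weights: dict[tuple[str, str], float] = {}
    for b in range(n_blocks):
        block = f"block_{b:02d}"
        totals[block] = float(np.round(rng.gamma(3.0, 50.0), 3))
        w = rng.gamma(1.5, 1.0, size=cells_per_block)
        for c in range(cells_per_block):
            weights[(block, f"{block}/cell_{c:02d}")] = float(np.round(w[c], 6))
    return totals, weights
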