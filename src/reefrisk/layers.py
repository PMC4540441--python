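"""Per-reef environmental layers: loading, discretization, effort, zoning.

The reef table is a pandas DataFrame with one row per reef: identity,
centroid coordinates (decimal degrees, WGS84), shelf position, no-take flag
and a continuous value per stressor layer.  Evidence for the network is the
reef's layer values re-coded into three ordered categories:

* temperature anomaly — ``above`` if > +1 °C, ``below`` if < −1 °C, else
  ``average`` (a fixed bleaching-relevant threshold, not an SD rule);
* every other layer — ``above``/``below`` if one standard deviation or more
  from the mean (boundary inclusive), else ``average``.

Layer statistics default to the supplied table over mid-shelf reefs; a stats
file can override them.  Fishing effort reported on a coarse grid is
reapportioned to fine cells proportionally to the fine-scale distribution,
and reefs inside no-take zones are assumed to carry zero effort.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LAYER_COLUMNS",
    "INPUT_LAYERS",
    "REEF_COLUMNS",
    "LayerStats",
    "discretize_layer",
    "discretize_temperature",
    "downscale_effort",
    "apply_zoning",
    "evidence_for_reef",
    "compute_layer_stats",
    "filter_mid_shelf",
    "read_reef_table",
    "write_reef_table",
    "read_layer_stats",
    "write_layer_stats",
    "read_effort_totals",
    "read_effort_weights",
    "predictions_to_geojson",
]

#: continuous layer columns carried by the reef table
LAYER_COLUMNS = (
    "temperature", "cyclones", "plume", "nutrients", "sediment",
    "pollution", "irradiance", "cots", "fishing",
)
#: layers used as network input evidence (CoTS outbreak history is kept in
#: the table but the default model elicits the CoTS event prior instead)
INPUT_LAYERS = (
    "temperature", "cyclones", "plume", "nutrients", "sediment",
    "pollution", "irradiance", "fishing",
)
REEF_COLUMNS = ("reef_id", "lon", "lat", "shelf", "no_take") + LAYER_COLUMNS

STATES = ("below", "average", "above")
TEMPERATURE_THRESHOLD_C = 1.0


@dataclass(frozen=True)
class LayerStats:
    """Mean and standard deviation of one layer, in the layer's units."""

    layer: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"layer {self.layer!r}: sd must be > 0, got {self.sd}")


def discretize_layer(value: float, stats: LayerStats) -> str:
    """Three-category SD re-coding; the ±1 SD boundaries are inclusive to
    the extreme categories ("one standard deviation *or more*")."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r} for layer {stats.layer!r}")
    if value >= stats.mean + stats.sd:
        return "above"
    if value <= stats.mean - stats.sd:
        return "below"
    return "average"


def discretize_temperature(anomaly: float) -> str:
    """±1 °C rule: strictly greater/less than 1 °C from the climatological
    mean is above/below; the boundary itself is average."""
    if not math.isfinite(anomaly):
        raise ValueError(f"non-finite temperature anomaly {anomaly!r}")
    if anomaly > TEMPERATURE_THRESHOLD_C:
        return "above"
    if anomaly < -TEMPERATURE_THRESHOLD_C:
        return "below"
    return "average"


def downscale_effort(
    coarse_totals: Mapping[Hashable, float],
    fine_weights: Mapping[tuple[Hashable, Hashable], float],
) -> dict[Hashable, float]:
    """Reapportion coarse-block effort totals onto fine cells.

    Each cell receives ``block_total * weight / sum_of_block_weights``,
    assuming the relative fine-scale distribution applies within the block;
    per-block sums are conserved exactly.  A block with positive total but
    zero total weight is an error; a zero-total block yields zero cells.
    """
    block_weight_sums: dict[Hashable, float] = {}
    for (block, _cell), w in fine_weights.items():
        if w < 0:
            raise ValueError(f"negative weight {w} in block {block!r}")
        block_weight_sums[block] = block_weight_sums.get(block, 0.0) + w
    out: dict[Hashable, float] = {}
    for (block, cell), w in fine_weights.items():
        total = coarse_totals.get(block, 0.0)
        if total == 0.0:
            out[cell] = 0.0
            continue
        wsum = block_weight_sums[block]
        if wsum == 0.0:
            raise ValueError(
                f"block {block!r} has total {total} but all-zero cell weights"
            )
        out[cell] = total * w / wsum
    return out


def apply_zoning(reefs: pd.DataFrame) -> pd.DataFrame:
    """Zero fishing effort on no-take reefs; everything else untouched."""
    if "no_take" not in reefs.columns:
        raise ValueError("reef table lacks a 'no_take' column")
    out = reefs.copy()
    out.loc[out["no_take"].astype(bool), "fishing"] = 0.0
    return out


def compute_layer_stats(
    reefs: pd.DataFrame,
    layers: Iterable[str] = INPUT_LAYERS,
    shelf: str | None = "mid",
) -> dict[str, LayerStats]:
    """Table-wide mean/SD per layer, by default over mid-shelf reefs."""
    df = filter_mid_shelf(reefs) if shelf == "mid" else reefs
    stats: dict[str, LayerStats] = {}
    for layer in layers:
        if layer not in df.columns:
            raise ValueError(f"reef table lacks layer column {layer!r}")
        vals = df[layer].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise ValueError(f"layer {layer!r} has zero variance; cannot discretize")
        stats[layer] = LayerStats(layer, float(vals.mean()), sd)
    return stats


def evidence_for_reef(
    reef: Mapping[str, float] | pd.Series,
    stats: Mapping[str, LayerStats],
) -> dict[str, str]:
    """Discretized evidence (one state per input node) at a reef centroid."""
    missing = [l for l in INPUT_LAYERS if l not in reef]
    if missing:
        raise ValueError(f"reef record missing layers: {missing}")
    evidence: dict[str, str] = {}
    for layer in INPUT_LAYERS:
        value = float(reef[layer])
        if layer == "temperature":
            evidence[layer] = discretize_temperature(value)
        else:
            if layer not in stats:
                raise ValueError(f"no layer statistics supplied for {layer!r}")
            evidence[layer] = discretize_layer(value, stats[layer])
    return evidence


def filter_mid_shelf(reefs: pd.DataFrame) -> pd.DataFrame:
    if "shelf" not in reefs.columns:
        raise ValueError("reef table lacks a 'shelf' column")
    return reefs[reefs["shelf"] == "mid"]


# ---------------------------------------------------------------------------
# Files

def read_reef_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REEF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reef table missing columns {sorted(missing)}")
    df["no_take"] = df["no_take"].astype(bool)
    bad_lat = df[(df["lat"] < -90) | (df["lat"] > 90)]
    bad_lon = df[(df["lon"] < -180) | (df["lon"] > 180)]
    if len(bad_lat) or len(bad_lon):
        raise ValueError(
            f"{path}: coordinates out of range for reefs "
            f"{sorted(set(bad_lat['reef_id']) | set(bad_lon['reef_id']))}"
        )
    if (df["fishing"] < 0).any() or (df["cyclones"] < 0).any():
        raise ValueError(f"{path}: negative effort or exposure counts")
    return df


def write_reef_table(reefs: pd.DataFrame, path: str | Path) -> None:
    reefs.to_csv(path, index=False)


def write_layer_stats(stats: Mapping[str, LayerStats], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["layer", "mean", "sd"])
        for layer in sorted(stats):
            s = stats[layer]
            writer.writerow([layer, repr(s.mean), repr(s.sd)])


def read_layer_stats(path: str | Path) -> dict[str, LayerStats]:
    out: dict[str, LayerStats] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["layer"]] = LayerStats(
                row["layer"], float(row["mean"]), float(row["sd"]))
    return out


def read_effort_totals(path: str | Path) -> dict[str, float]:
    with open(path, newline="") as fh:
        return {row["block_id"]: float(row["total"])
                for row in csv.DictReader(fh)}


def read_effort_weights(path: str | Path) -> dict[tuple[str, str], float]:
    with open(path, newline="") as fh:
        return {(row["block_id"], row["cell_id"]): float(row["weight"])
                for row in csv.DictReader(fh)}


def predictions_to_geojson(
    reefs: pd.DataFrame,
    predictions: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Point FeatureCollection of reef centroids with optional prediction
    properties (one property per named prediction set)."""
    features = []
    for _, row in reefs.iterrows():
        props: dict = {
            "reef_id": row["reef_id"],
            "shelf": row["shelf"],
            "no_take": bool(row["no_take"]),
        }
        if predictions:
            for name, mapping in predictions.items():
                value = mapping.get(row["reef_id"])
                props[name] = None if value is None else float(value)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["lon"]), float(row["lat"])]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


__all__.append("write_geojson")
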