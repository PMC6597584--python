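"""Quantitative-track manipulations: statistics, averages, normalization,
heat maps.

These are the browser-style derived quantities computed on scalar (float)
tracks: overall and per-time means and standard deviations, the per-time
"space average", the along-lineage "time average", per-time min-max "time
normalization", neighbor smoothing over an adjacency graph, and linear
blue-to-red heat-map colorization.

All derived tracks are themselves valid tracks (float or color) and
round-trip through the track reader/writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph
from .core import MorphoFormatError, ObjectKey
from .info_io import ColorValue, InfoTrack, ScalarValue
from .lineage import LineageGraph

__all__ = [
    "HeatmapSpec",
    "track_stats",
    "space_average",
    "time_average",
    "time_normalize",
    "to_heatmap",
    "neighbor_smooth",
]


@dataclass
class HeatmapSpec:
    """Linear two-color ramp: low color at range min, high at range max.

    Default is the blue-to-red convention (blue = low, red = high).  With
    ``vmin``/``vmax`` unset the range is data-driven; values outside an
    explicit range are clamped.
    """

    low: Tuple[int, int, int] = (0, 0, 255)
    high: Tuple[int, int, int] = (255, 0, 0)
    vmin: Optional[float] = None
    vmax: Optional[float] = None

    def __post_init__(self):
        for c in (*self.low, *self.high):
            if not (0 <= c <= 255):
                raise MorphoFormatError(f"heat-map color component {c} "
                                        "outside [0, 255]")
        if self.vmin is not None and self.vmax is not None \
                and not self.vmin < self.vmax:
            raise MorphoFormatError(
                f"heat-map range min {self.vmin} must be < max {self.vmax}")


def _require_float(track: InfoTrack) -> None:
    if track.info_type != "float":
        raise MorphoFormatError(
            f"operation requires a 'float' track, got {track.info_type!r}")


def _series(track: InfoTrack) -> pd.Series:
    return pd.Series({e.key: e.value for e in track.entries}, dtype=float)


def track_stats(track: InfoTrack) -> pd.DataFrame:
    """Count/mean/std/min/max, overall and per time point.

    The standard deviation is the population statistic (divisor ``n``):
    the track is treated as the complete object set, not a sample.
    """
    _require_float(track)
    if not track.entries:
        raise MorphoFormatError("cannot compute statistics of an empty track")
    s = _series(track)
    groups = {"overall": s}
    for t in sorted({k.t for k in s.index}):
        groups[t] = s[[k for k in s.index if k.t == t]]
    rows = []
    for label, grp in groups.items():
        v = grp.to_numpy()
        rows.append({
            "time": label,
            "count": len(v),
            "mean": float(np.mean(v)),
            "std": float(np.std(v)),  # population (ddof=0)
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        })
    return pd.DataFrame(rows).set_index("time")


def space_average(track: InfoTrack) -> InfoTrack:
    """Replace every value by the mean over all objects at its time point."""
    _require_float(track)
    if not track.entries:
        raise MorphoFormatError("cannot space-average an empty track")
    s = _series(track)
    means: Dict[int, float] = {}
    for t in {k.t for k in s.index}:
        vals = s[[k for k in s.index if k.t == t]]
        means[t] = float(vals.mean())
    entries = [ScalarValue(e.key, means[e.key.t]) for e in track.entries]
    return InfoTrack(name=f"{track.name}.spaceavg", info_type="float",
                     entries=entries)


def time_average(track: InfoTrack, graph: LineageGraph) -> InfoTrack:
    """Average each object's value along its identity chain in the lineage.

    An identity chain is the maximal run of one-to-one temporal links
    between events (divisions, fusions, appearance, disappearance) — the
    same physical object followed through time.  Every chain member gets
    the chain's mean value; objects absent from the graph would be an
    error, and chain members with no value are skipped in the mean.
    """
    _require_float(track)
    values = {e.key: e.value for e in track.entries}
    unknown = set(values) - graph.nodes
    if unknown:
        raise KeyError(
            "track keys not in lineage graph: "
            + ", ".join(str(k) for k in sorted(unknown)))
    out: Dict[ObjectKey, float] = {}
    for chain in graph.identity_chains():
        vals = [values[k] for k in chain if k in values]
        if not vals:
            continue
        mean = float(np.mean(vals))
        for k in chain:
            if k in values:
                out[k] = mean
    entries = [ScalarValue(e.key, out[e.key]) for e in track.entries]
    return InfoTrack(name=f"{track.name}.timeavg", info_type="float",
                     entries=entries)


def time_normalize(track: InfoTrack) -> InfoTrack:
    """Min-max scale values into [0, 1] within each time point.

    ``v -> (v - min_t) / (max_t - min_t)``; a constant time point maps to
    0 by convention.  Idempotent.
    """
    _require_float(track)
    if not track.entries:
        raise MorphoFormatError("cannot time-normalize an empty track")
    s = _series(track)
    lo: Dict[int, float] = {}
    hi: Dict[int, float] = {}
    for t in {k.t for k in s.index}:
        vals = s[[k for k in s.index if k.t == t]]
        lo[t], hi[t] = float(vals.min()), float(vals.max())
    entries = []
    for e in track.entries:
        t = e.key.t
        span = hi[t] - lo[t]
        v = 0.0 if span == 0 else (e.value - lo[t]) / span
        entries.append(ScalarValue(e.key, v))
    return InfoTrack(name=f"{track.name}.tnorm", info_type="float",
                     entries=entries)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def to_heatmap(track: InfoTrack, spec: HeatmapSpec | None = None) -> InfoTrack:
    """Colorize a scalar track as a linear heat map (default blue -> red).

    Each RGB channel is interpolated linearly between the low and high
    colors over the value range, with round-half-away-from-zero to
    integers.  A constant track maps everything to the low color.
    """
    _require_float(track)
    spec = spec or HeatmapSpec()
    if not track.entries:
        raise MorphoFormatError("cannot colorize an empty track")
    values = np.array([e.value for e in track.entries], dtype=float)
    vmin = spec.vmin if spec.vmin is not None else float(values.min())
    vmax = spec.vmax if spec.vmax is not None else float(values.max())
    if vmin > vmax:
        raise MorphoFormatError(f"heat-map range min {vmin} > max {vmax}")
    span = vmax - vmin
    entries = []
    for e in track.entries:
        if span == 0:
            frac = 0.0  # constant track: low color, as in time normalization
        else:
            frac = (min(max(e.value, vmin), vmax) - vmin) / span
        rgb = tuple(
            _round_half_away(l + frac * (h - l))
            for l, h in zip(spec.low, spec.high)
        )
        entries.append(ColorValue(e.key, *rgb))
    return InfoTrack(name=f"{track.name}.heatmap", info_type="color",
                     entries=entries)


def neighbor_smooth(track: InfoTrack, graph: AdjacencyGraph) -> InfoTrack:
    """Local space average: each value becomes the mean of itself and its
    neighbors' values (neighbors without a value are skipped)."""
    _require_float(track)
    values = {e.key: e.value for e in track.entries}
    entries = []
    for e in track.entries:
        vals = [e.value]
        if e.key in graph.g:
            vals += [values[n] for n in graph.neighbors(e.key) if n in values]
        entries.append(ScalarValue(e.key, float(np.mean(vals))))
    return InfoTrack(name=f"{track.name}.neighborsmooth", info_type="float",
                     entries=entries)
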