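"""The 18 purely spatial features: time-based, graph-based, and value-based.

All inputs come from the event set of a delta-transformed multichannel
waveform. Time-based features summarize per-channel event-time offsets
relative to the main channel (in μs). Graph-based features are computed on a
directed "event graph" whose nodes are unmasked channels and whose edges
connect every strictly-earlier event to every strictly-later one, weighted
by a transmission speed: electrode distance (mm) over time difference (s).
Value-based (SPD, spatial dispersion) features summarize the per-channel
maximal-negativity amplitudes scaled by the global maximum, using all
channels with no mask.

Degenerate inputs (fewer than two usable channels, or an empty edge set)
yield missing values (NaN), not zeros; the classifier imputes them with the
training-set median.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .core_data import DT_US, ProbeGeometry
from .delta import EVENT_NAMES, EventSet
from .registry import SPATIAL_FEATURES


@dataclass
class EventGraph:
    """Directed acyclic event graph over unmasked channels.

    ``times_us`` are event times, ``nodes`` the channel indices, and
    ``weights[i, j]`` the edge weight for every ordered pair with
    ``times_us[i] < times_us[j]`` (NaN where no edge exists).
    """

    nodes: np.ndarray
    times_us: np.ndarray
    weights: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(np.isfinite(self.weights).sum())


def _usable(ev: EventSet, event: str) -> np.ndarray:
    """Channels contributing to time/graph features: unmasked, valid event."""
    return ev.mask & ev.valid[event]


def time_based_features(ev: EventSet, event: str) -> tuple[float, float]:
    """(Time-lag-SS, Time-lag-SD) of one event.

    Offsets are the event times of usable non-main channels minus the
    main-channel event time, in μs. Time-lag-SS is the mean squared offset
    reported in 10^3 μs^2; Time-lag-SD is the population SD of the offsets
    in μs. With fewer than two usable channels both are NaN.
    """
    usable = _usable(ev, event)
    if not usable[ev.main_channel] or usable.sum() < 2:
        return np.nan, np.nan
    times = ev.times(event).astype(float) * DT_US
    others = np.nonzero(usable)[0]
    others = others[others != ev.main_channel]
    offsets = times[others] - times[ev.main_channel]
    ss = float(np.mean(offsets**2)) / 1e3
    sd = float(np.std(offsets))  # population SD
    return ss, sd


def build_event_graph(
    ev: EventSet, event: str, geometry: ProbeGeometry
) -> EventGraph:
    """Complete DAG over usable channels with distinct event times.

    Edge weight: Euclidean electrode distance (mm) / time difference (s),
    i.e. mm/s. Simultaneous events are not connected.
    """
    usable = np.nonzero(_usable(ev, event))[0]
    times_us = ev.times(event)[usable].astype(float) * DT_US
    dist_mm = geometry.distances_mm()[np.ix_(usable, usable)]
    n = usable.size
    weights = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            dt_s = (times_us[j] - times_us[i]) / 1e6
            if dt_s > 0:
                weights[i, j] = dist_mm[i, j] / dt_s
    return EventGraph(nodes=usable, times_us=times_us, weights=weights)


def _path_extrema(g: EventGraph, constrained: bool = True) -> tuple[float, float]:
    """(longest, shortest) total path weight by DP over the DAG.

    With ``constrained`` (default), paths must start at an earliest-event
    node and end at a latest-event node; otherwise any directed path counts
    (the unconstrained minimum degenerates to the single smallest edge).
    """
    n = g.times_us.size
    order = np.argsort(g.times_us, kind="stable")
    t_min, t_max = g.times_us.min(), g.times_us.max()
    best_max = np.full(n, -np.inf)
    best_min = np.full(n, np.inf)
    for i in order:
        if (not constrained) or g.times_us[i] == t_min:
            best_max[i] = 0.0
            best_min[i] = 0.0
    for j in order:
        for i in range(n):
            w = g.weights[i, j]
            if np.isfinite(w):
                if best_max[i] + w > best_max[j]:
                    best_max[j] = best_max[i] + w
                if best_min[i] + w < best_min[j]:
                    best_min[j] = best_min[i] + w
    if constrained:
        ends = np.nonzero(g.times_us == t_max)[0]
    else:
        ends = np.arange(n)
    longest = float(best_max[ends].max())
    shortest = float(best_min[ends].min())
    if not constrained:
        # exclude the empty path (a path needs at least one edge)
        finite = g.weights[np.isfinite(g.weights)]
        if finite.size == 0:
            return np.nan, np.nan
        shortest = float(finite.min())
    return longest, shortest


def graph_features(
    g: EventGraph, constrained_paths: bool = True
) -> tuple[float, float, float]:
    """(Average-weight, Longest-path, Shortest-path) of one event graph.

    All three are NaN (missing) when the edge set is empty.
    """
    finite = g.weights[np.isfinite(g.weights)]
    if finite.size == 0:
        return np.nan, np.nan, np.nan
    average = float(finite.mean())
    longest, shortest = _path_extrema(g, constrained=constrained_paths)
    return average, longest, shortest


def enumerate_path_extrema(g: EventGraph, constrained: bool = True) -> tuple[float, float]:
    """Brute-force longest/shortest path by exhaustive enumeration.

    Exponential; intended as an independent check for graphs with <= ~7
    nodes.
    """
    n = g.times_us.size
    t_min, t_max = g.times_us.min(), g.times_us.max()
    best_long, best_short = -np.inf, np.inf
    for r in range(2, n + 1):
        for perm in permutations(range(n), r):
            w = 0.0
            ok = True
            for a, b in zip(perm, perm[1:]):
                if np.isfinite(g.weights[a, b]):
                    w += g.weights[a, b]
                else:
                    ok = False
                    break
            if not ok:
                continue
            if constrained and not (
                g.times_us[perm[0]] == t_min and g.times_us[perm[-1]] == t_max
            ):
                continue
            best_long = max(best_long, w)
            best_short = min(best_short, w)
    if not np.isfinite(best_long):
        return np.nan, np.nan
    return best_long, best_short


def spd_features(ev: EventSet) -> tuple[float, float, float]:
    """(SPD-Count, SPD-SD, SPD-Area) from scaled maximal-negativity values.

    v = per-channel |maximal negativity| / global maximum, so v in [0, 1]
    with max(v) = 1. Count is the number of channels with v >= 0.5 (ties
    count); SD is the population SD of v; Area is the area under the curve of
    channel count versus threshold, which equals sum(v) exactly.
    """
    amp = np.abs(ev.neg_amplitude.astype(float))
    v = amp / amp.max()
    count = float((v >= 0.5).sum())
    sd = float(np.std(v))
    area = float(v.sum())
    return count, sd, area


def extract_spatial_features(
    ev: EventSet, geometry: ProbeGeometry, constrained_paths: bool = True
) -> dict[str, float]:
    """All 18 spatial features of one unit or chunk."""
    out: dict[str, float] = {}
    for event in EVENT_NAMES:
        ss, sd = time_based_features(ev, event)
        out[f"{event}-Time-lag-SS"] = ss
        out[f"{event}-Time-lag-SD"] = sd
        usable = _usable(ev, event)
        if usable.sum() < 2:
            avg = longest = shortest = np.nan
        else:
            g = build_event_graph(ev, event, geometry)
            avg, longest, shortest = graph_features(g, constrained_paths)
        out[f"{event}-Average-weight"] = avg
        out[f"{event}-Longest-path"] = longest
        out[f"{event}-Shortest-path"] = shortest
    count, sd, area = spd_features(ev)
    out["SPD-Count"] = count
    out["SPD-SD"] = sd
    out["SPD-Area"] = area
    return {name: out[name] for name in SPATIAL_FEATURES}
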