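"""Quantitative-track manipulations and heat-map colorization."""

import math
import warnings

import numpy as np
import pytest

from morphodyn.adjacency import AdjacencyGraph
from morphodyn.analytics import (
    HeatmapSpec,
    neighbor_smooth,
    space_average,
    time_average,
    time_normalize,
    to_heatmap,
    track_stats,
)
from morphodyn.core import MorphoFormatError, ObjectKey
from morphodyn.info_io import (
    InfoTrack,
    ScalarValue,
    TemporalLink,
    read_info_track,
    write_info_track,
)
from morphodyn.lineage import LineageGraph, build_lineage


def _float_track(items):
    return InfoTrack("f", "float",
                     [ScalarValue(ObjectKey(*k), v) for k, v in items])


def test_stats_small_examples():
    df = track_stats(_float_track([((0, 1, 0), 2.0), ((0, 2, 0), 4.0),
                                   ((0, 3, 0), 6.0)]))
    row = df.loc["overall"]
    assert row["mean"] == pytest.approx(4.0)
    assert row["std"] == pytest.approx(1.6329931618554518)  # population std
    single = track_stats(_float_track([((0, 1, 0), 5.0)]))
    assert single.loc["overall", "mean"] == 5.0
    assert single.loc["overall", "std"] == 0.0


def test_stats_empty_track_errors():
    with pytest.raises(MorphoFormatError):
        track_stats(_float_track([]))


def test_stats_match_two_pass_oracle():
    rng = np.random.default_rng(2)
    items = [((int(rng.integers(0, 5)), i, 0), float(rng.normal()))
             for i in range(10_000)]
    df = track_stats(_float_track(items))
    vals = [v for _, v in items]
    mean = sum(vals) / len(vals)
    std = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    assert df.loc["overall", "mean"] == pytest.approx(mean, rel=1e-9)
    assert df.loc["overall", "std"] == pytest.approx(std, rel=1e-9)
    for t in range(5):
        sub = [v for (tt, _, _), v in items if tt == t]
        assert df.loc[t, "mean"] == pytest.approx(sum(sub) / len(sub), rel=1e-9)


def test_space_average():
    out = space_average(_float_track([((0, 1, 0), 1.0), ((0, 2, 0), 3.0),
                                      ((1, 1, 0), 7.0)]))
    values = {e.key: e.value for e in out.entries}
    assert values[ObjectKey(0, 1, 0)] == 2.0
    assert values[ObjectKey(0, 2, 0)] == 2.0
    assert values[ObjectKey(1, 1, 0)] == 7.0  # single object: unchanged
    assert out.name.endswith(".spaceavg")


def test_space_average_matches_groupby_oracle():
    rng = np.random.default_rng(9)
    items = [((int(rng.integers(0, 6)), i, 0), float(rng.normal()))
             for i in range(300)]
    out = space_average(_float_track(items))
    got = {e.key: e.value for e in out.entries}
    for t in range(6):
        sub = [v for (tt, _, _), v in items if tt == t]
        if not sub:
            continue
        expect = sum(sub) / len(sub)
        for (tt, i, ch), _ in items:
            if tt == t:
                assert got[ObjectKey(tt, i, ch)] == pytest.approx(expect)


def _chain_graph(n):
    g = LineageGraph()
    keys = [ObjectKey(t, 1, 0) for t in range(n)]
    for k in keys:
        g.add_node(k)
    for a, b in zip(keys, keys[1:]):
        g.add_edge(a, b)
    return g, keys


def test_time_average_along_chain():
    g, keys = _chain_graph(3)
    track = InfoTrack("f", "float",
                      [ScalarValue(k, v) for k, v in zip(keys, (1.0, 2.0, 3.0))])
    out = time_average(track, g)
    assert all(e.value == 2.0 for e in out.entries)


def test_time_average_division_ends_chain():
    g = LineageGraph()
    a, b = ObjectKey(0, 1, 0), ObjectKey(1, 1, 0)
    c1, c2 = ObjectKey(2, 1, 0), ObjectKey(2, 2, 0)
    for k in (a, b, c1, c2):
        g.add_node(k)
    g.add_edge(a, b)
    g.add_edge(b, c1)
    g.add_edge(b, c2)
    track = InfoTrack("f", "float", [ScalarValue(a, 0.0), ScalarValue(b, 10.0),
                                     ScalarValue(c1, 100.0),
                                     ScalarValue(c2, 200.0)])
    out = time_average(track, g)
    got = {e.key: e.value for e in out.entries}
    # parent chain (a, b) excludes the children
    assert got[a] == got[b] == 5.0
    assert got[c1] == 100.0 and got[c2] == 200.0


def test_time_average_matches_chain_walk_oracle():
    rng = np.random.default_rng(21)
    g = LineageGraph()
    values = {}
    for cid in range(20):
        length = int(rng.integers(1, 8))
        keys = [ObjectKey(t, cid, 0) for t in range(length)]
        for k in keys:
            g.add_node(k)
            values[k] = float(rng.normal())
        for u, v in zip(keys, keys[1:]):
            g.add_edge(u, v)
    track = InfoTrack("f", "float",
                      [ScalarValue(k, v) for k, v in values.items()])
    out = time_average(track, g)
    got = {e.key: e.value for e in out.entries}
    for cid in range(20):
        chain = sorted(k for k in values if k.id == cid)
        expect = sum(values[k] for k in chain) / len(chain)
        for k in chain:
            assert got[k] == pytest.approx(expect)


def test_time_normalize_examples_and_idempotence():
    track = _float_track([((0, 1, 0), 2.0), ((0, 2, 0), 4.0), ((0, 3, 0), 6.0)])
    out = time_normalize(track)
    assert [e.value for e in out.entries] == [0.0, 0.5, 1.0]
    const = time_normalize(_float_track([((0, 1, 0), 5.0), ((0, 2, 0), 5.0)]))
    assert [e.value for e in const.entries] == [0.0, 0.0]
    twice = time_normalize(out)
    assert twice.entries == out.entries


def test_time_normalize_range_under_fuzzing():
    rng = np.random.default_rng(4)
    for _ in range(20):
        items = [((int(rng.integers(0, 4)), i, 0), float(rng.normal(scale=50)))
                 for i in range(int(rng.integers(1, 60)))]
        out = time_normalize(_float_track(items))
        assert all(0.0 <= e.value <= 1.0 for e in out.entries)


def test_heatmap_endpoints_blue_to_red():
    track = _float_track([((0, 1, 0), 0.0), ((0, 2, 0), 5.0), ((0, 3, 0), 10.0)])
    out = to_heatmap(track)
    rgb = {e.key: (e.r, e.g, e.b) for e in out.entries}
    assert rgb[ObjectKey(0, 1, 0)] == (0, 0, 255)    # min -> blue
    assert rgb[ObjectKey(0, 3, 0)] == (255, 0, 0)    # max -> red
    assert rgb[ObjectKey(0, 2, 0)] == (128, 0, 128)  # round half away from 0


def test_heatmap_constant_track_low_color():
    out = to_heatmap(_float_track([((0, 1, 0), 5.0), ((0, 2, 0), 5.0)]))
    assert all((e.r, e.g, e.b) == (0, 0, 255) for e in out.entries)


def test_heatmap_monotone_in_red():
    rng = np.random.default_rng(8)
    items = sorted(
        [((0, i, 0), float(rng.normal())) for i in range(50)],
        key=lambda kv: kv[1])
    out = to_heatmap(_float_track(items))
    reds = [e.r for e in out.entries]
    assert reds == sorted(reds)


def test_heatmap_explicit_range_clamps_and_validates():
    track = _float_track([((0, 1, 0), -10.0), ((0, 2, 0), 10.0)])
    out = to_heatmap(track, HeatmapSpec(vmin=0.0, vmax=1.0))
    rgb = [(e.r, e.g, e.b) for e in out.entries]
    assert rgb == [(0, 0, 255), (255, 0, 0)]
    with pytest.raises(MorphoFormatError):
        HeatmapSpec(vmin=1.0, vmax=1.0)


def test_neighbor_smooth():
    g = AdjacencyGraph()
    a, b, c, iso = (ObjectKey(0, i, 0) for i in (1, 2, 3, 9))
    g.add_edge(a, b)
    g.add_edge(a, c)
    track = InfoTrack("f", "float", [ScalarValue(a, 2.0), ScalarValue(b, 1.0),
                                     ScalarValue(c, 3.0), ScalarValue(iso, 7.0)])
    out = neighbor_smooth(track, g)
    got = {e.key: e.value for e in out.entries}
    assert got[a] == 2.0          # (2 + 1 + 3) / 3
    assert got[iso] == 7.0        # isolated: unchanged
    assert got[b] == pytest.approx(1.5)


def test_neighbor_smooth_matches_per_node_oracle():
    rng = np.random.default_rng(13)
    n = 60
    keys = [ObjectKey(0, i, 0) for i in range(n)]
    g = AdjacencyGraph()
    edges = set()
    for _ in range(120):
        i, j = rng.integers(0, n, 2)
        if i != j:
            g.add_edge(keys[int(i)], keys[int(j)])
            edges.add(frozenset((int(i), int(j))))
    values = {i: float(rng.normal()) for i in range(n)}
    track = InfoTrack("f", "float",
                      [ScalarValue(keys[i], values[i]) for i in range(n)])
    out = neighbor_smooth(track, g)
    got = {e.key: e.value for e in out.entries}
    for i in range(n):
        neigh = [j for e in edges if i in e for j in e if j != i]
        expect = np.mean([values[i]] + [values[j] for j in neigh])
        assert got[keys[i]] == pytest.approx(expect)


def test_derived_tracks_roundtrip():
    track = _float_track([((0, 1, 0), 1.25), ((0, 2, 0), -3.5), ((1, 1, 0), 9.0)])
    for derived in (space_average(track), time_normalize(track),
                    to_heatmap(track)):
        back = read_info_track(write_info_track(derived), name=derived.name)
        assert back.entries == derived.entries
        assert back.info_type == derived.info_type
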