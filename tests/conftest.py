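"""Shared fixtures: reference meshes, random-track generators, the small
synthetic embryo used across modules."""

from __future__ import annotations

import math
from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from morphodyn.core import MorphoScene, ObjectKey, TriMeshObject
from morphodyn.info_io import (
    ColorValue,
    GeneticLevel,
    GroupAssignment,
    InfoTrack,
    LinkedValue,
    ScalarValue,
    SelectionLabel,
    SpatialLink,
    SphereGlyph,
    TemporalLink,
    TextValue,
    VectorGlyph,
)
from morphodyn.synthetic import EmbryoSpec, generate_embryo

# --------------------------------------------------------------------------
# reference meshes
# --------------------------------------------------------------------------

CUBE_VERTICES = [
    (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (1.0, 1.0, 0.0), (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 1.0), (0.0, 1.0, 1.0),
]
CUBE_FACES = [
    (1, 3, 2), (1, 4, 3),          # bottom
    (5, 6, 7), (5, 7, 8),          # top
    (1, 2, 6), (1, 6, 5),          # front
    (3, 4, 8), (3, 8, 7),          # back
    (4, 1, 5), (4, 5, 8),          # left
    (2, 3, 7), (2, 7, 6),          # right
]


@pytest.fixture
def unit_cube() -> TriMeshObject:
    return TriMeshObject(key=ObjectKey(0, 1, 0),
                         vertices=list(CUBE_VERTICES),
                         faces=list(CUBE_FACES))


def icosphere(radius: float, subdivisions: int) -> TriMeshObject:
    """Icosahedron subdivided and projected onto a sphere (independent of
    the meshing pipeline)."""
    phi = (1 + math.sqrt(5)) / 2
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [np.array(v, dtype=float) for v in verts]

    def norm(v):
        return v / np.linalg.norm(v)

    verts = [norm(v) for v in verts]
    for _ in range(subdivisions):
        cache: Dict[Tuple[int, int], int] = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                verts.append(norm((verts[i] + verts[j]) / 2))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return TriMeshObject(
        key=ObjectKey(0, 1, 0),
        vertices=[tuple(float(x) * radius for x in v) for v in verts],
        faces=[(a + 1, b + 1, c + 1) for a, b, c in faces])


# --------------------------------------------------------------------------
# random tracks (seeded, used for round-trip fuzzing)
# --------------------------------------------------------------------------

def random_key(rng: np.random.Generator, t: int | None = None) -> ObjectKey:
    return ObjectKey(
        t=int(rng.integers(0, 50)) if t is None else t,
        id=int(rng.integers(0, 2000)),
        ch=int(rng.integers(0, 4)),
    )


def _random_float(rng) -> float:
    return float(np.round(rng.normal(scale=100.0), 9))


def _random_name(rng) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJ0123456789_ -"
    n = int(rng.integers(1, 15))
    s = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))
    return s.strip() or "x"


def random_track(rng: np.random.Generator, info_type: str, n: int) -> InfoTrack:
    """A valid random track of any of the 11 types, n entries."""
    entries: list = []
    used: Set[ObjectKey] = set()

    def fresh_key() -> ObjectKey:
        while True:
            k = random_key(rng)
            if k not in used:
                used.add(k)
                return k

    for _ in range(n):
        if info_type == "time":
            t = int(rng.integers(0, 40))
            entries.append(TemporalLink(random_key(rng, t),
                                        random_key(rng, t + int(rng.integers(1, 4)))))
        elif info_type == "space":
            t = int(rng.integers(0, 40))
            entries.append(SpatialLink(random_key(rng, t), random_key(rng, t)))
        elif info_type == "group":
            chain = tuple(_random_name(rng)
                          for _ in range(int(rng.integers(1, 4))))
            entries.append(GroupAssignment(fresh_key(), chain))
        elif info_type == "float":
            entries.append(ScalarValue(fresh_key(), _random_float(rng)))
        elif info_type == "selection":
            entries.append(SelectionLabel(fresh_key(),
                                          int(rng.integers(1, 256))))
        elif info_type == "color":
            entries.append(ColorValue(fresh_key(), *(int(x) for x in
                                                     rng.integers(0, 256, 3))))
        elif info_type == "string":
            entries.append(TextValue(fresh_key(), _random_name(rng)))
        elif info_type == "genetic":
            entries.append(GeneticLevel(fresh_key(), _random_float(rng)))
        elif info_type == "dict":
            t = int(rng.integers(0, 40))
            entries.append(LinkedValue(random_key(rng, t), random_key(rng, t),
                                       _random_float(rng)))
        elif info_type == "sphere":
            entries.append(SphereGlyph(fresh_key(),
                                       *(float(x) for x in rng.normal(size=3)),
                                       float(abs(rng.normal()) + 0.5)))
        elif info_type == "vector":
            xs = [float(x) for x in rng.normal(size=6)]
            entries.append(VectorGlyph(fresh_key(),
                                       xs[0], xs[1], xs[2],
                                       float(abs(rng.normal()) + 0.5),
                                       xs[3], xs[4], xs[5],
                                       float(abs(rng.normal()) + 0.5)))
        else:
            raise AssertionError(info_type)
    return InfoTrack(name="fuzz", info_type=info_type, entries=entries)


# --------------------------------------------------------------------------
# reachability oracle (independent of networkx)
# --------------------------------------------------------------------------

def brute_reachable(edges, seeds, forward=True) -> set:
    adj: Dict = {}
    for s, t in edges:
        if forward:
            adj.setdefault(s, set()).add(t)
        else:
            adj.setdefault(t, set()).add(s)
    out = set(seeds)
    stack = list(seeds)
    while stack:
        n = stack.pop()
        for m in adj.get(n, ()):
            if m not in out:
                out.add(m)
                stack.append(m)
    return out


def random_lineage_edges(rng: np.random.Generator, n_nodes: int):
    """Random time-layered DAG edges over ObjectKeys (<= n_nodes nodes)."""
    layers = int(rng.integers(2, 6))
    per = max(1, n_nodes // layers)
    nodes = [[ObjectKey(t, i, 0) for i in range(per)] for t in range(layers)]
    edges = []
    for t in range(layers - 1):
        for src in nodes[t]:
            for dst in nodes[t + 1]:
                if rng.random() < 0.15:
                    edges.append((src, dst))
    return [n for layer in nodes for n in layer], edges


# --------------------------------------------------------------------------
# the shared synthetic embryo (3 rounds, 1 fusion)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def embryo():
    spec = EmbryoSpec(rounds=3, timepoints=5, fusions=1, grid=48, seed=7)
    images, truth = generate_embryo(spec)
    return spec, images, truth
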