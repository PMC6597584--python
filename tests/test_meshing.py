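"""Label-image meshing: volumes, contacts, mesh metrics, decimation."""

import math

import numpy as np
import pytest

from morphodyn.core import MorphoFormatError, ObjectKey, TriMeshObject
from morphodyn.meshing import (
    LabelImage,
    boundary_edge_count,
    decimate_mesh,
    label_contacts,
    label_volumes,
    labels_to_meshes,
    mesh_surface_area,
    mesh_volume,
)

from conftest import icosphere


def cube_image(side=10, spacing=(1.0, 1.0, 1.0)):
    v = np.zeros((side + 4,) * 3, dtype=np.int32)
    v[2:2 + side, 2:2 + side, 2:2 + side] = 1
    return LabelImage(voxels=v, spacing=spacing)


def sphere_image(radius, grid=None, spacing=(1.0, 1.0, 1.0)):
    grid = grid or int(2 * radius + 8)
    c = grid / 2
    idx = np.indices((grid,) * 3)
    d2 = sum((idx[i] - c) ** 2 * spacing[i] ** 2 for i in range(3))
    v = (d2 <= radius ** 2).astype(np.int32)
    return LabelImage(voxels=v, spacing=spacing)


# ------------------------------------------------------------- volumes ----

def test_label_volumes_cube():
    track = label_volumes(cube_image(10))
    assert len(track.entries) == 1
    assert track.entries[0].value == 1000.0
    track2 = label_volumes(cube_image(10, spacing=(0.5, 0.5, 2.0)))
    assert track2.entries[0].value == pytest.approx(500.0)


def test_label_volumes_matches_counting_oracle():
    rng = np.random.default_rng(19)
    v = rng.integers(0, 5, size=(20, 20, 20)).astype(np.int32)
    img = LabelImage(voxels=v, spacing=(0.5, 1.0, 2.0))
    track = label_volumes(img)
    got = {e.key.id: e.value for e in track.entries}
    for lab in range(1, 5):
        count = int((v == lab).sum())
        if count:
            assert got[lab] == pytest.approx(count * 1.0)
    assert 0 not in got  # background excluded


# ------------------------------------------------------------ contacts ----

def test_contact_area_two_abutting_cubes():
    v = np.zeros((12, 12, 12), dtype=np.int32)
    v[1:6, 1:6, 1:6] = 1
    v[6:11, 1:6, 1:6] = 2
    img = LabelImage(voxels=v)
    dict_track, space_track = label_contacts(img)
    areas = {(e.source.id, e.target.id): e.value for e in dict_track.entries}
    assert areas[(1, 2)] == 25.0
    assert areas[(2, 1)] == 25.0  # symmetric
    assert len(space_track.entries) == 1


def test_contact_area_respects_spacing():
    v = np.zeros((4, 4, 4), dtype=np.int32)
    v[0:2] = 1
    v[2:4] = 2
    # contact plane is normal to axis 0 -> area = dy*dz per face
    img = LabelImage(voxels=v, spacing=(3.0, 0.5, 2.0))
    dict_track, _ = label_contacts(img)
    assert dict_track.entries[0].value == pytest.approx(16 * 0.5 * 2.0)


def test_disjoint_labels_no_contacts():
    v = np.zeros((10, 10, 10), dtype=np.int32)
    v[1:3, 1:3, 1:3] = 1
    v[6:8, 6:8, 6:8] = 2
    dict_track, space_track = label_contacts(LabelImage(voxels=v))
    assert dict_track.entries == [] and space_track.entries == []


def test_corner_touching_labels_not_neighbors():
    v = np.zeros((4, 4, 4), dtype=np.int32)
    v[0:2, 0:2, 0:2] = 1
    v[2:4, 2:4, 2:4] = 2  # share only a corner
    _, space_track = label_contacts(LabelImage(voxels=v))
    assert space_track.entries == []


def _face_scan_oracle(v, spacing):
    areas = {}
    face_area = {0: spacing[1] * spacing[2], 1: spacing[0] * spacing[2],
                 2: spacing[0] * spacing[1]}
    nx, ny, nz = v.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = v[x, y, z]
                if a == 0:
                    continue
                for axis, (dx, dy, dz) in enumerate(((1, 0, 0), (0, 1, 0),
                                                     (0, 0, 1))):
                    X, Y, Z = x + dx, y + dy, z + dz
                    if X < nx and Y < ny and Z < nz:
                        b = v[X, Y, Z]
                        if b != 0 and b != a:
                            key = (min(int(a), int(b)), max(int(a), int(b)))
                            areas[key] = areas.get(key, 0.0) + face_area[axis]
    return areas


def test_contacts_match_brute_force_face_scan():
    rng = np.random.default_rng(27)
    v = rng.integers(0, 4, size=(10, 10, 10)).astype(np.int32)
    spacing = (0.5, 1.0, 1.5)
    dict_track, space_track = label_contacts(LabelImage(voxels=v,
                                                        spacing=spacing))
    got = {(e.source.id, e.target.id): e.value for e in dict_track.entries
           if e.source.id < e.target.id}
    expect = _face_scan_oracle(v, spacing)
    assert set(got) == set(expect)
    for pair, area in expect.items():
        assert got[pair] == pytest.approx(area)
    assert {(e.a.id, e.b.id) for e in space_track.entries} == set(expect)


# ---------------------------------------------------------- mesh metrics ----

def test_cube_mesh_volume_and_area(unit_cube):
    assert mesh_volume(unit_cube) == pytest.approx(1.0)
    assert mesh_surface_area(unit_cube) == pytest.approx(6.0)


def test_volume_invariant_under_winding_reversal(unit_cube):
    flipped = TriMeshObject(unit_cube.key, unit_cube.vertices,
                            [(a, c, b) for a, b, c in unit_cube.faces])
    assert mesh_volume(flipped) == pytest.approx(mesh_volume(unit_cube))


def test_icosphere_volume_converges():
    r = 8.0
    sphere = icosphere(r, 3)
    expect = 4 / 3 * math.pi * r ** 3
    assert mesh_volume(sphere) == pytest.approx(expect, rel=0.02)
    assert mesh_surface_area(sphere) == pytest.approx(4 * math.pi * r ** 2,
                                                      rel=0.02)


def test_open_mesh_volume_rejected(unit_cube):
    open_mesh = TriMeshObject(unit_cube.key, unit_cube.vertices,
                              unit_cube.faces[:-1])
    assert boundary_edge_count(open_mesh) > 0
    with pytest.raises(MorphoFormatError, match="not closed"):
        mesh_volume(open_mesh)


# ------------------------------------------------------ labels_to_meshes ----

def test_cube_label_meshes_to_volume_within_2pct():
    scene = labels_to_meshes(cube_image(10))
    mesh = scene.objects[ObjectKey(0, 1, 0)]
    assert boundary_edge_count(mesh) == 0
    assert mesh_volume(mesh) == pytest.approx(1000.0, rel=0.02)


def test_two_disjoint_labels_two_objects():
    v = np.zeros((16, 16, 16), dtype=np.int32)
    v[2:6, 2:6, 2:6] = 1
    v[9:13, 9:13, 9:13] = 2
    scene = labels_to_meshes(LabelImage(voxels=v, time=3, channel=1))
    assert scene.keys == {ObjectKey(3, 1, 1), ObjectKey(3, 2, 1)}


def test_empty_image_and_bad_fraction_rejected():
    empty = LabelImage(voxels=np.zeros((5, 5, 5), dtype=np.int32))
    with pytest.raises(MorphoFormatError):
        labels_to_meshes(empty)
    with pytest.raises(MorphoFormatError):
        labels_to_meshes(cube_image(4), decimation_fraction=0.0)
    with pytest.raises(MorphoFormatError):
        labels_to_meshes(cube_image(4), decimation_fraction=1.5)


def test_decimation_identity_at_fraction_one():
    img = sphere_image(8)
    full = labels_to_meshes(img, decimation_fraction=1.0)
    again = labels_to_meshes(img, decimation_fraction=1.0)
    obj = full.objects[ObjectKey(0, 1, 0)]
    assert obj.faces == again.objects[ObjectKey(0, 1, 0)].faces


def test_decimation_reduces_faces_keeps_closed_and_volume():
    img = sphere_image(10)
    full = labels_to_meshes(img, decimation_fraction=1.0)
    deci = labels_to_meshes(img, decimation_fraction=0.25)
    f_full = full.objects[ObjectKey(0, 1, 0)]
    f_deci = deci.objects[ObjectKey(0, 1, 0)]
    assert f_deci.n_faces <= 0.3 * f_full.n_faces
    assert boundary_edge_count(f_deci) == 0
    assert mesh_volume(f_deci) == pytest.approx(mesh_volume(f_full), rel=0.05)


def test_sphere_mesh_volume_converges_with_resolution():
    expect = lambda r: 4 / 3 * math.pi * r ** 3
    errs = []
    for r in (8, 16):
        scene = labels_to_meshes(sphere_image(r))
        vol = mesh_volume(scene.objects[ObjectKey(0, 1, 0)])
        errs.append(abs(vol - expect(r)) / expect(r))
    assert errs[0] < 0.05
    assert errs[1] < errs[0]  # improves with resolution


def test_anisotropic_spacing_applied():
    img = cube_image(10, spacing=(0.5, 0.5, 2.0))
    mesh = labels_to_meshes(img).objects[ObjectKey(0, 1, 0)]
    assert mesh_volume(mesh) == pytest.approx(500.0, rel=0.02)
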