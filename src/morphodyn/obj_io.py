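"""Reader/writer for the morphodynamic OBJ dialect.

The dialect is plain Wavefront OBJ restricted to geometry, with one twist:
each ``g`` record names an elementary object by its object tuple
(``g t,id,ch``), and all following faces belong to that object.  Vertex
indices are file-global and 1-based (standard OBJ); on read they are
remapped to object-local 1-based indices.  A dataset typically stores one
file per time point, restarting vertex numbering in each file, so the
reader treats every physical stream's numbering as self-contained.

Only triangles are semantic; ``vn``/``vt`` records and ``f a/b/c`` index
suffixes are tolerated and discarded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, IO, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .core import (
    MorphoFormatError,
    MorphoScene,
    ObjectKey,
    TriMeshObject,
    format_object_key,
    parse_object_key,
)

__all__ = [
    "ObjDialectOptions",
    "read_morpho_obj",
    "write_morpho_obj",
    "scene_summary",
    "OBJECT_COUNT_GUIDANCE",
]

# Interactive viewers degrade beyond this many elementary objects.
OBJECT_COUNT_GUIDANCE = 500_000


@dataclass
class ObjDialectOptions:
    one_file_per_time: bool = True
    abbreviate_keys: bool = False
    emit_comments: bool = True


def _as_stream(source) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_morpho_obj(
    sources,
    default_time: int = 0,
    default_channel: int = 0,
    name: str = "scene",
) -> MorphoScene:
    """Read one or more OBJ streams (or strings) into a :class:`MorphoScene`.

    Each stream's vertex counter is self-contained.  Faces must follow a
    ``g`` record, reference only that object's vertices, and be triangles.
    Duplicate object keys across the whole input are an error.
    """
    if isinstance(sources, (str, io.IOBase)) or hasattr(sources, "read"):
        sources = [sources]
    scene = MorphoScene(name=name)
    for src in sources:
        _read_single_stream(_as_stream(src), scene, default_time, default_channel)
    return scene


def _read_single_stream(stream: IO[str], scene: MorphoScene,
                        default_time: int, default_channel: int) -> None:
    # file-global 1-based counter over every "v" in this stream.  A vertex
    # declared while an object is open belongs to that object (insertion
    # order preserved); a vertex declared before any "g" is adopted by the
    # first object whose face references it.
    n_global = 0
    coords: Dict[int, Tuple[float, float, float]] = {}   # unowned vertices
    owner: Dict[int, Tuple[ObjectKey, int]] = {}         # global -> (key, local)
    current: TriMeshObject | None = None

    def flush():
        nonlocal current
        if current is not None:
            scene.add(current)
            current = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rec = parts[0]
        if rec == "v":
            if len(parts) < 4:
                raise MorphoFormatError(f"vertex record needs 3 coordinates: {line!r}",
                                        line=lineno)
            try:
                xyz = (float(parts[1]), float(parts[2]), float(parts[3]))
            except ValueError:
                raise MorphoFormatError(f"non-numeric vertex coordinate in {line!r}",
                                        line=lineno) from None
            n_global += 1
            if current is not None:
                current.vertices.append(xyz)
                owner[n_global] = (current.key, len(current.vertices))
            else:
                coords[n_global] = xyz
        elif rec == "g":
            flush()
            if len(parts) < 2:
                raise MorphoFormatError("'g' record without an object tuple",
                                        line=lineno)
            key = parse_object_key(parts[1], default_time, default_channel,
                                   line=lineno)
            comment = " ".join(parts[2:]) if len(parts) > 2 else ""
            current = TriMeshObject(key=key, vertices=[], faces=[], comment=comment)
        elif rec == "f":
            if current is None:
                raise MorphoFormatError(
                    "face record before any 'g' object declaration", line=lineno)
            idx_tokens = parts[1:]
            if len(idx_tokens) != 3:
                raise MorphoFormatError(
                    f"face {line!r} has {len(idx_tokens)} vertices; only triangles "
                    "are allowed", line=lineno)
            face = []
            for tok in idx_tokens:
                base = tok.split("/")[0]  # drop texture/normal suffixes
                try:
                    gi = int(base)
                except ValueError:
                    raise MorphoFormatError(
                        f"non-integer face index {tok!r}", line=lineno) from None
                if not (1 <= gi <= n_global):
                    raise MorphoFormatError(
                        f"face index {gi} out of range [1, {n_global}]",
                        line=lineno)
                if gi in owner:
                    okey, local = owner[gi]
                    if okey != current.key:
                        raise MorphoFormatError(
                            f"vertex {gi} already belongs to object {okey}; "
                            "faces may not share vertices across objects",
                            line=lineno)
                else:  # unowned pre-"g" vertex: adopt it now
                    current.vertices.append(coords.pop(gi))
                    local = len(current.vertices)
                    owner[gi] = (current.key, local)
                face.append(local)
            current.faces.append(tuple(face))
        elif rec in ("vn", "vt", "o", "s", "usemtl", "mtllib"):
            continue  # tolerated, non-semantic
        else:
            raise MorphoFormatError(f"unknown OBJ record {rec!r}", line=lineno)
    flush()


def write_morpho_obj(
    scene: MorphoScene,
    options: ObjDialectOptions | None = None,
) -> Dict[int, str]:
    """Serialize a scene to OBJ text, returned as ``{time: text}``.

    With ``one_file_per_time=False`` the single stream is returned under
    key ``-1``.  Objects are emitted sorted by key; vertex numbering is
    1-based and restarts in every emitted stream.
    """
    options = options or ObjDialectOptions()
    groups: Dict[int, List[TriMeshObject]] = {}
    if options.one_file_per_time:
        for key, obj in sorted(scene.objects.items()):
            groups.setdefault(key.t, []).append(obj)
    else:
        groups[-1] = [obj for _, obj in sorted(scene.objects.items())]

    out: Dict[int, str] = {}
    for t, objs in sorted(groups.items()):
        buf = io.StringIO()
        if options.emit_comments:
            buf.write(f"# morphodynamic dataset: {scene.name}\n")
        offset = 0
        for obj in objs:
            token = format_object_key(obj.key, abbreviate=options.abbreviate_keys)
            g_line = f"g {token}"
            if obj.comment:
                g_line += f" {obj.comment}"
            buf.write(g_line + "\n")
            for x, y, z in obj.vertices:
                buf.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
            for a, b, c in obj.faces:
                buf.write(f"f {a + offset} {b + offset} {c + offset}\n")
            offset += len(obj.vertices)
        out[t] = buf.getvalue()
    return out


def write_morpho_obj_files(scene: MorphoScene, out_dir, stem: str | None = None,
                           options: ObjDialectOptions | None = None) -> List[str]:
    """Write one ``<stem>_t<T>.obj`` file per time point; returns the paths."""
    import os

    options = options or ObjDialectOptions(one_file_per_time=True)
    stem = stem or scene.name
    paths = []
    for t, text in write_morpho_obj(scene, options).items():
        fname = os.path.join(out_dir, f"{stem}_t{t}.obj")
        with open(fname, "w") as fh:
            fh.write(text)
        paths.append(fname)
    return paths


def scene_summary(scene: MorphoScene) -> pd.DataFrame:
    """Per-time table of object/vertex/face counts, with a total row.

    A ``warning`` column flags totals above the half-million-object
    guidance for interactive viewers.
    """
    rows = []
    for t in sorted(scene.times):
        objs = scene.at_time(t)
        rows.append({
            "time": t,
            "objects": len(objs),
            "vertices": sum(o.n_vertices for o in objs),
            "faces": sum(o.n_faces for o in objs),
        })
    total = {
        "time": "total",
        "objects": sum(r["objects"] for r in rows),
        "vertices": sum(r["vertices"] for r in rows),
        "faces": sum(r["faces"] for r in rows),
    }
    rows.append(total)
    df = pd.DataFrame(rows, columns=["time", "objects", "vertices", "faces"])
    df["warning"] = ""
    if total["objects"] > OBJECT_COUNT_GUIDANCE:
        df.loc[df.index[-1], "warning"] = (
            f"object count {total['objects']} exceeds the {OBJECT_COUNT_GUIDANCE} "
            "guidance for interactive viewing"
        )
    return df
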