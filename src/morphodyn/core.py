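"""Core domain types for morphodynamic datasets.

A morphodynamic dataset is a collection of *elementary objects* — cells,
organs, chambers, axons, whatever the dataset owner chose as the atomic
unit — each carrying a triangle surface mesh and uniquely named by an
*object tuple*: three non-negative integers ``t, id, ch`` giving the time
point, the object identifier within that time point, and the visualization
channel.  Datasets with a single time point and a single channel may
abbreviate the tuple to the bare ``id``.

Everything else in this package (annotation tracks, lineage graphs,
adjacency graphs, meshing output) is keyed by :class:`ObjectKey`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

__all__ = [
    "MorphoFormatError",
    "ObjectKey",
    "TriMeshObject",
    "MorphoScene",
    "parse_object_key",
    "format_object_key",
]


class MorphoFormatError(ValueError):
    """Raised on malformed dataset or track input.

    Carries an optional ``line`` attribute (1-based) for file diagnostics.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True, order=False)
class ObjectKey:
    """Unique name of one elementary object: time point, id, channel.

    Ordering is lexicographic on ``(t, ch, id)`` so that sorting a mixed
    key list groups objects by time, then channel.
    """

    t: int
    id: int
    ch: int = 0

    def __post_init__(self):
        for name in ("t", "id", "ch"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise MorphoFormatError(
                    f"object key field {name!r} must be a non-negative integer, got {v!r}"
                )

    def _sort_key(self) -> Tuple[int, int, int]:
        return (self.t, self.ch, self.id)

    def __lt__(self, other: "ObjectKey") -> bool:
        return self._sort_key() < other._sort_key()

    def __le__(self, other: "ObjectKey") -> bool:
        return self._sort_key() <= other._sort_key()

    def __gt__(self, other: "ObjectKey") -> bool:
        return self._sort_key() > other._sort_key()

    def __ge__(self, other: "ObjectKey") -> bool:
        return self._sort_key() >= other._sort_key()

    def __str__(self) -> str:
        return f"{self.t},{self.id},{self.ch}"


def parse_object_key(
    token: str,
    default_time: int = 0,
    default_channel: int = 0,
    line: int | None = None,
) -> ObjectKey:
    """Parse an object tuple token, either ``"t,id,ch"`` or the bare ``"id"``.

    A one-field token is the abbreviated form allowed for single-time,
    single-channel datasets; it resolves to ``(default_time, id,
    default_channel)``.  Whitespace around commas is tolerated.  Two-field
    tokens, non-integers and negative values are format errors.
    """
    fields = [f.strip() for f in token.split(",")]
    if len(fields) not in (1, 3):
        raise MorphoFormatError(
            f"object tuple {token!r} must have 1 or 3 comma-separated fields, "
            f"got {len(fields)}",
            line=line,
        )
    values = []
    for f in fields:
        try:
            values.append(int(f))
        except ValueError:
            raise MorphoFormatError(
                f"object tuple {token!r}: field {f!r} is not an integer", line=line
            ) from None
    if any(v < 0 for v in values):
        raise MorphoFormatError(
            f"object tuple {token!r} contains a negative field", line=line
        )
    if len(values) == 1:
        return ObjectKey(t=default_time, id=values[0], ch=default_channel)
    t, oid, ch = values
    return ObjectKey(t=t, id=oid, ch=ch)


def format_object_key(key: ObjectKey, abbreviate: bool = False) -> str:
    """Format a key as ``"t,id,ch"``; with ``abbreviate`` and t=ch=0, bare id."""
    if abbreviate and key.t == 0 and key.ch == 0:
        return str(key.id)
    return f"{key.t},{key.id},{key.ch}"


@dataclass
class TriMeshObject:
    """One elementary object's triangle surface mesh.

    ``vertices`` are float (x, y, z) rows in dataset length units;
    ``faces`` are 1-based index triples local to this object.
    """

    key: ObjectKey
    vertices: List[Tuple[float, float, float]]
    faces: List[Tuple[int, int, int]]
    comment: str = ""

    def validate(self) -> None:
        n = len(self.vertices)
        if self.faces and n == 0:
            raise MorphoFormatError(f"object {self.key}: faces without vertices")
        for f in self.faces:
            if len(f) != 3:
                raise MorphoFormatError(
                    f"object {self.key}: face {f} is not a triangle"
                )
            for idx in f:
                if not (1 <= idx <= n):
                    raise MorphoFormatError(
                        f"object {self.key}: face index {idx} outside [1, {n}]"
                    )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class MorphoScene:
    """A named collection of mesh objects, keyed by :class:`ObjectKey`."""

    name: str = "scene"
    objects: Dict[ObjectKey, TriMeshObject] = field(default_factory=dict)

    def add(self, obj: TriMeshObject) -> None:
        if obj.key in self.objects:
            raise MorphoFormatError(f"duplicate object key {obj.key}")
        obj.validate()
        self.objects[obj.key] = obj

    @property
    def times(self) -> Set[int]:
        return {k.t for k in self.objects}

    @property
    def channels(self) -> Set[int]:
        return {k.ch for k in self.objects}

    @property
    def keys(self) -> Set[ObjectKey]:
        return set(self.objects)

    def at_time(self, t: int) -> List[TriMeshObject]:
        return [o for k, o in sorted(self.objects.items()) if k.t == t]

    def __len__(self) -> int:
        return len(self.objects)
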