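"""Typed information tracks: the plain-text annotation format.

An information track is a ``.txt`` file projecting per-object (or
object-pair) data onto a morphodynamic dataset.  Every line is an entry of
the form ``OTP: property``; the property grammar depends on the track's
type, declared in a mandatory ``type: <information type>`` header.  Eleven
types exist:

========  ==================================  =============================
type      entry format                        meaning
========  ==================================  =============================
time      OTP1: OTP2                          OTP2 originates from OTP1
space     OTP1: OTP2                          adjacency at the same time
group     OTP: group1 (: subgroup2 ...)       hierarchy, largest first
float     OTP: number                         scalar property (heat map)
selection OTP: integer in [1, 255]            color-selection label
color     OTP: R,G,B  (each in [0, 255])      explicit RGB color
string    OTP: text                           qualitative annotation
genetic   OTP: number                         gene expression level
dict      OTP1: OTP2: number                  weighted object pair
sphere    OTP: x,y,z,r                        sphere glyph
vector    OTP: x1,y1,z1,s1: x2,y2,z2,s2       line-segment glyph
========  ==================================  =============================

The colon is the field delimiter at every level, so group names must be
colon-free.  ``#`` lines are comments; an optional ``name: <text>`` second
header carries the track name (for genetic tracks, the gene name).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import IO, Dict, List, Sequence, Tuple, Union

from .core import (
    MorphoFormatError,
    MorphoScene,
    ObjectKey,
    format_object_key,
    parse_object_key,
)

__all__ = [
    "INFO_TYPES",
    "InfoTrack",
    "TemporalLink",
    "SpatialLink",
    "GroupAssignment",
    "ScalarValue",
    "SelectionLabel",
    "ColorValue",
    "TextValue",
    "GeneticLevel",
    "LinkedValue",
    "SphereGlyph",
    "VectorGlyph",
    "read_info_track",
    "write_info_track",
    "validate_track_against_scene",
]

INFO_TYPES = (
    "time", "space", "group", "float", "selection", "color",
    "string", "genetic", "dict", "sphere", "vector",
)

# single-valued types: at most one entry per key (strict mode)
SINGLE_VALUED = {"float", "selection", "color", "string", "genetic"}


@dataclass(frozen=True)
class TemporalLink:
    source: ObjectKey
    target: ObjectKey

    def __post_init__(self):
        if self.source.t >= self.target.t:
            raise MorphoFormatError(
                f"temporal link {self.source} -> {self.target}: source must be "
                "at a previous time point"
            )


@dataclass(frozen=True)
class SpatialLink:
    a: ObjectKey
    b: ObjectKey

    def __post_init__(self):
        if self.a.t != self.b.t:
            raise MorphoFormatError(
                f"spatial link {self.a} -- {self.b}: objects must be at the "
                "same time point"
            )


@dataclass(frozen=True)
class GroupAssignment:
    key: ObjectKey
    chain: Tuple[str, ...]  # largest group first

    def __post_init__(self):
        if not self.chain:
            raise MorphoFormatError(f"group entry for {self.key} has no group name")
        for name in self.chain:
            if ":" in name or not name.strip():
                raise MorphoFormatError(
                    f"group name {name!r} must be non-empty and colon-free"
                )


@dataclass(frozen=True)
class ScalarValue:
    key: ObjectKey
    value: float


@dataclass(frozen=True)
class SelectionLabel:
    key: ObjectKey
    label: int

    def __post_init__(self):
        if not (1 <= self.label <= 255):
            raise MorphoFormatError(
                f"selection value {self.label} for {self.key} outside [1, 255]"
            )


@dataclass(frozen=True)
class ColorValue:
    key: ObjectKey
    r: int
    g: int
    b: int

    def __post_init__(self):
        for c in (self.r, self.g, self.b):
            if not (0 <= c <= 255):
                raise MorphoFormatError(
                    f"color component {c} for {self.key} outside [0, 255]"
                )


@dataclass(frozen=True)
class TextValue:
    key: ObjectKey
    text: str


@dataclass(frozen=True)
class GeneticLevel:
    key: ObjectKey
    level: float


@dataclass(frozen=True)
class LinkedValue:
    source: ObjectKey
    target: ObjectKey
    value: float


@dataclass(frozen=True)
class SphereGlyph:
    key: ObjectKey
    x: float
    y: float
    z: float
    r: float

    def __post_init__(self):
        if not self.r > 0:
            raise MorphoFormatError(f"sphere radius must be > 0, got {self.r}")


@dataclass(frozen=True)
class VectorGlyph:
    key: ObjectKey
    x1: float
    y1: float
    z1: float
    s1: float
    x2: float
    y2: float
    z2: float
    s2: float

    def __post_init__(self):
        if not (self.s1 > 0 and self.s2 > 0):
            raise MorphoFormatError(
                f"vector sizes must be > 0, got s1={self.s1}, s2={self.s2}"
            )


_ENTRY_CLASSES = {
    "time": TemporalLink,
    "space": SpatialLink,
    "group": GroupAssignment,
    "float": ScalarValue,
    "selection": SelectionLabel,
    "color": ColorValue,
    "string": TextValue,
    "genetic": GeneticLevel,
    "dict": LinkedValue,
    "sphere": SphereGlyph,
    "vector": VectorGlyph,
}


@dataclass
class InfoTrack:
    """A named, typed list of annotation entries.

    For genetic tracks ``name`` is the gene name, taken by convention from
    the information file's name.
    """

    name: str
    info_type: str
    entries: list

    def __post_init__(self):
        if not self.name:
            raise MorphoFormatError("information track must be given a name")
        if self.info_type not in INFO_TYPES:
            raise MorphoFormatError(
                f"unknown information type {self.info_type!r}; "
                f"expected one of {', '.join(INFO_TYPES)}"
            )
        cls = _ENTRY_CLASSES[self.info_type]
        for e in self.entries:
            if not isinstance(e, cls):
                raise MorphoFormatError(
                    f"entry {e!r} does not match track type {self.info_type!r}"
                )

    def keys(self) -> List[ObjectKey]:
        """All object keys referenced by the track, in entry order."""
        out: List[ObjectKey] = []
        for e in self.entries:
            if isinstance(e, (TemporalLink, LinkedValue)):
                out.extend((e.source, e.target))
            elif isinstance(e, SpatialLink):
                out.extend((e.a, e.b))
            else:
                out.append(e.key)
        return out

    def __len__(self) -> int:
        return len(self.entries)


def _parse_float(token: str, line: int) -> float:
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        raise MorphoFormatError(f"{token!r} is not a number", line=line) from None


def _parse_int(token: str, line: int) -> int:
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        raise MorphoFormatError(f"{token!r} is not an integer", line=line) from None


def _wrap(exc: MorphoFormatError, line: int) -> MorphoFormatError:
    if exc.line is None:
        return MorphoFormatError(str(exc), line=line)
    return exc


def _parse_entry(info_type: str, line_text: str, lineno: int,
                 default_time: int, default_channel: int):
    def key(tok: str) -> ObjectKey:
        return parse_object_key(tok, default_time, default_channel, line=lineno)

    parts = [p for p in line_text.split(":")]
    try:
        if info_type == "string":
            head, _, text = line_text.partition(":")
            if not _:
                raise MorphoFormatError("expected 'OTP: text'", line=lineno)
            return TextValue(key(head), text.strip())
        if info_type == "time":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP1: OTP2'", line=lineno)
            return TemporalLink(key(parts[0]), key(parts[1]))
        if info_type == "space":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP1: OTP2'", line=lineno)
            return SpatialLink(key(parts[0]), key(parts[1]))
        if info_type == "group":
            if len(parts) < 2:
                raise MorphoFormatError(
                    "expected 'OTP: group1 (: subgroup2 ...)'", line=lineno)
            chain = tuple(p.strip() for p in parts[1:])
            return GroupAssignment(key(parts[0]), chain)
        if info_type == "float":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP: number'", line=lineno)
            return ScalarValue(key(parts[0]), _parse_float(parts[1], lineno))
        if info_type == "selection":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP: integer'", line=lineno)
            return SelectionLabel(key(parts[0]), _parse_int(parts[1], lineno))
        if info_type == "color":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP: R,G,B'", line=lineno)
            rgb = [s.strip() for s in parts[1].split(",")]
            if len(rgb) != 3:
                raise MorphoFormatError("expected three color components R,G,B",
                                        line=lineno)
            r, g, b = (_parse_int(c, lineno) for c in rgb)
            return ColorValue(key(parts[0]), r, g, b)
        if info_type == "genetic":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP: number'", line=lineno)
            return GeneticLevel(key(parts[0]), _parse_float(parts[1], lineno))
        if info_type == "dict":
            if len(parts) != 3:
                raise MorphoFormatError("expected 'OTP1: OTP2: number'",
                                        line=lineno)
            return LinkedValue(key(parts[0]), key(parts[1]),
                               _parse_float(parts[2], lineno))
        if info_type == "sphere":
            if len(parts) != 2:
                raise MorphoFormatError("expected 'OTP: x,y,z,r'", line=lineno)
            nums = [s.strip() for s in parts[1].split(",")]
            if len(nums) != 4:
                raise MorphoFormatError("sphere needs exactly x,y,z,r",
                                        line=lineno)
            x, y, z, r = (_parse_float(n, lineno) for n in nums)
            return SphereGlyph(key(parts[0]), x, y, z, r)
        if info_type == "vector":
            if len(parts) != 3:
                raise MorphoFormatError(
                    "expected 'OTP: x1,y1,z1,s1: x2,y2,z2,s2'", line=lineno)
            a = [s.strip() for s in parts[1].split(",")]
            b = [s.strip() for s in parts[2].split(",")]
            if len(a) != 4 or len(b) != 4:
                raise MorphoFormatError(
                    "vector needs x1,y1,z1,s1 and x2,y2,z2,s2", line=lineno)
            vals = [_parse_float(n, lineno) for n in a + b]
            return VectorGlyph(key(parts[0]), *vals)
    except MorphoFormatError as exc:
        raise _wrap(exc, lineno) from None
    raise MorphoFormatError(f"unknown information type {info_type!r}", line=lineno)


def read_info_track(
    source: Union[str, IO[str]],
    name: str = "unnamed",
    default_time: int = 0,
    default_channel: int = 0,
    strict: bool = True,
) -> InfoTrack:
    """Parse an information track from a stream or string.

    The first non-comment line must be the ``type:`` header
    (case-insensitive).  An optional ``name:`` header overrides the
    ``name`` argument.  In strict mode, duplicate entries for one key in a
    single-valued track are an error; in lenient mode the last wins with a
    warning.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    info_type: str | None = None
    track_name = name
    entries: list = []
    seen_keys: Dict[ObjectKey, int] = {}

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if info_type is None:
            head, _, rest = line.partition(":")
            if head.strip().lower() != "type" or not _:
                raise MorphoFormatError(
                    f"first line must be a 'type:' header, got {line!r}",
                    line=lineno)
            declared = rest.strip().lower()
            if declared not in INFO_TYPES:
                raise MorphoFormatError(
                    f"unknown information type {rest.strip()!r}", line=lineno)
            info_type = declared
            continue
        head, sep, rest = line.partition(":")
        if head.strip().lower() == "name" and sep and not entries:
            track_name = rest.strip()
            continue
        entry = _parse_entry(info_type, line, lineno, default_time,
                             default_channel)
        if info_type in SINGLE_VALUED:
            k = entry.key
            if k in seen_keys:
                if strict:
                    raise MorphoFormatError(
                        f"duplicate entry for object {k} (first at line "
                        f"{seen_keys[k]})", line=lineno)
                warnings.warn(
                    f"line {lineno}: duplicate entry for object {k}; "
                    "keeping the last value", stacklevel=2)
                entries[:] = [e for e in entries if e.key != k]
            seen_keys[k] = lineno
        entries.append(entry)

    if info_type is None:
        raise MorphoFormatError("missing 'type:' header")
    return InfoTrack(name=track_name, info_type=info_type, entries=entries)


def _fmt_num(v: float) -> str:
    # repr round-trips floats exactly; integers print without '.0' noise
    if isinstance(v, float) and v.is_integer() and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def write_info_track(
    track: InfoTrack,
    abbreviate_keys: bool = False,
    emit_name: bool = False,
) -> str:
    """Serialize a track to its canonical text form.

    ``read_info_track(write_info_track(x)) == x`` for every valid track.
    """
    def k(key: ObjectKey) -> str:
        return format_object_key(key, abbreviate=abbreviate_keys)

    lines = [f"type:{track.info_type}"]
    if emit_name:
        lines.append(f"name:{track.name}")
    for e in track.entries:
        if isinstance(e, TemporalLink):
            lines.append(f"{k(e.source)}:{k(e.target)}")
        elif isinstance(e, SpatialLink):
            lines.append(f"{k(e.a)}:{k(e.b)}")
        elif isinstance(e, GroupAssignment):
            lines.append(":".join([k(e.key), *e.chain]))
        elif isinstance(e, ScalarValue):
            lines.append(f"{k(e.key)}:{_fmt_num(e.value)}")
        elif isinstance(e, SelectionLabel):
            lines.append(f"{k(e.key)}:{e.label}")
        elif isinstance(e, ColorValue):
            lines.append(f"{k(e.key)}:{e.r},{e.g},{e.b}")
        elif isinstance(e, TextValue):
            lines.append(f"{k(e.key)}:{e.text}")
        elif isinstance(e, GeneticLevel):
            lines.append(f"{k(e.key)}:{_fmt_num(e.level)}")
        elif isinstance(e, LinkedValue):
            lines.append(f"{k(e.source)}:{k(e.target)}:{_fmt_num(e.value)}")
        elif isinstance(e, SphereGlyph):
            lines.append(f"{k(e.key)}:" + ",".join(_fmt_num(v) for v in
                                                   (e.x, e.y, e.z, e.r)))
        elif isinstance(e, VectorGlyph):
            lines.append(
                f"{k(e.key)}:"
                + ",".join(_fmt_num(v) for v in (e.x1, e.y1, e.z1, e.s1))
                + ":" + ",".join(_fmt_num(v) for v in (e.x2, e.y2, e.z2, e.s2)))
        else:  # pragma: no cover - guarded by InfoTrack validation
            raise MorphoFormatError(f"cannot serialize entry {e!r}")
    return "\n".join(lines) + "\n"


def validate_track_against_scene(track: InfoTrack, scene: MorphoScene) -> List[str]:
    """Report every entry whose object key is absent from the scene.

    Returns human-readable diagnostics; an empty list means the track is
    fully consistent with the scene.
    """
    present = scene.keys
    diags: List[str] = []
    for i, e in enumerate(track.entries):
        missing = [key for key in _entry_keys(e) if key not in present]
        for key in missing:
            diags.append(
                f"entry {i + 1}: object {key} not present in scene "
                f"{scene.name!r}")
    return diags


def _entry_keys(e) -> Tuple[ObjectKey, ...]:
    if isinstance(e, (TemporalLink, LinkedValue)):
        return (e.source, e.target)
    if isinstance(e, SpatialLink):
        return (e.a, e.b)
    return (e.key,)
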