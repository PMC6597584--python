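# Methods

## The data model

A morphodynamic dataset is a time series of *elementary objects* — the
atomic units a dataset owner chose to expose (cells, organs, chambers,
axons).  Each object is a triangle surface mesh, and is uniquely named by
an *object tuple* of three non-negative integers `t,id,ch` (time point,
per-time identifier, visualization channel).  Datasets with a single time
point and channel may abbreviate the tuple to the bare `id`; this package
resolves abbreviated tuples to `t=0, ch=0` (writers always emit the full
form unless asked to abbreviate), since abbreviation is only legal when a
single time/channel slot exists.

Meshes travel as Wavefront OBJ restricted to geometry: `g <tuple>` opens
an object, `v`/`f` records follow, vertex indices are 1-based and
file-global.  The per-time numbering rule (vertex numbering restarts at
every time point) conflicts with single-file multi-time datasets, so the
writer emits one file per time point by default and the reader treats each
physical file's counter as self-contained, accepting both continuing and
restarting conventions.  Faces must be triangles; `vn`/`vt` records and
`f a/b/c` suffixes are tolerated and discarded.  Coordinates are written
with 6 decimals — sub-voxel precision at typical microscopy scales without
bloating files — and round-trip equality is defined at that printed
precision.

Annotations are plain-text *information tracks*: a `type:` header followed
by `OTP: property` entries, in eleven typed grammars (time, space, group,
float, selection, color, string, genetic, dict, sphere, vector).  The
colon is the delimiter at every level, so group names must be colon-free
(rejected on write).  Selection labels live in [1, 255], color components
in [0, 255], temporal links must advance in time, spatial links must not.
Duplicate entries for one key in single-valued tracks are an error in
strict mode and keep-last-with-warning in lenient mode (manual curation
implies overwrites).  Decimal separator is `.` only.  Floats are emitted
with `repr` so numeric round-trips are exact.

## Lineage

Temporal tracks define a DAG ordered by time.  Out-degree ≥ 2 marks a
division, in-degree ≥ 2 a fusion target; appearance/disappearance are
defined relative to the graph's own time span, so lineage is analyzable
without meshes.  Edges that skip time points are accepted with a warning —
continuity is a data-quality signal, not a format rule.

Selection propagation labels every node reachable from a labeled node in
the chosen direction; where conflicting labels meet (fusions going
forward, divisions going backward), the **smallest label wins**, with a
warning.  This tie-break is a design choice of this package (deterministic
and order-independent), not something the format prescribes.  `both`
alternates forward/backward sweeps to a fixed point.  Original entries are
never overwritten.  Propagation is idempotent.

The *identity chain* used by the time average is the maximal run of
one-to-one temporal links (out-degree 1 into in-degree 1) — the same
physical object tracked between events.

Fusion-free lineages can be exported as Newick with node names `t.id.ch`;
fusions make the graph a non-tree DAG, so Newick export then fails
explicitly.

## Adjacency

Space and dict tracks build one undirected graph per time point; dict
values become positive edge weights (contact areas, squared length
units).  Symmetric duplicates collapse; conflicting duplicate weights are
an error in strict mode.  Cross-channel edges at equal time are allowed —
this is our reading of "linked objects across channels", documented as an
interpretation.  Neighbor expansion is breadth-first closure of a given
radius around seed objects (radius 0 = seeds), monotone in the radius with
the connected component as fixed point.

## Quantitative manipulations

- **Statistics**: population standard deviation (divisor *n*) — the track
  is the complete object set, not a sample.
- **Space average**: per-time global mean assigned back to every object at
  that time.  A *neighbor-local* variant (`neighbor_smooth`: mean of self
  and valued neighbors) is provided under its own name rather than guessed
  into the same operation — the global/local reading is genuinely open.
- **Time average**: mean along each identity chain; events (division,
  fusion) end chains, so a parent's chain never includes its children.
- **Time normalization** is not defined by the format; we chose per-time
  min-max scaling `v → (v − min_t)/(max_t − min_t)` into [0, 1], with
  constant time points mapping to 0.  It is scale-free,
  visualization-friendly, and idempotent.
- **Heat maps**: linear interpolation per RGB channel between a low color
  at the range minimum and a high color at the maximum (defaults blue
  (0,0,255) → red (255,0,0), the usual convention), values clamped to an
  explicit range, rounding half-away-from-zero.  A constant track maps to
  the low color, mirroring the time-normalization convention.  No
  perceptual colormap: the target is the simple blue→red ramp.

## Genetics

"Expressed" means level strictly greater than a threshold (default 0), so
boolean 0/1 tracks behave as on/off.  The gene name is the track name (by
convention the information file's name).  Overlap/union act on full
`(t,id,ch)` keys, so stage-specific patterns fall out naturally.  The
two-gene selection track labels A-only 1, B-only 2, overlap 3; rendering
colors are the viewer's concern.

## Meshing pipeline

Per label: binary mask → marching cubes at iso-level 0.5 with physical
voxel spacing, mask padded by one voxel so surfaces close at image
borders; world position = voxel index × spacing, origin at the image
corner, no axis flips.  Per-object meshing means neighboring meshes may
interpenetrate slightly; that matches the per-object mesh model of the
browsers this format feeds.

Decimation is shortest-edge collapse to the midpoint, guarded by the
manifold link condition (the collapsing edge's endpoints must share
exactly the two opposite vertices) and a normal-flip rejection test; this
preserves topology and watertightness, stopping at the target fraction,
the tetrahedron minimum, or when no safe collapse remains.  No installed
library provides decimation, so it is implemented here; quadric-error
metrics were judged unnecessary for the convex-ish cell shapes this
pipeline targets.

Volumes: voxel count × dx·dy·dz per label.  Mesh volume: divergence
theorem over signed tetrahedra, absolute value returned; requires a closed
mesh (every edge in exactly two faces).  Contacts: every 6-connected voxel
face shared by two distinct foreground labels accumulates its oriented
face area (dy·dz, dx·dz or dx·dy) — 6-connectivity because corner-touching
labels share zero area, which keeps "contact area" well defined.

Expected accuracy: for convex blobs of radius ≥ 8 voxels, undecimated mesh
volume agrees with the voxel volume within ~2–5%, improving with
resolution; moderately decimated (≥ 0.3) post-division cell shapes in the
synthetic embryo stay within ~10%.  The half-million-object guidance for
interactive viewers is surfaced as a warning, never a hard limit.

## Synthetic embryo

The generator states a small ascidian-like early embryo: one ellipsoid
(semi-axes ≈ 0.40/0.34/0.28 of the grid, ±5% seeded jitter) in a 48³ unit
grid, three synchronous division rounds at t = 1..rounds, then one fusion
per time point (a seeded choice among touching pairs), identity steps
otherwise; five time points by default.  Division cuts across the longest
principal axis through the median projection (ties broken by lexicographic
voxel order): deterministic, balanced to within one voxel, volume
conserved exactly.  Gene expression is clade-wise — geneA marks the
root's first daughter clade, geneB the first granddaughter clade — so
overlap (= geneB's set) and union (= geneA's set) have known answers by
construction.

What a green test on this generator establishes: exact recovery of
lineage topology, adjacency, voxel volumes and expression sets from
emitted files, and mesh volumes within meshing tolerance.  What it does
not: robustness to segmentation noise, touching-label ambiguity, irregular
cell shapes, anisotropic spacing at extreme ratios, or real staging — the
embryo is a stated world, not a biophysical simulation.

## Numerical choices and degenerate inputs

- Whitespace around delimiters is ignored on input, never emitted.
- Empty tracks are valid files (header only); statistics on them are
  errors.
- `id = 0` is permitted (some segmentation exports start at 0);
  background handling is the meshing module's concern, where label 0 is
  reserved.
- Key ordering is lexicographic on `(t, ch, id)` — total, so every export
  is deterministic.
- Uniqueness is required of the full `(t,id,ch)` triple only; ids may
  repeat across channels at one time point.

## Known limitations

No server/upload features, no rendering, no interactive curation, no
automatic tracking from raw images.  The meshing step reproduces the
concept of compression into per-object surfaces, not any specific external
meshing algorithm.  The OBJ reader rejects unknown record types rather
than skipping them — auditing over permissiveness.
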