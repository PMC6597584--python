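# morphodyn

An offline toolkit for **morphodynamic browser datasets**: time series of
segmented biological objects (cells, organs, chambers, axons) represented
as per-object triangle surface meshes, with plain-text annotation tracks
projected onto them.

Web-based morphology browsers consume two kinds of files:

- **OBJ meshes** in which every elementary object is a named group
  (`g t,id,ch`), uniquely identified by its *object tuple* — time point
  `t`, per-time identifier `id`, visualization channel `ch`;
- **information tracks**: `.txt` files of `OTP: property` entries in
  eleven typed grammars (temporal links, spatial links, group
  hierarchies, scalar values, selections in [1, 255], RGB colors,
  qualitative text, gene-expression levels, weighted pair dictionaries,
  sphere and vector glyphs).

This package reads, validates and writes all of those formats offline, and
implements the analyses the browsers perform on them:

- **lineage**: build the temporal DAG from time tracks; a node with
  out-degree ≥ 2 is a division, in-degree ≥ 2 a fusion; descendants /
  ancestors queries; selection propagation along the lineage; TSV and
  Newick export;
- **adjacency**: per-time neighbor graphs from space/dict tracks,
  iterative neighbor expansion (breadth-first, radius *k*);
- **analytics**: per-time and overall mean/std (population, divisor *n*),
  space and along-lineage time averages, per-time min-max time
  normalization into [0, 1], neighbor smoothing, and blue→red heat-map
  colorization `RGB(v) = low + (v − vmin)/(vmax − vmin) · (high − low)`;
- **genetics**: expression catalogs with `expressed := level > threshold`
  (default 0, so boolean 0/1 tracks are on/off), pattern overlap ∩ and
  union ∪, per-object gene lists, two-gene selection tracks;
- **meshing**: segmented TIFF label stacks → one closed surface per label
  (marching cubes at iso-level 0.5 with physical voxel spacing), optional
  topology-preserving edge-collapse decimation, voxel volumes
  (count × dx·dy·dz), 6-connected contact areas and the adjacency graph;
  mesh volume by the divergence theorem and surface area;
- **synthetic embryo**: a seeded generator of a dividing/fusing toy embryo
  with full ground truth (lineage, volumes, adjacency, clade-wise gene
  expression), so every operation above is testable without downloads.

## Worked example

Generate a small embryo (2 division rounds, 4 time points) and inspect it:

```sh
$ morpho synth --rounds 2 --timepoints 4 --fusions 0 --grid 32 --seed 42 --out demo
wrote 11 files to demo (3 divisions, 0 fusions)

$ head -4 demo/embryo_lineage.txt
type:time
0,1,0:1,1,0
0,1,0:1,2,0
1,1,0:2,1,0

$ morpho info stats demo/embryo_volumes.txt
         count         mean          std     min     max
time
overall     11  2010.545455  1231.202691  1382.0  5529.0
0            1  5529.000000     0.000000  5529.0  5529.0
1            2  2764.500000     0.500000  2764.0  2765.0
2            4  1382.250000     0.433013  1382.0  1383.0
3            4  1382.250000     0.433013  1382.0  1383.0
```

The single starting cell occupies 5529 voxels (unit spacing, so volume
5529); each division round halves the volumes exactly (2764/2765, then
1382/1383 — balanced to within one voxel), and the last time point is an
identity step.  Event classification recovers the divisions:

```sh
$ morpho lineage events demo/embryo_lineage.txt | head -2
0,1,0	1,1,0	division
0,1,0	1,2,0	division
```

and a volume heat map maps the largest object to red and the daughters to
interpolated colors:

```sh
$ morpho info derive demo/embryo_volumes.txt --op heatmap | head -3
type:color
0,1,0:255,0,0
1,1,0:85,0,170
```

The same operations are available as a library:

```python
from morphodyn import read_info_track, build_lineage

with open("demo/embryo_lineage.txt") as fh:
    graph = build_lineage(read_info_track(fh, name="lineage"))
graph.divisions()      # {(0,1,0), (1,1,0), (1,2,0)}
```

## Acceptance script

`scripts/acceptance.py` exercises the full pipeline from scratch: it
generates a seeded synthetic embryo, writes the complete dataset (OBJ
meshes plus lineage, adjacency, contact-area, volume, genetic and
selection tracks), reads every file back through the parsers and
validators, and re-derives lineage events, adjacency, volumes and
expression sets, checking them against the generator's ground truth.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A one-line summary (object counts, event counts, validator diagnostics,
worst mesh-volume error) is printed to stderr.

See `docs/methods.md` for the data model, the algorithmic choices and
their rationale, and known limitations.
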