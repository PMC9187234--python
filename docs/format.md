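# File formats

## Network JSON dialect

The lossless interchange format for vessel networks. All coordinates are
micrometers, (x, y, z) order.

```json
{
 "nodes": [
  {"id": 0, "xyz": [0.0, 0.0, 0.0], "kind": "branching", "diameter": 4.2},
  {"id": 1, "xyz": [5.0, 0.0, 0.0], "kind": "interior"}
 ],
 "edges": [[0, 1]],
 "segments": [[0, 1, 7, 3]]
}
```

* `nodes[*].id` — integer node id (any non-negative integers; need not be
  contiguous).
* `nodes[*].kind` — `branching` (degree >= 3), `interior` (degree 2) or
  `endpoint` (degree 1; also used for isolated degree-0 nodes).
* `nodes[*].diameter` — optional, micrometers; topological descriptors never
  require it.
* `edges` — unordered node-id pairs.
* `segments` — ordered node-id paths partitioning the edge set; a closed
  segment repeats its anchor node at both ends.

Schema violations are reported with the offending field path
(e.g. `nodes[3] is missing key 'xyz'`).

## GraphML export

`write_graphml` emits nodes with `x`, `y`, `z`, `kind` and optional
`diameter` attributes. GraphML carries no segment decomposition; use the
JSON dialect when segments matter.

## Skeleton stacks

* TIFF stacks: any integer dtype, axis order (z, y, x), nonzero = foreground.
* NIfTI volumes: axis order (x, y, z), transposed on read.
* Voxel spacing `(dz, dy, dx)` in micrometers is supplied by the caller
  (CLI flag `--spacing dz dy dx`); it is not read from file metadata.

## Barcode CSV

One row per bar: `dimension,birth,death,essential`. Births and deaths are
filtration values (micrometers for radial filtrations, square micrometers
for alpha filtrations). Essential classes record the final filtration value
as their death and `essential=True`, so no information is lost.

## Simplex list (plain text)

`write_simplex_list` emits one simplex per line in filtration order:

```
dim v0 [v1 [v2 [v3]]] value
```

consumable by external persistent-homology tools for cross-checks.
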