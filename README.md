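# vesseltopo

Multiscale topological quantification of 3D blood-vessel networks.

High-resolution 3D microscopy of tumor vasculature reveals structural
abnormalities — twisted vessels, excess loops, avascular regions — that
single-scale morphology summaries (vessel counts, mean diameters, density)
cannot capture. `vesseltopo` quantifies these features with persistent
homology, for researchers analyzing skeletonized vascular image stacks or
pre-extracted spatial vessel graphs: it tracks connected components
(dimension 0), loops (dimension 1) and voids (dimension 2) across spatial
scale and compresses the resulting barcodes into interpretable scalar
descriptors, alongside the standard comparator metrics.

## The method

A vessel network is a spatial graph `(V, E)` with nodes embedded in 3D
(μm) and an explicit decomposition of `E` into vessel *segments* (maximal
paths between branching points/endpoints). Two filtrations feed the
persistence engine:

* **Radial filtration** — a sphere grows from the tumor center (the
  center of mass of the nodes) in `n_steps = 500` uniform radius
  increments; at radius `r` the complex contains every node within `r`
  and every edge whose endpoints are both inside. No triangles are ever
  filled, so homology lives in dimensions 0 and 1 and every loop class is
  essential. From the barcodes:
  - **topological tortuosity** = #{dim-0 bars with persistence ≤ 0.1·r_max}
    / #segments — a tortuous vessel crosses the growing sphere repeatedly,
    shedding many short-lived components;
  - **loops per segment** = #{dim-1 bars} / #segments, with
    #{dim-1 bars} = E − V + C exactly;
  - **shell profiles** — loops binned by birth radius into spherical
    shells, per day, normalized by day 0 (spatiotemporal sprouting maps).
* **Alpha-complex filtration** — the Delaunay triangulation of the node
  cloud filtered by squared circumradius α²; a simplex whose circumsphere
  contains another vertex inherits the minimum of its cofaces' values.
  The **void descriptor** is the median persistence of dimension-2 bars
  (μm²), a proxy for avascular-region volume.

Comparator metrics per segment: **clr** (endpoint chord / path length,
1 = straight) and **SOAM** (sum of angles between uniformly resampled
tangents, degrees), plus segment/branching-point counts, lengths and
diameters. Group statistics follow the conventional nonparametric battery:
Kruskal–Wallis, pairwise two-sided Wilcoxon rank-sum vs. control at
α = 0.05 without multiplicity correction, Pearson correlation heatmaps
with complete-linkage clustering.

Persistence is computed over GF(2) — a union-find sweep with the elder
rule for graph filtrations, boundary-matrix column reduction for
simplicial ones — and validated against an independent brute-force
boundary-rank oracle in the test suite.

## Worked example

```python
import vesseltopo as vt
from vesseltopo import synthetic as syn

cohort = syn.make_cohort(n_per_group=5, days=(0, 4), effect=0.5, seed=11)
table = vt.descriptor_table(cohort[cohort.day == 4], n_steps=500)
print(table.groupby("group").loops_per_segment.median().round(3))
print(vt.group_tests(table, "loops_per_segment").to_frame())
```

prints

```
group
control           0.382
sprouting_down    0.318
sprouting_up      0.417

             test                              groups  statistic  p_value  significant
   kruskal-wallis control/sprouting_down/sprouting_up  12.410127 0.002019         True
wilcoxon-rank-sum              sprouting_down/control   0.000000 0.010662         True
wilcoxon-rank-sum                sprouting_up/control  24.500000 0.015651         True
```

The simulated sprouting-increased group (+50% loop density by day 4)
shows a higher median loop count per vessel segment than control, the
sprouting-decreased group a lower one, and both separate significantly at
five subjects per group. More narrative walk-throughs live in
`examples/`: `radial_descriptors.py` (tortuosity/loops on coiled vessels
and loop grids), `avascular_voids.py` (void sizes of hollow shells),
`cohort_statistics.py` (the cohort battery above).

A thin CLI covers the same pipeline from the shell:

```bash
vesseltopo synth --kind grid -p nx_nodes=3 -p ny_nodes=3 -o net.json
vesseltopo describe net.json -o descriptors.csv
vesseltopo describe stack.tif --spacing 5.1 5.1 5.1 --z-rescale 0.835 \
    --subsample 2 -o descriptors.csv
vesseltopo cohort table.csv --value-col loops_per_segment -o tests.csv
```

File formats (network JSON dialect, barcode CSV, simplex lists) are
documented in `docs/format.md`; the scientific and numerical choices in
`docs/methods.md`.

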