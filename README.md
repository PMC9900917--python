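# spatialprep

Spatially resolved transcriptomics (SRT) experiments pair gene expression
with position in intact tissue — spot-based platforms such as Visium measure
~55 μm circular capture spots on a hexagonal lattice, imaging-based platforms
such as MERFISH count transcripts per segmented cell — and both come with
full-resolution microscopy images that are far too large to load whole.
`spatialprep` converts these outputs into self-contained **sample folders**
that a viewer (or any analysis script) can read *lazily*: it fetches only the
bytes it needs, when it needs them.

A sample folder contains:

- **`sample.json`** — a master manifest naming the images, overlays and
  feature groups, and anchoring pixels to physical scale (μm/px).
- **Tiled image pyramids** — valid tiled TIFFs in a cloud-optimized layout:
  level 0 is full resolution and level *k* has dimensions
  ⌈w/2ᵏ⌉ × ⌈h/2ᵏ⌉ (2×2 block-mean overviews), down to the first level that
  fits one tile.  All tile byte offsets live in a header region at the start
  of the file, so a client holding a byte-range reader (local seek+read or
  HTTP `Range:` requests) opens the store with one read and then pays only
  for the tiles intersecting its viewport.
- **Overlays** — ordered point layers (`id,x,y` CSV) in level-0 pixel
  coordinates: one row per spot or cell.
- **Chunked feature stores** — per-feature sparse vectors.  Each feature
  (gene) is serialized as `index,value` lines, deflate-compressed
  independently, and concatenated; a small JSON index maps feature name to
  byte range.  Reading one gene over *n* spots costs
  O(index + that record), not O(genes × spots).
- **Annotations** — labeled points, circles (diameter in μm) and polygons in
  a plain CSV; importable from napari point/shape tables; assignable to
  overlay points (circle: Euclidean distance ≤ d/2; polygon: even-odd rule
  with boundary inside; first matching record wins).

Converters are provided for Space Ranger-style Visium folders (tissue
positions in either CSV dialect, scalefactors JSON, MatrixMarket counts;
values stored as ln(1 + count), image Gaussian-filtered with σ = 4 px,
spots as 55 μm circles with μm/px = 55 / `spot_diameter_fullres`), for
Vizgen MERFISH-style tables (centroids mapped micron → mosaic pixel through
the provided 3×3 affine, counts stored raw), and for bare TIFFs (default
JPEG tiles at quality 90, or lossless deflate).

## Worked example

`examples/pyramid_lazy_read.py` builds a 2048² single-channel pyramid from
random pixels and reads a 100×100 viewport through a byte-counting reader:

```
pyramid: 4 levels, 5410010 bytes on disk
opening fetched 16384 header bytes
100x100 viewport: fetched 65562 tile bytes (1.51% of the file)
full read identical to input: True
```

The viewport touches one 256² tile, so the read costs one compressed tile
plus the one-off header — about 1.5% of the file — while the lossless full
read reproduces the input bit for bit.  `examples/convert_visium_sample.py`
runs the Visium converter on a synthetic Space Ranger folder:

```
validation findings: []
scale: 0.5 um/px; overlay: 50 spots, 55.0 um circles
Gene003: 3 expressing spots, max log1p value 2.4849, fetched 50 bytes
```

An empty findings list means the folder is internally consistent; the
single-gene read fetched only that gene's 50-byte compressed record.  The
other examples cover MERFISH conversion and annotation round-trip plus
label assignment.

There is also a thin CLI (`spatialprep prep-image | prep-visium |
prep-merfish | validate | annot-import | annot-export | annot-assign |
fixture`) mapping 1:1 onto the library; exit code 0 on success, 1 on
validation findings, 2 on usage errors.

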