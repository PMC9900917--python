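# Methods

## The sample-folder model

The package separates *coordinates* from *values*.  An **overlay** is an
ordered layer of points (Visium spots, segmented cells) sharing one
coordinate frame; a **feature** is a quantitative or categorical value
attached to each point (one gene's expression, a cluster label).  Because
SRT features usually share the same coordinates, storing the coordinates
once and the features as independent sparse records removes redundancy and
makes the lazy unit match the user action: selecting one gene loads one
record.

All overlay and annotation coordinates are expressed in level-0 pixel units
of the sample's image, origin top-left, x rightward, y downward, stored as
reals.  Physical scale is recovered through the manifest's single
`microns_per_pixel` value.  For Visium this scale is anchored by the spot
geometry: capture spots are 55 μm across, so
μm/px = 55 / `spot_diameter_fullres`.  For MERFISH the affine's linear part
implies the scale (mean of the two axis norms of its inverse action).

## Image pyramids

Levels are planned by repeated ceiling halving of (width, height) until the
larger dimension fits in one tile; level 0 is full resolution (the standard
cloud-optimized GeoTIFF overview convention — a viewer that counts levels
from the coarsest end can renumber using `n_levels` from the manifest).
Overviews are 2×2 block means: edge blocks average only the pixels that
exist, and integer outputs round half-up.  Block mean was chosen over
subsampling because it is artifact-free and exactly testable; the
downsampling factor 2 follows COG practice.

Files are classic little-endian tiled TIFFs written by the package itself:
one page per level (reduced-resolution pages flagged in `NewSubfileType`),
square tiles, planar channel storage (channels are toggled independently in
viewers, so one plane per channel keeps a channel read to its own tiles).
The defining layout property — and the reason the writer is in-package
rather than delegated to a general TIFF library — is that *every* IFD and
out-of-line tag value, including all `TileOffsets`/`TileByteCounts` arrays,
is serialized in one contiguous segment before any tile data.  A reader can
therefore build the complete tile index from a single initial range read
(16 KiB by default, extended geometrically in the rare case the header is
larger).  Output files remain standard TIFFs: the test suite checks that
tifffile, as an independent reader, decodes level 0 identically.

Tile codecs: deflate (zlib, lossless) or JPEG (one complete stream per tile,
Pillow-encoded, uint8 only).  Defaults: tile size 512, lossless for
converted samples, JPEG at quality 90 for bare image preprocessing.  Edge
tiles are zero-padded to the full tile size, as the TIFF tile model
requires; region reads crop the padding away.

`read_region` plans exactly the tiles whose level-0 footprint intersects the
viewport (half-open rectangle semantics, row-major order, no duplicates) and
reports the bytes it pulled through the `RangeReader`, which is what makes
the lazy-read bounds assertable rather than anecdotal.  A `CachingRangeReader`
gives repeat reads for free; an HTTP implementation with identical semantics
covers remote stores.

### Gaussian prefilter

The Visium converter smooths the image before pyramid construction to reduce
scanner artifacts.  The blur radius parameter is interpreted as the Gaussian
standard deviation in pixels (default 4), kernel truncated at 4σ, reflect
boundary; radius 0 is the identity.  "Radius" is genuinely ambiguous between
kernel extent and σ in common usage; σ was chosen because it is the sharper
contract and matches how scipy parameterizes the filter.

## Feature stores

`sparsify` splits a points × features matrix into per-column records (zeros
dropped, indices strictly increasing); NaNs are rejected rather than
silently imputed.  Each record is a sparse CSV text (`index,value` lines)
compressed with deflate; records are concatenated into `<name>.bin` and a
JSON sidecar `<name>.index.json` lists `{name, offset, length, n}` in write
order plus `n_points`, the overlay name, and (for categorical groups) the
code→label table.  One compressed record per feature makes byte ranges
non-overlapping and gap-free by construction, which validation re-checks.

Values are serialized as integers when integral and otherwise with Python's
shortest round-trip float representation, so a write→read cycle is exact —
the round-trip invariants (feature value equals ln(1+count); densify ∘ read ∘
write ∘ sparsify is the identity) hold bit-for-bit rather than to a printing
precision.  The same exact-repr choice applies to overlay CSVs, manifest
floats and annotation coordinates.

Counts from Visium are transformed as ln(1 + count).  The natural-log base
and unit pseudocount are the package's choice (log1p is the common
convention in the field's toolkits); no library-size normalization is
applied before the transform.  MERFISH counts are stored raw.

Categorical features ride the same machinery: labels are encoded as positive
integer codes (0 = unlabeled) against a stored table, so code 0 sparsifies
away exactly like a numeric zero.

## Converters

Visium: both tissue-position dialects (headerless 6-column and headered) are
sniffed by the presence of `barcode` in the first line.  Only `in_tissue = 1`
rows are kept; x/y come from the pixel *column*/*row* fields respectively.
The overlay is restricted to barcodes present in both the count matrix and
the in-tissue positions, **in count-matrix order**, so feature index i always
refers to overlay row i.  A counted barcode entirely absent from the
positions file aborts the conversion with examples.  The matrix is read from
the MatrixMarket triplet directory (`matrix.mtx`, `barcodes.tsv`,
`features.tsv`, optionally gzipped); HDF5 matrix containers are out of scope.

MERFISH: cell ids must agree exactly between the cell-by-gene table and the
metadata table (the error reports the set differences).  The affine CSV is
3×3 (a 2×3 file is promoted with bottom row 0,0,1), must be invertible, and
is applied as p_px = A·(x, y, 1)ᵀ.  No registration is performed — the
transform is taken as provided.

## Synthetic fixtures

The fixture module generates every input dialect the converters consume, as
a pure function of a seed (regeneration is bit-stable, which the tests
assert at the byte level).  Defaults describe a realistic small tissue
section: a 2000×2000 px image at 0.5 μm/px (so `spot_diameter_fullres` =
110 px), 50 spots on a hexagonal lattice with the 100/55 pitch-to-diameter
ratio of the real array plus 5 out-of-tissue rows, 20 genes, ~5% nonzero
density from log-uniform per-gene Poisson rates thinned to the target
density; MERFISH fixtures draw 100 cell centroids uniformly in a micron box
and map them through a known affine, storing the pixel truth alongside.

The fixtures emulate *format and geometry*, not biology: there are no
spatial expression domains, no marker-gene structure, no segmentation
errors, no image–coordinate misregistration.  Passing tests therefore
demonstrate that conversion, storage and readout are faithful and lazily
addressable — not that any biological signal is preserved beyond the values
themselves.

## Annotations

Native CSV schema: `label,geometry,data` with geometry ∈ {point, circle,
polygon} and coordinates space-separated inside the data field (polygon
vertices separated by `;`).  Circles store their diameter in μm and are
resolved to pixels at assignment time through the manifest scale, so the
same annotation file works across resolutions.  napari import maps the
(row, column) axis order to (y, x); shape tables keep polygon/rectangle
entries and skip geometries with no native counterpart.  Binary ROI
containers are out of scope.

Point-in-polygon uses the even-odd ray-crossing rule with boundary points
counted as inside (boundary detection via perpendicular distance below
1e-12 of the coordinate scale).  The tie-break for overlapping annotations
is first-record-wins; record order is user-meaningful.  Freestanding point
annotations mark locations and never capture overlay rows.

## Problem sizes and numerical choices

The test suite and acceptance script exercise: pyramids up to 4096² (256
tiles) for the byte-accounting bounds, 1024² three-channel images for the
lossless and JPEG round trips, feature stores of 2000 points × 500 genes at
5% density (exhaustive read-back), the 50-spot × 20-gene Visium and
100-cell × 30-gene MERFISH conversions end to end, 20 random star-shaped
simple polygons × 1000 points against an independent winding-number oracle,
and 100 randomized annotation sets.  These sizes make every check exact or
counter-based rather than statistical.

Known limitations: classic (32-bit offset) TIFF caps a pyramid file at 4 GiB;
JPEG tiles are uint8 grayscale per plane; manifests resolve local folders
only (remote access is exercised through the range-reader abstraction, not
URL manifests); no z-stack or time-series annotation frames.
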