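"""Class-level landscape pattern metrics from categorical rasters.

Implements the six indices used to characterise green and water patches —
patch count (NP), patch density (PD, patches per km^2), mean patch area
(AREA_MN, hectares), largest patch index (LPI, percent of landscape),
landscape shape index (LSI) and aggregation index (AI, percent) — with the
standard FRAGSTATS raster definitions:

* ``LSI = 0.25 * E / sqrt(A)`` with class edge length ``E`` and class area
  ``A`` in cell units; edges on the landscape boundary count.
* ``AI = 100 * g / g_max`` where ``g`` is the number of like adjacencies
  (4-neighbour, each shared edge counted once) and ``g_max`` is the maximum
  attainable for the class cell count via the largest-integer-square
  construction.

Patches are maximal connected components, 8-connected by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CategoricalRaster",
    "PatchSet",
    "LandscapeMetricsRecord",
    "label_patches",
    "class_metrics",
    "all_class_metrics",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_tiff",
    "write_tiff",
    "max_like_adjacencies",
]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CategoricalRaster:
    """Single-band integer raster with square cells.

    ``grid`` holds non-negative class labels; ``nodata_label`` marks cells
    outside the landscape (excluded from every area/edge count).
    """

    grid: np.ndarray
    cell_size_m: float
    nodata_label: int = -1

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("raster grid must be a 2-D rectangular array")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("raster grid must hold integer class labels")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        object.__setattr__(self, "grid", grid)

    @property
    def landscape_mask(self) -> np.ndarray:
        return self.grid != self.nodata_label

    @property
    def landscape_cells(self) -> int:
        return int(self.landscape_mask.sum())

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m ** 2

    def classes(self) -> list[int]:
        vals = np.unique(self.grid[self.landscape_mask])
        return [int(v) for v in vals]


@dataclass
class PatchSet:
    """Connected components of one class: disjoint, maximal, exhaustive."""

    class_label: int
    connectivity: int
    patches: list[frozenset] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def cell_counts(self) -> list[int]:
        return [len(p) for p in self.patches]


@dataclass(frozen=True)
class LandscapeMetricsRecord:
    """The six class-level indices; NaN marks metrics undefined for an
    empty class (everything except NP and PD)."""

    np: int
    pd: float
    area_mn: float
    lpi: float
    lsi: float
    ai: float

    def as_dict(self) -> dict[str, float]:
        return {"np": self.np, "pd": self.pd, "area_mn": self.area_mn,
                "lpi": self.lpi, "lsi": self.lsi, "ai": self.ai}


def label_patches(raster: CategoricalRaster, class_label: int,
                  connectivity: int = 8) -> PatchSet:
    """Label maximal connected components of ``class_label``.

    ``connectivity`` 8 (queen, default) or 4 (rook).  An absent class yields
    an empty patch set.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    mask = (raster.grid == class_label) & raster.landscape_mask
    labeled, n = ndimage.label(mask, structure=structure)
    patches = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(labeled == i)
        patches.append(frozenset(zip(rr.tolist(), cc.tolist())))
    return PatchSet(class_label=class_label, connectivity=connectivity,
                    patches=patches)


def _class_edge_cells(mask: np.ndarray) -> int:
    """Total class edge length in cell-edge units.

    Counts every 4-neighbour boundary between a class cell and a non-class
    cell, plus class edges on the grid/landscape boundary (nodata cells and
    the outside world both count as non-class)."""
    padded = np.pad(mask, 1, constant_values=False)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(padded, shift, axis=axis)
        edges += int((padded & ~neigh).sum())
    return edges


def _like_adjacencies(mask: np.ndarray) -> int:
    """Number of shared edges between same-class cell pairs (counted once)."""
    horiz = int((mask[:, :-1] & mask[:, 1:]).sum())
    vert = int((mask[:-1, :] & mask[1:, :]).sum())
    return horiz + vert


def max_like_adjacencies(n_cells: int) -> int:
    """Maximum 4-adjacency count attainable by ``n_cells`` cells.

    Largest-integer-square construction: with ``n = floor(sqrt(A))`` and
    ``m = A - n^2``, g_max = 2n(n-1), plus 2m-1 if 0 < m <= n, plus 2m-2 if
    m > n.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    n = math.isqrt(n_cells)
    m = n_cells - n * n
    g = 2 * n * (n - 1)
    if m == 0:
        return g
    if m <= n:
        return g + 2 * m - 1
    return g + 2 * m - 2


def class_metrics(patches: PatchSet, raster: CategoricalRaster) -> LandscapeMetricsRecord:
    """Compute the six class-level indices for a labeled class.

    Empty class: NP = 0, PD = 0, remaining metrics NaN (undefined, not
    zero).  A single-cell class has AI undefined (g_max = 0) and is
    reported as NaN.
    """
    if raster.landscape_cells < 1:
        raise ValueError("raster has no landscape cells")
    n_patches = len(patches)
    cell_area = raster.cell_area_m2
    landscape_km2 = raster.landscape_cells * cell_area / 1e6
    if n_patches == 0:
        return LandscapeMetricsRecord(np=0, pd=0.0, area_mn=math.nan,
                                      lpi=math.nan, lsi=math.nan, ai=math.nan)

    counts = np.array(patches.cell_counts)
    class_cells = int(counts.sum())
    mask = (raster.grid == patches.class_label) & raster.landscape_mask

    pd_ = n_patches / landscape_km2
    area_mn = counts.mean() * cell_area / 1e4          # hectares
    lpi = 100.0 * counts.max() / raster.landscape_cells
    edge = _class_edge_cells(mask)
    lsi = 0.25 * edge / math.sqrt(class_cells)
    g = _like_adjacencies(mask)
    g_max = max_like_adjacencies(class_cells)
    ai = 100.0 * g / g_max if g_max > 0 else math.nan
    return LandscapeMetricsRecord(np=n_patches, pd=pd_, area_mn=area_mn,
                                  lpi=lpi, lsi=lsi, ai=ai)


def all_class_metrics(raster: CategoricalRaster, connectivity: int = 8,
                      classes: list[int] | None = None
                      ) -> dict[int, LandscapeMetricsRecord]:
    """Metrics for every class present (or the requested subset)."""
    if classes is None:
        classes = [c for c in raster.classes() if c != 0]
    return {c: class_metrics(label_patches(raster, c, connectivity), raster)
            for c in classes}


# ---------------------------------------------------------------------------
# I/O: whitespace ASCII grid with a 2-line header, and single-band TIFF.

def write_ascii_grid(path, raster: CategoricalRaster) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"cell_size_m {raster.cell_size_m!r}\n")
        fh.write(f"nodata_label {raster.nodata_label}\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path) -> CategoricalRaster:
    with open(path, encoding="utf-8") as fh:
        header = {}
        for _ in range(2):
            key, val = fh.readline().split()
            header[key] = val
        grid = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    return CategoricalRaster(grid=grid,
                             cell_size_m=float(header["cell_size_m"]),
                             nodata_label=int(header["nodata_label"]))


def write_tiff(path, raster: CategoricalRaster) -> None:
    """Single-band integer TIFF (no geo-tags; cell size kept in metadata)."""
    import tifffile

    tifffile.imwrite(path, raster.grid.astype(np.int32),
                     metadata={"cell_size_m": raster.cell_size_m,
                               "nodata_label": raster.nodata_label})


def read_tiff(path, cell_size_m: float | None = None,
              nodata_label: int | None = None) -> CategoricalRaster:
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        grid = tf.asarray()
        meta = {}
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    return CategoricalRaster(
        grid=np.asarray(grid, dtype=np.int64),
        cell_size_m=cell_size_m if cell_size_m is not None
        else float(meta.get("cell_size_m", 1.0)),
        nodata_label=nodata_label if nodata_label is not None
        else int(meta.get("nodata_label", -1)),
    )
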