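"""Synthetic data generators with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_indicator_series` builds a yearly indicator matrix as
  linear trend + independent Gaussian noise per indicator, together with
  the composite-index truth series computed through the *same* min-max
  normalization and weighted-sum pathway as the real pipeline — so weight
  recovery and model fitting can be checked against a known answer.
* :func:`generate_raster` grows categorical patches on a grid by seeded
  region growing and reports the realized layout, giving landscape-metric
  oracles exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import lqci_series, normalize
from .landscape import CategoricalRaster

__all__ = [
    "SyntheticSpec",
    "generate_indicator_series",
    "PatchRequest",
    "RasterGenerationError",
    "generate_raster",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic indicator study.

    Per-indicator arrays (``trend_slopes``, ``noise_sd``, ``true_weights``,
    ``intercepts``) are broadcast from scalars.  ``true_weights`` are in
    percent, like the printed indicator weights.  Same spec + same seed
    always produces identical output.
    """

    n_years: int = 8
    n_indicators: int = 17
    trend_slopes: tuple | float = 1.0
    noise_sd: tuple | float = 0.05
    true_weights: tuple | float = 2.0
    intercepts: tuple | float = 10.0
    start_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.n_indicators < 1:
            raise ValueError("n_indicators must be >= 1")
        if np.any(np.asarray(self.noise_sd, dtype=float) < 0):
            raise ValueError("noise_sd must be >= 0")

    def _vec(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.n_indicators,))
        return np.array(arr)


def generate_indicator_series(spec: SyntheticSpec
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Generate (raw yearly matrix, truth composite series).

    Raw value of indicator j in year-index i is
    ``intercept_j + slope_j * i + N(0, sd_j)``.  The truth series is
    computed from the generated matrix via min-max normalization (benefit
    polarity) and the weighted sum with ``true_weights`` — the same code
    path the real pipeline uses.
    """
    slopes = spec._vec(spec.trend_slopes)
    sds = spec._vec(spec.noise_sd)
    weights = spec._vec(spec.true_weights)
    intercepts = spec._vec(spec.intercepts)
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_years)[:, None]
    raw = intercepts + slopes * t + rng.normal(0.0, 1.0, (spec.n_years, spec.n_indicators)) * sds
    years = list(range(spec.start_year, spec.start_year + spec.n_years))
    df = pd.DataFrame(raw, index=years,
                      columns=[f"X{j+1}" for j in range(spec.n_indicators)])
    df.index.name = "Year"
    truth = lqci_series(normalize(df, "benefit"), weights)
    return df, truth


@dataclass(frozen=True)
class PatchRequest:
    """One class's requested patch layout for the raster generator.

    ``aggregation`` in [0, 1]: 0 grows patches by uniform frontier choice
    (ragged), 1 always extends at the frontier cell with the most same-patch
    neighbours (compact).
    """

    class_label: int
    n_patches: int
    mean_patch_cells: int
    aggregation: float = 0.5

    def __post_init__(self) -> None:
        if self.class_label <= 0:
            raise ValueError("class_label must be positive (0 is background)")
        if self.n_patches < 0 or self.mean_patch_cells < 1:
            raise ValueError("invalid patch request")
        if not (0 <= self.aggregation <= 1):
            raise ValueError("aggregation must be in [0, 1]")


class RasterGenerationError(RuntimeError):
    """Patch packing failed within the retry budget."""


@dataclass
class RasterTruth:
    """Realized layout the generator reports as oracle ground truth."""

    patches: dict[int, list[frozenset]] = field(default_factory=dict)

    def patch_count(self, class_label: int) -> int:
        return len(self.patches.get(class_label, []))


_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
_NEIGHBORS4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def generate_raster(n_rows: int, n_cols: int, cell_size_m: float,
                    class_patches: list[PatchRequest], seed: int = 0,
                    max_retries: int = 200
                    ) -> tuple[CategoricalRaster, RasterTruth]:
    """Grow the requested patches on a background-0 grid.

    Patches of the same class are kept 8-disconnected from each other (a
    one-cell moat), so the reported patch count is exact under both 4- and
    8-connectivity.  Raises :class:`RasterGenerationError` when a patch
    cannot be placed within ``max_retries`` seeded attempts.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("raster dimensions must be >= 1")
    total_cells = sum(r.n_patches * r.mean_patch_cells for r in class_patches)
    if total_cells > n_rows * n_cols:
        raise RasterGenerationError(
            f"requested {total_cells} patch cells exceed grid size "
            f"{n_rows * n_cols}")
    rng = np.random.default_rng(seed)
    grid = np.zeros((n_rows, n_cols), dtype=np.int64)
    # blocked[r, c]: no same-class patch may use this cell (moat or taken)
    truth = RasterTruth()
    for req in class_patches:
        truth.patches.setdefault(req.class_label, [])
        for _ in range(req.n_patches):
            placed = _grow_one_patch(grid, req, rng, max_retries)
            truth.patches[req.class_label].append(placed)
    return CategoricalRaster(grid=grid, cell_size_m=cell_size_m), truth


def _grow_one_patch(grid: np.ndarray, req: PatchRequest,
                    rng: np.random.Generator, max_retries: int) -> frozenset:
    n_rows, n_cols = grid.shape
    target = req.mean_patch_cells

    def free(r, c):
        # free for this patch: background cell not 8-touching the same class
        if grid[r, c] != 0:
            return False
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and grid[rr, cc] == req.class_label:
                return False
        return True

    for _ in range(max_retries):
        r0 = int(rng.integers(n_rows))
        c0 = int(rng.integers(n_cols))
        if not free(r0, c0):
            continue
        cells = {(r0, c0)}
        ok = True
        while len(cells) < target:
            frontier = []
            for (r, c) in cells:
                for dr, dc in _NEIGHBORS4:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < n_rows and 0 <= cc < n_cols
                            and (rr, cc) not in cells and free(rr, cc)):
                        # candidate must not touch the same class elsewhere
                        frontier.append((rr, cc))
            if not frontier:
                ok = False
                break
            if rng.random() < req.aggregation:
                # prefer the candidate with most neighbours already in patch
                scores = [sum((rr + dr, cc + dc) in cells
                              for dr, dc in _NEIGHBORS4)
                          for rr, cc in frontier]
                best = max(scores)
                choices = [f for f, s in zip(frontier, scores) if s == best]
            else:
                choices = frontier
            cells.add(choices[int(rng.integers(len(choices)))])
        if ok:
            for (r, c) in cells:
                grid[r, c] = req.class_label
            return frozenset(cells)
    raise RasterGenerationError(
        f"could not place a {target}-cell patch of class {req.class_label} "
        f"after {max_retries} attempts (grid too crowded)")
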