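import numpy as np
import pytest

from lqci.study import load_study_samples


@pytest.fixture(scope="session")
def study_data():
    """The 8-year, 17-input study matrix and its truth targets."""
    X, y, years = load_study_samples()
    return X, y, years


def flood_fill_patches(grid, class_label, connectivity):
    """Independent brute-force connected-components oracle (no scipy)."""
    rows, cols = grid.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = set()
    patches = []
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] != class_label or (r, c) in seen:
                continue
            stack = [(r, c)]
            seen.add((r, c))
            comp = set()
            while stack:
                rr, cc = stack.pop()
                comp.add((rr, cc))
                for dr, dc in neigh:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < rows and 0 <= nc < cols
                            and grid[nr, nc] == class_label
                            and (nr, nc) not in seen):
                        seen.add((nr, nc))
                        stack.append((nr, nc))
            patches.append(frozenset(comp))
    return patches


def brute_force_class_metrics(grid, class_label, cell_size_m=100.0,
                              connectivity=8):
    """Cell-by-cell enumeration oracle for all six class metrics."""
    import math

    patches = flood_fill_patches(grid, class_label, connectivity)
    rows, cols = grid.shape
    landscape_cells = rows * cols  # oracle assumes no nodata
    landscape_km2 = landscape_cells * cell_size_m ** 2 / 1e6
    n = len(patches)
    if n == 0:
        return {"np": 0, "pd": 0.0, "area_mn": math.nan, "lpi": math.nan,
                "lsi": math.nan, "ai": math.nan}
    sizes = [len(p) for p in patches]
    area = sum(sizes)
    # edges: walk every class cell's 4 sides
    edge = 0
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] != class_label:
                continue
            for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or \
                        grid[nr, nc] != class_label:
                    edge += 1
    g = 0
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] != class_label:
                continue
            if c + 1 < cols and grid[r, c + 1] == class_label:
                g += 1
            if r + 1 < rows and grid[r + 1, c] == class_label:
                g += 1
    k = math.isqrt(area)
    m = area - k * k
    gmax = 2 * k * (k - 1)
    if m > 0:
        gmax += 2 * m - 1 if m <= k else 2 * m - 2
    return {
        "np": n,
        "pd": n / landscape_km2,
        "area_mn": (area / n) * cell_size_m ** 2 / 1e4,
        "lpi": 100.0 * max(sizes) / landscape_cells,
        "lsi": 0.25 * edge / math.sqrt(area),
        "ai": 100.0 * g / gmax if gmax > 0 else math.nan,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
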