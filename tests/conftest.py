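import heapq

import numpy as np
import pytest

from hfmap.grid import GridSpec
from hfmap.pipeline import run_pipeline
from hfmap.synthetic import generate_landscape


def make_grid(n_rows: int, n_cols: int, pixel: float = 30.0, crs: str = "EPSG:32718") -> GridSpec:
    """Grid with origin at (0, n_rows * pixel) so map coords are simple."""
    return GridSpec(crs, 0.0, n_rows * pixel, n_rows, n_cols, pixel)


@pytest.fixture(scope="session")
def bundle():
    """Default desk-scale synthetic landscape (500x500 at 30 m)."""
    return generate_landscape(1)


@pytest.fixture(scope="session")
def pipe(bundle):
    """Full pipeline result on the default landscape."""
    return run_pipeline(bundle)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_landscape(2, make_grid(120, 120))


def dijkstra_travel_time(cost: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Brute-force multi-source Dijkstra oracle, independent of the package.

    4-connected moves; step cost is the mean of the two pixels' crossing
    times; source pixels traverse at zero cost and start at time zero.
    """
    n_rows, n_cols = cost.shape
    c = cost.astype(float).copy()
    c[sources] = 0.0
    dist = np.full(cost.shape, np.inf)
    heap = []
    for r, col in np.argwhere(sources):
        dist[r, col] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(col)))
    while heap:
        d, r, col = heapq.heappop(heap)
        if d > dist[r, col]:
            continue
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, col + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols:
                nd = d + (c[r, col] + c[nr, nc]) / 2.0
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    return dist


@pytest.fixture
def dijkstra_oracle():
    return dijkstra_travel_time
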