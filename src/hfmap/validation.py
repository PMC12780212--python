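"""Map-accuracy assessment against visually interpreted plots.

The protocol: stratify a reference human-influence map into four strata
(breaks 4 / 8 / 18), allocate a total sample across strata by compromise
allocation (proportional, then small strata boosted to a floor), draw plot
locations by stratified random sampling (300 m square plots with 5 km
context buffers), score each plot visually per pressure (areas 0–3 by
coverage, lines/points 0–3 by occurrences, indirect pressure 0/1 by presence
in the buffer), standardize the visual scores against the per-pressure score
maxima into a [0, 1] index, and compare it with the normalized HF index via
a tolerance kappa (agreement when scores differ by less than 20% of the
scale), RMSE and R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import HFError
from .grid import RasterLayer

STRATA_BREAKS = (4.0, 8.0, 18.0)
STRATA_NAMES = {1: "very_low", 2: "low", 3: "medium", 4: "high"}

#: standardized stand-in value for an observed indirect pressure
INDIRECT_VISUAL_VALUE = 2.0


def stratify(reference: RasterLayer, breaks: Sequence[float] = STRATA_BREAKS) -> RasterLayer:
    """Reclassify a reference human-influence map into sampling strata.

    Very low < 4 ≤ low < 8 ≤ medium < 18 ≤ high.  The top stratum is
    everything at or above the last break.
    """
    valid = ~reference.nodata_mask
    if np.any(reference.values[valid] < 0):
        raise HFError("reference index cannot be negative")
    codes = np.digitize(reference.values, list(breaks)) + 1
    codes = codes.astype(np.int64)
    codes[~valid] = 255
    return RasterLayer(reference.grid, codes, "categorical", 255)


def allocate_samples(
    strata_areas: Sequence[float], total_n: int, min_per_stratum: int = 0
) -> list[int]:
    """Compromise allocation: proportional to stratum area, then every
    stratum raised to ``min_per_stratum`` with the excess taken from the
    largest strata; counts always sum to ``total_n``."""
    areas = np.asarray(strata_areas, dtype=float)
    k = len(areas)
    if k == 0 or np.any(areas < 0) or areas.sum() <= 0:
        raise HFError("strata areas must be non-negative with positive total")
    if total_n < k * min_per_stratum:
        raise HFError(
            f"total_n={total_n} cannot give {k} strata at least {min_per_stratum} each"
        )
    # proportional allocation, largest-remainder rounding to hit total_n
    quota = areas / areas.sum() * total_n
    counts = np.floor(quota).astype(int)
    remainder = total_n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    # boost small strata to the floor, taking from the currently largest
    counts = np.maximum(counts, 0)
    for i in range(k):
        while counts[i] < min_per_stratum:
            donor = int(np.argmax(counts))
            if counts[donor] <= min_per_stratum:
                raise HFError("allocation floor infeasible for the requested total")
            counts[donor] -= 1
            counts[i] += 1
    assert counts.sum() == total_n
    return counts.tolist()


@dataclass
class ValidationPlot:
    """One sample plot: location, stratum, visual scores and extracted HF."""

    x: float
    y: float
    row: int
    col: int
    stratum: str
    plot_size_m: float = 300.0
    buffer_radius_m: float = 5000.0
    visual_scores: dict = field(default_factory=dict)
    certain: bool = True
    visual_index: float | None = None
    hf_value: float | None = None


def draw_plots(
    strata: RasterLayer,
    counts: Sequence[int],
    seed: int,
    plot_size_m: float = 300.0,
    buffer_radius_m: float = 5000.0,
) -> list[ValidationPlot]:
    """Stratified random plot draw: per stratum, pixels uniformly without
    replacement; plot centers at pixel centers."""
    rng = np.random.default_rng(seed)
    plots: list[ValidationPlot] = []
    for code, name in STRATA_NAMES.items():
        n = counts[code - 1] if code - 1 < len(counts) else 0
        if n == 0:
            continue
        rows, cols = np.nonzero(strata.values == code)
        if len(rows) < n:
            raise HFError(
                f"stratum {name!r} has {len(rows)} pixels but {n} samples requested"
            )
        pick = rng.choice(len(rows), size=n, replace=False)
        for idx in pick:
            r, c = int(rows[idx]), int(cols[idx])
            x, y = strata.grid.pixel_center(r, c)
            plots.append(ValidationPlot(x, y, r, c, name, plot_size_m, buffer_radius_m))
    return plots


def standardize_visual(
    scores: Mapping[str, Sequence[float]],
    max_scores: Mapping[str, float],
    indirect_value: float = INDIRECT_VISUAL_VALUE,
) -> float:
    """Standardize per-pressure visual scores into a [0, 1] index.

    ``scores`` maps a pressure id to the visual scores (0–3) of its
    components; the ``IND`` entry holds a 0/1 presence flag which maps to
    ``indirect_value``.  Components are standardized to the pressure's score
    maximum, combined by maximum within the pressure, summed across pressures
    and divided by the sum of the pressure maxima.
    """
    total = 0.0
    for pid, max_score in max_scores.items():
        comps = scores.get(pid, ())
        comps = np.atleast_1d(np.asarray(comps, dtype=float))
        if comps.size == 0:
            continue
        if pid == "IND":
            if np.any((comps != 0) & (comps != 1)):
                raise HFError("indirect visual score must be 0 or 1 (presence)")
            value = indirect_value if comps.max() > 0 else 0.0
        else:
            if np.any(comps < 0) or np.any(comps > 3):
                raise HFError(f"pressure {pid}: visual scores must lie in [0, 3]")
            value = float(comps.max() / 3.0 * max_score)
        total += min(value, max_score)
    denom = float(sum(max_scores.values()))
    if denom <= 0:
        raise HFError("pressure maxima must sum to a positive value")
    return total / denom


def tolerance_kappa(
    a: Sequence[float], b: Sequence[float], tolerance: float = 0.20, chunk: int = 1024
) -> float:
    """Chance-corrected agreement of two continuous [0, 1] score vectors.

    Two scores agree when they differ by less than ``tolerance``.  Observed
    agreement is the paired agreement rate; chance agreement is the agreement
    rate over all ordered cross pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise HFError("tolerance_kappa needs two equal-length vectors, length >= 2")
    p_o = float(np.mean(np.abs(a - b) < tolerance))
    agree = 0
    for start in range(0, len(a), chunk):
        block = a[start : start + chunk, None]
        agree += int(np.count_nonzero(np.abs(block - b[None, :]) < tolerance))
    p_e = agree / (len(a) * len(b))
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise HFError("chance agreement is 1 (constant scores); kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def error_metrics(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """RMSE of the paired differences and R² (squared Pearson correlation).

    With zero variance in either vector R² is undefined: a warning is raised
    and NaN returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise HFError("error_metrics needs two equal-length vectors, length >= 3")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: R^2 undefined")
        return rmse, float("nan")
    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    return rmse, r2


@dataclass
class ValidationMetrics:
    kappa: float
    rmse: float
    r2: float
    tolerance: float = 0.20
    n_plots: int = 0


def extract_hf_at_plots(plots: list[ValidationPlot], hf_raster: RasterLayer) -> None:
    """Read the HF value at each plot's center pixel (in place)."""
    for p in plots:
        v = hf_raster.values[p.row, p.col]
        p.hf_value = None if v == hf_raster.nodata else float(v)


def evaluate_plots(
    plots: list[ValidationPlot],
    max_scores: Mapping[str, float],
    tolerance: float = 0.20,
) -> ValidationMetrics:
    """Compute the agreement metrics over certain plots with both scores.

    Visual indices are computed via :func:`standardize_visual` where absent;
    HF values are normalized by the sum of the pressure maxima so both
    vectors share the [0, 1] scale.
    """
    denom = float(sum(max_scores.values()))
    visual, hf = [], []
    for p in plots:
        if not p.certain or p.hf_value is None:
            continue
        if p.visual_index is None:
            p.visual_index = standardize_visual(p.visual_scores, max_scores)
        visual.append(p.visual_index)
        hf.append(p.hf_value / denom)
    if len(visual) < 3:
        raise HFError(f"only {len(visual)} usable plots; need at least 3")
    kappa = tolerance_kappa(visual, hf, tolerance)
    rmse, r2 = error_metrics(visual, hf)
    return ValidationMetrics(kappa, rmse, r2, tolerance, len(visual))
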