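"""Uniform square binning of registered marker coordinates.

The bin area follows the twice-expected-frequency rule for random spatial
fields: bin_area = 2 * sampling_area / n, giving an expected count of 2 per
bin under uniform intensity.  Counting uses half-open intervals
[edge_i, edge_{i+1}) on both axes with the terminal edge closed — the
standard histogram convention, so no point is double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely

from .geometry import Contour, as_points

logger = logging.getLogger(__name__)

_EDGE_TOL = 1e-6  # um; uniform-spacing tolerance on grid edges


class BinSpec(NamedTuple):
    bin_area: float  # um^2
    bin_side: float  # um


def optimal_bin_area(contour_area: float, mean_count: float) -> BinSpec:
    """Bin area from the 2*A/n rule; side length of the square bin.

    ``mean_count`` is the mean number of items (e.g. activated neurons) per
    subject by default; callers wanting the pooled-total variant pass that
    total instead.
    """
    if contour_area <= 0:
        raise ValueError("contour_area must be positive")
    if mean_count <= 0:
        raise ValueError(
            "mean_count must be positive; with no items the formula is "
            "undefined — choose a manual bin size instead")
    area = 2.0 * contour_area / mean_count
    return BinSpec(float(area), float(np.sqrt(area)))


@dataclass
class MarkerSet:
    """One subject/section/region's marker coordinates in a registered frame."""

    subject_id: str
    condition: str
    bregma_mm: float
    region: str
    points: np.ndarray
    z: np.ndarray | None = None
    registered: bool = True

    def __post_init__(self) -> None:
        self.points = as_points(self.points)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (len(self.points),):
                raise ValueError("z must have one value per point")

    @property
    def n_markers(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class BinGrid:
    """Uniform square-bin grid defined by its x and y edges (um)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_side: float
    overhang_x: bool = False  # last edge extends past the requested max
    overhang_y: bool = False

    def __post_init__(self) -> None:
        for name in ("x_edges", "y_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.ndim != 1 or len(edges) < 2:
                raise ValueError(f"{name} must contain at least 2 edges")
            step = np.diff(edges)
            if np.any(np.abs(step - self.bin_side) > _EDGE_TOL):
                raise ValueError(f"{name} spacing is not uniformly bin_side")
            object.__setattr__(self, name, edges)
        if self.bin_side <= 0:
            raise ValueError("bin_side must be positive")

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def n_bins(self) -> int:
        return self.nx * self.ny

    @property
    def bin_area(self) -> float:
        return self.bin_side ** 2

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def column_labels(self) -> list[str]:
        """Flattened row-major (x index outer) bin column names."""
        return [f"bin_{i}_{j}" for i in range(self.nx) for j in range(self.ny)]

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) centre coordinates matching the flattened order."""
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.column_stack([xc.ravel(), yc.ravel()])

    def contour_mask(self, contour: Contour) -> np.ndarray:
        """(nx, ny) True where the bin cell intersects the contour.

        Bins wholly outside the contour are flagged False so statistics can
        exclude them from the multiple-testing family.
        """
        mask = np.zeros((self.nx, self.ny), dtype=bool)
        poly = contour.polygon
        for i in range(self.nx):
            for j in range(self.ny):
                cell = shapely.box(self.x_edges[i], self.y_edges[j],
                                   self.x_edges[i + 1], self.y_edges[j + 1])
                mask[i, j] = poly.intersects(cell) and not poly.touches(cell)
        return mask


def build_grid(
    x_min: float, x_max: float, y_min: float, y_max: float, bin_side: float
) -> BinGrid:
    """Grid of square bins starting at (x_min, y_min) covering both ranges.

    The final edge on each axis may overhang the requested maximum so the
    largest coordinate is always covered; overhang is flagged on the grid.
    """
    if bin_side <= 0:
        raise ValueError("bin_side must be positive")
    if x_max <= x_min or y_max <= y_min:
        raise ValueError("max must exceed min on both axes")

    def axis_edges(lo: float, hi: float) -> tuple[np.ndarray, bool]:
        span = hi - lo
        n = int(np.ceil(span / bin_side - _EDGE_TOL))
        n = max(n, 1)
        edges = lo + bin_side * np.arange(n + 1)
        overhang = edges[-1] > hi + _EDGE_TOL
        return edges, overhang

    x_edges, ox = axis_edges(x_min, x_max)
    y_edges, oy = axis_edges(y_min, y_max)
    if ox or oy:
        logger.info("grid overhang: last bin extends past the data maximum "
                    "(x=%s, y=%s)", ox, oy)
    return BinGrid(x_edges, y_edges, float(bin_side), ox, oy)


def grid_from_marker_sets(
    marker_sets: Sequence[MarkerSet],
    bin_side: float,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> BinGrid:
    """Grid covering the pooled coordinate extent of all marker sets.

    Extent defaults to the pooled min/max of every subject's coordinates;
    either axis range can be overridden to mimic manual bin-end entry.
    """
    pooled = [m.points for m in marker_sets if m.n_markers]
    if not pooled and (x_range is None or y_range is None):
        raise ValueError("no markers to infer grid extent from; pass ranges")
    allpts = np.vstack(pooled) if pooled else np.zeros((0, 2))
    x_min, x_max = x_range if x_range else (allpts[:, 0].min(), allpts[:, 0].max())
    y_min, y_max = y_range if y_range else (allpts[:, 1].min(), allpts[:, 1].max())
    if x_max == x_min:
        x_max = x_min + bin_side
    if y_max == y_min:
        y_max = y_min + bin_side
    return build_grid(x_min, x_max, y_min, y_max, bin_side)


class BinCounts(NamedTuple):
    counts: np.ndarray   # (nx, ny) integer counts
    n_inside: int
    n_outside: int       # markers outside the grid extent, reported not dropped


def bin_counts(markers: MarkerSet, grid: BinGrid) -> BinCounts:
    """2D frequency counts of one marker set on the grid.

    Points on an interior shared edge belong to the higher-index bin; points
    exactly on the terminal edge belong to the last bin.  Points outside the
    grid extent are counted and reported, never silently dropped.
    """
    if not markers.registered:
        raise ValueError(
            f"marker set {markers.subject_id!r} is not registered; "
            "run register_to_anchor before binning")
    pts = markers.points
    if len(pts) == 0:
        return BinCounts(np.zeros((grid.nx, grid.ny), dtype=np.int64), 0, 0)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                  bins=[grid.x_edges, grid.y_edges])
    counts = counts.astype(np.int64)
    n_inside = int(counts.sum())
    n_outside = len(pts) - n_inside
    if n_outside:
        logger.warning("subject %s: %d markers outside the grid extent",
                       markers.subject_id, n_outside)
    return BinCounts(counts, n_inside, n_outside)


@dataclass
class BinMatrix:
    """Rows of flattened per-bin counts, one per (subject, section).

    ``values`` is (n_rows, nx*ny) in the grid's flattened row-major order;
    ``meta`` carries subject_id, condition, bregma_mm, region, n_markers and
    n_outside per row, aligned with ``values``.
    """

    grid: BinGrid
    values: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_bins:
            raise ValueError("values shape does not match the grid")
        if len(self.meta) != len(self.values):
            raise ValueError("meta rows must align with value rows")
        if (self.values < 0).any():
            raise ValueError("negative counts")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.meta["condition"].unique())

    def rows_for(self, condition: str) -> np.ndarray:
        sel = (self.meta["condition"] == condition).to_numpy()
        if not sel.any():
            raise KeyError(
                f"unknown condition {condition!r}; available: {self.conditions}")
        return self.values[sel]

    def subject_averaged(self) -> "BinMatrix":
        """One row per subject: multiple sections at a plane are averaged.

        Statistical tests require each individual to appear once, so this is
        the canonical input to the testing layer.
        """
        df = self.meta.copy()
        df["_row"] = np.arange(len(df))
        rows, meta_rows = [], []
        for (cond, subj), grp in df.groupby(["condition", "subject_id"], sort=True):
            rows.append(self.values[grp["_row"].to_numpy()].mean(axis=0))
            meta_rows.append({
                "subject_id": subj, "condition": cond,
                "bregma_mm": grp["bregma_mm"].iloc[0],
                "region": grp["region"].iloc[0],
                "n_markers": int(grp["n_markers"].sum()),
                "n_outside": int(grp["n_outside"].sum()),
            })
        return BinMatrix(self.grid, np.array(rows), pd.DataFrame(meta_rows))

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.grid.column_labels()
        out = pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.values, columns=cols)], axis=1)
        return out


def assemble_matrix(
    marker_sets: Sequence[MarkerSet],
    grid: BinGrid,
    allow_mixed: bool = False,
) -> BinMatrix:
    """Stack per-marker-set bin counts into one matrix on a shared grid.

    Rows are ordered deterministically by (condition, subject_id).  Mixing
    Bregma planes or regions is an error unless explicitly allowed.
    """
    if not marker_sets:
        raise ValueError("no marker sets given")
    if not allow_mixed:
        planes = {m.bregma_mm for m in marker_sets}
        regions = {m.region for m in marker_sets}
        if len(planes) > 1 or len(regions) > 1:
            raise ValueError(
                f"marker sets mix planes {sorted(planes)} / regions "
                f"{sorted(regions)}; pass allow_mixed=True to override")
    ordered = sorted(marker_sets, key=lambda m: (m.condition, m.subject_id))
    rows, meta = [], []
    for m in ordered:
        bc = bin_counts(m, grid)
        rows.append(bc.counts.ravel())
        meta.append({"subject_id": m.subject_id, "condition": m.condition,
                     "bregma_mm": m.bregma_mm, "region": m.region,
                     "n_markers": m.n_markers, "n_outside": bc.n_outside})
    return BinMatrix(grid, np.array(rows, dtype=np.int64), pd.DataFrame(meta))
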