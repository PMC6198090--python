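"""Mean, SD, CV, difference and q-value maps over a bin grid, plus rendering.

Every rendered image is accompanied by a machine-readable sidecar table of
the exact per-bin values used, so visual outputs always carry testable
numbers.  CV uses the sample (n-1) standard deviation; bins with zero mean
are masked invalid rather than forced to 0 or infinity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .binning import BinGrid, BinMatrix
from .geometry import Contour

VALID_STATISTICS = ("mean", "sd", "cv", "difference", "qvalue")


@dataclass
class DensityMap:
    """Per-bin statistic on a bin grid.

    ``values`` has shape (nx, ny); ``mask`` is True where the value is
    defined.  Units are neurons/bin for mean and difference maps, unitless
    for CV, and q for q-value maps.
    """

    grid: BinGrid
    values: np.ndarray
    statistic: str
    conditions: tuple[str, ...]
    n_subjects: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.statistic not in VALID_STATISTICS:
            raise ValueError(f"statistic must be one of {VALID_STATISTICS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("values shape must be (nx, ny)")
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite values inside the valid mask")

    def to_frame(self) -> pd.DataFrame:
        """Long-format sidecar table: one row per bin."""
        rows = []
        for i in range(self.grid.nx):
            for j in range(self.grid.ny):
                rows.append({
                    "bin_i": i, "bin_j": j,
                    "x_center_um": self.grid.x_centers[i],
                    "y_center_um": self.grid.y_centers[j],
                    "value": self.values[i, j] if self.mask[i, j] else np.nan,
                    "valid": bool(self.mask[i, j]),
                })
        return pd.DataFrame(rows)


def _condition_rows(matrix: BinMatrix, condition: str) -> np.ndarray:
    return matrix.rows_for(condition).astype(float)


def mean_map(matrix: BinMatrix, condition: str, normalize: bool = False) -> DensityMap:
    """Per-bin arithmetic mean across one condition's rows.

    With ``normalize`` each row is first divided by its marker total, giving
    per-subject rate maps instead of raw counts (an option for cohorts with
    very unequal totals; raw counts are the default).
    """
    rows = _condition_rows(matrix, condition)
    if normalize:
        totals = rows.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        rows = rows / totals
    vals = rows.mean(axis=0).reshape(matrix.grid.nx, matrix.grid.ny)
    return DensityMap(matrix.grid, vals, "mean", (condition,), len(rows))


def sd_map(matrix: BinMatrix, condition: str) -> DensityMap:
    rows = _condition_rows(matrix, condition)
    if len(rows) < 2:
        raise ValueError("SD map needs at least 2 subjects")
    vals = rows.std(axis=0, ddof=1).reshape(matrix.grid.nx, matrix.grid.ny)
    return DensityMap(matrix.grid, vals, "sd", (condition,), len(rows))


def cv_map(matrix: BinMatrix, condition: str) -> DensityMap:
    """Coefficient of variance map: sample SD divided by mean, per bin.

    Bins with zero mean are masked invalid — 0/0 carries no information.
    """
    rows = _condition_rows(matrix, condition)
    if len(rows) < 2:
        raise ValueError("CV map needs at least 2 subjects (SD undefined)")
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)
    mask = mean != 0
    cv = np.zeros_like(mean)
    cv[mask] = sd[mask] / mean[mask]
    shape = (matrix.grid.nx, matrix.grid.ny)
    return DensityMap(matrix.grid, cv.reshape(shape), "cv", (condition,),
                      len(rows), mask.reshape(shape))


def difference_map(map_a: DensityMap, map_b: DensityMap) -> DensityMap:
    """Bin-wise a - b of two mean maps on the identical grid."""
    for m in (map_a, map_b):
        if m.statistic != "mean":
            raise ValueError("difference maps are defined between mean maps")
    if (not np.array_equal(map_a.grid.x_edges, map_b.grid.x_edges)
            or not np.array_equal(map_a.grid.y_edges, map_b.grid.y_edges)):
        raise ValueError("grids differ; no silent resampling is performed")
    vals = map_a.values - map_b.values
    mask = map_a.mask & map_b.mask
    vals = np.where(mask, vals, 0.0)
    return DensityMap(map_a.grid, vals, "difference",
                      map_a.conditions + map_b.conditions,
                      min(map_a.n_subjects, map_b.n_subjects), mask)


def qvalue_map(grid: BinGrid, q_flat: np.ndarray,
               family_mask_flat: np.ndarray) -> DensityMap:
    """Map of FDR q-values; bins outside the testing family are masked."""
    shape = (grid.nx, grid.ny)
    q = np.asarray(q_flat, dtype=float).reshape(shape)
    mask = np.asarray(family_mask_flat, dtype=bool).reshape(shape)
    q = np.where(mask, q, 0.0)
    return DensityMap(grid, q, "qvalue", (), 0, mask)


def write_sidecar(dmap: DensityMap, path: str | os.PathLike) -> Path:
    path = Path(path)
    dmap.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def render_map(
    dmap: DensityMap,
    path: str | os.PathLike,
    contour: Contour | None = None,
    background: np.ndarray | None = None,
    um_per_px: float | None = None,
    offset_um: tuple[float, float] = (0.0, 0.0),
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    title: str | None = None,
) -> Path:
    """Render a density map to PNG or SVG with a value sidecar alongside.

    y axis is drawn downward ("ventral ->") to match the image-convention
    registration origin.  A background section image requires a um/px
    calibration; masked bins render in a distinct neutral colour.
    """
    path = Path(path)
    if background is not None and um_per_px is None:
        raise ValueError("background image given without um-per-pixel calibration")
    fig, ax = plt.subplots(figsize=(6, 5))
    try:
        if background is not None:
            h, w = background.shape[:2]
            x0, y0 = offset_um
            ax.imshow(background, extent=[x0, x0 + w * um_per_px,
                                          y0 + h * um_per_px, y0],
                      origin="upper", cmap="gray")
        data = np.ma.masked_where(~dmap.mask, dmap.values)
        cm = matplotlib.colormaps[cmap].copy()
        cm.set_bad("0.85")
        mesh = ax.pcolormesh(dmap.grid.x_edges, dmap.grid.y_edges, data.T,
                             cmap=cm, vmin=vmin, vmax=vmax,
                             alpha=0.8 if background is not None else 1.0)
        unit = {"mean": "neurons/bin", "sd": "neurons/bin",
                "difference": "neurons/bin", "cv": "CV", "qvalue": "q"}
        fig.colorbar(mesh, ax=ax, label=unit[dmap.statistic])
        if contour is not None:
            ring = np.vstack([contour.vertices, contour.vertices[:1]])
            ax.plot(ring[:, 0], ring[:, 1], color="black", lw=1.2)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)  ventral →")
        ax.invert_yaxis()
        ax.set_aspect("equal")
        cond = "/".join(dmap.conditions)
        ax.set_title(title or f"{dmap.statistic} map {cond}".strip())
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)
    write_sidecar(dmap, path.with_suffix(path.suffix + ".tsv"))
    return path
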