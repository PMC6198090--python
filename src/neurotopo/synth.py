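"""Synthetic cohorts with known ground truth for every pipeline stage.

Marker patterns are realisations of an inhomogeneous Poisson process: a
uniform background inside the region contour plus condition-specific
Gaussian hotspots truncated to the contour.  Feret tables get paired
per-plane means with subject-level normal noise.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import MarkerSet
from .geometry import Contour, point_in_contour, points_in_contour


@dataclass(frozen=True)
class Hotspot:
    """A 2D Gaussian cluster of extra activated neurons."""

    center: tuple[float, float]   # um, must lie inside the contour
    sd_um: float
    n_expected: float             # expected extra neurons per subject

    def __post_init__(self) -> None:
        if self.sd_um <= 0:
            raise ValueError("hotspot spatial SD must be positive")
        if self.n_expected < 0:
            raise ValueError("hotspot expectation must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic marker cohort."""

    contour: Contour
    n_subjects: Mapping[str, int]                 # condition -> subjects
    background_rate: float                        # neurons / um^2
    hotspots: Mapping[str, tuple[Hotspot, ...]] = field(default_factory=dict)
    bregma_mm: float = -3.36
    region: str = "LAd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        for cond, spots in self.hotspots.items():
            for h in spots:
                if not point_in_contour(h.center, self.contour):
                    raise ValueError(
                        f"hotspot centre {h.center} for condition {cond!r} "
                        "lies outside the contour")


def _uniform_in_contour(n: int, contour: Contour, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside the contour polygon."""
    if n == 0:
        return np.zeros((0, 2))
    xmin, ymin, xmax, ymax = contour.bounds
    out = []
    remaining = n
    while remaining > 0:
        batch = max(remaining * 2, 64)
        cand = np.column_stack([rng.uniform(xmin, xmax, batch),
                                rng.uniform(ymin, ymax, batch)])
        inside = cand[points_in_contour(cand, contour)]
        out.append(inside[:remaining])
        remaining -= len(inside[:remaining])
    return np.vstack(out)


def _gaussian_in_contour(n: int, center: tuple[float, float], sd: float,
                         contour: Contour, rng: np.random.Generator) -> np.ndarray:
    """Sample n points from an isotropic Gaussian truncated to the contour.

    Points landing outside are re-drawn so the expected extra count inside
    the region is met exactly.
    """
    if n == 0:
        return np.zeros((0, 2))
    out = []
    remaining = n
    while remaining > 0:
        batch = max(remaining * 2, 64)
        cand = rng.normal(loc=center, scale=sd, size=(batch, 2))
        inside = cand[points_in_contour(cand, contour)]
        out.append(inside[:remaining])
        remaining -= len(inside[:remaining])
    return np.vstack(out)


def simulate_markers(
    config: SimulationConfig,
) -> tuple[list[MarkerSet], pd.DataFrame]:
    """Draw one cohort of marker sets plus a per-point ground-truth table.

    Per subject: Poisson(background_rate x contour area) uniform background
    points, and per hotspot Poisson(n_expected) truncated-Gaussian points.
    The truth table records each point's generating component.
    """
    rng = np.random.default_rng(config.seed)
    area = config.contour.polygon.area
    marker_sets: list[MarkerSet] = []
    truth_rows = []
    for cond in sorted(config.n_subjects):
        n_subj = config.n_subjects[cond]
        spots = tuple(config.hotspots.get(cond, ()))
        for s in range(n_subj):
            subject_id = f"{cond}_{s + 1:02d}"
            parts, origins = [], []
            n_bg = rng.poisson(config.background_rate * area)
            parts.append(_uniform_in_contour(n_bg, config.contour, rng))
            origins += ["background"] * n_bg
            for h_idx, h in enumerate(spots):
                n_h = rng.poisson(h.n_expected)
                parts.append(_gaussian_in_contour(
                    n_h, h.center, h.sd_um, config.contour, rng))
                origins += [f"hotspot_{h_idx}"] * n_h
            pts = np.vstack(parts) if parts else np.zeros((0, 2))
            marker_sets.append(MarkerSet(
                subject_id=subject_id, condition=cond,
                bregma_mm=config.bregma_mm, region=config.region,
                points=pts, registered=True))
            for (x, y), origin in zip(pts, origins):
                truth_rows.append({"subject_id": subject_id, "condition": cond,
                                   "x": x, "y": y, "origin": origin})
    truth = pd.DataFrame(truth_rows,
                         columns=["subject_id", "condition", "x", "y", "origin"])
    return marker_sets, truth


def simulate_feret_table(
    planes: Sequence[float],
    plane_means_um: Sequence[float],
    noise_sd_um: float,
    n_subjects: Mapping[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Paired landmark Feret lengths: every subject measured at every plane."""
    if len(planes) != len(plane_means_um):
        raise ValueError("need one mean per plane")
    if any(m <= 0 for m in plane_means_um):
        raise ValueError("plane means must be positive")
    if noise_sd_um < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in sorted(n_subjects):
        for s in range(n_subjects[cond]):
            subject_id = f"{cond}_{s + 1:02d}"
            for plane, mean in zip(planes, plane_means_um):
                rows.append({
                    "subject_id": subject_id, "condition": cond,
                    "bregma_mm": float(plane),
                    "feret_um": float(mean + rng.normal(0.0, noise_sd_um)),
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# packaged two-condition study scenarios

# irregular simple octagon, roughly 360 x 300 um, like a traced subnucleus
_SCENARIO_VERTICES = (
    (0.0, 60.0), (90.0, 0.0), (230.0, 10.0), (340.0, 70.0),
    (360.0, 180.0), (300.0, 280.0), (150.0, 300.0), (30.0, 220.0),
)
SCENARIO_HOTSPOT_CENTER = (150.0, 110.0)
SCENARIO_HOTSPOT_SD = 30.0
SCENARIO_HOTSPOT_N = 80.0
SCENARIO_CONDITIONS = ("conditioned", "control")
SCENARIO_N_PER_CONDITION = 7
SCENARIO_FERET_PLANES = (2.64, 2.70, 2.76)
SCENARIO_FERET_MEANS = (2400.0, 2100.0, 1800.0)
SCENARIO_FERET_SD = 40.0


def scenario_contour() -> Contour:
    return Contour(np.array(_SCENARIO_VERTICES), label="LAd", bregma_mm=-3.36)


@dataclass
class StudyBundle:
    """A complete in-memory synthetic study: contour, markers, Feret table."""

    scenario: str
    contour: Contour
    marker_sets: list[MarkerSet]
    feret: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _scenario(seed: int, with_hotspot: bool) -> StudyBundle:
    contour = scenario_contour()
    area = contour.polygon.area
    hotspots: dict[str, tuple[Hotspot, ...]] = {}
    if with_hotspot:
        hotspots["conditioned"] = (
            Hotspot(SCENARIO_HOTSPOT_CENTER, SCENARIO_HOTSPOT_SD,
                    SCENARIO_HOTSPOT_N),
        )
    config = SimulationConfig(
        contour=contour,
        n_subjects={c: SCENARIO_N_PER_CONDITION for c in SCENARIO_CONDITIONS},
        background_rate=150.0 / area,
        hotspots=hotspots,
        seed=seed,
    )
    marker_sets, truth = simulate_markers(config)
    feret = simulate_feret_table(
        SCENARIO_FERET_PLANES, SCENARIO_FERET_MEANS, SCENARIO_FERET_SD,
        config.n_subjects, seed=seed + 1)
    name = "effect" if with_hotspot else "null"
    return StudyBundle(name, contour, marker_sets, feret, truth, config)


def scenario_effect(seed: int = 0) -> StudyBundle:
    """Two conditions, 7 + 7 subjects, planted hotspot in 'conditioned'."""
    return _scenario(seed, with_hotspot=True)


def scenario_null(seed: int = 0) -> StudyBundle:
    """Matched scenario with no condition difference (background only)."""
    return _scenario(seed, with_hotspot=False)
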