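"""Section-alignment quality control from landmark Feret lengths.

Sections assigned to one Bregma plane should have mutually consistent
landmark Feret lengths (no outliers, no condition effect), while different
planes should be statistically distinct.  This module provides the z-score
outlier screen, the per-plane-pair paired t-tests, and the within-plane
condition ANOVA that formalise those checks.

Feret records are a pandas DataFrame with columns
``subject_id, condition, bregma_mm, feret_um``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FERET_COLUMNS = ("subject_id", "condition", "bregma_mm", "feret_um")


def validate_feret(records: pd.DataFrame) -> pd.DataFrame:
    """Check the Feret-table schema and basic invariants."""
    missing = [c for c in FERET_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Feret table missing columns: {missing}")
    if (records["feret_um"] <= 0).any():
        raise ValueError("feret_um must be strictly positive")
    dup = records.duplicated(subset=["subject_id", "bregma_mm"])
    if dup.any():
        raise ValueError(
            "duplicate (subject_id, bregma_mm) Feret records: "
            f"{records.loc[dup, ['subject_id', 'bregma_mm']].values.tolist()}"
        )
    return records


@dataclass
class ZScoreResult:
    z: np.ndarray          # per-value z-score (nan when no variance)
    flags: np.ndarray      # |z| > threshold
    no_variance: bool      # constant input; z undefined, nothing flagged


def zscore_flag(values, threshold: float = 3.0) -> ZScoreResult:
    """Flag values whose |z| exceeds ``threshold`` SD units.

    Uses the sample (n-1) standard deviation.  Constant input yields a
    no-variance condition with zero flags instead of an error.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(v) < 3:
        raise ValueError("need at least 3 values for outlier screening")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        return ZScoreResult(np.full(len(v), np.nan), np.zeros(len(v), bool), True)
    z = (v - v.mean()) / sd
    return ZScoreResult(z, np.abs(z) > threshold, False)


def plane_distinctness(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test of Feret length for every pair of Bregma planes.

    Pairing is by subject; subjects missing either plane of a pair are
    dropped with a logged warning.  Returns one row per plane pair with
    columns ``plane_a, plane_b, n_pairs, t, p, distinct``.
    """
    validate_feret(records)
    planes = sorted(records["bregma_mm"].unique())
    if len(planes) < 2:
        raise ValueError("need measurements on at least 2 planes")
    wide = records.pivot(index="subject_id", columns="bregma_mm", values="feret_um")
    rows = []
    for a, b in itertools.combinations(planes, 2):
        paired = wide[[a, b]].dropna()
        dropped = len(wide) - len(paired)
        if dropped:
            logger.warning("plane pair (%s, %s): dropped %d unpaired subjects",
                           a, b, dropped)
        if len(paired) < 2:
            raise ValueError(f"fewer than 2 complete pairs for planes ({a}, {b})")
        diffs = paired[a].to_numpy() - paired[b].to_numpy()
        if np.all(diffs == 0.0):
            t, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # near-identical differences trigger a scipy precision
                # warning; the test statistic itself remains valid
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_rel(paired[a], paired[b])
        rows.append({"plane_a": a, "plane_b": b, "n_pairs": len(paired),
                     "t": float(t), "p": float(p), "distinct": bool(p < alpha)})
    return pd.DataFrame(rows)


@dataclass
class HomogeneityResult:
    plane: float
    f: float
    p: float
    aligned: bool                      # "no evidence of misalignment" at alpha
    n_per_condition: dict
    excluded_conditions: list = field(default_factory=list)


def condition_homogeneity(
    records: pd.DataFrame, plane: float, alpha: float = 0.05
) -> HomogeneityResult:
    """One-way ANOVA of Feret length across conditions at one plane.

    A non-significant F is reported as "no evidence of misalignment" —
    never as proof of alignment.  Conditions with fewer than 2 subjects are
    excluded with a warning.
    """
    validate_feret(records)
    at_plane = records[records["bregma_mm"] == plane]
    if at_plane.empty:
        raise ValueError(f"no records at plane {plane}")
    groups, excluded, sizes = [], [], {}
    for cond, grp in at_plane.groupby("condition"):
        if len(grp) < 2:
            logger.warning("condition %r has <2 subjects at plane %s; excluded",
                           cond, plane)
            excluded.append(cond)
            continue
        groups.append(grp["feret_um"].to_numpy())
        sizes[cond] = len(grp)
    if len(groups) < 2:
        raise ValueError("need >=2 conditions with >=2 subjects each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # all groups constant and equal
        f, p = 0.0, 1.0
    return HomogeneityResult(plane, float(f), float(p), bool(p >= alpha),
                             sizes, excluded)


@dataclass
class QcReport:
    """Combined alignment QC: z-scores, plane pair tests, condition tests."""

    records: pd.DataFrame              # input + z, outlier columns
    pair_tests: pd.DataFrame
    condition_tests: pd.DataFrame
    excluded: list                     # subject/plane keys excluded on request
    z_threshold: float
    alpha: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.records[self.records["outlier"]]

    @property
    def all_planes_distinct(self) -> bool:
        return bool(self.pair_tests["distinct"].all())

    @property
    def all_planes_aligned(self) -> bool:
        return bool((self.condition_tests["p"] >= self.alpha).all())


def run_qc(
    records: pd.DataFrame,
    z_threshold: float = 3.0,
    alpha: float = 0.05,
    group_by: str = "plane",
    exclude_outliers: bool = False,
) -> QcReport:
    """Run the full alignment QC battery on a Feret table.

    ``group_by`` selects the z-score grouping: ``"plane"`` pools conditions
    within each Bregma plane (default) or ``"plane_condition"`` scores
    within each plane-by-condition cell.  Flagged records are listed as
    excluded only when ``exclude_outliers`` is set; QC never silently drops
    data.
    """
    validate_feret(records)
    out = records.copy().reset_index(drop=True)
    if group_by == "plane":
        keys = ["bregma_mm"]
    elif group_by == "plane_condition":
        keys = ["bregma_mm", "condition"]
    else:
        raise ValueError("group_by must be 'plane' or 'plane_condition'")
    out["z"] = np.nan
    out["outlier"] = False
    for _, idx in out.groupby(keys).groups.items():
        res = zscore_flag(out.loc[idx, "feret_um"].to_numpy(), z_threshold)
        out.loc[idx, "z"] = res.z
        out.loc[idx, "outlier"] = res.flags
    pair_tests = plane_distinctness(out, alpha=alpha)
    cond_rows = []
    for plane in sorted(out["bregma_mm"].unique()):
        try:
            r = condition_homogeneity(out, plane, alpha=alpha)
        except ValueError:
            continue
        cond_rows.append({"plane": r.plane, "f": r.f, "p": r.p,
                          "aligned": r.aligned})
    condition_tests = pd.DataFrame(
        cond_rows, columns=["plane", "f", "p", "aligned"])
    excluded = (
        out.loc[out["outlier"], ["subject_id", "bregma_mm"]]
        .to_records(index=False).tolist()
        if exclude_outliers else []
    )
    return QcReport(out, pair_tests, condition_tests, excluded,
                    z_threshold, alpha)
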