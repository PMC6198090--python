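"""Plain-text readers/writers, the study manifest, and bundle export.

The canonical dialect is tab-separated with a one-line header, but readers
tolerate comma/whitespace delimiters and comment lines starting with ``#``
or ``;`` so that Neurolucida-style ASCII exports load unchanged.  All
coordinates are micrometres on disk; Bregma is millimetres.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_qc import FERET_COLUMNS, validate_feret
from .binning import BinGrid, BinMatrix, MarkerSet
from .geometry import Contour
from .synth import StudyBundle

logger = logging.getLogger(__name__)

_SPLIT = re.compile(r"[,\t;\s]+")
_COMMENT = ("#", ";")

MANIFEST_COLUMNS = ("path", "role", "subject_id", "condition",
                    "bregma_mm", "region")
ROLES = ("markers", "contour", "feret", "background-image")


def _numeric_rows(path: Path) -> tuple[list[list[float]], dict[str, str], int]:
    """Parse a tolerant delimited numeric file.

    Returns (rows, key=value header metadata, n_dropped_lines).
    """
    rows: list[list[float]] = []
    meta: dict[str, str] = {}
    dropped = 0
    first_bad: str | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(_COMMENT):
            body = line.lstrip("#; ").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        fields = [f for f in _SPLIT.split(line) if f]
        try:
            rows.append([float(f) for f in fields])
        except ValueError:
            dropped += 1
            if first_bad is None:
                first_bad = raw
    if not rows:
        raise ValueError(
            f"{path}: no parseable coordinate rows"
            + (f" (first offending line: {first_bad!r})" if first_bad else ""))
    if dropped:
        logger.info("%s: skipped %d non-numeric lines", path, dropped)
    return rows, meta, dropped


def read_contour(path: str | os.PathLike) -> Contour:
    """Read a contour file: one x, y vertex per line plus header metadata."""
    path = Path(path)
    rows, meta, _ = _numeric_rows(path)
    vertices = np.array([r[:2] for r in rows])
    bregma = meta.get("bregma_mm")
    return Contour(vertices, label=meta.get("label", ""),
                   bregma_mm=float(bregma) if bregma is not None else None)


def write_contour(contour: Contour, path: str | os.PathLike) -> Path:
    path = Path(path)
    lines = [f"# label={contour.label}"]
    if contour.bregma_mm is not None:
        lines.append(f"# bregma_mm={contour.bregma_mm}")
    lines += [f"{x:.6f}\t{y:.6f}" for x, y in contour.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_markers(
    path: str | os.PathLike,
    subject_id: str = "",
    condition: str = "",
    bregma_mm: float = np.nan,
    region: str = "",
    registered: bool = False,
) -> MarkerSet:
    """Read a marker coordinate file (x, y[, z] columns, tolerant dialect).

    Header metadata in the file (``# key=value``) fills in any identifier
    not passed explicitly; explicit arguments win.
    """
    path = Path(path)
    rows, meta, _ = _numeric_rows(path)
    pts = np.array([r[:2] for r in rows])
    z = None
    if all(len(r) >= 3 for r in rows):
        z = np.array([r[2] for r in rows])
    return MarkerSet(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        condition=condition or meta.get("condition", ""),
        bregma_mm=(bregma_mm if np.isfinite(bregma_mm)
                   else float(meta.get("bregma_mm", "nan"))),
        region=region or meta.get("region", ""),
        points=pts, z=z,
        registered=registered or meta.get("registered", "") == "true",
    )


def write_markers(markers: MarkerSet, path: str | os.PathLike) -> Path:
    path = Path(path)
    lines = [
        f"# subject_id={markers.subject_id}",
        f"# condition={markers.condition}",
        f"# bregma_mm={markers.bregma_mm}",
        f"# region={markers.region}",
        f"# registered={'true' if markers.registered else 'false'}",
        "# x_um\ty_um" + ("\tz_um" if markers.z is not None else ""),
    ]
    for i, (x, y) in enumerate(markers.points):
        row = f"{x:.6f}\t{y:.6f}"
        if markers.z is not None:
            row += f"\t{markers.z[i]:.6f}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feret(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return validate_feret(df[list(FERET_COLUMNS)])


def write_feret(records: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    validate_feret(records)
    records.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_grid(grid: BinGrid, path: str | os.PathLike) -> Path:
    """Sidecar file recording the exact bin edges in micrometres."""
    path = Path(path)
    lines = [f"# bin_side_um={grid.bin_side!r}",
             "x_edges\t" + "\t".join(f"{e:.6f}" for e in grid.x_edges),
             "y_edges\t" + "\t".join(f"{e:.6f}" for e in grid.y_edges)]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_bin_matrix(matrix: BinMatrix, path: str | os.PathLike) -> Path:
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep="\t", index=False,
                                 float_format="%.10g")
    write_grid(matrix.grid, path.with_suffix(".grid.tsv"))
    return path


# --------------------------------------------------------------------------
# manifest


@dataclass
class StudyManifest:
    """Maps data files to subject / condition / plane / region roles."""

    entries: pd.DataFrame
    base_dir: Path

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad_roles = set(self.entries["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown manifest roles: {sorted(bad_roles)}")
        for rel in self.entries["path"]:
            if not (self.base_dir / rel).exists():
                raise FileNotFoundError(f"manifest references missing file: {rel}")
        markers = self.entries[self.entries["role"] == "markers"]
        dup = markers.duplicated(subset=["subject_id", "bregma_mm", "region"])
        if dup.any():
            raise ValueError("duplicate (subject, plane, region) marker entries")
        contours = self.entries[self.entries["role"] == "contour"]
        for _, row in markers.iterrows():
            match = contours[(contours["region"] == row["region"])
                             & (contours["bregma_mm"] == row["bregma_mm"])]
            if match.empty:
                raise ValueError(
                    f"no contour entry for marker file {row['path']} "
                    f"(region={row['region']}, bregma={row['bregma_mm']})")

    def resolve(self, rel: str) -> Path:
        return self.base_dir / rel

    @property
    def marker_entries(self) -> pd.DataFrame:
        return self.entries[self.entries["role"] == "markers"]

    def contour_path(self, region: str, bregma_mm: float) -> Path:
        contours = self.entries[self.entries["role"] == "contour"]
        match = contours[(contours["region"] == region)
                         & (contours["bregma_mm"] == bregma_mm)]
        return self.resolve(match["path"].iloc[0])

    @property
    def feret_path(self) -> Path | None:
        feret = self.entries[self.entries["role"] == "feret"]
        return self.resolve(feret["path"].iloc[0]) if len(feret) else None


def read_manifest(path: str | os.PathLike) -> StudyManifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"subject_id": str, "condition": str, "region": str})
    df["subject_id"] = df["subject_id"].fillna("")
    df["condition"] = df["condition"].fillna("")
    df["region"] = df["region"].fillna("")
    return StudyManifest(df, path.parent)


def write_manifest(entries: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    entries.to_csv(path, sep="\t", index=False)
    return path


def load_config_file(path: str | os.PathLike) -> dict[str, str]:
    """Simple ``key = value`` configuration file; '#' comments allowed."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key=value): {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def write_bundle(bundle: StudyBundle, directory: str | os.PathLike) -> Path:
    """Write a synthetic study to disk in the canonical file dialects.

    Returns the manifest path.  Synthetic bundles exercise the exact same
    I/O path as real exports.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    contour_rel = "contour.txt"
    write_contour(bundle.contour, directory / contour_rel)
    entries.append({"path": contour_rel, "role": "contour", "subject_id": "",
                    "condition": "", "bregma_mm": bundle.contour.bregma_mm,
                    "region": bundle.contour.label})
    for m in bundle.marker_sets:
        rel = f"markers_{m.subject_id}.txt"
        write_markers(m, directory / rel)
        entries.append({"path": rel, "role": "markers",
                        "subject_id": m.subject_id, "condition": m.condition,
                        "bregma_mm": m.bregma_mm, "region": m.region})
    feret_rel = "feret.tsv"
    write_feret(bundle.feret, directory / feret_rel)
    entries.append({"path": feret_rel, "role": "feret", "subject_id": "",
                    "condition": "", "bregma_mm": np.nan, "region": ""})
    bundle.truth.to_csv(directory / "truth.tsv", sep="\t", index=False,
                        float_format="%.6f")
    manifest_path = directory / "manifest.tsv"
    write_manifest(pd.DataFrame(entries, columns=list(MANIFEST_COLUMNS)),
                   manifest_path)
    return manifest_path
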