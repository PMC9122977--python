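"""Reading, filtering, grouping, and QC of localization point clouds.

A single-molecule localization table holds one row per blinking event: 3D
position (nm), per-axis localization uncertainty sigma (nm), photon count
and acquisition frame.  Processing follows the standard staged contract:

1. permissive uncertainty pre-filter (drop events with sigma >= 30 nm on
   any axis),
2. strict filter (drop events whose sigma exceeds 15 nm on *all* three axes
   simultaneously),
3. spatial grouping of re-blinking events into per-oligo "group peaks"
   (density-based clustering; the centroid of a group estimates the oligo's
   position on the fiber),
4. image QC: an image qualifies for modelling only if group peaks cover at
   least a minimum fraction (default 30%) of the designed oligos.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

log = logging.getLogger(__name__)

#: Canonical in-memory column names.
FIELDS = ("x", "y", "z", "sigma_x", "sigma_y", "sigma_z", "photons", "frame")


class DialectError(ValueError):
    """A column-mapping configuration error (e.g. missing required column)."""


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from file column names to the eight required fields.

    ``scale`` factors convert position/sigma columns to nm at read time (1.0
    when the file is already in nm).
    """

    columns: dict = field(
        default_factory=lambda: {
            "x": "x_nm",
            "y": "y_nm",
            "z": "z_nm",
            "sigma_x": "sigma_x",
            "sigma_y": "sigma_y",
            "sigma_z": "sigma_z",
            "photons": "photons",
            "frame": "frame",
        }
    )
    scale: dict = field(default_factory=dict)
    sep: str | None = None  # None: sniff delimiter


DEFAULT_DIALECT = ColumnDialect()


@dataclass
class LocalizationTable:
    """Ordered collection of localization events for one image."""

    df: pd.DataFrame
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.df[["sigma_x", "sigma_y", "sigma_z"]].to_numpy(dtype=float)


@dataclass
class GroupPeak:
    """Centroid of the blinking events attributed to a single oligo."""

    cx: float
    cy: float
    cz: float
    n_events: int
    mean_sigma_x: float
    mean_sigma_y: float
    mean_sigma_z: float
    total_photons: float


@dataclass
class GroupPeakSet:
    """Oligo-level centroids derived from one localization table."""

    groups: list
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def positions(self) -> np.ndarray:
        if not self.groups:
            return np.empty((0, 3))
        return np.array([[g.cx, g.cy, g.cz] for g in self.groups], dtype=float)


@dataclass
class QCReport:
    """Image-level quality control against the designed probe set."""

    n_localizations: int
    n_filtered: int
    n_groups: int
    hull_volume: float
    n_designed_oligos: int
    min_fraction: float
    passed: bool

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_localizations(
    path, dialect: ColumnDialect = DEFAULT_DIALECT, source_id: str | None = None
) -> LocalizationTable:
    """Parse a delimited localization table into canonical nm columns.

    Rows with non-numeric values in any required column are dropped (the
    count is logged).  A missing required column raises :class:`DialectError`
    naming the column; an empty file yields an empty table with a warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty localization file")
        return LocalizationTable(pd.DataFrame(columns=list(FIELDS)), source_id or path.stem)
    try:
        raw = pd.read_csv(path, sep=dialect.sep, engine="python")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty localization file")
        return LocalizationTable(pd.DataFrame(columns=list(FIELDS)), source_id or path.stem)
    missing = [c for f, c in dialect.columns.items() if c not in raw.columns]
    if missing:
        raise DialectError(f"{path}: required column(s) missing: {', '.join(missing)}")
    df = pd.DataFrame({f: pd.to_numeric(raw[dialect.columns[f]], errors="coerce") for f in FIELDS})
    n_raw = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n_raw:
        log.info("%s: dropped %d malformed row(s)", path, n_raw - len(df))
    for f, s in dialect.scale.items():
        df[f] = df[f] * s
    log.info("%s: read %d localizations", path, len(df))
    return LocalizationTable(df, source_id or path.stem)


def write_localizations(table: LocalizationTable, path, dialect: ColumnDialect = DEFAULT_DIALECT) -> None:
    """Re-export a table in the same delimited dialect (inverse of read)."""
    out = table.df.rename(columns=dialect.columns)
    out.to_csv(path, sep=dialect.sep or ",", index=False)


def filter_by_uncertainty(
    table: LocalizationTable, max_sigma: float, mode: str = "all_axes"
) -> LocalizationTable:
    """Drop high-uncertainty localizations.

    ``mode="any_axis"`` keeps only events with sigma < ``max_sigma`` on
    every axis (the permissive 30 nm pre-filter: one bad axis disqualifies).
    ``mode="all_axes"`` removes an event only when its sigma exceeds
    ``max_sigma`` on all three axes simultaneously (the strict 15 nm rule as
    stated: an event with one good axis survives).
    """
    if max_sigma <= 0:
        raise ValueError("max_sigma must be positive")
    s = table.sigmas
    if mode == "any_axis":
        keep = (s < max_sigma).all(axis=1)
    elif mode == "all_axes":
        keep = ~(s > max_sigma).all(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = table.df.loc[keep].reset_index(drop=True)
    log.info(
        "%s: uncertainty filter (%g nm, %s) kept %d/%d",
        table.source_id, max_sigma, mode, len(out), len(table.df),
    )
    return LocalizationTable(out, table.source_id)


def group_peaks(
    table: LocalizationTable, radius: float = 50.0, min_events: int = 2
) -> GroupPeakSet:
    """Cluster blinking events into per-oligo group peaks.

    Density-based clustering (DBSCAN with ``eps=radius`` nm and
    ``min_samples=min_events``) assigns each localization to at most one
    group; noise points and clusters below ``min_events`` are discarded.
    Group centroids are photon-weighted means of member positions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if len(table) == 0:
        return GroupPeakSet([], table.source_id)
    labels = DBSCAN(eps=radius, min_samples=min_events).fit_predict(table.positions)
    groups: list[GroupPeak] = []
    df = table.df
    for lab in np.unique(labels):
        if lab < 0:
            continue
        member = df.loc[labels == lab]
        if len(member) < min_events:
            continue
        w = member["photons"].to_numpy(dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(member))
        pos = member[["x", "y", "z"]].to_numpy(dtype=float)
        c = (pos * w[:, None]).sum(axis=0) / w.sum()
        groups.append(
            GroupPeak(
                cx=float(c[0]), cy=float(c[1]), cz=float(c[2]),
                n_events=int(len(member)),
                mean_sigma_x=float(member["sigma_x"].mean()),
                mean_sigma_y=float(member["sigma_y"].mean()),
                mean_sigma_z=float(member["sigma_z"].mean()),
                total_photons=float(member["photons"].sum()),
            )
        )
    log.info("%s: %d group peaks from %d localizations", table.source_id, len(groups), len(df))
    return GroupPeakSet(groups, table.source_id)


def convex_hull_volume(points) -> float:
    """Convex-hull volume (nm^3) of a 3D point set; 0 for degenerate input."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        warnings.warn("fewer than 4 points: hull volume is degenerate (0)")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar/collinear) point set: hull volume 0")
        return 0.0


def image_qc(
    groups: GroupPeakSet,
    n_designed_oligos: int,
    min_fraction: float = 0.30,
    n_localizations: int = 0,
    n_filtered: int = 0,
) -> QCReport:
    """Qualify an image for modelling by probe coverage.

    Passes iff the group-peak count reaches
    ``ceil(min_fraction * n_designed_oligos)``.
    """
    if n_designed_oligos < 1:
        raise ValueError("n_designed_oligos must be >= 1")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * n_designed_oligos)
    n_groups = len(groups)
    hull = convex_hull_volume(groups.positions) if n_groups >= 4 else 0.0
    return QCReport(
        n_localizations=n_localizations,
        n_filtered=n_filtered,
        n_groups=n_groups,
        hull_volume=hull,
        n_designed_oligos=n_designed_oligos,
        min_fraction=min_fraction,
        passed=bool(n_groups >= threshold),
    )
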