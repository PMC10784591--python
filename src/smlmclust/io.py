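"""Localization and trajectory table I/O.

Localization tables follow the ThunderSTORM CSV export convention
(columns ``frame``, ``x [nm]``, ``y [nm]``, ``uncertainty [nm]``,
``intensity [photon]``); alternate column maps are configurable through a
:class:`Dialect`.  Coordinates are continuous nanometres with the origin at
the lower-left corner of the field and y increasing upward.  Raster maps
built downstream index pixels 0-based; a localization at ``(x, y)`` falls
in pixel ``(floor(x/px), floor(y/px))`` (half-open pixels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("smlmclust")

#: physical camera pixel size of the acquisition system, nm
CAMERA_PIXEL_NM = 47.1

LOCALIZATION_COLUMNS = ("frame", "x", "y", "uncertainty", "intensity")


class FormatError(ValueError):
    """A table file does not conform to the declared dialect."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from on-disk CSV headers to canonical names."""

    frame: str = "frame"
    x: str = "x [nm]"
    y: str = "y [nm]"
    uncertainty: str = "uncertainty [nm]"
    intensity: str = "intensity [photon]"

    def column_map(self) -> Mapping[str, str]:
        return {
            self.frame: "frame",
            self.x: "x",
            self.y: "y",
            self.uncertainty: "uncertainty",
            self.intensity: "intensity",
        }


THUNDERSTORM = Dialect()


@dataclass
class FieldBounds:
    """Axis-aligned rectangle in nm: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass
class LocalizationTable:
    """A per-channel table of localizations plus acquisition metadata.

    ``df`` holds one row per localization with canonical columns
    ``frame`` (1-based), ``x``/``y``/``uncertainty`` (nm) and ``intensity``
    (arbitrary units); an optional ``channel`` column labels the source.
    """

    df: pd.DataFrame
    frame_interval_ms: float = 33.0
    field_bounds: FieldBounds | None = None
    camera_pixel_nm: float = CAMERA_PIXEL_NM
    channel: str = "A"

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"localization table missing column(s): {missing}")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if len(self.df) and (self.df["uncertainty"] <= 0).any():
            raise ValueError("uncertainties must be positive")
        if self.field_bounds is None and len(self.df):
            # infer generous bounds from the data
            pad = 1.0
            self.field_bounds = FieldBounds(
                float(self.df["x"].min()) - pad,
                float(self.df["y"].min()) - pad,
                float(self.df["x"].max()) + pad,
                float(self.df["y"].max()) + pad,
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(float)

    @property
    def uncertainty(self) -> np.ndarray:
        return self.df["uncertainty"].to_numpy(float)

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return replace(self, df=df.reset_index(drop=True))


@dataclass
class Trajectory:
    """A tracked spot path: strictly increasing frames with nm positions."""

    id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval_ms: float = 33.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"trajectory {self.id}: frames must strictly increase")

    def __len__(self) -> int:
        return len(self.frames)


def read_localizations(
    path: str | Path,
    dialect: Dialect = THUNDERSTORM,
    frame_interval_ms: float = 33.0,
    field_bounds: FieldBounds | None = None,
    channel: str = "A",
) -> LocalizationTable:
    """Read a localization CSV in the given dialect.

    Rows with non-finite coordinates or uncertainty are dropped and the
    count is logged.  Raises :class:`FormatError` if a mandatory column is
    missing and ``ValueError`` on an empty file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty localization file")
    cmap = dialect.column_map()
    missing = [src for src in cmap if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns=cmap)[list(LOCALIZATION_COLUMNS)]
    finite = np.isfinite(df[["x", "y", "uncertainty"]].to_numpy(float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
    df = df[finite].reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    logger.info("read %d localizations from %s (dropped %d)", len(df), path, n_dropped)
    return LocalizationTable(
        df=df,
        frame_interval_ms=frame_interval_ms,
        field_bounds=field_bounds,
        channel=channel,
    )


def write_localizations(
    table: LocalizationTable,
    path: str | Path,
    dialect: Dialect = THUNDERSTORM,
    allow_empty: bool = False,
) -> Path:
    """Write a localization table as CSV (units nm), returning the path."""
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table without allow_empty=True")
    path = Path(path)
    inv = {v: k for k, v in dialect.column_map().items()}
    out = table.df[list(LOCALIZATION_COLUMNS)].rename(columns=inv)
    out.to_csv(path, index=False)
    logger.info("wrote %d localizations to %s", len(table), path)
    return path


def read_trajectories(
    path: str | Path, frame_interval_ms: float = 33.0
) -> list[Trajectory]:
    """Read a trajectory CSV with columns id, frame, x [nm], y [nm]."""
    df = pd.read_csv(path)
    required = {"id", "frame", "x [nm]", "y [nm]"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing trajectory column(s) {sorted(missing)}")
    out: list[Trajectory] = []
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                id=str(tid),
                frames=grp["frame"].to_numpy(int),
                x=grp["x [nm]"].to_numpy(float),
                y=grp["y [nm]"].to_numpy(float),
                frame_interval_ms=frame_interval_ms,
            )
        )
    return out


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in trajectories:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.id, f, x, y))
    pd.DataFrame(rows, columns=["id", "frame", "x [nm]", "y [nm]"]).to_csv(
        path, index=False
    )
    return path
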