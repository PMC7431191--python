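"""Reading and writing the package's on-disk formats.

Spine-tracking tables use a FIMTrack-like CSV dialect: one row per
(larva_id, frame) with columns ``larva_id, frame, time_s, x1..x5, y1..y5``.
Coordinates are in mm, image convention (y grows downward), frames are
0-based.  Point 3 (``x3, y3``) is the centroid.  Missing frames are gap
markers: they are preserved as NaN rows in memory and never interpolated
here — downstream analysis decides how to treat them.

Image stacks are multi-channel TIFF with axis order (channel, z, y, x) and
exactly two channels, named ``col`` and ``nau``.  Nuclear ROI masks are
integer-labelled single-channel 2D TIFFs (0 = background).

Generator/analysis parameters travel as YAML mappings with a
``config_version`` field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

CHANNEL_NAMES = ("col", "nau")

_TRACK_COLUMNS = ["larva_id", "frame", "time_s"] + [
    f"{ax}{i}" for i in range(1, 6) for ax in ("x", "y")
]


class SchemaError(ValueError):
    """A file does not conform to the declared dialect."""


@dataclass
class SpineTrack:
    """Per-larva time series of 5 ordered spine points (head to tail).

    ``points`` has shape (n_frames, 5, 2) in mm; frame k corresponds to
    time ``k / fps`` seconds.  Gap frames (untracked) are NaN rows.
    ``truth`` optionally carries simulation ground truth (per-cycle table)
    when the track was produced by the synthetic generator.
    """

    larva_id: str
    fps: float
    points: np.ndarray
    genotype: str = ""
    truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.points.ndim != 3 or self.points.shape[1:] != (5, 2):
            raise ValueError(
                f"points must have shape (n_frames, 5, 2), got {self.points.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a track needs at least 2 frames")
        with np.errstate(invalid="ignore"):
            bad = np.isinf(self.points).any()
        if bad:
            raise ValueError("coordinates must be finite or NaN (gap)")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def time(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.fps

    @property
    def centroid(self) -> np.ndarray:
        """(n_frames, 2) positions of the 3rd spine point."""
        return self.points[:, 2, :]

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean per-frame mask, True where the frame is a gap."""
        return np.isnan(self.points).any(axis=(1, 2))

    @property
    def duration(self) -> float:
        """Record span in seconds (n_frames / fps)."""
        return self.n_frames / self.fps


@dataclass
class ImageStack:
    """Two-channel 3D fluorescence stack, axes (channel, z, y, x)."""

    pixels: np.ndarray
    channel_names: tuple = CHANNEL_NAMES
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be 4D (c, z, y, x), got {self.pixels.ndim}D")
        if self.pixels.shape[0] != 2:
            raise ValueError(
                f"exactly 2 channels required, got {self.pixels.shape[0]}"
            )
        if np.nanmin(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
        return self.pixels[idx]


@dataclass
class NucleusMaskSet:
    """Integer-labelled 2D nuclear ROI mask (0 = background)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask must be integer-labelled")

    @property
    def ids(self) -> np.ndarray:
        """Sorted nucleus ids present in the mask (excluding background)."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def roi(self, nucleus_id: int) -> np.ndarray:
        m = self.labels == nucleus_id
        if not m.any():
            raise KeyError(f"nucleus id {nucleus_id} not present in mask")
        return m


# ---------------------------------------------------------------------------
# Track CSV I/O


def write_tracks(tracks, path) -> None:
    """Write tracks to one CSV in the package dialect.

    Gap frames are omitted from the file (that is the gap marker on disk);
    frame indices therefore need not be contiguous.
    """
    rows = []
    for tr in tracks:
        gaps = tr.gap_mask
        for k in range(tr.n_frames):
            if gaps[k]:
                continue
            row = {
                "larva_id": tr.larva_id,
                "frame": k,
                "time_s": k / tr.fps,
            }
            for i in range(5):
                row[f"x{i + 1}"] = tr.points[k, i, 0]
                row[f"y{i + 1}"] = tr.points[k, i, 1]
            rows.append(row)
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path, fps: Optional[float] = None, column_map: Optional[dict] = None):
    """Read spine tracks from CSV; returns a list of :class:`SpineTrack`.

    Parameters
    ----------
    fps : float, optional
        Frame rate; inferred from the ``time_s`` column when omitted.
    column_map : dict, optional
        Mapping from dialect column names to the names present in the file,
        for files exported with different headers.

    Missing frames between a larva's first and last frame become NaN gap
    rows in the returned track.  Duplicate (larva_id, frame) pairs and
    malformed values raise :class:`SchemaError` naming the offender.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no rows")

    dup = df.duplicated(subset=["larva_id", "frame"])
    if dup.any():
        r = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (larva_id, frame) = ({r['larva_id']}, {r['frame']})"
        )
    coord_cols = _TRACK_COLUMNS[3:]
    for c in ["frame", "time_s"] + coord_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            raise SchemaError(f"{path}: column {c!r} is not numeric")
    if not np.isfinite(df[coord_cols].to_numpy()).all():
        raise SchemaError(f"{path}: non-finite coordinate values")

    if fps is None:
        fps = _infer_fps(df)

    tracks = []
    for larva_id, g in df.groupby("larva_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        if (frames < 0).any():
            raise SchemaError(f"{path}: negative frame index for larva {larva_id}")
        n_frames = frames[-1] + 1
        pts = np.full((n_frames, 5, 2), np.nan)
        for i in range(5):
            pts[frames, i, 0] = g[f"x{i + 1}"].to_numpy()
            pts[frames, i, 1] = g[f"y{i + 1}"].to_numpy()
        n_gaps = n_frames - len(frames)
        if n_gaps:
            logger.info("larva %s: %d gap frame(s) preserved", larva_id, n_gaps)
        tracks.append(SpineTrack(larva_id=str(larva_id), fps=fps, points=pts))
    return tracks


def _infer_fps(df: pd.DataFrame) -> float:
    g = df.sort_values(["larva_id", "frame"])
    dt = g.groupby("larva_id")["time_s"].diff()
    dframe = g.groupby("larva_id")["frame"].diff()
    step = (dt / dframe).dropna()
    if step.empty or (step <= 0).any():
        raise SchemaError("cannot infer fps from time_s column")
    # snap away float noise from the time column (frame rates are not
    # meaningful beyond microhertz)
    return float(np.round(1.0 / step.median(), 6))


def write_cohort_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_cohort_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("larva_id", "genotype", "seed"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing metadata column {c!r}")
    return df


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: ImageStack, path) -> None:
    """Write a two-channel stack as 16-bit TIFF, axes (c, z, y, x).

    Values are rounded and clipped into the uint16 range; integer-valued
    inputs round-trip losslessly.
    """
    px = np.asarray(stack.pixels)
    if np.issubdtype(px.dtype, np.floating):
        px = np.clip(np.rint(px), 0, np.iinfo(np.uint16).max)
    data = px.astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "CZYX"})


def write_mask(masks: NucleusMaskSet, path) -> None:
    tifffile.imwrite(path, masks.labels.astype(np.uint16))


def read_stack(path_tiff, path_mask):
    """Read a stack and its nuclear mask; returns (ImageStack, NucleusMaskSet).

    Raises on channel count != 2 or (y, x) shape mismatch between the two
    files.  An all-background mask yields an empty mask set with a warning.
    """
    px = tifffile.imread(path_tiff)
    if px.ndim != 4:
        raise SchemaError(f"{path_tiff}: expected 4D (c, z, y, x), got {px.ndim}D")
    if px.shape[0] != 2:
        raise SchemaError(f"{path_tiff}: expected 2 channels, got {px.shape[0]}")
    labels = tifffile.imread(path_mask)
    if labels.ndim != 2:
        raise SchemaError(f"{path_mask}: mask must be 2D")
    if labels.shape != px.shape[2:]:
        raise SchemaError(
            f"mask shape {labels.shape} does not match stack (y, x) {px.shape[2:]}"
        )
    masks = NucleusMaskSet(labels=labels.astype(np.int64))
    if masks.ids.size == 0:
        warnings.warn(f"{path_mask}: mask contains no labelled nuclei")
        logger.warning("%s: mask contains no labelled nuclei", path_mask)
    return ImageStack(pixels=px), masks


# ---------------------------------------------------------------------------
# YAML configs


def save_config(mapping: dict, path) -> None:
    out = dict(mapping)
    out.setdefault("config_version", CONFIG_VERSION)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def load_packaged_config(name: str) -> dict:
    """Load one of the configs shipped with the package (by stem name)."""
    from importlib.resources import files

    res = files("larvaquant") / "configs" / f"{name}.yaml"
    cfg = yaml.safe_load(res.read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"packaged config {name!r} malformed")
    return cfg


def packaged_config_names():
    from importlib.resources import files

    d = files("larvaquant") / "configs"
    return sorted(p.name[:-5] for p in d.iterdir() if p.name.endswith(".yaml"))
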