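"""Readers/writers for the toolkit's standard artefacts.

All coordinates are physical micrometres in the image frame (origin at the
upper-left corner, y increasing downward); time is minutes internally, with
hours-post-injury kept only as display metadata. CSV files are
comma-separated, dot-decimal, UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon

__all__ = [
    "FormatError",
    "ValidationError",
    "Track",
    "TrackSet",
    "ImageStack",
    "OutlineStack",
    "MaskSeries",
    "read_tracks",
    "write_tracks",
    "read_outline_stack",
    "write_outline_stack",
    "read_image_stack",
    "write_image_stack",
    "read_mask_series",
    "write_mask_series",
    "load_config",
    "resolve_config",
]

CELL_TYPES = ("neuron", "microglia", "other")


class FormatError(ValueError):
    """A file does not match the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class Track:
    """One cell's time-stamped positions in physical units.

    Parameters
    ----------
    track_id : str
        Identifier unique within its :class:`TrackSet`.
    t : ndarray, minutes, strictly increasing.
    xy : ndarray of shape (n, 2) or (n, 3), micrometres. A third column is
        the optional z coordinate; 2D tracks simply omit it.
    cell_type : {"neuron", "microglia", "other"}
    animal_id : str
    """

    track_id: str
    t: np.ndarray
    xy: np.ndarray
    cell_type: str = "other"
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] not in (2, 3):
            raise ValidationError(
                f"track {self.track_id!r}: positions must be (n, 2) or (n, 3)"
            )
        if len(self.t) != len(self.xy):
            raise ValidationError(f"track {self.track_id!r}: t/position length mismatch")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValidationError(f"track {self.track_id!r}: non-finite coordinate")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError(
                f"track {self.track_id!r}: time stamps not strictly increasing"
            )
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"track {self.track_id!r}: unknown cell_type {self.cell_type!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def is_3d(self) -> bool:
        return self.xy.shape[1] == 3

    @property
    def xy2d(self) -> np.ndarray:
        """Planar (x, y) coordinates, shape (n, 2)."""
        return self.xy[:, :2]


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval: float = 1.0  # minutes, provenance metadata
    pixel_size: float = 1.0  # micrometres/pixel, provenance metadata

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValidationError("TrackSet must contain at least one track")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class ImageStack:
    """Time-lapse intensity data, axes (t, y, x) or (t, z, y, x)."""

    data: np.ndarray
    pixel_size: float  # micrometres
    frame_interval: float  # minutes
    z_step: float | None = None  # micrometres, 3D stacks only
    t0_hpi: float = 0.0  # hours post injury of the first frame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValidationError("ImageStack data must be (t, y, x) or (t, z, y, x)")
        if self.data.ndim == 4 and self.z_step is None:
            raise ValidationError("3D stack requires z_step")
        if np.any(self.data < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class OutlineStack:
    """Per-plane polygon outlines of an injury site.

    ``outlines`` maps each imaged optical plane (integer z index) to a simple
    polygon of (x, y) vertices in micrometres. An empty list is allowed and
    represents a fully healed (vanished) injury.
    """

    outlines: list[tuple[int, np.ndarray]]
    z_step: float  # micrometres between planes

    def __post_init__(self) -> None:
        checked = []
        for z_index, verts in self.outlines:
            verts = np.asarray(verts, dtype=float)
            _validate_polygon(verts, z_index)
            checked.append((int(z_index), verts))
        self.outlines = checked
        if self.z_step <= 0:
            raise ValidationError("z_step must be positive")

    def __len__(self) -> int:
        return len(self.outlines)


@dataclass
class MaskSeries:
    """Ordered binary masks from a laser-ablation time series."""

    masks: np.ndarray  # (n, y, x) bool
    times: np.ndarray  # seconds, strictly increasing
    pixel_size: float  # micrometres/pixel

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.masks.ndim != 3:
            raise ValidationError("masks must be a (n, y, x) array")
        if len(self.times) != self.masks.shape[0]:
            raise ValidationError("times length must match number of masks")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("mask times must be strictly increasing")

    def __len__(self) -> int:
        return self.masks.shape[0]


def _validate_polygon(verts: np.ndarray, z_index: int | None = None) -> Polygon:
    where = "" if z_index is None else f" at z_index {z_index}"
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValidationError(f"polygon{where}: need >= 3 (x, y) vertices")
    if not np.all(np.isfinite(verts)):
        raise ValidationError(f"polygon{where}: non-finite vertex")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise ValidationError(f"polygon{where}: self-intersecting or degenerate")
    return poly


# ---------------------------------------------------------------------------
# track CSV I/O
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["track_id", "cell_type", "animal_id", "t_min", "x_um", "y_um"]


def read_tracks(
    path: str | Path,
    dialect: str = "generic_csv",
    *,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    z_step: float = 1.0,
) -> TrackSet:
    """Read a cell-tracking table into a :class:`TrackSet`.

    ``generic_csv`` is this package's own format (columns ``track_id,
    cell_type, animal_id, t_min, x_um, y_um[, z_um]``, physical units).
    ``mtrackj_points`` maps a point export from a manual tracker by column
    position -- (track, point, x_px, y_px, z_plane, t_frame) -- and converts
    pixels/frames to micrometres/minutes using the keyword metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "generic_csv":
        df = pd.read_csv(path)
        missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        has_z = "z_um" in df.columns and df["z_um"].notna().all()
        tracks = []
        for tid, grp in df.groupby("track_id", sort=False):
            xy_cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
            t = grp["t_min"].to_numpy(float)
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"{path}: non-monotonic time within track {tid!r}"
                )
            tracks.append(
                Track(
                    track_id=str(tid),
                    t=t,
                    xy=grp[xy_cols].to_numpy(float),
                    cell_type=str(grp["cell_type"].iloc[0]),
                    animal_id=str(grp["animal_id"].iloc[0]),
                )
            )
        return TrackSet(tracks, frame_interval=frame_interval, pixel_size=pixel_size)
    if dialect == "mtrackj_points":
        df = pd.read_csv(path, header=0)
        if df.shape[1] < 6:
            raise FormatError(
                f"{path}: point export needs >= 6 columns "
                "(track, point, x_px, y_px, z_plane, t_frame)"
            )
        cols = df.columns
        tracks = []
        for tid, grp in df.groupby(cols[0], sort=False):
            grp = grp.sort_values(cols[1])
            t = grp.iloc[:, 5].to_numpy(float) * frame_interval
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"{path}: non-monotonic time within track {tid!r}"
                )
            xyz = np.column_stack(
                [
                    grp.iloc[:, 2].to_numpy(float) * pixel_size,
                    grp.iloc[:, 3].to_numpy(float) * pixel_size,
                    grp.iloc[:, 4].to_numpy(float) * z_step,
                ]
            )
            tracks.append(Track(track_id=str(tid), t=t, xy=xyz))
        return TrackSet(tracks, frame_interval=frame_interval, pixel_size=pixel_size)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet as a generic CSV, one row per sample.

    Rows are ordered deterministically (track id, then time); coordinates
    are written with 17 significant digits so a write/read round trip is
    lossless.
    """
    path = Path(path)
    rows = []
    for tr in sorted(ts.tracks, key=lambda tr: tr.track_id):
        for i in range(tr.n_samples):
            row = {
                "track_id": tr.track_id,
                "cell_type": tr.cell_type,
                "animal_id": tr.animal_id,
                "t_min": tr.t[i],
                "x_um": tr.xy[i, 0],
                "y_um": tr.xy[i, 1],
            }
            if tr.is_3d:
                row["z_um"] = tr.xy[i, 2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# outline stacks (JSON)
# ---------------------------------------------------------------------------


def read_outline_stack(path: str | Path) -> OutlineStack:
    """Read per-plane injury outlines from JSON (see :func:`write_outline_stack`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("z_step", "outlines"):
        if key not in doc:
            raise FormatError(f"{path}: missing key {key!r}")
    outlines = [
        (int(o["z_index"]), np.asarray(o["vertices"], dtype=float))
        for o in doc["outlines"]
    ]
    return OutlineStack(outlines=outlines, z_step=float(doc["z_step"]))


def write_outline_stack(stack: OutlineStack, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "z_step": stack.z_step,
        "outlines": [
            {"z_index": z, "vertices": verts.tolist()} for z, verts in stack.outlines
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
    return path


# ---------------------------------------------------------------------------
# TIFF stacks and masks
# ---------------------------------------------------------------------------


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF with metadata in the image description."""
    path = Path(path)
    meta = {
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "z_step": stack.z_step,
        "t0_hpi": stack.t0_hpi,
        "ndim": stack.data.ndim,
    }
    tifffile.imwrite(
        path, stack.data.astype(np.float32), description=json.dumps(meta),
        photometric="minisblack"
    )
    return path


def read_image_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing/unreadable metadata description") from exc
    if data.ndim == 2:
        data = data[None]
    if meta.get("ndim") == 4 and data.ndim == 3:
        # tifffile may flatten a (t, z, y, x) stack written page-wise
        raise FormatError(f"{path}: 4D metadata but 3D pages; rewrite the stack")
    return ImageStack(
        data=data,
        pixel_size=float(meta["pixel_size"]),
        frame_interval=float(meta["frame_interval"]),
        z_step=None if meta.get("z_step") is None else float(meta["z_step"]),
        t0_hpi=float(meta.get("t0_hpi", 0.0)),
    )


def write_mask_series(ms: MaskSeries, path: str | Path) -> Path:
    """Write masks as a 0/255 multi-page TIFF, times in the description."""
    path = Path(path)
    meta = {"times_s": ms.times.tolist(), "pixel_size": ms.pixel_size}
    tifffile.imwrite(
        path, (ms.masks.astype(np.uint8) * 255), description=json.dumps(meta),
        photometric="minisblack"
    )
    return path


def read_mask_series(path: str | Path) -> MaskSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing/unreadable metadata description") from exc
    if data.ndim == 2:
        data = data[None]
    return MaskSeries(
        masks=data > 0,
        times=np.asarray(meta["times_s"], dtype=float),
        pixel_size=float(meta["pixel_size"]),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML key/value configuration tree."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def resolve_config(user: dict, defaults: dict) -> dict:
    """Merge a user configuration over documented defaults.

    Unknown keys are rejected rather than silently ignored, so typos in a
    run configuration cannot change the analysis unnoticed.
    """
    unknown = sorted(set(user) - set(defaults))
    if unknown:
        raise ValidationError(f"unknown configuration key(s): {unknown}")
    merged = dict(defaults)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(defaults.get(key), dict):
            merged[key] = resolve_config(value, defaults[key])
        else:
            merged[key] = value
    return merged
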