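"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* Voxel grids are ``(z, y, x, channel)`` float arrays with calibration in µm,
  axis order ``(dz, dy, dx)``. Default calibration is 0.23 µm axially and
  0.1 µm laterally (widefield Z-stack acquisition).
* Single-molecule localization tables use nm throughout, with the origin at
  the top-left corner of raw pixel (0, 0). Frames are 0-based internally;
  the ThunderSTORM CSV dialect stores them 1-based and is converted on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, SchemaError

DEFAULT_VOXEL_SIZE = (0.23, 0.1, 0.1)  # (dz, dy, dx) µm

#: canonical localization-table columns, in storage order
LOC_COLUMNS = [
    "frame", "x", "y", "uncertainty", "sigma_psf", "photons",
    "merged_id", "is_fiducial",
]

_THUNDERSTORM_MAP = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "sigma [nm]": "sigma_psf",
    "intensity [photon]": "photons",
    "uncertainty [nm]": "uncertainty",
}
_SIMPLE_REQUIRED = ["frame", "x", "y", "uncertainty"]


@dataclass
class VoxelGrid:
    """Calibrated multichannel 3D intensity stack.

    Parameters
    ----------
    data
        ``(Z, Y, X, C)`` array of non-negative intensities. A 3D array is
        promoted to a single channel.
    voxel_size
        ``(dz, dy, dx)`` in µm, all positive.
    channel_names
        One name per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise FormatError(f"expected a 3D or 4D stack, got ndim={self.data.ndim}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[-1])]
        if len(self.channel_names) != self.data.shape[-1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[-1]} channels"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (Z, Y, X)."""
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel as a (Z, Y, X) view; accepts index or name."""
        if isinstance(key, str):
            if key not in self.channel_names:
                raise SchemaError(f"channel {key!r} not in {self.channel_names}")
            key = self.channel_names.index(key)
        if not 0 <= key < self.n_channels:
            raise SchemaError(f"channel index {key} out of range (n={self.n_channels})")
        return self.data[..., key]


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as TIFF with calibration metadata.

    Calibration and channel names are stored in the ImageDescription JSON so
    that :func:`read_stack` round-trips them exactly.
    """
    tifffile.imwrite(
        Path(path),
        np.ascontiguousarray(grid.data),
        metadata={
            "axes": "ZYXC",
            "voxel_size_um": list(grid.voxel_size),
            "channel_names": list(grid.channel_names),
        },
    )


def read_stack(
    path: str | Path,
    expected_channels: int | None = None,
    voxel_size: Sequence[float] | None = None,
) -> VoxelGrid:
    """Read a TIFF Z-stack into a calibrated :class:`VoxelGrid`.

    Calibration is taken from file metadata when present, else from the
    ``voxel_size`` argument, else package defaults (with a warning).

    Raises
    ------
    FormatError
        Unreadable file, or axis/channel-count mismatch.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except Exception as exc:  # tifffile raises a zoo of exceptions
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc

    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected Z-stack (3 or 4 axes), got {data.ndim} axes")

    names = list(meta.get("channel_names", []))
    if "voxel_size_um" in meta:
        cal = tuple(float(v) for v in meta["voxel_size_um"])
    elif voxel_size is not None:
        cal = tuple(float(v) for v in voxel_size)
    else:
        warnings.warn(
            f"{path}: no calibration metadata; assuming {DEFAULT_VOXEL_SIZE} µm",
            stacklevel=2,
        )
        cal = DEFAULT_VOXEL_SIZE

    grid = VoxelGrid(data.astype(np.float64), cal, names)
    if expected_channels is not None and grid.n_channels != expected_channels:
        raise FormatError(
            f"{path}: channel axis has {grid.n_channels} channels, "
            f"expected {expected_channels}"
        )
    return grid


def read_localizations(path: str | Path, dialect: str = "thunderstorm") -> pd.DataFrame:
    """Read a localization CSV into the canonical table.

    Dialects
    --------
    ``"thunderstorm"``
        Columns ``frame, x [nm], y [nm], sigma [nm], intensity [photon],
        uncertainty [nm]`` with 1-based frames (converted to 0-based).
    ``"simple"``
        Columns ``frame, x, y, uncertainty`` (nm, 0-based frames).

    Returns a DataFrame with columns :data:`LOC_COLUMNS`.
    """
    df = pd.read_csv(Path(path))
    df.columns = [c.strip() for c in df.columns]
    if dialect == "thunderstorm":
        required = list(_THUNDERSTORM_MAP)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing thunderstorm columns {missing}")
        out = df[required].rename(columns=_THUNDERSTORM_MAP)
        out["frame"] = out["frame"].astype(int) - 1  # 1-based on disk
    elif dialect == "simple":
        missing = [c for c in _SIMPLE_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        out = df[_SIMPLE_REQUIRED].copy()
        out["frame"] = out["frame"].astype(int)
        for opt in ("sigma_psf", "photons"):
            if opt in df.columns:
                out[opt] = df[opt]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in LOC_COLUMNS:
        if col not in out.columns:
            out[col] = False if col == "is_fiducial" else np.nan
    if "is_fiducial" in df.columns:
        out["is_fiducial"] = df["is_fiducial"].astype(bool)
    out["is_fiducial"] = out["is_fiducial"].astype(bool)
    return out[LOC_COLUMNS].reset_index(drop=True)


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical localization table in the ``simple`` dialect (nm units)."""
    cols = [c for c in LOC_COLUMNS if c in df.columns]
    write_measurements(df[cols], path)


def write_measurements(records, path: str | Path) -> None:
    """Write any flat record table as a reproducible CSV.

    Accepts a DataFrame, a list of dicts, or a list of dataclasses. Column
    order is preserved; floats are rendered at 6 significant digits, so two
    writes of the same input are byte-identical.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r if isinstance(r, dict) else vars(r) for r in records]
        df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False, float_format="%.6g", lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    """Write a JSON sidecar (ground truth, run manifests); arrays become lists."""

    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
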