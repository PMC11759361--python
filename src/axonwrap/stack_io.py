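"""Calibrated multichannel z-stack I/O and the plate manifest.

The whole pipeline assumes one axis convention: voxel arrays are indexed
``(channel, z, y, x)`` with z index 0 the first acquired slice, all
coordinates 0-based, and pixel centers at integer coordinates.  Physical
calibration (in-plane pixel size and axial step, both in micrometres)
travels with the array inside :class:`ImageStack` and survives a TIFF
round-trip via a JSON payload in the image description tag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: The three channel roles every stack must provide.
CHANNEL_ROLES = ("axon", "myelin", "nuclei")

_META_KEY = "axonwrap"


class StackError(ValueError):
    """Raised for malformed stacks, files or manifests."""


@dataclass
class ImageStack:
    """Three-channel voxel volume with physical calibration.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, n_slices, height, width)``.
    channel_roles
        Map from role (``"axon"``, ``"myelin"``, ``"nuclei"``) to channel
        index.  The three roles must map to distinct channels.
    pixel_size_um
        In-plane pixel size, µm per pixel.
    z_step_um
        Axial spacing between consecutive slices, µm.
    """

    voxels: np.ndarray
    channel_roles: Mapping[str, int]
    pixel_size_um: float
    z_step_um: float
    field_id: str = ""
    well_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise StackError(
                f"voxels must be (channel, z, y, x); got shape {self.voxels.shape}"
            )
        missing = [r for r in CHANNEL_ROLES if r not in self.channel_roles]
        if missing:
            raise StackError(f"missing channel role(s): {missing}")
        idx = [int(self.channel_roles[r]) for r in CHANNEL_ROLES]
        if len(set(idx)) != len(idx):
            raise StackError(f"channel roles must map to distinct channels: {idx}")
        n_chan = self.voxels.shape[0]
        if any(i < 0 or i >= n_chan for i in idx):
            raise StackError(
                f"channel index out of range for {n_chan}-channel stack: {idx}"
            )
        if not (self.pixel_size_um > 0):
            raise StackError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.z_step_um > 0):
            raise StackError(f"z_step_um must be > 0, got {self.z_step_um}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a channel role."""
        if role not in self.channel_roles:
            raise StackError(f"unknown channel role {role!r}")
        return self.voxels[int(self.channel_roles[role])]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a lossless multi-page TIFF in (C, Z, Y, X) order.

    Integer dtypes are written as-is; floating-point data as 32-bit float.
    Calibration, channel roles and labels go into the description tag and are
    recovered bit-exactly by :func:`read_stack`.  NaN voxels are rejected.
    """
    path = Path(path)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        if np.isnan(data).any():
            raise StackError("stack contains NaN voxels; refusing to write")
        data = data.astype(np.float32)
    meta = {
        _META_KEY: {
            "channel_roles": {k: int(v) for k, v in stack.channel_roles.items()},
            "pixel_size_um": float(stack.pixel_size_um),
            "z_step_um": float(stack.z_step_um),
            "field_id": stack.field_id,
            "well_id": stack.well_id,
            "condition": stack.condition,
        }
    }
    # tifffile's shaped description carries both the 4-D shape and our payload
    tifffile.imwrite(path, data, photometric="minisblack", metadata=meta)
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into a validated :class:`ImageStack`.

    Metadata embedded by :func:`write_stack` is used when present; explicit
    arguments always override file metadata (with a logged warning), because
    exported TIFFs frequently lack or corrupt physical calibration.

    Raises
    ------
    StackError
        If the file is unreadable, a channel role is missing, or no
        calibration is available from either source.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            shaped = tif.shaped_metadata
            desc = tif.pages[0].description or ""
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackError(f"cannot read stack {path}: {exc}") from exc

    meta: dict = {}
    if shaped:
        meta = dict(shaped[0]).get(_META_KEY, {})
    elif desc:
        try:
            meta = json.loads(desc).get(_META_KEY, {})
        except (json.JSONDecodeError, AttributeError):
            meta = {}

    if data.ndim == 3:
        # single-channel file; promote so the role check below reports cleanly
        data = data[None]
    if data.ndim != 4:
        raise StackError(f"expected a (C, Z, Y, X) stack in {path}, got {data.shape}")

    roles = dict(channel_map) if channel_map is not None else meta.get("channel_roles")
    if roles is None:
        raise StackError(f"{path}: no channel map given and none stored in file")
    for role in CHANNEL_ROLES:
        if role not in roles:
            raise StackError(f"{path}: missing role {role!r} in channel map")
        if not (0 <= int(roles[role]) < data.shape[0]):
            raise StackError(
                f"{path}: role {role!r} maps to channel {roles[role]} but file "
                f"has {data.shape[0]} channel(s)"
            )

    def _resolve(name: str, explicit: float | None) -> float:
        stored = meta.get(name)
        if explicit is not None:
            if stored is not None and not np.isclose(stored, explicit):
                logger.warning(
                    "%s: overriding file %s=%s with explicit %s", path, name, stored, explicit
                )
            return float(explicit)
        if stored is None:
            raise StackError(f"{path}: {name} not in file metadata and not given")
        return float(stored)

    return ImageStack(
        voxels=data,
        channel_roles=roles,
        pixel_size_um=_resolve("pixel_size_um", pixel_size_um),
        z_step_um=_resolve("z_step_um", z_step_um),
        field_id=str(meta.get("field_id", "")),
        well_id=str(meta.get("well_id", "")),
        condition=str(meta.get("condition", "")),
    )


@dataclass
class PlateManifest:
    """One row per imaged field: well, field, condition label, stack path."""

    table: pd.DataFrame = field(repr=False, default=None)

    REQUIRED = ("well_id", "field_id", "condition", "path")

    def __post_init__(self) -> None:
        if self.table is None:
            raise StackError("manifest table is required")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise StackError(f"manifest missing column(s): {missing}")
        dup = self.table.duplicated(subset=["well_id", "field_id"])
        if dup.any():
            rows = self.table.loc[dup, ["well_id", "field_id"]].to_records(index=False)
            raise StackError(f"duplicate (well_id, field_id) keys: {list(rows)[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())


def load_manifest(path: str | Path, check_paths: bool = True) -> PlateManifest:
    """Load and validate a plate manifest CSV.

    Relative stack paths are resolved against the manifest's directory.
    Every referenced file must exist unless ``check_paths`` is False.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"well_id": str, "field_id": str, "condition": str})
    manifest = PlateManifest(table=table)
    root = path.parent
    resolved = [
        p if Path(p).is_absolute() else str(root / p) for p in table["path"].astype(str)
    ]
    manifest.table = table.assign(path=resolved)
    if check_paths:
        for i, p in enumerate(resolved):
            if not Path(p).exists():
                row = table.iloc[i]
                raise StackError(
                    f"manifest row {i} (well {row['well_id']}, field "
                    f"{row['field_id']}): file not found: {p}"
                )
    return manifest
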