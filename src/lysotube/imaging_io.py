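"""TIFF stacks, sidecar metadata, CSV tables and screen manifests.

The sidecar JSON written next to every stack is the authoritative source of
pixel size and frame interval; TIFF resolution tags are used as a fallback,
and explicit defaults passed by the caller come last.  Whatever source wins
is logged, so a processing run can always be traced to its calibration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "StackMeta",
    "ConditionManifest",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "load_manifest",
]


@dataclass(frozen=True)
class StackMeta:
    """Calibration and layout of a time-lapse stack (axes T, Y, X)."""

    pixel_size_nm: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("channel0",)
    axes: str = "TYX"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")


@dataclass(frozen=True)
class ConditionManifest:
    """One screen condition (an siRNA) and the images acquired for it."""

    condition_id: str
    image_paths: tuple[Path, ...]
    role: str = "candidate"  # candidate | positive_control | negative_control
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("candidate", "positive_control", "negative_control"):
            raise ValueError(f"unknown manifest role: {self.role!r}")
        if len(self.image_paths) == 0:
            raise ValueError(f"condition {self.condition_id!r} has no images")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path, stack: np.ndarray, meta: StackMeta) -> Path:
    """Write a (T, Y, X) stack as multi-page TIFF plus a sidecar JSON."""
    path = Path(path)
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) stack, got shape {arr.shape}")
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = dataclasses.asdict(meta)
    sidecar["channel_names"] = list(meta.channel_names)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(
    path,
    default_pixel_size_nm: float | None = None,
    default_frame_interval_s: float | None = None,
) -> tuple[np.ndarray, StackMeta]:
    """Read a TIFF stack, normalising axes to (T, Y, X).

    Metadata resolution order: sidecar JSON > TIFF XResolution tag (pixel
    size only) > caller-supplied defaults.  A missing pixel size or frame
    interval with no default raises a ``ValueError`` naming the field.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"unsupported stack dimensionality: {arr.shape}")

    sidecar = _sidecar_path(path)
    meta_src: dict = {}
    if sidecar.exists():
        meta_src = json.loads(sidecar.read_text())
        source = "sidecar JSON"
    elif tag_px is not None:
        meta_src = {"pixel_size_nm": tag_px}
        source = "TIFF resolution tag"
    else:
        source = "caller defaults"

    pixel_size = meta_src.get("pixel_size_nm", default_pixel_size_nm)
    interval = meta_src.get("frame_interval_s", default_frame_interval_s)
    if pixel_size is None:
        raise ValueError(
            f"{path}: pixel_size_nm not found in sidecar or TIFF tags and no "
            "default supplied"
        )
    if interval is None:
        raise ValueError(
            f"{path}: frame_interval_s not found in sidecar and no default supplied"
        )
    logger.info("read %s: %d frames, metadata from %s", path.name, len(arr), source)
    meta = StackMeta(
        pixel_size_nm=float(pixel_size),
        frame_interval_s=float(interval),
        channel_names=tuple(meta_src.get("channel_names", ("channel0",))),
    )
    return arr, meta


def _pixel_size_from_tags(tif) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    unit_code = None
    if unit is not None:
        unit_code = int(getattr(unit.value, "value", unit.value))
    # pixels per unit -> nm per pixel; ResolutionUnit 3 = cm, 2 = inch
    unit_nm = {2: 2.54e7, 3: 1e7}.get(unit_code)
    if unit_nm is None:
        return None
    return unit_nm * den / num


def write_table(records: Sequence | pd.DataFrame, path, columns=None) -> Path:
    """Write records (dataclasses, dicts or a DataFrame) as CSV.

    An empty record list with ``columns`` given produces a header-only file.
    Floats are written at full round-trip precision.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=columns if (columns or not rows) else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    # default float formatting is the shortest round-trip representation
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_manifest(path) -> list[ConditionManifest]:
    """Load a screen manifest JSON: a list of condition entries.

    Each entry: ``{"condition_id": ..., "images": [...], "role": ...,
    "replicate_id": ...}``.  Every image path must exist; paths are resolved
    relative to the manifest file.
    """
    path = Path(path)
    entries = json.loads(path.read_text())
    manifests = []
    for entry in entries:
        paths = tuple((path.parent / p).resolve() for p in entry["images"])
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest {path}: image not found: {p}"
                )
        manifests.append(
            ConditionManifest(
                condition_id=entry["condition_id"],
                image_paths=paths,
                role=entry.get("role", "candidate"),
                replicate_id=entry.get("replicate_id", ""),
            )
        )
    return manifests
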