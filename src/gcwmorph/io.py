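"""Readers and writers for stacks, label maps, and morphometry reports.

Stacks and label maps are stored as multi-page 16-bit unsigned TIFF with a
small YAML sidecar carrying the channel layout and voxel geometry; this
keeps the on-disk dialect trivial and bit-exactly portable.  Page order is
channel-fastest: page ``z * n_channels + c`` holds slice ``z`` of channel
``c``.  Reports are written as an RFC-4180 per-granule CSV plus a JSON
summary.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ValidationError
from .types import (
    PER_GRANULE_COLUMNS,
    ChannelSpec,
    Direction,
    GCWEnvelope,
    ImageStack,
    LabelMap,
    Modality,
    MorphometryReport,
    VoxelGeometry,
)

PathLike = Union[str, os.PathLike]


def _channel_to_dict(spec: ChannelSpec) -> dict:
    d: dict = {"modality": spec.modality.value}
    if spec.modality is Modality.SHG:
        d["direction"] = spec.direction.value
        d["polarization_deg"] = spec.polarization_deg
    return d


def _channel_from_dict(d: dict) -> ChannelSpec:
    try:
        modality = Modality(d["modality"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad channel entry in metadata: {d!r}") from exc
    if modality is Modality.EF:
        return ChannelSpec(Modality.EF)
    try:
        return ChannelSpec(
            modality, Direction(d["direction"]), int(d["polarization_deg"])
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise FormatError(f"bad SHG channel entry in metadata: {d!r}") from exc


def _geometry_from_meta(meta: dict) -> VoxelGeometry:
    try:
        geo = meta["geometry"]
        pixel = float(geo["pixel_size_xy_um"])
        z_step = float(geo["z_step_um"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError("metadata is missing a valid 'geometry' section") from exc
    try:
        return VoxelGeometry(pixel, z_step)
    except ValidationError:
        raise


def write_stack(stack: ImageStack, path: PathLike, metadata_path: PathLike) -> None:
    """Write a multi-channel stack as uint16 multi-page TIFF + YAML sidecar.

    Float stacks are quantized to uint16 with a single global scale factor
    recorded in the metadata; uint16 stacks are written verbatim.
    """
    voxels = stack.voxels
    if voxels.dtype == np.uint16:
        pages = voxels
        scale = 1.0
    else:
        vmax = float(voxels.max(initial=0.0))
        scale = 65535.0 / vmax if vmax > 0 else 1.0
        pages = np.round(voxels * scale).astype(np.uint16)
    nz = stack.shape[0]
    # channel-fastest page order: (z, c, y, x)
    page_stream = np.transpose(pages, (1, 0, 2, 3)).reshape(
        nz * stack.n_channels, *stack.shape[1:]
    )
    tifffile.imwrite(path, page_stream, photometric="minisblack")
    meta = {
        "format": "gcwmorph-stack",
        "page_order": "channel_fastest",
        "intensity_scale": scale,
        "geometry": {
            "pixel_size_xy_um": stack.geometry.pixel_size_xy,
            "z_step_um": stack.geometry.z_step,
        },
        "shape": {
            "z": int(stack.shape[0]),
            "y": int(stack.shape[1]),
            "x": int(stack.shape[2]),
        },
        "channels": [_channel_to_dict(c) for c in stack.channels],
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_stack(path: PathLike, metadata_path: PathLike) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises :class:`FormatError` when the metadata is missing or contradicts
    the TIFF page count/shape.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    if not path.exists():
        raise FormatError(f"stack file not found: {path}")
    if not metadata_path.exists():
        raise FormatError(f"metadata file not found: {metadata_path}")
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "channels" not in meta:
        raise FormatError(f"metadata {metadata_path} lacks a 'channels' section")
    channels = [_channel_from_dict(d) for d in meta["channels"]]
    geometry = _geometry_from_meta(meta)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # corrupted TIFF
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(channels)
    if pages.shape[0] % n_channels != 0:
        raise FormatError(
            f"{pages.shape[0]} TIFF pages are not divisible by {n_channels} channels"
        )
    nz = pages.shape[0] // n_channels
    if "shape" in meta:
        declared = (meta["shape"]["z"], meta["shape"]["y"], meta["shape"]["x"])
        if declared != (nz, pages.shape[1], pages.shape[2]):
            raise FormatError(
                f"metadata shape {declared} contradicts TIFF pages {pages.shape}"
            )
    voxels = pages.reshape(nz, n_channels, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return ImageStack(channels=channels, voxels=voxels, geometry=geometry)


def write_labels(labels: LabelMap, path: PathLike, metadata_path: PathLike) -> None:
    if labels.n_labels > 65535:
        raise ValidationError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")
    meta = {
        "format": "gcwmorph-labels",
        "geometry": {
            "pixel_size_xy_um": labels.geometry.pixel_size_xy,
            "z_step_um": labels.geometry.z_step,
        },
        "n_labels": int(labels.n_labels),
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_labels(path: PathLike, metadata_path: PathLike) -> LabelMap:
    path, metadata_path = Path(path), Path(metadata_path)
    if not path.exists() or not metadata_path.exists():
        raise FormatError(f"label map files not found: {path}, {metadata_path}")
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    geometry = _geometry_from_meta(meta)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMap(labels=arr.astype(np.int32), geometry=geometry)


def write_envelope(envelope: GCWEnvelope, path: PathLike) -> None:
    tifffile.imwrite(
        path, envelope.mask.astype(np.uint16) * 65535, photometric="minisblack"
    )


def _report_paths(path: PathLike) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    return base.with_name(base.name + "_granules.csv"), base.with_name(
        base.name + "_summary.json"
    )


def write_report(report: MorphometryReport, path: PathLike) -> tuple[Path, Path]:
    """Write ``<path>_granules.csv`` and ``<path>_summary.json``.

    The report is re-validated before writing; numeric fields survive a
    round trip to 1e-9 relative (repr-precision floats).
    """
    report.validate()
    csv_path, json_path = _report_paths(path)
    report.per_granule.to_csv(csv_path, index=False, lineterminator="\r\n")
    summary = {
        "starch_fraction_mean": report.starch_fraction_mean,
        "starch_fraction_sd": report.starch_fraction_sd,
        "n_granules": report.n_granules,
        "class_number_pct": report.class_number_pct,
        "class_volume_pct": report.class_volume_pct,
        "length_um": report.length_um,
        "width_um": report.width_um,
        "depth_um": report.depth_um,
        "wall_class": report.wall_class,
        "extras": _jsonable(report.extras),
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return csv_path, json_path


def read_report(path: PathLike) -> MorphometryReport:
    csv_path, json_path = _report_paths(path)
    if not csv_path.exists() or not json_path.exists():
        raise FormatError(f"report files not found at base {path}")
    with open(json_path) as fh:
        summary = json.load(fh)
    if os.path.getsize(csv_path) > 0:
        per_granule = pd.read_csv(csv_path)
    else:
        per_granule = pd.DataFrame(columns=list(PER_GRANULE_COLUMNS))
    if per_granule.empty:
        per_granule = pd.DataFrame(columns=list(PER_GRANULE_COLUMNS))
    return MorphometryReport(
        starch_fraction_mean=summary.get("starch_fraction_mean"),
        starch_fraction_sd=summary.get("starch_fraction_sd"),
        per_granule=per_granule,
        class_number_pct=summary.get("class_number_pct", {}),
        class_volume_pct=summary.get("class_volume_pct", {}),
        length_um=summary.get("length_um"),
        width_um=summary.get("width_um"),
        depth_um=summary.get("depth_um"),
        wall_class=summary.get("wall_class"),
        extras=summary.get("extras", {}),
    )


def _jsonable(obj):
    """Best-effort conversion of nested report extras to JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj
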