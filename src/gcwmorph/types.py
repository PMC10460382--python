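"""Core domain types for multiphoton gas-cell-wall (GCW) quantification.

A dough GCW stack is a multi-channel 3D scalar field: eight polarized
second-harmonic-generation (SHG) channels (backward/forward detection at
linear polarization 0/45/90/135 degrees) that image starch granules, plus one
endogenous-fluorescence (EF) channel that images the gluten network.  Axis
order is fixed as ``(z, y, x)``; z index 0 is the shallowest slice and slice
``z`` covers physical depth ``[z * z_step, (z + 1) * z_step)`` (half-open).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

POLARIZATION_ANGLES = (0, 45, 90, 135)

#: Wheat-starch size-class boundaries in µm: C < 5, B in [5, 15], A > 15.
SIZE_CLASS_BOUNDS_UM = (5.0, 15.0)


class Modality(str, Enum):
    SHG = "SHG"
    EF = "EF"


class Direction(str, Enum):
    BACKWARD = "backward"
    FORWARD = "forward"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel dimensions of an acquisition.

    Defaults match a typical high-resolution GCW acquisition: 0.17 µm lateral
    pixels and a 0.5 µm z-step.
    """

    pixel_size_xy: float = 0.17
    z_step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and math.isfinite(self.pixel_size_xy)):
            raise ValidationError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if not (self.z_step > 0 and math.isfinite(self.z_step)):
            raise ValidationError(f"z_step must be > 0, got {self.z_step}")


@dataclass(frozen=True)
class ChannelSpec:
    """Identity of one acquisition channel.

    SHG channels carry a detection direction (backward/forward) and a linear
    polarization angle; the EF channel carries neither.
    """

    modality: Modality
    direction: Direction = Direction.NOT_APPLICABLE
    polarization_deg: Optional[int] = None

    def __post_init__(self) -> None:
        modality = Modality(self.modality)
        direction = Direction(self.direction)
        object.__setattr__(self, "modality", modality)
        object.__setattr__(self, "direction", direction)
        if modality is Modality.SHG:
            if direction is Direction.NOT_APPLICABLE:
                raise ValidationError("SHG channel requires a backward/forward direction")
            if self.polarization_deg not in POLARIZATION_ANGLES:
                raise ValidationError(
                    f"SHG polarization must be one of {POLARIZATION_ANGLES}, "
                    f"got {self.polarization_deg}"
                )
        else:
            if direction is not Direction.NOT_APPLICABLE or self.polarization_deg is not None:
                raise ValidationError("EF channel carries no direction or polarization")

    @property
    def label(self) -> str:
        if self.modality is Modality.EF:
            return "EF"
        prefix = "B" if self.direction is Direction.BACKWARD else "F"
        return f"{prefix}-SHG-{self.polarization_deg}"


def default_channel_layout() -> list[ChannelSpec]:
    """The standard 9-channel layout: {B,F}-SHG x {0,45,90,135} deg + EF."""
    specs = [
        ChannelSpec(Modality.SHG, direction, angle)
        for direction in (Direction.BACKWARD, Direction.FORWARD)
        for angle in POLARIZATION_ANGLES
    ]
    specs.append(ChannelSpec(Modality.EF))
    return specs


@dataclass
class ImageStack:
    """Multi-channel 3D intensity stack.

    ``voxels`` has shape ``(n_channels, z, y, x)``; all channels share the
    same grid and geometry.  Intensities must be finite and non-negative
    (either raw uint16 detector counts or float fields).
    """

    channels: list[ChannelSpec]
    voxels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"voxels must have shape (channels, z, y, x), got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel specs but {self.voxels.shape[0]} channel planes"
            )
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.isfinite(self.voxels).all():
                raise ValidationError("stack intensities must be finite")
            if (self.voxels < 0).any():
                raise ValidationError("stack intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(z, y, x) shape shared by all channels."""
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, spec: ChannelSpec) -> np.ndarray:
        for i, c in enumerate(self.channels):
            if c == spec:
                return self.voxels[i]
        raise InputError(f"channel {spec} not present in stack")

    def shg_channels(self) -> list[tuple[ChannelSpec, np.ndarray]]:
        return [
            (c, self.voxels[i])
            for i, c in enumerate(self.channels)
            if c.modality is Modality.SHG
        ]

    def ef_channel(self) -> np.ndarray:
        for i, c in enumerate(self.channels):
            if c.modality is Modality.EF:
                return self.voxels[i]
        raise InputError("stack has no EF channel")


@dataclass
class LabelMap:
    """Integer-labeled 3D segmentation: 0 = background, k >= 1 = granule id.

    Label ids form the contiguous set {1..K}.  Granule voxel sets are
    26-connected in 3D (8-connected in-plane); connectivity checking is
    optional because it is expensive on large volumes.
    """

    labels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"labels must be 3D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if (self.labels < 0).any():
            raise ValidationError("labels must be >= 0")
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValidationError("label ids must form a contiguous set {1..K}")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def check_connectivity(self) -> None:
        """Verify each label is a single 26-connected component (slow)."""
        from scipy import ndimage as ndi

        structure = np.ones((3, 3, 3), bool)
        for k in self.ids():
            _, n = ndi.label(self.labels == k, structure=structure)
            if n != 1:
                raise ValidationError(f"label {k} is not 26-connected ({n} components)")


@dataclass
class GCWEnvelope:
    """Per-slice binary mask delimiting the gas cell wall from the gas phase.

    ``z_extent`` is the inclusive slice range over which the mask is
    non-empty; ``depth_um`` is the z-extent span times the z-step.  Wall
    dimensions and the string/intact class are filled in by the
    morphometrics stage.
    """

    mask: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    length_um: Optional[float] = None
    width_um: Optional[float] = None
    depth_um: Optional[float] = None
    wall_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"envelope mask must be 3D, got ndim={self.mask.ndim}")
        if self.wall_class is not None and self.wall_class not in ("string", "intact"):
            raise ValidationError(f"wall_class must be 'string' or 'intact', got {self.wall_class!r}")

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def z_extent(self) -> Optional[tuple[int, int]]:
        """Inclusive (first, last) slice indices with a non-empty mask."""
        nonempty = np.flatnonzero(self.mask.any(axis=(1, 2)))
        if nonempty.size == 0:
            return None
        return int(nonempty[0]), int(nonempty[-1])

    @property
    def z_span_um(self) -> float:
        extent = self.z_extent
        if extent is None:
            return 0.0
        return (extent[1] - extent[0] + 1) * self.geometry.z_step


PER_GRANULE_COLUMNS = ("id", "z_slice", "max_feret_um", "volume_um3", "size_class")


@dataclass
class MorphometryReport:
    """Quantification output for one GCW.

    ``starch_fraction_mean``/``sd`` are the areal starch fraction (starch
    pixels over envelope pixels) averaged over slices spanning a fixed depth.
    ``per_granule`` holds one row per granule on the representative slice;
    the spherical-assumption volume V = pi d^3 / 6 must hold row-wise.  The
    per-class number and volume percentages each sum to 100.
    """

    starch_fraction_mean: Optional[float]
    starch_fraction_sd: Optional[float]
    per_granule: pd.DataFrame
    class_number_pct: dict[str, float]
    class_volume_pct: dict[str, float]
    length_um: Optional[float] = None
    width_um: Optional[float] = None
    depth_um: Optional[float] = None
    wall_class: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_granule = pd.DataFrame(
            self.per_granule, columns=list(PER_GRANULE_COLUMNS)
        )
        self.validate()

    def validate(self) -> None:
        if self.starch_fraction_mean is not None and not (
            0.0 <= self.starch_fraction_mean <= 1.0
        ):
            raise ValidationError(
                f"starch_fraction_mean must lie in [0, 1], got {self.starch_fraction_mean}"
            )
        n = len(self.per_granule)
        if n:
            d = self.per_granule["max_feret_um"].to_numpy(float)
            v = self.per_granule["volume_um3"].to_numpy(float)
            expected = np.pi * d**3 / 6.0
            if not np.allclose(v, expected, rtol=1e-9, atol=1e-12):
                raise ValidationError("per-granule volume must equal pi*d^3/6")
            for name, pct in (
                ("class_number_pct", self.class_number_pct),
                ("class_volume_pct", self.class_volume_pct),
            ):
                total = sum(pct.values())
                if abs(total - 100.0) > 1e-6:
                    raise ValidationError(f"{name} must sum to 100, got {total}")

    @property
    def n_granules(self) -> int:
        return len(self.per_granule)
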