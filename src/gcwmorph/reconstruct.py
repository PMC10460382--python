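"""Fusion of polarized backward/forward SHG channels and depth gating.

A single linear polarization angle excites only the amylopectin shells whose
radial direction is near that angle (the two-lobe pattern), so any single
SHG channel shows an incomplete granule outline.  Summing all channels —
both detection directions, all four angles — restores the complete outline;
this summed reconstruction is the default fusion.  Because SHG decays faster
with depth than the gluten autofluorescence, only a prefix of slices offers
enough contrast for segmentation; that prefix is the analyzable depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError, ParameterError
from .types import ImageStack, VoxelGeometry

#: Percentile used as the robust per-slice maximum (ignores hot pixels).
ROBUST_PERCENTILE = 99.0


@dataclass(frozen=True)
class AnalyzableDepth:
    """Inclusive slice range usable for segmentation, with its depth in µm."""

    start: int
    stop: int
    n_slices: int
    depth_um: float
    empty: bool = False

    def as_range(self) -> range:
        return range(0, 0) if self.empty else range(self.start, self.stop + 1)

    def contains(self, z: int) -> bool:
        return not self.empty and self.start <= z <= self.stop


def combine_polarizations(stack: ImageStack, method: str = "sum") -> np.ndarray:
    """Fuse all SHG channels (both directions, all angles) voxelwise.

    ``sum`` (default) or ``max`` over channels, rescaled back to the input
    dynamic range so thresholds remain comparable with single channels.
    """
    if method not in ("sum", "max"):
        raise ParameterError(f"method must be 'sum' or 'max', got {method!r}")
    shg = stack.shg_channels()
    if not shg:
        raise InputError("stack contains no SHG channel")
    fields = np.stack([f.astype(np.float32) for _, f in shg])
    combined = fields.sum(axis=0) if method == "sum" else fields.max(axis=0)
    peak = float(combined.max())
    input_peak = float(fields.max())
    if peak > 0:
        combined *= input_peak / peak
    return combined


def slice_robust_max(field: np.ndarray, percentile: float = ROBUST_PERCENTILE) -> np.ndarray:
    return np.percentile(
        field.reshape(field.shape[0], -1).astype(np.float32), percentile, axis=1
    )


def determine_analyzable_depth(
    field: np.ndarray,
    contrast_floor: float = 0.1,
    geometry: Optional[VoxelGeometry] = None,
) -> AnalyzableDepth:
    """Largest prefix of slices with enough contrast for segmentation.

    The per-slice robust (99th-percentile) maximum is compared against the
    brightest slice of the stack; the analyzable depth runs from the first
    slice at or above ``contrast_floor`` times that reference through the
    last consecutive such slice.  A contiguous prefix, not a per-voxel mask:
    truncation happens at slice level.  (Referencing the brightest rather
    than literally the first slice makes the gate robust to faint blur
    tails above the wall.)
    """
    if not 0.0 < contrast_floor < 1.0:
        raise ParameterError("contrast_floor must lie in (0, 1)")
    field = np.asarray(field)
    if field.ndim != 3 or field.size == 0:
        raise InputError("field must be a non-empty 3D array")
    geometry = geometry or VoxelGeometry()
    rmax = slice_robust_max(field)
    reference = float(rmax.max())
    if reference <= 0:
        return AnalyzableDepth(start=0, stop=-1, n_slices=0, depth_um=0.0, empty=True)
    qualifying = np.flatnonzero(rmax >= contrast_floor * reference)
    start = int(qualifying[0])
    stop = start
    for z in range(start, field.shape[0]):
        if rmax[z] >= contrast_floor * reference:
            stop = z
        else:
            break
    n = stop - start + 1
    return AnalyzableDepth(
        start=start, stop=stop, n_slices=n, depth_um=n * geometry.z_step
    )


@dataclass(frozen=True)
class OrientationResult:
    """Principal orientation of a masked SHG lobe pattern, in [0, 180) deg."""

    angle_deg: float
    anisotropy_ratio: float
    defined: bool


def compute_anisotropy_orientation(
    field: np.ndarray, granule_mask: np.ndarray, min_anisotropy: float = 1.1
) -> OrientationResult:
    """Intensity-weighted second-moment orientation of a masked signal.

    The two-lobe SHG pattern of a granule is oriented along the excitation
    polarization; the principal axis of the intensity-weighted covariance of
    in-plane coordinates recovers that angle.  Nearly isotropic patterns
    (axis ratio below ``min_anisotropy``) are flagged undefined.
    """
    field = np.asarray(field, np.float32)
    mask = np.asarray(granule_mask).astype(bool)
    if mask.shape != field.shape:
        raise InputError("field and mask shapes differ")
    if not mask.any():
        raise InputError("empty granule mask")
    if field.ndim == 2:
        field, mask = field[None], mask[None]
    zz, yy, xx = np.nonzero(mask)
    w = field[zz, yy, xx].astype(np.float64)
    total = w.sum()
    if total <= 0:
        return OrientationResult(angle_deg=0.0, anisotropy_ratio=1.0, defined=False)
    x = xx - (w * xx).sum() / total
    y = yy - (w * yy).sum() / total
    cxx = (w * x * x).sum() / total
    cyy = (w * y * y).sum() / total
    cxy = (w * x * y).sum() / total
    angle = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy)
    tr, det = cxx + cyy, cxx * cyy - cxy**2
    disc = max((tr / 2.0) ** 2 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    ratio = np.sqrt(lam1 / lam2) if lam2 > 0 else np.inf
    angle_deg = float(np.degrees(angle)) % 180.0
    return OrientationResult(
        angle_deg=angle_deg,
        anisotropy_ratio=float(ratio),
        defined=bool(ratio >= min_anisotropy),
    )
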