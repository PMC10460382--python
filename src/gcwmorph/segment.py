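"""Granule segmentation and EF-envelope delimitation.

The granule stage is an automated surrogate for slice-by-slice manual
tracing: smooth, threshold, close and fill (the centrosymmetric hilum is
dark inside a bright shell), then split touching granules with a
marker-based watershed on the anisotropy-aware distance transform, linked
in 3D.  The envelope stage thresholds the autofluorescence image per slice
and keeps the largest connected component — one gas cell wall per field of
view — smoothed morphologically to a clean outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, h_maxima, h_minima, remove_small_objects
from skimage.segmentation import watershed

from .errors import InputError, ParameterError
from .morphometry import StarchFractionResult, starch_fraction
from .reconstruct import AnalyzableDepth, slice_robust_max
from .types import GCWEnvelope, LabelMap, VoxelGeometry


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and morphology knobs for the granule segmentation.

    ``threshold`` is either the string ``"otsu"`` (computed on the smoothed,
    per-slice-normalized field) or an absolute value on that normalized
    scale.  Watershed markers come from the dark centrosymmetric hilum at
    each granule's core: ``hilum_h`` is the minimum intensity depth (on the
    normalized scale) of such a dark basin.  A connected starch blob with no
    detectable hilum (small granules blur it away) falls back to one marker
    at its distance-transform maximum.
    """

    smooth_sigma_um: float = 0.35
    threshold: Union[str, float] = "otsu"
    closing_radius_px: int = 2
    hilum_h: float = 0.08
    peak_h_um: float = 0.3
    marker_exclusion_um: float = 2.0
    min_size_voxels: int = 8

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ParameterError("threshold must be 'otsu' or a number")


def _normalize_slices(field: np.ndarray, floor_frac: float = 0.1) -> np.ndarray:
    """Divide each slice by its robust max to undo depth attenuation.

    The normalizer is clamped at ``floor_frac`` of the global robust max so
    that slices holding only blur tails or noise are not amplified to full
    scale.
    """
    rmax = slice_robust_max(field, 99.5)
    rmax = np.maximum(rmax, floor_frac * max(float(rmax.max()), 1e-12))
    rmax = np.where(rmax > 0, rmax, 1.0)
    return field / rmax[:, None, None]


def segment_granules(
    combined_shg: np.ndarray,
    z_range: AnalyzableDepth,
    geometry: VoxelGeometry,
    params: Optional[SegmentationParams] = None,
) -> LabelMap:
    """Segment starch granules from the fused SHG field within the
    analyzable depth.

    Pipeline: per-slice attenuation normalization -> Gaussian smoothing ->
    threshold -> per-slice morphological closing and hole filling (captures
    the dark hilum inside the bright shell) -> 3D marker-based watershed on
    the Euclidean distance transform (sampled with the physical voxel
    anisotropy) to split touching granules and link slices.  Slices outside
    the analyzable depth stay unlabeled.
    """
    params = params or SegmentationParams()
    field = np.asarray(combined_shg, np.float32)
    out = np.zeros(field.shape, np.int32)
    if z_range.empty or z_range.n_slices == 0:
        warnings.warn("empty analyzable depth: returning empty label map", stacklevel=2)
        return LabelMap(labels=out, geometry=geometry)
    sub = field[z_range.start : z_range.stop + 1]
    sub = _normalize_slices(sub)
    sigma_px = params.smooth_sigma_um / geometry.pixel_size_xy
    smoothed = ndi.gaussian_filter(sub, (0.0, sigma_px, sigma_px))
    if params.threshold == "otsu":
        thr = float(threshold_otsu(smoothed))
    else:
        thr = float(params.threshold)
    binary = smoothed > thr
    if not binary.any():
        warnings.warn("nothing above threshold: returning empty label map", stacklevel=2)
        return LabelMap(labels=out, geometry=geometry)
    selem = disk(params.closing_radius_px)
    for z in range(binary.shape[0]):
        plane = ndi.binary_closing(binary[z], structure=selem)
        binary[z] = ndi.binary_fill_holes(plane)
    binary = remove_small_objects(binary, params.min_size_voxels)
    if not binary.any():
        return LabelMap(labels=out, geometry=geometry)
    sampling = (geometry.z_step, geometry.pixel_size_xy, geometry.pixel_size_xy)
    distance = ndi.distance_transform_edt(binary, sampling=sampling)
    distance = ndi.gaussian_filter(distance, 1.0)
    # markers from the dark hilum cores: fill outside the starch with a high
    # plateau so h-minima finds only interior dark basins
    high = np.where(binary, smoothed, np.float32(smoothed.max() + 1.0))
    cores = h_minima(high, params.hilum_h).astype(bool)
    cores &= ndi.binary_erosion(
        binary, structure=np.ones((1, 3, 3), bool), iterations=2
    )
    cores = ndi.binary_dilation(cores, structure=np.ones((3, 3, 3), bool)) & binary
    # small granules blur their hilum away: add distance-transform peaks
    # that sit well clear of every detected core
    peaks = h_maxima(distance, params.peak_h_um).astype(bool) & binary
    if cores.any():
        d_to_core = ndi.distance_transform_edt(~cores, sampling=sampling)
        peaks &= d_to_core > params.marker_exclusion_um
    conn = np.ones((3, 3, 3), bool)
    markers, _ = ndi.label(cores | peaks, structure=conn)
    blobs, n_blobs = ndi.label(binary, structure=conn)
    has_core = np.zeros(n_blobs + 1, bool)
    has_core[np.unique(blobs[cores | peaks])] = True
    next_id = int(markers.max())
    for b in range(1, n_blobs + 1):
        if not has_core[b]:
            inside = np.where(blobs == b, distance, 0.0)
            next_id += 1
            markers[np.unravel_index(int(np.argmax(inside)), inside.shape)] = next_id
    labels3d = watershed(-distance, markers, mask=binary)
    labels3d = _relabel_contiguous(labels3d)
    out[z_range.start : z_range.stop + 1] = labels3d
    return LabelMap(labels=out, geometry=geometry)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1 if ids.size else 1, labels.dtype)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[labels]


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance: positive inside the mask, negative outside."""
    if not mask.any():
        return np.full(mask.shape, -np.inf)
    inside = ndi.distance_transform_edt(mask)
    outside = ndi.distance_transform_edt(~mask)
    return inside - outside


def interpolate_labels(labels: LabelMap, key_slices: list[int]) -> LabelMap:
    """Fill intermediate slices by per-label signed-distance interpolation.

    For a slice between two key slices, each label's signed distance fields
    on the bounding key slices are linearly blended; a pixel takes the label
    with the largest positive blended distance.  A label present on only one
    of the two bounding key slices is copied from that slice (flagged with a
    warning).  No label id absent from both bounding slices can appear.
    """
    if sorted(key_slices) != list(key_slices):
        raise ParameterError("key_slices must be sorted ascending")
    if len(key_slices) == 0:
        raise ParameterError("key_slices must not be empty")
    arr = labels.labels
    nz = arr.shape[0]
    if key_slices[0] < 0 or key_slices[-1] >= nz:
        raise ParameterError("key_slices outside the stack")
    out = np.zeros_like(arr)
    for z in key_slices:
        out[z] = arr[z]
    for z0, z1 in zip(key_slices[:-1], key_slices[1:]):
        if z1 - z0 < 2:
            continue
        plane0, plane1 = arr[z0], arr[z1]
        ids0 = set(np.unique(plane0[plane0 > 0]).tolist())
        ids1 = set(np.unique(plane1[plane1 > 0]).tolist())
        one_sided = ids0 ^ ids1
        if one_sided:
            warnings.warn(
                f"labels {sorted(one_sided)} present on only one of key slices "
                f"{z0}/{z1}: copied, not interpolated",
                stacklevel=2,
            )
        sd_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in ids0 | ids1:
            sd_cache[k] = (_signed_distance(plane0 == k), _signed_distance(plane1 == k))
        for z in range(z0 + 1, z1):
            t = (z - z0) / (z1 - z0)
            best = np.full(plane0.shape, -np.inf)
            plane_out = np.zeros_like(plane0)
            for k in sorted(ids0 | ids1):
                sd0, sd1 = sd_cache[k]
                if k in ids0 and k in ids1:
                    score = (1.0 - t) * sd0 + t * sd1
                elif k in ids0:
                    score = sd0
                else:
                    score = sd1
                win = score > np.maximum(best, 0.0)
                plane_out[win] = k
                best = np.maximum(best, score)
            out[z] = plane_out
    return LabelMap(labels=_relabel_contiguous(out), geometry=labels.geometry)


def _edt_dilation(mask: np.ndarray, radius_px: float) -> np.ndarray:
    if radius_px <= 0 or not mask.any():
        return mask
    return ndi.distance_transform_edt(~mask) <= radius_px


def _edt_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean (disk) morphological closing via two distance transforms."""
    if radius_px <= 0 or not mask.any():
        return mask
    dilated = _edt_dilation(mask, radius_px)
    return ndi.distance_transform_edt(dilated) > radius_px


def _edt_opening(mask: np.ndarray, radius_px: float) -> np.ndarray:
    if radius_px <= 0 or not mask.any():
        return mask
    eroded = ndi.distance_transform_edt(mask) > radius_px
    return _edt_dilation(eroded, radius_px)


def segment_envelope(
    ef: np.ndarray,
    threshold: float,
    geometry: VoxelGeometry,
    smoothing_radius_px: int = 2,
    closing_um: float = 3.0,
    z_limit: Optional[AnalyzableDepth] = None,
) -> GCWEnvelope:
    """Threshold the EF field per slice into the GCW envelope mask.

    Per slice: pixels at or above the threshold -> morphological closing at
    granule scale (``closing_um``; a row of touching granules must not sever
    the wall outline) -> largest 8-connected component -> hole filling
    (granule interiors are dark "empty" objects inside the gluten) ->
    opening for a smooth outline.  Slices with nothing above threshold stay
    empty; an entirely empty result is flagged with a warning.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    ef = np.asarray(ef, np.float32)
    if ef.ndim != 3:
        raise InputError("ef field must be 3D")
    closing_px = closing_um / geometry.pixel_size_xy
    mask = np.zeros(ef.shape, bool)
    z_iter = range(ef.shape[0]) if z_limit is None else z_limit.as_range()
    for z in z_iter:
        plane = ef[z] >= threshold
        if not plane.any():
            continue
        plane = _edt_closing(plane, closing_px)
        lab, n = ndi.label(plane, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        sizes = ndi.sum_labels(plane, lab, index=np.arange(1, n + 1))
        plane = lab == (1 + int(np.argmax(sizes)))
        plane = ndi.binary_fill_holes(plane)
        plane = _edt_opening(plane, float(smoothing_radius_px))
        mask[z] = ndi.binary_fill_holes(plane)
    if not mask.any():
        warnings.warn("nothing above the envelope threshold", stacklevel=2)
    return GCWEnvelope(mask=mask, geometry=geometry)


@dataclass
class ThresholdSweepResult:
    """Starch-fraction sensitivity to the envelope threshold.

    ``spread`` is max - min of the three fractions (low/base/high threshold);
    it is None (flagged) when any sweep point yields an empty envelope.
    """

    fraction_at_low: Optional[float]
    fraction_at_base: Optional[float]
    fraction_at_high: Optional[float]
    spread: Optional[float]
    thresholds: tuple[float, float, float]
    flagged: bool = False


def sweep_envelope_threshold(
    ef: np.ndarray,
    labels: LabelMap,
    base_threshold: float,
    rel_variation: float = 0.4,
    geometry: Optional[VoxelGeometry] = None,
    z_limit: Optional[AnalyzableDepth] = None,
    n_slices: int = 5,
    span_um: float = 6.0,
    discard_first: int = 1,
) -> ThresholdSweepResult:
    """Recompute envelope and starch fraction at threshold x (1 -/+ rel_variation).

    The measurement slices are fixed once from the base-threshold envelope,
    so the sweep isolates the effect of the envelope outline (the
    wall-thickness uncertainty of a manual threshold) from slice
    repositioning.  When granules sit
    interior to the wall, a higher threshold shrinks the envelope (the
    denominator) and raises the fraction, so the three values are ordered
    low <= base <= high.
    """
    if not 0.0 <= rel_variation < 1.0:
        raise ParameterError("rel_variation must lie in [0, 1)")
    geometry = geometry or labels.geometry
    thresholds = (
        base_threshold * (1.0 - rel_variation),
        base_threshold,
        base_threshold * (1.0 + rel_variation),
    )
    base_envelope = segment_envelope(ef, base_threshold, geometry, z_limit=z_limit)
    slices: Optional[list[int]] = None
    if not base_envelope.is_empty:
        try:
            base_result = starch_fraction(
                labels, base_envelope, n_slices=n_slices, span_um=span_um,
                discard_first=discard_first,
            )
            slices = [z for z, _ in base_result.per_slice]
        except (InputError, ParameterError):
            slices = None
    fractions: list[Optional[float]] = []
    flagged = False
    starch = labels.labels > 0
    for thr in thresholds:
        if slices is None:
            fractions.append(None)
            flagged = True
            continue
        envelope = (
            base_envelope if thr == base_threshold
            else segment_envelope(ef, thr, geometry, z_limit=z_limit)
        )
        per_slice = []
        for z in slices:
            env_px = int(envelope.mask[z].sum())
            if env_px == 0:
                continue
            per_slice.append(int((starch[z] & envelope.mask[z]).sum()) / env_px)
        if len(per_slice) < 2:
            fractions.append(None)
            flagged = True
            continue
        fractions.append(float(np.mean(per_slice)))
    if flagged:
        warnings.warn("threshold sweep has empty points; spread undefined", stacklevel=2)
        spread = None
    else:
        vals = [f for f in fractions if f is not None]
        spread = max(vals) - min(vals)
    return ThresholdSweepResult(
        fraction_at_low=fractions[0],
        fraction_at_base=fractions[1],
        fraction_at_high=fractions[2],
        spread=spread,
        thresholds=thresholds,
        flagged=flagged,
    )
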