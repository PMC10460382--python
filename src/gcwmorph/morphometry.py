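"""Per-granule and per-wall morphometrics.

All starch quantification is two-dimensional, on in-plane (x-y) masks: the
axial elongation artifact makes z-extents of granules unreliable, so granule
size is the Max-Feret diameter of a representative-slice mask and granule
volume uses the spherical assumption V = pi d^3 / 6.  Wheat-starch size
classes: A > 15 µm (large, lenticular), B in [5, 15] µm, C < 5 µm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .errors import InputError, ParameterError
from .types import (
    PER_GRANULE_COLUMNS,
    GCWEnvelope,
    LabelMap,
    SIZE_CLASS_BOUNDS_UM,
    VoxelGeometry,
)

SIZE_CLASSES = ("C", "B", "A")

#: Diameter bin edges (µm) for size-distribution histograms: 1 µm bins where
#: the C and B peaks sit, wider bins across the sparse A range.
DEFAULT_BIN_EDGES_UM = (
    0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0,
    12.0, 14.0, 16.0, 20.0, 24.0, 28.0, 32.0, 40.0,
)


def classify_granule_size(d: float) -> str:
    """A/B/C wheat-starch class of a Max-Feret diameter in µm.

    C if d < 5, B if 5 <= d <= 15 (closed interval), A if d > 15.
    """
    if d < 0 or not math.isfinite(d):
        raise InputError(f"diameter must be a finite value >= 0, got {d}")
    lo, hi = SIZE_CLASS_BOUNDS_UM
    if d < lo:
        return "C"
    if d <= hi:
        return "B"
    return "A"


def sphere_volume_from_feret(d: float) -> float:
    """Spherical-assumption granule volume V = pi d^3 / 6 (µm^3)."""
    if d < 0:
        raise InputError(f"diameter must be >= 0, got {d}")
    return math.pi * d**3 / 6.0


def max_feret_pair(mask2d: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Endpoints (as (x, y) pixel-center coords) and length in px of the
    Max-Feret diameter: the maximum distance between pixel centers."""
    mask = np.asarray(mask2d).astype(bool)
    if mask.ndim != 2:
        raise InputError(f"mask must be 2D, got ndim={mask.ndim}")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise InputError("empty mask has no Feret diameter")
    pts = np.column_stack([xs, ys]).astype(float)
    if pts.shape[0] == 1:
        return pts[0], pts[0], 0.0
    if pts.shape[0] > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    return pts[i], pts[j], float(math.sqrt(d2[i, j]))


def max_feret_diameter(mask2d: np.ndarray, geometry: VoxelGeometry) -> float:
    """Max-Feret diameter of an in-plane mask, in µm.

    Measured between pixel centers; a singleton mask is below resolution and
    returns 0.
    """
    _, _, d_px = max_feret_pair(mask2d)
    return d_px * geometry.pixel_size_xy


@dataclass
class SizeDistribution:
    """Number- and volume-weighted granule size distribution on one slice."""

    per_granule: pd.DataFrame
    class_number_pct: dict[str, float]
    class_volume_pct: dict[str, float]
    bin_edges_um: tuple
    bin_number_pct: np.ndarray
    bin_volume_pct: np.ndarray
    representative_z: int
    is_empty: bool = False

    @property
    def diameters_um(self) -> np.ndarray:
        return self.per_granule["max_feret_um"].to_numpy(float)


def _class_percentages(classes: Sequence[str], weights: np.ndarray) -> dict[str, float]:
    total = float(weights.sum())
    out = {}
    classes = np.asarray(classes)
    for cls in SIZE_CLASSES:
        out[cls] = float(weights[classes == cls].sum()) / total * 100.0 if total else 0.0
    return out


def select_representative_slice(
    labels: LabelMap, z_range: Optional[tuple[int, int]] = None
) -> int:
    """Slice carrying the most granule labels (ties go to the shallower slice)."""
    arr = labels.labels
    z0, z1 = (0, arr.shape[0] - 1) if z_range is None else z_range
    counts = [
        np.unique(arr[z][arr[z] > 0]).size for z in range(z0, z1 + 1)
    ]
    return z0 + int(np.argmax(counts))


def size_distribution(
    labels: LabelMap,
    representative_z: int,
    bin_edges_um: Sequence[float] = DEFAULT_BIN_EDGES_UM,
) -> SizeDistribution:
    """Per-granule Max-Feret sizes on one representative slice, with A/B/C
    class and histogram-bin shares by number and by spherical volume.

    Both percentage vectors sum to 100 whenever any granule is present.
    """
    arr = labels.labels
    if not 0 <= representative_z < arr.shape[0]:
        raise InputError(f"representative_z {representative_z} outside stack")
    plane = arr[representative_z]
    ids = np.unique(plane[plane > 0])
    edges = np.asarray(bin_edges_um, float)
    if ids.size == 0:
        warnings.warn("no granules on the representative slice", stacklevel=2)
        empty = pd.DataFrame(columns=list(PER_GRANULE_COLUMNS))
        return SizeDistribution(
            per_granule=empty,
            class_number_pct={},
            class_volume_pct={},
            bin_edges_um=tuple(edges),
            bin_number_pct=np.zeros(edges.size - 1),
            bin_volume_pct=np.zeros(edges.size - 1),
            representative_z=representative_z,
            is_empty=True,
        )
    objects = ndi.find_objects(plane)
    rows = []
    for k in ids:
        box = objects[int(k) - 1]
        d = max_feret_diameter(plane[box] == k, labels.geometry)
        rows.append(
            {
                "id": int(k),
                "z_slice": representative_z,
                "max_feret_um": d,
                "volume_um3": sphere_volume_from_feret(d),
                "size_class": classify_granule_size(d),
            }
        )
    table = pd.DataFrame(rows, columns=list(PER_GRANULE_COLUMNS))
    diam = table["max_feret_um"].to_numpy(float)
    vol = table["volume_um3"].to_numpy(float)
    classes = table["size_class"].to_numpy()
    n_counts, _ = np.histogram(diam, bins=edges)
    v_counts, _ = np.histogram(diam, bins=edges, weights=vol)
    return SizeDistribution(
        per_granule=table,
        class_number_pct=_class_percentages(classes, np.ones(diam.size)),
        class_volume_pct=_class_percentages(classes, vol),
        bin_edges_um=tuple(edges),
        bin_number_pct=n_counts / n_counts.sum() * 100.0,
        bin_volume_pct=v_counts / v_counts.sum() * 100.0 if v_counts.sum() else v_counts,
        representative_z=representative_z,
        is_empty=False,
    )


def histogram_modes(
    diameters_um: np.ndarray, bin_edges_um: Sequence[float] = DEFAULT_BIN_EDGES_UM
) -> list[float]:
    """Bin centers of the strict local maxima of the number density.

    Density (count / bin width) is used so unequal bins compare fairly;
    plateaus are merged and boundary bins count as one-sided maxima.
    """
    edges = np.asarray(bin_edges_um, float)
    counts, _ = np.histogram(np.asarray(diameters_um, float), bins=edges)
    widths = np.diff(edges)
    density = counts / widths
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = []
    n = density.size
    for i in range(n):
        if density[i] <= 0:
            continue
        j = i - 1
        while j >= 0 and density[j] == density[i]:
            j -= 1
        k = i + 1
        while k < n and density[k] == density[i]:
            k += 1
        left_ok = j < 0 or density[j] < density[i]
        right_ok = k >= n or density[k] < density[i]
        plateau_start = j + 1
        if left_ok and right_ok and i == plateau_start:  # one mode per plateau
            modes.append(float(centers[i]))
    return modes


@dataclass
class StarchFractionResult:
    """Areal starch fraction over evenly spaced slices of a fixed depth span."""

    mean: float
    sd: float
    per_slice: list[tuple[int, float]]
    n_slices_used: int


def starch_fraction(
    labels: LabelMap,
    envelope: GCWEnvelope,
    n_slices: int = 5,
    span_um: float = 6.0,
    discard_first: int = 1,
) -> StarchFractionResult:
    """Starch pixels over envelope pixels, averaged across slices.

    ``n_slices`` slices are evenly spaced across ``span_um`` of depth,
    starting ``discard_first`` slices below the top of the envelope (border
    slices under-sample granules).  The SD is the sample SD (ddof=1) across
    slices.
    """
    if n_slices < 2:
        raise ParameterError("n_slices must be >= 2")
    if envelope.is_empty:
        raise InputError("empty envelope")
    if discard_first < 0:
        raise ParameterError("discard_first must be >= 0")
    z0, z1 = envelope.z_extent
    dz = envelope.geometry.z_step
    start = z0 + discard_first
    span_slices = max(int(round(span_um / dz)), 1)
    stop = start + span_slices - 1
    if stop > z1:
        raise ParameterError(
            f"span of {span_um} µm starting after {discard_first} discarded "
            f"slice(s) does not fit the envelope extent [{z0}, {z1}]"
        )
    slices = np.unique(np.round(np.linspace(start, stop, n_slices)).astype(int))
    starch = labels.labels > 0
    per_slice: list[tuple[int, float]] = []
    for z in slices:
        env_px = int(envelope.mask[z].sum())
        if env_px == 0:
            warnings.warn(f"slice {z}: envelope empty, skipped", stacklevel=2)
            continue
        starch_px = int((starch[z] & envelope.mask[z]).sum())
        per_slice.append((int(z), starch_px / env_px))
    if len(per_slice) < 2:
        raise InputError("fewer than 2 usable slices for the starch fraction")
    vals = np.array([f for _, f in per_slice])
    return StarchFractionResult(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        per_slice=per_slice,
        n_slices_used=len(per_slice),
    )


@dataclass
class GCWDimensions:
    """Wall dimensions: L x W x D with the width profile along the length."""

    length_um: float
    width_um: float
    depth_um: float
    width_min_um: float
    width_max_um: float
    mid_slice: int


def _band_width_px(pts: np.ndarray, origin: np.ndarray, u: np.ndarray,
                   t_center: float, half_band: float = 1.0) -> Optional[float]:
    """In-plane extent (px) perpendicular to axis u in a band around t_center."""
    v = np.array([-u[1], u[0]])
    t = (pts - origin) @ u
    s = (pts - origin) @ v
    sel = np.abs(t - t_center) <= half_band
    if not sel.any():
        return None
    return float(s[sel].max() - s[sel].min() + 1.0)


def measure_gcw_dimensions(
    envelope: GCWEnvelope, geometry: Optional[VoxelGeometry] = None
) -> GCWDimensions:
    """L = Max-Feret of the mid-depth slice mask; W = extent perpendicular to
    the L axis at its midpoint; D = z-extent span times the z-step.

    The width is also profiled along the length (min/max over interior
    stations) because real walls taper; the mid-length value is the one
    reported as W.
    """
    if envelope.is_empty:
        raise InputError("empty envelope has no dimensions")
    geometry = geometry or envelope.geometry
    z0, z1 = envelope.z_extent
    zmid = (z0 + z1) // 2
    if not envelope.mask[zmid].any():
        nonempty = np.flatnonzero(envelope.mask.any(axis=(1, 2)))
        zmid = int(nonempty[np.argmin(np.abs(nonempty - zmid))])
    mask = envelope.mask[zmid]
    p, q, length_px = max_feret_pair(mask)
    px = geometry.pixel_size_xy
    if length_px == 0:
        return GCWDimensions(0.0, px, (z1 - z0 + 1) * geometry.z_step, px, px, zmid)
    u = (q - p) / length_px
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    w_mid = _band_width_px(pts, p, u, length_px / 2.0)
    widths = [
        w
        for f in np.linspace(0.1, 0.9, 9)
        if (w := _band_width_px(pts, p, u, f * length_px)) is not None
    ]
    return GCWDimensions(
        length_um=length_px * px,
        width_um=(w_mid if w_mid is not None else 1.0) * px,
        depth_um=(z1 - z0 + 1) * geometry.z_step,
        width_min_um=min(widths) * px if widths else 0.0,
        width_max_um=max(widths) * px if widths else 0.0,
        mid_slice=zmid,
    )


@dataclass
class WallClassification:
    wall_class: str
    indeterminate: bool
    depth_um: float
    width_um: float
    stack_depth_um: float


def classify_wall_type(
    envelope: GCWEnvelope,
    stack_depth_um: float,
    dimensions: Optional[GCWDimensions] = None,
) -> WallClassification:
    """String vs intact wall from the depth-to-stack and depth-to-width ratios.

    Strings — remnants of partially ruptured walls — occupy well under the
    stack depth and are about as deep as they are wide; intact walls span
    nearly the whole stack.  A wall matching neither rule is flagged
    indeterminate and assigned by the nearer depth ratio.
    """
    if dimensions is None:
        dimensions = measure_gcw_dimensions(envelope)
    d, w = dimensions.depth_um, dimensions.width_um
    if d <= 0.6 * stack_depth_um and d <= 1.5 * w:
        cls, indet = "string", False
    elif d >= 0.85 * stack_depth_um:
        cls, indet = "intact", False
    else:
        cls, indet = ("string" if d <= 0.725 * stack_depth_um else "intact"), True
    return WallClassification(
        wall_class=cls,
        indeterminate=indet,
        depth_um=d,
        width_um=w,
        stack_depth_um=stack_depth_um,
    )
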