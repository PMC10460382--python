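"""Synthetic multiphoton GCW scenes with ground truth.

Real polarized-SHG/EF stacks of proven dough are not publicly deposited, so
every downstream stage is validated against a simulator that reproduces the
optical phenomenology of such acquisitions:

* ellipsoidal starch granules with a trimodal (C/B/A) lognormal size mixture,
  A-type granules rendered oblate (lenticular);
* polarization-dependent two-lobe SHG on concentric shells with a dark
  centrosymmetric hilum, backward detection periphery-weighted and forward
  detection interior-weighted;
* a fibrillar endogenous-fluorescence (EF) gluten field with low-intensity
  granule-shaped voids and zero signal in the gas phase;
* stronger depth attenuation for SHG than for EF;
* an axial (z) elongation artifact modeled as anisotropic Gaussian blur, and
  signal-dependent (Poisson-like) shot noise.

All randomness flows from a single integer seed; stacks are byte-identical
across runs with the same parameters.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .errors import ParameterError, PlacementError, ValidationError
from .morphometry import classify_granule_size
from .types import (
    ChannelSpec,
    ImageStack,
    Modality,
    VoxelGeometry,
    default_channel_layout,
)

WALL_KINDS = ("string", "intact", "bulk")


@dataclass(frozen=True)
class GranuleTruth:
    """Ground truth for one starch granule.

    ``center_um`` is (x, y, z) in µm from the stack origin; ``semi_axes_um``
    is (a, b, c) with a the longest in-plane semi-axis and c the axial one;
    ``true_diameter_um`` is twice the longest semi-axis.
    """

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    orientation_rad: float
    true_diameter_um: float
    size_class: str

    def __post_init__(self) -> None:
        if min(self.semi_axes_um) <= 0:
            raise ValidationError(f"semi-axes must be > 0, got {self.semi_axes_um}")
        expected = classify_granule_size(self.true_diameter_um)
        if self.size_class != expected:
            raise ValidationError(
                f"size_class {self.size_class!r} inconsistent with "
                f"d={self.true_diameter_um:.3f} µm (expected {expected!r})"
            )


@dataclass(frozen=True)
class WallGeometry:
    """Nominal geometry of the simulated gas cell wall.

    Strings (partially ruptured walls) have depth comparable to their width
    and well short of the stack depth; intact walls span nearly the whole
    stack.  ``taper`` linearly narrows the wall from its mid-length width to
    ``width * (1 - taper)`` at the ends.
    """

    kind: str
    length_um: float
    width_um: float
    depth_um: float
    z_offset_um: float = 0.0
    rotation_deg: float = 0.0
    taper: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in WALL_KINDS:
            raise ValidationError(f"wall kind must be one of {WALL_KINDS}")
        if min(self.length_um, self.width_um, self.depth_um) <= 0:
            raise ValidationError("wall dimensions must be > 0")
        if not 0.0 <= self.taper < 1.0:
            raise ValidationError("taper must lie in [0, 1)")

    def validate_against_stack(self, stack_depth_um: float) -> None:
        if self.z_offset_um + self.depth_um > stack_depth_um + 1e-9:
            raise ValidationError("wall does not fit in the stack depth")
        if self.kind == "string":
            if not self.depth_um < 0.6 * stack_depth_um:
                raise ValidationError("string wall depth must be < 0.6 x stack depth")
            if not 0.5 * self.width_um <= self.depth_um <= 1.5 * self.width_um:
                raise ValidationError("string wall depth must be comparable to its width")
        elif self.kind == "intact":
            if not self.depth_um >= 0.9 * stack_depth_um:
                raise ValidationError("intact wall depth must be >= 0.9 x stack depth")

    @staticmethod
    def string_default(stack_depth_um: float, length_um: float = 125.0,
                       width_um: float = 12.0) -> "WallGeometry":
        """String geometry: depth ~ 0.4 x stack and comparable to the width."""
        depth = min(0.4 * stack_depth_um, 1.4 * width_um)
        depth = max(depth, 0.6 * width_um)
        z_off = 0.5 * (stack_depth_um - depth) * 0.5  # upper-middle of the stack
        return WallGeometry("string", length_um, width_um, depth, z_offset_um=z_off)

    @staticmethod
    def intact_default(stack_depth_um: float, length_um: float = 150.0,
                       width_um: float = 30.0) -> "WallGeometry":
        depth = 0.95 * stack_depth_um
        return WallGeometry("intact", length_um, width_um, depth, z_offset_um=0.0)


#: C/B/A lognormal diameter mixture: (mode µm, log-sd, number weight).
#: Modes follow the trimodal wheat-starch size distribution (~4/6/22 µm);
#: C granules dominate by number, A granules by volume.
DEFAULT_MIXTURE = (
    (4.0, 0.10, 0.50),   # C
    (6.0, 0.13, 0.42),   # B
    (22.0, 0.18, 0.08),  # A
)


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic scene, with one seed for every RNG."""

    mixture: tuple = DEFAULT_MIXTURE
    target_starch_fraction: float = 0.55
    hilum_radius_frac: float = 0.25
    lobe_exponent: float = 2.0
    atten_length_shg_um: float = 6.5
    atten_length_ef_um: float = 40.0
    z_elongation_factor: float = 3.0
    psf_sigma_um: float = 0.4
    noise_scale: float = 0.02
    seed: int = 0
    shape: tuple[int, int, int] = (84, 1024, 1024)
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    gluten_ef_level: float = 1.0
    granule_ef_frac: float = 0.15

    def __post_init__(self) -> None:
        if len(self.mixture) == 0:
            raise ParameterError("mixture must have at least one component")
        if any(len(t) != 3 for t in self.mixture):
            raise ParameterError(
                "mixture: each component must be a (mode_um, log_sd, weight) triple"
            )
        weights = [w for _, _, w in self.mixture]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-8:
            raise ParameterError(
                f"mixture weights must be non-negative and sum to 1, got {weights}"
            )
        if any(m <= 0 or s < 0 for m, s, _ in self.mixture):
            raise ParameterError("mixture modes must be > 0 and log-sd >= 0")
        if not 0.0 <= self.target_starch_fraction <= 0.8:
            raise ParameterError(
                "target_starch_fraction must lie in [0, 0.8] (random packing bound)"
            )
        if not 0.0 <= self.hilum_radius_frac < 1.0:
            raise ParameterError("hilum_radius_frac must lie in [0, 1)")
        if self.lobe_exponent <= 0:
            raise ParameterError("lobe_exponent must be > 0")
        if not self.atten_length_shg_um < self.atten_length_ef_um:
            raise ParameterError("SHG attenuation length must be shorter than EF's")
        if self.z_elongation_factor < 1.0:
            raise ParameterError("z_elongation_factor must be >= 1")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")

    @property
    def stack_depth_um(self) -> float:
        return self.shape[0] * self.geometry.z_step


@dataclass
class Scene:
    """A built scene: wall mask, placed granules, and the granule label grid."""

    params: SimulationParams
    wall: WallGeometry
    wall_mask: np.ndarray          # (z, y, x) bool
    granules: list[GranuleTruth]
    granule_labels: np.ndarray     # (z, y, x) int32, 0 = background
    achieved_fraction: float
    central_slices: tuple[int, ...]

    @property
    def geometry(self) -> VoxelGeometry:
        return self.params.geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wall_mask.shape

    @property
    def granule_mask(self) -> np.ndarray:
        return self.granule_labels > 0

    @property
    def gluten_mask(self) -> np.ndarray:
        return self.wall_mask & ~self.granule_mask

    def measured_central_fraction(self) -> float:
        """Areal starch fraction on the central wall slices, from the voxel grid."""
        zs = list(self.central_slices)
        wall_px = int(self.wall_mask[zs].sum())
        if wall_px == 0:
            return 0.0
        starch_px = int((self.granule_labels[zs] > 0).sum())
        return starch_px / wall_px


def _component_mu_sigma(mode_um: float, log_sd: float) -> tuple[float, float]:
    # lognormal mode = exp(mu - sigma^2)  =>  mu = ln(mode) + sigma^2
    return math.log(mode_um) + log_sd**2, log_sd


def sample_granule_population(
    params: SimulationParams, n: int, rng: Optional[np.random.Generator] = None
) -> list[GranuleTruth]:
    """Draw ``n`` granules from the C/B/A lognormal diameter mixture.

    A-type granules (> 15 µm) are oblate/lenticular (axial semi-axis
    c = 0.4 a); B and C types are near-spherical.  Centers are placeholders
    at the origin until :func:`build_scene` places the granules.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    weights = np.array([w for _, _, w in params.mixture], float)
    comps = rng.choice(len(params.mixture), size=n, p=weights / weights.sum())
    granules: list[GranuleTruth] = []
    for ci in comps:
        mode, log_sd, _ = params.mixture[ci]
        mu, sigma = _component_mu_sigma(mode, log_sd)
        d = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else mode
        size_class = classify_granule_size(d)
        a = d / 2.0
        if size_class == "A":
            b, c = a, 0.4 * a
        else:
            b = a * rng.uniform(0.85, 1.0)
            c = a * rng.uniform(0.85, 1.0)
        orientation = float(rng.uniform(0.0, np.pi))
        granules.append(
            GranuleTruth(
                center_um=(0.0, 0.0, 0.0),
                semi_axes_um=(a, b, c),
                orientation_rad=orientation,
                true_diameter_um=d,
                size_class=size_class,
            )
        )
    return granules


def _wall_masks(
    shape: tuple[int, int, int], geometry: VoxelGeometry, wall: WallGeometry,
    margin_px: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(3D wall mask, in-plane wall mask, eroded in-plane placement mask)."""
    nz, ny, nx = shape
    px = geometry.pixel_size_xy
    x = (np.arange(nx) + 0.5) * px - nx * px / 2.0
    y = (np.arange(ny) + 0.5) * px - ny * px / 2.0
    X, Y = np.meshgrid(x, y)
    th = math.radians(wall.rotation_deg)
    Xr = X * math.cos(th) + Y * math.sin(th)
    Yr = -X * math.sin(th) + Y * math.cos(th)
    half_len = wall.length_um / 2.0
    half_w = (wall.width_um / 2.0) * (
        1.0 - wall.taper * np.minimum(np.abs(Xr) / max(half_len, 1e-9), 1.0)
    )
    inplane = (np.abs(Xr) <= half_len) & (np.abs(Yr) <= half_w)
    zc = (np.arange(nz) + 0.5) * geometry.z_step
    zmask = (zc >= wall.z_offset_um) & (zc < wall.z_offset_um + wall.depth_um)
    mask3d = zmask[:, None, None] & inplane[None]
    from skimage.morphology import disk

    placement = ndi.binary_erosion(inplane, structure=disk(margin_px))
    return mask3d, inplane, placement


def _ellipsoid_indices(
    center_um: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    orientation: float,
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Voxel indices (zz, yy, xx) of an ellipsoid; None if out of canvas."""
    nz, ny, nx = shape
    px, dz = geometry.pixel_size_xy, geometry.z_step
    cx, cy, cz = center_um
    a, b, c = semi_axes
    r = max(a, b)
    ix0 = max(int((cx - r) / px) - 1, 0)
    ix1 = min(int((cx + r) / px) + 2, nx)
    iy0 = max(int((cy - r) / px) - 1, 0)
    iy1 = min(int((cy + r) / px) + 2, ny)
    iz0 = max(int((cz - c) / dz) - 1, 0)
    iz1 = min(int((cz + c) / dz) + 2, nz)
    if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
        return None
    xs = (np.arange(ix0, ix1) + 0.5) * px - cx
    ys = (np.arange(iy0, iy1) + 0.5) * px - cy
    zs = (np.arange(iz0, iz1) + 0.5) * dz - cz
    cth, sth = math.cos(orientation), math.sin(orientation)
    xl = xs[None, :] * cth + ys[:, None] * sth          # (ny', nx')
    yl = -xs[None, :] * sth + ys[:, None] * cth
    rho2_plane = (xl / a) ** 2 + (yl / b) ** 2           # (ny', nx')
    rho2 = rho2_plane[None] + (zs[:, None, None] / c) ** 2
    zz, yy, xx = np.nonzero(rho2 <= 1.0)
    if zz.size == 0:
        return None
    return zz + iz0, yy + iy0, xx + ix0


def build_scene(
    params: SimulationParams,
    wall: Optional[WallGeometry] = None,
    rng: Optional[np.random.Generator] = None,
    max_batches: int = 8,
    attempts_per_granule: int = 150,
) -> Scene:
    """Place non-overlapping granules in the wall until the target areal
    starch fraction is reached on the wall's central slices.

    Granules are drawn from the size mixture, sorted large-to-small, and
    placed by rejection sampling (greedy random sequential adsorption):
    largest bodies first, small C granules filling the remaining gaps,
    which is what allows dense dough-like packings.  Granules are kept a
    small gluten margin away from the wall boundary — in dough every
    granule is coated by the gluten film.  The achieved fraction is
    measured directly on the voxel grid and recorded exactly.
    """
    if wall is None:
        wall = WallGeometry.string_default(params.stack_depth_um)
    wall.validate_against_stack(params.stack_depth_um)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape, geometry = params.shape, params.geometry
    px, dz = geometry.pixel_size_xy, geometry.z_step
    wall_mask, inplane, placement = _wall_masks(shape, geometry, wall)
    if not wall_mask.any():
        raise ValidationError("wall geometry does not intersect the canvas")

    z_indices = np.flatnonzero(wall_mask.any(axis=(1, 2)))
    zc_idx = int(z_indices[len(z_indices) // 2])
    central = tuple(z for z in (zc_idx - 1, zc_idx, zc_idx + 1) if z in z_indices)

    labels = np.zeros(shape, np.int32)
    placed: list[GranuleTruth] = []
    target = params.target_starch_fraction
    wall_central_px = int(wall_mask[list(central)].sum())

    def fraction() -> float:
        if wall_central_px == 0:
            return 0.0
        return int((labels[list(central)] > 0).sum()) / wall_central_px

    frac = 0.0
    if target > 0:
        if not placement.any():
            raise PlacementError("wall footprint too small for any granule")
        # proposals are guided by the free-space distance transform on the
        # central slice, restricted to the wall's bounding box: large bodies
        # first, later granules slotted into the remaining gaps
        ys, xs = np.nonzero(placement)
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        place_box = placement[y0:y1, x0:x1]
        mean_area = max(
            sum(w * np.pi * (m / 2.0) ** 2 for m, _, w in params.mixture), 1e-6
        )
        needed_um2 = target * wall_central_px * px * px / max(len(central), 1)
        batch_n = max(150, int(6.0 * needed_um2 / mean_area) + 20)
        z_lo = wall.z_offset_um
        z_hi = wall.z_offset_um + wall.depth_um
        z_mid = 0.5 * (z_lo + z_hi)
        # the fill window: interior slices around mid-depth (boundary layers
        # of the wall are naturally starch-depleted); each new granule goes
        # to the currently least-starchy window slice so the depth profile
        # stays flat, as in real walls
        zc_um = (z_indices + 0.5) * dz
        window = z_indices[
            (zc_um >= max(z_lo + 1.75, z_mid - 4.0))
            & (zc_um <= min(z_hi - 1.75, z_mid + 4.0))
        ]
        if window.size == 0:
            window = np.array(central)
        wall_slice_px = wall_mask[window].sum(axis=(1, 2)).astype(float)
        overlap_used = 0
        overlap_budget = int(0.01 * labels.size)

        def filled() -> bool:
            # the whole fill window must carry the target load, not just the
            # central slices, so measured slices away from mid-depth are as
            # starchy as the middle
            if frac < target:
                return False
            wf = (labels[window] > 0).sum(axis=(1, 2)) / wall_slice_px
            return bool(wf.min() >= target - 0.04)

        for _ in range(max_batches):
            batch = sample_granule_population(params, batch_n, rng)
            batch.sort(key=lambda g: g.true_diameter_um, reverse=True)
            progressed = False
            for g in batch:
                if filled():
                    break
                a, b, c = g.semi_axes_um
                if 2 * c > wall.depth_um:
                    continue  # cannot fit the wall depth at all
                if 2 * min(a, b) > wall.width_um:
                    continue  # no orientation fits the wall width
                win_frac = (labels[window] > 0).sum(axis=(1, 2)) / wall_slice_px
                order = np.argsort(win_frac, kind="stable")
                pick = order[: max(1, (order.size + 2) // 3)]
                zt = int(window[int(rng.choice(pick))])
                occ = labels[zt, y0:y1, x0:x1] > 0
                free_dt = (
                    ndi.distance_transform_edt(np.pad(place_box & ~occ, 1))[1:-1, 1:-1]
                    * px
                )
                dt_max = float(free_dt.max())
                if dt_max < 0.45 * max(a, b):
                    continue  # no gap on this slice fits the granule
                tau = min(0.75 * max(a, b), dt_max)
                cand_y, cand_x = np.nonzero(free_dt >= tau)
                if cand_y.size == 0:
                    continue
                for _attempt in range(attempts_per_granule):
                    j = rng.integers(cand_y.size)
                    x_um = (x0 + cand_x[j] + rng.uniform()) * px
                    y_um = (y0 + cand_y[j] + rng.uniform()) * px
                    lo = z_lo + c
                    hi = z_hi - c
                    z_um = (zt + rng.uniform()) * dz
                    z_um = z_mid if hi <= lo else float(np.clip(z_um, lo, hi))
                    idx = _ellipsoid_indices(
                        (x_um, y_um, z_um), (a, b, c), g.orientation_rad,
                        shape, geometry,
                    )
                    if idx is None:
                        continue
                    zz, yy, xx = idx
                    if not placement[yy, xx].all():
                        continue
                    if not wall_mask[zz, yy, xx].all():
                        continue
                    # crowded granules may interpenetrate slightly (dough
                    # granules deform under pressure); contested voxels keep
                    # the first granule's label and a global budget holds
                    # total overlap under 1% of the stack voxels
                    contested = labels[zz, yy, xx] > 0
                    n_ov = int(contested.sum())
                    if n_ov > 0.3 * zz.size or overlap_used + n_ov > overlap_budget:
                        continue
                    lab = len(placed) + 1
                    fresh = ~contested
                    labels[zz[fresh], yy[fresh], xx[fresh]] = lab
                    new_frac = fraction()
                    if new_frac > target + 0.02:
                        labels[labels == lab] = 0  # would overshoot; try smaller
                        break
                    placed.append(dataclasses.replace(g, center_um=(x_um, y_um, z_um)))
                    overlap_used += n_ov
                    frac = new_frac
                    progressed = True
                    break
                if filled():
                    break
            if filled():
                break
            if not progressed:
                break
        frac = fraction()
        if abs(frac - target) > 0.02:
            raise PlacementError(
                f"could not reach target starch fraction {target:.2f}: "
                f"achieved {frac:.3f} after bounded retries"
            )
    return Scene(
        params=params,
        wall=wall,
        wall_mask=wall_mask,
        granules=placed,
        granule_labels=labels,
        achieved_fraction=fraction(),
        central_slices=central,
    )


def _attenuation(shape: tuple[int, int, int], geometry: VoxelGeometry,
                 length_um: float) -> np.ndarray:
    zc = (np.arange(shape[0]) + 0.5) * geometry.z_step
    return np.exp(-zc / length_um).astype(np.float32)[:, None, None]


def render_shg_channel(scene: Scene, spec: ChannelSpec) -> np.ndarray:
    """Render one polarized SHG channel (pre-blur, pre-noise).

    Per granule, intensity follows the two-lobe angular law
    ``|cos(theta_radial - theta_pol)| ** lobe_exponent`` on concentric
    ellipsoidal shells, is zero inside the centrosymmetric hilum, and is
    weighted toward the periphery for backward detection and toward the
    interior for forward detection (complementary linear ramps).  Gluten and
    gas produce no SHG.  The whole field is attenuated as
    ``exp(-z / atten_length_shg_um)``.
    """
    if spec.modality is not Modality.SHG:
        raise ParameterError("render_shg_channel requires an SHG channel spec")
    params = scene.params
    geometry = scene.geometry
    field_arr = np.zeros(scene.shape, np.float32)
    theta_pol = math.radians(float(spec.polarization_deg))
    backward = spec.direction.value == "backward"
    px, dz = geometry.pixel_size_xy, geometry.z_step
    h = params.hilum_radius_frac
    p = params.lobe_exponent
    for g in scene.granules:
        cx, cy, cz = g.center_um
        a, b, c = g.semi_axes_um
        idx = _ellipsoid_indices(g.center_um, g.semi_axes_um, g.orientation_rad,
                                 scene.shape, geometry)
        if idx is None:
            continue
        zz, yy, xx = idx
        dx = (xx + 0.5) * px - cx
        dy = (yy + 0.5) * px - cy
        dzu = (zz + 0.5) * dz - cz
        cth, sth = math.cos(g.orientation_rad), math.sin(g.orientation_rad)
        xl = dx * cth + dy * sth
        yl = -dx * sth + dy * cth
        rho = np.sqrt((xl / a) ** 2 + (yl / b) ** 2 + (dzu / c) ** 2)
        theta_r = np.arctan2(dy, dx)
        ang = np.abs(np.cos(theta_r - theta_pol)) ** p
        radial = rho if backward else (1.0 - rho)
        val = np.where(rho >= h, ang * np.clip(radial, 0.0, 1.0), 0.0)
        field_arr[zz, yy, xx] = val.astype(np.float32)
    field_arr *= _attenuation(scene.shape, geometry, params.atten_length_shg_um)
    return field_arr


def render_ef_channel(
    scene: Scene, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Render the endogenous-fluorescence channel (pre-blur, pre-noise).

    Gluten voxels carry a band-pass-filtered noise texture (fibrillar
    appearance) around a high mean level; granule interiors sit at a low but
    non-zero level ("empty" fluorescence objects); gas is dark.  Attenuation
    is ``exp(-z / atten_length_ef_um)`` — slower than the SHG decay, so the
    EF analyzable depth always exceeds the SHG one.
    """
    params = scene.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    noise = rng.standard_normal(scene.shape).astype(np.float32)
    lo = ndi.gaussian_filter(noise, (0.0, 1.0, 1.0))
    hi = ndi.gaussian_filter(noise, (0.0, 4.0, 4.0))
    texture = lo - hi
    sd = float(texture.std())
    if sd > 0:
        texture /= sd
    level = params.gluten_ef_level
    field_arr = np.zeros(scene.shape, np.float32)
    gluten = scene.gluten_mask
    field_arr[gluten] = np.clip(level * (1.0 + 0.35 * texture[gluten]), 0.15 * level, None)
    field_arr[scene.granule_mask] = params.granule_ef_frac * level
    field_arr *= _attenuation(scene.shape, scene.geometry, params.atten_length_ef_um)
    return field_arr


def apply_axial_elongation_and_noise(
    field_arr: np.ndarray,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply the PSF blur with axial elongation, then shot noise.

    The blur is Gaussian with lateral sigma ``psf_sigma_um`` and axial sigma
    ``z_elongation_factor`` times larger — the source of the tubular
    appearance of granules along z.  Noise is signal-dependent
    (Gaussian approximation to Poisson): sd = noise_scale * sqrt(intensity).
    """
    if params.z_elongation_factor < 1.0:
        raise ParameterError("z_elongation_factor must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    geometry = params.geometry
    sigma_lat_px = params.psf_sigma_um / geometry.pixel_size_xy
    sigma_z_slices = params.z_elongation_factor * params.psf_sigma_um / geometry.z_step
    out = ndi.gaussian_filter(
        np.asarray(field_arr, np.float32), (sigma_z_slices, sigma_lat_px, sigma_lat_px)
    )
    if params.noise_scale > 0:
        out = out + rng.standard_normal(out.shape).astype(np.float32) * (
            params.noise_scale * np.sqrt(np.clip(out, 0.0, None))
        )
        np.clip(out, 0.0, None, out=out)
    return out


@dataclass
class SimulationResult:
    """A simulated acquisition plus its serialized ground truth."""

    stack: ImageStack
    granules: list[GranuleTruth]
    wall_mask: np.ndarray
    achieved_fraction: float
    scene: Scene

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": i + 1,
                "x_um": g.center_um[0],
                "y_um": g.center_um[1],
                "z_um": g.center_um[2],
                "a_um": g.semi_axes_um[0],
                "b_um": g.semi_axes_um[1],
                "c_um": g.semi_axes_um[2],
                "orientation_rad": g.orientation_rad,
                "true_diameter_um": g.true_diameter_um,
                "size_class": g.size_class,
            }
            for i, g in enumerate(self.granules)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id", "x_um", "y_um", "z_um", "a_um", "b_um", "c_um",
                "orientation_rad", "true_diameter_um", "size_class",
            ],
        )

    def save(self, out_dir) -> dict[str, Path]:
        from . import io as gio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "stack": out / "stack.tif",
            "metadata": out / "stack.yaml",
            "truth_granules": out / "truth_granules.csv",
            "truth": out / "truth.json",
            "wall_mask": out / "wall_mask.tif",
        }
        gio.write_stack(self.stack, paths["stack"], paths["metadata"])
        self.truth_table().to_csv(paths["truth_granules"], index=False)
        import tifffile

        tifffile.imwrite(
            paths["wall_mask"], self.wall_mask.astype(np.uint16) * 65535,
            photometric="minisblack",
        )
        wall = self.scene.wall
        truth = {
            "achieved_starch_fraction": self.achieved_fraction,
            "n_granules": len(self.granules),
            "central_slices": list(self.scene.central_slices),
            "wall": {
                "kind": wall.kind,
                "length_um": wall.length_um,
                "width_um": wall.width_um,
                "depth_um": wall.depth_um,
                "z_offset_um": wall.z_offset_um,
                "rotation_deg": wall.rotation_deg,
                "taper": wall.taper,
            },
            "params": params_to_dict(self.scene.params),
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
        return paths


def simulate_stack(
    params: SimulationParams, wall: Optional[WallGeometry] = None
) -> SimulationResult:
    """Simulate a full 9-channel acquisition: {B,F}-SHG x 4 angles + EF.

    Deterministic given ``params.seed``: the scene, EF texture and per-channel
    noise streams are all derived from independent children of one seed
    sequence, so repeated runs produce byte-identical stacks.
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(12)
    scene = build_scene(params, wall, rng=np.random.default_rng(children[0]))
    specs = default_channel_layout()
    fields = np.zeros((len(specs),) + scene.shape, np.float32)
    for i, spec in enumerate(specs):
        if spec.modality is Modality.SHG:
            raw = render_shg_channel(scene, spec)
        else:
            raw = render_ef_channel(scene, rng=np.random.default_rng(children[1]))
        fields[i] = apply_axial_elongation_and_noise(
            raw, params, rng=np.random.default_rng(children[2 + i])
        )
    vmax = float(fields.max())
    scale = 60000.0 / vmax if vmax > 0 else 1.0
    voxels = np.round(fields * scale).astype(np.uint16)
    stack = ImageStack(channels=specs, voxels=voxels, geometry=params.geometry)
    return SimulationResult(
        stack=stack,
        granules=scene.granules,
        wall_mask=scene.wall_mask,
        achieved_fraction=scene.achieved_fraction,
        scene=scene,
    )


def params_to_dict(params: SimulationParams) -> dict:
    return {
        "mixture": [list(t) for t in params.mixture],
        "target_starch_fraction": params.target_starch_fraction,
        "hilum_radius_frac": params.hilum_radius_frac,
        "lobe_exponent": params.lobe_exponent,
        "atten_length_shg_um": params.atten_length_shg_um,
        "atten_length_ef_um": params.atten_length_ef_um,
        "z_elongation_factor": params.z_elongation_factor,
        "psf_sigma_um": params.psf_sigma_um,
        "noise_scale": params.noise_scale,
        "seed": params.seed,
        "shape": list(params.shape),
        "geometry": {
            "pixel_size_xy_um": params.geometry.pixel_size_xy,
            "z_step_um": params.geometry.z_step,
        },
        "gluten_ef_level": params.gluten_ef_level,
        "granule_ef_frac": params.granule_ef_frac,
    }


def params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    if "mixture" in d:
        d["mixture"] = tuple(tuple(t) for t in d["mixture"])
    if "shape" in d:
        d["shape"] = tuple(int(v) for v in d["shape"])
    if "geometry" in d and isinstance(d["geometry"], dict):
        geo = d["geometry"]
        d["geometry"] = VoxelGeometry(
            float(geo.get("pixel_size_xy_um", 0.17)), float(geo.get("z_step_um", 0.5))
        )
    allowed = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(d) - allowed
    if unknown:
        raise ParameterError(f"unknown simulation parameter(s): {sorted(unknown)}")
    return SimulationParams(**d)
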