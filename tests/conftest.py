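"""Shared fixtures: small ground-truthed scenes reused across the suite.

Everything is generated at test time from the simulator; the expensive
string-scene stack is session-scoped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gcwmorph import (
    GranuleTruth,
    ImageStack,
    Modality,
    VoxelGeometry,
    apply_axial_elongation_and_noise,
    build_scene,
    default_channel_layout,
    render_ef_channel,
    render_shg_channel,
    simulate_stack,
)
from gcwmorph.simulate import SimulationParams, WallGeometry, _ellipsoid_indices

warnings.filterwarnings("ignore", category=UserWarning, module="gcwmorph")


#: Canonical small-scale study scenes (256 px canvas, 24 µm stack).
STRING_WALL = WallGeometry("string", 38.0, 10.0, 11.5, z_offset_um=6.0)
INTACT_WALL = WallGeometry("intact", 38.0, 28.0, 22.0, z_offset_um=0.5)
SCENE_SHAPE = (48, 256, 256)


def make_sim_params(**overrides) -> SimulationParams:
    defaults = dict(shape=SCENE_SHAPE, target_starch_fraction=0.55, seed=1)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def geometry() -> VoxelGeometry:
    return VoxelGeometry()


@pytest.fixture(scope="session")
def string_result():
    """Default string scene: 9-channel stack + ground truth (session cached)."""
    return simulate_stack(make_sim_params(), STRING_WALL)


@pytest.fixture(scope="session")
def intact_result():
    return simulate_stack(make_sim_params(seed=2), INTACT_WALL)


def place_granule(scene, center_um, semi_axes_um, orientation_rad=0.0):
    """Manually stamp one granule into an (empty) scene, truth included."""
    d = 2.0 * max(semi_axes_um)
    from gcwmorph.morphometry import classify_granule_size

    g = GranuleTruth(
        center_um=tuple(center_um),
        semi_axes_um=tuple(semi_axes_um),
        orientation_rad=orientation_rad,
        true_diameter_um=d,
        size_class=classify_granule_size(d),
    )
    idx = _ellipsoid_indices(
        g.center_um, g.semi_axes_um, g.orientation_rad, scene.shape, scene.geometry
    )
    assert idx is not None, "granule outside the canvas"
    scene.granule_labels[idx] = len(scene.granules) + 1
    scene.granules.append(g)
    return g


def render_stack_from_scene(scene, params) -> ImageStack:
    """Render all 9 channels of a hand-built scene (with blur and noise)."""
    specs = default_channel_layout()
    fields = []
    rng_seed = params.seed
    for i, spec in enumerate(specs):
        if spec.modality is Modality.SHG:
            raw = render_shg_channel(scene, spec)
        else:
            raw = render_ef_channel(scene, rng=np.random.default_rng(rng_seed + 1))
        fields.append(
            apply_axial_elongation_and_noise(
                raw, params, rng=np.random.default_rng(rng_seed + 2 + i)
            )
        )
    fields = np.stack(fields)
    vmax = float(fields.max())
    scale = 60000.0 / vmax if vmax > 0 else 1.0
    return ImageStack(
        channels=specs,
        voxels=np.round(fields * scale).astype(np.uint16),
        geometry=params.geometry,
    )


@pytest.fixture(scope="session")
def single_granule_setup(geometry):
    """One isolated 10 µm granule in a gluten slab, plus its rendered stack."""
    params = make_sim_params(
        shape=(30, 128, 128), target_starch_fraction=0.0, seed=3
    )
    wall = WallGeometry("bulk", 18.0, 16.0, 12.0, z_offset_um=1.5)
    scene = build_scene(params, wall)
    granule = place_granule(scene, (10.88, 10.88, 7.5), (5.0, 4.8, 4.0), 0.4)
    stack = render_stack_from_scene(scene, params)
    return scene, granule, stack, params
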