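"""End-to-end quantification: fuse -> gate depth -> segment -> measure.

`quantify_stack` composes the full analysis of one 9-channel GCW stack and
returns a :class:`~gcwmorph.types.MorphometryReport` together with all
intermediate artifacts (fused field, analyzable depths, label map, envelope,
dimensions, sweep) so every stage remains inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
from skimage.filters import threshold_otsu

from .errors import InputError, ParameterError
from .morphometry import (
    DEFAULT_BIN_EDGES_UM,
    GCWDimensions,
    SizeDistribution,
    StarchFractionResult,
    WallClassification,
    classify_wall_type,
    measure_gcw_dimensions,
    select_representative_slice,
    size_distribution,
    starch_fraction,
)
from .reconstruct import (
    AnalyzableDepth,
    combine_polarizations,
    determine_analyzable_depth,
)
from .segment import (
    SegmentationParams,
    _normalize_slices,
    ThresholdSweepResult,
    segment_envelope,
    segment_granules,
    sweep_envelope_threshold,
)
from .types import GCWEnvelope, ImageStack, LabelMap, MorphometryReport


@dataclass(frozen=True)
class QuantifyParams:
    """Configuration of the quantification pipeline.

    ``envelope_threshold`` applies to the per-slice-normalized EF field
    (each slice divided by its robust max, which undoes depth attenuation).
    The default 0.25 sits just above the dark gas cavity — the envelope
    outline is a low cut on the blurred wall edge, so a +/-40%% variation
    shifts the outline by well under a granule radius; ``"otsu"`` computes a
    threshold from the within-depth intensity histogram instead.
    ``discard_first="auto"`` centers the measurement span in the usable
    depth, always discarding at least the first border slice.
    """

    fusion_method: str = "sum"
    contrast_floor: float = 0.1
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    envelope_threshold: Union[str, float] = 0.25
    envelope_smoothing_px: int = 2
    n_slices: int = 5
    span_um: float = 6.0
    discard_first: Union[str, int] = "auto"
    sweep_rel_variation: Optional[float] = None
    bin_edges_um: tuple = DEFAULT_BIN_EDGES_UM


@dataclass
class QuantifyResult:
    report: MorphometryReport
    labels: LabelMap
    envelope: GCWEnvelope
    combined_shg: np.ndarray
    shg_depth: AnalyzableDepth
    ef_depth: AnalyzableDepth
    dimensions: Optional[GCWDimensions]
    wall: Optional[WallClassification]
    distribution: SizeDistribution
    fraction: Optional[StarchFractionResult]
    sweep: Optional[ThresholdSweepResult]
    envelope_threshold: float


def _auto_measure_window(
    envelope: GCWEnvelope,
    shg_depth: AnalyzableDepth,
    labels: LabelMap,
    span_um: float,
    n_slices: int,
) -> Optional[tuple[int, float]]:
    """(discard_first, effective span µm) placing the span over the wall's
    granular region.

    The usable depth is where both the envelope exists and the SHG contrast
    allows segmentation.  Within it, the span is centered on the z-centroid
    of the segmented starch (the representative interior of the wall, away
    from the starch-depleted border slices); at least the first border slice
    is discarded when there is room.
    """
    extent = envelope.z_extent
    if extent is None or shg_depth.empty:
        return None
    e0, e1 = extent
    u0, u1 = max(e0, shg_depth.start), min(e1, shg_depth.stop)
    ulen = u1 - u0 + 1
    if ulen < max(n_slices, 3):
        return None
    dz = envelope.geometry.z_step
    span_slices = max(int(round(span_um / dz)), n_slices)
    eff = min(span_slices, ulen - 1)
    starch_per_slice = (labels.labels[u0 : u1 + 1] > 0).sum(axis=(1, 2)).astype(float)
    total = starch_per_slice.sum()
    if total > 0:
        center = u0 + float((starch_per_slice * np.arange(ulen)).sum() / total)
    else:
        center = (u0 + u1) / 2.0
    start_abs = int(round(center - (eff - 1) / 2.0))
    lo = u0 + (1 if ulen - eff >= 2 else 0)
    start_abs = max(lo, min(start_abs, u1 - eff + 1))
    return start_abs - e0, eff * dz


def quantify_stack(stack: ImageStack, params: Optional[QuantifyParams] = None) -> QuantifyResult:
    """Run the full GCW quantification on a multi-channel stack."""
    params = params or QuantifyParams()
    geometry = stack.geometry
    combined = combine_polarizations(stack, method=params.fusion_method)
    shg_depth = determine_analyzable_depth(combined, params.contrast_floor, geometry)
    ef = stack.ef_channel().astype(np.float32)
    ef_depth = determine_analyzable_depth(ef, params.contrast_floor, geometry)

    labels = segment_granules(combined, shg_depth, geometry, params.segmentation)

    # depth-normalize the EF for the envelope: each slice divided by its
    # robust max (clamped so blur-tail slices are not amplified); Otsu then
    # sits between the dark granule interiors and the gluten plateau, which
    # places the wall edge at the half-maximum of the blurred profile
    ef_env = _normalize_slices(ef, floor_frac=0.45)
    if params.envelope_threshold == "otsu":
        if ef_depth.empty:
            raise InputError("EF channel carries no signal; cannot set a threshold")
        sample = ef_env[ef_depth.start : ef_depth.stop + 1]
        thr = float(threshold_otsu(sample))
    else:
        thr = float(params.envelope_threshold)
    envelope = segment_envelope(
        ef_env, thr, geometry,
        smoothing_radius_px=params.envelope_smoothing_px, z_limit=ef_depth,
    )

    dimensions = None
    wall = None
    if not envelope.is_empty:
        dimensions = measure_gcw_dimensions(envelope, geometry)
        stack_depth_um = stack.shape[0] * geometry.z_step
        wall = classify_wall_type(envelope, stack_depth_um, dimensions)
        envelope.length_um = dimensions.length_um
        envelope.width_um = dimensions.width_um
        envelope.depth_um = dimensions.depth_um
        envelope.wall_class = wall.wall_class

    rep_z = (
        select_representative_slice(labels, (shg_depth.start, shg_depth.stop))
        if not shg_depth.empty
        else 0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        distribution = size_distribution(labels, rep_z, params.bin_edges_um)

    fraction = None
    discard_used: Optional[int] = None
    span_used: Optional[float] = None
    if not envelope.is_empty:
        if params.discard_first == "auto":
            window = _auto_measure_window(
                envelope, shg_depth, labels, params.span_um, params.n_slices
            )
        else:
            window = (int(params.discard_first), params.span_um)
        if window is not None:
            discard_used, span_used = window
            try:
                fraction = starch_fraction(
                    labels, envelope, n_slices=params.n_slices,
                    span_um=span_used, discard_first=discard_used,
                )
            except (InputError, ParameterError) as exc:
                warnings.warn(f"starch fraction unavailable: {exc}", stacklevel=2)

    sweep = None
    if params.sweep_rel_variation is not None and discard_used is not None:
        sweep = sweep_envelope_threshold(
            ef_env, labels, thr, params.sweep_rel_variation, geometry,
            z_limit=ef_depth, n_slices=params.n_slices,
            span_um=span_used, discard_first=discard_used,
        )

    extras = {
        "n_labels": labels.n_labels,
        "representative_slice": rep_z,
        "shg_analyzable": {
            "start": shg_depth.start, "stop": shg_depth.stop,
            "depth_um": shg_depth.depth_um, "empty": shg_depth.empty,
        },
        "ef_analyzable": {
            "start": ef_depth.start, "stop": ef_depth.stop,
            "depth_um": ef_depth.depth_um, "empty": ef_depth.empty,
        },
        "envelope_threshold": thr,
        "fraction_slices": [list(t) for t in fraction.per_slice] if fraction else None,
        "measure_discard_first": discard_used,
        "measure_span_um": span_used,
        "wall_indeterminate": wall.indeterminate if wall else None,
        "width_min_um": dimensions.width_min_um if dimensions else None,
        "width_max_um": dimensions.width_max_um if dimensions else None,
    }
    if sweep is not None:
        extras["threshold_sweep"] = {
            "rel_variation": params.sweep_rel_variation,
            "fraction_at_low": sweep.fraction_at_low,
            "fraction_at_base": sweep.fraction_at_base,
            "fraction_at_high": sweep.fraction_at_high,
            "spread": sweep.spread,
            "flagged": sweep.flagged,
        }
    report = MorphometryReport(
        starch_fraction_mean=fraction.mean if fraction else None,
        starch_fraction_sd=fraction.sd if fraction else None,
        per_granule=distribution.per_granule,
        class_number_pct=distribution.class_number_pct,
        class_volume_pct=distribution.class_volume_pct,
        length_um=dimensions.length_um if dimensions else None,
        width_um=dimensions.width_um if dimensions else None,
        depth_um=dimensions.depth_um if dimensions else None,
        wall_class=wall.wall_class if wall else None,
        extras=extras,
    )
    return QuantifyResult(
        report=report,
        labels=labels,
        envelope=envelope,
        combined_shg=combined,
        shg_depth=shg_depth,
        ef_depth=ef_depth,
        dimensions=dimensions,
        wall=wall,
        distribution=distribution,
        fraction=fraction,
        sweep=sweep,
        envelope_threshold=thr,
    )
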