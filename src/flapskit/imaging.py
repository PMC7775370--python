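"""Dual-channel epifluorescence enumeration of total and selfish cells.

Cells are detected in the DAPI (blue) channel by thresholding against the
image background (per-image median) at a signal-to-background ratio (SBR)
and filtering connected components by area. Substrate-stained ("selfish")
cells are DAPI objects co-localized with an FLA-PS (488, green) object that
passes the fixed criteria: area 0.17-0.3 um^2 (17-30 pixels at 0.1 um/px),
SBR >= 2.5, and >= 30% overlap of the green object's area with the DAPI
object. Field-of-view counts are scaled to volumetric abundances through
the filter geometry (effective filtration area / FOV area / volume filtered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for cell detection and selfish classification.

    The FLA criteria (SBR >= 2.5, area 0.17-0.3 um^2, overlap >= 0.30) are
    the fixed enumeration parameters; the DAPI thresholds are configurable
    analysis defaults. Overlap is measured as the shared pixel area divided
    by the FLA object's area (the smaller, substrate-signal object).
    """

    dapi_sbr_min: float = 2.0
    dapi_area_range: tuple[float, float] = (0.1, 1.5)
    fla_sbr_min: float = 2.5
    fla_area_range: tuple[float, float] = (0.17, 0.3)
    overlap_min: float = 0.30
    pixel_pitch: float = 0.1

    def __post_init__(self):
        for name in ("dapi_sbr_min", "fla_sbr_min", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.overlap_min <= 1.0:
            raise ValueError("overlap_min must be in (0, 1]")
        for name in ("dapi_area_range", "fla_area_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be a non-empty positive interval")

    def sbr_min(self, channel: str) -> float:
        return self.dapi_sbr_min if channel == "dapi" else self.fla_sbr_min

    def area_range(self, channel: str) -> tuple[float, float]:
        return self.dapi_area_range if channel == "dapi" else self.fla_area_range


@dataclass(frozen=True)
class DetectedObject:
    """One connected fluorescent object in a single channel."""

    object_id: int
    channel: str
    centroid: tuple[float, float]
    area_um2: float
    mean_signal: float
    background: float
    pixels: frozenset  # flattened pixel indices

    @property
    def sbr(self) -> float:
        return self.mean_signal / self.background


@dataclass(frozen=True)
class SelfishClassification:
    """Co-localization verdict for one DAPI object."""

    dapi_id: int
    positive: bool
    fla_id: int | None = None
    overlap_fraction: float = 0.0


@dataclass(frozen=True)
class FilterGeometry:
    """Geometry linking per-FOV counts to the filtered water volume."""

    filtration_area_mm2: float
    fov_area_mm2: float

    def __post_init__(self):
        if self.filtration_area_mm2 <= 0 or self.fov_area_mm2 <= 0:
            raise ValueError("filter and FOV areas must be positive")

    @property
    def area_ratio(self) -> float:
        return self.filtration_area_mm2 / self.fov_area_mm2


@dataclass(frozen=True)
class AbundanceEstimate:
    """Volumetric total and selfish cell abundances from FOV enumeration."""

    total_per_ml: float
    selfish_per_ml: float
    n_fov: int
    geometry: FilterGeometry
    volume_ml: float
    total_sd_per_ml: float = 0.0
    selfish_sd_per_ml: float = 0.0

    def __post_init__(self):
        if self.selfish_per_ml > self.total_per_ml + 1e-9:
            raise ValueError("selfish abundance cannot exceed total abundance")
        if self.n_fov < 1:
            raise ValueError("at least one field of view is required")

    @property
    def selfish_percent(self) -> float:
        return 100.0 * self.selfish_per_ml / self.total_per_ml \
            if self.total_per_ml > 0 else 0.0


def detect_objects(image, params: DetectionParams, channel: str = "dapi",
                   ) -> list[DetectedObject]:
    """Detect fluorescent objects in one channel.

    Background is the per-image median; candidate pixels have signal >=
    ``sbr_min x background`` and are grouped by 8-connectivity; components
    outside the channel's area window are discarded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    background = float(np.median(img))
    if background <= 0:
        raise ValueError("degenerate background: image median is not positive")
    sbr_min = params.sbr_min(channel)
    lo, hi = params.area_range(channel)
    pp2 = params.pixel_pitch ** 2

    mask = img >= sbr_min * background
    labels = cc_label(mask, connectivity=2)
    width = img.shape[1]
    out = []
    for region in regionprops(labels, intensity_image=img):
        area_um2 = region.area * pp2
        if not lo <= area_um2 <= hi:
            continue
        flat = frozenset(int(r * width + c) for r, c in region.coords)
        out.append(DetectedObject(
            object_id=len(out), channel=channel,
            centroid=tuple(float(v) for v in region.centroid),
            area_um2=float(area_um2),
            mean_signal=float(region.intensity_mean),
            background=background, pixels=flat))
    return out


def classify_selfish(dapi_objs: list[DetectedObject],
                     fla_objs: list[DetectedObject],
                     params: DetectionParams) -> list[SelfishClassification]:
    """Match FLA objects to DAPI objects by pixel overlap.

    Overlap is |FLA ∩ DAPI| / |FLA|. Pairs are assigned greedily,
    largest overlap first (ties broken by lower FLA id, then lower DAPI
    id); each FLA object matches at most one DAPI object and vice versa. A
    DAPI object is positive iff its matched overlap >= ``overlap_min``.
    """
    pairs = []
    for f in fla_objs:
        if not f.pixels:
            continue
        for d in dapi_objs:
            shared = len(f.pixels & d.pixels)
            if shared:
                pairs.append((shared / len(f.pixels), f.object_id, d.object_id))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    matched_f: set[int] = set()
    best: dict[int, tuple[int, float]] = {}
    for overlap, fid, did in pairs:
        if fid in matched_f or did in best:
            continue
        matched_f.add(fid)
        best[did] = (fid, overlap)

    out = []
    for d in dapi_objs:
        fid, overlap = best.get(d.object_id, (None, 0.0))
        positive = overlap >= params.overlap_min
        out.append(SelfishClassification(dapi_id=d.object_id, positive=positive,
                                         fla_id=fid if positive else None,
                                         overlap_fraction=float(overlap)))
    return out


def count_scene(blue, green, params: DetectionParams) -> tuple[int, int]:
    """(total, selfish) cell counts for one FOV pair."""
    dapi = detect_objects(blue, params, "dapi")
    fla = detect_objects(green, params, "fla")
    cls = classify_selfish(dapi, fla, params)
    return len(dapi), sum(c.positive for c in cls)


def counts_to_concentration(per_fov_counts, geometry: FilterGeometry,
                            volume_ml: float) -> tuple[float, float]:
    """Convert per-FOV counts to (cells ml^-1, per-FOV sd in cells ml^-1)."""
    counts = np.asarray(per_fov_counts, dtype=float)
    if counts.size < 1:
        raise ValueError("at least one field of view is required")
    if volume_ml <= 0:
        raise ValueError("filtered volume must be positive")
    scale = geometry.area_ratio / volume_ml
    sd = counts.std(ddof=1) if counts.size > 1 else 0.0
    return float(counts.mean() * scale), float(sd * scale)


def abundance_estimate(total_counts, selfish_counts, geometry: FilterGeometry,
                       volume_ml: float) -> AbundanceEstimate:
    """AbundanceEstimate from paired per-FOV total and selfish counts."""
    total_counts = np.asarray(total_counts)
    selfish_counts = np.asarray(selfish_counts)
    if total_counts.shape != selfish_counts.shape:
        raise ValueError("total and selfish count lists must align per FOV")
    total, total_sd = counts_to_concentration(total_counts, geometry, volume_ml)
    selfish, selfish_sd = counts_to_concentration(selfish_counts, geometry, volume_ml)
    return AbundanceEstimate(total_per_ml=total, selfish_per_ml=selfish,
                             n_fov=len(total_counts), geometry=geometry,
                             volume_ml=volume_ml, total_sd_per_ml=total_sd,
                             selfish_sd_per_ml=selfish_sd)


def enumerate_fovs(scenes, params: DetectionParams) -> pd.DataFrame:
    """Per-FOV object counts for a list of (blue, green) scenes."""
    rows = []
    for i, scene in enumerate(scenes):
        total, selfish = count_scene(scene.blue, scene.green, params)
        rows.append({"fov": i, "total": total, "selfish": selfish})
    return pd.DataFrame(rows)
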