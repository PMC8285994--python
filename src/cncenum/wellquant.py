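"""Per-cell multichannel quantification of microwell-chip images.

Turns a rendered (or ingested) chip scene into the canonical per-cell table:
locate the well grid, segment nucleated objects (DAPI in the fixed round, a
CD45/2-NBDG composite in the live round, before any DAPI is present), and
measure background-corrected mean intensities per channel for every object.

Measured intensities are plateau means: within each segmented object the
pixels above a fixed fraction of the object's amplitude (in the segmentation
channel) are averaged, per channel, minus the local per-well background
median.  The residual multiplicative footprint factor this leaves is common
to all cells on a chip and cancels in the leukocyte-anchored gate downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .chipsim import (
    CH_CD45,
    CH_DAPI,
    CH_NBDG,
    CH_NEUN,
    FIXED_ROUND,
    LIVE_ROUND,
    ChipLayout,
    SceneImage,
)
from .errors import GeometryError, InputError

#: Canonical per-cell table schema (column order is part of the contract).
RECORD_COLUMNS = [
    "cell_id", "sample_id", "block_id", "well_id", "round_id",
    "x_px", "y_px", "area_px2", "dapi", "neun", "cd45", "nbdg",
]

CHANNEL_TO_COLUMN = {CH_DAPI: "dapi", CH_NEUN: "neun", CH_CD45: "cd45", CH_NBDG: "nbdg"}

UNASSIGNED_WELL = -1


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected foreground components smaller than min_area pixels."""
    comp, n = ndi.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(comp.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[comp]


@dataclass
class SegmentationInfo:
    """Detection settings and image statistics actually used for one round."""

    round_id: str
    channel: str
    background: float
    noise_sd: float
    threshold: float
    n_objects: int


def locate_wells(image: SceneImage, layout: ChipLayout) -> pd.DataFrame:
    """One region per layout well: block_id, well_id, x_px, y_px, radius_px.

    The simulator renders scenes on the layout's own canvas, so well centers
    follow the regular grid directly; a dimension mismatch between image and
    layout raises :class:`GeometryError`.
    """
    if image.shape != layout.image_shape:
        raise GeometryError(
            f"image shape {image.shape} does not match layout shape {layout.image_shape}"
        )
    wells = layout.well_centers().copy()
    wells["radius_px"] = layout.well_radius_px
    return wells


def _segmentation_channel(image: SceneImage) -> tuple[np.ndarray, str]:
    """Round-appropriate segmentation image: DAPI after fixation, the
    max-composite of CD45 and 2-NBDG before it (no DAPI on live cells)."""
    if image.round_id == FIXED_ROUND:
        if CH_DAPI not in image.channels:
            raise InputError(f"fixed-round segmentation requires channel {CH_DAPI!r}")
        return image.channels[CH_DAPI].astype(np.float64), CH_DAPI
    if image.round_id == LIVE_ROUND:
        present = [c for c in (CH_CD45, CH_NBDG) if c in image.channels]
        if not present:
            raise InputError(
                f"live-round segmentation requires channel {CH_CD45!r} or {CH_NBDG!r}"
            )
        comp = image.channels[present[0]].astype(np.float64)
        for c in present[1:]:
            comp = np.maximum(comp, image.channels[c].astype(np.float64))
        return comp, "+".join(present)
    raise InputError(f"unknown round_id {image.round_id!r}")


def segment_cells(
    image: SceneImage,
    min_area: int = 20,
    detect_k: float = 3.0,
    peak_min_distance: int = 3,
) -> tuple[np.ndarray, SegmentationInfo]:
    """Label nucleated objects in the round's segmentation channel.

    Pixels above background + ``detect_k`` noise SDs (robust median/MAD
    estimates) form the foreground; small specks are removed, holes filled,
    and touching cells within a well are split by a seeded watershed on the
    smoothed intensity.  Deterministic.
    """
    img, channel = _segmentation_channel(image)
    background = float(np.median(img))
    noise_sd = float(1.4826 * np.median(np.abs(img - background)))
    # Floor keeps thresholding meaningful on noise-free synthetic scenes.
    threshold = background + max(detect_k * noise_sd, 0.5)

    mask = img > threshold
    mask = _drop_small(mask, int(min_area))
    mask = ndi.binary_fill_holes(mask)

    labels = np.zeros(img.shape, dtype=np.int32)
    n_objects = 0
    if mask.any():
        smooth = ndi.gaussian_filter(img, 1.0)
        comp, _ = ndi.label(mask)
        peaks = peak_local_max(
            smooth,
            min_distance=peak_min_distance,
            labels=comp,
            exclude_border=False,
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-smooth, markers, mask=mask).astype(np.int32)
        # components that received no marker (tiny/flat): keep them as objects
        orphan = mask & (labels == 0)
        if orphan.any():
            extra, n_extra = ndi.label(orphan)
            labels = np.where(orphan, extra + labels.max(), labels)
        # enforce min_area after splitting
        areas = np.bincount(labels.ravel())
        small = np.nonzero(areas < int(min_area))[0]
        if len(small):
            labels[np.isin(labels, small[small > 0])] = 0
        ids = np.unique(labels)
        ids = ids[ids > 0]
        n_objects = len(ids)
        if n_objects and (ids != np.arange(1, n_objects + 1)).any():
            remap = np.zeros(labels.max() + 1, dtype=np.int32)
            remap[ids] = np.arange(1, n_objects + 1)
            labels = remap[labels]

    info = SegmentationInfo(
        round_id=image.round_id,
        channel=channel,
        background=background,
        noise_sd=noise_sd,
        threshold=threshold,
        n_objects=n_objects,
    )
    return labels, info


def _well_background(
    channel_imgs: dict[str, np.ndarray],
    labels: np.ndarray,
    cx: float,
    cy: float,
    radius: float,
) -> dict[str, float]:
    """Per-channel median of non-object pixels in the well's bounding square."""
    h, w = labels.shape
    x0 = max(int(cx - radius), 0)
    x1 = min(int(math.ceil(cx + radius)) + 1, w)
    y0 = max(int(cy - radius), 0)
    y1 = min(int(math.ceil(cy + radius)) + 1, h)
    free = labels[y0:y1, x0:x1] == 0
    out: dict[str, float] = {}
    for col, img in channel_imgs.items():
        patch = img[y0:y1, x0:x1]
        out[col] = float(np.median(patch[free])) if free.any() else float(np.median(patch))
    return out


def measure_cells(
    labels: np.ndarray,
    image: SceneImage,
    wells: pd.DataFrame,
    sample_id: str,
    measure_frac: float = 0.7,
) -> pd.DataFrame:
    """Measure every labeled object into a canonical per-cell record.

    Each object is assigned to the well containing its centroid (well_id
    ``-1`` flags objects outside every well; they are kept, not dropped).
    Intensities are plateau means minus the per-well local background median,
    floored at 0; channels absent from the round are NaN.
    """
    seg_img, _ = _segmentation_channel(image)
    channel_imgs = {
        CHANNEL_TO_COLUMN[ch]: image.channels[ch].astype(np.float64)
        for ch in image.channels
        if ch in CHANNEL_TO_COLUMN
    }

    regions = regionprops(labels)
    if not regions:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    centroids = np.array([(r.centroid[1], r.centroid[0]) for r in regions])  # (x, y)
    tree = cKDTree(wells[["x_px", "y_px"]].to_numpy(float))
    dist, widx = tree.query(centroids)
    radius = wells["radius_px"].to_numpy(float)
    assigned = dist <= radius[widx] + 1.0

    bg_cache: dict[int, dict[str, float]] = {}
    wxy = wells[["x_px", "y_px", "radius_px"]].to_numpy(float)
    wkeys = wells[["block_id", "well_id"]].to_numpy(int)

    rows = []
    for i, region in enumerate(regions):
        ys, xs = region.coords[:, 0], region.coords[:, 1]
        if assigned[i]:
            wi = int(widx[i])
            block_id, well_id = int(wkeys[wi, 0]), int(wkeys[wi, 1])
            if wi not in bg_cache:
                bg_cache[wi] = _well_background(
                    channel_imgs, labels, wxy[wi, 0], wxy[wi, 1], wxy[wi, 2]
                )
            bg = bg_cache[wi]
        else:
            block_id, well_id = UNASSIGNED_WELL, UNASSIGNED_WELL
            pad = 8
            y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, labels.shape[0])
            x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, labels.shape[1])
            free = labels[y0:y1, x0:x1] == 0
            bg = {
                col: float(np.median(img[y0:y1, x0:x1][free])) if free.any() else 0.0
                for col, img in channel_imgs.items()
            }

        # plateau selection on the segmentation channel
        segvals = seg_img[ys, xs]
        amp = float(np.percentile(segvals, 90))
        if image.round_id == FIXED_ROUND and "dapi" in bg:
            seg_bg = bg["dapi"]
        else:
            cands = [bg[c] for c in ("cd45", "nbdg") if c in bg]
            seg_bg = float(np.median(cands)) if cands else (min(bg.values()) if bg else 0.0)
        cut = seg_bg + measure_frac * (amp - seg_bg)
        sel = segvals >= cut
        if not sel.any():
            sel = np.ones_like(sel, dtype=bool)

        record = {
            "cell_id": f"{sample_id}:{image.round_id}:{region.label:05d}",
            "sample_id": sample_id,
            "block_id": block_id,
            "well_id": well_id,
            "round_id": image.round_id,
            "x_px": float(centroids[i, 0]),
            "y_px": float(centroids[i, 1]),
            "area_px2": int(region.area),
        }
        for col in ("dapi", "neun", "cd45", "nbdg"):
            if col in channel_imgs:
                val = float(np.mean(channel_imgs[col][ys, xs][sel])) - bg[col]
                record[col] = max(val, 0.0)
            else:
                record[col] = np.nan
        rows.append(record)

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def quantify_round(
    image: SceneImage,
    layout: ChipLayout,
    sample_id: str,
    min_area: int = 20,
    detect_k: float = 3.0,
    measure_frac: float = 0.7,
) -> tuple[pd.DataFrame, SegmentationInfo]:
    """Convenience wrapper: locate wells, segment, measure one round."""
    wells = locate_wells(image, layout)
    labels, info = segment_cells(image, min_area=min_area, detect_k=detect_k)
    records = measure_cells(labels, image, wells, sample_id, measure_frac=measure_frac)
    return records, info


def match_rounds(
    live_records: pd.DataFrame,
    fixed_records: pd.DataFrame,
    tolerance: float = 3.0,
) -> pd.DataFrame:
    """Merge the two acquisition rounds, anchored on fixed-round cells.

    Greedy nearest-centroid matching within the same well, within
    ``tolerance`` pixels; ambiguities resolve by smallest distance, ties by
    lowest cell_id (deterministic).  Merged records carry fixed-round
    DAPI/NeuN/CD45 plus the matched live-round 2-NBDG; unmatched fixed-round
    cells keep NBDG missing (a cell absent from the live round never showed
    glucose uptake).
    """
    merged = fixed_records.copy().reset_index(drop=True)
    merged["nbdg"] = np.nan
    merged["matched_live_cell_id"] = pd.array([pd.NA] * len(merged), dtype="object")
    merged["match_dist_px"] = np.nan
    if len(merged) == 0 or len(live_records) == 0:
        return merged

    live_groups = {
        key: grp for key, grp in live_records.groupby(["block_id", "well_id"], sort=True)
    }
    fixed_idx_by_key = merged.groupby(["block_id", "well_id"], sort=True).groups

    for key, fidx in fixed_idx_by_key.items():
        lgrp = live_groups.get(key)
        if lgrp is None or len(lgrp) == 0:
            continue
        fsub = merged.loc[fidx]
        pairs = []
        lxy = lgrp[["x_px", "y_px"]].to_numpy(float)
        fxy = fsub[["x_px", "y_px"]].to_numpy(float)
        for a, (fi, frow) in enumerate(fsub.iterrows()):
            d = np.hypot(lxy[:, 0] - fxy[a, 0], lxy[:, 1] - fxy[a, 1])
            for b in np.nonzero(d <= tolerance)[0]:
                pairs.append((float(d[b]), str(frow["cell_id"]),
                              str(lgrp.iloc[b]["cell_id"]), fi, lgrp.index[b]))
        pairs.sort()
        used_f: set = set()
        used_l: set = set()
        for d, _fcid, lcid, fi, li in pairs:
            if fi in used_f or li in used_l:
                continue
            used_f.add(fi)
            used_l.add(li)
            merged.at[fi, "nbdg"] = live_records.at[li, "nbdg"]
            merged.at[fi, "matched_live_cell_id"] = lcid
            merged.at[fi, "match_dist_px"] = d
    return merged
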