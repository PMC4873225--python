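"""Organoid segmentation and morphometric descriptors.

Works on 2-D maximum-intensity projections of confocal stacks with a
live (calcein) and a dead (ethidium homodimer) channel.  The
descriptors quantify organoid growth and invasive phenotype: Area,
perimeter, Roundness (circularity), Roughness (boundary irregularity),
protrusion count and protrusion-area fraction (invasive processes),
live-stain Density, dead/apoptotic signal, and a cell-number estimate.
Condition-level summaries express each quantity as percent of an
untreated control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology

__all__ = [
    "OrganoidImage",
    "project_stack",
    "segment",
    "shape_features",
    "protrusion_features",
    "intensity_features",
    "cell_number",
    "measure_image",
    "condition_summary",
]

log = logging.getLogger(__name__)


@dataclass
class OrganoidImage:
    """Two-channel projection: live (calcein) and dead (EthD-1) intensities."""

    live: np.ndarray
    dead: np.ndarray
    pixel_scale: float | None = None  # µm per pixel

    def __post_init__(self) -> None:
        if self.live.shape != self.dead.shape:
            raise ValueError("channels must share shape")
        if (np.asarray(self.live) < 0).any() or (np.asarray(self.dead) < 0).any():
            raise ValueError("intensities must be non-negative")


def project_stack(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Maximum-intensity projection across focal slices."""
    arrays = [np.asarray(s) for s in stack]
    if not arrays:
        raise ValueError("empty stack")
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError("slice shapes differ")
    return np.maximum.reduce(arrays)


def segment(
    image: np.ndarray,
    threshold: float | str = "otsu",
    min_area: int = 50,
) -> np.ndarray:
    """Threshold + 8-connected labeling, small components removed.

    ``threshold`` is either a fixed intensity or ``"otsu"``.  Labels are
    renumbered deterministically by the top-left-most pixel of each
    component.  An all-background image yields zero labels.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=np.int32)
        thr = threshold_otsu(image)
    else:
        thr = float(threshold)
    fg = image > thr
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.reshape(-1))
    # deterministic order: first foreground pixel in raster scan; drop runts
    order = []
    seen: set[int] = set()
    for v in labels.reshape(-1):
        if v != 0 and v not in seen:
            seen.add(int(v))
            if areas[v] >= min_area:
                order.append(int(v))
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels]


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    return contour


def _contour_length(contour: np.ndarray) -> float:
    d = np.diff(contour, axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Area, perimeter, roundness and roughness of one organoid mask.

    Perimeter uses the weighted boundary-step estimator (axis-aligned
    border steps count 1, diagonal configurations sqrt(2)); a filled
    s x s square measures 4(s-1).
    Roundness = min(1, 4*pi*area/perimeter^2), 1 for a circle.
    Roughness is the mean absolute radial deviation of the boundary from
    the boundary of a morphologically smoothed (opened) copy of the
    mask, normalized by the equivalent radius sqrt(area/pi); a smooth
    convex blob scores near 0.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    perimeter = float(measure.perimeter(mask, neighborhood=4))
    roundness = min(1.0, 4.0 * math.pi * area / perimeter**2) if perimeter > 0 else 1.0

    r_eq = math.sqrt(area / math.pi)
    r_smooth = max(1, int(round(0.25 * r_eq)))
    smoothed = morphology.opening(mask, morphology.disk(r_smooth))
    if not smoothed.any():
        smoothed = mask  # opening erased everything; roughness degenerates to 0
    cy, cx = np.argwhere(mask).mean(axis=0)

    def radial_profile(m: np.ndarray, n_bins: int = 72) -> np.ndarray:
        c = _longest_contour(m)
        ang = np.arctan2(c[:, 0] - cy, c[:, 1] - cx)
        rad = np.hypot(c[:, 0] - cy, c[:, 1] - cx)
        bins = ((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        prof = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                prof[b] = rad[sel].max()
        # fill empty bins by nearest non-empty neighbour (circular)
        if np.isnan(prof).any():
            idx = np.arange(n_bins)
            good = ~np.isnan(prof)
            prof = np.interp(idx, idx[good], prof[good], period=n_bins)
        return prof

    prof_mask = radial_profile(mask)
    prof_smooth = radial_profile(smoothed)
    roughness = float(np.mean(np.abs(prof_mask - prof_smooth)) / r_eq)

    return {
        "area": float(area),
        "perimeter": perimeter,
        "roundness": float(roundness),
        "roughness": roughness,
    }


def protrusion_features(
    mask: np.ndarray, opening_radius: int, min_spike_area: int = 5
) -> dict[str, float]:
    """Protrusion count and area fraction via morphological opening.

    The organoid body is the opening of the mask with a disk of
    ``opening_radius``; protrusions are the 8-connected components of
    mask minus body with at least ``min_spike_area`` pixels.  Returns
    app_count (the protrusion count) and app_index (total protrusion
    area / mask area).  If opening erases the whole mask the result is
    flagged degenerate with count 0.
    """
    if opening_radius < 1:
        raise ValueError("opening_radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    body = morphology.opening(mask, morphology.disk(opening_radius))
    if not body.any():
        return {"app_count": 0, "app_index": 0.0, "degenerate": True}
    spikes = mask & ~body
    labels = measure.label(spikes, connectivity=2)
    count = 0
    spike_area = 0
    for region in measure.regionprops(labels):
        if region.area >= min_spike_area:
            count += 1
            spike_area += int(region.area)
    return {
        "app_count": count,
        "app_index": float(spike_area / mask.sum()),
        "degenerate": False,
    }


def intensity_features(image: OrganoidImage, mask: np.ndarray) -> dict[str, float]:
    """Live density plus dead/apoptosis stain statistics over one mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.shape != image.live.shape:
        raise ValueError("mask must match image shape")
    live = np.asarray(image.live, dtype=float)
    dead = np.asarray(image.dead, dtype=float)
    return {
        "density": float(live[mask].mean()),
        "ethd_mean": float(dead[mask].mean()),
        "ethd_total": float(dead[mask].sum()),
        "apoptosis_mean": float(dead[mask].mean()),
        "apoptosis_total": float(dead[mask].sum()),
    }


def cell_number(
    mask: np.ndarray,
    nuclei_image: np.ndarray | None = None,
    typical_cell_area: float | None = None,
) -> int:
    """Cell count inside a mask: nuclei blobs if imaged, else area/cell size."""
    mask = np.asarray(mask, dtype=bool)
    if nuclei_image is not None:
        labels = segment(np.where(mask, nuclei_image, 0), min_area=1)
        return int(labels.max())
    if typical_cell_area is not None:
        if typical_cell_area <= 0:
            raise ValueError("typical_cell_area must be positive")
        return int(round(mask.sum() / typical_cell_area))
    raise ValueError("supply a nuclei image or a typical cell area")


def measure_image(
    image: OrganoidImage,
    threshold: float | str = "otsu",
    min_area: int = 50,
    opening_radius: int | None = None,
    min_spike_area: int = 5,
    typical_cell_area: float = 100.0,
) -> pd.DataFrame:
    """Segment the live channel and tabulate every descriptor per organoid.

    ``opening_radius`` defaults to a quarter of the median equivalent
    radius of the segmented organoids (adaptive to organoid size).
    """
    labels = segment(np.asarray(image.live), threshold, min_area)
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame()
    if opening_radius is None:
        radii = [math.sqrt(np.sum(labels == i) / math.pi) for i in range(1, n + 1)]
        opening_radius = max(1, int(round(0.25 * float(np.median(radii)))))
    rows = []
    for i in range(1, n + 1):
        mask = labels == i
        feats = {"organoid": i}
        feats.update(shape_features(mask))
        feats.update(protrusion_features(mask, opening_radius, min_spike_area))
        feats.update(intensity_features(image, mask))
        feats["cell_number"] = cell_number(mask, typical_cell_area=typical_cell_area)
        rows.append(feats)
    return pd.DataFrame(rows).set_index("organoid")


def condition_summary(
    records: Mapping[str, pd.DataFrame] | pd.DataFrame,
    control_condition: str = "untreated",
) -> pd.DataFrame:
    """Percent-of-control condition table for the cytotoxicity readouts.

    Per condition: mean apoptosis signal, total apoptosis signal, mean
    dead-stain signal, total dead-stain signal and summed organoid area,
    each as a percentage of the control condition (control row = 100%).
    An empty condition yields a row of NaNs and a logged warning.
    """
    if isinstance(records, pd.DataFrame):
        grouped = {str(c): sub.drop(columns="condition") for c, sub in records.groupby("condition")}
    else:
        grouped = {str(k): v for k, v in records.items()}
    if control_condition not in grouped:
        raise ValueError(f"control condition {control_condition!r} absent")

    def reduce(df: pd.DataFrame) -> pd.Series | None:
        if df is None or len(df) == 0:
            return None
        return pd.Series({
            "apoptosis_mean": df["apoptosis_mean"].mean(),
            "apoptosis_total": df["apoptosis_total"].sum(),
            "ethd_mean": df["ethd_mean"].mean(),
            "ethd_total": df["ethd_total"].sum(),
            "area_sum": df["area"].sum(),
        })

    control = reduce(grouped[control_condition])
    if control is None:
        raise ValueError("control condition has no records")
    rows = {}
    for cond, df in grouped.items():
        r = reduce(df)
        if r is None:
            log.warning("condition %r has no organoid records", cond)
            rows[cond] = pd.Series(np.nan, index=control.index)
        else:
            rows[cond] = 100.0 * r / control
    out = pd.DataFrame(rows).T.sort_index()
    out.loc[control_condition] = 100.0
    out.index.name = "condition"
    return out
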