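"""Compartmented single-cell segmentation and per-cell measurement.

The pipeline mirrors the CellProfiler-style object hierarchy used for
endothelial monolayer morphometry: nuclei (primary objects) are
thresholded from the DAPI channel, whole cells (secondary objects) are
grown from the nuclei inside the actin foreground by seeded watershed,
cytoplasm (tertiary) is cell minus nucleus, and a fixed-thickness
membrane ring is cell minus the cell eroded by ``n`` pixels.  The key
junctional readout is the ratio of mean VE-cadherin fluorescence in the
membrane ring to the whole-cell mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "ImageStack",
    "LabelMaps",
    "DegenerateImageError",
    "li_threshold",
    "segment_primary",
    "segment_secondary",
    "tertiary_cytoplasm",
    "shrink_labels",
    "membrane_ring",
    "border_labels",
    "measure_shape",
    "measure_intensity",
    "junctional_ratio",
    "segment_stack",
    "measure_cells",
]

CHANNELS = ("nuclei", "actin", "ve_cadherin")

#: 8-connected structuring element used for per-object erosion.
_SE8 = np.ones((3, 3), dtype=bool)


class DegenerateImageError(ValueError):
    """Raised when an image has too little structure to threshold."""


@dataclass(frozen=True)
class ImageStack:
    """Registered multi-channel fluorescence image of one field of view."""

    nuclei: np.ndarray
    actin: np.ndarray
    ve_cadherin: np.ndarray
    pixel_size: float = 0.16  # um per pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {self.nuclei.shape, self.actin.shape, self.ve_cadherin.shape}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if self.nuclei.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        for name in CHANNELS:
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class LabelMaps:
    """Object hierarchy produced by the segmentation stage.

    ``primary`` (nuclei), ``secondary`` (cells, same label ids as their
    nuclei), ``tertiary`` (cytoplasm = cell minus nucleus), ``membrane``
    (ring of ``ring_px`` thickness) and bookkeeping sets: labels touching
    the image border (excluded from records), cells whose seed fell
    outside the actin foreground, and cells eroded to extinction by the
    ring operation.
    """

    primary: np.ndarray
    secondary: np.ndarray
    tertiary: np.ndarray
    membrane: np.ndarray
    shrunk: np.ndarray
    border_excluded: set[int] = field(default_factory=set)
    seed_outside_foreground: set[int] = field(default_factory=set)
    too_small_for_ring: set[int] = field(default_factory=set)
    ring_px: int = 3


def li_threshold(channel: np.ndarray) -> float:
    """Minimum cross-entropy (Li) threshold; foreground is strictly above."""
    channel = np.asarray(channel)
    if np.min(channel) == np.max(channel):
        raise DegenerateImageError("cannot threshold a constant image")
    return float(filters.threshold_li(channel))


def segment_primary(
    nuclei: np.ndarray,
    min_area_px: int = 50,
    declump: bool = False,
) -> np.ndarray:
    """Label nuclei: Li threshold, fill holes, 8-connected components.

    Components smaller than ``min_area_px`` are dropped and the survivors
    relabelled 1..n.  ``declump`` optionally splits touching nuclei by a
    distance-transform watershed (off by default).
    """
    mask = nuclei > li_threshold(nuclei)
    mask = ndi.binary_fill_holes(mask)
    if declump:
        dist = ndi.distance_transform_edt(mask)
        peaks = morphology.local_maxima(ndi.gaussian_filter(dist, 2.0)) & mask
        markers, _ = ndi.label(peaks, structure=_SE8)
        labels = segmentation.watershed(-dist, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask, structure=_SE8)
    counts = np.bincount(labels.ravel())
    small = np.nonzero(counts < min_area_px)[0]
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    if labels.max() == 0:
        import warnings

        warnings.warn("no nuclei survived thresholding/size filtering", stacklevel=2)
    return labels.astype(np.int32)


def segment_secondary(actin: np.ndarray, primary: np.ndarray) -> tuple[np.ndarray, set[int]]:
    """Grow cell labels from nuclei inside the actin foreground.

    The foreground is the hole-filled Li-threshold mask of the actin
    channel; every foreground pixel is assigned to exactly one nucleus by
    seeded watershed on the distance-to-seed landscape (distance to the
    seed centroids, so cell boundaries fall midway between nuclei
    regardless of nuclear shape), so cells inherit their nucleus' label
    id and partition the foreground.  Seed pixels are always included
    even when they fall outside the foreground; such cells are returned
    in the flagged set.
    """
    if primary.max() == 0:
        raise ValueError("segment_secondary requires at least one primary object")
    # light smoothing before thresholding and a closing before hole-filling
    # keep shot noise from punching gaps in the cortical actin network
    smoothed = ndi.gaussian_filter(np.asarray(actin, dtype=float), 1.0)
    mask = smoothed > li_threshold(smoothed)
    padded = np.pad(mask, 1, mode="edge")  # closing must not eat the frame edge
    padded = ndi.binary_closing(padded, structure=np.ones((3, 3), bool))
    mask = ndi.binary_fill_holes(padded[1:-1, 1:-1])
    flagged = {
        int(lab)
        for lab in np.unique(primary[(primary > 0) & ~mask])
    }
    mask = mask | (primary > 0)  # seeds always belong to their cell
    seed_pts = np.ones(primary.shape, dtype=bool)
    for cy, cx in ndi.center_of_mass(primary > 0, primary, np.unique(primary[primary > 0])):
        seed_pts[int(round(cy)), int(round(cx))] = False
    dist_to_seed = ndi.distance_transform_edt(seed_pts)
    labels = segmentation.watershed(dist_to_seed, markers=primary, mask=mask)
    return labels.astype(np.int32), flagged


def tertiary_cytoplasm(secondary: np.ndarray, primary: np.ndarray) -> np.ndarray:
    """Cytoplasm labels: per-cell set difference secondary minus primary."""
    prim_ids = set(np.unique(primary)) - {0}
    sec_ids = set(np.unique(secondary)) - {0}
    if not prim_ids <= sec_ids:
        raise ValueError(
            f"primary labels {sorted(prim_ids - sec_ids)} have no matching secondary object"
        )
    tertiary = secondary.copy()
    tertiary[primary > 0] = 0
    return tertiary


def shrink_labels(labels: np.ndarray, n_px: int) -> tuple[np.ndarray, set[int]]:
    """Erode each object independently by ``n_px`` 8-connected iterations.

    Objects are eroded within their own footprint (adjacent objects do not
    protect each other); ids eroded to extinction are returned alongside.
    """
    if n_px < 1:
        raise ValueError("n_px must be >= 1")
    out = np.zeros_like(labels)
    gone: set[int] = set()
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        pad = ((1, 1), (1, 1))
        obj = np.pad(labels[sl] == lab, pad)
        eroded = ndi.binary_erosion(obj, structure=_SE8, iterations=n_px)
        eroded = eroded[1:-1, 1:-1]
        if not eroded.any():
            gone.add(lab)
            continue
        out[sl][eroded] = lab
    return out, gone


def membrane_ring(
    secondary: np.ndarray, n_px: int = 3
) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Membrane ring of ``n_px`` thickness: cell minus its eroded interior.

    Returns (ring labels, shrunk labels, flagged ids).  A cell eroded to
    extinction keeps its whole footprint as the ring and is flagged.
    """
    shrunk, gone = shrink_labels(secondary, n_px)
    ring = secondary.copy()
    ring[shrunk > 0] = 0
    return ring, shrunk, gone


def border_labels(labels: np.ndarray) -> set[int]:
    """Ids of objects touching the image border."""
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(int(v) for v in np.unique(edge)) - {0}


def measure_shape(labels: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-object size/shape table.

    area is in um^2 (pixel count x pixel_size^2); eccentricity is that of
    the ellipse with matching second central moments; circularity is
    4 pi A / P^2 and compactness its reciprocal.
    """
    if labels.max() == 0:
        raise ValueError("no labelled objects to measure")
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        perim = p.perimeter
        area_px = p.area
        circ = 4.0 * np.pi * area_px / perim**2 if perim > 0 else np.nan
        rows.append(
            {
                "cell_id": p.label,
                "area_px": int(area_px),
                "area_um2": area_px * pixel_size**2,
                "eccentricity": p.eccentricity,
                "perimeter_px": perim,
                "circularity": circ,
                "compactness": 1.0 / circ if circ and circ > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def measure_intensity(labels: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Mean and integrated fluorescence intensity per labelled object."""
    if labels.shape != channel.shape:
        raise ValueError("label map and channel shapes differ")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    flat_lab = labels.ravel()
    flat_ch = np.asarray(channel, dtype=float).ravel()
    counts = np.bincount(flat_lab, minlength=labels.max() + 1)
    sums = np.bincount(flat_lab, weights=flat_ch, minlength=labels.max() + 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    df = pd.DataFrame(
        {
            "cell_id": ids,
            "mean_fi": means[ids],
            "integrated_fi": sums[ids],
            "n_px": counts[ids],
        }
    ).set_index("cell_id")
    df["empty"] = df["n_px"] == 0
    return df


def junctional_ratio(membrane_mean: float, whole_mean: float) -> float:
    """Membrane-to-whole-cell mean VE-cadherin intensity ratio."""
    if whole_mean == 0 or not np.isfinite(whole_mean):
        return np.nan
    return membrane_mean / whole_mean


def segment_stack(
    stack: ImageStack,
    min_nucleus_px: int = 50,
    min_cell_px: int = 200,
    ring_px: int = 3,
    declump: bool = False,
) -> LabelMaps:
    """Run the full object hierarchy on one image stack."""
    primary = segment_primary(stack.nuclei, min_area_px=min_nucleus_px, declump=declump)
    secondary, flagged = segment_secondary(stack.actin, primary)
    # drop cells below the minimum size together with their nuclei
    small = {
        int(lab)
        for lab in np.unique(secondary)
        if lab > 0 and np.sum(secondary == lab) < min_cell_px
    }
    if small:
        drop = np.isin(secondary, list(small))
        secondary = secondary.copy()
        secondary[drop] = 0
        primary = primary.copy()
        primary[np.isin(primary, list(small))] = 0
    tertiary = tertiary_cytoplasm(secondary, primary)
    ring, shrunk, gone = membrane_ring(secondary, ring_px)
    border = border_labels(secondary)
    return LabelMaps(
        primary=primary,
        secondary=secondary,
        tertiary=tertiary,
        membrane=ring,
        shrunk=shrunk,
        border_excluded=border,
        seed_outside_foreground=flagged - small,
        too_small_for_ring=gone,
        ring_px=ring_px,
    )


def measure_cells(stack: ImageStack, maps: LabelMaps) -> pd.DataFrame:
    """Per-cell morphometry table (border-touching cells excluded).

    One row per interior cell: shape measures plus mean/integrated
    intensity of every channel over the whole-cell, cytoplasm and
    membrane compartments, and the junctional VE-cadherin ratio (both
    mean-based, the primary readout, and integrated-based for
    comparison).
    """
    if maps.secondary.max() == 0:
        return pd.DataFrame()
    shape_df = measure_shape(maps.secondary, stack.pixel_size)
    parts = {"whole": maps.secondary, "cytoplasm": maps.tertiary, "membrane": maps.membrane}
    blocks = [shape_df]
    for comp, lab in parts.items():
        for ch in CHANNELS:
            idf = measure_intensity(lab, stack.channel(ch))
            idf = idf[["mean_fi", "integrated_fi"]]
            idf.columns = [f"{comp}_{ch}_mean", f"{comp}_{ch}_integrated"]
            blocks.append(idf)
    df = pd.concat(blocks, axis=1)
    df["junctional_ratio"] = [
        junctional_ratio(m, w)
        for m, w in zip(df["membrane_ve_cadherin_mean"], df["whole_ve_cadherin_mean"])
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["junctional_ratio_integrated"] = (
            df["membrane_ve_cadherin_integrated"] / df["whole_ve_cadherin_integrated"]
        )
    df["touches_border"] = df.index.isin(maps.border_excluded)
    df["ring_degenerate"] = df.index.isin(maps.too_small_for_ring)
    return df[~df["touches_border"]].drop(columns=["touches_border"])
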