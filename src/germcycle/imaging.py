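"""Nuclear/cytoplasmic fluorescence ratio quantification.

Segmentation follows the classic local-adaptive-threshold recipe: the whole
signal (e.g. STRA8) mask comes from Bernsen's mid-range rule, the nuclear
mask from the local-mean rule on the DAPI channel, optionally refined by
binary erosion/dilation/hole filling.  Per cell, the nuclear signal mask is
the intersection of the signal mask with the nucleus; the cytoplasmic mask
is the cell's signal component minus that nuclear part; the N/C ratio is
the ratio of mean signal intensity per pixel over the two regions.

Neighborhoods are disks (a square window is available) with replicate
padding at the borders, and components are labeled with 8-connectivity.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


def _infer_maxval(channel: np.ndarray, bit_depth: int | None) -> int:
    if bit_depth is None:
        bit_depth = 16 if channel.dtype == np.uint16 else 8
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    return 2 ** bit_depth - 1


def neighborhood_footprint(radius: int, square: bool = False) -> np.ndarray:
    """Disk (default) or square footprint of the given pixel radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if square:
        return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    yy, xx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2


def _warn_large_radius(channel: np.ndarray, radius: int) -> None:
    if radius > min(channel.shape) / 2:
        warnings.warn(
            f"radius {radius} exceeds half the smaller image dimension "
            f"{min(channel.shape)}; result dominated by global statistics",
            stacklevel=3,
        )


def bernsen_mask(
    channel: np.ndarray,
    radius: int = 15,
    contrast_min: float = 15,
    midgray: float | None = None,
    bit_depth: int | None = None,
    square: bool = False,
) -> np.ndarray:
    """Bernsen local threshold.

    For every pixel the local max and min over the disk neighborhood
    (replicate-padded) give mid-range ``(max + min) / 2`` and contrast
    ``max - min``.  High-contrast pixels (contrast >= ``contrast_min``) are
    foreground iff their value exceeds the mid-range; low-contrast regions
    are assigned wholly by comparing the mid-range against ``midgray``
    (default: half the bit-depth maximum).
    """
    maxval = _infer_maxval(channel, bit_depth)
    if midgray is None:
        midgray = maxval / 2
    _warn_large_radius(channel, radius)
    fp = neighborhood_footprint(radius, square)
    img = np.asarray(channel)
    local_max = ndimage.maximum_filter(img, footprint=fp, mode="nearest")
    local_min = ndimage.minimum_filter(img, footprint=fp, mode="nearest")
    midrange = (local_max.astype(float) + local_min) / 2.0
    contrast = local_max.astype(float) - local_min
    return np.where(contrast >= contrast_min, img > midrange,
                    midrange >= midgray)


def local_mean_mask(
    channel: np.ndarray,
    radius: int = 15,
    c: float = 0,
    square: bool = False,
) -> np.ndarray:
    """Local-mean threshold: foreground iff value > local mean - ``c``.

    The local mean is taken over the disk neighborhood with replicate
    padding; sums are computed in exact integer arithmetic for integer
    images so the rule is bit-reproducible.
    """
    _warn_large_radius(channel, radius)
    fp = neighborhood_footprint(radius, square)
    img = np.asarray(channel)
    if np.issubdtype(img.dtype, np.integer):
        local_sum = ndimage.correlate(
            img.astype(np.int64), fp.astype(np.int64), mode="nearest"
        )
    else:
        local_sum = ndimage.correlate(
            img.astype(float), fp.astype(float), mode="nearest"
        )
    local_mean = local_sum / fp.sum()
    return img > local_mean - c


def refine_mask(
    mask: np.ndarray,
    ops: Sequence[str],
    footprint: np.ndarray | None = None,
) -> np.ndarray:
    """Apply binary morphology steps (``erode``, ``dilate``, ``fill_holes``)
    in the given order.

    ``footprint`` defaults to the 3x3 disk (4-neighborhood cross).  Erosion
    treats out-of-image pixels as foreground and dilation as background, so
    structures at the border behave as if the image continued.
    ``fill_holes`` converts background components not connected to the
    border into foreground.
    """
    if footprint is None:
        footprint = neighborhood_footprint(1)
    out = np.asarray(mask, dtype=bool)
    for op in ops:
        if op == "erode":
            out = ndimage.binary_erosion(out, structure=footprint,
                                         border_value=1)
        elif op == "dilate":
            out = ndimage.binary_dilation(out, structure=footprint,
                                          border_value=0)
        elif op == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        else:
            raise ValueError(f"unknown morphology op {op!r}")
    return out


_EIGHT = np.ones((3, 3), dtype=int)


def nc_ratio(
    signal: np.ndarray,
    signal_mask: np.ndarray,
    dapi_mask: np.ndarray,
    min_px: int = 10,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Per-cell nuclear/cytoplasmic mean-intensity ratios.

    Nuclei are the 8-connected components of ``dapi_mask`` (those touching
    the image border are excluded by default).  For each nucleus the cell's
    signal component is the 8-connected component of ``signal_mask`` with
    the largest overlap; the nuclear signal region is that component
    intersected with the nucleus, the cytoplasmic region is the rest of the
    component.  Cells whose nuclear or cytoplasmic region holds fewer than
    ``min_px`` pixels are reported with an undefined ratio and a reason
    code.  Per cell, nuclear + cytoplasmic pixel counts equal the signal
    component's size exactly.
    """
    signal = np.asarray(signal, dtype=float)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    dapi_mask = np.asarray(dapi_mask, dtype=bool)
    if signal_mask.shape != signal.shape or dapi_mask.shape != signal.shape:
        raise ValueError("masks must match the signal channel's shape")

    nuc_lbl, n_nuc = ndimage.label(dapi_mask, structure=_EIGHT)
    sig_lbl, _ = ndimage.label(signal_mask, structure=_EIGHT)
    if n_nuc == 0:
        warnings.warn("no nuclei found in the DAPI mask", stacklevel=2)
        return pd.DataFrame(columns=[
            "cell_id", "centroid_row", "centroid_col", "nuclear_mean",
            "cytoplasmic_mean", "ratio", "nuclear_px", "cytoplasmic_px",
            "reason",
        ])

    border = np.zeros_like(dapi_mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(nuc_lbl[border & dapi_mask]))

    centroids = ndimage.center_of_mass(
        dapi_mask, nuc_lbl, range(1, n_nuc + 1)
    )
    rows = []
    cell_id = 0
    for i in range(1, n_nuc + 1):
        if exclude_border and i in border_ids:
            continue
        nucleus = nuc_lbl == i
        overlap_ids, overlap_counts = np.unique(
            sig_lbl[nucleus & signal_mask], return_counts=True
        )
        keep = overlap_ids > 0
        overlap_ids, overlap_counts = overlap_ids[keep], overlap_counts[keep]
        rec = {
            "cell_id": cell_id,
            "centroid_row": centroids[i - 1][0],
            "centroid_col": centroids[i - 1][1],
            "nuclear_mean": np.nan,
            "cytoplasmic_mean": np.nan,
            "ratio": np.nan,
            "nuclear_px": 0,
            "cytoplasmic_px": 0,
            "reason": "",
        }
        cell_id += 1
        if overlap_ids.size == 0:
            rec["reason"] = "empty nuclear region"
            rows.append(rec)
            continue
        comp_id = overlap_ids[np.argmax(overlap_counts)]
        component = sig_lbl == comp_id
        nuclear_region = component & nucleus
        cyto_region = component & ~nuclear_region
        rec["nuclear_px"] = int(nuclear_region.sum())
        rec["cytoplasmic_px"] = int(cyto_region.sum())
        if rec["nuclear_px"] > 0:
            rec["nuclear_mean"] = float(signal[nuclear_region].mean())
        if rec["cytoplasmic_px"] > 0:
            rec["cytoplasmic_mean"] = float(signal[cyto_region].mean())
        if rec["nuclear_px"] < min_px:
            rec["reason"] = "empty nuclear region" if rec["nuclear_px"] == 0 \
                else "nuclear region below min_px"
        elif rec["cytoplasmic_px"] < min_px:
            rec["reason"] = "cytoplasmic region below min_px"
        else:
            rec["ratio"] = rec["nuclear_mean"] / rec["cytoplasmic_mean"]
        rows.append(rec)
    return pd.DataFrame(rows)


def quantify_image(
    image: np.ndarray,
    dapi_channel: int = 0,
    signal_channel: int = 1,
    bernsen_radius: int = 6,
    contrast_min: float = 15,
    midgray: float | None = None,
    mean_radius: int = 15,
    mean_c: float = 0,
    refine_radius: int = 2,
    min_px: int = 10,
) -> pd.DataFrame:
    """Full quantification pipeline on a multi-channel image.

    Signal mask: Bernsen threshold with a neighborhood smaller than the
    cytoplasmic rim (a radius larger than the rim lets a bright nucleus
    dominate the local mid-range and erase the cytoplasm), followed by hole
    filling — which recovers whichever compartment is dimmer than the other
    as an enclosed hole — and an opening (erode + dilate, disk of
    ``refine_radius``) to drop noise speckle.  Nuclear mask: local-mean
    threshold on DAPI with the same refinement.  Ratios via
    :func:`nc_ratio`.
    """
    dapi = image[dapi_channel]
    signal = image[signal_channel]
    fp = neighborhood_footprint(refine_radius)
    smask = bernsen_mask(signal, radius=bernsen_radius,
                         contrast_min=contrast_min, midgray=midgray)
    smask = refine_mask(smask, ["fill_holes", "erode", "dilate"], fp)
    # DAPI: opening first — local-mean thresholding marks ~half of the flat
    # background, and filling before despeckling would fuse it into one blob.
    dmask = local_mean_mask(dapi, radius=mean_radius, c=mean_c)
    dmask = refine_mask(dmask, ["erode", "dilate", "fill_holes"], fp)
    return nc_ratio(signal, smask, dmask, min_px=min_px)
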