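"""Masking and segmentation: mitochondrial mask, foci segmentation,
mask-containment filtering, and cell-region construction.

Thresholding defaults to Otsu's method for reproducibility, with an
absolute-threshold override mirroring manual thresholding; the threshold
actually used is always recorded on the returned mask. Connected
components use 8-connectivity throughout.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

from .core import BinaryMask, CellRegion, FocusROI

__all__ = [
    "unsharp_mask",
    "segment_mask",
    "label_foci",
    "filter_by_mask",
    "build_cell_regions",
]

log = logging.getLogger(__name__)

#: Default minimum component size (px); rejects single-pixel noise at
#: super-resolution sampling.
DEFAULT_MIN_SIZE = 4


def unsharp_mask(
    channel: np.ndarray, radius: float = 100.0, weight: float = 0.7
) -> np.ndarray:
    """Unsharp-mask a channel: ``(I - weight * G_radius(I)) / (1 - weight)``.

    ``G_radius`` is Gaussian smoothing with sigma ``radius`` (pixels).
    Output is clipped at 0. The defaults (radius 100, weight 0.7) are
    the minimal processing applied to mitochondrial-network staining
    before intensity measurement; a constant image is returned
    unchanged, and weight 0 is the identity.
    """
    if not 0 <= weight < 1:
        raise ValueError("weight must satisfy 0 <= weight < 1 (>= 1 blows up)")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    img = np.asarray(channel, dtype=np.float64)
    blurred = img if radius == 0 else ndi.gaussian_filter(img, radius, mode="nearest")
    out = (img - weight * blurred) / (1.0 - weight)
    return np.clip(out, 0.0, None)


def segment_mask(
    channel: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    smooth_sigma: float = 0.0,
    pixel_size: float = 1.0,
) -> BinaryMask:
    """Threshold a channel into a binary mask.

    Parameters
    ----------
    method
        ``"otsu"`` (default) or ``"absolute"`` (requires ``threshold``).
    threshold
        Absolute intensity cutoff; pixels >= threshold are foreground.
    min_size
        Connected components smaller than this many pixels are removed.
    smooth_sigma
        Optional Gaussian pre-smoothing (pixels) applied before
        thresholding; a PSF-scale sigma acts as a matched filter and
        stabilizes focus boundaries against read noise.

    Returns a :class:`BinaryMask` whose ``threshold`` attribute records
    the cutoff used. An empty image yields an empty mask; a constant
    (degenerate-histogram) image under Otsu raises ``ValueError``.
    """
    img = np.asarray(channel, dtype=np.float64)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma, mode="nearest")
    if method == "absolute":
        if threshold is None:
            raise ValueError("method='absolute' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if img.max() == img.min():
            if img.max() == 0.0:
                # empty image: empty mask, by contract
                return BinaryMask(np.zeros(img.shape, bool), pixel_size, threshold=0.0)
            raise ValueError("degenerate histogram: constant non-zero image under Otsu")
        thr = float(threshold_otsu(img))
        # Otsu returns a value strictly below the upper class; use >= on
        # the next representable value so the lower class is excluded
        thr = np.nextafter(thr, np.inf)
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img >= thr
    if min_size > 1 and mask.any():
        lbl = sk_label(mask, connectivity=2)
        sizes = np.bincount(lbl.ravel())
        small = np.flatnonzero(sizes < min_size)
        mask = mask & ~np.isin(lbl, small[small > 0])
    log.debug("segment_mask: method=%s threshold=%g min_size=%d", method, thr, min_size)
    return BinaryMask(mask, pixel_size, threshold=thr)


def label_foci(mask: BinaryMask, channel: str = "") -> list[FocusROI]:
    """Split a binary mask into one :class:`FocusROI` per 8-connected
    component. Pixel sets are disjoint and their union is the mask."""
    lbl = sk_label(mask.raster, connectivity=2)
    n = lbl.max()
    foci: list[FocusROI] = []
    if n == 0:
        return foci
    # group pixel coordinates by label in one pass
    flat = lbl.ravel()
    idx = np.flatnonzero(flat)
    order = np.argsort(flat[idx], kind="stable")
    idx = idx[order]
    labels = flat[idx]
    bounds = np.searchsorted(labels, np.arange(1, n + 2))
    coords = np.column_stack(np.unravel_index(idx, lbl.shape))
    for i in range(n):
        pix = coords[bounds[i] : bounds[i + 1]]
        foci.append(FocusROI(focus_id=i, channel=channel, pixels=pix, pixel_size=mask.pixel_size))
    return foci


def filter_by_mask(
    foci: list[FocusROI], mito: BinaryMask, rule: str = "centroid"
) -> list[FocusROI]:
    """Drop foci that do not lie within the mitochondrial mask.

    ``rule`` decides containment: ``"centroid"`` (default) keeps a focus
    whose centroid pixel is inside the mask, ``"majority"`` requires
    strictly more than 50% of its pixels inside, ``"any"`` at least one
    pixel. Always ``any ⊇ majority`` and ``any ⊇ centroid``.
    """
    if rule not in ("centroid", "majority", "any"):
        raise ValueError(f"unknown containment rule {rule!r}")
    raster = mito.raster
    kept: list[FocusROI] = []
    for f in foci:
        inside = raster[f.pixels[:, 0], f.pixels[:, 1]]
        if rule == "any":
            keep = bool(inside.any())
        elif rule == "majority":
            keep = inside.sum() > 0.5 * len(inside)
        else:
            r, c = f.centroid
            keep = bool(raster[int(round(r)), int(round(c))])
        if keep:
            kept.append(f)
    log.debug("filter_by_mask(rule=%s): %d -> %d foci", rule, len(foci), len(kept))
    return kept


def build_cell_regions(
    dapi: np.ndarray | None = None,
    body: np.ndarray | None = None,
    *,
    pixel_size: float,
    nuclei_mask: np.ndarray | None = None,
    body_mask: np.ndarray | None = None,
    mito_mask: np.ndarray | None = None,
    nucleus_min_size: int = 16,
    body_min_size: int = 64,
    nucleus_smooth_sigma: float = 2.0,
    min_nucleus_contrast: float = 2.0,
) -> list[CellRegion]:
    """Partition a frame into cells seeded from nuclei.

    Nuclei are segmented from the DAPI channel (Otsu) unless a
    ``nuclei_mask`` is supplied; the cell-body foreground comes from
    ``body`` / ``body_mask``. Cells are obtained by watershed of the
    distance-to-nucleus map over the body foreground, so each cell
    contains exactly one nucleus, cells partition the foreground, and
    two nuclei sharing one body blob are split along the watershed
    line. A nucleus with no surrounding cytoplasm is flagged
    (``unassigned_geometry``). Zero nuclei yields an empty list.
    """
    if nuclei_mask is None:
        if dapi is None:
            raise ValueError("provide either dapi channel or nuclei_mask")
        dapi = np.asarray(dapi, dtype=np.float64)
        if dapi.max() == dapi.min():
            return []
        smoothed = (
            ndi.gaussian_filter(dapi, nucleus_smooth_sigma, mode="nearest")
            if nucleus_smooth_sigma > 0
            else dapi
        )
        nuclei_mask = segment_mask(
            smoothed, method="otsu", min_size=nucleus_min_size, pixel_size=pixel_size
        ).raster
        # contrast gate: Otsu splits even pure noise, so require the
        # candidate nuclei to actually stand out from the background
        if nuclei_mask.any() and not nuclei_mask.all():
            fg = smoothed[nuclei_mask].mean()
            bg = smoothed[~nuclei_mask].mean()
            if fg < min_nucleus_contrast * max(bg, 1e-12):
                log.info(
                    "no nuclei detected: foreground/background contrast "
                    "%.2f below %.2f", fg / max(bg, 1e-12), min_nucleus_contrast,
                )
                return []
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    lbl_n = sk_label(nuclei_mask, connectivity=2)
    n_cells = int(lbl_n.max())
    if n_cells == 0:
        return []

    if body_mask is None:
        if body is not None:
            body_arr = np.asarray(body, dtype=np.float64)
            if body_arr.max() == body_arr.min():
                body_mask = np.zeros(body_arr.shape, bool)
            else:
                body_mask = segment_mask(
                    body_arr, method="otsu", min_size=body_min_size,
                    pixel_size=pixel_size,
                ).raster
        else:
            body_mask = np.zeros(nuclei_mask.shape, bool)
    body_mask = np.asarray(body_mask, dtype=bool) | nuclei_mask

    dist = ndi.distance_transform_edt(~nuclei_mask)
    ws = watershed(dist, markers=lbl_n, mask=body_mask)

    mito_idx_all = (
        np.flatnonzero(np.asarray(mito_mask, dtype=bool)) if mito_mask is not None else None
    )
    regions: list[CellRegion] = []
    for i in range(1, n_cells + 1):
        nucleus_idx = np.flatnonzero(lbl_n == i)
        cell_idx = np.flatnonzero(ws == i)
        if len(cell_idx) == 0:  # nucleus fell outside body mask (cannot happen
            cell_idx = nucleus_idx  # after the union above, kept as a guard)
        mito_idx = (
            np.intersect1d(cell_idx, mito_idx_all) if mito_idx_all is not None else None
        )
        regions.append(
            CellRegion(
                cell_id=i - 1,
                shape=nuclei_mask.shape,
                pixel_size=pixel_size,
                nucleus_idx=nucleus_idx,
                cell_idx=cell_idx,
                mito_idx=mito_idx,
                unassigned_geometry=len(cell_idx) == len(nucleus_idx),
            )
        )
    return regions
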