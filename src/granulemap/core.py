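"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* rasters are 2-D numpy arrays indexed ``(row, col)``, 0-based,
  pixel-center coordinates;
* physical calibration is a scalar ``pixel_size`` in micrometres per
  pixel, so areas in um^2 are ``pixel count * pixel_size**2`` exactly;
* connected components use 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlacementError",
    "ConfigError",
    "ImageFrame",
    "BinaryMask",
    "FocusROI",
    "OverlapRecord",
    "OverlapSummary",
    "CellRegion",
    "PHASES",
]

#: Recognised cell-cycle phase labels (plus "unassigned" for failed calls).
PHASES = ("G1", "S", "G2")


class PlacementError(RuntimeError):
    """Synthetic-frame generation could not place an object after a
    bounded number of attempts (e.g. the mitochondrial network is too
    sparse to host the requested foci without violating the planted
    overlap-category constraints)."""


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class ImageFrame:
    """A calibrated multi-channel 2-D fluorescence image.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"dsRNA"``, ``"BrU"``,
        ``"mito"``, ``"DAPI"``) to a 2-D array of non-negative
        intensities. All channels must share a shape.
    pixel_size
        Physical pixel size in micrometres per pixel.
    frame_id
        Identifier carried into output tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_id: str = "frame-000"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.channels:
            raise ValueError("ImageFrame needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"frame {self.frame_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


@dataclass
class BinaryMask:
    """A boolean raster with physical calibration.

    ``threshold`` records the intensity cutoff that produced the mask
    (``None`` for masks not derived by thresholding).
    """

    raster: np.ndarray
    pixel_size: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.raster = np.asarray(self.raster, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.raster.sum())

    @property
    def area_um2(self) -> float:
        """True-pixel count times pixel_size^2, exactly."""
        return self.n_pixels * self.pixel_size**2


@dataclass
class FocusROI:
    """One segmented punctum (connected component of a thresholded
    channel) with shape descriptors in physical units.

    ``pixels`` is an ``(n, 2)`` integer array of (row, col) member
    pixels. Descriptors (axes, eccentricity) are ``None`` until filled
    by :func:`granulemap.colocal.shape_descriptors`.
    """

    focus_id: int
    channel: str
    pixels: np.ndarray
    pixel_size: float
    major_axis_um: float | None = None
    minor_axis_um: float | None = None
    eccentricity: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError("FocusROI needs a non-empty pixel set")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        """Unweighted mean of member pixel centers, (row, col)."""
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)

    def flat_indices(self, shape: tuple[int, int]) -> np.ndarray:
        return np.ravel_multi_index((self.pixels[:, 0], self.pixels[:, 1]), shape)


@dataclass
class OverlapRecord:
    """Overlap of one query focus against the union of reference foci.

    ``overlap_pct`` is 100 * intersection area / query focus area, i.e.
    the denominator is always the query focus's own area (asymmetric by
    design). ``category`` is one of ``"none"``, ``"partial"``,
    ``"complete"``.
    """

    focus_id: int
    query_channel: str
    reference_channel: str
    overlap_area_um2: float
    overlap_pct: float
    category: str | None = None


@dataclass
class OverlapSummary:
    """Per-frame composition of overlap categories, as percentages of
    the total number of query foci measured."""

    reference_channel: str
    n_foci: int
    pct_none: float
    pct_partial: float
    pct_complete: float

    def __post_init__(self) -> None:
        total = self.pct_none + self.pct_partial + self.pct_complete
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"category percentages sum to {total}, not 100")


@dataclass
class CellRegion:
    """One cell's nucleus / whole-cell / mitochondrial masks and phase.

    Masks are stored as flat (raveled) pixel index arrays against the
    frame ``shape`` to keep many-cell frames cheap; ``*_mask`` methods
    realize boolean rasters on demand. Invariants: the nucleus is a
    subset of the cell, the mitochondrial submask is a subset of the
    cell, and distinct cells are disjoint (guaranteed by construction
    in :func:`granulemap.segment.build_cell_regions`).
    """

    cell_id: int
    shape: tuple[int, int]
    pixel_size: float
    nucleus_idx: np.ndarray
    cell_idx: np.ndarray
    mito_idx: np.ndarray | None = None
    phase: str = "unassigned"
    #: True when the nucleus has no surrounding cytoplasm (cell == nucleus).
    unassigned_geometry: bool = False

    def __post_init__(self) -> None:
        self.nucleus_idx = np.asarray(self.nucleus_idx, dtype=np.intp)
        self.cell_idx = np.asarray(self.cell_idx, dtype=np.intp)
        if self.mito_idx is not None:
            self.mito_idx = np.asarray(self.mito_idx, dtype=np.intp)

    def _mask(self, idx: np.ndarray) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.flat[idx] = True
        return m

    def nucleus_mask(self) -> np.ndarray:
        return self._mask(self.nucleus_idx)

    def cell_mask(self) -> np.ndarray:
        return self._mask(self.cell_idx)

    def mito_mask(self) -> BinaryMask:
        idx = self.mito_idx if self.mito_idx is not None else np.empty(0, np.intp)
        return BinaryMask(self._mask(idx), self.pixel_size)

    @property
    def cytoplasm_idx(self) -> np.ndarray:
        """Whole-cell pixels minus nuclear pixels."""
        return np.setdiff1d(self.cell_idx, self.nucleus_idx, assume_unique=True)

    @property
    def cell_area_um2(self) -> float:
        return len(self.cell_idx) * self.pixel_size**2

    @property
    def cytoplasm_area_um2(self) -> float:
        return len(self.cytoplasm_idx) * self.pixel_size**2

    @property
    def nucleus_area_um2(self) -> float:
        return len(self.nucleus_idx) * self.pixel_size**2

    @property
    def mito_area_um2(self) -> float:
        if self.mito_idx is None:
            return 0.0
        return len(self.mito_idx) * self.pixel_size**2


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` items to categories by the largest-remainder rule.

    Deterministic, preserves the total exactly; ties on the remainder are
    broken by category-key order for reproducibility.
    """
    keys = sorted(fractions)
    quotas = {k: fractions[k] * n for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts
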