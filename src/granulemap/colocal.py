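"""Object-based colocalization: shape descriptors, pairwise overlap,
three-way categorization, and summary percentages.

Overlap is computed per query focus against the *union* of reference
foci (a query focus straddling two reference foci accumulates both) and
expressed as a percentage of the query focus's own area — asymmetric by
design. A focus is "none" at exactly zero intersection, "complete" when
its overlap percentage reaches ``100 - complete_tol`` (default
tolerance 1%, absorbing single boundary-pixel rasterization effects),
and "partial" otherwise. Intensity-correlation measures (Pearson,
Manders) are deliberately out of scope: the method is object-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FocusROI, OverlapRecord, OverlapSummary

__all__ = [
    "shape_descriptors",
    "compute_overlap",
    "categorize",
    "summarize",
    "size_stratified_overlap",
    "DEFAULT_COMPLETE_TOL",
]

#: Completeness tolerance in percentage points: overlap_pct >= 100 - tol
#: is scored "complete".
DEFAULT_COMPLETE_TOL = 1.0


def shape_descriptors(focus: FocusROI) -> FocusROI:
    """Fill area-equivalent ellipse descriptors on a focus, in place.

    Axes come from the ellipse with the same normalized second central
    moments as the pixel set (major/minor axis length = 4 * sqrt of the
    covariance eigenvalues, the standard moment-ellipse convention, so
    a disk of radius r has both axes equal to its diameter 2r).
    Eccentricity is ``sqrt(1 - (minor/major)^2)``. A single-pixel focus
    is degenerate: both axes are set to one pixel and eccentricity to 0.
    Collinear pixel sets (zero minor moment) are also flagged and given
    a one-pixel minor axis.
    """
    px = focus.pixel_size
    pts = focus.pixels.astype(np.float64)
    if len(pts) == 1:
        focus.major_axis_um = px
        focus.minor_axis_um = px
        focus.eccentricity = 0.0
        focus.degenerate = True
        return focus
    d = pts - pts.mean(axis=0)
    cov = d.T @ d / len(pts)
    lam_min, lam_max = np.linalg.eigvalsh(cov)
    major = 4.0 * np.sqrt(max(lam_max, 0.0))
    minor = 4.0 * np.sqrt(max(lam_min, 0.0))
    degenerate = False
    if minor <= 0.0:
        minor = 1.0  # collinear pixel set: one-pixel-wide ridge
        major = max(major, minor)
        degenerate = True
    focus.major_axis_um = major * px
    focus.minor_axis_um = minor * px
    ratio = min(focus.minor_axis_um / focus.major_axis_um, 1.0)
    focus.eccentricity = float(np.sqrt(max(1.0 - ratio**2, 0.0)))
    focus.degenerate = degenerate
    return focus


def categorize(
    record: OverlapRecord | float, complete_tol: float = DEFAULT_COMPLETE_TOL
) -> str:
    """Three-way overlap category from an overlap percentage.

    ``none`` at exactly 0%, ``complete`` at >= 100 - complete_tol,
    ``partial`` in between. Accepts a record (whose ``category`` field
    is also set) or a bare percentage.
    """
    pct = record.overlap_pct if isinstance(record, OverlapRecord) else float(record)
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"overlap_pct {pct} outside [0, 100]")
    if pct == 0.0:
        cat = "none"
    elif pct >= 100.0 - complete_tol:
        cat = "complete"
    else:
        cat = "partial"
    if isinstance(record, OverlapRecord):
        record.category = cat
    return cat


def compute_overlap(
    query_foci: list[FocusROI],
    reference_foci: list[FocusROI],
    frame_shape: tuple[int, int],
    complete_tol: float = DEFAULT_COMPLETE_TOL,
    reference_channel: str | None = None,
) -> list[OverlapRecord]:
    """Overlap of each query focus against the union of reference foci.

    Intersection areas are exact integer pixel counts times
    pixel_size^2. An empty reference list yields records with 0%
    overlap. Every query focus produces exactly one record.
    """
    union = np.zeros(frame_shape, dtype=bool)
    for f in reference_foci:
        union[f.pixels[:, 0], f.pixels[:, 1]] = True
    if reference_channel is None:
        reference_channel = reference_foci[0].channel if reference_foci else ""
    records: list[OverlapRecord] = []
    for f in query_foci:
        inter = int(union[f.pixels[:, 0], f.pixels[:, 1]].sum())
        pct = 100.0 * inter / f.n_pixels
        rec = OverlapRecord(
            focus_id=f.focus_id,
            query_channel=f.channel,
            reference_channel=reference_channel,
            overlap_area_um2=inter * f.pixel_size**2,
            overlap_pct=pct,
        )
        categorize(rec, complete_tol)
        records.append(rec)
    return records


def summarize(records: list[OverlapRecord]) -> OverlapSummary:
    """Category counts as percentages of the total number of foci
    measured. Raises on an empty record list (undefined percentages)."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    n = len(records)
    counts = {"none": 0, "partial": 0, "complete": 0}
    for r in records:
        if r.category not in counts:
            raise ValueError(f"record {r.focus_id} has no category; run categorize first")
        counts[r.category] += 1
    return OverlapSummary(
        reference_channel=records[0].reference_channel,
        n_foci=n,
        pct_none=100.0 * counts["none"] / n,
        pct_partial=100.0 * counts["partial"] / n,
        pct_complete=100.0 * counts["complete"] / n,
    )


def size_stratified_overlap(
    records: list[OverlapRecord], foci: list[FocusROI]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify focus areas by overlap class (zero vs any overlap).

    Returns ``(table, summary)``: a per-focus table with columns
    ``focus_id, area_um2, overlap_class`` where the class is
    ``"no overlap"`` at 0% and ``"partial-or-complete"`` otherwise, and
    a per-class summary with ``n``, ``mean_area_um2``, ``sd_area_um2``
    (sample SD, NaN for n < 2).
    """
    by_id = {r.focus_id: r for r in records}
    rows = []
    for f in foci:
        rec = by_id.get(f.focus_id)
        if rec is None:
            continue
        cls = "no overlap" if rec.overlap_pct == 0.0 else "partial-or-complete"
        rows.append(dict(focus_id=f.focus_id, area_um2=f.area_um2, overlap_class=cls))
    table = pd.DataFrame(rows, columns=["focus_id", "area_um2", "overlap_class"])
    if len(table):
        summary = (
            table.groupby("overlap_class")["area_um2"]
            .agg(n="size", mean_area_um2="mean", sd_area_um2=lambda s: s.std(ddof=1))
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["overlap_class", "n", "mean_area_um2", "sd_area_um2"]
        )
    return table, summary
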