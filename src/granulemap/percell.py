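"""Per-cell quantification and cell-cycle phase calling.

Metrics per cell: foci density per um^2 of mitochondrial network, mean
intensity within the mitochondrial submask, integrated (summed)
intensity over the cell, cytoplasmic and mitochondrial areas. Phases
are gated from marker means with the precedence S -> G2 -> G1: EdU
positivity (active replication) dominates because cyclin-A is present
in both S and G2; cyclin-A positivity then marks G2; a DAPI-positive
nucleus without either marker is G1; anything else is unassigned.
Summaries are descriptive only (mean, sample SD, n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask, CellRegion, FocusROI

__all__ = [
    "PhaseThresholds",
    "foci_density",
    "mean_mito_intensity",
    "integrated_intensity",
    "nuclear_mean",
    "classify_phase",
    "auto_thresholds",
    "assign_foci_to_cells",
    "quantify_cells",
    "group_summary",
]

log = logging.getLogger(__name__)


@dataclass
class PhaseThresholds:
    """Intensity cutoffs for phase gating (all >= 0).

    ``edu_pos``: mean nuclear EdU at or above which a cell is scored
    EdU-positive (S phase); ``cyclin_pos``: mean cyclin-A cutoff (G2);
    ``dapi_min``: minimum mean nuclear DAPI for a usable nucleus (G1).
    """

    edu_pos: float
    cyclin_pos: float
    dapi_min: float

    def __post_init__(self) -> None:
        if min(self.edu_pos, self.cyclin_pos, self.dapi_min) < 0:
            raise ValueError("phase thresholds must be >= 0")


def foci_density(foci: list[FocusROI], mito: BinaryMask) -> float:
    """Number of foci per um^2 of mitochondrial network.

    ``foci`` should already be containment-filtered / assigned to the
    cell. An empty mitochondrial mask makes the density undefined and
    raises ``ValueError``.
    """
    if mito.area_um2 == 0:
        raise ValueError("empty mitochondrial mask: density undefined")
    return len(foci) / mito.area_um2


def mean_mito_intensity(channel: np.ndarray, cell: CellRegion) -> float:
    """Mean intensity over the cell's mitochondrial submask
    (mito ∩ cell); NaN (flagged in the log) when the submask is empty."""
    if cell.mito_idx is None or len(cell.mito_idx) == 0:
        log.warning("cell %d has an empty mitochondrial submask", cell.cell_id)
        return float("nan")
    return float(np.asarray(channel).flat[cell.mito_idx].mean())


def integrated_intensity(
    channel: np.ndarray, cell: CellRegion, region: str = "cell"
) -> float:
    """Sum of intensities over the cell (``region="cell"``, default) or
    over the cytoplasm excluding the nucleus (``region="cytoplasm"``).
    Additive over disjoint partitions of the region by construction."""
    idx = cell.cell_idx if region == "cell" else cell.cytoplasm_idx
    return float(np.asarray(channel).flat[idx].sum())


def nuclear_mean(channel: np.ndarray, cell: CellRegion) -> float:
    """Mean intensity over the nucleus."""
    if len(cell.nucleus_idx) == 0:
        return float("nan")
    return float(np.asarray(channel).flat[cell.nucleus_idx].mean())


def classify_phase(
    cell: CellRegion,
    dapi: np.ndarray,
    edu: np.ndarray,
    cyclin: np.ndarray,
    thresholds: PhaseThresholds,
    cyclin_compartment: str = "cell",
) -> str:
    """Gate one cell into G1 / S / G2 / unassigned.

    Precedence S -> G2 -> G1: mean nuclear EdU >= ``edu_pos`` wins (S),
    then mean cyclin-A >= ``cyclin_pos`` (G2; measured over the whole
    cell by default, ``cyclin_compartment="nucleus"`` restricts it),
    then mean nuclear DAPI >= ``dapi_min`` (G1); otherwise unassigned.
    """
    if len(cell.nucleus_idx) == 0:
        return "unassigned"
    if nuclear_mean(edu, cell) >= thresholds.edu_pos:
        return "S"
    cyc_mean = (
        nuclear_mean(cyclin, cell)
        if cyclin_compartment == "nucleus"
        else float(np.asarray(cyclin).flat[cell.cell_idx].mean())
    )
    if cyc_mean >= thresholds.cyclin_pos:
        return "G2"
    if nuclear_mean(dapi, cell) >= thresholds.dapi_min:
        return "G1"
    return "unassigned"


def auto_thresholds(
    cells: list[CellRegion],
    dapi: np.ndarray,
    edu: np.ndarray,
    cyclin: np.ndarray,
    dapi_fraction: float = 0.2,
    cyclin_compartment: str = "cell",
) -> PhaseThresholds:
    """Derive phase thresholds from the per-cell marker distributions.

    EdU and cyclin-A cutoffs are Otsu thresholds on the per-cell mean
    marker values (sensible when both positive and negative cells are
    present; override manually otherwise). The DAPI minimum is
    ``dapi_fraction`` of the median nuclear DAPI mean — a presence
    check, since essentially every nucleus is DAPI-positive.
    """
    edu_means = np.array([nuclear_mean(edu, c) for c in cells], dtype=float)
    if cyclin_compartment == "nucleus":
        cyc_means = np.array([nuclear_mean(cyclin, c) for c in cells], dtype=float)
    else:
        cyc = np.asarray(cyclin)
        cyc_means = np.array([cyc.flat[c.cell_idx].mean() for c in cells], dtype=float)
    dapi_means = np.array([nuclear_mean(dapi, c) for c in cells], dtype=float)

    def otsu_or_mid(values: np.ndarray) -> float:
        # exact Otsu on the sample: exhaustive split maximizing the
        # between-class variance (histogram Otsu is unstable for the
        # few dozen values a frame of cells yields); the cutoff is the
        # midpoint of the optimal split
        vals = np.sort(values[np.isfinite(values)])
        if len(vals) < 2 or vals[-1] == vals[0]:
            return float(vals.mean()) if len(vals) else 0.0
        n = len(vals)
        best_score, best_cut = -np.inf, float(vals.mean())
        csum = np.cumsum(vals)
        for k in range(1, n):
            if vals[k] == vals[k - 1]:
                continue
            mu_lo = csum[k - 1] / k
            mu_hi = (csum[-1] - csum[k - 1]) / (n - k)
            score = k * (n - k) * (mu_lo - mu_hi) ** 2
            if score > best_score:
                best_score = score
                best_cut = 0.5 * (vals[k - 1] + vals[k])
        return float(best_cut)

    return PhaseThresholds(
        edu_pos=otsu_or_mid(edu_means),
        cyclin_pos=otsu_or_mid(cyc_means),
        dapi_min=dapi_fraction * float(np.nanmedian(dapi_means)),
    )


def assign_foci_to_cells(
    foci: list[FocusROI], cells: list[CellRegion]
) -> tuple[dict[int, list[FocusROI]], int]:
    """Assign each focus to the cell containing its centroid.

    Returns ``(by_cell, n_dropped)``; foci whose centroid lies outside
    every cell are dropped and counted (QC log).
    """
    if not cells:
        return {}, len(foci)
    shape = cells[0].shape
    lbl = np.full(shape, -1, dtype=int)
    for c in cells:
        lbl.flat[c.cell_idx] = c.cell_id
    by_cell: dict[int, list[FocusROI]] = {c.cell_id: [] for c in cells}
    dropped = 0
    for f in foci:
        r, c0 = f.centroid
        cid = int(lbl[int(round(r)), int(round(c0))])
        if cid < 0:
            dropped += 1
        else:
            by_cell[cid].append(f)
    if dropped:
        log.info("%d foci fell outside all cells and were dropped", dropped)
    return by_cell, dropped


def quantify_cells(
    channels: dict[str, np.ndarray],
    cells: list[CellRegion],
    foci_by_channel: dict[str, list[FocusROI]],
    intensity_channels: list[str] | None = None,
    thresholds: PhaseThresholds | None = None,
    phase_channels: tuple[str, str, str] = ("DAPI", "EdU", "cyclinA"),
    cyclin_compartment: str = "cell",
) -> pd.DataFrame:
    """One row of metrics per cell.

    Columns: ``cell_id, phase, cell_area_um2, cytoplasm_area_um2,
    mito_area_um2`` plus, per foci channel, ``{ch}_count`` and
    ``{ch}_density_per_um2`` (NaN when the cell's mitochondrial submask
    is empty) and, per intensity channel, ``{ch}_mean_mito_intensity``
    and ``{ch}_integrated_intensity``. Phases are gated when the three
    phase channels are present; thresholds default to
    :func:`auto_thresholds`.
    """
    if intensity_channels is None:
        intensity_channels = sorted(foci_by_channel)
    dapi_n, edu_n, cyc_n = phase_channels
    can_phase = all(n in channels for n in (dapi_n, edu_n, cyc_n)) and cells
    if can_phase and thresholds is None:
        thresholds = auto_thresholds(
            cells, channels[dapi_n], channels[edu_n], channels[cyc_n],
            cyclin_compartment=cyclin_compartment,
        )

    assigned: dict[str, dict[int, list[FocusROI]]] = {}
    for ch, foci in foci_by_channel.items():
        assigned[ch], _ = assign_foci_to_cells(foci, cells)

    rows = []
    for cell in cells:
        if can_phase:
            cell.phase = classify_phase(
                cell, channels[dapi_n], channels[edu_n], channels[cyc_n],
                thresholds, cyclin_compartment=cyclin_compartment,
            )
        row: dict[str, object] = dict(
            cell_id=cell.cell_id,
            phase=cell.phase,
            cell_area_um2=cell.cell_area_um2,
            cytoplasm_area_um2=cell.cytoplasm_area_um2,
            mito_area_um2=cell.mito_area_um2,
        )
        for ch in foci_by_channel:
            cell_foci = assigned[ch].get(cell.cell_id, [])
            row[f"{ch}_count"] = len(cell_foci)
            if cell.mito_area_um2 > 0:
                row[f"{ch}_density_per_um2"] = len(cell_foci) / cell.mito_area_um2
            else:
                row[f"{ch}_density_per_um2"] = float("nan")
        for ch in intensity_channels:
            if ch not in channels:
                continue
            row[f"{ch}_mean_mito_intensity"] = mean_mito_intensity(channels[ch], cell)
            row[f"{ch}_integrated_intensity"] = integrated_intensity(channels[ch], cell)
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(
    metrics: pd.DataFrame,
    group_by: str | list[str] = "phase",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group n, mean, and sample SD (n-1 denominator) of each
    metric; SD is NaN for singleton groups. Long format:
    one row per (group, metric)."""
    if isinstance(group_by, str):
        group_by = [group_by]
    if columns is None:
        columns = [
            c
            for c in metrics.columns
            if c not in group_by and pd.api.types.is_numeric_dtype(metrics[c])
            and c != "cell_id"
        ]
    rows = []
    for key, sub in metrics.groupby(group_by, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        for col in columns:
            vals = sub[col].dropna()
            rows.append(
                dict(
                    **dict(zip(group_by, key)),
                    metric=col,
                    n=len(vals),
                    mean=vals.mean() if len(vals) else float("nan"),
                    sd=vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                )
            )
    return pd.DataFrame(rows, columns=[*group_by, "metric", "n", "mean", "sd"])
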