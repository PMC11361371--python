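"""Synthetic multi-channel frame generator with exact ground truth.

Emulates the two imaging regimes used for mitochondrial RNA-granule
(MRG) work: a super-resolution (STED-like) regime at fine pixel pitch
for focus-level colocalization, and a confocal-like regime at coarser
pitch with whole cells for per-cell intensity / density / cell-cycle
measurements. Every planted object (focus pixel sets, overlap
categories, cell masks, phases) is recorded in a :class:`GroundTruth`
so analysis stages can be tested for exact recovery.

Planting guarantees, all exact on rasterized pixels:

* a "complete" focus is a disk concentric with its reference partner,
  one pixel of radius smaller, hence 100% contained;
* a "partial" focus is a disk offset from its partner so that the pixel
  intersection fraction lies strictly inside ``partial_overlap_range``;
* a "none" focus keeps a clearance gap from every reference focus;
* foci within one channel never touch (8-connectivity safe), so a
  threshold at half the planting intensity recovers the planted pixel
  sets exactly on noiseless, blur-free frames.

Counts per category follow the largest-remainder rule on the requested
composition. Noise is the standard fluorescence model: Gaussian point
spread, scaled-Poisson shot noise, additive Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    BinaryMask,
    CellRegion,
    ImageFrame,
    PlacementError,
    largest_remainder_counts,
)

__all__ = [
    "FociSpec",
    "OverlapComposition",
    "MarkerLevels",
    "NoiseParams",
    "GeneratorParams",
    "GroundTruth",
    "render_network",
    "generate_frame",
]

# ---------------------------------------------------------------------------
# parameters


@dataclass
class FociSpec:
    """Per-channel description of a punctate focus population.

    ``mean_area`` / ``area_cv`` parameterize a lognormal area
    distribution in um^2; ``intensity`` is the constant plateau value a
    planted focus is painted with (arbitrary units).
    """

    n_foci: int = 100
    mean_area: float = 0.019  # um^2, dsRNA-focus scale at STED sampling
    area_cv: float = 0.3
    intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.mean_area <= 0:
            raise ValueError("mean_area must be > 0")
        if self.n_foci < 0 or self.area_cv < 0 or self.intensity <= 0:
            raise ValueError("invalid FociSpec")


@dataclass
class OverlapComposition:
    """Planted fractions of overlap categories vs the reference channel."""

    complete: float = 0.03
    partial: float = 0.65
    none: float = 0.32

    def __post_init__(self) -> None:
        vals = (self.complete, self.partial, self.none)
        if any(v < 0 for v in vals):
            raise ValueError("composition fractions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("overlap composition fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"complete": self.complete, "partial": self.partial, "none": self.none}


@dataclass
class MarkerLevels:
    """Per-cell marker intensity populations for cell-cycle channels.

    Each cell draws its nuclear EdU and (whole-cell) cyclin-A level from
    a normal with mean ``*_pos`` or ``*_neg`` according to its planted
    phase, and SD ``level_sd`` (cell-to-cell variability). Defaults give
    cleanly separable positive/negative populations.
    """

    edu_pos: float = 150.0
    edu_neg: float = 15.0
    cyclin_pos: float = 150.0
    cyclin_neg: float = 15.0
    level_sd: float = 12.0
    dapi: float = 200.0

    def __post_init__(self) -> None:
        if self.level_sd < 0:
            raise ValueError("level_sd must be >= 0")


@dataclass
class NoiseParams:
    """Read + shot noise applied after PSF blur.

    ``poisson_scale`` converts intensity units to photon counts for the
    shot-noise draw (0 disables shot noise); ``gaussian_sd`` is the read
    noise SD in intensity units. Defaults give SNR ~ 10 against the
    default focus plateau of 200.
    """

    gaussian_sd: float = 20.0
    poisson_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")


def _default_foci_channels() -> dict[str, FociSpec]:
    # dsRNA foci average 0.019 um^2 and nascent BrU-RNA foci 0.017 um^2.
    return {
        "dsRNA": FociSpec(n_foci=100, mean_area=0.019),
        "BrU": FociSpec(n_foci=100, mean_area=0.017),
    }


@dataclass
class GeneratorParams:
    """Full description of one synthetic frame.

    The defaults are the STED-like focus-colocalization regime:
    0.02 um/px pitch, a tubular mitochondrial network covering ~15% of
    the frame, 100 dsRNA (query) and 100 BrU (reference) foci with the
    3% complete / 65% partial / 32% none overlap composition observed
    for dsRNA vs BrU, and no cells. Use :meth:`confocal` for the
    per-cell regime (0.1 um/px, whole cells with DAPI/EdU/cyclin-A).
    """

    frame_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.02  # um/px
    n_cells: int = 0
    network_density: float = 0.2
    tube_width: float = 0.3  # um, tubule diameter
    foci_channels: dict[str, FociSpec] = field(default_factory=_default_foci_channels)
    reference_channel: str = "BrU"
    composition: OverlapComposition = field(default_factory=OverlapComposition)
    partial_overlap_range: tuple[float, float] = (0.3, 0.7)
    phase_mix: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.5, "S": 0.3, "G2": 0.2}
    )
    markers: MarkerLevels = field(default_factory=MarkerLevels)
    noise: NoiseParams = field(default_factory=NoiseParams)
    psf_sigma: float = 0.04  # um
    cell_radius: float = 1.2  # um (scaled-down cell footprint)
    nucleus_radius: float = 0.5  # um
    mito_intensity: float = 120.0
    cellbody_intensity: float = 80.0
    dapi_channel: str = "DAPI"
    seed: int = 0
    max_attempts: int = 200  # placement attempts per object

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0 <= self.network_density < 1:
            raise ValueError("network_density must be in [0, 1)")
        lo, hi = self.partial_overlap_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("partial_overlap_range must satisfy 0 < lo < hi < 1")
        if abs(sum(self.phase_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phase_mix fractions must sum to 1")
        if any(v < 0 for v in self.phase_mix.values()):
            raise ValueError("phase_mix fractions must be >= 0")
        needs_ref = any(
            name != self.reference_channel and spec.n_foci > 0
            for name, spec in self.foci_channels.items()
        )
        if needs_ref and self.reference_channel not in self.foci_channels:
            raise ValueError(
                f"reference channel {self.reference_channel!r} missing from foci_channels"
            )
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        """Build params from plain (e.g. YAML-loaded) nested dicts."""
        kw = dict(data)
        if "frame_shape" in kw:
            kw["frame_shape"] = tuple(kw["frame_shape"])
        if "partial_overlap_range" in kw:
            kw["partial_overlap_range"] = tuple(kw["partial_overlap_range"])
        if "foci_channels" in kw:
            kw["foci_channels"] = {
                name: spec if isinstance(spec, FociSpec) else FociSpec(**spec)
                for name, spec in kw["foci_channels"].items()
            }
        for key, typ in (
            ("composition", OverlapComposition),
            ("markers", MarkerLevels),
            ("noise", NoiseParams),
        ):
            if key in kw and not isinstance(kw[key], typ):
                kw[key] = typ(**kw[key])
        return cls(**kw)

    @classmethod
    def confocal(cls, n_cells: int = 12, **overrides) -> "GeneratorParams":
        """Per-cell (confocal-like) preset: coarser pitch, whole cells,
        apparent (PSF-broadened) focus sizes."""
        kw = dict(
            frame_shape=(512, 512),
            pixel_size=0.1,
            n_cells=n_cells,
            tube_width=0.7,
            network_density=0.45,
            foci_channels={
                "dsRNA": FociSpec(n_foci=2 * n_cells, mean_area=0.10),
                "BrU": FociSpec(n_foci=2 * n_cells, mean_area=0.10),
            },
            cell_radius=2.4,
            nucleus_radius=0.9,
            psf_sigma=0.1,
        )
        kw.update(overrides)
        return cls(**kw)

    def noiseless(self) -> "GeneratorParams":
        """Copy with noise and blur disabled (planted rasters rendered
        exactly)."""
        return replace(self, noise=NoiseParams(0.0, 0.0), psf_sigma=0.0)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Generator-side record of everything planted in one frame.

    ``foci`` columns: channel, focus_id, category ("" for the reference
    channel), overlap_pct (exact, vs the union of reference foci),
    area_um2 (pixel count * pixel_size^2), centroid_row/col, partner_id,
    cell_id (-1 when outside all cells or no cells planted).
    ``cells`` columns: cell_id, phase, center_row/col, cell/nucleus/mito
    areas, edu_level, cyclin_level, dapi_level.
    """

    foci: pd.DataFrame
    foci_pixels: dict[tuple[str, int], np.ndarray]
    cells: pd.DataFrame
    cell_regions: list[CellRegion]
    network: np.ndarray
    pixel_size: float

    def category_counts(self, channel: str) -> dict[str, int]:
        sub = self.foci[self.foci.channel == channel]
        return {
            cat: int((sub.category == cat).sum())
            for cat in ("complete", "partial", "none")
        }

    def per_cell_foci_counts(self, channel: str) -> pd.Series:
        sub = self.foci[(self.foci.channel == channel) & (self.foci.cell_id >= 0)]
        counts = sub.groupby("cell_id").size()
        return counts.reindex(self.cells.cell_id, fill_value=0)

    def network_mask(self) -> BinaryMask:
        return BinaryMask(self.network, self.pixel_size)


# ---------------------------------------------------------------------------
# mitochondrial network


def _rng_for(params: GeneratorParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stream]))


def render_network(
    params: GeneratorParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render a tubular mitochondrial-network mask.

    Correlated random walks are accumulated and dilated to the tube
    width until the covered fraction reaches ``network_density``; each
    walk adds little coverage, keeping the final fraction within the
    +/-20% band of the request. Deterministic for a fixed seed.
    """
    if rng is None:
        rng = _rng_for(params, 17)
    h, w = params.frame_shape
    w_px = params.tube_width / params.pixel_size
    if w_px < 1.0:
        raise ValueError(
            f"tube_width {params.tube_width} um is {w_px:.2f} px at "
            f"{params.pixel_size} um/px; unresolvable (< 1 px)"
        )
    mask = np.zeros((h, w), dtype=bool)
    if params.network_density == 0:
        return mask

    skel = np.zeros((h, w), dtype=bool)
    # walk length tuned so a single walk adds ~1.5% coverage
    step_len = max(32, int(0.015 * h * w / w_px))
    for _ in range(1000):
        start = rng.uniform([0, 0], [h - 1, w - 1])
        turns = rng.normal(0.0, 0.25, size=step_len)
        turns[0] = rng.uniform(0, 2 * math.pi)
        angles = np.cumsum(turns)
        steps = np.stack([np.sin(angles), np.cos(angles)], axis=1)
        pos = start + np.cumsum(steps, axis=0)
        # reflect at the borders: fold coordinates into [0, n-1]
        for ax, n in enumerate((h, w)):
            p = np.remainder(pos[:, ax], 2 * (n - 1))
            pos[:, ax] = np.where(p > n - 1, 2 * (n - 1) - p, p)
        ij = np.round(pos).astype(int)
        skel[ij[:, 0], ij[:, 1]] = True
        mask = ndi.distance_transform_edt(~skel) <= w_px / 2.0
        if mask.mean() >= params.network_density:
            break
    return mask


# ---------------------------------------------------------------------------
# foci planting


def _disk_offsets(radius: float) -> np.ndarray:
    """(n, 2) integer offsets of the rasterized disk |p| <= radius."""
    r_int = int(math.ceil(radius))
    rr, cc = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    keep = rr**2 + cc**2 <= radius**2
    return np.stack([rr[keep], cc[keep]], axis=1)


def _sample_radii(
    spec: FociSpec, pixel_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample focus radii (px) from the lognormal area distribution."""
    n = spec.n_foci
    if spec.area_cv == 0:
        areas = np.full(n, spec.mean_area)
    else:
        sigma2 = math.log(1.0 + spec.area_cv**2)
        mu = math.log(spec.mean_area) - sigma2 / 2.0
        areas = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.sqrt(areas / math.pi) / pixel_size


@dataclass
class _PlantedFocus:
    channel: str
    focus_id: int
    center: tuple[int, int]
    radius: float
    pixels: np.ndarray  # (n, 2)
    category: str = ""  # "" for reference foci
    overlap_pct: float = 0.0
    partner_id: int = -1


def _inside(pix: np.ndarray, allowed: np.ndarray) -> bool:
    h, w = allowed.shape
    if (pix < 0).any() or (pix[:, 0] >= h).any() or (pix[:, 1] >= w).any():
        return False
    return bool(allowed[pix[:, 0], pix[:, 1]].all())


def _plant_foci(
    params: GeneratorParams,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> list[_PlantedFocus]:
    """Place all foci channels on the allowed (network) mask."""
    px = params.pixel_size
    dist = ndi.distance_transform_edt(allowed)
    h, w = allowed.shape
    cand = np.argwhere(dist >= 1.0)
    planted: list[_PlantedFocus] = []

    ref_name = params.reference_channel
    specs = dict(params.foci_channels)
    ref_spec = specs.pop(ref_name, None)

    # typical query radius sets the clearance reference foci keep from
    # each other so shifted partial partners have room
    q_radii = [
        math.sqrt(s.mean_area / math.pi) / px for s in specs.values() if s.n_foci > 0
    ]
    r_q_typ = max(q_radii) if q_radii else 0.0

    refs: list[_PlantedFocus] = []
    if ref_spec is not None and ref_spec.n_foci > 0:
        if len(cand) == 0:
            raise PlacementError("network too sparse to host any focus")
        radii = _sample_radii(ref_spec, px, rng)
        for i, r in enumerate(radii):
            placed = False
            for attempt in range(params.max_attempts):
                c = tuple(cand[rng.integers(len(cand))])
                if dist[c] < r + 1.0:
                    continue
                # generous spacing leaves room for shifted partial
                # partners; relax to the bare non-merge gap if the
                # network saturates
                clearance = r_q_typ if attempt < 0.6 * params.max_attempts else 0.0
                ok = True
                for f in refs:
                    gap = math.hypot(c[0] - f.center[0], c[1] - f.center[1])
                    if gap < r + f.radius + 2.0 + clearance:
                        ok = False
                        break
                if not ok:
                    continue
                offs = _disk_offsets(r)
                pix = offs + np.asarray(c)
                if not _inside(pix, allowed):
                    continue
                refs.append(
                    _PlantedFocus(ref_name, i, (int(c[0]), int(c[1])), float(r), pix)
                )
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place reference focus {i} of {ref_spec.n_foci} "
                    f"after {params.max_attempts} attempts (network too sparse?)"
                )
        planted.extend(refs)

    for channel, spec in specs.items():
        if spec.n_foci == 0:
            continue
        planted.extend(
            _plant_query_channel(
                params, channel, spec, refs, allowed, dist, cand, rng
            )
        )
    return planted


def _exact_fraction(q_pix: np.ndarray, p_pix: np.ndarray, shape) -> float:
    qi = np.ravel_multi_index((q_pix[:, 0], q_pix[:, 1]), shape)
    pi = np.ravel_multi_index((p_pix[:, 0], p_pix[:, 1]), shape)
    inter = np.intersect1d(qi, pi, assume_unique=True)
    return len(inter) / len(qi)


def _plant_query_channel(
    params: GeneratorParams,
    channel: str,
    spec: FociSpec,
    refs: list[_PlantedFocus],
    allowed: np.ndarray,
    dist: np.ndarray,
    cand: np.ndarray,
    rng: np.random.Generator,
) -> list[_PlantedFocus]:
    px = params.pixel_size
    shape = allowed.shape
    comp = params.composition.as_dict()
    counts = largest_remainder_counts(comp, spec.n_foci)
    n_partnered = counts["complete"] + counts["partial"]
    if n_partnered > len(refs):
        raise PlacementError(
            f"composition needs {n_partnered} reference partners but only "
            f"{len(refs)} reference foci exist"
        )
    radii = _sample_radii(spec, px, rng)
    categories = (
        ["complete"] * counts["complete"]
        + ["partial"] * counts["partial"]
        + ["none"] * counts["none"]
    )
    ref_pool = list(rng.permutation(len(refs))) if refs else []
    placed: list[_PlantedFocus] = []
    lo, hi = params.partial_overlap_range

    def collides_same_channel(pix_center, r) -> bool:
        # 4 px boundary gap: keeps channels 8-connectivity safe even
        # after blur-grown contours at permissive thresholds
        for f in placed:
            gap = math.hypot(pix_center[0] - f.center[0], pix_center[1] - f.center[1])
            if gap < r + f.radius + 4.0:
                return True
        return False

    for i, (cat, r) in enumerate(zip(categories, radii)):
        if cat == "complete":
            focus = _plant_complete(i, channel, r, refs, ref_pool, placed, rng, params)
        elif cat == "partial":
            focus = _plant_partial(
                i, channel, r, refs, ref_pool, placed, allowed, shape,
                (lo, hi), rng, params, collides_same_channel,
            )
        else:
            focus = _plant_none(
                i, channel, r, refs, allowed, dist, cand, rng, params,
                collides_same_channel,
            )
        placed.append(focus)
    return placed


def _plant_complete(
    i: int,
    channel: str,
    r: float,
    refs: list[_PlantedFocus],
    ref_pool: list[int],
    placed: list[_PlantedFocus],
    rng: np.random.Generator,
    params: GeneratorParams,
) -> _PlantedFocus:
    # prefer a partner the query fits inside with a 1 px radial margin;
    # otherwise shrink the query to the partner's radius minus 1 px
    pick = None
    for j, pi in enumerate(ref_pool):
        if refs[pi].radius >= r + 1.0:
            pick = j
            break
    if pick is None and ref_pool:
        pick = 0
    if pick is None:
        raise PlacementError("no reference partner available for a complete focus")
    partner = refs[ref_pool.pop(pick)]
    r_eff = min(r, partner.radius - 1.0)
    r_eff = max(r_eff, 0.5)  # at least a single-pixel focus
    pix = _disk_offsets(r_eff) + np.asarray(partner.center)
    return _PlantedFocus(
        channel, i, partner.center, float(r_eff), pix,
        category="complete", overlap_pct=100.0, partner_id=partner.focus_id,
    )


def _plant_partial(
    i, channel, r, refs, ref_pool, placed, allowed, shape,
    frac_range, rng, params, collides_same_channel,
) -> _PlantedFocus:
    lo, hi = frac_range
    offs = _disk_offsets(r)
    tried = 0
    while ref_pool and tried < params.max_attempts:
        partner = refs[ref_pool[0]]
        best = None
        for _ in range(24):
            tried += 1
            theta = rng.uniform(0, 2 * math.pi)
            target = rng.uniform(lo, hi)
            for d in np.arange(0.5, r + partner.radius, 0.5):
                dc = (
                    int(round(d * math.sin(theta))),
                    int(round(d * math.cos(theta))),
                )
                if dc == (0, 0):
                    continue
                c = (partner.center[0] + dc[0], partner.center[1] + dc[1])
                pix = offs + np.asarray(c)
                if not _inside(pix, allowed):
                    continue
                if collides_same_channel(c, r):
                    continue
                # must not touch any reference focus other than the partner
                clear = True
                for other in refs:
                    if other.focus_id == partner.focus_id:
                        continue
                    gap = math.hypot(c[0] - other.center[0], c[1] - other.center[1])
                    if gap < r + other.radius + 1.0:
                        clear = False
                        break
                if not clear:
                    continue
                frac = _exact_fraction(pix, partner.pixels, shape)
                if lo <= frac <= hi:
                    ref_pool.pop(0)
                    return _PlantedFocus(
                        channel, i, c, float(r), pix,
                        category="partial", overlap_pct=100.0 * frac,
                        partner_id=partner.focus_id,
                    )
                if 0.0 < frac < 1.0 and (
                    best is None or abs(frac - target) < abs(best[0] - target)
                ):
                    best = (frac, c, pix, partner.focus_id)
        if best is not None:
            ref_pool.pop(0)
            frac, c, pix, pid = best
            return _PlantedFocus(
                channel, i, c, float(r), pix,
                category="partial", overlap_pct=100.0 * frac, partner_id=pid,
            )
        # this partner is unusable (e.g. hemmed in); rotate it to the back
        ref_pool.append(ref_pool.pop(0))
    raise PlacementError(
        f"could not plant partial-overlap focus {i} on channel {channel!r}"
    )


def _plant_none(
    i, channel, r, refs, allowed, dist, cand, rng, params, collides_same_channel,
) -> _PlantedFocus:
    psf_px = params.psf_sigma / params.pixel_size
    safe = 3.0 + 2.0 * psf_px
    offs = _disk_offsets(r)
    for _ in range(params.max_attempts):
        c = tuple(int(v) for v in cand[rng.integers(len(cand))])
        if dist[c] < r + 1.0:
            continue
        if collides_same_channel(c, r):
            continue
        clear = all(
            math.hypot(c[0] - f.center[0], c[1] - f.center[1]) >= r + f.radius + safe
            for f in refs
        )
        if not clear:
            continue
        pix = offs + np.asarray(c)
        if not _inside(pix, allowed):
            continue
        return _PlantedFocus(channel, i, c, float(r), pix, category="none")
    raise PlacementError(
        f"could not plant zero-overlap focus {i} on channel {channel!r} "
        f"after {params.max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# cells


def _plant_cells(
    params: GeneratorParams, rng: np.random.Generator
) -> tuple[list[CellRegion], pd.DataFrame]:
    h, w = params.frame_shape
    px = params.pixel_size
    r_cell = params.cell_radius / px
    r_nuc = params.nucleus_radius / px
    if r_nuc >= r_cell:
        raise ValueError("nucleus_radius must be smaller than cell_radius")
    spacing = int(2 * r_cell + 4)
    rows = max((h - spacing // 2) // spacing, 0)
    cols = max((w - spacing // 2) // spacing, 0)
    if rows * cols < params.n_cells:
        raise PlacementError(
            f"frame {params.frame_shape} fits at most {rows * cols} cells of "
            f"radius {params.cell_radius} um, {params.n_cells} requested"
        )
    nodes = [
        (spacing // 2 + i * spacing + spacing // 2, spacing // 2 + j * spacing + spacing // 2)
        for i in range(rows)
        for j in range(cols)
    ]
    # clamp nodes into frame (grid arithmetic can overshoot by < spacing)
    nodes = [(min(r0, h - int(r_cell) - 2), min(c0, w - int(r_cell) - 2)) for r0, c0 in nodes]
    order = rng.permutation(len(nodes))[: params.n_cells]

    phase_counts = largest_remainder_counts(params.phase_mix, params.n_cells)
    phases = sum(([ph] * n for ph, n in sorted(phase_counts.items())), [])
    phases = [phases[k] for k in rng.permutation(params.n_cells)]

    mk = params.markers
    regions: list[CellRegion] = []
    rows_out = []
    for cid, node_i in enumerate(order):
        r0, c0 = nodes[node_i]
        jitter = rng.integers(-1, 2, size=2)
        center = (int(r0 + jitter[0]), int(c0 + jitter[1]))
        rc = r_cell * (1.0 + rng.uniform(-0.05, 0.05))
        cell_pix = _disk_offsets(rc) + np.asarray(center)
        nuc_pix = _disk_offsets(r_nuc) + np.asarray(center)
        cell_idx = np.ravel_multi_index((cell_pix[:, 0], cell_pix[:, 1]), (h, w))
        nuc_idx = np.ravel_multi_index((nuc_pix[:, 0], nuc_pix[:, 1]), (h, w))
        phase = phases[cid]
        edu_mean = mk.edu_pos if phase == "S" else mk.edu_neg
        cyc_mean = mk.cyclin_pos if phase in ("S", "G2") else mk.cyclin_neg
        edu = max(rng.normal(edu_mean, mk.level_sd), 0.0)
        cyc = max(rng.normal(cyc_mean, mk.level_sd), 0.0)
        dapi = max(rng.normal(mk.dapi, mk.level_sd), 0.0)
        regions.append(
            CellRegion(
                cell_id=cid, shape=(h, w), pixel_size=px,
                nucleus_idx=np.sort(nuc_idx), cell_idx=np.sort(cell_idx),
                phase=phase,
            )
        )
        rows_out.append(
            dict(
                cell_id=cid, phase=phase,
                center_row=center[0], center_col=center[1],
                cell_area_um2=len(cell_idx) * px**2,
                nucleus_area_um2=len(nuc_idx) * px**2,
                mito_area_um2=0.0,
                edu_level=edu, cyclin_level=cyc, dapi_level=dapi,
            )
        )
    return regions, pd.DataFrame(rows_out)


def _cell_network(
    params: GeneratorParams, cells_df: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Tubular network grown per cell (walks seeded in each cytoplasm),
    emulating the perinuclear mitochondrial network of adherent cells.
    The caller clips the result to cytoplasm-minus-nucleus."""
    h, w = params.frame_shape
    px = params.pixel_size
    w_px = params.tube_width / px
    if w_px < 1.0:
        raise ValueError("tube_width below one pixel is unresolvable")
    skel = np.zeros((h, w), dtype=bool)
    if params.network_density == 0 or not len(cells_df):
        return skel
    r_cell = params.cell_radius / px
    r_nuc = params.nucleus_radius / px
    annulus_area = math.pi * (r_cell**2 - r_nuc**2)
    # enough skeleton length for the requested coverage of the annulus
    walk_len = max(16, int(1.3 * params.network_density * annulus_area / w_px))
    for row in cells_df.itertuples():
        center = np.array([row.center_row, row.center_col], dtype=float)
        for _ in range(3):
            rad = rng.uniform(r_nuc + w_px / 2, r_cell - w_px / 2)
            ang = rng.uniform(0, 2 * math.pi)
            start = center + rad * np.array([math.sin(ang), math.cos(ang)])
            turns = rng.normal(0.0, 0.6, size=walk_len // 3)
            turns[0] = rng.uniform(0, 2 * math.pi)
            angles = np.cumsum(turns)
            steps = np.stack([np.sin(angles), np.cos(angles)], axis=1)
            pos = start + np.cumsum(steps, axis=0)
            # fold the walk back into the cell's annulus radially
            d = pos - center
            rr = np.hypot(d[:, 0], d[:, 1])
            rmax = r_cell - w_px / 2 - 1
            over = rr > rmax
            if over.any():
                pos[over] = center + d[over] * (rmax / rr[over])[:, None]
            ij = np.clip(np.round(pos).astype(int), [0, 0], [h - 1, w - 1])
            skel[ij[:, 0], ij[:, 1]] = True
    return ndi.distance_transform_edt(~skel) <= w_px / 2.0


# ---------------------------------------------------------------------------
# frame assembly


def _apply_noise(
    img: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> np.ndarray:
    psf_px = params.psf_sigma / params.pixel_size
    out = img.astype(np.float64)
    if psf_px > 0:
        out = ndi.gaussian_filter(out, psf_px, mode="nearest")
    if params.noise.poisson_scale > 0:
        scale = params.noise.poisson_scale
        nz = out > 0  # Poisson(0) == 0: draw only where signal exists
        shot = np.zeros_like(out)
        shot[nz] = rng.poisson(out[nz] * scale)
        out = shot / scale
    if params.noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, params.noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_frame(params: GeneratorParams) -> tuple[ImageFrame, GroundTruth]:
    """Generate one synthetic frame and its ground truth.

    Deterministic: two calls with identical ``params`` (including
    ``seed``) return bit-identical frames and truth tables. Raises
    :class:`~granulemap.core.PlacementError` when the requested objects
    cannot be placed under the category constraints.
    """
    h, w = params.frame_shape
    px = params.pixel_size

    rng_cells = _rng_for(params, 29)
    rng_foci = _rng_for(params, 41)
    rng_noise = _rng_for(params, 53)

    if params.n_cells > 0:
        regions, cells_df = _plant_cells(params, rng_cells)
        cyto_union = np.zeros((h, w), dtype=bool)
        nuc_union = np.zeros((h, w), dtype=bool)
        for reg in regions:
            cyto_union.flat[reg.cell_idx] = True
            nuc_union.flat[reg.nucleus_idx] = True
        network = _cell_network(params, cells_df, rng_cells) & cyto_union & ~nuc_union
        net_flat = network.ravel()
        for reg, row in zip(regions, cells_df.itertuples()):
            mito_idx = reg.cell_idx[net_flat[reg.cell_idx]]
            reg.mito_idx = mito_idx
            cells_df.loc[row.Index, "mito_area_um2"] = len(mito_idx) * px**2
    else:
        regions, cells_df = [], pd.DataFrame(
            columns=[
                "cell_id", "phase", "center_row", "center_col", "cell_area_um2",
                "nucleus_area_um2", "mito_area_um2", "edu_level", "cyclin_level",
                "dapi_level",
            ]
        )
        network = render_network(params)

    planted = _plant_foci(params, network, rng_foci)

    # cell assignment by centroid (disk centroid == planted center)
    cell_lbl = np.full((h, w), -1, dtype=int)
    for reg in regions:
        cell_lbl.flat[reg.cell_idx] = reg.cell_id

    foci_rows = []
    foci_pixels: dict[tuple[str, int], np.ndarray] = {}
    for f in planted:
        cr, cc = f.pixels.mean(axis=0)
        foci_rows.append(
            dict(
                channel=f.channel, focus_id=f.focus_id, category=f.category,
                overlap_pct=f.overlap_pct, area_um2=len(f.pixels) * px**2,
                centroid_row=cr, centroid_col=cc, partner_id=f.partner_id,
                cell_id=int(cell_lbl[f.center]) if regions else -1,
            )
        )
        foci_pixels[(f.channel, f.focus_id)] = f.pixels
    foci_df = pd.DataFrame(
        foci_rows,
        columns=[
            "channel", "focus_id", "category", "overlap_pct", "area_um2",
            "centroid_row", "centroid_col", "partner_id", "cell_id",
        ],
    )

    channels: dict[str, np.ndarray] = {}
    channels["mito"] = network.astype(np.float64) * params.mito_intensity
    for name, spec in params.foci_channels.items():
        chan = np.zeros((h, w), dtype=np.float64)
        for f in planted:
            if f.channel == name:
                chan[f.pixels[:, 0], f.pixels[:, 1]] = spec.intensity
        channels[name] = chan

    dapi = np.zeros((h, w), dtype=np.float64)
    edu = np.zeros_like(dapi)
    cyclin = np.zeros_like(dapi)
    body = np.zeros_like(dapi)
    for reg, row in zip(regions, cells_df.itertuples()):
        dapi.flat[reg.nucleus_idx] = row.dapi_level
        edu.flat[reg.nucleus_idx] = row.edu_level
        cyclin.flat[reg.cell_idx] = row.cyclin_level
        body.flat[reg.cell_idx] = params.cellbody_intensity
    channels[params.dapi_channel] = dapi
    channels["EdU"] = edu
    channels["cyclinA"] = cyclin
    channels["cellbody"] = body

    noisy = {k: _apply_noise(v, params, rng_noise) for k, v in channels.items()}
    frame = ImageFrame(noisy, pixel_size=px, frame_id=f"sim-{params.seed:06d}")
    truth = GroundTruth(
        foci=foci_df, foci_pixels=foci_pixels, cells=cells_df,
        cell_regions=regions, network=network, pixel_size=px,
    )
    return frame, truth
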