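"""Readers/writers, configuration, and the end-to-end pipeline.

Frames travel as multi-channel TIFF with channel names and pixel size
in the (JSON) image description; tables as UTF-8 comma-separated CSV
with '.' decimals; configuration as YAML. Every output table embeds the
package version and a hash of the configuration as leading comment
lines (``# ...``), so results are traceable to the exact settings; the
run log records every threshold and rule actually applied plus
per-frame object counts at each filter stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import BinaryMask, ConfigError, FocusROI, ImageFrame
from .colocal import (
    DEFAULT_COMPLETE_TOL,
    compute_overlap,
    shape_descriptors,
    summarize,
)
from .percell import PhaseThresholds, group_summary, quantify_cells
from .segment import (
    DEFAULT_MIN_SIZE,
    build_cell_regions,
    filter_by_mask,
    label_foci,
    segment_mask,
    unsharp_mask,
)
from .simulate import GeneratorParams, generate_frame

__all__ = [
    "PipelineConfig",
    "read_frame",
    "write_frame",
    "write_mask",
    "write_table",
    "run_pipeline",
    "config_hash",
]

log = logging.getLogger(__name__)

ROLES = ("mito", "query_foci", "reference_foci", "dapi", "edu", "cyclinA", "cellbody")


@dataclass
class PipelineConfig:
    """Single source of truth for pipeline parameters.

    ``roles`` maps channel names to roles (``mito``, ``query_foci``,
    ``reference_foci``, ``dapi``, ``edu``, ``cyclinA``, ``cellbody``);
    multiple channels may share the ``query_foci`` role. ``thresholds``
    maps channel names to absolute cutoffs; channels without an entry
    fall back to Otsu. A pixel size given here overrides file metadata
    (with a logged warning).
    """

    roles: dict[str, str] = field(
        default_factory=lambda: {
            "mito": "mito",
            "dsRNA": "query_foci",
            "BrU": "reference_foci",
            "DAPI": "dapi",
            "EdU": "edu",
            "cyclinA": "cyclinA",
            "cellbody": "cellbody",
        }
    )
    pixel_size: float | None = None
    thresholds: dict[str, float] = field(default_factory=dict)
    min_size: int = DEFAULT_MIN_SIZE
    smooth_sigma: float = 0.0
    containment_rule: str = "centroid"
    complete_tol: float = DEFAULT_COMPLETE_TOL
    unsharp: dict | None = None  # {"radius": 100, "weight": 0.7} to enable
    phase_thresholds: dict | None = None  # {"edu_pos", "cyclin_pos", "dapi_min"}
    cyclin_compartment: str = "cell"
    seed: int = 0
    out_dir: str = "granulemap-out"

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise ConfigError(f"unknown channel roles: {sorted(bad)}")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        if self.containment_rule not in ("centroid", "majority", "any"):
            raise ConfigError(f"unknown containment rule {self.containment_rule!r}")

    def channels_with_role(self, role: str) -> list[str]:
        return sorted(name for name, r in self.roles.items() if r == role)

    def one_channel(self, role: str) -> str | None:
        names = self.channels_with_role(role)
        if len(names) > 1:
            raise ConfigError(f"role {role!r} assigned to multiple channels: {names}")
        return names[0] if names else None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the canonicalized configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# frame / mask / table IO


def write_frame(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as a multi-page TIFF (one page per channel) with
    channel names, pixel size, and frame id in the image description."""
    names = sorted(frame.channels)
    stack = np.stack([frame.channels[n] for n in names])
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",  # 3-channel stacks are not RGB
        metadata={
            "axes": "CYX",
            "granulemap_channels": names,
            "pixel_size_um": frame.pixel_size,
            "frame_id": frame.frame_id,
        },
    )


def read_frame(
    path: str | Path,
    config: PipelineConfig | None = None,
    channel_names: list[str] | None = None,
    pixel_size: float | None = None,
) -> ImageFrame:
    """Read a multi-channel TIFF into a calibrated frame.

    Channel names come from the file metadata or ``channel_names``; the
    count must match the pages in the file and, when a config is given,
    every configured channel must be present. A pixel size from
    ``config``/``pixel_size`` overrides file metadata with a warning.
    """
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = channel_names or meta.get("granulemap_channels")
    if names is None:
        names = [f"ch{i}" for i in range(len(stack))]
    if len(names) != len(stack):
        raise ConfigError(
            f"{path}: {len(stack)} channel pages but {len(names)} channel names"
        )
    file_px = meta.get("pixel_size_um")
    override = pixel_size if pixel_size is not None else (
        config.pixel_size if config is not None else None
    )
    if override is not None:
        if file_px is not None and not np.isclose(file_px, override):
            log.warning(
                "%s: config pixel size %g um overrides file metadata %g um",
                path, override, file_px,
            )
        px = override
    elif file_px is not None:
        px = float(file_px)
    else:
        raise ConfigError(f"{path}: no pixel size in file metadata or config")
    if config is not None:
        missing = set(config.roles) - set(names)
        if missing:
            raise ConfigError(
                f"{path}: config names {len(config.roles)} channels but file "
                f"lacks {sorted(missing)} (has {names})"
            )
    frame_id = meta.get("frame_id", Path(path).stem)
    return ImageFrame(dict(zip(names, stack)), pixel_size=px, frame_id=frame_id)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        mask.raster.astype(np.uint8) * 255,
        metadata={"pixel_size_um": mask.pixel_size, "threshold": mask.threshold},
    )


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str) -> None:
    """CSV with provenance comment lines (package version, config hash).
    Read back with ``pandas.read_csv(path, comment='#')``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# granulemap {__version__}\n# config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# pipeline


def _segment_channel(
    frame: ImageFrame, name: str, config: PipelineConfig, apply_unsharp: bool = False
) -> BinaryMask:
    img = frame.channel(name)
    if apply_unsharp and config.unsharp:
        img = unsharp_mask(
            img,
            radius=config.unsharp.get("radius", 100.0),
            weight=config.unsharp.get("weight", 0.7),
        )
        log.info(
            "frame %s: unsharp mask on %r (radius=%g weight=%g)",
            frame.frame_id, name,
            config.unsharp.get("radius", 100.0), config.unsharp.get("weight", 0.7),
        )
    thr = config.thresholds.get(name)
    mask = segment_mask(
        img,
        method="absolute" if thr is not None else "otsu",
        threshold=thr,
        min_size=config.min_size,
        smooth_sigma=config.smooth_sigma,
        pixel_size=frame.pixel_size,
    )
    log.info(
        "frame %s: channel %r segmented at threshold %.4g (%s), %d px",
        frame.frame_id, name, mask.threshold,
        "absolute" if thr is not None else "otsu", mask.n_pixels,
    )
    return mask


def _analyse_frame(frame: ImageFrame, config: PipelineConfig) -> dict:
    """Run all applicable stages on one frame; returns DataFrames."""
    px = frame.pixel_size
    mito_name = config.one_channel("mito")
    query_names = [n for n in config.channels_with_role("query_foci") if n in frame.channels]
    ref_name = config.one_channel("reference_foci")
    if ref_name is not None and ref_name not in frame.channels:
        ref_name = None

    mito_mask = None
    if mito_name and mito_name in frame.channels:
        mito_mask = _segment_channel(frame, mito_name, config, apply_unsharp=True)

    foci_by_channel: dict[str, list[FocusROI]] = {}
    for name in query_names + ([ref_name] if ref_name else []):
        mask = _segment_channel(frame, name, config)
        foci = label_foci(mask, channel=name)
        n_before = len(foci)
        if mito_mask is not None:
            foci = filter_by_mask(foci, mito_mask, rule=config.containment_rule)
        log.info(
            "frame %s: channel %r foci %d before / %d after containment "
            "filtering (rule=%s)",
            frame.frame_id, name, n_before, len(foci), config.containment_rule,
        )
        for f in foci:
            shape_descriptors(f)
        foci_by_channel[name] = foci

    focus_rows = []
    summary_rows = []
    for name in query_names:
        foci = foci_by_channel.get(name, [])
        if ref_name is not None:
            records = compute_overlap(
                foci, foci_by_channel.get(ref_name, []), frame.shape,
                complete_tol=config.complete_tol, reference_channel=ref_name,
            )
            rec_by_id = {r.focus_id: r for r in records}
            if records:
                s = summarize(records)
                summary_rows.append(
                    dict(
                        frame=frame.frame_id, query_channel=name,
                        reference_channel=ref_name, n_foci=s.n_foci,
                        pct_none=s.pct_none, pct_partial=s.pct_partial,
                        pct_complete=s.pct_complete,
                    )
                )
        else:
            log.info(
                "frame %s: no reference channel; skipping colocalization for %r",
                frame.frame_id, name,
            )
            rec_by_id = {}
        for f in foci:
            rec = rec_by_id.get(f.focus_id)
            focus_rows.append(
                dict(
                    frame=frame.frame_id, channel=name, focus_id=f.focus_id,
                    centroid_row=f.centroid[0], centroid_col=f.centroid[1],
                    area_um2=f.area_um2, major_axis_um=f.major_axis_um,
                    minor_axis_um=f.minor_axis_um, eccentricity=f.eccentricity,
                    overlap_pct=rec.overlap_pct if rec else float("nan"),
                    category=rec.category if rec else "",
                )
            )

    per_cell = pd.DataFrame()
    dapi_name = config.one_channel("dapi")
    if dapi_name and dapi_name in frame.channels:
        body_name = config.one_channel("cellbody")
        cells = build_cell_regions(
            frame.channel(dapi_name),
            frame.channel(body_name) if body_name in frame.channels else None,
            pixel_size=px,
            mito_mask=mito_mask.raster if mito_mask is not None else None,
        )
        log.info("frame %s: %d cell regions", frame.frame_id, len(cells))
        if cells:
            pt = config.phase_thresholds
            thresholds = PhaseThresholds(**pt) if pt else None
            chan_map = {
                "DAPI": dapi_name,
                "EdU": config.one_channel("edu"),
                "cyclinA": config.one_channel("cyclinA"),
            }
            channels = dict(frame.channels)
            for std, actual in chan_map.items():
                if actual and actual in channels and std not in channels:
                    channels[std] = channels[actual]
            per_cell = quantify_cells(
                channels, cells, foci_by_channel,
                intensity_channels=query_names, thresholds=thresholds,
                cyclin_compartment=config.cyclin_compartment,
            )
            per_cell.insert(0, "frame", frame.frame_id)

    return dict(
        per_focus=pd.DataFrame(focus_rows),
        overlap_summary=pd.DataFrame(summary_rows),
        per_cell=per_cell,
        mito_mask=mito_mask,
    )


def run_pipeline(
    config: PipelineConfig,
    frames: list[ImageFrame | str | Path] | None = None,
    simulate: GeneratorParams | None = None,
    n_frames: int = 1,
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end run: mask -> ROIs -> containment filter -> descriptors
    -> overlap -> per-cell metrics -> summaries, written as CSVs.

    Inputs are either ``frames`` (ImageFrames or TIFF paths) or
    generator parameters (``simulate``; frame *i* uses seed
    ``simulate.seed + i``). Deterministic: identical config + seed give
    byte-identical CSVs. Returns the result DataFrames plus paths.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("granulemap")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        log.info("granulemap %s, config sha256 %s", __version__, cfg_hash)
        resolved: list[ImageFrame] = []
        if simulate is not None:
            for i in range(n_frames):
                p = dataclasses.replace(simulate, seed=simulate.seed + i)
                frame, _truth = generate_frame(p)
                resolved.append(frame)
        elif frames is not None:
            for f in frames:
                resolved.append(
                    f if isinstance(f, ImageFrame) else read_frame(f, config)
                )
        else:
            raise ConfigError("run_pipeline needs frames or generator parameters")

        per_focus, per_cell, summaries = [], [], []
        for frame in resolved:
            try:
                res = _analyse_frame(frame, config)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed on frame {frame.frame_id!r}: {exc}"
                ) from exc
            per_focus.append(res["per_focus"])
            summaries.append(res["overlap_summary"])
            if len(res["per_cell"]):
                per_cell.append(res["per_cell"])

        per_focus_df = pd.concat(per_focus, ignore_index=True) if per_focus else pd.DataFrame()
        summary_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
        per_cell_df = pd.concat(per_cell, ignore_index=True) if per_cell else pd.DataFrame()
        group_df = (
            group_summary(per_cell_df.drop(columns=["frame"]), group_by="phase")
            if len(per_cell_df)
            else pd.DataFrame()
        )

        paths = {}
        for name, df in [
            ("per_focus", per_focus_df),
            ("overlap_summary", summary_df),
            ("per_cell", per_cell_df),
            ("group_summary", group_df),
        ]:
            path = out / f"{name}.csv"
            write_table(df, path, cfg_hash)
            paths[name] = path
        log.info(
            "wrote %d focus rows, %d cell rows, %d summaries",
            len(per_focus_df), len(per_cell_df), len(summary_df),
        )
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)

    return dict(
        per_focus=per_focus_df,
        overlap_summary=summary_df,
        per_cell=per_cell_df,
        group_summary=group_df,
        paths=paths,
        config_hash=cfg_hash,
    )
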