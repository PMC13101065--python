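"""End-to-end orchestration: images -> heights -> masks -> features -> tables.

``run_pipeline`` drives the whole chain from a RunConfig: load frames
(fringe interferograms or precomputed height maps), reconstruct heights if
needed, crop each boxed cell, segment, background-correct, extract the
16-feature panel, and emit the paired-comparison and trend tables.  Every
output row is traceable to (plate, cell_id, timepoint); per-cell failures
are logged and skipped, and the run refuses to overwrite a directory
produced by a different configuration unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    read_boxes_csv,
    read_height_map,
    read_mask,
    read_tiff,
    write_features_csv,
    write_mask,
    write_tiff,
)
from .morphometry import CalibrationParams, FEATURE_NAMES, extract_all
from .phase import HeightMap, Interferogram, demodulate_fringes, phase_to_height, unwrap_goldstein
from .segmentation import (
    CellMask,
    aggregate_reports,
    background_correct,
    compare_masks,
    crop_cells,
    segment_cell,
)
from .stats import summarize_pairwise, trend_over_time

log = logging.getLogger("qpmorph")

__all__ = ["RunConfig", "run_pipeline", "reconstruct_frame", "verify_segmentation"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON-loadable)."""

    images: str = ""
    boxes_csv: str = ""
    out_dir: str = "qpmorph_run"
    input_kind: str = "height"            # "height" or "fringe"
    timepoints_min: Sequence[float] = ()  # one per TIFF page, in order
    pixel_size_um: float = 0.5
    wavelength_um: float = 0.633
    delta_n: float = 0.037
    pass_factor: int = 2
    alpha_ri_increment: float = 0.19
    radius_px: int = 50
    threshold_offset: float = 0.0
    imagej_compat: bool = False
    alpha: float = 0.05
    comparisons: Sequence[Sequence[float]] = ((-1.0, 10.0), (-1.0, 120.0), (10.0, 120.0))
    trend_features: Sequence[str] = ("volume", "surface_area", "sa_to_volume")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)

    def calibration(self) -> CalibrationParams:
        return CalibrationParams(
            pixel_size_um=self.pixel_size_um,
            wavelength_um=self.wavelength_um,
            alpha_ri_increment=self.alpha_ri_increment,
            delta_n=self.delta_n,
            pass_factor=self.pass_factor,
        )

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(self).items()}
        payload["comparisons"] = [list(c) for c in self.comparisons]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.input_kind not in ("height", "fringe"):
            raise ValueError("input_kind must be 'height' or 'fringe'")
        for name in ("images", "boxes_csv"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p!r}")


def reconstruct_frame(
    pixels: np.ndarray, cfg: RunConfig, carrier: Optional[Sequence[float]] = None
) -> HeightMap:
    """Fringe frame -> height map (demodulate, unwrap, convert)."""
    ig = Interferogram(pixels=pixels, pixel_size_um=cfg.pixel_size_um)
    wp = demodulate_fringes(ig, carrier=carrier)
    up = unwrap_goldstein(wp)
    return phase_to_height(
        up,
        wavelength_um=cfg.wavelength_um,
        delta_n=cfg.delta_n,
        pass_factor=cfg.pass_factor,
        pixel_size_um=cfg.pixel_size_um,
    )


def run_pipeline(cfg: RunConfig, force: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes heights/, masks/, features.csv, stats/ and run_metadata.json.
    Deterministic given config: rerunning with the same config reproduces
    features.csv bit-identically.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = Path(cfg.out_dir)
    meta_path = out / "run_metadata.json"
    chash = cfg.config_hash()
    if meta_path.exists():
        old = json.loads(meta_path.read_text())
        if old.get("config_hash") != chash and not force:
            raise FileExistsError(
                f"{out} was produced by a different configuration "
                f"({old.get('config_hash')} != {chash}); use force to overwrite"
            )
    (out / "heights").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)

    frames = read_tiff(cfg.images)
    if frames.ndim == 2:
        frames = frames[None]
    timepoints = list(cfg.timepoints_min) or list(range(1, frames.shape[0] + 1))
    if len(timepoints) != frames.shape[0]:
        raise ValueError(
            f"timepoints_min has {len(timepoints)} entries for {frames.shape[0]} pages"
        )
    boxes = read_boxes_csv(cfg.boxes_csv)
    calib = cfg.calibration()

    heights: dict[int, HeightMap] = {}
    for page in range(frames.shape[0]):
        if cfg.input_kind == "fringe":
            hm = reconstruct_frame(frames[page], cfg)
        else:
            hm = HeightMap(
                height_um=frames[page],
                pixel_size_um=cfg.pixel_size_um,
                wavelength_um=cfg.wavelength_um,
                delta_n=cfg.delta_n,
                pass_factor=cfg.pass_factor,
            )
        heights[page + 1] = hm
        write_tiff(out / "heights" / f"frame{page + 1:03d}.tif", hm.height_um)

    rows = []
    failures = []
    for box in boxes:
        page = int(box.frame_id)
        t = timepoints[page - 1]
        try:
            if page not in heights:
                raise ValueError(f"box references missing frame {page}")
            (_, crop), = crop_cells(heights[page], [box])
            cell_mask, particles = segment_cell(
                crop.height_um,
                radius_px=cfg.radius_px,
                offset=cfg.threshold_offset,
                imagej_compat=cfg.imagej_compat,
            )
            if cell_mask.empty:
                raise ValueError("empty mask after segmentation")
            corrected = background_correct(crop.height_um, particles)
            feats = extract_all(corrected, cell_mask, calib)
            write_mask(out / "masks" / f"{box.cell_id}_t{t:+.0f}.png", cell_mask.mask)
            row = feats.to_dict()
            row.update(
                plate="plate1",
                cell_id=box.cell_id,
                timepoint_min=float(t),
                n_components=cell_mask.n_components_before_selection,
            )
            rows.append(row)
        except Exception as exc:  # per-cell failure: log and continue
            log.warning("cell %s @ t=%s failed: %s", box.cell_id, t, exc)
            failures.append({"cell_id": box.cell_id, "timepoint_min": float(t),
                             "error": str(exc)})

    if not rows:
        raise RuntimeError("no cell was successfully processed")
    features = pd.DataFrame(rows)[
        ["plate", "cell_id", "timepoint_min", "n_components", *FEATURE_NAMES]
    ]
    write_features_csv(out / "features.csv", features)

    stats_written = []
    for t_ref, t_cmp in cfg.comparisons:
        present = set(features["timepoint_min"])
        if t_ref not in present or t_cmp not in present:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = summarize_pairwise(features, t_ref, t_cmp, alpha=cfg.alpha)
        except ValueError as exc:
            log.warning("comparison (%s, %s) skipped: %s", t_ref, t_cmp, exc)
            continue
        name = f"pairwise_{t_ref:+.0f}min_vs_{t_cmp:+.0f}min.csv"
        table.to_csv(out / "stats" / name, index=False)
        stats_written.append(name)

    trend_rows = []
    post = sorted(t for t in set(features["timepoint_min"]) if t > 0)
    if len(post) >= 3:
        for feat in cfg.trend_features:
            tr = trend_over_time(features, feat, timepoints=post)
            trend_rows.append({"parameter": feat, "tau_b": tr.tau_b,
                               "p_value": tr.p_value, "S": tr.S_statistic,
                               "n_timepoints": tr.series_length})
    if trend_rows:
        pd.DataFrame(trend_rows).to_csv(out / "stats" / "trends.csv", index=False)
        stats_written.append("trends.csv")

    meta = {
        "config_hash": chash,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(cfg).items()},
        "qpmorph_version": __version__,
        "seed": cfg.seed,
        "n_boxes": len(boxes),
        "n_rows": len(rows),
        "n_failures": len(failures),
        "failures": failures,
        "stats_tables": stats_written,
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return out


def _overlay_rgb(auto: np.ndarray, manual: np.ndarray) -> np.ndarray:
    """Boundary-difference overlay: auto-only red, manual-only green,
    agreement white."""
    rgb = np.zeros((*auto.shape, 3), dtype=np.uint8)
    both = auto & manual
    rgb[auto & ~manual] = (255, 0, 0)
    rgb[manual & ~auto] = (0, 255, 0)
    rgb[both] = (255, 255, 255)
    return rgb


def verify_segmentation(
    auto_dir: str | Path,
    manual_dir: str | Path,
    heights_dir: Optional[str | Path] = None,
    out_dir: Optional[str | Path] = None,
    calib: Optional[CalibrationParams] = None,
) -> pd.DataFrame:
    """Compare automated vs manual masks matched by filename.

    For each matched pair, features are extracted from each mask (with the
    corresponding height crop when ``heights_dir`` is given, otherwise
    shape-only on a unit-height surrogate) and compared as percent error,
    plus IoU.  Writes per-cell and per-feature average CSVs and Fig-style
    overlay PNGs when ``out_dir`` is given.  Unmatched files are reported.
    """
    import imageio.v3 as iio

    auto_dir, manual_dir = Path(auto_dir), Path(manual_dir)
    calib = calib or CalibrationParams()
    autos = {p.name: p for p in sorted(auto_dir.glob("*.png")) + sorted(auto_dir.glob("*.tif"))}
    manuals = {p.name: p for p in sorted(manual_dir.glob("*.png")) + sorted(manual_dir.glob("*.tif"))}
    if not autos or not manuals:
        raise ValueError("empty mask directory")
    unmatched = sorted(set(autos) ^ set(manuals))
    if unmatched:
        log.warning("unmatched mask files: %s", unmatched)

    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    per_cell = []
    reports = []
    for name in sorted(set(autos) & set(manuals)):
        am = read_mask(autos[name])
        mm = read_mask(manuals[name])
        if heights_dir is not None:
            h = read_tiff(Path(heights_dir) / (Path(name).stem + ".tif"))
        else:
            h = np.ones_like(am, dtype=float)  # unit height: shape features only
        fa = extract_all(h, am, calib).to_dict()
        fm = extract_all(h, mm, calib).to_dict()
        rep = compare_masks(CellMask(am), CellMask(mm), fa, fm)
        reports.append(rep)
        row = {"cell": Path(name).stem, "iou": rep.iou, **rep.percent_errors}
        per_cell.append(row)
        if out:
            iio.imwrite(out / f"overlay_{Path(name).stem}.png", _overlay_rgb(am, mm))

    per_cell_df = pd.DataFrame(per_cell)
    averages = aggregate_reports(reports)
    if out:
        per_cell_df.to_csv(out / "verification_per_cell.csv", index=False)
        pd.DataFrame(
            [{"feature": k, "avg_percent_error": v} for k, v in averages.items()]
        ).to_csv(out / "verification_averages.csv", index=False)
    per_cell_df.attrs["averages"] = averages
    per_cell_df.attrs["unmatched"] = unmatched
    return per_cell_df
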