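"""Shared readers/writers, run configuration, and the end-to-end pipeline.

Formats: TIFF/PNG images (8/16-bit, single page or stack), CSV tables
(layouts, region calls, competition records, growth curves), JSON
(configuration, tessellations, reports), SVG layout previews.  Every
pipeline run writes a provenance record (config hash, seed, versions) next
to its outputs so a run is reproducible from the record alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chamber import ChamberLayout
from .cooccurrence import cooccurrence_report, occurrence_by_flow_class
from .regions import (
    Tessellation,
    call_occupancy,
    columns_from_layout,
    detect_columns,
    integrate_bead_frames,
    region_mean_intensity,
    score_flow,
    tessellate,
)

logger = logging.getLogger("bioflow")

__all__ = [
    "FormatError",
    "RunConfig",
    "read_image",
    "write_image",
    "read_layout_csv",
    "write_layout_csv",
    "write_layout_svg",
    "write_region_calls",
    "read_region_calls",
    "run_pipeline",
]


class FormatError(ValueError):
    """Unreadable or unsupported image/table file."""


@dataclass
class RunConfig:
    """Everything that, together with the seed, determines a run's outputs."""

    seed: int = 0
    um_per_px: float = 8.0
    occupancy_method: str = "otsu"  # or "k_sigma"
    occupancy_k: float = 5.0
    flow_min_coverage: float = 0.001
    flow_k: float = 5.0
    # Which image channel index holds which strain.
    channel_wt: int = 0
    channel_mutant: int = 1
    occurrence_mode: str = "area"
    alpha: float = 0.05
    out_dir: str = "."

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_image(path):
    """Read a TIFF or PNG image; returns (array, metadata dict).

    Multi-page TIFFs come back as (pages, H, W) stacks.  Unreadable files
    raise :class:`FormatError` naming the offender rather than crashing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        elif suffix == ".png":
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise FormatError(f"unsupported image format {suffix!r}: {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise FormatError(f"corrupt or empty image file: {path}")
    meta = {"dtype": str(arr.dtype), "pages": arr.shape[0] if arr.ndim == 3 else 1}
    return arr, meta


def write_image(path, array: np.ndarray) -> None:
    """Write a 2D image or (pages, H, W) stack as 16-bit TIFF (or PNG if asked)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported output image format: {path}")


def write_layout_csv(layout: ChamberLayout, path) -> None:
    """Layout CSV (`cx_um,cy_um,r_um`) plus a sidecar JSON with chamber dims."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(layout.columns, columns=["cx_um", "cy_um", "r_um"]).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"width_um": layout.width, "height_um": layout.height, "depth_um": layout.depth},
            fh,
            indent=2,
        )


def read_layout_csv(path) -> ChamberLayout:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        cols = df[["cx_um", "cy_um", "r_um"]].to_numpy(dtype=float)
    except Exception as exc:
        raise FormatError(f"could not read layout CSV {path}: {exc}") from exc
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            dims = json.load(fh)
        width, height, depth = dims["width_um"], dims["height_um"], dims["depth_um"]
    else:
        width = float((cols[:, 0] + cols[:, 2]).max())
        height = float((cols[:, 1] + cols[:, 2]).max())
        depth = 75.0
    return ChamberLayout(width=width, height=height, depth=depth, columns=cols)


def write_layout_svg(layout: ChamberLayout, path) -> None:
    """Minimal SVG preview: chamber rectangle plus column disks."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {layout.width:.0f} '
        f'{layout.height:.0f}" width="800">',
        f'<rect width="{layout.width:.0f}" height="{layout.height:.0f}" '
        'fill="#f5f0e6" stroke="black"/>',
    ]
    for cx, cy, r in layout.columns:
        parts.append(f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="{r:.1f}" fill="#8a7b66"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))


_CALL_COLUMNS = ["region_id", "flow", "wt_call", "mut_call", "mean_gfp", "mean_mcherry", "area_um2"]


def write_region_calls(df: pd.DataFrame, path) -> None:
    df[_CALL_COLUMNS].to_csv(path, index=False)


def read_region_calls(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not read region calls {path}: {exc}") from exc
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"region-calls file {path} lacks columns {sorted(missing)}")
    return df


def analyze_scene(
    gfp: np.ndarray,
    mcherry: np.ndarray,
    beads: np.ndarray,
    config: RunConfig,
    layout: ChamberLayout | None = None,
    tess: Tessellation | None = None,
) -> tuple[pd.DataFrame, Tessellation]:
    """Region calls for one chamber: tessellate, score occupancy and flow."""
    if tess is None:
        if layout is not None:
            cols = columns_from_layout(layout, config.um_per_px)
        else:
            r_lo = 80.0 / config.um_per_px
            r_hi = 200.0 / config.um_per_px
            cols = detect_columns(gfp, (r_lo, r_hi))
        tess = tessellate(cols, gfp.shape, um_per_px=config.um_per_px)
    channels = (gfp, mcherry)
    mean_wt = region_mean_intensity(channels[config.channel_wt], tess)
    mean_mut = region_mean_intensity(channels[config.channel_mutant], tess)
    wt_call = call_occupancy(mean_wt, method=config.occupancy_method, k=config.occupancy_k)
    mut_call = call_occupancy(mean_mut, method=config.occupancy_method, k=config.occupancy_k)
    integrated = integrate_bead_frames(beads)
    flow = score_flow(integrated, tess, min_coverage=config.flow_min_coverage, k=config.flow_k)
    df = pd.DataFrame(
        {
            "region_id": np.arange(tess.n_regions),
            "flow": flow,
            "wt_call": wt_call,
            "mut_call": mut_call,
            "mean_gfp": mean_wt,
            "mean_mcherry": mean_mut,
            "area_um2": tess.effective_area_um2,
        }
    )
    return df, tess


def run_pipeline(
    config: RunConfig,
    replicates: list[dict],
    out_dir=None,
) -> dict:
    """Run the full co-occurrence analysis over replicate chambers.

    Each replicate dict supplies either in-memory arrays (``gfp``,
    ``mcherry``, ``beads`` and optionally ``layout``) or file paths
    (``gfp_path`` etc., ``layout_path``).  Writes per-replicate region
    calls, an occurrence summary CSV, a JSON test report and a provenance
    record; returns the report dict.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    for i, rep in enumerate(replicates):
        logger.info("pipeline: replicate %d", i)
        gfp = rep.get("gfp")
        if gfp is None:
            gfp, _ = read_image(rep["gfp_path"])
        mcherry = rep.get("mcherry")
        if mcherry is None:
            mcherry, _ = read_image(rep["mcherry_path"])
        beads = rep.get("beads")
        if beads is None:
            beads, _ = read_image(rep["beads_path"])
        layout = rep.get("layout")
        if layout is None and "layout_path" in rep:
            layout = read_layout_csv(rep["layout_path"])
        calls, tess = analyze_scene(gfp, mcherry, beads, config, layout=layout, tess=rep.get("tess"))
        write_region_calls(calls, out / f"calls_rep{i}.csv")
        with open(out / f"tessellation_rep{i}.json", "w") as fh:
            json.dump(tess.to_dict(), fh)
        summaries.append(
            occurrence_by_flow_class(calls, mode=config.occurrence_mode, replicate=i)
        )
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "occurrence_summary.csv", index=False)
    report = cooccurrence_report(summaries, alpha=config.alpha)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    provenance = {
        "config": asdict(config),
        "config_sha256_16": config.digest(),
        "seed": config.seed,
        "bioflow_version": __version__,
        "numpy_version": np.__version__,
        "n_replicates": len(replicates),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return report
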