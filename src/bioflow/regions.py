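"""Tessellation-region quantification of chamber micrographs.

The spatial unit of analysis is a triangular sampling region whose vertices
are column (obstacle) centres: column centres are detected (or registered
from a layout file), Delaunay-triangulated, and each triangle's pixel mask
is stripped of obstacle-covered pixels.  Per-region mean fluorescence
intensity is thresholded to call biofilm occupancy per channel, and an
integrated bead-streak image is thresholded to call local flow as open or
blocked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "ColumnSet",
    "Tessellation",
    "RegionState",
    "EmptyColumnSetError",
    "detect_columns",
    "columns_from_layout",
    "tessellate",
    "region_mean_intensity",
    "call_occupancy",
    "integrate_bead_frames",
    "score_flow",
]


class EmptyColumnSetError(ValueError):
    """No columns detected; supply a layout file instead."""


@dataclass(frozen=True)
class ColumnSet:
    """Circular obstacles in pixel coordinates: rows of (cx, cy, r)."""

    columns: np.ndarray
    source: str = "detected"  # or "layout_file"

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != 3:
            raise ValueError("columns must be an (n, 3) array of (cx, cy, r)")
        if len(cols) and np.any(cols[:, 2] <= 0):
            raise ValueError("column radii must be positive")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class Tessellation:
    """Delaunay triangulation of column centres with per-region pixel masks.

    ``label_image`` assigns each pixel (by its centre) to a triangle index,
    with -1 outside the convex hull; ``column_mask`` marks obstacle pixels.
    A region's *effective* mask is its triangle pixels minus obstacle
    pixels — the area over which intensities and streak coverage are
    averaged.
    """

    points: np.ndarray  # (n, 2) column centres, (x, y) px
    simplices: np.ndarray  # (m, 3) vertex index triples
    label_image: np.ndarray  # (H, W) int32, triangle id or -1
    column_mask: np.ndarray  # (H, W) bool
    um_per_px: float = 1.0
    effective_area_px: np.ndarray = field(init=False)
    overlap_area_px: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = len(self.simplices)
        inside = self.label_image >= 0
        self.overlap_area_px = np.bincount(
            self.label_image[inside & self.column_mask], minlength=m
        ).astype(float)
        total = np.bincount(self.label_image[inside], minlength=m).astype(float)
        self.effective_area_px = total - self.overlap_area_px

    @property
    def n_regions(self) -> int:
        return len(self.simplices)

    @property
    def effective_area_um2(self) -> np.ndarray:
        return self.effective_area_px * self.um_per_px**2

    def effective_mask(self, region: int) -> np.ndarray:
        return (self.label_image == region) & ~self.column_mask

    def centroids(self) -> np.ndarray:
        """Triangle vertex centroids, (m, 2) in (x, y) px."""
        return self.points[self.simplices].mean(axis=1)

    def interior_points(self) -> np.ndarray:
        """Most-interior effective pixel of each region, (m, 2) in (x, y) px.

        The pixel of a region's effective mask farthest from its boundary
        (pole of inaccessibility) — unlike the vertex centroid, guaranteed
        to lie off the obstacle disks; falls back to the centroid for
        regions with no effective pixels.
        """
        from scipy.ndimage import distance_transform_edt

        pts = self.centroids().copy()
        for i in range(self.n_regions):
            mask = self.effective_mask(i)
            if mask.any():
                edt = distance_transform_edt(mask)
                y, x = np.unravel_index(np.argmax(edt), edt.shape)
                pts[i] = (x, y)
        return pts

    def adjacency(self) -> list[set[int]]:
        """Region neighbours sharing a triangulation edge."""
        edges: dict[tuple[int, int], list[int]] = {}
        for t, (a, b, c) in enumerate(self.simplices):
            for e in ((a, b), (b, c), (a, c)):
                edges.setdefault(tuple(sorted(e)), []).append(t)
        adj: list[set[int]] = [set() for _ in range(self.n_regions)]
        for tris in edges.values():
            if len(tris) == 2:
                adj[tris[0]].add(tris[1])
                adj[tris[1]].add(tris[0])
        return adj

    def to_dict(self) -> dict:
        return {
            "um_per_px": self.um_per_px,
            "nodes_px": self.points.tolist(),
            "triangles": self.simplices.tolist(),
            "effective_area_px": self.effective_area_px.tolist(),
            "effective_area_um2": self.effective_area_um2.tolist(),
            "column_overlap_area_px": self.overlap_area_px.tolist(),
        }


@dataclass
class RegionState:
    """Per-region measurement bundle."""

    region_id: int
    mean_gfp: float
    mean_mcherry: float
    wt_call: bool
    mut_call: bool
    flow: str  # "open" | "blocked"


def columns_from_layout(layout, um_per_px: float) -> ColumnSet:
    """Register a physical chamber layout (um) into pixel coordinates."""
    cols = np.asarray(layout.columns, dtype=float) / float(um_per_px)
    return ColumnSet(columns=cols, source="layout_file")


def detect_columns(
    image: np.ndarray,
    expected_r_range: tuple[float, float],
    n_radii: int = 12,
    min_separation_factor: float = 1.5,
) -> ColumnSet:
    """Find dark circular obstacles in a fluorescence image.

    Columns appear as near-zero disks against the fluorescent background, so
    the image is inverted and edges vote in a circular Hough transform over
    the expected radius range.  Raises :class:`EmptyColumnSetError` when
    nothing is found (register a layout file with
    :func:`columns_from_layout` instead).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("detect_columns expects a single-channel 2D image")
    lo, hi = expected_r_range
    if not (0 < lo < hi):
        raise ValueError("expected_r_range must be an increasing positive pair")
    img = image.astype(float)
    span = img.max() - img.min()
    if span == 0:
        raise EmptyColumnSetError("uniform image: no columns detectable; use a layout file")
    # Columns are near-zero disks on a fluorescent background: invert,
    # split foreground/background, and let the disk boundaries vote.
    inv = (img.max() - img) / span
    dark = inv > threshold_otsu(inv)
    edges = canny(dark.astype(float), sigma=1.0)
    radii = np.arange(int(np.floor(lo)), int(np.ceil(hi)) + 1)
    accum = hough_circle(edges, radii)
    min_d = int(min_separation_factor * lo)
    _, cx, cy, r = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=min_d,
        min_ydistance=min_d,
        threshold=0.4 * accum.max(),
        normalize=True,
    )
    if len(cx) == 0:
        raise EmptyColumnSetError("no columns detected; use a layout file")
    cols = np.column_stack([cx, cy, r]).astype(float)
    # Refine each detection to subpixel accuracy from its dark connected
    # component (centroid + equivalent-disk radius); the Hough grid alone
    # quantizes radii to whole pixels.
    from scipy import ndimage

    labelled, _ = ndimage.label(dark)
    h_img, w_img = dark.shape
    for i, (x, y, rad) in enumerate(cols):
        lbl = labelled[int(round(y)), int(round(x))]
        if lbl == 0:
            continue
        comp = labelled == lbl
        area = comp.sum()
        r_eq = np.sqrt(area / np.pi)
        if lo * 0.7 <= r_eq <= hi * 1.3:
            ys, xs = np.nonzero(comp)
            # Skip truncated disks at the image border.
            if ys.min() > 0 and xs.min() > 0 and ys.max() < h_img - 1 and xs.max() < w_img - 1:
                cols[i] = (xs.mean(), ys.mean(), r_eq)
    # hough_circle_peaks enforces x/y separation independently; drop any
    # residual duplicate centres closer than a column radius.
    order = np.argsort(-cols[:, 2])
    kept: list[np.ndarray] = []
    for c in cols[order]:
        if all(np.hypot(c[0] - k[0], c[1] - k[1]) > max(c[2], k[2]) for k in kept):
            kept.append(c)
    return ColumnSet(columns=np.array(kept), source="detected")


def tessellate(cols: ColumnSet, image_shape: tuple[int, int], um_per_px: float = 1.0) -> Tessellation:
    """Delaunay-triangulate column centres and rasterize region masks.

    Each pixel centre is located in a triangle with scipy's point locator
    (deterministic); pixels outside the convex hull of the centres are
    excluded from analysis, and pixels under a column disk are removed from
    every region's effective mask.
    """
    pts = np.asarray(cols.columns, dtype=float)[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 columns to tessellate")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate column geometry (collinear centres?): {exc}") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate column geometry: all centres collinear")
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    label = tri.find_simplex(np.column_stack([xx.ravel(), yy.ravel()])).reshape(h, w)
    column_mask = np.zeros((h, w), dtype=bool)
    for cx, cy, r in cols.columns:
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        column_mask[y0:y1, x0:x1] |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
    return Tessellation(
        points=pts,
        simplices=np.asarray(tri.simplices, dtype=int),
        label_image=label.astype(np.int32),
        column_mask=column_mask,
        um_per_px=um_per_px,
    )


def region_mean_intensity(image: np.ndarray, tess: Tessellation) -> np.ndarray:
    """Mean intensity over each region's effective mask (columns excluded).

    Regions with no effective pixels get NaN (flagged, excluded downstream).
    """
    image = np.asarray(image)
    if image.shape != tess.label_image.shape:
        raise ValueError(
            f"image shape {image.shape} does not match tessellation raster "
            f"{tess.label_image.shape}"
        )
    m = tess.n_regions
    valid = (tess.label_image >= 0) & ~tess.column_mask
    sums = np.bincount(tess.label_image[valid], weights=image[valid].astype(float), minlength=m)
    counts = np.bincount(tess.label_image[valid], minlength=m).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means


def call_occupancy(
    means: np.ndarray,
    method: str = "otsu",
    k: float = 5.0,
) -> np.ndarray:
    """Call biofilm occupancy per region from mean intensities.

    ``otsu`` thresholds the distribution of region means at the value
    maximising between-class variance; ``k_sigma`` uses background median +
    k*MAD.  A region mean exactly at the threshold calls negative.  NaN
    means (zero-area regions) call negative.
    """
    means = np.asarray(means, dtype=float)
    finite = np.isfinite(means)
    if finite.sum() < 4:
        raise ValueError("need at least 4 regions with finite means to threshold")
    calls = np.zeros(means.shape, dtype=bool)
    vals = means[finite]
    if np.all(vals == vals[0]):
        warnings.warn("all region means identical; calling every region unoccupied")
        return calls
    if method == "otsu":
        thr = threshold_otsu(vals)
    elif method == "k_sigma":
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        thr = med + k * mad
    else:
        raise ValueError(f"unknown occupancy method: {method!r}")
    calls[finite] = vals > thr
    return calls


def integrate_bead_frames(stack: np.ndarray) -> np.ndarray:
    """Integrate a bead-streak stack by pixelwise maximum projection."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, H, W) array")
    return stack.max(axis=0)


def score_flow(
    integrated: np.ndarray,
    tess: Tessellation,
    min_coverage: float = 0.001,
    k: float = 5.0,
) -> np.ndarray:
    """Score each region open/blocked from an integrated bead-streak image.

    Streak pixels are those above the global background (median + k*MAD); a
    region is *open* when streak pixels cover at least ``min_coverage`` of
    its effective area (>= comparison: coverage exactly at threshold is
    open), otherwise *blocked*.  Returns an array of "open"/"blocked".
    """
    integrated = np.asarray(integrated, dtype=float)
    if integrated.shape != tess.label_image.shape:
        raise ValueError("integrated image shape does not match tessellation raster")
    med = np.median(integrated)
    mad = np.median(np.abs(integrated - med))
    streaks = integrated > med + k * mad
    labels = np.full(tess.n_regions, "blocked", dtype=object)
    if not streaks.any():
        warnings.warn("no streak pixels found; scoring every region as blocked")
        return labels
    valid = (tess.label_image >= 0) & ~tess.column_mask
    hits = np.bincount(
        tess.label_image[valid & streaks], minlength=tess.n_regions
    ).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = hits / tess.effective_area_px
    open_mask = np.where(tess.effective_area_px > 0, coverage >= min_coverage, False)
    labels[open_mask] = "open"
    return labels
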